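"""Clonotype definitions: nucleotide and functional, at alpha-beta/alpha/beta level.

Two families of clonotype definitions are implemented:

* **Nucleotide clonotypes** group cells with identical TCR gene segment usage
  and identical CDR3 nucleotide sequences on the chains considered. This is an
  exact partition by chain-set signature.

* **Functional clonotypes** group cells at the amino-acid level and tolerate
  chain dropout: a cell with a single detected alpha chain may belong to a
  clonotype whose cells carry two alpha chains, provided every chain the cell
  does carry matches the clonotype's chain set. Because the underlying "at
  least one shared chain, no contradicting chain" relation is not transitive,
  assignment is anchored on *maximal* observed signatures: each non-maximal
  seed group is merged into a compatible maximal clonotype, choosing the
  largest when several are compatible (ties broken by lexicographically
  smallest signature) and flagging those cells as ambiguous.

Clonotypes are numbered by descending size (1 = largest; equal sizes randomly
ordered with a seeded RNG) and ranked by competition ranking (equal sizes share
a rank).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .contig_io import Cell

LEVELS = ("ab", "a", "b")

#: Chain-set signature: sorted tuple of chain keys (locus, V, J, CDR3).
Signature = tuple[tuple[str, str, str, str], ...]


@dataclass
class ClonotypeTable:
    """Cell -> clonotype assignment at one definition level.

    ``level`` is one of ``nt-ab, nt-a, nt-b, fn-ab, fn-a, fn-b``.
    ``assignment`` maps barcode -> clonotype id; ``signatures`` maps clonotype
    id -> chain-set signature; ``ambiguous`` flags cells whose dropout-tolerant
    assignment had more than one compatible maximal clonotype.
    """

    level: str
    assignment: dict[str, int] = field(default_factory=dict)
    signatures: dict[int, Signature] = field(default_factory=dict)
    ambiguous: dict[str, bool] = field(default_factory=dict)
    numbers: dict[int, int] = field(default_factory=dict)
    ranks: dict[int, int] = field(default_factory=dict)

    @property
    def sizes(self) -> dict[int, int]:
        out: dict[int, int] = {}
        for cid in self.assignment.values():
            out[cid] = out.get(cid, 0) + 1
        return out

    def size_vector(self) -> np.ndarray:
        return np.array(sorted(self.sizes.values(), reverse=True))

    def cells_of(self, clonotype_id: int) -> list[str]:
        return [bc for bc, cid in self.assignment.items() if cid == clonotype_id]


def _chain_keys(cell: Cell, level: str, functional: bool) -> Signature:
    chains = []
    if level in ("ab", "a"):
        chains += cell.alpha_chains
    if level in ("ab", "b"):
        chains += cell.beta_chains
    keys = {c.aa_key() if functional else c.nt_key() for c in chains}
    return tuple(sorted(keys))


def _check_level(cells: list[Cell], level: str) -> None:
    if level not in LEVELS:
        raise ValueError(f"unknown level {level!r}; expected one of {LEVELS}")
    if level == "ab":
        for c in cells:
            if not c.alpha_chains or not c.beta_chains:
                raise ValueError(
                    f"cell {c.barcode} lacks an alpha or beta chain; "
                    "alpha-beta clonotype calling requires gated cells"
                )
    elif level == "a":
        if any(not c.alpha_chains for c in cells):
            raise ValueError("alpha-level calling requires every cell to carry an alpha chain")
    elif level == "b":
        if any(not c.beta_chains for c in cells):
            raise ValueError("beta-level calling requires every cell to carry a beta chain")


def call_nucleotide_clonotypes(cells: list[Cell], level: str = "ab") -> ClonotypeTable:
    """Partition cells by exact nucleotide chain-set signature."""
    _check_level(cells, level)
    table = ClonotypeTable(level=f"nt-{level}")
    ids: dict[Signature, int] = {}
    for cell in cells:
        sig = _chain_keys(cell, level, functional=False)
        if sig not in ids:
            ids[sig] = len(ids)
            table.signatures[ids[sig]] = sig
        table.assignment[cell.barcode] = ids[sig]
        table.ambiguous[cell.barcode] = False
    return table


def call_functional_clonotypes(cells: list[Cell], level: str = "ab") -> ClonotypeTable:
    """Dropout-tolerant amino-acid-level clonotype calling.

    Stage 1: group cells by exact amino-acid signature (seed groups).
    Stage 2: identify maximal signatures (not a strict subset of another
    observed signature at this level).
    Stage 3: merge each non-maximal group into a compatible maximal clonotype;
    compatibility requires the group's chains to be contained in the maximal
    signature and, at the alpha-beta level, sharing at least one alpha and one
    beta chain (at single-locus levels, at least one chain of that locus).
    Groups compatible with several maximal clonotypes go to the largest (ties:
    lexicographically smallest signature) and their cells are flagged ambiguous.
    """
    _check_level(cells, level)
    table = ClonotypeTable(level=f"fn-{level}")

    seed_groups: dict[Signature, list[str]] = {}
    for cell in cells:
        sig = _chain_keys(cell, level, functional=True)
        seed_groups.setdefault(sig, []).append(cell.barcode)

    sigs = list(seed_groups)
    sig_sets = {s: frozenset(s) for s in sigs}
    maximal = [
        s
        for s in sigs
        if not any(sig_sets[s] < sig_sets[t] for t in sigs if t != s)
    ]
    maximal_ids = {s: i for i, s in enumerate(sorted(maximal))}
    for s, i in maximal_ids.items():
        table.signatures[i] = s

    # seed counts of the maximal clonotypes themselves, used for the
    # largest-clonotype tie-break before any merging
    maximal_sizes = {s: len(seed_groups[s]) for s in maximal}

    def _compatible(group: Signature, maximal_sig: Signature) -> bool:
        gset, mset = sig_sets[group], sig_sets[maximal_sig]
        if not gset <= mset:
            return False
        shared = gset & mset
        if level == "ab":
            return any(k[0] == "TRA" for k in shared) and any(k[0] == "TRB" for k in shared)
        return len(shared) > 0

    for s in sigs:
        if s in maximal_ids:
            cid = maximal_ids[s]
            for bc in seed_groups[s]:
                table.assignment[bc] = cid
                table.ambiguous[bc] = False
            continue
        compatible = [m for m in maximal if _compatible(s, m)]
        if not compatible:
            # isolated group (can occur at single-locus levels); promote it
            cid = len(table.signatures)
            table.signatures[cid] = s
            for bc in seed_groups[s]:
                table.assignment[bc] = cid
                table.ambiguous[bc] = False
            continue
        # largest clonotype wins; ties go to the lexicographically smallest signature
        target = min(compatible, key=lambda m: (-maximal_sizes[m], m))
        cid = maximal_ids[target]
        flag = len(compatible) > 1
        for bc in seed_groups[s]:
            table.assignment[bc] = cid
            table.ambiguous[bc] = flag
    return table


def number_and_rank(table: ClonotypeTable, seed: int = 0) -> ClonotypeTable:
    """Assign size-based numbers (ties randomly ordered) and competition ranks.

    Numbers are a permutation of 1..K with 1 the largest clonotype; equal-size
    clonotypes are permuted by a seeded RNG. Ranks use competition ("min")
    ranking: sizes 5,3,3,1 -> ranks 1,2,2,4.
    """
    sizes = table.sizes
    rng = np.random.default_rng(seed)
    cids = list(sizes)
    rng.shuffle(cids)  # random order within ties
    cids.sort(key=lambda c: -sizes[c])
    table.numbers = {cid: i + 1 for i, cid in enumerate(cids)}
    ranks: dict[int, int] = {}
    for i, cid in enumerate(cids):
        if i > 0 and sizes[cid] == sizes[cids[i - 1]]:
            ranks[cid] = ranks[cids[i - 1]]
        else:
            ranks[cid] = i + 1
    table.ranks = ranks
    return table


def to_dataframe(table: ClonotypeTable):
    """Tidy cell-level view: barcode, clonotype_id, level, size, number, rank, ambiguous."""
    import pandas as pd

    sizes = table.sizes
    rows = [
        {
            "barcode": bc,
            "clonotype_id": cid,
            "level": table.level,
            "size": sizes[cid],
            "number": table.numbers.get(cid),
            "rank": table.ranks.get(cid),
            "ambiguous": table.ambiguous.get(bc, False),
        }
        for bc, cid in table.assignment.items()
    ]
    return pd.DataFrame(rows)
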