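"""Reading and gating of 10x V(D)J contig annotation tables.

The entry point of every repertoire analysis is the ``filtered_contig_annotations.csv``
table produced by the 10x VDJ pipeline: one row per assembled TCR contig per cell
barcode. This module parses that table, applies the standard contig-level filters
(high-confidence, full-length, productive, TRA/TRB only), assembles per-barcode
chain sets, removes barcodes whose chain count implies a captured doublet, and
gates cells into the MAIT or conventional-memory (Tmem) populations.

Gating rules
------------
* MAIT cells must carry at least one TRAV1-2 alpha chain and at least one beta
  chain (the semi-invariant MAIT TCRalpha uses TRAV1-2 / Valpha7.2).
* Tmem cells must carry at least one alpha and one beta chain; cells with an
  alpha chain using TRAV1-2 joined to TRAJ33, TRAJ12 or TRAJ20 with a 12
  amino-acid CDR3alpha are treated as contaminating MAIT cells and removed.
* Barcodes with two alpha and two beta chains, or more than two chains of
  either locus, are treated as cell doublets and discarded during assembly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import pandas as pd

logger = logging.getLogger(__name__)

#: TRAJ segments of the semi-invariant MAIT alpha chain.
MAIT_TRAJ = frozenset({"TRAJ33", "TRAJ12", "TRAJ20"})
#: CDR3alpha length (in amino acids, both flanking residues included) of the
#: canonical MAIT alpha chain.
MAIT_CDR3A_LENGTH = 12

_MANDATORY_COLUMNS = (
    "barcode",
    "chain",
    "v_gene",
    "j_gene",
    "cdr3",
    "cdr3_nt",
    "high_confidence",
    "full_length",
    "productive",
)

_TRUE_VALUES = {"True", "true", "TRUE"}
_FALSE_VALUES = {"False", "false", "FALSE", "None", "none"}


@dataclass(frozen=True)
class ContigRecord:
    """One assembled TCR contig (one row of the 10x contig table)."""

    barcode: str
    locus: str
    v_gene: str
    d_gene: str | None
    j_gene: str
    cdr3_nt: str
    cdr3_aa: str
    high_confidence: bool
    full_length: bool
    productive: bool
    umis: int


@dataclass(frozen=True)
class Chain:
    """A single TCR chain carried by a cell."""

    locus: str
    v_gene: str
    j_gene: str
    cdr3_nt: str
    cdr3_aa: str
    umis: int = 0

    def nt_key(self) -> tuple[str, str, str, str]:
        """Chain identity at the nucleotide level (V, J, CDR3nt; D excluded)."""
        return (self.locus, self.v_gene, self.j_gene, self.cdr3_nt)

    def aa_key(self) -> tuple[str, str, str, str]:
        """Chain identity at the amino-acid (functional) level."""
        return (self.locus, self.v_gene, self.j_gene, self.cdr3_aa)


@dataclass
class Cell:
    """A gated cell: barcode, sample metadata and its chain sets."""

    barcode: str
    alpha_chains: list[Chain] = field(default_factory=list)
    beta_chains: list[Chain] = field(default_factory=list)
    donor: str | None = None
    tissue: str | None = None
    condition: str | None = None
    timepoint: float | None = None
    population: str = "unassigned"

    @property
    def chains(self) -> list[Chain]:
        return self.alpha_chains + self.beta_chains

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "Cell":
        d = dict(d)
        d["alpha_chains"] = [Chain(**c) for c in d["alpha_chains"]]
        d["beta_chains"] = [Chain(**c) for c in d["beta_chains"]]
        return cls(**d)


def _parse_bool(value, column: str, row_index: int) -> bool:
    if isinstance(value, bool):
        return value
    text = str(value).strip()
    if text in _TRUE_VALUES:
        return True
    if text in _FALSE_VALUES:
        return False
    raise ValueError(
        f"unparseable boolean {value!r} in column {column!r} at row {row_index}"
    )


def read_contig_table(path) -> list[ContigRecord]:
    """Read a 10x-style contig annotation CSV into :class:`ContigRecord` rows.

    Boolean columns accept the 10x dialect values ``True/False/true/false/None``.
    Missing mandatory columns raise ``ValueError`` naming the column.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for column in _MANDATORY_COLUMNS:
        if column not in df.columns:
            raise ValueError(f"contig table is missing mandatory column {column!r}")
    records = []
    for i, row in enumerate(df.itertuples(index=False)):
        row = row._asdict()
        d_gene = row.get("d_gene", "None")
        umis = row.get("umis", "0")
        records.append(
            ContigRecord(
                barcode=row["barcode"],
                locus=row["chain"],
                v_gene=row["v_gene"],
                d_gene=None if d_gene in ("None", "", "none") else d_gene,
                j_gene=row["j_gene"],
                cdr3_nt=row["cdr3_nt"],
                cdr3_aa=row["cdr3"],
                high_confidence=_parse_bool(row["high_confidence"], "high_confidence", i),
                full_length=_parse_bool(row["full_length"], "full_length", i),
                productive=_parse_bool(row["productive"], "productive", i),
                umis=int(umis) if umis not in ("", "None") else 0,
            )
        )
    return records


def filter_contigs(records: list[ContigRecord]) -> list[ContigRecord]:
    """Keep high-confidence, full-length, productive TRA/TRB contigs.

    Order is preserved and the operation is idempotent.
    """
    return [
        r
        for r in records
        if r.high_confidence
        and r.full_length
        and r.productive
        and r.locus in ("TRA", "TRB")
        and r.cdr3_nt
        and r.cdr3_aa
    ]


def read_metadata(path) -> pd.DataFrame:
    """Read per-cell sample metadata (barcode, donor, tissue, condition, timepoint)."""
    meta = pd.read_csv(path, dtype={"barcode": str, "donor": str})
    if "barcode" not in meta.columns:
        raise ValueError("metadata is missing mandatory column 'barcode'")
    return meta.set_index("barcode")


def is_doublet_chain_count(n_alpha: int, n_beta: int) -> bool:
    """TCR-defined doublet rule: (2 alpha AND 2 beta) or >2 of either locus."""
    return (n_alpha == 2 and n_beta == 2) or n_alpha > 2 or n_beta > 2


def assemble_cells(
    records: list[ContigRecord],
    meta: pd.DataFrame | None = None,
) -> tuple[list[Cell], int]:
    """Group filtered contigs by barcode into cells, discarding TCR doublets.

    Duplicate contigs (same barcode, locus, V, J and CDR3nt) are collapsed to a
    single chain keeping the highest-UMI copy. Returns ``(cells, n_doublets)``.
    Barcodes absent from ``meta`` are flagged ``unassigned`` with a warning.
    """
    by_barcode: dict[str, dict[tuple, Chain]] = {}
    order: list[str] = []
    for r in records:
        if r.barcode not in by_barcode:
            by_barcode[r.barcode] = {}
            order.append(r.barcode)
        chain = Chain(
            locus=r.locus,
            v_gene=r.v_gene,
            j_gene=r.j_gene,
            cdr3_nt=r.cdr3_nt,
            cdr3_aa=r.cdr3_aa,
            umis=r.umis,
        )
        key = chain.nt_key()
        existing = by_barcode[r.barcode].get(key)
        if existing is None or chain.umis > existing.umis:
            by_barcode[r.barcode][key] = chain

    cells: list[Cell] = []
    n_doublets = 0
    for barcode in order:
        chains = list(by_barcode[barcode].values())
        alphas = [c for c in chains if c.locus == "TRA"]
        betas = [c for c in chains if c.locus == "TRB"]
        if is_doublet_chain_count(len(alphas), len(betas)):
            n_doublets += 1
            continue
        cell = Cell(barcode=barcode, alpha_chains=alphas, beta_chains=betas)
        if meta is not None:
            if barcode in meta.index:
                row = meta.loc[barcode]
                cell.donor = row.get("donor")
                cell.tissue = row.get("tissue")
                cell.condition = row.get("condition")
                tp = row.get("timepoint")
                cell.timepoint = float(tp) if tp is not None and tp == tp else None
            else:
                logger.warning("barcode %s absent from metadata; left unassigned", barcode)
        cells.append(cell)
    return cells, n_doublets


def _is_trav1_2(v_gene: str) -> bool:
    # allele suffixes ("*01") are ignored
    return v_gene.split("*")[0] == "TRAV1-2"


def is_mait_alpha(chain: Chain) -> bool:
    """The canonical semi-invariant MAIT alpha: TRAV1-2 + TRAJ33/12/20, 12-aa CDR3."""
    return (
        _is_trav1_2(chain.v_gene)
        and chain.j_gene.split("*")[0] in MAIT_TRAJ
        and len(chain.cdr3_aa) == MAIT_CDR3A_LENGTH
    )


def gate_cells(cells: list[Cell], population: str) -> list[Cell]:
    """Gate assembled cells into the MAIT or Tmem population.

    MAIT: at least one TRAV1-2 alpha chain and at least one beta chain.
    Tmem: at least one alpha and one beta chain, minus cells carrying a
    canonical MAIT alpha (assumed contaminating MAIT cells).
    """
    if population == "MAIT":
        gated = [
            c
            for c in cells
            if any(_is_trav1_2(a.v_gene) for a in c.alpha_chains) and c.beta_chains
        ]
    elif population == "Tmem":
        gated = [
            c
            for c in cells
            if c.alpha_chains
            and c.beta_chains
            and not any(is_mait_alpha(a) for a in c.alpha_chains)
        ]
    else:
        raise ValueError(f"unknown population {population!r}; expected 'MAIT' or 'Tmem'")
    for c in gated:
        c.population = population
    return gated
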