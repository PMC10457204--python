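"""Repertoire diversity, clonality, pairing, sharing and publicness statistics.

All metrics operate on :class:`~clonolink.clonotype_calling.ClonotypeTable`
objects or on gated cells; clonotype identity across samples is defined by
chain-set signature equality, so tables from different samples are comparable
as long as they were called at the same definition level.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .contig_io import Cell
from .clonotype_calling import ClonotypeTable

logger = logging.getLogger(__name__)


def shannon_index(sizes) -> float:
    """Shannon diversity H = -sum p_i ln p_i (natural log) of a clone-size vector."""
    sizes = np.asarray(list(sizes), dtype=float)
    if sizes.size == 0:
        raise ValueError("empty clone-size vector")
    p = sizes / sizes.sum()
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def clonality_curve(sizes) -> list[tuple[int, float]]:
    """Cumulative cell fraction against clonotype rank, largest clones first."""
    sizes = np.sort(np.asarray(list(sizes), dtype=float))[::-1]
    if sizes.size == 0:
        raise ValueError("empty clone-size vector")
    cum = np.cumsum(sizes) / sizes.sum()
    return [(r + 1, float(f)) for r, f in enumerate(cum)]


def chain_pairing_promiscuity(
    cells: list[Cell], focal_locus: str = "a", scope: str = "donor_tissue"
) -> dict[tuple, dict[tuple, int]]:
    """Per unique focal chain, the number of distinct partner-locus chains.

    Chains are identified at the nucleotide level. Every alpha-beta
    co-occurrence within a cell counts as a pairing (a cell with two alpha and
    one beta chain contributes one pairing per alpha). ``scope`` groups cells
    into ``donor_tissue`` (per donor and tissue), ``donor`` (tissues combined)
    or ``global`` (whole input); the result maps scope key -> focal chain key
    -> count of unique partner chains.
    """
    if focal_locus not in ("a", "b"):
        raise ValueError("focal_locus must be 'a' or 'b'")

    def scope_key(c: Cell):
        if scope == "donor_tissue":
            return (c.donor, c.tissue)
        if scope == "donor":
            return (c.donor,)
        if scope == "global":
            return ("all",)
        raise ValueError(f"unknown scope {scope!r}")

    partners: dict[tuple, dict[tuple, set]] = {}
    for cell in cells:
        focal = cell.alpha_chains if focal_locus == "a" else cell.beta_chains
        other = cell.beta_chains if focal_locus == "a" else cell.alpha_chains
        sk = scope_key(cell)
        bucket = partners.setdefault(sk, {})
        for f in focal:
            s = bucket.setdefault(f.nt_key(), set())
            for o in other:
                s.add(o.nt_key())
    return {
        sk: {fk: len(ps) for fk, ps in bucket.items()} for sk, bucket in partners.items()
    }


def promiscuous_fraction(cells: list[Cell], focal_locus: str = "a", scope: str = "donor") -> float:
    """Fraction of unique focal chains paired with more than one partner chain."""
    prom = chain_pairing_promiscuity(cells, focal_locus, scope)
    counts = [n for bucket in prom.values() for n in bucket.values()]
    if not counts:
        return float("nan")
    return float(np.mean([n > 1 for n in counts]))


MAIT_TRAJ_ROWS = ("TRAJ33", "TRAJ12", "TRAJ20")
TRBV_COLUMNS = ("TRBV6-1", "TRBV6-4", "TRBV20-1", "other")


def traj_trbv_pairing_table(cells: list[Cell]):
    """Percentage of TRAJ33/12/20 alpha chains paired with each focal TRBV gene.

    Returns a tidy DataFrame with one row per (donor, TRAJ) and percentage
    columns for TRBV6-1, TRBV6-4, TRBV20-1 and "other" (rows sum to 100), plus
    a cross-donor summary (mean and s.e.m. per TRAJ row). Donors lacking a
    TRAJ entirely contribute no row for it (missing, not zero).
    """
    import pandas as pd

    counts: dict[tuple, np.ndarray] = {}
    for cell in cells:
        for a in cell.alpha_chains:
            traj = a.j_gene.split("*")[0]
            if traj not in MAIT_TRAJ_ROWS:
                continue
            for b in cell.beta_chains:
                trbv = b.v_gene.split("*")[0]
                col = trbv if trbv in TRBV_COLUMNS else "other"
                key = (cell.donor, traj)
                row = counts.setdefault(key, np.zeros(len(TRBV_COLUMNS)))
                row[TRBV_COLUMNS.index(col)] += 1
    rows = []
    for (donor, traj), vec in sorted(counts.items(), key=lambda kv: (str(kv[0][0]), kv[0][1])):
        pct = 100.0 * vec / vec.sum()
        rows.append({"donor": donor, "traj": traj, **dict(zip(TRBV_COLUMNS, pct))})
    per_donor = pd.DataFrame(rows)
    if per_donor.empty:
        return per_donor, per_donor
    summary = (
        per_donor.groupby("traj")[list(TRBV_COLUMNS)]
        .agg(["mean", "sem"])
        .reindex([t for t in MAIT_TRAJ_ROWS if t in per_donor["traj"].values])
    )
    return per_donor, summary


def segment_usage(cells: list[Cell], segment: str = "TRAJ", unique: bool = False) -> dict[str, float]:
    """Proportion of chains using each gene of a segment class (TRAJ or TRBV).

    With ``unique=True`` each distinct chain (nucleotide identity) counts once,
    giving clonotype-level rather than cell-weighted usage.
    """
    if segment not in ("TRAJ", "TRBV"):
        raise ValueError("segment must be 'TRAJ' or 'TRBV'")
    chains = []
    for cell in cells:
        chains += cell.alpha_chains if segment == "TRAJ" else cell.beta_chains
    if unique:
        chains = list({c.nt_key(): c for c in chains}.values())
    if segment == "TRAJ":
        genes = [c.j_gene.split("*")[0] for c in chains]
    else:
        genes = [c.v_gene.split("*")[0] for c in chains]
    if not genes:
        return {}
    values, n = np.unique(genes, return_counts=True)
    total = n.sum()
    return {g: float(c) / total for g, c in zip(values, n)}


@dataclass
class SharingResult:
    """Cross-sample clonal overlap for one donor at one clonotype level."""

    pct_shared_a: float
    pct_shared_b: float
    shared_signatures: list
    n_cells_a: int
    n_cells_b: int


def cross_sample_sharing(table_a: ClonotypeTable, table_b: ClonotypeTable) -> SharingResult:
    """Percent of cells per sample in clonotypes whose signature occurs in both."""
    if table_a.level != table_b.level:
        raise ValueError(
            f"clonotype levels differ: {table_a.level} vs {table_b.level}"
        )
    sigs_a = set(table_a.signatures[cid] for cid in table_a.sizes)
    sigs_b = set(table_b.signatures[cid] for cid in table_b.sizes)
    shared = sigs_a & sigs_b

    def pct(table: ClonotypeTable) -> float:
        n = len(table.assignment)
        if n == 0:
            return float("nan")
        in_shared = sum(
            1 for cid in table.assignment.values() if table.signatures[cid] in shared
        )
        return 100.0 * in_shared / n

    return SharingResult(
        pct_shared_a=pct(table_a),
        pct_shared_b=pct(table_b),
        shared_signatures=sorted(shared),
        n_cells_a=len(table_a.assignment),
        n_cells_b=len(table_b.assignment),
    )


def shared_clonotype_frequency_correlation(
    table_a: ClonotypeTable, table_b: ClonotypeTable
) -> tuple[float, float]:
    """Pearson r of log10 within-sample frequencies over shared clonotypes.

    Returns ``(r, p)``; ``(nan, nan)`` when fewer than three clonotypes are
    shared (flagged undefined).
    """
    if table_a.level != table_b.level:
        raise ValueError("clonotype levels differ")
    freq_a = _signature_frequencies(table_a)
    freq_b = _signature_frequencies(table_b)
    shared = sorted(set(freq_a) & set(freq_b))
    if len(shared) < 3:
        logger.warning("fewer than 3 shared clonotypes; correlation undefined")
        return float("nan"), float("nan")
    x = np.log10([freq_a[s] for s in shared])
    y = np.log10([freq_b[s] for s in shared])
    if np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan"), float("nan")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def _signature_frequencies(table: ClonotypeTable) -> dict:
    sizes = table.sizes
    total = sum(sizes.values())
    return {table.signatures[cid]: n / total for cid, n in sizes.items()}


def publicness_spectrum(tables_by_donor: dict[str, ClonotypeTable]) -> dict[str, dict[int, int]]:
    """Cells per donor binned by clonotype occupancy (number of donors sharing it).

    Only functional-level tables are accepted: publicness is defined on
    amino-acid signatures. Occupancy k of a signature is the number of donors
    in which it occurs; each donor's cells are binned by their clonotype's k.
    """
    for donor, table in tables_by_donor.items():
        if not table.level.startswith("fn-"):
            raise ValueError(
                f"publicness requires functional-level tables; donor {donor} has {table.level}"
            )
    occupancy: dict = {}
    for table in tables_by_donor.values():
        for sig in set(table.signatures[cid] for cid in table.sizes):
            occupancy[sig] = occupancy.get(sig, 0) + 1
    report: dict[str, dict[int, int]] = {}
    n_donors = len(tables_by_donor)
    for donor, table in tables_by_donor.items():
        bins = {k: 0 for k in range(1, n_donors + 1)}
        for cid in table.assignment.values():
            bins[occupancy[table.signatures[cid]]] += 1
        report[donor] = bins
    return report


def public_signatures(tables_by_donor: dict[str, ClonotypeTable], min_donors: int) -> set:
    """Functional signatures occurring in at least ``min_donors`` donors."""
    occupancy: dict = {}
    for table in tables_by_donor.values():
        for sig in set(table.signatures[cid] for cid in table.sizes):
            occupancy[sig] = occupancy.get(sig, 0) + 1
    return {sig for sig, k in occupancy.items() if k >= min_donors}


def downsampled_comparison(
    labels_by_stratum: dict,
    seed: int = 0,
    n_reps: int = 100,
):
    """Equal-depth comparison of unique-clonotype counts and Shannon diversity.

    ``labels_by_stratum`` maps stratum (e.g. donor) -> ``(labels_a, labels_b)``
    where each is a sequence of per-cell clonotype ids for the two groups being
    compared. Within each stratum the larger group is downsampled without
    replacement to the smaller group's size, ``n_reps`` times; per-replicate
    metrics are retained and averaged. Empty strata are skipped with a warning.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    rows = []
    for stratum, (labels_a, labels_b) in labels_by_stratum.items():
        labels_a = np.asarray(labels_a)
        labels_b = np.asarray(labels_b)
        if labels_a.size == 0 or labels_b.size == 0:
            logger.warning("stratum %r has an empty group; skipped", stratum)
            continue
        n = min(labels_a.size, labels_b.size)
        for rep in range(n_reps):
            sub_a = labels_a if labels_a.size == n else rng.choice(labels_a, n, replace=False)
            sub_b = labels_b if labels_b.size == n else rng.choice(labels_b, n, replace=False)
            for group, sub in (("A", sub_a), ("B", sub_b)):
                sizes = np.unique(sub, return_counts=True)[1]
                rows.append(
                    {
                        "stratum": stratum,
                        "group": group,
                        "replicate": rep,
                        "n_cells": n,
                        "unique_clonotypes": int(sizes.size),
                        "shannon": shannon_index(sizes),
                    }
                )
    replicates = pd.DataFrame(rows)
    if replicates.empty:
        return replicates, replicates
    summary = (
        replicates.groupby(["stratum", "group"])[["unique_clonotypes", "shannon"]]
        .mean()
        .reset_index()
    )
    return replicates, summary


def tcr_capture_rate(n_cells_total: int, n_cells_with_clonotype: int) -> float:
    """Fraction of cells with a usable TCR; NaN (flagged) when the total is zero."""
    if n_cells_total < 0 or n_cells_with_clonotype < 0:
        raise ValueError("counts must be non-negative")
    if n_cells_with_clonotype > n_cells_total:
        raise ValueError("cells with clonotype cannot exceed total cells")
    if n_cells_total == 0:
        return float("nan")
    return n_cells_with_clonotype / n_cells_total
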