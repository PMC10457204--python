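"""Linking clonal identity to cell function.

Covers coreceptor (CD4/CD8/DN) assignment from normalized gene or protein
expression, Kruskal-Wallis tests of pseudotime differences between TCR-defined
groups (clonotypes or TRBV gene segments), cross-trajectory correlation of
group-average pseudotimes, the clone-size-vs-pseudotime correlation, and the
differential gene-importance rank statistic comparing two trajectories.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

GENE_CHANNELS = ("CD8A", "CD8B", "CD4")
PROTEIN_CHANNELS = ("CD8", "CD4")


def assign_coreceptor(expr: pd.DataFrame, mode: str = "gene") -> pd.DataFrame:
    """Label each cell CD8+, CD4+ or DN from normalized coreceptor expression.

    Gene mode: CD8+ if CD8A > 0 and/or CD8B > 0; CD4+ if CD4 > 0; DN if all
    three are undetected. A cell satisfying both the CD8 and CD4 rules is
    labeled CD8+ with ``ambiguous=True`` (the CD8 rule is evaluated first).

    Protein mode: CD8+ if CD8 > 0.3; else CD4+ if CD4 > 2.5 and CD8 < 0.2;
    else DN. Thresholds correspond to normalized antibody-count data.
    """
    if mode == "gene":
        channels = GENE_CHANNELS
    elif mode == "protein":
        channels = PROTEIN_CHANNELS
    else:
        raise ValueError("mode must be 'gene' or 'protein'")
    for ch in channels:
        if ch not in expr.columns:
            raise ValueError(f"missing expression channel {ch!r} for mode {mode!r}")

    labels = []
    ambiguous = []
    if mode == "gene":
        for _, row in expr.iterrows():
            cd8 = row["CD8A"] > 0 or row["CD8B"] > 0
            cd4 = row["CD4"] > 0
            if cd8:
                labels.append("CD8+")
                ambiguous.append(bool(cd4))
            elif cd4:
                labels.append("CD4+")
                ambiguous.append(False)
            else:
                labels.append("DN")
                ambiguous.append(False)
    else:
        for _, row in expr.iterrows():
            if row["CD8"] > 0.3:
                labels.append("CD8+")
            elif row["CD4"] > 2.5 and row["CD8"] < 0.2:
                labels.append("CD4+")
            else:
                labels.append("DN")
            ambiguous.append(False)
    return pd.DataFrame(
        {"coreceptor": labels, "ambiguous": ambiguous}, index=expr.index
    )


def pseudotime_group_association(
    pseudotime: pd.Series,
    groups: pd.Series,
    min_size: int = 20,
    min_frequency: float | None = None,
) -> dict:
    """Kruskal-Wallis test of pseudotime across TCR-defined groups.

    Groups with fewer than ``min_size`` cells are excluded; alternatively (for
    TRBV groupings) ``min_frequency`` retains groups above a cell-frequency
    threshold instead. Returns ``{"H", "p", "groups", "n_cells"}``; when fewer
    than two groups survive, H and p are NaN (flagged undefined).
    """
    df = pd.DataFrame({"pt": pseudotime, "group": groups}).dropna()
    counts = df["group"].value_counts()
    if min_frequency is not None:
        keep = counts[counts / counts.sum() > min_frequency].index
    else:
        keep = counts[counts >= min_size].index
    df = df[df["group"].isin(keep)]
    retained = sorted(df["group"].unique(), key=str)
    if len(retained) < 2:
        logger.warning("fewer than 2 retained groups; Kruskal-Wallis undefined")
        return {"H": float("nan"), "p": float("nan"), "groups": retained, "n_cells": len(df)}
    samples = [df.loc[df["group"] == g, "pt"].to_numpy() for g in retained]
    try:
        h, p = stats.kruskal(*samples)
    except ValueError:  # all values identical
        h, p = 0.0, 1.0
    return {"H": float(h), "p": float(p), "groups": retained, "n_cells": len(df)}


def cross_trajectory_group_correlation(
    pseudotime: pd.DataFrame, groups: pd.Series
) -> tuple[float, float]:
    """Spearman rho of per-group mean pseudotimes between two trajectories.

    ``pseudotime`` has one column per trajectory (cells x 2). Returns
    ``(rho, p)``; NaN when fewer than three groups are present on both
    trajectories.
    """
    if pseudotime.shape[1] != 2:
        raise ValueError("expected exactly two trajectory columns")
    df = pseudotime.copy()
    df["group"] = groups
    means = df.groupby("group").mean().dropna()
    if len(means) < 3:
        return float("nan"), float("nan")
    rho, p = stats.spearmanr(means.iloc[:, 0], means.iloc[:, 1])
    return float(rho), float(p)


def clone_size_pseudotime_correlation(
    pseudotime: pd.Series,
    clonotype_ids: pd.Series,
    min_cells: int = 20,
    per_clonotype: bool = False,
) -> tuple[float, float]:
    """Pearson r between log10 clonotype frequency and pseudotime.

    Clonotypes with fewer than ``min_cells`` cells are excluded. Each cell
    contributes one point (its clonotype's log10 frequency, its pseudotime);
    with ``per_clonotype=True`` points are clonotype means instead. Returns
    ``(r, p)``; NaN when the retained frequencies have zero variance or fewer
    than two clonotypes remain.
    """
    df = pd.DataFrame({"pt": pseudotime, "cid": clonotype_ids}).dropna()
    counts = df["cid"].value_counts()
    freqs = counts / counts.sum()  # frequency among cells with a clonotype
    keep = counts[counts >= min_cells].index
    df = df[df["cid"].isin(keep)]
    if df["cid"].nunique() < 2:
        logger.warning("fewer than 2 retained clonotypes; correlation undefined")
        return float("nan"), float("nan")
    df["logfreq"] = np.log10(df["cid"].map(freqs))
    if per_clonotype:
        df = df.groupby("cid")[["logfreq", "pt"]].mean()
    if df["logfreq"].nunique() == 1 or df["pt"].nunique() == 1:
        logger.warning("zero variance in frequency or pseudotime; correlation undefined")
        return float("nan"), float("nan")
    r, p = stats.pearsonr(df["logfreq"], df["pt"])
    return float(r), float(p)


def differential_gene_importance(
    importance_a: pd.DataFrame,
    importance_b: pd.DataFrame,
    fdr_thresh: float = 0.05,
    top_n: int = 150,
) -> pd.DataFrame:
    """Differential gene importance between two trajectories.

    Inputs are per-trajectory tables indexed by gene with columns
    ``importance``, ``rank`` (1 = most important) and ``fdr``. The ratio for
    gene g is ``max(rank_a, rank_b) / min(rank_a, rank_b)`` (always >= 1, and
    symmetric in the two trajectories). A gene is selected as differentially
    important iff its FDR is below ``fdr_thresh`` on at least one trajectory
    AND its rank is within the top ``top_n`` on at least one trajectory. The
    display transform ``log2(1/rank)`` is emitted per trajectory.
    """
    if set(importance_a.index) != set(importance_b.index):
        raise ValueError("gene universes differ between the two importance tables")
    b = importance_b.loc[importance_a.index]
    rank_a = importance_a["rank"].to_numpy(dtype=float)
    rank_b = b["rank"].to_numpy(dtype=float)
    ratio = np.maximum(rank_a, rank_b) / np.minimum(rank_a, rank_b)
    selected = (
        (importance_a["fdr"].to_numpy() < fdr_thresh)
        | (b["fdr"].to_numpy() < fdr_thresh)
    ) & ((rank_a <= top_n) | (rank_b <= top_n))
    return pd.DataFrame(
        {
            "rank_a": rank_a.astype(int),
            "rank_b": rank_b.astype(int),
            "ratio": ratio,
            "selected": selected,
            "log2_inv_rank_a": np.log2(1.0 / rank_a),
            "log2_inv_rank_b": np.log2(1.0 / rank_b),
        },
        index=importance_a.index,
    )
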