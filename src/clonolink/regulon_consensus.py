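"""Consensus regulons from repeated stochastic GRN inference, and AUCell scoring.

Gene-regulatory-network inference (e.g. GRNBoost2 within SCENIC) is stochastic:
each run can report a different set of regulons and different target genes per
transcription factor. Running the inference many times and keeping only what is
stable yields *high-confidence* regulons:

* a regulon is high-confidence if its TF occurs in **more than** 80% of runs
  and it retains at least five high-confidence targets;
* a target is high-confidence if it occurs in **more than** 80% of the runs
  that contain the TF's regulon (conditional denominator).

Per-cell regulon activity is scored with a recovery-curve AUC ("AUCell"): genes
are ranked by decreasing expression within each cell, the cumulative count of
gene-set members among the top ``top_fraction`` of the ranking is integrated,
and the area is normalized by the maximal achievable area, giving a score in
[0, 1] that depends only on within-cell expression ranks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats


@dataclass
class ConsensusRegulon:
    """A transcription factor with run-stability statistics."""

    tf: str
    run_occurrence: float
    target_occurrence: dict[str, float] = field(default_factory=dict)
    high_confidence_targets: frozenset[str] = frozenset()


def aggregate_regulon_runs(
    runs: list[dict[str, set]],
    regulon_thresh: float = 0.8,
    target_thresh: float = 0.8,
    min_targets: int = 5,
) -> list[ConsensusRegulon]:
    """Reduce per-run regulon maps (TF -> target set) to high-confidence regulons.

    Thresholds are strict: occurrence must exceed them, so a TF present in
    exactly 80 of 100 runs is excluded. Target occurrence is denominated by the
    number of runs containing the TF's regulon. Output order is alphabetical
    by TF, hence invariant to run order.
    """
    if not runs:
        raise ValueError("empty run set")
    n_runs = len(runs)
    tf_runs: dict[str, int] = {}
    target_counts: dict[str, dict[str, int]] = {}
    for run in runs:
        for tf, targets in run.items():
            tf_runs[tf] = tf_runs.get(tf, 0) + 1
            bucket = target_counts.setdefault(tf, {})
            for g in targets:
                bucket[g] = bucket.get(g, 0) + 1
    out = []
    for tf in sorted(tf_runs):
        occ = tf_runs[tf] / n_runs
        if occ <= regulon_thresh:
            continue
        t_occ = {g: c / tf_runs[tf] for g, c in target_counts[tf].items()}
        hc = frozenset(g for g, f in t_occ.items() if f > target_thresh)
        if len(hc) < min_targets:
            continue
        out.append(
            ConsensusRegulon(
                tf=tf,
                run_occurrence=occ,
                target_occurrence=t_occ,
                high_confidence_targets=hc,
            )
        )
    return out


def gene_occurrence_matrix(
    runs: list[dict[str, set]],
    genes: list[str],
    min_fraction: float = 0.5,
    regulon_thresh: float = 0.8,
    target_thresh: float = 0.8,
    min_targets: int = 5,
):
    """Gene x TF matrix of percent occurrence across all runs.

    Entry (g, tf) is the percentage of *all* runs in which g appears in tf's
    regulon. Only high-confidence TFs whose maximal occurrence over the
    supplied genes exceeds ``min_fraction`` (as a fraction) are retained.
    """
    import pandas as pd

    consensus = aggregate_regulon_runs(runs, regulon_thresh, target_thresh, min_targets)
    n_runs = len(runs)
    data = {}
    for reg in consensus:
        col = []
        for g in genes:
            count = sum(1 for run in runs if reg.tf in run and g in run[reg.tf])
            col.append(100.0 * count / n_runs)
        if max(col, default=0.0) > 100.0 * min_fraction:
            data[reg.tf] = col
    return pd.DataFrame(data, index=list(genes))


def aucell_score(
    expression,
    gene_set,
    top_fraction: float = 0.05,
    seed: int = 0,
    tie_method: str = "random",
) -> np.ndarray:
    """Per-cell recovery-curve AUC of a gene set within the top expression ranks.

    ``expression`` is a cells x genes DataFrame (or an array plus an aligned
    gene index via DataFrame). For each cell, genes are ranked by decreasing
    expression; ties are broken at random per cell with the seeded RNG
    (``tie_method='random'``, mirroring stochastic rank assignment) or by a
    deterministic stable order (``tie_method='first'``). With
    ``max_rank = ceil(top_fraction * n_genes)``, the recovery curve is the
    cumulative gene-set hit count at ranks 1..max_rank and the score is its
    area divided by the maximal achievable area (all ``min(|S|, max_rank)``
    hits packed at the top of the ranking).
    """
    import pandas as pd

    if not 0 < top_fraction < 1:
        raise ValueError("top_fraction must be in (0, 1)")
    if isinstance(expression, pd.DataFrame):
        genes = list(expression.columns)
        values = expression.to_numpy(dtype=float)
    else:
        raise TypeError("expression must be a cells x genes DataFrame")
    gene_set = set(gene_set)
    if not gene_set:
        raise ValueError("empty gene set")
    member = np.array([g in gene_set for g in genes])
    if not member.any():
        raise ValueError("gene set is disjoint from the expression gene universe")

    n_cells, n_genes = values.shape
    max_rank = math.ceil(top_fraction * n_genes)
    s = int(member.sum())
    h_max = min(s, max_rank)
    # maximal area: hits at ranks 1..h_max then flat
    ranks_grid = np.arange(1, max_rank + 1)
    max_area = float(np.minimum(ranks_grid, h_max).sum())

    rng = np.random.default_rng(seed)
    scores = np.empty(n_cells)
    for i in range(n_cells):
        if tie_method == "random":
            jitter = rng.random(n_genes)
            order = np.lexsort((jitter, -values[i]))
        elif tie_method == "first":
            order = np.argsort(-values[i], kind="stable")
        else:
            raise ValueError("tie_method must be 'random' or 'first'")
        top = order[:max_rank]
        hits = member[top]
        curve = np.cumsum(hits)
        scores[i] = float(curve.sum()) / max_area
    return scores


def score_regulons(
    expression,
    regulons: list[ConsensusRegulon],
    top_fraction: float = 0.05,
    seed: int = 0,
    tie_method: str = "random",
):
    """Activity matrix: cells x high-confidence regulons, AUCell scores in [0,1]."""
    import pandas as pd

    cols = {}
    for j, reg in enumerate(regulons):
        cols[reg.tf] = aucell_score(
            expression,
            reg.high_confidence_targets,
            top_fraction=top_fraction,
            seed=seed + j,
            tie_method=tie_method,
        )
    return pd.DataFrame(cols, index=expression.index)


def differential_regulon_activity(activity_a, activity_b, alpha: float = 0.01):
    """Rank-sum test of per-regulon activity between two cell groups.

    Returns a DataFrame with the Mann-Whitney statistic, raw and
    Bonferroni-adjusted p-values, mean difference ``mean(A) - mean(B)`` and a
    significance flag at the Bonferroni-adjusted ``alpha``; rows are ordered by
    decreasing absolute mean difference (the "largest difference" display
    order).
    """
    import pandas as pd

    if list(activity_a.columns) != list(activity_b.columns):
        raise ValueError("the two groups must be scored on identical regulons")
    if len(activity_a) < 2 or len(activity_b) < 2:
        raise ValueError("each group needs at least 2 cells")
    m = activity_a.shape[1]
    rows = []
    for reg in activity_a.columns:
        a = activity_a[reg].to_numpy()
        b = activity_b[reg].to_numpy()
        if np.all(a == a[0]) and np.all(b == b[0]) and a[0] == b[0]:
            stat, p = 0.0, 1.0
        else:
            stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
        rows.append(
            {
                "regulon": reg,
                "statistic": float(stat),
                "p_raw": float(p),
                "p_bonferroni": min(1.0, m * float(p)),
                "mean_difference": float(a.mean() - b.mean()),
            }
        )
    df = pd.DataFrame(rows)
    df["significant"] = df["p_bonferroni"] < alpha
    df["abs_difference"] = df["mean_difference"].abs()
    df = df.sort_values("abs_difference", ascending=False, kind="stable").reset_index(drop=True)
    return df.drop(columns="abs_difference")
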