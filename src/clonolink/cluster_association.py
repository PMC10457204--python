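"""Exact multinomial test of clonotype distribution across transcriptional clusters.

For every clonotype with at least ``min_cells`` cells in a sample, the null
hypothesis is that its cells fall into clusters following the sample-wide
cluster proportions. The test statistic is the multinomial probability of the
observed composition; the p-value sums the probability of every outcome as or
less likely than the observed one.

Two computational paths mirror the classical exact-multinomial-test (EMT)
strategy: full enumeration of all C(n+k-1, k-1) compositions when that count
("events") is below one million, and otherwise Monte-Carlo sampling with
``ntrial = min(10 * events, 1e8)`` draws. The Monte-Carlo p-value uses the
add-one estimator ``(1 + #{as-or-less-likely draws}) / (ntrial + 1)``, which is
a valid p-value and can never return exactly zero.

p-values are Bonferroni-adjusted within the family of clonotypes tested in the
same donor-sample.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import stats
from scipy.special import gammaln

EXACT_EVENT_LIMIT = 10**6
MAX_NTRIAL = 10**8
#: relative tolerance for "as or less likely" pmf comparisons, absorbing
#: floating-point ties so that enumeration order cannot change the p-value
PMF_TIE_RTOL = 1e-12


@dataclass
class AssociationResult:
    """Outcome of one clonotype-vs-cluster multinomial test."""

    clonotype_id: int | str
    observed: tuple[int, ...]
    null_probs: tuple[float, ...]
    events: int
    method: str  # "exact" or "monte_carlo"
    p_raw: float
    p_bonferroni: float = float("nan")
    ntrial: int | None = None
    size: int = 0


def composition_count(n: int, k: int) -> int:
    """Number of distinct outcomes: compositions of n cells into k clusters.

    Equals C(n+k-1, k-1), computed in exact integer arithmetic.
    """
    if n < 1 or k < 1:
        raise ValueError("n and k must be >= 1")
    return math.comb(n + k - 1, k - 1)


def _compositions(n: int, k: int) -> np.ndarray:
    """All compositions of n into k non-negative parts, via stars and bars."""
    from itertools import chain, combinations

    if k == 1:
        return np.full((1, 1), n, dtype=np.int64)
    n_comps = composition_count(n, k)
    bars = np.fromiter(
        chain.from_iterable(combinations(range(n + k - 1), k - 1)),
        dtype=np.int64,
        count=n_comps * (k - 1),
    ).reshape(n_comps, k - 1)
    bounded = np.hstack(
        [
            np.full((bars.shape[0], 1), -1, dtype=np.int64),
            bars,
            np.full((bars.shape[0], 1), n + k - 1, dtype=np.int64),
        ]
    )
    return np.diff(bounded, axis=1) - 1


def _log_pmf(counts: np.ndarray, log_probs: np.ndarray, n: int) -> np.ndarray:
    out = gammaln(n + 1) - gammaln(counts + 1).sum(axis=-1)
    # 0 * log(0) = 0 by convention for zero-probability clusters never observed
    with np.errstate(invalid="ignore"):
        contrib = counts * log_probs
    contrib = np.where(counts == 0, 0.0, contrib)
    return out + contrib.sum(axis=-1)


@lru_cache(maxsize=8)
def _null_log_pmf_distribution(n: int, probs: tuple[float, ...]):
    """Sorted log-pmf values over all compositions and their cumulative pmf.

    Cached because a scan tests many same-sized clonotypes against the same
    sample-wide null; the p-value for any observed vector is then a
    searchsorted lookup.
    """
    k = len(probs)
    comps = _compositions(n, k)
    log_probs = np.log(np.asarray(probs))
    logp = _log_pmf(comps, log_probs, n)
    order = np.argsort(logp)
    logp_sorted = logp[order]
    cum = np.cumsum(np.exp(logp_sorted))
    return logp_sorted, cum


def exact_multinomial_test(observed, null_probs) -> float:
    """Exact multinomial goodness-of-fit p-value by full enumeration.

    ``p = sum of Pr(c)`` over all compositions with
    ``Pr(c) <= Pr(observed) * (1 + 1e-12)``.
    """
    observed = np.asarray(observed, dtype=np.int64)
    probs = np.asarray(null_probs, dtype=float)
    n = int(observed.sum())
    k = observed.size
    if n < 1:
        raise ValueError("observed counts must sum to at least 1")
    if abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError("null probabilities must sum to 1")
    if k == 1:
        return 1.0
    events = composition_count(n, k)
    if events >= EXACT_EVENT_LIMIT:
        raise ValueError(
            f"{events} possible outcomes >= {EXACT_EVENT_LIMIT}; "
            "use monte_carlo_multinomial_test"
        )
    logp_sorted, cum = _null_log_pmf_distribution(n, tuple(probs))
    logp_obs = float(_log_pmf(observed[None, :], np.log(probs), n)[0])
    threshold = logp_obs + math.log1p(PMF_TIE_RTOL)
    idx = int(np.searchsorted(logp_sorted, threshold, side="right"))
    p = float(cum[idx - 1]) if idx > 0 else 0.0
    return min(max(p, math.exp(logp_obs)), 1.0)


def monte_carlo_multinomial_test(
    observed, null_probs, seed: int = 0, ntrial: int | None = None, chunk: int = 1_000_000
) -> tuple[float, int]:
    """Monte-Carlo multinomial p-value with the add-one estimator.

    ``ntrial`` defaults to ``min(10 * events, 1e8)``; pass a smaller value to
    force a cheaper estimate. Returns ``(p_est, ntrial)``.
    """
    observed = np.asarray(observed, dtype=np.int64)
    probs = np.asarray(null_probs, dtype=float)
    n = int(observed.sum())
    if abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError("null probabilities must sum to 1")
    events = composition_count(n, observed.size)
    if ntrial is None:
        ntrial = min(10 * events, MAX_NTRIAL)
    rng = np.random.default_rng(seed)
    log_probs = np.log(probs)
    logp_obs = float(_log_pmf(observed[None, :], log_probs, n)[0])
    threshold = logp_obs + math.log1p(PMF_TIE_RTOL)
    hits = 0
    remaining = ntrial
    while remaining > 0:
        m = min(chunk, remaining)
        draws = rng.multinomial(n, probs, size=m)
        logp = _log_pmf(draws, log_probs, n)
        hits += int((logp <= threshold).sum())
        remaining -= m
    return (1 + hits) / (ntrial + 1), ntrial


def multinomial_test(
    observed, null_probs, seed: int = 0, max_ntrial: int | None = None
) -> tuple[float, str, int, int | None]:
    """Dispatch to the exact or Monte-Carlo path based on the event count.

    Returns ``(p, method, events, ntrial)``. ``max_ntrial`` caps the
    Monte-Carlo sample count below the ``min(10*events, 1e8)`` default.
    """
    observed = np.asarray(observed, dtype=np.int64)
    events = composition_count(int(observed.sum()), observed.size)
    if events < EXACT_EVENT_LIMIT:
        return exact_multinomial_test(observed, null_probs), "exact", events, None
    ntrial = min(10 * events, MAX_NTRIAL)
    if max_ntrial is not None:
        ntrial = min(ntrial, max_ntrial)
    p, ntrial = monte_carlo_multinomial_test(observed, null_probs, seed=seed, ntrial=ntrial)
    return p, "monte_carlo", events, ntrial


def clonotype_cluster_scan(
    assignment: dict,
    cluster_labels: dict,
    min_cells: int = 20,
    seed: int = 0,
    loo_null: bool = False,
    max_ntrial: int | None = None,
) -> list[AssociationResult]:
    """Test every clonotype with >= ``min_cells`` cells for nonrandom cluster use.

    ``assignment`` maps barcode -> clonotype id (one donor-sample);
    ``cluster_labels`` maps barcode -> cluster label for all cells of the
    sample. Null probabilities are the sample-wide cluster proportions
    (including the tested clonotype's own cells unless ``loo_null``). Clusters
    with zero cells overall are dropped from the support. The Bonferroni family
    is the set of clonotypes tested in this sample.
    """
    clusters = sorted(set(cluster_labels.values()))
    totals = np.array(
        [sum(1 for c in cluster_labels.values() if c == cl) for cl in clusters], dtype=float
    )
    keep = totals > 0
    clusters = [cl for cl, k in zip(clusters, keep) if k]
    totals = totals[keep]
    cluster_index = {cl: i for i, cl in enumerate(clusters)}

    by_clonotype: dict = {}
    for bc, cid in assignment.items():
        by_clonotype.setdefault(cid, []).append(bc)

    tested = {cid: bcs for cid, bcs in by_clonotype.items() if len(bcs) >= min_cells}
    m = len(tested)
    results = []
    rng = np.random.default_rng(seed)
    for cid in sorted(tested, key=str):
        bcs = tested[cid]
        observed = np.zeros(len(clusters), dtype=np.int64)
        for bc in bcs:
            observed[cluster_index[cluster_labels[bc]]] += 1
        base = totals.copy()
        if loo_null:
            base = base - observed
            if (base <= 0).any():
                base = np.maximum(base, 0.5)
        probs = base / base.sum()
        sub_seed = int(rng.integers(0, 2**31 - 1))
        p, method, events, ntrial = multinomial_test(
            observed, probs, seed=sub_seed, max_ntrial=max_ntrial
        )
        results.append(
            AssociationResult(
                clonotype_id=cid,
                observed=tuple(int(x) for x in observed),
                null_probs=tuple(float(x) for x in probs),
                events=events,
                method=method,
                p_raw=p,
                p_bonferroni=min(1.0, m * p),
                ntrial=ntrial,
                size=len(bcs),
            )
        )
    return results


def size_significance_correlation(results: list[AssociationResult]) -> tuple[float, float]:
    """Spearman rho between clonotype size rank and Bonferroni-adjusted p.

    Size rank 1 is the largest clonotype, so a negative correlation between
    adjusted p and size corresponds to a *positive* rho against size rank.
    Returns ``(rho, p)``; ``(nan, nan)`` when undefined (fewer than three
    results, or no variation in either variable).
    """
    if len(results) < 3:
        return float("nan"), float("nan")
    sizes = np.array([r.size for r in results], dtype=float)
    pvals = np.array([r.p_bonferroni for r in results], dtype=float)
    size_rank = stats.rankdata(-sizes)  # rank 1 = largest
    if np.all(pvals == pvals[0]) or np.all(sizes == sizes[0]):
        return float("nan"), float("nan")
    rho, p = stats.spearmanr(size_rank, pvals)
    return float(rho), float(p)


def results_to_dataframe(results: list[AssociationResult]):
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "clonotype_id": r.clonotype_id,
                "size": r.size,
                "events": r.events,
                "method": r.method,
                "ntrial": r.ntrial,
                "p_raw": r.p_raw,
                "p_bonferroni": r.p_bonferroni,
                "observed": ";".join(map(str, r.observed)),
            }
            for r in results
        ]
    )
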