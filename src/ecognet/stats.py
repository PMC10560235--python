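"""Nonparametric statistics shared across the pipeline.

* cluster-based permutation testing of two trial ensembles over time,
* Wilcoxon signed-rank (exact for small n, normal approximation above),
* Benjamini-Hochberg step-up FDR control.

Permutation p-values follow the ``count / n_perm`` convention (the number of
null statistics at least as large as the observed one divided by the number
of permutations); a ``plus_one`` variant is selectable.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


def perm_pvalue(null: np.ndarray, observed: float, plus_one: bool = False) -> float:
    null = np.asarray(null)
    count = int(np.sum(null >= observed))
    if plus_one:
        return (count + 1) / (len(null) + 1)
    return count / len(null)


# ---------------------------------------------------------------------------
# Cluster-based permutation test
# ---------------------------------------------------------------------------

@dataclass
class Cluster:
    start_s: float
    end_s: float
    mass: float
    p: float

    @property
    def duration(self) -> float:
        return self.end_s - self.start_s


@dataclass
class ClusterResult:
    """Result of a 1-D cluster-based permutation test.

    ``clusters`` holds the reported clusters (p < alpha and duration >=
    min_duration); ``all_clusters`` every supra-threshold run with its p.
    """

    clusters: list[Cluster]
    all_clusters: list[Cluster]
    t_trace: np.ndarray
    times: np.ndarray
    n_perm: int
    alpha: float
    min_duration: float
    seed: int | None = None
    exact: bool = False

    @property
    def significant(self) -> bool:
        return len(self.clusters) > 0


def _welch_t(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    na, nb = a.shape[0], b.shape[0]
    ma, mb = a.mean(axis=0), b.mean(axis=0)
    va, vb = a.var(axis=0, ddof=1), b.var(axis=0, ddof=1)
    se2 = va / na + vb / nb
    se2 = np.maximum(se2, 1e-300)
    t = (ma - mb) / np.sqrt(se2)
    df = se2**2 / np.maximum(
        (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1), 1e-300
    )
    return t, df


def _cluster_masses(t: np.ndarray, thresh: np.ndarray) -> list[tuple[int, int, float]]:
    """Contiguous same-sign supra-threshold runs; (start, stop, mass)."""
    supra = np.abs(t) > thresh
    out = []
    i, n = 0, len(t)
    while i < n:
        if not supra[i]:
            i += 1
            continue
        j = i
        sign = np.sign(t[i])
        while j < n and supra[j] and np.sign(t[j]) == sign:
            j += 1
        out.append((i, j, float(t[i:j].sum())))
        i = j
    return out


def cluster_permutation_test(
    cond_a: np.ndarray,
    cond_b: np.ndarray,
    fs: float,
    n_perm: int = 1000,
    alpha: float = 0.05,
    cluster_alpha: float = 0.05,
    min_duration: float = 0.025,
    tmin: float = 0.0,
    seed: int | None = 0,
    plus_one: bool = False,
) -> ClusterResult:
    """Two-sample cluster-based permutation test over time.

    The pointwise statistic is a two-sided Welch t; contiguous same-sign
    supra-threshold runs are scored by their summed t (cluster mass); the
    null is the maximum absolute cluster mass over random relabelings of
    trials; each observed cluster's p is the fraction of null maxima at least
    as large. Clusters shorter than ``min_duration`` (s) are discarded from
    the reported set after p evaluation.

    When ``n_perm`` is at least the number of distinct relabelings, exact
    enumeration is used instead of random sampling.
    """
    a = np.atleast_2d(np.asarray(cond_a, dtype=float))
    b = np.atleast_2d(np.asarray(cond_b, dtype=float))
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("need >= 2 trials per condition")
    if a.shape[1] != b.shape[1]:
        raise ValueError("conditions must share the time axis")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    na = a.shape[0]
    pooled = np.concatenate([a, b], axis=0)
    n = pooled.shape[0]

    t_obs, df = _welch_t(a, b)
    thresh = sps.t.ppf(1 - cluster_alpha / 2, df)
    obs_clusters = _cluster_masses(t_obs, thresh)

    n_distinct = math.comb(n, na)
    exact = n_distinct <= n_perm
    if exact:
        logger.info("exact enumeration over %d relabelings", n_distinct)
        idx_iter = (np.array(c) for c in combinations(range(n), na))
        n_used = n_distinct
    else:
        rng = np.random.default_rng(seed)
        idx_iter = (rng.permutation(n)[:na] for _ in range(n_perm))
        n_used = n_perm

    null_max = np.zeros(n_used)
    mask = np.zeros(n, dtype=bool)
    for k, ia in enumerate(idx_iter):
        mask[:] = False
        mask[ia] = True
        t_p, df_p = _welch_t(pooled[mask], pooled[~mask])
        thr_p = sps.t.ppf(1 - cluster_alpha / 2, df_p)
        masses = _cluster_masses(t_p, thr_p)
        null_max[k] = max((abs(m) for _, _, m in masses), default=0.0)

    times = tmin + np.arange(a.shape[1]) / fs
    all_clusters = []
    for i, j, m in obs_clusters:
        p = perm_pvalue(null_max, abs(m), plus_one)
        all_clusters.append(Cluster(times[i], times[i] + (j - i) / fs, m, p))
    reported = [
        c for c in all_clusters
        if c.p < alpha and c.duration >= min_duration - 1e-12
    ]
    return ClusterResult(
        reported, all_clusters, t_obs, times, n_used, alpha, min_duration,
        seed, exact,
    )


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank
# ---------------------------------------------------------------------------

@dataclass
class WilcoxonResult:
    statistic: float  # W: smaller of the signed-rank sums
    p: float
    method: str  # "exact" or "approx"
    z: float | None = None
    n_nonzero: int = 0


def wilcoxon_signed_rank(x, y, exact_max_n: int = 25) -> WilcoxonResult:
    """Paired two-sided Wilcoxon signed-rank test.

    Uses the exact null distribution when the number of nonzero differences
    is at most ``exact_max_n`` (and ranks are untied), otherwise the normal
    approximation with continuity correction. Zero differences are dropped.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    d = x - y
    d = d[d != 0]
    if len(d) == 0:
        raise ValueError("degenerate input: all paired differences are zero")
    ranks = sps.rankdata(np.abs(d))
    tied = len(np.unique(ranks)) != len(ranks)
    use_exact = len(d) <= exact_max_n and not tied
    method = "exact" if use_exact else "approx"
    res = sps.wilcoxon(d, alternative="two-sided", correction=True,
                       method=method)
    z = getattr(res, "zstatistic", None)
    return WilcoxonResult(
        statistic=float(res.statistic),
        p=float(res.pvalue),
        method=method,
        z=None if z is None else float(z),
        n_nonzero=len(d),
    )


# ---------------------------------------------------------------------------
# Benjamini-Hochberg FDR
# ---------------------------------------------------------------------------

@dataclass
class FDRResult:
    reject: np.ndarray
    p_adjusted: np.ndarray
    q: float = 0.05
    extras: dict = field(default_factory=dict)


def bh_fdr(pvals, q: float = 0.05) -> FDRResult:
    """Benjamini-Hochberg step-up procedure at level ``q``.

    Rejects the hypotheses with the ``k`` smallest p-values where
    ``k = max{k : p_(k) <= k q / m}``; also returns BH-adjusted p-values.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return FDRResult(np.zeros(0, dtype=bool), np.zeros(0), q)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return FDRResult(reject, p_adj, q)
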