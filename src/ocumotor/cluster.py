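"""Cluster-based permutation test for paired time-course comparisons.

Family-wise error over time bins is controlled nonparametrically: adjacent
bins whose paired t-value exceeds the 97.5% quantile of the t-distribution
(same sign) are clustered, each cluster is scored by the sum of its member
t-values, and observed cluster masses are referred to the Monte-Carlo
distribution of the maximum |cluster mass| under random sign flips of the
per-participant difference series (1,000 partitions by default, or full
enumeration when the design allows).  A cluster is significant when its
p-value is at or below the critical alpha of 0.05.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .core import InsufficientDataError


@dataclass
class ClusterConfig:
    n_permutations: int = 1000
    cluster_threshold_quantile: float = 0.975
    test_alpha: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.cluster_threshold_quantile < 1:
            raise ValueError("quantile must be in (0, 1)")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")


@dataclass
class Cluster:
    first_bin: int
    last_bin: int  # inclusive
    sign: int
    mass: float
    p_value: float | None = None

    @property
    def n_bins(self) -> int:
        return self.last_bin - self.first_bin + 1


@dataclass
class ClusterResult:
    clusters: list[Cluster]
    t_series: np.ndarray
    threshold: float
    null_max_mass: np.ndarray
    n_participants: int
    n_partitions: int
    exact: bool
    alpha: float

    @property
    def significant(self) -> list[Cluster]:
        return [c for c in self.clusters if c.p_value is not None and c.p_value <= self.alpha]


def pointwise_paired_t(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Per-bin paired t statistic, t = mean(D) / (sd(D)/sqrt(n)), sample sd.

    A bin with sd(D)=0 and nonzero mean gets +/-inf (always
    supra-threshold); sd=0 with zero mean gives t=0.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("condition arrays must have the same shape")
    n = a.shape[0]
    if n < 2:
        raise InsufficientDataError("need >= 2 participants")
    d = a - b
    return _t_from_differences(d)


def _t_from_differences(d: np.ndarray) -> np.ndarray:
    n = d.shape[0]
    mean = d.mean(axis=0)
    sd = d.std(axis=0, ddof=1)
    t = np.zeros_like(mean)
    ok = sd > 0
    t[ok] = mean[ok] / (sd[ok] / np.sqrt(n))
    degen = ~ok & (mean != 0)
    t[degen] = np.sign(mean[degen]) * np.inf
    return t


def form_clusters(t_series: np.ndarray, threshold: float) -> list[Cluster]:
    """Maximal runs of adjacent bins beyond +/-threshold with a common sign;
    cluster mass is the sum of member t-values."""
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    t = np.asarray(t_series, dtype=float)
    out: list[Cluster] = []
    for sign in (1, -1):
        supra = t * sign > threshold
        padded = np.concatenate(([False], supra, [False]))
        edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
        for s, e in zip(edges[::2], edges[1::2]):
            out.append(
                Cluster(first_bin=int(s), last_bin=int(e - 1), sign=sign, mass=float(t[s:e].sum()))
            )
    out.sort(key=lambda c: c.first_bin)
    return out


def _max_cluster_masses(t_mat: np.ndarray, threshold: float) -> np.ndarray:
    """Per row of a (P, n_bins) t matrix: max |cluster mass| over both signs
    (0 when no bin is supra-threshold)."""
    P, nb = t_mat.shape
    out = np.zeros(P)
    for sign in (1.0, -1.0):
        supra = (t_mat * sign) > threshold
        vals = np.where(supra, t_mat * sign, 0.0)
        # cumulative-sum trick: mass of each run = difference of cumsums at edges
        for p in range(P):
            row = supra[p]
            if not row.any():
                continue
            padded = np.concatenate(([False], row, [False]))
            edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
            cs = np.concatenate(([0.0], np.cumsum(vals[p])))
            masses = cs[edges[1::2]] - cs[edges[::2]]
            out[p] = max(out[p], masses.max())
    return out


def cluster_permutation_test(
    a: np.ndarray, b: np.ndarray, cfg: ClusterConfig | None = None
) -> ClusterResult:
    """Paired cluster permutation test of condition ``a`` vs ``b``.

    ``a`` and ``b`` are (n_participants, n_bins) arrays of matched series.
    The null distribution flips the sign of each participant's difference
    series independently (the paired-design partition); when the design is
    small enough (2^n <= n_permutations) all sign patterns are enumerated,
    otherwise ``n_permutations`` random partitions are drawn from the
    seeded stream.  Cluster p-values use the +1-corrected Monte-Carlo
    estimate (1 + #{null >= |mass|}) / (n_partitions + 1), so p is never 0.
    """
    cfg = cfg or ClusterConfig()
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("condition arrays must have the same shape")
    n = a.shape[0]
    if n < 2:
        raise InsufficientDataError("need >= 2 participants")
    d = a - b
    threshold = float(stats.t.ppf(cfg.cluster_threshold_quantile, df=n - 1))
    t_obs = _t_from_differences(d)
    clusters = form_clusters(t_obs, threshold)

    exact = 2**n <= cfg.n_permutations
    if exact:
        n_part = 2**n
        bits = (np.arange(n_part)[:, None] >> np.arange(n)) & 1
        signs = 1.0 - 2.0 * bits  # (n_part, n)
    else:
        n_part = cfg.n_permutations
        rng = np.random.default_rng(cfg.seed)
        signs = rng.choice([-1.0, 1.0], size=(n_part, n))

    # t under sign flips: flipping d_i leaves d_i^2 unchanged, so only the
    # mean depends on the signs and the whole t matrix is one matmul
    mean = signs @ d / n
    ssq = np.sum(d**2, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        var = (ssq[None, :] - n * mean**2) / (n - 1)
        var = np.maximum(var, 0.0)
        t_null = np.where(
            var > 0,
            mean / np.sqrt(var / n),
            np.where(mean != 0, np.sign(mean) * np.inf, 0.0),
        )
    null_max = _max_cluster_masses(t_null, threshold)

    for c in clusters:
        ge = int(np.sum(null_max >= abs(c.mass)))
        c.p_value = (1.0 + ge) / (n_part + 1.0)
    return ClusterResult(
        clusters=clusters,
        t_series=t_obs,
        threshold=threshold,
        null_max_mass=null_max,
        n_participants=n,
        n_partitions=n_part,
        exact=exact,
        alpha=cfg.test_alpha,
    )
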