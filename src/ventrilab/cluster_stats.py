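"""Group-level sign-flip permutation inference with temporal clustering.

The null hypothesis of no group effect is simulated by flipping the sign
of each subject's whole chance-centered time course (AUC − 0.5, or raw
regression betas) with probability ½, recomputing the group statistic
(mean for AUC, one-sample t for betas), thresholding, and recording the
maximum cluster mass.  Observed clusters — contiguous supra-threshold runs
of at least four windows, scored by the sum of the statistic — are
compared against that null with the (1 + exceedances)/(1 + n) convention,
so the smallest attainable p at 3000 randomizations is 1/3001 ≈ 0.0003.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

log = logging.getLogger(__name__)

__all__ = [
    "Cluster",
    "ClusterResult",
    "find_clusters",
    "signflip_null",
    "cluster_p",
    "auc_first_level_threshold",
    "cluster_test",
    "conjunction_cluster_test",
    "t_critical",
]


@dataclass
class Cluster:
    """Contiguous supra-threshold run: [start, stop] window indices (inclusive)."""
    start: int
    stop: int
    mass: float
    p: float | None = None

    @property
    def size(self) -> int:
        return self.stop - self.start + 1


@dataclass
class ClusterResult:
    clusters: list[Cluster]
    threshold: float
    min_size: int
    n_rand: int
    two_sided: bool
    alpha: float = 0.01
    null_max_mass: np.ndarray | None = None

    def significant(self, alpha: float | None = None) -> list[Cluster]:
        a = self.alpha if alpha is None else alpha
        return [c for c in self.clusters if c.p is not None and c.p < a]

    def to_dict(self) -> dict:
        return {
            "threshold": float(self.threshold), "min_size": self.min_size,
            "n_rand": self.n_rand, "two_sided": self.two_sided, "alpha": self.alpha,
            "clusters": [{"start": c.start, "stop": c.stop,
                          "mass": float(c.mass), "p": c.p} for c in self.clusters],
        }


def t_critical(n_subjects: int, p: float = 0.01) -> float:
    """Two-sided parametric first-level threshold (df = n−1); 2.88 at n=19, p=.01."""
    return float(sps.t.ppf(1.0 - p / 2.0, df=n_subjects - 1))


def _runs(above: np.ndarray):
    """Start/stop (inclusive) of True runs in a boolean vector."""
    d = np.diff(np.concatenate([[0], above.astype(np.int8), [0]]))
    starts = np.flatnonzero(d == 1)
    stops = np.flatnonzero(d == -1) - 1
    return starts, stops


def find_clusters(stat_map: np.ndarray, threshold: float, min_size: int = 4,
                  two_sided: bool = True) -> list[Cluster]:
    """Maximal supra-threshold runs of length >= min_size, mass = sum of the map.

    Positive exceedances (map > threshold) and, when two-sided, negative
    ones (map < −threshold) are clustered separately.
    """
    m = np.asarray(stat_map, dtype=float)
    out: list[Cluster] = []
    sides = [m > threshold]
    if two_sided:
        sides.append(m < -threshold)
    for above in sides:
        for s, e in zip(*_runs(above)):
            if e - s + 1 >= min_size:
                out.append(Cluster(int(s), int(e), float(m[s: e + 1].sum())))
    out.sort(key=lambda c: c.start)
    return out


def _group_stats(flips: np.ndarray, data: np.ndarray, stat: str) -> np.ndarray:
    """Group statistic per randomization: flips (R×S) applied to data (S×W)."""
    S = data.shape[0]
    mean = flips @ data / S
    if stat == "mean":
        return mean
    if stat == "t":
        # sum of squares is flip-invariant
        msq = (data ** 2).mean(axis=0)[None, :]
        var = (msq - mean ** 2) * S / (S - 1)
        var = np.maximum(var, 1e-300)
        return mean / np.sqrt(var / S)
    raise ValueError(f"unknown stat {stat!r}")


def signflip_null(per_subject: np.ndarray, n_rand: int = 3000, seed: int = 0,
                  stat: str = "t", threshold: float | str = "auc",
                  min_size: int = 4, two_sided: bool = True):
    """Null distribution of the maximum cluster mass under subject sign flips.

    ``per_subject`` is subjects × windows of chance-centered statistics.
    Each randomization flips whole subject time courses, recomputes the
    group statistic (``"mean"`` or ``"t"``), thresholds, clusters, and
    keeps the largest |mass| (0 when no cluster survives).  With
    ``threshold="auc"`` the first-level threshold is the 99th percentile of
    the pooled randomized group statistics (the AUC convention); a float is
    used as a fixed (t) threshold.

    Returns ``(null_max_mass, threshold_used, randomized_stats)``.
    """
    data = np.asarray(per_subject, dtype=float)
    S = data.shape[0]
    if n_rand < 100:
        log.warning("n_rand=%d gives a coarse p resolution (floor %.3g)",
                    n_rand, 1.0 / (n_rand + 1))
    if S < 5:
        log.warning("only %d subjects: sign-flip null has at most 2^%d states", S, S)
    rng = np.random.default_rng(seed)
    flips = rng.integers(0, 2, size=(n_rand, S)) * 2.0 - 1.0
    rand_stats = _group_stats(flips, data, stat)
    if threshold == "auc":
        thr = auc_first_level_threshold(rand_stats)
    else:
        thr = float(threshold)
    null_max = np.zeros(n_rand)
    for i in range(n_rand):
        cl = find_clusters(rand_stats[i], thr, min_size=min_size, two_sided=two_sided)
        if cl:
            null_max[i] = max(abs(c.mass) for c in cl)
    return null_max, thr, rand_stats


def auc_first_level_threshold(null_values: np.ndarray) -> float:
    """99th percentile of the pooled randomized (chance-centered) values."""
    v = np.asarray(null_values, dtype=float).ravel()
    if v.size == 0:
        raise ValueError("empty null distribution")
    thr = float(np.percentile(v, 99.0))
    if thr == 0.0:
        log.warning("degenerate null: first-level threshold is 0")
    return thr


def cluster_p(clusters: list[Cluster], null_max_mass: np.ndarray) -> list[Cluster]:
    """Attach permutation p values: p = (1 + #{null >= |mass|}) / (1 + n_rand)."""
    null = np.asarray(null_max_mass, dtype=float)
    if null.size == 0:
        raise ValueError("empty null distribution")
    for c in clusters:
        c.p = float((1 + np.sum(null >= abs(c.mass))) / (1 + null.size))
    return clusters


def cluster_test(per_subject: np.ndarray, mode: str = "beta", n_rand: int = 3000,
                 seed: int = 0, alpha: float = 0.01, min_size: int = 4,
                 first_level_p: float = 0.01) -> ClusterResult:
    """Observed clusters plus their sign-flip permutation p values.

    ``mode="auc"``: ``per_subject`` are chance-centered AUC time courses;
    group statistic is the mean and the first-level threshold the 99th
    percentile of the pooled randomized values (one-sided, positive).
    ``mode="beta"``: per-subject regression betas; group statistic is the
    one-sample t and the first-level threshold the two-sided parametric
    critical t at ``first_level_p``.
    """
    data = np.asarray(per_subject, dtype=float)
    S = data.shape[0]
    if mode == "auc":
        stat, two_sided, thr_spec = "mean", False, "auc"
    elif mode == "beta":
        stat, two_sided = "t", True
        thr_spec = t_critical(S, first_level_p)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    null_max, thr, _ = signflip_null(data, n_rand=n_rand, seed=seed, stat=stat,
                                     threshold=thr_spec, min_size=min_size,
                                     two_sided=two_sided)
    observed = _group_stats(np.ones((1, S)), data, stat)[0]
    clusters = find_clusters(observed, thr, min_size=min_size, two_sided=two_sided)
    cluster_p(clusters, null_max)
    return ClusterResult(clusters=clusters, threshold=thr, min_size=min_size,
                         n_rand=n_rand, two_sided=two_sided, alpha=alpha,
                         null_max_mass=null_max)


def conjunction_cluster_test(betas_a: np.ndarray, betas_b: np.ndarray,
                             n_rand: int = 3000, seed: int = 0,
                             alpha: float = 0.01, min_size: int = 4,
                             first_level_p: float = 0.01) -> ClusterResult:
    """Cluster test on the conjunction (per-window minimum) of two t maps.

    Used for the two cross-paradigm directions: the same sign flip is
    applied to a subject's betas in both maps, both group t maps are
    recomputed, and the randomized conjunction map is clustered exactly
    like the observed one.
    """
    A = np.asarray(betas_a, dtype=float)
    B = np.asarray(betas_b, dtype=float)
    if A.shape != B.shape:
        raise ValueError("beta arrays must share subjects x windows shape")
    S = A.shape[0]
    thr = t_critical(S, first_level_p)
    rng = np.random.default_rng(seed)
    flips = rng.integers(0, 2, size=(n_rand, S)) * 2.0 - 1.0
    conj_rand = np.minimum(_group_stats(flips, A, "t"), _group_stats(flips, B, "t"))
    null_max = np.zeros(n_rand)
    for i in range(n_rand):
        cl = find_clusters(conj_rand[i], thr, min_size=min_size, two_sided=True)
        if cl:
            null_max[i] = max(abs(c.mass) for c in cl)
    ones = np.ones((1, S))
    observed = np.minimum(_group_stats(ones, A, "t"), _group_stats(ones, B, "t"))[0]
    clusters = find_clusters(observed, thr, min_size=min_size, two_sided=True)
    cluster_p(clusters, null_max)
    return ClusterResult(clusters=clusters, threshold=thr, min_size=min_size,
                         n_rand=n_rand, two_sided=True, alpha=alpha,
                         null_max_mass=null_max)
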