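"""Dependent-samples Monte-Carlo cluster-based permutation tests over
channel space and over time.

Element-wise paired t statistics are thresholded at the two-sided alpha
quantile of t(n-1); supra-threshold channels need at least ``min_nbchan``
same-sign supra-threshold neighbors; same-sign connected components form
clusters scored by size (element count; the summed t is also recorded).
The null distribution of the maximum cluster size (over both signs, so the
test is familywise two-sided) is built by sign-flipping the within-subject
condition differences, and cluster p-values use the (1 + exceedances) /
(1 + n_permutations) estimator, so p is never exactly zero.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "ClusterResult", "paired_tmap", "find_clusters",
    "cluster_permutation_test", "timecourse_cluster_test",
]

logger = logging.getLogger(__name__)


class ClusterError(ValueError):
    pass


@dataclass
class Cluster:
    members: list            # element indices (or channel names when mapped)
    size: int
    t_sum: float
    sign: int                # +1 / -1
    p_value: float = 1.0


@dataclass
class ClusterResult:
    clusters: list
    t_map: np.ndarray
    threshold: float
    max_stat_distribution: np.ndarray = field(default_factory=lambda: np.array([]))
    n_permutations: int = 0
    elements: list = field(default_factory=list)

    @property
    def significant(self):
        return [c for c in self.clusters if c.p_value < 0.05]

    def to_json(self, path) -> None:
        payload = {
            "n_permutations": self.n_permutations,
            "threshold": self.threshold,
            "clusters": [
                {"members": [self.elements[i] if self.elements else int(i)
                             for i in c.members],
                 "size": c.size, "t_sum": c.t_sum, "sign": c.sign,
                 "p_value": c.p_value}
                for c in self.clusters
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def paired_tmap(values_a: np.ndarray, values_b: np.ndarray) -> np.ndarray:
    """Paired t statistic per element; inputs are subjects x elements."""
    a, b = np.asarray(values_a, float), np.asarray(values_b, float)
    if a.shape != b.shape:
        raise ClusterError("condition arrays must have matching shapes")
    if a.shape[0] < 2:
        raise ClusterError("need at least 2 subjects")
    return _tmap_from_diffs(a - b)


def _tmap_from_diffs(d: np.ndarray) -> np.ndarray:
    n = d.shape[0]
    mean = d.mean(axis=0)
    sd = d.std(axis=0, ddof=1)
    zero_var = sd == 0
    if np.any(zero_var & (mean != 0)):
        logger.warning("zero difference variance at %d element(s); "
                       "t set to +-inf (treated as significant)",
                       int((zero_var & (mean != 0)).sum()))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    t = np.where(zero_var, np.where(mean == 0, 0.0, np.sign(mean) * np.inf), t)
    return t


def _components(members: np.ndarray, adjacency: np.ndarray) -> list:
    """Connected components of the vertex subset ``members`` (bool mask)."""
    idx = np.flatnonzero(members)
    unseen = set(idx.tolist())
    comps = []
    while unseen:
        seed = unseen.pop()
        comp, stack = [seed], [seed]
        while stack:
            v = stack.pop()
            for u in np.flatnonzero(adjacency[v]):
                if u in unseen:
                    unseen.remove(u)
                    comp.append(int(u))
                    stack.append(int(u))
        comps.append(sorted(comp))
    return comps


def find_clusters(t_map: np.ndarray, adjacency: np.ndarray,
                  alpha: float = 0.05, min_nbchan: int = 3,
                  df: int | None = None, threshold: float | None = None) -> list:
    """Same-sign connected clusters of supra-threshold elements.

    A channel is retained only if at least ``min_nbchan`` of its neighbors
    are supra-threshold with the same sign (set ``min_nbchan=0`` for
    temporal clustering, where the notion does not apply).
    """
    t_map = np.asarray(t_map, float)
    if threshold is None:
        if df is None:
            raise ClusterError("either df or an explicit threshold is required")
        threshold = stats.t.ppf(1 - alpha / 2, df)
    clusters = []
    for sign in (1, -1):
        supra = (sign * t_map) > threshold
        if min_nbchan > 0:
            nb_count = adjacency @ supra.astype(int)
            keep = supra & (nb_count >= min_nbchan)
        else:
            keep = supra
        for comp in _components(keep, adjacency):
            clusters.append(Cluster(
                members=comp, size=len(comp),
                t_sum=float(t_map[comp].sum()), sign=sign))
    return clusters


def _max_cluster_stat(t_map, adjacency, threshold, min_nbchan,
                      statistic="size") -> float:
    best = 0.0
    for sign in (1, -1):
        supra = (sign * t_map) > threshold
        if not supra.any():
            continue
        if min_nbchan > 0:
            keep = supra & ((adjacency @ supra.astype(int)) >= min_nbchan)
        else:
            keep = supra
        for comp in _components(keep, adjacency):
            stat = len(comp) if statistic == "size" else abs(t_map[comp].sum())
            best = max(best, stat)
    return best


def cluster_permutation_test(
    values_a: np.ndarray, values_b: np.ndarray, adjacency: np.ndarray,
    n_permutations: int = 2000, alpha: float = 0.05, min_nbchan: int = 3,
    rng=None, elements=None, statistic: str = "size",
) -> ClusterResult:
    """Within-subject two-condition cluster permutation test.

    ``values_*`` are subjects x elements.  The null is built by random sign
    flips of the per-subject differences (exact exchangeability for paired
    designs); per iteration the maximum cluster statistic over both signs is
    recorded, and each observed cluster gets
    p = (1 + #{null max >= observed stat}) / (1 + n_permutations).

    ``statistic`` selects the cluster score: ``size`` (element count, the
    default) or ``mass`` (absolute summed t).  The size statistic is heavily
    tied on small sensor arrays and therefore conservative; mass is
    continuous and calibrates tightly.
    """
    rng = np.random.default_rng(rng)
    a, b = np.asarray(values_a, float), np.asarray(values_b, float)
    if a.shape != b.shape:
        raise ClusterError("condition arrays must have matching shapes")
    d = a - b
    n = d.shape[0]
    if n < 5:
        logger.warning("only %d subjects: permutation resolution is coarse", n)
    threshold = stats.t.ppf(1 - alpha / 2, n - 1)
    t_obs = _tmap_from_diffs(d)
    clusters = find_clusters(t_obs, adjacency, alpha=alpha,
                             min_nbchan=min_nbchan, threshold=threshold)

    # all permutation t-maps at once: sums of d are linear in the signs,
    # and sum(d^2) is sign-invariant
    signs = rng.choice([-1.0, 1.0], size=(n_permutations, n))
    sum_d = signs @ d                       # (n_perm, e)
    sum_d2 = (d ** 2).sum(axis=0)           # (e,)
    mean = sum_d / n
    var = (sum_d2 / n - mean ** 2) * n / (n - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_perm = mean / np.sqrt(var / n)
    t_perm = np.nan_to_num(t_perm, nan=0.0, posinf=np.inf, neginf=-np.inf)

    null_max = np.empty(n_permutations)
    for i in range(n_permutations):
        null_max[i] = _max_cluster_stat(t_perm[i], adjacency, threshold,
                                        min_nbchan, statistic)
    for c in clusters:
        stat = c.size if statistic == "size" else abs(c.t_sum)
        c.p_value = float((1 + (null_max >= stat).sum()) / (1 + n_permutations))
    clusters.sort(key=lambda c: c.p_value)
    return ClusterResult(
        clusters=clusters, t_map=t_obs, threshold=float(threshold),
        max_stat_distribution=null_max, n_permutations=n_permutations,
        elements=list(elements) if elements is not None else [])


def timecourse_cluster_test(
    values_a: np.ndarray, values_b: np.ndarray, times: np.ndarray,
    n_permutations: int = 2000, alpha: float = 0.05, rng=None,
) -> ClusterResult:
    """Cluster permutation test over a band-power timecourse.

    Adjacency is temporal contiguity; the minimum-neighbor rule does not
    apply.  Cluster members index into ``times``.
    """
    times = np.asarray(times)
    n_t = times.size
    adjacency = np.zeros((n_t, n_t), dtype=bool)
    idx = np.arange(n_t - 1)
    adjacency[idx, idx + 1] = adjacency[idx + 1, idx] = True
    res = cluster_permutation_test(
        values_a, values_b, adjacency, n_permutations=n_permutations,
        alpha=alpha, min_nbchan=0, rng=rng,
        elements=[float(t) for t in times])
    return res
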