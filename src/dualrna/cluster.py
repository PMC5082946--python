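"""Temporal clustering of phage genes.

Genes are represented by their replicate-averaged normalized expression
across the time points of one condition, rescaled to a probability simplex
(the temporal *shape*, independent of expression level).  Two independent
clusterings are provided:

* k-medoids (PAM, classic BUILD + SWAP) on symmetrized Kullback-Leibler
  divergences, with the number of clusters chosen by the gap statistic;
* agglomerative hierarchical clustering with uncentered-correlation
  distance and complete linkage.

Clusters are labeled early / middle / late from the peak time of their
medoid, and labelings from two conditions (or two phages, via an ortholog
map) are compared by simple agreement.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

KL_EPS = 1e-6


class ClusteringError(ValueError):
    pass


# ---------------------------------------------------------------------------
# profiles and distances


def to_simplex(profiles: pd.DataFrame, eps: float = KL_EPS) -> pd.DataFrame:
    """Rescale each row to a probability vector (pseudocount then renormalize)."""
    arr = profiles.to_numpy(dtype=float) + eps
    if (arr < 0).any():
        raise ClusteringError("negative profile entries")
    return pd.DataFrame(
        arr / arr.sum(axis=1, keepdims=True),
        index=profiles.index,
        columns=profiles.columns,
    )


def kl_distance(p: np.ndarray, q: np.ndarray, eps: float = KL_EPS) -> float:
    """Symmetrized (Jeffreys) KL divergence, base-2 logs.

    d(p, q) = 1/2 [KL(p||q) + KL(q||p)] after adding a pseudocount and
    renormalizing; zero iff p == q.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ClusteringError("length mismatch")
    p = (p + eps) / (p + eps).sum()
    q = (q + eps) / (q + eps).sum()
    lr = np.log2(p / q)
    return float(0.5 * (np.sum(p * lr) - np.sum(q * lr)))


def kl_distance_matrix(profiles: pd.DataFrame, eps: float = KL_EPS) -> np.ndarray:
    """Pairwise symmetrized KL divergences between simplex rows."""
    p = to_simplex(profiles, eps).to_numpy()
    logp = np.log2(p)
    self_terms = np.sum(p * logp, axis=1)
    cross = p @ logp.T
    kl = self_terms[:, None] - cross  # kl[i, j] = KL(p_i || p_j)
    d = 0.5 * (kl + kl.T)
    np.fill_diagonal(d, 0.0)
    return np.maximum(d, 0.0)


# ---------------------------------------------------------------------------
# PAM


@dataclass
class ClusteringResult:
    k: int
    medoids: list[int]  # indices into the profile order
    assignment: np.ndarray  # gene -> medoid position (0..k-1)
    cost: float
    gene_ids: list[str] = field(default_factory=list)
    timing: dict[int, str] = field(default_factory=dict)  # cluster -> label

    def labels(self) -> pd.Series:
        """Per-gene timing label (requires label_timing to have run)."""
        return pd.Series(
            [self.timing[c] for c in self.assignment], index=self.gene_ids
        )


def _total_cost(d: np.ndarray, medoids: np.ndarray) -> tuple[float, np.ndarray]:
    sub = d[:, medoids]
    assign = np.argmin(sub, axis=1)
    cost = float(sub[np.arange(len(d)), assign].sum())
    return cost, assign


def _build_init(d: np.ndarray, k: int) -> list[int]:
    """Greedy BUILD: 1-medoid optimum first, then maximal-gain additions."""
    n = len(d)
    medoids = [int(np.argmin(d.sum(axis=1)))]
    while len(medoids) < k:
        current = d[:, medoids].min(axis=1)
        best_gain, best_j = -np.inf, None
        for j in range(n):
            if j in medoids:
                continue
            gain = np.maximum(current - d[:, j], 0.0).sum()
            if gain > best_gain + 1e-12:
                best_gain, best_j = gain, j
        medoids.append(best_j)
    return sorted(medoids)


def _swap_descent(
    d: np.ndarray, medoids: list[int], history: list[float] | None = None
) -> tuple[list[int], float]:
    """Best-improvement SWAP until 1-swap-optimal; lowest index wins ties.

    If ``history`` is given, the cost after each accepted swap is appended
    (starting with the initial cost) — the sequence is strictly decreasing.
    """
    n = len(d)
    medoids = sorted(medoids)
    cost, _ = _total_cost(d, np.array(medoids))
    if history is not None:
        history.append(cost)
    improved = True
    while improved:
        improved = False
        best = (cost, None, None)
        med_arr = np.array(medoids)
        is_medoid = np.zeros(n, dtype=bool)
        is_medoid[med_arr] = True
        for mi in range(len(medoids)):
            others = np.delete(med_arr, mi)
            if len(others):
                dmin_wo = d[:, others].min(axis=1)
            else:
                dmin_wo = np.full(n, np.inf)
            # cost of replacing medoid mi by each candidate j, vectorized
            costs = np.minimum(dmin_wo[:, None], d).sum(axis=0)
            costs[is_medoid] = np.inf
            j = int(np.argmin(costs))  # lowest index wins ties
            if costs[j] < best[0] - 1e-12:
                best = (float(costs[j]), mi, j)
        if best[1] is not None:
            cost, mi, j = best
            medoids[mi] = j
            medoids = sorted(medoids)
            improved = True
            if history is not None:
                history.append(cost)
    return medoids, cost


def pam(d: np.ndarray, k: int, seed: int = 0, n_restarts: int = 8) -> ClusteringResult:
    """Partitioning around medoids: BUILD + SWAP with seeded restarts.

    The SWAP descent accepts the best strictly-improving medoid/non-medoid
    exchange until none exists (1-swap-optimal).  Because the descent can
    stall in a local optimum, it is additionally started from
    ``n_restarts`` seeded random medoid sets; the lowest-cost final
    configuration wins (ties broken toward lexicographically smallest
    medoid set).  Deterministic given the seed.
    """
    d = np.asarray(d, dtype=float)
    n = len(d)
    if d.shape != (n, n):
        raise ClusteringError("distance matrix must be square")
    if not (1 <= k <= n):
        raise ClusteringError(f"k={k} outside [1, {n}]")

    rng = np.random.default_rng(seed)
    inits = [_build_init(d, k)]
    for _ in range(n_restarts):
        inits.append(sorted(rng.choice(n, size=k, replace=False).tolist()))

    best_medoids, best_cost = None, np.inf
    for init in inits:
        medoids, cost = _swap_descent(d, init)
        if cost < best_cost - 1e-12 or (
            abs(cost - best_cost) <= 1e-12
            and (best_medoids is None or medoids < best_medoids)
        ):
            best_medoids, best_cost = medoids, cost

    cost, assign = _total_cost(d, np.array(best_medoids))
    return ClusteringResult(
        k=k, medoids=list(best_medoids), assignment=assign, cost=cost
    )


def pam_exhaustive(d: np.ndarray, k: int) -> ClusteringResult:
    """Globally optimal k-medoids by enumerating all medoid subsets.

    Only feasible for small n; used as the oracle for PAM."""
    d = np.asarray(d, dtype=float)
    n = len(d)
    best = None
    for subset in combinations(range(n), k):
        c, assign = _total_cost(d, np.array(subset))
        if best is None or c < best[0] - 1e-12:
            best = (c, subset, assign)
    cost, medoids, assign = best
    return ClusteringResult(k=k, medoids=list(medoids), assignment=assign, cost=cost)


# ---------------------------------------------------------------------------
# gap statistic


@dataclass
class GapCurve:
    k_values: list[int]
    log_wk: list[float]
    ref_log_wk_mean: list[float]
    gap: list[float]
    se: list[float]
    chosen_k: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "k": self.k_values,
                "log_Wk": self.log_wk,
                "ref_log_Wk": self.ref_log_wk_mean,
                "gap": self.gap,
                "se": self.se,
            }
        )


def gap_select_k(
    profiles: pd.DataFrame,
    k_range: range | list[int] = range(1, 9),
    b_reference: int = 50,
    seed: int = 0,
    eps: float = KL_EPS,
) -> tuple[GapCurve, ClusteringResult]:
    """Choose k for PAM-on-KL by the gap statistic.

    W_k is the PAM total cost (sum of KL distances to medoids).  Reference
    datasets are drawn uniformly within the observed per-coordinate range of
    the simplex profiles and renormalized to the simplex.  The chosen k is
    the smallest k with Gap(k) >= Gap(k+1) - se(k+1) (one-standard-error
    rule); degenerate all-identical profiles yield k = 1.
    """
    if b_reference < 10:
        raise ClusteringError("need at least 10 reference datasets")
    k_values = sorted(k_range)
    simplex = to_simplex(profiles, eps)
    arr = simplex.to_numpy()
    n = len(arr)
    rng = np.random.default_rng(seed)

    d = kl_distance_matrix(profiles, eps)
    if np.allclose(d, 0.0):
        res = pam(d, 1)
        res.gene_ids = list(profiles.index)
        curve = GapCurve([1], [-np.inf], [-np.inf], [0.0], [0.0], 1)
        return curve, res

    tiny = 1e-12

    def log_wk_of(dist: np.ndarray, k: int) -> float:
        return float(np.log(pam(dist, k).cost + tiny))

    log_wk = [log_wk_of(d, k) for k in k_values]

    lo = arr.min(axis=0)
    hi = arr.max(axis=0)
    ref_logs = np.empty((b_reference, len(k_values)))
    for b in range(b_reference):
        ref = rng.uniform(lo, hi, size=arr.shape)
        ref = ref / ref.sum(axis=1, keepdims=True)
        dref = kl_distance_matrix(
            pd.DataFrame(ref), eps
        )
        for ki, k in enumerate(k_values):
            ref_logs[b, ki] = log_wk_of(dref, k)

    ref_mean = ref_logs.mean(axis=0)
    gap = ref_mean - np.array(log_wk)
    se = ref_logs.std(axis=0, ddof=1) * np.sqrt(1.0 + 1.0 / b_reference)

    chosen = k_values[-1]
    for ki in range(len(k_values) - 1):
        if gap[ki] >= gap[ki + 1] - se[ki + 1]:
            chosen = k_values[ki]
            break

    result = pam(d, chosen)
    result.gene_ids = list(profiles.index)
    curve = GapCurve(
        k_values=list(k_values),
        log_wk=list(map(float, log_wk)),
        ref_log_wk_mean=list(map(float, ref_mean)),
        gap=list(map(float, gap)),
        se=list(map(float, se)),
        chosen_k=chosen,
    )
    return curve, result


# ---------------------------------------------------------------------------
# hierarchical clustering


def uncentered_correlation_distance(profiles: pd.DataFrame) -> np.ndarray:
    """1 - sum(x*y) / sqrt(sum(x^2) * sum(y^2)); zero vectors get distance 1."""
    x = profiles.to_numpy(dtype=float)
    norms = np.sqrt((x**2).sum(axis=1))
    sim = x @ x.T
    denom = np.outer(norms, norms)
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(denom > 0, sim / denom, 0.0)
    d = 1.0 - sim
    np.fill_diagonal(d, 0.0)
    return np.clip(d, 0.0, 2.0)


def hierarchical_cluster(
    profiles: pd.DataFrame, n_clusters: int | None = None
) -> tuple[np.ndarray, pd.Series]:
    """Complete-linkage agglomeration on uncentered-correlation distances.

    Returns the scipy linkage matrix and (if ``n_clusters`` given) flat
    cluster assignments, else assignments at the default of 3 clusters.
    """
    if len(profiles) < 2:
        raise ClusteringError("need at least 2 profiles")
    d = uncentered_correlation_distance(profiles)
    z = hierarchy.linkage(squareform(d, checks=False), method="complete")
    k = n_clusters or 3
    flat = hierarchy.fcluster(z, t=k, criterion="maxclust")
    return z, pd.Series(flat, index=profiles.index)


def dendrogram_newick(z: np.ndarray, leaf_ids: list[str]) -> str:
    """Render a scipy linkage matrix as a Newick string."""
    from skbio.tree import TreeNode

    tree = TreeNode.from_linkage_matrix(z, leaf_ids)
    return str(tree)


# ---------------------------------------------------------------------------
# timing labels and concordance


def label_timing(
    result: ClusteringResult,
    profiles: pd.DataFrame,
    time_points: list[float],
    late_threshold: float = 4.5,
) -> ClusteringResult:
    """Label each cluster from its medoid's peak time.

    Peak at the first time point -> early; peak at or after
    ``late_threshold`` hours -> late; otherwise middle.  Several clusters
    may share a label.
    """
    if len(time_points) < 3:
        raise ClusteringError("need >= 3 time points to call timing")
    t = np.asarray(time_points, dtype=float)
    arr = profiles.to_numpy(dtype=float)
    for ci, m in enumerate(result.medoids):
        peak_t = t[int(np.argmax(arr[m]))]
        if peak_t == t[0]:
            label = "early"
        elif peak_t >= late_threshold:
            label = "late"
        else:
            label = "middle"
        result.timing[ci] = label
    result.gene_ids = list(profiles.index)
    return result


def cluster_concordance(
    labels_a: pd.Series,
    labels_b: pd.Series,
    gene_mapping: dict[str, str] | None = None,
) -> float:
    """Fraction of mapped genes whose timing labels agree.

    ``gene_mapping`` maps keys of ``labels_a`` to keys of ``labels_b``
    (identity if omitted, e.g. light vs dark of the same phage; an ortholog
    table for cross-phage comparison)."""
    if gene_mapping is None:
        shared = labels_a.index.intersection(labels_b.index)
        gene_mapping = {g: g for g in shared}
    if not gene_mapping:
        raise ClusteringError("empty gene mapping")
    agree = sum(
        1 for a, b in gene_mapping.items() if labels_a[a] == labels_b[b]
    )
    return agree / len(gene_mapping)


def temporal_profiles(
    norm_values: pd.DataFrame,
    samples: pd.DataFrame,
    light: str,
    infected: str = "infected",
    orientation: str = "sense",
    min_mean: float = 0.0,
) -> pd.DataFrame:
    """Replicate-averaged per-time-point profiles for one condition.

    Input is a normalized matrix slice; rows are (feature_id, orientation).
    Genes whose across-time mean is below ``min_mean`` are dropped (they
    carry no usable temporal shape).
    """
    sel = samples[(samples["light"] == light) & (samples["infected"] == infected)]
    vals = norm_values.xs(orientation, level="orientation")[sel.index]
    by_time = {}
    for t, group in sel.groupby("time_h"):
        by_time[t] = vals[group.index].mean(axis=1)
    prof = pd.DataFrame(by_time).sort_index(axis=1)
    return prof.loc[prof.mean(axis=1) >= min_mean]
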