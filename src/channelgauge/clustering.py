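"""Average-linkage RMSD clustering of trajectory frames with quality metrics.

Frames are compared by pairwise backbone RMSD after per-pair superposition
(typically on the pore-lining S6 helix backbone), clustered agglomeratively
with unweighted average linkage (UPGMA), and the cluster count chosen in two
stages: a scan over k with the Davies–Bouldin index and the explained
variance (SSR/SST) elbow, then an optional user override per system.

Because RMSD space carries no coordinates, cluster scatter and separation
use the medoid formulation: S_i is the mean distance of members to the
cluster medoid and M_ij the medoid–medoid distance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .metrics import kabsch_superpose
from .structure import SelectionSpec, Trajectory, resolve_selection

__all__ = [
    "DistanceMatrix",
    "ClusterResult",
    "pairwise_rmsd",
    "average_linkage",
    "davies_bouldin",
    "percent_variance",
    "choose_k",
    "representative_frames",
    "cluster_trajectory",
]


@dataclass
class DistanceMatrix:
    """Condensed pairwise frame RMSD matrix (Å)."""

    n_frames: int
    condensed: np.ndarray
    stride: int = 1
    frame_indices: np.ndarray | None = None

    def __post_init__(self) -> None:
        expect = self.n_frames * (self.n_frames - 1) // 2
        if self.condensed.shape != (expect,):
            raise ValueError(
                f"condensed length {self.condensed.shape} != n(n-1)/2 = {expect}"
            )

    def full(self) -> np.ndarray:
        from scipy.spatial.distance import squareform

        return squareform(self.condensed)


@dataclass
class ClusterResult:
    labels: np.ndarray
    k: int
    dbi_by_k: dict[int, float]
    ssr_sst_by_k: dict[int, float]
    chosen_k: int
    chosen_rule: str
    representatives: dict[int, int]
    populations: list[tuple[int, int]]  # (cluster, size) sorted descending
    stride: int = 1


def pairwise_rmsd(
    traj: Trajectory,
    sel: SelectionSpec,
    *,
    stride: int = 1,
    mass_weighted: bool = False,
) -> DistanceMatrix:
    """Condensed pairwise RMSD over (strided) frames on a selection.

    Every pair is superposed on the selection before measuring (fit =
    measure = selection), so frames differing only by rigid motion are at
    distance zero. A stride (default in the pipeline: 10) keeps the O(n²)
    matrix tractable for long trajectories and is recorded in the result.
    """
    idx = resolve_selection(traj.topology, sel)
    if idx.size == 0:
        raise ValueError("empty selection")
    which = np.arange(0, traj.n_frames, stride)
    sub = traj.frames[np.ix_(which, idx)]
    weights = traj.topology.masses[idx] if mass_weighted else None
    n = sub.shape[0]
    out = np.empty(n * (n - 1) // 2)
    pos = 0
    for i in range(n - 1):
        for j in range(i + 1, n):
            out[pos] = kabsch_superpose(sub[j], sub[i], weights).rmsd
            pos += 1
    return DistanceMatrix(n_frames=n, condensed=out, stride=stride, frame_indices=which)


def _cluster_key(members: frozenset[int]) -> int:
    return min(members)


def average_linkage(D: DistanceMatrix, k: int) -> np.ndarray:
    """Cut an unweighted average-linkage (UPGMA) agglomeration at k clusters.

    At each step the pair of clusters with the smallest mean inter-cluster
    RMSD merges; ties break on the smallest (i, j) pair of cluster indices,
    where a cluster is indexed by its smallest member frame. Labels are
    0..k-1 in order of smallest member.
    """
    n = D.n_frames
    if not 1 <= k <= n:
        raise ValueError(f"k={k} out of range [1, {n}]")
    full = D.full()
    clusters: dict[int, frozenset[int]] = {i: frozenset([i]) for i in range(n)}
    # dist[(a, b)] = mean pairwise distance between clusters keyed a < b
    dist: dict[tuple[int, int], float] = {}
    for i in range(n - 1):
        for j in range(i + 1, n):
            dist[(i, j)] = full[i, j]

    while len(clusters) > k:
        best = min(dist.items(), key=lambda kv: (kv[1], kv[0]))
        (a, b), _ = best
        na, nb = len(clusters[a]), len(clusters[b])
        merged = clusters[a] | clusters[b]
        del clusters[a], clusters[b]
        new_key = min(a, b)
        # Lance-Williams update for UPGMA: size-weighted mean of the two.
        for c in list(clusters):
            da = dist.pop((min(a, c), max(a, c)))
            db = dist.pop((min(b, c), max(b, c)))
            dist[(min(new_key, c), max(new_key, c))] = (na * da + nb * db) / (na + nb)
        dist.pop((a, b), None)
        clusters[new_key] = merged

    labels = np.empty(n, dtype=int)
    for lab, key in enumerate(sorted(clusters)):
        for m in clusters[key]:
            labels[m] = lab
    return labels


def _medoid(full: np.ndarray, members: np.ndarray) -> int:
    sub = full[np.ix_(members, members)]
    mean_d = sub.mean(axis=1)
    return int(members[int(np.argmin(mean_d))])  # ties: smallest index


def davies_bouldin(D: DistanceMatrix, labels: np.ndarray) -> float:
    """Davies–Bouldin index in the medoid formulation; lower is better.

    DBI = (1/k) Σ_i max_{j≠i} (S_i + S_j) / M_ij with S_i the mean member →
    medoid distance and M_ij the medoid–medoid distance. A singleton cluster
    contributes S = 0; coincident medoids are degenerate and raise.
    """
    full = D.full()
    ks = np.unique(labels)
    if ks.size < 2:
        raise ValueError("DBI needs k >= 2")
    medoids, scatters = [], []
    for c in ks:
        members = np.flatnonzero(labels == c)
        m = _medoid(full, members)
        medoids.append(m)
        scatters.append(full[m, members].mean())
    total = 0.0
    for i in range(ks.size):
        worst = 0.0
        for j in range(ks.size):
            if i == j:
                continue
            M = full[medoids[i], medoids[j]]
            if M <= 0:
                raise ValueError("degenerate clusters: coincident medoids")
            worst = max(worst, (scatters[i] + scatters[j]) / M)
        total += worst
    return total / ks.size


def percent_variance(D: DistanceMatrix, labels: np.ndarray) -> float:
    """Explained fraction of pairwise variance, SSR/SST in [0, 1].

    SST = Σ_{all pairs} d²/n; SSE = Σ_clusters Σ_{within pairs} d²/|c|;
    SSR = SST − SSE. k=1 gives 0, an all-singleton labeling gives 1.
    """
    full = D.full()
    n = D.n_frames
    sst = (full**2).sum() / 2 / n
    if sst == 0:
        return 0.0
    sse = 0.0
    for c in np.unique(labels):
        members = np.flatnonzero(labels == c)
        sub = full[np.ix_(members, members)]
        sse += (sub**2).sum() / 2 / members.size
    return float((sst - sse) / sst)


@dataclass
class KChoice:
    chosen_k: int
    rule: str  # "dbi_min+plateau" | "no_plateau"
    trace: list[dict] = field(default_factory=list)


def choose_k(
    dbi_by_k: dict[int, float],
    ssr_by_k: dict[int, float],
    *,
    plateau_threshold: float = 0.01,
) -> KChoice:
    """Two-criterion cluster-count choice with a full trace.

    The chosen k is the smallest that is a local DBI minimum AND whose
    SSR/SST gain to the next scanned k falls below ``plateau_threshold``
    (the variance curve has plateaued). If no k satisfies both, the best-DBI
    k is returned with status "no_plateau" so a per-system override can be
    applied in stage two.
    """
    ks = sorted(dbi_by_k)
    trace = []
    chosen = None
    for idx, k in enumerate(ks):
        dbi = dbi_by_k[k]
        prev_dbi = dbi_by_k[ks[idx - 1]] if idx > 0 else None
        next_dbi = dbi_by_k[ks[idx + 1]] if idx + 1 < len(ks) else None
        local_min = ((prev_dbi is None or dbi < prev_dbi)
                     and (next_dbi is None or dbi <= next_dbi))
        if idx + 1 < len(ks):
            gain = ssr_by_k[ks[idx + 1]] - ssr_by_k[k]
            plateau = gain < plateau_threshold
        else:
            gain, plateau = None, False
        trace.append({"k": k, "dbi": dbi, "ssr_sst": ssr_by_k[k],
                      "local_min": local_min, "ssr_gain": gain, "plateau": plateau})
        if chosen is None and local_min and plateau:
            chosen = k
    if chosen is not None:
        return KChoice(chosen_k=chosen, rule="dbi_min+plateau", trace=trace)
    best = min(ks, key=lambda k: (dbi_by_k[k], k))
    return KChoice(chosen_k=best, rule="no_plateau", trace=trace)


def representative_frames(D: DistanceMatrix, labels: np.ndarray) -> dict[int, int]:
    """Per cluster, the frame minimizing mean distance to co-members (medoid).

    Ties resolve to the smallest frame index; singletons represent themselves.
    """
    full = D.full()
    return {
        int(c): _medoid(full, np.flatnonzero(labels == c)) for c in np.unique(labels)
    }


def cluster_trajectory(
    traj: Trajectory,
    sel: SelectionSpec,
    *,
    k_scan: range | None = None,
    k_override: int | None = None,
    stride: int = 10,
    plateau_threshold: float = 0.01,
    mass_weighted: bool = False,
) -> ClusterResult:
    """Full two-stage clustering of a trajectory on a selection.

    Stage one scans k over ``k_scan`` (default 2..min(100, n−1)) computing
    DBI and SSR/SST per k; stage two accepts ``k_override`` (the per-system
    custom count) or falls back to :func:`choose_k`.
    """
    D = pairwise_rmsd(traj, sel, stride=stride, mass_weighted=mass_weighted)
    n = D.n_frames
    if k_scan is None:
        k_scan = range(2, min(100, n - 1) + 1)
    dbi_by_k: dict[int, float] = {}
    ssr_by_k: dict[int, float] = {}
    labels_by_k: dict[int, np.ndarray] = {}
    for k in k_scan:
        if not 2 <= k <= n:
            continue
        labels = average_linkage(D, k)
        labels_by_k[k] = labels
        try:
            dbi_by_k[k] = davies_bouldin(D, labels)
        except ValueError:
            dbi_by_k[k] = np.inf
        ssr_by_k[k] = percent_variance(D, labels)
    choice = choose_k(dbi_by_k, ssr_by_k, plateau_threshold=plateau_threshold)
    k_final = k_override if k_override is not None else choice.chosen_k
    labels = labels_by_k.get(k_final)
    if labels is None:
        labels = average_linkage(D, k_final)
    reps = representative_frames(D, labels)
    pops = sorted(
        ((int(c), int(np.sum(labels == c))) for c in np.unique(labels)),
        key=lambda t: (-t[1], t[0]),
    )
    return ClusterResult(
        labels=labels,
        k=k_final,
        dbi_by_k=dbi_by_k,
        ssr_sst_by_k=ssr_by_k,
        chosen_k=choice.chosen_k,
        chosen_rule=choice.rule,
        representatives=reps,
        populations=pops,
        stride=D.stride,
    )
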