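"""Scenario subset selection: standardize, Ward-seed, k-means, Rsq, representatives.

The selection algorithm proceeds in five steps:

1. standardize the delta variables and build a Euclidean distance matrix;
2. agglomerate with Ward's minimum-variance criterion;
3. cut the tree at k and take group centroids as seeds;
4. refine by k-means (Lloyd) from the hierarchical seeds plus many random
   restarts, keeping the partition with minimal within-cluster SS;
5. score the partition by Rsq = between-SS / total-SS.

Repeating 3-5 over k gives an Rsq profile from which an operating k is
chosen by a linear cost-benefit rule, and each cluster contributes the
member nearest its centroid as the representative scenario, weighted by
cluster size.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .errors import ComputationError, ValidationError
from .scenario_io import ScenarioTable

log = logging.getLogger("scenoset.clustering")


# ---------------------------------------------------------------------------
# Step 1: standardization and distances
# ---------------------------------------------------------------------------

@dataclass
class StandardizedMatrix:
    """Column-wise z-scores of the delta matrix plus the back-transform parameters."""

    values: np.ndarray           # n x p
    column_means: np.ndarray     # p
    column_sds: np.ndarray       # p, sample SD (ddof=1)
    variables: list[str]
    labels: list[str]            # scenario labels, row order

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def destandardize(self, Z: np.ndarray) -> np.ndarray:
        """Map points from z-score space back to the original delta units."""
        return np.asarray(Z) * self.column_sds + self.column_means


def standardize(table: ScenarioTable) -> StandardizedMatrix:
    """Z-score each delta column with the sample SD (n-1 denominator)."""
    if len(table) < 2:
        raise ValidationError("standardization needs at least 2 scenarios")
    X = table.delta_matrix()
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1)
    zero = np.flatnonzero(sds == 0)
    if zero.size:
        names = [table.variables[j] for j in zero]
        raise ValidationError(f"constant delta column(s) {names}: cannot standardize")
    return StandardizedMatrix((X - means) / sds, means, sds, list(table.variables),
                              table.labels)


def euclidean_distance_matrix(Z: StandardizedMatrix | np.ndarray) -> np.ndarray:
    """Full symmetric matrix of pairwise Euclidean distances."""
    V = Z.values if isinstance(Z, StandardizedMatrix) else np.asarray(Z, dtype=float)
    return squareform(pdist(V, metric="euclidean"))


# ---------------------------------------------------------------------------
# Step 2: Ward agglomeration (Lance-Williams on Euclidean distances)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Merge:
    members_a: frozenset
    members_b: frozenset
    height: float

    @property
    def members(self) -> frozenset:
        return self.members_a | self.members_b


@dataclass
class MergeTree:
    """The n-1 agglomeration events of a Ward clustering, in merge order."""

    n: int
    merges: list[Merge]

    def cut(self, k: int) -> np.ndarray:
        """Labels in 1..k after the first n-k merges; label 1 holds object 0."""
        if not 1 <= k <= self.n:
            raise ValidationError(f"k={k} out of range 1..{self.n}")
        parent = list(range(self.n))

        def find(a: int) -> int:
            while parent[a] != a:
                parent[a] = parent[parent[a]]
                a = parent[a]
            return a

        for m in self.merges[: self.n - k]:
            ra = find(min(m.members_a))
            rb = find(min(m.members_b))
            parent[max(ra, rb)] = min(ra, rb)
        labels = np.empty(self.n, dtype=int)
        relabel: dict[int, int] = {}
        for i in range(self.n):
            r = find(i)
            if r not in relabel:
                relabel[r] = len(relabel) + 1
            labels[i] = relabel[r]
        return labels


def ward_tree(D: np.ndarray) -> MergeTree:
    """Ward minimum-variance agglomeration of a Euclidean distance matrix.

    At every step the pair of clusters whose merge least increases the total
    within-cluster sum of squares is fused; inter-cluster distances are
    updated with the Lance-Williams recurrence on squared distances, so merge
    heights h satisfy h^2 = 2 * delta-SS and are non-decreasing.  Ties break
    on the smallest cluster-index pair for determinism.
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if D.shape != (n, n) or n < 2:
        raise ValidationError("ward_tree needs a square distance matrix with n >= 2")
    d2 = D.astype(float) ** 2
    size = np.ones(n)
    members: list[frozenset | None] = [frozenset({i}) for i in range(n)]
    active = np.ones(n, dtype=bool)
    merges: list[Merge] = []
    for _ in range(n - 1):
        best = (math.inf, -1, -1)
        idx = np.flatnonzero(active)
        for a_pos, i in enumerate(idx):
            for j in idx[a_pos + 1:]:
                if d2[i, j] < best[0] - 1e-15:
                    best = (d2[i, j], i, j)
        _, i, j = best
        h = math.sqrt(max(d2[i, j], 0.0))
        merges.append(Merge(members[i], members[j], h))
        si, sj = size[i], size[j]
        for v in idx:
            if v == i or v == j:
                continue
            sv = size[v]
            new = ((si + sv) * d2[i, v] + (sj + sv) * d2[j, v] - sv * d2[i, j]) / (
                si + sj + sv
            )
            d2[i, v] = d2[v, i] = new
        members[i] = members[i] | members[j]
        members[j] = None
        size[i] = si + sj
        active[j] = False
    return MergeTree(n, merges)


def seeds_from_tree(tree: MergeTree, Z: StandardizedMatrix, k: int) -> np.ndarray:
    """Centroids of the k tree-cut groups, in label order, standardized space."""
    labels = tree.cut(k)
    V = Z.values
    return np.array([V[labels == j].mean(axis=0) for j in range(1, k + 1)])


# ---------------------------------------------------------------------------
# Steps 3-5: k-means refinement and Rsq
# ---------------------------------------------------------------------------

@dataclass
class ClusterSolution:
    """A k-means partition at a Lloyd fixed point, with its sums of squares."""

    k: int
    assignment: np.ndarray       # per-object label in 1..k
    centroids: np.ndarray        # k x p, standardized space, label order
    within_ss: float
    between_ss: float
    total_ss: float
    rsq: float
    restarts_used: int

    def sizes(self) -> np.ndarray:
        """Cluster cardinalities nk_j in label order."""
        return np.bincount(self.assignment, minlength=self.k + 1)[1:]


def _restart_rng(rng_seed: int, k: int, r: int) -> np.random.Generator:
    # counter-based split: each (k, restart) pair gets an independent stream
    return np.random.default_rng(np.random.SeedSequence(rng_seed, spawn_key=(k, r)))


def _lloyd_batch(V: np.ndarray, inits: np.ndarray, max_iter: int = 300):
    """Run Lloyd's algorithm on a batch of initial centroid sets in lockstep.

    Empty clusters are repaired by relocating the empty centroid onto the
    point farthest from its currently assigned centroid, so every returned
    partition occupies exactly k labels.  Returns (labels, centroids, wss)
    with shapes (B, n), (B, k, p), (B,).
    """
    n, p = V.shape
    B, k, _ = inits.shape
    C = inits.astype(float).copy()
    labels = np.full((B, n), -1, dtype=int)
    eye = np.eye(k)
    for _ in range(max_iter):
        d2 = ((V[None, :, None, :] - C[:, None, :, :]) ** 2).sum(-1)  # B x n x k
        new_labels = d2.argmin(-1)
        counts = (new_labels[:, :, None] == np.arange(k)).sum(1)      # B x k
        eb, ej = np.nonzero(counts == 0)
        for b, j in zip(eb, ej):
            # relocate onto the point farthest from its assigned centroid,
            # never robbing a singleton cluster, so one pass cannot cascade
            own = d2[b, np.arange(n), new_labels[b]].copy()
            sizes = np.bincount(new_labels[b], minlength=k)
            own[sizes[new_labels[b]] <= 1] = -np.inf
            new_labels[b, int(own.argmax())] = j
        if (new_labels == labels).all():
            break
        labels = new_labels
        onehot = eye[labels]                                # B x n x k
        counts = onehot.sum(1)
        C = np.einsum("bnk,np->bkp", onehot, V) / counts[..., None]
    d2 = ((V[None, :, None, :] - C[:, None, :, :]) ** 2).sum(-1)
    wss = np.take_along_axis(d2, labels[..., None], axis=-1)[..., 0].sum(1)
    return labels, C, wss


def _solution_from_labels(V: np.ndarray, raw_labels: np.ndarray, k: int,
                          restarts_used: int) -> ClusterSolution:
    # relabel clusters 1..k by first appearance in data order (deterministic)
    relabel: dict[int, int] = {}
    assignment = np.empty(len(raw_labels), dtype=int)
    for i, lab in enumerate(raw_labels):
        if lab not in relabel:
            relabel[lab] = len(relabel) + 1
        assignment[i] = relabel[lab]
    if len(relabel) != k:
        raise ComputationError(f"partition occupies {len(relabel)} of {k} clusters")
    centroids = np.array([V[assignment == j].mean(axis=0) for j in range(1, k + 1)])
    grand = V.mean(axis=0)
    within = float(sum(((V[assignment == j] - centroids[j - 1]) ** 2).sum()
                       for j in range(1, k + 1)))
    sizes = np.bincount(assignment, minlength=k + 1)[1:]
    between = float((sizes[:, None] * (centroids - grand) ** 2).sum())
    total = float(((V - grand) ** 2).sum())
    if total <= 0:
        raise ComputationError("total sum of squares is zero: degenerate data")
    rsq = between / total
    return ClusterSolution(k, assignment, centroids, within, between, total,
                           min(max(rsq, 0.0), 1.0), restarts_used)


def kmeans_refine(Z: StandardizedMatrix, seeds: np.ndarray, restarts: int = 999,
                  rng_seed: int = 0,
                  extra_inits: list[np.ndarray] | None = None) -> ClusterSolution:
    """Best-of k-means: hierarchical seeds plus `restarts` random initializations.

    Every initialization is run to a Lloyd fixed point; the partition with
    the smallest within-cluster SS wins (ties prefer the hierarchical-seed
    run).  The result never has larger within-SS than the hierarchical-seed
    partition, since that run is always included.
    """
    V = Z.values
    seeds = np.atleast_2d(np.asarray(seeds, dtype=float))
    k = seeds.shape[0]
    n = V.shape[0]
    if k > n:
        raise ValidationError(f"k={k} exceeds n={n}")
    if restarts < 0:
        raise ValidationError("restarts must be >= 0")
    inits = [seeds]
    if extra_inits:
        inits.extend(np.atleast_2d(np.asarray(e, dtype=float)) for e in extra_inits)
    for r in range(restarts):
        rng = _restart_rng(rng_seed, k, r)
        inits.append(V[rng.choice(n, size=k, replace=False)])
    labels, _, wss = _lloyd_batch(V, np.stack(inits))
    best = int(np.argmin(np.round(wss, 12)))  # ties -> earliest (hierarchical seed)
    return _solution_from_labels(V, labels[best], k, restarts)


@dataclass
class RsqProfile:
    """Rsq as a function of k, for k = 1..k_max."""

    rsq: dict[int, float]

    @property
    def k_max(self) -> int:
        return max(self.rsq)

    def as_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        ks = np.array(sorted(self.rsq))
        return ks, np.array([self.rsq[k] for k in ks])


def _split_widest_init(V: np.ndarray, prev: ClusterSolution) -> np.ndarray:
    """Seeds for k+1: previous centroids plus the farthest point of the widest cluster."""
    worst, far = -1.0, 0
    for j in range(1, prev.k + 1):
        idx = np.flatnonzero(prev.assignment == j)
        d = ((V[idx] - prev.centroids[j - 1]) ** 2).sum(1)
        if d.sum() > worst:
            worst, far = d.sum(), idx[int(d.argmax())]
    return np.vstack([prev.centroids, V[far]])


def rsq_profile(Z: StandardizedMatrix, k_max: int | None = None, restarts: int = 999,
                rng_seed: int = 0,
                tree: MergeTree | None = None) -> tuple[RsqProfile, dict[int, ClusterSolution]]:
    """Compute Rsq(k) for k = 1..k_max with Ward-seeded, restarted k-means.

    Monotonicity is encouraged by also seeding each k with the (k-1)-solution
    split at its widest cluster; a residual finite-restart dip is rectified
    to the running maximum with a logged warning.  Returns the profile and
    the per-k solutions.
    """
    n = Z.n
    k_max = n if k_max is None else k_max
    if not 1 <= k_max <= n:
        raise ValidationError(f"k_max={k_max} out of range 1..{n}")
    if tree is None:
        tree = ward_tree(euclidean_distance_matrix(Z))
    profile: dict[int, float] = {}
    solutions: dict[int, ClusterSolution] = {}
    prev: ClusterSolution | None = None
    running = 0.0
    for k in range(1, k_max + 1):
        seeds = seeds_from_tree(tree, Z, k)
        extra = [_split_widest_init(Z.values, prev)] if prev is not None else None
        sol = kmeans_refine(Z, seeds, restarts=restarts, rng_seed=rng_seed,
                            extra_inits=extra)
        if sol.rsq < running - 1e-12:
            log.warning("Rsq dipped at k=%d (%.6f < %.6f); rectifying to running max",
                        k, sol.rsq, running)
            profile[k] = running
        else:
            running = sol.rsq
            profile[k] = sol.rsq
        solutions[k] = sol
        prev = sol
    return RsqProfile(profile), solutions


def select_k(profile: RsqProfile, cost_weight: float = 1.0) -> int:
    """Choose k maximizing net benefit B(k) = Rsq(k) - cost_weight*(k-1)/(k_max-1).

    The cost term is the cluster count normalized to [0, 1] like Rsq itself;
    the chosen k is where marginal benefit first stops paying for marginal
    cost.  Ties go to the smallest k.
    """
    ks, rs = profile.as_arrays()
    if len(ks) == 1:
        return int(ks[0])
    cost = cost_weight * (ks - ks[0]) / (ks[-1] - ks[0])
    benefit = rs - cost
    best = float(benefit.max())
    return int(ks[np.flatnonzero(benefit >= best - 1e-12)[0]])


# ---------------------------------------------------------------------------
# Representatives
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Representative:
    cluster: int
    key: tuple[str, str]
    index: int                    # row index in the scenario table
    size: int                     # nk_j
    distance: float               # to its cluster centroid, standardized space


@dataclass
class RepresentativeSet:
    """One nearest-to-centroid scenario per cluster, with cluster-size weights."""

    representatives: list[Representative]

    def __post_init__(self) -> None:
        total = sum(r.size for r in self.representatives)
        if total <= 0:
            raise ValidationError("empty representative set")
        self._total = total

    @property
    def n_scenarios(self) -> int:
        return self._total

    @property
    def weights(self) -> np.ndarray:
        """Normalized cluster-size weights nk_j / sum nk; they sum to 1."""
        return np.array([r.size / self._total for r in self.representatives])

    def size_of(self, key: tuple[str, str]) -> int:
        for r in self.representatives:
            if r.key == tuple(key):
                return r.size
        raise ValidationError(f"no representative with key {key}")

    @property
    def keys(self) -> list[tuple[str, str]]:
        return [r.key for r in self.representatives]


def select_representatives(solution: ClusterSolution, Z: StandardizedMatrix,
                           table: ScenarioTable) -> RepresentativeSet:
    """Per cluster, the member nearest the centroid (ties -> earliest table row)."""
    if len(table) != Z.n or len(solution.assignment) != Z.n:
        raise ValidationError("solution, matrix and table sizes disagree")
    reps = []
    for j in range(1, solution.k + 1):
        idx = np.flatnonzero(solution.assignment == j)
        d = np.sqrt(((Z.values[idx] - solution.centroids[j - 1]) ** 2).sum(1))
        pick = idx[int(np.argmin(np.round(d, 12)))]
        reps.append(Representative(j, table.keys[pick], int(pick), len(idx),
                                   float(d.min())))
    return RepresentativeSet(reps)


# ---------------------------------------------------------------------------
# Convenience driver
# ---------------------------------------------------------------------------

@dataclass
class ClusteringResult:
    Z: StandardizedMatrix
    tree: MergeTree
    profile: RsqProfile
    k: int
    solution: ClusterSolution
    representatives: RepresentativeSet


def cluster_scenarios(table: ScenarioTable, k: int | str = "auto", restarts: int = 999,
                      rng_seed: int = 0, cost_weight: float = 1.0) -> ClusteringResult:
    """Run the full selection pipeline on a scenario table."""
    Z = standardize(table)
    tree = ward_tree(euclidean_distance_matrix(Z))
    profile, solutions = rsq_profile(Z, restarts=restarts, rng_seed=rng_seed, tree=tree)
    if k == "auto":
        k_used = select_k(profile, cost_weight=cost_weight)
    else:
        k_used = int(k)
        if not 1 <= k_used <= Z.n:
            raise ValidationError(f"k={k_used} out of range 1..{Z.n}")
    sol = solutions[k_used]
    reps = select_representatives(sol, Z, table)
    return ClusteringResult(Z, tree, profile, k_used, sol, reps)


def result_to_dict(res: ClusteringResult, table: ScenarioTable) -> dict:
    """JSON-serializable export of a clustering run."""
    ks, rs = res.profile.as_arrays()
    return {
        "k": res.k,
        "rsq": res.solution.rsq,
        "restarts": res.solution.restarts_used,
        "assignment": {lab: int(a) for lab, a in zip(table.labels, res.solution.assignment)},
        "cluster_sizes": [int(s) for s in res.solution.sizes()],
        "centroids_standardized": res.solution.centroids.tolist(),
        "centroids_original_units": res.Z.destandardize(res.solution.centroids).tolist(),
        "variables": res.Z.variables,
        "rsq_profile": {int(k): float(r) for k, r in zip(ks, rs)},
        "representatives": [
            {"cluster": r.cluster, "model": r.key[0], "sres": r.key[1],
             "size": r.size, "weight": r.size / res.representatives.n_scenarios,
             "distance_to_centroid": r.distance}
            for r in res.representatives.representatives
        ],
    }
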