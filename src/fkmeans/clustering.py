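"""Hierarchical fractal-penalized K-means++ fibrosis segmentation.

The clustering operates on the voxels of the clipped LA mask.  Each point
carries its 3D position and its fractal dimension (FD); the distance between
a point ``x`` and a centroid ``c`` is

    d(x, c) = sqrt(||x - c||^2 + beta * (FD(x) - FD(c))^2
                              + gamma * (FD(x) - mean FD(c_i))^2)

where ``mean FD(c_i)`` is the mean FD of the points assigned to the cluster
in the previous Lloyd iteration (at iteration 0 it equals FD(c)).  The
penalty weights default to beta = 0.1 and gamma = 0.5.  With
``beta = gamma = 0`` the method reduces exactly to standard K-means++.

Clustering runs at three levels.  Within a level the number of clusters k is
swept upward through the level's range; after each fit the mean and variance
of FD inside the maximum-FD cluster are compared with the previous k's
values, and the sweep stops as soon as either change reaches its threshold
(|d mean| >= tau1 = 0.1 or |d var| >= tau2 = 0.05).  The maximum-FD cluster
of the stopping fit feeds the next level; after the last level it is the
fibrosis segmentation.  Sweeping k until the FD statistics of the candidate
cluster jump is what locks a cluster onto the fibrotic patch: as long as
clusters straddle the patch the statistics drift slowly, and the first k at
which a cluster isolates high-FD tissue produces the jump that selects it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import ValidationError
from .fractal import FDMap
from .io import LabelMask, Volume

logger = logging.getLogger(__name__)

DEFAULT_LEVEL_K_RANGES = ((2, 30), (2, 5), (2, 3))


@dataclass
class ClusterConfig:
    """Parameters of the hierarchical clustering.

    beta, gamma : FD penalty weights in the point-centroid distance
    tau1, tau2 : stopping thresholds on the change of mean / variance of FD
        in the maximum-FD cluster between consecutive k
    level_k_ranges : (k_min, k_max) per hierarchy level
    stop_mode : 'literal' stops when a change *reaches* the threshold;
        'stabilize' stops when the change falls below it
    coord_scale : multiplier applied to voxel coordinates in feature space
    """

    beta: float = 0.1
    gamma: float = 0.5
    tau1: float = 0.1
    tau2: float = 0.05
    level_k_ranges: tuple = DEFAULT_LEVEL_K_RANGES
    max_iter: int = 100
    tol: float = 1e-6
    seed: int = 0
    # coordinates enter the feature space in units of ~30 voxels (about one
    # atrial radius), so the FD penalty terms and spatial distances share
    # scale: coarse levels split spatially, refined levels split on texture
    coord_scale: float = 0.032
    stop_mode: str = "literal"
    use_intensity: bool = False

    def validate(self) -> None:
        if self.beta < 0 or self.gamma < 0:
            raise ValidationError("beta and gamma must be >= 0")
        if self.tau1 <= 0 or self.tau2 <= 0:
            raise ValidationError("tau1 and tau2 must be > 0")
        if len(self.level_k_ranges) != 3:
            raise ValidationError("exactly three hierarchy levels expected")
        for kmin, kmax in self.level_k_ranges:
            if not 1 <= kmin <= kmax:
                raise ValidationError(f"invalid k range ({kmin}, {kmax})")
        if self.stop_mode not in ("literal", "stabilize"):
            raise ValidationError(f"unknown stop_mode {self.stop_mode!r}")


@dataclass
class ClusterState:
    """State of one converged K-means fit."""

    points: np.ndarray          # (N, d) feature-space coordinates
    fd: np.ndarray              # (N,)
    assignments: np.ndarray     # (N,) cluster index
    centroids: np.ndarray       # (k, d)
    centroid_fd: np.ndarray     # (k,)
    cluster_fd_mean: np.ndarray  # (k,)
    cluster_fd_var: np.ndarray   # (k,)
    n_iter: int = 0
    converged: bool = True

    @property
    def k(self) -> int:
        return len(self.centroids)

    def max_fd_cluster(self) -> int:
        return int(np.argmax(self.cluster_fd_mean))


# ---------------------------------------------------------------------------
# distance and seeding
# ---------------------------------------------------------------------------

def fk_distance(x, c, fd_x, fd_c, mean_fd_ci, beta: float = 0.1,
                gamma: float = 0.5) -> float:
    """Penalized point-centroid distance (scalar form)."""
    if beta < 0 or gamma < 0:
        raise ValidationError("beta and gamma must be >= 0")
    x = np.asarray(x, dtype=np.float64)
    c = np.asarray(c, dtype=np.float64)
    return float(np.sqrt(((x - c) ** 2).sum()
                         + beta * (fd_x - fd_c) ** 2
                         + gamma * (fd_x - mean_fd_ci) ** 2))


def _sq_distances(points, fd, centroids, centroid_fd, mean_fd_ci,
                  beta, gamma) -> np.ndarray:
    """(N, k) squared penalized distances, vectorized."""
    d2 = ((points[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
    d2 += beta * (fd[:, None] - centroid_fd[None, :]) ** 2
    d2 += gamma * (fd[:, None] - mean_fd_ci[None, :]) ** 2
    return d2


def kmeanspp_init(points: np.ndarray, fd: np.ndarray, k: int,
                  config: ClusterConfig | None = None,
                  rng: np.random.Generator | None = None) -> np.ndarray:
    """K-means++ seeding under the penalized distance.

    Returns the indices of the chosen points.  Because no clusters exist
    during seeding, the mean-FD penalty uses the FD of the already chosen
    centroid.  Each next centroid is drawn with probability proportional to
    the squared distance to the nearest chosen centroid.
    """
    config = config or ClusterConfig()
    points = np.asarray(points, dtype=np.float64)
    fd = np.asarray(fd, dtype=np.float64)
    n = len(points)
    if k > n:
        raise ValidationError(f"k={k} exceeds the number of points n={n}")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    chosen = [int(rng.integers(n))]
    d2 = _sq_distances(points, fd, points[chosen], fd[chosen],
                       fd[chosen], config.beta, config.gamma)[:, 0]
    while len(chosen) < k:
        total = d2.sum()
        if total <= 0:  # all mass on chosen points: pick any unchosen point
            remaining = np.setdiff1d(np.arange(n), chosen)
            nxt = int(rng.choice(remaining))
        else:
            nxt = int(rng.choice(n, p=d2 / total))
        chosen.append(nxt)
        d2_new = _sq_distances(points, fd, points[[nxt]], fd[[nxt]],
                               fd[[nxt]], config.beta, config.gamma)[:, 0]
        d2 = np.minimum(d2, d2_new)
    return np.asarray(chosen, dtype=int)


# ---------------------------------------------------------------------------
# Lloyd iterations
# ---------------------------------------------------------------------------

def _nearest_point_fd(points, fd, centroid) -> float:
    i = int(np.argmin(((points - centroid) ** 2).sum(axis=1)))
    return float(fd[i])


def fkmeans_fit(points: np.ndarray, fd: np.ndarray, k: int,
                config: ClusterConfig | None = None,
                rng: np.random.Generator | None = None) -> ClusterState:
    """Fit k clusters with FD-penalized Lloyd iterations.

    Centroid positions are the coordinate means of their members; a
    centroid's FD is the FD of the member nearest to it (FD is defined on
    voxels, not at fractional positions).  The mean-FD penalty term uses the
    assignments of the previous iteration.  Empty clusters are re-seeded at
    the point farthest from its current centroid.  Iterations stop when the
    largest centroid displacement drops below ``config.tol`` or after
    ``config.max_iter`` iterations.
    """
    config = config or ClusterConfig()
    config.validate()
    points = np.asarray(points, dtype=np.float64)
    fd = np.asarray(fd, dtype=np.float64)
    if points.ndim != 2 or len(points) == 0:
        raise ValidationError("points must be a nonempty (N, d) array")
    if k < 1:
        raise ValidationError("k must be >= 1")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    idx = kmeanspp_init(points, fd, k, config, rng)
    centroids = points[idx].copy()
    centroid_fd = fd[idx].copy()
    mean_fd_ci = centroid_fd.copy()  # iteration 0: no previous assignments
    assignments = np.zeros(len(points), dtype=int)
    n_iter = 0
    converged = False
    for n_iter in range(1, config.max_iter + 1):
        d2 = _sq_distances(points, fd, centroids, centroid_fd, mean_fd_ci,
                           config.beta, config.gamma)
        assignments = np.argmin(d2, axis=1)
        # re-seed empty clusters at the worst-fit points; only take points
        # from clusters that can spare them, so the fix cannot cascade
        point_cost = d2[np.arange(len(points)), assignments].copy()
        counts = np.bincount(assignments, minlength=k)
        for j in range(k):
            if counts[j] == 0:
                eligible = counts[assignments] > 1
                cost = np.where(eligible, point_cost, -np.inf)
                worst = int(np.argmax(cost))
                counts[assignments[worst]] -= 1
                assignments[worst] = j
                counts[j] = 1
                point_cost[worst] = -np.inf
        new_centroids = np.empty_like(centroids)
        new_mean_fd = np.empty(k)
        for j in range(k):
            members = assignments == j
            new_centroids[j] = points[members].mean(axis=0)
            new_mean_fd[j] = fd[members].mean()
        shift = np.sqrt(((new_centroids - centroids) ** 2).sum(axis=1)).max()
        centroids = new_centroids
        centroid_fd = np.array([_nearest_point_fd(points, fd, c) for c in centroids])
        mean_fd_ci = new_mean_fd
        if shift < config.tol:
            converged = True
            break
    fd_mean = np.empty(k)
    fd_var = np.empty(k)
    for j in range(k):
        members = fd[assignments == j]
        fd_mean[j] = members.mean()
        fd_var[j] = members.var()
    return ClusterState(points=points, fd=fd, assignments=assignments,
                        centroids=centroids, centroid_fd=centroid_fd,
                        cluster_fd_mean=fd_mean, cluster_fd_var=fd_var,
                        n_iter=n_iter, converged=converged)


# ---------------------------------------------------------------------------
# stopping metric and level sweep
# ---------------------------------------------------------------------------

def stop_check(prev: tuple[float, float], curr: tuple[float, float],
               tau1: float, tau2: float,
               mode: str = "literal") -> tuple[bool, str]:
    """Compare (mean FD, var FD) of the max-FD cluster between consecutive k.

    In 'literal' mode the sweep stops when either change reaches its
    threshold; in 'stabilize' mode when both changes fall below them.
    Returns (stop, reason).
    """
    d_mean = abs(curr[0] - prev[0])
    d_var = abs(curr[1] - prev[1])
    if mode == "literal":
        if d_mean >= tau1:
            return True, f"|d mean FD|={d_mean:.4f} >= tau1={tau1}"
        if d_var >= tau2:
            return True, f"|d var FD|={d_var:.4f} >= tau2={tau2}"
        return False, "below thresholds"
    if mode == "stabilize":
        if d_mean < tau1 and d_var < tau2:
            return True, f"stabilized: |d mean|={d_mean:.4f} < tau1 and |d var|={d_var:.4f} < tau2"
        return False, "still changing"
    raise ValidationError(f"unknown stop mode {mode!r}")


@dataclass
class LevelResult:
    state: ClusterState | None
    selected_k: int
    candidate_idx: np.ndarray  # indices (into the level's input) of the max-FD cluster
    history: list = field(default_factory=list)  # (k, mean, var, stop_reason)
    skipped: bool = False


def run_level(points: np.ndarray, fd: np.ndarray, k_range: tuple[int, int],
              config: ClusterConfig, level_index: int = 0,
              rng: np.random.Generator | None = None,
              prev_level_stats: tuple[float, float] | None = None) -> LevelResult:
    """Sweep k through ``k_range``, stopping on the FD-statistics criterion.

    The (mean, var) of FD in the maximum-FD cluster is compared between
    consecutive fits; the index in the stopping rule runs over fits *and*
    levels, so the first fit of a level is checked against the previous
    level's final statistics (``prev_level_stats``).  A jump there means the
    previous level's candidate has already resolved into a distinct high-FD
    cluster, and the level keeps the k_min fit.  At the first level there is
    nothing to compare against, so its first fit never stops the sweep.

    Returns the state at the stopping k (or at k_max if the range is
    exhausted) and the indices of its maximum-FD cluster.  If no fit in the
    whole sweep moves the statistics — the candidate is homogeneous and
    further clustering is no longer necessary — the level passes its input
    through unchanged rather than handing on an arbitrary fragment.  If
    there are fewer points than k_min the level is likewise skipped.
    """
    k_min, k_max = k_range
    n = len(points)
    if n < k_min:
        logger.warning("level %d skipped: %d points < k_min=%d",
                       level_index, n, k_min)
        return LevelResult(state=None, selected_k=0,
                           candidate_idx=np.arange(n), skipped=True)
    if rng is None:
        rng = np.random.default_rng(config.seed)
    k_max = min(k_max, n)
    history = []
    prev_stats = prev_level_stats
    state = None
    stopped = False
    for k in range(k_min, k_max + 1):
        state = fkmeans_fit(points, fd, k, config, rng)
        j = state.max_fd_cluster()
        stats = (float(state.cluster_fd_mean[j]), float(state.cluster_fd_var[j]))
        if prev_stats is None:  # first fit of the first level
            history.append((k, *stats, "first k"))
        else:
            stop, reason = stop_check(prev_stats, stats, config.tau1,
                                      config.tau2, config.stop_mode)
            history.append((k, *stats, reason))
            if stop:
                logger.info("level %d stop at k=%d: %s", level_index, k, reason)
                stopped = True
                break
        prev_stats = stats
    if (not stopped and prev_level_stats is not None
            and float(np.var(fd)) <= config.tau2):
        # the sweep never reorganized the FD statistics and the candidate is
        # homogeneous (FD variance below the tau2 resolution): further
        # clustering is no longer necessary, pass the input through
        logger.info("level %d: no significant FD change in %s; candidate "
                    "passed through", level_index, k_range)
        return LevelResult(state=state, selected_k=state.k,
                           candidate_idx=np.arange(n), history=history,
                           skipped=True)
    j = state.max_fd_cluster()
    candidate = np.flatnonzero(state.assignments == j)
    return LevelResult(state=state, selected_k=state.k,
                       candidate_idx=candidate, history=history)


@dataclass
class SegmentationResult:
    mask: LabelMask
    level_masks: list  # per-level candidate masks (cumulative refinement)
    levels: list       # LevelResult per level


def segment_fibrosis(volume: Volume, clipped_la: LabelMask, fdmap: FDMap,
                     config: ClusterConfig | None = None,
                     return_details: bool = False):
    """Three-level hierarchical clustering on the clipped LA voxels.

    Each level clusters the previous level's maximum-FD cluster; the voxels
    of the final maximum-FD cluster form the fibrosis mask (label
    ``fibrosis``).
    """
    config = config or ClusterConfig()
    config.validate()
    region = clipped_la.data > 0
    if not region.any():
        raise ValidationError("clipped LA mask is empty")
    if fdmap.data.shape != region.shape:
        raise ValidationError("FD map grid does not match the mask")
    coords = np.argwhere(region)
    fd = fdmap.data[region]
    if np.isnan(fd).any():
        raise ValidationError("FD map contains NaN inside the clipped LA; "
                              "compute it with a covering region")
    points = coords.astype(np.float64) * np.asarray(volume.spacing) * config.coord_scale
    if config.use_intensity:
        points = np.column_stack([points, volume.data[region]])
    rng = np.random.default_rng(config.seed)
    active = np.arange(len(coords))
    levels = []
    level_masks = []
    prev_stats = None
    for li, k_range in enumerate(config.level_k_ranges):
        res = run_level(points[active], fd[active], tuple(k_range), config,
                        level_index=li, rng=rng, prev_level_stats=prev_stats)
        active = active[res.candidate_idx]
        # the statistics carried to the next level describe the candidate
        # that is actually handed on (identical to the stopping fit's max-FD
        # cluster when a stop fired; the unchanged input when passed through)
        if len(active):
            prev_stats = (float(fd[active].mean()), float(fd[active].var()))
        levels.append(res)
        m = np.zeros(region.shape, dtype=np.int32)
        sel = coords[active]
        out_map = dict(clipped_la.label_map)
        out_map.setdefault("fibrosis", 5)
        m[sel[:, 0], sel[:, 1], sel[:, 2]] = out_map["fibrosis"]
        level_masks.append(LabelMask(data=m, label_map=out_map,
                                     spacing=clipped_la.spacing, origin=clipped_la.origin))
    result = SegmentationResult(mask=level_masks[-1], level_masks=level_masks,
                                levels=levels)
    return result if return_details else result.mask


# ---------------------------------------------------------------------------
# baselines
# ---------------------------------------------------------------------------

def baseline_kmeans2d(volume: Volume, clipped_la: LabelMask, k: int = 3,
                      seed: int = 0) -> LabelMask:
    """Per-slice intensity-only K-means; fibrosis = brightest cluster.

    The classical comparison method: within each slice the clipped-LA pixels
    are partitioned on intensity alone and the cluster with the highest mean
    intensity is called fibrosis.
    """
    if k < 2:
        raise ValidationError("k must be >= 2")
    from sklearn.cluster import KMeans

    region = clipped_la.data > 0
    out = np.zeros(region.shape, dtype=np.int32)
    out_map = dict(clipped_la.label_map)
    out_map.setdefault("fibrosis", 5)
    fib_label = out_map["fibrosis"]
    for z in range(region.shape[2]):
        sl = region[:, :, z]
        n = int(sl.sum())
        if n == 0:
            continue
        vals = volume.data[:, :, z][sl].reshape(-1, 1)
        kk = min(k, n)
        if kk < 2 or np.ptp(vals) == 0:
            continue
        km = KMeans(n_clusters=kk, n_init=1, random_state=seed).fit(vals)
        means = [vals[km.labels_ == j].mean() for j in range(kk)]
        bright = int(np.argmax(means))
        mask2d = np.zeros_like(sl)
        mask2d[sl] = km.labels_ == bright
        out[:, :, z][mask2d] = fib_label
    return LabelMask(data=out, label_map=out_map,
                     spacing=clipped_la.spacing, origin=clipped_la.origin)


def baseline_region_grow(volume: Volume, seed_point, tol: float,
                         mask: np.ndarray | None = None) -> LabelMask:
    """26-connected region growing from a seed point.

    A voxel joins the region when its intensity differs from the running
    region mean by at most ``tol``.  Growth is optionally restricted to
    ``mask``.
    """
    seed_point = tuple(int(v) for v in seed_point)
    shape = volume.data.shape
    if any(not 0 <= s < n for s, n in zip(seed_point, shape)):
        raise ValidationError(f"seed point {seed_point} outside the volume")
    if mask is not None and not mask[seed_point]:
        raise ValidationError("seed point outside the growth mask")
    data = volume.data
    grown = np.zeros(shape, dtype=bool)
    grown[seed_point] = True
    total = data[seed_point]
    count = 1
    frontier = [seed_point]
    offsets = [(dx, dy, dz) for dx in (-1, 0, 1) for dy in (-1, 0, 1)
               for dz in (-1, 0, 1) if (dx, dy, dz) != (0, 0, 0)]
    while frontier:
        new_frontier = []
        mean = total / count
        for p in frontier:
            for off in offsets:
                q = (p[0] + off[0], p[1] + off[1], p[2] + off[2])
                if any(not 0 <= c < n for c, n in zip(q, shape)):
                    continue
                if grown[q] or (mask is not None and not mask[q]):
                    continue
                if abs(data[q] - mean) <= tol:
                    grown[q] = True
                    total += data[q]
                    count += 1
                    new_frontier.append(q)
        frontier = new_frontier
    out = np.where(grown, 5, 0).astype(np.int32)
    return LabelMask(data=out, label_map=dict(DEFAULT_LABEL_MAP_RG),
                     spacing=volume.spacing, origin=volume.origin)


DEFAULT_LABEL_MAP_RG = {"background": 0, "fibrosis": 5}
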