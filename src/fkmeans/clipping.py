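"""Voronoi-based clipping of mitral valve, pulmonary veins and appendage.

The clipping stage removes anatomical structures from an (over-inclusive)
left-atrial segmentation so that the downstream fibrosis clustering is not
confounded by their texture.  It proceeds in four steps, each exposed as a
function and chained by :func:`clip_pipeline`:

1. *Binarization* — intensities are z-normalized with the mean/std of the LA
   region and thresholded at 0.2 (``>= 0.2`` maps to foreground).
2. *Distance map* — per-slice distance of every pixel to the LA wall edge.
   The wall edge is the boundary of the morphologically opened LA mask, so
   thin attached tubes do not count as wall.  Candidate seeds are local
   distance maxima at least ``d_min`` from the wall (non-maximum suppression
   with radius ``nms_radius``): pixels "far from the wall" indicate
   structures (vein tips, valve centre) or the pool interior.
3. *Voronoi partition* — every foreground voxel in the dilated search region
   is assigned to its nearest seed (Euclidean in physical units, ties to the
   lowest seed index); face-sharing cells are adjacent.
4. *Feature truncation* — per cell, the mean fractal dimension and the
   tortuosity/width of the foreground component containing the seed are
   measured; for each adjacent pair differing by at least ``delta_fd`` in FD
   and ``delta_tort`` in tortuosity, the structure-like member (greater
   tortuosity, or greater FD on a tortuosity tie) is flagged and its voxels
   removed from the LA mask.

Truncation only ever removes voxels: the clipped mask is a subset of the
input mask.  With no seeds or no flagged cells, clipping is the identity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.feature import peak_local_max
from skimage.morphology import disk

from .errors import ConfigurationError, DegenerateInputError, ValidationError
from .fractal import FDMap, fd_map, tortuosity
from .io import LabelMask, Volume

SQRT2 = float(np.sqrt(2.0))


@dataclass
class ClipConfig:
    """Parameters of the clipping stage (defaults follow the method's
    reference settings: dilation disc radius 20 px, binarization threshold
    0.2, FD difference 0.7, tortuosity difference 1.0, FD scaling factor 7,
    minimum skeleton branch length 4)."""

    dilation_radius: int = 20
    bin_threshold: float = 0.2
    delta_fd: float = 0.7
    delta_tort: float = 1.0
    d_min: float = 3.0
    nms_radius: int = 5
    min_cell_voxels: int = 20
    min_branch_len: float = 4.0
    distance_mode: str = "exact"  # or "chamfer"
    rule: str = "and"  # conjunctive threshold rule; "or" for disjunctive
    wall_open_radius: int = 3
    # flagged cells are removed together with a margin of half the largest
    # box-counting window, so texture bleeding from a removed structure
    # cannot contaminate the FD of the remaining wall
    truncate_margin: int = 3
    R: int = 7

    def validate(self) -> None:
        if self.dilation_radius < 1:
            raise ConfigurationError("dilation_radius must be >= 1")
        if self.d_min <= 0:
            raise ConfigurationError("d_min must be > 0")
        if self.distance_mode not in ("exact", "chamfer"):
            raise ConfigurationError(f"unknown distance_mode {self.distance_mode!r}")
        if self.rule not in ("and", "or"):
            raise ConfigurationError(f"unknown rule {self.rule!r}")


@dataclass
class DistanceMap:
    """Per-voxel, per-slice distance (in voxels) to the LA wall edge."""

    data: np.ndarray
    wall_edge: np.ndarray
    mode: str = "exact"
    empty_slices: tuple[int, ...] = ()


@dataclass
class VoronoiPartition:
    seeds: np.ndarray  # (k, 3) voxel coordinates
    cell_of: np.ndarray  # int array, -1 outside the domain
    adjacency: set[tuple[int, int]]

    @property
    def n_cells(self) -> int:
        return len(self.seeds)

    def cell_mask(self, idx: int) -> np.ndarray:
        return self.cell_of == idx


@dataclass
class CellFeatures:
    """Per-cell descriptors; cells below the size floor are unfeatured."""

    fd_mean: dict[int, float] = field(default_factory=dict)
    tortuosity: dict[int, float] = field(default_factory=dict)
    avg_width: dict[int, float] = field(default_factory=dict)
    n_voxels: dict[int, int] = field(default_factory=dict)
    featured: dict[int, bool] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# steps
# ---------------------------------------------------------------------------

def normalize_and_binarize(volume: Volume, la_mask: LabelMask,
                           threshold: float = 0.2) -> Volume:
    """Z-normalize with the LA region's mean/std and threshold at ``threshold``.

    Normalized intensities >= threshold map to 1, the rest to 0.
    """
    region = la_mask.data > 0
    if not region.any():
        raise ValidationError("LA mask is empty")
    mu = float(volume.data[region].mean())
    sigma = float(volume.data[region].std())
    if sigma == 0.0:
        raise DegenerateInputError("zero intensity variance in the LA region")
    binary = ((volume.data - mu) / sigma >= threshold).astype(np.float64)
    return Volume(data=binary, spacing=volume.spacing, origin=volume.origin)


def dilate_roi(la_mask: LabelMask, radius: int = 20) -> np.ndarray:
    """Per-slice dilation of the LA mask with a disc structuring element."""
    if radius < 1:
        raise ConfigurationError("radius must be >= 1")
    mask = la_mask.data > 0
    if not mask.any():
        raise ValidationError("LA mask is empty")
    selem = disk(radius)
    out = np.zeros_like(mask)
    for z in range(mask.shape[2]):
        if mask[:, :, z].any():
            out[:, :, z] = ndimage.binary_dilation(mask[:, :, z], structure=selem)
    return out


def wall_edge_mask(la_mask: LabelMask, open_radius: int = 3) -> np.ndarray:
    """Boundary of the morphologically opened LA mask, per slice.

    Opening removes thin protruding structures (vein stumps) so the edge
    traces the atrial body wall rather than attached tubes.
    """
    mask = la_mask.data > 0
    body = mask
    if open_radius > 0:
        selem = disk(open_radius)
        body = np.zeros_like(mask)
        for z in range(mask.shape[2]):
            if mask[:, :, z].any():
                body[:, :, z] = ndimage.binary_opening(mask[:, :, z], structure=selem)
    edge = np.zeros_like(mask)
    for z in range(mask.shape[2]):
        sl = body[:, :, z]
        if sl.any():
            edge[:, :, z] = sl & ~ndimage.binary_erosion(sl)
    return edge


def _chamfer_slice(edge2d: np.ndarray) -> np.ndarray:
    """Two-pass 3x3 chamfer distance (weights 1 and sqrt(2)) to edge pixels."""
    nx, ny = edge2d.shape
    big = 1e9
    d = np.where(edge2d, 0.0, big)
    fwd = ((-1, -1, SQRT2), (-1, 0, 1.0), (-1, 1, SQRT2), (0, -1, 1.0))
    bwd = ((1, 1, SQRT2), (1, 0, 1.0), (1, -1, SQRT2), (0, 1, 1.0))
    for offsets, xs in ((fwd, range(nx)), (bwd, range(nx - 1, -1, -1))):
        reverse = offsets is bwd
        ys = range(ny - 1, -1, -1) if reverse else range(ny)
        for x in xs:
            for y in ys:
                best = d[x, y]
                for dx, dy, w in offsets:
                    u, v = x + dx, y + dy
                    if 0 <= u < nx and 0 <= v < ny and d[u, v] + w < best:
                        best = d[u, v] + w
                d[x, y] = best
    return d


def distance_map(binary_vol: Volume | np.ndarray, wall_edge: np.ndarray,
                 mode: str = "exact") -> DistanceMap:
    """Per-slice distance (voxels) from every pixel to the nearest wall-edge
    pixel; slices without any wall edge get distance 0 and are recorded."""
    data = binary_vol.data if isinstance(binary_vol, Volume) else np.asarray(binary_vol)
    if data.shape != wall_edge.shape:
        raise ValidationError(f"shape mismatch: {data.shape} vs {wall_edge.shape}")
    if mode not in ("exact", "chamfer"):
        raise ConfigurationError(f"unknown distance mode {mode!r}")
    out = np.zeros(data.shape, dtype=np.float64)
    empty = []
    for z in range(data.shape[2]):
        edge = wall_edge[:, :, z]
        if not edge.any():
            empty.append(z)
            continue
        if mode == "exact":
            out[:, :, z] = ndimage.distance_transform_edt(~edge)
        else:
            out[:, :, z] = _chamfer_slice(edge)
    return DistanceMap(data=out, wall_edge=wall_edge, mode=mode,
                       empty_slices=tuple(empty))


def select_candidates(dmap: DistanceMap, binary_vol: Volume | np.ndarray,
                      d_min: float = 3.0, nms_radius: int = 5) -> np.ndarray:
    """Local maxima of the distance map over the foreground, at least
    ``d_min`` from the wall, with non-maximum suppression.

    Returns an (n, 3) integer array of seed coordinates (possibly empty).
    """
    if d_min <= 0:
        raise ConfigurationError("d_min must be > 0")
    fg = binary_vol.data if isinstance(binary_vol, Volume) else np.asarray(binary_vol)
    fg = fg > 0
    masked = np.where(fg, dmap.data, 0.0)
    if masked.max() < d_min:
        return np.zeros((0, 3), dtype=int)
    peaks = peak_local_max(masked, min_distance=nms_radius,
                           threshold_abs=float(d_min), exclude_border=False)
    return peaks.astype(int)


def voronoi_partition(seeds: np.ndarray, domain: np.ndarray,
                      spacing=(1.0, 1.0, 1.0)) -> VoronoiPartition:
    """Nearest-seed assignment of domain voxels plus face-adjacency of cells.

    Distances are Euclidean in physical units; ties go to the lowest seed
    index.
    """
    seeds = np.asarray(seeds, dtype=np.float64).reshape(-1, 3)
    if len(seeds) == 0:
        raise ValidationError("no seeds: empty partition")
    domain = np.asarray(domain) > 0
    coords = np.argwhere(domain)
    cell_of = np.full(domain.shape, -1, dtype=np.int32)
    sp = np.asarray(spacing, dtype=np.float64)
    scaled_seeds = seeds * sp
    chunk = 262144
    for start in range(0, len(coords), chunk):
        block = coords[start:start + chunk].astype(np.float64) * sp
        d2 = ((block[:, None, :] - scaled_seeds[None, :, :]) ** 2).sum(axis=2)
        idx = np.argmin(d2, axis=1)  # ties resolve to the lowest index
        sel = coords[start:start + chunk]
        cell_of[sel[:, 0], sel[:, 1], sel[:, 2]] = idx
    adjacency: set[tuple[int, int]] = set()
    for axis in range(3):
        a = np.take(cell_of, range(0, cell_of.shape[axis] - 1), axis=axis)
        b = np.take(cell_of, range(1, cell_of.shape[axis]), axis=axis)
        both = (a >= 0) & (b >= 0) & (a != b)
        pairs = np.stack([a[both], b[both]], axis=1)
        for i, j in np.unique(pairs, axis=0):
            adjacency.add((int(min(i, j)), int(max(i, j))))
    return VoronoiPartition(seeds=seeds.astype(int), cell_of=cell_of,
                            adjacency=adjacency)


def cell_features(partition: VoronoiPartition, fdmap: FDMap,
                  binary_vol: Volume | np.ndarray,
                  min_branch_len: float = 4.0,
                  min_cell_voxels: int = 20,
                  spacing=(1.0, 1.0, 1.0)) -> CellFeatures:
    """Mean FD, tortuosity and average width per Voronoi cell.

    Features describe the candidate structure the cell localizes, i.e. the
    foreground connected component containing the cell's seed (the distant
    local maximum of the wall distance map), not incidental foreground the
    Voronoi boundary happens to enclose.  FD is averaged over that 3D
    component; tortuosity and width are measured in 2D on the seed's slice,
    matching the per-slice nature of the clipping.  Shapes whose skeleton
    degenerates to a point or a closed loop get tortuosity 1.0 (no
    elongation).  Cells smaller than ``min_cell_voxels`` are left unfeatured
    and never drive truncation.
    """
    fg = binary_vol.data if isinstance(binary_vol, Volume) else np.asarray(binary_vol)
    fg = fg > 0
    if fdmap.data.shape != fg.shape:
        raise ValidationError("FD map grid does not match the binary volume")
    feats = CellFeatures()
    structure = np.ones((3, 3, 3), dtype=int)
    for idx in range(partition.n_cells):
        cell_fg = (partition.cell_of == idx) & fg
        n = int(cell_fg.sum())
        feats.n_voxels[idx] = n
        if n < min_cell_voxels:
            feats.featured[idx] = False
            continue
        feats.featured[idx] = True
        seed = tuple(int(v) for v in partition.seeds[idx])
        labels, ncomp = ndimage.label(cell_fg, structure=structure)
        comp_label = labels[seed] if labels[seed] > 0 else \
            int(np.argmax(ndimage.sum_labels(np.ones_like(labels), labels,
                                             range(1, ncomp + 1)))) + 1
        comp = labels == comp_label
        feats.fd_mean[idx] = float(np.nanmean(fdmap.data[comp]))
        # 2D shape analysis in the seed's slice
        sl = comp[:, :, seed[2]]
        labels2d, n2d = ndimage.label(sl, structure=np.ones((3, 3), dtype=int))
        if labels2d[seed[0], seed[1]] > 0:
            shape2d = labels2d == labels2d[seed[0], seed[1]]
        elif n2d:
            sizes = ndimage.sum_labels(np.ones_like(labels2d), labels2d,
                                       range(1, n2d + 1))
            shape2d = labels2d == (int(np.argmax(sizes)) + 1)
        else:
            shape2d = None
        try:
            if shape2d is None:
                raise DegenerateInputError("no in-slice foreground")
            tres = tortuosity(shape2d, min_branch_len=min_branch_len,
                              spacing=spacing[:2])
            feats.tortuosity[idx] = float(tres.tortuosity)
            feats.avg_width[idx] = float(tres.avg_width)
        except (DegenerateInputError, ValidationError):
            feats.tortuosity[idx] = 1.0
            feats.avg_width[idx] = float(2.0 * ndimage.distance_transform_edt(
                comp, sampling=spacing).max())
    return feats


def truncate(partition: VoronoiPartition, feats: CellFeatures,
             la_mask: LabelMask, delta_fd: float = 0.7,
             delta_tort: float = 1.0, rule: str = "and",
             margin: int = 3) -> LabelMask:
    """Remove structure-like Voronoi cells from the LA mask.

    For each adjacent featured pair the FD and tortuosity differences are
    compared (``>=``) against the thresholds — conjunctively by default.  The
    flagged member is the one with greater tortuosity (vein-like); on a
    tortuosity tie within 0.1, the one with greater FD (valve-like).  Flagged
    voxels are removed together with a ``margin``-voxel dilation: box-counting
    windows of wall voxels within the margin straddle the removed structure,
    so their FD carries its texture.
    """
    flagged = flagged_cells(partition, feats, delta_fd, delta_tort, rule)
    out = la_mask.data.copy()
    if flagged:
        remove = np.isin(partition.cell_of, sorted(flagged))
        if margin > 0:
            remove = ndimage.binary_dilation(remove, iterations=margin)
        out[remove] = 0
    return LabelMask(data=out, label_map=dict(la_mask.label_map),
                     spacing=la_mask.spacing, origin=la_mask.origin)


def flagged_cells(partition: VoronoiPartition, feats: CellFeatures,
                  delta_fd: float = 0.7, delta_tort: float = 1.0,
                  rule: str = "and") -> set[int]:
    if rule not in ("and", "or"):
        raise ConfigurationError(f"unknown rule {rule!r}")
    flagged: set[int] = set()
    for i, j in sorted(partition.adjacency):
        if not (feats.featured.get(i) and feats.featured.get(j)):
            continue
        dfd = abs(feats.fd_mean[i] - feats.fd_mean[j])
        dt = abs(feats.tortuosity[i] - feats.tortuosity[j])
        hit = (dfd >= delta_fd and dt >= delta_tort) if rule == "and" \
            else (dfd >= delta_fd or dt >= delta_tort)
        if not hit:
            continue
        if dt > 0.1:
            victim = i if feats.tortuosity[i] > feats.tortuosity[j] else j
        else:
            victim = i if feats.fd_mean[i] > feats.fd_mean[j] else j
        flagged.add(victim)
    return flagged


def extract_wall(la_mask: LabelMask, thickness: int = 3) -> LabelMask:
    """Wall shell of an LA (cavity + wall) mask: the mask minus its 3D
    erosion by ``thickness`` iterations.  The clustering stage operates on
    wall voxels, not the blood pool."""
    if thickness < 1:
        raise ConfigurationError("thickness must be >= 1")
    mask = la_mask.data > 0
    if not mask.any():
        raise ValidationError("empty LA mask")
    interior = ndimage.binary_erosion(mask, iterations=thickness)
    shell = mask & ~interior
    return LabelMask(data=np.where(shell, la_mask.data, 0).astype(np.int32),
                     label_map=dict(la_mask.label_map),
                     spacing=la_mask.spacing, origin=la_mask.origin)


@dataclass
class ClipResult:
    """Clipped mask plus the intermediates, for inspection and logging."""

    mask: LabelMask
    binary: Volume
    dmap: DistanceMap
    partition: VoronoiPartition | None
    features: CellFeatures | None
    flagged: set[int]
    fdmap: FDMap


def clip_pipeline(volume: Volume, la_mask: LabelMask,
                  config: ClipConfig | None = None,
                  fdmap: FDMap | None = None,
                  return_details: bool = False):
    """Run the full clipping chain and return the clipped LA mask.

    The chain is: ROI dilation, normalization/binarization, wall-edge
    distance map, candidate seeds, Voronoi partition, per-cell features,
    truncation.  With no candidate seeds, clipping is the identity.
    """
    config = config or ClipConfig()
    config.validate()
    if volume.data.shape != la_mask.shape:
        raise ValidationError("volume and LA mask are on different grids")
    roi = dilate_roi(la_mask, config.dilation_radius)
    binary = normalize_and_binarize(volume, la_mask, config.bin_threshold)
    fg = (binary.data > 0) & roi
    edge = wall_edge_mask(la_mask, config.wall_open_radius)
    dmap = distance_map(binary, edge, mode=config.distance_mode)
    seeds = select_candidates(dmap, fg, d_min=config.d_min,
                              nms_radius=config.nms_radius)
    if fdmap is None:
        fdmap = fd_map(volume, R=config.R)
    if len(seeds) == 0:
        result = ClipResult(mask=LabelMask(data=la_mask.data.copy(),
                                           label_map=dict(la_mask.label_map),
                                           spacing=la_mask.spacing,
                                           origin=la_mask.origin),
                            binary=binary, dmap=dmap, partition=None,
                            features=None, flagged=set(), fdmap=fdmap)
        return result if return_details else result.mask
    partition = voronoi_partition(seeds, fg, spacing=volume.spacing)
    feats = cell_features(partition, fdmap, fg,
                          min_branch_len=config.min_branch_len,
                          min_cell_voxels=config.min_cell_voxels,
                          spacing=volume.spacing)
    flagged = flagged_cells(partition, feats, config.delta_fd,
                            config.delta_tort, config.rule)
    clipped = truncate(partition, feats, la_mask, config.delta_fd,
                       config.delta_tort, config.rule,
                       margin=config.truncate_margin)
    result = ClipResult(mask=clipped, binary=binary, dmap=dmap,
                        partition=partition, features=feats,
                        flagged=flagged, fdmap=fdmap)
    return result if return_details else result.mask
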