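"""Differential box-counting fractal dimension and skeleton shape descriptors.

The fractal dimension (FD) of a pixel is estimated from the local intensity
range at several window scales.  For a scale ``r`` the differential box count
is::

    N_r = (R^2 / r^2) * (M_r - m_r) / r + 1

where ``M_r`` and ``m_r`` are the maximum and minimum intensity inside the
``r``-window around the pixel and ``R`` is the maximum scaling factor.  FD is
the ordinary least-squares slope of ``log N_r`` against ``log(1/r)`` over the
scale set ``{r : 2 < r < R}``.  A constant patch therefore has FD exactly 0,
and adding a constant to all intensities leaves FD unchanged.  Values can be
negative for near-flat patches; they are retained, as downstream clustering
uses only relative ordering.

Window convention: the ``r``-window is the axis-aligned square of side ``r``
centred on the pixel; for even ``r`` the extra row/column falls on the
positive side.  At image borders the window is clipped to the image (the
default), or the image is reflect-padded when ``boundary='reflect'``.

Tortuosity of a tubular binary shape is the ratio L/D of the length of the
skeleton's longest path (the spine) to the Euclidean distance between the
spine's endpoints.  The average width is twice the distance-transform value
sampled along the spine.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import ndimage
from skimage.morphology import skeletonize

from .errors import ConfigurationError, DegenerateInputError, ValidationError
from .io import Volume

DEFAULT_R = 7  # maximum scaling factor
FD_SENTINEL = np.nan  # value stored outside the requested region


def scale_set(R: int) -> list[int]:
    """All integer scales r with 2 < r < R (strict on both sides)."""
    if R < 4:
        raise ConfigurationError(f"R={R} admits no scale r with 2 < r < R")
    return list(range(3, R))


@dataclass
class FDMap:
    """Per-voxel fractal-dimension map with the scale set that produced it."""

    data: np.ndarray
    R: int
    r_set: list[int]
    boundary: str = "clip"
    window: str = "side-r square, even r offset toward +axes"
    region: np.ndarray | None = field(default=None, repr=False)

    def values_at(self, coords: np.ndarray) -> np.ndarray:
        """FD values at an (n, 3) array of voxel coordinates."""
        coords = np.asarray(coords)
        return self.data[coords[:, 0], coords[:, 1], coords[:, 2]]


@dataclass
class TortuosityResult:
    tortuosity: float
    spine_length_L: float
    endpoint_distance_D: float
    avg_width: float
    n_branches: int


# ---------------------------------------------------------------------------
# differential box counting
# ---------------------------------------------------------------------------

def box_count(window: np.ndarray, r: int, R: int) -> float:
    """Differential box count N_r of one intensity window.

    ``window`` is the (possibly clipped) r-neighbourhood of a pixel.
    """
    if not 2 < r < R:
        raise ConfigurationError(f"scale r={r} must satisfy 2 < r < R={R}")
    window = np.asarray(window, dtype=np.float64)
    if window.size == 0:
        raise ValidationError("empty window")
    mr, Mr = float(window.min()), float(window.max())
    return (R * R) / (r * r) * (Mr - mr) / r + 1.0


def _window_bounds(center: int, r: int, n: int) -> tuple[int, int]:
    """Index range of the side-r window on one axis, clipped to [0, n)."""
    if r % 2:
        lo, hi = center - (r - 1) // 2, center + (r - 1) // 2 + 1
    else:  # even r: extra sample toward +axis
        lo, hi = center - (r // 2 - 1), center + r // 2 + 1
    return max(lo, 0), min(hi, n)


def _ols_slope(x: np.ndarray, y: np.ndarray) -> float:
    x = np.asarray(x, dtype=np.float64)
    xc = x - x.mean()
    return float(np.dot(xc, y - y.mean()) / np.dot(xc, xc))


def _single_scale_slope(log_nr: float, r: int, R: int) -> float:
    # a one-point regression is undefined; anchor the line at the coarsest
    # scale, where a single box suffices by convention (N_R := 1)
    return log_nr / np.log(R / r)


def fd_at(image: np.ndarray, x: int, y: int, R: int = DEFAULT_R) -> float:
    """FD of one pixel of a 2D image (window clipped at borders)."""
    image = np.asarray(image, dtype=np.float64)
    rs = scale_set(R)
    log_nr = []
    for r in rs:
        x0, x1 = _window_bounds(x, r, image.shape[0])
        y0, y1 = _window_bounds(y, r, image.shape[1])
        log_nr.append(np.log(box_count(image[x0:x1, y0:y1], r, R)))
    if len(rs) == 1:
        return float(_single_scale_slope(log_nr[0], rs[0], R))
    return _ols_slope(np.log(1.0 / np.asarray(rs)), np.asarray(log_nr))


def _range_filter(plane: np.ndarray, r: int) -> np.ndarray:
    """Per-pixel (max - min) over the side-r window, clipped at borders."""
    origin = 0 if r % 2 else -1
    mx = ndimage.maximum_filter(plane, size=r, mode="constant", cval=-np.inf, origin=origin)
    mn = ndimage.minimum_filter(plane, size=r, mode="constant", cval=np.inf, origin=origin)
    return mx - mn


def _fd_plane(plane: np.ndarray, R: int, boundary: str) -> np.ndarray:
    """Vectorized per-pixel FD of one 2D slice."""
    rs = scale_set(R)
    pad = 0
    work = plane
    if boundary == "reflect":
        pad = max(rs)
        work = np.pad(plane, pad, mode="reflect")
    logs = []
    for r in rs:
        nr = (R * R) / (r * r) * _range_filter(work, r) / r + 1.0
        logs.append(np.log(nr))
    if len(rs) == 1:
        out = _single_scale_slope(logs[0], rs[0], R)
    else:
        xs = np.log(1.0 / np.asarray(rs, dtype=np.float64))
        xc = xs - xs.mean()
        ymean = sum(logs) / len(logs)
        acc = np.zeros_like(work, dtype=np.float64)
        for w, ly in zip(xc, logs):
            acc += w * (ly - ymean)
        out = acc / np.dot(xc, xc)
    if pad:
        out = out[pad:-pad, pad:-pad]
    return out


def fd_map(volume: Volume | np.ndarray, R: int = DEFAULT_R,
           region: np.ndarray | None = None, boundary: str = "clip",
           three_d: bool = False) -> FDMap:
    """Per-voxel FD map, computed slice-wise over the z axis by default.

    Parameters
    ----------
    volume : Volume or 3D array
    R : maximum scaling factor (default 7, scales {3,...,R-1})
    region : optional boolean mask; voxels outside are set to NaN
    boundary : 'clip' (windows truncated at borders) or 'reflect'
    three_d : use cubic windows over the full volume instead of per-slice
        square windows (non-default variant).
    """
    data = volume.data if isinstance(volume, Volume) else np.asarray(volume, dtype=np.float64)
    if data.ndim != 3:
        raise ValidationError(f"expected a 3D volume, got shape {data.shape}")
    if region is not None and region.shape != data.shape:
        raise ValidationError(f"region shape {region.shape} != volume shape {data.shape}")
    if boundary not in ("clip", "reflect"):
        raise ConfigurationError(f"unknown boundary policy {boundary!r}")
    rs = scale_set(R)
    if three_d:
        out = _fd_volume_3d(data, R, boundary)
    else:
        out = np.empty_like(data, dtype=np.float64)
        for z in range(data.shape[2]):
            out[:, :, z] = _fd_plane(data[:, :, z], R, boundary)
    if region is not None:
        out = np.where(region, out, FD_SENTINEL)
    return FDMap(data=out, R=R, r_set=rs, boundary=boundary, region=region)


def _fd_volume_3d(data: np.ndarray, R: int, boundary: str) -> np.ndarray:
    rs = scale_set(R)
    pad = 0
    work = data
    if boundary == "reflect":
        pad = max(rs)
        work = np.pad(data, pad, mode="reflect")
    logs = []
    for r in rs:
        origin = 0 if r % 2 else -1
        mx = ndimage.maximum_filter(work, size=r, mode="constant", cval=-np.inf, origin=origin)
        mn = ndimage.minimum_filter(work, size=r, mode="constant", cval=np.inf, origin=origin)
        nr = (R * R) / (r * r) * (mx - mn) / r + 1.0
        logs.append(np.log(nr))
    if len(rs) == 1:
        out = _single_scale_slope(logs[0], rs[0], R)
    else:
        xs = np.log(1.0 / np.asarray(rs, dtype=np.float64))
        xc = xs - xs.mean()
        ymean = sum(logs) / len(logs)
        acc = np.zeros_like(work, dtype=np.float64)
        for w, ly in zip(xc, logs):
            acc += w * (ly - ymean)
        out = acc / np.dot(xc, xc)
    if pad:
        out = out[pad:-pad, pad:-pad, pad:-pad]
    return out


# ---------------------------------------------------------------------------
# skeleton tortuosity and width
# ---------------------------------------------------------------------------

def _largest_component(mask: np.ndarray) -> np.ndarray:
    labels, n = ndimage.label(mask, structure=np.ones((3,) * mask.ndim, dtype=int))
    if n == 0:
        raise ValidationError("empty mask")
    sizes = ndimage.sum_labels(np.ones_like(mask, dtype=np.int64), labels, range(1, n + 1))
    return labels == (int(np.argmax(sizes)) + 1)


def _skeleton_graph(skel: np.ndarray, spacing) -> nx.Graph:
    coords = np.argwhere(skel)
    index = {tuple(c): i for i, c in enumerate(coords)}
    g = nx.Graph()
    g.add_nodes_from(range(len(coords)))
    offsets = [o for o in np.ndindex(*(3,) * skel.ndim)
               if any(v != 1 for v in o)]
    spacing = np.asarray(spacing, dtype=np.float64)
    for c in coords:
        i = index[tuple(c)]
        for off in offsets:
            nb = tuple(c + np.asarray(off) - 1)
            j = index.get(nb)
            if j is not None and j > i:
                step = (np.asarray(off) - 1) * spacing
                g.add_edge(i, j, weight=float(np.linalg.norm(step)))
    for i, c in enumerate(coords):
        g.nodes[i]["coord"] = c
    return g


def _prune_short_branches(g: nx.Graph, min_len: float) -> nx.Graph:
    """Iteratively remove leaf branches whose arc length is below min_len."""
    g = g.copy()
    changed = True
    while changed and g.number_of_nodes() > 1:
        changed = False
        leaves = [n for n in g.nodes if g.degree(n) == 1]
        for leaf in leaves:
            if leaf not in g or g.degree(leaf) != 1:
                continue
            branch, length = [leaf], 0.0
            node = leaf
            while True:
                nbrs = [n for n in g.neighbors(node) if n not in branch]
                if not nbrs:
                    break
                nxt = nbrs[0]
                length += g.edges[node, nxt]["weight"]
                if g.degree(nxt) != 2:
                    break
                branch.append(nxt)
                node = nxt
            # prune the twig unless that would delete the whole skeleton
            if length < min_len and g.number_of_nodes() - len(branch) > 1:
                g.remove_nodes_from(branch)
                changed = True
    return g


def _longest_path(g: nx.Graph) -> tuple[list[int], float]:
    """Two-sweep eccentricity heuristic; exact on trees."""
    start = next(iter(g.nodes))
    dist = nx.single_source_dijkstra_path_length(g, start)
    u = max(dist, key=dist.get)
    dist_u, paths_u = nx.single_source_dijkstra(g, u)
    v = max(dist_u, key=dist_u.get)
    return paths_u[v], float(dist_u[v])


def tortuosity(shape_mask: np.ndarray, min_branch_len: float = 4,
               spacing=None) -> TortuosityResult:
    """Skeleton-based tortuosity, spine length and average width of a shape.

    The analysis is restricted to the largest connected component.  Branches
    shorter than ``min_branch_len`` are pruned from the skeleton; the spine is
    the longest geodesic path of what remains.  Raises
    :class:`DegenerateInputError` for closed loops (endpoint distance 0).
    """
    mask = np.asarray(shape_mask).astype(bool)
    if mask.ndim not in (2, 3):
        raise ValidationError(f"mask must be 2D or 3D, got {mask.ndim}D")
    if not mask.any():
        raise ValidationError("empty mask")
    if spacing is None:
        spacing = (1.0,) * mask.ndim
    mask = _largest_component(mask)
    skel = skeletonize(mask)
    if not skel.any():  # tiny blob: skeleton may vanish; keep its centroid
        skel = np.zeros_like(mask)
        c = tuple(int(round(v)) for v in ndimage.center_of_mass(mask))
        skel[c] = True
    g = _skeleton_graph(skel, spacing)
    if g.number_of_edges() == 0:
        raise DegenerateInputError("skeleton reduced to a point; tortuosity undefined")
    # keep the largest connected piece of the skeleton graph
    comp = max(nx.connected_components(g), key=len)
    g = g.subgraph(comp).copy()
    g = _prune_short_branches(g, float(min_branch_len))
    if g.number_of_edges() == 0:
        raise DegenerateInputError("skeleton pruned to a point; tortuosity undefined")
    n_branches = sum(1 for n in g.nodes if g.degree(n) == 1)
    if n_branches == 0:
        raise DegenerateInputError("skeleton is a closed loop (no endpoints); "
                                   "tortuosity undefined")
    path, L = _longest_path(g)
    a = g.nodes[path[0]]["coord"].astype(float) * np.asarray(spacing)
    b = g.nodes[path[-1]]["coord"].astype(float) * np.asarray(spacing)
    D = float(np.linalg.norm(a - b))
    # A closed loop skeletonizes to an arc whose endpoints are adjacent
    # pixels: treat a spine that returns (almost) to its start as degenerate.
    step = float(np.max(spacing))
    if D <= 0 or (D <= 2.0 * step and L > 6.0 * step):
        raise DegenerateInputError("spine endpoints coincide (closed loop)")
    edt = ndimage.distance_transform_edt(mask, sampling=spacing)
    widths = [2.0 * edt[tuple(g.nodes[n]["coord"])] for n in path]
    return TortuosityResult(
        tortuosity=L / D,
        spine_length_L=L,
        endpoint_distance_D=D,
        avg_width=float(np.mean(widths)),
        n_branches=n_branches,
    )
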