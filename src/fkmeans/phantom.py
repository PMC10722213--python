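"""Synthetic left-atrium phantom with ground-truth labels.

The phantom emulates the anatomy the pipeline must handle, not MRI physics:

* an ellipsoidal blood pool of high, homogeneous intensity surrounded by a
  thin lower-intensity wall (together the LA); the piecewise-constant
  anatomy is smoothed with a Gaussian to emulate partial-volume blur, so
  region interfaces are ramps rather than steps (as in real MRI);
* snake-like tubular pulmonary-vein (PV) branches attached at the equator,
  bright with high-spatial-frequency texture so that their differential
  box-counting FD clearly exceeds smooth regions and their centerline
  tortuosity reaches a configurable target;
* a smooth mitral-valve (MV) blob and appendage (LAA) lobe contiguous with
  the pool, both with blood-pool-like, low-texture intensity;
* one compact fibrosis patch inside the wall on the flat superior face with
  a seed-dependent azimuth.  The patch carries thresholded (binary +/-)
  high-frequency texture — so every box-counting window sees the same local
  range and the patch FD is spatially uniform — at full amplitude in its
  interior and half amplitude on its one-pixel border zone, plus a smooth
  enhancement (brightening) profile;
* Gaussian noise everywhere.

All randomness flows from one generator seeded by ``PhantomSpec.seed``, so a
given spec reproduces bit-identical volumes.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage
from scipy.optimize import brentq
from scipy.spatial import cKDTree

from .errors import IOFailure, ValidationError
from .io import DEFAULT_LABEL_MAP, LabelMask, Volume, write_mask, write_volume

_PV_AZIMUTHS_DEG = (-45.0, 0.0, 45.0, 135.0, -90.0, -135.0, 120.0, 155.0)
_MV_AZIMUTH_DEG = 180.0  # -x side
_LAA_AZIMUTH_DEG = 90.0  # +y side


@dataclass
class PhantomSpec:
    """Parameters of one synthetic LA volume.

    Geometric quantities are in voxels; intensities in arbitrary units chosen
    so that the blood pool, valve and veins binarize as foreground while the
    non-fibrotic wall does not.
    """

    shape: tuple[int, int, int] = (96, 96, 24)
    pool_radius_vox: tuple[float, float, float] = (26.0, 22.0, 7.0)
    wall_thickness_vox: int = 4
    n_pv_branches: int = 4
    pv_tortuosity_target: float = 2.0
    fibrosis_fraction: float = 0.1
    texture_amplitude: float = 25.0
    noise_sigma: float = 0.25
    seed: int = 0
    # secondary contrast / geometry parameters
    background_intensity: float = 20.0
    pool_intensity: float = 100.0
    wall_intensity: float = 70.0
    valve_intensity: float = 95.0
    pv_intensity: float = 135.0
    pv_radius_vox: float = 1.8
    pv_length_vox: float = 14.0
    mv_radius_vox: float = 6.0
    laa_radius_vox: float = 5.0
    partial_volume_blur: float = 1.5
    fib_enhancement: float = 15.0
    fib_rim_amp: float = 0.5
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def validate(self) -> None:
        if not 0.0 < self.fibrosis_fraction < 1.0:
            raise ValidationError(f"fibrosis_fraction must be in (0,1), got {self.fibrosis_fraction}")
        if self.noise_sigma < 0:
            raise ValidationError("noise_sigma must be >= 0")
        if self.wall_thickness_vox < 1:
            raise ValidationError("wall_thickness_vox must be >= 1")
        if self.n_pv_branches < 0:
            raise ValidationError("n_pv_branches must be >= 0")
        if self.n_pv_branches > len(_PV_AZIMUTHS_DEG):
            raise ValidationError(f"at most {len(_PV_AZIMUTHS_DEG)} PV branches supported")
        if self.pv_tortuosity_target < 1.0:
            raise ValidationError("pv_tortuosity_target must be >= 1")
        center = np.asarray(self.shape) / 2.0
        outer = np.asarray(self.pool_radius_vox) + self.wall_thickness_vox
        margin_xy = min(center[0] - outer[0], center[1] - outer[1])
        need = self.wall_thickness_vox + (self.pv_length_vox if self.n_pv_branches else 0)
        if margin_xy < need or center[2] - outer[2] < 1:
            raise ValidationError(
                f"pool (semi-axes {self.pool_radius_vox}, wall {self.wall_thickness_vox}) "
                f"does not fit in shape {self.shape} with margin for PV length {self.pv_length_vox}")


def _ellipsoid(shape, center, semi) -> np.ndarray:
    grids = np.ogrid[0:shape[0], 0:shape[1], 0:shape[2]]
    acc = np.zeros(shape, dtype=np.float64)
    for g, c, s in zip(grids, center, semi):
        acc = acc + ((g - c) / s) ** 2
    return acc <= 1.0


def _bandpass_texture(shape, rng, sigma_low: float = 1.5) -> np.ndarray:
    """Zero-mean unit-std high-frequency noise field."""
    white = rng.standard_normal(shape)
    bp = white - ndimage.gaussian_filter(white, sigma_low)
    return bp / bp.std()


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _pv_curve(p0: np.ndarray, direction: np.ndarray, wiggle: np.ndarray,
              length: float, target: float, n_periods: int = 1,
              n_samples: int = 600) -> np.ndarray:
    """Sample a sinusoidal centerline whose arc/chord ratio is ``target``.

    The chord runs ``length`` voxels along ``direction``; the oscillation is
    along ``wiggle`` with an integer number of periods so the endpoints sit on
    the chord and the analytic tortuosity is L/length.
    """
    omega = 2.0 * np.pi * n_periods / length

    def ratio(amp: float) -> float:
        t = np.linspace(0.0, length, 2048)
        return float(np.trapezoid(np.sqrt(1.0 + (amp * omega * np.cos(omega * t)) ** 2), t) / length)

    if target <= 1.0 + 1e-9:
        amp = 0.0
    else:
        amp = brentq(lambda a: ratio(a) - target, 0.0, 10.0 * length)
    t = np.linspace(0.0, length, n_samples)
    return p0[None, :] + t[:, None] * direction[None, :] + \
        (amp * np.sin(omega * t))[:, None] * wiggle[None, :]


def _rasterize_tube(shape, samples: np.ndarray, radius: float) -> np.ndarray:
    lo = np.maximum(np.floor(samples.min(axis=0) - radius - 1).astype(int), 0)
    hi = np.minimum(np.ceil(samples.max(axis=0) + radius + 1).astype(int) + 1, shape)
    if np.any(hi <= lo):
        return np.zeros(shape, dtype=bool)
    grids = np.mgrid[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]].reshape(3, -1).T
    tree = cKDTree(samples)
    d, _ = tree.query(grids, k=1)
    out = np.zeros(shape, dtype=bool)
    inside = grids[d <= radius]
    out[inside[:, 0], inside[:, 1], inside[:, 2]] = True
    return out


def _surface_point(center, semi, azimuth_rad: float) -> np.ndarray:
    d = np.array([np.cos(azimuth_rad), np.sin(azimuth_rad), 0.0])
    r = 1.0 / np.sqrt((d[0] / semi[0]) ** 2 + (d[1] / semi[1]) ** 2)
    return np.asarray(center) + d * r


def _erode_in_slice(mask: np.ndarray, iterations: int = 1) -> np.ndarray:
    out = np.zeros_like(mask)
    for z in range(mask.shape[2]):
        if mask[:, :, z].any():
            out[:, :, z] = ndimage.binary_erosion(mask[:, :, z],
                                                  iterations=iterations)
    return out


def generate_phantom(spec: PhantomSpec) -> tuple[Volume, LabelMask]:
    """Build the intensity volume and ground-truth label mask for ``spec``."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    shape = tuple(spec.shape)
    center = np.asarray(shape, dtype=np.float64) / 2.0
    semi_in = np.asarray(spec.pool_radius_vox, dtype=np.float64)
    semi_out = semi_in + spec.wall_thickness_vox

    pool = _ellipsoid(shape, center, semi_in)
    la = _ellipsoid(shape, center, semi_out)
    wall = la & ~pool

    labels = np.zeros(shape, dtype=np.int32)
    labels[la] = DEFAULT_LABEL_MAP["la"]

    data = np.full(shape, spec.background_intensity, dtype=np.float64)
    data[pool] = spec.pool_intensity
    data[wall] = spec.wall_intensity

    # --- fibrosis: compact patch on the superior (flat) wall ---------------
    wall_coords = np.argwhere(wall)
    n_fib = int(round(spec.fibrosis_fraction * len(wall_coords)))
    azim = rng.uniform(0.0, 2.0 * np.pi)
    rad_frac = rng.uniform(0.0, 0.35)
    patch_dir = np.array([rad_frac * np.cos(azim) * semi_out[0],
                          rad_frac * np.sin(azim) * semi_out[1],
                          semi_out[2]])
    patch_center = center + patch_dir
    order = np.argsort(np.linalg.norm(wall_coords - patch_center, axis=1))
    fib_coords = wall_coords[order[:n_fib]]
    fibrosis = np.zeros(shape, dtype=bool)
    if n_fib:
        fibrosis[fib_coords[:, 0], fib_coords[:, 1], fib_coords[:, 2]] = True
    labels[fibrosis] = DEFAULT_LABEL_MAP["fibrosis"]

    # --- smooth structures contiguous with the pool ------------------------
    mv_center = _surface_point(center, semi_out, np.deg2rad(_MV_AZIMUTH_DEG))
    mv = _ellipsoid(shape, mv_center, (spec.mv_radius_vox,) * 3) & ~la
    data[mv] = spec.valve_intensity
    labels[mv] = DEFAULT_LABEL_MAP["mv"]

    laa_center = _surface_point(center, semi_out, np.deg2rad(_LAA_AZIMUTH_DEG))
    laa = _ellipsoid(shape, laa_center,
                     (spec.laa_radius_vox, spec.laa_radius_vox,
                      spec.laa_radius_vox * 0.8)) & ~la & ~mv
    data[laa] = spec.valve_intensity
    labels[laa] = DEFAULT_LABEL_MAP["laa"]

    # partial-volume blur of the piecewise-constant anatomy
    if spec.partial_volume_blur > 0:
        data = ndimage.gaussian_filter(data, spec.partial_volume_blur)

    # smooth contrast enhancement of the fibrotic patch (LGE brightening)
    if spec.fib_enhancement and n_fib:
        data += ndimage.gaussian_filter(
            np.where(fibrosis, float(spec.fib_enhancement), 0.0), 1.5)

    # thresholded high-frequency texture: a binary +/- field gives every
    # window the same local intensity range, hence a spatially uniform FD
    texture = np.where(rng.standard_normal(shape) >= 0.0, 1.0, -1.0)
    amp = 0.5 * spec.texture_amplitude
    core = _erode_in_slice(fibrosis, 1)
    rim = fibrosis & ~core
    data[core] += amp * texture[core]
    data[rim] += spec.fib_rim_amp * amp * texture[rim]

    # --- pulmonary veins: crisp bright textured snakes ---------------------
    pv_texture = np.where(rng.standard_normal(shape) >= 0.0, 1.0, -1.0)
    for i in range(spec.n_pv_branches):
        phi = np.deg2rad(_PV_AZIMUTHS_DEG[i])
        p0 = _surface_point(center, semi_out - 1.0, phi)
        direction = _unit(np.array([np.cos(phi), np.sin(phi), 0.0]))
        # in-plane oscillation: the snake stays in its slice band, so its
        # per-slice cross-section shows the full winding shape
        wiggle = np.array([-np.sin(phi), np.cos(phi), 0.0])
        # solve for a slightly higher analytic ratio: the measured skeleton
        # retracts at the tube ends, shaving a few percent off L/D
        samples = _pv_curve(p0, direction, wiggle, spec.pv_length_vox,
                            spec.pv_tortuosity_target * 1.12, n_periods=1)
        if (samples - spec.pv_radius_vox - 1 < 0).any() or \
           (samples + spec.pv_radius_vox + 1 >= np.asarray(shape)).any():
            raise ValidationError("PV branch leaves the volume; enlarge shape or shorten pv_length_vox")
        tube = _rasterize_tube(shape, samples, spec.pv_radius_vox) & ~la
        data[tube] = spec.pv_intensity + 0.35 * spec.texture_amplitude * pv_texture[tube]
        labels[tube] = DEFAULT_LABEL_MAP["pv"]

    if spec.noise_sigma > 0:
        data += rng.normal(0.0, spec.noise_sigma, shape)

    volume = Volume(data=data, spacing=spec.spacing)
    mask = LabelMask(data=labels, spacing=spec.spacing)
    return volume, mask


# ---------------------------------------------------------------------------
# canonical fixture suite
# ---------------------------------------------------------------------------

SMALL_SPEC_KW = dict(shape=(48, 48, 16), pool_radius_vox=(12.0, 10.0, 4.0),
                     wall_thickness_vox=2, n_pv_branches=2, pv_length_vox=8.0,
                     pv_radius_vox=1.8, pv_tortuosity_target=1.4,
                     mv_radius_vox=3.5, laa_radius_vox=3.0)


def _fixture_specs() -> dict[str, PhantomSpec]:
    specs = {}
    for frac in (0.1, 0.2):
        for tag, kw, seed in (("small", SMALL_SPEC_KW, 11), ("large", {}, 23)):
            name = f"phantom_{tag}_f{int(frac * 100):02d}"
            specs[name] = PhantomSpec(fibrosis_fraction=frac, seed=seed, **kw)
    return specs


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def fixture_suite(out_dir) -> dict:
    """Write the canonical phantom set and a checksum manifest.

    Re-running is idempotent: missing or stale files are regenerated and the
    manifest always lists every file with its SHA-256.
    """
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise IOFailure(f"cannot create {out}: {exc}") from exc
    manifest = {"files": {}, "specs": {}}
    for name, spec in _fixture_specs().items():
        vol_path = out / f"{name}.nii"
        mask_path = out / f"{name}_mask.nii"
        volume, mask = generate_phantom(spec)
        write_volume(volume, vol_path)
        write_mask(mask, mask_path)
        for p in (vol_path, mask_path, mask_path.with_name(mask_path.stem + ".labels.json")):
            manifest["files"][p.name] = _sha256(p)
        manifest["specs"][name] = {k: (list(v) if isinstance(v, tuple) else v)
                                   for k, v in asdict(spec).items()}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
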