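"""Phantom self-evaluation harness.

Runs the full method on synthetic LA phantoms under the two clipping regimes
the evaluation protocol distinguishes — ground-truth ("manual") clipping and
automatic Voronoi clipping — plus the classical baselines, and scores
everything against the planted fibrosis.  Used by the acceptance script and
the acceptance tests.
"""

from __future__ import annotations

import numpy as np

from .clipping import ClipConfig, clip_pipeline, extract_wall
from .clustering import (
    ClusterConfig,
    baseline_kmeans2d,
    baseline_region_grow,
    segment_fibrosis,
)
from .fractal import fd_map
from .io import LabelMask
from .metrics import dice, precision_recall
from .phantom import PhantomSpec, generate_phantom

FIBROSIS = 5


def union_la_mask(mask: LabelMask) -> LabelMask:
    """Over-inclusive LA segmentation: every labelled structure as one blob
    (what an upstream atrium segmentation typically delivers)."""
    return LabelMask(data=(mask.data > 0).astype(np.int32),
                     label_map={"background": 0, "la": 1},
                     spacing=mask.spacing, origin=mask.origin)


def true_la_mask(mask: LabelMask) -> LabelMask:
    """Ground-truth LA (cavity + wall, fibrosis included), structures excluded."""
    la = np.isin(mask.data, [mask.label_map["la"], mask.label_map["fibrosis"]])
    return LabelMask(data=la.astype(np.int32),
                     label_map={"background": 0, "la": 1},
                     spacing=mask.spacing, origin=mask.origin)


def evaluate_phantom(seed: int, spec_kw: dict | None = None,
                     with_baselines: bool = True) -> dict:
    """Run both regimes and the baselines on one phantom; return the scores."""
    spec = PhantomSpec(seed=seed, **(spec_kw or {}))
    volume, mask = generate_phantom(spec)
    fib = mask.data == mask.label_map["fibrosis"]
    fdm = fd_map(volume, R=7)
    cluster_cfg = ClusterConfig(seed=seed)
    wall_t = spec.wall_thickness_vox

    manual_wall = extract_wall(true_la_mask(mask), thickness=wall_t)
    seg = segment_fibrosis(volume, manual_wall, fdm, cluster_cfg,
                           return_details=True)
    level_dice = [dice(lm.data > 0, fib) for lm in seg.level_masks]
    p_manual, r_manual = precision_recall(seg.mask.data > 0, fib)

    clip = clip_pipeline(volume, union_la_mask(mask), ClipConfig(),
                         fdmap=fdm, return_details=True)
    auto_wall = extract_wall(clip.mask, thickness=wall_t)
    seg_auto = segment_fibrosis(volume, auto_wall, fdm, cluster_cfg)

    out = {
        "seed": seed,
        "dice_manual": dice(seg.mask.data > 0, fib),
        "dice_auto": dice(seg_auto.data > 0, fib),
        "dice_clip": dice(clip.mask.data > 0, true_la_mask(mask).data > 0),
        "level_dice": level_dice,
        "precision_manual": p_manual,
        "recall_manual": r_manual,
        "n_fibrosis": int(fib.sum()),
    }
    if with_baselines:
        bk = baseline_kmeans2d(volume, manual_wall, k=3, seed=seed)
        fib_coords = np.argwhere(fib)
        seed_pt = tuple(fib_coords[len(fib_coords) // 2])
        rg = baseline_region_grow(volume, seed_pt, tol=8.0,
                                  mask=manual_wall.data > 0)
        out["dice_kmeans2d"] = dice(bk.data > 0, fib)
        out["dice_region_grow"] = dice(rg.data > 0, fib)
    return out


def zero_texture_fraction(seed: int, spec_kw: dict | None = None) -> float:
    """False-positive control: with no planted texture or enhancement, the
    fraction of wall voxels the method still calls fibrotic."""
    kw = dict(spec_kw or {})
    kw.update(texture_amplitude=0.0, fib_enhancement=0.0)
    spec = PhantomSpec(seed=seed, **kw)
    volume, mask = generate_phantom(spec)
    fdm = fd_map(volume, R=7)
    wall = extract_wall(true_la_mask(mask), thickness=spec.wall_thickness_vox)
    seg = segment_fibrosis(volume, wall, fdm, ClusterConfig(seed=seed))
    return float((seg.data > 0).sum() / (wall.data > 0).sum())


def run_battery(seeds, spec_kw: dict | None = None,
                zero_texture: bool = True) -> dict:
    """Evaluate several phantom seeds and aggregate."""
    per_seed = [evaluate_phantom(s, spec_kw) for s in seeds]
    agg = {
        "per_seed": per_seed,
        "mean_dice_manual": float(np.mean([r["dice_manual"] for r in per_seed])),
        "mean_dice_auto": float(np.mean([r["dice_auto"] for r in per_seed])),
        "mean_dice_clip": float(np.mean([r["dice_clip"] for r in per_seed])),
        "mean_dice_kmeans2d": float(np.mean([r["dice_kmeans2d"] for r in per_seed])),
        "mean_dice_region_grow": float(np.mean([r["dice_region_grow"] for r in per_seed])),
        "mean_precision_manual": float(np.mean([r["precision_manual"] for r in per_seed])),
        "mean_recall_manual": float(np.mean([r["recall_manual"] for r in per_seed])),
        "n_level_improved": int(sum(r["level_dice"][-1] >= r["level_dice"][0]
                                    for r in per_seed)),
    }
    if zero_texture:
        fracs = [zero_texture_fraction(s, spec_kw) for s in seeds]
        agg["zero_texture_fractions"] = fracs
        agg["mean_zero_texture_fraction"] = float(np.mean(fracs))
    return agg
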