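"""End-to-end orchestration: clip, FD map, cluster, evaluate, report.

The pipeline wires the stages together for file-based runs and parameter
sweeps.  Every stochastic component receives its seed from one master seed,
and a provenance record (configuration, seed, package version, input
checksums) is written next to the outputs so a run can be reproduced
exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__ as _version
from .clipping import ClipConfig, clip_pipeline, extract_wall
from .clustering import ClusterConfig, segment_fibrosis
from .errors import ValidationError
from .fractal import fd_map
from .io import LabelMask, Volume, read_mask, read_volume, write_mask
from .metrics import evaluate_masks

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of a full run.

    ``wall_thickness`` controls extraction of the myocardial shell from the
    clipped LA (cavity + wall) mask before clustering; set it to 0 when the
    input mask already delineates the wall only.
    """

    volume_path: str = ""
    la_mask_path: str = ""
    clipped_path: str | None = None   # provide to skip automatic clipping
    truth_path: str | None = None     # ground-truth fibrosis mask, optional
    out_dir: str = "fkmeans_run"
    clip: ClipConfig = field(default_factory=ClipConfig)
    cluster: ClusterConfig = field(default_factory=ClusterConfig)
    R: int = 7
    wall_thickness: int = 4
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        clip = ClipConfig(**raw.pop("clip", {}))
        cluster = ClusterConfig(**{k: (tuple(map(tuple, v)) if k == "level_k_ranges" else v)
                                   for k, v in raw.pop("cluster", {}).items()})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(clip=clip, cluster=cluster, **raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_full(config: RunConfig,
             volume: Volume | None = None,
             la_mask: LabelMask | None = None,
             truth: LabelMask | None = None) -> dict:
    """Run clipping, FD mapping, hierarchical clustering and evaluation.

    Inputs may be passed in memory (``volume``, ``la_mask``, ``truth``) or
    read from the paths in ``config``.  Returns a summary dict; all masks,
    the metric report and the provenance record are written to
    ``config.out_dir``.
    """
    t0 = time.time()
    config.cluster.seed = config.seed
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))

    prov_inputs = {}
    if volume is None:
        volume = read_volume(config.volume_path)
        prov_inputs["volume"] = _sha256(Path(config.volume_path))
    if la_mask is None and config.la_mask_path:
        la_mask = read_mask(config.la_mask_path)
        prov_inputs["la_mask"] = _sha256(Path(config.la_mask_path))
    if truth is None and config.truth_path:
        truth = read_mask(config.truth_path)
        prov_inputs["truth"] = _sha256(Path(config.truth_path))

    fdmap = fd_map(volume, R=config.R)

    if config.clipped_path:
        clipped = read_mask(config.clipped_path)
        prov_inputs["clipped"] = _sha256(Path(config.clipped_path))
        clip_info = {"mode": "provided"}
    else:
        if la_mask is None:
            raise ValidationError("either an LA mask or a clipped mask is required")
        result = clip_pipeline(volume, la_mask, config.clip, fdmap=fdmap,
                               return_details=True)
        clipped = result.mask
        clip_info = {"mode": "voronoi", "n_cells": 0 if result.partition is None
                     else result.partition.n_cells,
                     "flagged_cells": sorted(result.flagged)}
        write_mask(clipped, out / "clipped_la.nii.gz")

    domain = extract_wall(clipped, config.wall_thickness) \
        if config.wall_thickness > 0 else clipped

    seg = segment_fibrosis(volume, domain, fdmap, config.cluster,
                           return_details=True)
    write_mask(seg.mask, out / "fibrosis.nii.gz")

    summary = {
        "clip": clip_info,
        "levels": [{"selected_k": lv.selected_k, "skipped": lv.skipped,
                    "history": [{"k": h[0], "mean_fd": h[1], "var_fd": h[2],
                                 "stop": h[3]} for h in lv.history]}
                   for lv in seg.levels],
        "n_fibrosis_voxels": int((seg.mask.data > 0).sum()),
        "runtime_s": round(time.time() - t0, 2),
    }
    if truth is not None:
        report = evaluate_masks(seg.mask.data > 0, truth.data > 0,
                                spacing=volume.spacing)
        summary["metrics"] = report.as_dict()
    (out / "report.json").write_text(json.dumps(summary, indent=2))
    provenance = {"config": config.to_dict(), "inputs": prov_inputs,
                  "seed": config.seed, "version": _version}
    (out / "provenance.json").write_text(json.dumps(provenance, indent=2,
                                                    default=str))
    return summary


def parameter_sweep(volume: Volume, clipped_la: LabelMask, truth: LabelMask,
                    fdmaps_R: dict | None = None,
                    tau1_values=(0.05, 0.1, 0.2),
                    tau2_values=(0.025, 0.05, 0.1),
                    R_values=(4, 7, 8),
                    base_config: ClusterConfig | None = None,
                    csv_path=None) -> list[dict]:
    """Grid sweep over the stopping thresholds and the FD scaling factor.

    Runs the fibrosis segmentation once per (tau1, tau2, R) combination on a
    fixed input and records the Dice score against ``truth``; FD maps are
    computed once per R.  Returns the rows and optionally writes a CSV.
    """
    from .metrics import dice as dice_fn

    base = base_config or ClusterConfig()
    if fdmaps_R is None:
        fdmaps_R = {}
    rows = []
    for R in R_values:
        if R not in fdmaps_R:
            fdmaps_R[R] = fd_map(volume, R=R)
        for tau1 in tau1_values:
            for tau2 in tau2_values:
                cfg = dataclasses.replace(base, tau1=tau1, tau2=tau2)
                mask = segment_fibrosis(volume, clipped_la, fdmaps_R[R], cfg)
                rows.append({"tau1": tau1, "tau2": tau2, "R": R,
                             "dice": dice_fn(mask.data > 0, truth.data > 0)})
    if csv_path:
        import csv

        with open(csv_path, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=["tau1", "tau2", "R", "dice"])
            writer.writeheader()
            writer.writerows(rows)
    return rows
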