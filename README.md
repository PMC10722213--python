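# fkmeans

Fractal-guided K-means segmentation of left-atrial fibrosis from 3D
LGE-MRI-like volumes, with automatic Voronoi-based clipping of the mitral
valve, pulmonary veins and appendage.

## The problem

Fibrosis of the left-atrial (LA) wall retains gadolinium contrast and shows
up in late gadolinium enhancement (LGE) MRI as bright, texturally irregular
wall tissue. Quantifying it automatically is hard for two reasons: the
anatomical structures attached to the atrium (mitral valve MV, pulmonary
veins PVs, appendage LAA) mimic fibrotic signal and must be excluded first,
and plain intensity thresholds are unstable across scanners. This package
implements a texture-driven pipeline for both steps, aimed at researchers
evaluating fibrosis-segmentation methodology:

1. **Clipping** — the periatrial region is partitioned into Voronoi cells
   around candidates found far from the LA wall in a per-slice distance map.
   Each cell is described by its differential box-counting fractal dimension
   (FD) and the tortuosity of its skeleton spine; adjacent cells differing by
   at least 0.7 in FD *and* 1.0 in tortuosity indicate an attached structure
   (snake-like = vein), which is removed from the LA mask.
2. **Fibrosis clustering** — the clipped LA wall voxels are clustered by a
   hierarchical K-means++ whose distance between a point `x` and centroid `c`
   is penalized by fractal dimension,

   `d(x,c) = sqrt(||x−c||² + β·(FD(x)−FD(c))² + γ·(FD(x)−mean FD(cᵢ))²)`,

   with β = 0.1, γ = 0.5. Three levels with cluster ranges 2–30, 2–5, 2–3
   refine the candidate region; within each level the number of clusters
   grows until the mean/variance of FD in the maximum-FD cluster jumps by
   τ₁ = 0.1 / τ₂ = 0.05. The final maximum-FD cluster is the fibrosis mask.

The per-pixel FD uses differential box counting:
`N_r = (R²/r²)·(M_r − m_r)/r + 1` over window scales `2 < r < R` (R = 7), and
FD is the slope of `log N_r` vs `log(1/r)`. Tortuosity is the spine length
over the endpoint distance (L/D) of a shape's pruned skeleton.

A synthetic LA **phantom** generator (ellipsoidal pool and wall, snaking
textured veins with a configurable tortuosity target, smooth valve and
appendage, one compact textured fibrotic patch, partial-volume blur and
noise) makes every stage testable without patient data. Standard evaluation
metrics (Dice, precision, recall, ASSD, MSSD, HD, HD95, ICC(2,1)) are
included.

## A worked example

```python
import numpy as np
from fkmeans import (PhantomSpec, generate_phantom, fd_map, extract_wall,
                     ClusterConfig, LabelMask)
from fkmeans.clustering import segment_fibrosis
from fkmeans.metrics import dice

volume, truth = generate_phantom(PhantomSpec(seed=5))
la = np.isin(truth.data, [truth.label_map["la"], truth.label_map["fibrosis"]])
wall = extract_wall(LabelMask(data=la.astype(np.int32),
                              label_map={"background": 0, "la": 1}), thickness=4)
result = segment_fibrosis(volume, wall, fd_map(volume, R=7),
                          ClusterConfig(seed=5), return_details=True)
for i, mask in enumerate(result.level_masks, 1):
    print(f"level {i}: Dice = {dice(mask.data > 0, truth.data == 5):.3f}")
```

prints (seed 5)

```
level 1: Dice = 0.494
level 2: Dice = 0.940
level 3: Dice = 0.940
```

— the first level isolates a coarse high-FD region, the second locks onto
the planted patch, and the third finds nothing further to refine. The
scripts in `examples/` walk through each capability the same way (phantom
generation, FD maps, clipping with per-cell features, segmentation with the
stopping trace, the metric suite); `fkmeans --help` exposes the same
pipeline as a command-line tool (`phantom`, `fdmap`, `clip`, `segment`,
`evaluate`, `run`, `sweep`).

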