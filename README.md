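# adaptivetrack

Contour-based object tracking for 2D and 3D image sequences in which
every field — the level-set shape, the optical flow, the sparse
brightness error and the relaxed segmentation indicator — lives on an
adaptive quadtree (2D) or octree (3D) that is finest along the moving
front.  Away from the front, cells merge and carry pixel averages, so a
sequence is processed with a small fraction of the degrees of freedom
of the uniform pixel grid without giving up accuracy at the contour.

The intended users are people tracking deforming shapes in biomedical
image sequences — vessel cross-sections through a stack, a beating
heart over time, cells under large deformation — where the object's
boundary is the only region that needs full resolution.

## Method

Given consecutive frames `I(t-1)` and `I(t)` and the previous shape
`φ(t-1)` (a signed distance, interior `φ > 0`), each frame is processed
in three coupled pieces:

**Registration with sparse-error reconstruction.**  The displacement
`u` and the corruption field `G` (occlusion, shading, illumination
jumps) jointly minimise

    E(u, G) = ∫ ρ(|I(x+u, t) − I(x, t−1) − G|²)
            + α_u ∫ ρ(|∇u|² + |∇v|²) + α_g1 ∫ ρ(|G|²) + α_g2 ∫ ρ(|∇G|²)

with the Charbonnier penaliser `ρ(s²) = √(s² + ε²)`.  The
Euler–Lagrange system is solved coarse-to-fine with lagged-nonlinearity
fixed-point iterations; a shape-coupling term registers the previous
contour onto the current one inside a narrow band.

**Convex-relaxed segmentation.**  The indicator `φ⁰ ∈ [0, 1]` minimises
a weighted total variation plus a region term,

    min_{0≤φ⁰≤1}  TV_w(φ⁰) + α_s1 ∫ η(x) φ⁰ dx ,
    η = ln p(I|θ₂)/p(I|θ₁),  w = g + w_p·dp² + w_c·dc² ,

where `θ₁`/`θ₂` are foreground/background gray-level histograms,
`g = 1/(1 + γ|∇I_σ|²)` is the edge function, and `dp²`, `dc²` are the
squared dynamic-prior and flow-warped combination shapes, which make
the TV cheapest where the prior expects the contour.  The box
constraint is handled exactly by a penalty; the split problem
alternates a Chambolle dual projection step with a closed-form
pointwise update.

**Adaptive trees.**  All fields are node-sampled on a Whitney-refined
Quad-/Oc-tree: a cell is split while `min |φ|` over its corners is
below half the Lipschitz constant times its diagonal, so the finest
(pixel-sized) cells concentrate in a band around the zero level set.
The tree is 2:1 graded; missing neighbors at T-junctions are
reconstructed by third-order ghost interpolation, and all first/second
derivatives use nonuniform central or minmod-limited one-sided
differences that are exact on quadratics.  Thresholded indicators are
converted back to signed distance by a subcell-pinned reinitialization
solve of `φ_τ + S(φ)(|∇φ| − 1) = 0`.

## Worked example

Track the two-disk vortex benchmark — two textured disks (radii 0.15
and 0.10 in the unit square, interior intensities 200–255, exterior
50–155) deformed by the divergence-free field
`u = −sin²(πx) sin(2πy)`, `v = sin²(πy) sin(2πx)`:

```python
import numpy as np
from adaptivetrack import RunConfig, VortexSpec, make_vortex_sequence, track_sequence

spec = VortexSpec(n_frames=10, size=100, seed=0)
frames, truth = make_vortex_sequence(spec)
result = track_sequence(frames, truth[0], RunConfig(seed=0), truth_masks=truth)
d = [r["dice"] for r in result["diagnostics"][1:]]
print(f"mean Dice over tracked frames: {np.mean(d):.3f} (min {min(d):.3f})")
print(f"degrees of freedom: {result['diagnostics'][1]['leaf_count']} leaves "
      f"vs {100*100} uniform cells")
```

prints

```
mean Dice over tracked frames: 0.989 (min 0.986)
degrees of freedom: 1438 leaves vs 10000 uniform cells
```

i.e. the tracker follows the deforming disks at Dice ≈ 0.99 against the
RK4-traced ground truth while processing about 14% of the uniform
grid's cells.  Masks, sub-pixel contours and per-frame diagnostics can
be written with `adaptivetrack.io.write_outputs`, or from the shell:

```bash
adaptivetrack synth --frames 10 --size 100 --seed 0 --out data
adaptivetrack track2d --frames data/frames --init-mask data/truth/mask_0000.png \
    --truth data/truth --out results
adaptivetrack eval --pred results --truth data/truth
```

## Layout

- `adaptivetrack.tree` / `operators` — Quad-/Oc-tree construction,
  grading, vertex neighborhoods, sparse derivative operators
- `adaptivetrack.stencils` — ghost-node and finite-difference formulas
- `adaptivetrack.levelset` — interpolation, advection, reinitialization,
  mask ↔ signed-distance conversion
- `adaptivetrack.registration` — flow + sparse-error solver
- `adaptivetrack.segmentation` — histograms, edge/prior weights,
  relaxed TV segmentation
- `adaptivetrack.tracking` — per-frame pipeline and 3D initialisation
- `adaptivetrack.synthetic` — vortex/translation/sphere generators with
  analytic ground truth
- `adaptivetrack.io`, `adaptivetrack.cli`, `adaptivetrack.config` —
  files, command line, configuration

See `docs/methods.md` for the numerical choices and their rationale.
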