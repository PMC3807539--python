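# polarswarm

Unsupervised segmentation of star-convex organs in 2-D grayscale medical
images (CT/MR slices of the heart and ventricles are the motivating case) by
**multiswarm particle swarm optimization over constrained polar sections**,
with a **shape prior** built by aligning expert-delineated binary shapes.

Manual delineation of cardiac structures is slow and subjective; classic
active contours are sensitive to initialization and local minima. This
package replaces contour evolution with a global, population-based search:

1. **Shape prior.** A training set of binary shapes is aligned by per-shape
   similarity transforms (translation *a, b*, scale *s*, rotation *θ*)
   minimizing the pairwise overlap energy

   `E_alig = Σ_i Σ_{j≠i} ∫(Ĩ_i − Ĩ_j)² dA / ∫(Ĩ_i + Ĩ_j)² dA`

   by gradient descent. The aligned shapes are superimposed; the boundary of
   their union is the *template*.
2. **Placement.** The template is positioned on the target image at the
   translation maximizing the mutual information between the image and the
   two-level template rendering; the placed template centroid becomes the
   origin of a polar coordinate system with *K* angular sections (one per
   contour control point, or *snaxel*).
3. **Multiswarm search.** The template boundary radius in each section is
   rescaled by *n* evenly spaced factors, producing *n* scaled contours that
   bracket the target boundary. The *n* radii of each section seed one swarm
   of particles confined to that section's radial interval. Each swarm
   independently iterates the PSO update

   `v ← φ·v + κ·r₁·(p_best − x) + κ·r₂·(p_gbest − x)`, `x ← x + v`

   with inertia φ, learning factor κ, r₁, r₂ ~ U(0, 1), minimizing a fitness
   equal to the Euclidean distance-map value of the image edge set at the
   particle's position (0 = on an edge). Out-of-bound particles are clamped
   with zeroed velocity.
4. **Assembly.** The per-section best particles, connected in angular order,
   form the closed segmentation contour; its filled polygon is the result
   mask.

A Chan–Vese energy with shape prior (`E_T = w₁E₁ + w₂E₂ + w₃E₃`: region
fidelity with length/area penalties, squared Heaviside mismatch against the
transformed template, and an image-gradient coupling term) is provided for
scoring configurations and as an optional additive fitness term. Validation
uses five measures: Jaccard *J*, Dice *D = 2J/(1+J)*, Pearson correlation of
the indicator fields, directed Hausdorff distance between edge sets, and the
maximum cardinality similarity metric
`R_n = (N/(N−TP))·(TP/(TP+FN) − TP/N)`.

Because the clinical datasets behind the method are not publicly deposited,
the package ships a phantom generator (`polarswarm.phantoms`) producing
star-convex, noisy, cardiac-like images and training sets with *planted*
similarity transforms, so every stage is testable end to end.

## Worked example

```python
import numpy as np
from polarswarm import (PhantomSpec, PsoConfig, build_template, evaluate,
                        make_shape_mask, render_phantom, run_segmentation)

spec = PhantomSpec(seed=3)                      # noisy cardiac-like phantom
truth = make_shape_mask(spec, (128, 128))
image, truth = render_phantom(truth, spec)

template = build_template([make_shape_mask(PhantomSpec(seed=7), (128, 128))])
result = run_segmentation(image, template, PsoConfig(seed=1))

report = evaluate(truth, result.mask)
print(f"origin  = ({result.origin[0]:.1f}, {result.origin[1]:.1f})")
for k, v in report.as_dict().items():
    print(f"{k:11s} = {v:.4f}")
```

prints

```
origin  = (63.2, 73.8)
jaccard     = 0.9707
dice        = 0.9851
correlation = 0.9792
hausdorff   = 1.4142
mcsm        = 0.4163
```

The template was placed within a fraction of a pixel of the phantom, and the
45-point contour recovers 98.5 % Dice overlap with the ground truth despite
σ = 0.05 additive noise; the directed Hausdorff distance of 1.41 px says the
worst boundary point is a single diagonal pixel off. The MCSM at its strict
default (exact edge-pixel coincidence) is low by construction — rasterized
polygon edges rarely land on the exact truth edge pixels — and rises to ≈ 0.99
with a 1 px matching tolerance.

`PsoConfig()` defaults to the CT preset (9 scaled contours, 45 snaxels,
10 iterations, inertia 0.5, learning factor 0.9); `MR_PRESET` holds the MR
settings (7, 35, 10, 0.4, 0.7).

## Command line

```sh
polarswarm synth  --out data --seed 3                 # phantom + training set
polarswarm align  --shapes data/shapes --out template.png --params params.json
polarswarm segment --image data/image.png --template template.png \
                   --preset ct --seed 1 --out mask.png
polarswarm evaluate --ref data/truth.png --res mask.png --out report.json
polarswarm run    --config pipeline.yaml              # all stages + manifest
```

Every run is deterministic for a fixed seed; `run` writes a manifest with
input hashes, timings and the exact config so results can be reproduced
bit-for-bit.

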