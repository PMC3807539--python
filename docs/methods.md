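# Methods

This note records the model, the numerical choices, and the limits of what
the test suite demonstrates.

## Model and procedure

The segmentation target is assumed to be a single bright, quasi-convex
region on a darker background, **star-convex about the placed template
centroid**: every ray from the origin crosses the object boundary exactly
once. This is the geometric premise of the whole construction — each polar
section then contains exactly one boundary solution, so the search space
factorizes into K independent 1-D problems.

**Shape prior.** Training shapes are binary masks of the same organ drawn
by different observers (emulated here by planted similarity transforms of a
base shape). Alignment minimizes the normalized pairwise overlap energy
E_alig (a sum over ordered shape pairs of squared-difference over
squared-sum integrals) with respect to per-shape translation, scale and
rotation. The first shape is anchored at the identity: E_alig is invariant
under a global similarity transform of all shapes, and anchoring removes
that gauge freedom. The template is the pixelwise union of the aligned
shapes; its inner 4-connected boundary is the "maximum shape boundary" and
its foreground centroid is the reference origin for the polar grid.

**Placement.** The template union, rendered as a two-level image, is
translated over the frame; the translation maximizing the joint-histogram
mutual information (32 bins over [0, 1], natural log) wins, ties broken to
the smallest row then column. The default searches a stride-2 grid and
refines at stride 1 around the best cell; exhaustive stride-1 search is a
parameter away.

**Search.** Per section, particle radii are seeded by n factors evenly
spaced over `scale_range` applied to the template boundary radius at the
section bisector; the section's search interval is
[low·r_i, high·r_i]. Velocities start at zero — the scaled contours, not a
random cloud, are the intended initial population. Each swarm runs a fixed
number of synchronous PSO iterations (a stability stop — gbest change below
1e-6 for 3 consecutive iterations — is available via config). The fitness
of a particle is the bilinearly interpolated value of the Euclidean
distance transform of the image edge set at the particle's position;
positions outside the frame score +inf and are handled by the constraint
rule (clamp to the violated bound, zero the velocity; non-finite radii are
resampled uniformly in bounds). An optional fitness mode adds a per-section
shape penalty, the sector area between the particle radius and the template
radius, weighted by `energy_weight`; the default mode is pure distance-map
fitness.

**Determinism.** One master seed spawns one child RNG stream per section
(`numpy` SeedSequence), so the number of sections never perturbs another
section's draws, and identical inputs give bit-identical results.

## Parameters

| parameter | default | meaning |
|---|---|---|
| n_scaled_contours | 9 (CT) / 7 (MR) | particles per section, one per scaled contour |
| n_control_points | 45 (CT) / 35 (MR) | snaxels = polar sections K |
| iterations | 10 | synchronous PSO steps per swarm |
| inertia (φ) | 0.5 (CT) / 0.4 (MR) | weight of the previous velocity |
| learning (κ) | 0.9 (CT) / 0.7 (MR) | attraction to personal/swarm best |
| scale_range | (0.6, 1.4) | radial bracketing of the template contour |
| edge_threshold | 0.3 | edge = gradient magnitude > threshold × max |
| smooth_sigma | 1.0 px | Gaussian blur before the gradient |
| mi_bins / mi_stride | 32 / 2 | MI histogram bins, translation stride |

The CT/MR presets are the standard operating points of the method; the
remaining values are this package's choices. `scale_range` (0.6, 1.4)
spans ±40 % of the template radius — wide enough to bracket the boundary
deviations the phantoms produce (≤ 15 %) with a seeding step of 0.1·r per
contour. The edge detector is deliberately simple (central differences on
a lightly smoothed image with a relative threshold); the σ = 1 px blur
keeps σ = 0.05 intensity noise from seeding spurious edge pixels that
would anchor the distance map away from the true boundary.

## Energies

The Chan–Vese terms use the arctan-regularized Heaviside
H(v) = ½(1 + (2/π)·arctan(v/ε)) with ε = 1 by default: an ideal step would
make the energies ill-defined at φ = 0, and since no gradient flow is run,
the only requirement is a defined, monotone H with H(0) = ½. φ is the
signed Euclidean distance to the mask boundary, positive inside, with the
zero level on the half-pixel interface between the inner edge ring and the
background (the frame exterior counts as background, consistent with the
edge extraction). |∇H| is discretized with central differences and the
Euclidean norm of the two components. Default weights
w₁ = w₂ = w₃ = 1, μ = 0.1, ν = 0. This module scores configurations; it
does not evolve contours — the swarm search replaces level-set evolution.

## Alignment numerics

The overlap energy of binary resampled masks is piecewise constant in the
transform parameters, so descent uses central differences at per-parameter
probe units (0.5 px translation, 0.01 scale, 0.5° rotation) **scaled with
the current step length**: the gradient is measured at the scale of the
intended move, which keeps it defined on every plateau. Steps go along the
normalized negative gradient with backtracking halving from 8 probe units
down to 0.25; accepted steps strictly decrease the energy, so the trace is
monotone.

Descent from identity can stall in a joint local minimum where translation
compensates an unrecovered rotation. A warm-start stage therefore seeds
each shape by moment matching (scale from the area ratio, translation from
centroid matching) over a coarse rotation grid (±30° in 6° steps), refines
the three best candidates against the anchor, and keeps the winner — but
only if it lowers the energy, preserving monotonicity. Masks are resampled
by bilinear interpolation of the indicator thresholded at 0.5: output stays
binary while boundary aliasing (which otherwise floors E_alig and caps the
achievable energy reduction) is roughly halved relative to nearest
neighbour.

Rotation/scale pivot about the frame centre when a transform is applied to
a mask; the matrix itself is the ordered product translation × scale ×
rotation in (x, y) = (col, row) coordinates. Recovery of a planted
transform is judged by composing the recovered and planted centred maps
and reading the residual's translation norm, |s − 1| and |θ|.

## Phantoms

`make_shape_mask` rasterizes r(θ) = base(θ)·(1 + Σ_k a_k cos(kθ + φ_k)),
harmonics k = 2…5, with the summed |a_k| bounded by the perturbation
amplitude (< 0.5, keeping the shape star-convex); bases are a disk, an
ellipse, or a one-lobed "cardioid-like" profile. `render_phantom` paints
object/background intensities (0.8 / 0.2) plus clipped additive Gaussian
noise, default σ = 0.05. Default geometry: 128×128 frames, base radius
38 px. Training sets plant similarity transforms with |t| ≤ 6 px,
s ∈ [0.9, 1.1], |θ| ≤ 15° (resampled if the shape leaves the frame).

What the phantoms do **not** emulate: intensity inhomogeneity and partial
volume effects, textured backgrounds, neighbouring organs with competing
edges, anisotropic pixel spacing, and non-star-convex anatomy. Passing
tests therefore demonstrate the correctness of the machinery and its
behaviour under additive noise and shape variability — not clinical-grade
accuracy on real CT/MR data.

Planted-rotation recovery is exercised on elongated (ellipse-based)
shapes: for nearly circular shapes the rotation signal falls below the
rasterization noise floor and the pose is genuinely ambiguous — as it
would be for any method on such data.

## Known limitations

- One radial degree of freedom per section: boundaries that cross a
  section ray more than once (non-star-convex objects) cannot be
  represented; the phantom generator enforces star-convexity for this
  reason.
- The distance-map fitness is blind to edge polarity; a strong spurious
  edge inside the search annulus can capture a section's swarm. The
  optional energy fitness term mitigates this at the cost of biasing
  toward the template.
- MI placement searches translations only (the template is already scale-
  and rotation-normalized by the alignment stage); a target whose pose
  differs strongly from the training set will be placed suboptimally.
- Metrics require non-degenerate inputs (non-empty unions, non-constant
  indicators, non-empty edge sets); degenerate cases raise instead of
  returning conventional values.
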