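"""Synthetic cardiac-like phantoms: star-convex shapes, noisy renderings,
and training sets with planted similarity transforms.

The generators emulate what the method expects of a clinical slice: a
bright quasi-convex organ region on a darker background with additive
Gaussian noise and mild boundary concavities.  Shapes are star-convex
about their centre by construction — every radial ray crosses the boundary
exactly once — which is the geometric premise of the one-solution-per-
polar-section search.  All generators are bit-deterministic under a fixed
seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .alignment import ShapeParams, apply_transform, build_transform
from .imaging import as_mask

__all__ = [
    "PhantomSpec",
    "radial_profile",
    "make_shape_mask",
    "render_phantom",
    "make_training_set",
]


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one phantom.

    ``shape`` is ``disk``, ``ellipse`` or ``blob`` (a cardioid-like lobe);
    ``perturbation`` bounds the summed amplitude of random boundary
    harmonics (kept below 0.5 so the shape stays star-convex about its
    centre); intensities are in [0, 1] and ``noise_sigma`` is the additive
    Gaussian noise level in intensity units.
    """

    shape: str = "blob"
    radius: float = 38.0
    axes: tuple[float, float] | None = None  # ellipse semi-axes (a, b)
    perturbation: float = 0.12
    harmonics: tuple[int, ...] = (2, 3, 4, 5)
    object_intensity: float = 0.8
    background_intensity: float = 0.2
    noise_sigma: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.shape not in ("disk", "ellipse", "blob"):
            raise ValueError("shape must be disk, ellipse or blob")
        if self.object_intensity == self.background_intensity:
            raise ValueError("object and background intensities must differ")
        if not 0.0 <= self.perturbation < 0.5:
            raise ValueError("perturbation must lie in [0, 0.5)")
        if self.shape == "ellipse" and self.axes is None:
            raise ValueError("ellipse requires axes")


def radial_profile(spec: PhantomSpec, theta: np.ndarray) -> np.ndarray:
    """Boundary radius r(theta) of the phantom about its centre.

    Base profile (disk/ellipse/cardioid-like lobe) times
    ``1 + sum_k a_k cos(k theta + phi_k)`` with seeded coefficients whose
    summed magnitude is bounded by the perturbation amplitude.
    """
    t = np.asarray(theta, dtype=np.float64)
    if spec.shape == "disk":
        base = np.full_like(t, spec.radius)
    elif spec.shape == "ellipse":
        a, b = spec.axes
        base = a * b / np.sqrt((b * np.cos(t)) ** 2 + (a * np.sin(t)) ** 2)
    else:  # blob: mild single-lobe asymmetry, still star-convex
        base = spec.radius * (1.0 + 0.25 * np.cos(t))
    if spec.perturbation == 0:
        return base
    rng = np.random.default_rng(spec.seed)
    ks = np.array(spec.harmonics)
    amps = rng.uniform(0.2, 1.0, size=len(ks))
    amps *= spec.perturbation / amps.sum()
    phases = rng.uniform(0.0, 2.0 * math.pi, size=len(ks))
    wiggle = np.zeros_like(t)
    for k, a_k, p_k in zip(ks, amps, phases):
        wiggle += a_k * np.cos(k * t + p_k)
    return base * (1.0 + wiggle)


def make_shape_mask(
    spec: PhantomSpec,
    frame_shape: tuple[int, int] = (128, 128),
    center: tuple[float, float] | None = None,
) -> np.ndarray:
    """Rasterize the star-convex phantom boundary into a binary mask.

    A pixel is foreground iff its radius about the centre does not exceed
    ``r(theta)`` at its angle.  Raises if the shape would leave the frame.
    """
    h, w = frame_shape
    cr, cc = center if center is not None else ((h - 1) / 2.0, (w - 1) / 2.0)
    rows, cols = np.mgrid[0:h, 0:w]
    dr = rows - cr
    dc = cols - cc
    theta = np.arctan2(dr, dc)
    r_at = radial_profile(spec, theta)
    mask = (np.hypot(dr, dc) <= r_at).astype(np.uint8)
    # frame check: the analytic maximum radius must stay inside the border
    probe = radial_profile(spec, np.linspace(0.0, 2.0 * math.pi, 720))
    rmax = float(probe.max())
    if (cr - rmax < 0.5 or cc - rmax < 0.5
            or cr + rmax > h - 1.5 or cc + rmax > w - 1.5):
        raise ValueError("shape exceeds the frame")
    return mask


def render_phantom(
    mask: np.ndarray, spec: PhantomSpec
) -> tuple[np.ndarray, np.ndarray]:
    """Intensity rendering plus ground truth.

    Object/background intensities with additive seeded Gaussian noise,
    clipped to [0, 1]; the noiseless mask is returned as ground truth.
    """
    m = as_mask(mask)
    img = np.where(m > 0, spec.object_intensity, spec.background_intensity)
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
        img = img + rng.normal(0.0, spec.noise_sigma, size=m.shape)
    return np.clip(img, 0.0, 1.0), m.copy()


def make_training_set(
    base_mask: np.ndarray,
    n: int = 8,
    translate_range: float = 6.0,
    scale_range: tuple[float, float] = (0.9, 1.1),
    rotate_range: float = math.radians(15.0),
    seed: int = 0,
    max_attempts: int = 100,
) -> tuple[list[np.ndarray], list[ShapeParams]]:
    """n similarity-transformed copies of a base shape with planted params.

    Emulates a manually delineated training set (default 8 shapes) whose
    members differ in pose; the planted parameters are returned for
    recovery tests.  Transforms that push the shape out of frame (or to
    empty) are resampled, up to ``max_attempts`` per shape.
    """
    if n < 2:
        raise ValueError("need at least two training shapes")
    base = as_mask(base_mask)
    rng = np.random.default_rng(seed)
    masks: list[np.ndarray] = []
    planted: list[ShapeParams] = []
    for _ in range(n):
        for attempt in range(max_attempts):
            p = ShapeParams(
                a=float(rng.uniform(-translate_range, translate_range)),
                b=float(rng.uniform(-translate_range, translate_range)),
                s=float(rng.uniform(*scale_range)),
                theta=float(rng.uniform(-rotate_range, rotate_range)),
            )
            m = apply_transform(base, build_transform(p))
            in_frame = (
                m.any()
                and not m[0, :].any() and not m[-1, :].any()
                and not m[:, 0].any() and not m[:, -1].any()
            )
            if in_frame:
                masks.append(m)
                planted.append(p)
                break
        else:
            raise ValueError("could not place a transformed shape in frame")
    return masks, planted
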