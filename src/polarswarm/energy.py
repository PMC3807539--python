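"""Region/shape/image energies of the shape-prior active contour.

The total energy of a configuration ``phi`` (a signed-distance level-set
field) against an image ``I`` and a shape template is

    E_T = w1 E1 + w2 E2 + w3 E3

with ``E1`` the two-phase region (Chan--Vese) term with length and area
penalties, ``E2`` the squared Heaviside mismatch between ``phi`` and the
similarity-transformed template, and ``E3`` the squared difference between
the gradients of ``H(phi)`` and of the image.  This module *scores*
configurations; the search itself is performed by the polar multiswarm
optimizer, not by level-set evolution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alignment import SimilarityTransform, TemplateShape, apply_transform
from .imaging import as_image, signed_distance, smoothed_heaviside

__all__ = [
    "EnergyWeights",
    "EnergyBreakdown",
    "region_means",
    "region_energy",
    "shape_energy",
    "image_energy",
    "total_energy",
]

_DEGENERATE = 1e-9


@dataclass(frozen=True)
class EnergyWeights:
    """Weights of the three energy terms plus length/area penalties."""

    w1: float = 1.0
    w2: float = 1.0
    w3: float = 1.0
    mu: float = 0.1   # contour-length weight inside E1
    nu: float = 0.0   # area weight inside E1
    epsilon: float = 1.0  # Heaviside regularization width

    def __post_init__(self):
        if min(self.w1, self.w2, self.w3, self.mu, self.nu) < 0:
            raise ValueError("energy weights must be non-negative")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")


@dataclass(frozen=True)
class EnergyBreakdown:
    e1: float
    e2: float
    e3: float
    e_total: float
    c1: float
    c2: float


def region_means(image: np.ndarray, phi: np.ndarray, epsilon: float) -> tuple[float, float]:
    """Mean intensities of the object (``phi > 0``) and background regions.

    Weighted by the smoothed Heaviside, so both means are defined whenever
    neither region degenerates under the smoothing.
    """
    img = as_image(image)
    h = smoothed_heaviside(phi, epsilon)
    inside = float(h.sum())
    outside = float((1.0 - h).sum())
    if inside < _DEGENERATE or outside < _DEGENERATE:
        raise ValueError("empty region under Heaviside")
    c1 = float((img * h).sum()) / inside
    c2 = float((img * (1.0 - h)).sum()) / outside
    return c1, c2


def region_energy(image: np.ndarray, phi: np.ndarray, weights: EnergyWeights) -> float:
    """Two-phase fidelity plus length and area penalties (Chan--Vese)."""
    img = as_image(image)
    c1, c2 = region_means(img, phi, weights.epsilon)
    h = smoothed_heaviside(phi, weights.epsilon)
    fidelity = float(((img - c1) ** 2 * h).sum() + ((img - c2) ** 2 * (1.0 - h)).sum())
    gr, gc = np.gradient(h)
    length = float(np.hypot(gr, gc).sum())
    area = float(h.sum())
    return fidelity + weights.mu * length + weights.nu * area


def shape_energy(
    phi: np.ndarray,
    template: TemplateShape,
    transform: SimilarityTransform,
    epsilon: float,
) -> float:
    """Squared Heaviside mismatch between ``phi`` and the deformed template."""
    moved = apply_transform(template.union, transform)
    if not moved.any():
        raise ValueError("transform maps template fully outside the frame")
    phi_t = signed_distance(moved) if not moved.all() else None
    if phi_t is None:
        raise ValueError("transform maps template over the full frame")
    h = smoothed_heaviside(phi, epsilon)
    ht = smoothed_heaviside(phi_t, epsilon)
    return float(((h - ht) ** 2).sum())


def image_energy(phi: np.ndarray, image: np.ndarray, epsilon: float) -> float:
    """Squared difference between the gradients of ``H(phi)`` and the image."""
    img = as_image(image)
    h = smoothed_heaviside(phi, epsilon)
    ghr, ghc = np.gradient(h)
    gir, gic = np.gradient(img)
    return float(((ghr - gir) ** 2 + (ghc - gic) ** 2).sum())


def total_energy(
    image: np.ndarray,
    phi: np.ndarray,
    template: TemplateShape,
    transform: SimilarityTransform,
    weights: EnergyWeights | None = None,
) -> EnergyBreakdown:
    """Weighted sum ``w1 E1 + w2 E2 + w3 E3`` with its components."""
    w = weights or EnergyWeights()
    c1, c2 = region_means(image, phi, w.epsilon)
    e1 = region_energy(image, phi, w)
    e2 = shape_energy(phi, template, transform, w.epsilon)
    e3 = image_energy(phi, image, w.epsilon)
    return EnergyBreakdown(
        e1=e1, e2=e2, e3=e3,
        e_total=w.w1 * e1 + w.w2 * e2 + w.w3 * e3,
        c1=c1, c2=c2,
    )
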