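"""Binary shape alignment and template construction.

A training set of binary shapes (expert delineations of the same organ) is
brought into a common pose by per-shape similarity transforms — translation
``(a, b)``, isotropic scale ``s`` and in-plane rotation ``theta`` — found by
gradient descent on the pairwise overlap energy

    E_alig = sum_i sum_{j != i}  sum((S_i - S_j)^2) / sum((S_i + S_j)^2)

over the transformed shapes.  The aligned shapes are superimposed and the
boundary of their union becomes the shape template whose centroid later
anchors the polar coordinate system of the swarm search.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .imaging import as_mask, edge_mask

log = logging.getLogger(__name__)

__all__ = [
    "ShapeParams",
    "SimilarityTransform",
    "AlignConfig",
    "AlignmentResult",
    "TemplateShape",
    "build_transform",
    "transform_points",
    "apply_transform",
    "pair_energy",
    "alignment_energy",
    "align_shapes",
    "build_template",
    "centered_matrix",
    "params_from_matrix",
]


def _wrap_angle(theta: float) -> float:
    """Normalize an angle to (-pi, pi]."""
    t = math.remainder(theta, 2.0 * math.pi)
    return math.pi if t == -math.pi else t


@dataclass(frozen=True)
class ShapeParams:
    """Similarity-transform parameters ``[a, b, s, theta]``.

    ``a``/``b`` translate along x (columns) and y (rows) in pixels,
    ``s > 0`` scales isotropically and ``theta`` rotates counterclockwise
    in the (x, y) plane, normalized to (-pi, pi].
    """

    a: float = 0.0
    b: float = 0.0
    s: float = 1.0
    theta: float = 0.0

    def __post_init__(self):
        if not self.s > 0:
            raise ValueError("scale s must be positive")
        object.__setattr__(self, "theta", _wrap_angle(self.theta))

    def as_array(self) -> np.ndarray:
        return np.array([self.a, self.b, self.s, self.theta], dtype=np.float64)


@dataclass(frozen=True)
class SimilarityTransform:
    """Homogeneous 3x3 similarity transform ``M(a,b) @ H(s) @ R(theta)``."""

    matrix: np.ndarray
    params: ShapeParams


def build_transform(params: ShapeParams) -> SimilarityTransform:
    """Build the ordered product translation x scale x rotation.

    Maps ``(x, y) -> (s (x cos t - y sin t) + a, s (x sin t + y cos t) + b)``.
    """
    if not params.s > 0:
        raise ValueError("scale s must be positive")
    a, b, s, t = params.a, params.b, params.s, params.theta
    m_trans = np.array([[1, 0, a], [0, 1, b], [0, 0, 1]], dtype=np.float64)
    m_scale = np.diag([s, s, 1.0])
    c, sn = math.cos(t), math.sin(t)
    m_rot = np.array([[c, -sn, 0], [sn, c, 0], [0, 0, 1]], dtype=np.float64)
    return SimilarityTransform(matrix=m_trans @ m_scale @ m_rot, params=params)


def transform_points(transform: SimilarityTransform, xy: np.ndarray) -> np.ndarray:
    """Apply the homogeneous matrix to ``(n, 2)`` points in (x, y) order."""
    pts = np.atleast_2d(np.asarray(xy, dtype=np.float64))
    hom = np.column_stack([pts, np.ones(len(pts))])
    out = hom @ transform.matrix.T
    return out[:, :2]


def _rc_forward(params: ShapeParams) -> tuple[np.ndarray, np.ndarray]:
    """Linear part and translation of the map in (row, col) coordinates."""
    s, t = params.s, params.theta
    c, sn = math.cos(t), math.sin(t)
    lin = s * np.array([[c, sn], [-sn, c]], dtype=np.float64)
    off = np.array([params.b, params.a], dtype=np.float64)
    return lin, off


def apply_transform(
    mask: np.ndarray,
    transform: SimilarityTransform,
    about_origin: bool = False,
) -> np.ndarray:
    """Resample a mask under a similarity transform (binary output).

    The {0, 1} indicator is resampled bilinearly through the inverse map
    and thresholded at one half, which keeps the result binary while
    halving the boundary aliasing a pure nearest-neighbour lookup leaves
    (that aliasing otherwise floors the alignment energy).  By default
    rotation and scale pivot about the frame centre, which keeps
    translation, scale and rotation parameters decoupled during alignment;
    ``about_origin=True`` applies the matrix literally about pixel (0, 0).
    Pixels mapping outside the frame become background; output shares the
    input frame size.
    """
    m = as_mask(mask)
    lin, off = _rc_forward(transform.params)
    inv = np.linalg.inv(lin)
    if about_origin:
        offset = -inv @ off
    else:
        c0 = (np.array(m.shape, dtype=np.float64) - 1.0) / 2.0
        offset = c0 - inv @ (c0 + off)
    out = ndimage.affine_transform(
        m.astype(np.float64), inv, offset=offset, order=1, mode="constant", cval=0.0
    )
    return (out > 0.5).astype(np.uint8)


def centered_matrix(params: ShapeParams, frame_shape: tuple[int, int]) -> np.ndarray:
    """3x3 matrix of the centred map in (row, col, 1) homogeneous coords."""
    lin, off = _rc_forward(params)
    c0 = (np.array(frame_shape, dtype=np.float64) - 1.0) / 2.0
    mat = np.eye(3)
    mat[:2, :2] = lin
    mat[:2, 2] = c0 + off - lin @ c0
    return mat


def params_from_matrix(mat: np.ndarray, frame_shape: tuple[int, int]) -> ShapeParams:
    """Recover ``(a, b, s, theta)`` of a centred (row, col) similarity matrix."""
    lin = mat[:2, :2]
    s = math.sqrt(abs(np.linalg.det(lin)))
    # rc linear part is s * [[cos, sin], [-sin, cos]]
    theta = math.atan2(lin[0, 1], lin[0, 0])
    c0 = (np.array(frame_shape, dtype=np.float64) - 1.0) / 2.0
    off = mat[:2, 2] - c0 + lin @ c0
    return ShapeParams(a=float(off[1]), b=float(off[0]), s=s, theta=theta)


# ---------------------------------------------------------------------------
# Alignment energy
# ---------------------------------------------------------------------------

def pair_energy(a: np.ndarray, b: np.ndarray) -> float:
    """Overlap mismatch of one ordered shape pair (symmetric in a, b)."""
    fa = as_mask(a).astype(np.float64)
    fb = as_mask(b).astype(np.float64)
    denom = float(((fa + fb) ** 2).sum())
    if denom == 0.0:
        raise ValueError("degenerate pair: both shapes empty")
    return float(((fa - fb) ** 2).sum()) / denom


def alignment_energy(shapes: list[np.ndarray]) -> float:
    """Pairwise overlap energy summed over all ordered shape pairs."""
    if len(shapes) < 2:
        raise ValueError("need at least two shapes")
    masks = [as_mask(s) for s in shapes]
    frame = masks[0].shape
    for m in masks:
        if m.shape != frame:
            raise ValueError("shapes must share a frame size")
        if not m.any():
            raise ValueError("degenerate pair: empty shape")
    total = 0.0
    for i in range(len(masks)):
        for j in range(len(masks)):
            if i != j:
                total += pair_energy(masks[i], masks[j])
    return total


@dataclass(frozen=True)
class AlignConfig:
    """Descent settings for :func:`align_shapes`.

    Probe steps define the finite-difference units per parameter; the step
    along the normalized gradient starts at ``initial_step`` probe units and
    halves on failure down to ``min_step``.
    """

    translate_probe: float = 0.5       # px
    scale_probe: float = 0.01
    rotate_probe: float = math.radians(0.5)
    initial_step: float = 8.0          # in probe units
    min_step: float = 0.25
    max_iters: int = 150
    tol: float = 1e-9


@dataclass
class AlignmentResult:
    params: list[ShapeParams]
    aligned: list[np.ndarray]
    energy_trace: np.ndarray = field(default_factory=lambda: np.empty(0))


def _partial_energy(cand: np.ndarray, others: list[np.ndarray]) -> float:
    """Total-energy contribution of one shape: twice its pair sums."""
    return 2.0 * sum(pair_energy(cand, o) for o in others)


def _moments(mask: np.ndarray) -> tuple[np.ndarray, float]:
    """Foreground centroid (row, col) and area of a mask."""
    rows, cols = np.nonzero(mask)
    return np.array([rows.mean(), cols.mean()]), float(len(rows))


_INIT_THETAS = np.radians(np.arange(-30.0, 30.1, 6.0))
_N_STARTS = 3


def _descend_one(
    mask: np.ndarray,
    start: ShapeParams,
    others: list[np.ndarray],
    cfg: "AlignConfig",
    probes: np.ndarray,
    max_sweeps: int,
) -> tuple[float, ShapeParams, np.ndarray]:
    """Backtracking gradient descent of one shape against fixed others."""
    vec = start.as_array()
    cand = apply_transform(mask, build_transform(start))
    best_e = _partial_energy(cand, others) if cand.any() else math.inf
    for _ in range(max_sweeps):
        improved = False
        step = cfg.initial_step
        while step >= cfg.min_step:
            # central differences at probes scaled with the current step:
            # the binary-resampled energy is piecewise constant, so the
            # gradient must be measured at the scale of the intended move
            probe_eff = probes * max(step, 1.0)
            grad = np.zeros(4)
            for k in range(4):
                for sign in (+1.0, -1.0):
                    trial = vec.copy()
                    trial[k] += sign * probe_eff[k]
                    trial[2] = max(trial[2], 0.05)
                    e = _partial_energy(
                        apply_transform(mask, build_transform(ShapeParams(*trial))),
                        others,
                    )
                    grad[k] += sign * e
                grad[k] /= 2.0
            norm = np.linalg.norm(grad)
            if norm > 0.0:
                trial = vec - step * probes * (grad / norm)
                trial[2] = max(trial[2], 0.05)
                trial_mask = apply_transform(mask, build_transform(ShapeParams(*trial)))
                if trial_mask.any():
                    e = _partial_energy(trial_mask, others)
                    if e < best_e - 1e-12:
                        vec, cand, best_e = trial, trial_mask, e
                        improved = True
                        break
            step /= 2.0
        if not improved:
            break
    return best_e, ShapeParams(*vec), cand


def _init_candidates(mask: np.ndarray, anchor: np.ndarray) -> list[ShapeParams]:
    """Moment-matched starting poses against the anchor shape.

    Scale from the area ratio and translation from centroid matching over a
    coarse grid of rotations.  The pairwise energy couples rotation and
    translation, so descent from identity can stall in a local minimum
    where translation compensates a wrong rotation; refining the few best
    candidates and keeping the winner avoids that.
    """
    cen_i, area_i = _moments(mask)
    cen_a, area_a = _moments(anchor)
    s = math.sqrt(area_a / area_i)
    c0 = (np.array(mask.shape, dtype=np.float64) - 1.0) / 2.0
    scored: list[tuple[float, ShapeParams]] = [
        (pair_energy(mask, anchor), ShapeParams())
    ]
    for theta in _INIT_THETAS:
        lin = s * np.array(
            [[math.cos(theta), math.sin(theta)],
             [-math.sin(theta), math.cos(theta)]]
        )
        off = cen_a - (lin @ (cen_i - c0) + c0)  # (row, col) translation
        p = ShapeParams(a=float(off[1]), b=float(off[0]), s=s, theta=float(theta))
        cand = apply_transform(mask, build_transform(p))
        if cand.any():
            scored.append((pair_energy(cand, anchor), p))
    scored.sort(key=lambda t: t[0])
    return [p for _, p in scored[:_N_STARTS]]


def align_shapes(
    shapes: list[np.ndarray], config: AlignConfig | None = None
) -> AlignmentResult:
    """Align shapes by gradient descent on the pairwise overlap energy.

    The first shape is anchored at identity (removing the global-pose gauge
    freedom); each remaining shape takes steps along its numerically
    estimated negative gradient with backtracking halving, so accepted
    steps never increase the energy.  Iterates until no shape improves, the
    energy change falls below ``tol``, or ``max_iters`` is reached.
    """
    cfg = config or AlignConfig()
    masks = [as_mask(s) for s in shapes]
    if len(masks) < 2:
        raise ValueError("need at least two shapes")
    n = len(masks)
    params = [ShapeParams() for _ in range(n)]
    aligned = [m.copy() for m in masks]
    probes = np.array(
        [cfg.translate_probe, cfg.translate_probe, cfg.scale_probe, cfg.rotate_probe]
    )

    energy = alignment_energy(aligned)
    if not math.isfinite(energy):
        raise ValueError("non-finite alignment energy")
    trace = [energy]
    # stage 1: multi-start descent of each shape against the anchor,
    # accepted per shape only when it lowers the total energy (keeps the
    # trace monotone from the identity initialization)
    for i in range(1, n):
        best: tuple[float, ShapeParams, np.ndarray] | None = None
        for start in _init_candidates(masks[i], masks[0]):
            out = _descend_one(masks[i], start, [masks[0]], cfg, probes,
                               max_sweeps=cfg.max_iters)
            if best is None or out[0] < best[0]:
                best = out
        others = [aligned[j] for j in range(n) if j != i]
        delta = _partial_energy(best[2], others) - _partial_energy(aligned[i], others)
        if delta < 0:
            params[i], aligned[i] = best[1], best[2]
            energy += delta
    trace.append(energy)
    # stage 2: joint sweeps over all pairs until convergence
    for _ in range(cfg.max_iters):
        improved = False
        for i in range(1, n):
            others = [aligned[j] for j in range(n) if j != i]
            base = _partial_energy(aligned[i], others)
            e, cand_params, cand = _descend_one(
                masks[i], params[i], others, cfg, probes, max_sweeps=1
            )
            if e < base - 1e-12:
                params[i], aligned[i] = cand_params, cand
                energy += e - base
                improved = True
        if not math.isfinite(energy):
            raise ValueError("non-finite alignment energy")
        trace.append(energy)
        if not improved or abs(trace[-2] - trace[-1]) < cfg.tol:
            break
    # recompute exactly to shed accumulated increment error
    trace[-1] = alignment_energy(aligned)
    return AlignmentResult(params=params, aligned=aligned,
                           energy_trace=np.asarray(trace))


# ---------------------------------------------------------------------------
# Template
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TemplateShape:
    """Superposition of aligned shapes and its maximum boundary."""

    union: np.ndarray      # binary mask, pixelwise max of the aligned shapes
    boundary: np.ndarray   # edge_mask(union)
    centroid: tuple[float, float]  # (row, col) foreground centroid of union


def build_template(aligned: list[np.ndarray]) -> TemplateShape:
    """Superimpose aligned shapes; the union's edge is the template boundary."""
    if not aligned:
        raise ValueError("no shapes to superimpose")
    masks = [as_mask(s) for s in aligned]
    union = np.maximum.reduce(masks)
    if not union.any():
        raise ValueError("all shapes empty: no template")
    rows, cols = np.nonzero(union)
    centroid = (float(rows.mean()), float(cols.mean()))
    return TemplateShape(union=union, boundary=edge_mask(union), centroid=centroid)
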