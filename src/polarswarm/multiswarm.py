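"""Multiswarm PSO segmentation over constrained polar sections.

The pipeline: the shape template is placed on the image at the translation
maximizing mutual information; a polar coordinate system with K angular
sections is erected at the placed template centroid; the template boundary
radius in each section is rescaled by n evenly spaced factors, giving n
scaled contours whose intersections with each section seed one swarm of n
particles; each swarm searches its section's radial interval independently,
driven by the PSO velocity update

    v <- phi * v + kappa * r1 * (pbest - x) + kappa * r2 * (gbest - x)
    x <- x + v

with a fitness equal to the (bilinearly interpolated) Euclidean distance-map
value at the particle's position, so fitness 0 means "on an image edge".
The segmented object is the filled polygon through the K per-section best
particles in angular order.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from skimage.draw import polygon as draw_polygon

from .alignment import TemplateShape
from .imaging import (
    MIN_SIDE,
    as_image,
    distance_map,
    gradient_edge_mask,
)

log = logging.getLogger(__name__)

__all__ = [
    "PsoConfig",
    "PolarGrid",
    "Swarm",
    "SegmentationResult",
    "CT_PRESET",
    "MR_PRESET",
    "mutual_information",
    "locate_origin",
    "template_radii",
    "generate_scaled_contours",
    "fitness",
    "constrain",
    "pso_step",
    "assemble_contour",
    "run_segmentation",
]


@dataclass(frozen=True)
class PsoConfig:
    """Swarm search settings.

    Defaults follow the CT preset: 9 scaled contours, 45 snaxels
    (= polar sections), 10 iterations, inertia 0.5, learning factor 0.9.
    """

    n_scaled_contours: int = 9
    n_control_points: int = 45
    iterations: int = 10
    inertia: float = 0.5
    learning: float = 0.9
    seed: int = 0
    scale_range: tuple[float, float] = (0.6, 1.4)
    stability_stop: bool = False
    stability_tol: float = 1e-6
    stability_window: int = 3
    edge_threshold: float = 0.3
    smooth_sigma: float = 1.0
    mi_bins: int = 32
    mi_stride: int = 2
    fitness_mode: str = "distance"   # or "energy"
    energy_weight: float = 0.05

    def __post_init__(self):
        if self.n_scaled_contours < 1:
            raise ValueError("n_scaled_contours must be >= 1")
        if self.n_control_points < 3:
            raise ValueError("n_control_points must be >= 3")
        if self.iterations < 0:
            raise ValueError("iterations must be non-negative")
        if self.inertia < 0 or self.learning < 0:
            raise ValueError("inertia and learning must be non-negative")
        lo, hi = self.scale_range
        if not 0 < lo <= hi:
            raise ValueError("scale_range must satisfy 0 < low <= high")
        if self.fitness_mode not in ("distance", "energy"):
            raise ValueError("fitness_mode must be 'distance' or 'energy'")


CT_PRESET = PsoConfig()
MR_PRESET = PsoConfig(n_scaled_contours=7, n_control_points=35,
                      inertia=0.4, learning=0.7)


@dataclass(frozen=True)
class PolarGrid:
    """K angular sections partitioning [0, 2pi) around an origin.

    Section i covers ``[2 pi i / K, 2 pi (i+1) / K)``; its bisector is the
    mid angle and carries the section's 1-D radial search ray.
    """

    origin: tuple[float, float]  # (row, col)
    n_sections: int

    def __post_init__(self):
        if self.n_sections < 3:
            raise ValueError("need at least 3 sections")

    def bisector(self, i: int) -> float:
        return 2.0 * math.pi * (i + 0.5) / self.n_sections

    def point(self, i: int, radius: float) -> tuple[float, float]:
        """(row, col) of the point at ``radius`` along section i's bisector."""
        t = self.bisector(i)
        return (self.origin[0] + radius * math.sin(t),
                self.origin[1] + radius * math.cos(t))


# ---------------------------------------------------------------------------
# Mutual-information template placement
# ---------------------------------------------------------------------------

def mutual_information(a: np.ndarray, b: np.ndarray, bins: int = 32) -> float:
    """Mutual information (natural log) of the joint intensity histogram."""
    ia, ib = as_image(a), as_image(b)
    if ia.shape != ib.shape:
        raise ValueError("frame sizes must match")
    if bins < 2:
        raise ValueError("bins must be >= 2")
    joint, _, _ = np.histogram2d(
        ia.ravel(), ib.ravel(), bins=bins, range=[[0.0, 1.0], [0.0, 1.0]]
    )
    pxy = joint / joint.sum()
    px = pxy.sum(axis=1)
    py = pxy.sum(axis=0)
    outer = np.outer(px, py)
    nz = pxy > 0
    return float((pxy[nz] * np.log(pxy[nz] / outer[nz])).sum())


def locate_origin(
    image: np.ndarray,
    template: TemplateShape,
    search_stride: int = 2,
    bins: int = 32,
) -> tuple[float, float]:
    """Place the template on the image by maximum mutual information.

    The template union is rendered as a two-level full-frame image at every
    in-frame translation on a stride grid (then refined at stride 1 around
    the best cell).  Ties break to the smallest row, then column.  Returns
    the template centroid under the winning translation.
    """
    img = as_image(image)
    rows, cols = np.nonzero(template.union)
    r0, r1 = rows.min(), rows.max()
    c0, c1 = cols.min(), cols.max()
    crop = template.union[r0:r1 + 1, c0:c1 + 1].astype(np.float64)
    th, tw = crop.shape
    hh, ww = img.shape
    if th >= hh or tw >= ww:
        raise ValueError("template must be smaller than the frame")
    cen_r = template.centroid[0] - r0
    cen_c = template.centroid[1] - c0

    def score(dr: int, dc: int) -> float:
        canvas = np.zeros_like(img)
        canvas[dr:dr + th, dc:dc + tw] = crop
        return mutual_information(img, canvas, bins=bins)

    def scan(r_range, c_range):
        best, best_pos = -math.inf, None
        for dr in r_range:
            for dc in c_range:
                mi = score(dr, dc)
                if mi > best:  # strict: first (lexicographic) max wins ties
                    best, best_pos = mi, (dr, dc)
        return best_pos

    pos = scan(range(0, hh - th + 1, search_stride),
               range(0, ww - tw + 1, search_stride))
    if pos is None:
        raise ValueError("no valid template placement")
    if search_stride > 1:
        dr0, dc0 = pos
        pos = scan(
            range(max(0, dr0 - search_stride), min(hh - th, dr0 + search_stride) + 1),
            range(max(0, dc0 - search_stride), min(ww - tw, dc0 + search_stride) + 1),
        )
    return (pos[0] + cen_r, pos[1] + cen_c)


# ---------------------------------------------------------------------------
# Scaled contours
# ---------------------------------------------------------------------------

def template_radii(template: TemplateShape, grid: PolarGrid) -> np.ndarray:
    """Template boundary radius at each section bisector, about the centroid.

    Measured by marching outward along each bisector ray through the
    template union (star-convexity assumed: the last inside sample is the
    boundary).  A ray that never meets the template is filled by circular
    linear interpolation from its neighbours, with a logged warning.
    """
    union = template.union.astype(bool)
    cr, cc = template.centroid
    rmax = math.hypot(*union.shape)
    k = grid.n_sections
    radii = np.full(k, np.nan)
    ts = np.arange(0.0, rmax, 0.25)
    for i in range(k):
        ang = grid.bisector(i)
        rr = np.rint(cr + ts * math.sin(ang)).astype(int)
        cc_ = np.rint(cc + ts * math.cos(ang)).astype(int)
        ok = (rr >= 0) & (rr < union.shape[0]) & (cc_ >= 0) & (cc_ < union.shape[1])
        inside = np.zeros(len(ts), dtype=bool)
        inside[ok] = union[rr[ok], cc_[ok]]
        if inside.any():
            radii[i] = ts[np.nonzero(inside)[0][-1]]
    missing = np.isnan(radii)
    if missing.all():
        raise ValueError("no bisector ray meets the template boundary")
    if missing.any():
        log.warning("interpolating %d sections whose ray misses the template",
                    int(missing.sum()))
        idx = np.arange(k)
        good = idx[~missing]
        angles = 2.0 * np.pi * (idx + 0.5) / k
        radii[missing] = np.interp(
            angles[missing], angles[good], radii[good], period=2.0 * np.pi
        )
    return radii


def generate_scaled_contours(
    template: TemplateShape, grid: PolarGrid, config: PsoConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Seed radii and bounds per section from n rescaled template contours.

    Returns ``(radii, bounds)`` with ``radii[i]`` the n initial particle
    radii of section i (template radius times n factors evenly spaced over
    ``scale_range``) and ``bounds[i] = (low * r_i, high * r_i)``.
    """
    base = template_radii(template, grid)
    lo, hi = config.scale_range
    n = config.n_scaled_contours
    factors = np.linspace(lo, hi, n) if n > 1 else np.array([lo])
    radii = base[:, None] * factors[None, :]
    bounds = np.column_stack([lo * base, hi * base])
    return radii, bounds


# ---------------------------------------------------------------------------
# Fitness
# ---------------------------------------------------------------------------

def _bilinear(dmap: np.ndarray, row: float, col: float) -> float:
    """Bilinear interpolation with edge clamping inside the frame."""
    h, w = dmap.shape
    r0 = min(int(math.floor(row)), h - 2) if h > 1 else 0
    c0 = min(int(math.floor(col)), w - 2) if w > 1 else 0
    r0 = max(r0, 0)
    c0 = max(c0, 0)
    fr = row - r0
    fc = col - c0
    return float(
        dmap[r0, c0] * (1.0 - fr) * (1.0 - fc)
        + dmap[r0, min(c0 + 1, w - 1)] * (1.0 - fr) * fc
        + dmap[min(r0 + 1, h - 1), c0] * fr * (1.0 - fc)
        + dmap[min(r0 + 1, h - 1), min(c0 + 1, w - 1)] * fr * fc
    )


def fitness(radius: float, section: int, grid: PolarGrid, dmap: np.ndarray) -> float:
    """Distance-map value at the particle's point; +inf outside the frame."""
    if not math.isfinite(radius):
        return math.inf
    row, col = grid.point(section, radius)
    h, w = dmap.shape
    if not (0.0 <= row <= h - 1 and 0.0 <= col <= w - 1):
        return math.inf
    return _bilinear(dmap, row, col)


# ---------------------------------------------------------------------------
# Swarms
# ---------------------------------------------------------------------------

@dataclass
class Swarm:
    """One section's particle swarm (1-D radial positions)."""

    section: int
    x: np.ndarray          # particle radii
    v: np.ndarray          # velocities
    pb_x: np.ndarray       # personal best radii
    pb_f: np.ndarray       # personal best fitnesses
    gb_x: float            # swarm best radius
    gb_f: float            # swarm best fitness
    bounds: tuple[float, float]
    trace: list = field(default_factory=list)  # gb_f after each evaluation


def constrain(
    radius: np.ndarray, velocity: np.ndarray,
    bounds: tuple[float, float], rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Restrict improper particles to the section's radial search space.

    Radii outside ``[r_min, r_max]`` are clamped to the violated bound with
    velocity zeroed; non-finite radii are resampled uniformly in bounds.
    """
    lo, hi = bounds
    if not lo < hi:
        raise ValueError("bounds must satisfy r_min < r_max")
    x = np.array(radius, dtype=np.float64, copy=True)
    v = np.array(velocity, dtype=np.float64, copy=True)
    bad = ~np.isfinite(x)
    if bad.any():
        x[bad] = rng.uniform(lo, hi, size=int(bad.sum()))
        v[bad] = 0.0
    low = x < lo
    high = x > hi
    x[low] = lo
    x[high] = hi
    v[low | high] = 0.0
    return x, v


def init_swarm(
    section: int,
    seeds: np.ndarray,
    bounds: tuple[float, float],
    fitness_fn,
    rng: np.random.Generator,
) -> Swarm:
    """Build a swarm from its seed radii and evaluate initial bests."""
    x, v = constrain(seeds, np.zeros_like(seeds, dtype=np.float64), bounds, rng)
    f = np.array([fitness_fn(xi) for xi in x])
    best = int(np.argmin(f))
    sw = Swarm(section=section, x=x, v=v, pb_x=x.copy(), pb_f=f,
               gb_x=float(x[best]), gb_f=float(f[best]), bounds=bounds)
    sw.trace.append(sw.gb_f)
    return sw


def pso_step(
    swarm: Swarm, config: PsoConfig, rng: np.random.Generator, fitness_fn
) -> Swarm:
    """One synchronous PSO iteration: velocity/position update, constraint
    enforcement, fitness evaluation, pbest/gbest updates (in place)."""
    n = len(swarm.x)
    r1 = rng.random(n)
    r2 = rng.random(n)
    swarm.v = (
        config.inertia * swarm.v
        + config.learning * r1 * (swarm.pb_x - swarm.x)
        + config.learning * r2 * (swarm.gb_x - swarm.x)
    )
    swarm.x = swarm.x + swarm.v
    swarm.x, swarm.v = constrain(swarm.x, swarm.v, swarm.bounds, rng)
    f = np.array([fitness_fn(xi) for xi in swarm.x])
    better = f < swarm.pb_f
    swarm.pb_x[better] = swarm.x[better]
    swarm.pb_f[better] = f[better]
    best = int(np.argmin(swarm.pb_f))
    if swarm.pb_f[best] < swarm.gb_f:
        swarm.gb_f = float(swarm.pb_f[best])
        swarm.gb_x = float(swarm.pb_x[best])
    swarm.trace.append(swarm.gb_f)
    return swarm


# ---------------------------------------------------------------------------
# Assembly and the end-to-end run
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SegmentationResult:
    """Closed contour through the per-section best particles, and its mask."""

    contour: np.ndarray        # (K, 2) rows of (angle, radius), section order
    mask: np.ndarray           # filled polygon as a binary mask
    origin: tuple[float, float]
    fitness_trace: np.ndarray  # (K, iterations+1) per-swarm gbest history


def assemble_contour(
    swarms: list[Swarm], grid: PolarGrid, frame_shape: tuple[int, int]
) -> SegmentationResult:
    """Connect each swarm's best particle into a closed polygon mask."""
    radii = np.array([s.gb_x for s in swarms])
    fits = np.array([s.gb_f for s in swarms])
    if not np.isfinite(fits).all():
        raise ValueError("section unsolved: infinite best fitness")
    angles = np.array([grid.bisector(s.section) for s in swarms])
    rows = grid.origin[0] + radii * np.sin(angles)
    cols = grid.origin[1] + radii * np.cos(angles)
    rr, cc = draw_polygon(rows, cols, shape=frame_shape)
    mask = np.zeros(frame_shape, dtype=np.uint8)
    mask[rr, cc] = 1
    traces = np.array([s.trace for s in swarms])
    return SegmentationResult(
        contour=np.column_stack([angles, radii]),
        mask=mask,
        origin=grid.origin,
        fitness_trace=traces,
    )


def run_segmentation(
    image: np.ndarray,
    template: TemplateShape,
    config: PsoConfig | None = None,
    energy_weight: float | None = None,
) -> SegmentationResult:
    """Full single-image segmentation.

    Steps: gradient edge map -> distance map -> MI template placement ->
    polar grid with K = n_control_points sections -> scaled-contour seeding
    -> `iterations` independent PSO steps per swarm -> contour assembly.
    Deterministic for a fixed config (per-swarm child RNG streams spawned
    from ``config.seed``).
    """
    cfg = config or PsoConfig()
    img = as_image(image)
    if min(img.shape) < MIN_SIDE:
        raise ValueError(f"frame must be at least {MIN_SIDE}x{MIN_SIDE}")
    edges = gradient_edge_mask(img, cfg.edge_threshold, cfg.smooth_sigma)
    if not edges.any():
        raise ValueError("no edges to anchor fitness")
    dmap = distance_map(edges)
    origin = locate_origin(img, template, cfg.mi_stride, cfg.mi_bins)
    grid = PolarGrid(origin=origin, n_sections=cfg.n_control_points)
    radii, bounds = generate_scaled_contours(template, grid, cfg)
    base_r = template_radii(template, grid)
    streams = [np.random.default_rng(s)
               for s in np.random.SeedSequence(cfg.seed).spawn(cfg.n_control_points)]

    def make_fitness(i: int):
        if cfg.fitness_mode == "distance":
            return lambda r: fitness(r, i, grid, dmap)
        w = cfg.energy_weight if energy_weight is None else energy_weight
        sector = math.pi / cfg.n_control_points
        rt = base_r[i]

        def fit(r: float) -> float:
            d = fitness(r, i, grid, dmap)
            if not math.isfinite(d):
                return d
            # per-control-point shape term: sector area between r and the
            # template radius (the section's slice of the E2 mismatch)
            return d + w * sector * abs(r * r - rt * rt)

        return fit

    swarms = []
    for i in range(cfg.n_control_points):
        lo, hi = bounds[i]
        if not lo < hi:
            hi = lo + 1e-6
        fit_fn = make_fitness(i)
        sw = init_swarm(i, radii[i], (lo, hi), fit_fn, streams[i])
        stable = 0
        for _ in range(cfg.iterations):
            prev = sw.gb_f
            pso_step(sw, cfg, streams[i], fit_fn)
            if cfg.stability_stop:
                stable = stable + 1 if abs(prev - sw.gb_f) < cfg.stability_tol else 0
                if stable >= cfg.stability_window:
                    break
        swarms.append(sw)
    # pad traces to equal length for stacking when stability_stop cut short
    max_len = max(len(s.trace) for s in swarms)
    for s in swarms:
        s.trace.extend([s.trace[-1]] * (max_len - len(s.trace)))
    return assemble_contour(swarms, grid, img.shape)
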