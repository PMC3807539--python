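"""Validation metrics for comparing a reference and an automatic mask.

Five measures are provided: Jaccard ``|A∩B|/|A∪B|``, Dice
``2|A∩B|/(|A|+|B|)`` (always equal to ``2J/(1+J)``), Pearson correlation of
the flattened indicator fields, the directed Hausdorff distance between the
edge sets ``max_a min_b ||a-b||`` (symmetric variant optional), and the
maximum cardinality similarity metric (MCSM)

    R_n = (N / (N - TP)) * (TP / (TP + FN) - TP / N)

over edge pixels, where TP counts reference edge pixels matched by a result
edge pixel within a tolerance (default: exact coincidence), FN the
unmatched remainder and N the total pixel count.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
from scipy.spatial.distance import directed_hausdorff

from .imaging import as_mask, distance_map, edge_mask

__all__ = [
    "ConfusionCounts",
    "MetricReport",
    "jaccard",
    "dice",
    "correlation",
    "hausdorff_directed",
    "mcsm",
    "evaluate",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fn: int
    n_total: int


@dataclass(frozen=True)
class MetricReport:
    jaccard: float
    dice: float
    correlation: float
    hausdorff: float
    mcsm: float

    def as_dict(self) -> dict:
        return asdict(self)


def _pair(a, b):
    ma, mb = as_mask(a), as_mask(b)
    if ma.shape != mb.shape:
        raise ValueError("masks must share a frame size")
    return ma.astype(bool), mb.astype(bool)


def jaccard(a: np.ndarray, b: np.ndarray) -> float:
    """Intersection over union of two masks."""
    ma, mb = _pair(a, b)
    union = (ma | mb).sum()
    if union == 0:
        raise ValueError("undefined similarity: both masks empty")
    return float((ma & mb).sum()) / float(union)


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Twice the intersection over the summed region sizes."""
    ma, mb = _pair(a, b)
    total = ma.sum() + mb.sum()
    if total == 0:
        raise ValueError("undefined similarity: both masks empty")
    return 2.0 * float((ma & mb).sum()) / float(total)


def correlation(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation of the flattened {0,1} indicator fields."""
    ma, mb = _pair(a, b)
    fa = ma.ravel().astype(np.float64)
    fb = mb.ravel().astype(np.float64)
    if fa.std() == 0 or fb.std() == 0:
        raise ValueError("constant mask has no defined correlation")
    return float(np.corrcoef(fa, fb)[0, 1])


def hausdorff_directed(
    a: np.ndarray, b: np.ndarray, symmetric: bool = False
) -> float:
    """Directed Hausdorff distance between the masks' edge sets.

    ``max`` over A's edge pixels of the ``min`` distance to B's edge set;
    ``symmetric=True`` takes the max of both directions.
    """
    ea = np.argwhere(edge_mask(a))
    eb = np.argwhere(edge_mask(b))
    if len(ea) == 0 or len(eb) == 0:
        raise ValueError("empty edge set")
    d_ab = directed_hausdorff(ea, eb)[0]
    if not symmetric:
        return float(d_ab)
    return float(max(d_ab, directed_hausdorff(eb, ea)[0]))


def mcsm_counts(
    reference_edges: np.ndarray,
    result_edges: np.ndarray,
    match_tolerance: float = 0.0,
) -> ConfusionCounts:
    """TP/FN over edge pixels for the MCSM (N = total pixels in the frame)."""
    ref, res = _pair(reference_edges, result_edges)
    if not ref.any():
        raise ValueError("reference edge set is empty")
    n_ref = int(ref.sum())
    if res.any():
        dist = distance_map(res.astype(np.uint8))
        tp = int((dist[ref] <= match_tolerance).sum())
    else:
        tp = 0
    return ConfusionCounts(tp=tp, fn=n_ref - tp, n_total=ref.size)


def mcsm(
    reference_edges: np.ndarray,
    result_edges: np.ndarray,
    match_tolerance: float = 0.0,
) -> float:
    """Maximum cardinality similarity metric over edge pixel sets."""
    c = mcsm_counts(reference_edges, result_edges, match_tolerance)
    if c.tp == c.n_total:
        raise ValueError("degenerate MCSM: TP equals the pixel count")
    n = float(c.n_total)
    return (n / (n - c.tp)) * (c.tp / (c.tp + c.fn) - c.tp / n)


def evaluate(
    reference: np.ndarray,
    result: np.ndarray,
    symmetric_hausdorff: bool = False,
    mcsm_tolerance: float = 0.0,
) -> MetricReport:
    """All five metrics with a shared edge extraction."""
    ref, res = _pair(reference, result)
    ref_edges = edge_mask(ref.astype(np.uint8))
    res_edges = edge_mask(res.astype(np.uint8))
    return MetricReport(
        jaccard=jaccard(ref, res),
        dice=dice(ref, res),
        correlation=correlation(ref, res),
        hausdorff=hausdorff_directed(ref, res, symmetric=symmetric_hausdorff),
        mcsm=mcsm(ref_edges, res_edges, mcsm_tolerance),
    )
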