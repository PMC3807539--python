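"""Shared image and mask primitives.

Conventions used throughout the package:

* a *gray image* is a 2-D ``float64`` array with intensities in ``[0, 1]``
  (8-bit files are normalized on load);
* a *binary mask* is a 2-D ``uint8`` array over ``{0, 1}`` (stored on disk
  as ``{0, 255}`` PNG/PGM);
* coordinates are 0-based ``(row, col)`` with pixel centres at integer
  positions; for similarity transforms ``x`` is the column axis and ``y``
  the row axis;
* a *distance map* is the Euclidean distance transform of an edge set
  (zero exactly on edge pixels);
* a *level-set field* ``phi`` is signed distance to a mask boundary,
  positive on foreground pixels and negative on background.
"""

from __future__ import annotations

import logging

import numpy as np
from PIL import Image
from scipy import ndimage

log = logging.getLogger(__name__)

#: minimum frame side accepted by pipeline stages
MIN_SIDE = 8

__all__ = [
    "MIN_SIDE",
    "as_image",
    "as_mask",
    "load_image",
    "save_image",
    "load_mask",
    "save_mask",
    "edge_mask",
    "gradient_edge_mask",
    "distance_map",
    "signed_distance",
    "smoothed_heaviside",
]


def as_image(pixels: np.ndarray) -> np.ndarray:
    """Validate and coerce an array to the gray-image convention."""
    arr = np.asarray(pixels, dtype=np.float64)
    if arr.ndim != 2:
        raise ValueError(f"image must be 2-D, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError("image contains non-finite values")
    if arr.min() < 0.0 or arr.max() > 1.0:
        raise ValueError("image intensities must lie in [0, 1]")
    return arr


def as_mask(pixels: np.ndarray) -> np.ndarray:
    """Validate and coerce an array to the binary-mask convention."""
    arr = np.asarray(pixels)
    if arr.ndim != 2:
        raise ValueError(f"mask must be 2-D, got shape {arr.shape}")
    if arr.dtype == bool:
        return arr.astype(np.uint8)
    vals = np.unique(arr)
    if not np.isin(vals, (0, 1)).all():
        raise ValueError(f"mask values must be in {{0, 1}}, got {vals[:8]}")
    return arr.astype(np.uint8)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def load_image(path) -> np.ndarray:
    """Load an 8-bit grayscale PNG/PGM as a float image in [0, 1]."""
    with Image.open(path) as im:
        arr = np.asarray(im.convert("L"), dtype=np.float64)
    return arr / 255.0


def save_image(image: np.ndarray, path) -> None:
    """Write a [0, 1] float image as 8-bit grayscale."""
    arr = np.clip(np.asarray(image, dtype=np.float64), 0.0, 1.0)
    Image.fromarray(np.round(arr * 255.0).astype(np.uint8)).save(path)


def load_mask(path) -> np.ndarray:
    """Load a binary mask stored as {0, 255} (or {0, 1}) grayscale.

    Non-binary content is thresholded at half range with a logged warning.
    Round-trips bit-exactly with :func:`save_mask`.
    """
    with Image.open(path) as im:
        arr = np.asarray(im.convert("L"))
    vals = np.unique(arr)
    if not np.isin(vals, (0, 255)).all() and not np.isin(vals, (0, 1)).all():
        log.warning("mask file %s is not binary; thresholding at 0.5", path)
    return (arr.astype(np.float64) / max(arr.max(), 1) > 0.5).astype(np.uint8)


def save_mask(mask: np.ndarray, path) -> None:
    """Write a {0, 1} mask as an 8-bit {0, 255} grayscale file."""
    arr = as_mask(mask) * np.uint8(255)
    Image.fromarray(arr).save(path)


# ---------------------------------------------------------------------------
# Edge maps and distance fields
# ---------------------------------------------------------------------------

_CROSS = ndimage.generate_binary_structure(2, 1)
_SQUARE = ndimage.generate_binary_structure(2, 2)


def edge_mask(mask: np.ndarray, connectivity: int = 4) -> np.ndarray:
    """Inner boundary of a mask: foreground pixels with a background neighbour.

    Pixels outside the frame count as background, so a full-frame mask has
    its border ring as edge.  ``connectivity`` selects whether a background
    4-neighbour (default) or any 8-neighbour marks a pixel as edge.
    """
    m = as_mask(mask).astype(bool)
    if connectivity == 4:
        struct = _CROSS
    elif connectivity == 8:
        struct = _SQUARE
    else:
        raise ValueError("connectivity must be 4 or 8")
    interior = ndimage.binary_erosion(m, structure=struct, border_value=0)
    return (m & ~interior).astype(np.uint8)


def gradient_edge_mask(
    image: np.ndarray, threshold: float, smooth_sigma: float = 0.0
) -> np.ndarray:
    """Edge pixels of an intensity image by thresholded gradient magnitude.

    The gradient is computed by central differences (one-sided at the frame
    border); pixels whose magnitude exceeds ``threshold`` times the maximum
    magnitude are marked.  ``smooth_sigma > 0`` applies a Gaussian blur
    first, which suppresses noise-induced spurious edges.
    """
    img = as_image(image)
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    if smooth_sigma > 0:
        img = ndimage.gaussian_filter(img, smooth_sigma)
    gr, gc = np.gradient(img)
    mag = np.hypot(gr, gc)
    peak = mag.max()
    if peak == 0.0:
        log.warning("constant image: gradient edge mask is empty")
        return np.zeros_like(img, dtype=np.uint8)
    return (mag > threshold * peak).astype(np.uint8)


def distance_map(edges: np.ndarray) -> np.ndarray:
    """Exact Euclidean distance transform of an edge set.

    Zero exactly on edge pixels, elsewhere the distance to the nearest edge
    pixel.  Raises if the edge set is empty (nothing to anchor a fitness).
    """
    e = as_mask(edges)
    if not e.any():
        raise ValueError("no edges to anchor fitness")
    return ndimage.distance_transform_edt(e == 0)


def signed_distance(mask: np.ndarray) -> np.ndarray:
    """Signed distance field of a mask: positive inside, negative outside.

    The zero level set is placed on the half-pixel interface between the
    inner edge ring and the adjacent background, so ``|phi|`` agrees with
    the distance to the mask boundary within 0.5 px everywhere and
    ``phi > 0`` exactly on foreground pixels.
    """
    m = as_mask(mask).astype(bool)
    if not m.any():
        raise ValueError("empty mask has no boundary")
    if m.all():
        raise ValueError("full-frame mask has no boundary")
    # pad with one background ring: the frame exterior counts as background,
    # matching the edge_mask convention
    padded = np.pad(m, 1, constant_values=False)
    inside = ndimage.distance_transform_edt(padded)[1:-1, 1:-1]
    outside = ndimage.distance_transform_edt(~m)
    return np.where(m, inside - 0.5, -(outside - 0.5))


def smoothed_heaviside(value, epsilon: float):
    """C1-regularized Heaviside ``0.5 * (1 + (2/pi) * arctan(v / eps))``.

    Strictly monotone, maps 0 to 0.5 and satisfies ``H(x) + H(-x) = 1``.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    return 0.5 * (1.0 + (2.0 / np.pi) * np.arctan(np.asarray(value, dtype=np.float64) / epsilon))
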