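"""Shared fixtures and small mask factories for the test suite."""

from __future__ import annotations

import numpy as np
import pytest


def random_mask(rng: np.random.Generator, shape=(12, 12), p=0.4) -> np.ndarray:
    """Random binary mask guaranteed non-empty and non-full."""
    m = (rng.random(shape) < p).astype(np.uint8)
    m[shape[0] // 2, shape[1] // 2] = 1
    m[0, 0] = 0
    return m


def disk_mask(radius: float, shape=(32, 32), center=None) -> np.ndarray:
    h, w = shape
    cr, cc = center if center is not None else ((h - 1) / 2, (w - 1) / 2)
    rr, cc_ = np.mgrid[0:h, 0:w]
    return (np.hypot(rr - cr, cc_ - cc) <= radius).astype(np.uint8)


def brute_edges(mask: np.ndarray) -> np.ndarray:
    """Independent 4-neighbour edge scan (frame exterior = background)."""
    h, w = mask.shape
    out = np.zeros_like(mask)
    for r in range(h):
        for c in range(w):
            if not mask[r, c]:
                continue
            for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                rr, cc = r + dr, c + dc
                if not (0 <= rr < h and 0 <= cc < w) or not mask[rr, cc]:
                    out[r, c] = 1
                    break
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
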