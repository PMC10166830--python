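"""Programmatic body-silhouette masks.

The painting task records intensities on a fixed front-facing body outline
whose total in-silhouette pixel count (50,364 in the original canvas) is the
denominator of the size metric.  The original canvas is not redistributable,
so this module draws a geometrically simple silhouette with the same five
ROIs (head, chest, abdomen, arms, legs); all metrics use the mask's own
recorded pixel count, never a hard-coded constant, so any mask geometry
(including the canonical one, if supplied as a label grid) plugs in
unchanged.
"""

from __future__ import annotations

import numpy as np

from .core import BodyMask, ROI_LABELS

__all__ = ["make_body_mask"]

# Base-geometry design constants (rows x cols = 560 x 180 at scale 1.0).
_BASE_H, _BASE_W = 560, 180


def make_body_mask(scale: float = 1.0) -> BodyMask:
    """Draw a front-facing silhouette with 5 labeled ROIs.

    Parameters
    ----------
    scale:
        Linear scale factor.  ``scale=1.0`` gives a 560 x 180 canvas with
        ~46,000 in-silhouette pixels (same order as the original canvas);
        smaller scales give proportionally smaller masks for fast
        simulation.  Must keep every ROI non-empty (scale >= ~0.05).
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    h = max(int(round(_BASE_H * scale)), 12)
    w = max(int(round(_BASE_W * scale)), 8)
    grid = np.zeros((h, w), dtype=np.int64)
    rr, cc = np.ogrid[:h, :w]

    def frac(r0, r1, c0, c1):
        """Slices from base-geometry fractions."""
        return (slice(int(r0 * h), max(int(r1 * h), int(r0 * h) + 1)),
                slice(int(c0 * w), max(int(c1 * w), int(c0 * w) + 1)))

    # Head: ellipse centered near the top.
    cy, cx = 0.10 * h, 0.50 * w
    ry, rx = max(0.062 * h, 1.5), max(0.145 * w, 1.5)
    head = ((rr - cy) / ry) ** 2 + ((cc - cx) / rx) ** 2 <= 1.0
    grid[head] = ROI_LABELS["head"]

    # Torso: chest above, abdomen below.
    grid[frac(0.17, 0.375, 0.29, 0.71)] = ROI_LABELS["chest"]
    grid[frac(0.375, 0.535, 0.31, 0.69)] = ROI_LABELS["abdomen"]

    # Arms: two lateral columns flanking the torso.
    grid[frac(0.18, 0.59, 0.10, 0.265)] = ROI_LABELS["arms"]
    grid[frac(0.18, 0.59, 0.735, 0.90)] = ROI_LABELS["arms"]

    # Legs: two columns below the abdomen.
    grid[frac(0.535, 0.975, 0.31, 0.475)] = ROI_LABELS["legs"]
    grid[frac(0.535, 0.975, 0.525, 0.69)] = ROI_LABELS["legs"]

    return BodyMask(grid)
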