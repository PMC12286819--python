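"""Glottis mask extraction: thresholding and landmark geometry.

A glottis segmentation network emits a per-pixel probability map (post
sigmoid, values in [0, 1]).  Binarized at 0.5 the map is a conventional
glottis mask; binarized at a *very* small threshold (1e-15 … 1e-21) the
mask additionally covers a rough outline of the vocal folds, because the
network assigns tiny-but-nonzero probability to the high-contrast fold
region around the glottis.  Both masks feed the prompt-construction stages.

Coordinate convention, used throughout the package: 0-based, ``x`` = column
index increasing rightward, ``y`` = row index increasing downward, with
continuous coordinates placed at pixel centers.  Points are ``(x, y)``
pairs; arrays are indexed ``[y, x]``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Per-pixel glottis probability in [0, 1], shape (H, W), float.
ProbabilityMap = np.ndarray
#: Per-pixel boolean mask, shape (H, W).
BinaryMask = np.ndarray


class ClosedGlottisError(RuntimeError):
    """Raised when an operation needs a non-empty glottis mask.

    A fully closed glottis leaves the 0.5-threshold mask empty; callers
    decide the fallback (typically: flag the frame and emit empty fold
    labels rather than crash a batch run).
    """


@dataclass(frozen=True)
class GlottisLandmarks:
    """Top, middle and bottom points of a glottis mask plus its axis angle.

    ``top`` / ``bottom`` are the midpoints of the topmost / bottommost mask
    rows' pixel runs; ``middle`` is the pixel centroid of the mask (robust
    to asymmetric lens shapes).  ``axis_angle_deg`` is the angle of the
    top->bottom segment measured from the image vertical, in degrees;
    positive angles tilt the bottom of the axis toward increasing ``x``.
    """

    top: np.ndarray
    middle: np.ndarray
    bottom: np.ndarray
    axis_angle_deg: float

    @property
    def axis_vector(self) -> np.ndarray:
        """Unnormalized top->bottom vector ``(dx, dy)``."""
        return self.bottom - self.top

    @property
    def axis_length(self) -> float:
        return float(np.hypot(*(self.bottom - self.top)))


def binarize(prob: ProbabilityMap, threshold: float) -> BinaryMask:
    """Binarize a probability map with a strict ``p > threshold`` test.

    Strict inequality makes a threshold of exactly 0.5 deterministic on
    0.5-valued ties.  Thresholds apply to probabilities, not logits: adapt
    networks that emit logits by applying a sigmoid first.

    Parameters
    ----------
    prob
        Per-pixel probabilities in [0, 1].
    threshold
        Cut value, must lie strictly inside (0, 1).  The low-threshold
        fold-mining mode uses values down to 1e-21.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must be in (0, 1), got {threshold!r}")
    prob = np.asarray(prob)
    return prob > threshold


def glottis_landmarks(mask: BinaryMask) -> GlottisLandmarks:
    """Extract top/middle/bottom points and the axis angle of a glottis mask.

    ``top`` is the midpoint of the True run in the topmost occupied row
    (first and last True column averaged), ``bottom`` likewise for the
    bottommost row, and ``middle`` is the centroid of all True pixels.
    The axis angle is that of the top->bottom segment against the image
    vertical.  A single-pixel mask degenerates to top = middle = bottom
    with angle 0.

    Raises
    ------
    ClosedGlottisError
        If the mask is empty.
    """
    mask = np.asarray(mask, dtype=bool)
    ys, xs = np.nonzero(mask)
    if ys.size == 0:
        raise ClosedGlottisError("glottis mask is empty (closed glottis)")

    y_top = ys.min()
    y_bot = ys.max()
    top_run = xs[ys == y_top]
    bot_run = xs[ys == y_bot]
    top = np.array([(top_run.min() + top_run.max()) / 2.0, float(y_top)])
    bottom = np.array([(bot_run.min() + bot_run.max()) / 2.0, float(y_bot)])
    middle = np.array([xs.mean(), ys.mean()])

    d = bottom - top
    if np.allclose(d, 0.0):
        angle = 0.0
    else:
        # angle from vertical: atan2(dx, dy), dy points down
        angle = float(np.degrees(np.arctan2(d[0], d[1])))
    return GlottisLandmarks(top=top, middle=middle, bottom=bottom, axis_angle_deg=angle)
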