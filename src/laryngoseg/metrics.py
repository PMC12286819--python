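"""Dice evaluation and mask-derived clinical waveforms.

Segmentation quality is measured with an epsilon-guarded Dice coefficient,

    DC = (2 |GT ∩ Seg| + eps) / (|GT| + |Seg| + eps),  eps = 2.2204e-16,

whose guard makes two empty masks (complete glottal closure, or a fully
missed segmentation on an empty target) evaluate to 1 instead of 0/0.

The waveforms quantify fold vibration from a labeled mask sequence.  The
glottal midline is hypothesized from the glottis mask alone: D is the
bottom of the mask, C its centroid, and T the point where the ray D->C
leaves the mask.  Equidistant stations C_1..C_n on D->T carry
perpendiculars that intersect each fold at an inner point (nearer the
midline) and an outer point.  Per frame and station this yields

* VFM (vocal-fold movement): mean distance of the inner and outer points
  from the midline — tracks lateral fold excursion;
* VFW (vocal-fold width): inner-to-outer gap — stable for a rigid fold
  even while the glottis oscillates;
* GAW (glottal area waveform): glottis pixel count per frame.

Frames without a glottal area cannot support the midline construction and
are flagged as missing rather than dropped, so the series stay aligned
with the frame index; exclusion happens at export time.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .glottis import BinaryMask, ClosedGlottisError

#: Guard of the Dice denominator (machine epsilon of float64).
DICE_EPS = 2.2204e-16


def dice(gt: BinaryMask, seg: BinaryMask, eps: float = DICE_EPS) -> float:
    """Epsilon-guarded Dice similarity of two same-shaped binary masks."""
    gt = np.asarray(gt, dtype=bool)
    seg = np.asarray(seg, dtype=bool)
    if gt.shape != seg.shape:
        raise ValueError(f"mask shapes differ: {gt.shape} vs {seg.shape}")
    inter = np.logical_and(gt, seg).sum()
    return float((2.0 * inter + eps) / (gt.sum() + seg.sum() + eps))


@dataclass(frozen=True)
class MidlineGeometry:
    """Glottal midline D->T with centroid C and equidistant stations."""

    C: np.ndarray
    D: np.ndarray
    T: np.ndarray
    stations: np.ndarray  # (n, 2), C_i strictly between D and T

    @property
    def axis_unit(self) -> np.ndarray:
        d = self.T - self.D
        return d / np.hypot(*d)

    @property
    def left_normal(self) -> np.ndarray:
        """Unit perpendicular pointing toward the image-left fold."""
        a = self.axis_unit
        n = np.array([a[1], -a[0]])
        if n[0] > 0 or (n[0] == 0 and n[1] > 0):
            n = -n
        return n


@dataclass(frozen=True)
class FoldIntersections:
    """Per-station midline distances of the inner/outer fold boundary.

    Arrays have shape (n_stations,); NaN marks an absent intersection.
    ``inner`` is the first fold pixel met marching from the station toward
    the side, ``outer`` the last pixel of that contiguous fold run.
    """

    left_inner: np.ndarray
    left_outer: np.ndarray
    right_inner: np.ndarray
    right_outer: np.ndarray


@dataclass
class Waveform:
    """Per-station time series with a missing flag per frame."""

    values: np.ndarray  # (n_frames, n_stations), NaN where missing
    missing: np.ndarray  # (n_frames,) bool
    name: str = ""

    @property
    def n_frames(self) -> int:
        return int(self.values.shape[0])

    @property
    def n_stations(self) -> int:
        return int(self.values.shape[1])

    def station(self, i: int, drop_missing: bool = False) -> np.ndarray:
        v = self.values[:, i]
        return v[~self.missing] if drop_missing else v


def glottal_midline(glottis: BinaryMask, n: int = 3) -> MidlineGeometry:
    """Construct the glottal midline and its equidistant stations.

    D is the midpoint of the bottommost mask row's pixel run, C the mask
    centroid, and T the last mask sample along the ray D->C, found by
    marching at 0.25-px steps until the ray leaves the mask.  Stations are
    ``C_i = D + i (T - D) / (n + 1)``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    glottis = np.asarray(glottis, dtype=bool)
    ys, xs = np.nonzero(glottis)
    if ys.size == 0:
        raise ClosedGlottisError("empty glottis mask")
    y_bot = ys.max()
    run = xs[ys == y_bot]
    D = np.array([(run.min() + run.max()) / 2.0, float(y_bot)])
    C = np.array([xs.mean(), ys.mean()])
    d = C - D
    norm = np.hypot(*d)
    if norm < 1e-9:  # single-pixel / degenerate mask: point geometry
        T = C.copy()
    else:
        u = d / norm
        step = 0.25 * u
        h, w = glottis.shape
        p = D.copy()
        T = D.copy()
        last_px = None
        # 4 samples per px; diagonal of the image bounds the march
        for _ in range(int(4 * np.hypot(h, w)) + 8):
            p = p + step
            ix, iy = int(round(p[0])), int(round(p[1]))
            if not (0 <= iy < h and 0 <= ix < w) or not glottis[iy, ix]:
                break
            T = p.copy()
            last_px = (ix, iy)
        if last_px is not None:
            # T is the last mask *pixel* on the ray: pull the final sample
            # back to the projection of that pixel's center
            r_center = float(np.dot(np.array(last_px, dtype=float) - D, u))
            r_last = float(np.dot(T - D, u))
            T = D + min(r_last, r_center) * u
    frac = (np.arange(1, n + 1) / (n + 1.0))[:, None]
    stations = D[None, :] + frac * (T - D)[None, :]
    return MidlineGeometry(C=C, D=D, T=T, stations=stations)


def _march(
    mask: BinaryMask,
    origin: np.ndarray,
    direction: np.ndarray,
    max_radius: float,
) -> tuple[float, float]:
    """March 1-px steps; return (inner, outer) distances of the first fold run."""
    h, w = mask.shape
    inner = np.nan
    outer = np.nan
    in_run = False
    r = 1.0
    while r <= max_radius:
        p = origin + r * direction
        ix, iy = int(round(p[0])), int(round(p[1]))
        hit = 0 <= iy < h and 0 <= ix < w and bool(mask[iy, ix])
        if hit:
            if not in_run:
                inner = r
                in_run = True
            outer = r
        elif in_run:
            break  # end of the first contiguous run
        r += 1.0
    return inner, outer


def fold_intersections(
    left_fold: BinaryMask,
    right_fold: BinaryMask,
    geometry: MidlineGeometry,
    max_radius: float | None = None,
) -> FoldIntersections:
    """Intersect midline perpendiculars with both fold masks.

    From each station a perpendicular ray is marched toward each side at
    1-px steps up to ``max_radius`` (default: half the image width); the
    first fold pixel met is the inner boundary, the last pixel of that
    contiguous run the outer one.  Sides with no hit are NaN.
    """
    left_fold = np.asarray(left_fold, dtype=bool)
    right_fold = np.asarray(right_fold, dtype=bool)
    if max_radius is None:
        max_radius = left_fold.shape[1] / 2.0
    nl = geometry.left_normal
    n_st = geometry.stations.shape[0]
    li = np.full(n_st, np.nan)
    lo = np.full(n_st, np.nan)
    ri = np.full(n_st, np.nan)
    ro = np.full(n_st, np.nan)
    for i, c in enumerate(geometry.stations):
        li[i], lo[i] = _march(left_fold, c, nl, max_radius)
        ri[i], ro[i] = _march(right_fold, c, -nl, max_radius)
    return FoldIntersections(left_inner=li, left_outer=lo,
                             right_inner=ri, right_outer=ro)


def _frame_masks(frame) -> tuple[BinaryMask, BinaryMask, BinaryMask]:
    """Accept FrameResult-like objects or (glottis, left, right) triples."""
    if hasattr(frame, "glottis_mask"):
        return frame.glottis_mask, frame.left_mask, frame.right_mask
    g, l, r = frame
    return np.asarray(g, bool), np.asarray(l, bool), np.asarray(r, bool)


def _per_frame_series(
    frames: Sequence,
    n: int,
    max_radius: Optional[float],
    reduce,
    name_left: str,
    name_right: str,
) -> tuple[Waveform, Waveform]:
    if len(frames) < 1:
        raise ValueError("need at least one frame")
    n_frames = len(frames)
    left_vals = np.full((n_frames, n), np.nan)
    right_vals = np.full((n_frames, n), np.nan)
    missing = np.zeros(n_frames, dtype=bool)
    for t, frame in enumerate(frames):
        glottis, left, right = _frame_masks(frame)
        try:
            geom = glottal_midline(glottis, n)
        except ClosedGlottisError:
            missing[t] = True
            continue
        inter = fold_intersections(left, right, geom, max_radius)
        left_vals[t] = reduce(inter.left_inner, inter.left_outer)
        right_vals[t] = reduce(inter.right_inner, inter.right_outer)
    return (
        Waveform(values=left_vals, missing=missing, name=name_left),
        Waveform(values=right_vals, missing=missing.copy(), name=name_right),
    )


def vfm_series(
    frames: Sequence,
    n: int = 3,
    max_radius: Optional[float] = None,
) -> tuple[Waveform, Waveform]:
    """Vocal-fold movement waveform per side.

    VFM at a station is the mean of the inner and outer boundary distances
    from the midline — the excursion of the fold's center line.  Closed
    frames are flagged missing.
    """
    return _per_frame_series(
        frames, n, max_radius,
        lambda inner, outer: (inner + outer) / 2.0,
        "vfm-left", "vfm-right",
    )


def vfw_series(
    frames: Sequence,
    n: int = 3,
    max_radius: Optional[float] = None,
) -> tuple[Waveform, Waveform]:
    """Vocal-fold width waveform per side (outer minus inner distance)."""
    return _per_frame_series(
        frames, n, max_radius,
        lambda inner, outer: outer - inner,
        "vfw-left", "vfw-right",
    )


def gaw_series(glottis_masks: Sequence[BinaryMask]) -> Waveform:
    """Glottal area waveform: glottis pixel count per frame.

    An empty mask contributes area 0 (and is not flagged missing — zero
    area is the physiological closed-glottis value of the GAW).
    """
    if len(glottis_masks) < 1:
        raise ValueError("need at least one frame")
    vals = np.array(
        [float(np.asarray(m, dtype=bool).sum()) for m in glottis_masks]
    )[:, None]
    return Waveform(
        values=vals, missing=np.zeros(len(glottis_masks), dtype=bool), name="gaw"
    )


def dominant_frequency(series: np.ndarray) -> float:
    """Periodogram peak location (cycles/frame) of a 1-D series.

    NaNs are replaced by the series mean and the mean is removed before
    the periodogram, so the DC bin never wins.
    """
    from scipy import signal as _signal

    x = np.asarray(series, dtype=float).copy()
    if np.isnan(x).all():
        return float("nan")
    x[np.isnan(x)] = np.nanmean(x)
    x = x - x.mean()
    freqs, power = _signal.periodogram(x)
    if power.size <= 1:
        return float("nan")
    return float(freqs[1:][np.argmax(power[1:])])
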