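"""Synthetic laryngoscope phantom with analytic ground truth.

Real laryngeal high-speed video shows a dark lens-shaped glottis flanked by
two brighter vocal-fold bands on darker surrounding tissue.  The phantom
reproduces exactly that layout with fully analytic geometry so every
downstream stage — thresholding, box/point prompt construction, backend
prompting, waveform extraction — can be validated against closed-form
boundaries instead of hand-labeled data.

Geometry (in a frame aligned with the glottal axis):

* the glottis is a symmetric lens, the intersection of two circular arcs,
  with half-length ``h`` along the axis and half-width ``g(t)`` across it;
* the folds are two rigid bands of fixed width ``w`` whose inner edges sit
  at the current half-width, i.e. the bands translate laterally as the
  glottis opens and closes but never change width;
* the half-width oscillates as ``g(t) = g + A * sin(2 pi f t)``; frames
  where ``g(t) <= 0`` model complete glottal closure (empty glottis mask,
  fold bands still present and touching at the midline).

The axis is tilted by ``axis_angle_deg`` from the image vertical (positive
angles tilt the bottom of the axis toward increasing x), an illumination
gradient runs along the image diagonal, and Gaussian noise is added after
quantization.  The phantom also emulates two imperfect upstream models: a
glottis-probability-map generator reproducing the low-threshold fold-mining
phenomenon, and a fallible bounding-box detector with configurable failure
modes (missing box, grossly displaced box, undersized box).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .box_prompt import Box
from .glottis import BinaryMask, ProbabilityMap


@dataclass(frozen=True)
class PhantomParams:
    """Geometry, photometry and oscillation parameters of the phantom.

    Attributes
    ----------
    height, width
        Image size in pixels.
    center
        Glottis center ``(x, y)`` in continuous pixel coordinates.
    axis_angle_deg
        Glottal-axis tilt from the image vertical, degrees.
    half_length
        Glottis half-length ``h`` along the axis, pixels.
    half_width
        Nominal glottal half-width ``g`` across the axis, pixels.
    fold_width
        Width ``w`` of each rigid fold band, pixels.
    background_level, fold_level, glottis_level
        8-bit gray levels; folds are brighter than the surrounding tissue,
        the glottis darker.
    illumination_slope
        Linear gray-level gradient along the image diagonal, gray/pixel.
    noise_sigma
        Gaussian noise standard deviation, gray levels (added after
        quantization, result clipped to [0, 255]).
    osc_amplitude, osc_frequency
        Half-width oscillation amplitude ``A`` (pixels) and frequency ``f``
        (cycles/frame): ``g(t) = g + A sin(2 pi f t)``.
    seed
        Base seed; frame ``t`` derives its noise stream from ``(seed, t)``
        so a frame is reproducible in isolation.
    """

    height: int = 256
    width: int = 256
    center: tuple[float, float] = (128.0, 128.0)
    axis_angle_deg: float = 0.0
    half_length: float = 40.0
    half_width: float = 10.0
    fold_width: float = 14.0
    background_level: int = 60
    fold_level: int = 150
    glottis_level: int = 20
    illumination_slope: float = 0.0
    noise_sigma: float = 0.0
    osc_amplitude: float = 0.0
    osc_frequency: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.half_width < 0:
            raise ValueError("half_width must be >= 0")
        if self.half_width + self.fold_width >= self.width / 2:
            raise ValueError("glottis plus fold band must fit in half the image width")
        for name in ("background_level", "fold_level", "glottis_level"):
            v = getattr(self, name)
            if not 0 <= v <= 255:
                raise ValueError(f"{name} must be an 8-bit gray level, got {v}")
        if not self.fold_level > self.background_level > self.glottis_level:
            raise ValueError(
                "intensity ordering must be fold > background > glottis"
            )
        if self.half_length <= 0 or self.fold_width <= 0:
            raise ValueError("half_length and fold_width must be positive")
        if self.height < 8 or self.width < 8:
            raise ValueError("image must be at least 8x8")

    def half_width_at(self, t: int) -> float:
        """Oscillated glottal half-width ``g(t)`` (may be <= 0 when closed)."""
        return self.half_width + self.osc_amplitude * np.sin(
            2.0 * np.pi * self.osc_frequency * t
        )


@dataclass(frozen=True)
class PhantomFrame:
    """One rendered phantom frame with ground truth.

    ``analytic_boundaries`` maps each image row intersecting the fold bands
    to the four fold-edge x-coordinates (left-outer, left-inner,
    right-inner, right-outer) in continuous coordinates.
    """

    image: np.ndarray
    gt_glottis: BinaryMask
    gt_left_fold: BinaryMask
    gt_right_fold: BinaryMask
    analytic_boundaries: dict[int, tuple[float, float, float, float]]
    params: PhantomParams = field(repr=False)
    t: int = 0

    @property
    def gt_folds(self) -> BinaryMask:
        return self.gt_left_fold | self.gt_right_fold

    @property
    def gt_region(self) -> BinaryMask:
        """Fold bands plus glottal gap — the full target of a box prompt."""
        return self.gt_folds | self.gt_glottis

    def gt_box(self) -> Box:
        """Axis-aligned bounding box of the fold region (folds + glottis)."""
        ys, xs = np.nonzero(self.gt_region)
        return Box(float(xs.min()), float(ys.min()), float(xs.max()), float(ys.max()))


def _axis_frame(params: PhantomParams):
    """Per-pixel (u, v) coordinates in the axis-aligned frame.

    u is across the axis (positive toward the right fold), v along it
    (positive toward the bottom landmark).
    """
    th = np.radians(params.axis_angle_deg)
    a = np.array([np.sin(th), np.cos(th)])   # axis direction (top -> bottom)
    nvec = np.array([np.cos(th), -np.sin(th)])  # across-axis direction
    ys, xs = np.mgrid[0 : params.height, 0 : params.width]
    dx = xs - params.center[0]
    dy = ys - params.center[1]
    u = dx * nvec[0] + dy * nvec[1]
    v = dx * a[0] + dy * a[1]
    return u, v, a, nvec


def _lens_mask(u: np.ndarray, v: np.ndarray, h: float, g: float) -> np.ndarray:
    """Lens = intersection of two circular arcs with half-length h, half-width g."""
    if g <= 0:
        return np.zeros_like(u, dtype=bool)
    r = (h * h + g * g) / (2.0 * g)
    d = r - g
    left = (u - d) ** 2 + v**2 <= r * r
    right = (u + d) ** 2 + v**2 <= r * r
    return left & right


def generate_frame(params: PhantomParams, t: int = 0) -> PhantomFrame:
    """Render phantom frame ``t``.

    Deterministic given ``(params, t)``.  The glottal half-width at ``t``
    is ``g + A sin(2 pi f t)``; non-positive values yield an empty glottis
    mask (closed glottis) while the fold bands remain intact.
    """
    params.validate()
    g_t = params.half_width_at(t)
    g_eff = max(g_t, 0.0)
    h = params.half_length
    w = params.fold_width

    u, v, a, nvec = _axis_frame(params)

    glottis = _lens_mask(u, v, h, g_t)
    in_rows = np.abs(v) <= h
    left = (u >= -(g_eff + w)) & (u <= -g_eff) & in_rows & ~glottis
    right = (u >= g_eff) & (u <= g_eff + w) & in_rows & ~glottis & ~left

    img = np.full((params.height, params.width), float(params.background_level))
    img[left | right] = params.fold_level
    img[glottis] = params.glottis_level
    if params.illumination_slope != 0.0:
        ys, xs = np.mgrid[0 : params.height, 0 : params.width]
        diag = (xs + ys - (params.width + params.height) / 2.0) / np.sqrt(2.0)
        img = img + params.illumination_slope * diag
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    if params.noise_sigma > 0:
        rng = np.random.default_rng(np.random.SeedSequence([params.seed, t]))
        noisy = img.astype(float) + rng.normal(0.0, params.noise_sigma, img.shape)
        img = np.clip(np.rint(noisy), 0, 255).astype(np.uint8)

    boundaries = _analytic_boundaries(params, g_eff)
    return PhantomFrame(
        image=img,
        gt_glottis=glottis,
        gt_left_fold=left,
        gt_right_fold=right,
        analytic_boundaries=boundaries,
        params=params,
        t=t,
    )


def _analytic_boundaries(
    params: PhantomParams, g_eff: float
) -> dict[int, tuple[float, float, float, float]]:
    """Closed-form fold-edge x-coordinates per image row.

    The four band edges are the lines u = -(g+w), -g, g, g+w in the axis
    frame, restricted to |v| <= h.  For each integer row y, intersect the
    row with each edge line; a row enters the result only if all four
    intersections fall on the band (so rows clipped near the tilted ends
    are omitted).
    """
    th = np.radians(params.axis_angle_deg)
    cos_t, sin_t = np.cos(th), np.sin(th)
    if abs(cos_t) < 1e-9:  # axis horizontal: rows run along the bands
        return {}
    cx, cy = params.center
    h, w = params.half_length, params.fold_width
    edges = (-(g_eff + w), -g_eff, g_eff, g_eff + w)
    out: dict[int, tuple[float, float, float, float]] = {}
    for y in range(params.height):
        xs = []
        ok = True
        for c in edges:
            # point on edge: (x, y) = center + c * n + v * a
            vv = (y - cy + sin_t * c) / cos_t
            if abs(vv) > h:
                ok = False
                break
            xs.append(cx + cos_t * c + sin_t * vv)
        if ok:
            out[y] = tuple(xs)  # type: ignore[assignment]
    return out


def generate_sequence(params: PhantomParams, n_frames: int) -> list[PhantomFrame]:
    """Render ``n_frames`` consecutive frames with the oscillating half-width."""
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    return [generate_frame(params, t) for t in range(n_frames)]


def emulate_probability_map(
    frame: PhantomFrame,
    glottis_level: float = 0.95,
    fold_level: float = 1e-18,
    noise_rate: float = 0.01,
    seed: int = 0,
) -> ProbabilityMap:
    """Emulate a glottis network's probability map for a phantom frame.

    Glottis pixels receive ``glottis_level`` (>= 0.5, so a conventional 0.5
    threshold recovers exactly the glottis), fold pixels receive the tiny
    ``fold_level`` (< 0.5, recoverable only by the low-threshold mining
    mode), and a seeded random fraction ``noise_rate`` of background pixels
    also receives ``fold_level`` — the scattered false-positive speckle a
    real network produces at extreme thresholds.  Everything else is 0.
    """
    if not (0.0 < fold_level < 0.5 <= glottis_level <= 1.0):
        raise ValueError(
            "levels must satisfy 0 < fold_level < 0.5 <= glottis_level <= 1"
        )
    if not 0.0 <= noise_rate <= 1.0:
        raise ValueError("noise_rate must be a fraction in [0, 1]")
    prob = np.zeros(frame.image.shape, dtype=np.float64)
    prob[frame.gt_folds] = fold_level
    prob[frame.gt_glottis] = glottis_level
    if noise_rate > 0:
        rng = np.random.default_rng(np.random.SeedSequence([seed, frame.t]))
        bg = ~(frame.gt_folds | frame.gt_glottis)
        bg_idx = np.flatnonzero(bg.ravel())
        n_noise = int(np.floor(noise_rate * bg_idx.size))
        if n_noise > 0:
            chosen = rng.choice(bg_idx, size=n_noise, replace=False)
            flat = prob.ravel()
            flat[chosen] = fold_level
    return prob


def probability_provider(
    frame: PhantomFrame,
    glottis_level: float = 0.95,
    fold_level: float = 1e-18,
    noise_rate: float = 0.01,
    seed: int = 0,
):
    """Closure adapting the emulator to the ``provider(image) -> prob`` contract.

    The emulator reads the phantom ground truth, not the pixels, so the
    returned callable ignores its image argument (raw and contrast-enhanced
    images map to the same emulated output).
    """

    def _provider(image: np.ndarray) -> ProbabilityMap:
        return emulate_probability_map(
            frame, glottis_level=glottis_level, fold_level=fold_level,
            noise_rate=noise_rate, seed=seed,
        )

    return _provider


def jittered_detection(
    frame: PhantomFrame,
    mode: str = "ok",
    jitter: float = 5.0,
    seed: int = 0,
) -> Box | None:
    """Emulate a fallible fold-region detector.

    Modes reproduce the characteristic detector failures seen in practice:
    ``ok`` — the true fold-region box with per-corner uniform jitter up to
    ``jitter`` pixels; ``missing`` — no box at all; ``wrong`` — the box
    displaced by more than its own diagonal; ``small`` — the box shrunk to
    0.3x about its center.
    """
    if mode not in ("ok", "missing", "wrong", "small"):
        raise ValueError(f"unknown detection mode {mode!r}")
    if mode == "missing":
        return None
    true_box = frame.gt_box()
    rng = np.random.default_rng(np.random.SeedSequence([seed, frame.t]))
    if mode == "ok":
        j = rng.uniform(-jitter, jitter, size=4)
        b = Box(
            true_box.x_min + j[0],
            true_box.y_min + j[1],
            true_box.x_max + j[2],
            true_box.y_max + j[3],
        )
        return b.normalized()
    if mode == "wrong":
        diag = float(np.hypot(true_box.width, true_box.height))
        shift = 1.5 * diag
        return Box(
            true_box.x_min + shift,
            true_box.y_min + shift,
            true_box.x_max + shift,
            true_box.y_max + shift,
        )
    # small
    cx = (true_box.x_min + true_box.x_max) / 2.0
    cy = (true_box.y_min + true_box.y_max) / 2.0
    hw = 0.3 * true_box.width / 2.0
    hh = 0.3 * true_box.height / 2.0
    return Box(cx - hw, cy - hh, cx + hw, cy + hh)


def oscillating_params(**overrides) -> PhantomParams:
    """Convenience preset: a 100-frame-friendly oscillating phantom.

    Defaults to a 0.1 cycles/frame oscillation with amplitude half the
    nominal half-width, mirroring the cadence of clinical 100-frame
    excerpts used for waveform analysis.
    """
    base = dict(osc_amplitude=5.0, osc_frequency=0.1)
    base.update(overrides)
    return replace(PhantomParams(), **base)
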