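"""Point-prompt extraction from directional intensity derivatives.

Three scan lines orthogonal to the glottal axis pass through the quarter,
half and three-quarter points of the top->bottom glottis segment.  Along
each line the gray profile rises sharply where shadowed tissue meets the
bright fold surface and falls sharply where the surface drops back into
shadow, so the first smoothed-derivative local maximum to the left of the
glottis crossing marks the left fold boundary and the first local minimum
to the right marks the right one.  Up to six boundary points plus the
three glottis landmarks (top, middle/centroid, bottom) form the point
prompt; every point is labeled foreground.

Scan lines are evaluated in the original frame with an oriented direction
vector, not on a resampled image, so no interpolation artifacts enter the
extracted coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal

from .glottis import BinaryMask, GlottisLandmarks

DEFAULT_FRACTIONS = (0.25, 0.50, 0.75)


@dataclass(frozen=True)
class ScanLine:
    """A 1-px-sampled line orthogonal to the glottal axis.

    ``stations`` are signed distances from ``anchor`` along ``direction``
    (a unit vector oriented toward increasing x), clipped to the image.
    """

    anchor: np.ndarray
    direction: np.ndarray
    stations: np.ndarray
    name: str = ""

    def points(self) -> np.ndarray:
        """Image coordinates (N, 2) of all stations."""
        return self.anchor[None, :] + self.stations[:, None] * self.direction[None, :]


@dataclass(frozen=True)
class DerivativeProfile:
    """Gray values and smoothed first derivative along a scan line."""

    line: ScanLine
    gray: np.ndarray
    derivative: np.ndarray
    glottis_interval: tuple[int, int] | None  # inclusive station-index range

    def station_point(self, index: int) -> np.ndarray:
        return self.line.anchor + self.line.stations[index] * self.line.direction


@dataclass(frozen=True)
class PointPromptSet:
    """Foreground prompt points with per-point provenance tags."""

    points: np.ndarray  # (N, 2) image coords
    labels: np.ndarray  # (N,) all 1 (foreground)
    provenance: tuple[str, ...] = field(default=())

    def __len__(self) -> int:
        return int(self.points.shape[0])


def build_scan_lines(
    landmarks: GlottisLandmarks,
    image_shape: tuple[int, int],
    fractions: tuple[float, ...] = DEFAULT_FRACTIONS,
) -> list[ScanLine]:
    """Scan lines through the quadrisection points of the glottal axis.

    All lines share one direction, orthogonal to the top->bottom segment
    and oriented so increasing station moves toward increasing x.
    """
    axis = landmarks.axis_vector.astype(float)
    norm = np.hypot(*axis)
    if norm < 1e-9:
        raise ValueError("degenerate glottis axis: top == bottom")
    a = axis / norm
    d = np.array([a[1], -a[0]])  # orthogonal
    if d[0] < 0 or (d[0] == 0 and d[1] < 0):
        d = -d
    h, w = image_shape[:2]
    lines = []
    for frac in fractions:
        anchor = landmarks.top + frac * axis
        smin, smax = _clip_to_image(anchor, d, w, h)
        stations = np.arange(np.ceil(smin), np.floor(smax) + 1.0)
        lines.append(
            ScanLine(anchor=anchor, direction=d, stations=stations,
                     name=f"l{int(round(frac * 100))}")
        )
    return lines


def _clip_to_image(anchor, d, width, height):
    """Signed-station range keeping anchor + s*d inside the pixel grid."""
    smin, smax = -np.inf, np.inf
    for coord, dc, hi in ((anchor[0], d[0], width - 1), (anchor[1], d[1], height - 1)):
        if abs(dc) < 1e-12:
            if not 0 <= coord <= hi:
                return 0.0, -1.0  # empty
            continue
        lo_s = (0 - coord) / dc
        hi_s = (hi - coord) / dc
        lo_s, hi_s = min(lo_s, hi_s), max(lo_s, hi_s)
        smin, smax = max(smin, lo_s), min(smax, hi_s)
    return smin, smax


def derivative_profile(
    image: np.ndarray,
    line: ScanLine,
    glottis: BinaryMask,
    smooth_window: int = 5,
) -> DerivativeProfile:
    """Sample gray values along a line and smooth their first derivative.

    Gray values are bilinearly interpolated at 1-px stations; the central
    difference derivative is smoothed with a moving average of width
    ``smooth_window`` (odd) to suppress local noise extrema.  The glottis
    interval is the maximal station run inside the glottis mask that
    contains the anchor.
    """
    if smooth_window < 1 or smooth_window % 2 == 0:
        raise ValueError("smooth_window must be odd and >= 1")
    if line.stations.size == 0:
        raise ValueError("scan line lies fully outside the image")
    pts = line.points()
    gray = ndimage.map_coordinates(
        np.asarray(image, dtype=float), [pts[:, 1], pts[:, 0]], order=1, mode="nearest"
    )
    deriv = np.gradient(gray)
    if smooth_window > 1:
        kernel = np.ones(smooth_window) / smooth_window
        deriv = np.convolve(deriv, kernel, mode="same")

    glottis = np.asarray(glottis, dtype=bool)
    iy = np.clip(np.rint(pts[:, 1]).astype(int), 0, glottis.shape[0] - 1)
    ix = np.clip(np.rint(pts[:, 0]).astype(int), 0, glottis.shape[1] - 1)
    inside = glottis[iy, ix]
    interval = _run_containing(inside, int(np.argmin(np.abs(line.stations))))
    return DerivativeProfile(line=line, gray=gray, derivative=deriv,
                             glottis_interval=interval)


def _run_containing(inside: np.ndarray, anchor_idx: int) -> tuple[int, int] | None:
    if not inside[anchor_idx]:
        return None
    i0 = anchor_idx
    while i0 > 0 and inside[i0 - 1]:
        i0 -= 1
    i1 = anchor_idx
    while i1 < inside.size - 1 and inside[i1 + 1]:
        i1 += 1
    return (i0, i1)


def boundary_points(
    profile: DerivativeProfile,
    prominence: float = 5.0,
    max_radius: float | None = None,
) -> tuple[np.ndarray | None, np.ndarray | None]:
    """Left/right fold-boundary points from smoothed-derivative extrema.

    Scanning leftward from the glottis interval, the nearest strict local
    maximum of the smoothed derivative with at least the given prominence
    is the left boundary; symmetrically the nearest strict local minimum
    rightward is the right boundary.  Extrema farther than ``max_radius``
    from the axis are ignored (default: half the station range, set by the
    caller as half the image width).  A side with no qualifying extremum
    returns ``None``.

    Raises
    ------
    ValueError
        If the profile has no glottis interval (the caller drops the line).
    """
    if profile.glottis_interval is None:
        raise ValueError("profile has no glottis interval")
    i0, i1 = profile.glottis_interval
    d = profile.derivative
    st = profile.line.stations
    if max_radius is None:
        max_radius = 0.5 * (st[-1] - st[0] + 1)

    # plateau_size=(1, None) exposes plateau edges: a step edge smoothed by
    # the moving average yields a flat-topped extremum straddling the true
    # boundary, and the station nearest the glottis lies on the fold side.
    _maxima, max_props = signal.find_peaks(
        d, prominence=prominence, plateau_size=(1, None)
    )
    _minima, min_props = signal.find_peaks(
        -d, prominence=prominence, plateau_size=(1, None)
    )
    maxima = max_props["right_edges"]
    minima = min_props["left_edges"]

    left = None
    cand = maxima[(maxima < i0) & (np.abs(st[maxima]) <= max_radius)]
    if cand.size:
        left = profile.station_point(int(cand.max()))  # nearest to glottis
    right = None
    cand = minima[(minima > i1) & (np.abs(st[minima]) <= max_radius)]
    if cand.size:
        right = profile.station_point(int(cand.min()))
    return left, right


def assemble_point_prompts(
    per_line_points: list[tuple[np.ndarray | None, np.ndarray | None]],
    landmarks: GlottisLandmarks,
    include_glottis_points: bool = True,
) -> PointPromptSet:
    """Combine boundary points and glottis landmarks into one prompt set.

    With three scan lines all succeeding this yields the full nine-point
    prompt (six fold-boundary points plus top/middle/bottom of the
    glottis); missing boundary points simply reduce the count.  All points
    are foreground.  ``include_glottis_points`` exists because the glottal
    gap is arguably not fold tissue; the default keeps the landmarks in.
    """
    pts: list[np.ndarray] = []
    tags: list[str] = []
    for i, (left, right) in enumerate(per_line_points):
        if left is not None:
            pts.append(np.asarray(left, dtype=float))
            tags.append(f"boundary-left-{i}")
        if right is not None:
            pts.append(np.asarray(right, dtype=float))
            tags.append(f"boundary-right-{i}")
    if include_glottis_points:
        for tag, p in (
            ("glottis-top", landmarks.top),
            ("glottis-middle", landmarks.middle),
            ("glottis-bottom", landmarks.bottom),
        ):
            pts.append(np.asarray(p, dtype=float))
            tags.append(tag)
    points = np.array(pts, dtype=float) if pts else np.empty((0, 2))
    return PointPromptSet(
        points=points, labels=np.ones(len(pts), dtype=int), provenance=tuple(tags)
    )


def build_point_prompts(
    image: np.ndarray,
    glottis: BinaryMask,
    landmarks: GlottisLandmarks,
    *,
    smooth_window: int = 5,
    prominence: float = 5.0,
    fractions: tuple[float, ...] = DEFAULT_FRACTIONS,
    include_glottis_points: bool = True,
) -> PointPromptSet:
    """Full point-prompt pipeline for one frame."""
    h, w = np.asarray(image).shape[:2]
    lines = build_scan_lines(landmarks, (h, w), fractions)
    per_line: list[tuple[np.ndarray | None, np.ndarray | None]] = []
    for line in lines:
        try:
            prof = derivative_profile(image, line, glottis, smooth_window)
            per_line.append(
                boundary_points(prof, prominence=prominence, max_radius=0.5 * w)
            )
        except ValueError:
            per_line.append((None, None))  # line missed the glottis entirely
    return assemble_point_prompts(
        per_line, landmarks, include_glottis_points=include_glottis_points
    )
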