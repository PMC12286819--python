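"""Refined bounding-box prompt construction from low-threshold glottis masks.

The box prompt marks the vocal-fold region for the promptable backend.  It
is built by fusing two low-threshold masks (one from the raw frame, one
from a CLAHE contrast-enhanced frame, the latter trusted only inside the
coarse detector box so its extra speckle stays out of non-target areas),
adding the glottis mask, normalizing the pose so the glottal axis is
vertical and centered, morphologically closing the fused mask, selecting
the contour that encompasses the glottis, mapping that region's bounding
box back to the original frame, and averaging it with the detector's box.

The pose normalization removes camera-angle variation: boxes extracted on
the verticalized mask are tighter around the folds than boxes extracted on
an arbitrarily tilted mask.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import exposure, morphology

from .glottis import BinaryMask, ClosedGlottisError, GlottisLandmarks

#: Detector boxes with area below this (px^2) are treated as detector
#: failures and ignored — undersized boxes are a known failure mode.
MIN_DETECTOR_BOX_AREA = 25.0


@dataclass(frozen=True)
class Box:
    """Axis-aligned box in continuous pixel coordinates, corners inclusive."""

    x_min: float
    y_min: float
    x_max: float
    y_max: float

    def __post_init__(self) -> None:
        if self.x_min > self.x_max or self.y_min > self.y_max:
            raise ValueError(f"degenerate box ordering: {self}")

    @property
    def width(self) -> float:
        return self.x_max - self.x_min

    @property
    def height(self) -> float:
        return self.y_max - self.y_min

    @property
    def area(self) -> float:
        return self.width * self.height

    @property
    def center(self) -> np.ndarray:
        return np.array(
            [(self.x_min + self.x_max) / 2.0, (self.y_min + self.y_max) / 2.0]
        )

    def normalized(self) -> "Box":
        """Return a copy with corner ordering repaired (used after jitter)."""
        return Box(
            min(self.x_min, self.x_max),
            min(self.y_min, self.y_max),
            max(self.x_min, self.x_max),
            max(self.y_min, self.y_max),
        )

    def contains_point(self, p) -> bool:
        x, y = float(p[0]), float(p[1])
        return self.x_min <= x <= self.x_max and self.y_min <= y <= self.y_max

    def iou(self, other: "Box") -> float:
        ix = max(0.0, min(self.x_max, other.x_max) - max(self.x_min, other.x_min))
        iy = max(0.0, min(self.y_max, other.y_max) - max(self.y_min, other.y_min))
        inter = ix * iy
        union = self.area + other.area - inter
        return inter / union if union > 0 else 0.0

    def clip(self, width: float, height: float) -> "Box":
        return Box(
            max(0.0, self.x_min),
            max(0.0, self.y_min),
            min(float(width), self.x_max),
            min(float(height), self.y_max),
        )

    def pixel_mask(self, shape: tuple[int, int]) -> BinaryMask:
        """Boolean mask of pixels whose centers fall inside the box."""
        h, w = shape[:2]
        out = np.zeros((h, w), dtype=bool)
        x0 = max(0, int(np.ceil(self.x_min)))
        y0 = max(0, int(np.ceil(self.y_min)))
        x1 = min(w - 1, int(np.floor(self.x_max)))
        y1 = min(h - 1, int(np.floor(self.y_max)))
        if x1 >= x0 and y1 >= y0:
            out[y0 : y1 + 1, x0 : x1 + 1] = True
        return out

    def as_xyxy(self) -> tuple[float, float, float, float]:
        return (self.x_min, self.y_min, self.x_max, self.y_max)


@dataclass(frozen=True)
class RigidTransform:
    """Rotation about a center followed by a translation.

    ``apply`` maps a point ``p`` to ``R(angle) (p - center) + center +
    translation`` where ``R`` acts on (x, y) image coordinates (y down).
    ``apply_inverse`` undoes the map; round-tripping any point is exact to
    floating precision.
    """

    angle_deg: float
    center: np.ndarray
    translation: np.ndarray

    def _rot(self, deg: float) -> np.ndarray:
        r = np.radians(deg)
        c, s = np.cos(r), np.sin(r)
        return np.array([[c, -s], [s, c]])

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        out = (pts - self.center) @ self._rot(self.angle_deg).T + self.center
        out = out + self.translation
        return out.reshape(np.shape(points))

    def apply_inverse(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        out = (pts - self.translation - self.center) @ self._rot(-self.angle_deg).T
        out = out + self.center
        return out.reshape(np.shape(points))

    @property
    def is_identity(self) -> bool:
        return abs(self.angle_deg) < 1e-9 and np.allclose(self.translation, 0.0)

    def warp_mask(self, mask: BinaryMask) -> BinaryMask:
        """Resample a binary mask under the transform (nearest neighbor).

        Nearest-neighbor interpolation preserves binarity; the output grid
        has the same shape as the input.
        """
        if self.is_identity:
            return np.asarray(mask, dtype=bool).copy()
        h, w = mask.shape
        ys, xs = np.mgrid[0:h, 0:w]
        dest = np.stack([xs.ravel(), ys.ravel()], axis=1).astype(float)
        src = self.apply_inverse(dest)
        sampled = ndimage.map_coordinates(
            np.asarray(mask, dtype=np.uint8),
            [src[:, 1], src[:, 0]],
            order=0,
            mode="constant",
            cval=0,
        )
        return sampled.reshape(h, w).astype(bool)


def clahe_enhance(
    image: np.ndarray,
    clip_limit: float = 2.0,
    tile_grid: tuple[int, int] = (8, 8),
) -> np.ndarray:
    """Contrast-limited adaptive histogram equalization on an 8-bit image.

    ``clip_limit`` uses the conventional histogram-count parameterization
    (a multiple of the uniform bin height, default 2.0); ``tile_grid`` is
    the (rows, cols) tiling of the image.  RGB input is converted to
    luminance first.  Output is 8-bit with the same shape as the (gray)
    input.
    """
    rows, cols = tile_grid
    if rows <= 0 or cols <= 0:
        raise ValueError(f"tile_grid dims must be positive, got {tile_grid}")
    img = np.asarray(image)
    if img.ndim == 3:
        img = np.rint(
            0.299 * img[..., 0] + 0.587 * img[..., 1] + 0.114 * img[..., 2]
        ).astype(np.uint8)
    img = img.astype(np.uint8)
    if img.min() == img.max():
        return img.copy()  # nothing to equalize
    nbins = 256
    kernel = (max(1, img.shape[0] // rows), max(1, img.shape[1] // cols))
    out = exposure.equalize_adapthist(
        img, kernel_size=kernel, clip_limit=clip_limit / nbins, nbins=nbins
    )
    return np.clip(np.rint(out * 255.0), 0, 255).astype(np.uint8)


def merge_masks_in_box(
    base: BinaryMask, enhanced: BinaryMask, box: Box | None
) -> BinaryMask:
    """Replace ``base`` with ``enhanced`` inside the box, keep it outside.

    The enhanced (CLAHE-derived) mask is richer but noisier; restricting it
    to the detector box keeps its speckle out of non-target areas.  An
    absent box returns ``base`` unchanged.
    """
    base = np.asarray(base, dtype=bool)
    enhanced = np.asarray(enhanced, dtype=bool)
    if base.shape != enhanced.shape:
        raise ValueError("mask shapes differ")
    if box is None:
        return base.copy()
    inside = box.pixel_mask(base.shape)
    out = base.copy()
    out[inside] = enhanced[inside]
    return out


def normalize_pose(
    mask: BinaryMask,
    landmarks: GlottisLandmarks,
    image_center: tuple[float, float] | np.ndarray,
) -> tuple[BinaryMask, RigidTransform]:
    """Verticalize the glottal axis and center the glottis middle point.

    Returns the resampled mask together with the rigid transform used, so
    later stages can map results back into the original frame.
    """
    center = np.asarray(image_center, dtype=float)
    tf = RigidTransform(
        angle_deg=landmarks.axis_angle_deg,
        center=np.asarray(landmarks.middle, dtype=float),
        translation=center - np.asarray(landmarks.middle, dtype=float),
    )
    return tf.warp_mask(mask), tf


def close_and_select_contour(
    mask: BinaryMask, glottis: BinaryMask, kernel_radius: int = 5
) -> BinaryMask:
    """Close the mask and select the filled contour containing the glottis.

    Morphological closing with an elliptical (disk) structuring element
    connects separate-but-close fragments of the fold region.  Among the
    filled outer contours of ``mask | glottis``, the one containing at
    least 99% of glottis pixels is returned (largest area on ties); if
    none qualifies, the largest-area contour overlapping the glottis; if
    the glottis overlaps nothing, the glottis dilated by the kernel radius.
    """
    glottis = np.asarray(glottis, dtype=bool)
    if not glottis.any():
        raise ClosedGlottisError("cannot select a contour around an empty glottis")
    mask = np.asarray(mask, dtype=bool)
    footprint = morphology.disk(int(kernel_radius))
    closed = ndimage.binary_closing(mask | glottis, structure=footprint)
    filled = ndimage.binary_fill_holes(closed)
    labels, n = ndimage.label(filled)
    n_glottis = glottis.sum()
    best_contained = (0, 0)  # (area, label)
    best_overlap = (0, 0)
    for lab in range(1, n + 1):
        comp = labels == lab
        overlap = int((comp & glottis).sum())
        area = int(comp.sum())
        if overlap >= 0.99 * n_glottis and area > best_contained[0]:
            best_contained = (area, lab)
        if overlap > 0 and area > best_overlap[0]:
            best_overlap = (area, lab)
    if best_contained[1]:
        return labels == best_contained[1]
    if best_overlap[1]:
        return labels == best_overlap[1]
    return ndimage.binary_dilation(glottis, structure=footprint)


def region_box(region: BinaryMask, transform: RigidTransform) -> Box:
    """Bounding box of a pose-normalized region mapped back to the frame.

    Every true pixel center is pushed through the inverse transform so the
    box lives in the original frame's coordinates, sharing a coordinate
    system with the detector's box.
    """
    region = np.asarray(region, dtype=bool)
    ys, xs = np.nonzero(region)
    if ys.size == 0:
        raise ValueError("region is empty")
    pts = np.stack([xs, ys], axis=1).astype(float)
    back = transform.apply_inverse(pts)
    return Box(
        float(back[:, 0].min()),
        float(back[:, 1].min()),
        float(back[:, 0].max()),
        float(back[:, 1].max()),
    )


def average_boxes(a: Box, b: Box | None) -> Box:
    """Corner-wise mean of two boxes; detector failure (``b`` absent) keeps ``a``."""
    if b is None:
        return a
    return Box(
        (a.x_min + b.x_min) / 2.0,
        (a.y_min + b.y_min) / 2.0,
        (a.x_max + b.x_max) / 2.0,
        (a.y_max + b.y_max) / 2.0,
    )


def make_detector_labels(
    glottis: BinaryMask,
    margin: float,
    image_size: tuple[int, int],
) -> tuple[int, float, float, float, float] | None:
    """Detector training label: the glottis box grown by a margin.

    Rough fold-region boxes for detector training are generated by dilating
    the glottis bounding box by ``margin`` pixels (default elsewhere: 30,
    i.e. a few dozen) on every side, clipping to the image, and emitting a
    normalized ``(class, cx, cy, w, h)`` record with class 0.  An empty
    glottis yields ``None`` (no record).
    """
    if margin <= 0:
        raise ValueError("margin must be positive")
    glottis = np.asarray(glottis, dtype=bool)
    ys, xs = np.nonzero(glottis)
    if ys.size == 0:
        return None
    h, w = image_size
    box = Box(
        float(xs.min()) - margin,
        float(ys.min()) - margin,
        float(xs.max()) + margin,
        float(ys.max()) + margin,
    ).clip(w, h)
    cx = (box.x_min + box.x_max) / 2.0 / w
    cy = (box.y_min + box.y_max) / 2.0 / h
    return (0, cx, cy, box.width / w, box.height / h)


def valid_detector_box(box: Box | None) -> Box | None:
    """Filter out absent or degenerate (undersized) detector boxes."""
    if box is None or box.area < MIN_DETECTOR_BOX_AREA:
        return None
    return box


def build_box_prompt(
    image: np.ndarray,
    prob_provider,
    detector_box: Box | None,
    *,
    low_threshold: float = 1e-20,
    use_clahe: bool = True,
    clahe_clip: float = 2.0,
    clahe_tile: tuple[int, int] = (8, 8),
    closing_radius: int = 5,
) -> tuple[Box, dict]:
    """Run the full box-prompt pipeline on one frame.

    Steps: low-threshold mask from the raw frame (base); low-threshold mask
    from the CLAHE-enhanced frame (enhanced), merged into the base inside
    the detector box; union with the 0.5-threshold glottis mask; pose
    normalization; closing + glottis-containing contour selection; bounding
    box mapped back to the frame; corner-wise average with the detector
    box.  Returns the final box and a diagnostics dict.

    ``prob_provider`` is a callable ``image -> probability map`` (a real
    network adapter or the phantom emulator).
    """
    from .glottis import binarize, glottis_landmarks  # local: avoid cycle at import

    prob_raw = prob_provider(image)
    glottis = binarize(prob_raw, 0.5)
    if not glottis.any():
        raise ClosedGlottisError("0.5-threshold glottis mask is empty")
    base = binarize(prob_raw, low_threshold)
    det = valid_detector_box(detector_box)

    if use_clahe:
        enhanced_img = clahe_enhance(image, clip_limit=clahe_clip, tile_grid=clahe_tile)
        enhanced = binarize(prob_provider(enhanced_img), low_threshold)
        merged = merge_masks_in_box(base, enhanced, det)
    else:
        merged = base
    merged = merged | glottis

    landmarks = glottis_landmarks(glottis)
    h, w = np.asarray(image).shape[:2]
    # target center on a pixel center so the verticalized axis aligns with a
    # pixel column (a half-pixel target makes tip rasterization asymmetric)
    norm_mask, tf = normalize_pose(merged, landmarks, (w // 2, h // 2))
    norm_glottis = tf.warp_mask(glottis)
    if not norm_glottis.any():
        # degenerate resampling of a tiny glottis; fall back to unnormalized
        norm_mask, norm_glottis = merged, glottis
        tf = RigidTransform(0.0, np.zeros(2), np.zeros(2))
    region = close_and_select_contour(norm_mask, norm_glottis, closing_radius)
    own_box = region_box(region, tf)
    final = average_boxes(own_box, det)
    diagnostics = {
        "low_threshold": low_threshold,
        "use_clahe": use_clahe,
        "detector_box": det.as_xyxy() if det is not None else None,
        "own_box": own_box.as_xyxy(),
        "final_box": final.as_xyxy(),
        "axis_angle_deg": landmarks.axis_angle_deg,
    }
    return final, diagnostics
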