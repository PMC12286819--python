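"""Promptable-segmentation backend contract and deterministic mocks.

A backend is any callable taking an image plus prompts — foreground
points, an optional box, an optional rough-mask logits map from a previous
iteration — and returning ``(binary mask, mask logits, confidence score)``
with image-shaped mask and logits.  Foundation models (SAM, SAM2, ...)
plug in through thin adapters satisfying this contract; the mocks below
make the prompting pipeline testable without checkpoints.
"""

from __future__ import annotations

from typing import Optional, Protocol, runtime_checkable

import numpy as np
from skimage import filters

from .box_prompt import Box
from .glottis import BinaryMask

#: Logit magnitude used by mocks for in/out-of-mask pixels.
_LOGIT = 8.0


@runtime_checkable
class SegmentationBackend(Protocol):
    """Contract for promptable segmentation backends."""

    deterministic: bool

    def __call__(
        self,
        image: np.ndarray,
        points: Optional[np.ndarray],
        box: Optional[Box],
        mask_logits: Optional[np.ndarray],
    ) -> tuple[BinaryMask, np.ndarray, float]:
        ...


def _mask_logits(mask: BinaryMask) -> np.ndarray:
    return np.where(mask, _LOGIT, -_LOGIT)


def _full_mask(shape) -> BinaryMask:
    return np.ones(shape[:2], dtype=bool)


class OracleBackend:
    """Mock backend that knows the ground-truth target region.

    Returns the ground-truth region whenever the prompts are good — box
    IoU with the region's bounding box at least 0.5 and every point inside
    the region — and degrades gracefully otherwise: a given-but-poor box
    yields the box interior, points without a box yield the interior of
    the (slightly padded) point bounding box, and no prompts at all yield
    the whole image.  Confidence mirrors prompt quality, so the
    highest-score selection used in no-prompt mode is exercised.
    """

    deterministic = True

    def __init__(self, gt_region: BinaryMask):
        self.gt_region = np.asarray(gt_region, dtype=bool)
        ys, xs = np.nonzero(self.gt_region)
        if ys.size == 0:
            raise ValueError("OracleBackend needs a non-empty ground-truth region")
        self.gt_box = Box(float(xs.min()), float(ys.min()),
                          float(xs.max()), float(ys.max()))

    def __call__(self, image, points, box, mask_logits):
        shape = np.asarray(image).shape[:2]
        have_points = points is not None and len(points) > 0
        if box is not None:
            points_ok = (not have_points) or all(
                self._inside(p) for p in np.atleast_2d(points)
            )
            if box.iou(self.gt_box) >= 0.5 and points_ok:
                mask = self.gt_region.copy()
                return mask, _mask_logits(mask), 0.99
            mask = box.pixel_mask(shape)
            return mask, _mask_logits(mask), 0.6
        if have_points:
            pts = np.atleast_2d(points)
            pad = 2.0
            pb = Box(
                float(pts[:, 0].min()) - pad,
                float(pts[:, 1].min()) - pad,
                float(pts[:, 0].max()) + pad,
                float(pts[:, 1].max()) + pad,
            )
            mask = pb.pixel_mask(shape)
            return mask, _mask_logits(mask), 0.4
        mask = _full_mask(shape)
        return mask, _mask_logits(mask), 0.1

    def _inside(self, p) -> bool:
        # Continuous point vs rasterized region: the point counts as inside
        # if any of the four surrounding pixels belongs to the region
        # (half-pixel tolerance against edge jagging).
        x, y = float(p[0]), float(p[1])
        h, w = self.gt_region.shape
        for iy in {int(np.floor(y)), int(np.ceil(y))}:
            for ix in {int(np.floor(x)), int(np.ceil(x))}:
                if 0 <= iy < h and 0 <= ix < w and self.gt_region[iy, ix]:
                    return True
        return False


class BoxFillBackend:
    """Mock backend segmenting bright structure inside the box.

    Returns the box interior intersected with pixels brighter than the
    Otsu threshold of the interior (the whole image when no box is given).
    Knows nothing about ground truth, so it exercises the pipeline with a
    purely intensity-driven segmenter.
    """

    deterministic = True

    def __call__(self, image, points, box, mask_logits):
        img = np.asarray(image)
        if img.ndim == 3:
            img = img.mean(axis=2)
        shape = img.shape
        roi = box.pixel_mask(shape) if box is not None else _full_mask(shape)
        vals = img[roi]
        if vals.size == 0 or vals.min() == vals.max():
            mask = roi
        else:
            thr = filters.threshold_otsu(vals)
            mask = roi & (img > thr)
        return mask, _mask_logits(mask), 0.5
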