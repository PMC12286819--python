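"""File formats: frames, labeled masks, probability maps, boxes, prompts, CSV.

Conventions:

* frames — 8-bit PNG/TIFF, read in lexicographic name order; RGB converts
  to luminance, 16-bit rescales to 8-bit by its maximum;
* labeled masks — single-channel 8-bit PNG with fixed codes 0 background,
  85 glottis, 170 left fold, 255 right fold;
* probability maps — 32-bit float TIFF (low-threshold mining needs values
  down to 1e-21, far below 8-bit resolution);
* detector boxes — one-box-per-line text records ``class cx cy w h``, all
  normalized to [0, 1], one file per image with the same stem (the YOLO
  txt dialect);
* prompts — one JSON file per frame (points with provenance, box corners,
  config echo), round-trippable;
* waveforms and Dice reports — CSV via pandas.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import tifffile
from PIL import Image

from .box_prompt import Box
from .glottis import BinaryMask
from .metrics import Waveform
from .runner import (
    LBL_BACKGROUND,
    LBL_GLOTTIS,
    LBL_LEFT,
    LBL_RIGHT,
    FrameResult,
    PromptBundle,
)
from .point_prompt import PointPromptSet

#: Gray codes of the on-disk labeled-mask encoding.
LABEL_CODES = {LBL_BACKGROUND: 0, LBL_GLOTTIS: 85, LBL_LEFT: 170, LBL_RIGHT: 255}
_DECODE = {v: k for k, v in LABEL_CODES.items()}

_FRAME_SUFFIXES = (".png", ".tif", ".tiff")


def read_frames(path: str | Path) -> list[tuple[str, np.ndarray]]:
    """Read all PNG/TIFF frames of a directory in lexicographic name order.

    Returns ``(stem, image)`` pairs with 8-bit grayscale images.  RGB is
    converted to luminance; 16-bit input is rescaled to 8-bit by its
    maximum value.
    """
    path = Path(path)
    files = sorted(
        p for p in path.iterdir() if p.suffix.lower() in _FRAME_SUFFIXES
    )
    if not files:
        raise FileNotFoundError(f"no PNG/TIFF frames in {path}")
    frames = []
    for f in files:
        try:
            arr = _load_gray8(f)
        except Exception as exc:
            raise IOError(f"unreadable frame {f}") from exc
        frames.append((f.stem, arr))
    return frames


def _load_gray8(path: Path) -> np.ndarray:
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = np.asarray(Image.open(path))
    if arr.ndim == 3:
        arr = 0.299 * arr[..., 0] + 0.587 * arr[..., 1] + 0.114 * arr[..., 2]
    arr = np.asarray(arr)
    if arr.dtype == np.uint8:
        return arr
    peak = float(arr.max())
    if peak <= 0:
        return np.zeros(arr.shape, dtype=np.uint8)
    return np.clip(np.rint(arr.astype(float) / peak * 255.0), 0, 255).astype(np.uint8)


def write_frame(path: str | Path, image: np.ndarray) -> None:
    Image.fromarray(np.asarray(image, dtype=np.uint8)).save(path)


def write_labeled_mask(path: str | Path, labels: np.ndarray) -> None:
    """Write internal label codes as the fixed 0/85/170/255 gray encoding."""
    labels = np.asarray(labels)
    out = np.zeros(labels.shape, dtype=np.uint8)
    for internal, gray in LABEL_CODES.items():
        out[labels == internal] = gray
    Image.fromarray(out).save(path)


def read_labeled_mask(path: str | Path) -> np.ndarray:
    """Read a labeled mask, rejecting any pixel value outside the encoding."""
    arr = np.asarray(Image.open(path))
    if arr.ndim != 2:
        raise ValueError(f"labeled mask must be single-channel: {path}")
    values = np.unique(arr)
    bad = [int(v) for v in values if int(v) not in _DECODE]
    if bad:
        raise ValueError(f"unknown label values {bad} in {path}")
    out = np.zeros(arr.shape, dtype=np.uint8)
    for gray, internal in _DECODE.items():
        out[arr == gray] = internal
    return out


def write_probability_map(path: str | Path, prob: np.ndarray) -> None:
    tifffile.imwrite(path, np.asarray(prob, dtype=np.float32))


def read_probability_map(path: str | Path) -> np.ndarray:
    return np.asarray(tifffile.imread(path), dtype=np.float64)


def write_yolo_boxes(
    path: str | Path, records: Sequence[tuple[int, float, float, float, float]]
) -> None:
    """Write normalized ``class cx cy w h`` records, one per line."""
    lines = [
        f"{int(c)} {cx:.6f} {cy:.6f} {w:.6f} {h:.6f}"
        for c, cx, cy, w, h in records
    ]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_yolo_boxes(
    path: str | Path,
) -> list[tuple[int, float, float, float, float]]:
    out = []
    text = Path(path).read_text()
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 5:
            raise ValueError(f"malformed detector record in {path}: {line!r}")
        out.append((int(parts[0]), *(float(p) for p in parts[1:])))
    return out


def yolo_to_box(
    record: tuple[int, float, float, float, float], image_size: tuple[int, int]
) -> Box:
    """Convert a normalized record to pixel corner coordinates."""
    _cls, cx, cy, w, h = record
    ih, iw = image_size
    return Box(
        (cx - w / 2.0) * iw,
        (cy - h / 2.0) * ih,
        (cx + w / 2.0) * iw,
        (cy + h / 2.0) * ih,
    )


def write_prompts(
    path: str | Path,
    image_id: str,
    bundle: PromptBundle,
    config_echo: Optional[dict] = None,
) -> None:
    """Write one frame's prompt bundle as round-trippable JSON.

    The box field is an explicit ``null`` when the bundle carries no box.
    """
    points = []
    if bundle.points is not None:
        for p, lab, tag in zip(
            bundle.points.points, bundle.points.labels, bundle.points.provenance
        ):
            points.append(
                {"x": float(p[0]), "y": float(p[1]), "label": int(lab),
                 "provenance": tag}
            )
    doc = {
        "image_id": image_id,
        "points": points,
        "box": list(bundle.box.as_xyxy()) if bundle.box is not None else None,
        "iterations": bundle.iterations,
        "config": config_echo or {},
    }
    Path(path).write_text(json.dumps(doc, indent=2) + "\n")


def read_prompts(path: str | Path) -> tuple[str, PromptBundle, dict]:
    doc = json.loads(Path(path).read_text())
    pts = doc["points"]
    point_set = None
    if pts:
        point_set = PointPromptSet(
            points=np.array([[p["x"], p["y"]] for p in pts], dtype=float),
            labels=np.array([p["label"] for p in pts], dtype=int),
            provenance=tuple(p["provenance"] for p in pts),
        )
    box = Box(*doc["box"]) if doc["box"] is not None else None
    bundle = PromptBundle(points=point_set, box=box, iterations=doc["iterations"])
    return doc["image_id"], bundle, doc.get("config", {})


def waveforms_to_frame(
    vfm: tuple[Waveform, Waveform],
    vfw: tuple[Waveform, Waveform],
    gaw: Waveform,
    exclude_missing: bool = False,
) -> pd.DataFrame:
    """Tidy long-format table: frame, missing, side, station, vfm, vfw, gaw.

    ``exclude_missing`` drops closed-glottis frames (the convention for
    width-waveform export); by default they stay, flagged, so the series
    remain aligned with the frame index.
    """
    rows = []
    n_frames = gaw.n_frames
    for t in range(n_frames):
        miss = bool(vfm[0].missing[t])
        for side_idx, side in enumerate(("left", "right")):
            for s in range(vfm[side_idx].n_stations):
                rows.append(
                    {
                        "frame": t,
                        "missing": miss,
                        "side": side,
                        "station": s + 1,
                        "vfm_px": vfm[side_idx].values[t, s],
                        "vfw_px": vfw[side_idx].values[t, s],
                        "gaw_px2": gaw.values[t, 0],
                    }
                )
    df = pd.DataFrame(rows)
    if exclude_missing:
        df = df[~df["missing"]].reset_index(drop=True)
    return df


def dice_report(
    per_frame: Sequence[dict[str, float]],
) -> pd.DataFrame:
    """Per-frame Dice table with a trailing mean row."""
    df = pd.DataFrame(per_frame)
    mean = df.drop(columns=["frame"]).mean(numeric_only=True)
    mean_row = {"frame": "mean", **{k: float(v) for k, v in mean.items()}}
    return pd.concat([df, pd.DataFrame([mean_row])], ignore_index=True)


def frame_result_to_files(
    out_dir: str | Path,
    stem: str,
    result: FrameResult,
    config_echo: Optional[dict] = None,
) -> None:
    """Write a frame's labeled mask and prompt file side by side."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_labeled_mask(out_dir / f"{stem}_labels.png", result.labels)
    if result.prompts is not None:
        write_prompts(out_dir / f"{stem}_prompts.json", stem, result.prompts,
                      config_echo)
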