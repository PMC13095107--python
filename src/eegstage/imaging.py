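"""Windowing and 8-bit image encoding.

A denoised 256 Hz recording is cut into contiguous, non-overlapping 5-second
windows (1280 samples x 19 channels); any trailing partial window is
discarded. Each window is min-max quantized to an 8-bit grey image of the
same shape — the classifier's sample unit. Quantization is per segment, so
the encoding is invariant to affine amplitude changes of the window.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image

from .io import Recording
from .montage import LABELS, N_CHANNELS, TARGET_FS

__all__ = ["Segment", "SegmentImage", "segment", "to_image", "write_image", "read_image"]

WINDOW_S = 5
SEGMENT_ROWS = WINDOW_S * TARGET_FS  # 1280


@dataclass
class Segment:
    """A 5-second window of a recording: 1280 x 19 µV matrix plus provenance."""

    subject_id: str
    label: str
    index: int
    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if not np.isfinite(self.data).all():
            raise ValueError("segment contains non-finite values")


@dataclass
class SegmentImage:
    """8-bit quantized form of a Segment; ``scale`` records (min_µV, max_µV)."""

    subject_id: str
    label: str
    index: int
    pixels: np.ndarray
    scale: tuple[float, float]

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.uint8)
        if self.scale[0] > self.scale[1]:
            raise ValueError("scale min exceeds scale max")


def segment(rec: Recording, window_s: float = WINDOW_S) -> list[Segment]:
    """Cut a 256 Hz recording into non-overlapping ``window_s``-second pieces.

    Returns ``floor(n_samples / (fs * window_s))`` segments; windows are
    half-open ``[k*w, (k+1)*w)`` sample ranges. Short recordings yield an
    empty list.
    """
    if rec.fs != TARGET_FS:
        raise ValueError("segmentation expects a 256 Hz recording; down-sample first")
    if window_s <= 0:
        raise ValueError("window_s must be positive")
    w = int(round(window_s * rec.fs))
    count = rec.n_samples // w
    return [
        Segment(rec.subject_id, rec.label, k, rec.data[k * w : (k + 1) * w])
        for k in range(count)
    ]


def to_image(seg: Segment) -> SegmentImage:
    """Per-segment min-max quantization to 8 bits.

    ``pixel = round(255 * (v - min) / (max - min))``; a constant segment
    (max == min) maps every pixel to 0 by convention.
    """
    lo = float(seg.data.min())
    hi = float(seg.data.max())
    if hi > lo:
        pix = np.rint(255.0 * (seg.data - lo) / (hi - lo)).astype(np.uint8)
    else:
        pix = np.zeros_like(seg.data, dtype=np.uint8)
    return SegmentImage(seg.subject_id, seg.label, seg.index, pix, (lo, hi))


def dequantize(img: SegmentImage) -> np.ndarray:
    """Map pixels back to µV using the recorded scale (lossy inverse)."""
    lo, hi = img.scale
    return lo + img.pixels.astype(np.float64) * (hi - lo) / 255.0


_NAME_RE = re.compile(r"^(?P<sid>.+)__(?P<label>[A-Z]+)__(?P<idx>\d{5})\.(png|jpg)$")


def image_filename(img: SegmentImage, fmt: str = "png") -> str:
    """Canonical file name encoding subject id, label and segment index."""
    return f"{img.subject_id}__{img.label}__{img.index:05d}.{fmt}"


def parse_image_filename(name: str) -> tuple[str, str, int]:
    m = _NAME_RE.match(Path(name).name)
    if not m or m.group("label") not in LABELS:
        raise ValueError(f"not a segment-image file name: {name}")
    return m.group("sid"), m.group("label"), int(m.group("idx"))


def write_image(img: SegmentImage, path: str | Path, fmt: str = "png") -> Path:
    """Write the 8-bit image; PNG is lossless, JPG uses maximum quality.

    The single grey plane is replicated to three identical channels so the
    file is a conventional 8-bit colour container.
    """
    path = Path(path)
    rgb = np.repeat(img.pixels[:, :, None], 3, axis=2)
    im = Image.fromarray(rgb, mode="RGB")
    if fmt == "png":
        im.save(path, format="PNG")
    elif fmt == "jpg":
        im.save(path, format="JPEG", quality=100, subsampling=0)
    else:
        raise ValueError(f"unknown image format {fmt!r}")
    return path


def read_image(path: str | Path) -> SegmentImage:
    """Load a stored segment image, collapsing the replicated colour planes."""
    path = Path(path)
    sid, label, idx = parse_image_filename(path.name)
    arr = np.asarray(Image.open(path).convert("RGB"), dtype=np.float64)
    grey = np.rint(arr.mean(axis=2)).astype(np.uint8)
    return SegmentImage(sid, label, idx, grey, (0.0, 255.0))
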