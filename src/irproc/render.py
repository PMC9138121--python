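"""Quantitatively accurate false-color rendering of temperature frames.

The display range is chosen by histogram stretching: a stated fraction of
extreme pixels (0%, 0.3% or 3% for the low / normal / high contrast options)
is excluded from the mapped range, split between the two histogram tails.
The retained range maps linearly onto a 256-entry lookup table, so every
rendered pixel can be decoded back to a temperature within one LUT bin
width — rendered images remain measurements, not just pictures.

Two palettes are provided: the perceptually uniform "inferno" map (dark
purple through red and yellow; color-blind safe) and classic greyscale
(cold = black, warm = white).  Both have monotonically increasing luma, so
they survive black-and-white reproduction.
"""

from __future__ import annotations

import enum
import logging
import struct
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from PIL import Image, ImageDraw, ImageFont

from ._inferno import INFERNO_LUT
from .radiometry import TemperatureFrame

logger = logging.getLogger(__name__)


class RenderError(ValueError):
    pass


class Contrast(enum.Enum):
    """Histogram-stretch contrast level: total tail fraction excluded."""

    LOW = 0.0
    NORMAL = 0.003
    HIGH = 0.03


class Scope(enum.Enum):
    GLOBAL = "global"
    PER_IMAGE = "per-image"


class PaletteName(enum.Enum):
    INFERNO = "inferno"
    GREYSCALE = "grey"


@dataclass(frozen=True)
class DisplayRange:
    """Temperature interval mapped onto the full palette."""

    t_min: float
    t_max: float
    contrast: Contrast = Contrast.NORMAL
    scope: Scope = Scope.PER_IMAGE

    def __post_init__(self) -> None:
        if not (self.t_min < self.t_max):
            raise RenderError(f"invalid display range [{self.t_min}, {self.t_max}]")


@dataclass(frozen=True)
class Palette:
    name: PaletteName
    lut: tuple  # 256 RGB triplets

    def __post_init__(self) -> None:
        if len(self.lut) != 256:
            raise RenderError("palette LUT must have 256 entries")

    def as_array(self) -> np.ndarray:
        return np.asarray(self.lut, dtype=np.uint8)


_GREY_LUT = tuple((i, i, i) for i in range(256))

PALETTES = {
    PaletteName.INFERNO: Palette(PaletteName.INFERNO, INFERNO_LUT),
    PaletteName.GREYSCALE: Palette(PaletteName.GREYSCALE, _GREY_LUT),
}


def get_palette(name: str | PaletteName) -> Palette:
    if isinstance(name, str):
        name = PaletteName(name)
    return PALETTES[name]


# ---------------------------------------------------------------------------
# display range
# ---------------------------------------------------------------------------


def compute_display_range(
    values: np.ndarray | Iterable[float],
    contrast: Contrast = Contrast.NORMAL,
    scope: Scope = Scope.PER_IMAGE,
) -> DisplayRange:
    """Histogram-stretched display range over the pooled defined pixels.

    The total number of excluded pixels is ``round(f * n)`` for tail
    fraction ``f``; it is split between the tails, the odd pixel (if any)
    going to the upper tail.  Range endpoints are the nearest-rank order
    statistics just inside the excluded tails, so with distinct values
    exactly the excluded pixels fall strictly outside ``[t_min, t_max]``.

    A constant input yields a degenerate range; it is expanded by 0.5 degC
    on each side with a logged warning.
    """
    v = np.asarray(list(values) if not isinstance(values, np.ndarray) else values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size < 2:
        raise RenderError("display range needs at least two defined temperature values")
    v = np.sort(v, kind="stable")
    n = v.size
    m = int(round(contrast.value * n))
    m_low = m // 2
    m_high = m - m_low
    t_min = float(v[m_low])
    t_max = float(v[n - 1 - m_high])
    if not (t_min < t_max):
        logger.warning("degenerate temperature range at %.2f degC; expanding by +/-0.5", t_min)
        t_min, t_max = t_min - 0.5, t_max + 0.5
    return DisplayRange(t_min=t_min, t_max=t_max, contrast=contrast, scope=scope)


# ---------------------------------------------------------------------------
# palette application
# ---------------------------------------------------------------------------


def temperature_to_index(temp_C: np.ndarray, rng: DisplayRange) -> np.ndarray:
    """Linear map of temperatures to LUT indices 0..255.

    Mid-bin ties round half-up (the exact midpoint of the range maps to
    index 128).  Out-of-range values clamp to the endpoints; undefined
    pixels map to index 0.
    """
    span = rng.t_max - rng.t_min
    with np.errstate(invalid="ignore"):
        x = (np.asarray(temp_C, dtype=float) - rng.t_min) / span * 255.0
        idx = np.floor(x + 0.5)
        idx = np.clip(idx, 0, 255)
    idx = np.where(np.isfinite(idx), idx, 0).astype(np.uint8)
    return idx


def index_to_temperature(idx: np.ndarray, rng: DisplayRange) -> np.ndarray:
    """Decode LUT indices back to the bin-center temperatures."""
    span = rng.t_max - rng.t_min
    return rng.t_min + np.asarray(idx, dtype=float) / 255.0 * span


def apply_palette(
    frame: TemperatureFrame, rng: DisplayRange, palette: Palette | str | PaletteName
) -> np.ndarray:
    """Render a temperature frame to an ``(H, W, 3)`` uint8 RGB image."""
    if not isinstance(palette, Palette):
        palette = get_palette(palette)
    n_undef = int(np.count_nonzero(~frame.defined_mask()))
    if n_undef:
        logger.warning("%d undefined pixel(s) rendered at palette minimum", n_undef)
    idx = temperature_to_index(frame.temp_C, rng)
    return palette.as_array()[idx]


# ---------------------------------------------------------------------------
# scale bar
# ---------------------------------------------------------------------------


class BarSize(enum.Enum):
    SMALL = "small"
    LARGE = "large"


# (bar width, margin, font scale) per size
_BAR_GEOM = {BarSize.SMALL: (10, 4, 1), BarSize.LARGE: (20, 8, 2)}


def add_scale_bar(
    rgb: np.ndarray,
    rng: DisplayRange,
    palette: Palette | str | PaletteName,
    size: BarSize | str = BarSize.SMALL,
) -> np.ndarray:
    """Overlay a vertical palette bar with min/max labels (1 decimal, degC).

    The bar sits in the right margin of the image; warm (LUT top) is at the
    top.  Pixels outside the bar-and-label region are untouched.
    """
    if not isinstance(palette, Palette):
        palette = get_palette(palette)
    if isinstance(size, str):
        size = BarSize(size)
    bar_w, margin, fscale = _BAR_GEOM[size]
    h, w = rgb.shape[:2]
    label_h = 10 * fscale
    bar_h = h - 2 * margin - 2 * label_h
    needed_w = bar_w + 2 * margin + 40 * fscale
    if bar_h < 32 or w < needed_w:
        hint = " (try size=SMALL)" if size is BarSize.LARGE else ""
        raise RenderError(f"image {w}x{h} too small to host a {size.value} scale bar{hint}")
    out = Image.fromarray(np.ascontiguousarray(rgb))
    draw = ImageDraw.Draw(out)
    x0 = w - margin - bar_w
    y0 = margin + label_h
    lut = palette.as_array()
    # vertical gradient: top row shows LUT[255], bottom row LUT[0]
    for row in range(bar_h):
        li = 255 - int(round(row / (bar_h - 1) * 255))
        draw.line([(x0, y0 + row), (x0 + bar_w - 1, y0 + row)], fill=tuple(lut[li]))
    draw.rectangle([x0 - 1, y0 - 1, x0 + bar_w, y0 + bar_h], outline=(255, 255, 255))
    font = ImageFont.load_default()
    for text, y, anchor in (
        (f"{rng.t_max:.1f}", margin, "ra"),
        (f"{rng.t_min:.1f}", y0 + bar_h + 1, "ra"),
    ):
        draw.text((w - margin, y), text, fill=(255, 255, 255), font=font, anchor=anchor)
    return np.asarray(out)


def scale_bar_region(rgb_shape: tuple, size: BarSize | str = BarSize.SMALL) -> tuple:
    """Column index from which the scale-bar overlay may modify pixels."""
    if isinstance(size, str):
        size = BarSize(size)
    bar_w, margin, fscale = _BAR_GEOM[size]
    w = rgb_shape[1]
    return (0, w - margin - bar_w - 1 - 40 * fscale)


# ---------------------------------------------------------------------------
# video export (uncompressed AVI)
# ---------------------------------------------------------------------------


def export_video(
    frames: Sequence[np.ndarray], path: str | Path, fps: int = 10
) -> None:
    """Write RGB frames, in order, as an uncompressed RGB24 AVI file.

    Uncompressed DIB frames keep the export lossless and free of external
    codec dependencies; file size is ``3 * W * H`` bytes per frame.
    """
    frames = list(frames)
    if not frames:
        raise RenderError("need at least one frame")
    shapes = {f.shape for f in frames}
    if len(shapes) != 1:
        raise RenderError(f"mixed frame dimensions: {sorted(shapes)}")
    h, w = frames[0].shape[:2]
    if fps <= 0:
        raise RenderError("fps must be positive")
    row_bytes = (w * 3 + 3) & ~3  # rows padded to 4 bytes per the DIB spec
    frame_bytes = row_bytes * h
    n = len(frames)

    def chunk(fourcc: bytes, payload: bytes) -> bytes:
        pad = b"\x00" if len(payload) % 2 else b""
        return fourcc + struct.pack("<I", len(payload)) + payload + pad

    avih = struct.pack(
        "<14I",
        int(1e6 / fps), frame_bytes * fps, 0, 0x10,  # usec/frame, byterate, pad, HASINDEX
        n, 0, 1, frame_bytes, w, h, 0, 0, 0, 0,
    )
    strh = struct.pack(
        "<4s4sIHHIIIIIIIIhhhh",
        b"vids", b"DIB ", 0, 0, 0, 0, 1, fps, 0, n, frame_bytes, 0, 0, 0, 0, w, h
    )
    strf = struct.pack("<IiiHHIIiiII", 40, w, h, 1, 24, 0, frame_bytes, 0, 0, 0, 0)
    strl = chunk(b"LIST", b"strl" + chunk(b"strh", strh) + chunk(b"strf", strf))
    hdrl = chunk(b"LIST", b"hdrl" + chunk(b"avih", avih) + strl)

    movi_payload = b"movi"
    index = b""
    offset = 4
    for f in frames:
        # DIB: bottom-up rows, BGR byte order, 4-byte row padding
        bgr = np.ascontiguousarray(f[::-1, :, ::-1]).astype(np.uint8)
        if row_bytes != w * 3:
            padded = np.zeros((h, row_bytes), dtype=np.uint8)
            padded[:, : w * 3] = bgr.reshape(h, w * 3)
            payload = padded.tobytes()
        else:
            payload = bgr.tobytes()
        movi_payload += chunk(b"00db", payload)
        index += b"00db" + struct.pack("<III", 0x10, offset, len(payload))
        offset += 8 + len(payload) + (len(payload) % 2)
    riff = hdrl + chunk(b"LIST", movi_payload) + chunk(b"idx1", index)
    with open(path, "wb") as fh:
        fh.write(b"RIFF" + struct.pack("<I", 4 + len(riff)) + b"AVI " + riff)


def count_video_frames(path: str | Path) -> int:
    """Frame count declared in an AVI main header (for verification)."""
    data = Path(path).read_bytes()
    if data[:4] != b"RIFF" or data[8:12] != b"AVI ":
        raise RenderError("not an AVI file")
    pos = data.find(b"avih")
    if pos < 0:
        raise RenderError("no AVI main header")
    return struct.unpack_from("<I", data, pos + 8 + 16)[0]
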