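"""Reproducible per-object temperature statistics via 8-bit label masks.

A label mask is a single-channel 8-bit image of the same size as the
temperature frames: pixel value 0 is unmeasured background, values 1..255
identify up to 255 objects.  For every (image, object) pair the mean,
minimum, maximum and standard deviation of the defined temperatures are
reported.  Masks are ordinary PNG files, so they can be drawn or edited in
any image editor and reused to repeat the exact same measurement.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from PIL import Image

from .radiometry import TemperatureFrame

logger = logging.getLogger(__name__)


class MeasureError(ValueError):
    pass


@dataclass
class LabelMask:
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise MeasureError("label mask must be a single-channel 2-D image")
        if self.labels.dtype != np.uint8:
            if self.labels.min() < 0 or self.labels.max() > 255:
                raise MeasureError("label values must fit in 8 bits (0..255)")
            self.labels = self.labels.astype(np.uint8)

    @property
    def width(self) -> int:
        return self.labels.shape[1]

    @property
    def height(self) -> int:
        return self.labels.shape[0]

    def label_inventory(self) -> list[int]:
        """Sorted object labels present in the mask (background excluded)."""
        present = np.unique(self.labels)
        return [int(v) for v in present if v != 0]


@dataclass
class MeasurementRecord:
    """Summary statistics of one object in one image, in degrees C.

    The standard deviation is the population form (divide by n), with
    ``sd = 0`` for a single pixel; statistics are over defined pixels only.
    A label with no defined pixel yields ``pixel_count = 0`` and NaN stats.
    """

    image_id: str
    label: int
    mean: float
    min: float
    max: float
    sd: float
    pixel_count: int


def measure_objects(
    frames: Sequence[tuple[str, TemperatureFrame]], mask: LabelMask
) -> list[MeasurementRecord]:
    """Per-object statistics for every frame, one record per (image, label).

    Records are ordered lexicographically by image id, then by ascending
    label.  Undefined (NaN) pixels inside an object are excluded from the
    statistics; if every pixel of an object is undefined the record carries
    ``pixel_count = 0`` and NaN statistics (logged).
    """
    labels = mask.label_inventory()
    if not labels:
        logger.warning("mask contains no object labels (all background)")
    records: list[MeasurementRecord] = []
    for image_id, frame in sorted(frames, key=lambda p: p[0]):
        if frame.temp_C.shape != mask.labels.shape:
            raise MeasureError(
                f"{image_id}: frame {frame.temp_C.shape} does not match mask "
                f"{mask.labels.shape}"
            )
        defined = frame.defined_mask()
        for lab in labels:
            sel = (mask.labels == lab) & defined
            n = int(np.count_nonzero(sel))
            if n == 0:
                logger.warning("%s: object %d has no defined pixels", image_id, lab)
                records.append(
                    MeasurementRecord(image_id, lab, math.nan, math.nan, math.nan, math.nan, 0)
                )
                continue
            vals = frame.temp_C[sel]
            records.append(
                MeasurementRecord(
                    image_id=image_id,
                    label=lab,
                    mean=float(vals.mean()),
                    min=float(vals.min()),
                    max=float(vals.max()),
                    sd=float(vals.std(ddof=0)),
                    pixel_count=n,
                )
            )
    return records


def records_to_frame(records: Iterable[MeasurementRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "image": r.image_id,
                "label": r.label,
                "mean_C": r.mean,
                "min_C": r.min,
                "max_C": r.max,
                "sd_C": r.sd,
                "pixel_count": r.pixel_count,
            }
            for r in records
        ]
    )


def write_measurements_csv(records: Iterable[MeasurementRecord], path: str | Path) -> None:
    records_to_frame(records).to_csv(path, index=False, float_format="%.4f")


# ---------------------------------------------------------------------------
# mask I/O
# ---------------------------------------------------------------------------


def load_mask(path: str | Path) -> LabelMask:
    """Load an 8-bit single-channel mask image."""
    with Image.open(path) as im:
        if im.mode != "L":
            raise MeasureError(
                f"{path}: mask must be 8-bit single-channel (mode 'L'), got mode "
                f"{im.mode!r}; convert it to 8-bit greyscale first"
            )
        mask = LabelMask(labels=np.asarray(im))
    inv = mask.label_inventory()
    logger.info("mask %s: %d object label(s)", path, len(inv))
    return mask


def save_mask(mask: LabelMask, path: str | Path) -> None:
    Image.fromarray(mask.labels, mode="L").save(path, format="PNG")


def label_binary(binary: np.ndarray) -> LabelMask:
    """Convert a thresholded binary image to a sequentially labelled mask.

    Connected foreground components (8-connectivity) become objects 1, 2,
    ... in scan order, mirroring a threshold-then-select workflow for
    segmenting leaves or other objects.  More than 255 components is an
    error.
    """
    from scipy import ndimage

    lab, n = ndimage.label(np.asarray(binary) != 0, structure=np.ones((3, 3), dtype=int))
    if n > 255:
        raise MeasureError(f"{n} connected components exceed the 255-object capacity")
    return LabelMask(labels=lab.astype(np.uint8))
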