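"""Batch processing of image folders: raw extraction, temperature, outputs.

For every radiometric image in a folder the processor writes four files into
per-type subfolders — the extracted raw frame (``raw/<stem>.png``, 16-bit),
the temperature raster (``temp/<stem>.tif``, 32-bit float degC), a
false-color rendering (``color/<stem>.png``) and the temperature grid as
text (``text/<stem>.csv``) — plus one ``parameters.csv`` for the whole run
recording every value that went into the computation.  Re-running with that
table (the from-file mode) reproduces the temperature CSVs byte for byte.

Three parameterization modes mirror common field situations: use each
image's stored parameters; override the user-set parameters globally for
the whole folder (calibration constants still come from each file); or take
each image's user-set parameters from a CSV row keyed by filename.
"""

from __future__ import annotations

import dataclasses
import enum
import logging
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from . import flir_io, render
from .flir_io import ImageMetadata, ParameterRecord
from .radiometry import (
    AcquisitionParams,
    RawFrame,
    TemperatureFrame,
    frame_to_temperature,
)

logger = logging.getLogger(__name__)

SUBFOLDERS = ("raw", "temp", "color", "text")


class BatchError(Exception):
    pass


class NothingToProcessError(BatchError):
    pass


class Mode(enum.Enum):
    PER_IMAGE_STORED = "stored"
    GLOBAL_OVERRIDE = "global"
    FROM_FILE = "file"


@dataclass
class ProcessMode:
    """Parameterization mode for one run; exactly one mode is active."""

    mode: Mode = Mode.PER_IMAGE_STORED
    override: AcquisitionParams | None = None
    params_file: str | Path | None = None

    def __post_init__(self) -> None:
        if self.mode is Mode.GLOBAL_OVERRIDE and self.override is None:
            raise BatchError("global-override mode needs a set of acquisition parameters")
        if self.mode is Mode.FROM_FILE and self.params_file is None:
            raise BatchError("from-file mode needs a parameter table path")


@dataclass
class ImageResult:
    stem: str
    source: str
    outputs: dict = field(default_factory=dict)
    record: ParameterRecord | None = None
    error: str | None = None
    undefined_pixels: int = 0


@dataclass
class RunManifest:
    folder: str
    results: list[ImageResult] = field(default_factory=list)
    parameters_csv: str | None = None

    @property
    def n_ok(self) -> int:
        return sum(1 for r in self.results if r.error is None)

    @property
    def n_failed(self) -> int:
        return sum(1 for r in self.results if r.error is not None)

    @property
    def exit_status(self) -> int:
        """0 all processed, 1 partial failure, 2 nothing succeeded."""
        if self.n_ok == 0:
            return 2
        return 1 if self.n_failed else 0


# ---------------------------------------------------------------------------
# input discovery
# ---------------------------------------------------------------------------


def discover_inputs(folder: Path) -> list[Path]:
    """Radiometric JPEGs and sidecar raw rasters, case-insensitive by
    extension, in lexicographic filename order for determinism."""
    hits = []
    for p in sorted(folder.iterdir()):
        name = p.name.lower()
        if name.endswith((".jpg", ".jpeg")):
            hits.append(p)
        elif name.endswith((".raw.png", ".raw.tif", ".raw.tiff")):
            hits.append(p)
    return hits


def _sidecar_stem(path: Path) -> str:
    name = path.name
    for suffix in (".raw.png", ".raw.tif", ".raw.tiff"):
        if name.lower().endswith(suffix):
            return name[: -len(suffix)]
    return path.stem


def _load_sidecar(path: Path) -> tuple[RawFrame, ParameterRecord]:
    stem = _sidecar_stem(path)
    csv_path = path.with_name(f"{stem}.params.csv")
    if not csv_path.exists():
        raise BatchError(f"{path.name}: sidecar parameter file {csv_path.name} not found")
    rec = flir_io.read_parameter_table(csv_path)[0]
    if path.name.lower().endswith(".raw.png"):
        order = flir_io.resolve_byte_order("PNG", rec.cameraModel)
        arr = np.asarray(iio.imread(path)).astype(np.uint16)
        if order == "little":
            arr = arr.byteswap()
        raw = RawFrame(dn=arr)
    else:
        import tifffile

        raw = RawFrame(dn=tifffile.imread(path).astype(np.float64))
    rec.filename = path.name
    return raw, rec


def load_input(path: Path) -> tuple[RawFrame, ParameterRecord]:
    """Read one input (radiometric JPEG or sidecar pair) into a raw frame
    plus the parameter record stored with it."""
    if path.name.lower().endswith((".jpg", ".jpeg")):
        meta = flir_io.extract_metadata(path)
        order = flir_io.resolve_byte_order(meta.raw_image_type, meta.camera_model)
        raw = flir_io.extract_raw_frame(path, order)
        return raw, ParameterRecord.from_metadata(meta)
    return _load_sidecar(path)


# ---------------------------------------------------------------------------
# processing
# ---------------------------------------------------------------------------


def _apply_mode(
    rec: ParameterRecord, mode: ProcessMode, table: dict[str, ParameterRecord]
) -> ParameterRecord:
    if mode.mode is Mode.PER_IMAGE_STORED:
        return rec
    if mode.mode is Mode.GLOBAL_OVERRIDE:
        ov = mode.override
        return dataclasses.replace(
            rec,
            objEmissivity=ov.emissivity,
            airTemp_C=ov.air_temp_C,
            airRelHumidity_perc=ov.rel_humidity * 100.0,
            appReflTemp_C=ov.app_refl_temp_C,
            objDistance_m=ov.distance_m,
        )
    row = table.get(rec.filename)
    if row is None:
        raise BatchError(f"no parameter-table row for {rec.filename!r}")
    # user-set fields come from the table row; calibration stays per image
    return dataclasses.replace(
        rec,
        objEmissivity=row.objEmissivity,
        airTemp_C=row.airTemp_C,
        airRelHumidity_perc=row.airRelHumidity_perc,
        appReflTemp_C=row.appReflTemp_C,
        objDistance_m=row.objDistance_m,
    )


def process_folder(
    folder: str | Path,
    mode: ProcessMode | None = None,
    out_folder: str | Path | None = None,
    palette: str = "inferno",
    contrast: render.Contrast = render.Contrast.NORMAL,
) -> RunManifest:
    """Process every radiometric image in ``folder``.

    Per input, outputs land in the ``raw/``, ``temp/``, ``color/`` and
    ``text/`` subfolders of ``out_folder`` (default: the input folder), and
    one ``parameters.csv`` is written for the run.  Per-image failures are
    recorded in the manifest and do not abort the batch.
    """
    folder = Path(folder)
    mode = mode or ProcessMode()
    out = Path(out_folder) if out_folder is not None else folder
    inputs = discover_inputs(folder)
    if not inputs:
        raise NothingToProcessError(f"no radiometric images found in {folder}")

    table: dict[str, ParameterRecord] = {}
    if mode.mode is Mode.FROM_FILE:
        rows = flir_io.read_parameter_table(mode.params_file)
        table = {r.filename: r for r in rows}
        known = {p.name for p in inputs}
        for fname in table:
            if fname not in known:
                logger.warning("parameter row for %r matches no input file; skipped", fname)

    for sub in SUBFOLDERS:
        (out / sub).mkdir(parents=True, exist_ok=True)

    manifest = RunManifest(folder=str(folder))
    used_records: list[ParameterRecord] = []
    for path in inputs:
        stem = _sidecar_stem(path)
        result = ImageResult(stem=stem, source=str(path))
        manifest.results.append(result)
        try:
            raw, rec = load_input(path)
            rec = _apply_mode(rec, mode, table)
            temp = frame_to_temperature(raw, rec.acquisition(), rec.cal(), rec.atm())
            result.undefined_pixels = int(np.count_nonzero(~temp.defined_mask()))
            if result.undefined_pixels:
                logger.warning(
                    "%s: %d undefined pixel(s)", path.name, result.undefined_pixels
                )
            rng = render.compute_display_range(
                temp.temp_C[temp.defined_mask()], contrast, render.Scope.PER_IMAGE
            )
            rgb = render.apply_palette(temp, rng, palette)
            outputs = {
                "raw": out / "raw" / f"{stem}.png",
                "temp": out / "temp" / f"{stem}.tif",
                "color": out / "color" / f"{stem}.png",
                "text": out / "text" / f"{stem}.csv",
            }
            flir_io.write_raw_png(raw, outputs["raw"])
            flir_io.write_temperature_tiff(temp, outputs["temp"])
            iio.imwrite(outputs["color"], rgb)
            flir_io.write_temperature_csv(temp, outputs["text"])
            result.outputs = {k: str(v) for k, v in outputs.items()}
            result.record = rec
            used_records.append(rec)
        except Exception as exc:  # per-image failure: log and continue
            logger.error("%s: %s", path.name, exc)
            result.error = str(exc)

    params_csv = out / "parameters.csv"
    flir_io.write_parameter_table(used_records, params_csv)
    manifest.parameters_csv = str(params_csv)
    return manifest


def reprocess_from_manifest(
    parameters_csv: str | Path, folder: str | Path, out_folder: str | Path | None = None
) -> RunManifest:
    """Reproduce a previous run from its saved parameter table.

    Delegates to :func:`process_folder` in from-file mode; temperature CSVs
    are byte-identical to the original run for unchanged rows.
    """
    return process_folder(
        folder, ProcessMode(Mode.FROM_FILE, params_file=parameters_csv), out_folder
    )
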