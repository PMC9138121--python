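"""Reading radiometric JPEG files and the tool's CSV / raster formats.

Radiometric JPEGs store, besides the visible preview, a 16-bit raw sensor
frame (as an embedded PNG or TIFF) plus camera calibration, atmospheric and
user-set parameters as maker-note metadata tags.  Real camera files are read
through the ``exiftool`` utility when it is installed; fixture files written
by :mod:`irproc.fixtures` carry the same tag set in plain application
segments and are parsed natively, so the test suite needs no external
binaries.

The raw payload's byte order does not always match its container: PNG
payloads are little-endian although the PNG format is big-endian, so their
samples must be byte-swapped after decoding, while TIFF payloads decode
correctly as written.  A small set of camera models is known to invert this
rule; the exception list ships as a user-editable text file.
"""

from __future__ import annotations

import io
import json
import math
import shutil
import subprocess
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd
from PIL import Image

from .radiometry import (
    AcquisitionParams,
    AtmosphereModel,
    CalibrationConstants,
    RawFrame,
    TemperatureFrame,
)


class FlirIOError(Exception):
    """Base error for radiometric file I/O."""


class FormatError(FlirIOError):
    """File is not in the expected format."""


class MetadataIncompleteError(FlirIOError):
    """A required metadata tag is missing."""


class RawMissingError(FlirIOError):
    """The embedded raw thermal payload is absent."""


class SchemaError(FlirIOError):
    """A CSV table does not have the expected columns."""


# JPEG application segment used by fixture files.  Real cameras use
# maker-note EXIF tags instead; the fixture writer stores the same tag names
# as JSON so both paths produce identical metadata.
_APP7 = 0xE7
_META_MAGIC = b"IRMETA\x00"
_RAW_MAGIC = b"IRRAW\x00\x00"

#: EXIF tag names for the maker-note parameters, mapped to the parameter
#: table column that houses each one.
TAG_TO_COLUMN = {
    "Planck R1": "sensorG",
    "Planck O": "sensorO",
    "Planck B": "sensorB",
    "Planck F": "sensorF",
    "Planck R2": "sensorR",
    "Atmospheric Trans Alpha 1": "atmAlpha1",
    "Atmospheric Trans Alpha 2": "atmAlpha2",
    "Atmospheric Trans Beta 1": "atmBeta1",
    "Atmospheric Trans Beta 2": "atmBeta2",
    "Atmospheric Trans X": "atmX",
    "Reflected Apparent Temperature": "appReflTemp_C",
    "Atmospheric Temperature": "airTemp_C",
    "Emissivity": "objEmissivity",
    "Relative Humidity": "airRelHumidity_perc",
    "Object Distance": "objDistance_m",
    "Raw Thermal Image Type": "imageType",
    "Camera Model": "cameraModel",
}

#: Fixed, ordered column set of the per-run parameter table.
PARAMETER_COLUMNS = [
    "filename",
    "sensorG",
    "sensorO",
    "sensorB",
    "sensorF",
    "sensorR",
    "atmAlpha1",
    "atmAlpha2",
    "atmBeta1",
    "atmBeta2",
    "atmX",
    "appReflTemp_C",
    "airTemp_C",
    "objEmissivity",
    "airRelHumidity_perc",
    "objDistance_m",
    "imageType",
    "cameraModel",
]

_NUMERIC_COLUMNS = PARAMETER_COLUMNS[1:16]


def _data_file(name: str) -> Path:
    return Path(__file__).parent / "data" / name


def load_byte_order_exceptions(path: str | Path | None = None) -> list[str]:
    """Camera models whose raw payload byte order inverts the PNG/TIFF rule.

    Reads one model name per line, ignoring blanks and ``#`` comments, from
    ``path`` or from the packaged ``byte_order_exceptions.txt``.
    """
    p = Path(path) if path is not None else _data_file("byte_order_exceptions.txt")
    if not p.exists():
        return []
    models = []
    for line in p.read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            models.append(line)
    return models


# ---------------------------------------------------------------------------
# metadata containers
# ---------------------------------------------------------------------------


@dataclass
class ImageMetadata:
    """Everything extracted from one radiometric JPEG."""

    camera_model: str
    raw_image_type: str  # "PNG" or "TIFF"
    cal: CalibrationConstants
    atm: AtmosphereModel
    user: AcquisitionParams
    source_path: str
    timestamp: str | None = None


@dataclass
class ParameterRecord:
    """One parameter-table row: the full tag set for one image.

    Numeric values are kept in file units (humidity in percent); the
    ``cal`` / ``atm`` / ``acquisition`` methods convert to model units.
    """

    filename: str
    sensorG: float
    sensorO: float
    sensorB: float
    sensorF: float
    sensorR: float
    atmAlpha1: float
    atmAlpha2: float
    atmBeta1: float
    atmBeta2: float
    atmX: float
    appReflTemp_C: float
    airTemp_C: float
    objEmissivity: float
    airRelHumidity_perc: float
    objDistance_m: float
    imageType: str
    cameraModel: str
    extra: dict = field(default_factory=dict)

    def cal(self) -> CalibrationConstants:
        return CalibrationConstants(
            G=self.sensorG, O=self.sensorO, B=self.sensorB, R=self.sensorR, F=self.sensorF
        )

    def atm(self) -> AtmosphereModel:
        return AtmosphereModel(
            alpha1=self.atmAlpha1,
            alpha2=self.atmAlpha2,
            beta1=self.atmBeta1,
            beta2=self.atmBeta2,
            X=self.atmX,
        )

    def acquisition(self) -> AcquisitionParams:
        return AcquisitionParams(
            emissivity=self.objEmissivity,
            air_temp_C=self.airTemp_C,
            rel_humidity=normalize_humidity(self.airRelHumidity_perc),
            app_refl_temp_C=self.appReflTemp_C,
            distance_m=self.objDistance_m,
        )

    @classmethod
    def from_metadata(cls, meta: ImageMetadata) -> "ParameterRecord":
        return cls(
            filename=Path(meta.source_path).name,
            sensorG=meta.cal.G,
            sensorO=meta.cal.O,
            sensorB=meta.cal.B,
            sensorF=meta.cal.F,
            sensorR=meta.cal.R,
            atmAlpha1=meta.atm.alpha1,
            atmAlpha2=meta.atm.alpha2,
            atmBeta1=meta.atm.beta1,
            atmBeta2=meta.atm.beta2,
            atmX=meta.atm.X,
            appReflTemp_C=meta.user.app_refl_temp_C,
            airTemp_C=meta.user.air_temp_C,
            objEmissivity=meta.user.emissivity,
            airRelHumidity_perc=meta.user.rel_humidity * 100.0,
            objDistance_m=meta.user.distance_m,
            imageType=meta.raw_image_type,
            cameraModel=meta.camera_model,
        )


def normalize_humidity(value: float) -> float:
    """Relative humidity to a fraction: values above 1 are taken as percent."""
    return value / 100.0 if value > 1.0 else value


# ---------------------------------------------------------------------------
# JPEG segment parsing
# ---------------------------------------------------------------------------


def _iter_jpeg_segments(data: bytes) -> Iterator[tuple[int, bytes]]:
    """Yield ``(marker, payload)`` for each segment of a JPEG byte stream."""
    if len(data) < 2 or data[0:2] != b"\xff\xd8":
        raise FormatError("not a JPEG file (missing SOI marker)")
    pos = 2
    while pos + 4 <= len(data):
        if data[pos] != 0xFF:
            break
        marker = data[pos + 1]
        if marker in (0xD8, 0xD9) or 0xD0 <= marker <= 0xD7:
            pos += 2
            continue
        if marker == 0xDA:  # start of scan: entropy-coded data follows
            break
        length = int.from_bytes(data[pos + 2 : pos + 4], "big")
        payload = data[pos + 4 : pos + 2 + length]
        if len(payload) != length - 2:
            raise FormatError("truncated JPEG segment")
        yield marker, payload
        pos += 2 + length


def _collect_fixture_chunks(data: bytes) -> tuple[dict | None, bytes | None]:
    meta = None
    raw_chunks: dict[int, bytes] = {}
    n_total = None
    for marker, payload in _iter_jpeg_segments(data):
        if marker != _APP7:
            continue
        if payload.startswith(_META_MAGIC):
            meta = json.loads(payload[len(_META_MAGIC) :].decode("utf-8"))
        elif payload.startswith(_RAW_MAGIC):
            body = payload[len(_RAW_MAGIC) :]
            idx = int.from_bytes(body[0:2], "big")
            n_total = int.from_bytes(body[2:4], "big")
            raw_chunks[idx] = body[4:]
    if raw_chunks:
        if n_total is None or sorted(raw_chunks) != list(range(n_total)):
            raise FormatError("raw thermal payload is truncated (missing chunks)")
        raw = b"".join(raw_chunks[i] for i in range(n_total))
    else:
        raw = None
    return meta, raw


# ---------------------------------------------------------------------------
# metadata extraction
# ---------------------------------------------------------------------------

_REQUIRED_TAGS = [t for t in TAG_TO_COLUMN if t != "Camera Model"] + ["Camera Model"]


def _strip_units(value) -> float:
    if isinstance(value, str):
        value = value.strip().rstrip("Cm%").strip()
    try:
        return float(value)
    except (TypeError, ValueError) as exc:
        raise MetadataIncompleteError(f"unparseable tag value {value!r}") from exc


def _metadata_from_tags(tags: dict, path: str | Path) -> ImageMetadata:
    for tag in _REQUIRED_TAGS:
        if tag not in tags or tags[tag] in (None, ""):
            raise MetadataIncompleteError(f"required metadata tag missing: {tag!r}")
    num = {tag: _strip_units(tags[tag]) for tag in _REQUIRED_TAGS if tag not in
           ("Raw Thermal Image Type", "Camera Model")}
    raw_type = str(tags["Raw Thermal Image Type"]).strip().upper()
    if raw_type not in ("PNG", "TIFF"):
        raise FormatError(f"unsupported raw thermal image type {raw_type!r}")
    cal = CalibrationConstants(
        G=num["Planck R1"],
        O=num["Planck O"],
        B=num["Planck B"],
        R=num["Planck R2"],
        F=num["Planck F"],
    )
    atm = AtmosphereModel(
        alpha1=num["Atmospheric Trans Alpha 1"],
        alpha2=num["Atmospheric Trans Alpha 2"],
        beta1=num["Atmospheric Trans Beta 1"],
        beta2=num["Atmospheric Trans Beta 2"],
        X=num["Atmospheric Trans X"],
    )
    user = AcquisitionParams(
        emissivity=num["Emissivity"],
        air_temp_C=num["Atmospheric Temperature"],
        rel_humidity=normalize_humidity(num["Relative Humidity"]),
        app_refl_temp_C=num["Reflected Apparent Temperature"],
        distance_m=num["Object Distance"],
    )
    return ImageMetadata(
        camera_model=str(tags["Camera Model"]).strip(),
        raw_image_type=raw_type,
        cal=cal,
        atm=atm,
        user=user,
        source_path=str(path),
        timestamp=tags.get("Date/Time Original"),
    )


def _exiftool_tags(path: Path) -> dict | None:
    exe = shutil.which("exiftool")
    if exe is None:
        return None
    out = subprocess.run(
        [exe, "-j", str(path)], capture_output=True, text=True, check=False
    )
    if out.returncode != 0 or not out.stdout.strip():
        return None
    record = json.loads(out.stdout)[0]
    # exiftool JSON keys have no spaces; remap to the display tag names
    remap = {t.replace(" ", "").replace("/", ""): t for t in TAG_TO_COLUMN}
    remap["DateTimeOriginal"] = "Date/Time Original"
    remap["Model"] = "Camera Model"
    return {remap[k]: v for k, v in record.items() if k in remap}


def extract_metadata(path: str | Path) -> ImageMetadata:
    """Read the full Table-style tag set from a radiometric JPEG.

    Fixture files are parsed natively from their application segments; any
    other JPEG is handed to ``exiftool`` when available.  A JPEG without the
    maker-note tags raises :class:`MetadataIncompleteError`.
    """
    path = Path(path)
    data = path.read_bytes()
    meta_tags, _ = _collect_fixture_chunks(data)
    if meta_tags is None:
        meta_tags = _exiftool_tags(path)
    if meta_tags is None:
        raise MetadataIncompleteError(
            f"{path.name}: no radiometric metadata found (not a radiometric JPEG?)"
        )
    return _metadata_from_tags(meta_tags, path)


# ---------------------------------------------------------------------------
# raw payload
# ---------------------------------------------------------------------------


def resolve_byte_order(
    raw_image_type: str,
    camera_model: str,
    exceptions: Iterable[str] | None = None,
) -> str:
    """Byte order of the 16-bit raw payload: ``"little"`` or ``"big"``.

    PNG payloads are little-endian (they need a sample byte swap, since PNG
    itself stores big-endian); TIFF payloads are big-endian under the same
    convention.  Models on the exception list invert the rule.
    """
    if exceptions is None:
        exceptions = load_byte_order_exceptions()
    order = "little" if raw_image_type.upper() == "PNG" else "big"
    if camera_model in set(exceptions):
        order = "big" if order == "little" else "little"
    return order


def _decode_payload(payload: bytes) -> np.ndarray:
    try:
        with Image.open(io.BytesIO(payload)) as im:
            arr = np.asarray(im)
    except Exception as exc:
        raise FormatError(f"cannot decode embedded raw payload: {exc}") from exc
    if arr.ndim != 2:
        raise FormatError(f"embedded raw payload is not single-channel (shape {arr.shape})")
    if arr.dtype.kind not in ("u", "i") or arr.dtype.itemsize not in (2, 4):
        raise FormatError(f"embedded raw payload is not 16-bit (dtype {arr.dtype})")
    return arr.astype(np.uint16)


def extract_raw_frame(path: str | Path, byte_order: str = "little") -> RawFrame:
    """Extract the embedded 16-bit raw frame, applying the resolved byte order.

    Decoded sample values are byte-swapped when the payload order is
    ``"little"`` (the decoders honour the container's big-endian convention,
    so little-endian payloads come out swapped).
    """
    path = Path(path)
    _, raw = _collect_fixture_chunks(path.read_bytes())
    if raw is None:
        raise RawMissingError(f"{path.name}: no embedded raw thermal payload")
    arr = _decode_payload(raw)
    if byte_order == "little":
        arr = arr.byteswap()
    return RawFrame(dn=arr)


# ---------------------------------------------------------------------------
# parameter tables
# ---------------------------------------------------------------------------


def write_parameter_table(records: Iterable[ParameterRecord], path: str | Path) -> None:
    """Write one row per image with the fixed, ordered column set."""
    rows = []
    extra_cols: list[str] = []
    for rec in records:
        row = {c: getattr(rec, c) for c in PARAMETER_COLUMNS}
        for k, v in rec.extra.items():
            row[k] = v
            if k not in extra_cols:
                extra_cols.append(k)
        rows.append(row)
    df = pd.DataFrame(rows, columns=PARAMETER_COLUMNS + extra_cols)
    df.to_csv(path, index=False)


def read_parameter_table(path: str | Path) -> list[ParameterRecord]:
    """Read a parameter table; unknown columns are preserved in ``extra``."""
    try:
        df = pd.read_csv(path, dtype=str)
    except Exception as exc:
        raise FormatError(f"cannot read parameter table {path}: {exc}") from exc
    missing = [c for c in PARAMETER_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"parameter table missing column(s): {', '.join(missing)}")
    records = []
    extra_cols = [c for c in df.columns if c not in PARAMETER_COLUMNS]
    for i, row in df.iterrows():
        values = {}
        for col in _NUMERIC_COLUMNS:
            try:
                values[col] = float(row[col])
            except (TypeError, ValueError) as exc:
                raise FormatError(
                    f"row {i + 1} ({row['filename']!r}): column {col!r} is not numeric: "
                    f"{row[col]!r}"
                ) from exc
        records.append(
            ParameterRecord(
                filename=row["filename"],
                imageType=row["imageType"],
                cameraModel=row["cameraModel"],
                extra={c: row[c] for c in extra_cols},
                **values,
            )
        )
    return records


# ---------------------------------------------------------------------------
# temperature CSV rasters
# ---------------------------------------------------------------------------

#: Decimal places used when writing temperature CSVs.  Two decimals exceed
#: the radiometric resolution of consumer cameras and keep outputs
#: byte-reproducible across platforms.
TEMPERATURE_CSV_DECIMALS = 2


def write_temperature_csv(frame: TemperatureFrame, path: str | Path) -> None:
    """Write the temperature grid as comma-separated text, one image row per
    line, undefined pixels as ``NaN``."""
    fmt = f"{{:.{TEMPERATURE_CSV_DECIMALS}f}}"
    with open(path, "w", newline="\n") as fh:
        for row in frame.temp_C:
            fh.write(",".join("NaN" if not np.isfinite(v) else fmt.format(v) for v in row))
            fh.write("\n")


def read_temperature_csv(path: str | Path) -> TemperatureFrame:
    rows: list[list[float]] = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        try:
            rows.append([float(tok) for tok in line.split(",")])
        except ValueError as exc:
            raise FormatError(f"{path}: line {ln} is not numeric") from exc
    if not rows:
        raise FormatError(f"{path}: empty temperature CSV")
    widths = {len(r) for r in rows}
    if len(widths) != 1:
        raise FormatError(f"{path}: ragged rows (widths {sorted(widths)})")
    return TemperatureFrame(temp_C=np.array(rows, dtype=np.float64))


# ---------------------------------------------------------------------------
# raster outputs
# ---------------------------------------------------------------------------


def write_raw_png(raw: RawFrame, path: str | Path) -> None:
    """Write the raw DN grid as a 16-bit grayscale PNG (native sample values)."""
    dn = raw.dn
    if not raw.is_quantized:
        dn = np.clip(np.rint(dn), 0, 65535).astype(np.uint16)
    Image.fromarray(dn).save(path, format="PNG")


def write_temperature_tiff(frame: TemperatureFrame, path: str | Path) -> None:
    """Write the temperature grid as a 32-bit float TIFF in degrees C."""
    import tifffile

    tifffile.imwrite(path, frame.temp_C.astype(np.float32))


def read_temperature_tiff(path: str | Path) -> TemperatureFrame:
    import tifffile

    return TemperatureFrame(temp_C=tifffile.imread(path).astype(np.float64))
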