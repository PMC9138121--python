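"""Synthetic thermal scenes: forward radiometric model and camera-file writer.

A :class:`SceneSpec` describes a true temperature field (background plus
rectangle/disk objects, each with its own temperature and emissivity),
the acquisition conditions, and the camera constants.  The forward model
composes the raw sensor signal exactly as the conversion chain assumes —

    S = tau * S_obj + tau * S_refl + S_atm

with optional Gaussian DN noise and 16-bit quantization — and the packager
writes the result either as a sidecar pair (raw raster + one-row parameter
CSV) or as a self-contained radiometric JPEG with embedded payload and
metadata tags, readable as if it came from a camera.  Because the forward
model mirrors the inversion term for term, noiseless unquantized scenes
round-trip to machine precision, which is the backbone of the test suite.

The default camera constants and atmosphere coefficients are representative
magnitudes for consumer long-wave cameras, used only as test fixtures.
"""

from __future__ import annotations

import io
import json
import struct
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from PIL import Image

from . import flir_io
from .flir_io import ParameterRecord, TAG_TO_COLUMN
from .radiometry import (
    AcquisitionParams,
    AtmosphereModel,
    CalibrationConstants,
    RawFrame,
    TemperatureFrame,
    celsius_to_kelvin,
    component_signal,
    derive_atmosphere,
)

DEFAULT_CAL = CalibrationConstants(G=21106.77, O=7261.0, B=1501.0, R=0.012545, F=1.0)
DEFAULT_ATM = AtmosphereModel(
    alpha1=0.006569, alpha2=0.01262, beta1=-0.002276, beta2=-0.00667, X=1.9
)
DEFAULT_PARAMS = AcquisitionParams(
    emissivity=0.95, air_temp_C=20.0, rel_humidity=0.50, app_refl_temp_C=20.0, distance_m=1.0
)


class FixtureError(ValueError):
    pass


@dataclass(frozen=True)
class SceneObject:
    """One painted object: axis-aligned rectangle or disk.

    Rectangles are ``(x, y, w, h)``; disks are centred at ``(x, y)`` with
    radius ``w`` (``h`` ignored).  Coordinates are pixels and must lie
    inside the canvas.
    """

    shape: str  # "rectangle" | "disk"
    x: int
    y: int
    w: int
    h: int
    temperature_C: float
    emissivity: float = 0.95


@dataclass
class SceneSpec:
    width: int = 64
    height: int = 48
    background_C: float = 20.0
    background_emissivity: float = 0.95
    objects: list[SceneObject] = field(default_factory=list)
    params: AcquisitionParams = DEFAULT_PARAMS
    cal: CalibrationConstants = DEFAULT_CAL
    atm: AtmosphereModel = DEFAULT_ATM
    noise_sd_dn: float = 0.0
    quantize: bool = True
    seed: int = 0
    camera_model: str = "SyntheticCam LW-64"

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise FixtureError("canvas dimensions must be positive")
        if self.noise_sd_dn < 0:
            raise FixtureError("noise sd must be >= 0")

    @classmethod
    def from_json(cls, path: str | Path) -> "SceneSpec":
        d = json.loads(Path(path).read_text())
        d["objects"] = [SceneObject(**o) for o in d.get("objects", [])]
        for key, typ in (("params", AcquisitionParams), ("cal", CalibrationConstants),
                         ("atm", AtmosphereModel)):
            if key in d:
                d[key] = typ(**d[key])
        return cls(**d)

    def to_json(self, path: str | Path) -> None:
        d = asdict(self)
        Path(path).write_text(json.dumps(d, indent=2, sort_keys=True))


# ---------------------------------------------------------------------------
# scene generation
# ---------------------------------------------------------------------------


def generate_scene(spec: SceneSpec) -> tuple[TemperatureFrame, np.ndarray]:
    """Paint the true temperature field and the per-pixel emissivity map.

    Objects are painted over the background in list order (later objects
    overwrite earlier ones).  Deterministic: contains no randomness.
    """
    temp = np.full((spec.height, spec.width), spec.background_C, dtype=np.float64)
    emis = np.full((spec.height, spec.width), spec.background_emissivity, dtype=np.float64)
    yy, xx = np.mgrid[0 : spec.height, 0 : spec.width]
    for obj in spec.objects:
        if obj.shape == "rectangle":
            if obj.x < 0 or obj.y < 0 or obj.x + obj.w > spec.width or obj.y + obj.h > spec.height:
                raise FixtureError(f"rectangle {obj} outside the canvas")
            sel = (xx >= obj.x) & (xx < obj.x + obj.w) & (yy >= obj.y) & (yy < obj.y + obj.h)
        elif obj.shape == "disk":
            if (
                obj.x - obj.w < 0
                or obj.y - obj.w < 0
                or obj.x + obj.w >= spec.width
                or obj.y + obj.w >= spec.height
            ):
                raise FixtureError(f"disk {obj} outside the canvas")
            sel = (xx - obj.x) ** 2 + (yy - obj.y) ** 2 <= obj.w**2
        else:
            raise FixtureError(f"unknown object shape {obj.shape!r}")
        temp[sel] = obj.temperature_C
        emis[sel] = obj.emissivity
    return TemperatureFrame(temp_C=temp), emis


# ---------------------------------------------------------------------------
# forward signal model
# ---------------------------------------------------------------------------


def forward_signal(
    truth: TemperatureFrame, emissivity_map: np.ndarray, spec: SceneSpec
) -> RawFrame:
    """Compose the raw sensor signal from a true temperature field.

    Per pixel: the object signal at the pixel's true temperature and
    emissivity, plus the reflected and atmosphere signals, mixed by the
    transmissivity.  Gaussian DN noise (sd ``spec.noise_sd_dn``, seeded) is
    added before optional rounding to unsigned 16 bits; values clipped by
    quantization are counted and warned about.
    """
    emis = np.asarray(emissivity_map, dtype=np.float64)
    if emis.shape != truth.temp_C.shape:
        raise FixtureError("emissivity map does not match the temperature field")
    der = derive_atmosphere(spec.params, spec.cal, spec.atm)
    tau = der.tau
    B, F, G, R, O = spec.cal.B, spec.cal.F, spec.cal.G, spec.cal.R, spec.cal.O
    T_K = truth.temp_C + 273.15
    s_obj = G * emis / (R * (np.exp(B / T_K) - F)) + O
    # reflected signal depends on the pixel's emissivity; recompute the
    # radiance term once and scale by (1 - eps) per pixel
    refl_radiance = component_signal(
        celsius_to_kelvin(spec.params.app_refl_temp_C), 1.0, spec.cal, include_offset=False
    )
    s_refl = (1.0 - emis) * refl_radiance + O
    s = tau * s_obj + tau * s_refl + der.S_atm
    if spec.noise_sd_dn > 0:
        rng = np.random.default_rng(spec.seed)
        s = s + rng.normal(0.0, spec.noise_sd_dn, size=s.shape)
    n_clip = int(np.count_nonzero((s < 0) | (s > 65535)))
    if n_clip:
        import logging

        logging.getLogger(__name__).warning(
            "%d pixel(s) outside the 16-bit range were clipped", n_clip
        )
    s = np.clip(s, 0.0, 65535.0)
    if spec.quantize:
        return RawFrame(dn=np.rint(s).astype(np.uint16))
    return RawFrame(dn=s)


def render_scene(spec: SceneSpec) -> RawFrame:
    """Convenience: generate the scene and run the forward model."""
    truth, emis = generate_scene(spec)
    return forward_signal(truth, emis, spec)


# ---------------------------------------------------------------------------
# packaging
# ---------------------------------------------------------------------------


def _parameter_record(spec: SceneSpec, filename: str) -> ParameterRecord:
    return ParameterRecord(
        filename=filename,
        sensorG=spec.cal.G,
        sensorO=spec.cal.O,
        sensorB=spec.cal.B,
        sensorF=spec.cal.F,
        sensorR=spec.cal.R,
        atmAlpha1=spec.atm.alpha1,
        atmAlpha2=spec.atm.alpha2,
        atmBeta1=spec.atm.beta1,
        atmBeta2=spec.atm.beta2,
        atmX=spec.atm.X,
        appReflTemp_C=spec.params.app_refl_temp_C,
        airTemp_C=spec.params.air_temp_C,
        objEmissivity=spec.params.emissivity,
        airRelHumidity_perc=spec.params.rel_humidity * 100.0,
        objDistance_m=spec.params.distance_m,
        imageType="PNG",
        cameraModel=spec.camera_model,
    )


def _encode_payload(dn: np.ndarray, raw_type: str, byte_order: str) -> bytes:
    """Encode the DN grid as an embedded PNG/TIFF with the stated sample order.

    Decoders return true values for big-endian-conforming payloads, so a
    little-endian payload is emulated by storing byte-swapped samples.
    """
    store = dn.byteswap() if byte_order == "little" else dn
    buf = io.BytesIO()
    if raw_type == "PNG":
        Image.fromarray(store).save(buf, format="PNG")
    else:
        import tifffile

        tifffile.imwrite(buf, store, byteorder=">")
    return buf.getvalue()


def write_fixture_jpeg(
    raw: RawFrame,
    spec: SceneSpec,
    path: str | Path,
    raw_type: str = "PNG",
) -> Path:
    """Write a self-contained radiometric JPEG fixture.

    The visible part is an 8-bit preview of the raw frame; the 16-bit
    payload and the full tag set ride in application segments that
    :func:`irproc.flir_io.extract_metadata` and
    :func:`irproc.flir_io.extract_raw_frame` read back exactly.
    """
    path = Path(path)
    if not raw.is_quantized:
        raise FixtureError("JPEG packaging requires a quantized (uint16) raw frame")
    dn = raw.dn
    order = flir_io.resolve_byte_order(raw_type, spec.camera_model)
    payload = _encode_payload(dn, raw_type, order)

    tags = {
        "Planck R1": spec.cal.G,
        "Planck O": spec.cal.O,
        "Planck B": spec.cal.B,
        "Planck F": spec.cal.F,
        "Planck R2": spec.cal.R,
        "Atmospheric Trans Alpha 1": spec.atm.alpha1,
        "Atmospheric Trans Alpha 2": spec.atm.alpha2,
        "Atmospheric Trans Beta 1": spec.atm.beta1,
        "Atmospheric Trans Beta 2": spec.atm.beta2,
        "Atmospheric Trans X": spec.atm.X,
        "Reflected Apparent Temperature": spec.params.app_refl_temp_C,
        "Atmospheric Temperature": spec.params.air_temp_C,
        "Emissivity": spec.params.emissivity,
        "Relative Humidity": spec.params.rel_humidity * 100.0,
        "Object Distance": spec.params.distance_m,
        "Raw Thermal Image Type": raw_type,
        "Camera Model": spec.camera_model,
    }
    assert set(tags) == set(TAG_TO_COLUMN)

    # visible preview: raw frame stretched to 8 bits
    lo, hi = int(dn.min()), int(dn.max())
    preview = ((dn.astype(np.float64) - lo) / max(hi - lo, 1) * 255).astype(np.uint8)
    base = io.BytesIO()
    Image.fromarray(preview, mode="L").save(base, format="JPEG")
    base = base.getvalue()

    def app7(payload_bytes: bytes) -> bytes:
        length = len(payload_bytes) + 2
        return b"\xff" + bytes([flir_io._APP7]) + struct.pack(">H", length) + payload_bytes

    segments = [app7(flir_io._META_MAGIC + json.dumps(tags).encode("utf-8"))]
    chunk_size = 60000
    chunks = [payload[i : i + chunk_size] for i in range(0, len(payload), chunk_size)]
    for i, c in enumerate(chunks):
        segments.append(
            app7(flir_io._RAW_MAGIC + struct.pack(">HH", i, len(chunks)) + c)
        )
    out = base[:2] + b"".join(segments) + base[2:]
    path.write_bytes(out)
    return path


def write_sidecar_pair(raw: RawFrame, spec: SceneSpec, folder: str | Path, stem: str) -> tuple:
    """Write a sidecar fixture: raw raster plus one-row parameter CSV.

    Quantized frames become 16-bit PNGs following the little-endian payload
    rule (so the reader's byte-swap path is exercised); unquantized frames
    become 32-bit float TIFFs holding exact DN values.
    """
    folder = Path(folder)
    folder.mkdir(parents=True, exist_ok=True)
    rec = _parameter_record(spec, "")
    if raw.is_quantized:
        raw_path = folder / f"{stem}.raw.png"
        order = flir_io.resolve_byte_order("PNG", spec.camera_model)
        raw_path.write_bytes(_encode_payload(raw.dn, "PNG", order))
        rec.imageType = "PNG"
    else:
        import tifffile

        raw_path = folder / f"{stem}.raw.tif"
        tifffile.imwrite(raw_path, raw.dn.astype(np.float64))
        rec.imageType = "TIFF"
    rec.filename = raw_path.name
    csv_path = folder / f"{stem}.params.csv"
    flir_io.write_parameter_table([rec], csv_path)
    return raw_path, csv_path


def package_fixture(
    raw: RawFrame,
    spec: SceneSpec,
    folder: str | Path,
    stem: str,
    kind: str = "jpeg",
    raw_type: str = "PNG",
):
    """Package a raw frame as ``kind`` = ``"jpeg"`` or ``"sidecar"``."""
    folder = Path(folder)
    folder.mkdir(parents=True, exist_ok=True)
    if kind == "jpeg":
        return write_fixture_jpeg(raw, spec, folder / f"{stem}.jpg", raw_type=raw_type)
    if kind == "sidecar":
        return write_sidecar_pair(raw, spec, folder, stem)
    raise FixtureError(f"unknown packaging kind {kind!r}")
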