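"""Radiometric core: conversion between raw sensor signal and object temperature.

A microbolometer thermal camera reports, for every pixel, a digital number
(DN) that is linear in the radiance reaching the sensor.  The radiance is a
mixture of three sources: emission from the target object (attenuated by the
atmosphere), radiation from the surroundings reflected off the object (also
attenuated), and emission from the air column itself::

    S = tau * S_obj + tau * S_refl + S_atm

where ``tau`` is the atmospheric transmissivity over the object distance.
Each component signal follows the camera's calibration model

    S_x = G * w / (R * (exp(B / T) - F)) + O

with per-camera constants ``G, O, B, R, F`` and a source-specific weight
``w`` (object emissivity, air emissivity ``1 - tau``, or object reflectivity
``1 - emissivity``).  Solving the mixture for ``S_obj`` and inverting the
calibration model yields the object temperature.

All public temperatures are in degrees Celsius; kelvin is used internally.
Pixels whose object signal falls outside the invertible domain of the
calibration model (``S_obj <= O``) are undefined and carried as NaN.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

KELVIN_OFFSET = 273.15

#: Lower clamp applied to transmissivity to avoid division blow-ups for
#: absurd distances; clamping is logged.
TAU_FLOOR = 1e-6


class RadiometryError(ValueError):
    """Invalid parameter or out-of-domain value in the radiometric chain."""


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CalibrationConstants:
    """Per-camera sensor calibration constants.

    Parameters
    ----------
    G : float
        Sensor gain, DN per radiance unit. Positive.
    O : float
        Sensor offset in DN (typically a large negative number).
    B : float
        Exponential calibration constant, kelvin. Positive.
    R : float
        Radiance scaling constant. Positive.
    F : float
        Calibration constant generalising the literal 1 in the
        ``exp(B/T) - 1`` denominator; cameras store it explicitly and it is
        almost always exactly 1.
    """

    G: float
    O: float
    B: float
    R: float
    F: float = 1.0

    def __post_init__(self) -> None:
        for name in ("G", "R", "B", "F"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise RadiometryError(f"calibration constant {name} must be finite and > 0, got {v!r}")
        if not math.isfinite(self.O):
            raise RadiometryError(f"calibration constant O must be finite, got {self.O!r}")


@dataclass(frozen=True)
class AtmosphereModel:
    """Coefficients of the two-term exponential transmissivity model.

    ``alpha1/beta1`` and ``alpha2/beta2`` are the attenuation coefficients of
    the two exponential terms; ``X`` is the mixing weight between them.
    """

    alpha1: float
    alpha2: float
    beta1: float
    beta2: float
    X: float

    def __post_init__(self) -> None:
        for name in ("alpha1", "alpha2", "beta1", "beta2", "X"):
            if not math.isfinite(getattr(self, name)):
                raise RadiometryError(f"atmosphere coefficient {name} must be finite")
        if not (0.0 <= self.X <= 2.0):
            raise RadiometryError(f"atmosphere mixing weight X={self.X!r} outside sanity bound [0, 2]")


@dataclass(frozen=True)
class AcquisitionParams:
    """User-set per-image acquisition parameters.

    Parameters
    ----------
    emissivity : float
        Object emissivity, fraction in (0, 1].
    air_temp_C : float
        Air temperature in degrees C.
    rel_humidity : float
        Relative humidity as a fraction in [0, 1].  Values supplied in
        percent must be divided by 100 before construction (file readers in
        :mod:`irproc.flir_io` do this automatically).
    app_refl_temp_C : float
        Apparent reflected temperature in degrees C, measured off a
        near-perfect reflector such as crumpled aluminium foil.
    distance_m : float
        Object distance from the camera, metres.
    """

    emissivity: float
    air_temp_C: float
    rel_humidity: float
    app_refl_temp_C: float
    distance_m: float

    def __post_init__(self) -> None:
        if not (0.0 < self.emissivity <= 1.0):
            raise RadiometryError(f"emissivity must be in (0, 1], got {self.emissivity!r}")
        if not (0.0 <= self.rel_humidity <= 1.0):
            raise RadiometryError(
                f"relative humidity must be a fraction in [0, 1], got {self.rel_humidity!r}"
            )
        if self.distance_m < 0:
            raise RadiometryError(f"object distance must be >= 0, got {self.distance_m!r}")
        for name in ("air_temp_C", "app_refl_temp_C"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > -KELVIN_OFFSET):
                raise RadiometryError(f"{name}={v!r} is at or below absolute zero")


@dataclass(frozen=True)
class DerivedAtmosphere:
    """Per-frame quantities derived once from the acquisition parameters:
    air water content ``H``, transmissivity ``tau`` and the equivalent
    atmosphere / reflected signals in DN."""

    H: float
    tau: float
    S_atm: float
    S_refl: float


# ---------------------------------------------------------------------------
# raster containers
# ---------------------------------------------------------------------------


@dataclass
class RawFrame:
    """2-D raster of raw sensor digital numbers.

    ``dn`` is normally an unsigned 16-bit array as stored by the camera; a
    floating-point array within [0, 65535] is accepted for unquantized
    synthetic frames.
    """

    dn: np.ndarray

    def __post_init__(self) -> None:
        self.dn = np.asarray(self.dn)
        if self.dn.ndim != 2 or self.dn.size == 0:
            raise RadiometryError("raw frame must be a non-empty 2-D array")
        if np.issubdtype(self.dn.dtype, np.floating):
            if not np.all(np.isfinite(self.dn)):
                raise RadiometryError("raw frame contains non-finite values")
            if self.dn.min() < 0 or self.dn.max() > 65535:
                raise RadiometryError("raw frame values outside [0, 65535]")
        else:
            self.dn = self.dn.astype(np.uint16)

    @property
    def width(self) -> int:
        return self.dn.shape[1]

    @property
    def height(self) -> int:
        return self.dn.shape[0]

    @property
    def is_quantized(self) -> bool:
        return self.dn.dtype == np.uint16


@dataclass
class TemperatureFrame:
    """2-D raster of object temperatures in degrees C; undefined pixels NaN."""

    temp_C: np.ndarray

    def __post_init__(self) -> None:
        self.temp_C = np.asarray(self.temp_C, dtype=np.float64)
        if self.temp_C.ndim != 2 or self.temp_C.size == 0:
            raise RadiometryError("temperature frame must be a non-empty 2-D array")
        defined = self.temp_C[np.isfinite(self.temp_C)]
        if defined.size and defined.min() <= -KELVIN_OFFSET:
            raise RadiometryError("temperature frame contains values at or below absolute zero")

    @property
    def width(self) -> int:
        return self.temp_C.shape[1]

    @property
    def height(self) -> int:
        return self.temp_C.shape[0]

    def defined_mask(self) -> np.ndarray:
        return np.isfinite(self.temp_C)


# ---------------------------------------------------------------------------
# scalar operations
# ---------------------------------------------------------------------------


def celsius_to_kelvin(t_C: float) -> float:
    """Convert Celsius to kelvin, rejecting values at or below absolute zero."""
    if not (t_C > -KELVIN_OFFSET):
        raise RadiometryError(f"temperature {t_C!r} degC is at or below absolute zero")
    return t_C + KELVIN_OFFSET


def air_water_content(t_C: float, rel_humidity: float) -> float:
    """Air water content ``H`` from air temperature (degC) and relative humidity.

    Empirical cubic-exponential in ``t`` scaled by the humidity fraction::

        H = RH * exp(1.5587 + 6.939e-2 t - 2.7816e-4 t^2 + 6.8455e-7 t^3)
    """
    if not (0.0 <= rel_humidity <= 1.0):
        raise RadiometryError(f"relative humidity must be in [0, 1], got {rel_humidity!r}")
    if not math.isfinite(t_C):
        raise RadiometryError("air temperature must be finite")
    return rel_humidity * math.exp(
        1.5587 + 6.939e-2 * t_C - 2.7816e-4 * t_C**2 + 6.8455e-7 * t_C**3
    )


def atmospheric_transmissivity(distance_m: float, H: float, atm: AtmosphereModel) -> float:
    """Atmospheric transmissivity over ``distance_m`` metres of air with
    water content ``H``.

    Two-term exponential attenuation model::

        tau = X exp(-sqrt(d) (a1 + b1 sqrt(H))) + (1-X) exp(-sqrt(d) (a2 + b2 sqrt(H)))

    The result is clamped to [1e-6, 1]; clamping is logged since it only
    occurs for physically implausible inputs.
    """
    if distance_m < 0:
        raise RadiometryError(f"distance must be >= 0, got {distance_m!r}")
    if H < 0:
        raise RadiometryError(f"water content must be >= 0, got {H!r}")
    sd = math.sqrt(distance_m)
    sh = math.sqrt(H)
    tau = atm.X * math.exp(-sd * (atm.alpha1 + atm.beta1 * sh)) + (1.0 - atm.X) * math.exp(
        -sd * (atm.alpha2 + atm.beta2 * sh)
    )
    if tau > 1.0 or tau < TAU_FLOOR:
        clamped = min(max(tau, TAU_FLOOR), 1.0)
        logger.warning("transmissivity %.6g outside (0, 1]; clamped to %.6g", tau, clamped)
        tau = clamped
    return tau


def component_signal(
    T_K: float,
    weight: float,
    cal: CalibrationConstants,
    include_offset: bool = True,
) -> float:
    """Equivalent DN signal of one radiation source at temperature ``T_K``.

    ``S = G * weight / (R * (exp(B/T) - F)) + O``.  With ``weight`` set to
    the object emissivity this is the object signal; with ``1 - tau`` at air
    temperature, the atmosphere signal; with ``1 - emissivity`` at the
    apparent reflected temperature, the reflected signal.

    ``include_offset=False`` drops the ``+ O`` term, for reconciling against
    third-party formulations that add the sensor offset only once.
    """
    if not (T_K > 0):
        raise RadiometryError(f"absolute temperature must be > 0 K, got {T_K!r}")
    if not (0.0 <= weight <= 1.0):
        raise RadiometryError(f"component weight must be in [0, 1], got {weight!r}")
    denom = math.exp(cal.B / T_K) - cal.F
    if denom <= 0:
        raise RadiometryError(
            f"exp(B/T) <= F at T={T_K!r} K: calibration model not invertible here"
        )
    s = cal.G * weight / (cal.R * denom)
    return s + cal.O if include_offset else s


def object_signal(S, tau: float, S_refl: float, S_atm: float):
    """Object-emitted signal recovered from the total signal.

    Inverts the three-source mixture: ``S_obj = S/tau - S_refl - S_atm/tau``.
    ``S`` may be a scalar or an array.
    """
    if not (tau > 0):
        raise RadiometryError(f"transmissivity must be > 0, got {tau!r}")
    return np.asarray(S, dtype=np.float64) / tau - S_refl - S_atm / tau


def object_temperature(S_obj: float, emissivity: float, cal: CalibrationConstants) -> float:
    """Object temperature (kelvin) from the object signal.

    Exact inverse of :func:`component_signal` at the same emissivity::

        T = B / ln(G * eps / (R * (S_obj - O)) + F)

    No floor or clamp is applied to the result: arbitrarily cold scenes
    invert to their true temperature as long as ``S_obj > O``.
    """
    if not (0.0 < emissivity <= 1.0):
        raise RadiometryError(f"emissivity must be in (0, 1], got {emissivity!r}")
    if not (S_obj > cal.O):
        raise RadiometryError(
            f"object signal {S_obj!r} DN is not above the sensor offset {cal.O!r}; "
            "temperature undefined"
        )
    arg = cal.G * emissivity / (cal.R * (S_obj - cal.O)) + cal.F
    if not (arg > 1.0):
        # only reachable with F < 1 and a very large signal
        raise RadiometryError(f"log argument {arg!r} <= 1: signal outside the invertible range")
    return cal.B / math.log(arg)


# ---------------------------------------------------------------------------
# frame pipeline
# ---------------------------------------------------------------------------


def derive_atmosphere(
    params: AcquisitionParams,
    cal: CalibrationConstants,
    atm: AtmosphereModel,
    include_offset: bool = True,
) -> DerivedAtmosphere:
    """Compute the per-frame derived quantities H, tau, S_atm and S_refl."""
    H = air_water_content(params.air_temp_C, params.rel_humidity)
    tau = atmospheric_transmissivity(params.distance_m, H, atm)
    S_atm = component_signal(
        celsius_to_kelvin(params.air_temp_C), 1.0 - tau, cal, include_offset
    )
    S_refl = component_signal(
        celsius_to_kelvin(params.app_refl_temp_C), 1.0 - params.emissivity, cal, include_offset
    )
    return DerivedAtmosphere(H=H, tau=tau, S_atm=S_atm, S_refl=S_refl)


def frame_to_temperature(
    raw: RawFrame,
    params: AcquisitionParams,
    cal: CalibrationConstants,
    atm: AtmosphereModel,
    include_offset: bool = True,
) -> TemperatureFrame:
    """Convert a raw DN frame to object temperatures in degrees C.

    The derived atmosphere quantities are computed once per frame; each pixel
    is then inverted through the mixture model and the calibration model.
    Pixels whose object signal does not exceed the sensor offset are
    undefined and set to NaN (their count is logged); no other pixel ever
    raises.
    """
    der = derive_atmosphere(params, cal, atm, include_offset)
    s_obj = object_signal(raw.dn, der.tau, der.S_refl, der.S_atm)
    with np.errstate(invalid="ignore", divide="ignore"):
        arg = cal.G * params.emissivity / (cal.R * (s_obj - cal.O)) + cal.F
        valid = (s_obj > cal.O) & (arg > 1.0)
        n_bad = int(np.count_nonzero(~valid))
        if n_bad:
            logger.warning("%d pixel(s) outside the invertible signal range; set to NaN", n_bad)
        temp = np.full(s_obj.shape, np.nan)
        temp[valid] = cal.B / np.log(arg[valid]) - KELVIN_OFFSET
    return TemperatureFrame(temp_C=temp)
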