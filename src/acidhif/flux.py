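"""Plate-reader metabolic profiling: probe calibration and cumulative fluxes.

Cells in a weakly buffered, oil-covered well acidify the medium as they
ferment and deplete dissolved O2 as they respire.  A ratiometric pH probe
(HPTS-like) and a collisionally quenched O2 probe (RuBPY-like) report both
signals over time.  This module inverts the probe calibrations and converts
the resulting pH(t) and pO2(t) into cumulative acid production and O2
consumption:

    H+(t)  = beta * V * (pH(0) - pH(t))
    O2(t)  = alpha * V * (pO2(0) - pO2(t)) + ingress correction

where beta is the buffering capacity (mol L^-1 pH^-1) and alpha the O2
solubility (mol L^-1 per pressure unit).  Calibration constants are assay
configuration, supplied by the user.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class CalibrationError(ValueError):
    pass


class ProbeSaturationWarning(UserWarning):
    """Raw probe signal outside the calibrated range; value was clipped."""


@dataclass(frozen=True)
class PhProbeCalibration:
    """Ratiometric pH probe: ratio = r_min + (r_max - r_min) / (1 + 10**(pka - pH))."""

    pka: float = 7.3
    ratio_min: float = 0.2
    ratio_max: float = 5.0

    def __post_init__(self):
        if not self.ratio_min < self.ratio_max:
            raise CalibrationError("ratio_min must be < ratio_max")


@dataclass(frozen=True)
class O2ProbeCalibration:
    """Stern-Volmer quenching: intensity = I0 / (1 + k_sv * pO2)."""

    intensity_at_zero_o2: float = 1000.0
    stern_volmer_constant: float = 0.004  # per pressure unit (e.g. mmHg^-1)

    def __post_init__(self):
        if self.stern_volmer_constant <= 0:
            raise CalibrationError("stern_volmer_constant must be > 0")
        if self.intensity_at_zero_o2 <= 0:
            raise CalibrationError("intensity_at_zero_o2 must be > 0")


@dataclass(frozen=True)
class CalibrationParams:
    """Full assay calibration: probes plus medium physical constants."""

    ph_probe: PhProbeCalibration = field(default_factory=PhProbeCalibration)
    o2_probe: O2ProbeCalibration = field(default_factory=O2ProbeCalibration)
    buffering_capacity: float = 2e-3  # mol L^-1 pH^-1
    o2_solubility: float = 1.3e-6  # mol L^-1 mmHg^-1
    volume: float = 200e-6  # L
    oil_ingress_rate: float = 0.0  # h^-1, first-order toward atmosphere
    atmospheric_po2: float = 160.0  # mmHg

    def __post_init__(self):
        if self.buffering_capacity <= 0:
            raise CalibrationError("buffering_capacity must be > 0")
        if self.o2_solubility <= 0 or self.volume <= 0:
            raise CalibrationError("o2_solubility and volume must be > 0")


@dataclass
class FluorTimeCourse:
    """Raw probe signals versus time for one well."""

    time: np.ndarray  # hours, strictly increasing
    ph_probe_ratio: np.ndarray
    o2_probe_intensity: np.ndarray
    live_cell_signal: float | np.ndarray | None = None
    well_id: str = ""
    condition: str = ""

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.ph_probe_ratio = np.asarray(self.ph_probe_ratio, dtype=float)
        self.o2_probe_intensity = np.asarray(self.o2_probe_intensity, dtype=float)
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")


@dataclass
class FluxTimeCourse:
    """Calibrated pH / pO2 and cumulative fluxes for one well."""

    time: np.ndarray
    ph: np.ndarray
    po2: np.ndarray
    cumulative_acid: np.ndarray  # mol (or mol per live-cell-signal unit)
    cumulative_o2: np.ndarray
    well_id: str = ""
    condition: str = ""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_h": self.time,
                "ph": self.ph,
                "po2": self.po2,
                "cumulative_acid_mol": self.cumulative_acid,
                "cumulative_o2_mol": self.cumulative_o2,
                "well": self.well_id,
                "condition": self.condition,
            }
        )


def ph_to_ratio(ph, cal: PhProbeCalibration) -> np.ndarray:
    """Forward ratiometric model (the inverse of :func:`ratio_to_ph`)."""
    ph = np.asarray(ph, dtype=float)
    frac = 1.0 / (1.0 + 10.0 ** (cal.pka - ph))
    return cal.ratio_min + (cal.ratio_max - cal.ratio_min) * frac


def ratio_to_ph(ratio, cal: PhProbeCalibration) -> np.ndarray:
    """Invert the ratiometric calibration: pH = pKa + log10((R-Rmin)/(Rmax-R)).

    Ratios at or beyond the calibration bounds are clipped just inside the
    open interval and flagged with :class:`ProbeSaturationWarning`.
    """
    ratio = np.asarray(ratio, dtype=float)
    span = cal.ratio_max - cal.ratio_min
    eps = 1e-6 * span
    if np.any(ratio <= cal.ratio_min + eps) or np.any(ratio >= cal.ratio_max - eps):
        warnings.warn(
            "pH probe ratio outside calibrated range; clipped (probe saturation)",
            ProbeSaturationWarning,
            stacklevel=2,
        )
    r = np.clip(ratio, cal.ratio_min + eps, cal.ratio_max - eps)
    return cal.pka + np.log10((r - cal.ratio_min) / (cal.ratio_max - r))


def po2_to_intensity(po2, cal: O2ProbeCalibration) -> np.ndarray:
    po2 = np.asarray(po2, dtype=float)
    return cal.intensity_at_zero_o2 / (1.0 + cal.stern_volmer_constant * po2)


def intensity_to_po2(intensity, cal: O2ProbeCalibration) -> np.ndarray:
    """Invert Stern-Volmer quenching: pO2 = (I0/I - 1) / K_SV."""
    intensity = np.asarray(intensity, dtype=float)
    if np.any(intensity <= 0):
        raise ValueError("O2 probe intensity must be > 0")
    if np.any(intensity > cal.intensity_at_zero_o2):
        warnings.warn(
            "O2 probe intensity above I0; pO2 clipped to 0 (probe saturation)",
            ProbeSaturationWarning,
            stacklevel=2,
        )
    po2 = (cal.intensity_at_zero_o2 / intensity - 1.0) / cal.stern_volmer_constant
    return np.clip(po2, 0.0, None)


def cumulative_acid(
    ph_series: np.ndarray,
    cal: CalibrationParams,
    live_cell_signal: float | None = None,
) -> np.ndarray:
    """Cumulative H+ production from a calibrated pH series.

    H+(t) = beta * V * (pH(0) - pH(t)); optionally normalized to a per-well
    live-cell marker value.  Noise-driven negative values are retained (not
    clipped) to avoid biasing downstream slope estimates.
    """
    ph = np.asarray(ph_series, dtype=float)
    out = cal.buffering_capacity * cal.volume * (ph[0] - ph)
    if live_cell_signal is not None:
        if live_cell_signal <= 0:
            raise ValueError("live_cell_signal must be > 0")
        out = out / live_cell_signal
    return out


def cumulative_o2(po2_series: np.ndarray, cal: CalibrationParams, time: np.ndarray | None = None) -> np.ndarray:
    """Cumulative O2 consumption from a calibrated pO2 series.

    The naive depletion estimate alpha*V*(pO2(0) - pO2(t)) is corrected for
    atmospheric ingress through the oil barrier when ``oil_ingress_rate`` is
    set: consumed O2 additionally includes the integral of
    k_in * (pO2_atm - pO2) * alpha * V, accumulated by the trapezoid rule.
    """
    po2 = np.asarray(po2_series, dtype=float)
    out = cal.o2_solubility * cal.volume * (po2[0] - po2)
    if cal.oil_ingress_rate:
        if time is None:
            raise CalibrationError("time vector required for ingress correction")
        time = np.asarray(time, dtype=float)
        influx = cal.oil_ingress_rate * (cal.atmospheric_po2 - po2) * cal.o2_solubility * cal.volume
        correction = np.concatenate(
            ([0.0], np.cumsum(0.5 * (influx[1:] + influx[:-1]) * np.diff(time)))
        )
        out = out + correction
    return out


def calibrate_timecourse(
    raw: FluorTimeCourse,
    cal: CalibrationParams,
    normalize_to_live_cells: bool = False,
) -> FluxTimeCourse:
    """Full per-well pipeline: raw signals -> pH, pO2 -> cumulative fluxes."""
    ph = ratio_to_ph(raw.ph_probe_ratio, cal.ph_probe)
    po2 = intensity_to_po2(raw.o2_probe_intensity, cal.o2_probe)
    live = None
    if normalize_to_live_cells:
        if raw.live_cell_signal is None:
            raise CalibrationError("no live-cell signal on this well")
        live = float(np.atleast_1d(raw.live_cell_signal)[0])
    acid = cumulative_acid(ph, cal, live_cell_signal=live)
    o2 = cumulative_o2(po2, cal, time=raw.time)
    if live is not None:
        o2 = o2 / live
    return FluxTimeCourse(
        time=raw.time, ph=ph, po2=po2, cumulative_acid=acid, cumulative_o2=o2,
        well_id=raw.well_id, condition=raw.condition,
    )


@dataclass
class SlopeResult:
    slope_through_origin: float
    slope_free: float
    intercept_free: float
    pearson_r: float
    n: int


def lactate_slope(cumulative_h: np.ndarray, lactate: np.ndarray) -> SlopeResult:
    """Relate end-point lactate to cumulative H+ across paired wells.

    Returns the least-squares slope constrained through the origin (the
    headline 1:1 statistic) plus an unconstrained slope/intercept and the
    Pearson correlation as diagnostics.
    """
    x = np.asarray(cumulative_h, dtype=float)
    y = np.asarray(lactate, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 paired points")
    if np.allclose(x, x[0]) or np.allclose(y, y[0]):
        raise ValueError("degenerate input: zero variance")
    slope0 = float(np.dot(x, y) / np.dot(x, x))
    b, a = np.polyfit(x, y, 1)
    r = float(np.corrcoef(x, y)[0, 1])
    return SlopeResult(slope0, float(b), float(a), r, int(x.size))
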