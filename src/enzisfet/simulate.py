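"""Parametric simulator of an AChE-coated enzyme-ISFET carbaryl sensor.

The simulator is calibrated to the empirical relations a working sensor
of this type exhibits, not to device physics:

* a Nernstian pH response line (signal = ph_slope * pH + ph_intercept),
* a reference (no-carbaryl) gate-source response ``dVgs_ref`` that is
  Gaussian around a temperature-dependent mean,
* a log-linear enzyme-inhibition law, inhibition(%) =
  inhib_slope * ln(c) + inhib_intercept, clamped to [0, 100],
* the inhibited response dVgs_carbaryl = dVgs_ref * (1 - I/100),
* a vegetable-extract matrix effect that lowers inhibition by a few
  percent relative to buffer-diluted carbaryl,
* additive Gaussian measurement noise on signal and temperature.

All stochastic draws flow through a ``numpy.random.Generator`` so any
dataset is bit-reproducible from ``(SimParams, seed)``.
"""

from __future__ import annotations

import dataclasses
import io
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .exceptions import DomainError, UsageError

__all__ = [
    "SimParams",
    "MATRICES",
    "ph_response",
    "reference_signal",
    "inhibition_from_concentration",
    "carbaryl_signal",
    "generate_dataset",
    "generate_blanks",
    "write_sensor_log",
    "read_sensor_log",
    "DEFAULT_CONCENTRATIONS",
    "DEFAULT_TEMPERATURES",
]

#: valid sample matrices: plain PBS buffer or ethanolic vegetable extract
MATRICES = ("buffer", "extract")

#: the five carbaryl levels the assay is calibrated on, in molar
DEFAULT_CONCENTRATIONS = (1e-7, 1e-6, 1e-5, 1e-4, 1e-3)

#: the four solution temperatures of the measurement protocol, in Celsius
DEFAULT_TEMPERATURES = (20.0, 25.0, 30.0, 35.0)

#: CSV schema of a sensor log
LOG_COLUMNS = ["delta_vgs_mv", "temperature_c", "matrix", "concentration_m", "replicate"]


@dataclass
class SimParams:
    """All calibration constants the simulator is built from.

    Defaults reproduce the printed calibration behaviour of the real
    sensor; the two temperature coefficients and the noise SDs are
    documented stand-ins (the source experiments show the effects but
    print no numbers) and may be set to anything, including 0.

    Parameters
    ----------
    ph_slope, ph_intercept
        Nernstian pH line, mV per pH unit and mV. A slope in [45, 55]
        marks an acceptable sensor.
    ref_mean_25c, ref_sd
        Mean and SD of the reference (no-carbaryl) response at 25 C, mV.
    ref_temp_coeff
        Drift of the reference mean, mV per Celsius away from 25 C.
    inhib_slope, inhib_intercept
        Enzyme-inhibition calibration line, percent per ln(molar) and
        percent.
    inhib_temp_coeff
        Shift of inhibition with temperature, percent per Celsius.
    matrix_offset_range
        (low, high) percent by which vegetable-extract inhibition falls
        below buffer inhibition at the same concentration.
    mv_per_percent
        Signal equivalent of one percent inhibition, mV.
    signal_noise_sd, temp_noise_sd
        Additive measurement noise SDs, mV and Celsius.
    seed
        Default seed for generator-owned randomness.
    """

    ph_slope: float = 49.86
    ph_intercept: float = 418.98
    ref_mean_25c: float = 45.35
    ref_sd: float = 1.6
    ref_temp_coeff: float = 0.3
    inhib_slope: float = 6.6098
    inhib_intercept: float = 134.62
    inhib_temp_coeff: float = 0.4
    matrix_offset_range: tuple[float, float] = (2.68, 3.24)
    mv_per_percent: float = 0.45
    signal_noise_sd: float = 0.2
    temp_noise_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.matrix_offset_range
        if lo > hi:
            raise UsageError(f"matrix_offset_range low {lo} exceeds high {hi}")
        if self.ref_sd < 0 or self.signal_noise_sd < 0 or self.temp_noise_sd < 0:
            raise UsageError("noise standard deviations must be >= 0")

    @property
    def sensitivity_acceptable(self) -> bool:
        """True when the pH slope lies in the 45-55 mV/pH acceptance band."""
        return 45.0 <= self.ph_slope <= 55.0

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["matrix_offset_range"] = list(self.matrix_offset_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimParams":
        d = dict(d)
        if "matrix_offset_range" in d:
            d["matrix_offset_range"] = tuple(d["matrix_offset_range"])
        return cls(**d)

    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source: str | Path) -> "SimParams":
        if isinstance(source, Path) or (isinstance(source, str) and "\n" not in source and Path(source).exists()):
            text = Path(source).read_text()
        else:
            text = str(source)
        return cls.from_dict(yaml.safe_load(io.StringIO(text)))


def ph_response(ph: float, params: SimParams) -> float:
    """Deterministic ISFET signal (mV) at a given pH, from the pH line.

    Noise, if wanted, is the caller's business.
    """
    ph = float(ph)
    if not 0.0 <= ph <= 14.0:
        raise DomainError(f"pH {ph} outside [0, 14]")
    return params.ph_slope * ph + params.ph_intercept


def reference_signal(
    temperature,
    params: SimParams,
    rng: np.random.Generator | None = None,
):
    """Draw reference (no-carbaryl) response(s) dVgs_ref at `temperature` (mV).

    Normal around ``ref_mean_25c + ref_temp_coeff * (T - 25)`` with SD
    ``ref_sd``; with ``ref_sd == 0`` the mean is returned exactly.
    Accepts scalars or arrays and broadcasts.
    """
    t = np.asarray(temperature, dtype=float)
    if not np.all(np.isfinite(t)):
        raise DomainError("temperature must be finite")
    mean = params.ref_mean_25c + params.ref_temp_coeff * (t - 25.0)
    if params.ref_sd == 0:
        out = mean
    else:
        if rng is None:
            rng = params.rng()
        out = rng.normal(mean, params.ref_sd)
    return float(out) if np.isscalar(temperature) else out


def inhibition_from_concentration(concentration, temperature, params: SimParams):
    """Percent enzyme inhibition at carbaryl concentration `c` (molar) and T (C).

    ``inhib_slope * ln(c) + inhib_intercept + inhib_temp_coeff * (T - 25)``,
    clamped to [0, 100] after the temperature adjustment.  The line is an
    extrapolation outside the calibrated 1e-6..1e-4 M range (then clamped).
    """
    c = np.asarray(concentration, dtype=float)
    if np.any(c <= 0):
        raise DomainError("concentration must be > 0")
    t = np.asarray(temperature, dtype=float)
    raw = params.inhib_slope * np.log(c) + params.inhib_intercept
    raw = raw + params.inhib_temp_coeff * (t - 25.0)
    out = np.clip(raw, 0.0, 100.0)
    return float(out) if np.isscalar(concentration) and np.isscalar(temperature) else out


def carbaryl_signal(
    concentration,
    temperature,
    matrix: str,
    params: SimParams,
    rng: np.random.Generator | None = None,
):
    """Inhibited response dVgs_carbaryl (mV) for a carbaryl-exposed sensor.

    ``dVgs_ref(T) * (1 - I/100) + N(0, signal_noise_sd^2)`` where the
    inhibition I is reduced, for the extract matrix, by an offset drawn
    uniformly from ``matrix_offset_range``; the [0, 100] clamp is applied
    after the matrix adjustment.
    """
    if matrix not in MATRICES:
        raise UsageError(f"matrix must be one of {MATRICES}, got {matrix!r}")
    if rng is None:
        rng = params.rng()
    c = np.asarray(concentration, dtype=float)
    t = np.asarray(temperature, dtype=float)
    if np.any(c <= 0):
        raise DomainError("concentration must be > 0")
    raw = params.inhib_slope * np.log(c) + params.inhib_intercept
    raw = raw + params.inhib_temp_coeff * (t - 25.0)
    if matrix == "extract":
        lo, hi = params.matrix_offset_range
        offset = rng.uniform(lo, hi, size=np.broadcast(c, t).shape)
        raw = raw - offset
    inhibition = np.clip(raw, 0.0, 100.0)
    ref = reference_signal(t, params, rng)
    signal = np.asarray(ref) * (1.0 - inhibition / 100.0)
    if params.signal_noise_sd > 0:
        signal = signal + rng.normal(0.0, params.signal_noise_sd, size=np.shape(signal))
    if np.ndim(signal) == 0:
        return float(signal)
    return signal


def generate_dataset(
    concentrations,
    temperatures,
    replicates: int,
    matrix: str = "buffer",
    params: SimParams | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Simulate a full measurement campaign as a sensor-log DataFrame.

    One row per (concentration, temperature, replicate) triple, in that
    nesting order, with the generating concentration recorded as ground
    truth.  The recorded temperature is the nominal set point plus
    ``temp_noise_sd`` jitter, and the signal responds to that actual
    temperature (the thermistor is treated as exact).
    """
    params = params or SimParams()
    concentrations = list(concentrations)
    temperatures = list(temperatures)
    if not concentrations or not temperatures:
        raise UsageError("concentration and temperature lists must be non-empty")
    if replicates < 1:
        raise UsageError("replicates must be >= 1")
    if rng is None:
        rng = params.rng()

    rows = []
    for c in concentrations:
        for t_nom in temperatures:
            for rep in range(1, replicates + 1):
                t_actual = t_nom + (
                    rng.normal(0.0, params.temp_noise_sd) if params.temp_noise_sd > 0 else 0.0
                )
                signal = carbaryl_signal(c, t_actual, matrix, params, rng)
                rows.append(
                    {
                        "delta_vgs_mv": signal,
                        "temperature_c": t_actual,
                        "matrix": matrix,
                        "concentration_m": c,
                        "replicate": rep,
                        "temp_stratum": t_nom,
                    }
                )
    return pd.DataFrame(rows)


def generate_blanks(
    temperatures,
    replicates: int,
    params: SimParams | None = None,
    rng: np.random.Generator | None = None,
    sensor_offset: float = 0.0,
) -> pd.DataFrame:
    """Simulate no-carbaryl reference reads across temperatures.

    ``sensor_offset`` shifts every read by a constant (mV), emulating a
    sensor whose enzyme loading differs from the population the models
    were trained on — the situation the calibration-voltage step exists
    to correct.
    """
    params = params or SimParams()
    temperatures = list(temperatures)
    if not temperatures:
        raise UsageError("temperature list must be non-empty")
    if replicates < 1:
        raise UsageError("replicates must be >= 1")
    if rng is None:
        rng = params.rng()
    rows = []
    for t_nom in temperatures:
        for rep in range(1, replicates + 1):
            t_actual = t_nom + (
                rng.normal(0.0, params.temp_noise_sd) if params.temp_noise_sd > 0 else 0.0
            )
            signal = reference_signal(t_actual, params, rng) + sensor_offset
            rows.append(
                {
                    "delta_vgs_mv": float(signal),
                    "temperature_c": t_actual,
                    "matrix": "buffer",
                    "concentration_m": math.nan,
                    "replicate": rep,
                    "temp_stratum": t_nom,
                }
            )
    return pd.DataFrame(rows)


def write_sensor_log(df: pd.DataFrame, path: str | Path) -> None:
    """Write a sensor log as CSV: molar concentrations in scientific
    notation, missing concentration as an empty field."""
    out = df.loc[:, LOG_COLUMNS].copy()
    out["concentration_m"] = out["concentration_m"].map(
        lambda v: "" if pd.isna(v) else f"{v:.6e}"
    )
    out.to_csv(path, index=False)


def read_sensor_log(path: str | Path) -> pd.DataFrame:
    """Read a sensor log CSV; empty concentration fields become NaN.

    A ``temp_stratum`` column (nominal temperature) is reconstructed by
    rounding to the nearest 5 C so stratified splitting stays possible
    for logs that did not record set points.
    """
    df = pd.read_csv(path, dtype={"matrix": str})
    missing = [c for c in LOG_COLUMNS if c not in df.columns]
    if missing:
        raise UsageError(f"sensor log {path} lacks columns {missing}")
    df["concentration_m"] = pd.to_numeric(df["concentration_m"], errors="coerce")
    if "temp_stratum" not in df.columns:
        df["temp_stratum"] = (df["temperature_c"] / 5.0).round() * 5.0
    return df
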