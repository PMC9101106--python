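"""Two-stage signal compensation for sensor-to-sensor and matrix effects.

Enzyme loading varies between individual AChE-coated sensors, so the
same solution reads slightly differently on each device.  The scheme:

1. A single-input network (temperature -> reference signal) is trained
   once on blank reads from the sensor population.
2. A fresh sensor takes one (or a few, default 3) blank reads; the
   *calibration voltage* is the mean difference between what it read and
   what the reference model predicts at those temperatures.  That offset
   is subtracted from every subsequent reading.
3. Vegetable-extract samples inhibit the enzyme a few percent less than
   buffer-diluted carbaryl at the same concentration, which makes their
   signal read high; a *matrix correction* (percent gap times the
   0.45 mV-per-percent equivalence) is subtracted so extract readings
   land on the buffer-trained calibration.

Conventions: the calibration voltage is an additive offset (a
difference, not a ratio), and the matrix correction is stored as a
non-negative magnitude and subtracted — lower inhibition means a higher
signal, so the correction always pulls extract readings down.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import nn
from .exceptions import DataError, UsageError
from .model import FittedNetwork
from .preprocess import NormParams
from .simulate import SimParams

__all__ = [
    "CalibrationState",
    "fit_reference_model",
    "calibration_voltage",
    "compensate_signal",
    "matrix_correction_from_inhibition_gap",
    "default_matrix_correction",
    "calibrate",
]

#: blank reads averaged per sensor by default (triplicate protocol)
DEFAULT_BLANK_READS = 3


def matrix_correction_from_inhibition_gap(gap: float, mv_per_percent: float = 0.45) -> float:
    """mV correction equivalent to an inhibition deficit of ``gap`` percent."""
    gap = float(gap)
    if gap < 0:
        raise UsageError("inhibition gap must be >= 0")
    return gap * float(mv_per_percent)


def default_matrix_correction(params: SimParams | None = None) -> float:
    """Midpoint-of-range extract correction (mV) when the exact gap is unknown."""
    params = params or SimParams()
    lo, hi = params.matrix_offset_range
    return matrix_correction_from_inhibition_gap((lo + hi) / 2.0, params.mv_per_percent)


@dataclass
class CalibrationState:
    """Everything needed to compensate raw readings from one sensor."""

    reference_model: FittedNetwork
    calibration_voltage: float = 0.0
    matrix_correction: float = 0.0  # magnitude, mV; 0 for buffer samples

    def __post_init__(self) -> None:
        if not np.isfinite(self.calibration_voltage):
            raise UsageError("calibration_voltage must be finite")
        if self.matrix_correction < 0:
            raise UsageError("matrix_correction is a magnitude and must be >= 0")

    def compensate(self, delta_vgs):
        """Compensated signal: reading - calibration_voltage - matrix_correction."""
        out = np.asarray(delta_vgs, dtype=float) - self.calibration_voltage - self.matrix_correction
        return float(out) if np.ndim(delta_vgs) == 0 else out

    def to_dict(self) -> dict:
        return {
            "reference_model": self.reference_model.to_dict(),
            "calibration_voltage": float(self.calibration_voltage),
            "matrix_correction": float(self.matrix_correction),
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1, sort_keys=True))

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationState":
        return cls(
            reference_model=FittedNetwork.from_dict(d["reference_model"]),
            calibration_voltage=float(d["calibration_voltage"]),
            matrix_correction=float(d["matrix_correction"]),
        )

    @classmethod
    def load(cls, path: str | Path) -> "CalibrationState":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _norm_params_padded(table: pd.DataFrame) -> NormParams:
    """Min-max params; a constant target column gets a +/-1 mV pad so a
    flat reference (no temperature drift, no noise) is still trainable."""
    cols = list(table.columns)
    mins = table.min().to_numpy(dtype=float)
    maxs = table.max().to_numpy(dtype=float)
    for i, c in enumerate(cols):
        if not maxs[i] > mins[i]:
            if c == "delta_vgs_mv":
                mins[i] -= 1.0
                maxs[i] += 1.0
            else:
                raise DataError(f"degenerate column {c!r}: max == min")
    return NormParams(cols, mins, maxs)


def fit_reference_model(
    readings: pd.DataFrame,
    config: nn.TrainConfig | None = None,
    train_fraction: float = 0.8,
) -> FittedNetwork:
    """Train the single-input temperature -> reference-signal network.

    ``readings`` are blank (no carbaryl) reads with ``temperature_c`` and
    ``delta_vgs_mv`` columns spanning at least two temperatures.  Uses
    the 1-10-5-1 preset: learning rate 0.01, epoch cap 3000, stop at
    training MSE 0.01 (normalized) or on train/test divergence.
    """
    config = config or nn.single_input_config()
    if readings["temperature_c"].nunique() < 2:
        raise DataError("blank readings must span at least two temperatures")
    table = readings[["temperature_c", "delta_vgs_mv"]].astype(float).reset_index(drop=True)
    norm = _norm_params_padded(table)
    normed = norm.transform(table)
    x = normed["temperature_c"].to_numpy()[:, None]
    y = normed["delta_vgs_mv"].to_numpy()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 911]).generate_state(1)[0])
    n = len(x)
    k = max(1, min(n - 1, int(round(train_fraction * n))))
    perm = rng.permutation(n)
    tr, te = perm[:k], perm[k:]
    network, history = nn.train((x[tr], y[tr]), (x[te], y[te]), nn.SINGLE_INPUT_LAYERS, config)
    return FittedNetwork(
        network=network,
        norm=norm,
        feature_columns=["temperature_c"],
        target_column="delta_vgs_mv",
        target_transform="identity",
        history=history,
        metadata={
            "role": "reference_signal_model",
            "n_train": int(k),
            "n_test": int(n - k),
            "learning_rate": config.learning_rate,
            "max_epochs": config.max_epochs,
            "mse_stop_threshold": config.mse_stop_threshold,
        },
    )


def calibration_voltage(measured_blank, temperature, reference_model: FittedNetwork) -> float:
    """Per-sensor offset: measured blank minus model-predicted reference (mV).

    Arrays of k blank reads are averaged (triplicate protocol by
    default in :func:`calibrate`).
    """
    measured = np.atleast_1d(np.asarray(measured_blank, dtype=float))
    temps = np.atleast_1d(np.asarray(temperature, dtype=float))
    measured, temps = np.broadcast_arrays(measured, temps)
    predicted = reference_model.predict(temps[:, None])
    return float(np.mean(measured - predicted))


def compensate_signal(delta_vgs, state: CalibrationState):
    """Apply a sensor's full compensation to raw signal(s); see
    :meth:`CalibrationState.compensate`."""
    return state.compensate(delta_vgs)


def calibrate(
    blanks: pd.DataFrame,
    reference_model: FittedNetwork,
    matrix: str = "buffer",
    matrix_correction: float | None = None,
    n_reads: int = DEFAULT_BLANK_READS,
) -> CalibrationState:
    """Build a :class:`CalibrationState` from a sensor's blank reads.

    The first ``n_reads`` blank rows are averaged for the calibration
    voltage.  For ``matrix="extract"`` the default midpoint matrix
    correction is applied unless an explicit value is given.
    """
    if matrix not in ("buffer", "extract"):
        raise UsageError(f"unknown matrix {matrix!r}")
    if len(blanks) == 0:
        raise DataError("at least one blank read is required")
    use = blanks.head(n_reads)
    cal_v = calibration_voltage(
        use["delta_vgs_mv"].to_numpy(), use["temperature_c"].to_numpy(), reference_model
    )
    if matrix_correction is None:
        matrix_correction = default_matrix_correction() if matrix == "extract" else 0.0
    return CalibrationState(
        reference_model=reference_model,
        calibration_voltage=cal_v,
        matrix_correction=float(matrix_correction),
    )
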