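"""Min-max normalization, AWGN augmentation, and train/test splitting.

The network is trained on features and targets linearly rescaled to
[0, 1] by per-column minima and maxima (the inverse map recovers the
original scale exactly).  The regression target is, by default, the
base-10 logarithm of the molar carbaryl concentration: the assay spans
four decades, and on a raw molar scale all but the top level would
collapse into the bottom 0.1 % of the unit interval.  A ``raw`` mode is
retained for comparison.

Training-set normalization parameters are applied unchanged to the test
split (no refit) so no information leaks across the split; the variant
that refits on the test split's own extrema is available through
``CarbarylRegression(refit_norm_on_test=True)`` for reproduction
purposes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .exceptions import DataError, UsageError

__all__ = [
    "NormParams",
    "Dataset",
    "make_dataset",
    "minmax_normalize",
    "denormalize",
    "awgn_augment",
    "split",
    "FEATURE_COLUMNS",
    "TARGET_LOG10",
    "TARGET_RAW",
]

FEATURE_COLUMNS = ["delta_vgs_mv", "temperature_c"]
TARGET_LOG10 = "log10_concentration_m"
TARGET_RAW = "concentration_m"


@dataclass
class NormParams:
    """Per-column minima and maxima on the original scale.

    ``transform`` maps v -> (v - min)/(max - min); ``inverse`` maps back.
    Fitting a column with max == min raises :class:`DataError` (the map
    would be degenerate); applying stored params to out-of-range values
    clips to [0, 1] with a warning, since field readings may drift
    slightly outside the calibration range.
    """

    columns: list[str]
    mins: np.ndarray
    maxs: np.ndarray

    @classmethod
    def fit(cls, df: pd.DataFrame, columns: list[str] | None = None) -> "NormParams":
        columns = list(columns or df.columns)
        mins = df[columns].min().to_numpy(dtype=float)
        maxs = df[columns].max().to_numpy(dtype=float)
        degenerate = [c for c, lo, hi in zip(columns, mins, maxs) if not hi > lo]
        if degenerate:
            raise DataError(
                f"cannot fit min-max normalization: degenerate column(s) {degenerate} "
                "(max == min)"
            )
        return cls(columns, mins, maxs)

    def _cols(self, df: pd.DataFrame) -> list[str]:
        return [c for c in self.columns if c in df.columns]

    def transform(self, df: pd.DataFrame, clip: bool = True) -> pd.DataFrame:
        out = df.copy()
        for c in self._cols(df):
            i = self.columns.index(c)
            v = (out[c].to_numpy(dtype=float) - self.mins[i]) / (self.maxs[i] - self.mins[i])
            if clip and ((v < 0).any() or (v > 1).any()):
                warnings.warn(
                    f"values in column {c!r} fall outside the fitted range; clipping to [0, 1]",
                    RuntimeWarning,
                    stacklevel=2,
                )
                v = np.clip(v, 0.0, 1.0)
            out[c] = v
        return out

    def inverse(self, df: pd.DataFrame) -> pd.DataFrame:
        out = df.copy()
        for c in self._cols(df):
            i = self.columns.index(c)
            out[c] = out[c].to_numpy(dtype=float) * (self.maxs[i] - self.mins[i]) + self.mins[i]
        return out

    def transform_values(self, values, column: str, clip: bool = True) -> np.ndarray:
        i = self.columns.index(column)
        v = (np.asarray(values, dtype=float) - self.mins[i]) / (self.maxs[i] - self.mins[i])
        if clip and np.any((v < 0) | (v > 1)):
            warnings.warn(
                f"values in column {column!r} fall outside the fitted range; clipping to [0, 1]",
                RuntimeWarning,
                stacklevel=2,
            )
            v = np.clip(v, 0.0, 1.0)
        return v

    def inverse_values(self, values, column: str) -> np.ndarray:
        i = self.columns.index(column)
        return np.asarray(values, dtype=float) * (self.maxs[i] - self.mins[i]) + self.mins[i]

    def to_dict(self) -> dict:
        return {
            "columns": list(self.columns),
            "mins": [float(v) for v in self.mins],
            "maxs": [float(v) for v in self.maxs],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NormParams":
        return cls(list(d["columns"]), np.asarray(d["mins"], float), np.asarray(d["maxs"], float))


@dataclass
class Dataset:
    """Feature table + target vector + row provenance.

    ``provenance`` tracks each row's source base row, whether it is an
    AWGN replicate, and the nominal temperature stratum; ``norm`` is the
    :class:`NormParams` attached once the dataset has been normalized
    (covering both feature columns and the target column).
    """

    features: pd.DataFrame
    target: pd.Series
    provenance: pd.DataFrame
    norm: NormParams | None = None
    target_transform: str = "log10"

    def __post_init__(self) -> None:
        if len(self.features) != len(self.target) or len(self.features) != len(self.provenance):
            raise UsageError("features, target and provenance must have equal length")

    def __len__(self) -> int:
        return len(self.features)

    @property
    def n(self) -> int:
        return len(self)

    def xy(self) -> tuple[np.ndarray, np.ndarray]:
        """Features as (n, d) float array, target as (n,) float array."""
        return (
            self.features.to_numpy(dtype=float),
            self.target.to_numpy(dtype=float),
        )

    def _replace(self, **kw) -> "Dataset":
        return replace(self, **kw)


def make_dataset(log: pd.DataFrame, target_transform: str = "log10") -> Dataset:
    """Build a modelling Dataset from a sensor-log DataFrame.

    Rows without a recorded concentration (blank reads) are rejected;
    use them for calibration, not regression.
    """
    if target_transform not in ("log10", "raw"):
        raise UsageError(f"unknown target_transform {target_transform!r}")
    log = log.reset_index(drop=True)
    conc = log["concentration_m"].to_numpy(dtype=float)
    if np.any(~np.isfinite(conc)) or np.any(conc <= 0):
        raise DataError("every row needs a positive known concentration to form a dataset")
    if target_transform == "log10":
        target = pd.Series(np.log10(conc), name=TARGET_LOG10)
    else:
        target = pd.Series(conc, name=TARGET_RAW)
    features = log[FEATURE_COLUMNS].astype(float).reset_index(drop=True)
    stratum = log["temp_stratum"] if "temp_stratum" in log.columns else log["temperature_c"]
    provenance = pd.DataFrame(
        {
            "source_row": np.arange(len(log)),
            "augmented": False,
            "temp_stratum": stratum.to_numpy(dtype=float),
            "concentration_m": conc,
        }
    )
    return Dataset(features, target, provenance, norm=None, target_transform=target_transform)


def minmax_normalize(data: Dataset, params: NormParams | None = None) -> tuple[Dataset, NormParams]:
    """Normalize features and target to [0, 1] per column.

    When ``params`` is supplied it is applied unchanged (no refit, out of
    range values clipped with a warning); otherwise params are fitted on
    ``data`` itself.
    """
    if data.norm is not None:
        raise UsageError("dataset is already normalized")
    table = data.features.copy()
    table[data.target.name] = data.target.to_numpy()
    if params is None:
        params = NormParams.fit(table)
    normed = params.transform(table)
    features = normed[data.features.columns.tolist()]
    target = normed[data.target.name].rename(data.target.name)
    return data._replace(features=features, target=target, norm=params), params


def denormalize(values, params: NormParams, column: str) -> np.ndarray:
    """Inverse of the min-max map for a single named column."""
    if params is None:
        raise UsageError("denormalize requires fitted NormParams")
    return params.inverse_values(values, column)


def awgn_augment(
    data: Dataset,
    factor: int,
    signal_sd: float,
    temp_sd: float,
    rng: np.random.Generator,
) -> Dataset:
    """Multiply the dataset ``factor`` times with additive white Gaussian noise.

    Each original row is replicated ``factor`` times; independent
    zero-mean Gaussian noise is added to the signal and temperature
    features, targets are left untouched, and provenance records the
    source row.  Mimics measurement noise (thermal, electronic, ambient)
    so the model trains on realistically scattered inputs.
    """
    if factor < 1:
        raise UsageError("augmentation factor must be >= 1")
    if signal_sd < 0 or temp_sd < 0:
        raise UsageError("noise standard deviations must be >= 0")
    if data.norm is not None:
        raise UsageError("augment on the original scale, before normalization")
    n = len(data)
    reps = pd.concat([data.features] * factor, ignore_index=True)
    noise_sig = rng.normal(0.0, signal_sd, size=factor * n) if signal_sd > 0 else 0.0
    noise_tmp = rng.normal(0.0, temp_sd, size=factor * n) if temp_sd > 0 else 0.0
    reps["delta_vgs_mv"] = reps["delta_vgs_mv"].to_numpy() + noise_sig
    reps["temperature_c"] = reps["temperature_c"].to_numpy() + noise_tmp
    target = pd.concat([data.target] * factor, ignore_index=True)
    prov = pd.concat([data.provenance] * factor, ignore_index=True)
    prov["source_row"] = np.tile(data.provenance["source_row"].to_numpy(), factor)
    prov["augmented"] = True
    return data._replace(features=reps, target=target, provenance=prov)


def split(
    data: Dataset,
    train_fraction: float,
    stratify_by_temperature: bool = True,
    rng: np.random.Generator | None = None,
) -> tuple[Dataset, Dataset]:
    """Disjoint, exhaustive train/test split, optionally per temperature stratum.

    With stratification every nominal-temperature stratum is split at the
    same fraction (rounded to the nearest row), so e.g. 2000 rows over 4
    temperatures at 0.8 give 400 training and 100 testing rows per
    temperature.
    """
    if not 0.0 < train_fraction < 1.0:
        raise UsageError("train_fraction must be strictly between 0 and 1")
    if rng is None:
        rng = np.random.default_rng(0)
    n = len(data)
    if stratify_by_temperature:
        train_idx: list[np.ndarray] = []
        strata = data.provenance["temp_stratum"].to_numpy()
        for value in np.unique(strata):
            idx = np.flatnonzero(strata == value)
            k = int(round(train_fraction * len(idx)))
            if k == 0 or k == len(idx):
                raise DataError(
                    f"temperature stratum {value} has {len(idx)} rows; too small to split "
                    f"at fraction {train_fraction}"
                )
            train_idx.append(rng.permutation(idx)[:k])
        tr = np.sort(np.concatenate(train_idx))
    else:
        k = int(round(train_fraction * n))
        if k == 0 or k == n:
            raise DataError(f"{n} rows is too small to split at fraction {train_fraction}")
        tr = np.sort(rng.permutation(n)[:k])
    mask = np.zeros(n, dtype=bool)
    mask[tr] = True

    def take(m: np.ndarray) -> Dataset:
        return data._replace(
            features=data.features.loc[m].reset_index(drop=True),
            target=data.target.loc[m].reset_index(drop=True),
            provenance=data.provenance.loc[m].reset_index(drop=True),
        )

    return take(mask), take(~mask)
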