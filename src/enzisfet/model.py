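"""Model / Results objects for the concentration and reference regressions.

``CarbarylRegression`` is the user-facing model class: construct it from
a sensor-log DataFrame (or CSV), call :meth:`~CarbarylRegression.fit`,
and get a :class:`CarbarylResults` carrying the trained network, the
normalization parameters, per-epoch loss history, test-set metrics on
both the normalized and log10-molar scales, a ``summary()`` table,
prediction, plotting, and JSON serialization.

``FittedNetwork`` is the lower-level fitted artifact shared with the
single-input reference model used for signal compensation: network
weights + min-max parameters + target-transform tag, self-contained for
prediction (a saved file needs no training-time objects).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import nn, preprocess
from .exceptions import UsageError
from .metrics import Metrics, evaluate
from .nn import NetworkParams, TrainConfig, TrainHistory
from .preprocess import Dataset, NormParams

__all__ = ["FittedNetwork", "CarbarylRegression", "CarbarylResults"]

_FILE_FORMAT = "enzisfet-model/1"


@dataclass
class FittedNetwork:
    """A trained network bundled with everything prediction needs.

    ``target_transform`` is "log10" (target was log10 molar), "raw"
    (molar) or "identity" (target already on its physical scale, as in
    the temperature-to-reference model).
    """

    network: NetworkParams
    norm: NormParams
    feature_columns: list[str]
    target_column: str
    target_transform: str = "identity"
    history: TrainHistory | None = None
    metadata: dict = field(default_factory=dict)

    def predict_normalized(self, features: pd.DataFrame | np.ndarray) -> np.ndarray:
        """Network output on the normalized [0, 1] target scale."""
        if isinstance(features, pd.DataFrame):
            x = np.column_stack(
                [
                    self.norm.transform_values(features[c].to_numpy(), c)
                    for c in self.feature_columns
                ]
            )
        else:
            x = np.asarray(features, dtype=float)
            if x.ndim == 1 and len(self.feature_columns) > 1:
                x = x[None, :]
            elif x.ndim == 1:
                x = x[:, None]
            x = np.column_stack(
                [self.norm.transform_values(x[:, i], c) for i, c in enumerate(self.feature_columns)]
            )
        return nn.forward(x, self.network)

    def predict(self, features) -> np.ndarray:
        """Prediction on the original target scale (molar for "log10"/"raw")."""
        yn = self.predict_normalized(features)
        y = self.norm.inverse_values(yn, self.target_column)
        if self.target_transform == "log10":
            return np.power(10.0, y)
        return y

    def to_dict(self) -> dict:
        return {
            "format": _FILE_FORMAT,
            "network": self.network.to_dict(),
            "norm": self.norm.to_dict(),
            "feature_columns": list(self.feature_columns),
            "target_column": self.target_column,
            "target_transform": self.target_transform,
            "history": self.history.to_dict() if self.history is not None else None,
            "metadata": self.metadata,
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1, sort_keys=True))

    @classmethod
    def from_dict(cls, d: dict) -> "FittedNetwork":
        if d.get("format") != _FILE_FORMAT:
            raise UsageError(f"unrecognized model file format {d.get('format')!r}")
        return cls(
            network=NetworkParams.from_dict(d["network"]),
            norm=NormParams.from_dict(d["norm"]),
            feature_columns=list(d["feature_columns"]),
            target_column=d["target_column"],
            target_transform=d["target_transform"],
            history=TrainHistory.from_dict(d["history"]) if d.get("history") else None,
            metadata=d.get("metadata", {}),
        )

    @classmethod
    def load(cls, path: str | Path) -> "FittedNetwork":
        return cls.from_dict(json.loads(Path(path).read_text()))


class CarbarylRegression:
    """Multiple-input regression of carbaryl concentration on (signal, T).

    Parameters
    ----------
    data
        Sensor-log DataFrame with columns ``delta_vgs_mv``,
        ``temperature_c`` and a known ``concentration_m`` per row.
    target_transform
        "log10" (default) regresses on log10 molar concentration;
        "raw" on molarity directly.
    augment_factor, signal_noise_sd, temp_noise_sd
        AWGN augmentation: each row is replicated this many times with
        Gaussian noise (mV / Celsius) on the features.  Factor 1 with
        zero SDs disables augmentation.
    train_fraction, stratify_by_temperature
        Train/test split applied after augmentation.
    refit_norm_on_test
        When True, the test split is normalized by its own extrema
        instead of the training-set parameters.  Leaks split information
        and exists only to reproduce protocols that normalize each split
        independently; leave False for honest evaluation.
    seed
        Governs augmentation noise and the split.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        *,
        target_transform: str = "log10",
        augment_factor: int = 10,
        signal_noise_sd: float = 0.2,
        temp_noise_sd: float = 0.1,
        train_fraction: float = 0.8,
        stratify_by_temperature: bool = True,
        refit_norm_on_test: bool = False,
        seed: int = 0,
    ) -> None:
        self.data = data
        self.target_transform = target_transform
        self.augment_factor = augment_factor
        self.signal_noise_sd = signal_noise_sd
        self.temp_noise_sd = temp_noise_sd
        self.train_fraction = train_fraction
        self.stratify_by_temperature = stratify_by_temperature
        self.refit_norm_on_test = refit_norm_on_test
        self.seed = seed

    @classmethod
    def from_csv(cls, path: str | Path, **kwargs) -> "CarbarylRegression":
        from .simulate import read_sensor_log

        return cls(read_sensor_log(path), **kwargs)

    def _prepare(self) -> tuple[Dataset, Dataset, NormParams]:
        ss = np.random.SeedSequence(self.seed)
        rng_aug, rng_split = (np.random.default_rng(s) for s in ss.spawn(2))
        ds = preprocess.make_dataset(self.data, self.target_transform)
        if self.augment_factor > 1 or self.signal_noise_sd > 0 or self.temp_noise_sd > 0:
            ds = preprocess.awgn_augment(
                ds, self.augment_factor, self.signal_noise_sd, self.temp_noise_sd, rng_aug
            )
        train_ds, test_ds = preprocess.split(
            ds, self.train_fraction, self.stratify_by_temperature, rng_split
        )
        train_n, params = preprocess.minmax_normalize(train_ds)
        if self.refit_norm_on_test:
            test_n, _ = preprocess.minmax_normalize(test_ds)
        else:
            test_n, _ = preprocess.minmax_normalize(test_ds, params)
        return train_n, test_n, params

    def fit(
        self,
        config: TrainConfig | None = None,
        layer_sizes=nn.MULTI_INPUT_LAYERS,
    ) -> "CarbarylResults":
        """Normalize, split, and train the network; return results."""
        config = config or nn.multi_input_config(seed=self.seed)
        train_n, test_n, norm = self._prepare()
        network, history = nn.train(train_n, test_n, layer_sizes, config)
        fitted = FittedNetwork(
            network=network,
            norm=norm,
            feature_columns=list(train_n.features.columns),
            target_column=train_n.target.name,
            target_transform=self.target_transform,
            history=history,
            metadata={
                "layer_sizes": list(layer_sizes),
                "learning_rate": config.learning_rate,
                "max_epochs": config.max_epochs,
                "patience": config.patience,
                "seed": self.seed,
                "n_train": len(train_n),
                "n_test": len(test_n),
                "augment_factor": self.augment_factor,
                "signal_noise_sd": self.signal_noise_sd,
                "temp_noise_sd": self.temp_noise_sd,
            },
        )
        return CarbarylResults(self, fitted, train_n, test_n)


class CarbarylResults:
    """Fit results of :class:`CarbarylRegression`.

    Attributes
    ----------
    fitted : FittedNetwork
        Self-contained trained artifact (save with :meth:`save`).
    train_data, test_data : Dataset
        The normalized splits the network was trained/evaluated on.
    metrics_normalized : Metrics
        Test-set MSE/MAE/R-squared on the normalized [0, 1] target scale
        (the scale the headline figures are quoted on).
    metrics_log10 : Metrics or None
        Same residuals expressed in log10-molar units (decades), for the
        "log10" target transform.
    """

    def __init__(
        self,
        model: CarbarylRegression,
        fitted: FittedNetwork,
        train_data: Dataset,
        test_data: Dataset,
    ) -> None:
        self.model = model
        self.fitted = fitted
        self.train_data = train_data
        self.test_data = test_data

        xt, yt = test_data.xy()
        self._yhat_test = nn.forward(xt, fitted.network)
        self.metrics_normalized: Metrics = evaluate(yt, self._yhat_test)
        if fitted.target_transform == "log10":
            col = test_data.target.name
            y_dec = fitted.norm.inverse_values(yt, col)
            yhat_dec = fitted.norm.inverse_values(self._yhat_test, col)
            self.metrics_log10: Metrics | None = evaluate(y_dec, yhat_dec)
        else:
            self.metrics_log10 = None

    # -- convenience accessors -------------------------------------------------
    @property
    def history(self) -> TrainHistory:
        return self.fitted.history

    @property
    def network(self) -> NetworkParams:
        return self.fitted.network

    def predict(self, delta_vgs_mv, temperature_c, calibration=None) -> np.ndarray:
        """Predict molar carbaryl concentration(s) from raw readings.

        When a calibration state (see :mod:`enzisfet.compensation`) is
        given, its signal compensation is applied first.
        """
        sig = np.atleast_1d(np.asarray(delta_vgs_mv, dtype=float))
        tmp = np.atleast_1d(np.asarray(temperature_c, dtype=float))
        sig, tmp = np.broadcast_arrays(sig, tmp)
        if calibration is not None:
            sig = calibration.compensate(sig)
        out = self.fitted.predict(np.column_stack([sig, tmp]))
        return out if np.size(out) > 1 else float(out[0])

    def save(self, path: str | Path) -> None:
        self.fitted.save(path)

    def summary(self) -> str:
        """Plain-text summary table of the fit."""
        f = self.fitted
        m = self.metrics_normalized
        h = f.history
        lines = [
            "Carbaryl concentration regression (enzyme-ISFET, multiple-input)",
            "=" * 66,
            f"architecture        : {'-'.join(map(str, f.network.layer_sizes))} (tanh/tanh/ReLU)",
            f"target transform    : {f.target_transform}",
            f"train / test rows   : {f.metadata.get('n_train', '?')} / {f.metadata.get('n_test', '?')}",
            f"epochs run          : {h.n_epochs} (stop: {h.stop_reason}, best epoch {h.best_epoch})",
            f"learning rate       : {f.metadata.get('learning_rate', '?')}",
            "-" * 66,
            "test metrics (normalized target scale)",
            f"  MSE               : {m.mse:.6g}  ({m.mse_percent:.4g} %)",
            f"  MAE               : {m.mae:.6g}  ({m.mae_percent:.4g} %)",
            f"  R^2               : {m.r_squared:.4f}",
        ]
        if self.metrics_log10 is not None:
            ml = self.metrics_log10
            lines += [
                "test metrics (log10 molar scale, decades)",
                f"  RMSE              : {np.sqrt(ml.mse):.4g}",
                f"  MAE               : {ml.mae:.4g}",
                f"  R^2               : {ml.r_squared:.4f}",
            ]
        lines.append("=" * 66)
        return "\n".join(lines)

    # -- plotting --------------------------------------------------------------
    def plot_history(self, ax=None):
        """Train/test MSE learning curves."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        h = self.fitted.history
        ax.plot(h.train_mse, label="train MSE")
        ax.plot(h.test_mse, label="test MSE")
        ax.set_xlabel("epoch")
        ax.set_ylabel("MSE (normalized)")
        ax.set_yscale("log")
        ax.legend()
        return ax

    def plot_parity(self, ax=None):
        """Predicted vs actual normalized test targets."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        _, yt = self.test_data.xy()
        ax.scatter(yt, self._yhat_test, s=8, alpha=0.5)
        lim = [min(yt.min(), self._yhat_test.min()), max(yt.max(), self._yhat_test.max())]
        ax.plot(lim, lim, "k--", lw=1)
        ax.set_xlabel("actual (normalized)")
        ax.set_ylabel("predicted (normalized)")
        return ax
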