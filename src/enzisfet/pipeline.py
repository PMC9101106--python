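"""End-to-end orchestration: simulate -> augment -> split -> train both
networks -> calibrate -> evaluate, fully reproducible from (config, seed).

``run_pipeline`` produces the machine-readable report and (optionally)
all artifacts on disk: the simulated sensor log, the two model files,
the calibration state, and the report JSON.  Every random draw descends
from the single global seed, so two runs with the same config are
byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import metrics, nn, simulate
from .compensation import CalibrationState, calibrate, fit_reference_model
from .exceptions import EnzIsfetError
from .model import CarbarylRegression, CarbarylResults, FittedNetwork
from .simulate import DEFAULT_CONCENTRATIONS, DEFAULT_TEMPERATURES, SimParams

__all__ = ["PipelineConfig", "run_pipeline", "predict_concentration", "stage_seed"]

log = logging.getLogger("enzisfet")


def stage_seed(global_seed: int, stage: int) -> int:
    """Deterministic per-stage child seed (< 2**31) from the global seed."""
    return int(np.random.SeedSequence([int(global_seed), stage]).generate_state(1)[0] % (2**31))


@dataclass
class PipelineConfig:
    """Everything one pipeline run depends on.

    Defaults reproduce the reference measurement campaign: 5
    concentrations x 4 temperatures x 10 replicates = 200 base rows,
    AWGN x10 to 2000, stratified 80/20 split, the 2-20-16-1 and 1-10-5-1
    networks at learning rate 0.01 with epoch caps 5000 and 3000.
    """

    sim: SimParams = field(default_factory=SimParams)
    concentrations: tuple[float, ...] = DEFAULT_CONCENTRATIONS
    temperatures: tuple[float, ...] = DEFAULT_TEMPERATURES
    replicates: int = 10
    matrix: str = "buffer"
    target_transform: str = "log10"
    augment_factor: int = 10
    train_fraction: float = 0.8
    stratify_by_temperature: bool = True
    blank_replicates: int = 50
    multi_train: nn.TrainConfig = field(default_factory=nn.multi_input_config)
    single_train: nn.TrainConfig = field(default_factory=nn.single_input_config)
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sim"] = self.sim.to_dict()
        d["concentrations"] = [float(c) for c in self.concentrations]
        d["temperatures"] = [float(t) for t in self.temperatures]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "sim" in d:
            d["sim"] = SimParams.from_dict(d["sim"])
        for key in ("multi_train", "single_train"):
            if key in d and isinstance(d[key], dict):
                d[key] = nn.TrainConfig(**d[key])
        for key in ("concentrations", "temperatures"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _stage(name: str):
    """Decorator-free stage wrapper: re-raise with the failing stage named."""

    class _ctx:
        def __enter__(self):
            log.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, EnzIsfetError):
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
            log.info("stage %s: done", name)
            return False

    return _ctx()


def run_pipeline(config: PipelineConfig | None = None, outdir: str | Path | None = None) -> dict:
    """Execute the full scheme and return the report dict.

    With ``outdir`` set, writes ``dataset.csv``, ``model.json``,
    ``reference_model.json``, ``calibration.json`` and ``report.json``.
    """
    config = config or PipelineConfig()
    seed = config.seed
    report: dict = {
        "config_hash": config.hash(),
        "seed": seed,
        "stages": {},
    }

    with _stage("simulate"):
        sim = dataclasses.replace(config.sim, seed=stage_seed(seed, 0))
        base = simulate.generate_dataset(
            config.concentrations, config.temperatures, config.replicates, config.matrix, sim
        )
        blanks = simulate.generate_blanks(
            config.temperatures,
            config.blank_replicates,
            dataclasses.replace(config.sim, seed=stage_seed(seed, 1)),
        )

    with _stage("train_reference_model"):
        blank_ds = pd.concat([blanks] * config.augment_factor, ignore_index=True)
        rng_b = np.random.default_rng(stage_seed(seed, 2))
        if config.sim.temp_noise_sd > 0:
            blank_ds["temperature_c"] += rng_b.normal(
                0.0, config.sim.temp_noise_sd, size=len(blank_ds)
            )
        single_cfg = dataclasses.replace(config.single_train, seed=stage_seed(seed, 3))
        reference_model = fit_reference_model(blank_ds, single_cfg)

    with _stage("train_multi_model"):
        model = CarbarylRegression(
            base,
            target_transform=config.target_transform,
            augment_factor=config.augment_factor,
            signal_noise_sd=config.sim.signal_noise_sd,
            temp_noise_sd=config.sim.temp_noise_sd,
            train_fraction=config.train_fraction,
            stratify_by_temperature=config.stratify_by_temperature,
            seed=stage_seed(seed, 4),
        )
        multi_cfg = dataclasses.replace(config.multi_train, seed=stage_seed(seed, 5))
        results = model.fit(multi_cfg)

    with _stage("calibrate"):
        calibration = calibrate(blanks, reference_model, matrix=config.matrix)

    with _stage("evaluate"):
        # assay diagnostics recomputed from the simulated campaign
        ph_points = np.array([4.0, 7.0, 10.0])
        ph_line = metrics.fit_line(
            ph_points, [simulate.ph_response(p, config.sim) for p in ph_points], x_domain="pH"
        )
        at25 = base[base["temp_stratum"] == 25.0] if (base["temp_stratum"] == 25.0).any() else base
        ref25 = blanks[blanks["temp_stratum"] == 25.0]["delta_vgs_mv"]
        ref_mean = float(ref25.mean()) if len(ref25) else config.sim.ref_mean_25c
        ref_sd = float(ref25.std(ddof=1)) if len(ref25) > 1 else config.sim.ref_sd
        inhib = [
            metrics.percent_inhibition(ref_mean, s) for s in at25["delta_vgs_mv"].to_numpy()
        ]
        inhib_line = metrics.fit_line(
            np.log(at25["concentration_m"].to_numpy()), inhib, x_domain="ln_concentration"
        )
        lowest = at25[at25["concentration_m"] == at25["concentration_m"].min()]
        lod = metrics.lod_check(ref_sd, float(lowest["delta_vgs_mv"].mean()), ref_mean)

        strata = results.test_data.provenance["temp_stratum"]
        report.update(
            {
                "sizes": {
                    "base": int(len(base)),
                    "augmented": int(len(base) * config.augment_factor),
                    "train": int(len(results.train_data)),
                    "test": int(len(results.test_data)),
                    "train_per_stratum": {
                        str(k): int(v)
                        for k, v in results.train_data.provenance["temp_stratum"]
                        .value_counts()
                        .sort_index()
                        .items()
                    },
                    "test_per_stratum": {
                        str(k): int(v) for k, v in strata.value_counts().sort_index().items()
                    },
                },
                "metrics_normalized": results.metrics_normalized.to_dict(),
                "metrics_log10": (
                    results.metrics_log10.to_dict() if results.metrics_log10 else None
                ),
                "ph_line": dataclasses.asdict(ph_line),
                "sensitivity_acceptable": metrics.sensitivity_acceptable(ph_line.slope),
                "inhibition_line": dataclasses.asdict(inhib_line),
                "lod": dataclasses.asdict(lod),
                "calibration_voltage_mv": calibration.calibration_voltage,
                "reference_model": {
                    "stop_reason": reference_model.history.stop_reason,
                    "n_epochs": reference_model.history.n_epochs,
                    "best_test_mse": reference_model.history.best_test_mse,
                },
                "multi_model": {
                    "stop_reason": results.history.stop_reason,
                    "n_epochs": results.history.n_epochs,
                    "best_epoch": results.history.best_epoch,
                    "best_test_mse": results.history.best_test_mse,
                },
            }
        )

    if outdir is not None:
        with _stage("write_artifacts"):
            outdir = Path(outdir)
            outdir.mkdir(parents=True, exist_ok=True)
            simulate.write_sensor_log(base, outdir / "dataset.csv")
            simulate.write_sensor_log(blanks, outdir / "blanks.csv")
            results.save(outdir / "model.json")
            reference_model.save(outdir / "reference_model.json")
            calibration.save(outdir / "calibration.json")
            (outdir / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    return report


def predict_concentration(
    reading,
    model: FittedNetwork | CarbarylResults,
    calibration: CalibrationState | None = None,
) -> float:
    """Predict the molar carbaryl concentration of one sensor reading.

    ``reading`` is anything with ``delta_vgs_mv`` and ``temperature_c``
    entries (dict, Series, dataclass-like).  The signal is compensated
    (when a calibration is given), normalized with the stored training
    parameters, fed forward, denormalized, and mapped back from the
    target transform.  A temperature outside the modelled 20-35 C range
    triggers a warning but is still processed.
    """
    if isinstance(model, CarbarylResults):
        model = model.fitted
    get = reading.get if hasattr(reading, "get") else lambda k: getattr(reading, k)
    signal = float(get("delta_vgs_mv"))
    temp = float(get("temperature_c"))
    if not 20.0 <= temp <= 35.0:
        warnings.warn(
            f"temperature {temp} C outside the modelled 20-35 C range; prediction is an "
            "extrapolation",
            RuntimeWarning,
            stacklevel=2,
        )
    if calibration is not None:
        signal = calibration.compensate(signal)
    out = model.predict(np.array([[signal, temp]]))
    return float(out[0])
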