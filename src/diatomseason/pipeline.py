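"""End-to-end orchestration: counts -> EQR -> seasonal decomposition;
sensors -> antecedent windows -> ordination.

A :class:`PipelineConfig` (YAML on disk) names the inputs, the stages to
run and every stage parameter.  :func:`run_pipeline` validates the whole
configuration before any computation, executes the requested stages in
dependency order, and writes per-stage CSVs, a machine-readable
``summary.json``, a config snapshot and a run log into the run directory.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .antecedent import SensorSeries, build_env_matrix
from .asdhr import confidence_band, default_spec, fit_asdhr, fit_to_frame
from .diatom_metrics import CountMatrix, TraitTable, eqr_series
from .errors import ConfigError
from .ordination import pca_species, project_env
from .series import IrregularSeries
from .synthetic import gen_counts, gen_sensor, sample_schedule

logger = logging.getLogger("diatomseason.pipeline")

STAGES = ("simulate", "eqr", "asdhr", "antecedent", "ordination")


@dataclass
class PipelineConfig:
    """Everything needed to run the chain, round-trippable to YAML."""

    seed: int = 1
    stages: list = field(default_factory=lambda: list(STAGES))
    # input paths; unused when the simulate stage provides the data
    counts_path: str = ""
    traits_path: str = ""
    sensor_path: str = ""
    series_path: str = ""
    # simulate
    n_years: float = 5.5
    # eqr
    expected_index: float = 25.0
    # asdhr
    period: float = 1.0
    n_harmonics: int = 2
    trend_tvp: str = "irw"
    seasonal_tvp: str = "rw"
    band_level: float = 0.95
    # antecedent
    window_days: float = 21.0
    min_coverage: float = 0.5
    log_vars: list = field(default_factory=lambda: ["turbidity", "rainfall", "discharge"])
    log_a: float = 1.0
    log_b: float = 1.0
    # ordination
    n_axes: int = 2
    top_species: int = 10

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    def digest(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def validate(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ConfigError(f"unknown stages: {sorted(unknown)}")
        if not self.stages:
            raise ConfigError("no stages requested")
        simulate = "simulate" in self.stages
        needs_counts = {"eqr", "ordination"} & set(self.stages)
        needs_sensor = {"antecedent"} & set(self.stages)
        if not simulate:
            if needs_counts and not Path(self.counts_path).is_file():
                raise ConfigError(f"counts file not found: {self.counts_path!r}")
            if needs_sensor and not Path(self.sensor_path).is_file():
                raise ConfigError(f"sensor file not found: {self.sensor_path!r}")
            if "asdhr" in self.stages and "eqr" not in self.stages \
                    and not Path(self.series_path).is_file():
                raise ConfigError(f"series file not found: {self.series_path!r}")
        if self.traits_path and not Path(self.traits_path).is_file():
            raise ConfigError(f"traits file not found: {self.traits_path!r}")
        if not (self.period > 0):
            raise ConfigError("period must be positive")
        if not (1 <= self.n_harmonics <= 6):
            raise ConfigError("n_harmonics must lie in 1..6")
        if not (0.0 < self.band_level < 1.0):
            raise ConfigError("band_level must lie in (0, 1)")
        if not (0.0 <= self.expected_index < 100.0):
            raise ConfigError("expected_index must lie in [0, 100)")
        if not (self.window_days > 0):
            raise ConfigError("window_days must be positive")
        if not (0.0 <= self.min_coverage <= 1.0):
            raise ConfigError("min_coverage must lie in [0, 1]")
        if self.n_axes < 1 or self.top_species < 1:
            raise ConfigError("n_axes and top_species must be >= 1")
        if self.n_years < 1:
            raise ConfigError("n_years must be >= 1")


def run_pipeline(config: PipelineConfig, out_dir) -> Path:
    """Validate, run the requested stages in order, and write the run dir.

    Raises before writing anything if validation fails; a failed stage
    propagates (the CLI maps it to a nonzero exit status).
    """
    config.validate()
    run = Path(out_dir)
    run.mkdir(parents=True, exist_ok=True)
    config.to_yaml(run / "config.yaml")

    handler = logging.FileHandler(run / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("diatomseason")
    root.addHandler(handler)
    prior_level = root.level
    root.setLevel(logging.INFO)
    summary = {"package_version": __version__, "config_digest": config.digest(),
               "seed": config.seed, "stages": list(config.stages)}
    try:
        _run_stages(config, run, summary)
    finally:
        root.removeHandler(handler)
        root.setLevel(prior_level)
        handler.close()
    with open(run / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    return run


def _run_stages(config: PipelineConfig, run: Path, summary: dict) -> None:
    counts = traits = sensor = series = None
    if config.traits_path:
        traits = TraitTable.from_csv(config.traits_path)
    else:
        traits = TraitTable.bundled()

    if "simulate" in config.stages:
        logger.info("stage simulate: seed=%d n_years=%.2f", config.seed, config.n_years)
        times = sample_schedule(config.n_years, config.seed)
        counts, count_truth = gen_counts(times, seed=config.seed, traits=traits)
        counts.to_csv(run / "counts.csv")
        count_truth.to_json(run / "truth_counts.json")
        traits.to_csv(run / "traits.csv")
        if "antecedent" in config.stages:
            start = counts.sample_dates[0] - pd.Timedelta(days=config.window_days + 1)
            end = counts.sample_dates[-1] + pd.Timedelta(days=1)
            sensor, sensor_truth = gen_sensor(start, end, seed=config.seed)
            sensor.to_csv(run / "sensor.csv")
            sensor_truth.to_json(run / "truth_sensor.json")
    else:
        if config.counts_path:
            counts = CountMatrix.from_csv(config.counts_path)
        if config.sensor_path:
            sensor = SensorSeries.from_csv(config.sensor_path)
        if config.series_path:
            series = IrregularSeries.from_csv(config.series_path)

    if "eqr" in config.stages:
        logger.info("stage eqr: expected_index=%.1f", config.expected_index)
        results, series = eqr_series(counts, traits, config.expected_index)
        out = results.copy()
        out.insert(0, "date", out.index.strftime("%Y-%m-%d"))
        out.to_csv(run / "eqr_samples.csv", index=False)
        series.to_csv(run / "eqr_series.csv", value_name="eqr")
        summary["status_counts"] = results["status"].value_counts().to_dict()
        summary["n_samples"] = int(len(results))

    if "asdhr" in config.stages:
        if series is None:
            raise ConfigError("asdhr stage needs the eqr stage or a series file")
        logger.info("stage asdhr: period=%.2f harmonics=%d", config.period,
                    config.n_harmonics)
        spec = default_spec(config.period, config.n_harmonics,
                            trend=config.trend_tvp, seasonal=config.seasonal_tvp)
        fit = fit_asdhr(series, spec)
        fit_to_frame(fit, config.band_level).to_csv(run / "asdhr_fit.csv", index=False)
        summary["asdhr"] = fit.summary()
        with open(run / "asdhr_summary.json", "w") as fh:
            json.dump(fit.summary(), fh, indent=1, sort_keys=True)

    env = None
    if "antecedent" in config.stages:
        logger.info("stage antecedent: window=%.1f d", config.window_days)
        dates = counts.sample_dates if counts is not None else series.dates
        env = build_env_matrix(sensor, dates, config.window_days,
                               config.min_coverage, tuple(config.log_vars),
                               config.log_a, config.log_b)
        out = env.copy()
        out.insert(0, "date", out.index.strftime("%Y-%m-%d"))
        out.to_csv(run / "env.csv", index=False)
        summary["n_env_samples"] = int(len(env))

    if "ordination" in config.stages:
        if counts is None:
            raise ConfigError("ordination stage needs a count matrix")
        logger.info("stage ordination: axes=%d", config.n_axes)
        from .antecedent import log_transform
        logged = pd.DataFrame(
            log_transform(counts.counts.to_numpy(dtype=float), config.log_a,
                          config.log_b),
            index=counts.sample_dates, columns=counts.taxon_codes)
        if env is not None:
            common = logged.index.intersection(env.dropna().index)
            logged_used = logged.loc[common]
        else:
            logged_used = logged
        result = pca_species(logged_used, config.n_axes, config.top_species)
        result.sample_scores.assign(
            date=result.sample_scores.index.strftime("%Y-%m-%d")
        ).to_csv(run / "ordination_samples.csv", index=False)
        result.species_scores.assign(fit=result.species_fit).to_csv(
            run / "ordination_species.csv", index_label="taxon")
        summary["eigenvalue_fractions"] = [float(v) for v in result.eigenvalue_fractions]
        summary["top_species"] = result.top_species
        if env is not None:
            arrows = project_env(result, env.dropna())
            arrows.to_csv(run / "env_arrows.csv", index_label="variable")
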