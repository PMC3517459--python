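"""Run configuration, end-to-end pipeline execution, and table rendering.

``run_full_pipeline`` executes split -> screen -> select -> score -> group
-> validate on a cohort read from disk or drawn from the synthetic
generator, and ``render_tables`` mirrors every artifact to delimited text
and JSON under the output directory.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .cohort import Cohort, characteristics_to_json, default_factors, read_cohort
from .model import SurvivalScoreModel, SurvivalScoreResults
from .score import DEFAULT_GROUPING, PrognosticGrouping
from .simulate import GeneratorConfig, generate_cohort, reference_calibration

log = logging.getLogger("sccscore")


@dataclass
class RunConfig:
    """Every pipeline knob in one place; YAML-loadable."""

    input_path: str | None = None          # cohort file; exclusive with simulate
    simulate: bool = False
    simulate_arm: str = "test"
    simulate_n: int = 216
    survival_mode: str = "stratum"
    seed: int = 1234
    delimiter: str = ","
    age_cut: int = 63
    vertebrae_cut: int = 2
    interval_cut_months: float = 15.0
    motor_deficit_cut_days: int = 14
    alpha_uni: float = 0.05
    alpha_mv: float = 0.05
    trend: float = 0.06
    grouping: list | None = None           # [[label, lo, hi], ...]; None = default
    points_from: str = "rounded"
    tolerance_pct: float = 10.0
    output_dir: str = "sccscore_out"
    verbosity: str = "INFO"

    def __post_init__(self):
        for name in ("alpha_uni", "alpha_mv", "trend"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0,1), got {v}")
        if self.trend < self.alpha_mv:
            raise ValueError("trend must be >= alpha_mv")
        if self.input_path is None and not self.simulate:
            raise ValueError("either input_path or simulate must be given")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def factor_defs(self):
        return default_factors(
            age_cut=self.age_cut,
            vertebrae_cut=self.vertebrae_cut,
            interval_cut_months=self.interval_cut_months,
            motor_deficit_cut_days=self.motor_deficit_cut_days,
        )

    def grouping_def(self) -> PrognosticGrouping | None:
        if self.grouping is None:
            return None
        return PrognosticGrouping(tuple((str(l), int(lo), int(hi))
                                        for l, lo, hi in self.grouping))


def _load_cohort(config: RunConfig) -> Cohort:
    if config.input_path is not None:
        return read_cohort(config.input_path, delimiter=config.delimiter)
    gen = reference_calibration(config.simulate_arm, seed=config.seed)
    gen = dataclasses.replace(gen, n=config.simulate_n, survival_mode=config.survival_mode)
    return generate_cohort(gen)


def run_full_pipeline(config: RunConfig) -> SurvivalScoreResults:
    """Execute the whole scoring pipeline under one config.

    Stage failures surface as exceptions naming the stage; randomness (the
    synthetic input, when used) flows only through ``config.seed``.
    """
    logging.basicConfig(level=config.verbosity,
                        format="%(asctime)s %(name)s %(levelname)s %(message)s")
    log.info("thresholds: alpha_uni=%g alpha_mv=%g trend=%g; seed=%d",
             config.alpha_uni, config.alpha_mv, config.trend, config.seed)
    cohort = _load_cohort(config)
    log.info("cohort loaded: n=%d (%s)", len(cohort), cohort.label)
    model = SurvivalScoreModel(
        cohort,
        factors=config.factor_defs(),
        alpha_uni=config.alpha_uni,
        alpha_mv=config.alpha_mv,
        trend=config.trend,
        grouping=config.grouping_def(),
        points_from=config.points_from,
        tolerance_pct=config.tolerance_pct,
    )
    results = model.fit()
    log.info("score built on %d factors; range %d-%d",
             len(results.selected_factors),
             results.score_range.min_total, results.score_range.max_total)
    return results


def render_tables(results: SurvivalScoreResults, outdir: str | Path) -> list[Path]:
    """Write every available artifact as delimited text (+ JSON mirrors).

    A partially-filled results object renders whatever it has and warns
    about the rest.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _write(name, text):
        p = outdir / name
        p.write_text(text)
        written.append(p)

    def _csv(name, frame):
        p = outdir / name
        frame.to_csv(p, index=False)
        written.append(p)

    pieces = [
        ("characteristics.csv", lambda: results.characteristics, "csv"),
        ("characteristics.json",
         lambda: characteristics_to_json(results.characteristics), "text"),
        ("univariate.csv", lambda: results.screen.to_frame(), "csv"),
        ("cox.csv", lambda: results.cox.to_frame(), "csv"),
        ("score_table.csv", lambda: results.score_table.to_frame(), "csv"),
        ("score_table.json", lambda: results.score_table.to_json(), "text"),
        ("groups.csv", lambda: results.test_groups.to_frame(), "csv"),
        ("validation.csv", lambda: results.validation_report.to_frame(), "csv"),
        ("validation.json", lambda: results.validation_report.to_json(), "text"),
        ("summary.txt", lambda: results.summary(), "text"),
    ]
    for name, make, kind in pieces:
        try:
            obj = make()
        except Exception as exc:  # partial bundle: render what exists
            warnings.warn(f"skipping {name}: {exc}", stacklevel=2)
            continue
        (_csv if kind == "csv" else _write)(name, obj)

    for arm in ("test", "validation"):
        try:
            for g, frame in results.group_km_frames(arm).items():
                _csv(f"km_group_{g}_{arm}.csv", frame)
        except Exception as exc:
            warnings.warn(f"skipping KM export for {arm} arm: {exc}", stacklevel=2)

    _write("run_log.json", json.dumps({
        "timestamp": datetime.datetime.now().isoformat(timespec="seconds"),
        "alpha_uni": results.model.alpha_uni,
        "alpha_mv": results.model.alpha_mv,
        "trend": results.model.trend,
        "points_from": results.model.points_from,
        "tolerance_pct": results.model.tolerance_pct,
        "n_test": len(results.test),
        "n_validation": len(results.validation),
        "selected_factors": [f.name for f in results.selected_factors],
    }, indent=2))
    return written
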