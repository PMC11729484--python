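"""File formats, run configuration and report assembly.

All tabular interchange is RFC-4180 CSV, UTF-8, '.' decimal separator, so
golden files stay bit-stable across platforms.  Schemas:

``sets.csv``
    participant,condition,reps,mass_kg,distance_m,exo_moment_nm,excluded
``tasks.csv``
    participant,condition,mass_kg,distance_m,repetitions,period_s,exo_moment_nm
``band_curve.csv``
    displacement_m,force_n[,branch]   with branch in {loading, unloading}

Run configuration is a YAML file validated against :class:`RunConfig`
(unknown keys rejected; every length/mass/moment key carries its unit
suffix).  :func:`run_report` ties the stages together: read or generate a
case series, analyze every participant, and write the per-participant,
summary, sweep, breakeven and scenario tables with deterministic ordering.
Percent and Nm values are written at full precision — rounding to the
paper-style integer presentation happens only in the human-readable log.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, ValidationError

from ._errors import ConfigError, DomainError, SchemaError
from .case_series import (
    LiftingSet,
    ParticipantResult,
    analyze_sets,
    summarize_series,
)
from .damage import GRAVITY, DamageParams, LiftTask
from .exo import BandCurve, ExoSpec, effective_exo_moment
from .sweeps import breakeven_curve, damage_change_grid, productivity_scenarios
from .synth import GeneratorConfig, generate_band_curve, generate_case_series

__all__ = [
    "SETS_COLUMNS",
    "TASKS_COLUMNS",
    "read_sets_csv",
    "write_sets_csv",
    "read_tasks_csv",
    "read_band_curve_csv",
    "write_band_curve_csv",
    "read_exo_yaml",
    "results_to_dataframe",
    "summaries_to_dataframe",
    "DamageConfig",
    "ExoConfig",
    "SweepConfig",
    "SynthConfig",
    "RunConfig",
    "load_run_config",
    "run_report",
]

logger = logging.getLogger("liftrisk")

SETS_COLUMNS = [
    "participant",
    "condition",
    "reps",
    "mass_kg",
    "distance_m",
    "exo_moment_nm",
    "excluded",
]
TASKS_COLUMNS = [
    "participant",
    "condition",
    "mass_kg",
    "distance_m",
    "repetitions",
    "period_s",
    "exo_moment_nm",
]

_TRUE = {"true", "1", "yes"}
_FALSE = {"false", "0", "no", ""}


def _parse_int(value: str, what: str, row: int) -> int:
    try:
        as_float = float(value)
    except (TypeError, ValueError):
        raise SchemaError(f"row {row}: {what} {value!r} is not a number") from None
    if as_float != int(as_float):
        raise SchemaError(f"row {row}: {what} {value!r} must be an integer")
    return int(as_float)


def _parse_float(value: str, what: str, row: int) -> float:
    try:
        return float(value)
    except (TypeError, ValueError):
        raise SchemaError(f"row {row}: {what} {value!r} is not a number") from None


def read_sets_csv(path) -> List[LiftingSet]:
    """Read and validate a ``sets.csv``; errors cite the offending row.

    Row numbers are 1-based data rows (the header is row 0).  The
    ``excluded`` column is optional and defaults to false.
    """
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except FileNotFoundError:
        raise SchemaError(f"sets file not found: {path}") from None
    required = [c for c in SETS_COLUMNS if c != "excluded"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"sets file {path} missing columns: {missing}")
    sets: List[LiftingSet] = []
    for i, rec in enumerate(df.to_dict("records"), start=1):
        excl_raw = str(rec.get("excluded", "")).strip().lower()
        if excl_raw in _TRUE:
            excluded = True
        elif excl_raw in _FALSE:
            excluded = False
        else:
            raise SchemaError(f"row {i}: excluded flag {rec['excluded']!r} not boolean")
        try:
            sets.append(
                LiftingSet(
                    participant=str(rec["participant"]),
                    condition=str(rec["condition"]),
                    reps=_parse_int(rec["reps"], "reps", i),
                    mass=_parse_float(rec["mass_kg"], "mass_kg", i),
                    distance=_parse_float(rec["distance_m"], "distance_m", i),
                    exo_moment=_parse_float(rec["exo_moment_nm"], "exo_moment_nm", i),
                    excluded=excluded,
                )
            )
        except (SchemaError, DomainError) as exc:
            raise SchemaError(f"row {i}: {exc}") from None
    return sets


def write_sets_csv(sets: Sequence[LiftingSet], path) -> None:
    """Write lifting sets in the canonical column order."""
    df = pd.DataFrame(
        {
            "participant": [s.participant for s in sets],
            "condition": [s.condition for s in sets],
            "reps": [s.reps for s in sets],
            "mass_kg": [s.mass for s in sets],
            "distance_m": [s.distance for s in sets],
            "exo_moment_nm": [s.exo_moment for s in sets],
            "excluded": [str(s.excluded).lower() for s in sets],
        }
    )
    df.to_csv(path, index=False, lineterminator="\n")


def read_tasks_csv(path) -> List[Tuple[str, str, LiftTask, float]]:
    """Read a ``tasks.csv``; returns (participant, condition, task, exo_moment)."""
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except FileNotFoundError:
        raise SchemaError(f"tasks file not found: {path}") from None
    missing = [c for c in TASKS_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"tasks file {path} missing columns: {missing}")
    out = []
    for i, rec in enumerate(df.to_dict("records"), start=1):
        try:
            task = LiftTask(
                mass=_parse_float(rec["mass_kg"], "mass_kg", i),
                distance=_parse_float(rec["distance_m"], "distance_m", i),
                repetitions=_parse_int(rec["repetitions"], "repetitions", i),
                period=_parse_float(rec["period_s"], "period_s", i),
            )
        except DomainError as exc:
            raise SchemaError(f"row {i}: {exc}") from None
        out.append(
            (
                str(rec["participant"]),
                str(rec["condition"]),
                task,
                _parse_float(rec["exo_moment_nm"], "exo_moment_nm", i),
            )
        )
    return out


def read_band_curve_csv(path) -> BandCurve:
    """Read a band force-displacement curve, optionally with both branches."""
    try:
        df = pd.read_csv(path)
    except FileNotFoundError:
        raise SchemaError(f"band-curve file not found: {path}") from None
    for col in ("displacement_m", "force_n"):
        if col not in df.columns:
            raise SchemaError(f"band-curve file {path} missing column {col!r}")
    if "branch" in df.columns:
        bad = set(df["branch"]) - {"loading", "unloading"}
        if bad:
            raise SchemaError(f"unknown branch labels {sorted(bad)} in {path}")
        load = df[df["branch"] == "loading"]
        unload = df[df["branch"] == "unloading"]
        if load.empty:
            raise SchemaError(f"band-curve file {path} has no loading branch")
        if unload.empty:
            return BandCurve(load["displacement_m"].values, load["force_n"].values)
        return BandCurve(
            load["displacement_m"].values,
            load["force_n"].values,
            unload["displacement_m"].values,
            unload["force_n"].values,
        )
    return BandCurve(df["displacement_m"].values, df["force_n"].values)


def write_band_curve_csv(curve: BandCurve, path) -> None:
    frames = [
        pd.DataFrame(
            {
                "displacement_m": curve.displacement,
                "force_n": curve.force,
                "branch": "loading",
            }
        )
    ]
    if curve.unload_force is not None:
        frames.append(
            pd.DataFrame(
                {
                    "displacement_m": curve.unload_displacement,
                    "force_n": curve.unload_force,
                    "branch": "unloading",
                }
            )
        )
    pd.concat(frames).to_csv(path, index=False, lineterminator="\n")


def read_exo_yaml(path, band_curve: Optional[BandCurve] = None) -> ExoSpec:
    """Build an :class:`ExoSpec` from a YAML block (unit-suffixed keys).

    The band curve is read from the ``band_curve_csv`` key unless supplied
    directly.
    """
    try:
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
    except FileNotFoundError:
        raise ConfigError(f"exo config not found: {path}") from None
    if not isinstance(raw, dict):
        raise ConfigError(f"exo config {path} is not a mapping")
    cfg = ExoConfig.from_mapping(raw)
    if band_curve is None:
        if cfg.band_curve_csv is None:
            raise ConfigError("no band curve supplied (band_curve_csv missing)")
        band_curve = read_band_curve_csv(Path(path).parent / cfg.band_curve_csv)
    return cfg.to_spec(band_curve)


def results_to_dataframe(results: Sequence[ParticipantResult]) -> pd.DataFrame:
    """Tidy per-participant table: one row per participant-metric."""
    rows = []
    for r in results:
        metrics: Dict[str, Optional[float]] = {
            "exo_moment_nm": r.exo_moment,
            "pct_reps_vs_a1": r.pct_reps_vs_a1,
            "pct_reps_vs_a2": r.pct_reps_vs_a2,
            "pct_reps_vs_mean_controls": r.pct_reps_vs_mean_controls,
            "pct_damage_vs_a1": r.pct_damage_vs_a1,
            "pct_damage_vs_a2": r.pct_damage_vs_a2,
            "pct_damage_vs_mean_controls": r.pct_damage_vs_mean_controls,
            "damage_control_mean": r.damage_control_mean,
            "damage_exo_mean": r.damage_exo_mean,
            "reversal_reps": None if r.reversal_reps is None else float(r.reversal_reps),
            "reversal_damage": (
                None if r.reversal_damage is None else float(r.reversal_damage)
            ),
        }
        for metric, value in metrics.items():
            if value is None:
                continue
            rows.append(
                {
                    "participant": r.participant,
                    "design": r.design,
                    "excluded": str(r.excluded).lower(),
                    "metric": metric,
                    "value": value,
                }
            )
    return pd.DataFrame(rows)


def summaries_to_dataframe(results: Sequence[ParticipantResult]) -> pd.DataFrame:
    """Reps and damage series summaries as one tidy table."""
    rows = []
    for metric in ("reps", "damage"):
        s = summarize_series(results, metric)
        rows.append(
            {
                "metric": metric,
                "n_participants": s.n_participants,
                "n_increase": s.n_increase,
                "n_decrease": s.n_decrease,
                "range_low_pct": s.range_low,
                "range_high_pct": s.range_high,
                "mean_pct": s.mean,
                "n_reversal_confirmed": (
                    "" if s.n_reversal_confirmed is None else s.n_reversal_confirmed
                ),
            }
        )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# run configuration


class _StrictModel(BaseModel):
    model_config = ConfigDict(extra="forbid")


class DamageConfig(_StrictModel):
    gravity: float = GRAVITY
    sn_intercept: float = 9.0
    sn_slope: float = 0.0165
    moment_to_load_offset: float = 0.0
    moment_to_load_gain: float = 1.0
    power_exponent_C: float = 6.0

    def to_params(self) -> DamageParams:
        try:
            return DamageParams(
                gravity=self.gravity,
                sn_intercept=self.sn_intercept,
                sn_slope=self.sn_slope,
                moment_to_load_offset=self.moment_to_load_offset,
                moment_to_load_gain=self.moment_to_load_gain,
                power_exponent_C=self.power_exponent_C,
            )
        except DomainError as exc:
            raise ConfigError(str(exc)) from None


class ExoConfig(_StrictModel):
    max_stretch_m: float
    l5s1_to_skin_m: float
    skin_to_band_m: float
    device_mass_kg: float
    device_com_distance_m: float
    hysteresis_factor: float = 1.0
    timing_factor: float = 1.0
    band_curve_csv: Optional[str] = None

    @classmethod
    def from_mapping(cls, raw: dict) -> "ExoConfig":
        try:
            return cls(**raw)
        except ValidationError as exc:
            raise ConfigError(f"invalid exo config: {exc}") from None

    def to_spec(self, band_curve: BandCurve) -> ExoSpec:
        try:
            return ExoSpec(
                band_curve=band_curve,
                max_stretch=self.max_stretch_m,
                l5s1_to_skin=self.l5s1_to_skin_m,
                skin_to_band=self.skin_to_band_m,
                device_mass=self.device_mass_kg,
                device_com_distance=self.device_com_distance_m,
                hysteresis_factor=self.hysteresis_factor,
                timing_factor=self.timing_factor,
            )
        except DomainError as exc:
            raise ConfigError(str(exc)) from None


class SweepConfig(_StrictModel):
    exo_max_nm: float = 50.0
    exo_step_nm: float = 1.0
    increase_max_pct: float = 100.0
    increase_step_pct: float = 1.0
    nominal_masses_kg: List[float] = [5.0, 23.0, 45.0]
    distance_m: float = 0.60
    nominal_repetitions: int = 1000

    def exo_axis(self) -> np.ndarray:
        return np.arange(0.0, self.exo_max_nm + 1e-9, self.exo_step_nm)

    def increase_axis(self) -> np.ndarray:
        return np.arange(0.0, self.increase_max_pct + 1e-9, self.increase_step_pct)


class SynthConfig(_StrictModel):
    n_participants: int = 4
    design: str = "ABA"
    baseline_mean_reps: float = 14.0
    baseline_dispersion: float = 0.15
    exo_effect_multiplier: float = 1.34
    effect_sd: float = 0.15
    set_noise_sd: float = 0.05
    nonresponder_prob: float = 0.125
    nonresponder_multiplier: float = 0.7
    exo_moment_range_nm: List[float] = [27.0, 42.0]
    task_mass_kg: float = 55.0
    distance_range_m: List[float] = [0.55, 0.75]
    period_s: float = 6.0

    def to_generator_config(self, seed: int) -> GeneratorConfig:
        try:
            return GeneratorConfig(
                n_participants=self.n_participants,
                design=self.design,
                baseline_mean_reps=self.baseline_mean_reps,
                baseline_dispersion=self.baseline_dispersion,
                exo_effect_multiplier=self.exo_effect_multiplier,
                effect_sd=self.effect_sd,
                set_noise_sd=self.set_noise_sd,
                nonresponder_prob=self.nonresponder_prob,
                nonresponder_multiplier=self.nonresponder_multiplier,
                exo_moment_range=tuple(self.exo_moment_range_nm),
                task_mass_kg=self.task_mass_kg,
                distance_range_m=tuple(self.distance_range_m),
                period_s=self.period_s,
                seed=seed,
            )
        except ConfigError:
            raise


class RunConfig(_StrictModel):
    """Top-level run configuration; unknown keys are rejected."""

    damage: DamageConfig = DamageConfig()
    sweep: SweepConfig = SweepConfig()
    synth: Optional[SynthConfig] = None
    sets_csv: Optional[str] = None
    out_dir: str = "liftrisk_out"
    seed: int = 0
    log_level: str = "INFO"


def load_run_config(path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    try:
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
    except FileNotFoundError:
        raise ConfigError(f"config file not found: {path}") from None
    except yaml.YAMLError as exc:
        raise ConfigError(f"malformed YAML in {path}: {exc}") from None
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"config {path} is not a mapping")
    try:
        return RunConfig(**raw)
    except ValidationError as exc:
        raise ConfigError(f"invalid run config: {exc}") from None


def _float_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, lineterminator="\n")


def run_report(config: RunConfig, out_dir: Optional[Path] = None) -> Dict[str, Path]:
    """Run the full pipeline and write every report table.

    Reads (or synthesises) a case series, analyzes every participant,
    computes the sweep grids, breakeven curves and the four-scenario table,
    and writes them under ``out_dir`` with deterministic ordering.  Returns
    the mapping of artifact name to file path.  Re-running with the same
    config and inputs is byte-identical.
    """
    out = Path(out_dir if out_dir is not None else config.out_dir)
    params = config.damage.to_params()

    if config.synth is not None:
        sets = generate_case_series(config.synth.to_generator_config(config.seed))
        logger.info("generated synthetic case series: %d sets", len(sets))
    elif config.sets_csv is not None:
        sets = read_sets_csv(config.sets_csv)
        logger.info("read %d sets from %s", len(sets), config.sets_csv)
    else:
        raise ConfigError("run config needs either a synth block or sets_csv")
    if not sets:
        raise SchemaError("empty case series: no lifting sets to analyze")

    sets = sorted(sets, key=lambda s: (s.participant, s.condition))
    results = analyze_sets(sets, params)
    active = [r for r in results if not r.excluded]
    if not active:
        raise SchemaError("all participants are excluded; nothing to summarize")

    out.mkdir(parents=True, exist_ok=True)
    paths: Dict[str, Path] = {}

    paths["sets"] = out / "sets.csv"
    write_sets_csv(sets, paths["sets"])
    paths["participants"] = out / "participants.csv"
    _float_csv(results_to_dataframe(results), paths["participants"])
    paths["summary"] = out / "summary.csv"
    _float_csv(summaries_to_dataframe(active), paths["summary"])

    sw = config.sweep
    exo_axis, inc_axis = sw.exo_axis(), sw.increase_axis()
    rep_task = LiftTask(sw.nominal_masses_kg[0], sw.distance_m, sw.nominal_repetitions)
    grid = damage_change_grid("repetitions", rep_task, exo_axis, inc_axis, params)
    paths["sweep_repetitions"] = out / "sweep_repetitions.csv"
    _float_csv(grid.to_dataframe(), paths["sweep_repetitions"])
    for mass in sw.nominal_masses_kg:
        task = LiftTask(mass, sw.distance_m, sw.nominal_repetitions)
        grid = damage_change_grid("weight", task, exo_axis, inc_axis, params)
        key = f"sweep_weight_{mass:g}kg"
        paths[key] = out / f"{key}.csv"
        _float_csv(grid.to_dataframe(), paths[key])

    paths["breakeven_repetitions"] = out / "breakeven_repetitions.csv"
    _float_csv(
        breakeven_curve(
            "repetitions", inc_axis, sw.nominal_masses_kg[0], sw.distance_m, params
        ).to_dataframe(),
        paths["breakeven_repetitions"],
    )
    for mass in sw.nominal_masses_kg:
        key = f"breakeven_weight_{mass:g}kg"
        paths[key] = out / f"{key}.csv"
        _float_csv(
            breakeven_curve("weight", inc_axis, mass, sw.distance_m, params)
            .to_dataframe(),
            paths[key],
        )

    paths["scenarios"] = out / "scenarios.csv"
    _float_csv(productivity_scenarios(params), paths["scenarios"])

    for metric in ("reps", "damage"):
        s = summarize_series(active, metric)
        logger.info(
            "%s: %d up / %d down, range [%.0f, %.0f]%%, mean %.0f%%, reversals %s",
            metric, s.n_increase, s.n_decrease, s.range_low, s.range_high,
            s.mean, s.n_reversal_confirmed,
        )
    return paths
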