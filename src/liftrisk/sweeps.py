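"""Parameter sweeps and breakeven analysis.

How do exo assistance, lifting repetitions and object weight interact to
change cumulative back damage?  This module sweeps percent increases in
performance (repetitions or object weight) against exo moment, expressing
every cell as the percent change in cumulative damage relative to the
nominal no-exo task, and extracts the breakeven (zero-change) contours.

Under the log-linear S-N form the repetition breakeven has the closed form

    increase% = 100 * (10 ** (sn_slope * gain * M_exo) - 1)

independent of the nominal task, while the weight breakeven is the
model-independent ``increase% = 100 * M_exo / M`` (the extra weight must
restore exactly the moment the exo removed, for any strictly monotone
per-lift damage).  A Brent root-finder fallback covers non-affine
moment-to-load maps and doubles as an independent cross-check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Optional

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from ._errors import DomainError
from .damage import (
    DamageParams,
    LiftTask,
    cumulative_damage,
    load_moment,
    per_lift_damage,
)

__all__ = [
    "SweepGrid",
    "BreakevenCurve",
    "damage_change_grid",
    "breakeven_rep_increase",
    "breakeven_weight_increase",
    "breakeven_curve",
    "required_exo_moment",
    "productivity_scenarios",
]

Mode = Literal["repetitions", "weight"]

_MODES = ("repetitions", "weight")


def _check_mode(mode: str) -> None:
    if mode not in _MODES:
        raise DomainError(f"mode must be one of {_MODES}, got {mode!r}")


@dataclass(frozen=True)
class SweepGrid:
    """Damage-change surface over exo moment x performance increase.

    ``values[i, j]`` is the percent change in cumulative damage at
    ``exo_moments[i]`` and ``increases[j]`` relative to the nominal no-exo
    task; non-increasing along the exo axis and non-decreasing along the
    increase axis.
    """

    mode: str
    nominal_mass: float
    distance: float
    exo_moments: np.ndarray
    increases: np.ndarray
    values: np.ndarray

    def to_dataframe(self) -> pd.DataFrame:
        """Long-format table: exo_moment_nm, increase_pct, damage_change_pct."""
        mm, xx = np.meshgrid(self.exo_moments, self.increases, indexing="ij")
        return pd.DataFrame(
            {
                "exo_moment_nm": mm.ravel(),
                "increase_pct": xx.ravel(),
                "damage_change_pct": self.values.ravel(),
            }
        )


@dataclass(frozen=True)
class BreakevenCurve:
    """Zero-damage-change contour: required exo moment per increase level."""

    mode: str
    nominal_mass: float
    distance: float
    increases: np.ndarray
    required_exo_moments: np.ndarray

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "increase_pct": self.increases,
                "required_exo_moment_nm": self.required_exo_moments,
            }
        )


def damage_change_grid(
    mode: Mode,
    task: LiftTask,
    exo_moments: np.ndarray,
    increases: np.ndarray,
    params: DamageParams,
) -> SweepGrid:
    """Percent damage change vs the nominal no-exo task over a full grid.

    Repetition mode scales lift count by ``1 + x/100``; weight mode scales
    object mass.  All cells are ratios against the same nominal damage, so
    the result is invariant to the nominal repetition count.  In repetition
    mode the nominal moment cancels out of the damage ratio, so (for affine
    moment maps) the cell is computed directly as
    ``(1 + x/100) * 10**(-sn_slope*gain*M_exo)`` — independent of the
    nominal mass, with the exponential S-N form extended over the
    over-assistance corner where the exo moment exceeds the load moment.
    In weight mode (and for non-affine maps) effective moments are floored
    at zero.
    """
    _check_mode(mode)
    exo_moments = np.asarray(exo_moments, dtype=float)
    increases = np.asarray(increases, dtype=float)
    if exo_moments.size == 0 or increases.size == 0:
        raise DomainError("sweep axes must be non-empty")
    m_nom = load_moment(task.mass, task.distance, params.gravity)
    d_nom = per_lift_damage(m_nom, params)
    if d_nom == 0:
        raise DomainError("nominal task produces zero damage; no reference")
    mm, xx = np.meshgrid(exo_moments, increases, indexing="ij")
    if mode == "repetitions":
        if params.is_affine:
            ratio = (1.0 + xx / 100.0) * 10.0 ** (
                -params.sn_slope * params.moment_to_load_gain * mm
            )
        else:
            eff = np.maximum(m_nom - mm, 0.0)
            ratio = (1.0 + xx / 100.0) * per_lift_damage(eff, params) / d_nom
    else:
        eff = np.maximum(m_nom * (1.0 + xx / 100.0) - mm, 0.0)
        ratio = per_lift_damage(eff, params) / d_nom
    return SweepGrid(
        mode=mode,
        nominal_mass=task.mass,
        distance=task.distance,
        exo_moments=exo_moments,
        increases=increases,
        values=100.0 * (ratio - 1.0),
    )


def breakeven_rep_increase(
    exo_moment: float,
    params: DamageParams,
    task: Optional[LiftTask] = None,
    tol: float = 1e-9,
) -> float:
    """Repetition increase (%) that exactly offsets the exo's damage reduction.

    Closed form ``100 * (10**(sn_slope*gain*M_exo) - 1)`` for affine
    moment-to-load maps — independent of the nominal task.  With a callable
    map a nominal task is required and the breakeven is found by Brent
    root-finding to ``tol``.
    """
    if exo_moment < 0:
        raise DomainError(f"exo_moment must be >= 0 Nm, got {exo_moment}")
    if params.is_affine:
        return 100.0 * (
            10.0 ** (params.sn_slope * params.moment_to_load_gain * exo_moment) - 1.0
        )
    if task is None:
        raise DomainError("a nominal task is required for non-affine moment maps")
    m_nom = load_moment(task.mass, task.distance, params.gravity)
    if exo_moment > m_nom:
        raise DomainError(
            f"exo_moment {exo_moment} Nm exceeds nominal load moment {m_nom} Nm"
        )
    d_nom = per_lift_damage(m_nom, params)
    d_exo = per_lift_damage(m_nom - exo_moment, params)
    if d_exo == 0:
        raise DomainError("per-lift damage with exo is zero; breakeven undefined")
    # (1 + x/100) * d_exo = d_nom  =>  linear in x; solve directly but via
    # brentq for symmetry with the documented fallback contract.
    hi = 100.0 * (d_nom / d_exo - 1.0) + 1.0
    return float(
        brentq(
            lambda x: (1.0 + x / 100.0) * d_exo - d_nom,
            0.0,
            max(hi, 1.0),
            xtol=tol,
        )
    )


def breakeven_weight_increase(
    exo_moment: float,
    nominal_mass: float,
    distance: float,
    params: DamageParams,
    numeric: bool = False,
    tol: float = 1e-9,
) -> float:
    """Weight increase (%) that exactly offsets the exo's damage reduction.

    Solves ``damage(M*(1+x/100) - M_exo) = damage(M)``; for any strictly
    monotone per-lift damage the solution is the closed form
    ``x = 100 * M_exo / M``.  ``numeric=True`` uses the Brent root-finder
    instead (cross-check / non-monotone safety net).
    """
    if exo_moment < 0:
        raise DomainError(f"exo_moment must be >= 0 Nm, got {exo_moment}")
    m_nom = load_moment(nominal_mass, distance, params.gravity)
    if m_nom == 0:
        raise DomainError("nominal load moment is zero; weight breakeven undefined")
    closed = 100.0 * exo_moment / m_nom
    if not numeric:
        return closed
    d_nom = per_lift_damage(m_nom, params)

    def f(x: float) -> float:
        return per_lift_damage(max(m_nom * (1 + x / 100.0) - exo_moment, 0.0), params) - d_nom

    return float(brentq(f, 0.0, closed * 2.0 + 1.0, xtol=tol))


def required_exo_moment(
    increase: float,
    mode: Mode,
    nominal_mass: float,
    distance: float,
    params: DamageParams,
) -> float:
    """Exo moment (Nm) needed to hold cumulative damage constant.

    Inverse of the breakeven operations: for a weight increase the exo must
    absorb exactly the added load moment (proportional to nominal mass);
    for a repetition increase, ``log10(1 + x/100) / (sn_slope * gain)`` —
    independent of nominal mass.
    """
    _check_mode(mode)
    if increase < 0:
        raise DomainError(f"increase must be >= 0 %, got {increase}")
    if mode == "weight":
        m_nom = load_moment(nominal_mass, distance, params.gravity)
        return 0.01 * increase * m_nom
    if not params.is_affine:
        raise DomainError(
            "closed-form repetition inverse requires an affine moment map"
        )
    return math.log10(1.0 + increase / 100.0) / (
        params.sn_slope * params.moment_to_load_gain
    )


def breakeven_curve(
    mode: Mode,
    increases: np.ndarray,
    nominal_mass: float,
    distance: float,
    params: DamageParams,
) -> BreakevenCurve:
    """Zero-change contour sampled at the given increase levels."""
    increases = np.asarray(increases, dtype=float)
    req = np.array(
        [
            required_exo_moment(x, mode, nominal_mass, distance, params)
            for x in increases
        ]
    )
    return BreakevenCurve(
        mode=mode,
        nominal_mass=nominal_mass,
        distance=distance,
        increases=increases,
        required_exo_moments=req,
    )


def productivity_scenarios(
    params: DamageParams,
    mass: float = 22.7,
    distance: float = 0.70,
    repetitions: int = 1000,
    exo_moment: float = 30.0,
    increase_pct: float = 20.0,
) -> pd.DataFrame:
    """Four-scenario comparison of repetition vs weight productivity gains.

    A: nominal task, no exo.  B: same task with the exo.  C: exo plus a
    repetition increase.  D: exo plus the same percent weight increase.
    Damage changes are relative to scenario A.  Defaults: a 50 lb (22.7 kg)
    object at 70 cm lifted 1000 times with a 30 Nm exo moment and a 20%
    productivity increase.
    """
    scale = 1.0 + increase_pct / 100.0
    tasks = {
        "A": (LiftTask(mass, distance, repetitions), 0.0, "nominal, no exo"),
        "B": (LiftTask(mass, distance, repetitions), exo_moment, "exo, same task"),
        "C": (
            LiftTask(mass, distance, round(repetitions * scale)),
            exo_moment,
            f"exo, +{increase_pct:g}% repetitions",
        ),
        "D": (
            LiftTask(mass * scale, distance, repetitions),
            exo_moment,
            f"exo, +{increase_pct:g}% weight",
        ),
    }
    nominal = cumulative_damage(tasks["A"][0], 0.0, params).cumulative_damage
    rows = []
    for name, (task, exo, desc) in tasks.items():
        res = cumulative_damage(task, exo, params)
        rows.append(
            {
                "scenario": name,
                "description": desc,
                "mass_kg": task.mass,
                "repetitions": task.repetitions,
                "exo_moment_nm": exo,
                "cumulative_damage": res.cumulative_damage,
                "damage_change_pct": 100.0
                * (res.cumulative_damage - nominal)
                / nominal,
            }
        )
    return pd.DataFrame(rows)
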