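"""Fatigue-failure cumulative damage model of the low back during lifting.

The low back is treated as a mechanical structure subject to fatigue: every
lift applies a peak lumbar moment, an S-N (load versus cycles-to-failure)
relationship converts that moment into the fraction of fatigue life consumed
by one lift, and damage accumulates linearly over lifts (Palmgren-Miner
rule).  A back exosuit contributes an assistive lumbar extension moment that
is subtracted from the load moment before the S-N lookup, which is why even
modest assistance produces large damage reductions: per-lift damage grows
exponentially with peak moment while total damage grows only linearly with
repetitions.

Model summary
-------------
peak load moment      ``M = m g d``  (object mass x gravity x horizontal
                      object-to-hip distance; surrogate for peak low-back
                      loading at the deepest part of the lift)
effective moment      ``M_eff = max(M - M_exo, 0)``
cycles to failure     ``log10 N_f = a - b * L(M_eff)`` with intercept ``a``,
                      slope ``b`` (per Nm) and an optional affine map ``L``
                      from lumbar moment to the tissue load driving fatigue
per-lift damage       ``D_1 = 1 / N_f`` (capped at 1)
cumulative damage     ``D = n * D_1`` for ``n`` repetitions

The default slope ``b = 0.0165`` per Nm is the value over-determined by the
breakeven behaviour of the fatigue-failure ergonomic assessment the model
reproduces (a 15.3 Nm assistive moment is offset by a 79% repetition
increase, 42.3 Nm by 399%).  The intercept only sets the absolute damage
scale and cancels in every percent-change output.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Union

import numpy as np

from ._errors import DomainError, UndefinedComparisonError

__all__ = [
    "GRAVITY",
    "LB_TO_KG",
    "DEFAULT_SN_SLOPE",
    "DEFAULT_SN_INTERCEPT",
    "ClampWarning",
    "DamageCapWarning",
    "LiftTask",
    "DamageParams",
    "DamageResult",
    "load_moment",
    "effective_moment",
    "per_lift_damage",
    "cumulative_damage",
    "percent_change_damage",
    "power_law_damage_ratio",
]

#: Standard gravitational acceleration, m/s^2.
GRAVITY = 9.81

#: Pounds-to-kilograms conversion, applied only at interface boundaries.
LB_TO_KG = 0.45359237

#: Default decline of log10(cycles-to-failure) per Nm of lumbar moment.
DEFAULT_SN_SLOPE = 0.0165

#: Default log10(cycles-to-failure) at zero effective load.  Pure scale
#: constant: cancels in all damage ratios and percent changes.  Chosen so
#: N_f stays above one cycle for lumbar moments up to ~545 Nm, beyond the
#: whole envelope swept by the breakeven analyses.
DEFAULT_SN_INTERCEPT = 9.0

ArrayLike = Union[float, np.ndarray]


class ClampWarning(UserWarning):
    """Exo assistance exceeded the load moment; effective moment clamped at 0."""


class DamageCapWarning(UserWarning):
    """Parameters implied N_f < 1; per-lift damage capped at 1."""


@dataclass(frozen=True)
class LiftTask:
    """One lifting condition.

    Parameters
    ----------
    mass : float
        Object mass, kg.
    distance : float
        Maximum horizontal object-to-hip distance, m.
    repetitions : int
        Number of lifts performed.
    period : float
        Seconds per lift (cadence), default 6 s (10 lifts/min).
    """

    mass: float
    distance: float
    repetitions: int
    period: float = 6.0

    def __post_init__(self) -> None:
        if self.mass < 0:
            raise DomainError(f"mass must be >= 0 kg, got {self.mass}")
        if self.distance < 0:
            raise DomainError(f"distance must be >= 0 m, got {self.distance}")
        if self.repetitions < 0 or self.repetitions != int(self.repetitions):
            raise DomainError(
                f"repetitions must be a non-negative integer, got {self.repetitions}"
            )
        if self.period <= 0:
            raise DomainError(f"period must be > 0 s, got {self.period}")

    @property
    def duration(self) -> float:
        """Total bout duration, s."""
        return self.repetitions * self.period


@dataclass(frozen=True)
class DamageParams:
    """Constants of the moment -> per-lift-damage relationship.

    ``moment_to_load_offset`` / ``moment_to_load_gain`` define an affine map
    from lumbar moment (Nm) to the tissue load consumed by the S-N curve;
    the identity default routes the moment straight through.  Some
    fatigue-failure formulations instead regress moment onto compressive
    force — supply the affine coefficients (offsets cancel in all
    ratio-based outputs) or, for a non-affine map, ``moment_to_load_fn``.

    ``power_exponent_C`` is the tissue-specific constant of the alternative
    force^C damage relationship; mechanical fatigue studies place it between
    4 and 9 depending on tissue.
    """

    gravity: float = GRAVITY
    sn_intercept: float = DEFAULT_SN_INTERCEPT
    sn_slope: float = DEFAULT_SN_SLOPE
    moment_to_load_offset: float = 0.0
    moment_to_load_gain: float = 1.0
    moment_to_load_fn: Optional[Callable[[float], float]] = field(
        default=None, compare=False
    )
    power_exponent_C: float = 6.0

    def __post_init__(self) -> None:
        if self.gravity <= 0:
            raise DomainError(f"gravity must be > 0, got {self.gravity}")
        if self.sn_slope <= 0:
            raise DomainError(f"sn_slope must be > 0, got {self.sn_slope}")
        if self.moment_to_load_fn is None and self.moment_to_load_gain <= 0:
            raise DomainError(
                f"moment_to_load_gain must be > 0, got {self.moment_to_load_gain}"
            )
        if not (4.0 <= self.power_exponent_C <= 9.0):
            warnings.warn(
                f"power_exponent_C={self.power_exponent_C} is outside the "
                "empirically supported range [4, 9]",
                UserWarning,
                stacklevel=2,
            )

    @property
    def is_affine(self) -> bool:
        """True when the moment -> load map is the affine (or identity) form."""
        return self.moment_to_load_fn is None

    def moment_to_load(self, moment: ArrayLike) -> ArrayLike:
        """Map a lumbar moment (Nm) to the tissue load used by the S-N curve."""
        if self.moment_to_load_fn is not None:
            if np.ndim(moment) == 0:
                return self.moment_to_load_fn(float(moment))
            return np.vectorize(self.moment_to_load_fn)(moment)
        out = self.moment_to_load_offset + self.moment_to_load_gain * np.asarray(
            moment, dtype=float
        )
        return float(out) if np.ndim(moment) == 0 else out


@dataclass(frozen=True)
class DamageResult:
    """Damage bookkeeping for one lifting bout."""

    load_moment: float
    exo_moment: float
    effective_moment: float
    per_lift_damage: float
    cumulative_damage: float
    repetitions: int


def load_moment(mass: float, distance: float, gravity: float = GRAVITY) -> float:
    """Peak load moment about the low back, Nm.

    The object's weight multiplied by the maximum horizontal distance from
    the object to the hip — a practical surrogate for peak low-back loading
    at the deepest part of the lift.
    """
    if mass < 0:
        raise DomainError(f"mass must be >= 0 kg, got {mass}")
    if distance < 0:
        raise DomainError(f"distance must be >= 0 m, got {distance}")
    if gravity <= 0:
        raise DomainError(f"gravity must be > 0, got {gravity}")
    return mass * gravity * distance


def effective_moment(load_moment: float, exo_moment: float) -> float:
    """Load moment remaining after exo assistance, Nm; floored at zero.

    An exo moment exceeding the load moment is outside the model's intended
    regime; the result is clamped to 0 and a :class:`ClampWarning` is
    emitted.
    """
    if load_moment < 0:
        raise DomainError(f"load_moment must be >= 0 Nm, got {load_moment}")
    if exo_moment < 0:
        raise DomainError(f"exo_moment must be >= 0 Nm, got {exo_moment}")
    eff = load_moment - exo_moment
    if eff < 0:
        warnings.warn(
            f"exo moment ({exo_moment} Nm) exceeds load moment ({load_moment} Nm); "
            "effective moment clamped to 0",
            ClampWarning,
            stacklevel=2,
        )
        return 0.0
    return eff


def per_lift_damage(moment: ArrayLike, params: DamageParams) -> ArrayLike:
    """Fraction of fatigue life consumed by one lift at the given moment.

    ``1 / N_f`` with ``log10 N_f = sn_intercept - sn_slope * L(moment)``.
    Strictly increasing in moment and in (0, 1]; values implying less than
    one cycle to failure are capped at 1 with a :class:`DamageCapWarning`.
    Accepts scalars or numpy arrays.
    """
    arr = np.asarray(moment, dtype=float)
    if np.any(arr < 0):
        raise DomainError("moment must be >= 0 Nm")
    log10_nf = params.sn_intercept - params.sn_slope * np.asarray(
        params.moment_to_load(arr), dtype=float
    )
    if np.any(log10_nf < 0):
        warnings.warn(
            "S-N parameters imply N_f < 1 cycle; per-lift damage capped at 1",
            DamageCapWarning,
            stacklevel=2,
        )
        log10_nf = np.maximum(log10_nf, 0.0)
    dmg = 10.0 ** (-log10_nf)
    if np.ndim(moment) == 0:
        return float(dmg)
    return dmg


def cumulative_damage(
    task: LiftTask, exo_moment: float, params: DamageParams
) -> DamageResult:
    """Cumulative low-back damage for a lifting bout, with full bookkeeping.

    Exactly linear in repetitions: every lift in the bout is assumed to
    occur at the same peak effective moment.
    """
    lm = load_moment(task.mass, task.distance, params.gravity)
    eff = effective_moment(lm, exo_moment)
    d1 = per_lift_damage(eff, params)
    return DamageResult(
        load_moment=lm,
        exo_moment=exo_moment,
        effective_moment=eff,
        per_lift_damage=d1,
        cumulative_damage=task.repetitions * d1,
        repetitions=task.repetitions,
    )


def percent_change_damage(with_exo: float, without_exo: float) -> float:
    """Percent change in cumulative damage with versus without the exo.

    ``100 * (with - without) / without``; negative values mean the exo
    reduced damage.
    """
    if without_exo == 0:
        raise UndefinedComparisonError(
            "percent change undefined against zero reference damage"
        )
    return 100.0 * (with_exo - without_exo) / without_exo


def power_law_damage_ratio(load_ratio: float, C: float) -> float:
    """Per-lift damage ratio under the force^C damage relationship.

    For tissues whose cumulative damage is proportional to peak force raised
    to a tissue-specific exponent ``C`` (empirically 4-9), a peak-load ratio
    ``r`` maps to a damage ratio ``r**C``.  E.g. ``load_ratio=0.9`` gives the
    damage remaining after a 10% reduction in peak loading.
    """
    if load_ratio <= 0:
        raise DomainError(f"load_ratio must be > 0, got {load_ratio}")
    if not (4.0 <= C <= 9.0):
        warnings.warn(
            f"C={C} is outside the empirically supported range [4, 9]",
            UserWarning,
            stacklevel=2,
        )
    return load_ratio**C
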