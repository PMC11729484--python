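"""Endurance and damage analytics for single-case lifting designs.

Participants lift to failure repeatedly under alternating control (no exo,
conditions ``A1, A2, ...``) and intervention (exo worn, ``B1, B2, ...``)
sets.  For AB designs only the with/without contrast is available; ABA
withdrawal designs additionally support the reversal effect — endurance
rises when the exo is donned (B vs A1) and falls again when it is doffed
(A2 vs B) — which strengthens the causal reading of the contrast.

For every participant this module computes percent changes in lifting
repetitions and in modelled cumulative back damage (B relative to A1, to
A2, and to the mean of the control sets), plus reversal flags, and
aggregates them into series-level counts, ranges and means.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from statistics import mean
from typing import Dict, List, Optional, Sequence

from ._errors import DomainError, SchemaError, UndefinedComparisonError
from .damage import (
    DamageParams,
    effective_moment,
    load_moment,
    per_lift_damage,
)

__all__ = [
    "CONDITION_PATTERN",
    "LiftingSet",
    "ParticipantResult",
    "SeriesSummary",
    "percent_change_reps",
    "analyze_participant",
    "analyze_sets",
    "reversal_counts",
    "summarize_series",
]

#: Valid condition labels: A/B optionally followed by a phase number.
CONDITION_PATTERN = re.compile(r"^(A|B)([0-9]*)$")


def _normalize_condition(label: str) -> str:
    """Canonicalise a condition label: bare 'A'/'B' become 'A1'/'B1'."""
    m = CONDITION_PATTERN.match(label.strip())
    if not m:
        raise SchemaError(
            f"unknown condition label {label!r}; expected A1/B/A2/B2/A3 style"
        )
    phase = m.group(2) or "1"
    return f"{m.group(1)}{phase}"


@dataclass(frozen=True)
class LiftingSet:
    """One lifting set: a participant lifting to failure under one condition.

    Control (``A*``) sets must carry ``exo_moment = 0``; the task geometry
    (object mass, horizontal distance) is the participant's own measured
    values and is carried on every set.
    """

    participant: str
    condition: str
    reps: int
    mass: float
    distance: float
    exo_moment: float = 0.0
    excluded: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "condition", _normalize_condition(self.condition))
        if self.reps < 0 or self.reps != int(self.reps):
            raise DomainError(f"reps must be a non-negative integer, got {self.reps}")
        if self.mass < 0 or self.distance < 0:
            raise DomainError("mass and distance must be >= 0")
        if self.exo_moment < 0:
            raise DomainError(f"exo_moment must be >= 0 Nm, got {self.exo_moment}")
        if self.is_control and self.exo_moment != 0:
            raise DomainError(
                f"control set {self.condition} must have exo_moment = 0, "
                f"got {self.exo_moment} Nm"
            )

    @property
    def is_control(self) -> bool:
        return self.condition.startswith("A")


@dataclass(frozen=True)
class ParticipantResult:
    """Per-participant endurance and damage contrasts.

    Percent fields follow the ``100 * (B - ref) / ref`` convention; the
    ``*_vs_a2`` fields and the reversal flags are ``None`` for AB designs,
    where a second control set does not exist.
    """

    participant: str
    design: str
    reps_controls: Dict[str, int]
    reps_exo: Dict[str, int]
    exo_moment: float
    pct_reps_vs_a1: float
    pct_reps_vs_a2: Optional[float]
    pct_reps_vs_mean_controls: float
    pct_damage_vs_a1: float
    pct_damage_vs_a2: Optional[float]
    pct_damage_vs_mean_controls: float
    damage_control_mean: float
    damage_exo_mean: float
    reversal_reps: Optional[bool]
    reversal_damage: Optional[bool]
    excluded: bool = False


@dataclass(frozen=True)
class SeriesSummary:
    """Series-level counts and spread of one percent-change metric."""

    metric: str
    n_participants: int
    n_increase: int
    n_decrease: int
    range_low: float
    range_high: float
    mean: float
    n_reversal_confirmed: Optional[int]


def percent_change_reps(exo_reps: float, control_reps: float) -> float:
    """Percent change in lifts performed with versus without the exo."""
    if control_reps == 0:
        raise UndefinedComparisonError(
            "percent change undefined against zero control repetitions"
        )
    return 100.0 * (exo_reps - control_reps) / control_reps


def _set_damage(s: LiftingSet, params: DamageParams) -> float:
    lm = load_moment(s.mass, s.distance, params.gravity)
    eff = effective_moment(lm, s.exo_moment)
    return s.reps * per_lift_damage(eff, params)


def analyze_participant(
    sets: Sequence[LiftingSet], params: DamageParams
) -> ParticipantResult:
    """All endurance and damage contrasts for one participant.

    Requires at least one control (A) and one intervention (B) set, all
    from the same participant.  Multi-B designs (ABABA) compare the mean of
    the B sets against each control; reversal flags use the classic triple
    (A1, first B, A2) and are defined only when A2 exists.
    """
    if not sets:
        raise SchemaError("no lifting sets supplied")
    participants = {s.participant for s in sets}
    if len(participants) != 1:
        raise SchemaError(f"sets span multiple participants: {sorted(participants)}")
    by_cond = {s.condition: s for s in sets}
    if len(by_cond) != len(sets):
        raise SchemaError("duplicate condition labels for one participant")
    controls = sorted(c for c in by_cond if c.startswith("A"))
    exo_conds = sorted(c for c in by_cond if c.startswith("B"))
    if not controls or not exo_conds:
        raise SchemaError(
            "participant needs at least one A (control) and one B (exo) set; "
            f"got {sorted(by_cond)}"
        )
    if "A1" not in by_cond:
        raise SchemaError("first control set A1 is required")

    # canonical phase order: A1, B1, A2, B2, A3 ...
    order = sorted(by_cond, key=lambda c: (int(c[1:]), 0 if c[0] == "A" else 1))
    design = "".join(c[0] for c in order)

    reps_controls = {c: by_cond[c].reps for c in controls}
    reps_exo = {c: by_cond[c].reps for c in exo_conds}
    mean_control_reps = mean(reps_controls.values())
    mean_exo_reps = mean(reps_exo.values())

    dmg_controls = {c: _set_damage(by_cond[c], params) for c in controls}
    dmg_exo = {c: _set_damage(by_cond[c], params) for c in exo_conds}
    mean_control_dmg = mean(dmg_controls.values())
    mean_exo_dmg = mean(dmg_exo.values())

    has_a2 = "A2" in by_cond
    first_b = exo_conds[0]

    def pct(new: float, old: float) -> float:
        if old == 0:
            raise UndefinedComparisonError("zero reference in percent change")
        return 100.0 * (new - old) / old

    reversal_reps = reversal_damage = None
    if has_a2:
        b_reps = by_cond[first_b].reps
        reversal_reps = (b_reps > by_cond["A1"].reps) and (by_cond["A2"].reps < b_reps)
        b_dmg = dmg_exo[first_b]
        reversal_damage = (b_dmg < dmg_controls["A1"]) and (dmg_controls["A2"] > b_dmg)

    return ParticipantResult(
        participant=sets[0].participant,
        design=design,
        reps_controls=reps_controls,
        reps_exo=reps_exo,
        exo_moment=mean(by_cond[c].exo_moment for c in exo_conds),
        pct_reps_vs_a1=percent_change_reps(mean_exo_reps, by_cond["A1"].reps),
        pct_reps_vs_a2=(
            percent_change_reps(mean_exo_reps, by_cond["A2"].reps) if has_a2 else None
        ),
        pct_reps_vs_mean_controls=percent_change_reps(mean_exo_reps, mean_control_reps),
        pct_damage_vs_a1=pct(mean_exo_dmg, dmg_controls["A1"]),
        pct_damage_vs_a2=(pct(mean_exo_dmg, dmg_controls["A2"]) if has_a2 else None),
        pct_damage_vs_mean_controls=pct(mean_exo_dmg, mean_control_dmg),
        damage_control_mean=mean_control_dmg,
        damage_exo_mean=mean_exo_dmg,
        reversal_reps=reversal_reps,
        reversal_damage=reversal_damage,
        excluded=any(s.excluded for s in sets),
    )


def analyze_sets(
    sets: Sequence[LiftingSet], params: DamageParams
) -> List[ParticipantResult]:
    """Group sets by participant and analyze each; stable participant order."""
    groups: Dict[str, List[LiftingSet]] = {}
    for s in sets:
        groups.setdefault(s.participant, []).append(s)
    return [analyze_participant(g, params) for _, g in sorted(groups.items())]


def reversal_counts(
    results: Sequence[ParticipantResult], metric: str = "reps"
) -> Optional[int]:
    """Number of participants with a confirmed reversal for the metric.

    AB participants (no A2) carry no reversal information and are excluded;
    returns ``None`` when no participant has a defined reversal flag.
    """
    if metric not in ("reps", "damage"):
        raise DomainError(f"metric must be 'reps' or 'damage', got {metric!r}")
    flags = [
        getattr(r, f"reversal_{metric}")
        for r in results
        if getattr(r, f"reversal_{metric}") is not None
    ]
    if not flags:
        return None
    return sum(flags)


def summarize_series(
    results: Sequence[ParticipantResult], metric: str = "reps"
) -> SeriesSummary:
    """Counts, range and mean of the vs-mean-controls percent change.

    Excluded participants are dropped before summarising.
    """
    if metric not in ("reps", "damage"):
        raise DomainError(f"metric must be 'reps' or 'damage', got {metric!r}")
    kept = [r for r in results if not r.excluded]
    if not kept:
        raise SchemaError("no non-excluded participants to summarize")
    values = [getattr(r, f"pct_{metric}_vs_mean_controls") for r in kept]
    return SeriesSummary(
        metric=metric,
        n_participants=len(kept),
        n_increase=sum(v > 0 for v in values),
        n_decrease=sum(v < 0 for v in values),
        range_low=min(values),
        range_high=max(values),
        mean=mean(values),
        n_reversal_confirmed=reversal_counts(kept, metric),
    )
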