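"""Synthetic case-series, band-curve and exosuit-spec generation.

Emulates the structure of small single-case lifting studies: 4-5
participants per series lifting a heavy object (45-55 kg) to failure at a
6-s cadence under alternating control/exo conditions (AB, ABA or ABABA),
with exo moments in a configurable Nm interval and a known multiplicative
ground-truth endurance effect.  Because the true effect is known, the
case-series analytics can be tested for parameter recovery on data with a
realistic count structure.

Count model: each participant has a latent endurance (Gamma-distributed
around ``baseline_mean_reps`` with coefficient of variation
``baseline_dispersion`` — a negative-binomial-style overdispersion) and a
participant-specific endurance multiplier (lognormal with mean
``exo_effect_multiplier`` and between-participant spread ``effect_sd``).
Non-responders — participants whose endurance does not improve, as seen
occasionally in practice — draw a multiplier below 1 instead.  Each set's
count gets independent lognormal set-to-set noise, is rounded and floored
at one lift.  A single integer seed makes every output reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np

from ._errors import ConfigError, DomainError
from .case_series import LiftingSet
from .damage import GRAVITY
from .exo import BandCurve, ExoSpec, effective_exo_moment

__all__ = [
    "GeneratorConfig",
    "generate_case_series",
    "generate_band_curve",
    "generate_exo_specs",
]

_DESIGNS = {
    "AB": ("A1", "B1"),
    "ABA": ("A1", "B1", "A2"),
    "ABABA": ("A1", "B1", "A2", "B2", "A3"),
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Ground-truth parameters of a synthetic case series.

    Defaults mirror an ABA withdrawal series with four participants lifting
    a 55 kg object: baseline endurance around 14 lifts per set, a 1.34x
    endurance effect with moderate between-participant spread, exo moments
    in 27-42 Nm, and a 1-in-8 non-responder probability.
    """

    n_participants: int = 4
    design: str = "ABA"
    baseline_mean_reps: float = 14.0
    baseline_dispersion: float = 0.15  # CV of latent endurance across participants
    exo_effect_multiplier: float = 1.34
    effect_sd: float = 0.15  # between-participant lognormal sigma of the effect
    set_noise_sd: float = 0.05  # within-participant set-to-set lognormal sigma
    nonresponder_prob: float = 0.125
    nonresponder_multiplier: float = 0.7
    exo_moment_range: Tuple[float, float] = (27.0, 42.0)
    task_mass_kg: float = 55.0
    distance_range_m: Tuple[float, float] = (0.55, 0.75)
    period_s: float = 6.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.design not in _DESIGNS:
            raise ConfigError(f"design must be one of {sorted(_DESIGNS)}, got {self.design!r}")
        if self.n_participants < 1:
            raise ConfigError("n_participants must be >= 1")
        if self.baseline_mean_reps <= 0:
            raise ConfigError("baseline_mean_reps must be > 0")
        if self.exo_effect_multiplier <= 0:
            raise ConfigError("exo_effect_multiplier must be > 0")
        for name in ("baseline_dispersion", "effect_sd", "set_noise_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if not (0 <= self.nonresponder_prob <= 1):
            raise ConfigError("nonresponder_prob must be in [0, 1]")
        if not (0 < self.nonresponder_multiplier):
            raise ConfigError("nonresponder_multiplier must be > 0")
        lo, hi = self.exo_moment_range
        if not (0 <= lo <= hi):
            raise ConfigError("exo_moment_range must satisfy 0 <= low <= high")
        lo, hi = self.distance_range_m
        if not (0 < lo <= hi):
            raise ConfigError("distance_range_m must satisfy 0 < low <= high")


def _lognormal_mean(rng: np.random.Generator, mean: float, sigma: float) -> float:
    """Lognormal draw with the given arithmetic mean."""
    if sigma == 0:
        return mean
    return float(rng.lognormal(math.log(mean) - 0.5 * sigma**2, sigma))


def generate_case_series(config: GeneratorConfig) -> List[LiftingSet]:
    """Generate one synthetic case series as a list of lifting sets.

    Deterministic under ``config.seed``; the returned sets are ordered by
    participant then phase.
    """
    rng = np.random.default_rng(config.seed)
    conditions = _DESIGNS[config.design]
    sets: List[LiftingSet] = []
    for i in range(config.n_participants):
        pid = f"S{i + 1}"
        if config.baseline_dispersion > 0:
            shape = 1.0 / config.baseline_dispersion**2
            latent = float(rng.gamma(shape, config.baseline_mean_reps / shape))
        else:
            latent = config.baseline_mean_reps
        if rng.uniform() < config.nonresponder_prob:
            effect = _lognormal_mean(
                rng, config.nonresponder_multiplier, config.effect_sd
            )
        else:
            effect = _lognormal_mean(rng, config.exo_effect_multiplier, config.effect_sd)
        exo_moment = float(rng.uniform(*config.exo_moment_range))
        distance = float(rng.uniform(*config.distance_range_m))
        for cond in conditions:
            target = latent * (effect if cond.startswith("B") else 1.0)
            if config.set_noise_sd > 0:
                target *= float(
                    rng.lognormal(-0.5 * config.set_noise_sd**2, config.set_noise_sd)
                )
            reps = max(1, round(target))
            sets.append(
                LiftingSet(
                    participant=pid,
                    condition=cond,
                    reps=reps,
                    mass=config.task_mass_kg,
                    distance=distance,
                    exo_moment=exo_moment if cond.startswith("B") else 0.0,
                )
            )
    return sets


def generate_band_curve(
    stiffness: float,
    softening: float = 0.0,
    hysteresis_loss: float = 0.0,
    n_samples: int = 20,
    max_displacement: float = 0.30,
) -> BandCurve:
    """Synthetic elastic-band force-displacement curve.

    Loading force ``f(s) = k s (1 + softening * s / s_max)`` — linear for
    ``softening = 0``, progressively stiffening otherwise.  The unloading
    branch is the loading branch scaled by ``1 - hysteresis_loss``, which
    makes the hysteresis-loop area fraction exactly the requested loss
    (real bands close the loop at peak stretch; the pointwise scaling is a
    deliberate simplification that preserves the energy budget).
    """
    if stiffness <= 0:
        raise DomainError(f"stiffness must be > 0 N/m, got {stiffness}")
    if not (0 <= hysteresis_loss < 1):
        raise DomainError(f"hysteresis_loss must be in [0, 1), got {hysteresis_loss}")
    if softening < 0:
        raise DomainError(f"softening must be >= 0, got {softening}")
    if n_samples < 2:
        raise DomainError("need at least 2 samples")
    if max_displacement <= 0:
        raise DomainError("max_displacement must be > 0 m")
    disp = np.linspace(0.0, max_displacement, n_samples)
    force = stiffness * disp * (1.0 + softening * disp / max_displacement)
    if hysteresis_loss == 0:
        return BandCurve(disp, force, disp.copy(), force.copy())
    return BandCurve(disp, force, disp.copy(), (1.0 - hysteresis_loss) * force)


def generate_exo_specs(
    n: int,
    seed: int,
    target_interval: Tuple[float, float] = (15.0, 26.0),
    stretch_range: Tuple[float, float] = (0.12, 0.25),
    gravity: float = GRAVITY,
    max_attempts: int = 100,
) -> List[ExoSpec]:
    """Sample ``n`` exosuit specs whose effective moments land in an interval.

    Geometry, device mass and correction factors are sampled from plausible
    anthropometric/device ranges; the band stiffness is then solved so the
    effective exo moment hits a target drawn uniformly from
    ``target_interval``.  Deeper stretches (a wearer bending further) are
    modelled through ``stretch_range``.  An infeasible interval raises
    after a bounded number of attempts.
    """
    if n < 1:
        raise DomainError(f"n must be >= 1, got {n}")
    lo, hi = target_interval
    if not (0 < lo <= hi):
        raise DomainError(f"infeasible target interval {target_interval}")
    s_lo, s_hi = stretch_range
    if not (0 < s_lo <= s_hi):
        raise DomainError(f"invalid stretch range {stretch_range}")
    rng = np.random.default_rng(seed)
    specs: List[ExoSpec] = []
    for _ in range(n):
        for attempt in range(max_attempts):
            target = float(rng.uniform(lo, hi))
            hyst = float(rng.uniform(0.85, 0.95))
            timing = float(rng.uniform(0.90, 0.98))
            l5s1 = float(rng.uniform(0.07, 0.10))
            skin = float(rng.uniform(0.02, 0.05))
            mass = float(rng.uniform(2.0, 4.0))
            com = float(rng.uniform(0.08, 0.15))
            stretch = float(rng.uniform(s_lo, s_hi))
            arm = l5s1 + skin
            flexion = mass * gravity * com
            force = (target + flexion) / (arm * hyst * timing)
            stiffness = force / stretch
            curve = generate_band_curve(
                stiffness, softening=0.0, hysteresis_loss=1.0 - hyst,
                max_displacement=1.5 * stretch,
            )
            spec = ExoSpec(
                band_curve=curve,
                max_stretch=stretch,
                l5s1_to_skin=l5s1,
                skin_to_band=skin,
                device_mass=mass,
                device_com_distance=com,
                hysteresis_factor=hyst,
                timing_factor=timing,
            )
            eff = effective_exo_moment(spec, gravity).effective_exo_moment
            if lo - 1e-9 <= eff <= hi + 1e-9:
                specs.append(spec)
                break
        else:
            raise DomainError(
                f"could not realise an effective moment in {target_interval} Nm "
                f"after {max_attempts} attempts"
            )
    return specs
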