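"""Effective exosuit lumbar-moment estimation.

A passive back exosuit assists lifting through elastic bands running along
the back.  At the deepest part of a lift the bands reach their maximum
stretch; the band force at that stretch (from the manufacturer's
force-displacement curve), multiplied by the bands' moment arm about the
L5/S1 joint, gives the peak lumbar extension moment the device can deliver.
Two multiplicative corrections (band hysteresis, and the slight timing
offset between peak exo moment and peak lumbar loading) and one additive
correction (the flexion moment created by the trunk-worn device mass)
reduce that peak to the effective exo moment fed to the damage model.

    effective = peak_extension * hysteresis * timing - device_weight_flexion

floored at zero.  Hysteresis and timing scale the delivered band force, so
they are applied before the static device-weight moment is subtracted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np

from ._errors import DomainError
from .damage import GRAVITY, ClampWarning

__all__ = [
    "BandCurve",
    "ExoSpec",
    "ExoMomentEstimate",
    "band_force",
    "moment_arm",
    "peak_extension_moment",
    "weight_flexion_moment",
    "effective_exo_moment",
]


@dataclass(frozen=True)
class BandCurve:
    """Elastic-band force-displacement curve.

    The loading branch is a strictly-increasing displacement grid with
    non-negative, non-decreasing forces.  An optional unloading branch
    (force while the band shortens) must lie at or below the loading branch
    at equal displacement — the area between the branches is the hysteresis
    loop (energy lost per cycle).
    """

    displacement: np.ndarray
    force: np.ndarray
    unload_displacement: Optional[np.ndarray] = None
    unload_force: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        disp = np.asarray(self.displacement, dtype=float)
        force = np.asarray(self.force, dtype=float)
        object.__setattr__(self, "displacement", disp)
        object.__setattr__(self, "force", force)
        if disp.size == 0:
            raise DomainError("band curve is empty")
        if disp.size != force.size:
            raise DomainError("displacement and force arrays differ in length")
        if disp.size > 1 and np.any(np.diff(disp) <= 0):
            raise DomainError("band-curve displacements must be strictly increasing")
        if np.any(force < 0):
            raise DomainError("band-curve forces must be non-negative")
        if force.size > 1 and np.any(np.diff(force) < 0):
            raise DomainError(
                "loading-branch forces must be non-decreasing with displacement"
            )
        if (self.unload_displacement is None) != (self.unload_force is None):
            raise DomainError("unloading branch needs both displacement and force")
        if self.unload_displacement is not None:
            ud = np.asarray(self.unload_displacement, dtype=float)
            uf = np.asarray(self.unload_force, dtype=float)
            object.__setattr__(self, "unload_displacement", ud)
            object.__setattr__(self, "unload_force", uf)
            if ud.size != uf.size or ud.size == 0:
                raise DomainError("malformed unloading branch")
            if ud.size > 1 and np.any(np.diff(ud) <= 0):
                raise DomainError("unloading displacements must be strictly increasing")
            inside = (ud >= disp[0]) & (ud <= disp[-1])
            loading_at = np.interp(ud[inside], disp, force)
            if np.any(uf[inside] > loading_at + 1e-9):
                raise DomainError(
                    "unloading force exceeds loading force at equal displacement"
                )

    @classmethod
    def from_samples(
        cls,
        samples: Sequence[Tuple[float, float]],
        unloading: Optional[Sequence[Tuple[float, float]]] = None,
    ) -> "BandCurve":
        """Build a curve from (displacement m, force N) pairs."""
        d, f = zip(*samples) if samples else ((), ())
        if unloading:
            ud, uf = zip(*unloading)
            return cls(np.array(d), np.array(f), np.array(ud), np.array(uf))
        return cls(np.array(d), np.array(f))

    @property
    def max_displacement(self) -> float:
        return float(self.displacement[-1])

    def hysteresis_loss_fraction(self) -> float:
        """Fraction of loading-branch energy lost over a stretch cycle.

        Trapezoidal areas under the loading and unloading branches; 0 when
        no unloading branch is defined.
        """
        if self.unload_force is None:
            return 0.0
        a_load = float(np.trapezoid(self.force, self.displacement))
        a_unload = float(np.trapezoid(self.unload_force, self.unload_displacement))
        if a_load == 0:
            return 0.0
        return 1.0 - a_unload / a_load


@dataclass(frozen=True)
class ExoSpec:
    """Physical description of one fitted exosuit on one wearer."""

    band_curve: BandCurve
    max_stretch: float  # peak band stretch at the deepest part of the lift, m
    l5s1_to_skin: float  # L5/S1 joint centre to low-back skin surface, m
    skin_to_band: float  # skin surface to band line of action, m
    device_mass: float  # trunk-worn exosuit mass, kg
    device_com_distance: float  # horizontal distance of that mass from L5/S1, m
    hysteresis_factor: float = 1.0
    timing_factor: float = 1.0

    def __post_init__(self) -> None:
        for name in ("max_stretch", "l5s1_to_skin", "skin_to_band",
                     "device_mass", "device_com_distance"):
            if getattr(self, name) < 0:
                raise DomainError(f"{name} must be >= 0, got {getattr(self, name)}")
        for name in ("hysteresis_factor", "timing_factor"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise DomainError(f"{name} must be in (0, 1], got {v}")


@dataclass(frozen=True)
class ExoMomentEstimate:
    """Every component of the effective exo-moment estimate, inspectable."""

    peak_band_force: float
    moment_arm: float
    peak_extension_moment: float
    weight_flexion_moment: float
    effective_exo_moment: float


def band_force(stretch: float, curve: BandCurve) -> float:
    """Band force at a given stretch by piecewise-linear interpolation.

    No extrapolation: elastic bands stiffen nonlinearly, so a stretch
    outside the sampled range is a hard error rather than a fabricated
    force.
    """
    if stretch < 0:
        raise DomainError(f"stretch must be >= 0 m, got {stretch}")
    if stretch == 0 and curve.displacement[0] > 0:
        return 0.0
    if stretch < curve.displacement[0] or stretch > curve.max_displacement:
        raise DomainError(
            f"stretch {stretch} m outside sampled range "
            f"[{curve.displacement[0]}, {curve.max_displacement}] m"
        )
    return float(np.interp(stretch, curve.displacement, curve.force))


def moment_arm(l5s1_to_skin: float, skin_to_band: float) -> float:
    """Moment arm of the bands about the lumbar spine: the two distances summed."""
    if l5s1_to_skin < 0 or skin_to_band < 0:
        raise DomainError("moment-arm components must be >= 0 m")
    return l5s1_to_skin + skin_to_band


def peak_extension_moment(force: float, arm: float) -> float:
    """Peak lumbar extension moment generated by the bands, Nm."""
    if force < 0:
        raise DomainError(f"force must be >= 0 N, got {force}")
    if arm < 0:
        raise DomainError(f"arm must be >= 0 m, got {arm}")
    return force * arm


def weight_flexion_moment(
    device_mass: float, com_distance: float, gravity: float = GRAVITY
) -> float:
    """Lumbar flexion moment created by the trunk-worn device weight, Nm."""
    if device_mass < 0 or com_distance < 0 or gravity < 0:
        raise DomainError("weight-flexion inputs must be >= 0")
    return device_mass * gravity * com_distance


def effective_exo_moment(spec: ExoSpec, gravity: float = GRAVITY) -> ExoMomentEstimate:
    """Effective exo moment at the time of peak lumbar loading.

    Peak band force x moment arm, derated multiplicatively for hysteresis
    and moment-timing mismatch, minus the device-weight flexion moment;
    floored at zero with a warning if the corrections exceed the assistance.
    """
    f = band_force(spec.max_stretch, spec.band_curve)
    arm = moment_arm(spec.l5s1_to_skin, spec.skin_to_band)
    peak = peak_extension_moment(f, arm)
    flexion = weight_flexion_moment(spec.device_mass, spec.device_com_distance, gravity)
    eff = peak * spec.hysteresis_factor * spec.timing_factor - flexion
    if eff < 0:
        warnings.warn(
            "device-weight flexion moment exceeds corrected extension moment; "
            "effective exo moment clamped to 0",
            ClampWarning,
            stacklevel=2,
        )
        eff = 0.0
    return ExoMomentEstimate(
        peak_band_force=f,
        moment_arm=arm,
        peak_extension_moment=peak,
        weight_flexion_moment=flexion,
        effective_exo_moment=eff,
    )
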