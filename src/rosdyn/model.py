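"""Three-compartment model of rod outer segment (ROS) disc renewal.

Discs are tracked by the length they occupy in three compartments: growth
(G, nascent discs at the ROS base), mature (M, the main stack) and shed
(S, discs engulfed by the retinal pigmented epithelium).  In dimensional
form (lengths in μm, time in days):

    dLg/dt = μ0·δ(t)·Lmax/(Lg+Lm) − αg·Lg
    dLm/dt = αg·Lg − γ(t)·αs·Lm
    dLs/dt = γ(t)·αs·Lm − μs·Ls

Disc addition saturates as the total length Lt = Lg+Lm approaches the
anatomical maximum Lmax.  Retinal detachment (RD) at t = 0 scales addition
by δ0 ∈ [0,1] and removal by γ0 ≥ 0 until reattachment at t = Ta, after
which both factors revert to 1 (normal renewal).

Rescaling lengths by Lmax and time by 1/αg yields the nondimensional
system with parameters μ̄0 = μ0/(αg·Lmax), ᾱs = αs/αg, μ̄s = μs/αg and
the growth compartment's own decay coefficient equal to one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .geometry import MOUSE, DiscGeometry, compartment_length, discs_from_length

__all__ = [
    "LT_FLOOR",
    "ModelParameters",
    "DetachmentSchedule",
    "CompartmentState",
    "NondimensionalParameters",
    "ModelDomainError",
    "evaluate_schedule",
    "rhs_dimensional",
    "rhs_nondimensional",
    "nondimensionalize",
    "dimensionalize",
]

#: Smallest admissible total length (μm) when the addition term is active.
#: The addition rate divides by Lg+Lm, so states at zero total length with
#: δ > 0 are outside the model's domain.
LT_FLOOR = 1e-12


class ModelDomainError(ValueError):
    """A state or configuration outside the model's domain of validity."""


@dataclass(frozen=True)
class ModelParameters:
    """Dimensional rate and geometry constants of the renewal model.

    Defaults are the mouse/rat values: μ0 = 2.2 μm/day, αg = 0.85 /day,
    αs = 0.155 /day, μs = 0.3 /day, Lmax = 30 μm, mouse disc geometry.
    """

    mu0: float = 2.2  # disc-addition scale, μm/day
    alpha_g: float = 0.85  # maturation/translocation rate, 1/day
    alpha_s: float = 0.155  # shedding rate, 1/day
    mu_s: float = 0.3  # disposal rate, 1/day
    Lmax: float = 30.0  # maximum ROS length, μm
    delta_T: float = 1.638e-2  # disc thickness, μm
    delta_s: float = 1.556e-2  # disc–disc spacing, μm

    def __post_init__(self) -> None:
        bad = [
            name
            for name in ("mu0", "alpha_g", "alpha_s", "mu_s", "Lmax", "delta_T", "delta_s")
            if not getattr(self, name) > 0
        ]
        if bad:
            raise ValueError(f"model parameters must be strictly positive: {bad}")

    @property
    def geometry(self) -> DiscGeometry:
        return DiscGeometry(self.delta_T, self.delta_s)

    @property
    def d_max(self) -> float:
        """Fractional maximum disc count implied by Lmax (consistent by construction)."""
        return discs_from_length(self.Lmax, self.geometry)

    def replace(self, **kwargs) -> "ModelParameters":
        import dataclasses

        return dataclasses.replace(self, **kwargs)


@dataclass(frozen=True)
class DetachmentSchedule:
    """Piecewise-constant detachment severities γ(t), δ(t).

    Detachment occurs at T0 = 0; on [T0, Ta) addition is scaled by
    ``delta0`` and removal by ``gamma0``; from the reattachment time Ta on,
    both are 1 (right-continuous at Ta).  ``Ta = inf`` models a retina that
    is never reattached.
    """

    delta0: float = 1.0
    gamma0: float = 1.0
    Ta: float = math.inf
    T0: float = field(default=0.0)

    def __post_init__(self) -> None:
        if not 0.0 <= self.delta0 <= 1.0:
            raise ValueError("delta0 must lie in [0, 1]")
        if self.gamma0 < 0:
            raise ValueError("gamma0 must be non-negative")
        if self.T0 != 0.0:
            raise ValueError("T0 is fixed at 0 (time origin is the detachment time)")
        if not self.Ta > self.T0:
            raise ValueError("reattachment time Ta must exceed T0")

    @classmethod
    def normal(cls) -> "DetachmentSchedule":
        """Normal renewal: γ = δ = 1 for all time."""
        return cls(delta0=1.0, gamma0=1.0)

    def evaluate(self, t):
        """Return ``(gamma, delta)`` at time ``t`` (days); vectorised over arrays."""
        t = np.asarray(t, dtype=float)
        if np.any(t < 0):
            raise ValueError("time must be non-negative")
        detached = t < self.Ta
        gamma = np.where(detached, self.gamma0, 1.0)
        delta = np.where(detached, self.delta0, 1.0)
        if t.ndim == 0:
            return float(gamma), float(delta)
        return gamma, delta

    def regime_at_infinity(self) -> tuple[float, float]:
        """The ``(gamma, delta)`` pair that holds asymptotically."""
        if math.isinf(self.Ta):
            return self.gamma0, self.delta0
        return 1.0, 1.0


@dataclass(frozen=True)
class CompartmentState:
    """Lengths (μm) occupied by discs in the G, M and S compartments.

    The total ROS length is ``Lg + Lm``: shed discs sit inside the RPE and
    do not contribute to the outer-segment length.
    """

    Lg: float
    Lm: float
    Ls: float

    def __post_init__(self) -> None:
        if self.Lg < 0 or self.Lm < 0 or self.Ls < 0:
            raise ValueError("compartment lengths must be non-negative")

    @property
    def total_length(self) -> float:
        """Total ROS length Lt = Lg + Lm, μm."""
        return self.Lg + self.Lm

    def as_array(self) -> np.ndarray:
        return np.array([self.Lg, self.Lm, self.Ls], dtype=float)

    @classmethod
    def from_array(cls, y) -> "CompartmentState":
        return cls(float(y[0]), float(y[1]), float(y[2]))

    @classmethod
    def from_discs(cls, G: float, M: float, S: float, geom: DiscGeometry = MOUSE) -> "CompartmentState":
        """Build a state from per-compartment disc counts (0 discs → 0 μm)."""
        return cls(
            compartment_length(G, geom),
            compartment_length(M, geom),
            compartment_length(S, geom),
        )

    def to_discs(self, geom: DiscGeometry = MOUSE) -> tuple[float, float, float]:
        """Fractional per-compartment disc counts."""
        return (
            discs_from_length(self.Lg, geom),
            discs_from_length(self.Lm, geom),
            discs_from_length(self.Ls, geom),
        )


@dataclass(frozen=True)
class NondimensionalParameters:
    """Parameters of the rescaled system (lengths / Lmax, time × αg)."""

    mu0_bar: float  # dimensionless addition scale μ0/(αg·Lmax)
    alpha_s_bar: float  # dimensionless shedding rate αs/αg
    mu_s_bar: float  # dimensionless disposal rate μs/αg
    tau_scale: float  # time scale 1/αg, days

    def __post_init__(self) -> None:
        if not (
            self.mu0_bar > 0 and self.alpha_s_bar > 0 and self.mu_s_bar > 0 and self.tau_scale > 0
        ):
            raise ValueError("nondimensional parameters must be strictly positive")


def nondimensionalize(params: ModelParameters) -> NondimensionalParameters:
    """Map dimensional parameters to the nondimensional set (μ̄0, ᾱs, μ̄s, 1/αg)."""
    return NondimensionalParameters(
        mu0_bar=params.mu0 / (params.alpha_g * params.Lmax),
        alpha_s_bar=params.alpha_s / params.alpha_g,
        mu_s_bar=params.mu_s / params.alpha_g,
        tau_scale=1.0 / params.alpha_g,
    )


def dimensionalize(
    nd: NondimensionalParameters, Lmax: float, geom: DiscGeometry = MOUSE
) -> ModelParameters:
    """Invert :func:`nondimensionalize` given the length scale ``Lmax``.

    αg is recovered from the stored time scale; the disc geometry does not
    participate in the scaling and must be supplied (defaults to mouse).
    """
    alpha_g = 1.0 / nd.tau_scale
    return ModelParameters(
        mu0=nd.mu0_bar * alpha_g * Lmax,
        alpha_g=alpha_g,
        alpha_s=nd.alpha_s_bar * alpha_g,
        mu_s=nd.mu_s_bar * alpha_g,
        Lmax=Lmax,
        delta_T=geom.delta_T,
        delta_s=geom.delta_s,
    )


def evaluate_schedule(schedule: DetachmentSchedule, t):
    """Evaluate the detachment step functions; returns ``(gamma, delta)``."""
    return schedule.evaluate(t)


def _as_array(state) -> np.ndarray:
    if isinstance(state, CompartmentState):
        return state.as_array()
    return np.asarray(state, dtype=float)


def _rates(y: np.ndarray, gamma: float, delta: float, mu0: float, Lmax: float,
           alpha_g: float, alpha_s: float, mu_s: float) -> np.ndarray:
    Lg, Lm, Ls = y
    Lt = Lg + Lm
    if delta > 0:
        if Lt < LT_FLOOR:
            raise ModelDomainError(
                f"total length {Lt:g} μm below the admissible floor with delta={delta:g} > 0 "
                "(singular addition term)"
            )
        addition = mu0 * delta * Lmax / Lt
    else:
        addition = 0.0
    removal = gamma * alpha_s * Lm
    return np.array([addition - alpha_g * Lg, alpha_g * Lg - removal, removal - mu_s * Ls])


def rhs_dimensional(state, t: float, params: ModelParameters, schedule: DetachmentSchedule) -> np.ndarray:
    """Right-hand side of the dimensional system, μm/day."""
    gamma, delta = schedule.evaluate(t)
    return _rates(
        _as_array(state), gamma, delta,
        params.mu0, params.Lmax, params.alpha_g, params.alpha_s, params.mu_s,
    )


def rhs_nondimensional(state, tau: float, nd: NondimensionalParameters,
                       schedule: DetachmentSchedule) -> np.ndarray:
    """Right-hand side of the rescaled system (scaled lengths per scaled time).

    The schedule is defined in days, so it is evaluated at t = τ·(1/αg).
    """
    gamma, delta = schedule.evaluate(tau * nd.tau_scale)
    return _rates(
        _as_array(state), gamma, delta,
        mu0=nd.mu0_bar, Lmax=1.0, alpha_g=1.0, alpha_s=nd.alpha_s_bar, mu_s=nd.mu_s_bar,
    )
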