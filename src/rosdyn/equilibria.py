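"""Equilibria and linear stability of the nondimensional renewal system.

Setting the rescaled rates to zero gives, for δ ≠ 0 and γ > 0, a feasible
equilibrium

    E1 = (γᾱs·m, m, (γᾱs/μ̄s)·m),   m = sqrt( μ̄0·δ / (γᾱs·(γᾱs+1)) ),

its mirror image E2 = −E1 (not biologically feasible: lengths are
non-negative), and for δ = 0 the single equilibrium E0 at the origin.
The Jacobian is

    J = [[−a−1, −a,    0   ],
         [ 1,   −γᾱs,  0   ],
         [ 0,    γᾱs, −μ̄s ]],   a = δ·μ̄0/(Lg+Lm)²,

whose third column shows that the shed compartment never feeds back on the
outer segment.  One eigenvalue is always −μ̄s; the other two are roots of
λ² + (a+γᾱs+1)λ + (a + γᾱs(a+1)), which have negative real parts for any
positive parameters, so E1 (and E0 when γ > 0) is asymptotically stable.

When both addition and removal are halted (δ = γ = 0) the system is linear
and solvable in closed form; the total length Lg+Lm is conserved.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import (
    CompartmentState,
    ModelDomainError,
    ModelParameters,
    NondimensionalParameters,
    nondimensionalize,
)

__all__ = [
    "EquilibriumPoint",
    "EquilibriumReport",
    "NoFiniteEquilibriumError",
    "equilibrium_points",
    "jacobian",
    "characteristic_eigenvalues",
    "classify_stability",
    "analytic_frozen_solution",
    "equilibrium_total_length",
]

STABLE = "asymptotically stable"
NEUTRAL = "neutrally stable"
UNSTABLE = "unstable"
INFEASIBLE = "not biologically feasible"


class NoFiniteEquilibriumError(ModelDomainError):
    """δ ≠ 0 with γ = 0: discs accumulate and the total length is unbounded."""


@dataclass
class EquilibriumPoint:
    label: str  # "E0", "E1" or "E2"
    state: np.ndarray  # scaled (Lg, Lm, Ls)
    feasible: bool
    a_coeff: float  # a = δ·μ̄0/(Lg+Lm)² at the point (0 when δ = 0)
    eigenvalues: np.ndarray | None = None
    stability: str | None = None

    @property
    def total_length(self) -> float:
        """Scaled total length Lg* + Lm* at the point."""
        return float(self.state[0] + self.state[1])


@dataclass
class EquilibriumReport:
    """Equilibria of the rescaled system for one (δ, γ) regime."""

    nd: NondimensionalParameters
    delta: float
    gamma: float
    points: list[EquilibriumPoint] = field(default_factory=list)

    def point(self, label: str) -> EquilibriumPoint:
        for p in self.points:
            if p.label == label:
                return p
        raise KeyError(label)

    def to_frame(self, params: ModelParameters | None = None) -> pd.DataFrame:
        """Flat table of points; adds μm columns when parameters are given."""
        rows = []
        for p in self.points:
            row = {
                "label": p.label,
                "Lg_scaled": p.state[0],
                "Lm_scaled": p.state[1],
                "Ls_scaled": p.state[2],
                "Lt_scaled": p.total_length,
                "stability": p.stability,
            }
            if params is not None:
                row.update(
                    Lg_um=p.state[0] * params.Lmax,
                    Lm_um=p.state[1] * params.Lmax,
                    Ls_um=p.state[2] * params.Lmax,
                    Lt_um=p.total_length * params.Lmax,
                )
            if p.eigenvalues is not None:
                for i, lam in enumerate(p.eigenvalues, start=1):
                    row[f"eig{i}_re"] = lam.real
                    row[f"eig{i}_im"] = lam.imag
            rows.append(row)
        return pd.DataFrame(rows)


def equilibrium_points(nd: NondimensionalParameters, delta: float, gamma: float) -> EquilibriumReport:
    """Closed-form equilibria of the rescaled system for constant (δ, γ).

    Raises :class:`NoFiniteEquilibriumError` for δ ≠ 0 with γ = 0 (no
    removal: the total length grows without bound).
    """
    if delta < 0 or gamma < 0:
        raise ValueError("delta and gamma must be non-negative")
    report = EquilibriumReport(nd=nd, delta=delta, gamma=gamma)
    if delta == 0:
        report.points.append(
            EquilibriumPoint(label="E0", state=np.zeros(3), feasible=True, a_coeff=0.0)
        )
        return report
    if gamma == 0:
        raise NoFiniteEquilibriumError(
            "no finite equilibrium for delta > 0 with gamma = 0: "
            "disc addition without removal grows the ROS without bound"
        )
    eps = gamma * nd.alpha_s_bar
    m = math.sqrt(nd.mu0_bar * delta / (eps * (eps + 1.0)))
    e1 = np.array([eps * m, m, eps / nd.mu_s_bar * m])
    a1 = delta * nd.mu0_bar / (e1[0] + e1[1]) ** 2
    report.points.append(EquilibriumPoint(label="E1", state=e1, feasible=True, a_coeff=a1))
    report.points.append(EquilibriumPoint(label="E2", state=-e1, feasible=False, a_coeff=a1))
    return report


def jacobian(state, nd: NondimensionalParameters, delta: float, gamma: float) -> np.ndarray:
    """Jacobian of the rescaled system at a (scaled) state."""
    y = state.as_array() if isinstance(state, CompartmentState) else np.asarray(state, float)
    lt = y[0] + y[1]
    if delta > 0:
        if lt == 0:
            raise ModelDomainError("Jacobian singular at zero total length with delta > 0")
        a = delta * nd.mu0_bar / lt**2
    else:
        a = 0.0
    eps = gamma * nd.alpha_s_bar
    return np.array(
        [
            [-a - 1.0, -a, 0.0],
            [1.0, -eps, 0.0],
            [0.0, eps, -nd.mu_s_bar],
        ]
    )


def characteristic_eigenvalues(
    nd: NondimensionalParameters, delta: float, gamma: float, a_coeff: float
) -> np.ndarray:
    """Eigenvalues from the factored characteristic polynomial.

    The polynomial factors as −(λ+μ̄s)·[λ² + (a+γᾱs+1)λ + (a+γᾱs(a+1))];
    used as a symbolic cross-check against the numerical eigensolver.
    """
    eps = gamma * nd.alpha_s_bar
    b = a_coeff + eps + 1.0
    c = a_coeff + eps * (a_coeff + 1.0)
    disc = complex(b * b - 4.0 * c) ** 0.5
    return np.array([-nd.mu_s_bar, (-b + disc) / 2.0, (-b - disc) / 2.0])


def classify_stability(report: EquilibriumReport) -> EquilibriumReport:
    """Fill in eigenvalues (numerical) and stability labels for every point.

    Feasible points are labelled asymptotically stable when every
    eigenvalue has strictly negative real part; the mirror point E2 keeps
    its "not biologically feasible" label (its spectrum equals E1's).
    """
    for p in report.points:
        if p.label == "E0" and report.gamma == 0:
            # frozen regime: linear system, eigenvalues straight off the diagonal
            p.eigenvalues = np.array([-1.0, 0.0, -report.nd.mu_s_bar], dtype=complex)
        else:
            J = jacobian(p.state, report.nd, report.delta, report.gamma)
            p.eigenvalues = np.linalg.eigvals(J)
        if not p.feasible:
            p.stability = INFEASIBLE
        elif np.all(p.eigenvalues.real < 0):
            p.stability = STABLE
        elif np.any(p.eigenvalues.real > 0):
            p.stability = UNSTABLE
        else:
            # frozen regime (δ=γ=0): a line of equilibria, one neutral direction
            p.stability = NEUTRAL
    return report


def analytic_frozen_solution(initial, tau, nd: NondimensionalParameters) -> np.ndarray:
    """Closed-form solution of the fully frozen regime (δ = 0, γ = 0).

    Lg(τ) = Lg0·e^{−τ};  Lm(τ) = Lg0 + Lm0 − Lg0·e^{−τ};
    Ls(τ) = Ls0·e^{−μ̄s·τ}.  The total length Lg+Lm is conserved.  For
    array ``tau`` the result has shape (3, len(tau)).
    """
    y0 = initial.as_array() if isinstance(initial, CompartmentState) else np.asarray(initial, float)
    tau = np.asarray(tau, dtype=float)
    decay = np.exp(-tau)
    lg = y0[0] * decay
    lm = y0[0] + y0[1] - y0[0] * decay
    ls = y0[2] * np.exp(-nd.mu_s_bar * tau)
    return np.array([lg, lm, ls])


def equilibrium_total_length(params: ModelParameters, delta: float, gamma: float) -> float:
    """Asymptotic total ROS length (μm) for a constant (δ, γ) regime.

    Returns 0 for δ = 0 with γ > 0, +inf for δ > 0 with γ = 0, and the E1
    total length otherwise.  The fully frozen regime (δ = γ = 0) conserves
    the initial total length and has no state-independent value: rejected.
    """
    if delta == 0 and gamma == 0:
        raise ModelDomainError(
            "frozen regime conserves the initial total length; no intrinsic equilibrium length"
        )
    if delta == 0:
        return 0.0
    if gamma == 0:
        return math.inf
    nd = nondimensionalize(params)
    report = equilibrium_points(nd, delta, gamma)
    return report.point("E1").total_length * params.Lmax
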