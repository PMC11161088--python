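"""Cell-death versus regeneration regions in the (ν, ε) rate plane.

During detachment the model is governed by the effective disc addition
rate ν = δ·μ0 (μm/day) and removal rate ε = γ·αs (1/day).  With both
positive, the asymptotic total ROS length is

    Lt∞(ν, ε) = sqrt( Lmax·ν·(αg + ε) / (αg·ε) ),

so the outer segment eventually falls below a critical length Lc exactly
when Lt∞ < Lc.  Writing κ = αg·Lc²/Lmax, that condition is equivalent to
the inequality pair

    ν < κ   and   ε > αg·ν/(κ − ν)          (cell death)

while ν ≥ κ, or ε ≤ αg·ν/(κ − ν), guarantees regeneration for any
reattachment time.  The classifier below compares the closed-form
asymptotic length against Lc (the unambiguous, simulation-verifiable
definition); the inequality form is provided separately and the test suite
asserts their equivalence away from the boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import ModelParameters

__all__ = [
    "DeathRegionQuery",
    "kappa",
    "asymptotic_total_length",
    "classify",
    "classify_by_inequalities",
    "boundary_curve",
    "region_grid",
    "DEATH",
    "REGENERATION",
    "BOUNDARY",
    "FROZEN",
]

DEATH = "death"
REGENERATION = "regeneration"
BOUNDARY = "boundary"
#: ν = ε = 0: nothing is added or removed, the length is conserved, and the
#: verdict depends only on whether the initial length already sits below Lc.
FROZEN = "frozen"

#: Relative half-width of the band around the boundary classified as such.
BOUNDARY_BAND = 1e-9


@dataclass(frozen=True)
class DeathRegionQuery:
    """A point in the effective-rate plane together with the death threshold."""

    nu: float  # effective addition rate ν = δ·μ0, μm/day
    eps: float  # effective removal rate ε = γ·αs, 1/day
    Lc: float  # critical length, μm

    def __post_init__(self) -> None:
        if self.nu < 0 or self.eps < 0:
            raise ValueError("effective rates must be non-negative")
        if not self.Lc > 0:
            raise ValueError("critical length must be positive")


def kappa(params: ModelParameters, Lc: float) -> float:
    """Addition-rate threshold κ = αg·Lc²/Lmax (μm/day) for a critical length Lc.

    On the region boundary the asymptotic total length equals Lc; addition
    rates ν ≥ κ guarantee regeneration for every removal rate.
    """
    if not 0 < Lc < params.Lmax:
        raise ValueError("critical length must lie in (0, Lmax)")
    return params.alpha_g * Lc**2 / params.Lmax


def asymptotic_total_length(params: ModelParameters, nu: float, eps: float) -> float:
    """Asymptotic total ROS length (μm) under effective rates (ν, ε).

    Returns +inf when removal is absent but addition persists, 0 when
    addition is absent but removal persists; the frozen pair (0, 0) has no
    intrinsic asymptote and is rejected.
    """
    if nu < 0 or eps < 0:
        raise ValueError("effective rates must be non-negative")
    if nu == 0 and eps == 0:
        raise ValueError("frozen regime (nu = eps = 0) conserves the initial length")
    if eps == 0:
        return math.inf
    if nu == 0:
        return 0.0
    return math.sqrt(params.Lmax * nu * (params.alpha_g + eps) / (params.alpha_g * eps))


def classify(query: DeathRegionQuery, params: ModelParameters) -> str:
    """Verdict for one (ν, ε) point: death, regeneration, boundary or frozen.

    Authoritative form: the closed-form asymptotic total length is compared
    with Lc; points whose asymptote sits within a relative band of width
    ``BOUNDARY_BAND`` around Lc are labelled "boundary".
    """
    if not query.Lc < params.Lmax:
        raise ValueError("critical length must be below Lmax")
    if query.nu == 0 and query.eps == 0:
        return FROZEN
    lt_inf = asymptotic_total_length(params, query.nu, query.eps)
    if math.isinf(lt_inf):
        return REGENERATION
    if abs(lt_inf - query.Lc) <= BOUNDARY_BAND * query.Lc:
        return BOUNDARY
    return DEATH if lt_inf < query.Lc else REGENERATION


def classify_by_inequalities(query: DeathRegionQuery, params: ModelParameters) -> str:
    """Verdict via the inequality form of the region criteria.

    Death requires ν < κ together with ε > αg·ν/(κ−ν); every other
    non-frozen point regenerates.  Equivalent to :func:`classify` away from
    the boundary band; kept separate as a cross-check.
    """
    if query.nu == 0 and query.eps == 0:
        return FROZEN
    k = kappa(params, query.Lc)
    if query.nu >= k:
        return REGENERATION
    threshold = params.alpha_g * query.nu / (k - query.nu)
    return DEATH if query.eps > threshold else REGENERATION


def boundary_curve(params: ModelParameters, Lc: float, nu_grid) -> np.ndarray:
    """Removal rate ε on the death/regeneration boundary for each ν in (0, κ).

    ε_boundary(ν) = αg·ν/(κ−ν); increasing in ν and diverging as ν → κ⁻.
    """
    k = kappa(params, Lc)
    nu = np.asarray(nu_grid, dtype=float)
    if np.any(nu <= 0) or np.any(nu >= k):
        raise ValueError(f"boundary grid values must lie strictly inside (0, kappa={k:g})")
    return params.alpha_g * nu / (k - nu)


def region_grid(
    params: ModelParameters, Lc: float, nu_values, eps_values
) -> pd.DataFrame:
    """Classify a Cartesian grid of (ν, ε) points; long-format table for mapping."""
    rows = []
    for nu in np.asarray(nu_values, dtype=float):
        for eps in np.asarray(eps_values, dtype=float):
            verdict = classify(DeathRegionQuery(nu=nu, eps=eps, Lc=Lc), params)
            rows.append({"nu": nu, "eps": eps, "verdict": verdict})
    return pd.DataFrame(rows)
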