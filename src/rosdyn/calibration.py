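"""Grid-sweep estimation of the shedding and disposal rates.

The shedding rate αs and disposal rate μs are estimated by sweeping a
rectangular grid of candidate pairs, integrating the model at each pair,
and scoring the unweighted sum of squared residuals between the model's
mature-compartment length Lm and an observed Lm series at the observation
times.  The full objective surface is returned alongside the argmin so
that identifiability can be read off the profiles.

A structural caveat, visible directly in the model: the shed compartment
never feeds back on (Lg, Lm), so Lm carries no information about μs under
any detachment schedule — the μs profile of the objective is flat (up to
solver round-off).  The sweep keeps μs on the grid so the flat profile is
surfaced rather than hidden, but only αs is genuinely identified by
mature-length data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import CompartmentState, DetachmentSchedule, ModelParameters
from .simulate import DEFAULT_ATOL, DEFAULT_RTOL, SimulationError, integrate
from .synthetic import SyntheticDataset

__all__ = ["SweepResult", "sweep_fit", "default_grid"]


def default_grid(center: float, span: float = 0.5, n: int = 21) -> np.ndarray:
    """Log-uniform grid of ``n`` values covering ``center``·[1−span, 1+span]."""
    if not (center > 0 and 0 < span < 1 and n >= 2):
        raise ValueError("need center > 0, span in (0,1) and n >= 2")
    return np.geomspace(center * (1.0 - span), center * (1.0 + span), n)


@dataclass
class SweepResult:
    """Objective surface of a (αs, μs) sweep and its argmin."""

    alpha_s_values: np.ndarray
    mu_s_values: np.ndarray
    objective: np.ndarray  # shape (n_alpha_s, n_mu_s); NaN where integration failed
    best_alpha_s: float
    best_mu_s: float
    best_objective: float

    @property
    def best(self) -> tuple[float, float]:
        return self.best_alpha_s, self.best_mu_s

    @property
    def alpha_s_profile(self) -> np.ndarray:
        """Objective minimised over μs, per αs value."""
        return np.nanmin(self.objective, axis=1)

    @property
    def mu_s_profile(self) -> np.ndarray:
        """Objective minimised over αs, per μs value."""
        return np.nanmin(self.objective, axis=0)

    def to_frame(self) -> pd.DataFrame:
        a, m = np.meshgrid(self.alpha_s_values, self.mu_s_values, indexing="ij")
        return pd.DataFrame(
            {"alpha_s": a.ravel(), "mu_s": m.ravel(), "sse_um2": self.objective.ravel()}
        )


def _observed(observed) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(observed, SyntheticDataset):
        return observed.times, observed.observed_Lm
    times, values = observed
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if times.shape != values.shape or times.ndim != 1:
        raise ValueError("observed series must be two equal-length 1-D arrays")
    if np.any(np.diff(times) <= 0):
        raise ValueError("observation times must be strictly increasing")
    return times, values


def sweep_fit(
    observed,
    fixed: ModelParameters,
    schedule: DetachmentSchedule,
    initial: CompartmentState,
    alpha_s_values=None,
    mu_s_values=None,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
) -> SweepResult:
    """Sweep (αs, μs) pairs against an observed mature-length series.

    ``observed`` is a :class:`~rosdyn.synthetic.SyntheticDataset` or a
    ``(times, Lm)`` pair.  ``fixed`` supplies every parameter other than
    the swept pair (its αs and μs entries centre the default grids).
    Integration failures at a grid point are recorded as NaN in the
    objective, not raised.
    """
    times, y_obs = _observed(observed)
    a_vals = np.asarray(
        default_grid(fixed.alpha_s) if alpha_s_values is None else alpha_s_values, dtype=float
    )
    m_vals = np.asarray(
        default_grid(fixed.mu_s) if mu_s_values is None else mu_s_values, dtype=float
    )
    if a_vals.size == 0 or m_vals.size == 0:
        raise ValueError("sweep grids must be non-empty")
    objective = np.full((a_vals.size, m_vals.size), np.nan)
    for i, a in enumerate(a_vals):
        for j, m in enumerate(m_vals):
            params = fixed.replace(alpha_s=float(a), mu_s=float(m))
            try:
                traj = integrate(initial, params, schedule, horizon=float(times[-1]),
                                 grid=times, rtol=rtol, atol=atol)
            except SimulationError:
                continue
            resid = traj.Lm - y_obs
            objective[i, j] = float(resid @ resid)
    if np.all(np.isnan(objective)):
        raise SimulationError("integration failed at every grid point")
    flat = np.nanargmin(objective)
    bi, bj = np.unravel_index(flat, objective.shape)
    return SweepResult(
        alpha_s_values=a_vals,
        mu_s_values=m_vals,
        objective=objective,
        best_alpha_s=float(a_vals[bi]),
        best_mu_s=float(m_vals[bj]),
        best_objective=float(objective[bi, bj]),
    )
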