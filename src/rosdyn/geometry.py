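"""Conversions between rod outer segment (ROS) disc counts and lengths.

A ROS containing ``N`` stacked discs has length ``ΔT·N + Δs·(N−1)`` where
``ΔT`` is the mean disc thickness and ``Δs`` the mean disc–disc spacing
(one spacing fewer than discs).  The inverse map, ``N = (L+Δs)/(Δs+ΔT)``,
is fractional for generic lengths; a nearest-integer view is provided for
reporting.  Default geometry is the mouse measurements (ΔT = 1.638e-2 μm,
Δs = 1.556e-2 μm).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "DiscGeometry",
    "MOUSE",
    "length_from_discs",
    "discs_from_length",
    "nearest_disc_count",
    "lmax_from_dmax",
    "compartment_length",
]


@dataclass(frozen=True)
class DiscGeometry:
    """Disc stacking geometry of a rod outer segment.

    Parameters
    ----------
    delta_T : float
        Average disc thickness, μm.
    delta_s : float
        Average disc–disc spacing, μm.
    """

    delta_T: float = 1.638e-2
    delta_s: float = 1.556e-2

    def __post_init__(self) -> None:
        if not (self.delta_T > 0 and self.delta_s > 0):
            raise ValueError("disc thickness and spacing must be strictly positive")

    @property
    def pitch(self) -> float:
        """Centre-to-centre distance between adjacent discs, μm."""
        return self.delta_T + self.delta_s


#: Mouse disc geometry (package default).
MOUSE = DiscGeometry()


def length_from_discs(n, geom: DiscGeometry = MOUSE):
    """ROS length (μm) of a stack of ``n`` discs; requires ``n >= 1``."""
    n = np.asarray(n, dtype=float)
    if np.any(n < 1):
        raise ValueError("disc count must be >= 1 (a stack subtracts one spacing)")
    out = geom.delta_T * n + geom.delta_s * (n - 1.0)
    return float(out) if out.ndim == 0 else out


def discs_from_length(length, geom: DiscGeometry = MOUSE):
    """Fractional disc count corresponding to a ROS of the given length (μm)."""
    length = np.asarray(length, dtype=float)
    if np.any(length < 0):
        raise ValueError("length must be non-negative")
    out = (length + geom.delta_s) / geom.pitch
    return float(out) if out.ndim == 0 else out


def nearest_disc_count(length, geom: DiscGeometry = MOUSE):
    """Nearest-integer disc count for a ROS of the given length (μm)."""
    n = discs_from_length(length, geom)
    out = np.rint(np.asarray(n)).astype(int)
    return int(out) if out.ndim == 0 else out


def lmax_from_dmax(d_max, geom: DiscGeometry = MOUSE):
    """Maximum ROS length (μm) for a maximum disc count ``d_max``."""
    return length_from_discs(d_max, geom)


def compartment_length(n, geom: DiscGeometry = MOUSE):
    """Length (μm) occupied by ``n`` discs of one compartment; 0 for ``n = 0``.

    Identical to :func:`length_from_discs` for ``n >= 1`` but maps an empty
    compartment to zero length rather than rejecting it.
    """
    n = np.asarray(n, dtype=float)
    if np.any(n < 0):
        raise ValueError("disc count must be non-negative")
    out = np.where(n > 0, geom.delta_T * n + geom.delta_s * (n - 1.0), 0.0)
    return float(out) if out.ndim == 0 else out
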