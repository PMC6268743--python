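"""Broken-and-intact-cells (BIC) analytic extraction curve.

The model splits the extract between open (broken) cells at the particle
surface, extracted quickly through a fluid film, and intact cells extracted
slowly by diffusion through cell walls.  With plug flow of solvent, a
fluid-phase equilibrium concentration equal to the solubility C0, and the
fluid-phase accumulation term neglected, the extraction curve e(t) has a
closed three-period form controlled by two dimensionless groups

    Z = k_f * a * rho_f * N / (F * (1 - eps) * rho_s)      (fluid film)
    W = k_s * a * N / (F * (1 - eps))                      (solid diffusion)

and by the specific solvent consumption Q = F*t/N.  Period 1 (Q < q_m)
drains the open cells at a constant, nearly saturated outlet concentration;
in period 2 (q_m <= Q < q_n) a depletion front at dimensionless position
z_w travels through the bed while both reservoirs are being extracted;
period 3 (Q >= q_n) is the pure slow extraction of intact cells.

The three branches are algebraically continuous at q_m and q_n, and
e -> q0 as t -> infinity.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np

from .errors import DomainError, InconsistencyError
from .systems import (
    BedSpec,
    ExtractInventory,
    SolventSpec,
    TransferCoeffs,
    solvent_to_feed,
)

__all__ = ["BicDerived", "bic_groups", "bic_boundaries", "bic_derived", "bic_yield"]

_EXP_CLIP = 700.0  # exp() overflow guard for float64


@dataclass(frozen=True)
class BicDerived:
    """Dimensionless groups and period boundaries of the BIC curve.

    ``q_m`` and ``q_n`` are the specific solvent consumptions (kg CO2 per
    kg plant) at which the depletion front enters, respectively leaves,
    the bed; they are ``None`` until computed from a solute inventory.
    """

    Z: float
    W: float
    q_m: float | None = None
    q_n: float | None = None


def bic_groups(
    bed: BedSpec, solvent: SolventSpec, coeffs: TransferCoeffs
) -> BicDerived:
    """Dimensionless fluid-phase (Z) and solid-phase (W) groups.

    Z measures how closely the outlet approaches saturation during the
    fast period (outlet concentration C0*(1 - exp(-Z))); W sets the decay
    of the slow period.  A zero mass-transfer coefficient produces a
    degenerate zero group, which is flagged with a warning because the
    closed-form curve is undefined there.
    """
    denom = solvent.F * (1.0 - bed.epsilon)
    if not denom > 0:
        raise DomainError("zero solvent flow")
    Z = coeffs.k_f * bed.a * solvent.rho_f * bed.N / (denom * bed.rho_s)
    W = coeffs.k_s * bed.a * bed.N / denom
    if Z == 0.0 or W == 0.0:
        warnings.warn(
            "degenerate dimensionless group (Z or W is zero); the analytic "
            "curve is undefined for zero mass-transfer coefficients",
            stacklevel=2,
        )
    return BicDerived(Z=Z, W=W)


def bic_boundaries(inv: ExtractInventory, d: BicDerived) -> tuple[float, float]:
    """Period boundaries (q_m, q_n) in specific solvent consumption.

    q_m = r*q0/(C0*Z) is when the open cells at the bed inlet are
    exhausted; q_n = q_m + ln[(1-r) + r*exp(W*q0/C0)]/W is when the
    depletion front reaches the bed outlet.  For r = 1 the identity
    q_n - q_m = q0/C0 holds.
    """
    if not (d.Z > 0 and d.W > 0):
        raise DomainError(f"Z and W must be positive, got Z={d.Z}, W={d.W}")
    if not inv.r * inv.q0 > 0:
        raise DomainError("r*q0 must be positive")
    q_m = inv.r * inv.q0 / (inv.C0 * d.Z)
    A = d.W * inv.q0 / inv.C0
    if A > _EXP_CLIP:
        # ln[(1-r) + r e^A] = A + ln(r + (1-r) e^-A); exact in float64
        log_term = A + np.log(inv.r + (1.0 - inv.r) * np.exp(-A))
    else:
        log_term = np.log((1.0 - inv.r) + inv.r * np.exp(A))
    q_n = q_m + log_term / d.W
    return float(q_m), float(q_n)


def bic_derived(
    bed: BedSpec,
    solvent: SolventSpec,
    inv: ExtractInventory,
    coeffs: TransferCoeffs,
) -> BicDerived:
    """Groups and boundaries in one call."""
    d = bic_groups(bed, solvent, coeffs)
    q_m, q_n = bic_boundaries(inv, d)
    return BicDerived(Z=d.Z, W=d.W, q_m=q_m, q_n=q_n)


def _e_period1(Q, C0: float, Z: float):
    return C0 * Q * -np.expm1(-Z)


def _e_period2(Q, C0: float, q0: float, r: float, Z: float, W: float, q_m: float):
    """Depletion-front period.  z_w is the dimensionless front position."""
    x = W * (Q - q_m)
    arg = (np.exp(np.minimum(x, _EXP_CLIP)) - (1.0 - r)) / r
    if np.any(arg <= 0):
        raise InconsistencyError("non-positive logarithm argument in period 2")
    z_w = Z * (C0 / (W * q0)) * np.log(arg)
    return C0 * (Q - q_m * np.exp(np.minimum(z_w - Z, _EXP_CLIP)))


def _e_period3(Q, C0: float, q0: float, r: float, W: float, q_m: float):
    A = W * q0 / C0
    # (1-r)*(e^A - 1)*e^(W*(q_m - Q)) rewritten to avoid overflow at large A
    expo = np.minimum(A + W * (q_m - Q), _EXP_CLIP)
    term = (1.0 - r) * -np.expm1(-A) * np.exp(expo)
    return q0 - (C0 / W) * np.log1p(term)


def bic_yield(
    t,
    bed: BedSpec,
    solvent: SolventSpec,
    inv: ExtractInventory,
    coeffs: TransferCoeffs,
) -> np.ndarray | float:
    """Extraction yield e(t), kg extract per kg plant.

    Evaluates the three-period closed form at scalar or array times.
    Points falling exactly on a period boundary are evaluated with the
    higher-period branch; continuity makes the choice observationally
    irrelevant.  ``e(0) = 0`` and ``e`` is bounded by ``q0``.
    """
    d = bic_derived(bed, solvent, inv, coeffs)
    Q = np.atleast_1d(solvent_to_feed(t, solvent.F, bed.N))
    e = np.empty_like(Q)
    m1 = Q < d.q_m
    m3 = Q >= d.q_n
    m2 = ~m1 & ~m3
    if np.any(m1):
        e[m1] = _e_period1(Q[m1], inv.C0, d.Z)
    if np.any(m2):
        e[m2] = _e_period2(Q[m2], inv.C0, inv.q0, inv.r, d.Z, d.W, d.q_m)
    if np.any(m3):
        e[m3] = _e_period3(Q[m3], inv.C0, inv.q0, inv.r, d.W, d.q_m)
    if np.isscalar(t) or np.ndim(t) == 0:
        return float(e[0])
    return e
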