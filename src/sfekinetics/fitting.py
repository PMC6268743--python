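"""Least-squares parameter estimation and the AAD% goodness measure.

The objective is the plain (unweighted) sum of squared yield residuals;
AAD% — the mean absolute relative deviation over points with a non-zero
observed yield — is reported alongside but never optimized, because
optimizing a relative measure would overweight the small early yields.

Because the saturation concentration C0 and the film coefficient k_f both
act on the initial slope, they are not simultaneously identifiable from a
single extraction run; :func:`fit_bic` therefore requires C0 (and q0, r)
to be fixed externally, e.g. from a large-residence-time measurement via
``estimate_C0``, and estimates only (k_f, k_s).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .bic import bic_yield
from .errors import ConvergenceError, DomainError
from .partition import (
    composite_curve,
    ks_from_slow_period,
    partition_coefficient,
    r_from_crossing,
    two_line_fit,
)
from .systems import (
    BedSpec,
    ExtractionCurve,
    ExtractInventory,
    SolventSpec,
    TransferCoeffs,
)

__all__ = ["FitResult", "aad", "fit_bic", "fit_partition"]

DEFAULT_SEED = 20250901
# two decades either side of the coefficient magnitudes typical for
# volatile-oil extraction
KF_BOUNDS = (1e-8, 1e-4)
KS_BOUNDS = (1e-10, 1e-6)


@dataclass(frozen=True)
class FitResult:
    """Estimated parameters with goodness-of-fit diagnostics."""

    model: str
    params: dict[str, float]
    fixed: dict[str, float]
    aad_pct: float
    residuals: np.ndarray
    n_points: int
    converged: bool
    sse: float
    seed: int | None = None
    extras: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.aad_pct < 0:
            raise DomainError("AAD% cannot be negative")


def aad(obs: ExtractionCurve, fit: ExtractionCurve) -> float:
    """Absolute average relative deviation, percent.

    AAD% = (100/n) * sum |e_fit - e_obs| / e_obs over the points with
    e_obs > 0 (the t = 0 point is naturally excluded).  Requires matched
    time grids.
    """
    if len(obs) != len(fit) or not np.allclose(obs.t, fit.t, rtol=1e-9, atol=1e-9):
        raise DomainError("AAD requires matched time grids")
    mask = obs.e > 0
    if not np.any(mask):
        raise DomainError("no points with positive observed yield")
    return float(
        100.0 * np.mean(np.abs(fit.e[mask] - obs.e[mask]) / obs.e[mask])
    )


def fit_bic(
    curve: ExtractionCurve,
    bed: BedSpec,
    solvent: SolventSpec,
    C0: float,
    q0: float,
    r: float,
    n_starts: int = 8,
    seed: int = DEFAULT_SEED,
    kf_bounds: tuple[float, float] = KF_BOUNDS,
    ks_bounds: tuple[float, float] = KS_BOUNDS,
) -> FitResult:
    """Estimate (k_f, k_s) of the BIC model by bounded multistart least squares.

    The search runs in log10 space with starts drawn log-uniformly inside
    the bounds from a seeded generator, so the result is reproducible; the
    best converged start by SSE wins.
    """
    if np.all(curve.e == 0):
        raise DomainError("curve of zeros carries no kinetic information")
    inv = ExtractInventory(q0=q0, C0=C0, r=r)
    t = curve.t

    def resid(p):
        coeffs = TransferCoeffs(k_f=10.0 ** p[0], k_s=10.0 ** p[1])
        return bic_yield(t, bed, solvent, inv, coeffs) - curve.e

    lo = np.log10([kf_bounds[0], ks_bounds[0]])
    hi = np.log10([kf_bounds[1], ks_bounds[1]])
    rng = np.random.default_rng(seed)
    starts = rng.uniform(lo, hi, size=(n_starts, 2))
    best = None
    failures = []
    for x0 in starts:
        try:
            sol = least_squares(resid, x0=x0, bounds=(lo, hi), method="trf")
        except Exception as exc:  # invalid parameter region
            failures.append(str(exc))
            continue
        if not sol.success:
            failures.append(sol.message)
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise ConvergenceError(
            f"no start converged out of {n_starts}; messages: {failures[:3]}"
        )
    k_f, k_s = 10.0 ** best.x[0], 10.0 ** best.x[1]
    fit_curve = ExtractionCurve(
        t, bic_yield(t, bed, solvent, inv, TransferCoeffs(k_f=k_f, k_s=k_s))
    )
    res = curve.e - fit_curve.e
    return FitResult(
        model="bic",
        params={"k_f": float(k_f), "k_s": float(k_s)},
        fixed={"C0": C0, "q0": q0, "r": r},
        aad_pct=aad(curve, fit_curve),
        residuals=-res,
        n_points=len(curve),
        converged=True,
        sse=float(np.sum(res**2)),
        seed=seed,
    )


def fit_partition(
    curve: ExtractionCurve,
    bed: BedSpec,
    solvent: SolventSpec,
    q0: float | None = None,
    corrected: bool = False,
    tail: str = "exponential",
) -> FitResult:
    """Simplified partition-model evaluation of one extraction curve.

    Composes the two-line fit, the crossing-point identification of r,
    the saturation condition for K and the slow-period conversion for
    k_s; reports the AAD% of the composite fitted curve.  ``q0`` may be
    supplied (e.g. from exhaustive extraction); otherwise the fitted
    slow-period asymptote q0_hat is used.
    """
    res = two_line_fit(curve, bed, solvent, q0=q0, tail=tail)
    q0_used = q0 if q0 is not None else res.q0_hat
    inv = ExtractInventory(q0=q0_used, C0=res.C0_hat, r=0.5)  # r placeholder
    r = r_from_crossing(res, inv, bed, solvent)
    inv = ExtractInventory(q0=q0_used, C0=res.C0_hat, r=r)
    K = partition_coefficient(inv, bed, solvent)
    k_s = ks_from_slow_period(res, bed, K=K, solvent=solvent, corrected=corrected)
    e_fit = composite_curve(curve.t, bed, solvent, inv, res.C2)
    fit_curve = ExtractionCurve(curve.t, np.maximum(e_fit, 0.0))
    residuals = fit_curve.e - curve.e
    return FitResult(
        model="partition",
        params={
            "C0": float(res.C0_hat),
            "C1": float(res.C1),
            "C2": float(res.C2),
            "r": float(r),
            "K": float(K),
            "k_s": float(k_s),
            "q0": float(q0_used),
        },
        fixed={} if q0 is None else {"q0": q0},
        aad_pct=aad(curve, fit_curve),
        residuals=residuals,
        n_points=len(curve),
        converged=True,
        sse=float(np.sum(residuals**2)),
        extras={"t_c": res.t_c, "e_c": res.e_c},
    )
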