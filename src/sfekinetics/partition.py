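"""Linear-partition extraction model and its simplified two-line evaluation.

This is the model for solutes that interact with the plant matrix: at
equilibrium the fluid-phase concentration is proportional to the solid-phase
concentration, c = K*q.  With large residence times the film resistance is
negligible and the extraction curve separates into a fast, near-linear
period at saturated outflow and a slow exponential tail.  The simplified
evaluation fits the two periods separately,

    fast period:  e = (C0*F/N) * t                       (through the origin)
    slow period:  e = q0 * (1 - C1 * exp(-C2 * t))

locates their crossing point (t_c, C0*F*t_c/N), and reads the model
parameters off the fitted coefficients:

    r   = C0*F*t_c / (N*q0)            (yield fraction at the crossing)
    K   = C0 / (r*q0 - C0*gamma)       (saturation of the in-bed solvent)
    k_s = C2 / a                       (simplified; optionally *(1 + K*gamma))

where gamma is the in-bed solvent-to-solid mass ratio.  A strictly linear
slow period is available behind ``tail="linear"`` for comparison, but it has
no asymptote at q0 and gives C2 the wrong units for the k_s conversion, so
the exponential form is the default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq, least_squares

from .errors import (
    CurveError,
    DomainError,
    InconsistencyError,
    InfeasibilityError,
    NoCrossingError,
    SegmentationError,
)
from .systems import (
    BedSpec,
    ExtractionCurve,
    ExtractInventory,
    SolventSpec,
    residence_time,
)

__all__ = [
    "TwoLineResult",
    "OpenCellState",
    "equilibrium_fluid_conc",
    "composite_curve",
    "two_line_fit",
    "r_from_crossing",
    "initial_open_cell_state",
    "partition_coefficient",
    "ks_from_slow_period",
    "estimate_C0",
]

# fitted tail slopes within 5% of the fast-period slope at the candidate
# crossing indicate a single-period (degenerate) curve
_PARALLEL_TOL = 0.05


def equilibrium_fluid_conc(q_solid: float, K: float) -> float:
    """Equilibrium fluid concentration c = K*q for a solid loading q."""
    if q_solid < 0:
        raise DomainError(f"solid concentration must be non-negative, got {q_solid}")
    if not K > 0:
        raise DomainError(f"partition coefficient must be positive, got {K}")
    return K * q_solid


@dataclass(frozen=True)
class TwoLineResult:
    """Coefficients of the simplified two-line evaluation.

    Attributes
    ----------
    C0_hat : float
        Equilibrium concentration from the fast-period slope times N/F.
    slope : float
        Fast-period slope de/dt, kg/kg/s.
    C1, C2 : float
        Slow-period amplitude (dimensionless) and rate (1/s) coefficients.
    q0_hat : float
        Asymptote of the slow-period fit (the supplied q0 when it was fixed).
    t_c, e_c : float
        Crossing-point time (s) and yield (kg/kg).
    breakpoint : int
        Number of points assigned to the fast period.
    sse : float
        Total sum of squared residuals of the two segment fits.
    """

    C0_hat: float
    slope: float
    C1: float
    C2: float
    q0_hat: float
    t_c: float
    e_c: float
    breakpoint: int
    sse: float

    def tail(self, t):
        """Slow-period model q0_hat*(1 - C1*exp(-C2*t))."""
        return self.q0_hat * (1.0 - self.C1 * np.exp(-self.C2 * np.asarray(t, float)))

    def line(self, t):
        """Fast-period model slope*t."""
        return self.slope * np.asarray(t, float)


@dataclass(frozen=True)
class OpenCellState:
    """Open-cell solid loading and fluid concentration at t = 0."""

    q1_0: float
    c_0: float


def composite_curve(
    t,
    bed: BedSpec,
    solvent: SolventSpec,
    inv: ExtractInventory,
    C2: float,
) -> np.ndarray:
    """Two-period composite curve used to emulate partition-model data.

    The fast period is the saturated line (C0*F/N)*t up to the crossing
    time t_c = r*q0*N/(C0*F); the slow period is the exponential
    q0*(1 - C1*exp(-C2*t)) with C1 chosen so the two branches meet at t_c.
    """
    if not C2 > 0:
        raise DomainError(f"C2 must be positive, got {C2}")
    slope = inv.C0 * solvent.F / bed.N
    t_c = inv.r * inv.q0 / slope
    C1 = (1.0 - inv.r) * np.exp(C2 * t_c)
    t = np.asarray(t, dtype=float)
    return np.where(
        t < t_c, slope * t, inv.q0 * (1.0 - C1 * np.exp(-C2 * t))
    )


def _fit_tail_exponential(t2, e2, q0_fixed):
    """Fit e = q0*(1 - C1*exp(-C2*t)) on the tail points.

    With a supplied q0 the fit is a linear regression on log(q0 - e);
    otherwise a bounded nonlinear least squares with the asymptote free,
    initialized just above the largest observed yield.  Returns
    (q0_hat, C1, C2, sse) with sse measured in yield space, or None when
    the candidate segment admits no valid tail (used to reject
    breakpoints during segmentation).
    """
    if q0_fixed is not None:
        resid0 = q0_fixed - e2
        if np.all(resid0 > 0):
            b, lna = np.polyfit(t2, np.log(resid0), 1)
            C2 = -b
            if not C2 > 0:
                return None
            C1 = np.exp(lna) / q0_fixed
        else:
            # noisy tail points may overshoot the fixed asymptote; fall back
            # to a nonlinear fit of (C1, C2) with the asymptote held
            b, lna = np.polyfit(t2, np.log(np.maximum(resid0, 1e-6 * q0_fixed)), 1)
            x0 = [lna - np.log(q0_fixed), np.log(max(-b, 0.1 / max(t2[-1], 1.0)))]

            def resid(p):
                return q0_fixed * (1.0 - np.exp(p[0] - np.exp(p[1]) * t2)) - e2

            sol = least_squares(resid, x0=x0, bounds=([-50.0, -50.0], [50.0, 50.0]))
            if not sol.success:
                return None
            C1, C2 = float(np.exp(sol.x[0])), float(np.exp(sol.x[1]))
        q0_hat = q0_fixed
    else:
        q0_init = 1.05 * float(np.max(e2))
        resid0 = np.maximum(q0_init - e2, 1e-300)
        b, lna = np.polyfit(t2, np.log(resid0), 1)
        C2_init = max(-b, 1.0 / max(t2[-1], 1.0))
        C1_init = max(np.exp(lna) / q0_init, 1e-12)

        def resid(p):
            q0h, lc1, lc2 = p
            return q0h * (1.0 - np.exp(lc1) * np.exp(-np.exp(lc2) * t2)) - e2

        emax = float(np.max(e2))
        sol = least_squares(
            resid,
            x0=[q0_init, np.log(C1_init), np.log(C2_init)],
            bounds=([emax, -50.0, -50.0], [np.inf, 50.0, 50.0]),
            method="trf",
        )
        if not sol.success:
            return None
        q0_hat, C1, C2 = sol.x[0], float(np.exp(sol.x[1])), float(np.exp(sol.x[2]))
    fit = q0_hat * (1.0 - C1 * np.exp(-C2 * t2))
    return float(q0_hat), float(C1), float(C2), float(np.sum((fit - e2) ** 2))


def _fit_tail_linear(t2, e2):
    """Straight-line tail e = C1 + C2*t (comparison variant)."""
    C2, C1 = np.polyfit(t2, e2, 1)
    fit = C1 + C2 * t2
    return float(C1), float(C2), float(np.sum((fit - e2) ** 2))


def two_line_fit(
    curve: ExtractionCurve,
    bed: BedSpec,
    solvent: SolventSpec,
    q0: float | None = None,
    tail: str = "exponential",
    min_seg: int = 3,
) -> TwoLineResult:
    """Simplified two-line evaluation of an extraction curve.

    The breakpoint between fast-period and slow-period points is chosen by
    minimizing the total SSE over all admissible splits with at least
    ``min_seg`` points per segment (ties broken toward the earlier
    breakpoint).  The crossing time is found by root bisection between the
    fitted branches.

    Raises
    ------
    SegmentationError
        Fewer than 5 points, or no admissible split.
    CurveError
        Non-monotone yields.
    NoCrossingError
        The two fitted branches do not cross inside the observed span
        (e.g. a strictly linear single-period curve).
    """
    if len(curve) < 5 or len(curve) < 2 * min_seg:
        raise SegmentationError(
            f"need at least {max(5, 2 * min_seg)} points, got {len(curve)}"
        )
    if not curve.is_nondecreasing():
        raise CurveError("extraction curve must be non-decreasing")
    if tail not in ("exponential", "linear"):
        raise ValueError(f"unknown tail model {tail!r}")

    t, e = curve.t, curve.e
    candidates = []
    for k in range(min_seg, len(curve) - min_seg + 1):
        t1, e1 = t[:k], e[:k]
        t2, e2 = t[k:], e[k:]
        denom = float(np.sum(t1 * t1))
        if denom == 0.0:
            continue
        slope = float(np.sum(t1 * e1)) / denom
        sse1 = float(np.sum((e1 - slope * t1) ** 2))
        if tail == "exponential":
            tail_fit = _fit_tail_exponential(t2, e2, q0)
            if tail_fit is None:
                continue
            q0_hat, C1, C2, sse2 = tail_fit
        else:
            C1, C2, sse2 = _fit_tail_linear(t2, e2)
            q0_hat = float("nan")
        candidates.append((sse1 + sse2, k, slope, q0_hat, C1, C2))
    if not candidates:
        raise SegmentationError("no admissible breakpoint produced a valid tail fit")

    # splits whose fitted branches do not cross are inadmissible: walk the
    # candidates in SSE order (stable sort, so ties go to the earlier
    # breakpoint) until one yields a crossing
    candidates.sort(key=lambda c: c[0])
    last_err: Exception = NoCrossingError("fitted fast and slow periods do not cross")
    for total, k, slope, q0_hat, C1, C2 in candidates:
        if not slope > 0:
            continue
        if tail == "exponential":
            def tail_f(x, q0h=q0_hat, c1=C1, c2=C2):
                return q0h * (1.0 - c1 * np.exp(-c2 * x))
        else:
            def tail_f(x, c1=C1, c2=C2):
                return c1 + c2 * x
        try:
            t_c = _find_crossing(t, k, slope, tail_f)
        except NoCrossingError as err:
            last_err = err
            continue
        # guard against near-parallel segments (single-period curves)
        d_tail = (tail_f(t_c + 1e-6 * t[-1]) - tail_f(t_c)) / (1e-6 * t[-1])
        if abs(d_tail - slope) < _PARALLEL_TOL * slope:
            last_err = NoCrossingError(
                "fitted segments are nearly parallel at the crossing"
            )
            continue
        return TwoLineResult(
            C0_hat=slope * bed.N / solvent.F,
            slope=slope,
            C1=C1,
            C2=C2,
            q0_hat=q0_hat,
            t_c=float(t_c),
            e_c=float(slope * t_c),
            breakpoint=k,
            sse=total,
        )
    raise last_err


def _find_crossing(t, k, slope, tail_f):
    """Root of line(t) - tail(t), bracketed near the breakpoint.

    Tries the design bracket (one fast-period spacing either side of the
    breakpoint) first, then falls back to a scan of the whole observed
    span for a sign change.
    """
    def f(x):
        return slope * x - tail_f(x)

    spacing = t[k - 1] - t[k - 2] if k >= 2 else t[1] - t[0]
    lo, hi = max(t[k] - spacing, 0.0), t[k - 1] + spacing
    xtol = 1e-6 * t[-1]
    if f(lo) * f(hi) < 0:
        return brentq(f, lo, hi, xtol=xtol)
    grid = np.linspace(t[0] if t[0] > 0 else xtol, t[-1], 512)
    vals = f(grid)
    sign_change = np.nonzero(np.diff(np.sign(vals)) != 0)[0]
    if sign_change.size == 0:
        raise NoCrossingError("fitted fast and slow periods do not cross")
    i = sign_change[0]
    return brentq(f, grid[i], grid[i + 1], xtol=xtol)


def r_from_crossing(
    res: TwoLineResult,
    inv: ExtractInventory,
    bed: BedSpec,
    solvent: SolventSpec,
) -> float:
    """Easily accessible fraction r = C0*F*t_c/(N*q0) = e_c/q0.

    The yield fraction extracted at the crossing point is identified with
    the open-cell fraction of the total extractable content.
    """
    if not inv.q0 > 0:
        raise DomainError("q0 must be positive")
    if not res.t_c > 0:
        raise DomainError("crossing time must be positive")
    r = res.C0_hat * solvent.F * res.t_c / (bed.N * inv.q0)
    if not 0.0 < r <= 1.0:
        raise InconsistencyError(
            f"r = {r:.4g} outside (0, 1]; bad segmentation or wrong q0"
        )
    return float(r)


def partition_coefficient(
    inv: ExtractInventory, bed: BedSpec, solvent: SolventSpec
) -> float:
    """Partition coefficient K = C0/(r*q0 - C0*gamma).

    Imposes that the solvent held in the bed at t = 0 is saturated (c = C0)
    after equilibrating with the open cells.  Infeasible when the open-cell
    inventory r*q0 cannot raise the in-bed solvent to C0.
    """
    gamma = bed.gamma(solvent.rho_f)
    denom = inv.r * inv.q0 - inv.C0 * gamma
    if denom <= 0:
        raise InfeasibilityError(
            "r*q0 <= C0*gamma: in-bed solvent cannot reach the saturation "
            "concentration C0"
        )
    return float(inv.C0 / denom)


def initial_open_cell_state(
    inv: ExtractInventory, bed: BedSpec, solvent: SolventSpec
) -> OpenCellState:
    """Open-cell loading after equilibration with the in-bed solvent.

    Mass balance over open cells and bed fluid, r*q0 = q1_0*(1 + K*gamma),
    gives q1_0 = r*q0/(1 + K*gamma) and c_0 = K*q1_0.  With K from
    :func:`partition_coefficient`, c_0 equals C0 identically.
    """
    if inv.K is None:
        raise DomainError("K must be set on the inventory")
    gamma = bed.gamma(solvent.rho_f)
    q1_0 = inv.r * inv.q0 / (1.0 + inv.K * gamma)
    return OpenCellState(q1_0=float(q1_0), c_0=float(inv.K * q1_0))


def ks_from_slow_period(
    res: TwoLineResult,
    bed: BedSpec,
    K: float | None = None,
    solvent: SolventSpec | None = None,
    corrected: bool = False,
) -> float:
    """Solid-phase coefficient from the slow-period rate, k_s = C2/a.

    The default is the simplified conversion.  With ``corrected=True`` the
    solvent-holdup factor (1 + K*gamma) is applied; under typical operating
    conditions K*gamma is a few percent, which is why the simplified form
    is standard.
    """
    if not bed.a > 0:
        raise DomainError("specific surface must be positive")
    k_s = res.C2 / bed.a
    if corrected:
        if K is None or solvent is None:
            raise DomainError("corrected conversion needs K and the solvent spec")
        k_s *= 1.0 + K * bed.gamma(solvent.rho_f)
    return float(k_s)


def estimate_C0(
    curve: ExtractionCurve,
    bed: BedSpec,
    solvent: SolventSpec,
    n_initial: int | None = None,
    t_r_warn: float = 30.0,
) -> float:
    """Saturation concentration from the initial slope, C0 = slope*N/F.

    The estimate is only meaningful when the residence time is large
    enough for the outflow to be saturated during the fast period; a
    warning is emitted when t_r falls below ``t_r_warn`` seconds.

    With ``n_initial`` the slope is a through-origin fit on that many
    leading points; otherwise the two-line segmentation chooses the
    fast-period segment.
    """
    if n_initial is not None:
        if n_initial < 3 or len(curve) < n_initial:
            raise SegmentationError("need at least 3 points in the initial segment")
        t1, e1 = curve.t[:n_initial], curve.e[:n_initial]
        denom = float(np.sum(t1 * t1))
        if denom == 0.0:
            raise SegmentationError("initial segment has no positive times")
        slope = float(np.sum(t1 * e1)) / denom
    else:
        slope = two_line_fit(curve, bed, solvent).slope
    if not slope > 0:
        raise DomainError("zero initial slope: C0 estimate is invalid")
    t_r = residence_time(bed, solvent)
    if t_r < t_r_warn:
        warnings.warn(
            f"residence time {t_r:.1f} s < {t_r_warn:.0f} s: outflow may not be "
            "saturated, C0 estimate doubtful",
            stacklevel=2,
        )
    return float(slope * bed.N / solvent.F)
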