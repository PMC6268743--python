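"""Physical system descriptions shared by every model in the package.

Strict SI units throughout: masses in kg, lengths in m, times in s.
Extraction yields ``e`` and solid-phase contents ``q`` are mass ratios in
kg extract per kg of plant material as fed; fluid-phase concentrations are
kg extract per kg CO2.

The packed bed is described by :class:`BedSpec` (feed mass, void fraction,
solid density, particle size), the solvent stream by :class:`SolventSpec`
(mass flow rate and CO2 density at the operating point — the density is an
input, never computed from P and T), the solute inventory by
:class:`ExtractInventory` and the two mass-transfer coefficients by
:class:`TransferCoeffs`.  :class:`ExtractionCurve` is the universal exchange
object: an ordered series of (time, cumulative yield) points.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import CurveError, DomainError

__all__ = [
    "BedSpec",
    "SolventSpec",
    "ExtractInventory",
    "TransferCoeffs",
    "ExtractionCurve",
    "surface_to_volume",
    "solvent_to_feed",
    "residence_time",
]


def surface_to_volume(d_p: float) -> float:
    """Specific surface of spherical particles, a = 6/d_p (m^-1).

    Parameters
    ----------
    d_p : float
        Mean particle diameter in m; must be positive.
    """
    if not d_p > 0:
        raise DomainError(f"particle diameter must be positive, got {d_p}")
    return 6.0 / d_p


def solvent_to_feed(t, F: float, N: float):
    """Specific solvent consumption Q = F*t/N (kg CO2 per kg plant).

    Normalizes extraction time to the amount of solvent passed per unit
    feed; both analytic models are naturally expressed in Q.  Accepts a
    scalar or array time and returns the matching shape.
    """
    if not F > 0:
        raise DomainError(f"flow rate must be positive, got {F}")
    if not N > 0:
        raise DomainError(f"feed mass must be positive, got {N}")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise DomainError("negative extraction time")
    q = F * t / N
    return float(q) if q.ndim == 0 else q


@dataclass(frozen=True)
class BedSpec:
    """Packed bed of milled plant material.

    Attributes
    ----------
    N : float
        Feed mass of plant material, kg.
    epsilon : float
        Bed void fraction, dimensionless, in (0, 1).
    rho_s : float
        Density of the plant solid, kg/m^3.
    d_p : float
        Mean particle diameter, m.
    """

    N: float
    epsilon: float
    rho_s: float
    d_p: float

    def __post_init__(self) -> None:
        if not self.N > 0:
            raise DomainError(f"feed mass must be positive, got {self.N}")
        if not 0.0 < self.epsilon < 1.0:
            raise DomainError(f"void fraction must lie in (0, 1), got {self.epsilon}")
        if not self.rho_s > 0:
            raise DomainError(f"solid density must be positive, got {self.rho_s}")
        if not self.d_p > 0:
            raise DomainError(f"particle diameter must be positive, got {self.d_p}")

    @property
    def a(self) -> float:
        """Surface-to-volume ratio of the particles, 6/d_p, m^-1."""
        return surface_to_volume(self.d_p)

    @property
    def V_bed(self) -> float:
        """Bed volume N/((1-eps)*rho_s), m^3."""
        return self.N / ((1.0 - self.epsilon) * self.rho_s)

    def gamma(self, rho_f: float) -> float:
        """In-bed solvent-to-solid mass ratio eps*rho_f/((1-eps)*rho_s)."""
        if not rho_f > 0:
            raise DomainError(f"solvent density must be positive, got {rho_f}")
        return self.epsilon * rho_f / ((1.0 - self.epsilon) * self.rho_s)


@dataclass(frozen=True)
class SolventSpec:
    """CO2 stream at the operating point.

    ``P`` (MPa) and ``T`` (K) are carried as metadata only; the density
    ``rho_f`` is always an explicit input.
    """

    F: float
    rho_f: float
    P: float | None = None
    T: float | None = None

    def __post_init__(self) -> None:
        if not self.F > 0:
            raise DomainError(f"flow rate must be positive, got {self.F}")
        if not self.rho_f > 0:
            raise DomainError(f"CO2 density must be positive, got {self.rho_f}")


def residence_time(bed: BedSpec, solvent: SolventSpec) -> float:
    """Mean solvent residence time eps*V_bed*rho_f/F, s.

    A large residence time means the solution leaving the extractor is
    saturated during the fast period, which is what justifies reading the
    equilibrium concentration C0 off the initial slope.
    """
    return bed.epsilon * bed.V_bed * solvent.rho_f / solvent.F


@dataclass(frozen=True)
class ExtractInventory:
    """Solute parameters of the plant charge.

    Attributes
    ----------
    q0 : float
        Total extractable content, kg extract per kg plant.
    C0 : float
        Initial equilibrium (saturation) concentration in the fluid phase,
        kg extract per kg CO2.
    r : float
        Fraction of the extract that is easily accessible (open cells near
        the particle surface), in (0, 1].
    K : float, optional
        Linear solid-fluid partition coefficient; only the partition model
        uses it.
    """

    q0: float
    C0: float
    r: float
    K: float | None = None

    def __post_init__(self) -> None:
        if not self.q0 > 0:
            raise DomainError(f"q0 must be positive, got {self.q0}")
        if not self.C0 > 0:
            raise DomainError(f"C0 must be positive, got {self.C0}")
        if not 0.0 < self.r <= 1.0:
            raise DomainError(f"r must lie in (0, 1], got {self.r}")
        if self.K is not None and not self.K > 0:
            raise DomainError(f"K must be positive when set, got {self.K}")


@dataclass(frozen=True)
class TransferCoeffs:
    """Film (fluid-side) and solid-side mass-transfer coefficients, m/s.

    Multiplying by the specific surface ``a`` gives the volumetric
    coefficients k_f*a and k_s*a in 1/s that set the time scales of the
    fast and slow extraction periods.
    """

    k_f: float
    k_s: float

    def __post_init__(self) -> None:
        if self.k_f < 0:
            raise DomainError(f"k_f must be non-negative, got {self.k_f}")
        if self.k_s < 0:
            raise DomainError(f"k_s must be non-negative, got {self.k_s}")

    def k_f_a(self, a: float) -> float:
        """Volumetric fluid-phase coefficient k_f*a, 1/s."""
        return self.k_f * a

    def k_s_a(self, a: float) -> float:
        """Volumetric solid-phase coefficient k_s*a, 1/s."""
        return self.k_s * a


@dataclass(frozen=True)
class ExtractionCurve:
    """Ordered (t, e) series: cumulative yield vs extraction time.

    Time must be strictly increasing and non-negative; yields must be
    non-negative; a point at t = 0, when present, must have e = 0 (nothing
    has been collected when the solution starts leaving the extractor).
    Between sample points the curve is interpreted piecewise-linearly and
    no other interpolation convention is used anywhere in the package.
    """

    t: np.ndarray
    e: np.ndarray

    def __post_init__(self) -> None:
        t = np.atleast_1d(np.asarray(self.t, dtype=float))
        e = np.atleast_1d(np.asarray(self.e, dtype=float))
        if t.shape != e.shape or t.ndim != 1:
            raise CurveError("t and e must be 1-D arrays of equal length")
        if t.size and t[0] < 0:
            raise CurveError("negative time in extraction curve")
        if np.any(np.diff(t) <= 0):
            raise CurveError("time must be strictly increasing")
        if np.any(e < 0):
            raise CurveError("negative yield in extraction curve")
        if t.size and t[0] == 0.0 and e[0] != 0.0:
            raise CurveError("yield at t = 0 must be 0")
        t.flags.writeable = False
        e.flags.writeable = False
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "e", e)

    def __len__(self) -> int:
        return self.t.size

    @classmethod
    def from_points(cls, points: Iterable[tuple[float, float]]) -> "ExtractionCurve":
        arr = np.asarray(list(points), dtype=float)
        if arr.size == 0:
            return cls(np.empty(0), np.empty(0))
        return cls(arr[:, 0], arr[:, 1])

    def interp(self, times) -> np.ndarray:
        """Piecewise-linear yield at arbitrary times within the span."""
        return np.interp(np.asarray(times, dtype=float), self.t, self.e)

    def to_frame(self) -> pd.DataFrame:
        """Two-column frame with the package's standard header."""
        return pd.DataFrame({"t_s": self.t, "e_kg_per_kg": self.e})

    def is_nondecreasing(self, atol: float = 0.0) -> bool:
        return bool(np.all(np.diff(self.e) >= -atol))
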