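"""Synthetic extraction curves with the structure of gravimetric yield data.

Real extraction curves are cumulative oil masses weighed at successive
times: a near-linear saturated start followed by an exponential diffusion
tail.  The generator evaluates one of the package's models on a time grid
and applies multiplicative Gaussian noise (gravimetric relative error is
roughly scale-free; additive noise is available as an option), clips
negatives and enforces monotonicity by a cumulative maximum — a cumulative
weighed yield cannot decrease.

Seven per-species scenario presets ship with the package (operating
conditions plus fitted solute parameters and mass-transfer coefficients
for both models); the easily accessible fraction r is not a reported
per-species quantity, so presets declare r = 0.5 explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

import numpy as np
import yaml

from .bic import bic_yield
from .errors import DomainError
from .partition import composite_curve
from .systems import (
    BedSpec,
    ExtractionCurve,
    ExtractInventory,
    SolventSpec,
    TransferCoeffs,
)

__all__ = ["ScenarioPreset", "list_presets", "get_preset", "generate"]


@dataclass(frozen=True)
class ScenarioPreset:
    """One plant-species extraction scenario.

    ``coeffs`` carries the BIC-model pair (k_f, k_s); ``k_s_partition``
    is the partition-model solid-phase coefficient, whose volumetric form
    k_s*a is the slow-period rate C2 of the composite curve.
    """

    name: str
    common_name: str
    bed: BedSpec
    solvent: SolventSpec
    inv: ExtractInventory
    coeffs: TransferCoeffs
    k_s_partition: float

    @property
    def C2(self) -> float:
        """Slow-period rate coefficient implied by k_s_partition, 1/s."""
        return self.k_s_partition * self.bed.a


@lru_cache(maxsize=1)
def _load_presets() -> dict[str, ScenarioPreset]:
    text = resources.files("sfekinetics").joinpath("presets/plants.yaml").read_text()
    raw = yaml.safe_load(text)
    presets = {}
    for row in raw["presets"]:
        bed = BedSpec(
            N=row["N"], epsilon=row["epsilon"], rho_s=row["rho_s"], d_p=row["d_p"]
        )
        solvent = SolventSpec(
            F=row["F"], rho_f=row["rho_f"], P=row["P_MPa"], T=row["T_K"]
        )
        inv = ExtractInventory(q0=row["q0"], C0=row["C0"], r=row["r"])
        coeffs = TransferCoeffs(k_f=row["k_f_bic"], k_s=row["k_s_bic"])
        presets[row["name"]] = ScenarioPreset(
            name=row["name"],
            common_name=row["common_name"],
            bed=bed,
            solvent=solvent,
            inv=inv,
            coeffs=coeffs,
            k_s_partition=row["k_s_partition"],
        )
    return presets


def list_presets() -> list[str]:
    """Names of the shipped species scenarios."""
    return list(_load_presets())


def get_preset(name: str) -> ScenarioPreset:
    presets = _load_presets()
    if name not in presets:
        raise DomainError(
            f"unknown preset {name!r}; available: {', '.join(presets)}"
        )
    return presets[name]


def _model_curve(model, times, bed, solvent, inv, coeffs, C2):
    if model == "bic":
        if coeffs is None:
            raise DomainError("bic generation needs transfer coefficients")
        return bic_yield(times, bed, solvent, inv, coeffs)
    if model in ("partition", "composite"):
        if C2 is None:
            raise DomainError("composite generation needs the slow-period rate C2")
        return composite_curve(times, bed, solvent, inv, C2)
    raise ValueError(f"unknown model {model!r}")


def generate(
    preset: ScenarioPreset | str | None = None,
    model: str = "composite",
    times=None,
    noise_sd_rel: float = 0.0,
    seed: int | None = None,
    *,
    bed: BedSpec | None = None,
    solvent: SolventSpec | None = None,
    inv: ExtractInventory | None = None,
    coeffs: TransferCoeffs | None = None,
    C2: float | None = None,
    additive_sd: float = 0.0,
) -> ExtractionCurve:
    """Generate one synthetic extraction curve.

    Parameters
    ----------
    preset : ScenarioPreset or str, optional
        Scenario supplying bed/solvent/inventory/coefficients; any of the
        explicit keyword objects overrides the preset's.
    model : {"bic", "partition", "composite"}
        "bic" evaluates the three-period analytic curve from (k_f, k_s);
        "partition" and "composite" evaluate the two-period composite
        curve — "partition" derives the slow-period rate from the
        preset's partition-model k_s (C2 = k_s*a, the simplified
        conversion), "composite" requires an explicit C2.
    times : array-like
        Sampling times in s.
    noise_sd_rel : float
        Relative standard deviation of multiplicative Gaussian noise.
    seed : int, optional
        Seed for the noise generator; the same seed reproduces the curve
        bit for bit.
    additive_sd : float
        Standard deviation of optional additive noise, kg/kg.
    """
    if isinstance(preset, str):
        preset = get_preset(preset)
    if preset is not None:
        bed = bed or preset.bed
        solvent = solvent or preset.solvent
        inv = inv or preset.inv
        coeffs = coeffs or preset.coeffs
        if C2 is None and model == "partition":
            C2 = preset.C2
    if bed is None or solvent is None or inv is None:
        raise DomainError("generation needs bed, solvent and inventory specs")
    if noise_sd_rel < 0 or additive_sd < 0:
        raise DomainError("noise levels must be non-negative")
    if times is None:
        raise DomainError("a sampling-time grid is required")
    times = np.asarray(times, dtype=float)

    e = np.asarray(_model_curve(model, times, bed, solvent, inv, coeffs, C2))
    if noise_sd_rel > 0 or additive_sd > 0:
        rng = np.random.default_rng(seed)
        if noise_sd_rel > 0:
            e = e * (1.0 + rng.normal(0.0, noise_sd_rel, size=e.shape))
        if additive_sd > 0:
            e = e + rng.normal(0.0, additive_sd, size=e.shape)
        e = np.maximum.accumulate(np.maximum(e, 0.0))
        if times[0] == 0.0:
            e[0] = 0.0
    return ExtractionCurve(times, e)
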