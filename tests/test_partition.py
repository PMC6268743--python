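"""Partition model: two-line evaluation, crossing point, K and k_s recovery."""

import numpy as np
import pytest

from sfekinetics import (
    BedSpec,
    ExtractionCurve,
    ExtractInventory,
    SolventSpec,
    composite_curve,
    equilibrium_fluid_conc,
    estimate_C0,
    initial_open_cell_state,
    ks_from_slow_period,
    partition_coefficient,
    r_from_crossing,
    two_line_fit,
)
from sfekinetics.errors import (
    CurveError,
    DomainError,
    InconsistencyError,
    InfeasibilityError,
    NoCrossingError,
    SegmentationError,
)
from sfekinetics.partition import TwoLineResult

BED = BedSpec(N=0.1, epsilon=0.4, rho_s=750.0, d_p=0.5e-3)
SOLVENT = SolventSpec(F=4.7e-4, rho_f=385.0)


def _result(**over):
    base = dict(
        C0_hat=1.4e-3, slope=6.58e-6, C1=0.8, C2=1.8e-4, q0_hat=0.03437,
        t_c=2000.0, e_c=6.58e-6 * 2000.0, breakpoint=4, sse=0.0,
    )
    base.update(over)
    return TwoLineResult(**base)


class TestEquilibrium:
    def test_linear_relationship(self):
        assert equilibrium_fluid_conc(0.0, 0.11) == 0.0
        assert equilibrium_fluid_conc(0.0132, 0.11) == pytest.approx(1.45e-3, rel=2e-3)
        assert equilibrium_fluid_conc(0.02, 0.11) == pytest.approx(
            2 * equilibrium_fluid_conc(0.01, 0.11), rel=1e-12
        )

    def test_rejects_bad_inputs(self):
        with pytest.raises(DomainError):
            equilibrium_fluid_conc(-0.01, 0.11)
        with pytest.raises(DomainError):
            equilibrium_fluid_conc(0.01, 0.0)


class TestTwoLineFit:
    def test_noiseless_roundtrip_recovers_coefficients(self, grid_5h):
        inv = ExtractInventory(q0=0.03437, C0=1.4e-3, r=0.5)
        e = composite_curve(grid_5h, BED, SOLVENT, inv, C2=1.8e-4)
        res = two_line_fit(ExtractionCurve(grid_5h, e), BED, SOLVENT)
        assert res.slope == pytest.approx(6.58e-6, rel=5e-3)
        assert res.C2 == pytest.approx(1.8e-4, rel=5e-3)
        assert res.C0_hat == pytest.approx(1.4e-3, rel=5e-3)
        assert res.q0_hat == pytest.approx(0.03437, rel=5e-3)
        # crossing time is where the saturated line reaches r*q0
        assert res.t_c == pytest.approx(0.5 * 0.03437 / 6.58e-6, rel=1e-2)

    def test_single_period_line_has_no_crossing(self):
        t = np.linspace(0.0, 10000.0, 12)
        curve = ExtractionCurve(t, 6.58e-6 * t)
        with pytest.raises((NoCrossingError, SegmentationError)):
            two_line_fit(curve, BED, SOLVENT)

    def test_too_few_points(self):
        t = np.array([0.0, 100.0, 200.0])
        with pytest.raises(SegmentationError):
            two_line_fit(ExtractionCurve(t, 6.58e-6 * t), BED, SOLVENT)

    def test_rejects_non_monotone_curve(self, grid_5h):
        inv = ExtractInventory(q0=0.03437, C0=1.4e-3, r=0.5)
        e = composite_curve(grid_5h, BED, SOLVENT, inv, C2=1.8e-4).copy()
        e[10] = e[9] * 0.5
        with pytest.raises(CurveError):
            two_line_fit(ExtractionCurve(grid_5h, e), BED, SOLVENT)


class TestCrossingPoint:
    def test_reference_r(self):
        inv = ExtractInventory(q0=0.03437, C0=1.4e-3, r=0.5)
        r = r_from_crossing(_result(), inv, BED, SOLVENT)
        assert r == pytest.approx(0.383, rel=2e-3)

    def test_full_accessibility_when_crossing_at_q0(self):
        inv = ExtractInventory(q0=0.03437, C0=1.4e-3, r=0.5)
        t_c = inv.q0 / 6.58e-6  # e_c = q0
        r = r_from_crossing(_result(t_c=t_c, e_c=inv.q0), inv, BED, SOLVENT)
        assert r == pytest.approx(1.0, rel=1e-9)

    def test_out_of_range_r_is_inconsistent(self):
        inv = ExtractInventory(q0=0.002, C0=1.4e-3, r=0.5)  # e_c > q0
        with pytest.raises(InconsistencyError):
            r_from_crossing(_result(), inv, BED, SOLVENT)
        with pytest.raises(DomainError):
            r_from_crossing(_result(t_c=0.0), inv, BED, SOLVENT)


class TestPartitionCoefficient:
    def test_reference_value(self):
        inv = ExtractInventory(q0=0.03437, C0=1.4e-3, r=0.383)
        assert partition_coefficient(inv, BED, SOLVENT) == pytest.approx(
            0.110, rel=5e-3
        )

    def test_no_holdup_limit(self):
        # vanishing void fraction -> gamma ~ 0 -> K -> C0/(r*q0)
        thin = BedSpec(N=0.1, epsilon=1e-6, rho_s=750.0, d_p=0.5e-3)
        inv = ExtractInventory(q0=0.03437, C0=1.4e-3, r=0.383)
        K = partition_coefficient(inv, thin, SOLVENT)
        assert K == pytest.approx(inv.C0 / (inv.r * inv.q0), rel=1e-4)

    def test_infeasible_when_inventory_too_small(self):
        gamma = BED.gamma(SOLVENT.rho_f)
        inv = ExtractInventory(q0=1.4e-3 * gamma / 0.5, C0=1.4e-3, r=0.5)
        with pytest.raises(InfeasibilityError):
            partition_coefficient(inv, BED, SOLVENT)


class TestOpenCellState:
    def test_reference_value(self):
        inv = ExtractInventory(q0=0.03437, C0=1.4e-3, r=0.383, K=0.110)
        st = initial_open_cell_state(inv, BED, SOLVENT)
        assert st.q1_0 == pytest.approx(0.01268, rel=2e-3)
        assert st.c_0 == pytest.approx(0.110 * st.q1_0, rel=1e-12)

    def test_no_dissolution_limit(self):
        inv = ExtractInventory(q0=0.03437, C0=1.4e-3, r=0.383, K=1e-12)
        st = initial_open_cell_state(inv, BED, SOLVENT)
        assert st.q1_0 == pytest.approx(inv.r * inv.q0, rel=1e-9)

    def test_infinite_holdup_limit(self):
        dense = SolventSpec(F=4.7e-4, rho_f=1e9)
        inv = ExtractInventory(q0=0.03437, C0=1.4e-3, r=0.383, K=0.11)
        st = initial_open_cell_state(inv, BED, dense)
        assert st.q1_0 < 1e-4 * inv.r * inv.q0

    @pytest.mark.parametrize("r,q0,C0", [(0.383, 0.03437, 1.4e-3), (0.7, 0.02, 2e-3)])
    def test_saturation_consistency(self, r, q0, C0):
        """K from the saturation condition reproduces c_0 = C0 exactly."""
        inv = ExtractInventory(q0=q0, C0=C0, r=r)
        K = partition_coefficient(inv, BED, SOLVENT)
        st = initial_open_cell_state(
            ExtractInventory(q0=q0, C0=C0, r=r, K=K), BED, SOLVENT
        )
        assert abs(st.c_0 - C0) <= 1e-12 * C0


class TestSlowPeriodConversion:
    def test_simplified_inversion(self):
        assert ks_from_slow_period(_result(), BED) == pytest.approx(1.5e-8, rel=1e-9)

    def test_holdup_correction_factor(self):
        gamma = BED.gamma(SOLVENT.rho_f)
        K = 0.04 / gamma  # K*gamma = 0.04
        simple = ks_from_slow_period(_result(), BED)
        corr = ks_from_slow_period(_result(), BED, K=K, solvent=SOLVENT, corrected=True)
        assert corr / simple == pytest.approx(1.04, rel=1e-9)
        tiny = ks_from_slow_period(_result(), BED, K=1e-15, solvent=SOLVENT, corrected=True)
        assert tiny == pytest.approx(simple, rel=1e-9)


class TestEstimateC0:
    def test_reference_value(self, grid_5h):
        inv = ExtractInventory(q0=0.03437, C0=1.4e-3, r=0.5)
        e = composite_curve(grid_5h, BED, SOLVENT, inv, C2=1.8e-4)
        C0 = estimate_C0(ExtractionCurve(grid_5h, e), BED, SOLVENT)
        assert C0 == pytest.approx(1.4e-3, rel=5e-3)

    def test_inverse_proportionality_to_flow(self):
        t = np.linspace(0.0, 1000.0, 5)
        curve = ExtractionCurve(t, 6.58e-6 * t)
        c_lo = estimate_C0(curve, BED, SOLVENT, n_initial=5)
        c_hi = estimate_C0(curve, BED, SolventSpec(F=2 * 4.7e-4, rho_f=385.0), n_initial=5)
        assert c_hi == pytest.approx(0.5 * c_lo, rel=1e-12)

    def test_zero_slope_flagged(self):
        t = np.linspace(0.0, 1000.0, 5)
        with pytest.raises(DomainError):
            estimate_C0(ExtractionCurve(t, np.zeros(5)), BED, SOLVENT, n_initial=5)

    def test_warns_on_short_residence_time(self):
        t = np.linspace(0.0, 1000.0, 5)
        curve = ExtractionCurve(t, 6.58e-6 * t)
        fast = SolventSpec(F=0.1, rho_f=385.0)  # t_r ~ 0.3 s
        with pytest.warns(UserWarning, match="residence time"):
            estimate_C0(curve, BED, fast, n_initial=5)


def test_fast_slope_insensitive_to_film_coefficient(pennyroyal):
    """With near-saturated outflow (Z >= 5) the period-1 slope carries no
    information about k_f — the basis for fixing C0 from the initial slope."""
    from sfekinetics import TransferCoeffs, plugflow_solve

    p = pennyroyal
    slopes = []
    for k_f in (2.3e-6, 1e-5):  # Z ~ 5 and ~ 22
        sol = plugflow_solve(
            p.bed, p.solvent, p.inv, TransferCoeffs(k_f=k_f, k_s=p.coeffs.k_s),
            mode="bic", t_end=400.0, n_cells=100,
        )
        mask = sol.curve.t > 50.0
        t1, e1 = sol.curve.t[mask], sol.curve.e[mask]
        slopes.append(np.sum(t1 * e1) / np.sum(t1 * t1))
    assert abs(slopes[1] - slopes[0]) / slopes[0] < 0.01
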