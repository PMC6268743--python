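"""Three-period analytic extraction curve: values, continuity, asymptotes."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sfekinetics import (
    BedSpec,
    ExtractInventory,
    SolventSpec,
    TransferCoeffs,
    bic_boundaries,
    bic_derived,
    bic_groups,
    bic_yield,
)
from sfekinetics.bic import _e_period1, _e_period2, _e_period3
from sfekinetics.errors import DomainError

BED = BedSpec(N=0.1, epsilon=0.4, rho_s=750.0, d_p=0.5e-3)
SOLVENT = SolventSpec(F=4.7e-4, rho_f=385.0)


def test_groups_reference_values(pennyroyal):
    d = bic_groups(pennyroyal.bed, pennyroyal.solvent, pennyroyal.coeffs)
    # k_f = 1.95e-6, a = 12000: Z = k_f*a*rho_f*N/(F*(1-eps)*rho_s)
    assert d.Z == pytest.approx(4.26, rel=2e-3)
    # k_s = 0.89e-8: W = k_s*a*N/(F*(1-eps))
    assert d.W == pytest.approx(0.0379, rel=2e-3)


def test_zero_coefficient_flags_degenerate_group():
    with pytest.warns(UserWarning, match="degenerate"):
        d = bic_groups(BED, SOLVENT, TransferCoeffs(k_f=0.0, k_s=1e-8))
    assert d.Z == 0.0
    with pytest.raises(DomainError):
        bic_boundaries(ExtractInventory(q0=0.03, C0=1.4e-3, r=0.5), d)


def test_boundary_qm_reference_value():
    inv = ExtractInventory(q0=0.03437, C0=1.4e-3, r=0.5)
    d = bic_groups(BED, SOLVENT, TransferCoeffs(k_f=1.95e-6, k_s=0.89e-8))
    q_m, q_n = bic_boundaries(inv, d)
    assert q_m == pytest.approx(2.88, rel=2e-3)  # r*q0/(C0*Z)
    assert q_n > q_m


def test_fully_accessible_extract_identity():
    """For r = 1 the period-2 width collapses to q_n - q_m = q0/C0."""
    inv = ExtractInventory(q0=0.03437, C0=1.4e-3, r=1.0)
    d = bic_groups(BED, SOLVENT, TransferCoeffs(k_f=1.95e-6, k_s=0.89e-8))
    q_m, q_n = bic_boundaries(inv, d)
    assert q_n - q_m == pytest.approx(inv.q0 / inv.C0, rel=1e-12)


def test_slow_transfer_limit_of_period_two_width():
    """As the solid-phase coefficient vanishes the depletion front is
    driven by film transfer alone: q_n - q_m -> r*q0/C0 (the solvent
    needed to dissolve the open-cell inventory at saturation), while the
    slow period that follows stalls (e stuck near the crossing yield)."""
    inv = ExtractInventory(q0=0.03437, C0=1.4e-3, r=0.5)
    d = bic_groups(BED, SOLVENT, TransferCoeffs(k_f=1.95e-6, k_s=1e-14))
    q_m, q_n = bic_boundaries(inv, d)
    assert q_n - q_m == pytest.approx(inv.r * inv.q0 / inv.C0, rel=1e-3)
    coeffs = TransferCoeffs(k_f=1.95e-6, k_s=1e-14)
    t_n = 2.0 * q_n * BED.N / SOLVENT.F
    e = bic_yield(t_n, BED, SOLVENT, inv, coeffs)
    assert e == pytest.approx(inv.r * inv.q0, rel=1e-3)


def test_curve_endpoints(pennyroyal):
    """e(0) = 0 and e -> q0; the period-3 tail decays like exp(-W*(Q-q_m)),
    so twelve decay constants past the period-2 width suffice for 1e-4*q0."""
    p = pennyroyal
    assert bic_yield(0.0, p.bed, p.solvent, p.inv, p.coeffs) == 0.0
    d = bic_derived(p.bed, p.solvent, p.inv, p.coeffs)
    A = d.W * p.inv.q0 / p.inv.C0
    q_far = d.q_m + (A + 12.0) / d.W
    t_far = q_far * p.bed.N / p.solvent.F
    e_far = bic_yield(t_far, p.bed, p.solvent, p.inv, p.coeffs)
    assert abs(e_far - p.inv.q0) < 1e-4 * p.inv.q0


def test_initial_slope_matches_saturated_outflow(pennyroyal):
    p = pennyroyal
    d = bic_derived(p.bed, p.solvent, p.inv, p.coeffs)
    dt = 1e-3
    slope = bic_yield(dt, p.bed, p.solvent, p.inv, p.coeffs) / dt
    expected = (p.solvent.F / p.bed.N) * p.inv.C0 * -np.expm1(-d.Z)
    assert slope == pytest.approx(expected, rel=1e-9)
    # as Z -> inf this approaches the partition model's period-1 line C0*F/N
    fast = TransferCoeffs(k_f=1e-4, k_s=p.coeffs.k_s)
    slope_fast = bic_yield(dt, p.bed, p.solvent, p.inv, fast) / dt
    assert slope_fast == pytest.approx(p.inv.C0 * p.solvent.F / p.bed.N, rel=1e-9)


_params = dict(
    k_f=st.floats(1e-7, 1e-5),
    k_s=st.floats(1e-9, 1e-7),
    C0=st.floats(5e-4, 3e-3),
    q0=st.floats(2e-3, 4e-2),
    r=st.floats(0.05, 0.95),
)


@settings(max_examples=60, derandomize=True, deadline=None)
@given(**_params)
def test_branch_continuity_at_period_boundaries(k_f, k_s, C0, q0, r):
    """The piecewise branches agree at q_m and q_n to 1e-10*q0."""
    inv = ExtractInventory(q0=q0, C0=C0, r=r)
    d = bic_derived(BED, SOLVENT, inv, TransferCoeffs(k_f=k_f, k_s=k_s))
    e1 = _e_period1(np.array([d.q_m]), C0, d.Z)[0]
    e2m = _e_period2(np.array([d.q_m]), C0, q0, r, d.Z, d.W, d.q_m)[0]
    e2n = _e_period2(np.array([d.q_n]), C0, q0, r, d.Z, d.W, d.q_m)[0]
    e3 = _e_period3(np.array([d.q_n]), C0, q0, r, d.W, d.q_m)[0]
    assert abs(e1 - e2m) < 1e-10 * q0
    assert abs(e2n - e3) < 1e-10 * q0


@settings(max_examples=40, derandomize=True, deadline=None)
@given(**_params)
def test_curve_monotone_and_bounded(k_f, k_s, C0, q0, r):
    inv = ExtractInventory(q0=q0, C0=C0, r=r)
    coeffs = TransferCoeffs(k_f=k_f, k_s=k_s)
    d = bic_derived(BED, SOLVENT, inv, coeffs)
    t_n = d.q_n * BED.N / SOLVENT.F
    t = np.linspace(0.0, 2.0 * t_n, 400)
    e = bic_yield(t, BED, SOLVENT, inv, coeffs)
    assert np.all(np.diff(e) >= -1e-12 * q0)
    assert np.all(e >= 0.0)
    assert np.all(e <= q0 * (1 + 1e-12))
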