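"""Simplified two-line evaluation of a partition-model extraction curve.

Generates a noiseless 25-point pennyroyal curve over 5 h, fits the
saturated fast-period line and the exponential slow period, and converts
the coefficients into the physical parameters: the crossing point gives
the easily accessible fraction r, the saturation condition gives the
partition coefficient K, and the slow-period rate gives k_s = C2/a.
"""

import numpy as np

from sfekinetics import (
    ExtractInventory,
    generate,
    get_preset,
    initial_open_cell_state,
    ks_from_slow_period,
    partition_coefficient,
    r_from_crossing,
    two_line_fit,
)

p = get_preset("Mentha pulegium")
times = np.linspace(0.0, 5 * 3600.0, 25)
curve = generate(p, model="partition", times=times)

res = two_line_fit(curve, p.bed, p.solvent)
print(f"fast-period slope  = {res.slope:.3e} kg/kg/s  -> C0 = {res.C0_hat:.2e} kg/kg")
print(f"slow period        : C1 = {res.C1:.3f}, C2 = {res.C2:.3e} 1/s")
print(f"crossing point     : t_c = {res.t_c:.0f} s, e_c = {res.e_c * 1e3:.2f} g/kg")

r = r_from_crossing(res, p.inv, p.bed, p.solvent)
inv = ExtractInventory(q0=p.inv.q0, C0=res.C0_hat, r=r)
K = partition_coefficient(inv, p.bed, p.solvent)
state = initial_open_cell_state(
    ExtractInventory(q0=p.inv.q0, C0=res.C0_hat, r=r, K=K), p.bed, p.solvent
)
k_s = ks_from_slow_period(res, p.bed)
print(f"r = {r:.3f}  K = {K:.4f}  q1(0) = {state.q1_0 * 1e3:.2f} g/kg")
print(f"k_s = {k_s:.3e} m/s (generating value {p.k_s_partition:.3e})")
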