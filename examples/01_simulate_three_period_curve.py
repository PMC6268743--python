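"""Evaluate the three-period broken-and-intact-cells curve for pennyroyal.

Builds the shipped pennyroyal scenario (10.0 MPa, 323 K, 0.5 mm particles,
F = 4.7e-4 kg/s) and prints the dimensionless groups, the period
boundaries, and the extraction yield at a few times.  Z measures how close
the outflow is to saturation during the fast period; q_m and q_n bracket
the travelling depletion front in units of kg CO2 per kg plant.
"""

import numpy as np

from sfekinetics import bic_derived, bic_yield, get_preset, solvent_to_feed

p = get_preset("Mentha pulegium")
d = bic_derived(p.bed, p.solvent, p.inv, p.coeffs)
print(f"Z = {d.Z:.3f}  W = {d.W:.4f}")
print(f"q_m = {d.q_m:.2f}  q_n = {d.q_n:.2f}  (kg CO2 / kg plant)")

for t in [0.0, 900.0, 3600.0, 7200.0, 14400.0]:
    e = bic_yield(t, p.bed, p.solvent, p.inv, p.coeffs)
    Q = solvent_to_feed(t, p.solvent.F, p.bed.N)
    print(f"t = {t:7.0f} s  Q = {Q:6.2f}  e = {e * 1e3:.3f} g/kg")
print(f"total extractable content q0 = {p.inv.q0 * 1e3:.2f} g/kg")
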