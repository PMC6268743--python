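"""Round-trip the two-line evaluation over all seven shipped species.

For each scenario preset, generates a noiseless partition-model curve on
a grid adapted to that species' kinetics and recovers the solid-phase
mass-transfer coefficient; the relative error column shows that the
evaluation pipeline is exact on its own model family across the full
parameter range of the shipped scenarios.
"""

import numpy as np

from sfekinetics import generate, get_preset, ks_from_slow_period, list_presets, two_line_fit

print(f"{'species':<28} {'k_s gen':>10} {'k_s fit':>10} {'rel err':>8}")
for name in list_presets():
    p = get_preset(name)
    t_c = p.inv.r * p.inv.q0 * p.bed.N / (p.inv.C0 * p.solvent.F)
    times = np.unique(np.concatenate([
        np.linspace(0.0, t_c, 8, endpoint=False),
        t_c + np.linspace(0.0, 5.0 / p.C2, 17),
    ]))
    curve = generate(p, model="partition", times=times)
    res = two_line_fit(curve, p.bed, p.solvent)
    k_s = ks_from_slow_period(res, p.bed)
    err = k_s / p.k_s_partition - 1.0
    print(f"{name:<28} {p.k_s_partition:10.2e} {k_s:10.2e} {100 * err:+7.3f}%")
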