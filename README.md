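# sfekinetics

Mass-transfer modelling of supercritical-CO₂ extraction of plant volatile
oils: extraction-curve simulation, the simplified two-line evaluation, and
least-squares recovery of mass-transfer coefficients from measured curves.

## The problem

Supercritical CO₂ extraction of volatile oils from milled aromatic plants
(pennyroyal, fennel, coriander, savory, winter savory, cotton lavender,
thyme) produces *extraction curves*: cumulative oil yield
e (kg·(kg plant)⁻¹) versus time. Engineers fitting these curves need the
parameters that let them scale the process — the solute solubility, the
accessible fraction of the oil, and the film and intra-particle
mass-transfer coefficients. This package implements the two packed-bed
model families used for that purpose and the fitting procedures that
recover their parameters, for people who design or evaluate supercritical
extraction experiments.

Both models assume plug flow of solvent through the bed and distinguish
easily accessible extract in open (broken) cells near the particle
surface, removed quickly through a fluid film, from extract in intact
cells removed slowly by diffusion through cell walls.

**Three-period (broken-and-intact-cells) model.** With fluid-phase
equilibrium at the solubility C₀ and the fluid accumulation term
neglected, the curve e(Q), with Q = F·t/N the specific solvent
consumption, has a closed three-period form governed by two dimensionless
groups

```
Z = k_f a ρ_f N / (F (1−ε) ρ_s)        (film transfer)
W = k_s a N / (F (1−ε))                (intra-particle diffusion)
```

with a = 6/d_p the specific particle surface. Period 1 (Q < q_m, with
q_m = r·q₀/(C₀·Z)) is the near-saturated linear start; in period 2 a
depletion front crosses the bed; period 3 is the exponential diffusion
tail approaching the total extractable content q₀.

**Linear-partition model, two-line evaluation.** For solutes interacting
with the plant matrix, equilibrium is c = K·q. With large residence time
the film resistance is negligible and the curve is evaluated with two
fitted branches,

```
fast:  e = (C₀ F / N) · t             slow:  e = q₀ (1 − C₁ e^(−C₂ t))
```

whose crossing point (t_c, C₀·F·t_c/N) gives the accessible fraction
r = C₀·F·t_c/(N·q₀), the saturation condition gives
K = C₀/(r·q₀ − C₀·γ) with γ = ε·ρ_f/((1−ε)·ρ_s) the in-bed
solvent-to-solid ratio, and the slow-period rate gives k_s = C₂/a
(optionally corrected by (1 + K·γ)).

A brute-force plug-flow finite-volume solver of the full two-phase
balances serves as an independent numerical cross-check of both closed
forms, and a seeded synthetic-curve generator (with presets for the seven
plant species) emulates gravimetric extraction measurements so every
stage is testable without laboratory data.

## Worked example

Evaluate a noiseless 25-point pennyroyal curve (10.0 MPa, 323 K,
F = 4.7·10⁻⁴ kg·s⁻¹, 0.5 mm particles) with the two-line procedure
(`python examples/02_two_line_evaluation.py`):

```
fast-period slope  = 6.580e-06 kg/kg/s  -> C0 = 1.40e-03 kg/kg
slow period        : C1 = 0.800, C2 = 1.800e-04 1/s
crossing point     : t_c = 2612 s, e_c = 17.19 g/kg
r = 0.500  K = 0.0838  q1(0) = 16.71 g/kg
k_s = 1.500e-08 m/s (generating value 1.500e-08)
```

The fast-period slope times N/F returns the solubility C₀ = 1.40·10⁻³
kg/kg; the crossing at 2612 s says half of the 34.37 g/kg total oil sits
in open cells (r = 0.5); and the slow-period rate converts to a
solid-phase coefficient k_s = 1.50·10⁻⁸ m/s — identical to the value the
curve was generated from, confirming the evaluation is exact on its own
model family. The same round trip with 2% gravimetric noise
(`examples/03_fit_roundtrip_with_noise.py`) recovers the three-period
model's coefficients to a few percent:

```
k_f: fitted 2.017e-06 m/s, generating 1.950e-06 m/s (+3.4%)
k_s: fitted 8.952e-09 m/s, generating 8.900e-09 m/s (+0.6%)
AAD = 1.04% over 25 points (multistart seed 20250901)
```

The other examples simulate the three-period curve, cross-check it
against the plug-flow solver (0.2% maximum deviation, solute balance
closed to 2·10⁻¹⁴), and survey all seven species presets.

A thin CLI wraps the same functions: `sfekinetics presets | generate |
simulate | twoline | fit | oracle-check`, reading two-column curve files
and a flat YAML config, and writing reports plus JSON run manifests.

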