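# Methods

This note documents the models, the numerical choices, and the design
decisions behind `sfekinetics`, including what the synthetic-data
generator does and does not emulate.

## Physical setting and conventions

A packed bed of milled plant material (feed mass N, void fraction ε,
solid density ρ_s, mean particle diameter d_p) is percolated by
supercritical CO₂ (mass flow F, density ρ_f at the operating pressure and
temperature). All quantities are strict SI. Yields e and solid-phase
contents q are mass ratios per kg of plant **as fed**; fluid-phase
concentrations c are kg extract per kg CO₂. The CO₂ density is always an
input — the package deliberately contains no equation of state.

Derived quantities used throughout: specific particle surface a = 6/d_p
(spheres), bed volume V_bed = N/((1−ε)ρ_s), in-bed solvent-to-solid mass
ratio γ = ε·ρ_f/((1−ε)ρ_s), and mean residence time t_r = ε·V_bed·ρ_f/F.
t = 0 is the moment solution starts leaving the extractor; curves are
cumulative yields at sample times, interpreted piecewise-linearly and in
no other way anywhere in the package.

## Three-period (broken-and-intact-cells) curve

Assumptions: plug flow; fluid-phase equilibrium at the solubility C₀;
film transfer orders of magnitude faster than intra-particle diffusion;
fluid-phase accumulation neglected. With Q = F·t/N and the groups
Z = k_f·a·ρ_f·N/(F(1−ε)ρ_s) and W = k_s·a·N/(F(1−ε)):

- period 1 (Q < q_m = r·q₀/(C₀Z)): e = C₀·Q·(1 − e^(−Z));
- period 2 (q_m ≤ Q < q_n): e = C₀·[Q − q_m·e^(z_w − Z)] with front
  coordinate z_w = Z·(C₀/(W·q₀))·ln{[e^(W(Q−q_m)) − (1−r)]/r} and
  q_n = q_m + ln[(1−r) + r·e^(W·q₀/C₀)]/W;
- period 3 (Q ≥ q_n): e = q₀ − (C₀/W)·ln{1 + (1−r)(e^(W·q₀/C₀) − 1)·
  e^(W(q_m − Q))}.

The three branches are algebraically continuous at q_m and q_n (verified
symbolically and tested to 10⁻¹⁰·q₀ over randomized parameters); e(0) = 0
and e → q₀. Boundary points are evaluated with the higher-period branch —
continuity makes the choice observationally irrelevant. Two limits worth
recording because they are easy to get wrong: as W → 0⁺ the period-2
width tends to the finite value r·q₀/C₀ (the front is film-driven; what
diverges is the *duration* of period 3, the yield stalling near r·q₀),
and the period-3 approach to q₀ has decay exponent W·(Q − q_m) − W·q₀/C₀,
so "large Q" must be measured against that exponent, not against a fixed
multiple of q_n. Exponentials are clipped at exp(700) and the period-3
logarithm is computed via log1p on a rearranged argument, so the curve is
finite for any parameters inside the fitting bounds.

## Partition model and the simplified two-line evaluation

For solutes interacting with the matrix, solid and fluid are locally in
linear equilibrium c = K·q. The simplified evaluation fits two branches
in the (t, e) plane: the saturated line e = (C₀F/N)·t through the origin,
and the slow period e = q₀(1 − C₁e^(−C₂t)). The crossing (t_c, C₀Ft_c/N)
identifies r = C₀Ft_c/(N·q₀); imposing that the solvent held in the bed
at t = 0 equilibrated with the open cells to exactly C₀ gives
K = C₀/(r·q₀ − C₀γ) (infeasible, and reported as such, when the open-cell
inventory cannot saturate the holdup); the slow-period rate converts as
k_s = C₂/a, with the holdup correction (1 + K·γ) available behind a flag
(it is a few percent under typical conditions, which is why the
simplified form is the default).

Design choices where the procedure itself is under-specified:

- **Shape of the slow period.** A literal straight line has no asymptote
  at q₀ and gives C₂ the wrong units for the k_s conversion, so the
  exponential form is the default; a strictly linear tail is available
  behind `tail="linear"` for comparison.
- **Segmentation.** The breakpoint between fast and slow points minimizes
  the total SSE over all splits with ≥ 3 points per segment, ties broken
  toward the earlier breakpoint. Splits whose fitted branches do not
  cross inside the observed span are inadmissible: candidates are walked
  in SSE order until one crosses. On noiseless two-period curves the
  first candidate always crosses, so this fallback changes nothing there;
  with noise it rescues the occasional split that absorbs the first tail
  point into the line. Strictly single-period curves exhaust all
  candidates and raise a no-crossing error, with a 5% slope-parallelism
  guard to catch exponentials degenerating into lines.
- **Tail fitting.** With q₀ known, linear regression on log(q₀ − e)
  (falling back to a bounded nonlinear fit of (C₁, C₂) when noisy points
  overshoot the asymptote); with q₀ free, bounded nonlinear least squares
  in (q₀, ln C₁, ln C₂) initialized at q₀ = 1.05·max(e) and the
  log-linear slope.
- **Crossing search.** Brent root finding on line − tail, first inside a
  bracket one fast-period spacing either side of the breakpoint, then on
  the first sign change of a 512-point scan of the observed span,
  tolerance 10⁻⁶·t_max.
- **C₀ estimation.** C₀ = (fast-period slope)·N/F. The estimate is only
  meaningful when the outflow is saturated during the fast period, so a
  warning is emitted when t_r < 30 s (configurable).

## Least-squares fitting and AAD%

The objective is the plain unweighted SSE on yields. AAD% — the mean of
|e_fit − e_obs|/e_obs over points with e_obs > 0, in percent — is
reported but never optimized, because a relative objective would
overweight the small early yields. For the three-period model only
(k_f, k_s) are estimated; C₀, q₀ and r must be fixed externally, since C₀
and k_f act on the same observable (the initial slope) and are not
jointly identifiable from one run — the test suite demonstrates the flat
SSE valley directly. The search runs in log₁₀ space with bounds
k_f ∈ [10⁻⁸, 10⁻⁴] m/s and k_s ∈ [10⁻¹⁰, 10⁻⁶] m/s (two decades around
the magnitudes typical for volatile-oil extraction) and 8 multistart
points drawn log-uniformly from a generator seeded with 20250901 by
default, so results are reproducible; noiseless round trips recover the
generating coefficients to ~10⁻⁷ relative, and with 1% gravimetric noise
the median k_s error over randomized parameter sets stays below 10% for
both model families.

## Plug-flow cross-check solver

An independent finite-volume integrator of the full two-phase balances
(first-order upwind advection, explicit Euler, CFL-limited steps) serves
as the numerical oracle for both closed forms. Per axial cell:
ε·ρ_f·∂c/∂t + (F/A_bed)·∂c/∂z equals the transfer source; open cells
lose extract through the film (driving force c* − c with c* = C₀ in the
three-period closure, c* = K·q₁ in the partition closure); intact cells
lose extract at rate ∝ k_s·a. Choices that matter:

- **Coefficient conventions.** The two model families place the (1−ε)
  factor differently in their volumetric coefficients: the three-period
  groups imply transfer rates per bed volume of k_f·a·ρ_f·Δc and
  k_s·a·ρ_s·q₂·(·), while the two-line conversion k_s = C₂/a implies a
  solid rate of k_s·a per particle volume. The solver follows the
  convention of the family it cross-checks (an extra 1/(1−ε) on both
  fluxes in three-period mode); with a single fixed convention the two
  codes would describe different physical systems and the comparison
  would be meaningless.
- **Sequential slow extraction.** In three-period mode, intact cells at a
  bed location start releasing only once the open cells there are empty,
  mirroring the model family's assumption. Without the gate, inlet-region
  intact cells release into unsaturated solvent from t = 0 and the
  numeric curve runs a systematic ~5% above the closed form at the
  period-2/3 transition, an offset that does not shrink with grid
  refinement because it is physical, not numerical.
- **Initial state.** The bed starts at the quasi-steady fast-period
  profile, matching the t = 0 convention: in partition mode
  q₁ = r·q₀/(1 + Kγ) with c = K·q₁ uniform; in three-period mode
  c(z) = C₀(1 − e^(−Z·z/L)) with the local open-cell loading depleted by
  exactly the dissolved amount. Both make the initial solute inventory
  exactly N·q₀, so the discrete balance (solids + bed fluid + collected)
  closes to round-off (~10⁻¹⁴ relative; the tests require 10⁻⁸).
- **Stability.** The explicit update couples advection and source
  amplification additively, so the step is cfl/Σ(rates), not the naive
  CFL bound alone; transfer fluxes are clamped at the per-step reservoir
  inventory to keep concentrations non-negative without breaking the
  balance (the clamped flux enters both phases).
- **Geometry.** A_bed comes from V_bed with a 5:1 length-to-diameter
  aspect ratio; the solution depends on the cross-section only through
  the residence time, and the tests verify aspect-ratio invariance.

Measured agreement at the pennyroyal scenario (400 cells, 4 h): analytic
three-period curve vs solver 0.2% maximum relative deviation, first-order
grid convergence. The two-line composite curve vs the partition-mode
solver agrees to ~5% after one residence time: the full model's slow
period decays slightly slower than C₂ = k_s·a because the bed-average
fluid concentration is not negligible against K·q₂
(N·k_s·a/(F·K) ≈ 0.35 here). That systematic offset is a property of the
simplified evaluation itself, and the corresponding test asserts the
cross-check at 8%.

## Synthetic data

The generator evaluates a model curve on a sampling grid and applies
multiplicative Gaussian noise (gravimetric relative error is roughly
scale-free; additive noise is available), clips negatives, and enforces
monotonicity with a cumulative maximum — cumulative weighed yields cannot
decrease. Curves are reproducible bit-for-bit from a seed. Scenario
presets for the seven plant species carry the operating conditions and
the fitted parameter values of each species; quantities that are not
species-specific measurements are package defaults, stated explicitly and
always overridable: ε = 0.4, ρ_s = 750 kg·m⁻³, ρ_f = 385 kg·m⁻³ (CO₂
near 10 MPa / 323 K), N = 0.1 kg (mid-range of the 70–120 g charges such
experiments use), and r = 0.5, since the accessible fraction is not
reported per species. Particle sizes are 0.5 mm (pennyroyal) and 0.6 mm
(the others), the millimetre scale at which these extractions are run.

What the generator does **not** emulate: wax co-extraction and separator
fractionation, flow-rate drift, temperature or pressure gradients, axial
dispersion, and measurement-time jitter. Passing round trips therefore
show that the estimation pipeline is consistent and noise-robust on the
models' own curve shapes — not that the models describe any particular
plant. One structural bias is worth knowing: on curve regions flatter
than the noise scale, the monotonic projection necessarily drags the
running maximum upward, so ensemble means converge to the noiseless curve
only where inter-sample increments exceed the noise standard deviation;
the law-of-large-numbers test runs on the steep region for exactly that
reason.

## Problem sizes

The standard round-trip design is 25 samples over 5 h (8 h when the free
asymptote is fitted), matching a realistic gravimetric sampling schedule;
the cross-check solver runs 400 axial cells over 4 h (≈ 9·10⁴ steps) in a
few seconds; randomized property suites use 20–60 parameter sets. These
sizes were chosen so that each check is comfortably resolved — the
round-trip identities hold to far better than the tolerances asserted.

## Known limitations

- The two-line evaluation assumes a visible two-period structure; curves
  that are single-period over the observed span are rejected rather than
  extrapolated.
- No uncertainty quantification beyond residuals and AAD% (no bootstrap
  confidence intervals).
- The partition-model variants for non-interacting solutes and combined
  film/internal resistances are out of scope, as are axial dispersion and
  non-isothermal operation.
- k_s from the two-line slow period inherits the ~15% systematic
  difference between C₂ and the full model's effective tail rate
  discussed above; users needing the full-model coefficient should fit
  the plug-flow solver directly.
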