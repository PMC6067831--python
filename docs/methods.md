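# Methods

## Model

The HPA axis is modeled as five nondimensional delay differential
equations (README for the equations). Concentration units are set by
steady-state reference levels and time by the plasma cortisol clearance
rate, so one dimensionless time unit is 7.2/ln 2 ≈ 10.39 min. Conversions
(`minutes_to_dimensionless`, `rate_ratio_from_halflives`) keep protocol
clock times and drug half-lives consistent with that scaling: the 15-min
adrenal delay is `t_d = 1.44`, the 9-h DST draw is 51.99 units, and the
relative clearances of dexamethasone and cosyntropin are `p7 = 7.2/240 =
0.03` and `p8 = 1.7` (7.2/4.1 truncated to the conventional value; the
exact ratio 1.756 is available from the helper).

Assumptions inherited with the model structure:

* the cortisol–receptor complex is at quasi-steady state and acts only
  through the product `o·r`;
* CRH self-upregulation acts through pituitary auto/paracrine signaling,
  as a Hill term in the circulating-CRH equation;
* dexamethasone penetrates the brain poorly, so `o_exo` is added to
  cortisol in the pituitary feedback and GR-production terms but **not**
  in the hypothalamic synthesis target `c∞(o)`;
* the synaptic drive `I(t)` is piecewise constant (basal `I0` plus
  rectangular stressor steps); no circadian modulation is included.

## Parameters

All rate constants except two have established nondimensional values,
kept as defaults of `ParameterSet` (q0 = 28, q1 = 0.04, q2 = 1.8,
gc_max = 42, n = 5, k = 2.83, b = 0.6, p2 = 15, p3 = 7.2, p4 = 0.05,
p5 = 0.11, p6 = 2.9, t_d = 1.44, I0 = 1, p7 = 0.03, p8 = 1.7). Where
sources disagree on the Hill coefficient (n = 5 vs n = 6), the default is
n = 5; sweeps make it trivial to regenerate either variant. Since only the
product `q0·I` enters the release balance, bistability is exactly
invariant under `q0 → λq0, I0 → I0/λ` (tested).

### The two calibrated constants

`c_inf_bar` (the stored-CRH synthesis floor under full cortisol
suppression) and `t_c` (the relaxation time of the stored pool) have no
established nondimensional values. They were fixed once by the documented
search in `scripts/calibrate.py`:

* `c_inf_bar` positions the cs-nullcline horizontally. The fold of the
  reference c-nullcline spans cs ∈ [0.653, 0.884] while the averaged
  feedback term `⟨e^{−b·o}⟩` contributes ≈ 0.50–0.56 over the fold's
  c-range, so only `c_inf_bar` ≈ 0.15–0.30 yields three intersections.
  The shipped value is **0.18**.
* `t_c` sets how far the slow variables drift during the 9 h of a DST.
  Too small (≲ 100) and the diseased state slides past the lower knee
  while suppressed, destroying the diseased-more-suppressed signature;
  larger values saturate. The shipped value is **120** (≈ 21 h), at the
  slow end of the "minutes to hours" description of CRH stores but
  required by the slow post-DEX nullcline relaxation the protocols rely
  on.

The selection rule (period-averaged suppressions inside 63 ± 5 and
73 ± 5, diseased strictly above normal in both measurement modes, best
margin on the normal state) was fixed before the scan; both constants
remain ordinary overridable fields.

## Numerics

**Integrator.** Method of steps with classical fixed-step RK4 (default
step 0.01 ≈ 6 s). The delayed terms `a(t−t_d)`, `a_exo(t−t_d)` are read
from the stored solution by cubic Hermite interpolation of node values and
node derivatives, keeping the scheme fourth order (verified by a
Richardson test: error ratios ≈ 16 per step halving, and agreement with an
independent adaptive method-of-steps reference built on scipy's RK45).
Node derivatives are stored two-sided because the right-hand side is
discontinuous at rectangle-input edges and at the history junction; the
integrator also restarts exactly at every such edge so no step straddles a
discontinuity (the drug compartment matches its closed form to ~1e−9
through pulse edges that do not fall on step multiples). Splitting a run
and continuing from the stored tail reproduces the unsplit run to <1e−8.
RK4 can undershoot the invariant boundary of the nonnegative orthant by
O(h⁵); values above −1e−9 are clamped to zero, anything lower aborts the
run with the failure time. There is no randomness anywhere; runs are
bit-reproducible from their resolved configuration.

**PA attractor detection.** At clamped `c` the subsystem is integrated for
a burn-in (default 300 units, doubled up to twice when detection fails
near the Hopf onset) plus a 120-unit recording. Periodicity is detected
from upward crossings of cortisol through its window mean; a relative
peak-to-trough amplitude below 1e−6 declares a fixed point; a cycle whose
crossing intervals have not stabilized to 0.5% raises an explicit
unresolved-attractor error rather than guessing. Phase θ = 0 is anchored
at the cortisol maximum (the phase origin is otherwise a free convention);
orbits are resampled at 256 uniform phases, so cycle averages are plain
means of a uniform periodic sample (spectrally accurate; doubling the
resolution moves `⟨e^{−b·o}⟩` by <1e−6).

**Nullclines and fixed points.** The c-nullcline is parameterized by `c`
with `cs` in closed form (a point exists iff `0 ≤ u < 1`); knees are local
extrema of `cs` along the curve from a 3-point slope stencil, refined by a
local parabola. The cs-nullcline evaluates the averaged synthesis target
per grid `c`; samples are flagged by whether the underlying attractor
cycles. Intersections are roots of the difference of the two single-valued
branches, refined by Brent's method with the averaged target re-evaluated
at each iterate (xtol 1e−4 in `c`; the closed-form balance is satisfied to
1e−10, the averaged balance to the characterization's own ~1e−3
reproducibility). Stability is classified by integrating the full system
from ±0.01 perturbations in `cs` — the reduced description sits on an
oscillatory, delayed fast subsystem, so a pointwise Jacobian is
ill-defined — and among stable points the larger attractor cortisol
average is labeled *normal*, the smaller *diseased*.

## Protocols and measurement conventions

* **DST.** Dose at t = 0 (30-min rectangle, height 2), draw 9 h later.
  Pre-dose cortisol is the period average of the attractor by default; the
  instantaneous mode reads the cycle maximum (the draw-at-peak variant).
  The post-dose value is a trailing one-period average (the state no
  longer oscillates, so this matches the instantaneous reading). The
  residual oscillation amplitude is measured after removing the linear
  recovery drift over the final period window: the drift (~0.009 per time
  unit as DEX clears) would otherwise dominate the genuinely ceased
  ultradian cycling by two orders of magnitude.
* **Feedback-drop metric.** Pituitary suppression is quantified as
  `Δfa = fa(⟨o·r⟩_pre) − fa((o* + o_exo)·r*)` at the draw; its basin
  asymmetry is a direct consequence of `fa` being decreasing and convex.
* **Cosyntropin test.** The dose is a 30-min rectangle into `a_exo`,
  timed so the infusion starts at a requested phase of the cortisol cycle
  (predicted from the equilibrated baseline's last peak and period). No
  dose height is established; the package convention (height 15) drives
  the normal-subject peak to ≈ 8 nondimensional cortisol units — the
  regime in which the phase spread of peaks (~8%) is comparable to a 10%
  reactivity deficit, which is the regime the test's interpretive
  difficulties live in. Reported quantities: absolute peak during the
  response window, and the *response* (peak minus baseline cycle mean).
* **Adrenal reactivity.** Cortisol is kept in reactivity-independent
  units so subjects are directly comparable; a gain factor λ then scales
  the half-max complex constants as `p2 → p2/λ`, `p4 → p4/λ²`. Under this
  convention a 10% hyporeactive adrenal *raises* baseline cortisol
  slightly (the loop over-compensates via the GR branch) while its mean
  stimulated response is slightly lower. This mapping is a package
  convention (the complex-scaling direction is not uniquely determined by
  the nondimensionalization alone); `p2`/`p4` can always be set directly.
* **Two-stage test.** DST plus a synaptic-drive step (default
  `I_ext = 0.5`, 60 min, at the 9-h draw). The embedded DST statistics are
  measured at the draw, i.e. at stressor onset, before the stressor acts.
* **Basin transitions.** After a transient input the system relaxes under
  basal drive for 10·t_c and is assigned to the nearest stable fixed point
  in the `(cs, c)` plane (relative distance threshold 0.25; otherwise
  "unresolved").

## What the simulations do and do not show

The model is a mechanistic caricature tuned for qualitative structure:
nondimensional hormone levels, a single lumped delay, no circadian drive,
no measurement noise, no inter-subject parameter variability. Passing
tests show that the *mechanisms* — delay-induced ultradian rhythm,
fold-induced bistability, convexity-driven suppression asymmetry,
phase-confounded stimulation responses, and the discriminating two-stage
response reversal — are genuine consequences of the equations at the
reference parameters. They do not show that real cortisol time series are
quantitatively reproduced: absolute suppression percentages depend on the
two calibrated constants (hence the ±5-point comparison bands), the
cosyntropin results are relational because the dose height is a
convention, and clinical data add circadian gating and sampling noise that
this model deliberately omits.

## Known limitations

* The stability classifier probes ±0.01 in `cs` only; degenerate or
  near-tangential intersections are reported rather than resolved.
* Near the Hopf onset the attractor converges slowly; the adaptive
  burn-in handles the default parameter ranges, but extreme parameter
  combinations can still raise unresolved-attractor errors (by design).
* The solver is specialized to this model's right-hand side (plus the
  clamped-CRH variant); it is validated against an independent adaptive
  reference on these equations, not a general-purpose DDE library.
* `t_c = 120` (~21 h) is slower than the qualitative "minutes to hours"
  description of CRH store turnover; the DST/two-stage phenomenology
  requires the slow end, and the value should be revisited if the stored
  pool is ever measured directly.
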