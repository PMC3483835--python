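# Methods

## Model and assumptions

The package models one protein species in an average cell with two
coupled first-order pools:

    dM/dt = T(t) − k_M M(t)
    dP/dt = R(t) M(t) − (D(t) + V) P(t)

Transcription `T` balances mRNA decay at baseline (`T = k_M M₀`), so the
declared mRNA copy number is the baseline steady level. All conversions
between half-lives/doubling times (hours) and rates (per hour) use ln 2.
Assumptions inherited from this form:

- **First-order kinetics everywhere.** Degradation is not saturable, there
  is no zero-order component, and pools are deterministic continuous
  quantities (no birth–death stochasticity, no cell-cycle phase
  structure).
- **Dilution as a loss term on protein only.** Growth enters as
  `V = ln2 / doubling_time` applied to P. The user-supplied mRNA
  half-life is interpreted as the *effective* decay measured in an mRNA
  decay experiment (chemical decay plus whatever dilution the
  measurement already contains), so no second dilution term is added to
  the mRNA equation. This is a documented convention, not a claim about
  mechanism; users who have chemical-only mRNA half-lives in dividing
  cells should pre-correct them.
- **Degradation-only vs effective half-life.** `protein_half_life` always
  means ln2/D. The effective removal half-life ln2/(D+V) is exposed on
  `RateConstants.effective_half_life` and is the quantity a chase
  experiment in dividing cells actually measures; estimator results
  carry an explicit `concept` label so the two are never silently
  conflated.

## Scenario propagation

Perturbations are instantaneous multiplier steps (synthesis,
transcription, degradation) or a label switch; drug uptake and washout
kinetics are not modeled (a delayed onset emulates a lag). Within each
piecewise-constant segment the mRNA relaxes exponentially to its new
steady level and each protein pool has the closed form

    P(τ) = P(0) e^(−kτ) + s R [ M_∞ φ₁(k, τ) + (M(0) − M_∞) φ₂(k_M, k, τ) ]

with φ₁ = (1 − e^(−kτ))/k and φ₂ = (e^(−k_M τ) − e^(−kτ))/(k − k_M).
State is continuous across breakpoints, so composed scenarios are exact
up to floating point. Numerical guards: φ₁ uses `expm1`; φ₂ switches to
its limit τ·e^(−kτ) when |k − k_M| ≤ 1e-9·max(k, k_M) (the two-term form
loses all significant digits near degeneracy) and to φ₁(k_M, τ) when
k = 0 (a full degradation block in non-dividing cells, giving the linear
accumulation dP/dt = R M). Continuity across the degeneracy switch is
verified to < 1e-6.

Labeled pools: the label routes *new synthesis* only; both pools share
the same loss rate unless the optional labeled-pool degradation
multiplier is set (default 1, i.e. newly synthesized protein is
kinetically identical to pre-existing protein — the biological caveat
that maturation, PTMs or PPIs may differentiate them is representable
only through that knob). Pulse-chase assumes instantaneous label
availability; a starvation-induced acceleration of degradation before or
during the pulse can be expressed via `pulse_degradation_multiplier` but
has no built-in rate law. `protein_total` is defined as labeled +
unlabeled, so conservation is structural; the SILAC total-invariance
check is therefore a real test of the segment solutions, not of the sum.

siRNA knockdown is a transcription multiplier (mRNA relaxes to f·M₀ with
rate k_M, default residual fraction f = 0.2) with an optional independent
translation multiplier, since interference can act through decay,
translation inhibition, or both.

## Reference integrator

`integrate_reference` is the package's independent oracle: it integrates
the raw right-hand side with SciPy's DOP853 at rtol 1e-11 and scaled
atol, restarting at every perturbation breakpoint so discontinuities are
never stepped across, and capping the step at 1/32 of each segment so
dense-output interpolation at requested times retains full accuracy. An
adaptive high-order method was chosen over a hand-rolled fixed-step
scheme because it provides the same tail-accuracy guarantee with
standard, well-tested machinery; the analytic paths are held to 1e-6
agreement against it on randomized parameter sets (half-lives
log-uniform in [0.1, 100] h, doubling times non-dividing or 12–72 h),
with deviations measured on the steady-state scale because the
trajectories themselves decay below the resolution of a pointwise ratio.

## Measurement model

Densitometry-style noise is multiplicative lognormal with mean exactly 1
(σ² = ln(1 + cv²), mean correction −σ²/2), default cv = 0.10 — a typical
value for careful quantitative blotting; replicates default to 3. Signals
are expressed on the relative scale (true value over the t = 0 truth),
optionally censored at a detection floor (default 0 = off), then
normalized to the t = 0 replicate mean, mirroring percent-of-initial
plotting; normalization is idempotent. The heavy-fraction channel is
already a ratio that starts at zero, so it is reported unnormalized.
Not modeled: blot saturation, antibody cross-reactivity, correlated
replicate error. Consequently, passing recovery tests show estimator
correctness under well-behaved multiplicative noise, not robustness to
the structured artifacts of real blots.

## Estimators

- `log_linear`: OLS of log signal vs time over all replicate points;
  stderr of the half-life by the delta method from the slope's
  covariance.
- `nonlinear_1exp` (default): least squares of A·e^(−kt) initialized
  from the log-linear fit; stderr from the fit covariance.
- `t50_interpolated`: monotone piecewise-linear interpolation of the
  replicate means to 50% of the initial mean, earliest crossing on ties;
  no stderr. This model-free reading is used to *define* the apparent
  half-life of confounded designs, because it is the closest
  formalization of reading a chase blot; nothing in the model prescribes
  a particular apparent-half-life estimator, so this is a design choice.

Blind two-exponential deconvolution of a single protein trace (jointly
recovering k_M and k_P) is deliberately out of scope: the problem is
poorly identifiable and the package instead reports the bias explicitly.

The bias grid simulates each (mRNA, protein) half-life pair noiselessly
over eight slow half-lives at 4001 points (interpolation error ~1e-5 on
the ratio, negligible against the 2% statements made about it) and
reports apparent/true-effective ratios. CHX-chase grids are refused:
that design is unbiased by construction and the grid would be uniformly
1.

## Checklist engine

The appraisal rule base is a versioned YAML data file: ten study-type
rows with their conclusions, and twelve design-combination rules, each a
pattern of alternative-groups over tick ids (the (1|2) group encodes
"untagged or tagged"). Conclusion and control strings are stored as
exact text because the precise wording of what a design can conclude is
the substance being encoded. Matching semantics: a rule matches when
every group intersects the tick set; among matching rules, any rule
whose consumed ticks are a strict subset of another's is dropped
(superset wins — the published rule set defines no other precedence, so
this specificity order is a documented choice). Grades are ordered
good_evidence > good_approach > partial > insufficient >
not_good_approach and the report carries the worst grade among the
surviving rules; when no combination rule matches, the per-row
conclusions and the worst row grade apply, so every valid tick set
yields a report. Ticking both 1 and 2 warns and proceeds with the union.

## Problem sizes and tolerances

Default verification sizes, chosen to make the checks statistically
meaningful while keeping the whole suite interactive: 100 random
parameter sets for oracle equivalence (1e-6), 10 sets for steady-state
invariance (1e-8 over ten effective half-lives) and conservation
(1e-8), 200 seeded fits for noisy recovery (≥90% within 15% of truth,
median within 5%, at cv 0.10, 3 replicates, 8 time points over 4
half-lives). All randomness flows from explicit integer seeds;
`scripts/acceptance.py` derives every generator from its `--seed`
argument.

## Known limitations

- No mechanistic model of inhibitor side effects: the transcriptional
  upregulation that degradation inhibitors can cause is a free
  multiplier the user must supply, as no quantitative rate law is
  available for it.
- Folding, chaperone engagement, aggregation, tag effects and
  compartment transport are outside the model; the checklist engine
  covers them qualitatively, the simulator not at all.
- Per-average-cell accounting: population heterogeneity and cell-cycle
  phase effects on dilution are not represented.
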