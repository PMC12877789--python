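# Methods

## Grain-filling model

Grain dry-weight accumulation after anthesis is modelled with the
four-parameter Richards function

    W(t) = A (1 + B e^{-k t})^{-1/N}

with `A` the asymptotic final grain weight (mg per grain in the synthetic
data; the unit is a dataset-level convention that the traits inherit), `k`
a rate constant (d⁻¹), and `B`, `N` shape coefficients. `N = 1` recovers
the logistic. The model assumes a single sigmoid trajectory per plot —
no distinction between superior and inferior grain positions, and no
late-season weight loss.

The filling process is decomposed at the two zeros of the third
time-derivative of `W` and at the 99 %-of-asymptote time. Writing
`u = B e^{-kt}` and `D = sqrt(N² + 6N + 5)`, the third derivative vanishes
at `u₁ = (N² + 3N + ND)/2` and `u₂ = (N² + 3N − ND)/2`, so

    T1 = −(1/k) ln(u₁/B),  T2 = −(1/k) ln(u₂/B),
    T3 = −(1/k) ln[((100/99)^N − 1)/B]

and `T_slow = T1`, `T_fast = T2 − T1`, `T_slight = T3 − T2`. `T3` satisfies
`W(T3) = 0.99 A` identically. `T_fast = ln(u₁/u₂)/k` depends only on
`(k, N)` — not on `B`, which shifts both phase boundaries equally. The
rates are `GFR_max = kA(N+1)^{-(N+1)/N}` (the rate at the inflection
point, where `u = N`) and `GFR_mean = Ak/(2(N+2))`, the standard closed
forms of the grain-filling literature; the averaging interval behind the
mean-rate expression is a convention this package adopts rather than
re-derives. `T3 > T2` requires
`(100/99)^N − 1 < u₂`; parameter sets violating it (very large `N`) raise
a named ordering error rather than returning inconsistent phases.

Evaluation is overflow-safe: with `z = ln B − kt`, the weight is computed
as `A exp(−logaddexp(0, z)/N)`, so extreme `|kt|` cannot overflow.

### Fitting

Unweighted least squares via `scipy.optimize.least_squares` with bounds
`A ∈ (0, 3·max w]`, `B, k, N ∈ (1e−6, 1e3]`. The start is data-driven:
`A₀ = 1.05·max(w)`; `k₀` from the slope of `logit(W/A₀)` against `t`
(exact for a logistic, clipped to [0.01, 1]); `N₀ = 1`; `B₀` chosen so the
curve passes through the first observation. If the first attempt fails or
leaves `r² < 0.98`, a deterministic 3×3×3 multiplicative grid
(`{0.5, 1, 2}` on `k₀`, `N₀`, `B₀`) is tried and the lowest-RSS solution
kept. Richards fits are initialisation-sensitive; the grid makes recovery
robust without randomness. Non-convergence of every start raises, carrying
the diagnostics — there is no silent fallback. A fitted curve whose slow
phase ends before anthesis (`T1 ≤ 0`) is returned with a quality flag and
excluded from downstream aggregation, preserving auditability over
clamping. Day 0 is anthesis; the day-0 weight is simply the first sample.

Approximate standard errors come from the Gauss–Newton covariance
(finite-difference Jacobian at the optimum); they are reporting aids, not
inferential guarantees, since the noise is assumed i.i.d. Gaussian.

## Linear-plateau yield response

`GY(N) = intercept + N_r·min(N, N_cs)`. For a fixed breakpoint the model
is linear, so the residual sum of squares is profiled over a deterministic
candidate set — the observed rates plus a 1 kg N ha⁻¹ grid — each solved
in closed form, followed by bounded scalar refinement within ± one grid
step. Ties go to the smallest breakpoint, matching the definition of the
critical supply as the *minimum* rate achieving maximum yield. Continuity
(`GY_max = intercept + N_r·N_cs`) holds by construction. Fits are on
replicate-level points by default (a means option exists); fitting is per
cultivar × year. Degenerate inputs (all yields equal) and N-depressed
(negative-slope) responses are returned flagged, not raised. A breakpoint
landing on the maximum tested rate means the plateau was not observed
within the design and is flagged as such.

## SPAD senescence

SPAD(t) is fitted with a least-squares quadratic `a t² + b t + c`
(`numpy.polyfit`). The chlorophyll degradation rate is the curvature
magnitude `CDR = |2a|` (SPAD d⁻²), which is invariant to the time origin
and to any linear trend. Because the field literature also describes CDR
as the slope of a straight-line regression of SPAD on time (SPAD d⁻¹),
that `linear_decline_rate` is computed alongside, and the pipeline takes a
`cdr_mode` switch (default: the quadratic curvature). The dimensional
ambiguity between the two is documented, not resolved. With fewer than
three points the quadratic is unavailable and only the linear rate is
returned, flagged.

## Nitrogen accounting

Budgets are computed per plot from organ N amounts
(`biomass × concentration`, g m⁻²): `NTA = N_aa − N_vtm`,
`NTE = 100·NTA/N_aa`, `CNTA = 100·NTA/N_gm`. CNTA is read as the
pre-anthesis share of grain N; its complement is post-anthesis uptake.
A plot that gained vegetative N after anthesis yields a negative NTA with
a flag (excluded from sensitivity aggregation). Per-organ translocation is
the organ-wise anthesis-minus-maturity difference for leaf and
stem + chaff.

Efficiency indices convert everything to kg ha⁻¹ first (g m⁻² × 10,
t ha⁻¹ × 1000): `NUtE = GY/N_am`, `NUpE = N_am/N_e`, `NUE = GY/N_e`, so
`NUE = NUtE·NUpE` exactly. The effective supply `N_e` is fertilizer N plus
a per-trial soil-N constant (default 60 kg ha⁻¹, configurable) — soil N
is not simulated dynamically.

The N nutrition index uses the critical dilution curve
`NC_cri = 4.59·W_shoot^−0.41` with shoot biomass in **t ha⁻¹** and N in %.
Dilution curves of this family are parameterised in Mg (t) ha⁻¹; with
biomass in kg ha⁻¹ the same coefficients give absurd concentrations
(≈ 0.1 % at 8 t ha⁻¹), so t ha⁻¹ is the default and a `kg_ha` override
exists for users who want the literal alternative. `NC_act` is total
aboveground N over total aboveground biomass at anthesis, spike included.

## Sensitivity and path analysis

Trait sensitivity to N supply is the OLS slope of the trait on the N rate,
computed per cultivar × year on treatment means over replicates (flagged
fits excluded; exclusion counts appear in the run manifest). With four
rates the regression has two residual degrees of freedom — slopes are
descriptive plasticity measures, not hypothesis tests. Cross-trait
correlations of slopes over five cultivars are reported with a low-power
flag for the same reason.

The path decomposition standardizes the data and solves
`R_pred · p = r_resp` for the direct coefficients (equivalently, they are
the standardized multiple-regression coefficients); the indirect
contribution of predictor *i* via *j* is `r_ij · p_j`, so
`r(i, response) = direct_i + Σ_{j≠i} indirect_{ij}` holds to machine
precision, and the full `R² = Σ_i direct_i · r_i`. Indirect paths are
first-order pairwise only; no chained routes. A near-singular predictor
correlation matrix (condition number > 1e10) is rejected with the
condition number in the message. The pipeline pools years and N levels
for the yield-component path analysis.

## Synthetic trial generator

The generator emulates the assumed data-generating structure of a
two-year × five-cultivar × four-rate (0/75/150/225 kg N ha⁻¹) × three-rep
trial: grain series every 6 d from 0–36 d post-anthesis, SPAD at
7/14/21/28 d, organ N snapshots at anthesis/maturity, plot yields with
components. Every cultivar response to N is linear with saturation at the
cultivar's true critical supply.

Richards parameters are derived by inversion: since
`T_fast = ln(u₁/u₂)/k`, the rate constant is solved from the target
`T_fast`, with `B` and `N` held at profile values — so the generated curve
hits the target duration exactly, which the tests verify to 1e−9 d.
N budgets are constructed exactly (translocated fraction of anthesis N,
then grain N scaled so the post-anthesis uptake share matches the
profile), so `n_am = n_vtm + n_gm` and `n_gm = NTA + uptake` hold
identically before noise.

Noise defaults: grain σ = 0.5 weight units, SPAD σ = 0.8, yield
σ = 0.2 t ha⁻¹, and 5 % CV on N-pool biomass and concentration
(independently, so tabulated amount = biomass × concentration stays
consistent). These levels make recovery non-trivial but leave the
cultivar orderings identifiable. The five default profiles are invented
values chosen to encode the qualitative gradients of era-spanning cultivar
panels — N_r from 0.014 to 0.022 t ha⁻¹ per kg N ha⁻¹, N_cs from 130 to
152 kg N ha⁻¹, pre-anthesis grain-N share from 60 % to 78 %, CDR
decreasing with modernity — without claiming any real plot-level values.
A mild additive year effect distinguishes the two seasons.

One seed feeds `numpy.random.SeedSequence`, spawned into four per-table
substreams; identical seed + design gives byte-identical CSVs. Noise-driven
negative grain weights are floored at 0.01 and counted.

**What passing tests do and do not show.** The generator draws i.i.d.
Gaussian noise around the very model families the pipeline fits; real
trials add split-plot error structure, spatial trends, weather-driven
deviations from the Richards shape, measurement-device bias and missing
samples. Recovery results here demonstrate correctness of the estimators
under their own assumptions, not field-scale robustness; headline field
statistics from real trials (specific path coefficients, critical
supplies, variance-explained percentages) are functions of unavailable
raw data and are not reproduced.

## Numerical choices and problem sizes

* Breakpoint profiling grid 1 kg N ha⁻¹ with 1e−8 bounded refinement;
  RSS comparisons use a 1e−12 tie threshold with ties resolved to the
  smaller breakpoint.
* Least-squares tolerances 1e−12 (xtol/ftol/gtol), max 2000 evaluations
  per start.
* Oracle tests locate third-derivative zeros by bisection on a
  fourth-order central second difference of the filling rate with step
  1e−3/k (scaled to the curve's time constant to keep cancellation error
  flat across the parameter box).
* Test and verification sizes: 200–1000 random parameter draws for the
  closed-form/oracle comparisons, 200 seeded noisy Richards fits, 500
  seeded breakpoint recoveries, and 20 seeded end-to-end trials (120 plots
  each) for the ordering-recovery checks — sizes at which each check is
  stable well inside its tolerance.

## Known limitations

* Per-plot Richards fits on 7 points estimate 4 parameters; `B` and `N`
  are weakly identified at grain σ = 0.5 (wide standard errors), though
  `A` and the phase durations remain stable.
* The conventional mean filling rate `Ak/(2(N+2))` is adopted as is; it is
  not the time-average of the rate over any of the phase intervals.
* The linear-plateau breakpoint is only identified when the design brackets
  it; with all rates below the true `N_cs` the fit correctly reports an
  unobserved plateau, and `N_r` then underestimates nothing but `N_cs` is
  censored at the top rate.
* Sensitivity slopes assume linearity of trait responses in N; the
  generator's saturating responses make the recovered slopes effective
  (design-averaged) sensitivities, which is also how the truth table
  records them.
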