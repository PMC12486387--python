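# Methods

## The model

`mckm` models a fed-batch GS-CHO culture with eight coupled states: viable
cell concentration `Xv` [10^9 cells/L], product titre `P` [g/L], glucose
`glc` [g/L], glutamine `gln` [mM], glutamate `glu` [mM], ammonium `amm`
[mM], lactate `lac` [g/L], and an estimated specific growth rate `mu_est`
[1/h].

Growth is Monod on glucose, the only growth-limiting substrate in
glutamine-synthetase cultures (glutamate is supplied in excess and
glutamine is produced intracellularly):

    mu = mu_max * glc / (K_glc + glc)

Death is a Monod-type function of ammonium, the dominant cytotoxic
by-product:

    mu_d = k_d * amm / (KD_amm + amm)

All other specific rates are growth-associated (Luedeking–Piret) with one
yield coefficient each, plus a maintenance glucose draw `m_glc`:

    dXv/dt  = (mu - mu_d) * Xv
    dP/dt   =  mu * Y_P_X * Xv
    dglc/dt = -(mu / Y_X_glc + m_glc) * Xv
    dgln/dt = (-mu / Y_X_gln + Y_gln_glu * mu / Y_X_glu) * Xv
    dglu/dt = -(mu / Y_X_glu) * Xv
    damm/dt =  (mu / Y_X_amm) * Xv
    dlac/dt =  q_lac * Xv

Lactate switches from overflow production to consumption when glucose
falls below a threshold `alpha_glc`:

    q_lac = +Y_lac_glc * q_glc   while glc >= alpha_glc   (production)
    q_lac = -mu / Y_X_lac        while glc <  alpha_glc   (consumption)

A `lactate_switch_as_printed` flag flips the inequality; it exists only
for comparison against an alternative piecewise writing of the switch that
contradicts its biological direction (consumption begins upon glucose
depletion), and is off by default.

The eighth state propagates the growth-rate estimate by the chain rule of
the Monod law,

    dmu_est/dt = mu_max * (dglc/dt) * K_glc / (K_glc + glc)^2,

so that, during regression, the growth-rate series derived from cell
counts is fitted by a trajectory consistent with glucose-limited growth.
This is the model's mechanistic constraint against overfitting 13
parameters to 49 numbers.

### Units

Glucose, lactate and titre are in gram units, amino species in mM, biomass
in 10^9 cells/L, time in hours — the unit system of the bounds table, so
its bounds apply without conversion. `mckm.model` ships conversion helpers
(glucose MW 180.16 g/mol, lactate MW 90.08 g/mol) for users with molar
assay data.

### The 13 parameters

| name | unit | lb | default IG | ub |
|---|---|---|---|---|
| mu_max | 1/h | 0.01 | per-run (fallback 0.055) | 0.1 |
| k_d | 1/h | 1e-4 | 0.016 | 0.1 |
| K_glc | g/L | 0.1 | per-run (fallback 5.05) | 10 |
| m_glc | g/(1e9 cells)/h | 0 | 0.006192 | 1 |
| Y_X_glc | 1e9 cells/g | 0.1 | per-run mass balance | 10 |
| Y_X_gln | 1e9 cells/mmol | 0.1 | per-run mass balance | 10 |
| Y_X_glu | 1e9 cells/mmol | 0.001 | per-run mass balance | 20 |
| Y_lac_glc | g/g | 0.1 | 0.615 | 2 (stoichiometric cap) |
| Y_X_amm | 1e9 cells/mmol | 0.1 | per-run mass balance | 20 |
| Y_gln_glu | mol/mol | 0.001 | 0.7 | 1 (stoichiometric cap) |
| Y_X_lac | 1e9 cells/g | 0.01 | per-run mass balance | 5 |
| Y_P_X | g/(1e9 cells) | 1e-4 | per-run mass balance | 1 |
| KD_amm | mM | 0 | 5 | 100 |

## Fed-batch simulation

Discrete bolus feeds are handled by chaining batch integrations between
consecutive sampling times (6 integrations for the canonical 7 samples).
At each boundary that carries a feed event the volume increases by the
bolus volume, every concentration is diluted, and glucose/glutamate
receive the fed mass — so mass balance closes exactly by construction.

`mu_est` is not a concentration and is not diluted. It *is* updated across
the glucose jump: because its ODE is the exact chain-rule derivative of
the Monod law, the consistent discrete update is

    mu_est += mu(glc_post_feed) - mu(glc_pre_feed).

Without this update the growth state can only ratchet downward over a fed
culture (feeds restore glucose but never the growth state), drifting far
below any data-derived growth estimate and dominating the regression
objective with a structural artefact. With the update, a consistently
initialised `mu_est` tracks `mu(glc(t))` exactly, which is the behaviour
the constraint is meant to encode.

### Events and degenerate states

The switch makes the right-hand side discontinuous at `glc = alpha_glc`;
glucose is non-increasing inside a feed-free interval, so at most one
downward crossing occurs and the integrator (explicit RK 4(5), rtol 1e-6 /
atol 1e-8 by default) detects it with a terminal event and restarts on the
other branch. Similarly, each depletable species (glc, gln, glu, lac)
raises a terminal event at zero and is pinned at exactly zero for the rest
of the interval: none of them feeds back into other rates once exhausted
(growth stops with glucose anyway), so pinning is the model's own dynamics
without the step-size chatter of a hard clamp. The maintenance glucose
draw vanishes at `glc = 0` so that clamping cannot create mass.

`alpha_glc` defaults to 0.5 g/L — a stand-in on the depletion scale set by
typical K_glc estimates (0.5–1 g/L); fit it to data when the switch point
matters.

## Per-run regression

1. **Growth-rate expansion.** `mu_est[i] = (ln Xv[i] - ln Xv[i-1]) /
   (t[i] - t[i-1])` assigned to the right endpoint, with the first entry
   duplicating the second so the series spans all samples. The backward
   assignment partially cancels two opposing biases (the within-interval
   averaging lag and the death-rate contamination of log-differences).
2. **Initial guesses.** Six yields from end-to-start mass balances,
   `Y_i/j = |Δm_i| / (|Δm_j| + fed m_j)` with `m = c·V`; `mu_max` and
   `K_glc` from a bounded Monod fit of `mu_est` vs glucose on the first
   four samples (the exponential phase); everything else from the bounds
   table. Cohort-wide minima/maxima of the yield estimates can serve as
   yield bounds when fitting a campaign; a single-run cohort widens its
   degenerate bounds by ±10%.
3. **Objective.** All 8 variables are min-max normalised with the *data's*
   scaling; the cost is the sum of squared residuals over samples 2..T of
   every non-missing entry (the first sample defines the initial
   condition). Variables are equally weighted; constant columns are
   excluded; a failed simulation returns a large finite penalty so the
   local optimiser can back off.
4. **Optimisation.** Bounded trust-region-reflective least squares on the
   residual vector, with an evaluation budget of 3000 simulations per
   stage counting the finite-difference Jacobian columns (13 + 1
   simulations per iteration). Two numerical choices matter and are easy
   to get wrong:
   - the Jacobian step (relative 1e-4, then 1e-5 in a warm-started polish
     pass at rtol 1e-8) must sit well above the integrator's relative
     error, otherwise the Jacobian is integration noise and the trust
     region stalls in false valleys;
   - step scaling is physical (the default-guess magnitude, floored at 1%
     of the box width) rather than Jacobian-adaptive; adaptive scaling
     lets near-flat directions — notably `m_glc`, which can trade off
     against `Y_X_glc` almost freely — take enormous steps into spurious
     local minima.
5. **Automated balancing.** If the free 13-parameter fit reaches R² ≥ 0.90
   on both biomass and titre it is returned as `mode="free"`. Otherwise
   two 12-parameter refits run — `K_glc` pinned at its initial guess, then
   `mu_max` — and the candidate with the highest min(R²_Xv, R²_P) wins.
   Candidates within 1e-3 of the best are ties (R² differences below that
   are noise at this scale) and resolve in favour of the reduced models,
   `fixed_K_glc` first, because removing one growth parameter is exactly
   what neutralises the mu_max/K_glc collinearity.

R² is computed per variable on the raw scale (Σ(data-pred)²/Σ(data-mean)²
complement); NRMSE is the RMSE of min-max-normalised series ×100, hence
unit-free. Missing entries are masked from both.

## Identifiability

Sensitivities are central finite differences of the fed-batch simulation
(relative step 1e-3, integration at rtol 1e-9 — finite differencing
amplifies integrator error by 1/(2h), so looser tolerances drown
structural zeros in step-control noise), evaluated at sampling times,
time-averaged, scaled by the parameter value and the variable's
trajectory range. The collinearity index of a parameter pair is
1/sqrt(λ_min) of the Gram matrix of unit-normalised sensitivity columns
(closed form 1/sqrt(1-|cos φ|) for two columns); CI > 20 flags practical
non-identifiability, and exactly proportional columns report +inf.

Two pairs are structurally collinear in this model: (`Y_lac_glc`,
`Y_X_lac`) both act only on lactate, and (`Y_gln_glu`, `Y_X_gln`) both act
only on glutamine, so each pair's sensitivity columns are proportional by
construction. The identifiability report flags both on the default
configuration. (`m_glc`, `Y_X_glc`) are *practically* collinear whenever
the growth rate varies little over the culture; recovered `m_glc` values
are therefore not biologically interpretable.

## Synthetic campaigns

The generator emulates a 15 mL minibioreactor screening campaign: ~15-day
cultures sampled on days 0, 3, 6, 8, 10, 13, 15; five 0.5 mL boluses of
concentrated glucose (100 g/L) and glutamate (70 mM) after samples 2–6,
sized so each feed raises glucose by ≈3 g/L; initial conditions
Xv 0.3×10^9 cells/L, glc 6 g/L, glu 4 mM, gln 0.5 mM, amm 1 mM,
lac 0.2 g/L, P 0 (plausible seed-train values; all config-overridable).
Clone parameters are drawn independently from truncated normals with the
published campaign means/spreads as defaults; no parameter covariance is
published, so none is modelled — a documented limitation. Measurement
noise is multiplicative lognormal per variable (assay error scales with
magnitude; defaults 3–5% CV), entries go missing independently at a small
rate (never the first cell count), and the `mu_est` column is recomputed
from the noisy counts exactly as for real data. A fully uncorrupted run
returns the simulated states verbatim, so noise-free observations equal
the simulation bit-for-bit.

For clone sampling the `Y_X_gln` truncation bound is widened to 100
because the published campaign mean (43.3×10^9 cells/mmol) lies above the
literature default bound of 10 — in fitted cohorts the yield bounds come
from cohort mass balances, not the literature table.

Stability across passages is a purely synthetic stand-in: unstable clones
multiply `Y_P_X` by U(0.6, 0.9) each passage, stable clones by
U(0.97, 1.03).

What passing tests on these data do *not* show: robustness to feed-recipe
mismatch (real campaigns approximate one run's schedule for all cultures),
correlated assay drift, non-lognormal outliers, or metabolic behaviours
outside the model class (e.g. ammonium drops from GS conversion, double
lactate switches). On real data the glucose/glutamate R² are expected to
be far lower than on synthetic data for exactly the first reason.

## Cohort analysis and LDA

Per-run fits are aggregated into a runs × parameters table, summarised per
campaign (mean and clone-to-clone sample std). Performance labels are a
within-campaign median split on final titre (ties land in the top class,
so labels are rank-based and unit-free). Fisher LDA runs on standardised
parameters (they span ~6 orders of magnitude); the direction is
`w ∝ Σ_pooled⁻¹ (μ₁ − μ₀)`, defined up to sign and scale; accuracy is
leave-one-out with the midpoint threshold; an optional ridge
(ε·trace/p) handles small cohorts with singular pooled covariance.

## Known limitations

- `mu_max` recovery carries a systematic low bias of roughly 10–15% under
  realistic conditions: the data-side growth estimate is contaminated by
  death (`ln`-differences measure `mu − mu_d`), while the model-side
  `mu_est` tracks `mu` alone. The bias is intrinsic to the estimator, not
  to the optimiser (fits started at the truth land in the same place).
- `m_glc` and, to a lesser degree, `Y_X_glc` sit in a near-flat trade-off;
  `m_glc` estimates are not interpretable.
- The lactate and glutamine yield pairs are structurally non-identifiable
  (see above); their absolute values should not be interpreted, only
  compared across runs fitted the same way.
- Glutamine can deplete for strong-consumption parameter draws; the model
  pins it at zero (no feedback exists to make this matter), which is a
  modelling convenience, not biology.
- No pH, temperature, DO or product-quality effects; single mAb species;
  no continuous feeding or perfusion.

## Problem sizes used in the shipped checks

The self-consistency and recovery experiments in `scripts/acceptance.py`
use one reference clone (the published campaign means clipped into the
default bounds), 7 samples per run, and 50 noise realisations at 2% CV
for the recovery median — sizes at which the medians are stable to ~0.5
percentage points across seeds.
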