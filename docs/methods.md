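# Methods

## The estimand

Selection on a quantitative trait is measured on the relative-fitness scale.
For individual *i* in sex × birth-year cohort *c*,

```
w_i = W_i / W̄_c            (relative lifetime reproductive success, rLRS)
z_i = (x_i − x̄_c) / s_c    (cohort z-score of the timing trait, sample SD)
```

with `W_i` the number of children ever born and `x_i` one of AFB, ALB or IBI.
The linear selection gradient `β` is the OLS slope of `w` on `z` (identically
`cov(w, z)/var(z)`). The quadratic gradient `γ` is **twice** the `z²`
coefficient of `w = a + β_Q z + ½γ z² + ε`, so that `½γ` is the curvature of
the fitted surface and its stationary point sits at `−β_Q/γ`. Linear `β`s are
reported from the pure linear model; the quadratic model reports both `β_Q`
and `γ`.

Traits:

- AFB = first_child_year − birth_year, ALB = last_child_year − birth_year,
  in whole years: the register supplies calendar years only, so nothing finer
  than year resolution exists.
- IBI = (ALB − AFB) / n_children, defined only for parity ≥ 2. One-child
  parents are *excluded* from IBI analyses rather than assigned a zero
  interval (which would put a spike at 0 in the interval distribution); the
  exclusion count is logged.

Cohort means `W̄_c` include every cohort member — childless individuals and
those with unknown education — while education-stratified regressions use only
the four known attainment levels. Standardization is likewise pooled across
education within sex × cohort (an option standardizes within stratum for
sensitivity analyses). Filtering keeps birth cohorts 1925–1977 and individuals
who survived to age 15 (death age absent, or ≥ 15, inclusive).

Confidence intervals are classical OLS with the 1.96 normal critical value.
Because rLRS is a scaled count whose variance grows with its mean, a
heteroskedasticity-robust (HC1) option is available throughout. No
multiple-testing correction is applied; the CI non-overlap rule (touching
intervals count as overlapping) is used to flag indicative differences, and
comparison counts are logged so users can correct afterwards.

Minimum stratum size is 30 by default; smaller strata are omitted with a
warning, never silently pooled. Degenerate inputs — all-childless cohorts
(rLRS undefined), standardization groups of size < 2 or zero variance,
regressions with < 3 distinct z values for the quadratic model — are dropped
or raise, and every drop is logged.

## The synthetic register

The generator emulates a register extract of the kind the analysis targets:

- birth cohorts uniform over 1925–1977; configurable sex ratio;
- education composition drifting across cohort blocks (primary shrinking,
  secondary/vocational/tertiary expanding, a small "unknown" share);
- per sex × education: childlessness probability, parous mean offspring count,
  AFB mean/SD (optionally with a linear cohort trend), IBI mean/SD;
- deaths before age 15 with a configurable probability (death age is recorded
  only for those deaths, so the survival filter has real work to do);
- a fitness function on latent standardized traits `v_t` (unit variance by
  construction):

  ```
  λ = mean_children · max(ε, 1 + Σ_t [β*_t v_t + ½γ*_t (v_t² − 1)]),  ε = 0.01
  W | parous ~ min_parity + Poisson(max(λ − min_parity, 0))
  ```

  The `(v² − 1)` centring keeps `E[W]` unaffected by `γ*`, decoupling
  directional and quadratic truth. The shifted-Poisson count model keeps
  `E[W | parous, v] = λ` *exactly* wherever `λ ≥ min_parity` — a
  zero-truncated Poisson with rate λ would have mean `λ/(1−e^{−λ})`,
  non-linear in λ, which attenuates gradients by ~17% at λ ≈ 2.3 and would
  make the configured truth unrecoverable. Activations of the fitness floor ε
  and of the parity floor are logged; in the default scenario they stay below
  0.1% of parous draws.
- birth years honour the timing identity: `first = birth + round(AFB)`,
  `last = first + round(IBI·W)` (or anchored on ALB when selection targets
  ALB, reconstructing backwards), so a register round-trip reproduces the
  latent traits up to whole-year rounding;
- father under-registration: each child of a male record is unlinked
  independently with an education-specific probability q; counts and
  first/last years are recomputed from the surviving links (a man losing all
  links becomes childless). Child years are reconstructed internally as evenly
  spaced between first and last births.

Randomness is counter-based (Philox): one seed keys a substream per field,
consumed in row order, so enlarging the population never changes earlier
individuals, and the same config + seed reproduce the dataset byte-for-byte.

### What the generator does *not* emulate

Joint distributions of a real register (education–timing–fertility
dependence beyond stratum means), migration, adult mortality, partnership
structure, twins, or calibration to any actual national register. Passing
recovery tests therefore demonstrates that the *estimation chain* is unbiased
and correctly calibrated under its stated model — not that any particular
real-world gradient has a given value.

## Recovery experiment design

The recovery experiments configure strong, register-study-sized truths (β* = −0.30 and
−0.14 on AFB, β* = +0.38 on ALB, γ* = −0.40 on IBI) and ask the full pipeline
to find them at n = 50,000 per stratum. Three design constraints matter, all
consequences of the estimand itself:

1. **Realizability.** Expected relative fitness must be non-negative. With an
   unbounded normal trait, `1 + ½(−0.40)(z²−1)` is negative beyond
   |z| ≈ 2.45 (about 1.4% of draws) and `1 + 0.38z` below z ≈ −2.6; any
   non-negative count mean must floor there, and the flooring alone biases
   the OLS `γ̂` by ≈ +0.044 (Hermite projection of the floored region), with
   a further bias from conditioning on parity ≥ 2. The recovery scenarios
   therefore draw the latent trait truncated at ±1.5 latent SD (rescaled to
   unit variance; standardized support ≈ ±2.02) and raise mean parity (4.5
   for the β scenarios; 5.5 with parity floor 2 for the IBI scenario) so the
   configured fitness function is a strictly positive, un-floored conditional
   mean over the whole trait support. Under these conditions the configured
   gradient *is* the regression estimand, and recovery tests measure
   estimator error only.
2. **The parous scale.** Timing traits exist only for parous individuals. With
   childless fraction p and the full-cohort rLRS denominator, the parous-only
   regression estimates β*/(1−p). The recovery scenarios set structural
   childlessness to zero (equivalently one may use the parous-mean rLRS
   basis, which is implemented as an option); real-data analyses default to
   the full-cohort denominator, and users should remember that timing-trait
   regressions then sit on a slightly inflated scale. This is also why the
   default-scenario stratified estimates in the README's worked example are
   somewhat larger in magnitude than the generator's configured truths:
   childless conditioning (≈ +11%) plus standardization pooled across
   education strata with different trait means/SDs both rescale the slope.
3. **Year resolution.** The register stores whole years, so the derived
   interval is `round(IBI·W)/W`. This rounding noise is largest exactly where
   parity is low — at extreme z under stabilizing selection — and with an
   interval SD of 0.6 years it attenuated measured curvature by ~12%. The IBI
   scenario uses interval SD 1.4 years, making rounding a ~1% variance share;
   the residual attenuation of about 0.01 on `γ̂` is visible in the recovery
   tables and is documented rather than corrected.

Replicate counts and sizes used by the shipped tests and the acceptance
script: 200 replicates (tests) / 40 (acceptance script, for speed) at
n = 50,000 per stratum for recovery; 500 / 300 replicates at n = 5,000 for
null calibration; 120,000 individuals for the under-registration experiment;
100,000 for the end-to-end determinism check. The default analysis register in
`analysis/01_simulate_register.py` has 100,000 individuals.

## Null calibration and bias direction

With a flat fitness surface the generated counts are homoskedastic given the
trait, so classical OLS intervals should cover β = 0 at their nominal 95%;
the calibration experiment verifies this within binomial tolerance.

The under-registration experiment makes the male-parity caveat quantitative:
with truly identical fitness everywhere, raising the father-unlink probability
for primary-educated men alone drags their measured mean relative fitness down
and pushes every higher-education contrast up — spurious selection against the
least-educated men and in favour of the better-educated, of a size comparable
to genuine gradients. Estimates of selection on *timing* are less exposed,
since they condition on linked (parous) men.

## Default scenario parameters

Chosen once as register-plausible values: parous mean counts 2.1–2.45 per
stratum so that full-stratum completed fertility lands near 2.1 (primary
women) and 1.7 (tertiary women); childlessness 10–18%; AFB means 21.5 (primary
women) to 27 (tertiary men) with SDs ≈ 4; interval mean ≈ 2 years; infant
(pre-15) death probability 2%; father-unlink probabilities 4–8% by education;
selection truths moderate (|β| ≤ 0.25, |γ| ≤ 0.15) so the fitness floor stays
inactive (< 0.1%) with unbounded traits. The generator's guard rails
(|β*| ≤ 0.4, |γ*| ≤ 0.6, probabilities in [0,1], positive SDs) are enforced at
config validation, before any sampling.

## Known limitations

- Gradients are per-trait (univariate); no joint multi-trait gradients, no
  selection-differential decomposition, no heritability.
- The parity-conditioning scale issue (point 2 above) is inherent to
  register timing traits; both denominators are provided but neither makes
  parous-only regressions estimate the full-population gradient.
- CIs are analytic (classical or HC1); no bootstrap CIs beyond the test-suite
  cross-check of prediction bands.
- Whole-year resolution bounds how well short interbirth intervals can be
  measured; nothing in the package attempts sub-year imputation.
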