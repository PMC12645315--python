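# regselect

Register-based analysis of natural selection on human reproductive timing.

National population registers record, for every individual, sex, birth year,
educational attainment, the number of children ever born, and the birth years
of the first and last child. From these five facts one can ask a classical
question of evolutionary demography: is there measurable selection on the
*timing* of reproduction — age at first birth (AFB), age at last birth (ALB),
and the average interbirth interval (IBI) — and does it differ by sex and
education?

`regselect` implements the standard Lande–Arnold machinery for this setting:

- **relative fitness** `w_i = W_i / W̄(sex, cohort)` — offspring count divided
  by the mean offspring count of the individual's sex × birth-year cohort
  (childless individuals and those with unknown education included in the
  mean), so cohort mean relative fitness is 1;
- **cohort z-scores** `z_i` of each timing trait, standardized within
  sex × birth-year cohort with the sample SD;
- **linear gradients** `β` from `w = a + βz + ε` — directional selection in
  SD units — and **quadratic gradients** from
  `w = a + β_Q z + ½γ z² + ε`, where the reported `γ` is twice the fitted
  `z²` coefficient; negative `γ` indicates a concave (stabilizing-type)
  fitness surface with peak at `−β_Q/γ`;
- stratification by sex, education (primary / secondary / vocational /
  tertiary; "unknown" contributes to cohort means but never forms a stratum)
  and birth cohort, with 95% CIs and the non-overlap rule for flagging
  indicative differences;
- **education gradients**: mean relative-fitness contrasts of each attainment
  level against primary education, per sex.

Because real register extracts cannot be redistributed, the package ships a
**synthetic register generator** with known ground truth: cohort-drifting
education composition, stratum-specific childlessness and timing
distributions, offspring counts drawn from configurable linear/quadratic
fitness functions of the standardized traits, and education-dependent
under-registration of father–child links. Every estimator in the package is
validated by parameter recovery against these configured truths, so the whole
chain is testable without any real data.

## Layout

- `src/regselect/` — the library: `register` (I/O, validation, filters,
  timing traits), `selection` (relative fitness, z-scores, gradients),
  `trends` (cohort means and extremes), `simulate` (the generator),
  `scenarios` (ready-made configurations), `experiments` (Monte-Carlo
  validation runs), `cli` (command-line pipeline).
- `analysis/` — numbered narrative drivers (`01_simulate_register.py` …
  `05_underregistration_bias.py`) that write tables under `results/`.
- `docs/methods.md` — the model, the generator, and every numerical choice.
- `docs/data_dictionary.md` — the register CSV schema.

## Worked example

```sh
python analysis/01_simulate_register.py --n 100000 --seed 0
python analysis/03_selection_gradients.py
```

prints, among other lines:

```
linear AFB gradients, women (rLRS per SD of trait):
  primary     beta = -0.322  [-0.333, -0.311]  n=13349
  secondary   beta = -0.202  [-0.213, -0.192]  n=12639
  vocational  beta = -0.206  [-0.217, -0.194]  n=9452
  tertiary    beta = -0.125  [-0.139, -0.111]  n=5705
primary vs tertiary women, AFB: CIs do not overlap -> indicative difference
quadratic IBI gradients (gamma) range: -0.101 to -0.065 (stabilizing if negative)
```

Read: among primary-educated women in the simulated register, one standard
deviation of later first birth costs about 0.32 units of relative fitness
(≈ 32% of the cohort mean offspring count); selection for earlier first birth
is roughly 2.5× stronger at the bottom of the education distribution than at
the top, and the two strata's confidence intervals are far from overlapping.
The small negative `γ` values on the interbirth interval indicate mild
stabilizing selection on the pace of reproduction. (These estimates come from
the default synthetic scenario; see `docs/methods.md` for why stratified
estimates on the default analysis scale are expected to differ somewhat from
the generator's configured truths, and how the controlled recovery
experiments close that gap.)

The same pipeline is available as a CLI:

```sh
regselect simulate  --config cfg.yaml --out reg
regselect summarize --register reg.csv --out summary.csv --by sex,education
regselect gradients --register reg.csv --out gradients.csv --trait AFB --model both
```

Each command writes a JSON manifest (input/output digests, seed, row counts);
data outputs are byte-identical across re-runs with the same config.

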