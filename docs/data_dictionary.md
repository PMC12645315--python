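# Register CSV data dictionary

One row per individual; UTF-8, comma-delimited, header required, empty field
means "absent". No quoting is needed for any token below.

| column             | type / tokens                                                | meaning                                                     |
|--------------------|--------------------------------------------------------------|-------------------------------------------------------------|
| `person_id`        | opaque string                                                | stable identifier; never interpreted                        |
| `sex`              | `F` or `M`                                                   | registered sex                                              |
| `birth_year`       | integer calendar year                                        | defines the birth cohort                                    |
| `education`        | `primary`, `secondary`, `vocational`, `tertiary`, `unknown`  | highest completed attainment; `unknown` is a first-class category |
| `n_children`       | non-negative integer                                         | children ever born (linked children, for men)               |
| `first_child_year` | integer calendar year, or empty                              | birth year of first child; present iff `n_children ≥ 1`     |
| `last_child_year`  | integer calendar year, or empty                              | birth year of last child; present iff `n_children ≥ 1`      |
| `age_at_death`     | non-negative integer years, or empty                         | recorded death age; absent means no recorded death          |

Row invariants (enforced on read and write):

- `n_children ≥ 1` ⇔ both child years present; childless rows carry no child years;
- `last_child_year ≥ first_child_year`; equal when `n_children = 1`;
- `first_child_year > birth_year`.

Derived quantities (units: years): `AFB = first_child_year − birth_year`,
`ALB = last_child_year − birth_year`, `IBI = (ALB − AFB)/n_children` (defined
only for `n_children ≥ 2`).

## Gradient output CSV

`trait,sex,education,cohort_from,cohort_to,model,beta,se_beta,beta_ci_low,beta_ci_high,gamma,se_gamma,gamma_ci_low,gamma_ci_high,n`
— one row per stratum × model; gamma columns are empty for linear fits;
`trait` is `AFB`/`ALB`/`IBI` or `EDUCATION` (contrasts vs. primary).

## Curve output CSV

`trait,sex,education,z,fit,ci_low,ci_high` — the fitted quadratic fitness
surface with a pointwise 95% band on a z grid.

## Cohort summary CSV

`variable,sex,education,birth_year,mean,ci_low,ci_high,n` — per-cohort means
with 95% CIs; `variable` is `offspring`, `AFB`, `ALB` or `IBI`; `education`
is a level or `all`.
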