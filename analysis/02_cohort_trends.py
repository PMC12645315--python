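"""Descriptive cohort surfaces: fertility and timing means by cohort, sex, education.

Reads results/register.csv (run 01_simulate_register.py first), writes
results/cohort_summary.csv and results/extreme_cohorts.csv, and reports the
cohorts of maximum/minimum fertility and the education gap in completed
fertility among women.
"""

from pathlib import Path

import pandas as pd

from regselect.register import apply_filters, read_register
from regselect.trends import VARIABLES, cohort_summary, extreme_cohorts

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    df = apply_filters(read_register(RESULTS / "register.csv"))

    tables = [cohort_summary(df, v, by=("sex", "education")) for v in VARIABLES]
    tables += [cohort_summary(df, v, by=("sex",)) for v in VARIABLES]
    summary = pd.concat(tables, ignore_index=True)
    summary.to_csv(RESULTS / "cohort_summary.csv", index=False, float_format="%.12g")

    offspring = summary[(summary["variable"] == "offspring") & (summary["education"] != "all")]
    extremes = extreme_cohorts(offspring)
    extremes.to_csv(RESULTS / "extreme_cohorts.csv", index=False, float_format="%.12g")

    pooled = summary[(summary["variable"] == "offspring") & (summary["education"] == "all")]
    peak = pooled.loc[pooled["mean"].idxmax()]
    print(f"peak cohort fertility: {peak['mean']:.2f} children ({peak['sex']}, born {int(peak['birth_year'])})")

    women = offspring[offspring["sex"] == "F"]
    gap = {
        edu: (women[women["education"] == edu]["mean"] * women[women["education"] == edu]["n"]).sum()
        / women[women["education"] == edu]["n"].sum()
        for edu in ("primary", "tertiary")
    }
    print(
        f"completed fertility, women: primary {gap['primary']:.2f} vs tertiary {gap['tertiary']:.2f} "
        f"(gap {gap['primary']-gap['tertiary']:.2f} children)"
    )
    print(f"wrote {RESULTS/'cohort_summary.csv'} and {RESULTS/'extreme_cohorts.csv'}")


if __name__ == "__main__":
    main()
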