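"""How missing father-child links masquerade as selection on education.

One population with identical fitness in every stratum is degraded twice: with
a uniform per-child unlink probability, and with the probability raised for
primary-educated men only. The education contrasts estimated from the degraded
data show the induced artefact. Writes results/underregistration.csv.
"""

import argparse
from pathlib import Path

import pandas as pd

from regselect import experiments

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--n", type=int, default=120_000)
    parser.add_argument("--seed", type=int, default=0)
    args = parser.parse_args()

    res = experiments.underregistration_experiment(args.n, seed=args.seed)
    rows = []
    for condition in ("uniform", "raised"):
        r = res[condition]
        rows.append(
            {
                "condition": condition,
                "q_primary": res["q_background"] if condition == "uniform" else res["q_primary_raised"],
                "mean_rlrs_primary_men": r["mean_rlrs_primary_men"],
                **{f"beta_{k}": v for k, v in r["contrasts"].items()},
            }
        )
    table = pd.DataFrame(rows)
    RESULTS.mkdir(exist_ok=True)
    table.to_csv(RESULTS / "underregistration.csv", index=False, float_format="%.12g")

    u, r = res["uniform"], res["raised"]
    print("true fitness identical in every stratum; only father-link completeness differs\n")
    print(table.round(4).to_string(index=False))
    print(
        f"\nraising the unlink probability for primary-educated men from {res['q_background']} to "
        f"{res['q_primary_raised']} lowered their measured mean relative fitness by "
        f"{u['mean_rlrs_primary_men']-r['mean_rlrs_primary_men']:.3f} and inflated the tertiary-vs-primary "
        f"contrast by {r['contrasts']['tertiary']-u['contrasts']['tertiary']:.3f} — spurious selection "
        "against the least-educated men and in favour of the better-educated."
    )
    print(f"wrote {RESULTS/'underregistration.csv'}")


if __name__ == "__main__":
    main()
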