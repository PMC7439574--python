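#!/usr/bin/env python
"""Epigenetic age predictions and cohort delta-age statistics.

Applies the packaged three-CpG blood clock to the simulated cohort, then
summarises each group: MAE, mean delta age, R^2 against chronological age,
and Welch t tests of patient deltas versus healthy donors.
"""

import argparse
from pathlib import Path

import pandas as pd

from methamp import cohort_summary, predict_epigenetic_age
from methamp.io import read_cohort_csv, write_table


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--cohort", type=Path, default=Path("results/sim/cohort.csv"))
    parser.add_argument("--out-dir", type=Path, default=Path("results"))
    args = parser.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    subjects = read_cohort_csv(args.cohort)
    rows = []
    for s in subjects:
        pred = predict_epigenetic_age(s.betas)
        rows.append(
            {
                "subject_id": s.subject_id,
                "group": s.group.value,
                "age_years": s.chronological_age,
                "predicted_age": pred,
                "delta_age": pred - s.chronological_age,
            }
        )
    preds = pd.DataFrame(rows)
    write_table(preds, args.out_dir / "epigenetic_age.csv", sort_by=["subject_id"])

    healthy = preds.loc[preds.group == "healthy", "delta_age"].tolist()
    summaries = []
    for group, sub in preds.groupby("group"):
        ref = healthy if group != "healthy" else None
        s = cohort_summary(
            sub["delta_age"].tolist(),
            sub["age_years"].tolist(),
            sub["predicted_age"].tolist(),
            ref,
            group=str(group),
        )
        summaries.append(s)
        line = (
            f"{s.group:8s} n={s.n:4d}  MAE={s.mae:6.2f} y  "
            f"mean delta={s.mean_delta:+6.2f} y  R^2={s.r_squared:.2f}"
        )
        if s.p_value is not None:
            line += f"  vs healthy: t={s.t_statistic:+.2f}, p={s.p_value:.2e}"
        print(line)

    write_table(
        pd.DataFrame(
            [
                {
                    "group": s.group, "n": s.n, "mae": s.mae,
                    "mean_delta": s.mean_delta, "r_squared": s.r_squared,
                    "t_statistic": s.t_statistic, "p_value": s.p_value,
                }
                for s in summaries
            ]
        ),
        args.out_dir / "epigenetic_age_summary.csv",
        sort_by=["group"],
    )
    print(f"wrote {args.out_dir}/epigenetic_age.csv and epigenetic_age_summary.csv")


if __name__ == "__main__":
    main()
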