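"""Behavioural learning analysis: corrected estimates, deltas, ANOVA.

Reads the block-RMSE table written by 01_simulate_cohort.py (or regenerates
it), fits the first/last-5-block regression lines to obtain corrected
performance estimates T0..T5 per sequence type, computes learning deltas,
and runs the group x time x sequence-type repeated-measures ANOVA.
"""

import argparse
import pathlib

import pandas as pd

from betalearn.performance import corrected_estimates, learning_deltas, tabulate_blocks
from betalearn.simulate import CohortSpec, generate_cohort, score_tracking_trials
from betalearn.stats import rm_anova


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out-dir", default="results")
    args = ap.parse_args()
    out = pathlib.Path(args.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    blocks_csv = out / "block_rmse.csv"
    if blocks_csv.exists():
        table = tabulate_blocks(pd.read_csv(blocks_csv))
        cov = pd.read_csv(out / "covariates.csv")
    else:
        ds = generate_cohort(CohortSpec(seed=args.seed), tracking="traces",
                             eeg="none")
        table = tabulate_blocks(score_tracking_trials(ds.tracking_trials))
        cov = ds.covariate_table

    est = corrected_estimates(table)
    est.to_csv(out / "corrected_estimates.csv", index=False)
    deltas = learning_deltas(est)
    deltas.to_csv(out / "learning_deltas.csv", index=False)

    print("mean corrected estimates (deg RMSE):")
    print(est.groupby("sequence_kind")[["T0", "T1", "T2", "T3", "T4", "T5"]]
          .mean().round(2).to_string())
    print("\nmean learning deltas (% of T0, positive = improvement):")
    print(deltas.groupby("sequence_kind")[
        ["online_pct", "offline1_pct", "overnight_pct", "total1_pct", "total2_pct"]
    ].mean().round(1).to_string())

    # group x sequence x time ANOVA on T0..T4 estimates
    long = est.melt(id_vars=["subject_id", "sequence_kind"],
                    value_vars=["T0", "T1", "T2", "T3", "T4"],
                    var_name="time", value_name="rmse")
    long = long.merge(cov[["subject_id", "group"]], on="subject_id")
    res = rm_anova(long, dv="rmse", subject="subject_id", between="group",
                   within=["sequence_kind", "time"])
    res.table.to_csv(out / "anova_performance.csv", index=False)
    print("\nANOVA (group x sequence x time):")
    print(res.table[["effect", "F", "df1", "df2", "p", "np2", "gg_corrected"]]
          .round(4).to_string(index=False))


if __name__ == "__main__":
    main()
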