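"""EEG beta-power features from simulated sessions, end to end.

For a reduced cohort, synthesizes cued-movement EEG epochs (1/f background
plus amplitude-modulated beta activity), runs the Morlet time-frequency
chain with percent-baseline normalization, extracts BB / MRBD / PMBR from
the group-specific windows and electrode pools, and compares the extracted
percentages against each subject's planted values.
"""

import argparse
import pathlib

import pandas as pd

from betalearn.simulate import CohortSpec, generate_cohort, simulate_eeg_session
from betalearn.spectral import compute_beta_features


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--n-per-group", type=int, default=2)
    ap.add_argument("--n-trials", type=int, default=40)
    ap.add_argument("--out-dir", default="results")
    args = ap.parse_args()
    out = pathlib.Path(args.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    ds = generate_cohort(
        CohortSpec(n_young=args.n_per_group, n_elderly=args.n_per_group,
                   seed=args.seed),
        tracking="table", eeg="none",
    )
    rows = []
    for i, subj in enumerate(ds.subjects):
        es = simulate_eeg_session(subj, n_trials=args.n_trials, n_channels=8,
                                  seed=args.seed * 1000 + i)
        f = compute_beta_features(es, subj.group)
        rows.append(dict(
            subject_id=subj.subject_id, group=subj.group,
            mrbd_contra_planted=subj.mrbd_contra, mrbd_contra=f["mrbd_contra"],
            mrbd_ipsi_planted=subj.mrbd_ipsi, mrbd_ipsi=f["mrbd_ipsi"],
            pmbr_contra_planted=subj.pmbr_contra, pmbr_contra=f["pmbr_contra"],
            pmbr_ipsi_planted=subj.pmbr_ipsi, pmbr_ipsi=f["pmbr_ipsi"],
            bb_contra=f["bb_contra"], bb_ipsi=f["bb_ipsi"],
        ))
    table = pd.DataFrame(rows)
    table.to_csv(out / "extracted_beta_features.csv", index=False)
    print(table.round(1).to_string(index=False))
    for feat in ("mrbd_contra", "mrbd_ipsi", "pmbr_contra", "pmbr_ipsi"):
        err = (table[feat] - table[f"{feat}_planted"]).abs()
        print(f"{feat}: mean |recovery error| = {err.mean():.2f} pp")


if __name__ == "__main__":
    main()
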