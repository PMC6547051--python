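"""Predict post-training performance from beta features and prior skill.

Runs the full predictive chain on the default cohort: z-scored candidate
matrices (22 regressors for the T2 models, 29 for T4), forward/backward
stepwise selection, leave-one-out cross-validation, and a label-permutation
test on the actual-vs-predicted correlation.  Writes one JSON record per
outcome model.
"""

import argparse
import json
import pathlib

from betalearn.pipeline import predict_learning_outcomes
from betalearn.simulate import CohortSpec, generate_cohort


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--n-perm", type=int, default=100)
    ap.add_argument("--policy", default="refit_inside_folds",
                    choices=["refit_inside_folds", "fixed_model"])
    ap.add_argument("--out-dir", default="results")
    args = ap.parse_args()
    out = pathlib.Path(args.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    ds = generate_cohort(CohortSpec(seed=args.seed), tracking="traces",
                         eeg="none")
    results = predict_learning_outcomes(ds, n_perm=args.n_perm,
                                        seed=args.seed, policy=args.policy)
    payload = {}
    for outcome, res in results.items():
        payload[outcome] = dict(
            selected=res.model.selected,
            beta=[round(float(b), 4) for b in res.model.beta],
            r_squared=round(res.model.r_squared, 4),
            loocv_r=round(res.r_actual_pred, 4),
            permutation_p=round(res.permutation_p, 4),
            n_permutations=res.n_iterations,
        )
        print(f"{outcome}: R2={payload[outcome]['r_squared']:.2f} "
              f"LOOCV r={res.r_actual_pred:.2f} perm p={res.permutation_p:.3f}")
        for name, b in zip(res.model.selected, res.model.beta):
            print(f"    {name:>22s}  beta = {b:+.2f}")
    with open(out / "prediction_models.json", "w") as f:
        json.dump(payload, f, indent=2)
    print(f"wrote {out / 'prediction_models.json'}")


if __name__ == "__main__":
    main()
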