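#!/usr/bin/env python
"""Species classification experiments: three feature sets (non-EFD, EFD,
both) x five algorithms, by resubstitution and replicated 10-fold
cross-validation for SVM and random forest."""

import argparse
import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

from valvemorph import classify as cl
from valvemorph.io import read_feature_table


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--out", type=Path, default=Path("results"))
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--replicates", type=int, default=10)
    args = parser.parse_args()

    feats = read_feature_table(args.out / "features.csv")
    consensus = pd.read_csv(args.out / "consensus.csv", dtype={"specimen_id": str})
    labels = cl.classification_labels(consensus)
    sets = cl.build_feature_sets(feats)
    rng = np.random.default_rng(args.seed)

    rows, cv_rows = [], []
    for name, (_, matrix) in sets.items():
        for algo in cl.ALGORITHMS:
            try:
                rep = cl.fit_predict_resubstitution(
                    matrix, labels, algo, name, seed=int(rng.integers(2**31))
                )
            except ValueError as exc:
                rep = cl.ClassifierReport(algo, name, len(matrix), None, None, True, str(exc))
            rows.append(dataclasses.asdict(rep))
        for algo in ("svm", "random_forest"):
            try:
                cv = cl.cross_validate(
                    matrix, labels, algo, replicates=args.replicates,
                    seed=int(rng.integers(2**31)), feature_set=name,
                )
            except ValueError:
                continue
            cv_rows.append(
                {"algorithm": algo, "feature_set": name, "replicates": cv.replicates,
                 "mean_pct": cv.mean_pct, "min_pct": cv.min_pct, "max_pct": cv.max_pct}
            )

    resub = pd.DataFrame(rows)
    resub.to_csv(args.out / "classification_resubstitution.csv", index=False)
    cv_df = pd.DataFrame(cv_rows)
    cv_df.to_csv(args.out / "classification_cv.csv", index=False)

    ok = resub[~resub["not_applicable"]]
    best = ok.sort_values("misclassified").iloc[0]
    print(
        f"resubstitution over {resub['feature_set'].nunique()} feature sets x "
        f"{resub['algorithm'].nunique()} algorithms; best: {best['algorithm']} on "
        f"{best['feature_set']} ({int(best['misclassified'])} of {int(best['n_cases'])} "
        "misclassified); CV means (%): "
        + ", ".join(
            f"{r.algorithm}/{r.feature_set} {r.mean_pct:.1f}" for r in cv_df.itertuples()
        )
    )


if __name__ == "__main__":
    main()
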