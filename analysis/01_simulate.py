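#!/usr/bin/env python
"""Generate the synthetic study cohort: valve outlines, striated masked
images for a stratified subset, a 12-participant vote table, and the
ground-truth table. Writes everything under results/data/."""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from valvemorph.io import write_masked_image
from valvemorph.pipeline import StudyConfig
from valvemorph.synthetic import (
    StriaTextureParams,
    SyntheticValveParams,
    default_cohort_spec,
    generate_cohort,
    generate_striated_image,
)


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--out", type=Path, default=Path("results/data"))
    parser.add_argument("--n", type=int, nargs=3, default=(60, 40, 30),
                        metavar=("RIT", "OBL", "SUB"))
    parser.add_argument("--n-images", type=int, default=30)
    args = parser.parse_args()

    spec = default_cohort_spec(n_per_species=tuple(args.n))
    cohort = generate_cohort(spec, seed=args.seed, render_images=False)
    args.out.mkdir(parents=True, exist_ok=True)

    outlines = cohort["outlines"]
    n_pts = outlines[0].n_points
    rows = []
    for o in outlines:
        row = {"id": o.specimen_id}
        row.update({f"X{i+1}": o.points[i, 0] for i in range(n_pts)})
        row.update({f"Y{i+1}": o.points[i, 1] for i in range(n_pts)})
        rows.append(row)
    pd.DataFrame(rows).to_csv(args.out / "outlines.csv", index=False)
    cohort["truth"].to_csv(args.out / "ground_truth.csv", index=False)

    votes = cohort["votes"].votes.copy()
    votes.insert(0, "id", votes.index)
    votes.replace("missing", "").to_csv(args.out / "votes.csv", index=False)

    truth = cohort["truth"].set_index("specimen_id")
    rng = np.random.default_rng(args.seed + 1)
    img_dir = args.out / "images"
    img_dir.mkdir(exist_ok=True)
    img_ids = []
    for _, grp in truth.groupby("species"):
        k = max(2, int(round(args.n_images * len(grp) / len(truth))))
        img_ids.extend(rng.choice(grp.index, size=min(k, len(grp)), replace=False))
    for sid in sorted(img_ids):
        row = truth.loc[sid]
        vp = SyntheticValveParams(
            length=float(row["length"]), width=float(row["width_param"]),
            h=float(row["h"]), bulge=float(row["bulge"]),
        )
        tp = StriaTextureParams(
            density=float(row["stria_density"]),
            theta_deg=float(row["stria_orientation"]),
        )
        img, _ = generate_striated_image(vp, tp, seed=int(rng.integers(2**31)), specimen_id=sid)
        write_masked_image(img, img_dir / f"{sid}.png")

    print(
        f"cohort: {len(outlines)} outlines ({dict(truth['species'].value_counts())}), "
        f"{len(img_ids)} masked images, votes from 12 participants -> {args.out}"
    )


if __name__ == "__main__":
    main()
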