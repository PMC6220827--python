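#!/usr/bin/env python
"""Multiexpert consensus analytics: per-specimen majority votes, the
agreement cascade (full agreement, then allowing 1-3 dissenters, per
experience group), pairwise inter-participant similarity with an
average-linkage ordering, ternary vote coordinates, and agreement as a
function of valve length."""

import argparse
import json
from pathlib import Path

import pandas as pd

from valvemorph import consensus as cons
from valvemorph.io import read_feature_table, read_vote_table


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--data", type=Path, default=Path("results/data"))
    parser.add_argument("--out", type=Path, default=Path("results"))
    args = parser.parse_args()

    votes = read_vote_table(args.data / "votes.csv")
    df = cons.consensus_table(votes)
    df.to_csv(args.out / "consensus.csv", index=False)

    s = cons.agreement_summary(votes)
    (args.out / "agreement.json").write_text(
        json.dumps(
            {
                "n_specimens": s.n_specimens,
                "full_agreement_count": s.full_agreement_count,
                "full_agreement_fraction": s.full_agreement_fraction,
                "allow_k_counts": s.allow_k_counts,
                "per_group": s.per_group,
            },
            indent=2,
        )
    )
    sim = cons.pairwise_similarity(votes)
    sim.to_csv(args.out / "similarity.csv")

    coords = []
    for sid in votes.specimen_ids:
        res = cons.majority_vote(votes.votes.loc[sid], sid)
        if sum(res.counts[sp] for sp in ("ritscheri", "obliquecostata", "sublinearis")):
            x, y = cons.ternary_coordinates(res)
            coords.append({"specimen_id": sid, "x": x, "y": y})
    pd.DataFrame(coords).to_csv(args.out / "ternary.csv", index=False)

    feats = read_feature_table(args.out / "features.csv")
    lengths = feats.set_index("specimen_id")["length"]
    win = cons.length_window_agreement(votes, lengths)
    win.to_csv(args.out / "length_window_agreement.csv", index=False)

    ks = s.allow_k_counts
    print(
        f"{s.n_specimens} specimens: {s.full_agreement_count} "
        f"({100 * s.full_agreement_fraction:.1f}%) in full agreement; "
        f"allowing 1/2/3 dissenters: {ks[1]}/{ks[2]}/{ks[3]}; "
        f"per group: "
        + ", ".join(f"{g} {100 * v[2]:.1f}%" for g, v in s.per_group.items())
    )


if __name__ == "__main__":
    main()
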