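"""Multiexpert consensus analytics for specimen vote tables.

Implements the majority-vote gold standard (label with the highest number of
votes; ties become "ambiguous"), agreement summaries allowing k dissenters,
pairwise inter-participant similarity, ternary vote coordinates, and
agreement as a function of valve length.

Conventions (configurable where noted): "complete agreement" counts a
specimen only when all nonempty votes agree on a single species label — a
shared "ambiguous" vote is not an identification; for the k-dissent
statistic, dissent is counted against the majority label, so specimens
without a species majority never reach full agreement; out-of-group votes
count as nonambiguous identifications in pairwise similarity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .io import SPECIES, VoteTable

__all__ = [
    "ConsensusResult",
    "AgreementSummary",
    "majority_vote",
    "consensus_table",
    "agreement_summary",
    "pairwise_similarity",
    "similarity_clustering",
    "ternary_coordinates",
    "length_window_agreement",
]

VOTE_CATEGORIES_NONMISSING = SPECIES + ("ambiguous", "out_of_group")


@dataclass
class ConsensusResult:
    specimen_id: str
    counts: dict  # per nonmissing category
    n_votes: int
    majority_label: str
    percent_agree: float
    tie: bool


def majority_vote(votes: "pd.Series | list[str]", specimen_id: str = "") -> ConsensusResult:
    """Majority label of one specimen's votes.

    Missing votes are excluded; a tie for the maximum among the five
    categories yields "ambiguous" with ``tie=True``. ``percent_agree`` is the
    top category's share of all nonempty votes.
    """
    labels = list(votes)
    counts = {c: labels.count(c) for c in VOTE_CATEGORIES_NONMISSING}
    n_votes = sum(counts.values())
    if n_votes == 0:
        raise ValueError(f"{specimen_id or 'specimen'}: all votes missing")
    top = max(counts.values())
    winners = [c for c, v in counts.items() if v == top]
    tie = len(winners) > 1
    return ConsensusResult(
        specimen_id=specimen_id,
        counts=counts,
        n_votes=n_votes,
        majority_label="ambiguous" if tie else winners[0],
        percent_agree=top / n_votes,
        tie=tie,
    )


def consensus_table(table: VoteTable) -> pd.DataFrame:
    """Per-specimen consensus rows for a whole vote table."""
    rows = []
    for sid in table.specimen_ids:
        res = majority_vote(table.votes.loc[sid], specimen_id=sid)
        rows.append(
            {
                "specimen_id": sid,
                **{f"n_{c}": res.counts[c] for c in VOTE_CATEGORIES_NONMISSING},
                "n_votes": res.n_votes,
                "majority_label": res.majority_label,
                "percent_agree": res.percent_agree,
                "tie": res.tie,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class AgreementSummary:
    n_specimens: int
    full_agreement_count: int
    full_agreement_fraction: float
    allow_k_counts: dict  # k -> count of specimens with <= k dissenters
    per_group: dict  # group -> (n, full-agreement count, fraction)


def agreement_summary(
    table: VoteTable, participant_ids: list[str] | None = None, max_k: int = 3
) -> AgreementSummary:
    """Counts of specimens in full agreement, and allowing k dissenters.

    Full agreement requires all nonempty votes to be the same single species
    label. Allowing k counts specimens whose nonempty votes deviate from the
    species majority label in at most k participants. Specimens without any
    nonempty vote in the subset are excluded.
    """
    sub = table.subset(participant_ids) if participant_ids is not None else table
    if not sub.participants:
        raise ValueError("empty participant subset")
    full = 0
    dissent_counts = []
    n_specimens = 0
    for sid in sub.specimen_ids:
        votes = [v for v in sub.votes.loc[sid] if v != "missing"]
        if not votes:
            continue
        n_specimens += 1
        res = majority_vote(votes, sid)
        if res.majority_label in SPECIES and not res.tie:
            dissent = len(votes) - res.counts[res.majority_label]
            if dissent == 0:
                full += 1
        else:
            dissent = None
        dissent_counts.append(dissent)
    allow_k = {
        k: sum(1 for d in dissent_counts if d is not None and d <= k)
        for k in range(max_k + 1)
    }
    per_group = {}
    if participant_ids is None:
        for group in ("experienced", "novice"):
            ids = table.participant_ids(group)
            if ids:
                g = agreement_summary(table, ids, max_k=max_k)
                per_group[group] = (
                    g.n_specimens,
                    g.full_agreement_count,
                    g.full_agreement_fraction,
                )
    return AgreementSummary(
        n_specimens=n_specimens,
        full_agreement_count=full,
        full_agreement_fraction=full / n_specimens if n_specimens else np.nan,
        allow_k_counts=allow_k,
        per_group=per_group,
    )


def pairwise_similarity(table: VoteTable) -> pd.DataFrame:
    """Participant-by-participant proportion of identical, nonempty,
    nonambiguous identifications; unit diagonal; NaN where a pair never
    co-labeled a specimen."""
    ids = [p.id for p in table.participants]
    if len(ids) < 2:
        raise ValueError("need at least 2 participants")
    arr = table.votes[ids].to_numpy()
    usable = (arr != "missing") & (arr != "ambiguous")
    n = len(ids)
    sim = np.full((n, n), np.nan)
    for i in range(n):
        sim[i, i] = 1.0
        for j in range(i + 1, n):
            both = usable[:, i] & usable[:, j]
            if both.any():
                sim[i, j] = sim[j, i] = float(
                    np.mean(arr[both, i] == arr[both, j])
                )
    return pd.DataFrame(sim, index=ids, columns=ids)


def similarity_clustering(similarity: pd.DataFrame) -> np.ndarray:
    """Average-linkage hierarchical clustering of 1 - similarity (for the
    report's participant ordering)."""
    dist = 1.0 - similarity.to_numpy()
    np.fill_diagonal(dist, 0.0)
    dist = np.nan_to_num(dist, nan=1.0)
    dist = (dist + dist.T) / 2.0
    return hierarchy.average(squareform(dist, checks=False))


# tips of an equilateral triangle with unit heights (side 2/sqrt(3))
_TRIANGLE_TIPS = {
    "ritscheri": np.array([0.0, 0.0]),
    "obliquecostata": np.array([2.0 / np.sqrt(3.0), 0.0]),
    "sublinearis": np.array([1.0 / np.sqrt(3.0), 1.0]),
}


def ternary_coordinates(result: ConsensusResult) -> tuple[float, float]:
    """Planar coordinates of a specimen's species-vote composition in an
    equilateral triangle with unit heights; the distance from each tip's
    opposite edge equals that species' renormalized vote fraction."""
    species_votes = np.array([result.counts[s] for s in SPECIES], dtype=float)
    total = species_votes.sum()
    if total == 0:
        raise ValueError(f"{result.specimen_id}: no species votes")
    frac = species_votes / total
    xy = sum(f * _TRIANGLE_TIPS[s] for f, s in zip(frac, SPECIES))
    return float(xy[0]), float(xy[1])


def length_window_agreement(
    table: VoteTable,
    lengths: "pd.Series | dict",
    window: float = 10.0,
    threshold: float = 0.9,
) -> pd.DataFrame:
    """Per length-window fraction of specimens with >= ``threshold`` percent
    agreement. Windows of ``window`` um tile the observed length range; empty
    windows are reported with n=0 and a missing fraction."""
    lengths = pd.Series(lengths)
    missing = [s for s in table.specimen_ids if s not in lengths.index]
    if missing:
        raise ValueError(f"lengths missing for specimens: {missing[:5]}")
    cons = consensus_table(table).set_index("specimen_id")
    lo = float(lengths.loc[table.specimen_ids].min())
    hi = float(lengths.loc[table.specimen_ids].max())
    edges = np.arange(lo, hi + window, window)
    rows = []
    for left in edges[:-1] if len(edges) > 1 else [lo]:
        right = left + window
        in_win = [
            s
            for s in table.specimen_ids
            if left <= lengths.loc[s] < right
            or (right >= hi and lengths.loc[s] == hi)
        ]
        n = len(in_win)
        if n:
            frac = float(np.mean(cons.loc[in_win, "percent_agree"] >= threshold))
        else:
            frac = np.nan
        rows.append({"window_start": left, "window_end": right, "n": n, "fraction": frac})
    return pd.DataFrame(rows)
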