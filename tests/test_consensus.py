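from collections import Counter

import numpy as np
import pandas as pd
import pytest

from valvemorph.consensus import (
    agreement_summary,
    consensus_table,
    length_window_agreement,
    majority_vote,
    pairwise_similarity,
    similarity_clustering,
    ternary_coordinates,
)
from valvemorph.io import SPECIES, Participant, VoteTable
from valvemorph.synthetic import VoteSimulationSpec, generate_vote_table


def make_table(rows, participants=None):
    """rows: dict specimen_id -> list of votes."""
    n = len(next(iter(rows.values())))
    participants = participants or [
        Participant(f"P{i+1}", "experienced" if i < n // 2 else "novice") for i in range(n)
    ]
    votes = pd.DataFrame.from_dict(rows, orient="index", columns=[p.id for p in participants])
    return VoteTable(specimen_ids=list(rows), participants=participants, votes=votes)


class TestMajorityVote:
    def test_unanimous(self):
        res = majority_vote(["ritscheri"] * 11)
        assert res.majority_label == "ritscheri"
        assert res.percent_agree == 1.0 and not res.tie

    def test_split_vote(self):
        votes = ["ritscheri"] * 3 + ["obliquecostata"] * 7 + ["sublinearis"] + ["ambiguous"]
        res = majority_vote(votes)
        assert res.majority_label == "obliquecostata"
        assert res.percent_agree == pytest.approx(7 / 12)

    def test_tie_becomes_ambiguous(self):
        res = majority_vote(["ritscheri"] * 5 + ["obliquecostata"] * 5 + ["sublinearis"])
        assert res.tie and res.majority_label == "ambiguous"

    def test_missing_excluded_from_counts(self):
        res = majority_vote(["ritscheri", "missing", "missing", "ritscheri"])
        assert res.n_votes == 2 and res.percent_agree == 1.0

    def test_all_missing_raises(self):
        with pytest.raises(ValueError):
            majority_vote(["missing"] * 3)

    def test_column_order_invariance(self):
        votes = ["ritscheri", "obliquecostata", "ritscheri", "ambiguous"]
        a = majority_vote(votes)
        b = majority_vote(votes[::-1])
        assert a.majority_label == b.majority_label
        assert a.percent_agree == b.percent_agree


def brute_force_agreement(table, max_k=3):
    """Independent enumeration of the full/k-dissent agreement counts."""
    full = 0
    k_counts = Counter()
    n = 0
    for sid in table.specimen_ids:
        votes = [v for v in table.votes.loc[sid] if v != "missing"]
        if not votes:
            continue
        n += 1
        counts = Counter(votes)
        top_label, top = counts.most_common(1)[0]
        is_tie = sum(1 for v in counts.values() if v == top) > 1
        if top_label in SPECIES and not is_tie:
            dissent = len(votes) - top
            for k in range(max_k + 1):
                if dissent <= k:
                    k_counts[k] += 1
            if dissent == 0:
                full += 1
    return n, full, dict(k_counts)


class TestAgreement:
    def test_identity_table_full_agreement(self):
        spec = VoteSimulationSpec(
            n_specimens=30,
            confusion_experienced=np.eye(3), confusion_novice=np.eye(3),
            ambiguity_experienced=0, ambiguity_novice=0,
            missing_experienced=0, missing_novice=0,
        )
        table, _ = generate_vote_table(spec, seed=0)
        s = agreement_summary(table)
        assert s.full_agreement_fraction == 1.0
        assert all(v == 30 for v in s.allow_k_counts.values())

    def test_matches_brute_force_on_fixture(self):
        table = make_table(
            {
                "a": ["ritscheri"] * 5,
                "b": ["ritscheri"] * 4 + ["obliquecostata"],
                "c": ["ambiguous"] * 5,
                "d": ["ritscheri", "ritscheri", "obliquecostata", "obliquecostata", "missing"],
                "e": ["sublinearis", "sublinearis", "sublinearis", "missing", "ambiguous"],
            }
        )
        s = agreement_summary(table)
        n, full, k_counts = brute_force_agreement(table)
        assert s.n_specimens == n
        assert s.full_agreement_count == full
        for k, c in k_counts.items():
            assert s.allow_k_counts[k] == c

    def test_one_dissenter_everywhere(self):
        table = make_table(
            {f"s{i}": ["ritscheri"] * 4 + ["obliquecostata"] for i in range(6)}
        )
        s = agreement_summary(table)
        assert s.full_agreement_count == 0
        assert s.allow_k_counts[1] == 6

    def test_k_counts_monotone_on_random_tables(self):
        spec = VoteSimulationSpec(n_specimens=40)
        for seed in range(5):
            table, _ = generate_vote_table(spec, seed=seed)
            s = agreement_summary(table)
            counts = [s.allow_k_counts[k] for k in sorted(s.allow_k_counts)]
            assert counts == sorted(counts)

    def test_per_group_split(self):
        spec = VoteSimulationSpec(n_specimens=60)
        table, _ = generate_vote_table(spec, seed=3)
        s = agreement_summary(table)
        assert set(s.per_group) == {"experienced", "novice"}
        exp = agreement_summary(table, table.participant_ids("experienced"))
        assert s.per_group["experienced"][1] == exp.full_agreement_count

    def test_empty_subset_raises(self):
        table = make_table({"a": ["ritscheri"] * 4})
        with pytest.raises(ValueError):
            agreement_summary(table, [])


class TestPairwiseSimilarity:
    def test_identical_and_discordant(self):
        table = make_table(
            {f"s{i}": [v, v, "ritscheri" if v == "obliquecostata" else "obliquecostata"]
             for i, v in enumerate(["ritscheri", "obliquecostata"] * 3)},
        )
        sim = pairwise_similarity(table)
        assert sim.iloc[0, 1] == 1.0
        assert sim.iloc[0, 2] == 0.0
        np.testing.assert_allclose(np.diag(sim), 1.0)
        np.testing.assert_allclose(sim.to_numpy(), sim.to_numpy().T)

    def test_ambiguous_and_missing_excluded(self):
        table = make_table(
            {
                "a": ["ritscheri", "ritscheri"],
                "b": ["ambiguous", "ritscheri"],
                "c": ["missing", "obliquecostata"],
                "d": ["obliquecostata", "sublinearis"],
                "e": ["out_of_group", "out_of_group"],
            }
        )
        sim = pairwise_similarity(table)
        # usable pairs: a (match), d (mismatch), e (match) -> 2/3
        assert sim.iloc[0, 1] == pytest.approx(2 / 3)

    def test_clustering_linkage_shape(self):
        spec = VoteSimulationSpec(n_specimens=40)
        table, _ = generate_vote_table(spec, seed=1)
        sim = pairwise_similarity(table)
        Z = similarity_clustering(sim)
        assert Z.shape == (len(sim) - 1, 4)


class TestTernary:
    def test_pure_vote_at_tip(self):
        res = majority_vote(["ritscheri"] * 10)
        assert ternary_coordinates(res) == (0.0, 0.0)

    def test_even_split_at_centroid(self):
        res = majority_vote(["ritscheri", "obliquecostata", "sublinearis"])
        x, y = ternary_coordinates(res)
        assert x == pytest.approx(1 / np.sqrt(3))
        assert y == pytest.approx(1 / 3)

    def test_two_species_on_edge_midpoint(self):
        res = majority_vote(["ritscheri", "obliquecostata"])
        x, y = ternary_coordinates(res)
        assert (x, y) == (pytest.approx(1 / np.sqrt(3)), pytest.approx(0.0))

    def test_ambiguous_renormalized_out(self):
        res = majority_vote(["ritscheri", "ritscheri", "ambiguous", "ambiguous"])
        assert ternary_coordinates(res) == (0.0, 0.0)

    def test_no_species_votes_raises(self):
        res = majority_vote(["ambiguous"] * 4)
        with pytest.raises(ValueError):
            ternary_coordinates(res)


class TestLengthWindows:
    def test_unanimous_everywhere(self):
        table = make_table({f"s{i}": ["ritscheri"] * 4 for i in range(8)})
        lengths = pd.Series(np.linspace(30, 75, 8), index=table.specimen_ids)
        win = length_window_agreement(table, lengths)
        assert (win.loc[win["n"] > 0, "fraction"] == 1.0).all()

    def test_hand_counted_mix(self):
        rows = {f"u{i}": ["ritscheri"] * 4 for i in range(3)}
        rows.update({f"d{i}": ["ritscheri", "ritscheri", "obliquecostata", "obliquecostata"] for i in range(2)})
        table = make_table(rows)
        lengths = pd.Series([31, 32, 33, 35, 36], index=table.specimen_ids)
        win = length_window_agreement(table, lengths, window=10, threshold=0.9)
        assert len(win) == 1
        assert win.iloc[0]["n"] == 5
        assert win.iloc[0]["fraction"] == pytest.approx(3 / 5)

    def test_empty_window_reported_missing(self):
        table = make_table({"a": ["ritscheri"] * 4, "b": ["ritscheri"] * 4})
        lengths = pd.Series([30.0, 55.0], index=["a", "b"])
        win = length_window_agreement(table, lengths, window=10)
        empty = win[win["n"] == 0]
        assert len(empty) >= 1
        assert empty["fraction"].isna().all()


class TestConsensusTable:
    def test_counts_sum_to_votes(self):
        spec = VoteSimulationSpec(n_specimens=25)
        table, _ = generate_vote_table(spec, seed=6)
        df = consensus_table(table)
        count_cols = [c for c in df.columns if c.startswith("n_") and c != "n_votes"]
        assert (df[count_cols].sum(axis=1) == df["n_votes"]).all()
        assert ((df["percent_agree"] > 0) & (df["percent_agree"] <= 1)).all()
        assert (df.loc[df["tie"], "majority_label"] == "ambiguous").all()
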