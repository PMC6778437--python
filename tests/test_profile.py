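"""Unweighted and bootstrap-weighted profile combination."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from taxawalk import (
    RankAssignment,
    ValidationError,
    combine_rank,
    unweighted_shares,
    weighted_shares,
)

TAXA = [f"T{i}" for i in range(12)]


def make_assignment(pid, taxa, support=None, fallback=False, none=False):
    ranks = {
        r: frozenset(taxa) if not none else frozenset({"None"})
        for r in ("species", "genus", "family", "order", "class", "phylum")
    }
    return RankAssignment(
        protein_id=pid,
        support=support,
        root_fallback=fallback,
        none_flag=none,
        ranks=ranks,
    )


def random_assignments(rng, n):
    out = []
    for i in range(n):
        k = int(rng.integers(1, 6))
        taxa = list(rng.choice(TAXA, size=k, replace=False))
        support = float(rng.integers(0, 101))
        out.append(make_assignment(f"P{i}", taxa, support=support))
    return out


class TestShares:
    def test_five_way_ambiguity_gives_point_two_each(self):
        shares = unweighted_shares(["A", "B", "C", "D", "E"])
        assert shares == {t: pytest.approx(0.2) for t in "ABCDE"}

    def test_unique_assignment_gets_full_protein(self):
        assert unweighted_shares(["X"]) == {"X": 1.0}

    def test_two_taxa_at_80_percent_support_get_point_four(self):
        shares = weighted_shares(["X", "Y"], support=80.0)
        assert shares == {"X": pytest.approx(0.4), "Y": pytest.approx(0.4)}

    def test_single_taxon_full_support(self):
        assert weighted_shares(["X"], support=100.0) == {"X": pytest.approx(1.0)}

    def test_fallback_weight_is_one(self):
        assert weighted_shares(["X", "Y"], support=None, root_fallback=True) == {
            "X": pytest.approx(0.5),
            "Y": pytest.approx(0.5),
        }

    def test_empty_taxon_set_rejected(self):
        with pytest.raises(ValidationError):
            unweighted_shares([])

    def test_out_of_range_support_rejected(self):
        with pytest.raises(ValidationError):
            weighted_shares(["X"], support=120.0)

    @given(
        taxa=st.sets(st.sampled_from(TAXA), min_size=1, max_size=8),
        support=st.floats(min_value=0.0, max_value=100.0, allow_nan=False),
    )
    @settings(max_examples=200, derandomize=True)
    def test_shares_sum_to_one_and_weighting_is_a_scalar(self, taxa, support):
        u = unweighted_shares(taxa)
        assert sum(u.values()) == pytest.approx(1.0)
        w = weighted_shares(taxa, support=support)
        for t in taxa:
            assert w[t] == pytest.approx(u[t] * support / 100.0)


class TestCombine:
    def test_unanimous_taxon_scores_full_count(self):
        assignments = [make_assignment(f"P{i}", ["X"], support=90.0) for i in range(3)]
        prof = combine_rank(assignments, "genus")
        assert prof.frame.loc["X", "unweighted"] == pytest.approx(3.0)
        assert prof.frame.loc["X", "unweighted_pct"] == pytest.approx(100.0)
        assert prof.frame.loc["X", "weighted_pct"] == pytest.approx(100.0)

    def test_subthreshold_taxon_excluded_and_share_resplit(self):
        assignments = [
            make_assignment("P1", ["X"], support=90.0),
            make_assignment("P2", ["X", "Y"], support=90.0),
        ]
        prof = combine_rank(assignments, "genus")
        assert prof.excluded == ("Y",)
        assert prof.frame.loc["X", "unweighted"] == pytest.approx(2.0)
        assert "Y" not in prof.frame.index

    def test_drop_mode_forfeits_excluded_mass(self):
        assignments = [
            make_assignment("P1", ["X"], support=90.0),
            make_assignment("P2", ["X", "Y"], support=90.0),
        ]
        prof = combine_rank(assignments, "genus", mode="drop")
        assert prof.excluded == ("Y",)
        assert prof.frame.loc["X", "unweighted"] == pytest.approx(1.5)

    def test_all_taxa_excluded_protein_reassigned_to_none(self):
        assignments = [
            make_assignment("P1", ["X"], support=90.0),
            make_assignment("P2", ["X"], support=90.0),
            make_assignment("P3", ["Z", "W"], support=90.0),
        ]
        prof = combine_rank(assignments, "genus")
        assert set(prof.excluded) == {"Z", "W"}
        assert prof.frame.loc["None", "unweighted"] == pytest.approx(1.0)
        assert prof.frame["unweighted"].sum() == pytest.approx(3.0)

    def test_conservation_fixed_point_and_bounds_on_random_profiles(self):
        rng = np.random.default_rng(37)
        for _ in range(200):
            assignments = random_assignments(rng, int(rng.integers(3, 15)))
            prof = combine_rank(assignments, "family")
            # conservation: unweighted mass equals number of proteins
            assert prof.frame["unweighted"].sum() == pytest.approx(len(assignments))
            assert prof.frame["unweighted_pct"].sum() == pytest.approx(100.0)
            # every retained taxon meets the threshold
            retained = prof.frame.drop(index="None", errors="ignore")
            assert (retained["unweighted"] >= 1.0 - 1e-9).all()
            # weighted never exceeds unweighted when supports <= 100
            assert (
                prof.frame["weighted"] <= prof.frame["unweighted"] + 1e-9
            ).all()
            # fixed point: recombining the surviving sets changes nothing
            survivors = [
                make_assignment(pid, sorted(taxa), support=a.support)
                for (pid, taxa), a in zip(
                    sorted(prof.assigned_sets.items()),
                    sorted(assignments, key=lambda a: a.protein_id),
                )
            ]
            again = combine_rank(survivors, "family")
            assert again.excluded == ()
            assert set(again.frame.index) == set(prof.frame.index)
            assert np.allclose(
                again.frame.sort_index()["unweighted"],
                prof.frame.sort_index()["unweighted"],
            )

    def test_order_invariance(self):
        rng = np.random.default_rng(41)
        assignments = random_assignments(rng, 20)
        forward = combine_rank(assignments, "order")
        backward = combine_rank(list(reversed(assignments)), "order")
        assert forward.frame.equals(backward.frame)
        assert forward.excluded == backward.excluded

    def test_iteration_terminates_with_cascading_exclusions(self):
        # chain where excluding one taxon pushes the next below threshold
        assignments = [
            make_assignment("P1", ["A", "B"], support=100.0),
            make_assignment("P2", ["A", "B"], support=100.0),
            make_assignment("P3", ["B", "C"], support=100.0),
            make_assignment("P4", ["C"], support=100.0),
        ]
        prof = combine_rank(assignments, "class")
        assert prof.frame["unweighted"].sum() == pytest.approx(4.0)
        retained = prof.frame.drop(index="None", errors="ignore")
        assert (retained["unweighted"] >= 1.0 - 1e-9).all()

    def test_empty_assignment_list_rejected(self):
        with pytest.raises(ValidationError):
            combine_rank([], "genus")
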