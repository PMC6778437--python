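"""Global pairwise identity, NR reduction and copy statistics."""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from taxawalk import (
    SequenceRecord,
    SimConfig,
    ValidationError,
    copy_identity_stats,
    global_identity,
    identity_matrix,
    nr_reduce,
    simulate_sequences,
)

DNA = st.text(alphabet="ACGT", min_size=1, max_size=12)


def oracle_optimal_identities(a: str, b: str) -> set[int]:
    """Identity counts of every co-optimal global alignment (tiny strings).

    Enumerates all monotone alignments recursively under the default
    scoring (match +1, mismatch -1, gap open -2, extend -1) and returns the
    set of match counts achieved at the optimal score.
    """

    best: dict[tuple, tuple[float, set[int]]] = {}

    def go(i, j, in_gap_a, in_gap_b):
        key = (i, j, in_gap_a, in_gap_b)
        if key in best:
            return best[key]
        if i == len(a) and j == len(b):
            return (0.0, {0})
        options = []
        if i < len(a) and j < len(b):
            sub, matches = go(i + 1, j + 1, False, False)
            score = 1.0 if a[i] == b[j] else -1.0
            options.append((sub + score, {m + (a[i] == b[j]) for m in matches}))
        if i < len(a):
            sub, matches = go(i + 1, j, True, False)
            options.append((sub + (-1.0 if in_gap_a else -2.0), set(matches)))
        if j < len(b):
            sub, matches = go(i, j + 1, False, True)
            options.append((sub + (-1.0 if in_gap_b else -2.0), set(matches)))
        top = max(s for s, _ in options)
        combined = set()
        for s, m in options:
            if s == top:
                combined |= m
        best[key] = (top, combined)
        return best[key]

    score, matches = go(0, 0, False, False)
    return matches


class TestGlobalIdentity:
    def test_identical_sequences_are_100(self):
        assert global_identity("ACGTACGT", "ACGTACGT") == 100.0

    def test_single_substitution_without_gaps(self):
        assert global_identity("ACGT", "ACGA") == 75.0

    def test_shorter_sequence_is_the_denominator(self):
        # perfect prefix of half the length: 100% of the shorter
        assert global_identity("ACGTACGT", "ACGT") == 100.0

    def test_symmetric_and_case_insensitive(self):
        rng = np.random.default_rng(43)
        bases = np.array(list("ACGT"))
        for _ in range(100):
            a = "".join(bases[rng.integers(0, 4, rng.integers(5, 40))])
            b = "".join(bases[rng.integers(0, 4, rng.integers(5, 40))])
            ab = global_identity(a, b)
            assert ab == global_identity(b, a)
            assert ab == global_identity(a.lower(), b)

    def test_alphabet_mismatch_rejected(self):
        with pytest.raises(ValidationError, match="alphabet"):
            global_identity("ACGT", "MKLVWF")

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValidationError):
            global_identity("", "ACGT")

    @given(a=DNA, b=DNA)
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_identity_matches_a_cooptimal_alignment(self, a, b):
        matches = oracle_optimal_identities(a, b)
        ident = global_identity(a, b)
        assert any(
            ident == pytest.approx(m / min(len(a), len(b)) * 100.0)
            for m in matches
        )

    def test_matrix_symmetric_with_unit_diagonal(self):
        seqs, _ = simulate_sequences(SimConfig(seed=3, n_parents=2,
                                               copies_per_parent=1, seq_length=100))
        mat = identity_matrix(seqs)
        assert (mat.values == mat.values.T).all()
        assert (np.diag(mat.values) == 100.0).all()
        assert ((mat.values >= 0) & (mat.values <= 100)).all()


class TestNrReduce:
    def test_longer_member_of_duplicate_pair_retained(self):
        long = SequenceRecord("long", "ACGT" * 25)  # 100 nt
        short = SequenceRecord("short", ("ACGT" * 25)[:80])
        kept = nr_reduce([short, long], threshold=99.0)
        assert [r.id for r in kept] == ["long"]

    def test_distinct_sequences_unchanged(self):
        rng = np.random.default_rng(47)
        bases = np.array(list("ACGT"))
        seqs = [
            SequenceRecord(f"s{i}", "".join(bases[rng.integers(0, 4, 200)]))
            for i in range(5)
        ]
        kept = nr_reduce(seqs, threshold=99.0)
        assert kept == seqs

    def test_idempotent_and_output_below_threshold(self):
        seqs, _ = simulate_sequences(
            SimConfig(seed=53, n_parents=3, copies_per_parent=2,
                      seq_length=300, target_identity=0.998)
        )
        kept = nr_reduce(seqs, threshold=99.0)
        assert nr_reduce(kept, threshold=99.0) == kept
        for a, b in itertools.combinations(kept, 2):
            assert global_identity(a, b) < 99.0

    def test_length_tie_broken_lexicographically(self):
        a = SequenceRecord("aaa", "ACGTACGTAC")
        b = SequenceRecord("bbb", "ACGTACGTAC")
        kept = nr_reduce([b, a], threshold=99.0)
        assert [r.id for r in kept] == ["aaa"]


class TestCopyStats:
    def test_identical_copies(self):
        seqs = [SequenceRecord(f"c{i}", "ACGTACGTACGT") for i in range(4)]
        stats = copy_identity_stats(seqs)
        assert stats.mean_identity == 100.0
        assert stats.consensus.seq == "ACGTACGTACGT"
        assert stats.n_pairs == 6

    def test_mean_with_one_diverged_copy(self):
        rng = np.random.default_rng(59)
        bases = np.array(list("ACGT"))
        parent = bases[rng.integers(0, 4, 1000)]
        diverged = parent.copy()
        for pos in (10, 250, 600, 900):  # 4 substitutions -> 99.6% to others
            diverged[pos] = bases[(np.where(bases == diverged[pos])[0][0] + 1) % 4]
        seqs = [SequenceRecord(f"c{i}", "".join(parent)) for i in range(3)]
        seqs.append(SequenceRecord("c3", "".join(diverged)))
        stats = copy_identity_stats(seqs)
        # (3 x 100 + 3 x 99.6) / 6
        assert stats.mean_identity == pytest.approx(99.8)
        assert stats.consensus.seq == "".join(parent)

    def test_majority_consensus_with_tiebreak(self):
        seqs = [
            SequenceRecord("a", "ACGT"),
            SequenceRecord("b", "ACGT"),
            SequenceRecord("c", "ACGA"),
        ]
        assert copy_identity_stats(seqs).consensus.seq == "ACGT"

    def test_single_sequence_rejected(self):
        with pytest.raises(ValidationError):
            copy_identity_stats([SequenceRecord("a", "ACGT")])

    def test_planted_identity_within_three_binomial_sd(self):
        p, L = 0.97, 2000
        cfg = SimConfig(seed=61, n_parents=2, copies_per_parent=2,
                        seq_length=L, target_identity=p, max_trim=1)
        seqs, truth = simulate_sequences(cfg)
        by_id = {r.id: r for r in seqs}
        sd = 100.0 * np.sqrt(p * (1 - p) / L)
        for copy_id, parent_id in truth.copy_parent.items():
            ident = global_identity(by_id[copy_id], by_id[parent_id])
            assert abs(ident - 100.0 * p) <= 3.0 * sd + 0.2
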