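"""Local alignment, fragment search and mature-peptide coverage."""

import itertools

import numpy as np
import pytest

from knotminer.mapping import (
    FragmentMatch,
    MsmsFragment,
    ScoringScheme,
    compute_coverage,
    local_align,
    search_fragments,
    substitution_score,
)
from knotminer.precursor import Precursor
from oracles import biopython_local_score, exhaustive_local_score

SCHEME = ScoringScheme()


class TestLocalAlign:
    def test_contained_fragment_is_fully_identical(self):
        aln = local_align("IFECVFSCDIEK", "IFECVFSCDIEKEGKPCKPK")
        assert aln.percent_identity == 100.0
        assert aln.target_span == (0, 12)

    def test_x_matches_any_and_leaves_identity_full(self):
        aln = local_align("CVFSCDXEK", "CVFSCDIEK")
        assert aln.percent_identity == 100.0
        assert aln.n_columns == 8  # the X column is excluded

    def test_self_alignment_scores_diagonal_sum(self):
        pep = "IFECVFSCDIEK"
        aln = local_align(pep, pep)
        expected = sum(substitution_score(SCHEME, a, a) for a in pep)
        assert aln.score == pytest.approx(expected)
        assert aln.percent_identity == 100.0

    def test_isoleucine_leucine_equivalence_is_optional(self):
        assert local_align("KIKIK", "KLKLK").percent_identity == 100.0
        strict = ScoringScheme(il_equivalent=False)
        assert local_align("KIKIK", "KLKLK", strict).percent_identity < 100.0

    def test_empty_sequence_errors(self):
        with pytest.raises(ValueError):
            local_align("", "ACD")
        with pytest.raises(ValueError):
            local_align("ACD", "")

    def test_score_symmetric_under_swap(self, rng):
        letters = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
        for _ in range(50):
            a = "".join(rng.choice(letters, size=int(rng.integers(3, 20))))
            b = "".join(rng.choice(letters, size=int(rng.integers(3, 20))))
            x, y = local_align(a, b), local_align(b, a)
            assert x.score == pytest.approx(y.score)
            assert x.percent_identity == pytest.approx(y.percent_identity)

    def test_gap_costs_are_affine(self):
        # one long gap must beat two separate gaps of the same total length
        aln = local_align("WWWWYYYWWWW", "WWWWWWWW")
        assert aln.score == pytest.approx(
            8 * substitution_score(SCHEME, "W", "W")
            + SCHEME.gap_open + 3 * SCHEME.gap_extend
        )

    def test_all_short_pairs_match_exhaustive_oracle(self):
        """DP equals brute-force path enumeration on all tiny pairs."""
        seqs = [
            "".join(p)
            for n in (1, 2, 3)
            for p in itertools.product("CK", repeat=n)
        ]
        for a in seqs:
            for b in seqs:
                assert local_align(a, b).score == pytest.approx(
                    exhaustive_local_score(a, b, SCHEME)
                )

    def test_random_pairs_match_biopython_oracle(self, rng):
        letters = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
        for _ in range(200):
            a = "".join(rng.choice(letters, size=int(rng.integers(1, 9))))
            b = "".join(rng.choice(letters, size=int(rng.integers(1, 9))))
            ours = local_align(a, b, SCHEME).score
            assert ours == pytest.approx(biopython_local_score(a, b, SCHEME))


def _table1_precursor():
    return Precursor(
        orf_ref="c7142",
        signal="MKTLVLVAVLGLALA",
        propeptide="SEDIKLCLKIAEEER",
        mature="IFECVFSCDIEKEGKPCKPKGDKSAAAAAAAA",
        signal_score=3.0,
        cleavage_rule="PQM",
    )


def _decoy(ref="dec1"):
    return Precursor(
        orf_ref=ref,
        signal="MKTLVLVAVLGLALA",
        propeptide="",
        mature="QNQNQNQNQNQNQNQNQNQNQN",
        signal_score=3.0,
        cleavage_rule="fallback",
    )


class TestSearchFragments:
    def test_reported_fragments_hit_their_precursor_top_ranked(self):
        frags = [
            MsmsFragment("21-22/a-b_1", "IKLCLKI", 444.36, 2, "K", None),
            MsmsFragment("21-22/a-b_2", "IFECVFSCDIEK", 773.98, 2, None, "E"),
            MsmsFragment("21-22/a-b_3", "IFECVFSCDIEKEGKPCKPK", 618.64, 4, None, "G"),
            MsmsFragment("21-22/c_1", "CVFSCDXEK", 579.10, 2),
        ]
        hits = search_fragments(frags, [_decoy(), _table1_precursor()])
        for frag in frags:
            assert hits[frag.id], frag.id
            assert hits[frag.id][0].target_ref == "c7142"
        assert hits["21-22/a-b_1"][0].region == "propeptide"
        assert hits["21-22/a-b_2"][0].region == "mature"
        assert hits["21-22/a-b_2"][0].percent_identity == 100.0

    def test_no_similarity_gives_empty_hit_list(self):
        frags = [MsmsFragment("f", "WWWWWWW", 500.0, 1)]
        hits = search_fragments(frags, [("t1", "GGGGGGGG")], min_score=25.0)
        assert hits["f"] == []

    def test_identical_targets_tie_in_db_order(self):
        frags = [MsmsFragment("f", "IFECVFSCDIEK", 773.98, 2)]
        db = [("b", "IFECVFSCDIEKEG"), ("a", "IFECVFSCDIEKEG")]
        hits = search_fragments(frags, db)
        assert [h.target_ref for h in hits["f"]] == ["b", "a"]
        assert hits["f"][0].score == hits["f"][1].score

    def test_empty_database_errors(self):
        with pytest.raises(ValueError):
            search_fragments([], [])


class TestCoverage:
    def make(self, spans):
        return [
            FragmentMatch("f", "t", s, 100.0, 50.0, "mature", s) for s in spans
        ]

    def test_single_span_66_percent(self):
        # 21 of 32 mature residues -> 65.6, printed as 66
        cov = compute_coverage(self.make([(0, 21)]), 32)
        assert cov == pytest.approx(65.625)
        assert round(cov) == 66

    def test_adjacent_spans_cover_fully(self):
        assert compute_coverage(self.make([(0, 5), (5, 10)]), 10) == 100.0

    def test_overlaps_counted_once(self):
        assert compute_coverage(self.make([(0, 6), (4, 10)]), 20) == 50.0

    def test_no_matches_zero(self):
        assert compute_coverage([], 32) == 0.0

    def test_monotone_and_bounded(self, rng):
        spans = [
            tuple(sorted(rng.integers(0, 40, size=2))) for _ in range(20)
        ]
        spans = [(s, e) for s, e in spans if e > s]
        prev = 0.0
        for k in range(len(spans) + 1):
            cov = compute_coverage(self.make(spans[:k]), 40)
            assert cov >= prev - 1e-12
            assert cov <= 100.0
            prev = cov

    def test_mature_len_precondition(self):
        with pytest.raises(ValueError):
            compute_coverage([], 0)
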