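import math
import random

import pytest

from mipscan import (
    BuiltinSearchBackend,
    Calibration,
    PrecomputedSearchBackend,
    ProteinRecord,
    Proteome,
    ScoringScheme,
    evalue_of,
    search,
    smith_waterman,
)
from mipscan.io_formats import AMINO_ACIDS

from ._oracle import naive_local_score

SCHEME = ScoringScheme()


def _random_proteome(rng, prefix, n, length):
    return Proteome(
        ProteinRecord(
            id=f"{prefix}{i}",
            sequence="".join(rng.choice(AMINO_ACIDS) for _ in range(length)),
        )
        for i in range(n)
    )


class TestSmithWaterman:
    def test_self_alignment_score_is_diagonal_sum(self):
        seq = "HEAGAWGHEE"
        expected = sum(SCHEME.matrix[c, c] for c in seq)
        score, q_span, s_span, identity = smith_waterman(seq, seq, SCHEME)
        assert score == expected == 62
        assert q_span == s_span == (1, len(seq))
        assert identity == 1.0

    def test_all_negative_substitution_gives_empty_alignment(self):
        score, q_span, s_span, identity = smith_waterman("AAAA", "WWWW", SCHEME)
        assert score == 0
        assert q_span is None and s_span is None
        assert identity == 0.0

    def test_empty_sequence_is_error(self):
        with pytest.raises(ValueError):
            smith_waterman("", "MKV", SCHEME)

    def test_ambiguous_x_scores_worst_case(self):
        # X against anything gets the matrix minimum, so a run of X cannot
        # produce a positive-scoring alignment.
        score, *_ = smith_waterman("XXXXXXXX", "MKVLLAGH", SCHEME)
        assert score == 0
        assert SCHEME.matrix["X", "W"] == SCHEME.matrix["W", "X"] < 0

    def test_matches_naive_full_dp_oracle_on_100_random_pairs(self):
        rng = random.Random(1234)
        for _ in range(100):
            a = "".join(rng.choice(AMINO_ACIDS) for _ in range(rng.randint(10, 50)))
            b = "".join(rng.choice(AMINO_ACIDS) for _ in range(rng.randint(10, 50)))
            expected = naive_local_score(
                a, b, SCHEME.matrix, SCHEME.gap_open, SCHEME.gap_extend
            )
            assert smith_waterman(a, b, SCHEME)[0] == expected

    def test_score_symmetric_in_arguments(self):
        rng = random.Random(7)
        for _ in range(20):
            a = "".join(rng.choice(AMINO_ACIDS) for _ in range(30))
            b = "".join(rng.choice(AMINO_ACIDS) for _ in range(30))
            assert smith_waterman(a, b, SCHEME)[0] == smith_waterman(b, a, SCHEME)[0]


class TestScoringScheme:
    def test_gap_penalty_ordering_enforced(self):
        with pytest.raises(ValueError):
            ScoringScheme(gap_open=1, gap_extend=2)


class TestEvalue:
    def test_algebraic_identity_e_equals_one(self):
        cal = Calibration(query_length=100, effective_db_length=10_000)
        s = math.log(cal.k * cal.query_length * cal.effective_db_length) / cal.lambda_
        assert evalue_of(s, cal) == pytest.approx(1.0)

    def test_doubling_database_doubles_e(self):
        cal1 = Calibration(query_length=100, effective_db_length=10_000)
        cal2 = Calibration(query_length=100, effective_db_length=20_000)
        assert evalue_of(40, cal2) == pytest.approx(2 * evalue_of(40, cal1))

    def test_published_constants_direct_evaluation(self):
        # E = K*m*n*exp(-lambda*S) with lambda=0.267, K=0.041, m=100,
        # n=10000, S=40: hand evaluation of the closed form.
        cal = Calibration(
            lambda_=0.267, k=0.041, query_length=100, effective_db_length=10_000
        )
        assert evalue_of(40, cal) == pytest.approx(
            0.041 * 100 * 10_000 * math.exp(-0.267 * 40)
        )
        assert evalue_of(40, cal) == pytest.approx(0.94, abs=0.01)

    def test_strictly_decreasing_in_score(self):
        cal = Calibration(query_length=100, effective_db_length=10_000)
        values = [evalue_of(s, cal) for s in range(0, 100, 10)]
        assert all(x > y for x, y in zip(values, values[1:]))

    def test_invalid_constants_rejected(self):
        with pytest.raises(ValueError):
            Calibration(lambda_=0.0)


class TestSearch:
    def test_exact_copy_in_database_is_reported(self):
        rng = random.Random(5)
        q = _random_proteome(rng, "q", 1, 300)
        db = Proteome(
            [ProteinRecord(id="copy", sequence=q["q0"].sequence)]
            + list(_random_proteome(rng, "d", 3, 300))
        )
        hits = search(q, db, cutoff=1e-7)
        assert ("q0", "copy") in {(h.query_id, h.subject_id) for h in hits}

    def test_random_queries_find_nothing_at_stringent_cutoff(self):
        rng = random.Random(99)
        queries = _random_proteome(rng, "q", 20, 50)
        db = _random_proteome(rng, "d", 20, 200)
        assert search(queries, db, cutoff=1e-7) == []

    def test_hits_at_tight_cutoff_subset_of_loose(self):
        rng = random.Random(11)
        queries = _random_proteome(rng, "q", 5, 80)
        db = _random_proteome(rng, "d", 10, 120)
        tight = {(h.query_id, h.subject_id) for h in search(queries, db, 1e-7)}
        loose = {(h.query_id, h.subject_id) for h in search(queries, db, 0.5)}
        assert tight <= loose

    def test_empty_inputs_are_errors(self):
        rng = random.Random(3)
        prot = _random_proteome(rng, "p", 2, 30)
        with pytest.raises(ValueError):
            search(Proteome(), prot, 1.0)
        with pytest.raises(ValueError):
            search(prot, Proteome(), 1.0)

    def test_deterministic_hit_order(self):
        rng = random.Random(21)
        queries = _random_proteome(rng, "q", 3, 60)
        db = Proteome(
            ProteinRecord(id=f"d{i}", sequence=queries[f"q{i % 3}"].sequence)
            for i in range(6)
        )
        hits = search(queries, db, 10.0)
        assert hits == sorted(hits, key=lambda h: (h.query_id, h.evalue, h.subject_id))


class TestPrecomputedBackend:
    def test_unknown_id_error_names_the_id(self):
        from mipscan import SearchHit

        ghost = SearchHit(query_id="tf1", subject_id="ghost", raw_score=50, evalue=1e-9)
        with pytest.raises(ValueError, match="ghost"):
            PrecomputedSearchBackend([ghost], [], [], known_ids={"tf1", "p1"})

    def test_cutoff_and_membership_filtering(self):
        from mipscan import SearchHit

        prot = Proteome([ProteinRecord(id="p1", sequence="MKVLLA")])
        tfs = Proteome([ProteinRecord(id="tf1", sequence="MKVLLA")])
        hits = [
            SearchHit(query_id="tf1", subject_id="p1", raw_score=40, evalue=1e-3),
            SearchHit(query_id="tf1", subject_id="p1", raw_score=20, evalue=0.9),
        ]
        backend = PrecomputedSearchBackend(hits, [], [], known_ids={"tf1", "p1"})
        kept = backend.search_stage(tfs, prot, cutoff=1e-2, stage="tier1")
        assert [h.evalue for h in kept] == [1e-3]
        assert backend.search_stage(tfs, prot, cutoff=1e-2, stage="tier2") == []
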