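"""Local alignment, E-value statistics and the translated search, checked
against an independent Gotoh dynamic-programming oracle."""

import math

import numpy as np
import pytest

from rhizocomp.homology import (DEFAULT_SCHEME, ScoringScheme, bitscore,
                                evalue, local_align, search, top_hit,
                                top_hits_by_query)
from rhizocomp.orfscan import translate_frames
from rhizocomp.seqio import HomologyHit, ProteinRecord, TranscriptRecord
from rhizocomp.synthdata import _back_translate

AA20 = "ACDEFGHIKLMNPQRSTVWY"


def sw_affine_oracle(a, b, scheme=DEFAULT_SCHEME):
    """Textbook Gotoh local alignment: a gap of length g costs
    gap_open + g * gap_extend. Independent of the production engine."""
    matrix = scheme.matrix
    go, ge = scheme.gap_open, scheme.gap_extend
    n, m = len(a), len(b)
    NEG = -10**9
    H = [[0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]
    F = [[NEG] * (m + 1) for _ in range(n + 1)]
    best = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(E[i][j - 1] - ge, H[i][j - 1] - go - ge)
            F[i][j] = max(F[i - 1][j] - ge, H[i - 1][j] - go - ge)
            sub = int(matrix[a[i - 1], b[j - 1]])
            H[i][j] = max(0, H[i - 1][j - 1] + sub, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


def random_peptide(rng, n):
    return "".join(AA20[i] for i in rng.integers(0, 20, size=n))


class TestLocalAlign:
    def test_identical_short_peptides(self):
        # BLOSUM62 diagonal: M=5, K=5, V=4
        assert local_align("MKV", "MKV").score == 14

    def test_single_substitution(self):
        # best local alignment scores 5 - 1 + 4
        assert local_align("MKV", "MAV").score == 8

    def test_empty_query_scores_zero(self):
        assert local_align("", "MKV").score == 0

    def test_unalignable_pair_scores_zero(self):
        assert local_align("W", "P").score == 0

    def test_character_outside_alphabet_raises(self):
        with pytest.raises(ValueError, match="alphabet"):
            local_align("MKO", "MKV")

    def test_symmetry(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            a = random_peptide(rng, int(rng.integers(3, 25)))
            b = random_peptide(rng, int(rng.integers(3, 25)))
            assert local_align(a, b).score == local_align(b, a).score

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_gotoh_oracle(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(20):
            a = random_peptide(rng, int(rng.integers(2, 30)))
            b = random_peptide(rng, int(rng.integers(2, 30)))
            assert local_align(a, b).score == sw_affine_oracle(a, b)

    def test_spans_cover_positive_alignment(self):
        aln = local_align("AAMKVAA", "WWMKVWW")
        assert aln.score == 14
        assert (aln.a_start, aln.a_end) == (3, 5)
        assert (aln.b_start, aln.b_end) == (3, 5)
        assert aln.identities == 3 and aln.align_len == 3


class TestEvalue:
    def test_direct_evaluation(self):
        # 0.041 * 100 * 100 * exp(-0.267 * 50)
        assert evalue(50, 100, 100) == pytest.approx(6.54e-4, rel=0.01)

    def test_large_score_drives_e_to_zero(self):
        assert evalue(10_000, 100, 100) == 0.0

    def test_doubling_database_doubles_e(self):
        assert evalue(40, 100, 2000) == pytest.approx(2 * evalue(40, 100, 1000))

    def test_monotone_decreasing_in_score(self):
        es = [evalue(s, 300, 10_000) for s in range(10, 200, 10)]
        assert all(x > y for x, y in zip(es, es[1:]))

    def test_bitscore_formula(self):
        s = 123
        expected = (0.267 * s - math.log(0.041)) / math.log(2)
        assert bitscore(s) == pytest.approx(expected)

    def test_invalid_search_space_raises(self):
        with pytest.raises(ValueError):
            evalue(50, 0, 100)


def make_query(rng, peptide, qid):
    """Nucleotide query encoding a peptide (uniform codons, no UTR)."""
    return TranscriptRecord(id=qid, seq=_back_translate(rng, peptide))


class TestSearch:
    def test_planted_homolog_is_reported(self):
        rng = np.random.default_rng(3)
        pep = "M" + random_peptide(rng, 200)
        query = make_query(rng, pep, "q1")
        db = [ProteinRecord(id="s1", seq=pep),
              ProteinRecord(id="s2", seq="M" + random_peptide(rng, 180))]
        hits = search([query], db, evalue_cutoff=1e-20)
        assert [h.subject_id for h in hits] == ["s1"]
        assert hits[0].evalue < 1e-20

    def test_random_query_vs_unrelated_db_is_empty(self):
        rng = np.random.default_rng(4)
        query = make_query(rng, random_peptide(rng, 150), "q1")
        db = [ProteinRecord(id=f"s{i}", seq=random_peptide(rng, 150))
              for i in range(5)]
        assert search([query], db, evalue_cutoff=1e-20) == []

    def test_small_instance_equals_bruteforce_oracle(self):
        """Hit set identical to all-pairs Gotoh + closed-form E over all
        six frames, on a 5x5 instance with planted homologies."""
        rng = np.random.default_rng(9)
        peps = ["M" + random_peptide(rng, 80) for _ in range(5)]
        queries = [make_query(rng, p, f"q{i}") for i, p in enumerate(peps)]
        db = [ProteinRecord(id=f"s{i}", seq=peps[i] if i < 3
                            else "M" + random_peptide(rng, 80))
              for i in range(5)]
        cutoff = 1e-10
        n_db = sum(p.length_aa for p in db)
        expected = set()
        for q in queries:
            frames = translate_frames(q.seq)
            for s in db:
                best = 0
                best_m = 1
                for aa in frames.values():
                    score = sw_affine_oracle(aa, s.seq)
                    if score > best:
                        best, best_m = score, len(aa)
                if best > 0 and evalue(best, best_m, n_db) < cutoff:
                    expected.add((q.id, s.id, best))
        hits = search(queries, db, evalue_cutoff=cutoff)
        assert {(h.query_id, h.subject_id, h.raw_score) for h in hits} == expected

    def test_database_permutation_invariance(self):
        rng = np.random.default_rng(12)
        peps = ["M" + random_peptide(rng, 100) for _ in range(4)]
        queries = [make_query(rng, p, f"q{i}") for i, p in enumerate(peps)]
        db = [ProteinRecord(id=f"s{i}", seq=p) for i, p in enumerate(peps)]
        fwd = search(queries, db, evalue_cutoff=1e-5)
        rev = search(queries, db[::-1], evalue_cutoff=1e-5)
        key = lambda h: (h.query_id, h.subject_id, h.raw_score, h.evalue)
        assert sorted(map(key, fwd)) == sorted(map(key, rev))

    def test_reported_evalues_recompute_exactly(self):
        rng = np.random.default_rng(13)
        pep = "M" + random_peptide(rng, 150)
        query = make_query(rng, pep, "q1")
        db = [ProteinRecord(id="s1", seq=pep)]
        (hit,) = search([query], db, evalue_cutoff=1e-5)
        frames = translate_frames(query.seq)
        m = len(frames[hit.frame])
        assert hit.evalue == evalue(hit.raw_score, m, db[0].length_aa)
        assert hit.evalue < 1e-5

    def test_seeded_mode_keeps_strong_hits(self):
        rng = np.random.default_rng(14)
        pep = "M" + random_peptide(rng, 150)
        query = make_query(rng, pep, "q1")
        db = [ProteinRecord(id="s1", seq=pep),
              ProteinRecord(id="s2", seq="M" + random_peptide(rng, 150))]
        full = search([query], db, evalue_cutoff=1e-20)
        seeded = search([query], db, evalue_cutoff=1e-20, seeded=True)
        assert {h.subject_id for h in seeded} == {h.subject_id for h in full}

    def test_empty_database_raises(self):
        with pytest.raises(ValueError):
            search([TranscriptRecord(id="q", seq="ATG")], [])


def hit(subject, bits, ev=1e-30):
    return HomologyHit("q", subject, 100.0, 10, 0, 0, 1, 30, 1, 10, ev, bits)


class TestTopHit:
    def test_single_hit(self):
        h = hit("s1", 50.0)
        assert top_hit([h]) is h

    def test_higher_bitscore_wins(self):
        assert top_hit([hit("s1", 40.0), hit("s2", 50.0)]).subject_id == "s2"

    def test_bitscore_tie_broken_by_evalue_then_subject(self):
        assert top_hit([hit("s1", 50.0, 1e-20),
                        hit("s2", 50.0, 1e-30)]).subject_id == "s2"
        assert top_hit([hit("sB", 50.0), hit("sA", 50.0)]).subject_id == "sA"

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            top_hit([])

    def test_grouping_by_query(self):
        hits = [hit("s1", 40.0), hit("s2", 60.0)]
        hits[0].query_id = "qa"
        hits[1].query_id = "qa"
        tops = top_hits_by_query(hits)
        assert tops["qa"].subject_id == "s2"
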