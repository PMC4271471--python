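"""Banded extension DP, E-values and hit filtering."""

import math

import numpy as np
import pytest

from seedband import (
    BandSpec,
    Hit,
    InputError,
    ParameterError,
    ScoringScheme,
    Seed,
    banded_extend,
    compute_evalue,
    filter_hits,
    reverse_complement,
)
from conftest import mutate_dna, random_dna
from oracles import extend_score_oracle, seeded_pair_score_oracle

SCORING = ScoringScheme()
WIDE = BandSpec(half_width=256)


def _plant_seed(rng, n, k, sub_rate=0.1, indel_rate=0.03):
    """Query/ref pair sharing one exact k-window; returns (q, r, qs, rs)."""
    query = random_dna(rng, n)
    qs = int(rng.integers(0, n - k + 1))
    left = mutate_dna(rng, query[:qs], sub_rate, indel_rate)
    right = mutate_dna(rng, query[qs + k :], sub_rate, indel_rate)
    ref = left + query[qs : qs + k] + right
    return query, ref, qs, len(left)


class TestBandedExtendExamples:
    def test_perfect_match_both_modes(self, rng):
        seq = random_dna(rng, 20)
        for mode in ("global", "local"):
            hit = banded_extend(seq, seq, Seed(0, 7, 0, 7), 6, mode=mode, band=WIDE)
            assert hit.score == 20
            assert hit.identity == 1.0
            assert hit.aln_length == 20
            assert (hit.q_start, hit.q_end, hit.r_start, hit.r_end) == (0, 20, 0, 20)

    def test_internal_substitution_global(self):
        q = "ACGTACGTACGTACGTACGT"
        r = q[:2] + "T" + q[3:]  # one substitution at position 2, outside the seed
        hit = banded_extend(q, r, Seed(0, 8, 0, 8), 6, mode="global", band=WIDE)
        assert hit.score == 19 * 1 - 3
        assert hit.identity == pytest.approx(19 / 20)
        assert hit.mismatches == 1

    def test_terminal_mismatch_trimmed_in_local_mode(self):
        q = "ACGTACGTACGTACGTACGT"
        r = "T" + q[1:]  # substitution at the very first base
        glob = banded_extend(q, r, Seed(0, 8, 0, 8), 6, mode="global", band=WIDE)
        loc = banded_extend(q, r, Seed(0, 8, 0, 8), 6, mode="local", band=WIDE)
        assert glob.score == 19 - 3
        assert loc.score == 19  # trims the negative-scoring terminal column
        assert loc.q_start == 1 and glob.q_start == 0

    def test_gap_opening_example(self):
        hit = banded_extend(
            "AAAATTTT", "AAAACCCCTTTT", Seed(0, 0, 0, 0), 4, mode="global", band=BandSpec(6)
        )
        s = SCORING
        assert hit.score == 8 * s.match + s.gap_open + 4 * s.gap_extend
        assert hit.gap_opens == 1
        assert hit.aln_length == 12

    def test_zero_band_is_gapless_diagonal(self, rng):
        q = random_dna(rng, 40)
        r = mutate_dna(rng, q, sub_rate=0.2, indel_rate=0.0)
        r = r[:17] + q[17:23] + r[23:]  # force the seed window to match
        hit = banded_extend(q, r, Seed(0, 17, 0, 17), 6, mode="global", band=BandSpec(0))
        # oracle: plain running sum along the one diagonal
        expected = sum(1 if a == b else -3 for a, b in zip(q, r))
        assert hit.score == expected
        assert hit.gap_opens == 0

    def test_mismatched_seed_windows_rejected(self):
        with pytest.raises(InputError):
            banded_extend("AAAA", "CCCC", Seed(0, 0, 0, 0), 4, band=WIDE)


class TestBandedExactnessAgainstOracle:
    @pytest.mark.parametrize("mode", ["global", "local"])
    def test_full_width_band_equals_unbanded_dp(self, rng, mode):
        for _ in range(60):
            n = int(rng.integers(30, 120))
            q, r, qs, rs = _plant_seed(rng, n, k=8)
            hit = banded_extend(q, r, Seed(0, qs, 0, rs), 8, mode=mode, band=WIDE)
            expected = seeded_pair_score_oracle(q, r, qs, rs, 8, SCORING, mode == "global")
            if mode == "local" and expected <= 0:
                assert hit is None
            else:
                assert hit.score == expected

    def test_band_monotonicity_and_local_dominates_global(self, rng):
        for _ in range(20):
            q, r, qs, rs = _plant_seed(rng, 80, k=8, sub_rate=0.15, indel_rate=0.05)
            seed = Seed(0, qs, 0, rs)
            prev = None
            for hw in (0, 2, 4, 8, 16, 64):
                hit = banded_extend(q, r, seed, 8, mode="global", band=BandSpec(hw))
                if hit is None:
                    continue
                if prev is not None:
                    assert hit.score >= prev
                prev = hit.score
            glob = banded_extend(q, r, seed, 8, mode="global", band=WIDE)
            loc = banded_extend(q, r, seed, 8, mode="local", band=WIDE)
            assert loc.score >= glob.score

    def test_strand_symmetry(self, rng):
        for _ in range(10):
            q, r, qs, rs = _plant_seed(rng, 60, k=8)
            fwd = banded_extend(q, r, Seed(0, qs, 0, rs), 8, mode="global", band=WIDE)
            rq, rr = reverse_complement(q), reverse_complement(r)
            seed_rc = Seed(0, len(q) - qs - 8, 0, len(r) - rs - 8)
            rev = banded_extend(rq, rr, seed_rc, 8, mode="global", band=WIDE)
            assert fwd.score == rev.score

    def test_identity_bounds(self, rng):
        for _ in range(20):
            q, r, qs, rs = _plant_seed(rng, 70, k=8, sub_rate=0.2, indel_rate=0.05)
            hit = banded_extend(q, r, Seed(0, qs, 0, rs), 8, mode="global", band=WIDE)
            assert 0.0 <= hit.identity <= 1.0
            gap_cols = hit.aln_length - hit.mismatches - round(hit.identity * hit.aln_length)
            if hit.identity == 1.0:
                assert hit.mismatches == 0 and gap_cols == 0


def test_oracle_agrees_with_biopython_global(rng):
    """Sanity-check the test oracle itself against Bio.Align on plain
    anchored-start global alignments (free right end on the reference)."""
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    s = SCORING
    aligner.match_score = s.match
    aligner.mismatch_score = s.mismatch
    aligner.open_gap_score = s.gap_open + s.gap_extend
    aligner.extend_gap_score = s.gap_extend
    aligner.open_right_insertion_score = 0
    aligner.extend_right_insertion_score = 0
    for _ in range(15):
        q = random_dna(rng, int(rng.integers(5, 40)))
        r = mutate_dna(rng, q, 0.15, 0.05)
        if not r:
            continue
        expected = aligner.score(r, q)  # target=r, query=q
        got = extend_score_oracle(q, r, s.match, s.mismatch, s.gap_open, s.gap_extend, True)
        assert got == expected


class TestEvalue:
    def test_score_zero_is_kmn(self):
        s = ScoringScheme()
        evalue, _ = compute_evalue(0, 100, 1000, s)
        assert evalue == pytest.approx(s.K * 100 * 1000)

    def test_linear_in_database_length(self):
        e1, _ = compute_evalue(40, 100, 10**6, SCORING)
        e2, _ = compute_evalue(40, 100, 2 * 10**6, SCORING)
        assert e2 == pytest.approx(2 * e1)

    def test_worked_example(self):
        s = ScoringScheme(lam=0.625, K=0.41)
        evalue, bitscore = compute_evalue(40, 100, 10**6, s)
        assert evalue == pytest.approx(0.41 * 1e8 * math.exp(-25), rel=1e-12)
        assert evalue == pytest.approx(5.7e-4, rel=0.01)
        assert bitscore == pytest.approx((0.625 * 40 - math.log(0.41)) / math.log(2))

    def test_monotonicity(self):
        e_lo, b_lo = compute_evalue(10, 100, 1000, SCORING)
        e_hi, b_hi = compute_evalue(20, 100, 1000, SCORING)
        assert e_hi < e_lo and b_hi > b_lo

    def test_bad_lengths(self):
        with pytest.raises(ParameterError):
            compute_evalue(10, 0, 1000, SCORING)


class TestFilterHits:
    def _hit(self, evalue, aln_length):
        return Hit("q", "r", 0, 0, 10, 0, 10, 10, 1.0, aln_length, 0, 0, evalue, 10.0)

    def test_evalue_filter(self):
        hits = [self._hit(10.0, 50), self._hit(1e-5, 50)]
        assert filter_hits(hits, 1e-3, 0) == [hits[1]]

    def test_threshold_inclusive(self):
        hits = [self._hit(1e-3, 50)]
        assert filter_hits(hits, 1e-3, 0) == hits

    def test_min_length_zero_passes_everything(self):
        hits = [self._hit(1e-9, 1), self._hit(1e-9, 500)]
        assert filter_hits(hits, 1.0, 0) == hits
        assert filter_hits(hits, 1.0, 30) == [hits[1]]


def test_scoring_scheme_validation():
    with pytest.raises(ParameterError):
        ScoringScheme(match=-1)
    with pytest.raises(ParameterError):
        ScoringScheme(gap_extend=0)
    with pytest.raises(ParameterError):
        ScoringScheme(lam=0.0)
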