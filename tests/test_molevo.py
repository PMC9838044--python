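"""NG86 Ka/Ks, codon alignment, identity ranking, and clock dating."""

import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hdzip import simulate
from hdzip.molevo import (
    ClockParams,
    CodonAlignment,
    align_codon_pair,
    compute_ka_ks,
    divergence_time,
    jukes_cantor,
    kaks_ratio,
    pairwise_identity,
    select_duplicate_pairs,
)


class TestCodonAlignment:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError, match="equal length"):
            CodonAlignment("ATG", "ATGGCC")
        with pytest.raises(ValueError, match="divisible by 3"):
            CodonAlignment("ATGC", "ATGC")
        with pytest.raises(ValueError, match="non-ACGT"):
            CodonAlignment("ATN", "ATG")
        with pytest.raises(ValueError, match="stop"):
            CodonAlignment("TGAGCC", "TGGGCC")


class TestComputeKaKs:
    def test_identical_sequences(self):
        r = compute_ka_ks(CodonAlignment("ATGGCCAAA", "ATGGCCAAA"))
        assert r.ka == 0.0 and r.ks == 0.0
        assert not r.omega_defined

    def test_hand_worked_example(self):
        """One synonymous third-position change across three codons."""
        r = compute_ka_ks(CodonAlignment("TTTGATGCC", "TTCGATGCC"))
        assert r.s_sites == pytest.approx(5.0 / 3.0, abs=1e-12)
        assert r.n_sites == pytest.approx(22.0 / 3.0, abs=1e-12)
        assert (r.sd, r.nd) == (1.0, 0.0)
        assert r.sd / r.s_sites == pytest.approx(0.6, abs=1e-12)
        assert r.ks == pytest.approx(-0.75 * math.log(0.2), abs=1e-9)
        assert r.ka == 0.0

    def test_symmetry_under_swap(self):
        for seed in range(5):
            a, b, _ = simulate.gen_cds_pair(80, 0.3, 0.2, seed=seed)
            r1 = compute_ka_ks(CodonAlignment(a, b))
            r2 = compute_ka_ks(CodonAlignment(b, a))
            assert r1.ks == pytest.approx(r2.ks, abs=1e-12)
            assert r1.ka == pytest.approx(r2.ka, abs=1e-12)
            assert r1.s_sites == pytest.approx(r2.s_sites, abs=1e-12)

    def test_site_conservation_exact(self):
        for seed in range(5):
            a, b, _ = simulate.gen_cds_pair(60, 0.2, 0.1, seed=seed)
            r = compute_ka_ks(CodonAlignment(a, b))
            assert r.s_sites + r.n_sites == pytest.approx(180.0, abs=1e-9)

    def test_saturation_flag(self):
        # ps = 1 > 3/4: every codon synonymous-different at its 4-fold site
        a = "GGA" * 10
        b = "GGC" * 10
        r = compute_ka_ks(CodonAlignment(a, b))
        assert r.saturated_s and math.isnan(r.ks)

    def test_matches_biopython_reference(self):
        """Independent NG86 route: Biopython's cal_dn_ds on the same pairs."""
        codonseq = pytest.importorskip("Bio.codonalign.codonseq")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for seed in range(5):
                a, b, _ = simulate.gen_cds_pair(100, 0.25, 0.1, seed=40 + seed)
                dn, ds = codonseq.cal_dn_ds(
                    codonseq.CodonSeq(a), codonseq.CodonSeq(b), method="NG86"
                )
                r = compute_ka_ks(CodonAlignment(a, b))
                assert r.ka == pytest.approx(dn, abs=1e-9)
                assert r.ks == pytest.approx(ds, abs=1e-9)


class TestJukesCantor:
    @given(st.floats(min_value=0.0, max_value=0.74, exclude_max=True),
           st.floats(min_value=1e-6, max_value=0.74, exclude_max=True))
    @settings(max_examples=100, derandomize=True)
    def test_monotone_increasing(self, p, dp):
        q = min(p + dp, 0.7499)
        assert jukes_cantor(q) >= jukes_cantor(p)

    def test_saturation_nan(self):
        assert math.isnan(jukes_cantor(0.75))
        assert math.isnan(jukes_cantor(0.9))


class TestRatioAndClock:
    def test_published_ratio_arithmetic(self):
        assert round(kaks_ratio(0.205, 0.364), 3) == 0.563
        assert round(kaks_ratio(0.159, 0.383), 3) == 0.415

    def test_undefined_and_zero(self):
        assert math.isnan(kaks_ratio(0.2, 0.0))
        assert kaks_ratio(0.0, 0.3) == 0.0

    def test_clock_dates(self):
        assert divergence_time(0.364) == pytest.approx(28.0, abs=1e-9)
        assert divergence_time(0.0) == 0.0

    def test_clock_linearity(self):
        t1 = divergence_time(0.2)
        assert divergence_time(0.4) == pytest.approx(2 * t1, rel=1e-12)
        fast = ClockParams(lam=1.3e-08)
        assert divergence_time(0.2, fast) == pytest.approx(t1 / 2, rel=1e-12)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            divergence_time(-0.1)
        with pytest.raises(ValueError):
            ClockParams(lam=0.0)


class TestDuplicatePairSelection:
    def test_identical_pair_ranked_first(self):
        recs = [
            ("x1", "ATGGCCAAAGGG"), ("x2", "ATGGCCAAAGGG"),
            ("y1", "ATGTTTCCCGGG"), ("y2", "TACAGGCATCAT"),
        ]
        ranked = select_duplicate_pairs(recs)
        assert ranked[0][:2] == ("x1", "x2")
        assert ranked[0][2] == 100.0
        assert all(a != b for a, b, _ in ranked)  # no self-pairs

    def test_ranking_matches_bruteforce_identity(self):
        """Equal-length gap-free sequences: identity reduces to Hamming."""
        rng = np.random.default_rng(21)
        base = "".join(rng.choice(list("ACGT"), 60))

        def mutate(seq, k):
            s = list(seq)
            for pos in rng.choice(len(s), size=k, replace=False):
                s[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[s[pos]]
            return "".join(s)

        # sparse mutations keep the gap-free alignment optimal, so the
        # Hamming oracle applies
        recs = {"s0": base, "s1": mutate(base, 1), "s2": mutate(base, 3),
                "s3": mutate(base, 6)}
        ranked = select_duplicate_pairs(recs.items())
        oracle = sorted(
            (
                (-sum(x == y for x, y in zip(recs[a], recs[b])) / 60 * 100, a, b)
                for a, b in [("s0", "s1"), ("s0", "s2"), ("s0", "s3"),
                             ("s1", "s2"), ("s1", "s3"), ("s2", "s3")]
            )
        )
        assert [(a, b) for _, a, b in oracle] == [(a, b) for a, b, _ in ranked]
        for (score, a, b), (_, _, got) in zip(oracle, ranked):
            assert got == pytest.approx(-score, abs=1e-9)

    def test_short_sequence_skipped(self):
        with pytest.warns(UserWarning, match="shorter than one codon"):
            ranked = select_duplicate_pairs(
                [("tiny", "AT"), ("a", "ATGGCC"), ("b", "ATGGCG")]
            )
        assert {x for pair in ranked for x in pair[:2]} == {"a", "b"}


class TestCodonAwareAlignment:
    def test_gap_columns_removed(self):
        # b lacks one internal codon; alignment drops the gapped column
        a = "ATGGCCAAAGGGTTT"
        b = "ATGGCCGGGTTT"
        aln = align_codon_pair(a, b)
        assert len(aln.seq_a) == len(aln.seq_b) == 12
        assert compute_ka_ks(aln).nd == 0.0

    def test_identity_of_identical_sequences(self):
        assert pairwise_identity("ATGGCC", "ATGGCC") == 100.0
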