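"""qfrag coverage, summit detection, Poisson testing and the full caller."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import (
    make_hitset,
    oracle_bh,
    oracle_free_standing,
    oracle_qfrag_coverage,
    random_hitset,
)
from qnexus import (
    PeakCallParams,
    bh_adjust,
    call_peaks,
    deduplicate,
    find_summits,
    poisson_pvalue,
    qfrag_coverage,
    summit_lambda,
    write_narrowpeak,
    write_summit_bed,
    write_summit_tsv,
)
from qnexus.synthetic_data import SimConfig, simulate_hits


class TestQfragCoverage:
    def test_single_pair_covers_closed_interval(self):
        hs = make_hitset({"c": 1000}, fwd=[("c", 100)], rev=[("c", 115)])
        depth = qfrag_coverage(hs, 13, 23)["c"]
        assert np.all(depth[100:116] == 1)
        assert depth[99] == 0 and depth[116] == 0

    def test_pair_below_qmin_excluded(self):
        hs = make_hitset({"c": 1000}, fwd=[("c", 100)], rev=[("c", 112)])
        assert qfrag_coverage(hs, 13, 23)["c"].sum() == 0

    def test_two_overlapping_qfrags(self):
        hs = make_hitset({"c": 1000}, fwd=[("c", 100), ("c", 105)], rev=[("c", 118)])
        depth = qfrag_coverage(hs, 13, 23)["c"]
        assert np.all(depth[105:119] == 2)
        assert np.all(depth[100:105] == 1)

    def test_matches_interval_stacking_oracle(self, rng):
        for _ in range(30):
            hs = random_hitset(rng, n_hits=int(rng.integers(1, 200)), chrom_len=400)
            got = qfrag_coverage(hs, 5, 20)["c"]
            expected = oracle_qfrag_coverage(hs, "c", 5, 20)
            assert np.array_equal(got[1:], expected[1:])


class TestFindSummits:
    def test_unique_maximum(self):
        depth = np.zeros(301, dtype=np.int64)
        for i, d in enumerate(range(1, 8)):
            depth[143 + i] = d
        depth[150] = 8
        for i, d in enumerate(range(6, 0, -1)):
            depth[151 + i] = d
        assert find_summits(depth, 13) == [150]

    def test_plateau_yields_central_position(self):
        depth = np.zeros(301, dtype=np.int64)
        depth[140:161] = 3
        assert find_summits(depth, 13) == [150]

    def test_two_separated_maxima_both_reported(self):
        depth = np.zeros(301, dtype=np.int64)
        for i in range(31):  # V-shaped dip between maxima at 100 and 130
            depth[100 + i] = max(1, 5 - min(i, 30 - i))
        assert find_summits(depth, 13) == [100, 130]

    def test_close_maxima_suppressed(self):
        depth = np.zeros(301, dtype=np.int64)
        depth[100] = 3
        depth[105] = 2  # within radius of the higher maximum
        assert find_summits(depth, 13) == [100]

    def test_all_zero_profile(self):
        assert find_summits(np.zeros(100, dtype=np.int64), 13) == []

    def test_every_summit_is_free_standing(self, rng):
        # post-hoc check of the definition, and plateau de-duplication:
        # every reported summit qualifies, one summit per qualifying run
        for _ in range(20):
            hs = random_hitset(rng, n_hits=150, chrom_len=300)
            depth = qfrag_coverage(hs, 5, 20)["c"]
            summits = find_summits(depth, 5)
            qualifying = oracle_free_standing(depth, 5)
            assert set(summits) <= set(qualifying)
            # runs of adjacent qualifying positions collapse to one summit
            runs = 0
            prev = None
            for q in qualifying:
                if prev is None or q != prev + 1 or depth[q] != depth[prev]:
                    runs += 1
                prev = q
            assert len(summits) == runs


class TestStatistics:
    def test_lambda_printed_formula(self):
        assert summit_lambda(1000, 10**6, 23) == pytest.approx(0.046)
        assert summit_lambda(0, 10**6, 23) == 0.0
        assert summit_lambda(1000, 10**6, 46) == pytest.approx(0.092)
        with pytest.raises(ValueError):
            summit_lambda(10, 0, 23)

    def test_poisson_upper_tail_against_series(self):
        assert poisson_pvalue(0, 5.0) == 1.0
        assert poisson_pvalue(1, 1.0) == pytest.approx(1 - math.exp(-1), rel=1e-12)
        # direct series evaluation as the oracle
        lam, k = 0.046, 5
        expected = 1.0 - sum(
            math.exp(-lam) * lam**i / math.factorial(i) for i in range(k)
        )
        assert poisson_pvalue(k, lam) == pytest.approx(expected, rel=1e-12)
        with pytest.raises(ValueError):
            poisson_pvalue(-1, 1.0)

    def test_pvalue_monotone_in_k(self):
        ps = [poisson_pvalue(k, 0.7) for k in range(10)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_bh_hand_example(self):
        assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])
        assert bh_adjust([0.2]) == pytest.approx([0.2])

    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0, allow_nan=False), min_size=1, max_size=50)
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_bh_matches_step_up_oracle(self, p_values):
        got = bh_adjust(p_values)
        assert np.allclose(got, oracle_bh(p_values), atol=1e-12)

    def test_bh_invariant_under_permutation(self, rng):
        p = rng.random(40)
        perm = rng.permutation(40)
        assert np.allclose(bh_adjust(p)[perm], bh_adjust(p[perm]))


class TestCallPeaks:
    def test_idealized_single_site(self):
        # forward pile-up at s-9, reverse at s+9, w=18: one summit at the
        # plateau centre s, k = total reads of the two pile-ups
        s = 500
        hs = make_hitset({"c": 1000}, fwd=[("c", s - 9, 20)], rev=[("c", s + 9, 20)])
        result = call_peaks(hs, PeakCallParams(width=18))
        assert len(result.summits) == 1
        summit = result.summits[0]
        assert summit.pos == s
        assert summit.k == 40
        assert summit.qfrag_depth == 400
        assert summit.lam == pytest.approx(2 * 23 * 40 / 1000)
        assert summit.p_value < 1e-10
        assert summit.q_value == pytest.approx(summit.p_value)  # single test

    def test_empty_hitset_gives_empty_result(self):
        hs = make_hitset({"c": 1000})
        result = call_peaks(hs, PeakCallParams(width=18))
        assert result.summits == [] and result.n_tested == 0

    def test_all_covered_summits_tested_and_sorted(self, rng):
        hs = random_hitset(rng, n_hits=400, chrom_len=2000)
        result = call_peaks(hs, PeakCallParams(width=12, deviation=5))
        depth = qfrag_coverage(hs, 7, 17)["c"]
        for s in result.summits:
            assert depth[s.pos] == s.qfrag_depth >= 1
        ps = [s.p_value for s in result.summits]
        assert ps == sorted(ps)

    def test_top_n_truncation_and_q_cutoff(self, rng):
        hs = random_hitset(rng, n_hits=400, chrom_len=2000)
        full = call_peaks(hs, PeakCallParams(width=12))
        top2 = call_peaks(hs, PeakCallParams(width=12, top_n=2))
        assert len(top2.summits) == min(2, len(full.summits))
        assert [s.pos for s in top2.summits] == [s.pos for s in full.summits[:2]]
        strict = call_peaks(hs, PeakCallParams(width=12, q_value_cutoff=0.0))
        assert strict.summits == []

    def test_width_estimated_internally_when_not_given(self):
        cfg = SimConfig(seed=9, n_sites=50, genome=(("chrS1", 300_000),))
        hits, _ = simulate_hits(cfg)
        dedup, _ = deduplicate(hits)
        result = call_peaks(dedup, PeakCallParams())
        assert result.width_estimated
        assert abs(result.params.width - cfg.protected_width) <= 1

    def test_output_files(self, tmp_path):
        s = 500
        hs = make_hitset({"c": 1000}, fwd=[("c", s - 9, 20)], rev=[("c", s + 9, 20)])
        result = call_peaks(hs, PeakCallParams(width=18))
        write_summit_bed(result, tmp_path / "p.bed")
        write_narrowpeak(result, tmp_path / "p.narrowPeak", {"c": 1000})
        write_summit_tsv(result, tmp_path / "p.tsv")
        bed = (tmp_path / "p.bed").read_text().splitlines()
        chrom, start, end, name, score = bed[0].split("\t")
        assert (chrom, int(start), int(end)) == ("c", s - 1, s)  # 0-based half-open
        np_fields = (tmp_path / "p.narrowPeak").read_text().split("\t")
        assert int(np_fields[1]) == s - 1 - 2 and int(np_fields[2]) == s + 2  # +-2 bp
        assert int(np_fields[9]) == 2  # summit offset within the extended interval
        tsv = (tmp_path / "p.tsv").read_text().splitlines()
        assert tsv[0].startswith("chrom\tpos")
        assert len(tsv) == 2
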