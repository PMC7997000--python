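import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from snipage.core_io import SignalTrack
from snipage.validation import (chia_support, compare_distance_distributions,
                                derived_allele_frequency, enrichment_test,
                                imbalance_score, imbalance_test,
                                matched_background_pairs,
                                nearest_snp_distance, score_windows)


def snp_df(positions, chrom="chr1"):
    return pd.DataFrame({"chrom": chrom, "pos": positions},
                        index=[f"s{i}" for i in range(len(positions))])


class TestScoreWindows:
    def test_constant_track(self):
        track = SignalTrack([("chr1", 0, 10_000, 2.0)])
        scores = score_windows(snp_df([5000]), track, width=200)
        assert scores["s0"] == pytest.approx(2.0)

    def test_zero_fill_for_uncovered(self):
        # half the window covered at 4.0, the rest uncovered
        track = SignalTrack([("chr1", 4899, 4999, 4.0)])
        scores = score_windows(snp_df([5000]), track, width=200)
        assert scores["s0"] == pytest.approx(2.0)

    def test_brute_force_per_base_oracle(self):
        rng = np.random.default_rng(51)
        for _ in range(50):
            runs = []
            pos = 0
            for _ in range(rng.integers(3, 10)):
                pos += int(rng.integers(1, 50))
                width = int(rng.integers(1, 60))
                runs.append(("chr1", pos, pos + width,
                             float(rng.uniform(0, 5))))
                pos += width
            track = SignalTrack(runs)
            center = int(rng.integers(100, 400))
            w = 200
            per_base = sum(track.value_at("chr1", p)
                           for p in range(center - 1 - w // 2,
                                          center - 1 + w // 2))
            scores = score_windows(snp_df([center]), track, width=w)
            assert scores["s0"] == pytest.approx(per_base / w, abs=1e-10)

    def test_linearity_in_track(self):
        runs = [("chr1", 4950, 5050, 3.0)]
        scaled = [("chr1", 4950, 5050, 7.5)]
        s1 = score_windows(snp_df([5000]), SignalTrack(runs), 200)["s0"]
        s2 = score_windows(snp_df([5000]), SignalTrack(scaled), 200)["s0"]
        assert s2 == pytest.approx(2.5 * s1)


class TestEnrichmentTest:
    def test_identical_samples_p_half(self):
        rng = np.random.default_rng(52)
        x = rng.normal(size=80)
        res = enrichment_test(x, x, "greater")
        assert 0.4 < res.p < 0.6

    def test_separated_samples(self):
        rng = np.random.default_rng(53)
        bg = rng.normal(size=50)
        res = enrichment_test(bg + 10, bg, "greater")
        assert res.p < 1e-10

    def test_all_tied_warns_p_one(self):
        with pytest.warns(UserWarning, match="tied"):
            res = enrichment_test([1.0] * 5, [1.0] * 5)
        assert res.p == 1.0

    def test_size_under_null(self):
        rng = np.random.default_rng(54)
        hits = 0
        sims = 500
        for _ in range(sims):
            fg, bg = rng.normal(size=(2, 100))
            hits += enrichment_test(fg, bg, "greater").p < 0.05
        assert abs(hits / sims - 0.05) < 0.025

    def test_empty_sample_errors(self):
        with pytest.raises(ValueError, match="non-empty"):
            enrichment_test([], [1.0])


class TestImbalance:
    def test_balanced_counts_zero(self):
        assert imbalance_score(10, 10) == 0.0

    def test_two_to_one(self):
        expected = abs(np.log2((20 + 1e-6) / (10 + 1e-6)))
        assert imbalance_score(20, 10) == pytest.approx(expected)
        assert imbalance_score(20, 10) == pytest.approx(1.0, abs=1e-6)

    def test_zero_count_stabilizer(self):
        expected = abs(np.log2(1e-6 / (15 + 1e-6)))
        assert imbalance_score(0, 15) == pytest.approx(expected)
        assert imbalance_score(0, 15) == pytest.approx(23.838, abs=1e-3)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.integers(0, 1000), st.integers(0, 1000))
    def test_symmetry_and_zero_iff_equal(self, n1, n2):
        assert imbalance_score(n1, n2) == imbalance_score(n2, n1)
        assert (imbalance_score(n1, n2) == 0.0) == (n1 == n2)

    def test_planted_imbalance_detected(self):
        rng = np.random.default_rng(55)
        n1 = rng.binomial(30, 0.7, size=200)
        obs = pd.DataFrame({"n_allele1": n1, "n_allele2": 30 - n1})
        res, _ = imbalance_test(obs, seed=1)
        assert res.p < 1e-3

    def test_low_depth_sites_excluded(self):
        obs = pd.DataFrame({"n_allele1": [5, 20], "n_allele2": [4, 15]})
        res, n_excluded = imbalance_test(obs, seed=1)
        assert n_excluded == 1 and res.n_fg == 1

    def test_all_low_depth_errors(self):
        obs = pd.DataFrame({"n_allele1": [3], "n_allele2": [4]})
        with pytest.raises(ValueError, match="depth"):
            imbalance_test(obs, seed=1)


class TestChiaSupport:
    LINKS = pd.DataFrame([{"chrom_a": "chr1", "start_a": 100, "end_a": 200,
                           "chrom_b": "chr1", "start_b": 5000,
                           "end_b": 5100, "count": 2}])

    def pairs(self, pos, tss):
        return pd.DataFrame([{"chrom": "chr1", "pos": pos, "tss": tss}])

    def test_bridging_link_counted(self):
        s = chia_support(self.pairs(151, 5051), self.LINKS,
                         promoter_halfwidth=100)
        assert s.iloc[0] == 1

    def test_snp_outside_anchor(self):
        s = chia_support(self.pairs(301, 5051), self.LINKS,
                         promoter_halfwidth=100)
        assert s.iloc[0] == 0

    def test_both_anchors_on_snp_not_bridging(self):
        links = pd.DataFrame([{"chrom_a": "chr1", "start_a": 100,
                               "end_a": 200, "chrom_b": "chr1",
                               "start_b": 120, "end_b": 220, "count": 1}])
        s = chia_support(self.pairs(151, 900_000), links,
                         promoter_halfwidth=100)
        assert s.iloc[0] == 0


class TestMatchedBackground:
    def test_tolerance_always_respected(self):
        rng = np.random.default_rng(56)
        fg = pd.DataFrame({"distance": rng.integers(10_000, 900_000, 80)})
        cand = pd.DataFrame({"distance": rng.integers(5_000, 1_000_000,
                                                      5000)})
        fg_m, bg_m = matched_background_pairs(fg, cand, seed=1)
        ratio = bg_m["distance"].to_numpy() / fg_m["distance"].to_numpy()
        assert ((ratio >= 0.9) & (ratio <= 1.1)).all()

    def test_self_matching_null(self):
        rng = np.random.default_rng(57)
        fg = pd.DataFrame({"distance": rng.integers(10_000, 900_000, 100)})
        fg_m, bg_m = matched_background_pairs(fg, fg.copy(), seed=2)
        res = enrichment_test(fg_m["distance"], bg_m["distance"], "greater")
        assert 0.2 < res.p < 0.8

    def test_matching_quality(self):
        rng = np.random.default_rng(58)
        fg = pd.DataFrame({"distance": rng.integers(10_000, 900_000, 500)})
        cand = pd.DataFrame({"distance": rng.integers(5_000, 1_000_000,
                                                      20_000)})
        fg_m, bg_m = matched_background_pairs(fg, cand, seed=3)
        from scipy.stats import mannwhitneyu
        _, p = mannwhitneyu(fg_m["distance"], bg_m["distance"])
        assert p > 0.05

    def test_unmatched_majority_errors(self):
        fg = pd.DataFrame({"distance": [100_000] * 10})
        cand = pd.DataFrame({"distance": [500_000] * 10})
        with pytest.raises(ValueError, match="unmatched"):
            matched_background_pairs(fg, cand, seed=1)


class TestNearestDistance:
    def test_basic_minimum(self):
        d = nearest_snp_distance(snp_df([1000]), snp_df([400, 1300]))
        assert d.iloc[0] == 300

    def test_coincident_zero(self):
        d = nearest_snp_distance(snp_df([400]), snp_df([400, 1300]))
        assert d.iloc[0] == 0

    def test_missing_chromosome_infinite(self):
        d = nearest_snp_distance(snp_df([1000], chrom="chr2"),
                                 snp_df([400]))
        assert np.isinf(d.iloc[0])

    def test_exhaustive_oracle(self):
        rng = np.random.default_rng(59)
        for _ in range(50):
            q = rng.integers(0, 10_000, size=20)
            r = rng.integers(0, 10_000, size=30)
            d = nearest_snp_distance(snp_df(q), snp_df(r))
            expected = [min(abs(int(x) - int(y)) for y in r) for x in q]
            np.testing.assert_array_equal(d.to_numpy(), expected)

    def test_empty_reference_errors(self):
        with pytest.raises(ValueError, match="empty"):
            nearest_snp_distance(snp_df([1]), snp_df([]))


class TestDistanceComparison:
    def test_dominated_sample(self):
        rng = np.random.default_rng(60)
        ctrl = rng.uniform(1000, 2000, 100)
        res = compare_distance_distributions(ctrl / 2, ctrl, "less")
        assert res.p < 1e-6

    def test_equal_samples(self):
        rng = np.random.default_rng(61)
        x = rng.uniform(0, 1, 100)
        res = compare_distance_distributions(x, x, "less")
        assert 0.4 < res.p < 0.6

    def test_infinite_excluded(self):
        fg = [1.0, 2.0, np.inf]
        ctrl = [5.0, 6.0, 7.0]
        res = compare_distance_distributions(fg, ctrl, "less")
        assert res.n_fg == 2


class TestDAF:
    def test_derived_allele_rule(self):
        table = pd.DataFrame({
            "ref": ["A", "C", "G"],
            "alt": ["G", "T", "A"],
            "ancestral": ["A", "T", "C"],   # alt derived, ref derived, n/a
            "alt_freq": [0.3, 0.2, 0.4]})
        daf = derived_allele_frequency(table)
        assert daf.iloc[0] == pytest.approx(0.3)
        assert daf.iloc[1] == pytest.approx(0.8)
        assert len(daf) == 2
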