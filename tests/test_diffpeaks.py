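"""Consensus peaks, counting, normalisation and NB/Wald tests."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from scipy.special import comb

from rloopedit.diffpeaks import (
    classify_induced,
    consensus_peaks,
    count_in_features,
    gene_set_overlap_test,
    normalize_median_of_ratios,
    test_differential,
    test_interaction,
)
from rloopedit.intervals import PeakSet

from _util import make_peakset


class TestConsensus:
    def test_two_of_three_retained_one_of_three_dropped(self):
        reps = [
            make_peakset([("c", 100, 200, "+"), ("c", 5000, 5100, "+")]),
            make_peakset([("c", 150, 250, "+")]),
            make_peakset([("c", 9000, 9100, "+")]),
        ]
        out = consensus_peaks(reps, min_recurrence=2, merge_within=1000)
        assert len(out) == 1
        row = out.df.iloc[0]
        assert row.start == 100 and row.end == 250

    def test_same_strand_merge_opposite_kept(self):
        reps = [
            make_peakset([("c", 0, 100, "+"), ("c", 1000, 1100, "+"), ("c", 1000, 1100, "-")]),
            make_peakset([("c", 0, 100, "+"), ("c", 1000, 1100, "+"), ("c", 1000, 1100, "-")]),
        ]
        out = consensus_peaks(reps, min_recurrence=2, merge_within=1000)
        plus = out.df[out.df.strand == "+"]
        assert len(plus) == 1  # 900 bp gap merged
        assert len(out.df[out.df.strand == "-"]) == 1

    def test_matches_brute_force_recurrence(self, rng):
        for _ in range(20):
            reps = []
            all_peaks = []
            for r in range(3):
                rows = []
                for _ in range(int(rng.integers(3, 15))):
                    s = int(rng.integers(0, 20_000))
                    e = s + int(rng.integers(50, 400))
                    rows.append(("c", s, e, "+"))
                    all_peaks.append((s, e, r))
                reps.append(make_peakset(rows))
            out = consensus_peaks(reps, min_recurrence=2, merge_within=0)
            # brute force: positions covered by peaks from >=2 replicates,
            # via overlap chains
            covered = np.zeros((3, 21_000), dtype=bool)
            for s, e, r in all_peaks:
                covered[r, s:e] = True
            # chain-based recurrence: a consensus chain region must contain
            # overlapping peaks from >= 2 distinct replicates
            for row in out.df.itertuples(index=False):
                reps_hit = {
                    r for s, e, r in all_peaks if s < row.end and row.start < e
                }
                assert len(reps_hit) >= 2

    def test_too_few_replicates_raises(self):
        with pytest.raises(ValueError):
            consensus_peaks([make_peakset([("c", 0, 10)])], min_recurrence=2)


class TestCounting:
    def test_midpoint_containment_and_boundary(self):
        features = make_peakset([("c", 100, 200)])
        features.df.loc[0, "name"] = "f"
        inside = make_peakset([("c", 140, 160)])  # midpoint 150
        at_start = make_peakset([("c", 50, 150)])  # midpoint 100 == start
        at_end = make_peakset([("c", 150, 250)])  # midpoint 200 == end
        counts = count_in_features(
            {"a": inside, "b": at_start, "c": at_end}, features
        )
        assert counts.loc["f", "a"] == 1
        assert counts.loc["f", "b"] == 1  # half-open: start included
        assert counts.loc["f", "c"] == 0  # end excluded

    def test_disjoint_features_conserve_totals(self, rng):
        features = make_peakset([("c", i * 1000, i * 1000 + 800) for i in range(10)])
        features.df["name"] = [f"f{i}" for i in range(10)]
        frags = make_peakset(
            [("c", int(s), int(s) + 100) for s in rng.integers(0, 10_000, 200)]
        )
        counts = count_in_features({"s": frags}, features)
        assert counts["s"].sum() <= 200


class TestNormalization:
    def test_identical_columns_unit_factors(self):
        counts = pd.DataFrame({"a": [10, 20, 30], "b": [10, 20, 30]})
        sf = normalize_median_of_ratios(counts)
        np.testing.assert_allclose(sf, 1.0)

    def test_doubled_column_factor_two(self):
        counts = pd.DataFrame({"a": [10, 20, 30], "b": [20, 40, 60]})
        sf = normalize_median_of_ratios(counts)
        assert sf["b"] / sf["a"] == pytest.approx(2.0)

    def test_feature_order_invariance(self, rng):
        counts = pd.DataFrame(rng.integers(1, 100, size=(50, 4)))
        shuffled = counts.sample(frac=1, random_state=0)
        pd.testing.assert_series_equal(
            normalize_median_of_ratios(counts),
            normalize_median_of_ratios(shuffled),
        )

    def test_all_zero_rows_fall_back_with_warning(self):
        counts = pd.DataFrame({"a": [0, 5], "b": [3, 0]})
        with pytest.warns(UserWarning):
            sf = normalize_median_of_ratios(counts)
        assert (sf > 0).all()


def simulate_counts(rng, n=300, reps=3, fc=1.0, frac=0.0, mean=50, disp=0.1):
    base = mean * np.exp(rng.normal(0, 0.5, n))
    induced = np.zeros(n, dtype=bool)
    induced[: int(frac * n)] = True
    cols = {}
    cond = {}
    for g, label in ((0, "ctl"), (1, "trt")):
        for i in range(reps):
            mu = base * np.where(induced & (g == 1), fc, 1.0)
            r = 1 / disp
            cols[f"{label}_{i}"] = rng.negative_binomial(r, r / (r + mu))
            cond[f"{label}_{i}"] = label
    return pd.DataFrame(cols), pd.Series(cond), induced


class TestDifferential:
    def test_label_swap_negates_log2fc_exactly(self, rng):
        counts, cond, _ = simulate_counts(rng, fc=2.0, frac=0.3)
        res = test_differential(counts, cond)
        swapped = cond.map({"ctl": "z", "trt": "a"})
        res_sw = test_differential(counts, swapped)
        np.testing.assert_allclose(res_sw["log2FC"], -res["log2FC"])
        np.testing.assert_allclose(res_sw["p"], res["p"])

    def test_all_zero_features_flagged(self):
        counts = pd.DataFrame(
            {"a": [0, 10], "b": [0, 12], "c": [0, 9], "d": [0, 11]}
        )
        cond = pd.Series({"a": "x", "b": "x", "c": "y", "d": "y"})
        res = test_differential(counts, cond)
        assert res["all_zero"].iloc[0]
        assert res["p"].iloc[0] == 1.0 and res["log2FC"].iloc[0] == 0.0

    def test_bh_fdr_monotone_in_sorted_p(self, rng):
        counts, cond, _ = simulate_counts(rng, n=200)
        res = test_differential(counts, cond).sort_values("p")
        assert (np.diff(res["FDR"]) >= -1e-12).all()
        # BH rejections contain Bonferroni rejections
        bonf = res["p"] <= 0.05 / len(res)
        assert (res.loc[bonf, "FDR"] <= 0.05).all()

    def test_scaling_one_sample_leaves_log2fc_unchanged(self, rng):
        counts, cond, _ = simulate_counts(rng, n=400)
        res = test_differential(counts, cond, refine_size_factors=False)
        scaled = counts.copy()
        scaled["trt_0"] = scaled["trt_0"] * 3
        sf0 = normalize_median_of_ratios(counts)
        sf1 = normalize_median_of_ratios(scaled)
        # only factor ratios are identified: relative factor scales by c exactly
        rel0 = sf0["trt_0"] / sf0["ctl_0"]
        rel1 = sf1["trt_0"] / sf1["ctl_0"]
        assert rel1 / rel0 == pytest.approx(3.0, rel=1e-9)
        res_s = test_differential(scaled, cond, refine_size_factors=False)
        # pseudocount makes very low-abundance features slightly sensitive
        solid = res["baseMean"] > 5
        np.testing.assert_allclose(
            res_s.loc[solid, "log2FC"], res.loc[solid, "log2FC"], atol=2e-2
        )

    def test_insufficient_replicates_rejected(self):
        counts = pd.DataFrame({"a": [1], "b": [2], "c": [3]}, index=["f"]).T.T
        cond = pd.Series({"a": "x", "b": "x", "c": "y"})
        with pytest.raises(ValueError):
            test_differential(counts, cond)


class TestInteraction:
    def _design(self, rng, n=400, reps=3, interaction_fc=1.0, disp=0.1):
        base = 50 * np.exp(rng.normal(0, 0.5, n))
        hit = np.zeros(n, dtype=bool)
        hit[: n // 5] = True
        cols, fa, fb = {}, {}, {}
        for a in (0, 1):
            for b in (0, 1):
                for i in range(reps):
                    s = f"a{a}b{b}_{i}"
                    mu = base * (2.0**a) * (1.5**b)
                    if a and b:
                        mu = mu * np.where(hit, interaction_fc, 1.0)
                    r = 1 / disp
                    cols[s] = rng.negative_binomial(r, r / (r + mu))
                    fa[s] = f"A{a}"
                    fb[s] = f"B{b}"
        return pd.DataFrame(cols), pd.Series(fa), pd.Series(fb), hit

    def test_planted_interaction_recovered(self, rng):
        counts, fa, fb, hit = self._design(rng, interaction_fc=0.5)
        res = test_interaction(counts, fa, fb)
        assert res["interaction_log2"][hit].mean() == pytest.approx(-1.0, abs=0.2)
        assert abs(res["interaction_log2"][~hit].mean()) < 0.1
        # a halved treatment effect is a subtle signal at 3 replicates:
        # demand stochastically smaller p-values, not high power
        assert res.loc[hit, "p"].median() < res.loc[~hit, "p"].median() / 2

    def test_simultaneous_relabeling_invariance(self, rng):
        counts, fa, fb, _ = self._design(rng, interaction_fc=0.5)
        res = test_interaction(counts, fa, fb)
        # swap both factors: (A,B) -> (A',B') with both level orders flipped
        fa2 = fa.map({"A0": "Z1", "A1": "Z0"})
        fb2 = fb.map({"B0": "Y1", "B1": "Y0"})
        res2 = test_interaction(counts, fa2, fb2)
        np.testing.assert_allclose(
            res["interaction_log2"], res2["interaction_log2"], atol=1e-12
        )

    def test_empty_cell_rejected(self, rng):
        counts, fa, fb, _ = self._design(rng)
        cols = [c for c in counts.columns if not c.startswith("a1b1")]
        with pytest.raises(ValueError):
            test_interaction(counts[cols], fa[cols], fb[cols])


class TestClassifyInduced:
    def _results(self, fdrs, fcs, base_means=None):
        n = len(fdrs)
        return pd.DataFrame(
            {
                "baseMean": base_means if base_means is not None else np.ones(n),
                "log2FC": np.log2(fcs),
                "SE": np.ones(n),
                "p": fdrs,  # p==FDR for this construction
                "FDR": fdrs,
            },
            index=[f"f{i}" for i in range(n)],
        )

    def test_thresholds_inclusive(self):
        res = self._results([0.05, 0.051], [1.5, 3.0])
        out = classify_induced(res)
        assert bool(out["induced"].iloc[0]) is True
        assert bool(out["induced"].iloc[1]) is False

    def test_direction_recorded(self):
        res = self._results([0.01, 0.01], [2.0, 1 / 2.0])
        out = classify_induced(res)
        assert list(out["direction"]) == ["up", "down"]

    def test_top_fraction_filter_counts(self):
        res = self._results([0.01] * 100, [2.0] * 100, base_means=np.arange(100.0))
        out = classify_induced(res, top_fraction=0.25)
        assert (~out["filtered"]).sum() == 25
        assert out["filtered"].sum() == 75
        # the kept quarter is the top by base mean
        assert out.loc[~out["filtered"], "baseMean"].min() == 75.0


class TestGeneSetOverlap:
    def test_all_hits_inside_set(self):
        universe = {f"g{i}" for i in range(100)}
        gene_set = {f"g{i}" for i in range(10)}
        hits = set(gene_set)
        out = gene_set_overlap_test(hits, {"s": gene_set}, universe)
        assert out["p_value"].iloc[0] == pytest.approx(1 / comb(100, 10), rel=1e-9)

    def test_zero_overlap_near_one(self):
        universe = {f"g{i}" for i in range(100)}
        out = gene_set_overlap_test(
            {"g50", "g51"}, {"s": {"g0", "g1"}}, universe
        )
        assert out["p_value"].iloc[0] > 0.9

    def test_matches_exact_enumeration_small_universe(self):
        universe = {f"g{i}" for i in range(20)}
        gene_set = {f"g{i}" for i in range(6)}
        hits = {"g0", "g1", "g10", "g11", "g12"}
        k_obs = len(hits & gene_set)
        out = gene_set_overlap_test(hits, {"s": gene_set}, universe)
        # enumerate all hit subsets is expensive; enumerate overlap counts
        N, K, n = 20, 6, 5
        p_exact = sum(
            comb(K, k) * comb(N - K, n - k) / comb(N, n)
            for k in range(k_obs, min(K, n) + 1)
        )
        assert out["p_value"].iloc[0] == pytest.approx(p_exact, rel=1e-9)

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            gene_set_overlap_test({"a"}, {"s": {"a"}}, set())
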