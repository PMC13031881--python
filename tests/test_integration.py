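"""Proximity, concordance, enrichment, timing-quartile and gene-assignment rules."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from rloopedit.integration import (
    AnnotationCatalogue,
    chi_square_2x2,
    classify_proximity,
    consequence_enrichment,
    random_site_sample,
    region_to_gene,
    replication_quartile_rates,
    state_enrichment,
    strand_concordance,
)
from rloopedit.intervals import PeakSet, total_bases
from rloopedit.spectra import classify_all
from rloopedit.tracks import SignalTrack

from _util import make_peakset


class TestProximity:
    def test_overlap_proximal_distal_labels(self):
        query = make_peakset(
            [("c", 1000, 2000), ("c", 1000, 2000), ("c", 1000, 2000)]
        )
        # references chosen so each query-level relationship is exercised
        ref_overlap = make_peakset([("c", 1500, 1600)])
        ref_proximal = make_peakset([("c", 2500, 2600)])
        ref_distal = make_peakset([("c", 3502, 3600)])
        assert classify_proximity(query, ref_overlap)[0].iloc[0] == "overlapping"
        labels, _ = classify_proximity(query, ref_proximal, d=1500)
        assert labels.iloc[0] == "proximal"  # gap 500
        labels, _ = classify_proximity(query, ref_distal, d=1500)
        assert labels.iloc[0] == "distal"  # gap 1502

    def test_gap_boundary_inclusive(self):
        query = make_peakset([("c", 0, 1000)])
        at_d = make_peakset([("c", 2500, 2600)])  # gap exactly 1500
        past_d = make_peakset([("c", 2501, 2600)])  # gap 1501
        assert classify_proximity(query, at_d, d=1500)[0].iloc[0] == "proximal"
        assert classify_proximity(query, past_d, d=1500)[0].iloc[0] == "distal"

    def test_empty_reference_warns_all_distal(self):
        query = make_peakset([("c", 0, 100)])
        empty = make_peakset([])
        with pytest.warns(UserWarning):
            labels, fractions = classify_proximity(query, empty)
        assert (labels == "distal").all()
        assert fractions["distal"] == 1.0

    def test_fractions_order_invariant(self, rng):
        rows = [("c", int(s), int(s) + 100) for s in rng.integers(0, 50_000, 30)]
        ref = make_peakset([("c", int(s), int(s) + 200) for s in rng.integers(0, 50_000, 10)])
        _, f1 = classify_proximity(make_peakset(rows), ref)
        rng.shuffle(rows)
        _, f2 = classify_proximity(make_peakset(rows), ref)
        pd.testing.assert_series_equal(f1, f2)


class TestConcordance:
    GENOME = {"c": "ATTCAT" * 500}  # TCA motifs every 6 bp (positions 3, 9, ...)

    def _classified(self, positions):
        muts = pd.DataFrame(
            [("c", p, "C", "T", "s") for p in positions],
            columns=["contig", "position", "ref", "alt", "sample"],
        )
        return classify_all(muts, self.GENOME)

    def test_full_concordance_when_planted(self):
        rloops = make_peakset([("c", 0, 60, "+")])
        res = strand_concordance(self._classified([3, 9, 15]), rloops)
        assert res.fraction == 1.0
        assert res.n_in_rloop == 3

    def test_hybrid_interpretation_flips(self):
        rloops = make_peakset([("c", 0, 60, "+")])
        res = strand_concordance(
            self._classified([3, 9]), rloops, rloop_strand_means="hybrid"
        )
        assert res.fraction == 0.0

    def test_ambiguous_double_overlap_excluded(self):
        rloops = make_peakset([("c", 0, 60, "+"), ("c", 0, 60, "-")])
        res = strand_concordance(self._classified([3]), rloops)
        assert res.n_excluded_ambiguous == 1
        assert res.n_in_rloop == 0

    def test_no_overlap_gives_empty_result(self):
        rloops = make_peakset([("c", 2000, 2100, "+")])
        res = strand_concordance(self._classified([3]), rloops)
        assert res.fraction is None and res.n_in_rloop == 0

    def test_planted_concordance_recovered_within_binomial_ci(
        self, artifacts, default_config
    ):
        classified = classify_all(artifacts["mutations"], artifacts["genome"])
        res = strand_concordance(classified, artifacts["rloops"])
        assert res.ci_low <= default_config.concordance <= res.ci_high
        # and equals the realised planted fraction exactly
        truth = artifacts["mutation_truth"]
        planted = truth[truth["kind"] == "rloop"]["concordant"].astype(bool)
        assert res.n_in_rloop == len(planted)
        assert res.fraction == pytest.approx(planted.mean())


class TestRandomSites:
    def test_uniform_within_bounds_and_deterministic(self):
        a = random_site_sample({"c": 1000}, n=10, seed=4)
        b = random_site_sample({"c": 1000}, n=10, seed=4)
        pd.testing.assert_frame_equal(a, b)
        assert a["position"].between(0, 999).all()

    def test_exclusion_respected(self):
        excl = make_peakset([("c", 0, 500)])
        sites = random_site_sample({"c": 1000}, n=200, seed=0, exclusion=excl)
        assert (sites["position"] >= 500).all()

    def test_full_exclusion_raises(self):
        excl = make_peakset([("c", 0, 1000)])
        with pytest.raises(ValueError):
            random_site_sample({"c": 1000}, n=1, seed=0, exclusion=excl)


class TestConsequenceEnrichment:
    def test_priority_rule_and_closed_form(self):
        coding = make_peakset([("c", 0, 100)])
        regulatory = make_peakset([("c", 50, 200)])
        catalogue = AnnotationCatalogue([("coding", coding), ("regulatory", regulatory)])
        sites = pd.DataFrame({"contig": ["c", "c", "c"], "position": [60, 150, 500]})
        labels = catalogue.assign(sites)
        # 60 is in coding AND regulatory: priority decides
        assert list(labels) == ["coding", "regulatory", "intergenic"]

    def test_planted_regulatory_enrichment(self):
        regulatory = make_peakset([("c", 0, 1000)])
        catalogue = AnnotationCatalogue([("regulatory", regulatory)])
        variants = pd.DataFrame({"contig": "c", "position": np.arange(10, 900, 30)})
        randoms = random_site_sample({"c": 10_000}, n=2000, seed=1)
        out = consequence_enrichment(variants, catalogue, randoms)
        reg = out[out["category"] == "regulatory"].iloc[0]
        assert reg["variant_fraction"] == 1.0
        assert reg["enrichment"] > 5
        # chi-square equals the closed form on the same table
        a, c = reg["n_variant"], reg["n_random"]
        table = [[a, len(variants) - a], [c, len(randoms) - c]]
        stat, _ = chi_square_2x2(table)
        assert reg["chi2"] == pytest.approx(stat, rel=1e-12)

    def test_uniform_variants_yield_null_enrichment(self):
        regulatory = make_peakset([("c", 0, 5000)])
        catalogue = AnnotationCatalogue([("regulatory", regulatory)])
        variants = random_site_sample({"c": 10_000}, n=3000, seed=2)
        randoms = random_site_sample({"c": 10_000}, n=3000, seed=3)
        out = consequence_enrichment(variants, catalogue, randoms)
        assert out["enrichment"].between(0.9, 1.1).all()
        assert (out["p_value"] > 0.01).all()


class TestStateEnrichment:
    def test_formula_oracle(self):
        # all targets inside a state covering 10% of the genome
        seg = make_peakset([("c", 0, 1000), ("c", 1000, 10_000)])
        seg.df.loc[seg.df["start"] == 0, "name"] = "active"
        seg.df.loc[seg.df["start"] == 1000, "name"] = "quiet"
        targets = make_peakset([("c", 100, 200), ("c", 300, 400)])
        out = state_enrichment(targets, seg, genome_bases=10_000)
        active = out[out["state"] == "active"].iloc[0]
        assert active["enrichment"] == pytest.approx(10.0)
        quiet = out[out["state"] == "quiet"].iloc[0]
        assert quiet["enrichment"] == pytest.approx(0.0)

    def test_tiling_targets_give_unit_enrichment(self):
        seg = make_peakset([("c", 0, 4000), ("c", 4000, 10_000)])
        seg.df.loc[0, "name"] = "a"
        seg.df.loc[1, "name"] = "b"
        targets = make_peakset([("c", 0, 10_000)])
        out = state_enrichment(targets, seg, genome_bases=10_000)
        assert np.allclose(out["enrichment"], 1.0)

    def test_flank_expansion_of_point_targets(self):
        seg = make_peakset([("c", 0, 500), ("c", 500, 1000)])
        seg.df.loc[0, "name"] = "a"
        seg.df.loc[1, "name"] = "b"
        # point at 499 expanded +-200 straddles both states
        targets = make_peakset([("c", 499, 500)])
        out = state_enrichment(
            targets, seg, genome_bases=1000, flank=200, contig_lengths={"c": 1000}
        )
        a = out[out["state"] == "a"].iloc[0]
        assert a["target_bases_in_state"] == 201  # 299..499 inclusive


class TestReplicationQuartiles:
    def _track(self, values, bin_width=100):
        t = SignalTrack(bin_width, {"c": bin_width * len(values)})
        t.values["c"] = np.asarray(values, dtype=float)
        return t

    def test_uniform_mutations_flat_rates(self, rng):
        track = self._track(rng.normal(size=400))
        muts = pd.DataFrame(
            {
                "contig": "c",
                "position": rng.integers(0, 40_000, size=4000),
            }
        )
        out = replication_quartile_rates(muts, track)
        assert np.allclose(out["relative_rate"], 1.0, atol=0.2)

    def test_constant_track_tie_rule_gives_flat_rates(self, rng):
        track = self._track(np.zeros(400))
        muts = pd.DataFrame(
            {"contig": "c", "position": rng.integers(0, 40_000, size=4000)}
        )
        out = replication_quartile_rates(muts, track)
        assert np.allclose(out["relative_rate"], 1.0, atol=0.25)
        assert np.allclose(out["covered_mb"], out["covered_mb"].iloc[0])

    def test_planted_bias_in_earliest_quartile(self):
        from rloopedit.synthetic import (
            SyntheticConfig,
            generate_genome,
            generate_timing_track,
            plant_mutations,
        )

        cfg = SyntheticConfig(
            seed=21, timing_mut_bias=2.0, n_background_mut=2000,
            n_rloop_mut=0, n_clusters=0,
        )
        genome, rloops = generate_genome(cfg)
        timing = generate_timing_track(cfg)
        muts, truth = plant_mutations(genome, rloops, cfg, timing=timing)
        out = replication_quartile_rates(muts, timing)
        ratio = out["rate_per_mb"].iloc[3] / out["rate_per_mb"].iloc[0]
        assert ratio == pytest.approx(2.0, rel=0.25)

    def test_uncovered_mutations_counted(self):
        track = self._track([1.0, np.nan, 2.0, 3.0])
        muts = pd.DataFrame({"contig": ["c", "c"], "position": [150, 250]})
        out = replication_quartile_rates(muts, track, n_quantiles=2)
        assert out.attrs["n_excluded"] == 1


class TestRegionToGene:
    TSS = pd.DataFrame(
        {
            "gene": ["g1"],
            "contig": ["c"],
            "position": [50_000],
            "strand": ["+"],
        }
    )

    def test_basal_and_near_upstream_region_associates(self):
        regions = make_peakset([("c", 42_000, 42_500)])  # 3 kb past basal edge
        regions.df.loc[0, "name"] = "r"
        out = region_to_gene(regions, self.TSS, contig_lengths={"c": 3_000_000})
        assert out["r"] == ["g1"]

    def test_region_beyond_one_megabase_not_associated(self):
        tss = self.TSS.copy()
        regions = make_peakset([("c", 2_200_000, 2_200_500)])
        regions.df.loc[0, "name"] = "r"
        out = region_to_gene(regions, tss, contig_lengths={"c": 3_000_000})
        assert out["r"] == []

    def test_domains_of_close_genes_abut_and_both_catch_midpoint(self):
        tss = pd.DataFrame(
            {
                "gene": ["a", "b"],
                "contig": ["c", "c"],
                "position": [100_000, 110_000],
                "strand": ["+", "+"],
            }
        )
        regions = make_peakset([("c", 103_000, 103_200)])
        regions.df.loc[0, "name"] = "r"
        out = region_to_gene(regions, tss, contig_lengths={"c": 1_000_000})
        assert out["r"] == ["a", "b"]

    def test_minus_strand_basal_is_mirrored(self):
        tss = pd.DataFrame(
            {"gene": ["g"], "contig": ["c"], "position": [50_000], "strand": ["-"]}
        )
        # 3 kb downstream in genome coordinates = upstream of a minus gene
        regions = make_peakset([("c", 53_000, 53_100)])
        regions.df.loc[0, "name"] = "r"
        out = region_to_gene(regions, tss, contig_lengths={"c": 3_000_000})
        assert out["r"] == ["g"]


class TestChiSquare:
    def test_closed_form_value(self):
        stat, p = chi_square_2x2([[10, 20], [30, 40]])
        assert stat == pytest.approx(100 * (10 * 40 - 20 * 30) ** 2 / (30 * 70 * 40 * 60), rel=1e-12)
        assert stat == pytest.approx(0.79365079, rel=1e-6)
        # independent check against scipy
        s2, p2, _, _ = sps.chi2_contingency([[10, 20], [30, 40]], correction=False)
        assert stat == pytest.approx(s2, rel=1e-9)
        assert p == pytest.approx(p2, rel=1e-9)

    def test_proportional_rows_give_zero(self):
        stat, p = chi_square_2x2([[10, 20], [20, 40]])
        assert stat == 0.0 and p == 1.0

    def test_transpose_invariance(self, rng):
        for _ in range(20):
            t = rng.integers(1, 100, size=(2, 2))
            s1, _ = chi_square_2x2(t)
            s2, _ = chi_square_2x2(t.T)
            assert s1 == pytest.approx(s2, rel=1e-12)

    def test_zero_margin_raises(self):
        with pytest.raises(ValueError, match="exact"):
            chi_square_2x2([[0, 0], [5, 10]])
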