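"""GC-skew, G4Hunter and metaprofile behaviour against direct-count oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from rloopedit.genome import reverse_complement
from rloopedit.seqfeatures import (
    g4hunter_base_scores,
    g4hunter_scan,
    g4hunter_score,
    gc_skew_track,
    profile_around,
)
from rloopedit.tracks import SignalTrack

from _util import brute_force_g4_scan, make_peakset, random_genome


class TestGcSkew:
    @pytest.mark.parametrize(
        "window_seq,expected",
        [("GGGG", 1.0), ("GCGC", 0.0), ("GGCTA", (2 - 1) / 3)],
    )
    def test_direct_count_oracle(self, window_seq, expected):
        plus, _ = gc_skew_track({"c": window_seq}, window=len(window_seq))
        assert plus.values["c"][0] == pytest.approx(expected)

    def test_no_strong_bases_is_missing(self):
        plus, _ = gc_skew_track({"c": "ATATAT"}, window=6)
        assert np.isnan(plus.values["c"][0])

    def test_minus_track_is_negation(self):
        genome = {"c": random_genome(np.random.default_rng(0), 2000)}
        plus, minus = gc_skew_track(genome, window=200)
        np.testing.assert_allclose(plus.values["c"], -minus.values["c"])

    @given(st.text(alphabet="ACGT", min_size=10, max_size=80))
    def test_negation_under_reverse_complement(self, seq):
        plus, _ = gc_skew_track({"c": seq}, window=len(seq))
        rc_plus, _ = gc_skew_track({"c": reverse_complement(seq)}, window=len(seq))
        a, b = plus.values["c"][0], rc_plus.values["c"][0]
        if np.isnan(a):
            assert np.isnan(b)
        else:
            assert a == pytest.approx(-b)
            assert -1.0 <= a <= 1.0


class TestG4Hunter:
    def test_telomeric_repeat_hand_computed(self):
        # four G3 runs of 3 bases scoring 3 each: 36 over 21 bases
        assert g4hunter_score("GGGTTAGGGTTAGGGTTAGGG") == pytest.approx(36 / 21)

    def test_at_only_scores_zero(self):
        assert g4hunter_score("ATATAT") == 0.0

    def test_run_capping_at_four(self):
        # six consecutive G score 4 each
        assert g4hunter_score("GGGGGG") == pytest.approx(4.0)
        assert -4.0 <= g4hunter_score("CCCCCCCC") <= 4.0

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            g4hunter_score("")

    @given(st.text(alphabet="ACGTN", min_size=1, max_size=60))
    def test_antisymmetry_under_reverse_complement(self, seq):
        assert g4hunter_score(seq) == pytest.approx(
            -g4hunter_score(reverse_complement(seq))
        )


class TestG4Scan:
    def test_at_repeat_genome_has_no_hits(self):
        intervals, density = g4hunter_scan({"c": "AT" * 200}, window=25, threshold=1.2)
        assert len(intervals) == 0
        assert density.values["c"].sum() == 0

    def test_planted_motif_gives_one_plus_interval(self, rng):
        motif = "GGGTGGGTGGGTGGGT"
        for _ in range(5):
            # AT background cannot reach the threshold on its own
            background = "".join(rng.choice(list("AT"), size=400))
            seq = background[:200] + motif + background[200:]
            intervals, _ = g4hunter_scan({"c": seq}, window=25, threshold=1.2)
            assert len(intervals) == 1
            row = intervals.df.iloc[0]
            assert row.strand == "+"
            assert row.start <= 200 and row.end >= 200 + len(motif)

    def test_c_rich_motif_is_minus_strand(self):
        seq = "AT" * 100 + "CCCACCCACCCACCC" + "TA" * 100
        intervals, _ = g4hunter_scan({"c": seq}, window=25, threshold=1.2)
        assert (intervals.df["strand"] == "-").all()

    def test_threshold_zero_covers_everything(self):
        genome = {"c": random_genome(np.random.default_rng(1), 500)}
        intervals, _ = g4hunter_scan(genome, window=25, threshold=0.0)
        covered = np.zeros(500, dtype=bool)
        for row in intervals.df.itertuples(index=False):
            covered[row.start : row.end] = True
        assert covered.all()

    def test_matches_exhaustive_window_oracle(self, rng):
        for _ in range(10):
            seq = random_genome(rng, 800, gc=0.5)
            intervals, _ = g4hunter_scan({"c": seq}, window=25, threshold=1.0)
            expected = brute_force_g4_scan(
                seq, g4hunter_base_scores(seq), window=25, threshold=1.0
            )
            got = [
                (row.start, row.end, 1.0 if row.strand == "+" else -1.0)
                for row in intervals.df.itertuples(index=False)
            ]
            assert got == expected

    def test_density_counts_overlapping_intervals(self):
        seq = "AT" * 60 + "GGGGGGGGGGGGGGGGGGGGGGGGG" + "AT" * 60
        intervals, density = g4hunter_scan(
            {"c": seq}, window=25, threshold=1.2, density_bin=100
        )
        assert len(intervals) == 1
        row = intervals.df.iloc[0]
        touched = set(range(row.start // 100, (row.end - 1) // 100 + 1))
        for b, v in enumerate(density.values["c"]):
            assert v == (1 if b in touched else 0)


class TestProfile:
    def _constant_track(self, value=2.5, length=10_000, bin_width=100):
        t = SignalTrack(bin_width, {"c": length})
        t.values["c"] = np.full(t.n_bins("c"), value)
        return t

    def test_constant_track_gives_flat_profile(self):
        track = self._constant_track()
        anchors = make_peakset([("c", 4000, 4200), ("c", 6000, 6500)])
        prof = profile_around(anchors, track, flank=1000)
        assert (prof["mean"] == 2.5).all()
        assert (prof["ci95"] == 0.0).all()
        assert list(prof["rel_pos"]) == list(-prof["rel_pos"][::-1])

    def test_single_anchor_equals_track_slice(self):
        track = self._constant_track()
        track.values["c"][:] = np.arange(track.n_bins("c"), dtype=float)
        anchors = make_peakset([("c", 5000, 5001)])
        prof = profile_around(anchors, track, flank=500)
        mid_bin = 5000 // 100
        expected = track.values["c"][mid_bin - 5 : mid_bin + 5]
        np.testing.assert_allclose(prof["mean"], expected)
        assert (prof["ci95"] == 0.0).all()

    def test_minus_strand_anchor_reversed_and_flipped(self):
        track = self._constant_track()
        track.values["c"][:] = np.arange(track.n_bins("c"), dtype=float)
        plus = make_peakset([("c", 5000, 5001, "+")])
        minus = make_peakset([("c", 5000, 5001, "-")])
        p_plus = profile_around(plus, track, flank=500, strand_aware=True,
                                antisymmetric=True)
        p_minus = profile_around(minus, track, flank=500, strand_aware=True,
                                 antisymmetric=True)
        np.testing.assert_allclose(
            p_plus["mean"].to_numpy(), -p_minus["mean"].to_numpy()[::-1]
        )

    def test_contig_edges_contribute_only_defined_positions(self):
        track = self._constant_track(length=1000)
        anchors = make_peakset([("c", 100, 101)])
        prof = profile_around(anchors, track, flank=500)
        assert prof["n"].iloc[0] == 0  # hangs off the left end
        assert prof["n"].iloc[-1] == 1

    def test_flank_must_align_to_bins(self):
        track = self._constant_track()
        anchors = make_peakset([("c", 5000, 5001)])
        with pytest.raises(ValueError):
            profile_around(anchors, track, flank=550)

    def test_shuffled_anchors_recover_global_mean(self, rng):
        track = SignalTrack(100, {"c": 100_000})
        track.values["c"] = rng.normal(0.7, 1.0, size=track.n_bins("c"))
        anchors = make_peakset(
            [("c", int(p), int(p) + 1) for p in rng.integers(2000, 98_000, size=300)]
        )
        prof = profile_around(anchors, track, flank=1000)
        global_mean = track.global_mean()
        within = (
            np.abs(prof["mean"] - global_mean) <= prof["ci95"] + 1e-12
        )
        assert within.mean() > 0.85

    def test_planted_skew_plateau_recovered(self, artifacts, default_config):
        genome = artifacts["genome"]
        rloops = artifacts["rloops"]
        plus, _ = gc_skew_track(genome, window=200)
        prof = profile_around(
            rloops, plus, flank=2000, strand_aware=True, antisymmetric=True
        )
        central = prof[np.abs(prof["rel_pos"]) <= 100]
        expected = (default_config.skew_strength - (1 - default_config.skew_strength))
        for _, row in central.iterrows():
            assert abs(row["mean"] - expected) <= max(row["ci95"], 0.02)
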