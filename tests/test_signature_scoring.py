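import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from attenscan import (CandidateCriteria, GeneModel, SignalTrack,
                       SimulationConfig, SiteTrack, build_heatmap, categorize,
                       normalized_enrichment, peak_height, pol2_travel_ratio,
                       promoter_window, reference_normalize,
                       select_candidates, simulate_genome)
from attenscan.signature_scoring import ScoringError
from attenscan.track_io import GenomicWindow

from _oracles import mirror_genome, naive_candidates, naive_heatmap


class TestPromoterWindow:
    def test_plus_strand_arithmetic(self):
        g = GeneModel("g", "chrI", "+", 1000, 2000)
        win = promoter_window(g, 100, 300)
        assert (win.start, win.end, win.strand) == (900, 1300, "+")

    def test_minus_strand_mirrored(self):
        g = GeneModel("g", "chrI", "-", 200, 1001)  # atg at 1000
        win = promoter_window(g, 100, 300)
        assert (win.start, win.end, win.strand) == (700, 1100, "-")

    def test_clipped_at_chromosome_start(self):
        g = GeneModel("g", "chrI", "+", 50, 500)
        assert promoter_window(g, 100, 300).start == 0

    def test_tss_anchor_preferred(self):
        g = GeneModel("g", "chrI", "+", 1000, 2000, tss_pos=940)
        assert promoter_window(g, 100, 300).start == 840

    def test_degenerate_extents_rejected(self):
        g = GeneModel("g", "chrI", "+", 1000, 2000)
        with pytest.raises(ScoringError):
            promoter_window(g, 0, 0)


class TestPeakAndRatios:
    def test_signal_peak_is_max(self):
        trk = SignalTrack.from_intervals(
            [("chrI", 0, 3, 1.0), ("chrI", 3, 5, 9.0), ("chrI", 5, 9, 4.0)])
        assert peak_height(trk, GenomicWindow("chrI", 0, 9)) == 9.0
        assert peak_height(trk, GenomicWindow("chrI", 0, 9), stat="sum") == \
            pytest.approx(1 * 3 + 9 * 2 + 4 * 4)

    def test_site_peak_max_matching_strand(self):
        st = SiteTrack.from_sites(
            [("chrI", 5, "+", 12), ("chrI", 7, "+", 30), ("chrI", 6, "-", 99)])
        assert peak_height(st, GenomicWindow("chrI", 0, 10, "+")) == 30.0
        assert peak_height(st, GenomicWindow("chrI", 0, 4, "+")) == 0.0

    def test_normalized_enrichment(self):
        assert normalized_enrichment(30, 10) == 3.0
        assert normalized_enrichment(10, 10) == 1.0

    def test_zero_polII_guarded_by_epsilon(self, caplog):
        with caplog.at_level("WARNING", logger="attenscan"):
            assert normalized_enrichment(5.0, 0.0, epsilon=1.0) == 5.0
        assert "epsilon" in caplog.text

    def test_reference_normalize(self):
        R = reference_normalize({"a": 3.0, "ref": 2.0}, "ref")
        assert R == {"a": 1.5, "ref": 1.0}

    @pytest.mark.parametrize("records", [{"a": 1.0}, {"a": 1.0, "ref": 0.0}])
    def test_reference_missing_or_zero_is_hard_error(self, records):
        with pytest.raises(ScoringError):
            reference_normalize(records, "ref", factor="Hrp1")


class TestCategorize:
    @pytest.mark.parametrize("R,expected", [
        (0.5, "low"), (1.0, "intermediate"), (1.6, "high"),
        (0.67, "low"), (1.5, "intermediate"),  # boundary convention
        (0.0, "low"), (0.671, "intermediate"), (1.501, "high"),
    ])
    def test_bins(self, R, expected):
        assert categorize(R) == expected

    def test_negative_rejected(self):
        with pytest.raises(ScoringError):
            categorize(-0.1)

    @settings(derandomize=True, max_examples=100)
    @given(st.floats(min_value=0, max_value=10, allow_nan=False))
    def test_matches_piecewise_definition(self, R):
        expected = "low" if R <= 0.67 else ("intermediate" if R <= 1.5 else "high")
        assert categorize(R) == expected


class TestHeatmapAndCandidates:
    def test_reference_row_is_all_ones_intermediate(self, small_sim):
        table = build_heatmap(small_sim.genes, small_sim.tracks,
                              {"pA": small_sim.sites["pA"]},
                              reference_gene_id="NRD1LIKE")
        R = table.pivot("R")
        assert np.allclose(R.loc["NRD1LIKE"], 1.0)
        cats = table.pivot("category").loc["NRD1LIKE"]
        assert set(cats) == {"intermediate"}

    def test_single_reference_gene_table_of_ones(self, small_sim):
        ref = [g for g in small_sim.genes if g.gene_id == "NRD1LIKE"]
        table = build_heatmap(ref, small_sim.tracks,
                              {"pA": small_sim.sites["pA"]},
                              reference_gene_id="NRD1LIKE")
        assert np.allclose(table.pivot("R").values, 1.0)

    def test_cells_match_per_base_oracle(self, noisy_sim):
        table = build_heatmap(noisy_sim.genes, noisy_sim.tracks,
                              {"pA": noisy_sim.sites["pA"]},
                              reference_gene_id="NRD1LIKE")
        oracle = naive_heatmap(noisy_sim.genes, noisy_sim.tracks,
                               noisy_sim.sites["pA"], "NRD1LIKE")
        for gid in table.gene_order:
            for factor in table.factors:
                cell = table.cell(gid, factor)
                r, R, cat = oracle[gid][factor]
                assert cell.r == pytest.approx(r, rel=1e-12)
                assert cell.R == pytest.approx(R, rel=1e-12)
                assert cell.category == cat

    def test_candidate_selection_rule(self, small_sim):
        table = build_heatmap(small_sim.genes, small_sim.tracks,
                              {"pA": small_sim.sites["pA"]},
                              reference_gene_id="NRD1LIKE")
        cands = select_candidates(table)
        oracle = naive_heatmap(small_sim.genes, small_sim.tracks,
                               small_sim.sites["pA"], "NRD1LIKE")
        assert cands == naive_candidates(oracle)
        assert set(cands) == set(small_sim.truth.genes_of_class("hybrid_attenuated"))

    def test_depletion_requirement_rejects(self):
        # Hrp1/pA enriched but Nrd1 not depleted -> rejected
        import pandas as pd
        from attenscan.signature_scoring import HeatmapTable
        rows = []
        values = {"pA": 2.0, "Hrp1": 2.0, "Nrd1": 1.0, "Nab3": 0.3}
        for gid, scale in [("ref", None), ("g", None)]:
            for f, R in values.items():
                Rv = 1.0 if gid == "ref" else R
                rows.append(dict(gene_id=gid, factor=f, raw_peak=1, polII_peak=1,
                                 r=Rv, R=Rv, category="intermediate"))
        table = HeatmapTable(records=pd.DataFrame(rows), reference_gene_id="ref",
                             factors=("pA", "Hrp1", "Nrd1", "Nab3"),
                             gene_order=("ref", "g"))
        assert select_candidates(table) == []
        relaxed = CandidateCriteria(deplete_mode="any")
        assert select_candidates(table, relaxed) == ["g"]

    def test_missing_criterion_factor_is_error(self, small_sim):
        table = build_heatmap(small_sim.genes, small_sim.tracks,
                              {"pA": small_sim.sites["pA"]},
                              reference_gene_id="NRD1LIKE")
        with pytest.raises(ScoringError, match="absent"):
            select_candidates(table, CandidateCriteria(enrich_factors=("Sen1",),
                                                       deplete_factors=()))

    def test_threshold_monotonicity(self, noisy_sim):
        table = build_heatmap(noisy_sim.genes, noisy_sim.tracks,
                              {"pA": noisy_sim.sites["pA"]},
                              reference_gene_id="NRD1LIKE")
        base = set(select_candidates(table))
        for enrich_thr, deplete_thr in [(2.0, 0.67), (1.5, 0.4), (3.0, 0.2)]:
            stricter = set(select_candidates(table, CandidateCriteria(
                enrich_threshold=enrich_thr, deplete_threshold=deplete_thr)))
            assert stricter <= base

    @pytest.mark.parametrize("constant", [0.25, 7.0])
    def test_global_scale_invariance(self, small_sim, constant):
        scaled_tracks = {
            name: SignalTrack.from_intervals(
                [(c, s, e, v * constant) for c, s, e, v in trk.iter_runs()])
            for name, trk in small_sim.tracks.items()}
        scaled_sites = {"pA": SiteTrack.from_sites(
            [(c, p, s, cnt * constant)
             for c, p, s, cnt in small_sim.sites["pA"].iter_sites()])}
        base = build_heatmap(small_sim.genes, small_sim.tracks,
                             {"pA": small_sim.sites["pA"]},
                             reference_gene_id="NRD1LIKE")
        scaled = build_heatmap(small_sim.genes, scaled_tracks, scaled_sites,
                               reference_gene_id="NRD1LIKE")
        assert np.allclose(base.pivot("R").values, scaled.pivot("R").values)
        assert select_candidates(base) == select_candidates(scaled)

    def test_single_factor_rescale_changes_r_not_R(self, small_sim):
        c = 3.0
        tracks = dict(small_sim.tracks)
        tracks["Hrp1"] = SignalTrack.from_intervals(
            [(ch, s, e, v * c) for ch, s, e, v in tracks["Hrp1"].iter_runs()])
        base = build_heatmap(small_sim.genes, small_sim.tracks,
                             {"pA": small_sim.sites["pA"]},
                             reference_gene_id="NRD1LIKE")
        scaled = build_heatmap(small_sim.genes, tracks,
                               {"pA": small_sim.sites["pA"]},
                               reference_gene_id="NRD1LIKE")
        assert np.allclose(scaled.pivot("r")["Hrp1"],
                           c * base.pivot("r")["Hrp1"])
        assert np.allclose(scaled.pivot("R").values, base.pivot("R").values)

    def test_strand_symmetry_under_genome_mirror(self, small_sim):
        mirrored = mirror_genome(small_sim, mirror_point=1_000_000)
        base = build_heatmap(small_sim.genes, small_sim.tracks,
                             {"pA": small_sim.sites["pA"]},
                             reference_gene_id="NRD1LIKE")
        flipped = build_heatmap(mirrored.genes, mirrored.tracks,
                                {"pA": mirrored.sites["pA"]},
                                reference_gene_id="NRD1LIKE")
        assert np.allclose(base.pivot("R").values, flipped.pivot("R").values)

    def test_missing_polII_track_is_error(self, small_sim):
        tracks = {k: v for k, v in small_sim.tracks.items() if k != "PolII"}
        with pytest.raises(ScoringError, match="PolII"):
            build_heatmap(small_sim.genes, tracks, {"pA": small_sim.sites["pA"]},
                          reference_gene_id="NRD1LIKE")


class TestTravelRatio:
    def test_uniform_track_gives_one(self):
        g = GeneModel("g", "chrI", "+", 1000, 2500, tss_pos=950)
        trk = SignalTrack.from_intervals([("chrI", 0, 4000, 6.0)])
        assert pol2_travel_ratio(trk, g) == pytest.approx(1.0)

    def test_planted_fold_recovered_exactly(self, small_sim):
        from _oracles import naive_signal_mean, track_to_basemap
        basemap = track_to_basemap(small_sim.tracks["PolII"])
        for g in small_sim.genes:
            if small_sim.truth.labels[g.gene_id] == "non_attenuated":
                continue
            ratio = pol2_travel_ratio(small_sim.tracks["PolII"], g)
            assert ratio == pytest.approx(4.0, rel=1e-12)
            win = promoter_window(g)
            if g.strand == "+":
                body = (win.end, g.orf_end)
            else:
                body = (g.orf_start, win.start)
            expected = (naive_signal_mean(basemap, g.chrom, win.start, win.end)
                        / naive_signal_mean(basemap, g.chrom, *body))
            assert ratio == pytest.approx(expected, rel=1e-12)

    def test_five_to_body_ratio(self):
        g = GeneModel("g", "chrI", "+", 1000, 2500)
        trk = SignalTrack.from_intervals(
            [("chrI", 900, 1300, 10.0), ("chrI", 1300, 2500, 2.0)])
        assert pol2_travel_ratio(trk, g) == pytest.approx(5.0)
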