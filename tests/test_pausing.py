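"""Gene windows, pausing/retention indices, filters, metagenes."""

import math

import numpy as np
import pandas as pd
import pytest

from prophasetx.pausing import (
    filter_eligible,
    gene_windows,
    pausing_index_table,
    peak_centered_metaplot,
    scaled_metagene,
    summarize_gene,
    summarize_genes,
)
from prophasetx.tracks import GenomicInterval, SignalTrack

CHROM = 100_000


def _gene(start, end, strand, name="g"):
    return GenomicInterval("chr1", start, end, strand, name)


class TestWindows:
    def test_plus_strand_windows(self):
        w = gene_windows(_gene(1000, 3000, "+"), CHROM)
        assert (w.pause.start, w.pause.end) == (1000, 1250)
        assert (w.body.start, w.body.end) == (1250, 3000)
        assert (w.postpas.start, w.postpas.end) == (3000, 8000)
        assert not w.clipped

    def test_minus_strand_windows_mirror_plus(self):
        w = gene_windows(_gene(1000, 3000, "-"), CHROM)
        assert (w.pause.start, w.pause.end) == (2750, 3000)
        assert (w.body.start, w.body.end) == (1000, 2750)
        assert (w.postpas.start, w.postpas.end) == (0, 1000)  # clipped at 0
        assert w.clipped
        # mirror check: reflecting a plus-strand gene through the genome
        # midpoint maps its windows onto the minus-strand gene's windows
        size = 4000
        wp = gene_windows(GenomicInterval("c", 1000, 3000, "+"), size)
        wm = gene_windows(GenomicInterval("c", 1000, 3000, "-"), size)
        assert (size - wp.pause.end, size - wp.pause.start) == (
            wm.pause.start, wm.pause.end,
        )
        assert (size - wp.body.end, size - wp.body.start) == (
            wm.body.start, wm.body.end,
        )

    def test_short_gene_is_ineligible(self):
        with pytest.raises(ValueError, match="shorter than pause window"):
            gene_windows(_gene(0, 200, "+"), CHROM)


class TestEligibility:
    def _df(self, rows):
        return pd.DataFrame(
            rows, columns=["chrom", "start", "end", "name", "score", "strand"]
        )

    def test_isolated_long_gene_kept(self):
        genes = self._df([("chr1", 1000, 3000, "a", 0, "+")])
        assert len(filter_eligible(genes)) == 1

    def test_short_gene_dropped(self):
        genes = self._df([("chr1", 1000, 1400, "a", 0, "+")])
        assert filter_eligible(genes).empty

    def test_crowded_three_prime_end_dropped(self):
        # neighbor TSS 3000 bp past the first gene's 3' end: both checked
        genes = self._df(
            [
                ("chr1", 1000, 3000, "a", 0, "+"),
                ("chr1", 6000, 9000, "b", 0, "+"),
            ]
        )
        kept = filter_eligible(genes)["name"].tolist()
        assert "a" not in kept
        # gene b's 3' end (9000) is 8000 bp from a's TSS (1000): kept
        assert "b" in kept

    def test_boundary_is_inclusive_at_5000(self):
        genes = self._df(
            [
                ("chr1", 1000, 3000, "a", 0, "+"),
                ("chr1", 8000, 11000, "b", 0, "+"),
            ]
        )
        assert "a" in filter_eligible(genes)["name"].tolist()


class TestSummaries:
    def test_hand_computed_indices(self, hand_gene_track):
        d = hand_gene_track
        gene = _gene(0, 2250, "+", "g1")
        summ = summarize_gene(d["tracks"], gene, d["sizes"]["chr1"])
        assert summ.pause_count == 10.0 and summ.body_count == 40.0
        assert summ.pausing_index == pytest.approx(2.0)  # 0.04 / 0.02
        assert summ.retention_index == pytest.approx(4.0)  # 0.02 / 0.005

    def test_zero_body_signal_gives_missing_pi(self):
        sizes = {"chr1": CHROM}
        track = SignalTrack(sizes, "+")
        track.set_intervals("chr1", [0], [100], [5.0])  # pause-only signal
        tracks = {"+": track, "-": SignalTrack(sizes, "-")}
        summ = summarize_gene(tracks, _gene(0, 2000, "+"), CHROM)
        assert math.isnan(summ.pausing_index)
        assert math.isnan(summ.retention_index)

    def test_too_short_gene_has_no_summary(self, hand_gene_track):
        d = hand_gene_track
        assert summarize_gene(d["tracks"], _gene(0, 200, "+"), CHROM) is None

    def test_scale_invariance_is_exact(self, dataset):
        """PI/RI are bit-identical under any positive track rescaling."""
        genes, sizes = dataset["genes"], dataset["sizes"]
        base = summarize_genes(dataset["tracks"]["LZ"], genes, sizes)
        for factor in (2.7e-6, 1 / 3, math.pi, 1e9):
            scaled_tracks = {
                s: t.rescaled(factor) for s, t in dataset["tracks"]["LZ"].items()
            }
            scaled = summarize_genes(scaled_tracks, genes, sizes)
            assert scaled["pausing_index"].equals(base["pausing_index"])
            assert scaled["retention_index"].equals(base["retention_index"])

    def test_strand_symmetry(self):
        """Reflecting the genome and swapping strands preserves summaries."""
        size = 20_000
        rng = np.random.default_rng(11)
        dense = rng.poisson(0.1, size).astype(float)
        fwd = {
            "+": SignalTrack.from_dense({"c": dense}, {"c": size}, "+"),
            "-": SignalTrack({"c": size}, "-"),
        }
        rev = {
            "-": SignalTrack.from_dense({"c": dense[::-1].copy()}, {"c": size}, "-"),
            "+": SignalTrack({"c": size}, "+"),
        }
        gene_fwd = GenomicInterval("c", 4000, 9000, "+", "g")
        gene_rev = GenomicInterval("c", size - 9000, size - 4000, "-", "g")
        a = summarize_gene(fwd, gene_fwd, size)
        b = summarize_gene(rev, gene_rev, size)
        assert a.pause_count == b.pause_count
        assert a.body_count == b.body_count
        assert a.pausing_index == b.pausing_index
        assert a.retention_index == b.retention_index

    def test_planted_stage_ordering_recovered(self, pi_table):
        """Planted pausing relaxes across stages: median PI LZ > P > D."""
        med = pi_table.groupby("stage")["pausing_index"].median()
        assert med["LZ"] > med["P"] > med["D"]
        # matched-pairs direction: per-gene LZ - P differences mostly positive
        wide = pi_table.pivot(index="gene_id", columns="stage",
                              values="pausing_index").dropna()
        assert (wide["LZ"] > wide["P"]).mean() > 0.8

    def test_identical_tracks_give_zero_paired_differences(self, dataset):
        tracks = {"A": dataset["tracks"]["LZ"], "B": dataset["tracks"]["LZ"]}
        tbl = pausing_index_table(tracks, dataset["genes"], dataset["sizes"])
        wide = tbl.pivot(index="gene_id", columns="stage",
                         values="pausing_index").dropna()
        assert (wide["A"] == wide["B"]).all()

    def test_planted_pause_body_ratio_recovered(self, dataset):
        """Median PI within 10% of the planted rate ratio at high counts."""
        cfg = dataset["cfg"]
        med = (
            pausing_index_table(dataset["tracks"], dataset["genes"],
                                dataset["sizes"])
            .groupby("stage")["pausing_index"].median()
        )
        for stage, rates in cfg.stage_params.items():
            planted = rates.pause_rate / rates.body_rate
            assert med[stage] == pytest.approx(planted, rel=0.10)


class TestMetagene:
    def _uniform_setup(self, value=1.5):
        sizes = {"c": 60_000}
        dense = np.full(60_000, value)
        tracks = {
            "+": SignalTrack.from_dense({"c": dense}, sizes, "+"),
            "-": SignalTrack.from_dense({"c": dense}, sizes, "-"),
        }
        genes = pd.DataFrame(
            [
                ("c", 5000, 9000, "g1", 0, "+"),
                ("c", 20000, 26000, "g2", 0, "-"),
                ("c", 40000, 44000, "g3", 0, "+"),
            ],
            columns=["chrom", "start", "end", "name", "score", "strand"],
        )
        return tracks, genes, sizes

    def test_constant_track_gives_flat_profile(self):
        tracks, genes, sizes = self._uniform_setup(1.5)
        prof = scaled_metagene(tracks, genes, sizes, n_sub=50, seed=4)
        np.testing.assert_allclose(prof["median"], 1.5)

    def test_profile_invariant_to_gene_order(self):
        tracks, genes, sizes = self._uniform_setup()
        a = scaled_metagene(tracks, genes, sizes, n_sub=20, seed=9)
        b = scaled_metagene(tracks, genes.iloc[::-1], sizes, n_sub=20, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_planted_pause_enrichment_in_profile(self):
        """A 3x pause-over-body rate ratio shows at the profile 5' peak."""
        from prophasetx.sim import SimConfig, StageRates, generate_annotation, \
            simulate_stage_tracks

        ratios = []
        for seed in range(20):
            cfg = SimConfig(
                seed=seed, n_chroms=1, chrom_length=120_000, n_genes=8,
                gene_length_range=(4000, 4000),
                stage_params={"LZ": StageRates(0.9, 0.3, 0.0)},
                activity={"LZ": 1.0},
            )
            genes, sizes = generate_annotation(cfg)
            tracks = simulate_stage_tracks(cfg, genes, sizes)
            prof = scaled_metagene(tracks["LZ"], genes, sizes, n_sub=40,
                                   body_bins=16, seed=seed)
            body = prof[prof.region == "body"]["median"].to_numpy()
            # 250/4000 bp of pause occupy the first body bin at 16 bins
            ratios.append(body[0] / np.median(body[4:]))
        assert np.mean(ratios) == pytest.approx(3.0, rel=0.12)

    def test_too_few_genes_errors(self):
        tracks, genes, sizes = self._uniform_setup()
        with pytest.raises(ValueError, match=">= 2"):
            scaled_metagene(tracks, genes.iloc[:1], sizes)

    def test_oversized_subsample_reduced_with_warning(self):
        tracks, genes, sizes = self._uniform_setup()
        with pytest.warns(UserWarning, match="reduced"):
            scaled_metagene(tracks, genes, sizes, n_sub=5, subsample_frac=5.0)


class TestPeakMetaplot:
    def test_delta_signal_gives_single_bin_spike(self):
        sizes = {"c": 50_000}
        dense = np.zeros(50_000)
        dense[25_000] = 100.0
        track = SignalTrack.from_dense({"c": dense}, sizes)
        peaks = pd.DataFrame({"chrom": ["c"], "start": [24_990], "end": [25_010]})
        prof, mat = peak_centered_metaplot(track, peaks, sizes, flank=1000, bins=20)
        assert np.count_nonzero(mat) == 1
        assert mat[0, 10] == 1.0  # 100 reads / 100-bp center bin

    def test_uniform_track_gives_flat_profile(self):
        sizes = {"c": 50_000}
        track = SignalTrack.from_dense({"c": np.full(50_000, 0.7)}, sizes)
        peaks = pd.DataFrame(
            {"chrom": ["c", "c"], "start": [12_000, 30_000], "end": [12_400, 30_400]}
        )
        prof, _ = peak_centered_metaplot(track, peaks, sizes, flank=2000, bins=40)
        np.testing.assert_allclose(prof["mean"], 0.7)

    def test_symmetric_signal_gives_symmetric_profile(self):
        sizes = {"c": 50_000}
        dense = np.zeros(50_000)
        dense[24_000:26_000] = 2.0
        track = SignalTrack.from_dense({"c": dense}, sizes)
        peaks = pd.DataFrame({"chrom": ["c"], "start": [24_995], "end": [25_005]})
        prof, _ = peak_centered_metaplot(track, peaks, sizes, flank=4000, bins=40)
        np.testing.assert_allclose(
            prof["mean"].to_numpy(), prof["mean"].to_numpy()[::-1]
        )

    def test_sorting_matrix_rows(self):
        sizes = {"c": 50_000}
        dense = np.zeros(50_000)
        dense[10_000:10_100] = 1.0
        dense[30_000:30_100] = 5.0
        track = SignalTrack.from_dense({"c": dense}, sizes)
        peaks = pd.DataFrame(
            {"chrom": ["c", "c"], "start": [9_950, 29_950], "end": [10_150, 30_150]}
        )
        _, mat = peak_centered_metaplot(
            track, peaks, sizes, flank=1000, bins=10,
            sort_by=np.array([1.0, 5.0]),
        )
        assert mat[0].sum() > mat[1].sum()
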