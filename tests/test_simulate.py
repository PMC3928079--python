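"""Generator behaviour: determinism, spacing law, fragment spread, labels."""
import math

import numpy as np
import pandas as pd
import pytest

from capra.core import GenomicInterval
from capra.simulate import (
    SimulationConfig,
    assign_cap_labels,
    simulate_annotation,
    simulate_expression_counts,
    simulate_gene_study,
    simulate_nucleosome_array,
    simulate_ptm_tracks,
    simulate_reads,
)


class TestAnnotation:
    def test_empty_when_no_genes(self):
        cfg = SimulationConfig(seed=0, n_genes=0)
        genes, expr, dhs = simulate_annotation(cfg)
        assert genes == [] and len(expr) == 0 and dhs == []

    def test_deterministic_given_seed(self):
        cfg = SimulationConfig(seed=5, n_genes=30, genome=(("c", 200_000),))
        g1, e1, d1 = simulate_annotation(cfg)
        g2, e2, d2 = simulate_annotation(cfg)
        assert g1 == g2 and d1 == d2
        pd.testing.assert_frame_equal(e1, e2)

    def test_dhs_count_is_top_tertile(self):
        cfg = SimulationConfig(seed=3, n_genes=50, genome=(("c", 400_000),))
        genes, _, dhs = simulate_annotation(cfg)
        assert len(dhs) == math.ceil(len(genes) / 3)
        tss = {g.tss: g for g in genes}
        for iv in dhs:
            assert iv.width == 200
            assert (iv.start + iv.end) // 2 in tss

    def test_genes_do_not_overlap(self):
        cfg = SimulationConfig(seed=4, n_genes=40, genome=(("c", 300_000),))
        genes, _, _ = simulate_annotation(cfg)
        prev_end = -1
        strands = []
        for g in sorted(genes, key=lambda g: g.start):
            assert g.start > prev_end
            prev_end = g.end
            strands.append(g.strand)
        assert set(strands) == {"+", "-"}

    def test_genome_too_small(self):
        cfg = SimulationConfig(seed=0, n_genes=100, genome=(("c", 10_000),))
        with pytest.raises(ValueError, match="too small"):
            simulate_annotation(cfg)


class TestNucleosomeArray:
    def test_zero_jitter_gives_exact_spacing(self):
        region = GenomicInterval("c", 0, 1000)
        mids = simulate_nucleosome_array(region, 180, 0, rng=1)
        assert np.all(np.diff(mids) == 180)
        assert mids[0] < 180

    def test_spacing_mean_recovers_nrl(self):
        region = GenomicInterval("c", 0, 2_000_000)
        mids = simulate_nucleosome_array(region, 180, 5, rng=2)
        spacings = np.diff(mids)
        assert spacings.size > 10_000
        assert abs(spacings.mean() - 180) < 0.2
        assert spacings.min() >= 148

    def test_short_region_boundary(self):
        mids = simulate_nucleosome_array(GenomicInterval("c", 0, 150), 180, 5, rng=3)
        assert mids.size <= 1

    def test_overlapping_nrl_rejected(self):
        with pytest.raises(ValueError, match="147"):
            simulate_nucleosome_array(GenomicInterval("c", 0, 1000), 147, 5, rng=0)


class TestCapLabels:
    def _nucs(self, n=2000):
        return pd.DataFrame({"chrom": "c", "midpoint": np.arange(n) * 180 + 90,
                             "nuc_id": np.arange(n)})

    def test_zero_slope_is_coin_flip(self):
        cfg = SimulationConfig(seed=9, ratio_slope=0.0, genome=(("c", 400_000),))
        nucs, _ = assign_cap_labels(self._nucs(), [], pd.DataFrame(
            columns=["gene_id", "log_expr"]), cfg)
        assert np.allclose(nucs["p_hmgd"], 0.5)
        frac = (nucs["label"] == "hmgd").mean()
        assert 0.45 < frac < 0.55

    def test_logistic_probabilities(self):
        # closed form at slope 1: p(z=3) ~ 0.953, p(z=-3) ~ 0.047
        assert math.isclose(1 / (1 + math.exp(-3)), 0.9526, abs_tol=5e-4)
        assert math.isclose(1 / (1 + math.exp(3)), 0.0474, abs_tol=5e-4)
        cfg = SimulationConfig(seed=0, ratio_slope=1.0, genome=(("c", 400_000),))
        genes, expr, _ = simulate_annotation(
            SimulationConfig(seed=1, n_genes=9, genome=(("c", 400_000),)))
        nucs, _ = assign_cap_labels(self._nucs(), genes, expr, cfg)
        # nucleosomes far from every TSS sit at the intergenic baseline z=-1
        base = 1 / (1 + math.exp(1))
        assert (np.isclose(nucs["p_hmgd"], base)).sum() > len(nucs) // 2

    def test_labels_partition(self):
        cfg = SimulationConfig(seed=2, genome=(("c", 400_000),))
        nucs, _ = assign_cap_labels(self._nucs(), [], pd.DataFrame(
            columns=["gene_id", "log_expr"]), cfg)
        assert set(nucs["label"]) <= {"hmgd", "h1"}
        assert nucs["nuc_id"].is_unique


class TestReads:
    def _labeled(self, n=3000):
        rng = np.random.default_rng(0)
        return pd.DataFrame(
            {"chrom": "c", "midpoint": np.arange(n) * 180 + 400,
             "nuc_id": np.arange(n),
             "label": rng.choice(["hmgd", "h1"], size=n)}
        )

    def test_degenerate_fragment_length(self):
        cfg = SimulationConfig(seed=1, fraglen_sd=0, genome=(("c", 600_000),))
        reads = simulate_reads(self._labeled(), cfg)["total"]
        assert (reads["fragment_length"] == 146).all()

    def test_central_95_matches_printed_window(self):
        cfg = SimulationConfig(seed=2, genome=(("c", 600_000),), depth=40)
        reads = simulate_reads(self._labeled(), cfg)["total"]
        lengths = np.sort(reads["fragment_length"].to_numpy())
        lo = lengths[int(0.025 * lengths.size)]
        hi = lengths[int(0.975 * lengths.size)]
        assert abs(lo - 101) <= 1 and abs(hi - 191) <= 1

    def test_pair_midpoint_blur_rms(self):
        cfg = SimulationConfig(seed=3, genome=(("c", 600_000),))
        reads = simulate_reads(self._labeled(), cfg)["total"]
        mid = (reads["start"] + reads["end"] - 1) // 2
        true = reads["nuc_id"].to_numpy() * 180 + 400
        rms = np.sqrt(((mid - true) ** 2).mean())
        assert abs(rms - 3.0) < 0.3

    def test_chip_experiments_sample_matching_labels_only(self):
        cfg = SimulationConfig(seed=4, genome=(("c", 600_000),))
        labeled = self._labeled()
        reads = simulate_reads(labeled, cfg)
        hmgd_ids = set(labeled.loc[labeled["label"] == "hmgd", "nuc_id"])
        assert set(reads["hmgd"]["nuc_id"]) <= hmgd_ids
        assert set(reads["h1"]["nuc_id"]).isdisjoint(hmgd_ids)

    def test_single_end_mode(self):
        cfg = SimulationConfig(seed=5, genome=(("c", 600_000),))
        reads = simulate_reads(self._labeled(500), cfg, paired=False)["total"]
        assert set(reads["strand"]) == {"+", "-"}
        assert (reads["end"] - reads["start"] == 36).all()
        assert not reads["mate_present"].any()


class TestPtmAndCounts:
    def test_noiseless_tracks_correlate_at_unit(self, gene_study):
        genes, expr = gene_study.genes, gene_study.expression
        values, _ = simulate_ptm_tracks(genes, expr, noise_sd=0.0, rng=0)
        c = values.corr()
        assert c.loc["activating_1", "activating_2"] == pytest.approx(1.0)
        assert c.loc["activating_1", "repressive_1"] == pytest.approx(-1.0)

    def test_noisy_within_family_correlation(self, gene_study):
        genes, expr = gene_study.genes, gene_study.expression
        values, _ = simulate_ptm_tracks(genes, expr, amplitude=1.0, noise_sd=1.0,
                                        rng=1)
        c = values.corr()
        within = c.loc["activating_1", "activating_2"]
        # variance arithmetic: a^2 / (a^2 + sigma^2) = 0.5
        assert abs(within - 0.5) < 0.25

    def test_expression_counts_recover_truth(self):
        cfg = SimulationConfig(seed=6, n_genes=500,
                               genome=(("c", 2_000_000), ("d", 2_000_000)))
        genes, expr, _ = simulate_annotation(cfg)
        counts = simulate_expression_counts(genes, expr, 1_000_000, rng=2)
        from capra.expression import expression_table
        tab = expression_table(counts)
        r = np.corrcoef(tab["log_expr"],
                        expr.set_index("gene_id").loc[tab["gene_id"], "log_expr"])[0, 1]
        assert r > 0.95


class TestStudyDeterminism:
    def test_same_config_byte_identical(self):
        cfg = SimulationConfig(seed=42, n_genes=20, genome=(("c", 100_000),))
        t1 = simulate_gene_study(cfg)
        t2 = simulate_gene_study(cfg)
        pd.testing.assert_frame_equal(t1.nucleosomes, t2.nucleosomes)
        for k in t1.reads:
            pd.testing.assert_frame_equal(t1.reads[k], t2.reads[k])
        pd.testing.assert_frame_equal(t1.ptm, t2.ptm)
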