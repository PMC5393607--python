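"""Planted-truth generator: determinism, planted counts, and statistical self-tests."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from bivalscreen import (
    CANDIDATE_SYMBOLS,
    SimConfig,
    annotate_expression,
    CandidateRecord,
    ChromatinState,
    generate_annotation,
    generate_truth,
    make_promoter_window,
    simulate_counts,
    simulate_reads,
    simulate_tf_peaks,
)
from bivalscreen.calling import background_rate
from bivalscreen.core import count_overlapping


@pytest.fixture(scope="module")
def default_truth(default_config):
    return generate_truth(default_config)


@pytest.fixture(scope="module")
def default_libraries(default_config, default_truth):
    genes = generate_annotation(default_config, default_truth)
    return genes, simulate_reads(default_truth, genes, default_config)


class TestGenerateTruth:
    def test_osteoclast_plants_exact_screen_counts(self, default_truth):
        switch = (default_truth["state_pre"] == "bivalent") & (
            default_truth["state_post"] == "k4_monovalent"
        )
        assert int(switch.sum()) == 49
        assert int(default_truth["tf_peak_planted"].sum()) == 33
        # TF peaks only on switch genes
        assert (default_truth["tf_peak_planted"] & ~switch).sum() == 0

    def test_candidate_symbols_sit_on_tf_planted_genes(self, default_truth):
        tf_symbols = set(default_truth.loc[default_truth["tf_peak_planted"], "symbol"])
        assert tf_symbols == set(CANDIDATE_SYMBOLS)
        assert default_truth["symbol"].is_unique

    def test_distractor_proportions(self, default_config, default_truth):
        pairs = default_truth.groupby(["state_pre", "state_post"]).size()
        assert pairs[("bivalent", "bivalent")] == round(0.10 * default_config.n_genes)
        assert pairs[("k4_monovalent", "k4_monovalent")] == round(0.20 * default_config.n_genes)
        assert pairs[("bivalent", "unmarked")] == round(0.05 * default_config.n_genes)

    def test_same_seed_identical_truth(self, default_config, default_truth):
        again = generate_truth(SimConfig())
        pd.testing.assert_frame_equal(again, default_truth)

    def test_too_few_genes_for_scenario(self):
        with pytest.raises(ValueError, match="n_genes >= 49"):
            SimConfig(n_genes=10)

    def test_random_scenario_all_unmarked_has_no_switches(self):
        cfg = SimConfig(
            n_genes=100, scenario="random", random_proportions={"unmarked": 1.0}
        )
        truth = generate_truth(cfg)
        assert (truth["state_pre"] == "unmarked").all()
        assert (truth["state_post"] == "unmarked").all()


class TestGenerateAnnotation:
    def test_zero_genes_gives_empty_annotation(self, tmp_path):
        cfg = SimConfig(n_genes=0)
        assert generate_annotation(cfg, path=tmp_path / "a.gtf") == []

    def test_promoter_windows_never_overlap(self, small_config):
        genes = generate_annotation(small_config)
        by_chrom = {}
        for g in genes:
            by_chrom.setdefault(g.chrom, []).append(g.tss)
        for tsss in by_chrom.values():
            tsss.sort()
            assert all(
                b - a >= 2 * small_config.flank for a, b in zip(tsss, tsss[1:])
            )
        assert all(
            small_config.flank <= g.tss <= small_config.chrom_length - small_config.flank
            for g in genes
        )

    def test_same_seed_byte_identical_gtf(self, small_config, tmp_path):
        p1, p2 = tmp_path / "a.gtf", tmp_path / "b.gtf"
        generate_annotation(small_config, path=p1)
        generate_annotation(SimConfig(**dataclasses.asdict(small_config)), path=p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_too_dense_layout_is_a_config_error(self):
        cfg = SimConfig(n_genes=500, n_chroms=1, chrom_length=1_000_000, n_switch=49)
        with pytest.raises(ValueError, match="cannot fit"):
            generate_annotation(cfg)


def _window_counts(config, genes, lib, gene_ids):
    index = lib.index()
    wanted = set(gene_ids)
    return np.array(
        [
            count_overlapping(index, make_promoter_window(g, config.flank).interval)
            for g in genes
            if g.gene_id in wanted
        ]
    )


class TestSimulateReads:
    def test_background_component_matches_planted_rate_within_1pct(
        self, default_config, default_libraries
    ):
        """lambda from the background read count reproduces lambda_bg_per_window."""
        _, libraries = default_libraries
        for lib in libraries.values():
            stats = dataclasses.replace(lib.stats, total_reads=lib.n_background)
            lam = background_rate(stats, 2 * default_config.flank)
            assert lam == pytest.approx(default_config.lambda_bg_per_window, rel=0.01)

    def test_whole_library_lambda_is_inflated_by_enrichment(
        self, default_config, default_libraries
    ):
        """Full totals include planted enrichment, so lambda sits above background."""
        _, libraries = default_libraries
        for lib in libraries.values():
            lam = background_rate(lib.stats, 2 * default_config.flank)
            assert lam > default_config.lambda_bg_per_window * 1.05

    def test_planted_windows_hit_fold_times_lambda_within_5pct(
        self, default_config, default_truth, default_libraries
    ):
        genes, libraries = default_libraries
        planted = default_truth.loc[
            default_truth["state_post"] == "bivalent", "gene_id"
        ]
        assert len(planted) >= 100
        counts = _window_counts(
            default_config, genes, libraries[("H3K27me3", "post")], planted
        )
        expected = default_config.enrichment_fold * default_config.lambda_bg_per_window
        assert counts.mean() == pytest.approx(expected, rel=0.05)

    def test_fold_one_means_no_detectable_enrichment(self):
        cfg = SimConfig(
            n_genes=600, n_chroms=2, chrom_length=4_000_000,
            enrichment_fold=1.0, seed=5,
        )
        truth = generate_truth(cfg)
        genes = generate_annotation(cfg, truth)
        lib = simulate_reads(truth, genes, cfg)[("H3K4me3", "pre")]
        k4_pre = truth["state_pre"].isin(["bivalent", "k4_monovalent"])
        planted = _window_counts(cfg, genes, lib, truth.loc[k4_pre, "gene_id"])
        background = _window_counts(cfg, genes, lib, truth.loc[~k4_pre, "gene_id"])
        assert len(planted) + len(background) >= 500
        se = np.sqrt(planted.var() / len(planted) + background.var() / len(background))
        assert abs(planted.mean() - background.mean()) < 3 * se

    def test_zero_background_and_no_marks_gives_empty_library(self):
        cfg = SimConfig(
            n_genes=50, n_chroms=1, chrom_length=2_000_000,
            lambda_bg_per_window=0.0, scenario="random",
            random_proportions={"unmarked": 1.0},
        )
        truth = generate_truth(cfg)
        genes = generate_annotation(cfg, truth)
        libraries = simulate_reads(truth, genes, cfg)
        assert all(lib.stats.total_reads == 0 for lib in libraries.values())

    def test_same_seed_identical_reads(self, small_config):
        truth = generate_truth(small_config)
        genes = generate_annotation(small_config, truth)
        a = simulate_reads(truth, genes, small_config)
        b = simulate_reads(truth, genes, small_config)
        for key in a:
            np.testing.assert_array_equal(a[key].starts, b[key].starts)


class TestSimulateTfPeaks:
    def test_one_peak_per_planted_gene_overlapping_its_window(self, small_config):
        truth = generate_truth(small_config)
        genes = generate_annotation(small_config, truth)
        peaks = simulate_tf_peaks(truth, genes, small_config)
        assert len(peaks) == small_config.n_tf_bound
        planted_idx = np.flatnonzero(truth["tf_peak_planted"].to_numpy())
        for peak, gi in zip(peaks, planted_idx):
            window = make_promoter_window(genes[gi], small_config.flank)
            assert count_overlapping([peak], window.interval) == 1

    def test_no_planted_genes_no_peaks(self, small_config):
        cfg = dataclasses.replace(small_config, n_tf_bound=0)
        truth = generate_truth(cfg)
        genes = generate_annotation(cfg, truth)
        assert simulate_tf_peaks(truth, genes, cfg) == []

    def test_same_seed_identical_file(self, small_config, tmp_path):
        truth = generate_truth(small_config)
        genes = generate_annotation(small_config, truth)
        p1, p2 = tmp_path / "a.bed", tmp_path / "b.bed"
        simulate_tf_peaks(truth, genes, small_config, path=p1)
        simulate_tf_peaks(truth, genes, small_config, path=p2)
        assert p1.read_bytes() == p2.read_bytes()


def _recover_lfc(truth, pre, post, gene_ids):
    candidates = [
        CandidateRecord(
            gene_id=g, symbol=g, state_pre=ChromatinState.BIVALENT,
            state_post=ChromatinState.K4_MONOVALENT, is_switch=True, tf_bound=True,
        )
        for g in gene_ids
    ]
    annotated = annotate_expression(candidates, pre["pre"], post["post"])
    return np.array([r.log2fc_expression for r in annotated])


class TestSimulateCounts:
    def test_null_lfc_distribution_centered_at_zero(self, default_config):
        cfg = dataclasses.replace(default_config, switch_lfc=0.0)
        truth = generate_truth(cfg)
        pre, post = simulate_counts(truth, cfg)
        lfc = _recover_lfc(truth, pre, post, truth["gene_id"])
        assert abs(lfc.mean()) < 0.1

    def test_planted_positive_lfc_recovered(self, default_config, default_truth):
        pre, post = simulate_counts(default_truth, default_config)
        switch_ids = default_truth.loc[
            default_truth["expression_lfc_planted"] == default_config.switch_lfc,
            "gene_id",
        ]
        lfc = _recover_lfc(default_truth, pre, post, switch_ids)
        assert lfc.mean() == pytest.approx(default_config.switch_lfc, abs=0.5)

    def test_same_seed_identical_counts(self, small_config, tmp_path):
        truth = generate_truth(small_config)
        simulate_counts(truth, small_config, out_dir=tmp_path / "a")
        simulate_counts(truth, small_config, out_dir=tmp_path / "b")
        for name in ("counts_pre.tsv", "counts_post.tsv"):
            assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()
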