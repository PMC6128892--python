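from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from chromexpress.simulate import (
    SimulationConfig,
    make_genomes,
    make_truth,
    simulate_all,
    simulate_chip_sample,
    simulate_de_table,
    simulate_expression_profiles,
    write_dataset,
)


class TestMakeGenomes:
    def test_genes_tile_without_overlap_alternating_strands(self):
        config = SimulationConfig(
            seed=0, n_genes=10, chrom_len=100_000, n_de_up=1, n_de_down=1
        )
        space, genes = make_genomes(config)
        assert len(genes) == 10
        assert sum(g.strand == "+" for g in genes) == 5
        for a, b in zip(genes, genes[1:]):
            assert a.end <= b.start
        assert space.spike_chroms == ["spike_chr1"]

    def test_deterministic_under_seed(self, small_config):
        _, genes_a = make_genomes(small_config)
        _, genes_b = make_genomes(small_config)
        assert genes_a == genes_b

    def test_zero_genes_rejected(self):
        with pytest.raises(ValueError):
            make_genomes(SimulationConfig(n_genes=0))

    def test_too_short_chromosome_is_sizing_error(self):
        with pytest.raises(ValueError, match="too short"):
            make_genomes(SimulationConfig(n_genes=100, chrom_len=100_000))


class TestTruth:
    def test_exact_class_counts(self, small_dataset):
        counts = small_dataset.truth.genes["class_label"].value_counts()
        n = small_dataset.config.n_genes
        for label, prop in small_dataset.config.class_proportions.items():
            if label != "none":
                assert counts[label] == round(prop * n)

    def test_every_gene_has_one_truth_record(self, small_dataset):
        truth = small_dataset.truth.genes
        assert truth.index.is_unique
        assert len(truth) == small_dataset.config.n_genes


class TestChipSample:
    def test_spike_count_invariant_across_conditions(self, small_config, small_dataset):
        # the spike-in contract: identical expected spike yield per condition
        for mark in ("H3K4me3", "input"):
            counts = {}
            for cond in ("control", "knockdown"):
                frags = small_dataset.fragments[(mark, cond)]
                counts[cond] = sum(1 for c in frags.chroms if c.startswith("spike_"))
            assert counts["control"] == counts["knockdown"]

    def test_null_shift_gives_equal_target_counts(self, small_config):
        space, genes = make_genomes(small_config)
        truth = make_truth(small_config, genes)
        frags = {
            cond: simulate_chip_sample(small_config, genes, truth, "H3K4me3", cond)
            for cond in ("control", "knockdown")
        }
        targets = {
            cond: sum(1 for c in f.chroms if c == "chr1") for cond, f in frags.items()
        }
        assert targets["control"] == targets["knockdown"]

    def test_shift_doubles_target_to_spike_ratio(self, small_config):
        config = replace(small_config, global_chip_shift=2.0)
        space, genes = make_genomes(config)
        truth = make_truth(config, genes)
        ratios = {}
        for cond in ("control", "knockdown"):
            frags = simulate_chip_sample(config, genes, truth, "H3K4me3", cond)
            n_spike = sum(1 for c in frags.chroms if c.startswith("spike_"))
            ratios[cond] = (len(frags) - n_spike) / n_spike
        assert ratios["knockdown"] == pytest.approx(2 * ratios["control"], rel=1e-3)

    def test_input_coverage_is_flat_over_tss_bins(self, small_config, small_dataset):
        from chromexpress.spike_norm import coverage, partition

        frags = small_dataset.fragments[("input", "control")]
        part = partition(frags, small_dataset.space)
        track = coverage(part.target, small_dataset.space, bin_size=10)
        # average profile across TSS windows: slope of a linear fit ~ 0
        half = 100
        rows = []
        for g in small_dataset.genes:
            c = g.tss // 10
            row = track.values["chr1"][c - half : c + half]
            rows.append(row[::-1] if g.strand == "-" else row)
        mean_profile = np.mean(rows, axis=0)
        x = np.arange(2 * half)
        slope = np.polyfit(x, mean_profile, 1)[0]
        # an enriched mark's profile rises by orders of magnitude more
        assert abs(slope) * len(x) < 0.2 * mean_profile.mean()

    def test_unknown_mark_rejected(self, small_config, small_dataset):
        with pytest.raises(ValueError, match="unknown mark"):
            simulate_chip_sample(
                small_config, small_dataset.genes, small_dataset.truth, "H3K9me3", "control"
            )

    def test_determinism_byte_identical_outputs(self, small_config, tmp_path):
        ds_a = simulate_all(small_config, marks=("H3K4me3", "input"))
        ds_b = simulate_all(small_config, marks=("H3K4me3", "input"))
        paths_a = write_dataset(ds_a, tmp_path / "a")
        paths_b = write_dataset(ds_b, tmp_path / "b")
        for key in paths_a:
            assert paths_a[key].read_bytes() == paths_b[key].read_bytes(), key


class TestExpressionProfiles:
    def test_rows_sum_to_one(self, small_dataset):
        sums = small_dataset.expression[["prop_X1", "prop_X2", "prop_Xins"]].sum(axis=1)
        assert np.allclose(sums, 1.0, atol=1e-9)

    def test_true_class_always_majority(self, small_dataset):
        truth = small_dataset.truth.genes["class_label"]
        expr = small_dataset.expression.set_index("gene_id")
        for gene_id, label in truth.items():
            props = expr.loc[gene_id]
            if label == "none":
                assert props.max() < 0.5
            else:
                assert props[f"prop_{label}"] > 0.5


class TestDeTable:
    def test_planted_counts_recovered_exactly(self, small_config):
        space, genes = make_genomes(small_config)
        truth = make_truth(small_config, genes)
        table = simulate_de_table(small_config, genes, truth)
        import math

        cut = math.log2(1.5)
        up = ((table["log2fc"] >= cut) & (table["p_value"] < 0.05)).sum()
        down = ((table["log2fc"] <= -cut) & (table["p_value"] < 0.05)).sum()
        assert (up, down) == (small_config.n_de_up, small_config.n_de_down)

    def test_infeasible_counts_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_genes=10, n_de_up=6, n_de_down=6)

    def test_copula_couples_truth_at_requested_strength(self):
        # planted (not measured) coupling: Spearman between true mark change
        # and log2fc within the coupled class tracks coupling_rho
        from scipy.stats import spearmanr

        recovered = {}
        for rho in (0.0, -0.5, -0.9):
            vals = []
            for seed in range(5):
                config = SimulationConfig(seed=seed, coupling_rho=rho)
                _, genes = make_genomes(config)
                truth = make_truth(config, genes).genes
                sub = truth[truth["class_label"] == "X1"]
                change = (
                    sub["enrich_H3K4me1_knockdown"] - sub["enrich_H3K4me1_control"]
                )
                vals.append(spearmanr(change, sub["log2fc"]).statistic)
            recovered[rho] = np.mean(vals)
        assert abs(recovered[0.0]) < 0.1
        assert recovered[-0.5] == pytest.approx(-0.5, abs=0.05)
        assert recovered[-0.9] == pytest.approx(-0.9, abs=0.05)
        # monotonicity: stronger planted coupling, stronger recovered coupling
        assert abs(recovered[-0.9]) > abs(recovered[-0.5]) > abs(recovered[0.0])
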