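import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from chromexpress.integration import (
    ConstantInputError,
    WindowError,
    correlate_by_class,
    gene_signal_change,
    signal_change_table,
    spearman,
)
from chromexpress.io_formats import GeneModel, GenomeSpace
from chromexpress.spike_norm import CoverageTrack


from oracles import naive_spearman_rho


class TestSpearman:
    def test_perfect_monotone(self):
        rho, _ = spearman([1, 2, 3], [10, 20, 30])
        assert rho == pytest.approx(1.0)

    def test_perfect_inverse(self):
        rho, _ = spearman([1, 2, 3], [3, 2, 1])
        assert rho == pytest.approx(-1.0)

    def test_tied_data_matches_naive_average_rank_formula(self):
        x, y = [1, 1, 2, 3], [2, 1, 4, 3]
        rho, _ = spearman(x, y)
        assert rho == pytest.approx(naive_spearman_rho(x, y), abs=1e-12)

    def test_matches_naive_oracle_on_random_vectors(self, rng):
        for _ in range(50):
            n = int(rng.integers(4, 25))
            x = np.round(rng.normal(size=n), 1)  # rounding induces ties
            y = np.round(rng.normal(size=n), 1)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            rho, _ = spearman(x, y)
            assert rho == pytest.approx(naive_spearman_rho(x, y), abs=1e-12)

    def test_agrees_with_scipy(self, rng):
        x, y = rng.normal(size=40), rng.normal(size=40)
        rho, p = spearman(x, y)
        ref = stats.spearmanr(x, y)
        assert rho == pytest.approx(ref.statistic, abs=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=1e-6)

    def test_exact_p_equals_enumeration_oracle(self, rng):
        # literal enumeration over all n! orderings using the naive rho
        for n in (4, 5, 6, 7):
            for _ in range(4):
                x = np.round(rng.normal(size=n), 1)
                y = np.round(rng.normal(size=n), 1)
                if np.ptp(x) == 0 or np.ptp(y) == 0:
                    continue
                rho, p = spearman(x, y)
                obs = abs(naive_spearman_rho(x, y))
                hits = sum(
                    abs(naive_spearman_rho(x, perm)) >= obs - 1e-12
                    for perm in itertools.permutations(y)
                )
                assert p == pytest.approx(hits / math.factorial(n), abs=1e-12)

    def test_perfect_rank_agreement_small_n(self):
        rho, p = spearman([1, 2, 3, 4], [10, 20, 30, 40])
        assert rho == 1.0
        assert p == pytest.approx(2 / math.factorial(4))

    def test_symmetry_and_monotone_invariance(self, rng):
        x, y = rng.normal(size=15), rng.normal(size=15)
        assert spearman(x, y) == spearman(y, x)
        rho_a, _ = spearman(x, y)
        rho_b, _ = spearman(np.exp(x), y**3 + 5 * y)
        assert rho_a == pytest.approx(rho_b, abs=1e-12)

    def test_constant_vector_raises_distinct_error(self):
        with pytest.raises(ConstantInputError):
            spearman([1, 1, 1], [1, 2, 3])


class TestGeneSignalChange:
    @pytest.fixture
    def big_space(self):
        return GenomeSpace(chrom_sizes={"chr1": 100_000})

    def _tracks(self, big_space, kd_fill, ctrl_fill):
        kd = CoverageTrack.zeros(big_space, bin_size=10, state="subtracted")
        ctrl = CoverageTrack.zeros(big_space, bin_size=10, state="subtracted")
        kd.values["chr1"][:] = kd_fill
        ctrl.values["chr1"][:] = ctrl_fill
        return kd, ctrl

    def test_identical_tracks_zero_delta(self, big_space):
        kd, ctrl = self._tracks(big_space, 2.0, 2.0)
        gene = GeneModel("a", "chr1", 50_000, 52_000, "+")
        assert gene_signal_change(kd, ctrl, gene).delta == 0.0

    def test_uniform_shift_recovered(self, big_space):
        kd, ctrl = self._tracks(big_space, 7.0, 2.0)
        gene = GeneModel("a", "chr1", 50_000, 52_000, "+")
        assert gene_signal_change(kd, ctrl, gene).delta == pytest.approx(5.0)

    def test_matches_per_bp_oracle_when_bin_aligned(self, big_space, rng):
        kd, ctrl = self._tracks(big_space, 0.0, 0.0)
        kd.values["chr1"][:] = rng.random(10_000)
        gene = GeneModel("a", "chr1", 50_000, 52_000, "+")  # tss bin-aligned
        change = gene_signal_change(kd, ctrl, gene, window=1000)
        per_bp = np.repeat(kd.values["chr1"], 10)
        expected = per_bp[gene.tss - 1000 : gene.tss + 1000].mean()
        assert change.delta == pytest.approx(expected)

    def test_gene_body_region(self, big_space, rng):
        kd, ctrl = self._tracks(big_space, 0.0, 1.0)
        gene = GeneModel("a", "chr1", 50_000, 52_000, "+")
        change = gene_signal_change(kd, ctrl, gene, region="gene_body")
        assert change.delta == pytest.approx(-1.0)

    def test_window_off_chromosome_raises_and_batch_skips(self, big_space):
        kd, ctrl = self._tracks(big_space, 1.0, 0.0)
        edge = GeneModel("edge", "chr1", 500, 2_500, "+")
        ok = GeneModel("ok", "chr1", 50_000, 52_000, "+")
        with pytest.raises(WindowError):
            gene_signal_change(kd, ctrl, edge)
        table = signal_change_table(kd, ctrl, [edge, ok])
        assert list(table["gene_id"]) == ["ok"]


class TestCorrelateByClass:
    def _inputs(self, rho_sign=1.0, n=40):
        rng = np.random.default_rng(3)
        log2fc = rng.normal(0, 1.5, n)
        delta = rho_sign * log2fc + rng.normal(0, 0.1, n)
        ids = [f"g{i}" for i in range(n)]
        de = pd.DataFrame({"gene_id": ids, "log2fc": log2fc})
        changes = pd.DataFrame({"gene_id": ids, "region": "tss_window", "delta": delta})
        labels = pd.DataFrame({"gene_id": ids, "class_label": ["X1"] * n})
        return de, changes, labels

    def test_strong_positive_coupling_detected(self):
        de, changes, labels = self._inputs()
        out = correlate_by_class(de, changes, labels, mark="H3K4me3")
        row = out[(out["filter"] == "none")].iloc[0]
        assert row["rho"] > 0.9 and row["significant"]

    def test_filter_can_sharpen_a_noisy_tail(self):
        # monotone coupling only among |log2fc| >= 1; the middle scrambled
        rng = np.random.default_rng(9)
        log2fc = np.concatenate([np.linspace(-3, -1, 10), np.linspace(1, 3, 10),
                                 rng.uniform(-0.9, 0.9, 30)])
        delta = np.concatenate([np.linspace(-3, -1, 10), np.linspace(1, 3, 10),
                                rng.permutation(np.linspace(-0.5, 0.5, 30))])
        ids = [f"g{i}" for i in range(50)]
        de = pd.DataFrame({"gene_id": ids, "log2fc": log2fc})
        changes = pd.DataFrame({"gene_id": ids, "region": "tss_window", "delta": delta})
        labels = pd.DataFrame({"gene_id": ids, "class_label": ["X1"] * 50})
        out = correlate_by_class(de, changes, labels, mark="H3K4me1")
        filtered = out[out["filter"] == "abs_log2fc_ge_1"].iloc[0]
        unfiltered = out[out["filter"] == "none"].iloc[0]
        assert filtered["rho"] == pytest.approx(1.0)
        assert filtered["n"] == 20
        assert filtered["rho"] > unfiltered["rho"]

    def test_small_class_gets_reason_code(self):
        de, changes, labels = self._inputs(n=2)
        out = correlate_by_class(de, changes, labels, mark="H3K4me3", filters=("none",))
        row = out.iloc[0]
        assert np.isnan(row["rho"]) and row["reason"] == "n_lt_3"
        assert not row["significant"]

    def test_missing_genes_are_excluded_and_counted(self):
        de, changes, labels = self._inputs(n=10)
        changes = changes.iloc[:7]
        out = correlate_by_class(de, changes, labels, mark="H3K4me3", filters=("none",))
        assert out.iloc[0]["n"] == 7
        assert out.iloc[0]["n_excluded"] == 3
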