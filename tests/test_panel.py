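import math

import numpy as np
import pandas as pd
import pytest

from csea import (
    DegenerateInputError,
    ExpressionPanel,
    PanelMetadata,
    TStatMatrix,
    compute_tc_tstats,
    filter_cell_types,
    filter_genes,
    normalize_log2_cpm,
    select_signatures,
    signature_size,
)
from csea.io import save_signature_panel


META = PanelMetadata(panel_id="T")


def make_panel(counts, cell_types, gene_ids=None):
    counts = np.asarray(counts)
    gene_ids = gene_ids or [f"g{i}" for i in range(counts.shape[0])]
    cell_ids = [f"c{j}" for j in range(counts.shape[1])]
    return ExpressionPanel(counts, gene_ids, cell_ids, list(cell_types), META)


class TestNormalizeLog2CPM:
    @pytest.mark.parametrize(
        "counts, expected",
        [
            ([[5]], [[math.log2(1e6 + 1)]]),
            ([[1], [3]], [[math.log2(250001)], [math.log2(750001)]]),
            ([[0], [2]], [[0.0], [math.log2(1e6 + 1)]]),
        ],
    )
    def test_examples(self, counts, expected):
        np.testing.assert_allclose(normalize_log2_cpm(np.array(counts)), expected)

    def test_cpm_columns_sum_to_one_million(self):
        rng = np.random.default_rng(0)
        counts = rng.poisson(2.0, size=(50, 8)) + 1
        cpm = 2.0 ** normalize_log2_cpm(counts) - 1.0
        np.testing.assert_allclose(cpm.sum(axis=0), 1e6, rtol=1e-9)

    def test_zero_library_cell_rejected_by_name(self):
        counts = np.array([[1, 0], [2, 0]])
        with pytest.raises(DegenerateInputError, match="cellB"):
            normalize_log2_cpm(counts, cell_ids=["cellA", "cellB"])


class TestFilterGenes:
    def test_zero_thresholds_are_identity(self):
        panel = make_panel([[0, 1], [5, 0]], ["A", "B"])
        out = filter_genes(panel, min_cells=0, min_fraction=0.0)
        assert out.gene_ids == panel.gene_ids

    def test_rarely_detected_gene_removed(self):
        counts = np.zeros((2, 1000), dtype=int)
        counts[0, :2] = 1  # detected in 2 cells only
        counts[1, :] = 1
        panel = make_panel(counts, ["A"] * 500 + ["B"] * 500)
        out = filter_genes(panel, min_cells=3, min_fraction=0.0)
        assert out.gene_ids == ["g1"]

    def test_ubiquitous_gene_always_survives_fraction(self):
        counts = np.ones((1, 40), dtype=int)
        panel = make_panel(counts, ["A"] * 20 + ["B"] * 20)
        out = filter_genes(panel, min_cells=0, min_fraction=1.0)
        assert out.gene_ids == ["g0"]

    def test_empty_result_is_an_error(self):
        panel = make_panel(np.zeros((2, 4), dtype=int), ["A", "A", "B", "B"])
        with pytest.raises(DegenerateInputError):
            filter_genes(panel, min_cells=1, min_fraction=0.0)


class TestFilterCellTypes:
    def test_threshold_is_inclusive_at_30(self):
        sizes = {"A": 29, "B": 30, "C": 500}
        labels = [ct for ct, n in sizes.items() for _ in range(n)]
        panel = make_panel(np.ones((2, len(labels)), dtype=int), labels)
        out = filter_cell_types(panel, min_cells=30)
        assert sorted(set(out.cell_types)) == ["B", "C"]
        assert out.n_cells == 530

    def test_all_large_types_identity(self):
        labels = ["A"] * 30 + ["B"] * 31
        panel = make_panel(np.ones((2, 61), dtype=int), labels)
        assert filter_cell_types(panel).n_cells == 61

    def test_fewer_than_two_survivors_is_an_error(self):
        labels = ["A"] * 29 + ["B"] * 29 + ["C"] * 31
        panel = make_panel(np.ones((2, 89), dtype=int), labels)
        with pytest.raises(DegenerateInputError):
            filter_cell_types(panel, min_cells=30)


class TestTStatistics:
    def test_matches_indicator_ols(self):
        """The pooled two-sample t equals the OLS t of the group indicator."""
        statsmodels = pytest.importorskip("statsmodels.api")
        expr = np.array([2.0, 3.0, 0.0, 1.0, 0.0])
        labels = ["focal", "focal", "rest", "rest", "rest"]
        ts = compute_tc_tstats(expr[None, :], labels)
        X = statsmodels.add_constant(np.array([1.0, 1.0, 0.0, 0.0, 0.0]))
        fit = statsmodels.OLS(expr, X).fit()
        j = ts.tc_labels.index("focal")
        assert ts.values[0, j] == pytest.approx(fit.tvalues[1], rel=1e-12)

    def test_matches_indicator_ols_random_matrix(self):
        statsmodels = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(5)
        norm = rng.normal(size=(6, 12))
        labels = ["a"] * 4 + ["b"] * 4 + ["c"] * 4
        ts = compute_tc_tstats(norm, labels)
        for j, tc in enumerate(ts.tc_labels):
            ind = np.array([1.0 if l == tc else 0.0 for l in labels])
            X = statsmodels.add_constant(ind)
            for g in range(norm.shape[0]):
                fit = statsmodels.OLS(norm[g], X).fit()
                assert ts.values[g, j] == pytest.approx(fit.tvalues[1], rel=1e-9)

    def test_constant_gene_maps_to_zero(self):
        norm = np.full((1, 8), 3.7)
        ts = compute_tc_tstats(norm, ["a"] * 4 + ["b"] * 4)
        assert np.all(ts.values == 0.0)

    def test_two_type_panel_columns_are_negatives(self):
        rng = np.random.default_rng(6)
        norm = rng.normal(size=(20, 10))
        ts = compute_tc_tstats(norm, ["a"] * 5 + ["b"] * 5)
        np.testing.assert_allclose(ts.values[:, 0], -ts.values[:, 1], atol=1e-10)

    def test_singleton_type_rejected(self):
        with pytest.raises(ValueError, match="single cell"):
            compute_tc_tstats(np.zeros((1, 3)), ["a", "a", "b"])


class TestSelectSignatures:
    @pytest.mark.parametrize("n_universe, expected", [(1000, 50), (10, 1), (19, 1), (21, 1), (40, 2)])
    def test_signature_size_rule(self, n_universe, expected):
        assert signature_size(n_universe, 0.05) == expected

    def test_sizes_realized_per_tc(self):
        rng = np.random.default_rng(7)
        genes = [f"g{i:04d}" for i in range(1000)]
        ts = TStatMatrix(rng.normal(size=(1000, 3)), genes, ["a", "b", "c"])
        sp = select_signatures(ts, top_fraction=0.05)
        assert all(len(v) == 50 for v in sp.signatures.values())

    def test_all_ties_resolved_lexicographically(self):
        genes = ["zz", "mm", "aa", "bb"]
        ts = TStatMatrix(np.zeros((4, 2)), genes, ["a", "b"])
        sp = select_signatures(ts, top_fraction=0.5)
        assert sp.signatures["a"] == ["aa", "bb"]
        assert sp.signatures["b"] == ["aa", "bb"]

    def test_ordered_by_descending_tstat(self):
        genes = ["g0", "g1", "g2", "g3"]
        ts = TStatMatrix(np.array([[1.0], [3.0], [2.0], [0.0]]), genes, ["a"])
        sp = select_signatures(ts, top_fraction=0.75)
        assert sp.signatures["a"] == ["g1", "g2", "g0"]

    def test_byte_identical_exports(self, sim_bundle, tmp_path):
        """Identical inputs must serialize to byte-identical bundles."""
        _, _, sp = sim_bundle
        save_signature_panel(sp, tmp_path / "one")
        save_signature_panel(sp, tmp_path / "two")
        for name in ("signatures.gmt", "tstats.tsv", "panel.json"):
            assert (tmp_path / "one" / name).read_bytes() == (tmp_path / "two" / name).read_bytes()


class TestIngestNormalization:
    def test_duplicate_symbols_keep_larger_total(self):
        counts = pd.DataFrame(
            [[1, 1], [5, 5], [2, 2]],
            index=[" tp53", "TP53", "BRCA1"],
            columns=["c0", "c1"],
        )
        ann = pd.DataFrame({"cell_id": ["c0", "c1"], "cell_type": ["A", "B"]})
        panel = ExpressionPanel.from_frames(counts, ann, META)
        assert sorted(panel.gene_ids) == ["BRCA1", "TP53"]
        row = panel.counts[panel.gene_ids.index("TP53")]
        assert row.tolist() == [5, 5]

    def test_unannotated_cell_rejected(self):
        counts = pd.DataFrame([[1]], index=["A1"], columns=["c0"])
        ann = pd.DataFrame({"cell_id": ["other"], "cell_type": ["A"]})
        with pytest.raises(ValueError, match="annotation"):
            ExpressionPanel.from_frames(counts, ann, META)
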