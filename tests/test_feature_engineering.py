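import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from castle_sc import (
    DegenerateDataError,
    FeatureSet,
    GeneExpressionDataset,
    InputError,
    bin_values,
    engineer_features,
    mutual_information,
)
from castle_sc.feature_engineering import (
    align_common_genes,
    drop_constant_bins,
    filter_rare_genes,
    prune_correlated,
    select_top_mean,
    select_top_mi,
)


def _ds(matrix, gene_ids, labels=None):
    matrix = np.asarray(matrix, dtype=float)
    n = matrix.shape[0]
    return GeneExpressionDataset(
        matrix, gene_ids, [f"c{i}" for i in range(n)], labels or ["T"] * n
    )


class TestAlign:
    def test_intersection_in_source_order(self):
        s = _ds(np.ones((2, 3)), ["A", "B", "C"])
        t = _ds(np.ones((2, 3)), ["B", "C", "D"])
        s2, t2, common = align_common_genes(s, t)
        assert common == ["B", "C"]
        assert s2.gene_ids == t2.gene_ids == ["B", "C"]

    def test_identical_sets_unchanged(self):
        s = _ds(np.arange(6).reshape(2, 3), ["A", "B", "C"])
        t = _ds(np.arange(6).reshape(2, 3), ["A", "B", "C"])
        s2, t2, _ = align_common_genes(s, t)
        np.testing.assert_array_equal(s2.matrix, s.matrix)
        np.testing.assert_array_equal(t2.matrix, t.matrix)

    def test_disjoint_sets_error(self):
        with pytest.raises(DegenerateDataError, match="no shared genes"):
            align_common_genes(_ds(np.ones((1, 1)), ["A"]), _ds(np.ones((1, 1)), ["B"]))


class TestRareGeneFilter:
    def _pair(self, nz_src, nz_tgt):
        # one gene; given number of non-zero cells in each dataset of 10 cells
        src = np.zeros((10, 1))
        src[:nz_src, 0] = 1.0
        tgt = np.zeros((10, 1))
        tgt[:nz_tgt, 0] = 1.0
        return _ds(src, ["g"]), _ds(tgt, ["g"])

    def test_below_threshold_removed(self):
        s, t = self._pair(5, 4)  # 9 pooled non-zero cells
        with pytest.raises(DegenerateDataError):
            filter_rare_genes(s, t, min_cells=10)

    def test_boundary_retained(self):
        s, t = self._pair(5, 5)  # exactly 10: "less than" is strict
        s2, t2 = filter_rare_genes(s, t, min_cells=10)
        assert s2.gene_ids == ["g"]

    def test_zero_threshold_vacuous(self):
        s, t = self._pair(0, 0)
        s2, _ = filter_rare_genes(s, t, min_cells=0)
        assert s2.gene_ids == ["g"]


class TestTopMean:
    def test_pooled_mean_definition(self):
        s = _ds([[2.0], [2.0]], ["X"])
        t = _ds([[4.0], [4.0]], ["X"])
        # pooled mean (2+2+4+4)/4 = 3.0; with one gene, that gene is selected
        assert select_top_mean(s, t, k=1) == ["X"]

    def test_single_gene_any_k(self):
        s = _ds([[1.0]], ["only"])
        assert select_top_mean(s, s, k=100) == ["only"]

    def test_matches_exhaustive_recomputation(self):
        rng = np.random.default_rng(11)
        genes = [f"g{i:03d}" for i in range(500)]
        sm = rng.gamma(1.0, 2.0, size=(40, 500))
        tm = rng.gamma(1.0, 2.0, size=(25, 500))
        s, t = _ds(sm, genes), _ds(tm, genes)
        got = select_top_mean(s, t, k=100)
        # independent oracle: sort all pooled means exhaustively
        pooled = (sm.sum(0) + tm.sum(0)) / (40 + 25)
        oracle = [g for _, g in sorted(zip(-pooled, genes))][:100]
        assert got == oracle


class TestBinning:
    def test_interval_boundaries(self):
        vals = np.array([[0.0, 0.5, 1.0, 1.01, 6.0, 6.01]])
        codes = bin_values(vals).codes
        assert codes.tolist() == [[0, 1, 1, 2, 2, 3]]

    def test_all_zero_column(self):
        assert bin_values(np.zeros((3, 1))).codes.tolist() == [[0], [0], [0]]

    def test_rebinning_codes_is_not_identity(self):
        # guard: the interval map sends code 3 -> 2, so codes must never be re-binned
        codes = np.array([[0.0, 1.0, 2.0, 3.0]])  # a code row fed back as values
        rebinned = bin_values(codes).codes
        assert rebinned.tolist() == [[0, 1, 2, 2]]
        assert not np.array_equal(codes, rebinned)

    def test_negative_rejected(self):
        with pytest.raises(InputError):
            bin_values(np.array([[-1.0]]))

    def test_zero_conservation(self):
        rng = np.random.default_rng(3)
        m = rng.gamma(0.5, 2.0, size=(30, 8)) * (rng.random((30, 8)) > 0.4)
        binned = bin_values(m)
        assert (binned.codes == 0).sum() == (m == 0).sum()


def _mi_oracle(x, y):
    """Independent double-loop plug-in MI in bits."""
    x, y = list(x), list(y)
    n = len(x)
    total = 0.0
    for xv in set(x):
        for yv in set(y):
            nxy = sum(1 for a, b in zip(x, y) if a == xv and b == yv)
            if nxy == 0:
                continue
            px = sum(1 for a in x if a == xv) / n
            py = sum(1 for b in y if b == yv) / n
            total += (nxy / n) * math.log2((nxy / n) / (px * py))
    return total


class TestMutualInformation:
    def test_constant_feature_is_zero(self):
        assert mutual_information([1] * 6, list("aabbcc")) == pytest.approx(0.0)

    def test_perfect_binary_dependence_is_one_bit(self):
        x = [0, 0, 1, 1]
        assert mutual_information(x, x) == pytest.approx(1.0)

    def test_random_table_matches_double_loop_oracle(self):
        rng = np.random.default_rng(5)
        x = rng.integers(0, 4, size=60)
        y = rng.choice(list("abc"), size=60)
        assert mutual_information(x, y) == pytest.approx(_mi_oracle(x, y), abs=1e-12)

    def test_length_mismatch(self):
        with pytest.raises(InputError):
            mutual_information([1, 2], [1, 2, 3])

    def test_exhaustive_small_tables(self):
        # every 2x2 contingency table with cell counts <= 5
        for a, b, c, d in itertools.product(range(6), repeat=4):
            if a + b + c + d < 2:
                continue
            x = [0] * (a + b) + [1] * (c + d)
            y = [0] * a + [1] * b + [0] * c + [1] * d
            assert mutual_information(x, y) == pytest.approx(
                _mi_oracle(x, y), abs=1e-12
            )


class TestTopMI:
    def test_tracking_gene_ranked_first(self):
        rng = np.random.default_rng(9)
        labels = np.repeat(["a", "b"], 30)
        noise = rng.integers(0, 4, size=(60, 5)).astype(float)
        signal = np.where(labels == "a", 0.5, 7.0)[:, None]
        binned = bin_values(
            np.hstack([noise, signal]), feature_ids=[f"n{i}" for i in range(5)] + ["sig"]
        )
        assert select_top_mi(binned, labels, k=1) == ["sig"]

    def test_k_exceeding_gene_count(self):
        binned = bin_values(np.array([[0.0, 7.0], [7.0, 0.0]]), feature_ids=["a", "b"])
        assert sorted(select_top_mi(binned, ["x", "y"], k=10)) == ["a", "b"]

    def test_single_class_rejected(self):
        binned = bin_values(np.zeros((3, 2)), feature_ids=["a", "b"])
        with pytest.raises(DegenerateDataError, match="one class"):
            select_top_mi(binned, ["same"] * 3, k=1)

    def test_matches_exhaustive_mi_oracle(self):
        # graded label dependence so the top-k boundary is not a float tie
        rng = np.random.default_rng(21)
        labels = rng.choice(["a", "b", "c"], size=120)
        noise = rng.integers(0, 4, size=(120, 180)).astype(float)
        sig_cols = []
        for strength in np.linspace(0.2, 1.0, 20):
            flip = rng.random(120) > strength
            col = np.select([labels == "a", labels == "b"], [0.5, 3.0], 7.0)
            col[flip] = rng.integers(0, 4, size=flip.sum())
            sig_cols.append(col)
        values = np.hstack([noise, np.column_stack(sig_cols)])
        genes = [f"g{i:03d}" for i in range(200)]
        binned = bin_values(values, feature_ids=genes)
        got = set(select_top_mi(binned, labels, k=20))
        mis = [_mi_oracle(binned.codes[:, j], labels) for j in range(200)]
        oracle = set(
            g for _, g in sorted(zip(mis, genes), key=lambda p: (-p[0], p[1]))[:20]
        )
        assert got == oracle
        # and the per-feature MI values agree with the oracle numerically
        for j in rng.choice(200, size=25, replace=False):
            assert mutual_information(binned.codes[:, j], labels) == pytest.approx(
                mis[j], abs=1e-12
            )


class TestCorrelationPruning:
    def test_duplicate_column_dropped_once(self):
        rng = np.random.default_rng(1)
        col = rng.random(20)
        vals = np.column_stack([col, col])
        retained, dropped = prune_correlated(vals, ["first", "second"])
        assert retained == ["first"]
        assert dropped == {"second": "correlated_with:first"}

    def test_anticorrelated_pair_both_retained(self):
        rng = np.random.default_rng(2)
        col = rng.random(20)
        retained, dropped = prune_correlated(np.column_stack([col, -col + 1]), ["a", "b"])
        assert retained == ["a", "b"]  # threshold is on signed r, not |r|

    def test_abs_mode_drops_anticorrelated(self):
        rng = np.random.default_rng(2)
        col = rng.random(20)
        retained, _ = prune_correlated(
            np.column_stack([col, -col + 1]), ["a", "b"], use_abs=True
        )
        assert retained == ["a"]

    def test_zero_variance_dropped(self):
        vals = np.column_stack([np.ones(10), np.arange(10.0)])
        retained, dropped = prune_correlated(vals, ["flat", "ramp"])
        assert retained == ["ramp"]
        assert dropped["flat"] == "zero_variance"

    def test_soundness_on_random_features(self):
        rng = np.random.default_rng(8)
        base = rng.normal(size=(50, 6))
        mix = rng.normal(size=(6, 30))
        vals = base @ mix + 0.15 * rng.normal(size=(50, 30))
        order = [f"f{i:02d}" for i in range(30)]
        retained, dropped = prune_correlated(vals, order, r_max=0.9)
        corr = np.corrcoef(vals, rowvar=False)
        idx = {g: j for j, g in enumerate(order)}
        # exhaustive pairwise oracle: no retained pair above threshold
        for a, b in itertools.combinations(retained, 2):
            assert corr[idx[a], idx[b]] <= 0.9
        # every dropped feature exceeds the threshold with its recorded partner
        for g, reason in dropped.items():
            partner = reason.split(":", 1)[1]
            assert corr[idx[g], idx[partner]] > 0.9
            assert partner in retained


class TestConstantBins:
    def test_constant_column_removed(self):
        binned = bin_values(
            np.array([[7.0, 0.0], [8.0, 3.0]]), feature_ids=["const3", "varies"]
        )
        out, removed = drop_constant_bins(binned)
        assert out.feature_ids == ["varies"] and removed == ["const3"]

    def test_two_bin_column_retained(self):
        binned = bin_values(np.array([[0.0], [7.0]]), feature_ids=["g"])
        out, removed = drop_constant_bins(binned)
        assert out.feature_ids == ["g"]

    def test_pooled_constancy_rule(self):
        # constant in source but varying in target -> retained under pooling
        src = bin_values(np.array([[7.0], [7.0]]), feature_ids=["g"])
        tgt = bin_values(np.array([[0.0], [7.0]]), feature_ids=["g"])
        out, removed = drop_constant_bins(src, pooled_with=tgt)
        assert out.feature_ids == ["g"] and removed == []

    def test_all_constant_error(self):
        binned = bin_values(np.full((3, 2), 7.0), feature_ids=["a", "b"])
        with pytest.raises(DegenerateDataError, match="no informative"):
            drop_constant_bins(binned)


class TestPipeline:
    def test_union_bound_and_monotonicity(self, small_pair):
        source, target, _ = small_pair
        fset, sb, tb = engineer_features(source, target, source.labels, k=50)
        n_mi = sum("mi_selected" in fset.provenance[g] for g in fset.genes)
        union_size = len(fset.genes) + len(fset.dropped)
        assert 50 <= union_size <= 100  # k to 2k before pruning
        # pruning and constant-bin removal only ever shrink the set
        assert len(fset.genes) <= union_size
        assert sb.codes.shape == (source.n_cells, len(fset.genes))
        assert tb.codes.shape == (target.n_cells, len(fset.genes))

    def test_minimal_two_gene_run(self):
        rng = np.random.default_rng(4)
        m = rng.gamma(2.0, 1.0, size=(30, 2))
        labels = ["a"] * 15 + ["b"] * 15
        s = _ds(m, ["g1", "g2"], labels)
        t = _ds(rng.gamma(2.0, 1.0, size=(20, 2)), ["g1", "g2"])
        fset, _, _ = engineer_features(s, t, labels, k=1, min_cells=1)
        assert len(fset.genes) >= 1

    def test_identical_inputs_give_identical_binned(self, small_pair):
        source, _, _ = small_pair
        fset, sb, tb = engineer_features(source, source, source.labels, k=30)
        np.testing.assert_array_equal(sb.codes, tb.codes)

    def test_determinism(self, small_pair):
        source, target, _ = small_pair
        a = engineer_features(source, target, source.labels, k=40)
        b = engineer_features(source, target, source.labels, k=40)
        assert a[0].to_json() == b[0].to_json()
        np.testing.assert_array_equal(a[1].codes, b[1].codes)

    def test_feature_set_json_round_trip(self, small_pair):
        source, target, _ = small_pair
        fset, _, _ = engineer_features(source, target, source.labels, k=30)
        again = FeatureSet.from_json(fset.to_json())
        assert again == fset


@given(st.data())
@settings(max_examples=20, deadline=None)
def test_union_bound_property(data):
    """United mean/MI selection always lands in [k, 2k] genes before pruning."""
    rng = np.random.default_rng(data.draw(st.integers(0, 2**31 - 1)))
    n_genes = data.draw(st.integers(120, 300))
    n_cells = data.draw(st.integers(24, 60))
    k = 50
    genes = [f"g{i:04d}" for i in range(n_genes)]
    labels = list(np.where(rng.random(n_cells) < 0.5, "a", "b"))
    if len(set(labels)) < 2:
        labels[0] = "a"
        labels[1] = "b"
    sm = rng.gamma(1.0, 2.0, size=(n_cells, n_genes)) * (rng.random((n_cells, n_genes)) > 0.3)
    tm = rng.gamma(1.0, 2.0, size=(n_cells, n_genes)) * (rng.random((n_cells, n_genes)) > 0.3)
    s = _ds(sm, genes, labels)
    t = _ds(tm, genes)
    fset, _, _ = engineer_features(s, t, labels, k=k, min_cells=1)
    union_size = len(fset.genes) + len(fset.dropped)
    assert k <= union_size <= 2 * k
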