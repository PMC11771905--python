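"""DEG screening: fold change, moderated/ordinary t, BH, filtering."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from netreg import bh_adjust, filter_degs, gen_expression, log2_fold_change, moderated_t
from netreg.degs import deg_table
from netreg.expression import ExpressionMatrix


def _matrix(ctrl: np.ndarray, case: np.ndarray, genes=None) -> ExpressionMatrix:
    ctrl, case = np.atleast_2d(ctrl), np.atleast_2d(case)
    genes = genes or [f"g{i}" for i in range(ctrl.shape[0])]
    samples = [f"c{j}" for j in range(ctrl.shape[1])] + [f"t{j}" for j in range(case.shape[1])]
    groups = pd.Series(["control"] * ctrl.shape[1] + ["case"] * case.shape[1], index=samples)
    return ExpressionMatrix(
        pd.DataFrame(np.hstack([ctrl, case]), index=genes, columns=samples), groups
    )


class TestLog2FoldChange:
    def test_log_scale_is_difference_of_means(self):
        m = _matrix(np.full((1, 3), 6.0), np.full((1, 3), 8.0))
        assert log2_fold_change(m).iloc[0] == pytest.approx(2.0)

    def test_identical_means_give_zero(self):
        m = _matrix(np.array([[1.0, 2.0, 3.0]]), np.array([[3.0, 2.0, 1.0]]))
        assert log2_fold_change(m).iloc[0] == pytest.approx(0.0)

    def test_linear_scale_equals_log_ratio(self):
        m = _matrix(np.array([[50.0]]), np.array([[200.0]]))
        lfc = log2_fold_change(m, scale="linear", pseudocount=0.0)
        assert lfc.iloc[0] == pytest.approx(np.log2(200 / 50))

    def test_linear_scale_matches_geometric_mean_ratio(self):
        rng = np.random.default_rng(0)
        ctrl = rng.uniform(10, 100, size=(5, 4))
        case = rng.uniform(10, 100, size=(5, 4))
        lfc = log2_fold_change(_matrix(ctrl, case), scale="linear", pseudocount=0.0)
        gm = np.log2(stats.gmean(case, axis=1) / stats.gmean(ctrl, axis=1))
        np.testing.assert_allclose(lfc.to_numpy(), gm, rtol=1e-12)


class TestModeratedT:
    def test_identical_groups_give_t0_p1(self):
        vals = np.array([[5.0, 6.0, 7.0]])
        m = _matrix(np.vstack([vals, [[1, 2, 3]]]), np.vstack([vals, [[4, 5, 6]]]))
        res = moderated_t(m)
        assert res["t"].iloc[0] == 0.0
        assert res["p"].iloc[0] == pytest.approx(1.0)

    def test_ordinary_equals_pooled_t(self):
        rng = np.random.default_rng(1)
        ctrl = rng.normal(5, 1, size=(50, 4))
        case = rng.normal(5.5, 1, size=(50, 5))
        res = moderated_t(_matrix(ctrl, case), test="ordinary")
        t_ref, p_ref = stats.ttest_ind(case, ctrl, axis=1, equal_var=True)
        np.testing.assert_allclose(res["t"].to_numpy(), t_ref, rtol=1e-10)
        np.testing.assert_allclose(res["p"].to_numpy(), p_ref, rtol=1e-10)

    def test_hand_computed_example(self):
        # control (1,2,3), case (4,5,6): pooled s^2 = 1, t = 3/sqrt(2/3) on 4 df
        res = moderated_t(_matrix(np.array([[1.0, 2, 3]]), np.array([[4.0, 5, 6]])), test="ordinary")
        assert res["t"].iloc[0] == pytest.approx(3.0 / np.sqrt(2.0 / 3.0))
        assert res["p"].iloc[0] < 0.05

    def test_moderation_shrinks_extreme_variances(self):
        rng = np.random.default_rng(2)
        ctrl = rng.normal(0, 1, size=(200, 5))
        case = rng.normal(0, 1, size=(200, 5))
        mat = _matrix(ctrl, case)
        mod = moderated_t(mat)
        assert mod.attrs["d0"] > 0
        # the gene with the smallest sample variance has its variance pulled
        # up toward the prior, so its moderated |t| is less extreme than raw
        ordinary = moderated_t(mat, test="ordinary")
        smallest_var = ((ctrl.var(axis=1) + case.var(axis=1))).argmin()
        assert abs(mod["t"].iloc[smallest_var]) <= abs(ordinary["t"].iloc[smallest_var])

    def test_all_zero_variance_errors(self):
        vals = np.ones((3, 3))
        with pytest.raises(ValueError, match="degenerate variance"):
            moderated_t(_matrix(vals, vals * 2))


class TestBHAdjust:
    @pytest.mark.parametrize(
        "p_in, expected",
        [
            ([0.05], [0.05]),
            ([0.01, 0.02, 0.03], [0.03, 0.03, 0.03]),
            ([0.01, 0.04], [0.02, 0.04]),
        ],
    )
    def test_worked_examples(self, p_in, expected):
        np.testing.assert_allclose(bh_adjust(p_in), expected, rtol=1e-12)

    def test_matches_scipy_reference(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(size=200)
        np.testing.assert_allclose(
            bh_adjust(p), stats.false_discovery_control(p, method="bh"), rtol=1e-12
        )

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=50))
    def test_adjusted_at_least_input_and_rank_monotone(self, p):
        p = np.array(p)
        adj = bh_adjust(p)
        assert np.all(adj >= p - 1e-15)
        assert np.all(adj <= 1.0)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-15)

    def test_idempotent_on_constant_ladder(self):
        p = np.full(5, 0.2)
        np.testing.assert_allclose(bh_adjust(bh_adjust(p)), bh_adjust(p))


class TestFilterDegs:
    def test_toy_table_keeps_exactly_first_two(self, toy_deg_records):
        out = filter_degs(toy_deg_records)
        assert list(out.index) == ["A", "B"]
        assert out.attrs["n_up"] == 1
        assert out.attrs["n_down"] == 1

    def test_empty_input(self):
        empty = pd.DataFrame(columns=["log2fc", "p", "padj"])
        out = filter_degs(empty)
        assert len(out) == 0
        assert out.attrs["n_up"] == 0 and out.attrs["n_down"] == 0

    def test_permutation_invariant(self, toy_deg_records):
        shuffled = toy_deg_records.sample(frac=1, random_state=0)
        a = filter_degs(toy_deg_records).sort_index()
        b = filter_degs(shuffled).sort_index()
        pd.testing.assert_frame_equal(a, b)

    def test_threshold_strictness(self):
        # |lfc| >= 1 inclusive, p < 0.05 strict, padj <= 0.05 inclusive
        records = pd.DataFrame(
            {
                "log2fc": [1.0, 1.5, 1.5],
                "p": [0.01, 0.05, 0.01],
                "padj": [0.05, 0.01, 0.0500001],
            },
            index=["at_lfc", "at_p", "over_padj"],
        )
        kept = filter_degs(records)
        assert list(kept.index) == ["at_lfc"]


class TestPlantedRecovery:
    def test_strong_effects_recovered_and_nulls_controlled(self):
        n_null_pass = []
        for seed in (11, 12, 13):
            matrix, truth = gen_expression(
                n_genes=1000, n_per_group=10, n_deg=60, effect_lfc=2.0, seed=seed
            )
            table = deg_table(matrix)
            hits = filter_degs(table)
            planted = set(truth.index[truth["planted"]])
            assert planted <= set(hits.index), "every |lfc|=2 planted gene recovered"
            n_null_pass.append(len(set(hits.index) - planted))
        n_null = 1000 - 60
        assert all(n <= 0.05 * n_null + 5 for n in n_null_pass)

    def test_null_simulation_type_i_control(self):
        matrix, _ = gen_expression(n_genes=800, n_per_group=8, n_deg=0, seed=5)
        hits = filter_degs(deg_table(matrix))
        assert len(hits) <= 0.05 * 800 + 5

    def test_direction_matches_planted_sign(self):
        matrix, truth = gen_expression(n_genes=500, n_per_group=10, n_deg=40, seed=6)
        hits = filter_degs(deg_table(matrix))
        planted = truth[truth["planted"]]
        for gene, row in planted.iterrows():
            assert hits.loc[gene, "direction"] == ("up" if row["true_lfc"] > 0 else "down")

    def test_nan_genes_dropped_with_warning(self, caplog):
        matrix, _ = gen_expression(n_genes=50, n_per_group=5, n_deg=0, seed=8)
        matrix.values.iloc[0, 0] = np.nan
        with caplog.at_level("WARNING", logger="netreg"):
            table = deg_table(matrix)
        assert len(table) == 49
        assert any("dropping" in rec.message for rec in caplog.records)
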