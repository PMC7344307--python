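"""Feature selectors: MI estimator, LASSO, PCA, SWLDA, pair closure."""

import numpy as np
import pytest

import tempocsp as tc
from tempocsp.select import (
    default_lambda_grid,
    lambda_max,
    marginal_pair_selection,
)
from tempocsp.csp import pair_partner

from conftest import random_feature_table
from _oracles import gaussian_mixture_mi_bits, qp_lasso, stepwise_entry_order


class TestMiScore:
    def test_bounded_by_label_entropy(self):
        rng = np.random.default_rng(0)
        labels = np.repeat([1, 2], 100)
        for _ in range(5):
            v = rng.normal(size=200) + (labels == 2) * rng.uniform(0, 4)
            mi = tc.mi_score(v, labels)
            assert 0.0 <= mi <= 1.0

    def test_well_separated_gaussians_near_one_bit(self):
        rng = np.random.default_rng(1)
        labels = np.repeat([1, 2], 200)
        v = np.concatenate([rng.normal(-5, 1, 200), rng.normal(5, 1, 200)])
        truth = gaussian_mixture_mi_bits(-5, 5)
        assert truth == pytest.approx(1.0, abs=1e-3)
        assert tc.mi_score(v, labels) == pytest.approx(truth, abs=0.1)

    def test_independent_feature_near_zero(self):
        labels = np.repeat([1, 2], 200)
        scores = [
            tc.mi_score(np.random.default_rng(seed).normal(size=400), labels)
            for seed in range(10)
        ]
        assert max(scores) < 0.05

    def test_constant_or_single_class_rejected(self):
        labels = np.repeat([1, 2], 10)
        with pytest.raises(ValueError, match="constant"):
            tc.mi_score(np.ones(20), labels)
        with pytest.raises(ValueError, match="two classes"):
            tc.mi_score(np.random.default_rng(0).normal(size=20), np.ones(20))

    def test_symmetric_under_relabeling(self):
        rng = np.random.default_rng(2)
        labels = np.repeat([1, 2], 50)
        v = rng.normal(size=100) + (labels == 2) * 1.5
        assert tc.mi_score(v, labels) == pytest.approx(tc.mi_score(v, 3 - labels), abs=1e-12)


class TestMuin:
    def test_top_pairs_selected(self):
        rng = np.random.default_rng(3)
        table = random_feature_table(rng, signal_cols=(0, 3), shift=3.0)
        res = tc.select_muin(table, k=4)
        assert set(res.selected_columns) >= {0, 3}
        assert len(res.selected_columns) == 4

    def test_segment1_signal_selects_segment1_pair(self):
        """ERD confined to the first window: the discriminative pair comes
        from segment 1 of a real synthetic decomposition."""
        cfg = tc.SynthConfig(
            n_trials_per_class=30,
            erd_specs=(
                tc.ErdSpec(class_label=1, channels=(2,), windows_s=((0.0, 1.5),)),
                tc.ErdSpec(class_label=2, channels=(5,), windows_s=((0.0, 1.5),)),
            ),
            seed=21,
        )
        ts = tc.generate_mi_trialset(cfg)
        segs = tc.decompose_trialset(ts)
        models = [tc.fit_csp(s.signals[s.labels == 1], s.signals[s.labels == 2]) for s in segs]
        table = tc.build_feature_table(models, segs)
        res = tc.select_muin(table, k=4)
        segments_used = {c // 4 + 1 for c in res.selected_columns}
        assert 1 in segments_used

    def test_degenerate_duplicate_columns_deterministic(self):
        rng = np.random.default_rng(4)
        labels = np.repeat([1, 2], 30)
        col = rng.normal(size=60) + (labels == 2) * 1.0
        values = np.tile(col[:, None], (1, 20))
        table = tc.FeatureTable(
            values=values,
            column_provenance=[(j // 4 + 1, j % 4 + 1) for j in range(20)],
            labels=labels,
        )
        a = tc.select_muin(table, k=4)
        b = tc.select_muin(table, k=4)
        assert a.selected_columns == b.selected_columns == [0, 3, 1, 2]


class TestLasso:
    def test_full_shrinkage_bound(self):
        rng = np.random.default_rng(5)
        table = random_feature_table(rng, signal_cols=(2,))
        F, y = table.values, table.labels.astype(float)
        beta, _ = tc.solve_lasso(F, y, lambda_max(F, y) * 1.001)
        assert np.allclose(beta, 0.0)
        # grid therefore starts all-zero and must adjust downward
        grid = default_lambda_grid(F, y)
        beta0, _ = tc.solve_lasso(F, y, grid[0])
        assert np.allclose(beta0, 0.0, atol=1e-8)

    def test_orthonormal_design_soft_threshold(self):
        rng = np.random.default_rng(6)
        raw = rng.normal(size=(50, 20))
        q, _ = np.linalg.qr(raw - raw.mean(axis=0))  # centered orthonormal columns
        y = rng.normal(size=50) + 2.0
        b = q.T @ y
        for lam in np.geomspace(np.abs(2 * b).max() * 0.9, 1e-3, 10):
            beta, _ = tc.solve_lasso(q, y, lam)
            expected = np.sign(b) * np.maximum(np.abs(b) - lam / 2, 0.0)
            assert np.allclose(beta, expected, atol=1e-6)

    def test_zero_penalty_reproduces_least_squares(self):
        rng = np.random.default_rng(7)
        F = rng.normal(size=(40, 10))
        y = rng.normal(size=40)
        beta, b0 = tc.solve_lasso(F, y, 0.0)
        X = np.column_stack([np.ones(40), F])
        ref, *_ = np.linalg.lstsq(X, y, rcond=None)
        assert np.allclose(beta, ref[1:], atol=1e-8)
        assert b0 == pytest.approx(ref[0], abs=1e-8)

    def test_matches_qp_oracle_on_general_design(self):
        rng = np.random.default_rng(8)
        F = rng.normal(size=(40, 8)) @ (np.eye(8) + 0.4 * rng.normal(size=(8, 8)))
        y = F[:, 0] - 0.5 * F[:, 3] + rng.normal(size=40) * 0.5 + 1.5
        for lam in (0.5, 5.0, 20.0):
            mine, _ = tc.solve_lasso(F, y, lam)
            oracle = qp_lasso(F, y, lam)
            assert np.allclose(mine, oracle, atol=1e-6)

    def test_select_returns_pair_closed_k(self):
        rng = np.random.default_rng(9)
        table = random_feature_table(rng, signal_cols=(4, 7), shift=2.5)
        res = tc.lasso_select(table, k=4)
        assert len(res.selected_columns) == 4
        for c in res.selected_columns:
            assert pair_partner(c) in res.selected_columns
        assert res.meta["lambda"] > 0
        assert set(res.selected_columns) >= {4, 7}

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(10)
        table = random_feature_table(rng, signal_cols=(8, 11), shift=2.0)
        res1 = tc.lasso_select(table, k=4)
        flipped = tc.FeatureTable(
            values=table.values, column_provenance=table.column_provenance,
            labels=3 - table.labels,
        )
        res2 = tc.lasso_select(flipped, k=4)
        assert set(res1.selected_columns) == set(res2.selected_columns)


class TestPCA:
    def test_single_variance_axis(self):
        rng = np.random.default_rng(11)
        labels = np.repeat([1, 2], 25)
        values = np.zeros((50, 20))
        values[:, 0] = rng.normal(size=50) * 3
        values += rng.normal(size=(50, 20)) * 1e-6
        table = tc.FeatureTable(
            values=values,
            column_provenance=[(j // 4 + 1, j % 4 + 1) for j in range(20)],
            labels=labels,
        )
        res = tc.pca_transform(table, k=1)
        e1 = np.zeros(20)
        e1[0] = 1.0
        assert np.allclose(np.abs(res.transform[0]), e1, atol=1e-4)

    def test_full_rank_reconstruction(self):
        rng = np.random.default_rng(12)
        table = random_feature_table(rng, n=30, p=8)
        res = tc.pca_transform(table, k=8)
        centered = table.values - res.meta["center"]
        recon = res.apply(table.values) @ res.transform
        assert np.allclose(recon, centered, atol=1e-10)

    def test_captured_variance_matches_eigensolver(self):
        rng = np.random.default_rng(13)
        table = random_feature_table(rng, n=50, p=20)
        res = tc.pca_transform(table, k=4)
        cov = np.cov(table.values, rowvar=False)
        eigs = np.sort(np.linalg.eigvalsh(cov))[::-1]
        assert res.meta["captured_variance"] == pytest.approx(eigs[:4].sum(), rel=1e-10)
        assert np.allclose(res.transform @ res.transform.T, np.eye(4), atol=1e-10)

    def test_k_above_rank_rejected(self):
        rng = np.random.default_rng(14)
        labels = np.repeat([1, 2], 25)
        values = np.tile(rng.normal(size=(50, 1)), (1, 20))
        table = tc.FeatureTable(
            values=values,
            column_provenance=[(j // 4 + 1, j % 4 + 1) for j in range(20)],
            labels=labels,
        )
        with pytest.raises(ValueError, match="rank"):
            tc.pca_transform(table, k=4)


class TestSwlda:
    def test_perfect_predictor_enters_first(self):
        rng = np.random.default_rng(15)
        table = random_feature_table(rng, n=200, p=20)
        table.values[:, 5] = table.labels.astype(float)
        res = tc.swlda_select(table, k=4)
        assert res.meta["trace"][0][0] == "add"
        assert res.meta["trace"][0][1] == 5
        assert 5 in res.selected_columns

    def test_noise_tables_capped_at_k(self):
        for seed in range(5):
            table = random_feature_table(np.random.default_rng(seed), n=100, p=20)
            res = tc.swlda_select(table, k=4)
            assert len(res.selected_columns) in (0, 4)

    def test_entry_order_matches_exhaustive_oracle(self):
        """3-column toy with controlled correlations: the stepwise entry
        sequence equals an independent brute-force enumeration."""
        rng = np.random.default_rng(16)
        n = 120
        z = rng.normal(size=n)
        labels = np.where(z + rng.normal(size=n) * 0.8 > 0, 2, 1)
        y = labels.astype(float)
        F = np.column_stack([
            z + rng.normal(size=n) * 0.5,
            z + rng.normal(size=n) * 1.5,
            rng.normal(size=n),
        ])
        oracle_order = stepwise_entry_order(F, y, p_enter=0.1, p_remove=0.15, k=3)
        table = tc.FeatureTable(
            values=np.column_stack([F, rng.normal(size=(n, 1))]),
            column_provenance=[(1, 1), (1, 2), (1, 3), (1, 4)],
            labels=labels,
        )
        res = tc.swlda_select(table, k=2)
        mine_order = [j for op, j, _ in res.meta["trace"] if op == "add"]
        assert mine_order[: len(oracle_order)] == oracle_order[: len(mine_order)]
        for op, j, p in res.meta["trace"]:
            if op == "add":
                assert p < 0.1

    def test_empty_selection_flagged_and_fallback_works(self):
        labels = np.repeat([1, 2], 50)
        # features totally uninformative and mutually identical -> no entry
        rng = np.random.default_rng(17)
        values = rng.normal(size=(100, 20)) * 1e-12 + rng.normal(size=(100, 1)) * 0
        values += rng.normal(size=(100, 20)) * 1.0
        table = tc.FeatureTable(
            values=values,
            column_provenance=[(j // 4 + 1, j % 4 + 1) for j in range(20)],
            labels=labels,
        )
        res = tc.swlda_select(table, k=4, p_enter=1e-12)
        assert res.meta.get("empty") is True
        fb = marginal_pair_selection(table, k=4)
        assert len(fb.selected_columns) == 4


class TestCommonProperties:
    @pytest.mark.parametrize("selector", [tc.select_muin, tc.lasso_select, tc.swlda_select])
    def test_rerun_equality(self, selector):
        table = random_feature_table(np.random.default_rng(18), signal_cols=(1, 2), shift=2.0)
        a = selector(table, 4)
        b = selector(table, 4)
        assert a.selected_columns == b.selected_columns

    @pytest.mark.parametrize("seed", range(8))
    def test_pair_closure_on_random_tables(self, seed):
        rng = np.random.default_rng(100 + seed)
        table = random_feature_table(rng, signal_cols=tuple(rng.integers(0, 20, size=2)))
        for selector in (tc.select_muin, tc.lasso_select, tc.swlda_select):
            res = selector(table, 4)
            for c in res.selected_columns:
                assert pair_partner(c) in res.selected_columns

    def test_odd_k_rejected(self, feature_table):
        with pytest.raises(ValueError, match="even"):
            tc.select_muin(feature_table, k=3)
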