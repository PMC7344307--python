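"""CSP fitting, log-variance features, and the feature table."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import tempocsp as tc
from tempocsp.csp import pair_partner


def toy_trials(cov: np.ndarray, n_trials: int, n_samples: int, seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    chol = np.linalg.cholesky(cov)
    return np.einsum("ij,njs->nis", chol, rng.normal(size=(n_trials, cov.shape[0], n_samples)))


class TestClassCovariance:
    def test_energy_in_one_channel(self):
        trial = np.array([[1.0, -1.0, 1.0, -1.0], [0.0, 0.0, 0.0, 0.0]])
        cov = tc.class_covariance([trial])
        assert np.allclose(cov, np.diag([1.0, 0.0]))

    def test_unit_trace_and_scale_invariance(self):
        rng = np.random.default_rng(0)
        trials = rng.normal(size=(5, 3, 50))
        cov = tc.class_covariance(trials)
        assert np.trace(cov) == pytest.approx(1.0, abs=1e-12)
        assert np.allclose(tc.class_covariance(10 * trials), cov)

    def test_zero_energy_trial_named(self):
        trials = [np.ones((2, 10)), np.zeros((2, 10))]
        with pytest.raises(ValueError, match="trial 1"):
            tc.class_covariance(trials)


class TestFitCSP:
    def test_identical_covariances_give_half_eigenvalues(self):
        cov = np.diag([2.0, 1.0, 0.5])
        t1 = toy_trials(cov, 30, 500, 1)
        t2 = toy_trials(cov, 30, 500, 2)
        model = tc.fit_csp(t1, t2, m=1)
        assert np.allclose(model.eigenvalues, 0.5, atol=0.03)

    def test_opposite_channel_energy_toy(self):
        """Class 1 energetic on channel A, class 2 on channel B: top filter's
        variance ratio matches a brute-force search over unit vectors."""
        c1 = np.diag([1.0, 0.01])
        c2 = np.diag([0.01, 1.0])
        t1 = toy_trials(c1, 40, 1000, 3)
        t2 = toy_trials(c2, 40, 1000, 4)
        model = tc.fit_csp(t1, t2, m=1)
        cov1 = tc.class_covariance(t1)
        cov2 = tc.class_covariance(t2)
        angles = np.deg2rad(np.arange(0, 180, 0.1))
        ws = np.stack([np.cos(angles), np.sin(angles)])
        ratios = np.einsum("ca,cd,da->a", ws, cov1, ws) / np.einsum(
            "ca,cd,da->a", ws, cov1 + cov2, ws
        )
        w = model.W_2m[:, 0]
        fitted_ratio = w @ cov1 @ w / (w @ (cov1 + cov2) @ w)
        assert fitted_ratio >= ratios.max() - 1e-9
        assert fitted_ratio >= 0.97

    def test_shapes_pairing_and_normalization(self):
        rng = np.random.default_rng(5)
        t1 = rng.normal(size=(20, 10, 300))
        t2 = rng.normal(size=(20, 10, 300)) * 1.5
        model = tc.fit_csp(t1, t2, m=2)
        assert model.W_full.shape == (10, 10)
        assert model.W_2m.shape == (10, 4)
        assert [model.pair_index(j) for j in range(4)] == [3, 2, 1, 0]
        assert np.all(np.diff(model.eigenvalues) <= 1e-12)
        assert model.eigenvalues.min() >= 0 and model.eigenvalues.max() <= 1
        comp = tc.class_covariance(t1) + tc.class_covariance(t2)
        for j in range(4):
            w = model.W_2m[:, j]
            assert w @ comp @ w == pytest.approx(1.0, abs=1e-9)

    def test_class_swap_reverses_order_up_to_sign(self):
        rng = np.random.default_rng(6)
        t1 = rng.normal(size=(15, 4, 200)) * np.array([2, 1, 1, 1])[None, :, None]
        t2 = rng.normal(size=(15, 4, 200)) * np.array([1, 1, 1, 2])[None, :, None]
        a = tc.fit_csp(t1, t2, m=2)
        b = tc.fit_csp(t2, t1, m=2)
        assert np.allclose(a.eigenvalues, 1 - b.eigenvalues[::-1], atol=1e-9)
        # same filter set, reversed columns (signs already canonical)
        assert np.allclose(np.abs(a.W_full), np.abs(b.W_full[:, ::-1]), atol=1e-7)

    def test_scalar_scaling_invariance(self):
        rng = np.random.default_rng(7)
        t1 = rng.normal(size=(10, 3, 100))
        t2 = rng.normal(size=(10, 3, 100))
        a = tc.fit_csp(t1, t2, m=1)
        b = tc.fit_csp(7.5 * t1, 7.5 * t2, m=1)
        assert np.allclose(a.W_full, b.W_full)

    def test_rank_deficiency_detected_and_shrinkage_recovers(self):
        rng = np.random.default_rng(8)
        base = rng.normal(size=(10, 2, 100))
        dup = np.concatenate([base, base[:, :1]], axis=1)  # channel 3 = channel 1
        with pytest.raises(np.linalg.LinAlgError, match="shrinkage"):
            tc.fit_csp(dup, dup * 1.1, m=1)
        model = tc.fit_csp(dup, dup * 1.1, m=1, shrinkage=0.05)
        assert np.all(np.isfinite(model.W_2m))

    def test_deep_erd_low_noise_drives_top_eigenvalue_to_one(self):
        cfg = tc.SynthConfig(
            n_trials_per_class=20,
            noise_sd=1e-3,
            erd_specs=(
                tc.ErdSpec(class_label=1, channels=(2,), depth=0.99, windows_s=((0.0, 6.0),)),
                tc.ErdSpec(class_label=2, channels=(5,), depth=0.99, windows_s=((0.0, 6.0),)),
            ),
            seed=9,
        )
        seg = tc.decompose_trialset(tc.generate_mi_trialset(cfg))[0]
        model = tc.fit_csp(seg.signals[seg.labels == 1], seg.signals[seg.labels == 2])
        assert model.eigenvalues[0] >= 0.95


class TestFeatures:
    def test_identity_filters_give_log_channel_variance(self):
        rng = np.random.default_rng(10)
        e = rng.normal(size=(2, 400)) * np.array([[2.0], [0.5]])
        model = tc.CSPModel(W_full=np.eye(2), W_2m=np.eye(2), eigenvalues=np.array([1.0, 0.0]), m=1)
        f = tc.extract_features(model, e)
        assert np.allclose(f, np.log(e.var(axis=1)))

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.floats(min_value=0.1, max_value=50.0))
    def test_scaling_law(self, a):
        rng = np.random.default_rng(11)
        e = rng.normal(size=(3, 200))
        model = tc.CSPModel(
            W_full=np.eye(3), W_2m=np.eye(3)[:, :2], eigenvalues=np.ones(3), m=1
        )
        base = tc.extract_features(model, e)
        scaled = tc.extract_features(model, a * e)
        assert np.allclose(scaled - base, 2 * np.log(a), atol=1e-9)

    def test_zero_variance_projection_rejected(self):
        model = tc.CSPModel(
            W_full=np.eye(2), W_2m=np.eye(2), eigenvalues=np.ones(2), m=1
        )
        bad = np.vstack([np.random.default_rng(0).normal(size=50), np.zeros(50)])
        with pytest.raises(ValueError, match="filter 1"):
            tc.extract_features(model, bad)

    def test_feature_separation_sign_matches_eigenvalue_order(self):
        c1 = np.diag([1.0, 0.05])
        c2 = np.diag([0.05, 1.0])
        t1 = toy_trials(c1, 30, 500, 12)
        t2 = toy_trials(c2, 30, 500, 13)
        model = tc.fit_csp(t1, t2, m=1)
        f1 = tc.extract_features(model, t1).mean(axis=0)
        f2 = tc.extract_features(model, t2).mean(axis=0)
        # filter 0 (top eigenvalue) favors class-1 variance, filter 1 class-2
        assert f1[0] > f2[0]
        assert f1[1] < f2[1]


class TestFeatureTable:
    def test_shape_and_provenance(self, feature_table, small_ts):
        assert feature_table.values.shape == (small_ts.n_trials, 20)
        # column 7 (1-based) = index 6 -> segment 2, filter 3 in segment-major order
        assert feature_table.column_provenance[6] == (2, 3)
        assert feature_table.column_names()[6] == "s2_f3"

    def test_pairing_involution(self, feature_table):
        for col in range(20):
            p = feature_table.partner(col)
            assert p != col
            assert feature_table.partner(p) == col
            assert p // 4 == col // 4  # same segment
        assert pair_partner(0) == 3 and pair_partner(1) == 2

    def test_row_permutation_equivariance(self, csp_models, segments):
        table = tc.build_feature_table(csp_models, segments)
        perm = np.random.default_rng(2).permutation(table.n_trials)
        permuted = tc.build_feature_table(csp_models, [s.subset(perm) for s in segments])
        assert np.allclose(permuted.values, table.values[perm])

    def test_model_segment_count_mismatch(self, csp_models, segments):
        with pytest.raises(ValueError, match="models"):
            tc.build_feature_table(csp_models[:4], segments)

    def test_csv_roundtrip(self, feature_table, tmp_path):
        import pandas as pd

        path = tmp_path / "table.csv"
        feature_table.to_csv(path)
        df = pd.read_csv(path)
        assert list(df.columns[:2]) == ["label", "s1_f1"]
        assert np.allclose(df.iloc[:, 1:].to_numpy(), feature_table.values)
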