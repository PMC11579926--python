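"""Encoding model: basis, design matrix, evidence-optimized ridge, kernels."""

import numpy as np
import pandas as pd
import pytest

from dalearn import cohort
from dalearn.encoding import (
    KernelSpec,
    build_design_matrix,
    contrast_dependence,
    detect_first_movement,
    fit_ridge_evidence,
    make_basis,
    model_r2,
    reconstruct_kernels,
    ridge_solution,
)
from dalearn.events import stim_label


class TestBasis:
    def test_partition_of_unity_in_interior(self):
        basis = make_basis(8)
        spacing = basis.centers[1] - basis.centers[0]
        interior = slice(int(np.ceil(2 * spacing)),
                         int(np.floor(49 - 2 * spacing)))
        sums = basis.B.sum(axis=1)[interior]
        assert np.allclose(sums, sums[0], atol=1e-9)

    def test_columns_peak_at_their_centers(self):
        basis = make_basis(8)  # integer centers: 0, 7, ..., 49
        for j, c in enumerate(basis.centers):
            assert basis.B[int(c), j] == pytest.approx(1.0, abs=1e-12)
            assert basis.B[:, j].argmax() == int(c)

    def test_nonnegative_and_causal(self):
        basis = make_basis(7)
        assert np.all(basis.B >= 0)
        assert basis.B.shape == (50, 7)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            make_basis(1)
        with pytest.raises(ValueError):
            make_basis(51)


class TestFirstMovement:
    def test_flat_wheel_gives_none(self):
        t = np.arange(0, 5, 0.01)
        assert detect_first_movement(t, np.zeros_like(t), 1.0) is None

    def test_ramp_crossing(self):
        t = np.arange(0, 5, 0.01)
        pos = np.where(t > 2.0, 0.05 * (t - 2.0), 0.0)  # 0.1 rad at t=4
        got = detect_first_movement(t, pos, 1.5)
        assert got == pytest.approx(4.01, abs=0.011)  # first strict crossing

    def test_exact_threshold_not_detected(self):
        t = np.array([0.0, 1.0, 2.0])
        pos = np.array([0.0, 0.1, 0.1])
        assert detect_first_movement(t, pos, 0.0) is None

    def test_quiescent_end_outside_support(self):
        t = np.arange(0, 2, 0.01)
        with pytest.raises(ValueError):
            detect_first_movement(t, np.zeros_like(t), 5.0)


class TestDesignMatrix:
    def test_no_events_gives_intercept_only(self):
        basis = make_basis(5)
        empty = pd.DataFrame({c: [] for c in (
            "session_index", "trial_index", "side", "contrast",
            "quiescent_duration", "stim_onset_time", "first_movement_time",
            "feedback_time", "choice", "correct", "reward_volume")})
        X = build_design_matrix(empty, basis, KernelSpec(kind="stim"), 100)
        assert np.allclose(X[:, 0], 1.0)
        assert np.allclose(X[:, 1:], 0.0)

    def test_single_event_fills_one_block(self):
        basis = make_basis(5)
        tr = pd.DataFrame({
            "session_index": [1], "trial_index": [1], "side": ["left"],
            "contrast": [0.25], "quiescent_duration": [0.5],
            "stim_onset_time": [1.0], "first_movement_time": [np.nan],
            "feedback_time": [np.nan], "choice": [pd.NA], "correct": [pd.NA],
            "reward_volume": [0.0]})
        spec = KernelSpec(kind="stim")
        X = build_design_matrix(tr, basis, spec, 200)
        nz = [j for j in range(1, X.shape[1]) if np.any(X[:, j])]
        assert len(nz) == 5
        block = spec.labels.index(stim_label("left", 0.25))
        assert nz == list(range(1 + block * 5, 1 + (block + 1) * 5))
        s = 50
        assert np.allclose(X[s:s + 50, nz], basis.B)

    def test_full_task_has_40_kernel_blocks(self, simulated_mouse):
        trials, _ = simulated_mouse
        sess = trials[trials["session_index"] == 1]
        spec = KernelSpec()
        assert spec.n_kernels == 40
        basis = make_basis(4)
        n = int((sess["feedback_time"].max() + 2) * 50)
        X = build_design_matrix(sess, basis, spec, n)
        assert X.shape[1] == 1 + 40 * 4
        # stimulus = 4 kernels per side, action = 8 per side
        stim = [l for l in spec.labels if l.startswith("stim")]
        act = [l for l in spec.labels if l.startswith("action")]
        out = [l for l in spec.labels if l.startswith("outcome")]
        assert (len(stim), len(act), len(out)) == (8, 16, 16)
        for side in ("left", "right"):
            assert sum(l.split("_")[1] == side for l in stim) == 4
            assert sum(l.split("_")[1] == side for l in act) == 8

    def test_pre_exposure_design_restricted_to_stimulus(self):
        spec = KernelSpec(kind="stim")
        assert spec.n_kernels == 8
        basis = make_basis(6)
        cohort_spec = cohort.default_cohort_spec(n_mice=1, n_sessions=1,
                                                 trials_per_session=10,
                                                 seed=23)
        trials, trace = cohort.simulate_pre_exposure(cohort_spec, 0)
        X = build_design_matrix(trials, basis, spec, trace.values.size)
        assert X.shape[1] == 1 + 8 * 6


class TestRidge:
    def test_matches_normal_equations_oracle(self, rng):
        n, p = 400, 30
        X = np.column_stack([np.ones(n), rng.normal(size=(n, p - 1))])
        beta_true = rng.normal(size=p)
        f = X @ beta_true + rng.normal(0, 0.5, n)
        fit = fit_ridge_evidence(X, f)
        # brute-force normal equations at the fitted hyperparameters
        P = np.diag([0.0] + [fit.gamma] * (p - 1))
        brute = np.linalg.solve(X.T @ X / fit.sigma_f2 + P,
                                X.T @ f / fit.sigma_f2)
        assert np.allclose(fit.beta, brute, atol=1e-8)

    def test_closed_form_identity_holds_exactly(self, rng):
        n, p = 200, 10
        X = np.column_stack([np.ones(n), rng.normal(size=(n, p - 1))])
        f = rng.normal(size=n)
        fit = fit_ridge_evidence(X, f)
        assert np.allclose(fit.beta, fit.Sigma @ (X.T @ f) / fit.sigma_f2,
                           atol=1e-10)
        assert np.allclose(fit.Sigma, fit.Sigma.T)
        assert np.all(np.linalg.eigvalsh(fit.Sigma) > 0)

    def test_orthonormal_design_closed_form(self, rng):
        """With orthonormal columns and sigma_f^2 = 1 the ridge weight is
        (X'f)_j / (1 + gamma)."""
        n, p = 300, 6
        Q, _ = np.linalg.qr(rng.normal(size=(n, p)))
        f = rng.normal(size=n)
        gamma = 3.7
        beta, _ = ridge_solution(Q, f, gamma, 1.0, penalize_intercept=True)
        assert np.allclose(beta, (Q.T @ f) / (1 + gamma), atol=1e-10)

    def test_infinite_shrinkage_zeroes_weights(self, rng):
        n, p = 100, 5
        X = np.column_stack([np.ones(n), rng.normal(size=(n, p - 1))])
        f = rng.normal(size=n)
        beta, _ = ridge_solution(X, f, 1e12, 1.0)
        assert np.allclose(beta[1:], 0.0, atol=1e-6)

    def test_noiseless_recovery(self, rng):
        n, p = 500, 20
        X = np.column_stack([np.ones(n), rng.normal(size=(n, p - 1))])
        beta_true = rng.normal(size=p)
        f = X @ beta_true
        fit = fit_ridge_evidence(X, f)
        assert np.allclose(fit.beta, beta_true, atol=1e-3)
        assert fit.gamma < 1e-2 or fit.sigma_f2 < 1e-6

    def test_evidence_is_local_maximum_in_gamma(self, rng):
        from dalearn.encoding import _evidence_terms

        n, p = 300, 15
        X = np.column_stack([np.ones(n), rng.normal(size=(n, p - 1))])
        f = X @ rng.normal(size=p) * 0.3 + rng.normal(0, 1.0, n)
        fit = fit_ridge_evidence(X, f)
        Xc = X[:, 1:] - X[:, 1:].mean(axis=0)
        fc = f - f.mean()
        eig, Q = np.linalg.eigh(Xc.T @ Xc)
        proj2 = (Q.T @ (Xc.T @ fc)) ** 2
        ev = lambda g: _evidence_terms(np.maximum(eig, 0), proj2,
                                       float(fc @ fc), n, g, fit.sigma_f2)
        e0 = ev(fit.gamma)
        assert ev(fit.gamma * 1.1) <= e0 + 1e-9
        assert ev(fit.gamma * 0.9) <= e0 + 1e-9

    def test_degenerate_inputs_rejected(self, rng):
        X = np.ones((10, 20))
        with pytest.raises(ValueError):
            fit_ridge_evidence(X, rng.normal(size=10))
        X2 = np.column_stack([np.ones(50), rng.normal(size=(50, 3))])
        f = rng.normal(size=50)
        f[3] = np.nan
        with pytest.raises(ValueError):
            fit_ridge_evidence(X2, f)


class TestKernelReconstruction:
    def test_zero_weights_give_zero_kernels(self):
        basis = make_basis(5)
        spec = KernelSpec(kind="stim")
        from dalearn.encoding import RidgeFit

        p = 1 + 8 * 5
        fit = RidgeFit(beta=np.zeros(p), gamma=1.0, sigma_f2=1.0,
                       log_evidence=0.0, Sigma=np.eye(p), n_samples=100)
        ks = reconstruct_kernels(fit, basis, spec)
        assert all(np.allclose(k, 0) for k in ks.kernels.values())
        assert all(v == 0 for v in ks.l2.values())

    def test_unit_bump_l2_equals_column_norm(self):
        basis = make_basis(5)
        spec = KernelSpec(kind="stim")
        from dalearn.encoding import RidgeFit

        p = 1 + 8 * 5
        beta = np.zeros(p)
        beta[1] = 1.0  # first basis bump of the first kernel
        fit = RidgeFit(beta=beta, gamma=1.0, sigma_f2=1.0, log_evidence=0.0,
                       Sigma=np.eye(p), n_samples=100)
        ks = reconstruct_kernels(fit, basis, spec)
        lab = spec.labels[0]
        assert ks.l2[lab] == pytest.approx(np.linalg.norm(basis.B[:, 0]))


class TestContrastDependence:
    def _kernel_set(self, k_hi, k_lo):
        from dalearn.encoding import KernelSet

        kernels = {stim_label("right", 1.0): k_hi,
                   stim_label("right", 0.0625): k_lo}
        return KernelSet(kernels=kernels,
                         l2={k: float(np.linalg.norm(v))
                             for k, v in kernels.items()})

    def test_identical_kernels_give_zero(self):
        k = np.ones(50) / np.sqrt(50)
        assert contrast_dependence(self._kernel_set(k, k), "right") == 0.0

    def test_hand_computed_metrics(self):
        k_lo = np.zeros(50)
        k_lo[0] = 1.0  # unit norm
        k_hi = 2.0 * k_lo
        ks = self._kernel_set(k_hi, k_lo)
        assert contrast_dependence(ks, "right") == pytest.approx(1.0)
        assert contrast_dependence(ks, "right", metric="norm-of-diff") \
            == pytest.approx(1.0)

    def test_sign_flips_when_low_contrast_stronger(self):
        k_lo = np.zeros(50)
        k_lo[0] = 2.0
        k_hi = 0.5 * k_lo
        assert contrast_dependence(self._kernel_set(k_hi, k_lo), "right") < 0

    def test_missing_kernel_errors(self):
        ks = self._kernel_set(np.ones(50), np.ones(50))
        with pytest.raises(ValueError):
            contrast_dependence(ks, "left")


class TestModelR2:
    def _setup(self, rng):
        n = 2000
        X = np.column_stack([np.ones(n), rng.normal(size=(n, 3))])
        beta = np.array([0.1, 1.0, -0.5, 0.3])
        f = X @ beta
        trials = pd.DataFrame({
            "stim_onset_time": [1.0, 10.0], "feedback_time": [3.0, 12.0]})
        return X, beta, f, trials

    def test_perfect_prediction_gives_one(self, rng):
        from dalearn.encoding import RidgeFit

        X, beta, f, trials = self._setup(rng)
        fit = RidgeFit(beta=beta, gamma=1, sigma_f2=1, log_evidence=0,
                       Sigma=np.eye(4), n_samples=len(f))
        assert model_r2(fit, X, f, trials) == pytest.approx(1.0)

    def test_mean_prediction_gives_zero(self, rng):
        from dalearn.encoding import RidgeFit

        X, beta, f, trials = self._setup(rng)
        mask = np.zeros(len(f), bool)
        for s, e in ((50, 200), (500, 650)):
            mask[s:e] = True
        const = np.zeros(4)
        const[0] = f[mask].mean()
        fit = RidgeFit(beta=const, gamma=1, sigma_f2=1, log_evidence=0,
                       Sigma=np.eye(4), n_samples=len(f))
        got = model_r2(fit, np.column_stack([np.ones(len(f)),
                                             np.zeros((len(f), 3))]),
                       f, trials)
        assert got == pytest.approx(0.0, abs=1e-12)
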