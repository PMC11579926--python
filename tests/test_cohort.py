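"""Synthetic-cohort generator: task statistics, determinism, ground truth."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dalearn import cohort
from dalearn.behavior.fit import predict_psychometric


class TestSimulateTrials:
    def test_deterministic_under_fixed_seed(self, small_spec):
        a = cohort.simulate_trials(small_spec, 0, 1)
        b = cohort.simulate_trials(small_spec, 0, 1)
        pd.testing.assert_frame_equal(a, b)

    def test_different_sessions_differ(self, small_spec):
        a = cohort.simulate_trials(small_spec, 0, 0)
        b = cohort.simulate_trials(small_spec, 0, 1)
        assert not a["side"].equals(b["side"])

    def test_quiescent_durations_within_truncation_bounds(self):
        spec = cohort.CohortSpec(n_mice=1, n_sessions=1,
                                 trials_per_session=400, seed=3)
        tr = cohort.simulate_trials(spec, 0, 0)
        q = tr["quiescent_duration"]
        assert q.between(0.4, 0.7).all()

    def test_timestamps_strictly_ordered_within_trial(self, small_spec):
        tr = cohort.simulate_trials(small_spec, 0, 0)
        assert (tr["stim_onset_time"] < tr["first_movement_time"]).all()
        assert (tr["first_movement_time"] < tr["feedback_time"]).all()
        assert tr["stim_onset_time"].is_monotonic_increasing

    def test_side_frequency_matches_fair_coin(self):
        spec = cohort.CohortSpec(n_mice=1, n_sessions=1,
                                 trials_per_session=10_000, seed=5)
        tr = cohort.simulate_trials(spec, 0, 0)
        f = (tr["side"] == "right").mean()
        sd = 0.5 / np.sqrt(len(tr))
        assert abs(f - 0.5) < 3 * sd

    def test_rejects_bad_contrast_set(self):
        with pytest.raises(ValueError):
            cohort.CohortSpec(contrast_set=())
        with pytest.raises(ValueError):
            cohort.CohortSpec(contrast_set=(0.5, 1.5))
        with pytest.raises(ValueError):
            cohort.CohortSpec(contrast_set=(0.25, 0.5))  # no 100%


class TestQuiescentSampler:
    def test_empirical_cdf_matches_truncated_exponential(self, rng):
        draws = cohort.sample_quiescent(rng, 100_000)
        lo, hi, mean = 0.4, 0.7, 0.55
        dist = stats.truncexpon(b=(hi - lo) / mean, loc=lo, scale=mean)
        ks = stats.kstest(draws, dist.cdf)
        assert ks.pvalue > 0.01


class TestWeightTrajectories:
    def test_zero_learning_rates_give_flat_curves(self):
        p = cohort.MouseLearningParams(bias_init=0.7, bias_decay=0.0,
                                       rate_right=0.0, rate_left=0.0,
                                       history_weight=0.4)
        spec = cohort.CohortSpec(n_mice=1, n_sessions=5,
                                 learning_params=(p,), seed=0)
        w = cohort.make_weight_trajectories(spec, 0)
        assert np.allclose(w[:, 0], 0.7)
        assert np.allclose(w[:, 1], 0.0)
        assert np.allclose(w[:, 3], 0.4)

    def test_asymmetric_rates_order_final_weights(self):
        p = cohort.MouseLearningParams(rate_right=0.5, rate_left=0.05,
                                       asym_right=4.0, asym_left=4.0)
        spec = cohort.CohortSpec(n_mice=1, n_sessions=10,
                                 learning_params=(p,), seed=0)
        w = cohort.make_weight_trajectories(spec, 0)
        assert w[-1, 1] > w[-1, 2]

    def test_matches_closed_form(self):
        p = cohort.MouseLearningParams(rate_right=0.2, asym_right=3.0)
        spec = cohort.CohortSpec(n_mice=1, n_sessions=8,
                                 learning_params=(p,), seed=0)
        w = cohort.make_weight_trajectories(spec, 0)
        d = 5
        assert w[d - 1, 1] == pytest.approx(3.0 * (1 - np.exp(-0.2 * d)))


class TestSimulateChoices:
    def test_zero_weights_give_even_split(self, small_spec):
        spec = cohort.CohortSpec(n_mice=1, n_sessions=1,
                                 trials_per_session=6000, seed=9)
        tr = cohort.simulate_trials(spec, 0, 0)
        w = np.zeros((1, 4))
        out = cohort.simulate_choices(tr, w, 2.5, 0.5, seed=1)
        f = (out["choice"] == "right").mean()
        assert abs(f - 0.5) < 3 * 0.5 / np.sqrt(len(out))

    def test_huge_right_weight_saturates(self):
        spec = cohort.CohortSpec(n_mice=1, n_sessions=1,
                                 trials_per_session=300, seed=2)
        tr = cohort.simulate_trials(spec, 0, 0)
        w = np.array([[0.0, 10.0, 0.0, 0.0]])
        out = cohort.simulate_choices(tr, w, 2.5, 0.5, seed=4)
        right_full = out[(out["side"] == "right") & (out["contrast"] == 1.0)]
        assert (right_full["choice"] == "right").mean() > 0.95

    def test_correct_iff_choice_equals_side(self, simulated_mouse):
        trials, _ = simulated_mouse
        assert (trials["correct"]
                == (trials["choice"] == trials["side"])).all()
        assert np.allclose(trials["reward_volume"],
                           np.where(trials["correct"], 3.0, 0.0))

    def test_missing_session_weights_rejected(self, small_spec):
        tr = cohort.simulate_trials(small_spec, 0, 2)  # session_index 3
        with pytest.raises(ValueError, match="session"):
            cohort.simulate_choices(tr, np.zeros((2, 4)), 2.5, 0.5, seed=0)

    def test_psychometric_curve_matches_model_prediction(self):
        """Empirical choice rates from many simulated trials agree with the
        model's psychometric prediction within Monte-Carlo error."""
        beta = np.array([[0.3, 2.0, 1.5, 0.0]])  # no history coupling
        spec = cohort.CohortSpec(n_mice=1, n_sessions=1,
                                 trials_per_session=5000, seed=21)
        tr = cohort.simulate_trials(spec, 0, 0)
        out = cohort.simulate_choices(tr, beta, 2.5, 0.5, seed=8)
        for side in ("left", "right"):
            for c in spec.contrast_set:
                sub = out[(out["side"] == side) & (out["contrast"] == c)]
                signed = c if side == "right" else -c
                p = predict_psychometric(beta[0], 2.5, np.array([signed]))[0]
                n = len(sub)
                emp = (sub["choice"] == "right").mean()
                assert abs(emp - p) < 4 * np.sqrt(p * (1 - p) / n)


class TestSimulatePhotometry:
    def _single_event_trials(self, t=2.0):
        return pd.DataFrame({
            "session_index": [1], "trial_index": [1], "side": ["right"],
            "contrast": [1.0], "quiescent_duration": [0.5],
            "stim_onset_time": [t], "first_movement_time": [np.nan],
            "feedback_time": [np.nan], "choice": [pd.NA], "correct": [pd.NA],
            "reward_volume": [0.0]})

    def test_single_event_places_kernel_exactly(self, small_spec):
        k = cohort.make_ground_truth_kernels(small_spec, 0, "DMS",
                                             kind="stim")
        tr = self._single_event_trials()
        trace = cohort.simulate_photometry(tr, k, noise_sd=0.0,
                                           drift_spec=None, kind="stim")
        s = int(round(2.0 * 50))
        lab = "stim_right_100"
        assert np.allclose(trace.values[s:s + 50], k.kernels[lab])
        assert np.allclose(np.delete(trace.values,
                                     np.arange(s, s + 50)), 0.0)

    def test_overlapping_events_superpose(self, small_spec):
        k = cohort.make_ground_truth_kernels(small_spec, 0, "DMS",
                                             kind="stim")
        tr = pd.concat([self._single_event_trials(2.0),
                        self._single_event_trials(2.3)], ignore_index=True)
        tr["trial_index"] = [1, 2]
        trace = cohort.simulate_photometry(tr, k, noise_sd=0.0,
                                           drift_spec=None, kind="stim")
        one = cohort.simulate_photometry(self._single_event_trials(2.0), k,
                                         noise_sd=0.0, drift_spec=None,
                                         kind="stim")
        two = cohort.simulate_photometry(self._single_event_trials(2.3), k,
                                         noise_sd=0.0, drift_spec=None,
                                         kind="stim")
        n = trace.values.size
        pad = lambda v: np.pad(v, (0, n - v.size)) if v.size < n else v[:n]
        assert np.allclose(trace.values, pad(one.values) + pad(two.values))

    def test_noise_variance_in_event_free_segment(self, small_spec):
        k = cohort.make_ground_truth_kernels(small_spec, 0, "DMS",
                                             kind="stim")
        tr = self._single_event_trials(40.0)
        trace = cohort.simulate_photometry(tr, k, noise_sd=1.0,
                                           drift_spec=None, kind="stim",
                                           seed=3)
        free = trace.values[:int(39 * 50)]
        assert np.var(free) == pytest.approx(1.0, rel=0.1)

    def test_contra_stimulus_gain_monotone_in_contrast(self, small_spec):
        from dalearn.events import stim_label

        k = cohort.make_ground_truth_kernels(small_spec, 0, "DMS")
        contra = ("right" if small_spec.hemisphere_per_region["DMS"] == "left"
                  else "left")
        peaks = [k.kernels[stim_label(contra, c)].max()
                 for c in small_spec.contrast_set]
        assert all(np.diff(peaks) > 0)


class TestPreExposure:
    def test_condition_set_and_trial_count(self):
        spec = cohort.default_cohort_spec(n_mice=1, n_sessions=1,
                                          trials_per_session=10, seed=17)
        trials, trace = cohort.simulate_pre_exposure(spec, 0)
        conds = set(zip(trials["side"], trials["contrast"]))
        assert len(conds) == 8
        assert 250 <= len(trials) <= 272
        assert np.allclose(np.diff(trials["stim_onset_time"]), 10.0)
        assert trials["choice"].isna().all()
        assert (trials["reward_volume"] == 0).all()
        assert trace.values.size > 0
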