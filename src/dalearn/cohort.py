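"""Synthetic cohorts: simulated mice with known learning trajectories.

Emulates the statistical structure of a visual two-alternative forced-choice
wheel task: uniformly random stimulus side and contrast, truncated-
exponential quiescent periods, reward for moving the grating to center.
Choices are drawn from the same generative model the behavioral fit assumes
(session-evolving weights, tanh contrast transform, exponentially filtered
choice history), and photometry is a sum of event-triggered kernels plus
white noise and slow baseline drift — so every downstream stage can be
tested against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .events import DEFAULT_CONTRASTS, SIDES, extract_events, kernel_labels
from .behavior.design import transform_contrast
from .photometry import PhotometryTrace

__all__ = [
    "MouseLearningParams",
    "reference_mouse_params",
    "TASK_CONTRASTS_5",
    "DriftSpec",
    "CohortSpec",
    "GroundTruthKernels",
    "default_cohort_spec",
    "simulate_trials",
    "make_weight_trajectories",
    "simulate_choices",
    "make_ground_truth_kernels",
    "simulate_photometry",
    "simulate_pre_exposure",
    "sample_quiescent",
]

REGIONS = ("DMS", "DLS", "NAc")
REWARD_UL = 3.0  # reward volume per correct trial, microliters
KERNEL_N_LAGS = 50  # 1 s at 50 Hz
FS = 50.0


@dataclass(frozen=True)
class MouseLearningParams:
    """Ground-truth learning-curve parameters for one simulated mouse.

    Stimulus weights follow saturating-exponential growth
    ``A * (1 - exp(-rate * d))`` per side across sessions ``d``; the bias
    decays exponentially from its initial level; the choice-history weight is
    constant.
    """

    bias_init: float = 0.0
    bias_decay: float = 0.15  # per-session decay rate of the bias
    rate_right: float = 0.15
    rate_left: float = 0.15
    asym_right: float = 4.0
    asym_left: float = 4.0
    history_weight: float = 0.5


def reference_mouse_params() -> MouseLearningParams:
    """Learning-curve parameters of the reference simulated mouse.

    Calibrated to the psychometric performance of a well-trained animal in
    this task: with contrast-transform shape ``alpha = 2.5`` the late
    stimulus weights (~5) give ~99% accuracy at full contrast and ~65-70%
    at 6.25% contrast.  The choice-history weight (1.2) reflects the strong
    perseveration of mice in unshaped training; it also makes the history
    time constant sharply identified, as the very small between-animal
    spread of fitted time constants in real cohorts implies it must be.
    Used by recovery experiments.
    """
    return MouseLearningParams(bias_init=1.0, bias_decay=0.15,
                               rate_right=0.18, rate_left=0.14,
                               asym_right=5.0, asym_left=4.6,
                               history_weight=1.2)


# the five contrast levels of the training task; the encoding model's
# default set drops 50% (one kernel per contrast per side)
TASK_CONTRASTS_5 = (0.0625, 0.125, 0.25, 0.5, 1.0)


@dataclass(frozen=True)
class DriftSpec:
    """Slow baseline drift: a sum of low-frequency sinusoids, random phase."""

    amplitude: float = 0.5
    n_components: int = 3
    freq_lo: float = 0.001  # Hz
    freq_hi: float = 0.01


@dataclass(frozen=True)
class CohortSpec:
    n_mice: int = 2
    n_sessions: int = 20
    trials_per_session: int = 300
    contrast_set: tuple = DEFAULT_CONTRASTS
    hemisphere_per_region: dict = field(
        default_factory=lambda: {"DMS": "left", "DLS": "right", "NAc": "right"})
    learning_params: tuple = ()  # one MouseLearningParams per mouse
    alpha_true: float = 2.5
    pi_true: float = 0.52
    kernel_gains: tuple = ()  # per mouse: dict region -> gain
    noise_sd: float = 0.02
    drift: DriftSpec = DriftSpec()
    seed: int = 0

    def __post_init__(self):
        if min(self.n_mice, self.n_sessions, self.trials_per_session) < 1:
            raise ValueError("all counts must be >= 1")
        cs = tuple(self.contrast_set)
        if not cs or any(not (0.0 < c <= 1.0) for c in cs):
            raise ValueError("contrast_set values must lie in (0, 1]")
        if list(cs) != sorted(cs):
            raise ValueError("contrast_set must be sorted ascending")
        if cs[-1] != 1.0:
            raise ValueError("contrast_set must include full (100%) contrast")
        if not 0.0 < self.pi_true < 1.0:
            raise ValueError("pi_true must be in (0, 1)")
        if self.alpha_true <= 0:
            raise ValueError("alpha_true must be positive")
        if self.learning_params and len(self.learning_params) != self.n_mice:
            raise ValueError("need learning_params for every mouse")
        if self.kernel_gains and len(self.kernel_gains) != self.n_mice:
            raise ValueError("need kernel_gains for every mouse")

    def params_for(self, mouse: int) -> MouseLearningParams:
        if self.learning_params:
            return self.learning_params[mouse]
        return MouseLearningParams()

    def gains_for(self, mouse: int) -> dict:
        if self.kernel_gains:
            return self.kernel_gains[mouse]
        return {r: 1.0 for r in REGIONS}


def default_cohort_spec(n_mice: int = 6, n_sessions: int = 20,
                        trials_per_session: int = 300,
                        seed: int = 0, **overrides) -> CohortSpec:
    """A heterogeneous cohort: mice with weak, left or right initial bias.

    Initial-bias levels and side-specific learning rates vary across mice so
    that early bias predicts late stimulus-weight asymmetry, mirroring the
    diversity of real learning trajectories.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 9001]))
    params, gains = [], []
    bias_kinds = ["weak", "left", "right"]
    for m in range(n_mice):
        kind = bias_kinds[m % 3]
        b0 = {"weak": 0.0, "left": -1.2, "right": 1.2}[kind]
        b0 += rng.normal(0, 0.2)
        # a biased mouse learns the favored side faster (constructed coupling)
        tilt = 0.4 * np.tanh(b0)
        params.append(MouseLearningParams(
            bias_init=b0,
            bias_decay=rng.uniform(0.08, 0.2),
            rate_right=max(0.03, 0.15 + 0.05 * tilt + rng.normal(0, 0.02)),
            rate_left=max(0.03, 0.15 - 0.05 * tilt + rng.normal(0, 0.02)),
            asym_right=max(0.5, 4.0 + tilt + rng.normal(0, 0.3)),
            asym_left=max(0.5, 4.0 - tilt + rng.normal(0, 0.3)),
            history_weight=rng.uniform(0.3, 0.7),
        ))
        gains.append({r: float(rng.uniform(0.5, 1.5)) for r in REGIONS})
    return CohortSpec(n_mice=n_mice, n_sessions=n_sessions,
                      trials_per_session=trials_per_session,
                      learning_params=tuple(params), kernel_gains=tuple(gains),
                      seed=seed, **overrides)


def _rng(spec: CohortSpec, *keys: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([spec.seed, *keys]))


def sample_quiescent(rng: np.random.Generator, n: int, mean: float = 0.55,
                     lo: float = 0.4, hi: float = 0.7) -> np.ndarray:
    """Quiescent-period durations: exponential(mean) truncated to [lo, hi].

    Sampled by rejection from the parent exponential, matching the task's
    generative rule.
    """
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.exponential(mean, size=2 * (n - filled) + 8)
        keep = draw[(draw >= lo) & (draw <= hi)]
        take = min(keep.size, n - filled)
        out[filled:filled + take] = keep[:take]
        filled += take
    return out


# timing layout constants (seconds); the task specifies the quiescent rule,
# movement/feedback latencies here are simulator conventions
ITI_S = 0.5
MOVE_LO_S, MOVE_HI_S = 0.2, 0.8
FEEDBACK_LAG_S = 0.1
POST_FEEDBACK_S = 1.5


def simulate_trials(spec: CohortSpec, mouse: int, session: int) -> pd.DataFrame:
    """One session's trial stream, with choices/outcomes left unfilled.

    Sides are uniform over left/right, contrasts uniform over the spec's
    contrast set, quiescent durations truncated-exponential.  The RNG is
    derived deterministically from (seed, mouse, session).
    """
    rng = _rng(spec, 1, mouse, session)
    n = spec.trials_per_session
    side = np.asarray(SIDES)[rng.integers(0, 2, size=n)]
    contrast = rng.choice(np.asarray(spec.contrast_set, dtype=float), size=n)
    quiescent = sample_quiescent(rng, n)
    move_lat = rng.uniform(MOVE_LO_S, MOVE_HI_S, size=n)

    stim, move, feedback = np.empty(n), np.empty(n), np.empty(n)
    t = 0.0
    for i in range(n):
        stim[i] = t + ITI_S + quiescent[i]
        move[i] = stim[i] + move_lat[i]
        feedback[i] = move[i] + FEEDBACK_LAG_S
        t = feedback[i] + POST_FEEDBACK_S
    return pd.DataFrame({
        "session_index": session + 1,
        "trial_index": np.arange(1, n + 1),
        "side": side,
        "contrast": contrast,
        "quiescent_duration": quiescent,
        "stim_onset_time": stim,
        "first_movement_time": move,
        "feedback_time": feedback,
        "choice": pd.Series([pd.NA] * n, dtype="object"),
        "correct": pd.Series([pd.NA] * n, dtype="object"),
        "reward_volume": np.nan,
    })


def make_weight_trajectories(spec: CohortSpec, mouse: int) -> np.ndarray:
    """Ground-truth per-session weights, shape (n_sessions, 4).

    Columns: bias, right-stim, left-stim, history.  Deterministic closed
    form: saturating-exponential stimulus weights, exponentially decaying
    bias, constant history weight.
    """
    p = spec.params_for(mouse)
    d = np.arange(1, spec.n_sessions + 1, dtype=float)
    bias = p.bias_init * np.exp(-p.bias_decay * (d - 1))
    right = p.asym_right * (1.0 - np.exp(-p.rate_right * d))
    left = p.asym_left * (1.0 - np.exp(-p.rate_left * d))
    hist = np.full_like(d, p.history_weight)
    return np.column_stack([bias, right, left, hist])


def simulate_choices(trials: pd.DataFrame, weights: np.ndarray,
                     alpha_true: float, pi_true: float,
                     seed) -> pd.DataFrame:
    """Draw choices from the generative model and fill outcomes.

    ``weights`` is the (n_sessions, 4) ground-truth trajectory; each trial's
    p(right) is the logistic of ``[1, x_R, -x_L, c_t] . beta_d`` exactly as
    the behavioral model defines it.  ``correct`` iff choice equals the
    stimulus side; correct trials earn a 3 ul reward.
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    out = trials.copy()
    weights = np.atleast_2d(weights)
    sessions = out["session_index"].to_numpy()
    if sessions.max() > weights.shape[0]:
        raise ValueError("trials reference a session without weights")
    choices = np.empty(len(out), dtype=object)
    correct = np.empty(len(out), dtype=bool)
    pos = 0
    for sidx, grp in out.groupby("session_index", sort=True):
        beta = weights[int(sidx) - 1]
        side = grp["side"].to_numpy()
        xs = transform_contrast(grp["contrast"].to_numpy(dtype=float),
                                alpha_true)
        u = rng.uniform(size=len(grp))
        c = 0.0
        for i in range(len(grp)):
            x_r = xs[i] if side[i] == "right" else 0.0
            x_l = xs[i] if side[i] == "left" else 0.0
            p_right = expit(beta[0] + beta[1] * x_r - beta[2] * x_l
                            + beta[3] * c)
            y = u[i] < p_right
            choices[pos] = "right" if y else "left"
            correct[pos] = (choices[pos] == side[i])
            c = c + pi_true * ((1.0 if y else -1.0) - c)
            pos += 1
    out["choice"] = choices
    out["correct"] = correct
    out["reward_volume"] = np.where(correct, REWARD_UL, 0.0)
    return out


@dataclass
class GroundTruthKernels:
    """Per-event-label 1 s (50-sample) kernels used to synthesize photometry."""

    kernels: dict  # label -> (KERNEL_N_LAGS,) array
    fs: float = FS

    def __post_init__(self):
        for lab, k in self.kernels.items():
            if len(k) != KERNEL_N_LAGS:
                raise ValueError(f"kernel {lab} must have {KERNEL_N_LAGS} samples")


def _bump(peak_time_s: float = 0.2, fs: float = FS,
          n: int = KERNEL_N_LAGS) -> np.ndarray:
    """Smooth causal bump (gamma-like), unit peak amplitude."""
    t = np.arange(n) / fs
    tau = peak_time_s / 2.0
    k = (t / tau) ** 2 * np.exp(-t / tau)
    return k / k.max()


def make_ground_truth_kernels(spec: CohortSpec, mouse: int, region: str,
                              kind: str = "full") -> GroundTruthKernels:
    """Ground-truth kernel set for one mouse/region.

    Contralateral stimulus kernels scale monotonically with contrast
    (gain proportional to ``0.3 + 0.7 * contrast``); ipsilateral stimulus
    responses are weaker and contrast-flat.  Action and outcome kernels are
    modest fixed-shape bumps so the full-task signal is realistic but the
    stimulus contrast gradient stays the recoverable feature of interest.
    """
    hemi = spec.hemisphere_per_region.get(region)
    if hemi not in SIDES:
        raise ValueError(f"unknown hemisphere for region {region!r}")
    contra = "right" if hemi == "left" else "left"
    gain = spec.gains_for(mouse).get(region, 1.0)
    shape_stim = _bump(0.2)
    shape_action = _bump(0.3)
    shape_outcome = _bump(0.25)
    kernels = {}
    for lab in kernel_labels(spec.contrast_set, kind=kind):
        parts = lab.split("_")
        if parts[0] == "stim":
            side, pct = parts[1], float(parts[2]) / 100.0
            if side == contra:
                kernels[lab] = gain * (0.3 + 0.7 * pct) * shape_stim
            else:
                kernels[lab] = 0.3 * gain * shape_stim
        elif parts[0] == "action":
            kernels[lab] = 0.4 * gain * shape_action
        else:  # outcome
            amp = 0.8 if parts[3] == "reward" else -0.3
            kernels[lab] = amp * gain * shape_outcome
    return GroundTruthKernels(kernels=kernels, fs=FS)


def _drift(n: int, fs: float, drift: DriftSpec | None,
           rng: np.random.Generator) -> np.ndarray:
    if drift is None or drift.amplitude == 0:
        return np.zeros(n)
    t = np.arange(n) / fs
    out = np.zeros(n)
    for _ in range(drift.n_components):
        f = rng.uniform(drift.freq_lo, drift.freq_hi)
        phase = rng.uniform(0, 2 * np.pi)
        out += np.sin(2 * np.pi * f * t + phase)
    return drift.amplitude / drift.n_components * out


def simulate_photometry(trials: pd.DataFrame, kernels: GroundTruthKernels,
                        noise_sd: float = 0.02,
                        drift_spec: DriftSpec | None = None,
                        fs: float = FS, seed=0, kind: str = "full",
                        region: str = "", hemisphere: str = "",
                        baseline: float = 0.0) -> PhotometryTrace:
    """Event-kernel superposition plus white noise and slow drift.

    The trace covers the session (last event + 1 s margin).  With
    ``baseline > 0`` the output is a raw-stage fluorescence trace
    ``baseline * (1 + signal)``; otherwise the dF/F-scale signal itself is
    returned (stage ``dff``).
    """
    if fs != kernels.fs:
        raise ValueError("sampling rate must match the kernel sampling rate")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    events = extract_events(trials, kind=kind)
    t_end = max(t for t, _ in events) + 1.0 + KERNEL_N_LAGS / fs
    n = int(np.ceil(t_end * fs))
    signal = np.zeros(n)
    for t_ev, lab in events:
        s = int(round(t_ev * fs))
        if s >= n:
            raise ValueError(f"event at {t_ev:.3f}s beyond trace horizon")
        k = kernels.kernels[lab]
        stop = min(s + KERNEL_N_LAGS, n)
        signal[s:stop] += k[:stop - s]
    signal = signal + rng.normal(0.0, noise_sd, size=n) \
        + _drift(n, fs, drift_spec, rng)
    time = np.arange(n) / fs
    if baseline > 0:
        return PhotometryTrace(time=time, values=baseline * (1.0 + signal),
                               stage="raw", fs=fs, region=region,
                               hemisphere=hemisphere)
    return PhotometryTrace(time=time, values=signal, stage="dff", fs=fs,
                           region=region, hemisphere=hemisphere)


PRE_EXPOSURE_ITI_S = 10.0
PRE_EXPOSURE_MIN_TRIALS = 250
PRE_EXPOSURE_MAX_TRIALS = 272


def simulate_pre_exposure(spec: CohortSpec, mouse: int, region: str = "DMS"):
    """Passive stimulus pre-exposure ('session 0') trials and photometry.

    250-272 trials, 10 s between stimulus onsets, condition drawn uniformly
    from the 8 (contrast x side) combinations; no choices, no rewards.
    Photometry is generated from stimulus kernels only.
    """
    rng = _rng(spec, 2, mouse)
    n = int(rng.integers(PRE_EXPOSURE_MIN_TRIALS, PRE_EXPOSURE_MAX_TRIALS + 1))
    conditions = [(s, c) for s in SIDES for c in spec.contrast_set]
    pick = rng.integers(0, len(conditions), size=n)
    side = np.asarray([conditions[i][0] for i in pick])
    contrast = np.asarray([conditions[i][1] for i in pick])
    stim = PRE_EXPOSURE_ITI_S * (1 + np.arange(n, dtype=float))
    trials = pd.DataFrame({
        "session_index": 0,
        "trial_index": np.arange(1, n + 1),
        "side": side,
        "contrast": contrast,
        "quiescent_duration": np.nan,
        "stim_onset_time": stim,
        "first_movement_time": np.nan,
        "feedback_time": np.nan,
        "choice": pd.Series([pd.NA] * n, dtype="object"),
        "correct": pd.Series([pd.NA] * n, dtype="object"),
        "reward_volume": 0.0,
    })
    kernels = make_ground_truth_kernels(spec, mouse, region, kind="stim")
    trace = simulate_photometry(trials, kernels, noise_sd=spec.noise_sd,
                                drift_spec=spec.drift, seed=rng, kind="stim",
                                region=region,
                                hemisphere=spec.hemisphere_per_region[region])
    return trials, trace
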