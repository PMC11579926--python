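"""Fit the session-evolving choice model to one simulated mouse.

Recovers per-session psychophysical weights (bias, stimulus sensitivities,
choice history) and the shared shape parameters alpha (contrast transform)
and pi (history time constant) by NUTS sampling.  Uses a deliberately small
mouse so the example runs in about a minute.
"""

import numpy as np
import pandas as pd

from dalearn import cohort
from dalearn.behavior import (
    ChoiceData, SamplerConfig, fit_posterior, predict_psychometric,
    summarize_weights,
)

spec = cohort.default_cohort_spec(n_mice=1, n_sessions=5,
                                  trials_per_session=250, seed=7)
weights = cohort.make_weight_trajectories(spec, 0)
frames = [cohort.simulate_choices(cohort.simulate_trials(spec, 0, d),
                                  weights, spec.alpha_true, spec.pi_true,
                                  seed=100 + d)
          for d in range(spec.n_sessions)]
data = ChoiceData.from_trials(pd.concat(frames, ignore_index=True))

res = fit_posterior(data, sampler=SamplerConfig(chains=2, warmup=250,
                                                draws=250, seed=1))
traj = summarize_weights(res)
print(f"posterior alpha: {traj.alpha_mean:.2f} (truth {spec.alpha_true})")
print(f"posterior pi:    {traj.pi_mean:.2f} (truth {spec.pi_true})")
print(traj.table[traj.table["weight"] == "right_stim"]
      [["session", "mean", "lo95", "hi95"]].to_string(index=False))

# The right-stimulus weight grows across sessions (the mouse is learning);
# the 95% intervals should usually cover the generating trajectory.
last = traj.table[traj.table["session"] == spec.n_sessions]
w_last = last.set_index("weight")["mean"]
curve = predict_psychometric(
    w_last[["bias", "right_stim", "left_stim", "history"]].to_numpy(),
    traj.alpha_mean, np.array([-1, -0.25, -0.0625, 0.0625, 0.25, 1.0]))
print("final-session psychometric p(right):",
      np.round(curve, 2), "for signed contrasts -100%..100%")
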