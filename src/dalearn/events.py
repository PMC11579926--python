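"""Canonical task-event labels shared by the simulator and the encoding model.

The full task has 40 event kernels: 8 stimulus (side x 4 contrasts),
16 action (choice side x contrast x correct/incorrect, triggered at first
wheel movement) and 16 outcome (choice side x contrast x reward/timeout,
triggered at feedback).  Pre-exposure sessions have only the 8 stimulus
kernels.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

SIDES = ("left", "right")
DEFAULT_CONTRASTS = (0.0625, 0.125, 0.25, 1.0)


def format_pct(contrast: float) -> str:
    """Contrast fraction -> percent label, e.g. 0.0625 -> '6.25'."""
    pct = contrast * 100.0
    return f"{pct:g}"


def stim_label(side: str, contrast: float) -> str:
    return f"stim_{side}_{format_pct(contrast)}"


def action_label(choice: str, contrast: float, correct: bool) -> str:
    return f"action_{choice}_{format_pct(contrast)}_{'correct' if correct else 'incorrect'}"


def outcome_label(choice: str, contrast: float, correct: bool) -> str:
    return f"outcome_{choice}_{format_pct(contrast)}_{'reward' if correct else 'timeout'}"


def kernel_labels(contrasts=DEFAULT_CONTRASTS, kind: str = "full") -> list[str]:
    """Ordered kernel labels: 40 for the full task, 8 for pre-exposure."""
    labels = [stim_label(s, c) for s in SIDES for c in contrasts]
    if kind == "stim":
        return labels
    if kind != "full":
        raise ValueError(f"unknown kernel set kind {kind!r}")
    labels += [action_label(s, c, ok)
               for s in SIDES for c in contrasts for ok in (True, False)]
    labels += [outcome_label(s, c, ok)
               for s in SIDES for c in contrasts for ok in (True, False)]
    return labels


def extract_events(trials: pd.DataFrame, kind: str = "full"):
    """(time, label) pairs for every kernel-triggering event in a session."""
    events = []
    for row in trials.itertuples(index=False):
        events.append((float(row.stim_onset_time),
                       stim_label(row.side, row.contrast)))
        if kind == "stim":
            continue
        correct = bool(row.correct)
        if row.first_movement_time is not None and np.isfinite(row.first_movement_time):
            events.append((float(row.first_movement_time),
                           action_label(row.choice, row.contrast, correct)))
        events.append((float(row.feedback_time),
                       outcome_label(row.choice, row.contrast, correct)))
    events.sort(key=lambda e: e[0])
    return events
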