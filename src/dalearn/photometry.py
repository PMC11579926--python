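"""Fiber-photometry preprocessing: dF/F, z-scoring, resampling and QC.

The processing chain is raw -> dF/F -> z, enforced through a stage tag on
each trace.  dF/F is computed against a +/-30 s rolling-average baseline;
z-scoring uses the whole-session mean and SD; recordings qualify for
analysis only if every 10-minute block contains at least one transient that
simultaneously exceeds 1% dF/F and 3 session SDs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "PhotometryTrace",
    "compute_dff",
    "zscore_session",
    "qc_recording",
    "resample_trace",
    "QCReport",
]

STAGES = ("raw", "dff", "z")


@dataclass
class PhotometryTrace:
    """A fluorescence time series from one fiber in one session.

    ``time`` is in seconds (session-relative); ``fs`` is the sampling rate if
    the grid is uniform, else None.  ``stage`` tags the processing state.
    """

    time: np.ndarray
    values: np.ndarray
    stage: str = "raw"
    fs: float | None = None
    region: str = ""
    hemisphere: str = ""
    session_id: str = ""

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")
        if self.time.shape != self.values.shape:
            raise ValueError("time and values must have equal length")
        if self.time.size >= 2:
            dt = np.diff(self.time)
            if np.any(dt <= 0):
                raise ValueError("time must be strictly increasing")
            if self.fs is None and np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
                self.fs = 1.0 / float(np.mean(dt))

    @property
    def duration(self) -> float:
        return float(self.time[-1] - self.time[0]) if self.time.size else 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_s": self.time, "fluorescence": self.values})


def _require_stage(trace: PhotometryTrace, stage: str, op: str):
    if trace.stage != stage:
        raise ValueError(f"{op} expects a {stage!r}-stage trace, "
                         f"got {trace.stage!r}")


def compute_dff(raw: PhotometryTrace, window_s: float = 30.0) -> PhotometryTrace:
    """Fractional fluorescence change (F - F0) / F0.

    The baseline F0 is the centered rolling average of the raw signal over
    +/- ``window_s`` seconds; windows shrink at the session edges so that no
    samples are lost and no NaNs appear.
    """
    _require_stage(raw, "raw", "compute_dff")
    if raw.fs is None:
        raise ValueError("compute_dff needs a uniformly sampled trace")
    half = int(round(window_s * raw.fs))
    f = pd.Series(raw.values)
    f0 = f.rolling(window=2 * half + 1, center=True, min_periods=1).mean().to_numpy()
    if np.any(f0 <= 0):
        raise ValueError("nonpositive rolling baseline; input looks corrupt")
    dff = (raw.values - f0) / f0
    return replace(raw, values=dff, stage="dff")


def zscore_session(dff: PhotometryTrace) -> PhotometryTrace:
    """Z-score a dF/F trace using the whole-session mean and SD."""
    _require_stage(dff, "dff", "zscore_session")
    sd = float(np.std(dff.values))
    if sd == 0.0:
        raise ValueError("zero variance; cannot z-score")
    z = (dff.values - float(np.mean(dff.values))) / sd
    return replace(dff, values=z, stage="z")


@dataclass
class QCReport:
    passed: bool
    transient_count: int
    blocks: list = field(default_factory=list)  # per block: transient count
    short_recording: bool = False


def _transient_runs(values: np.ndarray, sd: float,
                    dff_threshold: float = 0.01, sd_multiple: float = 3.0):
    """Maximal contiguous runs jointly above both transient thresholds."""
    above = (values >= dff_threshold) & (values > sd_multiple * sd)
    if not above.any():
        return []
    edges = np.flatnonzero(np.diff(np.concatenate([[False], above, [False]])))
    return list(zip(edges[::2], edges[1::2]))


def qc_recording(dff: PhotometryTrace, block_s: float = 600.0,
                 min_tail_s: float = 300.0) -> QCReport:
    """Transient-based inclusion criterion for one recording.

    The recording is split into consecutive 10-min blocks from session start;
    it passes if every block contains at least one transient (a maximal run
    of samples jointly >= 1% dF/F and > 3 session SDs).  A trailing partial
    block is evaluated if it is at least 5 min long, otherwise ignored.
    Recordings shorter than one block are evaluated as a single short block
    and flagged.
    """
    _require_stage(dff, "dff", "qc_recording")
    sd = float(np.std(dff.values))
    runs = _transient_runs(dff.values, sd)
    starts = np.array([dff.time[s] for s, _ in runs])
    t0 = dff.time[0] if dff.time.size else 0.0
    duration = dff.duration
    short = duration < block_s
    n_blocks = max(1, int(duration // block_s))
    block_counts = []
    for b in range(n_blocks):
        lo = t0 + b * block_s
        hi = lo + block_s
        block_counts.append(int(np.sum((starts >= lo) & (starts < hi)))
                            if starts.size else 0)
    tail = duration - n_blocks * block_s
    if not short and tail >= min_tail_s:
        lo = t0 + n_blocks * block_s
        block_counts.append(int(np.sum(starts >= lo)) if starts.size else 0)
    passed = all(c >= 1 for c in block_counts)
    return QCReport(passed=passed, transient_count=len(runs),
                    blocks=block_counts, short_recording=short)


def resample_trace(trace: PhotometryTrace, target_fs: float = 50.0) -> PhotometryTrace:
    """Linear interpolation onto a uniform grid spanning the original support."""
    t = trace.time
    if np.any(np.diff(t) == 0):
        raise ValueError("duplicate timestamps")
    step = 1.0 / target_fs
    n = int(np.floor((t[-1] - t[0]) / step)) + 1
    grid = t[0] + step * np.arange(n)
    vals = np.interp(grid, t, trace.values)
    return replace(trace, time=grid, values=vals, fs=target_fs)
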