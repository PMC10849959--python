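"""ΔF/F conversion, calcium-transient detection and event statistics.

The baseline F0 of each ROI is the lower 25th quartile of the raw
fluorescence in a ±600-s sliding window; ΔF/F = (F − F0)/F0.  A calcium
transient is a run of at least three consecutive frames in which ΔF/F
exceeds a threshold of 3 s.d. above the mean of the ΔF/F trace.  Event
amplitude/frequency and window-mean z-scores summarize each ROI before and
after a treatment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class RoiTrace:
    """Raw fluorescence of one ROI (microglia soma or process segment)."""

    values: np.ndarray  # fluorescence, arbitrary units, one per frame
    frame_rate: float  # Hz
    roi_id: str = "roi0"
    compartment: str = "process"  # "soma" or "process"
    cell_id: str = "cell0"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("trace must be 1-D")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("trace contains non-finite values")
        if not self.frame_rate > 0:
            raise ValueError("frame_rate must be positive")

    @property
    def n_frames(self) -> int:
        return int(self.values.size)

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate


@dataclass
class TraceSet:
    """A collection of ROI traces sharing one frame clock."""

    traces: list[RoiTrace]

    def __post_init__(self) -> None:
        if not self.traces:
            raise ValueError("TraceSet must contain at least one trace")
        rates = {t.frame_rate for t in self.traces}
        if len(rates) != 1:
            raise ValueError("all traces must share the same frame rate")
        lengths = {t.n_frames for t in self.traces}
        if len(lengths) != 1:
            raise ValueError("all traces must have the same length")

    @property
    def frame_rate(self) -> float:
        return self.traces[0].frame_rate

    @property
    def n_frames(self) -> int:
        return self.traces[0].n_frames

    def values_matrix(self) -> np.ndarray:
        """(n_frames, n_rois) matrix of raw values."""
        return np.column_stack([t.values for t in self.traces])


@dataclass
class DffTrace:
    """ΔF/F trace with its per-frame baseline."""

    dff: np.ndarray
    f0: np.ndarray
    source: RoiTrace

    @property
    def frame_rate(self) -> float:
        return self.source.frame_rate


@dataclass(frozen=True)
class CaEvent:
    """One detected calcium transient."""

    onset_frame: int
    peak_frame: int
    amplitude: float  # peak ΔF/F within the suprathreshold run
    duration_s: float


@dataclass
class EventStats:
    """Summary of one ROI's activity in a time window."""

    mean_level_z: float
    amp_mean: float  # NaN when no event peaks fall in the window
    freq_per_min: float
    window: tuple[float, float]


def sliding_baseline(
    trace: RoiTrace, half_window_s: float = 600.0, quantile: float = 0.25
) -> np.ndarray:
    """Per-frame baseline: lower quartile in a ±``half_window_s`` window.

    The window is truncated (not reflected) at the trace edges.  The
    quantile uses the linear-interpolation definition.
    """
    if trace.n_frames < 2:
        raise ValueError("trace must have at least 2 frames")
    if np.all(trace.values <= 0):
        raise ValueError("trace is non-positive everywhere; ΔF/F undefined")
    w = int(round(half_window_s * trace.frame_rate))
    f0 = (
        pd.Series(trace.values)
        .rolling(window=2 * w + 1, center=True, min_periods=1)
        .quantile(quantile, interpolation="linear")
        .to_numpy()
    )
    return f0


def compute_dff(trace: RoiTrace, f0: np.ndarray) -> DffTrace:
    """ΔF/F = (F − F0) / F0."""
    f0 = np.asarray(f0, dtype=float)
    if f0.shape != trace.values.shape:
        raise ValueError("f0 must match the trace length")
    if np.any(f0 <= 0):
        raise ValueError("f0 must be positive everywhere")
    return DffTrace(dff=(trace.values - f0) / f0, f0=f0, source=trace)


def zscore_trace(
    values: np.ndarray, frame_rate: float, baseline_window: tuple[float, float]
) -> np.ndarray:
    """Standardize a trace against the mean/SD of a baseline period.

    ``baseline_window`` is (start_s, end_s), half-open in frames; the SD
    uses the n−1 denominator.
    """
    values = np.asarray(values, dtype=float)
    start, end = baseline_window
    i0 = max(int(np.floor(start * frame_rate)), 0)
    i1 = min(int(np.ceil(end * frame_rate)), values.size)
    base = values[i0:i1]
    if base.size < 2:
        raise ValueError("baseline window must contain at least 2 frames")
    sd = base.std(ddof=1)
    if sd == 0:
        raise ValueError("baseline has zero variance; z-score undefined")
    return (values - base.mean()) / sd


def detect_events(
    d: DffTrace,
    n_sd: float = 3.0,
    min_frames: int = 3,
    smooth_frames: int = 0,
) -> list[CaEvent]:
    """Threshold-based calcium transient detection.

    The threshold is ``mean + n_sd * sd`` of the full ΔF/F trace.  An
    event is a maximal run of at least ``min_frames`` consecutive frames
    strictly above threshold; runs separated by one or more subthreshold
    frames are distinct events.  ``smooth_frames > 1`` applies a moving
    average of that width to the trace before thresholding (alternative
    reading of the three-frame rule).
    """
    dff = np.asarray(d.dff, dtype=float)
    if dff.size < min_frames:
        raise ValueError("trace shorter than min_frames")
    if smooth_frames > 1:
        kernel = np.ones(smooth_frames) / smooth_frames
        test = np.convolve(dff, kernel, mode="same")
    else:
        test = dff
    sd = test.std(ddof=1)
    if sd == 0:
        warnings.warn("zero-variance ΔF/F trace; no events detectable", stacklevel=2)
        return []
    theta = test.mean() + n_sd * sd
    above = test > theta
    events: list[CaEvent] = []
    run_starts = np.flatnonzero(above & ~np.concatenate(([False], above[:-1])))
    run_ends = np.flatnonzero(above & ~np.concatenate((above[1:], [False]))) + 1
    for s, e in zip(run_starts, run_ends):
        if e - s < min_frames:
            continue
        peak = s + int(np.argmax(dff[s:e]))
        events.append(
            CaEvent(
                onset_frame=int(s),
                peak_frame=peak,
                amplitude=float(dff[peak]),
                duration_s=(e - s) / d.frame_rate,
            )
        )
    return events


def match_events(
    detected: list[CaEvent],
    true_onsets_s: list[float],
    frame_rate: float,
    tol_frames: int = 2,
) -> tuple[int, int, int]:
    """Greedy one-to-one matching of detected to true events by onset.

    A detection counts as a true positive when its onset frame is within
    ``tol_frames`` of a not-yet-matched true onset (first frame at or
    after the true onset time).  Returns (tp, fp, fn).
    """
    true_frames = [int(np.ceil(o * frame_rate)) for o in true_onsets_s]
    used: set[int] = set()
    tp = fp = 0
    for ev in detected:
        match = next(
            (
                j
                for j, tf in enumerate(true_frames)
                if j not in used and abs(ev.onset_frame - tf) <= tol_frames
            ),
            None,
        )
        if match is None:
            fp += 1
        else:
            used.add(match)
            tp += 1
    return tp, fp, len(true_frames) - len(used)


def event_stats(
    events: list[CaEvent],
    z: np.ndarray,
    frame_rate: float,
    window: tuple[float, float],
) -> EventStats:
    """Mean z level, mean event amplitude and event rate in a window.

    Events are assigned to the window by peak time; ``amp_mean`` is NaN
    when no event peak falls inside.
    """
    start, end = window
    if end <= start:
        raise ValueError("window must have positive duration")
    z = np.asarray(z, dtype=float)
    i0 = max(int(np.floor(start * frame_rate)), 0)
    i1 = min(int(np.ceil(end * frame_rate)), z.size)
    if i1 <= i0:
        raise ValueError("window outside the trace span")
    in_window = [
        ev for ev in events if start <= ev.peak_frame / frame_rate < end
    ]
    minutes = (end - start) / 60.0
    amps = [ev.amplitude for ev in in_window]
    return EventStats(
        mean_level_z=float(np.mean(z[i0:i1])),
        amp_mean=float(np.mean(amps)) if amps else float("nan"),
        freq_per_min=len(in_window) / minutes,
        window=(float(start), float(end)),
    )


def pre_post_change(before: EventStats, after: EventStats) -> dict[str, float]:
    """Per-quantity differences (after − before); NaN propagates."""
    return {
        "mean_level_z": after.mean_level_z - before.mean_level_z,
        "amp_mean": after.amp_mean - before.amp_mean,
        "freq_per_min": after.freq_per_min - before.freq_per_min,
    }


def analyze_trace(
    trace: RoiTrace,
    baseline_window: tuple[float, float],
    pre_window: tuple[float, float],
    post_window: tuple[float, float],
    n_sd: float = 3.0,
    min_frames: int = 3,
    half_window_s: float = 600.0,
) -> dict[str, float]:
    """Full per-ROI pipeline: baseline, ΔF/F, events, pre/post contrast."""
    f0 = sliding_baseline(trace, half_window_s=half_window_s)
    d = compute_dff(trace, f0)
    z = zscore_trace(trace.values, trace.frame_rate, baseline_window)
    events = detect_events(d, n_sd=n_sd, min_frames=min_frames)
    before = event_stats(events, z, trace.frame_rate, pre_window)
    after = event_stats(events, z, trace.frame_rate, post_window)
    delta = pre_post_change(before, after)
    return {f"delta_{k}": v for k, v in delta.items()}
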