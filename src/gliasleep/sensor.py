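"""GRAB-sensor (norepinephrine / adenosine) pharmacology quantification.

Each session is a set of 8-12 ROI traces imaged at 1.68 Hz.  Every ROI is
z-scored against its own pre-treatment baseline and the session trace is
the unweighted mean of the ROI z-scores.  Treatment effects are window
contrasts of the session trace: Δz = mean(post window) − mean(pre window),
with the [−20, 0] vs [40, 60] min windows for local drug application and
the full pre-injection baseline vs [20, 120] min for systemic injections.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .calcium import TraceSet, zscore_trace

#: local drug application windows, minutes relative to treatment
PRE_WINDOW_DRUG_MIN = (-20.0, 0.0)
POST_WINDOW_DRUG_MIN = (40.0, 60.0)
#: systemic (i.p. injection) post window, minutes relative to treatment
POST_WINDOW_INJECTION_MIN = (20.0, 120.0)


@dataclass
class SensorSession:
    """z-scored sensor ROI traces with the treatment timestamp."""

    roi_z: np.ndarray  # (n_frames, n_rois)
    frame_rate: float
    treatment_time_s: float
    treatment_label: str = ""
    baseline_window_s: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.roi_z = np.atleast_2d(np.asarray(self.roi_z, dtype=float))
        if self.roi_z.shape[1] < 1:
            raise ValueError("session needs at least one ROI")
        if not 0 <= self.treatment_time_s <= self.duration_s:
            raise ValueError("treatment time outside the recording")

    @property
    def n_frames(self) -> int:
        return int(self.roi_z.shape[0])

    @property
    def n_rois(self) -> int:
        return int(self.roi_z.shape[1])

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.frame_rate

    def session_trace(self) -> np.ndarray:
        """Unweighted mean of the ROI z-scores per frame."""
        return self.roi_z.mean(axis=1)


@dataclass
class WindowContrast:
    """A pre/post window contrast of the session z trace."""

    pre_window_min: tuple[float, float]
    post_window_min: tuple[float, float]
    delta_z: float


def session_zscore(
    rois: TraceSet,
    baseline_window: tuple[float, float],
    treatment_time_s: float,
    treatment_label: str = "",
) -> SensorSession:
    """Z-score each ROI against its own baseline period.

    ROIs with zero baseline variance are dropped with a warning; an error
    is raised if none survive.
    """
    columns = []
    for trace in rois.traces:
        try:
            columns.append(zscore_trace(trace.values, rois.frame_rate, baseline_window))
        except ValueError:
            warnings.warn(
                f"ROI {trace.roi_id} has zero baseline variance; dropped",
                stacklevel=2,
            )
    if not columns:
        raise ValueError("all ROIs had zero baseline variance")
    return SensorSession(
        roi_z=np.column_stack(columns),
        frame_rate=rois.frame_rate,
        treatment_time_s=treatment_time_s,
        treatment_label=treatment_label,
        baseline_window_s=(float(baseline_window[0]), float(baseline_window[1])),
    )


def _window_mean(s: SensorSession, window_min: tuple[float, float]) -> float:
    """Mean session z over a window given in minutes relative to treatment."""
    start_s = s.treatment_time_s + window_min[0] * 60.0
    end_s = s.treatment_time_s + window_min[1] * 60.0
    if end_s <= start_s:
        raise ValueError("window must have positive duration")
    i0 = int(np.floor(start_s * s.frame_rate))
    i1 = int(np.ceil(end_s * s.frame_rate))
    if i0 < 0 or i1 > s.n_frames:
        raise ValueError(
            f"window [{window_min[0]}, {window_min[1]}] min not covered by "
            f"the recording"
        )
    return float(s.session_trace()[i0:i1].mean())


def delta_z(
    s: SensorSession,
    pre_min: tuple[float, float] = PRE_WINDOW_DRUG_MIN,
    post_min: tuple[float, float] = POST_WINDOW_DRUG_MIN,
) -> WindowContrast:
    """Δz = mean(post window) − mean(pre window) of the session trace.

    Windows are in minutes relative to the treatment time; conventionally
    the pre window ends at 0 and the post window starts after it, but the
    contrast itself is defined for any pair of non-degenerate windows
    inside the recording (swapping them negates Δz).
    """
    return WindowContrast(
        pre_window_min=tuple(map(float, pre_min)),
        post_window_min=tuple(map(float, post_min)),
        delta_z=_window_mean(s, post_min) - _window_mean(s, pre_min),
    )


def delta_z_injection(
    s: SensorSession,
    post_min: tuple[float, float] = POST_WINDOW_INJECTION_MIN,
) -> WindowContrast:
    """Systemic-injection contrast: post window vs the z-scoring baseline.

    The pre window is the session's own baseline period (the window the
    ROI z-scores were computed against), so its mean is 0 by construction
    up to ROI weighting.
    """
    if s.baseline_window_s is None:
        pre_min = (-s.treatment_time_s / 60.0, 0.0)
    else:
        pre_min = (
            (s.baseline_window_s[0] - s.treatment_time_s) / 60.0,
            (s.baseline_window_s[1] - s.treatment_time_s) / 60.0,
        )
    return WindowContrast(
        pre_window_min=tuple(map(float, pre_min)),
        post_window_min=tuple(map(float, post_min)),
        delta_z=_window_mean(s, post_min) - _window_mean(s, pre_min),
    )
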