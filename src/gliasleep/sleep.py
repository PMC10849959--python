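"""EEG/EMG sleep-stage scoring and hypnogram metrics.

Brain states are scored per non-overlapping 5-s epoch from the EEG power
spectrum and the EMG amplitude: wake is high muscle tone, REM is low muscle
tone with a dominant theta (6-9 Hz) rhythm, and NREM is low muscle tone with
dominant delta (0.5-4 Hz) power.  Consecutive epochs of the same state are
merged into episodes, from which time-in-state percentages, mean episode
durations and episode rates are derived.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

#: canonical state labels: wake, NREM sleep, REM sleep
STATES = ("W", "N", "R")

#: frequency bands (Hz) used for scoring
DELTA_BAND = (0.5, 4.0)
THETA_BAND = (6.0, 9.0)
TOTAL_BAND = (0.0, 25.0)


@dataclass
class Recording:
    """A paired EEG/EMG recording.

    Parameters
    ----------
    eeg, emg
        Voltage traces in microvolts, equal length, sampled at ``fs`` Hz.
    fs
        Sampling rate in Hz (1500 Hz for the amplifier settings emulated
        by the synthetic generator).
    start_time_s
        Absolute time of the first sample, seconds.
    """

    eeg: np.ndarray
    emg: np.ndarray
    fs: float
    start_time_s: float = 0.0

    def __post_init__(self) -> None:
        self.eeg = np.asarray(self.eeg, dtype=float)
        self.emg = np.asarray(self.emg, dtype=float)
        if self.eeg.ndim != 1 or self.emg.ndim != 1:
            raise ValueError("eeg and emg must be 1-D arrays")
        if self.eeg.shape != self.emg.shape:
            raise ValueError("eeg and emg must have the same length")
        if not self.fs > 0:
            raise ValueError("fs must be positive")

    @property
    def duration_s(self) -> float:
        return self.eeg.size / self.fs


@dataclass
class Hypnogram:
    """Per-epoch state labels over a session."""

    states: np.ndarray  # array of "W" / "N" / "R"
    epoch_s: float = 5.0

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype="<U1")
        if self.states.size == 0:
            raise ValueError("hypnogram must contain at least one epoch")
        if not self.epoch_s > 0:
            raise ValueError("epoch_s must be positive")
        bad = set(self.states.tolist()) - set(STATES)
        if bad:
            raise ValueError(f"unknown state labels: {sorted(bad)}")

    @property
    def n_epochs(self) -> int:
        return int(self.states.size)

    @property
    def duration_s(self) -> float:
        return self.n_epochs * self.epoch_s


@dataclass(frozen=True)
class Episode:
    """A maximal run of identical epoch labels."""

    state: str
    start_s: float
    duration_s: float


@dataclass
class StateMetrics:
    """Time-in-state and episode statistics for one hypnogram.

    ``percent_time`` has one row per time bin with columns ``bin_start_s``
    and one column per state; the three state columns sum to 100 in every
    row.  ``mean_episode_duration_s`` is NaN for a state with no episode in
    the window (the state is missing, not zero-duration).
    """

    percent_time: pd.DataFrame
    mean_episode_duration_s: dict[str, float]
    episodes_per_hour: dict[str, float]


def epoch_spectrogram(
    rec: Recording, epoch_s: float = 5.0
) -> tuple[np.ndarray, np.ndarray]:
    """FFT power spectral density of the EEG for each non-overlapping epoch.

    Returns ``(freqs, psd)`` where ``psd`` has shape
    ``(n_epochs, n_freqs)`` in µV²/Hz.  A trailing partial epoch is
    dropped.  With a 5-s epoch at 1500 Hz the frequency resolution is
    0.2 Hz.
    """
    n = int(round(epoch_s * rec.fs))
    if n < 2:
        raise ValueError("epoch_s too short for the sampling rate")
    n_epochs = rec.eeg.size // n
    if n_epochs == 0:
        raise ValueError(
            f"recording ({rec.eeg.size} samples) shorter than one "
            f"{epoch_s}-s epoch ({n} samples)"
        )
    segments = rec.eeg[: n_epochs * n].reshape(n_epochs, n)
    freqs, psd = signal.periodogram(
        segments, fs=rec.fs, detrend="constant", axis=-1
    )
    return freqs, psd


def band_power(freqs: np.ndarray, psd: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Trapezoidal integral of the PSD over ``[lo, hi]`` Hz.

    Band edges that fall between frequency samples are linearly
    interpolated so that the integration limits are honoured exactly.
    """
    psd = np.atleast_2d(np.asarray(psd, dtype=float))
    lo = max(lo, float(freqs[0]))
    hi = min(hi, float(freqs[-1]))
    if hi <= lo:
        return np.zeros(psd.shape[0])
    inner = (freqs > lo) & (freqs < hi)
    grid = np.concatenate(([lo], freqs[inner], [hi]))
    values = np.empty((psd.shape[0], grid.size))
    values[:, 1:-1] = psd[:, inner]
    values[:, 0] = _interp_rows(lo, freqs, psd)
    values[:, -1] = _interp_rows(hi, freqs, psd)
    return np.trapezoid(values, grid, axis=-1)


def _interp_rows(x: float, xp: np.ndarray, fp: np.ndarray) -> np.ndarray:
    """Linear interpolation of each row of ``fp`` (sampled at ``xp``) at x."""
    i = int(np.clip(np.searchsorted(xp, x), 1, xp.size - 1))
    x0, x1 = xp[i - 1], xp[i]
    w = 0.0 if x1 == x0 else (x - x0) / (x1 - x0)
    return (1 - w) * fp[:, i - 1] + w * fp[:, i]


def emg_rms_per_epoch(
    emg: np.ndarray,
    fs: float,
    epoch_s: float,
    n_epochs: int,
    band: tuple[float, float] = (10.0, 300.0),
) -> np.ndarray:
    """Per-epoch RMS of the band-passed, rectified EMG."""
    n = int(round(epoch_s * fs))
    emg = np.asarray(emg, dtype=float)
    lo, hi = band
    hi = min(hi, 0.45 * fs)  # keep the filter edge below Nyquist
    if np.any(emg):
        if hi > lo:
            sos = signal.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
        else:
            sos = signal.butter(4, lo, btype="highpass", fs=fs, output="sos")
        filtered = signal.sosfiltfilt(sos, emg)
    else:
        filtered = emg
    segments = np.abs(filtered[: n_epochs * n]).reshape(n_epochs, n)
    return np.sqrt(np.mean(segments**2, axis=-1))


def extract_features(
    freqs: np.ndarray,
    psd: np.ndarray,
    emg: np.ndarray,
    fs: float,
    epoch_s: float = 5.0,
    emg_band: tuple[float, float] = (10.0, 300.0),
) -> pd.DataFrame:
    """Per-epoch scoring features.

    Returns a frame with columns ``epoch_index``, ``power_delta``,
    ``power_theta``, ``power_total_0_25``, ``theta_delta_ratio`` and
    ``emg_rms``.  The EMG trace must cover the same number of complete
    epochs as the PSD.
    """
    psd = np.atleast_2d(psd)
    n_epochs = psd.shape[0]
    n = int(round(epoch_s * fs))
    if np.asarray(emg).size // n != n_epochs:
        raise ValueError(
            f"EMG covers {np.asarray(emg).size // n} complete epochs but the "
            f"PSD has {n_epochs}"
        )
    delta = band_power(freqs, psd, *DELTA_BAND)
    theta = band_power(freqs, psd, *THETA_BAND)
    total = band_power(freqs, psd, *TOTAL_BAND)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(delta > 0, theta / delta, np.inf)
    rms = emg_rms_per_epoch(emg, fs, epoch_s, n_epochs, band=emg_band)
    return pd.DataFrame(
        {
            "epoch_index": np.arange(n_epochs),
            "power_delta": delta,
            "power_theta": theta,
            "power_total_0_25": total,
            "theta_delta_ratio": ratio,
            "emg_rms": rms,
        }
    )


def _two_means_midpoint(x: np.ndarray) -> float:
    """Midpoint of a 2-class 1-D k-means clustering of ``x``."""
    x = np.sort(np.asarray(x, dtype=float))
    c0, c1 = np.quantile(x, [0.1, 0.9])
    if c0 == c1:
        return float(c0)
    for _ in range(100):
        cut = (c0 + c1) / 2.0
        lower, upper = x[x <= cut], x[x > cut]
        if lower.size == 0 or upper.size == 0:
            break
        n0, n1 = float(lower.mean()), float(upper.mean())
        if n0 == c0 and n1 == c1:
            break
        c0, c1 = n0, n1
    return float((c0 + c1) / 2.0)


def emg_threshold_from_features(emg_rms: np.ndarray) -> float:
    """Data-driven wake/sleep EMG cut: midpoint of 2-means on log RMS."""
    log_rms = np.log(np.maximum(np.asarray(emg_rms, float), 1e-12))
    return float(np.exp(_two_means_midpoint(log_rms)))


def classify_epochs(
    features: pd.DataFrame,
    emg_threshold: float | None = None,
    ratio_threshold: float = 1.5,
    smooth: bool = True,
) -> Hypnogram:
    """Score each epoch as wake, NREM or REM.

    Decision rule per epoch: high EMG -> wake; otherwise a theta/delta
    ratio above ``ratio_threshold`` -> REM; otherwise NREM.  When
    ``emg_threshold`` is None it is derived from the session itself
    (two-class clustering of log EMG RMS).  With ``smooth`` enabled,
    isolated single epochs flanked by two identical states are relabelled
    to the flanking state.
    """
    if len(features) == 0:
        raise ValueError("no epochs to classify")
    rms = features["emg_rms"].to_numpy(dtype=float)
    ratio = features["theta_delta_ratio"].to_numpy(dtype=float)
    if not np.isfinite(ratio_threshold):
        raise ValueError("ratio_threshold must be finite")
    if emg_threshold is None:
        emg_threshold = emg_threshold_from_features(rms[np.isfinite(rms)])
    states = np.where(
        rms > emg_threshold, "W", np.where(ratio > ratio_threshold, "R", "N")
    ).astype("<U1")
    bad = ~(np.isfinite(rms) & np.isfinite(ratio))
    # a theta/delta ratio of +inf (zero delta) is a legitimate REM call
    bad &= ~(np.isfinite(rms) & np.isposinf(ratio))
    if np.any(bad):
        warnings.warn(
            f"{int(bad.sum())} epochs had non-finite features; labelled W",
            stacklevel=2,
        )
        states[bad] = "W"
    if smooth:
        states = smooth_singletons(states)
    return Hypnogram(states=states)


def smooth_singletons(states: np.ndarray) -> np.ndarray:
    """Replace isolated single-epoch states flanked by identical states."""
    out = states.copy()
    for i in range(1, out.size - 1):
        if out[i - 1] == out[i + 1] != out[i]:
            out[i] = out[i - 1]
    return out


def apply_override(h: Hypnogram, overrides: dict[int, str]) -> Hypnogram:
    """Apply manual per-epoch relabels (epoch index -> state)."""
    states = h.states.copy()
    for idx, state in overrides.items():
        if state not in STATES:
            raise ValueError(f"unknown state {state!r} for epoch {idx}")
        if not 0 <= idx < states.size:
            raise ValueError(f"override epoch {idx} outside hypnogram")
        states[idx] = state
    return Hypnogram(states=states, epoch_s=h.epoch_s)


def merge_episodes(h: Hypnogram) -> list[Episode]:
    """Run-length merge consecutive identical epochs into episodes."""
    states = h.states
    boundaries = np.flatnonzero(states[1:] != states[:-1]) + 1
    starts = np.concatenate(([0], boundaries))
    ends = np.concatenate((boundaries, [states.size]))
    return [
        Episode(
            state=str(states[s]),
            start_s=s * h.epoch_s,
            duration_s=(e - s) * h.epoch_s,
        )
        for s, e in zip(starts, ends)
    ]


def expand_episodes(episodes: list[Episode], epoch_s: float) -> Hypnogram:
    """Inverse of :func:`merge_episodes`: tile episodes back into epochs."""
    labels: list[str] = []
    for ep in episodes:
        n = ep.duration_s / epoch_s
        if abs(n - round(n)) > 1e-9:
            raise ValueError("episode duration not a multiple of epoch_s")
        labels.extend([ep.state] * int(round(n)))
    return Hypnogram(states=np.array(labels), epoch_s=epoch_s)


def state_metrics(h: Hypnogram, bin_s: float) -> StateMetrics:
    """Percent time per bin, mean episode duration and episode rate.

    ``bin_s`` must be a positive integer multiple of the epoch length.
    The trailing bin may be shorter; percentages are computed relative to
    the epochs it actually contains so each row still sums to 100.
    """
    if bin_s < h.epoch_s:
        raise ValueError("bin_s must be at least one epoch")
    per_bin = bin_s / h.epoch_s
    if abs(per_bin - round(per_bin)) > 1e-9:
        raise ValueError("bin_s must be an integer multiple of epoch_s")
    per_bin = int(round(per_bin))
    rows = []
    for start in range(0, h.n_epochs, per_bin):
        chunk = h.states[start : start + per_bin]
        row = {"bin_start_s": start * h.epoch_s}
        for s in STATES:
            row[s] = 100.0 * np.count_nonzero(chunk == s) / chunk.size
        rows.append(row)
    episodes = merge_episodes(h)
    hours = h.duration_s / 3600.0
    mean_dur: dict[str, float] = {}
    rate: dict[str, float] = {}
    for s in STATES:
        durs = [ep.duration_s for ep in episodes if ep.state == s]
        mean_dur[s] = float(np.mean(durs)) if durs else float("nan")
        rate[s] = len(durs) / hours
    return StateMetrics(
        percent_time=pd.DataFrame(rows),
        mean_episode_duration_s=mean_dur,
        episodes_per_hour=rate,
    )


def normalized_spectrum(
    rec: Recording,
    h: Hypnogram,
    state: str,
    fmax: float = 25.0,
) -> tuple[np.ndarray, np.ndarray]:
    """State-conditioned EEG spectrum normalized to unit total power.

    The PSDs of all epochs scored as ``state`` are averaged and divided by
    the integral of that average over [0, ``fmax``] Hz, so the returned
    density integrates to 1.
    """
    if state not in STATES:
        raise ValueError(f"unknown state {state!r}")
    freqs, psd = epoch_spectrogram(rec, epoch_s=h.epoch_s)
    n = min(psd.shape[0], h.n_epochs)
    mask = h.states[:n] == state
    if not np.any(mask):
        raise ValueError(f"no epochs of state {state!r} in the hypnogram")
    mean_psd = psd[:n][mask].mean(axis=0)
    keep = freqs <= fmax
    freqs, mean_psd = freqs[keep], mean_psd[keep]
    total = np.trapezoid(mean_psd, freqs)
    if total <= 0:
        raise ValueError("zero total power; cannot normalize")
    return freqs, mean_psd / total
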