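"""Synthetic session generators with embedded ground truth.

Every input the pipeline consumes can be generated here with known hidden
structure: EEG/EMG sessions whose brain states follow a first-order Markov
chain at epoch resolution, ROI calcium traces with planted exponential-decay
transients, GRAB-sensor sessions with a saturating step drug effect and
optional brain-state coupling, and 3D volumes of spherical "microglia" with
scattered bouton points whose minimal distances are analytic.

All generators are pure functions of their configuration (including the
seed): the same config yields bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .calcium import RoiTrace, TraceSet
from .distance import VolumeScene
from .sleep import Hypnogram, Recording, STATES

#: synthesis bands (Hz): delta, theta, and a broadband floor
SYNTH_BANDS = {
    "delta": (0.5, 4.0),
    "theta": (6.0, 9.0),
    "broad": (0.5, 25.0),
}


def default_transition_matrix() -> np.ndarray:
    """Epoch-resolution (5 s) transition matrix over (W, N, R).

    Dwell times are geometric: roughly 2.8 min wake, 2.4 min NREM and
    0.8 min REM episodes, with REM entered only from NREM and exited to
    wake -- the usual rodent sleep architecture.
    """
    return np.array(
        [
            [0.970, 0.030, 0.000],
            [0.020, 0.965, 0.015],
            [0.100, 0.000, 0.900],
        ]
    )


#: per-state mean band power (µV², per band) for the default generator;
#: NREM is delta-dominated, REM theta-dominated, wake desynchronized.
DEFAULT_BAND_POWER = {
    "W": {"delta": 1.0, "theta": 1.0, "broad": 1.0},
    "N": {"delta": 5.0, "theta": 0.5, "broad": 1.0},
    "R": {"delta": 0.5, "theta": 5.0, "broad": 1.0},
}

#: per-state EMG RMS amplitude (µV): high muscle tone only in wake
DEFAULT_EMG_AMP = {"W": 5.0, "N": 1.0, "R": 1.0}


@dataclass
class GroundTruth:
    """Hidden structure of a generated dataset."""

    hypnogram_true: Hypnogram | None = None
    events_true: list[list[tuple[float, float]]] | None = None  # (onset_s, amp)
    effect_true: np.ndarray | None = None  # per-ROI injected Δz
    distances_true: np.ndarray | None = None  # per-bouton analytic µm


@dataclass
class SleepSynthConfig:
    duration_s: float = 3600.0
    fs: float = 1500.0
    epoch_s: float = 5.0
    transition_matrix: np.ndarray = field(default_factory=default_transition_matrix)
    band_power: dict[str, dict[str, float]] = field(
        default_factory=lambda: {s: dict(DEFAULT_BAND_POWER[s]) for s in STATES}
    )
    emg_amp: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_EMG_AMP))
    initial_state: str | None = None  # None -> stationary distribution
    seed: int = 0

    def __post_init__(self) -> None:
        self.transition_matrix = np.asarray(self.transition_matrix, dtype=float)
        if self.transition_matrix.shape != (3, 3):
            raise ValueError("transition_matrix must be 3x3 over (W, N, R)")
        if np.any(self.transition_matrix < 0) or np.any(
            np.abs(self.transition_matrix.sum(axis=1) - 1.0) > 1e-9
        ):
            raise ValueError("transition_matrix rows must be stochastic")
        top_edge = max(hi for _, hi in SYNTH_BANDS.values())
        if not self.fs > 2 * top_edge:
            raise ValueError(f"fs must exceed twice the top band edge ({top_edge} Hz)")
        frames = self.epoch_s * self.fs
        if abs(frames - round(frames)) > 1e-9:
            raise ValueError("epoch_s × fs must be an integer sample count")
        if self.duration_s < self.epoch_s:
            raise ValueError("duration must cover at least one epoch")
        if self.initial_state is not None and self.initial_state not in STATES:
            raise ValueError(f"unknown initial state {self.initial_state!r}")


def stationary_distribution(transition_matrix: np.ndarray) -> np.ndarray:
    """Stationary occupancy of a row-stochastic chain (left eigenvector)."""
    w, v = np.linalg.eig(np.asarray(transition_matrix, float).T)
    i = int(np.argmin(np.abs(w - 1.0)))
    pi = np.real(v[:, i])
    return pi / pi.sum()


def sample_markov_states(
    transition_matrix: np.ndarray,
    n_epochs: int,
    rng: np.random.Generator,
    initial_state: str | None = None,
) -> np.ndarray:
    """Draw a state sequence; the first state comes from the stationary
    distribution unless given explicitly."""
    cum = np.cumsum(transition_matrix, axis=1)
    states = np.empty(n_epochs, dtype=np.int64)
    if initial_state is None:
        states[0] = rng.choice(3, p=stationary_distribution(transition_matrix))
    else:
        states[0] = STATES.index(initial_state)
    u = rng.random(n_epochs)
    for k in range(1, n_epochs):
        states[k] = np.searchsorted(cum[states[k - 1]], u[k])
    return np.array(STATES)[states]


def _band_noise(
    n: int, fs: float, band: tuple[float, float], rng: np.random.Generator
) -> np.ndarray:
    """Unit-variance Gaussian noise band-limited to ``band`` Hz."""
    white = rng.standard_normal(n)
    sos = signal.butter(4, band, btype="bandpass", fs=fs, output="sos")
    x = signal.sosfiltfilt(sos, white)
    return x / x.std()


def gen_sleep_session(cfg: SleepSynthConfig) -> tuple[Recording, GroundTruth]:
    """EEG/EMG with state-dependent band power and EMG amplitude.

    The EEG is a sum over bands of unit-variance band-limited noise scaled
    per epoch by the hidden state's configured band power (so per-epoch
    band variance follows the state); the EMG is white noise scaled to the
    state's RMS amplitude.
    """
    rng = np.random.default_rng(cfg.seed)
    epoch_len = int(round(cfg.epoch_s * cfg.fs))
    n_epochs = int(cfg.duration_s // cfg.epoch_s)
    n = n_epochs * epoch_len
    states = sample_markov_states(
        cfg.transition_matrix, n_epochs, rng, cfg.initial_state
    )
    eeg = np.zeros(n)
    for band_name, edges in SYNTH_BANDS.items():
        amp_per_epoch = np.sqrt(
            [cfg.band_power[s][band_name] for s in states]
        )
        eeg += np.repeat(amp_per_epoch, epoch_len) * _band_noise(
            n, cfg.fs, edges, rng
        )
    emg_amp = np.repeat([cfg.emg_amp[s] for s in states], epoch_len)
    emg = emg_amp * rng.standard_normal(n)
    rec = Recording(eeg=eeg, emg=emg, fs=cfg.fs)
    truth = GroundTruth(hypnogram_true=Hypnogram(states=states, epoch_s=cfg.epoch_s))
    return rec, truth


@dataclass
class CalciumSynthConfig:
    """Microglia-like calcium traces: sparse transients on a noisy baseline.

    Defaults emulate baseline two-photon GCaMP6s recordings of microglia
    processes: infrequent events (about four per ROI per 40 min), decay
    over ~10 s, and peak ΔF/F amplitudes whose minimum stays at least five
    times the ΔF/F frame noise (≈0.11 for the default baseline/noise).
    """

    n_rois: int = 10
    frame_rate: float = 0.84
    duration_s: float = 2400.0
    event_rate_per_min: float = 0.1
    event_amp_mean: float = 0.8  # peak ΔF/F
    event_amp_sd: float = 0.08
    decay_tau_s: float = 10.0
    baseline_level: float = 100.0
    drift_amplitude: float = 3.0
    noise_sd: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rois < 1:
            raise ValueError("need at least one ROI")
        if self.duration_s * self.frame_rate < 1:
            raise ValueError("duration too short for a single frame")
        if self.event_rate_per_min < 0:
            raise ValueError("event_rate must be nonnegative")
        if self.decay_tau_s <= 0:
            raise ValueError("decay_tau must be positive")
        if self.noise_sd < 0 or self.event_amp_sd < 0:
            raise ValueError("spread parameters must be nonnegative")
        if self.baseline_level <= 0:
            raise ValueError("baseline_level must be positive")


def gen_calcium(cfg: CalciumSynthConfig) -> tuple[TraceSet, GroundTruth]:
    """ROI fluorescence = baseline + slow drift + transients + noise.

    Transients rise instantaneously at Poisson-process onsets and decay
    exponentially; their amplitude is the configured peak ΔF/F relative
    to the local (drifting) baseline.  ``events_true`` records each ROI's
    (onset_s, peak ΔF/F) pairs.
    """
    rng = np.random.default_rng(cfg.seed)
    n_frames = int(cfg.duration_s * cfg.frame_rate)
    t = np.arange(n_frames) / cfg.frame_rate
    traces: list[RoiTrace] = []
    events_true: list[list[tuple[float, float]]] = []
    for r in range(cfg.n_rois):
        phase = rng.uniform(0, 2 * np.pi)
        period = rng.uniform(0.5, 1.0) * cfg.duration_s
        drift = cfg.drift_amplitude * np.sin(2 * np.pi * t / period + phase)
        base = cfg.baseline_level + drift
        n_events = rng.poisson(cfg.event_rate_per_min * cfg.duration_s / 60.0)
        onsets = np.sort(rng.uniform(0, cfg.duration_s, size=n_events))
        amps = np.clip(
            rng.normal(cfg.event_amp_mean, cfg.event_amp_sd, size=n_events),
            0.05 * cfg.event_amp_mean,
            None,
        )
        values = base.copy()
        roi_events = []
        for onset, amp in zip(onsets, amps):
            local_base = cfg.baseline_level + cfg.drift_amplitude * np.sin(
                2 * np.pi * onset / period + phase
            )
            lag = t - onset
            kernel = np.where(lag >= 0, np.exp(-np.maximum(lag, 0) / cfg.decay_tau_s), 0.0)
            values += amp * local_base * kernel
            roi_events.append((float(onset), float(amp)))
        values += cfg.noise_sd * rng.standard_normal(n_frames)
        traces.append(
            RoiTrace(
                values=values,
                frame_rate=cfg.frame_rate,
                roi_id=f"roi{r:03d}",
                compartment="process",
                cell_id=f"cell{r:03d}",
            )
        )
        events_true.append(roi_events)
    return TraceSet(traces=traces), GroundTruth(events_true=events_true)


@dataclass
class SensorSynthConfig:
    """GRAB-sensor session: baseline, step-like drug effect, state coupling.

    The drug effect is a saturating exponential step of size
    ``effect_size_z`` (in units of the frame noise SD) starting at the
    treatment time; the default 600-s time constant mimics effects that
    develop over tens of minutes.
    """

    n_rois: int = 10
    frame_rate: float = 1.68
    duration_s: float = 7200.0
    treatment_time_s: float = 2400.0
    effect_size_z: float = 0.0
    effect_onset_tau_s: float = 600.0
    state_coupling: dict[str, float] | None = None  # state -> offset (noise-SD units)
    baseline_level: float = 100.0
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rois < 1:
            raise ValueError("need at least one ROI")
        if not 0 < self.treatment_time_s < self.duration_s:
            raise ValueError("treatment time must fall inside the recording")
        if self.effect_onset_tau_s <= 0:
            raise ValueError("effect_onset_tau must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.state_coupling is not None:
            bad = set(self.state_coupling) - set(STATES)
            if bad:
                raise ValueError(f"unknown states in coupling: {sorted(bad)}")


def gen_sensor(
    cfg: SensorSynthConfig, hypnogram: Hypnogram | None = None
) -> tuple[TraceSet, GroundTruth]:
    """Raw sensor traces; z-score them with :func:`gliasleep.sensor.session_zscore`.

    When ``state_coupling`` is set, a hypnogram covering the recording must
    be supplied (or one is drawn from the default Markov chain); per-frame
    offsets of ``coupling[state] × noise_sd`` are added.  ``effect_true``
    is the injected step size per ROI, in noise-SD (≈ z-score) units.
    """
    rng = np.random.default_rng(cfg.seed)
    n_frames = int(cfg.duration_s * cfg.frame_rate)
    t = np.arange(n_frames) / cfg.frame_rate
    lag = t - cfg.treatment_time_s
    step = np.where(lag > 0, 1.0 - np.exp(-np.maximum(lag, 0) / cfg.effect_onset_tau_s), 0.0)
    offsets = np.zeros(n_frames)
    if cfg.state_coupling:
        if hypnogram is None:
            states = sample_markov_states(
                default_transition_matrix(),
                int(np.ceil(cfg.duration_s / 5.0)),
                np.random.default_rng(cfg.seed + 1),
            )
            hypnogram = Hypnogram(states=states, epoch_s=5.0)
        epoch_idx = np.minimum(
            np.floor(t / hypnogram.epoch_s).astype(int), hypnogram.n_epochs - 1
        )
        frame_state = hypnogram.states[epoch_idx]
        for state, level in cfg.state_coupling.items():
            offsets[frame_state == state] = level * cfg.noise_sd
    signal_au = (
        cfg.baseline_level
        + cfg.effect_size_z * cfg.noise_sd * step
        + offsets
    )
    traces = [
        RoiTrace(
            values=signal_au + cfg.noise_sd * rng.standard_normal(n_frames),
            frame_rate=cfg.frame_rate,
            roi_id=f"roi{r:03d}",
        )
        for r in range(cfg.n_rois)
    ]
    truth = GroundTruth(
        effect_true=np.full(cfg.n_rois, float(cfg.effect_size_z)),
        hypnogram_true=hypnogram,
    )
    return TraceSet(traces=traces), truth


@dataclass
class VolumeSynthConfig:
    """Spherical "microglia" scattered in an anisotropic voxel grid."""

    shape_voxels: tuple[int, int, int] = (32, 64, 64)  # (z, y, x)
    voxel_size_um: tuple[float, float, float] = (1.0, 0.41, 0.41)
    n_spheres: int = 20
    radius_um: tuple[float, float] = (2.0, 5.0)
    n_boutons: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.voxel_size_um):
            raise ValueError("voxel sizes must be positive")
        if self.n_spheres == 0 and self.n_boutons > 0:
            raise ValueError("boutons need at least one sphere for distances")
        extents = [
            (n - 1) * v for n, v in zip(self.shape_voxels, self.voxel_size_um)
        ]
        if 2 * self.radius_um[1] > min(extents):
            raise ValueError("largest sphere does not fit inside the volume")
        if not 0 < self.radius_um[0] <= self.radius_um[1]:
            raise ValueError("radius range must be positive and ordered")


def sphere_min_distances(
    points_xyz_um: np.ndarray,
    centers_xyz_um: np.ndarray,
    radii_um: np.ndarray,
) -> np.ndarray:
    """Analytic minimal distance from points to a union of spheres.

    For each point p: min over spheres of max(0, |p − c| − r); zero for
    points inside any sphere.
    """
    p = np.atleast_2d(np.asarray(points_xyz_um, float))
    c = np.atleast_2d(np.asarray(centers_xyz_um, float))
    r = np.asarray(radii_um, float)
    d = np.linalg.norm(p[:, None, :] - c[None, :, :], axis=2) - r[None, :]
    return np.maximum(d, 0.0).min(axis=1)


def gen_volume(cfg: VolumeSynthConfig) -> tuple[VolumeScene, GroundTruth]:
    """Rasterized spheres plus uniformly scattered bouton points.

    ``distances_true`` holds the analytic minimal surface distance
    ``max(0, |p − c| − r)`` minimized over spheres; the voxel-based module
    agrees with it to within one voxel diagonal.
    """
    rng = np.random.default_rng(cfg.seed)
    nz, ny, nx = cfg.shape_voxels
    vz, vy, vx = cfg.voxel_size_um
    extents = np.array([(nz - 1) * vz, (ny - 1) * vy, (nx - 1) * vx])  # (z, y, x)
    radii = rng.uniform(cfg.radius_um[0], cfg.radius_um[1], size=cfg.n_spheres)
    # sphere centres drawn so each sphere fits entirely inside the volume
    centers = np.column_stack(
        [rng.uniform(radii, extents[a] - radii) for a in range(3)]
    )  # (n_spheres, 3) physical (z, y, x)
    zc = np.arange(nz) * vz
    yc = np.arange(ny) * vy
    xc = np.arange(nx) * vx
    mask = np.zeros((nz, ny, nx), dtype=bool)
    for (czi, cyi, cxi), r in zip(centers, radii):
        dz2 = (zc - czi) ** 2
        dy2 = (yc - cyi) ** 2
        dx2 = (xc - cxi) ** 2
        mask |= (
            dz2[:, None, None] + dy2[None, :, None] + dx2[None, None, :]
        ) <= r**2
    boutons_zyx = rng.uniform(0, extents, size=(cfg.n_boutons, 3))
    boutons_xyz = boutons_zyx[:, ::-1]
    if cfg.n_boutons:
        distances_true = sphere_min_distances(
            boutons_xyz, centers[:, ::-1], radii
        )
    else:
        distances_true = np.empty(0)
    scene = VolumeScene(
        mask=mask, voxel_size_um=cfg.voxel_size_um, boutons_um=boutons_xyz
    )
    return scene, GroundTruth(distances_true=distances_true)
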