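"""Readers and writers for the pipeline's interchange formats.

CSV (+ JSON sidecar for metadata) and NPZ are the canonical formats;
volumes travel as multi-page TIFF z-stacks with a bouton CSV.  EDF input
is supported when ``mne`` is installed.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .calcium import CaEvent, RoiTrace, TraceSet
from .distance import DistanceResult, VolumeScene
from .sleep import Hypnogram, Recording
from .synth import GroundTruth


def sidecar_path(path: str | Path) -> Path:
    return Path(str(path) + ".json")


def _write_sidecar(path: str | Path, meta: dict) -> None:
    sidecar_path(path).write_text(json.dumps(meta, indent=2, sort_keys=True))


def _read_sidecar(path: str | Path) -> dict:
    return json.loads(sidecar_path(path).read_text())


# -- recordings ---------------------------------------------------------------

def write_recording(rec: Recording, path: str | Path) -> None:
    """Write EEG/EMG to ``.npz`` (preferred) or ``.csv`` plus a sidecar."""
    path = Path(path)
    if path.suffix == ".npz":
        np.savez(path, eeg=rec.eeg, emg=rec.emg)
    elif path.suffix == ".csv":
        pd.DataFrame({"eeg": rec.eeg, "emg": rec.emg}).to_csv(path, index=False)
    else:
        raise ValueError(f"unsupported recording format {path.suffix!r}")
    _write_sidecar(
        path,
        {"fs": rec.fs, "start_time_s": rec.start_time_s, "channels": ["eeg", "emg"]},
    )


def read_recording(path: str | Path) -> Recording:
    path = Path(path)
    if path.suffix == ".edf":
        return _read_edf(path)
    meta = _read_sidecar(path)
    if path.suffix == ".npz":
        with np.load(path) as data:
            eeg, emg = data["eeg"], data["emg"]
    elif path.suffix == ".csv":
        frame = pd.read_csv(path)
        eeg, emg = frame["eeg"].to_numpy(), frame["emg"].to_numpy()
    else:
        raise ValueError(f"unsupported recording format {path.suffix!r}")
    return Recording(
        eeg=eeg, emg=emg, fs=float(meta["fs"]), start_time_s=float(meta.get("start_time_s", 0.0))
    )


def _read_edf(path: Path) -> Recording:
    try:
        import mne
    except ImportError as err:  # pragma: no cover - optional dependency
        raise ImportError(
            "EDF input requires the optional 'mne' dependency"
        ) from err
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    names = {n.upper(): n for n in raw.ch_names}
    try:
        eeg = raw.get_data(picks=[names["EEG"]])[0] * 1e6
        emg = raw.get_data(picks=[names["EMG"]])[0] * 1e6
    except KeyError as err:
        raise ValueError("EDF must contain channels named EEG and EMG") from err
    return Recording(eeg=eeg, emg=emg, fs=float(raw.info["sfreq"]))


# -- hypnograms ---------------------------------------------------------------

def write_hypnogram(h: Hypnogram, path: str | Path) -> None:
    pd.DataFrame(
        {
            "epoch_index": np.arange(h.n_epochs),
            "start_s": np.arange(h.n_epochs) * h.epoch_s,
            "state": h.states,
        }
    ).to_csv(path, index=False)


def read_hypnogram(path: str | Path) -> Hypnogram:
    frame = pd.read_csv(path)
    if len(frame) > 1:
        epoch_s = float(frame["start_s"].iloc[1] - frame["start_s"].iloc[0])
    else:
        epoch_s = 5.0
    return Hypnogram(states=frame["state"].to_numpy(dtype="<U1"), epoch_s=epoch_s)


def read_override(path: str | Path) -> dict[int, str]:
    """Manual relabel file: CSV with epoch_index,state columns."""
    frame = pd.read_csv(path)
    return {
        int(row.epoch_index): str(row.state)
        for row in frame.itertuples(index=False)
    }


# -- ROI traces ---------------------------------------------------------------

def write_traces(ts: TraceSet, path: str | Path) -> None:
    """CSV with ``time_s`` plus one column per ROI, sidecar with metadata."""
    path = Path(path)
    n = ts.n_frames
    data = {"time_s": np.arange(n) / ts.frame_rate}
    for tr in ts.traces:
        data[tr.roi_id] = tr.values
    pd.DataFrame(data).to_csv(path, index=False)
    _write_sidecar(
        path,
        {
            "frame_rate": ts.frame_rate,
            "compartment": {t.roi_id: t.compartment for t in ts.traces},
            "cell_id": {t.roi_id: t.cell_id for t in ts.traces},
        },
    )


def read_traces(path: str | Path) -> TraceSet:
    path = Path(path)
    meta = _read_sidecar(path)
    frame = pd.read_csv(path)
    roi_cols = [c for c in frame.columns if c != "time_s"]
    traces = [
        RoiTrace(
            values=frame[c].to_numpy(dtype=float),
            frame_rate=float(meta["frame_rate"]),
            roi_id=c,
            compartment=meta.get("compartment", {}).get(c, "process"),
            cell_id=meta.get("cell_id", {}).get(c, c),
        )
        for c in roi_cols
    ]
    return TraceSet(traces=traces)


# -- events and stats ---------------------------------------------------------

def events_to_frame(
    events_by_roi: dict[str, list[CaEvent]], frame_rate: float
) -> pd.DataFrame:
    rows = []
    for roi_id, events in events_by_roi.items():
        for ev in events:
            rows.append(
                {
                    "roi_id": roi_id,
                    "onset_s": ev.onset_frame / frame_rate,
                    "peak_s": ev.peak_frame / frame_rate,
                    "amplitude": ev.amplitude,
                    "duration_s": ev.duration_s,
                }
            )
    return pd.DataFrame(
        rows, columns=["roi_id", "onset_s", "peak_s", "amplitude", "duration_s"]
    )


# -- volumes ------------------------------------------------------------------

def write_volume(scene: VolumeScene, mask_path: str | Path, boutons_path: str | Path) -> None:
    """Multi-page uint8 TIFF (0/255) plus bouton CSV and voxel sidecar."""
    import tifffile

    tifffile.imwrite(mask_path, (scene.mask.astype(np.uint8) * 255))
    _write_sidecar(mask_path, {"voxel_size_um": list(scene.voxel_size_um)})
    pd.DataFrame(scene.boutons_um, columns=["x_um", "y_um", "z_um"]).to_csv(
        boutons_path, index=False
    )


def read_volume(
    mask_path: str | Path,
    boutons_path: str | Path,
    voxel_size_um: tuple[float, float, float] | None = None,
) -> VolumeScene:
    import tifffile

    mask = tifffile.imread(mask_path) > 0
    if voxel_size_um is None:
        voxel_size_um = tuple(_read_sidecar(mask_path)["voxel_size_um"])
    boutons = pd.read_csv(boutons_path)[["x_um", "y_um", "z_um"]].to_numpy(float)
    return VolumeScene(mask=mask, voxel_size_um=voxel_size_um, boutons_um=boutons)


def write_distances(result: DistanceResult, path: str | Path) -> None:
    pd.DataFrame({"distance_um": result.distances_um}).to_csv(path, index=False)
    hist = pd.DataFrame(
        {
            "bin_start_um": result.bin_edges_um[:-1],
            "bin_end_um": result.bin_edges_um[1:],
            "count": result.histogram,
        }
    )
    hist.to_csv(Path(path).with_name(Path(path).stem + "_hist.csv"), index=False)


# -- ground truth -------------------------------------------------------------

def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    payload: dict = {}
    if truth.hypnogram_true is not None:
        payload["hypnogram_true"] = {
            "states": truth.hypnogram_true.states.tolist(),
            "epoch_s": truth.hypnogram_true.epoch_s,
        }
    if truth.events_true is not None:
        payload["events_true"] = [
            [[onset, amp] for onset, amp in roi] for roi in truth.events_true
        ]
    if truth.effect_true is not None:
        payload["effect_true"] = np.asarray(truth.effect_true).tolist()
    if truth.distances_true is not None:
        payload["distances_true"] = np.asarray(truth.distances_true).tolist()
    Path(path).write_text(json.dumps(payload))
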