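"""End-to-end orchestration: synth → score → detect → align → contrast.

``run_pipeline`` executes the stages named in a single config document in
dependency order, writing every artifact as CSV/NPZ/TIFF plus a provenance
JSON.  Re-running with the same config and seed reproduces all numeric
outputs byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import align as align_mod
from . import calcium as ca
from . import distance as dist_mod
from . import io as gio
from . import sensor as sensor_mod
from . import sleep as sleep_mod
from . import stats as stats_mod
from . import synth

__version__ = "0.1.0"


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def _validate_inputs(config: dict) -> None:
    """Fail before any stage runs if a referenced input file is missing."""
    for stage, stanza in config.items():
        if not isinstance(stanza, dict):
            continue
        for key, value in stanza.items():
            if key.endswith(("_path", "_file")) and value is not None:
                if not Path(value).exists():
                    raise PipelineError(
                        f"stage '{stage}': input file not found: {value}"
                    )


def run_pipeline(config: dict, out_dir: str | Path) -> Path:
    """Run the configured stages; returns the artifact directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _validate_inputs(config)
    seed = int(config.get("seed", 0))
    runtimes: dict[str, float] = {}
    state: dict = {}

    stages = [
        ("synth", _stage_synth),
        ("sleep", _stage_sleep),
        ("calcium", _stage_calcium),
        ("align", _stage_align),
        ("sensor", _stage_sensor),
        ("distance", _stage_distance),
        ("stats", _stage_stats),
    ]
    for name, fn in stages:
        if name not in config:
            continue
        t0 = time.perf_counter()
        try:
            fn(config[name] or {}, seed, out, state)
        except PipelineError:
            raise
        except Exception as err:
            raise PipelineError(f"stage '{name}': {err}") from err
        runtimes[name] = time.perf_counter() - t0

    provenance = {
        "config_sha256": hashlib.sha256(
            json.dumps(config, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "seed": seed,
        "version": __version__,
        "runtimes_s": runtimes,
    }
    (out / "provenance.json").write_text(json.dumps(provenance, indent=2))
    return out


# -- stages -------------------------------------------------------------------

def _stage_synth(stanza: dict, seed: int, out: Path, state: dict) -> None:
    if "sleep" in stanza:
        cfg = synth.SleepSynthConfig(**{"seed": seed, **stanza["sleep"]})
        rec, truth = synth.gen_sleep_session(cfg)
        gio.write_recording(rec, out / "recording.npz")
        gio.write_ground_truth(truth, out / "sleep_truth.json")
        state["recording"] = rec
        state["hypnogram_true"] = truth.hypnogram_true
    if "calcium" in stanza:
        cfg = synth.CalciumSynthConfig(**{"seed": seed, **stanza["calcium"]})
        traces, truth = synth.gen_calcium(cfg)
        gio.write_traces(traces, out / "calcium_traces.csv")
        gio.write_ground_truth(truth, out / "calcium_truth.json")
        state["calcium_traces"] = traces
        state["calcium_cfg"] = cfg
    if "sensor" in stanza:
        cfg = synth.SensorSynthConfig(**{"seed": seed, **stanza["sensor"]})
        traces, truth = synth.gen_sensor(cfg)
        gio.write_traces(traces, out / "sensor_traces.csv")
        gio.write_ground_truth(truth, out / "sensor_truth.json")
        state["sensor_traces"] = traces
        state["sensor_cfg"] = cfg
        state["sensor_hypnogram"] = truth.hypnogram_true
    if "volume" in stanza:
        cfg = synth.VolumeSynthConfig(
            **{
                "seed": seed,
                **{
                    k: tuple(v) if isinstance(v, list) else v
                    for k, v in stanza["volume"].items()
                },
            }
        )
        scene, truth = synth.gen_volume(cfg)
        gio.write_volume(scene, out / "microglia_mask.tif", out / "boutons.csv")
        gio.write_ground_truth(truth, out / "volume_truth.json")
        state["volume"] = scene


def _stage_sleep(stanza: dict, seed: int, out: Path, state: dict) -> None:
    if stanza.get("recording_path"):
        rec = gio.read_recording(stanza["recording_path"])
    elif "recording" in state:
        rec = state["recording"]
    else:
        raise PipelineError("stage 'sleep': no recording available")
    epoch_s = float(stanza.get("epoch_s", 5.0))
    freqs, psd = sleep_mod.epoch_spectrogram(rec, epoch_s=epoch_s)
    features = sleep_mod.extract_features(freqs, psd, rec.emg, rec.fs, epoch_s)
    h = sleep_mod.classify_epochs(
        features,
        emg_threshold=stanza.get("emg_threshold"),
        ratio_threshold=float(stanza.get("ratio_threshold", 1.5)),
        smooth=bool(stanza.get("smooth", True)),
    )
    if stanza.get("override_path"):
        h = sleep_mod.apply_override(h, gio.read_override(stanza["override_path"]))
    gio.write_hypnogram(h, out / "hypnogram.csv")
    metrics = sleep_mod.state_metrics(h, bin_s=float(stanza.get("bin_s", 1800.0)))
    metrics.percent_time.to_csv(out / "state_percent.csv", index=False)
    pd.DataFrame(
        {
            "state": list(sleep_mod.STATES),
            "mean_episode_duration_s": [
                metrics.mean_episode_duration_s[s] for s in sleep_mod.STATES
            ],
            "episodes_per_hour": [
                metrics.episodes_per_hour[s] for s in sleep_mod.STATES
            ],
        }
    ).to_csv(out / "episode_metrics.csv", index=False)
    state["hypnogram"] = h


def _stage_calcium(stanza: dict, seed: int, out: Path, state: dict) -> None:
    if stanza.get("traces_path"):
        traces = gio.read_traces(stanza["traces_path"])
    elif "calcium_traces" in state:
        traces = state["calcium_traces"]
    else:
        raise PipelineError("stage 'calcium': no traces available")
    n_sd = float(stanza.get("n_sd", 3.0))
    min_frames = int(stanza.get("min_frames", 3))
    half_window_s = float(stanza.get("half_window_s", 600.0))
    events_by_roi: dict[str, list[ca.CaEvent]] = {}
    for trace in traces.traces:
        f0 = ca.sliding_baseline(trace, half_window_s=half_window_s)
        d = ca.compute_dff(trace, f0)
        events_by_roi[trace.roi_id] = ca.detect_events(
            d, n_sd=n_sd, min_frames=min_frames
        )
    gio.events_to_frame(events_by_roi, traces.frame_rate).to_csv(
        out / "calcium_events.csv", index=False
    )
    state["calcium_events"] = events_by_roi


def _stage_align(stanza: dict, seed: int, out: Path, state: dict) -> None:
    h = state.get("sensor_hypnogram") or state.get("hypnogram")
    if stanza.get("hypnogram_path"):
        h = gio.read_hypnogram(stanza["hypnogram_path"])
    traces = state.get("sensor_traces")
    if stanza.get("traces_path"):
        traces = gio.read_traces(stanza["traces_path"])
    if h is None or traces is None:
        raise PipelineError("stage 'align': needs a hypnogram and traces")
    z = np.mean(
        [
            ca.zscore_trace(t.values, traces.frame_rate, (0.0, h.duration_s))
            for t in traces.traces
        ],
        axis=0,
    )
    rows = []
    for from_state, to_state in (("N", "W"), ("W", "N")):
        transitions = align_mod.find_transitions(
            h,
            from_state,
            to_state,
            min_flank_s=float(stanza.get("min_flank_s", 30.0)),
        )
        if not transitions:
            continue
        aligned = align_mod.align_traces(
            z,
            traces.frame_rate,
            transitions,
            window_s=(
                float(stanza.get("pre_s", 60.0)),
                float(stanza.get("post_s", 60.0)),
            ),
        )
        contrast = align_mod.transition_contrast(aligned)
        rows.append(
            {
                "transition": f"{from_state}->{to_state}",
                "n": aligned.matrix.shape[0],
                "contrast": contrast,
            }
        )
    pd.DataFrame(rows).to_csv(out / "transition_contrasts.csv", index=False)


def _stage_sensor(stanza: dict, seed: int, out: Path, state: dict) -> None:
    traces = state.get("sensor_traces")
    if stanza.get("traces_path"):
        traces = gio.read_traces(stanza["traces_path"])
    if traces is None:
        raise PipelineError("stage 'sensor': no traces available")
    cfg = state.get("sensor_cfg")
    treatment_time_s = float(
        stanza.get("treatment_time_s", cfg.treatment_time_s if cfg else 2400.0)
    )
    session = sensor_mod.session_zscore(
        traces,
        baseline_window=(0.0, treatment_time_s),
        treatment_time_s=treatment_time_s,
        treatment_label=str(stanza.get("treatment_label", "")),
    )
    pre = tuple(stanza.get("pre_min", sensor_mod.PRE_WINDOW_DRUG_MIN))
    post = tuple(stanza.get("post_min", sensor_mod.POST_WINDOW_DRUG_MIN))
    contrast = sensor_mod.delta_z(session, pre_min=pre, post_min=post)
    pd.DataFrame(
        [
            {
                "treatment": session.treatment_label,
                "delta_z": contrast.delta_z,
                "pre_start_min": contrast.pre_window_min[0],
                "pre_end_min": contrast.pre_window_min[1],
                "post_start_min": contrast.post_window_min[0],
                "post_end_min": contrast.post_window_min[1],
            }
        ]
    ).to_csv(out / "sensor_contrast.csv", index=False)


def _stage_distance(stanza: dict, seed: int, out: Path, state: dict) -> None:
    if stanza.get("mask_path") and stanza.get("boutons_path"):
        scene = gio.read_volume(stanza["mask_path"], stanza["boutons_path"])
    elif "volume" in state:
        scene = state["volume"]
    else:
        raise PipelineError("stage 'distance': no volume available")
    result = dist_mod.min_distances(scene, bin_um=float(stanza.get("bin_um", 1.0)))
    gio.write_distances(result, out / "bouton_distances.csv")


def _stage_stats(stanza: dict, seed: int, out: Path, state: dict) -> None:
    events = state.get("calcium_events")
    traces = state.get("calcium_traces")
    cfg = state.get("calcium_cfg")
    if not events or traces is None:
        raise PipelineError("stage 'stats': needs calcium events upstream")
    mid = (cfg.duration_s / 2.0) if cfg else traces.n_frames / traces.frame_rate / 2.0
    end = traces.n_frames / traces.frame_rate
    pre, post = [], []
    for trace in traces.traces:
        z = ca.zscore_trace(trace.values, traces.frame_rate, (0.0, mid))
        evs = events[trace.roi_id]
        pre.append(
            ca.event_stats(evs, z, traces.frame_rate, (0.0, mid)).freq_per_min
        )
        post.append(
            ca.event_stats(evs, z, traces.frame_rate, (mid, end)).freq_per_min
        )
    result = stats_mod.paired_compare(np.array(pre), np.array(post))
    pd.DataFrame(
        [
            {
                "comparison": "event_freq_pre_vs_post",
                "test": result.test_name,
                "statistic": result.statistic,
                "p_value": result.p_value,
            }
        ]
    ).to_csv(out / "stats_results.csv", index=False)
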