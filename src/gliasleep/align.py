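"""State-conditioned means and brain-state-transition-triggered averages.

Any z-scored trace (microglia calcium, GRAB sensor) can be summarized
against a hypnogram: the mean level within a state, and the average trace
around NREM→wake / wake→NREM transitions with flanking-episode duration
criteria.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .sleep import Hypnogram, merge_episodes

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Transition:
    """A state boundary flanked by sufficiently long episodes."""

    time_s: float
    from_state: str
    to_state: str

    def __post_init__(self) -> None:
        if self.from_state == self.to_state:
            raise ValueError("transition requires distinct states")


@dataclass
class AlignedTraces:
    """Trace segments stacked around transitions.

    ``matrix`` has one row per usable transition; ``offsets_s`` is the
    common time grid relative to the transition (negative = before).
    ``sem`` is NaN at every offset when only one row is available.
    """

    matrix: np.ndarray
    offsets_s: np.ndarray
    mean: np.ndarray
    sem: np.ndarray


def frame_states(
    h: Hypnogram, n_frames: int, frame_rate: float
) -> np.ndarray:
    """Map each frame to its epoch's state (half-open epochs, floor rule)."""
    t = np.arange(n_frames) / frame_rate
    idx = np.floor(t / h.epoch_s).astype(int)
    if idx[-1] >= h.n_epochs:
        raise ValueError("hypnogram does not cover the trace span")
    return h.states[idx]


def state_mean(
    z: np.ndarray,
    frame_rate: float,
    h: Hypnogram,
    state: str,
    exclude: frozenset[str] | set[str] = frozenset({"R"}),
) -> float:
    """Mean of ``z`` over frames whose epoch is labelled ``state``.

    Returns NaN when the state is absent from the covered span.  States
    in ``exclude`` are never averaged (REM is excluded by default because
    imaging during REM is confounded by hemodynamic changes).
    """
    if state in exclude:
        raise ValueError(f"state {state!r} is in the excluded set")
    z = np.asarray(z, dtype=float)
    labels = frame_states(h, z.size, frame_rate)
    mask = labels == state
    if not np.any(mask):
        return float("nan")
    return float(z[mask].mean())


def find_transitions(
    h: Hypnogram,
    from_state: str,
    to_state: str,
    min_flank_s: float = 30.0,
) -> list[Transition]:
    """Boundaries where a long-enough episode of ``from_state`` is
    immediately followed by a long-enough episode of ``to_state``."""
    if from_state == to_state:
        raise ValueError("from_state and to_state must differ")
    episodes = merge_episodes(h)
    out: list[Transition] = []
    for prev, nxt in zip(episodes, episodes[1:]):
        if (
            prev.state == from_state
            and nxt.state == to_state
            and prev.duration_s >= min_flank_s
            and nxt.duration_s >= min_flank_s
        ):
            out.append(
                Transition(time_s=nxt.start_s, from_state=from_state, to_state=to_state)
            )
    return out


def align_traces(
    z: np.ndarray,
    frame_rate: float,
    transitions: list[Transition],
    window_s: tuple[float, float] = (60.0, 60.0),
) -> AlignedTraces:
    """Stack trace segments around transitions on a common offset grid.

    ``window_s`` is (pre, post) in seconds, both positive.  Segments use
    nearest-frame sampling on the trace's own frame grid; transitions whose
    window extends past the trace are dropped (logged).  Raises when no
    transition is usable.
    """
    pre, post = window_s
    if pre < 0 or post < 0 or pre + post == 0:
        raise ValueError("window must be nonempty")
    z = np.asarray(z, dtype=float)
    n_pre = int(round(pre * frame_rate))
    n_post = int(round(post * frame_rate))
    offsets = np.arange(-n_pre, n_post + 1) / frame_rate
    rows = []
    for tr in transitions:
        center = int(round(tr.time_s * frame_rate))
        lo, hi = center - n_pre, center + n_post
        if lo < 0 or hi >= z.size:
            logger.info(
                "transition at %.1f s dropped: window exceeds trace", tr.time_s
            )
            continue
        rows.append(z[lo : hi + 1])
    if not rows:
        raise ValueError("no transition has a fully covered window")
    matrix = np.vstack(rows)
    mean = matrix.mean(axis=0)
    if matrix.shape[0] > 1:
        sem = matrix.std(axis=0, ddof=1) / np.sqrt(matrix.shape[0])
    else:
        sem = np.full(matrix.shape[1], np.nan)
    return AlignedTraces(matrix=matrix, offsets_s=offsets, mean=mean, sem=sem)


def transition_contrast(aligned: AlignedTraces) -> float:
    """mean(post-transition) − mean(pre-transition) of the aligned average."""
    pre = aligned.mean[aligned.offsets_s < 0]
    post = aligned.mean[aligned.offsets_s > 0]
    if pre.size == 0 or post.size == 0:
        raise ValueError("window must include frames on both sides of 0")
    return float(post.mean() - pre.mean())
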