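"""Stance/swing/abnormal frame labelling and gait-cycle segmentation.

Touch-down (stance onset) is taken at local maxima of the smoothed
anterior-positive pendulum angle — the limb at maximal protraction — and
lift-off (swing onset) at local minima (maximal retraction).  A gait
cycle runs stance-onset to stance-onset, so stance precedes swing within
each cycle.  Any cycle containing an unreliable (abnormal) frame fails QC
and is excluded from downstream statistics.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy.signal import find_peaks

from . import kinematics
from .kinematics import AngleSample

DEFAULT_SMOOTH_WINDOW = 5
DEFAULT_MIN_HALF_CYCLE_MS = 60.0


class InsufficientDataError(ValueError):
    """Too few frames or onsets to perform the requested segmentation."""


class PhaseLabel(str, Enum):
    STANCE = "stance"
    SWING = "swing"
    ABNORMAL = "abnormal"


@dataclass(frozen=True)
class GaitCycle:
    """One stance-onset -> swing-onset -> next-stance-onset triple.

    Durations are frame counts converted at the session frame rate;
    ``cycle_ms = stance_ms + swing_ms`` by construction.
    """

    stance_onset: int
    swing_onset: int
    end: int
    stance_ms: float
    swing_ms: float
    cycle_ms: float
    qc_pass: bool

    def __post_init__(self) -> None:
        if not (self.stance_onset < self.swing_onset < self.end):
            raise ValueError("cycle onsets must be strictly ordered")


def _moving_average(x: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with edge shrinkage (no phase shift)."""
    if window <= 1:
        return x.astype(float)
    kernel = np.ones(window) / window
    smoothed = np.convolve(x, kernel, mode="same")
    # renormalise the shrinking edge windows
    norm = np.convolve(np.ones_like(x, dtype=float), kernel, mode="same")
    return smoothed / norm


def detect_transitions(
    pendulum: np.ndarray,
    fps: float,
    smooth_window: int = DEFAULT_SMOOTH_WINDOW,
    min_half_cycle_ms: float = DEFAULT_MIN_HALF_CYCLE_MS,
    min_prominence_frac: float = 0.2,
) -> tuple[np.ndarray, np.ndarray]:
    """Find stance and swing onsets from the pendulum-angle trace.

    Parameters
    ----------
    pendulum:
        Anterior-positive pendulum angle per frame, degrees.
    fps:
        Frame rate; converts the refractory period to frames.
    smooth_window:
        Centered moving-average width in frames applied before peak
        picking (default 5).
    min_half_cycle_ms:
        Extrema of the same kind closer than this are duplicates: the
        more extreme one is kept.  Default 60 ms, about half the
        shortest physiological swing duration.
    min_prominence_frac:
        Peaks must rise at least this fraction of the trace's 5-95
        percentile span above their surroundings; rejects residual
        noise wiggles on the slow stance-phase retraction that survive
        smoothing.

    Returns
    -------
    (stance_onsets, swing_onsets):
        Frame indices; alternation is enforced (between two stance
        onsets exactly one swing onset survives).
    """
    pend = np.asarray(pendulum, dtype=float)
    if fps <= 0:
        raise ValueError("fps must be positive")
    if pend.size < 3:
        raise InsufficientDataError("pendulum trace too short")
    smoothed = _moving_average(pend, smooth_window)
    distance = max(1, int(round(min_half_cycle_ms / 1000.0 * fps)))
    span = float(np.percentile(smoothed, 95) - np.percentile(smoothed, 5))
    prominence = min_prominence_frac * span if span > 0 else None
    maxima, _ = find_peaks(smoothed, distance=distance, prominence=prominence)
    minima, _ = find_peaks(-smoothed, distance=distance, prominence=prominence)

    # merge and enforce strict alternation, keeping the more extreme of
    # any same-kind run
    events = sorted(
        [(int(i), "max") for i in maxima] + [(int(i), "min") for i in minima]
    )
    cleaned: list[tuple[int, str]] = []
    for idx, kind in events:
        if cleaned and cleaned[-1][1] == kind:
            prev_idx, _ = cleaned[-1]
            better = (
                idx if (smoothed[idx] > smoothed[prev_idx]) == (kind == "max") else prev_idx
            )
            cleaned[-1] = (better, kind)
        else:
            cleaned.append((idx, kind))
    stance = np.array([i for i, k in cleaned if k == "max"], dtype=int)
    swing = np.array([i for i, k in cleaned if k == "min"], dtype=int)
    return stance, swing


def label_frames(
    samples: list[AngleSample],
    transitions: tuple[np.ndarray, np.ndarray],
) -> list[PhaseLabel]:
    """Assign every frame exactly one of stance / swing / abnormal.

    Frames in [stance_onset, swing_onset) are stance, [swing_onset, next
    stance_onset) swing.  Invalid frames (likelihood gate or degenerate
    geometry) are abnormal regardless of phase, as are frames before the
    first and at/after the last detected transition.
    """
    stance_onsets, swing_onsets = transitions
    n = len(samples)
    labels = [PhaseLabel.ABNORMAL] * n
    events = sorted(
        [(int(i), PhaseLabel.STANCE) for i in stance_onsets]
        + [(int(i), PhaseLabel.SWING) for i in swing_onsets]
    )
    for k in range(len(events) - 1):
        start, phase = events[k]
        stop = events[k + 1][0]
        for i in range(max(start, 0), min(stop, n)):
            labels[i] = phase
    for i, s in enumerate(samples):
        if not s.valid:
            labels[i] = PhaseLabel.ABNORMAL
    return labels


def segment_cycles(
    labels: list[PhaseLabel],
    transitions: tuple[np.ndarray, np.ndarray],
    fps: float,
) -> list[GaitCycle]:
    """Segment labelled frames into gait cycles with QC flags.

    One cycle per consecutive pair of stance onsets; the intervening
    swing onset splits it.  ``qc_pass`` is False iff any frame inside the
    cycle is abnormal.
    """
    stance_onsets, swing_onsets = transitions
    stance_onsets = np.asarray(stance_onsets, dtype=int)
    swing_onsets = np.asarray(swing_onsets, dtype=int)
    if stance_onsets.size < 2:
        raise InsufficientDataError("need at least 2 stance onsets")
    frame_ms = 1000.0 / fps
    cycles: list[GaitCycle] = []
    for a, b in zip(stance_onsets, stance_onsets[1:]):
        inside = swing_onsets[(swing_onsets > a) & (swing_onsets < b)]
        if inside.size != 1:
            continue  # alternation violated locally; skip this pair
        m = int(inside[0])
        qc = all(
            labels[i] != PhaseLabel.ABNORMAL for i in range(a, min(b, len(labels)))
        )
        cycles.append(
            GaitCycle(
                stance_onset=int(a),
                swing_onset=m,
                end=int(b),
                stance_ms=(m - a) * frame_ms,
                swing_ms=(b - m) * frame_ms,
                cycle_ms=(b - a) * frame_ms,
                qc_pass=qc,
            )
        )
    return cycles


def label_session(
    session,
    likelihood_threshold: float = 0.8,
    smooth_window: int = DEFAULT_SMOOTH_WINDOW,
    min_half_cycle_ms: float = DEFAULT_MIN_HALF_CYCLE_MS,
):
    """Offline labelling pipeline for one session.

    Runs angle extraction, pendulum-extremum transition detection, frame
    labelling and cycle segmentation; returns
    ``(angle_samples, labels, transitions, cycles)``.
    """
    samples = kinematics.angles_from_session(session, likelihood_threshold)
    pend = np.array([s.pendulum_deg for s in samples])
    # interpolate over invalid frames so dropouts cannot fake extrema
    bad = ~np.isfinite(pend)
    if bad.any() and (~bad).any():
        idx = np.arange(len(pend))
        pend[bad] = np.interp(idx[bad], idx[~bad], pend[~bad])
    transitions = detect_transitions(
        pend, session.fps, smooth_window, min_half_cycle_ms
    )
    labels = label_frames(samples, transitions)
    cycles = segment_cycles(labels, transitions, session.fps)
    return samples, labels, transitions, cycles
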