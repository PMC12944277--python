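"""Streaming closed-loop simulator.

Replays a session frame by frame through the deployed signal path:
landmarks -> joint angles -> fixed-width serial codec -> classifier ->
debounced phase machine -> phase-triggered stimulation.  Processing is
strictly causal — no frame is inspected before its turn, and offline
pendulum-based transition detection is never consulted: at runtime the
classifier alone drives the state, exactly as on the embedded target.

Latency is reported analytically (serial wire time from the transmission
model plus measured wall-clock per software stage) and labelled a
simulation; it does not model any particular hardware.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np

from . import kinematics
from .gait_events import PhaseLabel
from .phase_classifier import MlpModel, PhasePosterior, predict
from .pose_io import (
    SERIAL_FRAME_BYTES,
    SerialFrameError,
    Session,
    decode_angle_frame,
    encode_angle_frame,
    serial_transmission_time,
)
from .stimulation import PhaseState, StimConfig, StimTrain, schedule_train, update_state


@dataclass
class LoopTickRecord:
    """Everything the loop knew and decided at one frame."""

    frame_index: int
    angles: tuple[float, float, float] | None
    posterior: PhasePosterior | None
    state: PhaseLabel
    stance_line: bool
    swing_line: bool
    dropped: bool
    stage_ms: dict[str, float] = field(default_factory=dict)


@dataclass
class RunSummary:
    n_frames: int
    n_dropped: int
    phase_counts: dict[str, int]
    serial_ms_115200: float
    serial_ms_921600: float
    mean_stage_ms: dict[str, float]


def run_stream(
    session: Session,
    model: MlpModel,
    stim_config: StimConfig | None = None,
    debounce_frames: int = 2,
    serial_bits_per_byte: int = 10,
) -> tuple[list[LoopTickRecord], dict[str, StimTrain], RunSummary]:
    """Run the closed loop over a session.

    Returns per-tick records, the stance/swing channel stimulation
    trains, and a summary with phase counts and the analytic latency
    budget.  A malformed or un-encodable serial frame is logged as a
    drop (the state machine holds its last state) — never a crash.
    """
    if stim_config is None:
        stim_config = StimConfig()
    state = PhaseState()
    ticks: list[LoopTickRecord] = []
    timeline: list[PhaseLabel] = []
    stage_totals: dict[str, float] = {"angles": 0.0, "codec": 0.0, "inference": 0.0, "state": 0.0}
    n_dropped = 0

    for frame in session.frames:
        rec_angles = None
        posterior = None
        dropped = False
        stage_ms: dict[str, float] = {}

        t0 = time.perf_counter()
        sample = kinematics.angles_from_frame(
            frame, travel_direction=session.travel_direction
        )
        t1 = time.perf_counter()
        stage_ms["angles"] = (t1 - t0) * 1000.0
        try:
            payload = encode_angle_frame(
                (sample.hip_deg, sample.knee_deg, sample.ankle_deg)
            ).payload
            rec_angles = decode_angle_frame(payload)
        except (SerialFrameError, ValueError):
            dropped = True
            n_dropped += 1
        t2 = time.perf_counter()
        stage_ms["codec"] = (t2 - t1) * 1000.0

        if not dropped:
            posterior = predict(model, rec_angles)
            t3 = time.perf_counter()
            stage_ms["inference"] = (t3 - t2) * 1000.0
            state = update_state(state, posterior, debounce_frames)
            stage_ms["state"] = (time.perf_counter() - t3) * 1000.0
        else:
            # dropped frame: machine holds, but time still advances
            state = PhaseState(
                state.current, state.since, state.candidate,
                state.candidate_count, state.frame + 1,
            )
            stage_ms["inference"] = 0.0
            stage_ms["state"] = 0.0

        for k, v in stage_ms.items():
            stage_totals[k] += v
        timeline.append(state.current)
        ticks.append(
            LoopTickRecord(
                frame_index=frame.frame_index,
                angles=rec_angles,
                posterior=posterior,
                state=state.current,
                stance_line=state.stance_line,
                swing_line=state.swing_line,
                dropped=dropped,
                stage_ms=stage_ms,
            )
        )

    trains = {
        ch: schedule_train(timeline, session.fps, stim_config, ch)
        for ch in ("stance", "swing")
    }
    counts = {label.value: sum(1 for t in timeline if t == label) for label in PhaseLabel}
    n = max(len(ticks), 1)
    summary = RunSummary(
        n_frames=len(ticks),
        n_dropped=n_dropped,
        phase_counts=counts,
        serial_ms_115200=serial_transmission_time(
            SERIAL_FRAME_BYTES, 115_200, serial_bits_per_byte
        ),
        serial_ms_921600=serial_transmission_time(
            SERIAL_FRAME_BYTES, 921_600, serial_bits_per_byte
        ),
        mean_stage_ms={k: v / n for k, v in stage_totals.items()},
    )
    return ticks, trains, summary


def agreement_with_ground_truth(
    ticks: list[LoopTickRecord],
    truth_labels: list[PhaseLabel],
    exclude_window: int = 3,
) -> float:
    """Frame-level agreement between runtime states and ground truth.

    Frames within ``exclude_window`` of a ground-truth label change are
    excluded: the debounce deliberately trades a couple of frames of lag
    for stability, and scoring those frames would measure the debounce,
    not the classifier.
    """
    n = min(len(ticks), len(truth_labels))
    changes = [
        i for i in range(1, n) if truth_labels[i] != truth_labels[i - 1]
    ]
    excluded = set()
    for c in changes:
        excluded.update(range(max(0, c - exclude_window), min(n, c + exclude_window + 1)))
    scored = [i for i in range(n) if i not in excluded]
    if not scored:
        return float("nan")
    hits = sum(1 for i in scored if ticks[i].state == truth_labels[i])
    return hits / len(scored)
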