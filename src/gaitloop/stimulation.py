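"""Debounced phase state machine and biphasic stimulation synthesis.

Softmax posteriors are post-processed into a 3-state machine (stance /
swing / abnormal): the argmax candidate must persist for a configurable
number of consecutive frames before the state switches, except abnormal,
which takes over immediately as a safety override and silences both
channels.  Two reciprocal indicator lines mirror the state (never both
HIGH).

Stimulation is a charge-balanced symmetric biphasic pulse — a negative
then a positive phase of equal width and amplitude (default 200 µs each)
— repeated at the pulse frequency (default 100 Hz) for as long as the
triggering phase persists.  Amplitudes are quantised 12-bit DAC levels
(4096 steps); one channel serves stance (DAC1), the other swing (DAC2).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .gait_events import PhaseLabel
from .phase_classifier import PhasePosterior

DAC_LEVELS = 4096  # 12-bit converter


class StimConfigError(ValueError):
    pass


@dataclass(frozen=True)
class StimConfig:
    """Stimulation waveform and scheduling parameters.

    phase_width_us:
        Width of EACH of the two pulse phases, microseconds.
    frequency_hz:
        Pulse repetition rate while a gait phase persists.
    amplitude_level:
        DAC amplitude, integer in [0, 4095].
    sample_rate_hz:
        Synthesis grid; 1 MHz makes a 200 µs phase exactly 200 samples.
    burst_mode:
        ``phase_locked`` repeats pulses for the whole detected phase;
        ``fixed_duration`` emits pulses only for ``burst_duration_s``
        after each phase onset.
    onset_delay_us:
        Delay from phase onset to the first pulse.
    """

    phase_width_us: float = 200.0
    frequency_hz: float = 100.0
    amplitude_level: int = 1000
    sample_rate_hz: float = 1_000_000.0
    burst_mode: str = "phase_locked"
    burst_duration_s: float = 0.1
    onset_delay_us: float = 0.0

    def __post_init__(self) -> None:
        if not (0 <= self.amplitude_level < DAC_LEVELS):
            raise StimConfigError(
                f"amplitude_level must be in [0, {DAC_LEVELS - 1}]"
            )
        if self.phase_width_us <= 0 or self.frequency_hz <= 0:
            raise StimConfigError("phase width and frequency must be positive")
        if 2 * self.phase_width_us * 1e-6 > 1.0 / self.frequency_hz:
            raise StimConfigError("biphasic pulse does not fit in one period")
        if self.burst_mode not in ("phase_locked", "fixed_duration"):
            raise StimConfigError(f"unknown burst_mode {self.burst_mode!r}")

    @property
    def period_s(self) -> float:
        return 1.0 / self.frequency_hz

    @property
    def pulse_samples(self) -> int:
        return 2 * int(round(self.phase_width_us * 1e-6 * self.sample_rate_hz))


@dataclass
class PhaseState:
    """Current debounced phase plus the two reciprocal indicator lines."""

    current: PhaseLabel = PhaseLabel.ABNORMAL
    since: int = 0
    candidate: PhaseLabel | None = None
    candidate_count: int = 0
    frame: int = -1

    @property
    def stance_line(self) -> bool:
        return self.current == PhaseLabel.STANCE

    @property
    def swing_line(self) -> bool:
        return self.current == PhaseLabel.SWING


def update_state(
    state: PhaseState, posterior: PhasePosterior, debounce_frames: int = 2
) -> PhaseState:
    """Advance the phase machine by one frame.

    The argmax label must persist ``debounce_frames`` consecutive frames
    to take effect; an abnormal argmax switches immediately (safety:
    stimulation must stop at once on unreliable input) and lowers both
    indicator lines.
    """
    cand = posterior.label
    frame = state.frame + 1
    if cand == state.current:
        return replace(state, candidate=None, candidate_count=0, frame=frame)
    if cand == PhaseLabel.ABNORMAL:
        return PhaseState(PhaseLabel.ABNORMAL, since=frame, frame=frame)
    count = state.candidate_count + 1 if cand == state.candidate else 1
    if count >= debounce_frames:
        return PhaseState(cand, since=frame, frame=frame)
    return replace(state, candidate=cand, candidate_count=count, frame=frame)


def synth_pulse(config: StimConfig) -> np.ndarray:
    """One symmetric biphasic pulse on the synthesis grid.

    Negative phase first, then positive, each ``phase_width_us`` wide at
    ``amplitude_level``; the sample sum is exactly zero (charge balance).
    """
    n = int(round(config.phase_width_us * 1e-6 * config.sample_rate_hz))
    pulse = np.empty(2 * n, dtype=float)
    pulse[:n] = -config.amplitude_level
    pulse[n:] = +config.amplitude_level
    return pulse


@dataclass
class StimTrain:
    """Sample-accurate waveform for one stimulation channel."""

    channel: str  # "stance" (DAC1) or "swing" (DAC2)
    samples: np.ndarray
    pulse_onsets_s: np.ndarray
    sample_rate_hz: float

    def inter_onset_intervals_s(self) -> np.ndarray:
        return np.diff(self.pulse_onsets_s)


def _phase_intervals(labels: list[PhaseLabel], fps: float, phase: PhaseLabel):
    """Contiguous [start_s, end_s) intervals where the timeline is `phase`."""
    dt = 1.0 / fps
    intervals = []
    start = None
    for i, lab in enumerate(labels):
        if lab == phase and start is None:
            start = i
        elif lab != phase and start is not None:
            intervals.append((start * dt, i * dt))
            start = None
    if start is not None:
        intervals.append((start * dt, len(labels) * dt))
    return intervals


def schedule_train(
    phase_timeline: list[PhaseLabel],
    fps: float,
    config: StimConfig,
    channel: str,
) -> StimTrain:
    """Synthesize one channel's pulse train for a debounced phase timeline.

    The first pulse of every detected phase fires at onset plus
    ``onset_delay_us``; further pulses follow at the pulse period while
    the phase persists (or for the fixed burst).  A pulse only starts if
    it completes before the phase ends — trains truncate between pulses,
    never mid-pulse.
    """
    if channel not in ("stance", "swing"):
        raise ValueError("channel must be 'stance' or 'swing'")
    phase = PhaseLabel.STANCE if channel == "stance" else PhaseLabel.SWING
    total_s = len(phase_timeline) / fps
    n_samples = int(round(total_s * config.sample_rate_hz))
    samples = np.zeros(n_samples)
    pulse = synth_pulse(config)
    onsets: list[float] = []
    pulse_dur_s = config.pulse_samples / config.sample_rate_hz
    for start_s, end_s in _phase_intervals(phase_timeline, fps, phase):
        t = start_s + config.onset_delay_us * 1e-6
        if config.burst_mode == "fixed_duration":
            end_s = min(end_s, t + config.burst_duration_s)
        while t + pulse_dur_s <= end_s + 1e-12:
            i0 = int(round(t * config.sample_rate_hz))
            if i0 + len(pulse) > n_samples:
                break
            samples[i0 : i0 + len(pulse)] += pulse
            onsets.append(t)
            t += config.period_s
    return StimTrain(channel, samples, np.asarray(onsets), config.sample_rate_hz)
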