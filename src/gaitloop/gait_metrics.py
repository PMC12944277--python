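"""Spatiotemporal and kinematic gait summaries.

Covers per-cycle temporal metrics (stance/swing/cycle duration, stance
duty factor), joint range of motion, 0-100% cycle normalisation,
stick-diagram export, animal-level aggregation (one animal = one
biological replicate; no cycle pooling, which would pseudoreplicate) and
Welch's t-test on group summary statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .gait_events import GaitCycle, InsufficientDataError, PhaseLabel
from .kinematics import AngleSample
from .pose_io import LANDMARKS, Session

NORMALIZED_GRID = np.linspace(0.0, 100.0, 101)

JOINTS = ("hip", "knee", "ankle")


def duty_factor(stance_ms: float, cycle_ms: float) -> float:
    """Stance duration as a percentage of cycle duration."""
    if not (0 < stance_ms < cycle_ms):
        raise ValueError("need 0 < stance_ms < cycle_ms")
    return 100.0 * stance_ms / cycle_ms


def joint_rom(trace) -> tuple[float, float, float]:
    """(min, max, range of motion) of a joint-angle trace in degrees."""
    t = np.asarray(trace, dtype=float)
    if t.size == 0:
        raise ValueError("empty trace")
    lo, hi = float(np.min(t)), float(np.max(t))
    return lo, hi, hi - lo


def percent_change(reference: float, test: float) -> float:
    """Reduction of ``test`` relative to ``reference``, in percent.

    Positive when the test value is smaller.  Display convention is to
    round to the nearest integer; the returned value is full precision.
    """
    if reference <= 0:
        raise ValueError("reference must be positive")
    return 100.0 * (reference - test) / reference


def welch_t_from_summary(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> tuple[float, float, float]:
    """Welch's unpaired t-test from group summary statistics.

    Returns ``(t, df, p_two_sided)`` with the Welch-Satterthwaite
    degrees of freedom.  Groups are animal-level means; n is the number
    of animals.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least 2 replicates per group")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be non-negative")
    if sd1 == 0 and sd2 == 0:
        if mean1 == mean2:
            raise ValueError("undefined statistic: zero variance, equal means")
    res = stats.ttest_ind_from_stats(
        mean1, sd1, n1, mean2, sd2, n2, equal_var=False
    )
    se1, se2 = sd1**2 / n1, sd2**2 / n2
    df = (se1 + se2) ** 2 / (se1**2 / (n1 - 1) + se2**2 / (n2 - 1))
    return float(res.statistic), float(df), float(res.pvalue)


@dataclass(frozen=True)
class NormalizedCycle:
    """A joint-angle trace resampled onto the 101-point 0-100% grid."""

    grid: np.ndarray
    trace: np.ndarray


def normalize_cycle(trace, cycle: GaitCycle) -> NormalizedCycle:
    """Resample a within-cycle trace onto the 0-100% grid (101 points).

    ``trace`` holds one angle per frame of the whole session; the slice
    ``[stance_onset, end]`` is linearly interpolated onto the grid.
    Cycles failing QC or shorter than 4 frames are rejected.
    """
    if not cycle.qc_pass:
        raise ValueError("cannot normalise a QC-failing cycle")
    t = np.asarray(trace, dtype=float)[cycle.stance_onset : cycle.end + 1]
    if t.size < 4:
        raise InsufficientDataError("cycle too short to resample")
    src = np.linspace(0.0, 100.0, t.size)
    return NormalizedCycle(NORMALIZED_GRID, np.interp(NORMALIZED_GRID, src, t))


def average_normalized_cycles(cycles: list[NormalizedCycle]) -> NormalizedCycle:
    """Pointwise mean trace across normalised cycles."""
    if not cycles:
        raise InsufficientDataError("no cycles to average")
    stacked = np.stack([c.trace for c in cycles])
    return NormalizedCycle(NORMALIZED_GRID, stacked.mean(axis=0))


@dataclass
class AnimalSummary:
    """One animal's means across its QC-passing gait cycles."""

    animal_id: str
    n_cycles_used: int
    cycle_ms: float
    stance_ms: float
    swing_ms: float
    duty_factor_pct: float
    joint_min_deg: dict[str, float] = field(default_factory=dict)
    joint_max_deg: dict[str, float] = field(default_factory=dict)
    joint_rom_deg: dict[str, float] = field(default_factory=dict)


def summarize_animal(
    animal_id: str,
    cycles: list[GaitCycle],
    angle_samples: list[AngleSample] | None = None,
    duty_mode: str = "mean_of_ratios",
) -> AnimalSummary:
    """Per-animal means over QC-passing cycles.

    Duty factor is computed per cycle then averaged (``mean_of_ratios``,
    the default, matching the one-animal-one-replicate convention); the
    ``ratio_of_means`` variant divides mean stance by mean cycle.
    Joint extrema/ROM are taken per cycle from the angle samples and then
    averaged.
    """
    used = [c for c in cycles if c.qc_pass]
    if not used:
        raise InsufficientDataError(f"animal {animal_id}: no QC-passing cycles")
    stance = np.array([c.stance_ms for c in used])
    swing = np.array([c.swing_ms for c in used])
    cyc = np.array([c.cycle_ms for c in used])
    if duty_mode == "mean_of_ratios":
        duty = float(np.mean([duty_factor(c.stance_ms, c.cycle_ms) for c in used]))
    elif duty_mode == "ratio_of_means":
        duty = duty_factor(float(stance.mean()), float(cyc.mean()))
    else:
        raise ValueError(f"unknown duty_mode {duty_mode!r}")

    jmin: dict[str, float] = {}
    jmax: dict[str, float] = {}
    jrom: dict[str, float] = {}
    if angle_samples is not None:
        traces = {
            "hip": np.array([s.hip_deg for s in angle_samples]),
            "knee": np.array([s.knee_deg for s in angle_samples]),
            "ankle": np.array([s.ankle_deg for s in angle_samples]),
        }
        for joint, trace in traces.items():
            per_cycle = [
                joint_rom(trace[c.stance_onset : c.end + 1]) for c in used
            ]
            jmin[joint] = float(np.mean([p[0] for p in per_cycle]))
            jmax[joint] = float(np.mean([p[1] for p in per_cycle]))
            jrom[joint] = float(np.mean([p[2] for p in per_cycle]))

    return AnimalSummary(
        animal_id=animal_id,
        n_cycles_used=len(used),
        cycle_ms=float(cyc.mean()),
        stance_ms=float(stance.mean()),
        swing_ms=float(swing.mean()),
        duty_factor_pct=duty,
        joint_min_deg=jmin,
        joint_max_deg=jmax,
        joint_rom_deg=jrom,
    )


@dataclass
class GroupStats:
    """Per-metric mean and SD across animal means (n = animals)."""

    group: str
    n: int
    mean: dict[str, float]
    sd: dict[str, float]


def aggregate_group(group: str, animals: list[AnimalSummary]) -> GroupStats:
    """Mean and SD over animal-level means; never pools cycles."""
    if not animals:
        raise ValueError("need at least one animal")
    metrics = {
        "cycle_ms": [a.cycle_ms for a in animals],
        "stance_ms": [a.stance_ms for a in animals],
        "swing_ms": [a.swing_ms for a in animals],
        "duty_factor_pct": [a.duty_factor_pct for a in animals],
    }
    for joint in JOINTS:
        if all(joint in a.joint_rom_deg for a in animals):
            metrics[f"rom_{joint}_deg"] = [a.joint_rom_deg[joint] for a in animals]
    mean = {k: float(np.mean(v)) for k, v in metrics.items()}
    # single animal: SD undefined, flagged as 0.0 by convention
    sd = {
        k: (float(np.std(v, ddof=1)) if len(v) > 1 else 0.0)
        for k, v in metrics.items()
    }
    return GroupStats(group=group, n=len(animals), mean=mean, sd=sd)


def stick_diagram(
    session: Session,
    labels: list[PhaseLabel],
    frame_step: int = 1,
) -> pd.DataFrame:
    """Stick-figure segments (crest-hip-knee-ankle-MTP) per selected frame.

    Each frame contributes 4 ordered segments coloured by phase: stance
    black, swing red.  Abnormal frames are omitted.
    """
    rows = []
    for i, (frame, label) in enumerate(zip(session.frames, labels)):
        if i % frame_step or label == PhaseLabel.ABNORMAL:
            continue
        color = "black" if label == PhaseLabel.STANCE else "red"
        for a, b in zip(LANDMARKS[:-1], LANDMARKS[1:]):
            pa, pb = frame.point(a), frame.point(b)
            rows.append(
                {
                    "frame": frame.frame_index,
                    "segment": f"{a}-{b}",
                    "x0": pa[0], "y0": pa[1], "x1": pb[0], "y1": pb[1],
                    "phase": label.value,
                    "color": color,
                }
            )
    return pd.DataFrame(rows)


def plot_stick_diagram(segments: pd.DataFrame, ax=None):
    """Render stick-diagram segments with matplotlib (y axis flipped)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for _, row in segments.iterrows():
        ax.plot([row.x0, row.x1], [row.y0, row.y1], color=row.color, lw=0.8)
    ax.invert_yaxis()
    ax.set_aspect("equal")
    return ax
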