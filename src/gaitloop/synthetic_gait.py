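"""Synthetic sham / SCI treadmill gait sessions with full ground truth.

The generator produces what the rest of the pipeline consumes — landmark
trajectories with per-landmark likelihoods at a fixed frame rate — by
running the analysis chain in reverse:

1. per-cycle timing is drawn jointly (cycle duration and stance duty
   factor), so group means match configured temporal statistics;
2. hip/knee/ankle trajectories follow shape-preserving spline templates
   over the normalised cycle, time-warped to each cycle's stance/swing
   split, with optional angle jitter;
3. a 2-D limb chain (iliac crest - hip - knee - ankle - MTP) is emitted
   by forward kinematics, rotated about the hip so the limb-axis
   (pendulum) angle peaks exactly at stance onset and bottoms at swing
   onset;
4. abnormal bouts perturb landmarks and drop their likelihoods below the
   0.8 reliability gate.

Every stage records its ground truth so downstream operations (event
detection, metrics, classifier training, the closed loop) can be scored
against it.

Sham versus injured (SCI) templates differ the way hindlimb kinematics
do after a thoracic contusion: the injured ankle trace is depressed
(never recovering full plantarflexion before toe-off) and the injured
hip initially extends the "wrong" way in early stance.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.interpolate import CubicHermiteSpline, PchipInterpolator

from .gait_events import PhaseLabel
from .kinematics import angles_from_frame
from .pose_io import LandmarkFrame, Session


class GaitGenConfigError(ValueError):
    pass


# Group temporal statistics: cycle duration (ms) and stance duty factor (%).
# Dispersion is applied per cycle; stance = duty x cycle, swing the rest,
# so the duty factor has the configured mean by construction.
SHAM_TEMPORAL = {"cycle_ms": (438.87, 51.62), "duty_pct": (67.14, 0.76)}
SCI_TEMPORAL = {"cycle_ms": (295.36, 45.34), "duty_pct": (67.66, 1.89)}


def _keypoints(group: str, stance_end: float) -> dict[str, list[tuple[float, float]]]:
    """Per-joint template keypoints (cycle %, degrees).

    ``stance_end`` is the nominal stance/swing boundary in percent; the
    ankle maximum sits there (peak plantarflexion before toe-off) and
    the ankle minimum at mid-swing (maximal dorsiflexion).
    """
    s = stance_end
    mid_swing = (s + 100.0) / 2.0
    if group == "sham":
        return {
            "hip": [(0, 95.0), (0.3 * s, 112.0), (s, 88.0), (mid_swing, 92.0), (100, 95.0)],
            "knee": [(0, 110.0), (0.4 * s, 85.0), (s, 100.0), (mid_swing, 125.0), (100, 110.0)],
            "ankle": [(0, 88.48), (s, 118.30), (mid_swing, 74.37), (100, 88.48)],
        }
    if group == "sci":
        return {
            # injured hip initially decreases in early stance (reversed)
            "hip": [(0, 95.0), (0.3 * s, 85.0), (s, 100.0), (mid_swing, 92.0), (100, 95.0)],
            "knee": [(0, 108.0), (0.4 * s, 84.0), (s, 98.0), (mid_swing, 120.0), (100, 108.0)],
            # depressed ankle: barely any plantarflexion peak, deep minimum
            "ankle": [(0, 73.67), (s, 76.42), (mid_swing, 42.32), (100, 73.67)],
        }
    raise GaitGenConfigError(f"unknown group {group!r}")


@dataclass
class GaitGenConfig:
    """All knobs of the synthetic session generator.

    Temporal parameters default to the configured group's treadmill
    statistics; angle templates to that group's joint trajectory shapes.
    ``noise_deg`` is the SD of frame-wise angle jitter;
    ``inter_animal_sd_ms`` shifts each virtual animal's cycle-duration
    mean (0 by default: all animals share the group mean).
    """

    group: str = "sham"
    fps: float = 156.0
    duration_s: float = 180.0
    cycle_ms: tuple[float, float] | None = None  # (mean, sd)
    duty_pct: tuple[float, float] | None = None  # (mean, sd)
    templates: dict[str, list[tuple[float, float]]] | None = None
    segment_lengths_mm: tuple[float, float, float, float] = (8.0, 15.0, 16.0, 9.0)
    noise_deg: float = 1.0
    pendulum_amplitude_deg: float = 20.0
    abnormal_rate_per_s: float = 0.02
    abnormal_duration_s: tuple[float, float] = (0.5, 1.5)
    abnormal_perturb_mm: float = 10.0
    inter_animal_sd_ms: float = 0.0
    px_per_mm: float = 5.0
    travel_direction: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        temporal = {"sham": SHAM_TEMPORAL, "sci": SCI_TEMPORAL}.get(self.group)
        if temporal is None:
            raise GaitGenConfigError(f"unknown group {self.group!r}")
        if self.cycle_ms is None:
            self.cycle_ms = temporal["cycle_ms"]
        if self.duty_pct is None:
            self.duty_pct = temporal["duty_pct"]
        if self.templates is None:
            self.templates = _keypoints(self.group, self.duty_pct[0])
        if self.fps <= 0 or self.duration_s <= 0:
            raise GaitGenConfigError("fps and duration must be positive")
        if not (0 < self.duty_pct[0] < 100):
            raise GaitGenConfigError("duty factor mean must be in (0, 100)")
        if self.cycle_ms[1] < 0 or self.duty_pct[1] < 0 or self.noise_deg < 0:
            raise GaitGenConfigError("dispersions must be non-negative")
        if self.cycle_ms[0] * self.duty_pct[0] / 100.0 >= self.cycle_ms[0]:
            raise GaitGenConfigError("stance mean must be below cycle mean")
        for joint, pts in self.templates.items():
            if any(not (0 <= v <= 180) for _, v in pts):
                raise GaitGenConfigError(f"{joint} template leaves [0, 180] deg")
        if any(l <= 0 for l in self.segment_lengths_mm):
            raise GaitGenConfigError("segment lengths must be positive")


@dataclass
class GroundTruth:
    """Oracle channel emitted alongside each synthetic session."""

    labels: list[PhaseLabel]
    cycle_start_frames: np.ndarray  # stance-onset frame of each full cycle
    stance_ms: np.ndarray  # realised per-cycle stance durations
    swing_ms: np.ndarray
    angles: np.ndarray  # (n_frames, 3): hip, knee, ankle degrees (pre-noise target incl. jitter)
    pendulum_deg: np.ndarray


def _truncnorm(rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float) -> float:
    if sd == 0:
        return mean
    if lo >= hi:
        raise GaitGenConfigError("infeasible truncation bounds")
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return x
    raise GaitGenConfigError("truncated-normal rejection did not converge")


def sample_cycles(config: GaitGenConfig, n_cycles: int, rng: np.random.Generator,
                  cycle_mean_shift_ms: float = 0.0) -> list[tuple[float, float]]:
    """Draw per-cycle (stance_ms, swing_ms) pairs.

    Cycle duration and duty factor are drawn from truncated normals
    (mean +/- 3 SD, and above two frame periods); stance = duty x cycle
    so the duty factor carries the configured mean exactly.
    """
    cm, csd = config.cycle_ms
    cm += cycle_mean_shift_ms
    dm, dsd = config.duty_pct
    min_ms = 2 * 1000.0 / config.fps
    out = []
    for _ in range(n_cycles):
        for _attempt in range(1000):
            cyc = _truncnorm(rng, cm, csd, max(cm - 3 * csd, min_ms), cm + 3 * csd)
            duty = _truncnorm(rng, dm, dsd, max(dm - 3 * dsd, 1.0), min(dm + 3 * dsd, 99.0))
            stance = duty / 100.0 * cyc
            swing = cyc - stance
            if stance > min_ms and swing > min_ms:
                out.append((stance, swing))
                break
        else:
            raise GaitGenConfigError("could not draw a physical cycle")
    return out


def template_spline(keypoints: Sequence[tuple[float, float]]) -> PchipInterpolator:
    """Shape-preserving interpolant through (cycle %, degrees) keypoints.

    PCHIP is monotone between keypoints, so template extrema are attained
    exactly at their keypoints and never overshot.
    """
    pts = sorted(keypoints)
    x = np.array([p for p, _ in pts], dtype=float)
    y = np.array([v for _, v in pts], dtype=float)
    return PchipInterpolator(x, y)


def _pendulum_profile(cycle_ms: float, stance_ms: float, amplitude: float,
                      corner_ms: float = 30.0, corner_drop: float = 0.2) -> CubicHermiteSpline:
    """Pendulum angle over one cycle: +A at stance onset, -A at swing onset.

    Each extremum sits inside a symmetric parabolic neighbourhood of
    half-width ``corner_ms`` (falling ``corner_drop`` x amplitude at its
    edge), joined by cubic Hermite arcs.  Local symmetry matters: a
    symmetric smoothing kernel then cannot displace the extremum, so
    event detection stays unbiased even though the stance lobe is much
    flatter than the swing lobe.
    """
    a = amplitude
    s, c = stance_ms, cycle_ms
    h = min(corner_ms, 0.33 * s, 0.33 * (c - s))
    c0 = corner_drop * a / h**2
    slope = 2 * c0 * h
    t = np.array([0.0, h, s - h, s, s + h, c - h, c])
    y = np.array([a, a - c0 * h**2, -a + c0 * h**2, -a, -a + c0 * h**2, a - c0 * h**2, a])
    dydt = np.array([0.0, -slope, -slope, 0.0, slope, slope, 0.0])
    return CubicHermiteSpline(t, y, dydt)


def render_angles(
    cycles: list[tuple[float, float]],
    config: GaitGenConfig,
    rng: np.random.Generator,
    n_frames: int | None = None,
) -> GroundTruth:
    """Frame-wise joint-angle and pendulum traces for a cycle plan.

    Templates are evaluated at a phase warped so the template's nominal
    stance/swing boundary maps onto each cycle's own split; frame-wise
    Gaussian jitter of SD ``noise_deg`` is added to the joint angles and
    the pendulum alike (the jittered values are what the landmarks will
    encode, so they are the ground truth).
    """
    fps = config.fps
    stance_end = config.duty_pct[0]
    splines = {j: template_spline(k) for j, k in config.templates.items()}

    starts_ms = np.concatenate([[0.0], np.cumsum([s + w for s, w in cycles])])
    total_ms = starts_ms[-1]
    if n_frames is None:
        n_frames = int(np.floor(total_ms / 1000.0 * fps))
    times_ms = np.arange(n_frames) / fps * 1000.0
    if times_ms[-1] >= total_ms:
        raise GaitGenConfigError("cycle plan shorter than requested duration")

    angles = np.empty((n_frames, 3))
    pend = np.empty(n_frames)
    labels: list[PhaseLabel] = []
    cyc_idx = np.searchsorted(starts_ms, times_ms, side="right") - 1
    for k, (stance, swing) in enumerate(cycles):
        mask = cyc_idx == k
        if not mask.any():
            continue
        local = times_ms[mask] - starts_ms[k]
        cyc = stance + swing
        in_stance = local < stance
        phase = np.where(
            in_stance,
            local / stance * stance_end,
            stance_end + (local - stance) / swing * (100.0 - stance_end),
        )
        for j, joint in enumerate(("hip", "knee", "ankle")):
            angles[mask, j] = splines[joint](phase)
        pend[mask] = _pendulum_profile(cyc, stance, config.pendulum_amplitude_deg)(local)
        labels.extend(
            PhaseLabel.STANCE if st else PhaseLabel.SWING for st in in_stance
        )
    if config.noise_deg > 0:
        angles = np.clip(angles + rng.normal(0, config.noise_deg, angles.shape), 0.5, 179.5)
        pend = pend + rng.normal(0, config.noise_deg, pend.shape)

    cycle_start_frames = np.ceil(starts_ms[:-1] / 1000.0 * fps).astype(int)
    return GroundTruth(
        labels=labels,
        cycle_start_frames=cycle_start_frames,
        stance_ms=np.array([s for s, _ in cycles]),
        swing_ms=np.array([w for _, w in cycles]),
        angles=angles,
        pendulum_deg=pend,
    )


def _rot(deg: float) -> np.ndarray:
    r = np.radians(deg)
    return np.array([[np.cos(r), -np.sin(r)], [np.sin(r), np.cos(r)]])


def emit_landmarks(truth: GroundTruth, config: GaitGenConfig,
                   rng: np.random.Generator) -> Session:
    """Forward-kinematic landmark emission (the inverse of angle extraction).

    A 2-D chain crest-hip-knee-ankle-MTP is posed from the joint angles
    (alternating flexion sides give the physiological zig-zag), then
    rigidly rotated about the hip so the hip->MTP axis realises the
    prescribed pendulum angle; rigid rotation leaves all joint angles
    untouched.  The hip translates on a slow low-amplitude orbit.
    Coordinates are emitted in image pixels (y grows downward).
    """
    l0, l1, l2, l3 = config.segment_lengths_mm
    n = len(truth.angles)
    frames: list[LandmarkFrame] = []
    base = np.array([80.0, 60.0])  # hip anchor, mm in math coords (y up)
    for i in range(n):
        hip_deg, knee_deg, ankle_deg = truth.angles[i]
        t = i / config.fps
        hip_pos = base + np.array([2.0 * np.sin(2 * np.pi * 0.5 * t),
                                   1.0 * np.sin(2 * np.pi * 1.1 * t)])
        a_thigh = -70.0  # provisional absolute thigh angle; fixed by rotation below
        a_crest = a_thigh + hip_deg
        a_shank = a_thigh + 180.0 - knee_deg
        a_foot = a_shank - (180.0 - ankle_deg)

        def dir_of(a_deg: float) -> np.ndarray:
            r = np.radians(a_deg)
            return np.array([np.cos(r), np.sin(r)])

        p2 = hip_pos
        p3 = p2 + l1 * dir_of(a_thigh)
        p4 = p3 + l2 * dir_of(a_shank)
        p5 = p4 + l3 * dir_of(a_foot)
        p1 = p2 + l0 * dir_of(a_crest)

        # measure current pendulum (y-up coords: angle from downward vertical,
        # anterior = +x) and rotate the whole chain about the hip to match
        v = p5 - p2
        current = np.degrees(np.arctan2(v[0], -v[1]))
        rot = _rot(truth.pendulum_deg[i] - current)
        pts = np.stack([p1, p2, p3, p4, p5])
        pts = (pts - p2) @ rot.T + p2

        if config.travel_direction == -1:
            pts[:, 0] = 2 * base[0] - pts[:, 0]
        # mm (y up) -> image pixels (y down)
        xy = np.empty_like(pts)
        xy[:, 0] = pts[:, 0] * config.px_per_mm
        xy[:, 1] = (120.0 - pts[:, 1]) * config.px_per_mm
        lk = rng.uniform(0.9, 1.0, size=5)
        frames.append(LandmarkFrame(i, xy, lk))
    return Session(
        frames,
        fps=config.fps,
        units="pixel",
        group=config.group,
        travel_direction=config.travel_direction,
    )


def inject_abnormal(session: Session, truth: GroundTruth, config: GaitGenConfig,
                    rng: np.random.Generator) -> tuple[Session, GroundTruth]:
    """Overlay abnormal bouts: perturbed landmarks with low likelihoods.

    Bout starts follow a Poisson process at ``abnormal_rate_per_s``;
    durations are uniform in ``abnormal_duration_s``.  During a bout at
    least two landmarks are displaced in a random direction by a
    distance in [0.8, 2.0] x ``abnormal_perturb_mm`` — a guaranteed
    minimum offset, so abnormal poses are geometrically separated from
    normal gait rather than merely noisy — their likelihoods drop to
    [0.2, 0.6] (strictly below the 0.8 gate) and ground-truth labels
    switch to abnormal.
    """
    if config.abnormal_rate_per_s == 0:
        return session, truth
    n = len(session.frames)
    fps = session.fps
    labels = list(truth.labels)
    frames = list(session.frames)
    t = rng.exponential(1.0 / config.abnormal_rate_per_s)
    while t < n / fps:
        dur = rng.uniform(*config.abnormal_duration_s)
        i0, i1 = int(t * fps), min(n, int((t + dur) * fps))
        n_landmarks = rng.integers(2, 6)
        which = rng.choice(5, size=n_landmarks, replace=False)
        for i in range(i0, i1):
            xy = frames[i].xy.copy()
            lk = frames[i].likelihood.copy()
            theta = rng.uniform(0, 2 * np.pi, size=len(which))
            radius = config.px_per_mm * config.abnormal_perturb_mm * rng.uniform(
                0.8, 2.0, size=len(which)
            )
            xy[which] += radius[:, None] * np.stack([np.cos(theta), np.sin(theta)], axis=1)
            lk[which] = rng.uniform(0.2, 0.6, size=len(which))
            frames[i] = LandmarkFrame(i, xy, lk)
            labels[i] = PhaseLabel.ABNORMAL
        t += dur + rng.exponential(1.0 / config.abnormal_rate_per_s)
    return replace(session, frames=frames), replace(truth, labels=labels)


def generate_session(config: GaitGenConfig,
                     cycle_mean_shift_ms: float = 0.0) -> tuple[Session, GroundTruth]:
    """Full generator: timing plan -> angles -> landmarks -> abnormal bouts."""
    rng = np.random.default_rng(config.seed)
    n_frames = int(round(config.duration_s * config.fps))
    # over-plan cycles, then trim the frame grid to the requested duration
    n_cycles = int(np.ceil(config.duration_s * 1000.0 / config.cycle_ms[0] * 1.5)) + 3
    cycles = sample_cycles(config, n_cycles, rng, cycle_mean_shift_ms)
    truth = render_angles(cycles, config, rng, n_frames=n_frames)
    # keep only cycles fully inside the frame window for the oracle arrays
    full = truth.cycle_start_frames[1:] <= n_frames
    truth = replace(
        truth,
        stance_ms=truth.stance_ms[: len(truth.cycle_start_frames) - 1][full],
        swing_ms=truth.swing_ms[: len(truth.cycle_start_frames) - 1][full],
        cycle_start_frames=truth.cycle_start_frames[:-1][full],
    )
    session = emit_landmarks(truth, config, rng)
    return inject_abnormal(session, truth, config, rng)


def generate_group(config: GaitGenConfig, n_animals: int = 3,
                   seed: int | None = None) -> list[tuple[str, Session, GroundTruth]]:
    """Generate a cohort of virtual animals from one group configuration."""
    base_seed = config.seed if seed is None else seed
    rng = np.random.default_rng(base_seed)
    out = []
    for k in range(n_animals):
        shift = rng.normal(0, config.inter_animal_sd_ms) if config.inter_animal_sd_ms else 0.0
        cfg = replace(config, seed=int(base_seed + 1000 * (k + 1)))
        session, truth = generate_session(cfg, cycle_mean_shift_ms=shift)
        session.subject_label = f"{config.group}_{k + 1}"
        out.append((session.subject_label, session, truth))
    return out
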