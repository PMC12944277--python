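"""Joint angles from hindlimb landmarks via the vector-cosine method.

The hip angle is subtended at the hip by the iliac crest and the knee;
the knee angle at the knee by hip and ankle; the ankle angle at the
ankle by knee and MTP.  All three are interior angles in [0, 180] deg and
are invariant to translation, rotation and uniform scaling of the frame.

The pendulum angle is the signed angle of the hip->MTP limb axis against
the downward vertical through the hip: positive when the MTP is anterior
to the hip (direction of travel), negative when posterior.  Its extrema
mark touch-down (maximal protraction) and lift-off (maximal retraction).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .pose_io import LandmarkFrame, Session

#: Frames whose minimum landmark likelihood falls below this are unreliable.
DEFAULT_LIKELIHOOD_THRESHOLD = 0.8


class DegenerateGeometryError(ValueError):
    """Two landmarks coincide, so an angle is undefined for this frame."""


@dataclass(frozen=True)
class AngleSample:
    """Per-frame joint angles (degrees) plus the pose-quality gate."""

    frame_index: int
    hip_deg: float
    knee_deg: float
    ankle_deg: float
    pendulum_deg: float
    min_likelihood: float
    valid: bool


def joint_angle(vertex, a, b) -> float:
    """Interior angle at ``vertex`` between rays to ``a`` and ``b``, degrees.

    arccos of the normalised dot product, clamped into [-1, 1] against
    floating-point overshoot so collinear points give exactly 0 or 180.
    """
    u = np.asarray(a, dtype=float) - np.asarray(vertex, dtype=float)
    v = np.asarray(b, dtype=float) - np.asarray(vertex, dtype=float)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise DegenerateGeometryError("zero-length limb segment")
    cosang = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def pendulum_angle(frame: LandmarkFrame, travel_direction: int = 1) -> float:
    """Signed hip->MTP angle from the downward vertical, degrees.

    Image coordinates (y grows downward) are assumed; ``travel_direction``
    is +1 when the animal moves toward +x.  Anterior placement of the MTP
    gives a positive angle.
    """
    v = frame.point("mtp") - frame.point("hip")
    if np.allclose(v, 0.0):
        raise DegenerateGeometryError("MTP coincides with hip")
    # downward vertical is +y in image coordinates
    return float(np.degrees(np.arctan2(travel_direction * v[0], v[1])))


def angles_from_frame(
    frame: LandmarkFrame,
    likelihood_threshold: float = DEFAULT_LIKELIHOOD_THRESHOLD,
    travel_direction: int = 1,
) -> AngleSample:
    """Compute the hip/knee/ankle angle triple and the validity gate.

    A frame is valid when every landmark likelihood is at or above the
    threshold (0.8 by default; exactly 0.8 counts as valid).  Degenerate
    geometry marks the frame invalid rather than raising.
    """
    min_lk = float(frame.likelihood.min())
    valid = min_lk >= likelihood_threshold
    try:
        hip = joint_angle(frame.point("hip"), frame.point("iliac_crest"), frame.point("knee"))
        knee = joint_angle(frame.point("knee"), frame.point("hip"), frame.point("ankle"))
        ankle = joint_angle(frame.point("ankle"), frame.point("knee"), frame.point("mtp"))
        pend = pendulum_angle(frame, travel_direction)
    except DegenerateGeometryError:
        hip = knee = ankle = pend = float("nan")
        valid = False
    return AngleSample(frame.frame_index, hip, knee, ankle, pend, min_lk, valid)


def angles_from_session(
    session: Session,
    likelihood_threshold: float = DEFAULT_LIKELIHOOD_THRESHOLD,
) -> list[AngleSample]:
    """Per-frame angle samples for a whole session, preserving order."""
    return [
        angles_from_frame(f, likelihood_threshold, session.travel_direction)
        for f in session.frames
    ]


def angle_table(samples: list[AngleSample]):
    """Angle samples as a pandas DataFrame (frame, hip, knee, ankle, ...)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "frame": [s.frame_index for s in samples],
            "hip_deg": [s.hip_deg for s in samples],
            "knee_deg": [s.knee_deg for s in samples],
            "ankle_deg": [s.ankle_deg for s in samples],
            "pendulum_deg": [s.pendulum_deg for s in samples],
            "min_likelihood": [s.min_likelihood for s in samples],
            "valid": [s.valid for s in samples],
        }
    )
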