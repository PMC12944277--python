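"""Landmark CSV I/O, spatial calibration, and the serial angle-frame codec.

The pose CSV dialect is the three-header-row convention emitted by
markerless pose-estimation tools (scorer / bodyparts / coords), with one
``x, y, likelihood`` column triple per tracked landmark.  Coordinates are
image-style: the y axis grows downward.  Five hindlimb landmarks are
tracked: iliac crest, hip, knee, ankle and the metatarsophalangeal (MTP)
joint.

The serial codec emulates the fixed-width ASCII joint-angle frame sent
over a USART link to the stimulation controller: three zero-padded
``DDD.DD`` fields, comma-separated, newline-terminated — exactly 21 bytes.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

#: Canonical landmark order: proximal to distal along the hindlimb.
LANDMARKS = ("iliac_crest", "hip", "knee", "ankle", "mtp")

SERIAL_FRAME_BYTES = 21


class PoseFormatError(ValueError):
    """The CSV does not follow the expected pose-tool dialect."""


class SerialFrameError(ValueError):
    """A serial payload is malformed; the runtime treats it as a dropped frame."""


@dataclass(frozen=True)
class LandmarkFrame:
    """One video frame: (x, y, likelihood) for each of the 5 landmarks.

    ``xy`` is a (5, 2) array in the order of :data:`LANDMARKS`;
    ``likelihood`` a length-5 array in [0, 1].
    """

    frame_index: int
    xy: np.ndarray
    likelihood: np.ndarray

    def __post_init__(self) -> None:
        xy = np.asarray(self.xy, dtype=float)
        lk = np.asarray(self.likelihood, dtype=float)
        if xy.shape != (5, 2):
            raise ValueError(f"xy must be (5, 2), got {xy.shape}")
        if lk.shape != (5,):
            raise ValueError(f"likelihood must be length 5, got {lk.shape}")
        if np.any(lk < 0) or np.any(lk > 1):
            raise ValueError("likelihoods must lie in [0, 1]")
        object.__setattr__(self, "xy", xy)
        object.__setattr__(self, "likelihood", lk)

    def point(self, name: str) -> np.ndarray:
        return self.xy[LANDMARKS.index(name)]


@dataclass
class Session:
    """An ordered sequence of landmark frames plus acquisition metadata.

    Parameters
    ----------
    frames:
        Landmark frames with strictly increasing ``frame_index``.
    fps:
        Acquisition frame rate in frames per second (default 156).
    units:
        ``"pixel"`` or ``"mm"``; millimetre sessions carry the scalar
        ``mm_per_pixel`` used to calibrate them.
    group:
        ``"sham"``, ``"sci"`` or ``"unknown"``.
    travel_direction:
        +1 if the animal travels toward +x in image coordinates, -1
        otherwise.  Only the pendulum-angle sign depends on it.
    """

    frames: list[LandmarkFrame]
    fps: float = 156.0
    units: str = "pixel"
    mm_per_pixel: float | None = None
    subject_label: str = ""
    group: str = "unknown"
    travel_direction: int = 1

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if self.units not in ("pixel", "mm"):
            raise ValueError(f"unknown units {self.units!r}")
        if self.units == "mm" and not (self.mm_per_pixel and self.mm_per_pixel > 0):
            raise ValueError("mm units require a positive mm_per_pixel")
        idx = [f.frame_index for f in self.frames]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("frame_index must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)


def read_pose_csv(
    path: str | Path,
    fps: float = 156.0,
    *,
    subject_label: str = "",
    group: str = "unknown",
    travel_direction: int = 1,
) -> Session:
    """Read a three-header-row pose CSV into a :class:`Session`.

    The header rows are ``scorer``, ``bodyparts`` and ``coords``; every one
    of the five expected landmarks must contribute an ``x, y, likelihood``
    column triple.  Unknown extra body parts are rejected.
    """
    path = Path(path)
    with path.open(newline="") as fh:
        rows = list(csv.reader(fh))
    if len(rows) < 4:
        raise PoseFormatError(f"{path}: expected 3 header rows plus data")
    bodyparts_row, coords_row = rows[1], rows[2]
    columns: dict[tuple[str, str], int] = {}
    for i, (bp, coord) in enumerate(zip(bodyparts_row[1:], coords_row[1:]), start=1):
        bp, coord = bp.strip(), coord.strip()
        if not bp:
            continue
        if bp not in LANDMARKS:
            raise PoseFormatError(f"{path}: unknown body part {bp!r}")
        columns[(bp, coord)] = i
    for bp in LANDMARKS:
        for coord in ("x", "y", "likelihood"):
            if (bp, coord) not in columns:
                raise PoseFormatError(f"{path}: missing {coord!r} column for {bp!r}")

    frames: list[LandmarkFrame] = []
    for row_number, row in enumerate(rows[3:], start=4):
        if not row or all(not c.strip() for c in row):
            continue
        try:
            frame_index = int(float(row[0]))
            xy = np.empty((5, 2))
            lk = np.empty(5)
            for j, bp in enumerate(LANDMARKS):
                xy[j, 0] = float(row[columns[(bp, "x")]])
                xy[j, 1] = float(row[columns[(bp, "y")]])
                lk[j] = float(row[columns[(bp, "likelihood")]])
        except (ValueError, IndexError) as exc:
            raise PoseFormatError(f"{path}: non-numeric or short row {row_number}") from exc
        frames.append(LandmarkFrame(frame_index, xy, lk))
    return Session(
        frames,
        fps=fps,
        subject_label=subject_label,
        group=group,
        travel_direction=travel_direction,
    )


def write_pose_csv(session: Session, path: str | Path, scorer: str = "gaitloop") -> Path:
    """Write a session in the same dialect accepted by :func:`read_pose_csv`."""
    if not session.frames:
        raise ValueError("cannot write an empty session")
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["scorer"] + [scorer] * 15)
        writer.writerow(["bodyparts"] + [bp for bp in LANDMARKS for _ in range(3)])
        writer.writerow(["coords"] + ["x", "y", "likelihood"] * 5)
        for frame in session.frames:
            row: list[str] = [str(frame.frame_index)]
            for j in range(5):
                row.append(f"{frame.xy[j, 0]:.6f}")
                row.append(f"{frame.xy[j, 1]:.6f}")
                row.append(f"{frame.likelihood[j]:.6f}")
            writer.writerow(row)
    return path


def apply_calibration(session: Session, square_size_mm: float, square_size_px: float) -> Session:
    """Convert a pixel-unit session to millimetres via a checkerboard square.

    The scalar factor is ``square_size_mm / square_size_px``; likelihoods
    are untouched and joint angles are unaffected (scaling is uniform).
    """
    if square_size_mm <= 0 or square_size_px <= 0:
        raise ValueError("square sizes must be positive")
    if session.units == "mm":
        raise ValueError("session is already calibrated to mm")
    factor = square_size_mm / square_size_px
    frames = [
        LandmarkFrame(f.frame_index, f.xy * factor, f.likelihood.copy())
        for f in session.frames
    ]
    return replace(session, frames=frames, units="mm", mm_per_pixel=factor)


# ---------------------------------------------------------------------------
# Serial angle-frame codec


@dataclass(frozen=True)
class SerialFrame:
    """A 21-byte ASCII joint-angle frame and the angles it encodes."""

    payload: bytes
    angles: tuple[float, float, float]


def encode_angle_frame(angles: Sequence[float]) -> SerialFrame:
    """Encode (hip, knee, ankle) degrees as a fixed-width 21-byte frame.

    Each angle is rendered ``%06.2f`` (zero-padded, two decimals), the
    three fields comma-joined and newline-terminated.
    """
    hip, knee, ankle = (float(a) for a in angles)
    for a in (hip, knee, ankle):
        if not (0.0 <= a <= 999.99) or not np.isfinite(a):
            raise ValueError(f"angle {a} outside encodable range [0, 999.99]")
    payload = f"{hip:06.2f},{knee:06.2f},{ankle:06.2f}\n".encode("ascii")
    assert len(payload) == SERIAL_FRAME_BYTES
    return SerialFrame(payload, (hip, knee, ankle))


def decode_angle_frame(payload: bytes) -> tuple[float, float, float]:
    """Decode a 21-byte frame back to (hip, knee, ankle) degrees.

    Raises :class:`SerialFrameError` on any malformed payload; callers in
    the runtime loop treat that as a dropped frame, never a crash.
    """
    if len(payload) != SERIAL_FRAME_BYTES:
        raise SerialFrameError(f"expected {SERIAL_FRAME_BYTES} bytes, got {len(payload)}")
    if not payload.endswith(b"\n"):
        raise SerialFrameError("missing newline terminator")
    fields = payload[:-1].split(b",")
    if len(fields) != 3 or any(len(f) != 6 for f in fields):
        raise SerialFrameError("malformed field layout")
    out = []
    for f in fields:
        try:
            text = f.decode("ascii")
        except UnicodeDecodeError as exc:
            raise SerialFrameError("non-ASCII byte in frame") from exc
        if text[3] != "." or not (text[:3] + text[4:]).isdigit():
            raise SerialFrameError(f"malformed numeric field {text!r}")
        out.append(float(text))
    return tuple(out)  # type: ignore[return-value]


def serial_transmission_time(n_bytes: int, baud: float, bits_per_byte: int = 10) -> float:
    """Wire time in milliseconds for ``n_bytes`` at ``baud`` bits/s.

    The default 10 bits per byte models 8N1 framing (start + 8 data +
    stop).  A 21-byte frame at 921,600 bps takes ~0.23 ms; the same frame
    at 115,200 bps takes ~1.82 ms.
    """
    if n_bytes <= 0 or baud <= 0 or bits_per_byte <= 0:
        raise ValueError("all arguments must be positive")
    return n_bytes * bits_per_byte / baud * 1000.0
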