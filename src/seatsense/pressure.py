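"""Data model and I/O for seat-pressure recordings.

A body-pressure measurement mat is a grid of piezoresistive sensors (by
default 32 x 32 = 1024 sensors covering the seat surface) sampled at 50 Hz.
One *frame* is the 2-D array of non-negative sensor readings at a single
time point; a *sequence* is the ordered stack of frames recorded during one
motion trial, together with its metadata (subject, reaching task, body side,
posture label).

Coordinate convention (fixed and documented so downstream features are
reproducible): sensor ``i`` at row ``r``, column ``c`` (1-based) has lateral
coordinate ``x_i = c`` (left edge of the seat = column 1) and longitudinal
coordinate ``y_i = r`` (front edge = row 1).

Sequences are stored on disk in a plain-text dialect: each frame is
``n_rows`` lines of ``n_cols`` whitespace- or comma-separated numbers,
frames are separated by a single blank line, and lines starting with ``#``
are comments.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import IO, Iterable, Union

import numpy as np

__all__ = [
    "TASKS",
    "SIDES",
    "LABELS",
    "TrialMeta",
    "PressureSequence",
    "read_pressure_ascii",
    "write_pressure_ascii",
    "read_sequence_csv",
    "write_sequence_csv",
    "remove_offset",
]

#: The three seated reaching tasks of the experimental design.
TASKS = ("back-and-forth", "side-to-side", "up-and-down")
#: Body side performing the reach.
SIDES = ("healthy", "affected")
#: Posture classes: noncompensation, trunk lean-forward, trunk rotation,
#: shoulder elevation.
LABELS = ("NC", "TLF", "TR", "SE")

#: A single pressure frame is a plain 2-D ``(n_rows, n_cols)`` float array.
PressureFrame = np.ndarray

#: A per-sensor offset matrix recorded with the mat unloaded, used to remove
#: the device's default bias level.
BiasMatrix = np.ndarray


@dataclass
class TrialMeta:
    """Metadata of one motion trial."""

    subject: str = ""
    task: str = ""
    side: str = ""
    label: str = ""

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass
class PressureSequence:
    """Ordered pressure frames of one motion trial.

    Parameters
    ----------
    frames
        Array of shape ``(T, n_rows, n_cols)`` with ``T >= 1`` frames of
        non-negative sensor values (device units).
    sample_rate
        Sampling frequency in Hz (the mat records at 50 Hz).
    meta
        Trial metadata.
    """

    frames: np.ndarray
    sample_rate: float = 50.0
    meta: TrialMeta = field(default_factory=TrialMeta)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError(
                f"frames must be (T, n_rows, n_cols), got shape {self.frames.shape}"
            )
        if self.frames.shape[0] < 1:
            raise ValueError("a pressure sequence needs at least one frame")
        if np.any(self.frames < 0):
            raise ValueError("pressure values must be non-negative")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_rows(self) -> int:
        return self.frames.shape[1]

    @property
    def n_cols(self) -> int:
        return self.frames.shape[2]

    def frame(self, t: int) -> PressureFrame:
        """Return frame ``t`` (0-based) as a 2-D array."""
        return self.frames[t]


def _open_maybe(source: Union[str, Path, IO[str]], mode: str):
    if isinstance(source, (str, Path)):
        return open(source, mode), True
    return source, False


def read_pressure_ascii(
    source: Union[str, Path, IO[str]],
    sample_rate: float = 50.0,
    meta: TrialMeta | None = None,
) -> PressureSequence:
    """Parse a plain-text pressure export into a :class:`PressureSequence`.

    Frames are blocks of equal-length numeric rows separated by blank lines;
    ``#`` lines are ignored. Raises ``ValueError`` naming the offending line
    for ragged rows, negative values, inconsistent frame shapes, or an
    empty stream.
    """
    stream, close = _open_maybe(source, "r")
    try:
        frames: list[np.ndarray] = []
        rows: list[list[float]] = []
        width: int | None = None
        for lineno, raw in enumerate(stream, start=1):
            line = raw.strip()
            if line.startswith("#"):
                continue
            if not line:
                if rows:
                    frames.append(np.array(rows, dtype=float))
                    rows, width = [], None
                continue
            try:
                values = [float(v) for v in line.replace(",", " ").split()]
            except ValueError as exc:
                raise ValueError(f"line {lineno}: non-numeric value ({exc})") from None
            if width is None:
                width = len(values)
            elif len(values) != width:
                raise ValueError(
                    f"line {lineno}: expected {width} values, got {len(values)}"
                )
            if any(v < 0 for v in values):
                raise ValueError(f"line {lineno}: negative pressure value")
            rows.append(values)
        if rows:
            frames.append(np.array(rows, dtype=float))
        if not frames:
            raise ValueError("empty pressure stream: no frames found")
        shapes = {f.shape for f in frames}
        if len(shapes) != 1:
            raise ValueError(f"frames have inconsistent shapes: {sorted(shapes)}")
        return PressureSequence(
            np.stack(frames), sample_rate=sample_rate, meta=meta or TrialMeta()
        )
    finally:
        if close:
            stream.close()


def write_pressure_ascii(
    seq: PressureSequence,
    sink: Union[str, Path, IO[str]],
    decimals: int = 3,
    comments: Iterable[str] = (),
) -> None:
    """Write a sequence in the plain-text dialect (deterministic formatting).

    ``decimals`` fixes the number of decimal places; ``comments`` become
    leading ``#`` header lines.
    """
    stream, close = _open_maybe(sink, "w")
    try:
        for c in comments:
            stream.write(f"# {c}\n")
        for t in range(seq.n_frames):
            if t > 0:
                stream.write("\n")
            for row in seq.frames[t]:
                stream.write(" ".join(f"{v:.{decimals}f}" for v in row))
                stream.write("\n")
    finally:
        if close:
            stream.close()


def write_sequence_csv(seq: PressureSequence, path: Union[str, Path]) -> None:
    """Store a sequence as CSV (one row per frame, sensors flattened
    row-major) with a JSON side-car holding shape, rate and metadata."""
    path = Path(path)
    flat = seq.frames.reshape(seq.n_frames, -1)
    np.savetxt(path, flat, delimiter=",", fmt="%.6g")
    sidecar = {
        "n_rows": seq.n_rows,
        "n_cols": seq.n_cols,
        "sample_rate": seq.sample_rate,
        "meta": seq.meta.as_dict(),
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def read_sequence_csv(path: Union[str, Path]) -> PressureSequence:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    flat = np.loadtxt(path, delimiter=",", ndmin=2)
    frames = flat.reshape(-1, sidecar["n_rows"], sidecar["n_cols"])
    return PressureSequence(
        frames,
        sample_rate=sidecar["sample_rate"],
        meta=TrialMeta(**sidecar["meta"]),
    )


def remove_offset(seq: PressureSequence, bias: BiasMatrix) -> PressureSequence:
    """Subtract the per-sensor bias matrix from every frame.

    The mat modules carry a device-specific offset, recorded with the seat
    unloaded. Differences that would go negative are clipped to zero
    (pressure cannot be negative). Metadata is preserved.
    """
    bias = np.asarray(bias, dtype=float)
    if bias.shape != seq.frames.shape[1:]:
        raise ValueError(
            f"bias shape {bias.shape} does not match frame shape {seq.frames.shape[1:]}"
        )
    corrected = np.maximum(seq.frames - bias, 0.0)
    return PressureSequence(corrected, sample_rate=seq.sample_rate, meta=seq.meta)
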