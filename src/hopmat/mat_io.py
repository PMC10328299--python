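"""Data model and text I/O for pressure-sensing-mat recordings.

A recording is a time-ordered sequence of pressure frames from a rectangular
grid of capacitive sensors (the reference device: 32 x 32 sensors of
10 x 10 mm sampled at 10 Hz, sensitive between 3 and 240 kPa).  Frames are
stored sparsely: only sensors with a strictly positive reading appear; all
other cells are implicitly zero.

The canonical on-disk form is the PMAT-CSV dialect, a plain UTF-8 text
format::

    #rows=32
    #cols=32
    #sensor_mm=10
    #hz=10
    #pmin_kpa=3
    #pmax_kpa=240
    #nframes=12
    #animal=r01
    frame,row,col,pressure_kpa
    0,5,7,100.0

Header lines are ``#key=value``; unrecognised keys are preserved verbatim as
free metadata (animal, session, run, direction_override, ...).  Sample lines
carry 0-based ``frame,row,col`` indices and the pressure in kPa.  Readings
below the device's sensitive minimum may legitimately appear in files
(sensor noise); the reader keeps them — thresholding belongs to
segmentation, not to I/O.  Readings above the device maximum are invalid
input: a saturated sensor clips at ``pmax_kpa``.

Conventions used throughout the package: indices are 0-based, frame 0 is
earliest, and row 0 / col 0 is the top-left sensor with the mat viewed from
above.  Time is ``frame_index / frame_rate_hz``; the device clock is fixed,
so no per-frame timestamps are stored.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "SAMPLE_DTYPE",
    "GridSpec",
    "FrameSequence",
    "LamenessScore",
    "MatFormatError",
    "SampleValidationError",
    "make_samples",
    "read_frame_sequence",
    "write_frame_sequence",
    "validate_sequence",
    "read_scores",
    "write_scores",
]

#: Structured dtype of one active sensor reading.
SAMPLE_DTYPE = np.dtype(
    [
        ("frame", np.int64),
        ("row", np.int64),
        ("col", np.int64),
        ("pressure", np.float64),
    ]
)


class MatFormatError(ValueError):
    """A PMAT-CSV file is malformed (bad header or sample line)."""


class SampleValidationError(ValueError):
    """A sample violates the grid/pressure invariants of a recording."""


def make_samples(records) -> np.ndarray:
    """Build a sample array from an iterable of (frame, row, col, pressure).

    Returns an array of :data:`SAMPLE_DTYPE` sorted by (frame, row, col).
    """
    arr = np.array(list(records), dtype=SAMPLE_DTYPE)
    if arr.size:
        arr = arr[np.lexsort((arr["col"], arr["row"], arr["frame"]))]
    return arr


@dataclass(frozen=True)
class GridSpec:
    """Geometry and acquisition parameters of the sensor mat."""

    n_rows: int = 32
    n_cols: int = 32
    sensor_size_mm: float = 10.0
    frame_rate_hz: float = 10.0
    p_min_kpa: float = 3.0
    p_max_kpa: float = 240.0

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and one column")
        if self.sensor_size_mm <= 0:
            raise ValueError("sensor_size_mm must be positive")
        if self.frame_rate_hz <= 0:
            raise ValueError("frame_rate_hz must be positive")
        if not self.p_min_kpa < self.p_max_kpa:
            raise ValueError("p_min_kpa must be below p_max_kpa")

    @property
    def sensor_area_m2(self) -> float:
        """Area of one sensor in square metres."""
        return (self.sensor_size_mm / 1000.0) ** 2


@dataclass
class FrameSequence:
    """A sparse pressure recording plus its run metadata.

    ``samples`` is a structured array (:data:`SAMPLE_DTYPE`); each
    (frame, row, col) cell appears at most once and carries a strictly
    positive pressure in kPa.  ``meta`` holds free string metadata such as
    ``animal``, ``session``, ``run`` and ``direction_override``.
    """

    grid: GridSpec
    n_frames: int
    samples: np.ndarray
    meta: dict[str, str] = field(default_factory=dict)

    @property
    def direction_override(self) -> int | None:
        """Travel-direction override from metadata: +1, -1 or None."""
        raw = self.meta.get("direction_override")
        if raw is None or raw == "" or raw.lower() == "none":
            return None
        value = int(raw)
        if value not in (+1, -1):
            raise ValueError(f"direction_override must be +1 or -1, got {raw!r}")
        return value

    def to_dense(self) -> np.ndarray:
        """Materialise the sparse samples as a (n_frames, n_rows, n_cols) array."""
        dense = np.zeros((self.n_frames, self.grid.n_rows, self.grid.n_cols))
        s = self.samples
        dense[s["frame"], s["row"], s["col"]] = s["pressure"]
        return dense

    def with_samples(self, samples: np.ndarray, n_frames: int | None = None) -> "FrameSequence":
        """Copy of this sequence with a different sample array."""
        return replace(
            self,
            samples=samples,
            n_frames=self.n_frames if n_frames is None else n_frames,
            meta=dict(self.meta),
        )


@dataclass(frozen=True)
class LamenessScore:
    """One visual lameness score on the ordinal 0-4 scale.

    0 is a clinically sound gait; 4 is no load at all on the affected limb.
    """

    animal_id: str
    session_id: str
    score: int

    def __post_init__(self) -> None:
        if self.score not in (0, 1, 2, 3, 4):
            raise ValueError(f"lameness score must be in 0..4, got {self.score}")


# Header keys that configure the grid; anything else is free metadata.
_GRID_KEYS = {"rows", "cols", "sensor_mm", "hz", "pmin_kpa", "pmax_kpa", "nframes"}


def _parse_header_value(key: str, raw: str, lineno: int):
    try:
        if key in ("rows", "cols", "nframes"):
            return int(raw)
        return float(raw)
    except ValueError as exc:
        raise MatFormatError(f"line {lineno}: header {key}={raw!r} is not numeric") from exc


def validate_sequence(seq: FrameSequence) -> list[str]:
    """Check every invariant of a :class:`FrameSequence`.

    Returns a list of human-readable violation descriptions, empty iff the
    sequence is valid.  Never raises: this is a reporting operation.
    """
    violations: list[str] = []
    g = seq.grid
    s = seq.samples
    if seq.n_frames < 0:
        violations.append(f"n_frames is negative ({seq.n_frames})")
    if s.dtype != SAMPLE_DTYPE:
        violations.append(f"samples dtype is {s.dtype}, expected {SAMPLE_DTYPE}")
        return violations
    for name, upper, label in (
        ("frame", seq.n_frames, "n_frames"),
        ("row", g.n_rows, "n_rows"),
        ("col", g.n_cols, "n_cols"),
    ):
        bad = (s[name] < 0) | (s[name] >= upper)
        for rec in s[bad]:
            violations.append(
                f"index out of bounds: {name}={rec[name]} not in [0, {label}={upper}) "
                f"at (frame={rec['frame']}, row={rec['row']}, col={rec['col']})"
            )
    nonpos = s["pressure"] <= 0
    for rec in s[nonpos]:
        violations.append(
            f"non-positive pressure {rec['pressure']} at "
            f"(frame={rec['frame']}, row={rec['row']}, col={rec['col']})"
        )
    above = s["pressure"] > g.p_max_kpa
    for rec in s[above]:
        violations.append(
            f"pressure {rec['pressure']} kPa exceeds device maximum {g.p_max_kpa} kPa at "
            f"(frame={rec['frame']}, row={rec['row']}, col={rec['col']})"
        )
    if s.size:
        keys = np.stack([s["frame"], s["row"], s["col"]], axis=1)
        uniq, counts = np.unique(keys, axis=0, return_counts=True)
        for key in uniq[counts > 1]:
            violations.append(
                f"duplicate sample at (frame={key[0]}, row={key[1]}, col={key[2]})"
            )
    return violations


def read_frame_sequence(path) -> FrameSequence:
    """Read a PMAT-CSV file into a validated :class:`FrameSequence`.

    Raises :class:`MatFormatError` for malformed lines (naming the line) and
    :class:`SampleValidationError` for samples that violate the grid bounds
    or the pressure range, naming the offending (frame, row, col).
    """
    headers: dict[str, float | int] = {}
    meta: dict[str, str] = {}
    records: list[tuple[int, int, int, float]] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw_line in enumerate(fh, start=1):
            line = raw_line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:]
                if "=" not in body:
                    raise MatFormatError(f"line {lineno}: header {line!r} lacks '='")
                key, _, value = body.partition("=")
                key = key.strip()
                value = value.strip()
                if key in _GRID_KEYS:
                    headers[key] = _parse_header_value(key, value, lineno)
                else:
                    meta[key] = value
                continue
            if line.lower().startswith("frame,"):
                continue  # optional column-name line
            parts = line.split(",")
            if len(parts) != 4:
                raise MatFormatError(
                    f"line {lineno}: expected 'frame,row,col,pressure_kpa', got {line!r}"
                )
            try:
                frame, row, col = (int(p) for p in parts[:3])
                pressure = float(parts[3])
            except ValueError as exc:
                raise MatFormatError(f"line {lineno}: non-numeric sample {line!r}") from exc
            records.append((frame, row, col, pressure))

    for required in ("rows", "cols", "hz"):
        if required not in headers:
            raise MatFormatError(f"missing required header '#{required}='")
    grid = GridSpec(
        n_rows=int(headers["rows"]),
        n_cols=int(headers["cols"]),
        sensor_size_mm=float(headers.get("sensor_mm", 10.0)),
        frame_rate_hz=float(headers["hz"]),
        p_min_kpa=float(headers.get("pmin_kpa", 3.0)),
        p_max_kpa=float(headers.get("pmax_kpa", 240.0)),
    )
    max_frame = max((r[0] for r in records), default=-1)
    n_frames = int(headers.get("nframes", max_frame + 1))
    seq = FrameSequence(grid=grid, n_frames=n_frames, samples=make_samples(records), meta=meta)
    violations = validate_sequence(seq)
    if violations:
        raise SampleValidationError("; ".join(violations))
    return seq


def _fmt_number(x: float) -> str:
    """Shortest decimal that round-trips the float exactly."""
    if float(x) == int(x) and abs(x) < 1e15:
        return str(int(x))
    return repr(float(x))


def write_frame_sequence(seq: FrameSequence, path) -> None:
    """Write a valid :class:`FrameSequence` as PMAT-CSV.

    The written file reads back to an identical sequence: samples compare
    equal as sets and pressures are printed with full round-trip precision.
    """
    violations = validate_sequence(seq)
    if violations:
        raise SampleValidationError("; ".join(violations))
    g = seq.grid
    lines = [
        f"#rows={g.n_rows}",
        f"#cols={g.n_cols}",
        f"#sensor_mm={_fmt_number(g.sensor_size_mm)}",
        f"#hz={_fmt_number(g.frame_rate_hz)}",
        f"#pmin_kpa={_fmt_number(g.p_min_kpa)}",
        f"#pmax_kpa={_fmt_number(g.p_max_kpa)}",
        f"#nframes={seq.n_frames}",
    ]
    for key in sorted(seq.meta):
        lines.append(f"#{key}={seq.meta[key]}")
    lines.append("frame,row,col,pressure_kpa")
    s = seq.samples
    order = np.lexsort((s["col"], s["row"], s["frame"])) if s.size else []
    for rec in s[order]:
        lines.append(
            f"{rec['frame']},{rec['row']},{rec['col']},{repr(float(rec['pressure']))}"
        )
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")


def read_scores(path) -> pd.DataFrame:
    """Read visual lameness scores from a plain CSV.

    Requires columns ``animal_id``, ``session_id``, ``score`` (``run_id`` is
    accepted and carried through if present).  Scores must be integers 0-4.
    """
    df = pd.read_csv(path, dtype={"animal_id": str, "session_id": str})
    missing = {"animal_id", "session_id", "score"} - set(df.columns)
    if missing:
        raise MatFormatError(f"scores file missing columns: {sorted(missing)}")
    scores = df["score"].to_numpy()
    if not np.all(np.isin(scores, [0, 1, 2, 3, 4])):
        bad = sorted(set(scores) - {0, 1, 2, 3, 4})
        raise SampleValidationError(f"lameness scores outside 0..4: {bad}")
    df["score"] = df["score"].astype(int)
    return df


def write_scores(scores: pd.DataFrame, path) -> None:
    """Write a scores table as plain CSV."""
    scores.to_csv(path, index=False)
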