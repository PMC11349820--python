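"""Event-stream I/O and pseudo-frame rendering.

An event-based vision sensor (EVS) reports per-pixel brightness changes as an
asynchronous stream of *events*: (timestamp, x, y, polarity).  This module
defines the in-memory container (:class:`EventStream`, a thin wrapper around a
NumPy structured array), two on-disk dialects (a ``t_us,x,y,p`` CSV and a
16-byte-per-record little-endian binary format), and pseudo-frame rendering —
accumulating polarities over short windows to produce images for visual
confirmation of what the sensor saw.

Timestamps are integer microseconds.  Coordinates are 0-based with the origin
at the top-left, x rightward, y downward (image-sensor convention).  Polarity
is +1 for a brightness increase and -1 for a decrease.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import BoundsError, ConfigError, OrderingError, ParseError

#: structured dtype of one event record
EVENT_DTYPE = np.dtype([("t", "<u8"), ("x", "<u2"), ("y", "<u2"), ("p", "<i1")])

#: default sensor geometry (width, height) in pixels
DEFAULT_GEOMETRY = (1280, 720)

CSV_HEADER = "t_us,x,y,p"

_BINARY_MAGIC = b"EVSTRM01"
#: on-disk record: uint64 t, uint16 x, uint16 y, int8 p, 3 pad bytes (16 B)
_BINARY_RECORD_DTYPE = np.dtype(
    [("t", "<u8"), ("x", "<u2"), ("y", "<u2"), ("p", "<i1"), ("_pad", "V3")]
)


@dataclass
class EventStream:
    """A time-ordered sequence of events from a sensor of fixed geometry."""

    width: int
    height: int
    events: np.ndarray = field(default_factory=lambda: np.empty(0, EVENT_DTYPE))

    def __post_init__(self):
        if self.events.dtype != EVENT_DTYPE:
            raise TypeError(f"events must have dtype {EVENT_DTYPE}")

    @classmethod
    def from_arrays(cls, t, x, y, p, geometry=DEFAULT_GEOMETRY) -> "EventStream":
        """Build and validate a stream from parallel coordinate arrays."""
        t = np.asarray(t, dtype=np.uint64)
        x = np.asarray(x)
        y = np.asarray(y)
        p = np.asarray(p)
        ev = np.empty(t.shape[0], EVENT_DTYPE)
        ev["t"], ev["x"], ev["y"], ev["p"] = t, x, y, p
        stream = cls(int(geometry[0]), int(geometry[1]), ev)
        stream.validate()
        return stream

    @property
    def geometry(self) -> tuple[int, int]:
        return (self.width, self.height)

    def __len__(self) -> int:
        return self.events.shape[0]

    def __eq__(self, other) -> bool:
        if not isinstance(other, EventStream):
            return NotImplemented
        return self.geometry == other.geometry and np.array_equal(
            self.events, other.events
        )

    def validate(self) -> "EventStream":
        """Check ordering, polarity and geometry invariants; return self."""
        ev = self.events
        if len(ev):
            dt = np.diff(ev["t"].astype(np.int64))
            if (dt < 0).any():
                i = int(np.argmax(dt < 0)) + 1
                raise OrderingError(
                    f"timestamps decrease at record {i + 1} "
                    f"(t={ev['t'][i]} after t={ev['t'][i - 1]})"
                )
            if (ev["x"] >= self.width).any() or (ev["y"] >= self.height).any():
                raise BoundsError(
                    f"event coordinates outside geometry {self.geometry}"
                )
            if not np.isin(ev["p"], (-1, 1)).all():
                raise ParseError("polarity must be +1 or -1")
        return self


def read_events(path, dialect: str = "csv", geometry=None) -> EventStream:
    """Read an event stream from ``path`` in the named dialect.

    ``geometry`` defaults to 1280x720 for CSV; the binary dialect stores its
    geometry in the file header.  Malformed rows raise :class:`ParseError`
    naming the line; decreasing timestamps raise :class:`OrderingError`
    (corrupt input is surfaced, never silently re-sorted).
    """
    if dialect == "csv":
        return _read_csv(path, geometry or DEFAULT_GEOMETRY)
    if dialect == "binary":
        return _read_binary(path)
    raise ConfigError(f"unknown dialect {dialect!r}")


def write_events(stream: EventStream, path, dialect: str = "csv") -> None:
    """Write ``stream`` so that :func:`read_events` round-trips bit-exactly."""
    if dialect == "csv":
        df = pd.DataFrame(
            {
                "t_us": stream.events["t"],
                "x": stream.events["x"],
                "y": stream.events["y"],
                "p": stream.events["p"],
            }
        )
        df.to_csv(path, index=False)
    elif dialect == "binary":
        header = (
            _BINARY_MAGIC
            + np.uint16(stream.width).tobytes()
            + np.uint16(stream.height).tobytes()
            + b"\x00" * 4
        )
        rec = np.zeros(len(stream), _BINARY_RECORD_DTYPE)
        for f in ("t", "x", "y", "p"):
            rec[f] = stream.events[f]
        with open(path, "wb") as fh:
            fh.write(header)
            rec.tofile(fh)
    else:
        raise ConfigError(f"unknown dialect {dialect!r}")


def _read_csv(path, geometry) -> EventStream:
    with open(path, "r") as fh:
        header = fh.readline().strip()
    if header != CSV_HEADER:
        raise ParseError(f"expected header {CSV_HEADER!r}, got {header!r}", line=1)
    try:
        df = pd.read_csv(path, header=0, names=["t_us", "x", "y", "p"])
    except Exception as exc:  # malformed CSV structure
        raise ParseError(str(exc)) from exc
    for col in df.columns:
        if len(df) and not np.issubdtype(df[col].dtype, np.integer):
            _locate_bad_row(path)
    return _finish(df["t_us"], df["x"], df["y"], df["p"], geometry, first_line=2)


def _locate_bad_row(path):
    """Scan for the first non-integer row to report a precise line number."""
    with open(path, "r") as fh:
        fh.readline()
        for lineno, raw in enumerate(fh, start=2):
            parts = raw.strip().split(",")
            try:
                if len(parts) != 4:
                    raise ValueError("wrong field count")
                [int(v) for v in parts]
            except ValueError:
                raise ParseError(f"malformed row {raw.strip()!r}", line=lineno)
    raise ParseError("non-integer values in event columns")


def _read_binary(path) -> EventStream:
    size = os.path.getsize(path)
    with open(path, "rb") as fh:
        header = fh.read(16)
        if len(header) < 16 or header[:8] != _BINARY_MAGIC:
            raise ParseError("bad magic; not a binary event stream", line=1)
        width = int(np.frombuffer(header, "<u2", 1, 8)[0])
        height = int(np.frombuffer(header, "<u2", 1, 10)[0])
        body = size - 16
        if body % _BINARY_RECORD_DTYPE.itemsize:
            raise ParseError(
                f"truncated record at byte {16 + body - body % 16}",
                line=body // 16 + 1,
            )
        rec = np.fromfile(fh, _BINARY_RECORD_DTYPE)
    return _finish(rec["t"], rec["x"], rec["y"], rec["p"], (width, height), 1)


def _finish(t, x, y, p, geometry, first_line) -> EventStream:
    t = np.asarray(t)
    x = np.asarray(x)
    y = np.asarray(y)
    p = np.asarray(p)
    n = len(t)
    if n:
        if (np.asarray(t, np.int64) < 0).any():
            i = int(np.argmax(np.asarray(t, np.int64) < 0))
            raise ParseError("negative timestamp", line=first_line + i)
        bad = ~np.isin(p, (-1, 1))
        if bad.any():
            i = int(np.argmax(bad))
            raise ParseError(f"polarity {p[i]} not in {{+1,-1}}", line=first_line + i)
        dt = np.diff(t.astype(np.int64))
        if (dt < 0).any():
            i = int(np.argmax(dt < 0)) + 1
            raise OrderingError("timestamp decreases", line=first_line + i)
        oob = (x < 0) | (x >= geometry[0]) | (y < 0) | (y >= geometry[1])
        if oob.any():
            i = int(np.argmax(oob))
            raise BoundsError(
                f"line {first_line + i}: event ({x[i]},{y[i]}) outside "
                f"geometry {tuple(geometry)}"
            )
    return EventStream.from_arrays(t, x, y, p, geometry)


@dataclass
class PseudoFrame:
    """Signed polarity accumulation over one half-open time window [t_start, t_end)."""

    t_start: int
    t_end: int
    image: np.ndarray  # (height, width) int32, 0 where no events

    def three_state(self) -> np.ndarray:
        """Render as {-1, 0, +1}: net-negative / no-event / net-positive pixels."""
        return np.sign(self.image).astype(np.int8)


def render_pseudo_frames(stream: EventStream, interval_ms: float) -> list[PseudoFrame]:
    """Accumulate polarities into frames tiling [t_first, t_last].

    Window k covers [t_first + k*interval, t_first + (k+1)*interval); each
    event lands in exactly one frame and contributes its polarity to its pixel.
    """
    if interval_ms <= 0:
        raise ConfigError("interval must be positive")
    interval_us = int(round(interval_ms * 1000))
    if interval_us <= 0:
        raise ConfigError("interval shorter than 1 us")
    ev = stream.events
    if not len(ev):
        return []
    t0 = int(ev["t"][0])
    k = ((ev["t"].astype(np.int64) - t0) // interval_us).astype(np.int64)
    n_frames = int(k[-1]) + 1
    frames = []
    h, w = stream.height, stream.width
    pol = ev["p"].astype(np.int32)
    for f in range(n_frames):
        sel = k == f
        img = np.zeros((h, w), np.int32)
        np.add.at(img, (ev["y"][sel], ev["x"][sel]), pol[sel])
        frames.append(
            PseudoFrame(t0 + f * interval_us, t0 + (f + 1) * interval_us, img)
        )
    return frames


def save_pseudo_frames(frames, out_dir, prefix: str = "frame") -> list[str]:
    """Export frames as 8-bit PNGs (negative=0, none=128, positive=255)."""
    import imageio.v3 as iio

    os.makedirs(out_dir, exist_ok=True)
    paths = []
    for i, fr in enumerate(frames):
        img = ((fr.three_state().astype(np.int16) + 1) * 127 + 1).clip(0, 255)
        path = os.path.join(out_dir, f"{prefix}_{i:05d}.png")
        iio.imwrite(path, img.astype(np.uint8))
        paths.append(path)
    return paths


def save_frame_stack(frames, path) -> None:
    """Export all frames losslessly as one multi-page TIFF of int32 sums."""
    import tifffile

    stack = np.stack([fr.image for fr in frames]) if frames else np.zeros(
        (0, 1, 1), np.int32
    )
    tifffile.imwrite(path, stack, photometric="minisblack")
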