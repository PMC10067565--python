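"""Frame-sequence container, event log, and region-of-interest masks.

The :class:`FrameSequence` is the single exchange format between the thorax
simulator and the analysis modules: ``T x 1024`` pixel impedance frames on a
32 x 32 grid sampled at a fixed rate, plus a time-sorted event log (posture
changes, PEEP changes, apnea windows, bolus injections) and free-form
metadata.

Grid orientation is body-fixed: row 0 is ventral (anterior), row 31 dorsal,
column 0 the animal's right side, 0-based row-major pixel indexing.  The
electrode belt rotates with the animal, so pixel coordinates and ROI masks
never change with posture; only the gravity axis does.

On disk a sequence is one binary array store for the frames
(``<base>.frames.npy``, little-endian float64, shape ``T x 1024``) plus a
JSON sidecar (``<base>.meta.json``) holding the frame rate, start time,
events, and metadata.  A delimited-text export is provided for
interoperability.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np

from .errors import EventError, FormatError

GRID_SIZE = 32
N_PIXELS = GRID_SIZE * GRID_SIZE

EVENT_KINDS = frozenset(
    {
        "position_change",
        "peep_change",
        "bolus_injection",
        "apnea_start",
        "apnea_end",
        "step_measurement",
    }
)

HALF_LABELS = ("ventral", "dorsal")
SIDE_LABELS = ("right_lung", "left_lung")
QUADRANT_LABELS = ("upper_right", "upper_left", "lower_right", "lower_left")

_FORMAT_VERSION = 1


@dataclass(frozen=True)
class Event:
    """A timestamped protocol event.

    ``payload`` is kind-specific: posture label/angle for position changes,
    the new PEEP for PEEP changes, bolus volume/concentration for injections.
    """

    time: float
    kind: str
    payload: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise EventError(f"unknown event kind {self.kind!r}")


def _validate_events(events: Sequence[Event]) -> None:
    times = [e.time for e in events]
    if any(b < a for a, b in zip(times, times[1:])):
        raise EventError("events must be time-sorted")
    # apnea windows must pair up and enclose every bolus injection
    stack: list[float] = []
    windows: list[tuple[float, float]] = []
    for e in events:
        if e.kind == "apnea_start":
            if stack:
                raise EventError("nested apnea windows are not allowed")
            stack.append(e.time)
        elif e.kind == "apnea_end":
            if not stack:
                raise EventError("apnea_end without matching apnea_start")
            windows.append((stack.pop(), e.time))
    if stack:
        raise EventError("apnea_start without matching apnea_end")
    for e in events:
        if e.kind == "bolus_injection" and not any(
            a <= e.time <= b for a, b in windows
        ):
            raise EventError("bolus_injection must lie inside an apnea window")


class FrameSequence:
    """Timestamped pixel-impedance frames with an event log.

    Parameters
    ----------
    frame_rate:
        Sampling rate in Hz.
    frames:
        ``(T, 1024)`` array of impedance values (arbitrary units).
    events:
        Time-sorted :class:`Event` list; apnea windows must pair up and
        bolus injections must fall inside one.
    metadata:
        Free-form key-value store (subject id, scenario hash, ...).
    t0:
        Time of the first frame, seconds.
    times:
        Optional explicit time axis; must be uniform at ``1/frame_rate``
        within 1e-9.  When omitted it is derived from ``t0``.
    """

    def __init__(
        self,
        frame_rate: float,
        frames: np.ndarray,
        events: Sequence[Event] = (),
        metadata: Mapping | None = None,
        t0: float = 0.0,
        times: np.ndarray | None = None,
    ) -> None:
        if frame_rate <= 0:
            raise FormatError("frame_rate must be positive")
        frames = np.asarray(frames, dtype=float)
        if frames.ndim != 2 or frames.shape[1] != N_PIXELS:
            raise FormatError(
                f"frames must have shape (T, {N_PIXELS}), got {frames.shape}"
            )
        if not np.all(np.isfinite(frames)):
            raise FormatError("frames contain non-finite values")
        if times is not None:
            times = np.asarray(times, dtype=float)
            if times.shape != (frames.shape[0],):
                raise FormatError("times length must equal frame count")
            if times.size:
                expected = times[0] + np.arange(times.size) / frame_rate
                if np.max(np.abs(times - expected)) > 1e-9:
                    raise FormatError("times must be uniform at 1/frame_rate")
                t0 = float(times[0])
        self.frame_rate = float(frame_rate)
        self.frames = frames
        self.t0 = float(t0)
        self.events = list(events)
        _validate_events(self.events)
        self.metadata = dict(metadata or {})

    # ------------------------------------------------------------------
    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def duration(self) -> float:
        return self.n_frames / self.frame_rate

    @property
    def times(self) -> np.ndarray:
        """Uniform time axis in seconds (derived, exactly ``1/frame_rate``)."""
        return self.t0 + np.arange(self.n_frames) / self.frame_rate

    def index_at(self, time: float) -> int:
        """Frame index closest to ``time`` (clipped to the sequence)."""
        i = int(round((time - self.t0) * self.frame_rate))
        return min(max(i, 0), self.n_frames - 1)

    def events_of(self, kind: str) -> list[Event]:
        return [e for e in self.events if e.kind == kind]

    def apnea_windows(self) -> list[tuple[float, float]]:
        starts = iter(self.events_of("apnea_start"))
        ends = iter(self.events_of("apnea_end"))
        return [(a.time, b.time) for a, b in zip(starts, ends)]

    def slice(self, t_start: float, t_stop: float) -> "FrameSequence":
        """Sub-sequence covering ``[t_start, t_stop)`` (events filtered)."""
        i0 = int(np.ceil((t_start - self.t0) * self.frame_rate - 1e-9))
        i1 = int(np.ceil((t_stop - self.t0) * self.frame_rate - 1e-9))
        i0, i1 = max(i0, 0), min(max(i1, 0), self.n_frames)
        sub_events = [e for e in self.events if t_start <= e.time < t_stop]
        # keep apnea pairing valid when a window straddles the cut
        try:
            return FrameSequence(
                self.frame_rate,
                self.frames[i0:i1],
                sub_events,
                self.metadata,
                t0=self.t0 + i0 / self.frame_rate,
            )
        except EventError:
            sub_events = [
                e
                for e in sub_events
                if e.kind not in ("apnea_start", "apnea_end", "bolus_injection")
            ]
            return FrameSequence(
                self.frame_rate,
                self.frames[i0:i1],
                sub_events,
                self.metadata,
                t0=self.t0 + i0 / self.frame_rate,
            )

    def __eq__(self, other: object) -> bool:  # pragma: no cover - convenience
        if not isinstance(other, FrameSequence):
            return NotImplemented
        return (
            self.frame_rate == other.frame_rate
            and self.t0 == other.t0
            and np.array_equal(self.frames, other.frames)
            and self.events == other.events
            and self.metadata == other.metadata
        )


# ----------------------------------------------------------------------
# On-disk format
# ----------------------------------------------------------------------

def _paths(path: str | Path) -> tuple[Path, Path]:
    base = Path(path)
    return base.with_suffix(base.suffix + ".frames.npy"), base.with_suffix(
        base.suffix + ".meta.json"
    )


def write_sequence(seq: FrameSequence, path: str | Path) -> None:
    """Write ``seq`` as ``<path>.frames.npy`` + ``<path>.meta.json``."""
    frames_path, meta_path = _paths(path)
    frames_path.parent.mkdir(parents=True, exist_ok=True)
    np.save(frames_path, seq.frames.astype("<f8"), allow_pickle=False)
    meta = {
        "format_version": _FORMAT_VERSION,
        "frame_rate": seq.frame_rate,
        "t0": seq.t0,
        "n_frames": seq.n_frames,
        "events": [
            {"time": e.time, "kind": e.kind, "payload": e.payload}
            for e in seq.events
        ],
        "metadata": seq.metadata,
    }
    meta_path.write_text(json.dumps(meta, indent=1))


def read_sequence(path: str | Path) -> FrameSequence:
    """Read a sequence written by :func:`write_sequence`."""
    frames_path, meta_path = _paths(path)
    if not frames_path.exists() or not meta_path.exists():
        raise FormatError(f"no frame sequence at {path}")
    try:
        meta = json.loads(meta_path.read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"malformed sidecar {meta_path}: {exc}") from exc
    try:
        frames = np.load(frames_path, allow_pickle=False)
    except ValueError as exc:
        raise FormatError(f"malformed frame store {frames_path}: {exc}") from exc
    if meta.get("format_version") != _FORMAT_VERSION:
        raise FormatError("unsupported format version")
    if frames.ndim != 2 or frames.shape[1] != N_PIXELS:
        raise FormatError(
            f"frame store has shape {frames.shape}, expected (T, {N_PIXELS})"
        )
    if frames.shape[0] != meta.get("n_frames"):
        raise FormatError("frame count disagrees between store and sidecar")
    events = [
        Event(e["time"], e["kind"], e.get("payload", {})) for e in meta["events"]
    ]
    return FrameSequence(
        meta["frame_rate"], frames, events, meta.get("metadata", {}), t0=meta["t0"]
    )


def export_table(seq: FrameSequence, path: str | Path) -> None:
    """Delimited-text export (one row per frame: time + 1024 pixel values)."""
    import pandas as pd

    cols = [f"px{i:04d}" for i in range(N_PIXELS)]
    df = pd.DataFrame(seq.frames, columns=cols)
    df.insert(0, "time_s", seq.times)
    df.to_csv(path, sep="\t", index=False)


# ----------------------------------------------------------------------
# Regions of interest
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class ROIMask:
    """Pixel-to-region assignment on the 32 x 32 grid.

    Every lung pixel carries exactly one label per scheme:

    - ``half``: ventral / dorsal (anterior vs posterior half),
    - ``side``: right_lung / left_lung (anatomical sides),
    - ``quadrant``: upper_right, upper_left, lower_right, lower_left,
      where each quadrant is the intersection of a half and a side, so the
      quadrant partition refines the half partition exactly.
    """

    lung_mask: np.ndarray  # (1024,) bool
    half: np.ndarray  # (1024,) <U8, '' outside the lung
    side: np.ndarray
    quadrant: np.ndarray

    def __post_init__(self) -> None:
        for arr in (self.lung_mask, self.half, self.side, self.quadrant):
            if arr.shape != (N_PIXELS,):
                raise FormatError("ROI arrays must have length 1024")

    @property
    def lung_pixels(self) -> np.ndarray:
        return np.flatnonzero(self.lung_mask)

    def labels(self, scheme: str) -> tuple[str, ...]:
        return {
            "half": HALF_LABELS,
            "side": SIDE_LABELS,
            "quadrant": QUADRANT_LABELS,
            "global": ("lung",),
        }[scheme]

    def pixels(self, scheme: str, label: str) -> np.ndarray:
        """Pixel indices carrying ``label`` under ``scheme``."""
        if scheme == "global":
            return self.lung_pixels
        arr = getattr(self, scheme)
        if label not in self.labels(scheme):
            raise KeyError(f"unknown {scheme} label {label!r}")
        return np.flatnonzero(arr == label)

    def partition(self, scheme: str) -> dict[str, np.ndarray]:
        """Boolean masks per label; an exact partition of the lung mask."""
        return {
            lab: (getattr(self, scheme) == lab) if scheme != "global" else self.lung_mask
            for lab in self.labels(scheme)
        }

    def iter_schemes(self) -> Iterator[str]:
        return iter(("half", "side", "quadrant"))

    # -- JSON import/export -------------------------------------------
    def to_json(self, path: str | Path) -> None:
        data = {
            "grid_size": GRID_SIZE,
            "lung_mask": self.lung_mask.astype(int).tolist(),
            "half": self.half.tolist(),
            "side": self.side.tolist(),
            "quadrant": self.quadrant.tolist(),
        }
        Path(path).write_text(json.dumps(data))

    @classmethod
    def from_json(cls, path: str | Path) -> "ROIMask":
        data = json.loads(Path(path).read_text())
        if data.get("grid_size") != GRID_SIZE:
            raise FormatError("ROI mask grid size must be 32")
        return cls(
            np.asarray(data["lung_mask"], dtype=bool),
            np.asarray(data["half"], dtype="<U8"),
            np.asarray(data["side"], dtype="<U10"),
            np.asarray(data["quadrant"], dtype="<U11"),
        )


def default_roi_mask(grid_size: int = GRID_SIZE) -> ROIMask:
    """Geometric two-ellipse lung mask with halves, sides, and quadrants.

    The two lung fields are mirror-symmetric ellipses about the midline
    column; the ventral/dorsal split is at the mid-depth row.  This is a
    declared geometric approximation (no anatomical segmentation), and can
    be replaced via :meth:`ROIMask.from_json`.
    """
    if grid_size != GRID_SIZE:
        raise FormatError("only the 32 x 32 grid is supported")
    rows, cols = np.mgrid[0:grid_size, 0:grid_size]
    r_c = (grid_size - 1) / 2.0  # 15.5
    # mirror-symmetric centers about the midline column
    c_right, c_left = 7.5, grid_size - 1 - 7.5
    semi_row, semi_col = 10.5, 5.5
    right = ((rows - r_c) / semi_row) ** 2 + ((cols - c_right) / semi_col) ** 2 <= 1.0
    left = ((rows - r_c) / semi_row) ** 2 + ((cols - c_left) / semi_col) ** 2 <= 1.0
    lung = (right | left).ravel()

    half = np.full(N_PIXELS, "", dtype="<U8")
    side = np.full(N_PIXELS, "", dtype="<U10")
    quadrant = np.full(N_PIXELS, "", dtype="<U11")
    ventral = (rows < grid_size // 2).ravel()
    right_flat, left_flat = right.ravel(), left.ravel()
    half[lung & ventral] = "ventral"
    half[lung & ~ventral] = "dorsal"
    side[lung & right_flat] = "right_lung"
    side[lung & left_flat] = "left_lung"
    quadrant[lung & ventral & right_flat] = "upper_right"
    quadrant[lung & ventral & left_flat] = "upper_left"
    quadrant[lung & ~ventral & right_flat] = "lower_right"
    quadrant[lung & ~ventral & left_flat] = "lower_left"
    return ROIMask(lung, half, side, quadrant)


def dependent_lung(posture) -> str:
    """Side label of the gravitationally dependent lung in a lateral posture.

    In the lateral-left posture the animal lies toward its left, so the left
    lung is dependent; mirror-wise for lateral right.  The supine posture has
    no single dependent lung and raises ``ValueError``.
    """
    label = getattr(posture, "label", posture)
    if label == "lateral_left":
        return "left_lung"
    if label == "lateral_right":
        return "right_lung"
    raise ValueError(f"no dependent lung defined for posture {label!r}")
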