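"""Core in-memory containers shared by all pipeline stages.

Conventions used throughout the package:

* time is in seconds, zero-based;
* epoch intervals are half-open ``[start, end)``;
* activity is on a df/F scale (fractional fluorescence change);
* coordinates are in centimetres.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

BEHAVIOR_LABELS = ("approach", "eat", "rear", "other")

#: Priority used when epochs of different labels overlap on one sample.
LABEL_PRIORITY = ("eat", "approach", "rear")


# ---------------------------------------------------------------------------
# Behavior-side containers
# ---------------------------------------------------------------------------


@dataclass
class Arena:
    """Arena geometry used by the rearing detector.

    ``kind`` is ``"circular"`` (cricket enclosure; rearing is detected when the
    head exceeds a minimum distance from the centre) or ``"rectangular"``
    (walnut assay; rearing is a vertical-coordinate threshold).
    """

    kind: Literal["circular", "rectangular"]
    center: tuple[float, float] | None = None
    radius: float | None = None
    wall_margin: float = 2.0
    height_threshold: float | None = None

    def __post_init__(self) -> None:
        if self.kind == "circular":
            if self.center is None or self.radius is None:
                raise ValueError("circular arena requires center and radius")
        elif self.kind == "rectangular":
            if self.height_threshold is None:
                raise ValueError("rectangular arena requires height_threshold")
        else:
            raise ValueError(f"unknown arena kind {self.kind!r}")


@dataclass
class PoseTrack:
    """Per-frame body-part coordinates from a markerless pose tracker.

    ``parts`` maps a body-part name (nose, ear_left, ear_right, tailbase, ...)
    to an (n, 2) array of xy coordinates in cm.  ``target`` is the tracked food
    source, if present.  ``missing`` flags samples whose tracker likelihood
    fell below threshold; detectors treat those coordinates as invalid.
    """

    time: np.ndarray
    parts: dict[str, np.ndarray]
    target: np.ndarray | None = None
    arena: Arena | None = None
    missing: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        if self.time.ndim != 1 or self.time.size < 2:
            raise ValueError("time must be a 1-D array with >= 2 samples")
        dt = np.diff(self.time)
        if np.any(dt <= 0):
            raise ValueError("time must be strictly increasing")
        # uniform sampling within 1% jitter
        if np.max(np.abs(dt - dt.mean())) > 0.01 * dt.mean():
            raise ValueError("sampling must be uniform within 1% jitter")
        for name, xy in self.parts.items():
            xy = np.asarray(xy, dtype=float)
            if xy.shape != (self.time.size, 2):
                raise ValueError(f"part {name!r} has shape {xy.shape}")
            self.parts[name] = xy
        if self.target is not None:
            self.target = np.asarray(self.target, dtype=float)
            if self.target.shape != (self.time.size, 2):
                raise ValueError("target shape must match time")

    @property
    def rate(self) -> float:
        return 1.0 / float(np.mean(np.diff(self.time)))

    @property
    def duration(self) -> float:
        return float(self.time[-1] - self.time[0] + 1.0 / self.rate)

    def head_position(self, definition: str = "ear_midpoint") -> np.ndarray:
        """Head position: midpoint of the two ears (default) or the nose."""
        if definition == "ear_midpoint":
            try:
                return 0.5 * (self.parts["ear_left"] + self.parts["ear_right"])
            except KeyError as exc:
                raise KeyError(f"pose track lacks part {exc.args[0]!r}") from exc
        if definition == "nose":
            if "nose" not in self.parts:
                raise KeyError("pose track lacks part 'nose'")
            return self.parts["nose"]
        raise ValueError(f"unknown head definition {definition!r}")


@dataclass
class BehaviorEpochs:
    """Labeled half-open time intervals ``(label, start_s, end_s)``."""

    entries: list[tuple[str, float, float]]

    def __post_init__(self) -> None:
        cleaned = []
        for label, start, end in self.entries:
            start, end = float(start), float(end)
            if not start < end:
                raise ValueError(f"epoch {label!r}: start {start} !< end {end}")
            if start < 0:
                raise ValueError(f"epoch {label!r} starts before time zero")
            cleaned.append((str(label), start, end))
        cleaned.sort(key=lambda e: (e[1], e[2], e[0]))
        by_label: dict[str, float] = {}
        for label, start, end in cleaned:
            if label in by_label and start < by_label[label]:
                raise ValueError(f"overlapping {label!r} epochs")
            by_label[label] = max(end, by_label.get(label, end))
        self.entries = cleaned

    def of_label(self, label: str) -> list[tuple[float, float]]:
        return [(s, e) for lab, s, e in self.entries if lab == label]

    def onsets(self, label: str) -> np.ndarray:
        return np.array([s for lab, s, _ in self.entries if lab == label])

    def count(self, label: str) -> int:
        return sum(1 for lab, _, _ in self.entries if lab == label)

    def labels(self) -> list[str]:
        return sorted({lab for lab, _, _ in self.entries})

    def __len__(self) -> int:
        return len(self.entries)


# ---------------------------------------------------------------------------
# Trace-side containers
# ---------------------------------------------------------------------------


@dataclass
class TraceMatrix:
    """Cells x samples activity matrix in df/F units with a sampling rate."""

    cell_ids: list[str]
    rate: float
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.cell_ids = [str(c) for c in self.cell_ids]
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (cells x samples)")
        if self.values.shape[0] != len(self.cell_ids):
            raise ValueError("row count must match cell_ids")
        if not self.rate > 0:
            raise ValueError("rate must be positive")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("trace values must be finite")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.rate

    def subset(self, cell_ids: list[str]) -> "TraceMatrix":
        index = {c: i for i, c in enumerate(self.cell_ids)}
        missing = [c for c in cell_ids if c not in index]
        if missing:
            raise KeyError(f"cell ids not in trace matrix: {missing}")
        rows = [index[c] for c in cell_ids]
        return TraceMatrix(list(cell_ids), self.rate, self.values[rows])


@dataclass
class EventAlignedTensor:
    """Peri-event activity: events x offsets x cells around event onsets."""

    values: np.ndarray  # (n_events, n_offsets, n_cells)
    offsets: np.ndarray  # seconds relative to onset
    cell_ids: list[str]
    event_times: np.ndarray
    window: tuple[float, float]
    label: str = ""
    n_dropped: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.offsets = np.asarray(self.offsets, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("tensor must be events x offsets x cells")
        if self.values.shape[1] != self.offsets.size:
            raise ValueError("offset axis mismatch")
        if self.values.shape[2] != len(self.cell_ids):
            raise ValueError("cell axis mismatch")

    @property
    def n_events(self) -> int:
        return self.values.shape[0]

    def event_average(self) -> np.ndarray:
        """Mean over events -> (offsets, cells)."""
        return self.values.mean(axis=0)


@dataclass
class PhotometryRecording:
    """Dual-channel fiber-photometry session: 470-nm signal + 405-nm reference."""

    time: np.ndarray
    sig470: np.ndarray
    ref405: np.ndarray
    rate: float

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.sig470 = np.asarray(self.sig470, dtype=float)
        self.ref405 = np.asarray(self.ref405, dtype=float)
        if not (self.time.shape == self.sig470.shape == self.ref405.shape):
            raise ValueError("channel lengths differ")
        if not (
            np.all(np.isfinite(self.sig470)) and np.all(np.isfinite(self.ref405))
        ):
            raise ValueError("photometry channels must be finite")
        if not self.rate > 0:
            raise ValueError("rate must be positive")


# ---------------------------------------------------------------------------
# Cross-session containers
# ---------------------------------------------------------------------------


@dataclass
class CoRegistrationMap:
    """One-to-one pairing of cell ids across two imaging sessions."""

    pairs: list[tuple[str, str]]

    def __post_init__(self) -> None:
        self.pairs = [(str(a), str(b)) for a, b in self.pairs]
        a_side = [a for a, _ in self.pairs]
        b_side = [b for _, b in self.pairs]
        if len(set(a_side)) != len(a_side) or len(set(b_side)) != len(b_side):
            raise ValueError("co-registration map must be one-to-one")

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class ClusterEmbedding:
    """Behavior-labeled samples in a (reduced) activity space."""

    coords: np.ndarray  # (n_samples, n_dims)
    labels: np.ndarray  # (n_samples,) str
    assay: np.ndarray | None = None
    explained_variance: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.coords.ndim != 2 or self.coords.shape[1] < 1:
            raise ValueError("coords must be (samples, dims) with dims >= 1")
        if self.labels.shape[0] != self.coords.shape[0]:
            raise ValueError("labels must match samples")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coords must be finite")


@dataclass
class CellBehaviorClass:
    """Per cell x behavior GLM weight and its bootstrap classification."""

    cell_id: str
    behavior: str
    glm_weight: float
    null_quantile: float
    label: Literal["+", "-", "ns"]

    def __post_init__(self) -> None:
        if not 0.0 <= self.null_quantile <= 1.0:
            raise ValueError("null_quantile must lie in [0, 1]")
        if self.label not in ("+", "-", "ns"):
            raise ValueError(f"bad class {self.label!r}")


@dataclass
class StatResult:
    """One statistical comparison, with optional FDR family bookkeeping."""

    name: str
    test: str
    statistic: float
    p_value: float
    n: tuple[int, ...]
    z_value: float | None = None
    q_value: float | None = None
    family: str | None = None
    direction: str | None = None
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or np.isnan(self.p_value)):
            raise ValueError("p must lie in [0, 1]")

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "test": self.test,
            "statistic": float(self.statistic),
            "z_value": None if self.z_value is None else float(self.z_value),
            "p_value": float(self.p_value),
            "q_value": None if self.q_value is None else float(self.q_value),
            "n": list(self.n),
            "family": self.family,
            "direction": self.direction,
            "flags": list(self.flags),
        }
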