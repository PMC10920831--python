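"""Behavioral epoch detection from pose tracks.

Approach epochs are maximal intervals of continuous movement toward the food
source during which the distance to the source decreases by at least 10 cm
and speed stays at or above 2 cm/s; rearing is a head-position threshold
against the arena geometry.  Eating cannot be derived from pose (it is scored
manually in real experiments) and is ingested from epoch tables instead.
"""

from __future__ import annotations

import numpy as np

from .datatypes import Arena, BehaviorEpochs, PoseTrack, LABEL_PRIORITY


def compute_speed(
    pose: PoseTrack,
    part: str = "head",
    smoothing_window: float = 0.0,
) -> np.ndarray:
    """Per-sample speed (cm/s) of a body part.

    Central-difference displacement over dt, boxcar-smoothed over
    ``smoothing_window`` seconds.  ``part`` may be any tracked part name or
    ``"head"`` for the ear-midpoint head position.  First/last samples take
    the nearest valid (one-sided) estimate.
    """
    if smoothing_window < 0:
        raise ValueError("smoothing_window must be >= 0")
    if part == "head":
        xy = pose.head_position()
    else:
        if part not in pose.parts:
            raise KeyError(f"pose track lacks part {part!r}")
        xy = pose.parts[part]
    t = pose.time
    n = t.size
    speed = np.empty(n)
    # central differences in the interior, one-sided at the edges
    speed[1:-1] = np.hypot(
        xy[2:, 0] - xy[:-2, 0], xy[2:, 1] - xy[:-2, 1]
    ) / (t[2:] - t[:-2])
    speed[0] = speed[1]
    speed[-1] = speed[-2]
    if smoothing_window > 0:
        width = max(1, int(round(smoothing_window * pose.rate)))
        if width > 1:
            kernel = np.ones(width) / width
            padded = np.concatenate(
                [np.full(width // 2, speed[0]), speed, np.full(width - 1 - width // 2, speed[-1])]
            )
            speed = np.convolve(padded, kernel, mode="valid")
    return speed


def distance_to_target(pose: PoseTrack, head_definition: str = "ear_midpoint") -> np.ndarray:
    if pose.target is None:
        raise ValueError("pose track has no food-target coordinates")
    head = pose.head_position(head_definition)
    delta = head - pose.target
    return np.hypot(delta[:, 0], delta[:, 1])


def detect_approach(
    pose: PoseTrack,
    min_decrease: float = 10.0,
    min_speed: float = 2.0,
    jitter_tolerance: float = 0.5,
    speed_smoothing: float = 0.2,
    head_definition: str = "ear_midpoint",
) -> BehaviorEpochs:
    """Detect food-approach epochs.

    An approach is a maximal interval during which, sample to sample, the
    distance to the food source is non-increasing (up to ``jitter_tolerance``
    cm of pose-tracking jitter per step), speed is >= ``min_speed`` cm/s at
    every sample, and the total distance decrease over the interval is at
    least ``min_decrease`` cm.
    """
    dist = distance_to_target(pose, head_definition)
    speed = compute_speed(pose, "head", speed_smoothing)
    t = pose.time
    n = t.size

    # a step i -> i+1 is admissible when the distance does not increase beyond
    # the jitter tolerance and both endpoint samples are fast enough
    step_ok = (
        (np.diff(dist) <= jitter_tolerance)
        & (speed[:-1] >= min_speed)
        & (speed[1:] >= min_speed)
    )

    entries: list[tuple[str, float, float]] = []
    i = 0
    while i < n - 1:
        if not step_ok[i]:
            i += 1
            continue
        j = i
        while j < n - 1 and step_ok[j]:
            j += 1
        # maximal run of admissible steps spans samples i..j
        if dist[i] - dist[j] >= min_decrease:
            entries.append(("approach", float(t[i]), float(t[j])))
        i = j
    return BehaviorEpochs(entries)


def detect_rearing(
    pose: PoseTrack,
    arena: Arena | None = None,
    head_definition: str = "ear_midpoint",
) -> BehaviorEpochs:
    """Detect rearing epochs from arena geometry.

    Circular arenas (cricket assay): rearing while the head is farther from
    the centre than ``radius - wall_margin``.  Rectangular arenas (walnut
    assay): rearing while the vertical coordinate exceeds the configured
    threshold.  Contiguous supra-threshold runs merge into single epochs.
    """
    arena = arena or pose.arena
    if arena is None:
        raise ValueError("no arena descriptor available")
    head = pose.head_position(head_definition)
    if arena.kind == "circular":
        cx, cy = arena.center
        r = np.hypot(head[:, 0] - cx, head[:, 1] - cy)
        above = r > (arena.radius - arena.wall_margin)
    else:
        above = head[:, 1] > arena.height_threshold

    t = pose.time
    dt = 1.0 / pose.rate
    entries: list[tuple[str, float, float]] = []
    n = t.size
    i = 0
    while i < n:
        if not above[i]:
            i += 1
            continue
        j = i
        while j < n and above[j]:
            j += 1
        entries.append(("rear", float(t[i]), float(t[j - 1] + dt)))
        i = j
    return BehaviorEpochs(entries)


def rasterize(
    epochs: BehaviorEpochs,
    time_base: np.ndarray,
    fill: str = "other",
    priority: tuple[str, ...] = LABEL_PRIORITY,
) -> np.ndarray:
    """Label every sample of ``time_base`` by the epoch containing it.

    Intervals are half-open ``[start, end)``.  When epochs of different
    labels overlap a sample, the fixed priority (eat > approach > rear, then
    first-seen order for labels outside the priority list) wins, so ties are
    deterministic.
    """
    time_base = np.asarray(time_base, dtype=float)
    if time_base.ndim != 1:
        raise ValueError("time base must be 1-D")
    if np.any(np.diff(time_base) < 0):
        raise ValueError("time base must be monotone non-decreasing")
    known = list(priority)
    extras = [lab for lab in epochs.labels() if lab not in known and lab != fill]
    order = known + sorted(extras)
    labels = np.full(time_base.shape, fill, dtype=object)
    # paint lowest priority first so higher priority overwrites
    for label in reversed(order):
        for start, end in epochs.of_label(label):
            mask = (time_base >= start) & (time_base < end)
            labels[mask] = label
    return labels.astype(str)


def epochs_from_labels(labels: np.ndarray, time_base: np.ndarray, fill: str = "other") -> BehaviorEpochs:
    """Reconstruct epochs from a per-sample label vector (inverse of rasterize
    up to grid resolution)."""
    labels = np.asarray(labels)
    time_base = np.asarray(time_base, dtype=float)
    dt = float(np.mean(np.diff(time_base))) if time_base.size > 1 else 1.0
    entries = []
    i, n = 0, labels.size
    while i < n:
        if labels[i] == fill:
            i += 1
            continue
        j = i
        while j < n and labels[j] == labels[i]:
            j += 1
        entries.append((str(labels[i]), float(time_base[i]), float(time_base[j - 1] + dt)))
        i = j
    return BehaviorEpochs(entries)
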