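"""Synthetic feeding-assay sessions with planted ground truth.

The generator emulates every input kind the pipeline consumes — pose tracks,
behavior epoch tables, calcium-trace matrices, cross-session co-registration
maps, and dual-channel photometry — with known ground truth, so every
downstream stage is testable without real recordings.

Generative model
----------------
Behavior follows repeating foraging cycles: the animal wanders to a start
point, runs straight toward the food target at 3 cm/s (approach), eats at the
target, then visits the enclosure wall (rear).  Cell activity is a Poisson
event train whose rate is ``base_rate`` times a per-cell, per-behavior
multiplier, convolved with a slow double-exponential calcium-indicator
kernel, plus i.i.d. Gaussian noise on the df/F scale.  Cell types: eat-
(eating suppresses firing), eat+ (eating elevates it), approach+ (elevated
during approach), and unmodulated (all multipliers exactly 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.signal import fftconvolve

from .behavior import rasterize
from .config import GeneratorConfig
from .datatypes import (
    Arena,
    BehaviorEpochs,
    CoRegistrationMap,
    PhotometryRecording,
    PoseTrack,
    TraceMatrix,
)

CELL_TYPES = ("eat-", "eat+", "approach+", "unmodulated")


@dataclass
class GroundTruth:
    """Planted parameters of one synthetic session."""

    cell_modulation: dict[str, dict[str, float]]
    cell_types: dict[str, str]
    epoch_schedule: list[tuple[str, float, float]]
    seed: int
    kernel_tau_rise: float
    kernel_tau_decay: float
    noise_sd: float
    base_rate: float
    shared_ensembles: set[str] = field(default_factory=set)

    def multipliers(self, label: str) -> np.ndarray:
        """Per-cell multiplier vector for one behavior label (cell-id order)."""
        return np.array(
            [self.cell_modulation[c].get(label, 1.0) for c in self.cell_modulation]
        )


@dataclass
class SessionBundle:
    """One complete synthetic session on a shared time base."""

    pose: PoseTrack
    epochs: BehaviorEpochs
    traces: TraceMatrix
    truth: GroundTruth
    events: np.ndarray  # planted Poisson event counts, cells x trace samples


# ---------------------------------------------------------------------------
# behavioral schedule and pose realization
# ---------------------------------------------------------------------------


def _plan_cycle(cfg: GeneratorConfig, pos: np.ndarray, rng: np.random.Generator):
    """One foraging cycle as (label, start_xy, end_xy, duration) segments."""
    target = np.asarray(cfg.target_xy, dtype=float)
    theta = rng.uniform(0.0, 2.0 * np.pi)
    start_pt = target + cfg.approach_start_distance * np.array(
        [np.cos(theta), np.sin(theta)]
    )
    phi = rng.uniform(0.0, 2.0 * np.pi)
    wall_pt = (cfg.arena_radius - cfg.rear_wall_offset) * np.array(
        [np.cos(phi), np.sin(phi)]
    )
    segs = []
    d0 = np.linalg.norm(start_pt - pos)
    if d0 > 0:
        segs.append((None, pos.copy(), start_pt, d0 / cfg.wander_speed))
    segs.append(
        (
            "approach",
            start_pt,
            target,
            cfg.approach_start_distance / cfg.approach_speed,
        )
    )
    segs.append(("eat", target, target, cfg.eat_duration))
    d1 = np.linalg.norm(wall_pt - target)
    segs.append((None, target, wall_pt, d1 / cfg.wander_speed))
    segs.append(("rear", wall_pt, wall_pt, cfg.rear_duration))
    return segs, wall_pt


def _realize_pose(
    cfg: GeneratorConfig, rng: np.random.Generator
) -> tuple[PoseTrack, BehaviorEpochs]:
    """Pose track + epoch schedule realizing the foraging cycles."""
    n_frames = int(round(cfg.duration * cfg.behavior_rate))
    dt = 1.0 / cfg.behavior_rate
    time = np.arange(n_frames) * dt

    pos = np.array([0.0, -0.5 * cfg.arena_radius])
    segments: list[tuple[str | None, np.ndarray, np.ndarray, float]] = []
    t = 0.0
    while True:
        cycle, end_pos = _plan_cycle(cfg, pos, rng)
        cycle_len = sum(d for _, _, _, d in cycle)
        if t + cycle_len > cfg.duration:
            break
        segments.extend(cycle)
        t += cycle_len
        pos = end_pos
    if t < cfg.duration:  # stationary tail
        segments.append((None, pos.copy(), pos.copy(), cfg.duration - t))

    head = np.empty((n_frames, 2))
    entries: list[tuple[str, float, float]] = []
    seg_start = 0.0
    for label, p0, p1, dur in segments:
        lo = int(np.ceil(seg_start * cfg.behavior_rate - 1e-9))
        hi = min(int(np.ceil((seg_start + dur) * cfg.behavior_rate - 1e-9)), n_frames)
        if hi > lo:
            frac = (time[lo:hi] - seg_start) / dur
            head[lo:hi] = p0 + np.outer(frac, p1 - p0)
        if label is not None:
            entries.append((label, seg_start, min(seg_start + dur, cfg.duration)))
        seg_start += dur

    # tracker jitter, small relative to the 0.5 cm distance tolerance
    head = head + rng.normal(0.0, 0.01, size=head.shape)

    # heading from motion; carry the last heading while stationary
    vel = np.gradient(head, dt, axis=0)
    speed = np.hypot(vel[:, 0], vel[:, 1])
    heading = np.zeros_like(head)
    current = np.array([1.0, 0.0])
    for i in range(n_frames):
        if speed[i] > 0.5:
            current = vel[i] / speed[i]
        heading[i] = current
    perp = np.column_stack([-heading[:, 1], heading[:, 0]])

    parts = {
        "nose": head + 1.5 * heading,
        "ear_left": head + 1.0 * perp,
        "ear_right": head - 1.0 * perp,
        "tailbase": head - 3.0 * heading,
    }
    target_track = np.tile(np.asarray(cfg.target_xy, dtype=float), (n_frames, 1))
    arena = Arena(kind="circular", center=(0.0, 0.0), radius=cfg.arena_radius)
    pose = PoseTrack(time=time, parts=parts, target=target_track, arena=arena)
    return pose, BehaviorEpochs(entries)


# ---------------------------------------------------------------------------
# cell ensembles and calcium traces
# ---------------------------------------------------------------------------


def _assign_cell_types(cfg: GeneratorConfig, rng: np.random.Generator) -> list[str]:
    counts = [
        int(round(cfg.frac_eat_neg * cfg.n_cells)),
        int(round(cfg.frac_eat_pos * cfg.n_cells)),
        int(round(cfg.frac_approach_pos * cfg.n_cells)),
    ]
    counts.append(cfg.n_cells - sum(counts))
    if counts[-1] < 0:  # rounding pushed us over; trim the largest group
        counts[int(np.argmax(counts[:3]))] += counts[-1]
        counts[-1] = 0
    types = [t for t, c in zip(CELL_TYPES, counts) for _ in range(c)]
    rng.shuffle(types)
    return types


def _draw_modulation(
    cfg: GeneratorConfig, cell_types: list[str], rng: np.random.Generator
) -> dict[str, dict[str, float]]:
    table: dict[str, dict[str, float]] = {}
    for i, ctype in enumerate(cell_types):
        mult = {"approach": 1.0, "eat": 1.0, "rear": 1.0, "other": 1.0}
        jitter = float(np.exp(rng.normal(0.0, cfg.multiplier_jitter_sigma)))
        if ctype == "eat-":
            mult["eat"] = cfg.eat_neg_multiplier * jitter
        elif ctype == "eat+":
            mult["eat"] = cfg.eat_pos_multiplier * jitter
        elif ctype == "approach+":
            mult["approach"] = cfg.approach_pos_multiplier * jitter
        table[f"cell_{i:04d}"] = mult
    return table


def calcium_kernel(tau_rise: float, tau_decay: float, rate: float) -> np.ndarray:
    """Double-exponential indicator kernel sampled at ``rate``, peak 1."""
    t = np.arange(0.0, 8.0 * tau_decay, 1.0 / rate)
    k = np.exp(-t / tau_decay) - np.exp(-t / tau_rise)
    peak = k.max()
    return k / peak if peak > 0 else k


def _synthesize_traces(
    cfg: GeneratorConfig,
    epochs: BehaviorEpochs,
    modulation: dict[str, dict[str, float]],
    rng: np.random.Generator,
) -> tuple[TraceMatrix, np.ndarray]:
    n_samples = int(round(cfg.duration * cfg.trace_rate))
    trace_time = np.arange(n_samples) / cfg.trace_rate
    labels = rasterize(epochs, trace_time)
    cell_ids = list(modulation)

    mult = np.ones((len(cell_ids), n_samples))
    for lab in ("approach", "eat", "rear"):
        mask = labels == lab
        if mask.any():
            col = np.array([modulation[c][lab] for c in cell_ids])
            mult[:, mask] = col[:, None]

    rate_per_bin = cfg.base_rate * mult / cfg.trace_rate
    events = rng.poisson(rate_per_bin)
    kernel = calcium_kernel(cfg.kernel_tau_rise, cfg.kernel_tau_decay, cfg.trace_rate)
    values = fftconvolve(events.astype(float), kernel[None, :], axes=1)[
        :, :n_samples
    ]
    if cfg.noise_sd > 0:
        values = values + rng.normal(0.0, cfg.noise_sd, size=values.shape)
    return TraceMatrix(cell_ids, cfg.trace_rate, values), events


# ---------------------------------------------------------------------------
# public generators
# ---------------------------------------------------------------------------


def generate_session(config: GeneratorConfig, seed: int) -> SessionBundle:
    """Generate one complete synthetic session.

    Identical ``(config, seed)`` pairs yield byte-identical bundles.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    pose, epochs = _realize_pose(config, rng)
    cell_types = _assign_cell_types(config, rng)
    modulation = _draw_modulation(config, cell_types, rng)
    traces, events = _synthesize_traces(config, epochs, modulation, rng)
    truth = GroundTruth(
        cell_modulation=modulation,
        cell_types=dict(zip(traces.cell_ids, cell_types)),
        epoch_schedule=list(epochs.entries),
        seed=int(seed),
        kernel_tau_rise=config.kernel_tau_rise,
        kernel_tau_decay=config.kernel_tau_decay,
        noise_sd=config.noise_sd,
        base_rate=config.base_rate,
    )
    return SessionBundle(pose=pose, epochs=epochs, traces=traces, truth=truth, events=events)


def generate_assay_pair(
    config: GeneratorConfig,
    overlap: set[str],
    seed: int,
    dropout: float = 0.0,
) -> tuple[SessionBundle, SessionBundle, CoRegistrationMap]:
    """Two sessions of the same cells with a configurable shared encoding.

    For behavior labels in ``overlap`` the per-cell rate multipliers are
    identical across the two sessions (a conserved ensemble); other labels'
    multipliers are drawn independently (assay-specific encoding).  The
    co-registration map pairs each cell with itself, with a ``dropout``
    fraction of pairs removed at random, mimicking imperfect registration.
    """
    vocab = {"approach", "eat", "rear", "other"}
    if not set(overlap) <= vocab:
        raise ValueError(f"overlap labels must be within {sorted(vocab)}")
    if not 0.0 <= dropout <= 1.0:
        raise ValueError("dropout must lie in [0, 1]")
    seq = np.random.SeedSequence(seed)
    seed_a, seed_b, seed_map = (int(s) for s in seq.generate_state(3) >> 1)
    bundle_a = generate_session(config, seed_a)
    bundle_b = generate_session(config, seed_b)

    # share the overlap labels' multipliers, then resynthesize session B
    for cell, mult_a in bundle_a.truth.cell_modulation.items():
        for lab in overlap:
            bundle_b.truth.cell_modulation[cell][lab] = mult_a[lab]
    rng_b = np.random.default_rng(seed_b + 1)
    traces_b, events_b = _synthesize_traces(
        config, bundle_b.epochs, bundle_b.truth.cell_modulation, rng_b
    )
    bundle_b.traces = traces_b
    bundle_b.events = events_b
    bundle_a.truth.shared_ensembles = set(overlap)
    bundle_b.truth.shared_ensembles = set(overlap)

    rng_map = np.random.default_rng(seed_map)
    keep = rng_map.random(len(bundle_a.traces.cell_ids)) >= dropout
    pairs = [(c, c) for c, k in zip(bundle_a.traces.cell_ids, keep) if k]
    return bundle_a, bundle_b, CoRegistrationMap(pairs)


def generate_photometry(
    config: GeneratorConfig,
    artifact_amplitude: float | None = None,
    seed: int = 0,
) -> dict:
    """Dual-channel photometry with a planted shared motion artifact.

    The 405-nm reference carries baseline + artifact + noise; the 470-nm
    signal additionally carries behavior-locked calcium transients.  Returns
    the recording plus the planted artifact, transient series, and event
    times for validation.
    """
    config.validate()
    if artifact_amplitude is None:
        artifact_amplitude = config.artifact_amplitude
    if artifact_amplitude < 0:
        raise ValueError("artifact_amplitude must be >= 0")
    rng = np.random.default_rng(seed)
    rate = config.photometry_rate
    n = int(round(config.duration * rate))
    time = np.arange(n) / rate

    if artifact_amplitude > 0:
        raw = rng.normal(size=n)
        smooth = gaussian_filter1d(raw, sigma=config.artifact_timescale * rate)
        sd = smooth.std()
        artifact = artifact_amplitude * (smooth / sd if sd > 0 else smooth)
    else:
        rng.normal(size=n)  # keep the stream aligned across amplitudes
        artifact = np.zeros(n)

    # behavior-locked transients every ~30 s on average
    n_events = max(1, int(config.duration / 30.0))
    event_times = np.sort(
        rng.uniform(10.0, max(config.duration - 10.0, 10.0), size=n_events)
    )
    kernel = calcium_kernel(config.kernel_tau_rise, config.kernel_tau_decay, rate)
    impulses = np.zeros(n)
    for t in event_times:
        idx = int(round(t * rate))
        if 0 <= idx < n:
            impulses[idx] += 1.0
    transients = config.transient_amplitude * np.convolve(impulses, kernel)[:n]

    noise_sig = rng.normal(0.0, config.photometry_noise_sd, size=n)
    noise_ref = rng.normal(0.0, config.photometry_noise_sd, size=n)
    sig470 = config.photometry_baseline_sig + artifact + transients + noise_sig
    ref405 = config.photometry_baseline_ref + artifact + noise_ref
    rec = PhotometryRecording(time=time, sig470=sig470, ref405=ref405, rate=rate)
    return {
        "recording": rec,
        "artifact": artifact,
        "transients": transients,
        "event_times": event_times,
    }
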