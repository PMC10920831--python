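"""Trace-level preprocessing and event-locked quantification.

Covers the inclusion filter on per-cell variance, peri-event tensor
extraction, pre/post-eating modulation deltas, mean peak amplitude,
isosbestic photometry correction, and epoch-mean contrasts.
"""

from __future__ import annotations

import warnings

import numpy as np

from .datatypes import BehaviorEpochs, EventAlignedTensor, PhotometryRecording, TraceMatrix


def variance_filter(
    traces: TraceMatrix, fraction: float = 0.10
) -> tuple[TraceMatrix, list[str]]:
    """Keep cells whose variance is >= ``fraction`` of the maximum variance
    among non-outlier cells.

    Outliers (cells whose variance exceeds Q3 + 1.5*IQR across cells) are
    flagged first so a single extreme cell cannot set the reference; the
    reference is the maximum variance among the remaining cells.  Returns the
    filtered matrix and the excluded cell ids.
    """
    if traces.n_cells < 1:
        raise ValueError("need at least one cell")
    variances = traces.values.var(axis=1)
    q1, q3 = np.percentile(variances, [25, 75])
    outlier = variances > q3 + 1.5 * (q3 - q1)
    if np.all(outlier):  # degenerate; fall back to all cells
        outlier = np.zeros_like(outlier)
    reference = float(variances[~outlier].max())
    if reference == 0.0:
        warnings.warn("all traces constant; variance filter keeps every cell")
        kept = np.ones(traces.n_cells, dtype=bool)
    else:
        kept = variances >= fraction * reference
    kept_ids = [c for c, k in zip(traces.cell_ids, kept) if k]
    excluded = [c for c, k in zip(traces.cell_ids, kept) if not k]
    return traces.subset(kept_ids), excluded


def align_to_events(
    traces: TraceMatrix,
    event_times: np.ndarray,
    window: tuple[float, float],
    label: str = "",
) -> EventAlignedTensor:
    """Extract peri-event segments ``[t - pre, t + post)`` on the trace grid.

    Events closer than ``pre`` to the session start or ``post`` to its end
    are dropped and counted in ``n_dropped``.
    """
    pre, post = window
    if pre <= 0 or post <= 0:
        raise ValueError("window pre and post must be positive")
    event_times = np.asarray(event_times, dtype=float)
    n_pre = int(round(pre * traces.rate))
    n_post = int(round(post * traces.rate))
    offsets = (np.arange(-n_pre, n_post)) / traces.rate

    segments = []
    kept_times = []
    dropped = 0
    for t in event_times:
        center = int(round(t * traces.rate))
        lo, hi = center - n_pre, center + n_post
        if lo < 0 or hi > traces.n_samples:
            dropped += 1
            continue
        segments.append(traces.values[:, lo:hi].T)  # (offsets, cells)
        kept_times.append(t)
    if segments:
        values = np.stack(segments, axis=0)
    else:
        values = np.empty((0, offsets.size, traces.n_cells))
    return EventAlignedTensor(
        values=values,
        offsets=offsets,
        cell_ids=list(traces.cell_ids),
        event_times=np.asarray(kept_times),
        window=(float(pre), float(post)),
        label=label,
        n_dropped=dropped,
    )


def pre_post_modulation(
    tensor: EventAlignedTensor,
    pre_window: float = 5.0,
    post_window: float = 5.0,
) -> np.ndarray:
    """Per-cell eating-modulation delta: post-onset minus pre-onset df/F.

    For each cell, the mean over events of (mean activity in
    ``[0, post_window)`` minus mean activity in ``[-pre_window, 0)``).
    """
    if tensor.n_events == 0:
        raise ValueError("tensor retains zero events; modulation undefined")
    pre_lo, post_hi = tensor.window
    if pre_window > pre_lo + 1e-9 or post_window > post_hi + 1e-9:
        raise ValueError("modulation windows exceed the tensor window")
    pre_mask = (tensor.offsets >= -pre_window) & (tensor.offsets < 0)
    post_mask = (tensor.offsets >= 0) & (tensor.offsets < post_window)
    if not pre_mask.any() or not post_mask.any():
        raise ValueError("modulation windows contain no samples")
    per_event = (
        tensor.values[:, post_mask, :].mean(axis=1)
        - tensor.values[:, pre_mask, :].mean(axis=1)
    )  # (events, cells)
    return per_event.mean(axis=0)


def mean_peak_amplitude(trace: np.ndarray) -> tuple[float, bool]:
    """Average amplitude of strict local maxima of one cell's trace.

    A sample is a peak when both neighbors are strictly smaller; plateaus
    count once at their first sample.  Returns ``(amplitude, found)``;
    traces with no maxima return ``(0.0, False)``.
    """
    trace = np.asarray(trace, dtype=float)
    if trace.ndim != 1 or trace.size < 3:
        raise ValueError("need a 1-D trace with >= 3 samples")
    peaks = []
    i = 1
    n = trace.size
    while i < n - 1:
        if trace[i] > trace[i - 1]:
            j = i
            while j < n - 1 and trace[j + 1] == trace[j]:
                j += 1  # walk across a plateau
            if j < n - 1 and trace[j + 1] < trace[j]:
                peaks.append(trace[i])  # plateau takes its first sample
            i = j + 1
        else:
            i += 1
    if not peaks:
        return 0.0, False
    return float(np.mean(peaks)), True


def photometry_correct(
    rec: PhotometryRecording, robust: bool = False
) -> np.ndarray:
    """Remove motion/bleaching artifacts using the 405-nm isosbestic channel.

    The calcium-independent reference is fit to the 470-nm signal by an
    affine least-squares regression over the whole session; the corrected
    trace is ``(sig470 - fit) / fit``, a df/F-scale series with mean ~ 0.
    Any artifact expressible as an affine function of the reference is
    removed exactly.  A constant reference carries no artifact information:
    the function falls back to a baseline-percentile df/F with a warning.
    """
    if rec.time.size < 100:
        raise ValueError("need at least 100 samples for a stable fit")
    ref = rec.ref405
    sig = rec.sig470
    if np.ptp(ref) == 0:
        warnings.warn(
            "constant 405-nm reference; falling back to percentile df/F"
        )
        f0 = np.percentile(sig, 10)
        if f0 == 0:
            f0 = 1.0
        return (sig - f0) / f0
    design = np.column_stack([np.ones_like(ref), ref])
    if robust:
        import statsmodels.api as sm

        fit = sm.RLM(sig, design).fit().fittedvalues
    else:
        coef, *_ = np.linalg.lstsq(design, sig, rcond=None)
        fit = design @ coef
    return (sig - fit) / fit


def epoch_mean_difference(
    series: np.ndarray,
    time: np.ndarray,
    on_epochs: list[tuple[float, float]],
    off_epochs: list[tuple[float, float]],
) -> float:
    """Mean df/F over ON epochs minus mean df/F over OFF epochs."""
    if not on_epochs or not off_epochs:
        raise ValueError("both epoch sets must be non-empty")
    series = np.asarray(series, dtype=float)
    time = np.asarray(time, dtype=float)

    def mask_of(epochs: list[tuple[float, float]]) -> np.ndarray:
        m = np.zeros(time.shape, dtype=bool)
        for start, end in epochs:
            m |= (time >= start) & (time < end)
        return m

    on = mask_of(on_epochs)
    off = mask_of(off_epochs)
    if not on.any() or not off.any():
        raise ValueError("an epoch set covers no samples")
    return float(series[on].mean() - series[off].mean())


def epochs_to_intervals(epochs: BehaviorEpochs, label: str) -> list[tuple[float, float]]:
    """Convenience: the (start, end) pairs of one label."""
    return epochs.of_label(label)
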