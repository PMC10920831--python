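"""Independent brute-force oracles used to cross-check the implementation.

Each function here is written as the most direct possible computation of the
quantity — exhaustive scans, per-sample loops, explicit enumeration — and
deliberately shares no code with the package.
"""

from __future__ import annotations

import itertools

import numpy as np


def speed_two_point(time: np.ndarray, xy: np.ndarray) -> np.ndarray:
    """Two-point central-difference speed with one-sided edges."""
    n = len(time)
    out = np.zeros(n)
    for i in range(1, n - 1):
        dx = xy[i + 1, 0] - xy[i - 1, 0]
        dy = xy[i + 1, 1] - xy[i - 1, 1]
        out[i] = np.sqrt(dx * dx + dy * dy) / (time[i + 1] - time[i - 1])
    out[0] = out[1]
    out[-1] = out[-2]
    return out


def approach_intervals_scan(
    dist: np.ndarray,
    speed: np.ndarray,
    time: np.ndarray,
    min_decrease: float,
    min_speed: float,
    tol: float,
) -> list[tuple[float, float]]:
    """Exhaustive scan over all candidate intervals for approach epochs.

    An interval [i, j] is admissible when every step keeps the distance
    non-increasing up to ``tol`` and every sample is at least ``min_speed``
    fast; epochs are the maximal (non-extendable) admissible intervals whose
    total distance decrease is >= ``min_decrease``.
    """
    n = len(dist)

    def step_admissible(k: int) -> bool:
        return (
            dist[k + 1] - dist[k] <= tol
            and speed[k] >= min_speed
            and speed[k + 1] >= min_speed
        )

    def interval_admissible(i: int, j: int) -> bool:
        return all(step_admissible(k) for k in range(i, j))

    epochs = []
    for i in range(n - 1):
        for j in range(i + 1, n):
            if not interval_admissible(i, j):
                continue
            left_max = i == 0 or not step_admissible(i - 1)
            right_max = j == n - 1 or not step_admissible(j)
            if left_max and right_max and dist[i] - dist[j] >= min_decrease:
                epochs.append((float(time[i]), float(time[j])))
    return sorted(set(epochs))


def threshold_runs(above: np.ndarray, time: np.ndarray, dt: float) -> list[tuple[float, float]]:
    """Contiguous supra-threshold runs as (start, end) epochs."""
    epochs = []
    start = None
    for i, flag in enumerate(above):
        if flag and start is None:
            start = time[i]
        if not flag and start is not None:
            epochs.append((float(start), float(time[i - 1] + dt)))
            start = None
    if start is not None:
        epochs.append((float(start), float(time[-1] + dt)))
    return epochs


def rasterize_membership(
    entries: list[tuple[str, float, float]],
    time_base: np.ndarray,
    priority: tuple[str, ...],
    fill: str = "other",
) -> np.ndarray:
    """Per-sample membership scan honoring the label priority."""
    out = []
    rank = {lab: k for k, lab in enumerate(priority)}

    def key(lab: str):
        return (rank[lab], "") if lab in rank else (len(rank), lab)

    for t in time_base:
        hits = [lab for lab, s, e in entries if s <= t < e]
        out.append(min(hits, key=key) if hits else fill)
    return np.array(out)


def variance_filter_two_pass(values: np.ndarray, fraction: float) -> np.ndarray:
    """Boolean kept-mask from an explicit two-pass variance rule."""
    variances = np.array([np.var(row) for row in values])
    q1 = np.percentile(variances, 25)
    q3 = np.percentile(variances, 75)
    non_outlier = [v for v in variances if v <= q3 + 1.5 * (q3 - q1)]
    reference = max(non_outlier) if non_outlier else max(variances)
    if reference == 0:
        return np.ones(len(variances), dtype=bool)
    return variances >= fraction * reference


def local_maxima_mean(trace: np.ndarray) -> tuple[float, bool]:
    """Three-point strict local-maximum scan (no plateaus in inputs)."""
    peaks = [
        trace[i]
        for i in range(1, len(trace) - 1)
        if trace[i] > trace[i - 1] and trace[i] > trace[i + 1]
    ]
    if not peaks:
        return 0.0, False
    return float(np.mean(peaks)), True


def silhouette_brute(coords: np.ndarray, labels: np.ndarray) -> float:
    """Per-sample silhouette via explicit loops."""
    n = len(labels)
    uniq = sorted(set(labels))
    scores = []
    for i in range(n):
        own = [j for j in range(n) if labels[j] == labels[i] and j != i]
        if not own:
            scores.append(0.0)
            continue
        a = np.mean([np.linalg.norm(coords[i] - coords[j]) for j in own])
        b = min(
            np.mean(
                [
                    np.linalg.norm(coords[i] - coords[j])
                    for j in range(n)
                    if labels[j] == lab
                ]
            )
            for lab in uniq
            if lab != labels[i]
        )
        denom = max(a, b)
        scores.append(0.0 if denom == 0 else (b - a) / denom)
    return float(np.mean(scores))


def mahalanobis_solve(ref: np.ndarray, query: np.ndarray) -> np.ndarray:
    """Explicit inverse-based Mahalanobis distances."""
    mu = ref.mean(axis=0)
    cov_inv = np.linalg.inv(np.cov(ref, rowvar=False))
    out = []
    for y in np.atleast_2d(query):
        d = y - mu
        out.append(np.sqrt(d @ cov_inv @ d))
    return np.array(out)


def signed_rank_exact(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Exhaustive sign-assignment enumeration of the Wilcoxon signed-rank
    test (tie-free inputs)."""
    diff = np.asarray(x, float) - np.asarray(y, float)
    diff = diff[diff != 0]
    n = len(diff)
    ranks = np.argsort(np.argsort(np.abs(diff))) + 1.0
    w_plus = float(ranks[diff > 0].sum())
    dist = []
    for signs in itertools.product([0, 1], repeat=n):
        dist.append(float(sum(r for r, s in zip(ranks, signs) if s)))
    dist = np.array(dist)
    stat = min(w_plus, n * (n + 1) / 2.0 - w_plus)
    p = min(1.0, 2.0 * np.mean(dist <= stat))
    return stat, p


def rank_sum_exact(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Exhaustive enumeration of the two-sample rank-sum (Mann-Whitney U)
    null for small tie-free samples."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n1, n2 = len(x), len(y)
    combined = np.concatenate([x, y])
    ranks = np.argsort(np.argsort(combined)) + 1.0
    u_obs = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)
    us = []
    all_ranks = np.arange(1.0, n1 + n2 + 1.0)
    for subset in itertools.combinations(range(n1 + n2), n1):
        us.append(float(all_ranks[list(subset)].sum() - n1 * (n1 + 1) / 2.0))
    us = np.array(us)
    p = min(1.0, 2.0 * min(np.mean(us <= u_obs), np.mean(us >= u_obs)))
    return u_obs, p


def bh_step_up(p_values: np.ndarray) -> np.ndarray:
    """Hand-rolled Benjamini-Hochberg step-up."""
    p = np.asarray(p_values, float)
    m = len(p)
    order = np.argsort(p)
    q = np.empty(m)
    prev = 1.0
    for rank_idx in range(m - 1, -1, -1):
        i = order[rank_idx]
        val = min(prev, p[i] * m / (rank_idx + 1))
        q[i] = val
        prev = val
    return q
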