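"""Supervised analyses: matched-sample decoding and bootstrap GLM cell
classification.

Decoding uses multinomial logistic regression on matched behavior /
non-behavior time-points with five-fold cross-validation and a 10-s temporal
gap between training and validation sets, so chance accuracy is 50%.  Cell
classification fits a per-cell GLM against a behavior indicator and compares
the coefficient with a bootstrap null built from 100 onset randomizations:
cells beyond 95% of the null are behavior-modulated (+ or -).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.linear_model import LogisticRegression

from .behavior import rasterize
from .datatypes import (
    BehaviorEpochs,
    CellBehaviorClass,
    EventAlignedTensor,
    CoRegistrationMap,
    TraceMatrix,
)


@dataclass
class DecodingDataset:
    """Matched behavior / non-behavior feature rows with time stamps."""

    features: np.ndarray  # (rows, cells)
    labels: np.ndarray  # 1 = behavior, 0 = non-behavior
    times: np.ndarray  # s, for gap enforcement
    behavior: str

    def __post_init__(self) -> None:
        n = self.features.shape[0]
        if not (self.labels.shape[0] == n and self.times.shape[0] == n):
            raise ValueError("rows, labels and times must align")
        if int(self.labels.sum()) * 2 != n:
            raise ValueError("class counts must be equal")


@dataclass
class DecodingResult:
    fold_accuracies: list[float]
    mean_accuracy: float
    chance: float = 0.5
    n_folds: int = 5
    skipped_folds: int = 0


# ---------------------------------------------------------------------------
# decoding
# ---------------------------------------------------------------------------


def session_inclusion(epochs: BehaviorEpochs, behavior: str, min_count: int = 5) -> bool:
    """Sessions with fewer than ``min_count`` behaviors are excluded."""
    return epochs.count(behavior) >= min_count


def build_decoding_dataset(
    traces: TraceMatrix,
    epochs: BehaviorEpochs,
    behavior: str,
    window_after_onset: float = 2.0,
    seed: int = 0,
    zscore: bool = True,
    single_point: bool = False,
) -> DecodingDataset:
    """Select matched behavior and non-behavior time-points.

    Positive rows are all trace samples within ``(onset, onset + window]``
    after each onset of ``behavior`` (``single_point=True`` instead takes the
    one sample at onset + window); negatives are an equal count sampled
    uniformly without replacement from samples outside all epochs of that
    behavior.
    """
    onsets = epochs.onsets(behavior)
    if onsets.size == 0:
        raise ValueError(f"no epochs of behavior {behavior!r}")
    rate = traces.rate
    t = traces.time
    pos_idx: list[int] = []
    for onset in onsets:
        if single_point:
            idx = int(round((onset + window_after_onset) * rate))
            if 0 <= idx < traces.n_samples:
                pos_idx.append(idx)
        else:
            lo = int(np.floor(onset * rate)) + 1
            hi = int(np.floor((onset + window_after_onset) * rate)) + 1
            pos_idx.extend(range(max(lo, 0), min(hi, traces.n_samples)))
    pos_idx = sorted(set(pos_idx))

    in_behavior = np.zeros(traces.n_samples, dtype=bool)
    for start, end in epochs.of_label(behavior):
        in_behavior |= (t >= start) & (t < end)
    # window samples may extend past the epoch end; exclude them from negatives
    candidates = np.flatnonzero(~in_behavior)
    candidates = np.setdiff1d(candidates, np.asarray(pos_idx, dtype=int))
    if candidates.size < len(pos_idx):
        raise ValueError(
            f"insufficient non-behavior samples: need {len(pos_idx)}, "
            f"have {candidates.size}"
        )
    rng = np.random.default_rng(seed)
    neg_idx = np.sort(rng.choice(candidates, size=len(pos_idx), replace=False))

    X = traces.values
    if zscore:
        mu = X.mean(axis=1, keepdims=True)
        sd = X.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        X = (X - mu) / sd
    idx = np.concatenate([pos_idx, neg_idx]).astype(int)
    labels = np.concatenate([np.ones(len(pos_idx)), np.zeros(len(neg_idx))])
    order = np.argsort(idx, kind="stable")
    return DecodingDataset(
        features=X[:, idx[order]].T,
        labels=labels[order],
        times=t[idx[order]],
        behavior=behavior,
    )


def crossval_decode(
    dataset: DecodingDataset,
    k: int = 5,
    min_gap: float = 10.0,
    seed: int = 0,
    ridge_c: float = 100.0,
) -> DecodingResult:
    """K-fold cross-validated multinomial logistic decoding.

    Rows are partitioned into ``k`` contiguous-in-time folds; any training
    row within ``min_gap`` seconds of the validation fold is dropped from
    training, so temporally autocorrelated activity cannot leak across the
    split.  The classifier is softmax regression with only a small ridge
    penalty.
    """
    n = dataset.features.shape[0]
    for cls in (0, 1):
        if int(np.sum(dataset.labels == cls)) < k:
            raise ValueError("need >= k rows per class")
    order = np.argsort(dataset.times, kind="stable")
    X = dataset.features[order]
    y = dataset.labels[order]
    t = dataset.times[order]
    bounds = np.linspace(0, n, k + 1).astype(int)

    fold_acc: list[float] = []
    skipped = 0
    for f in range(k):
        lo, hi = bounds[f], bounds[f + 1]
        val = np.zeros(n, dtype=bool)
        val[lo:hi] = True
        t_lo, t_hi = t[lo], t[hi - 1]
        train = ~val & ((t < t_lo - min_gap) | (t > t_hi + min_gap))
        if (
            val.sum() == 0
            or np.unique(y[train]).size < 2
            or np.unique(y[val]).size < 2
        ):
            skipped += 1
            warnings.warn(f"fold {f} lost an entire class; skipped")
            continue
        clf = LogisticRegression(
            C=ridge_c, max_iter=2000, random_state=seed
        )
        clf.fit(X[train], y[train])
        fold_acc.append(float(np.mean(clf.predict(X[val]) == y[val])))
    if not fold_acc:
        raise ValueError("all folds skipped; decoding impossible")
    return DecodingResult(
        fold_accuracies=fold_acc,
        mean_accuracy=float(np.mean(fold_acc)),
        n_folds=k,
        skipped_folds=skipped,
    )


# ---------------------------------------------------------------------------
# GLM cell classification
# ---------------------------------------------------------------------------


def behavior_indicator(
    epochs: BehaviorEpochs, behavior: str, time: np.ndarray
) -> np.ndarray:
    """0/1 per-sample indicator of one behavior on a given time base."""
    ind = np.zeros(time.shape, dtype=float)
    for start, end in epochs.of_label(behavior):
        ind[(time >= start) & (time < end)] = 1.0
    return ind


def fit_behavior_glm(trace: np.ndarray, indicator: np.ndarray) -> float:
    """Behavior coefficient of a Gaussian identity-link GLM.

    Least-squares fit of ``trace ~ intercept + beta * indicator``; with a
    binary indicator the coefficient equals the in-behavior minus
    out-of-behavior mean activity.
    """
    trace = np.asarray(trace, dtype=float)
    indicator = np.asarray(indicator, dtype=float)
    if np.ptp(indicator) == 0:
        raise ValueError("behavior indicator is constant; coefficient undefined")
    design = np.column_stack([np.ones_like(indicator), indicator])
    coef, *_ = np.linalg.lstsq(design, trace, rcond=None)
    return float(coef[1])


def _glm_weights_matrix(values: np.ndarray, indicator: np.ndarray) -> np.ndarray:
    """Vectorized behavior coefficients for all cells at once (binary
    indicator closed form: in-mean minus out-mean)."""
    mask = indicator > 0.5
    if mask.all() or not mask.any():
        raise ValueError("behavior indicator is constant; coefficient undefined")
    return values[:, mask].mean(axis=1) - values[:, ~mask].mean(axis=1)


def randomize_onsets(
    epochs: BehaviorEpochs,
    behavior: str,
    duration: float,
    rng: np.random.Generator,
) -> BehaviorEpochs:
    """Redraw epoch start times uniformly, preserving durations, order and
    non-overlap within the session bounds."""
    durations = [e - s for s, e in epochs.of_label(behavior)]
    if not durations:
        raise ValueError(f"no epochs of behavior {behavior!r}")
    free = duration - sum(durations)
    if free <= 0:
        raise ValueError("epochs cover the whole session; no placement freedom")
    cuts = np.sort(rng.uniform(0.0, free, size=len(durations)))
    entries = []
    offset = 0.0
    for cut, dur in zip(cuts, durations):
        start = cut + offset
        entries.append((behavior, float(start), float(start + dur)))
        offset += dur
    return BehaviorEpochs(entries)


def bootstrap_onset_null(
    traces: TraceMatrix | np.ndarray,
    epochs: BehaviorEpochs,
    behavior: str,
    n_shuffles: int = 100,
    seed: int = 0,
    rate: float | None = None,
) -> np.ndarray:
    """Bootstrap null of GLM coefficients from randomized behavior onsets.

    Epoch start times are redrawn ``n_shuffles`` times (durations preserved,
    non-overlap enforced); each shuffled schedule is shared by all cells of
    the session and the coefficient recomputed.  Returns an array of shape
    ``(n_shuffles,)`` for a single trace or ``(n_cells, n_shuffles)`` for a
    matrix.
    """
    if isinstance(traces, TraceMatrix):
        values, rate_ = traces.values, traces.rate
    else:
        values = np.atleast_2d(np.asarray(traces, dtype=float))
        if rate is None:
            raise ValueError("rate required for bare arrays")
        rate_ = rate
    duration = values.shape[1] / rate_
    time = np.arange(values.shape[1]) / rate_
    rng = np.random.default_rng(seed)
    null = np.empty((values.shape[0], n_shuffles))
    for s in range(n_shuffles):
        shuffled = randomize_onsets(epochs, behavior, duration, rng)
        ind = behavior_indicator(shuffled, behavior, time)
        null[:, s] = _glm_weights_matrix(values, ind)
    return null[0] if null.shape[0] == 1 and not isinstance(traces, TraceMatrix) else null


def classify_cell(
    beta: float, null: np.ndarray, quantile: float = 0.95
) -> CellBehaviorClass:
    """Classify one cell's behavior coefficient against its bootstrap null.

    "+" if beta exceeds at least ``quantile`` of the null values, "-" if at
    least ``quantile`` of the null values exceed beta, else "ns".  Exact
    ties count against significance.
    """
    null = np.asarray(null, dtype=float)
    if null.size == 0:
        raise ValueError("empty null distribution")
    frac_below = float(np.mean(null < beta))
    frac_above = float(np.mean(null > beta))
    if frac_below >= quantile:
        label = "+"
    elif frac_above >= quantile:
        label = "-"
    else:
        label = "ns"
    return CellBehaviorClass(
        cell_id="",
        behavior="",
        glm_weight=float(beta),
        null_quantile=frac_below,
        label=label,
    )


def classify_cells(
    traces: TraceMatrix,
    epochs: BehaviorEpochs,
    behavior: str,
    n_shuffles: int = 100,
    quantile: float = 0.95,
    seed: int = 0,
) -> list[CellBehaviorClass]:
    """Bootstrap classification of every cell for one behavior."""
    ind = behavior_indicator(epochs, behavior, traces.time)
    betas = _glm_weights_matrix(traces.values, ind)
    null = bootstrap_onset_null(traces, epochs, behavior, n_shuffles, seed)
    out = []
    for cid, beta, cell_null in zip(traces.cell_ids, betas, null):
        cls = classify_cell(float(beta), cell_null, quantile)
        cls.cell_id = cid
        cls.behavior = behavior
        out.append(cls)
    return out


# ---------------------------------------------------------------------------
# cross-assay correlations
# ---------------------------------------------------------------------------


def weight_correlation(
    weights_a: dict[str, float],
    weights_b: dict[str, float],
    coreg: CoRegistrationMap,
) -> dict:
    """Spearman correlation of GLM weights across co-registered cells."""
    pairs = [
        (weights_a[a], weights_b[b])
        for a, b in coreg.pairs
        if a in weights_a and b in weights_b
    ]
    if len(pairs) < 3:
        raise ValueError("need >= 3 co-registered cells with weights")
    x, y = map(np.asarray, zip(*pairs))
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return {"rho": np.nan, "p_value": np.nan, "n": len(pairs), "flag": "constant ranks"}
    rho, p = stats.spearmanr(x, y)
    return {"rho": float(rho), "p_value": float(p), "n": len(pairs), "flag": None}


def fisher_r_to_z(r1: float, r2: float, n1: int, n2: int) -> tuple[float, float]:
    """Compare two correlations via the Fisher r-to-z transformation."""
    if n1 <= 3 or n2 <= 3:
        raise ValueError("need n > 3 per correlation")
    z = (np.arctanh(r1) - np.arctanh(r2)) / np.sqrt(
        1.0 / (n1 - 3) + 1.0 / (n2 - 3)
    )
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)


def profile_correlation(
    tensor_a: EventAlignedTensor,
    tensor_b: EventAlignedTensor,
    cells: list[str] | None = None,
) -> dict:
    """Pearson correlation of event-averaged activity profiles across assays.

    Per-cell event-averaged peri-onset profiles are concatenated across the
    chosen (co-registered) cells and correlated between the two assays.
    """
    if tensor_a.offsets.size != tensor_b.offsets.size or not np.allclose(
        tensor_a.offsets, tensor_b.offsets
    ):
        raise ValueError("tensors must share an offset grid")
    prof_a = tensor_a.event_average()  # (offsets, cells)
    prof_b = tensor_b.event_average()
    if cells is not None:
        ia = [tensor_a.cell_ids.index(c) for c in cells]
        ib = [tensor_b.cell_ids.index(c) for c in cells]
        prof_a = prof_a[:, ia]
        prof_b = prof_b[:, ib]
    x = prof_a.T.ravel()
    y = prof_b.T.ravel()
    if x.size <= 3:
        raise ValueError("need n > 3 concatenated profile samples")
    r, p = stats.pearsonr(x, y)
    return {"rho": float(r), "p_value": float(p), "n": int(x.size)}
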