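"""Time-resolved multivariate decoding of epoched EEG.

The 12-condition problem is decomposed into all 66 binary problems.  For
each pair and timepoint a linear SVM (C = 1) is trained on pseudotrials
(averages of ``chunk_size`` randomly-chunked same-condition trials) using
leave-one-pseudotrial-out cross-validation, with the samples of a moving
window concatenated as features (the window widens the feature set, it is
not a smoother).  The random allocation of trials to chunks is repeated
``n_iter`` times (default 50) and accuracies averaged.  Chance is 50%
because results are averaged over pairs.

Per-fold feature vectors are mean-centred with the training mean; both the
centring and the classifier run in Gram space (see ``_svm``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _svm
from .rdm import PAIR_ACROSS, PAIR_WITHIN_PEOPLE, PAIR_WITHIN_PLACES
from .synth import CATEGORY_PEOPLE, EpochedEEG, _rng_for

__all__ = [
    "Pseudotrials",
    "DecodingTimeseries",
    "TimeGenMatrix",
    "make_pseudotrials",
    "decode_timecourse",
    "aggregate_pairs",
    "time_generalize",
]


@dataclass
class Pseudotrials:
    """Chunk-averaged trials per condition plus the chunk assignment.

    ``data`` is ``(n_conditions, n_pseudo, channels, time)``; ``chunks``
    maps ``(condition, pseudo)`` to the original trial indices that were
    averaged.  Leftover trials (``n mod chunk_size``) are dropped.
    """

    data: np.ndarray
    chunks: list[list[np.ndarray]]
    conditions: np.ndarray


@dataclass
class DecodingTimeseries:
    """Accuracy (%) over time, per pair or aggregated.

    ``accuracy`` is ``(n_pairs, n_time)`` for level ``per_pair`` and
    ``(n_time,)`` for aggregated levels.
    """

    time_ms: np.ndarray
    accuracy: np.ndarray
    level: str
    n_iterations: int
    pairs: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if np.nanmin(self.accuracy) < 0 or np.nanmax(self.accuracy) > 100:
            raise ValueError("accuracies must lie in [0, 100]%")


@dataclass
class TimeGenMatrix:
    """Train-time x test-time accuracy (%) for category decoding."""

    time_ms: np.ndarray
    accuracy: np.ndarray
    level: str = "category"
    n_iterations: int = 10

    def __post_init__(self) -> None:
        if self.accuracy.shape != (len(self.time_ms), len(self.time_ms)):
            raise ValueError("time-generalization matrix must be square on the grid")
        if np.nanmin(self.accuracy) < 0 or np.nanmax(self.accuracy) > 100:
            raise ValueError("accuracies must lie in [0, 100]%")


def _condition_categories(epochs: EpochedEEG) -> np.ndarray:
    lab = epochs.labels
    cats = []
    for c in range(1, epochs.n_conditions + 1):
        sub = lab.loc[lab["condition"] == c, "category"]
        if len(sub) == 0:
            raise ValueError(f"condition {c} has no trials")
        cats.append(sub.iloc[0])
    return np.asarray(cats)


def _pair_frame(categories: np.ndarray) -> pd.DataFrame:
    n = len(categories)
    iu, ju = np.triu_indices(n, 1)
    both_people = (categories[iu] == CATEGORY_PEOPLE) & (categories[ju] == CATEGORY_PEOPLE)
    both_places = (categories[iu] != CATEGORY_PEOPLE) & (categories[ju] != CATEGORY_PEOPLE)
    kind = np.where(
        both_people, PAIR_WITHIN_PEOPLE, np.where(both_places, PAIR_WITHIN_PLACES, PAIR_ACROSS)
    )
    return pd.DataFrame({"i": iu, "j": ju, "kind": kind})


def make_pseudotrials(
    epochs: EpochedEEG, chunk_size: int, seed: int | np.random.Generator = 0
) -> Pseudotrials:
    """Randomly partition each condition's trials into chunks and average.

    Each condition's trials are permuted and split into
    ``floor(n / chunk_size)`` chunks of exactly ``chunk_size``; each
    pseudotrial is the element-wise mean of its chunk.  Decoding
    additionally requires at least two pseudotrials per condition, checked
    by the cross-validation step.
    """
    if chunk_size < 1:
        raise ValueError("chunk_size must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else _rng_for(seed, "pseudotrials")
    conditions = np.arange(1, epochs.n_conditions + 1)
    per_cond_chunks: list[list[np.ndarray]] = []
    n_pseudo = None
    for c in conditions:
        idx = epochs.condition_trials(int(c))
        if len(idx) < chunk_size:
            raise ValueError(
                f"condition {c} has {len(idx)} trials; needs >= {chunk_size}"
            )
        perm = rng.permutation(idx)
        k = len(idx) // chunk_size
        chunks = [perm[i * chunk_size : (i + 1) * chunk_size] for i in range(k)]
        per_cond_chunks.append(chunks)
        n_pseudo = k if n_pseudo is None else min(n_pseudo, k)
    n_ch, n_t = epochs.data.shape[1], epochs.data.shape[2]
    data = np.empty((len(conditions), n_pseudo, n_ch, n_t), dtype=epochs.data.dtype)
    for ci, chunks in enumerate(per_cond_chunks):
        for pi in range(n_pseudo):
            data[ci, pi] = epochs.data[chunks[pi]].mean(axis=0)
        per_cond_chunks[ci] = chunks[:n_pseudo]
    return Pseudotrials(data=data, chunks=per_cond_chunks, conditions=conditions)


def _windowed(features: np.ndarray, window: int, time_step: int) -> tuple[np.ndarray, np.ndarray]:
    """Concatenate the samples of a centred moving window.

    ``features`` is ``(samples, channels, time)``; returns
    ``(time_indices, W)`` with ``W`` of shape
    ``(n_kept_times, samples, channels * window)``.  Edge timepoints
    without a complete window are dropped.
    """
    n_s, n_ch, n_t = features.shape
    if window < 1:
        raise ValueError("window must be >= 1")
    if n_t < window:
        raise ValueError("epoch shorter than the window")
    sw = np.lib.stride_tricks.sliding_window_view(features, window, axis=2)
    # sw: (samples, channels, n_t - window + 1, window)
    half = window // 2
    centers = np.arange(half, n_t - (window - 1 - half))[::time_step]
    w = sw[:, :, centers - half, :]  # (samples, channels, kept, window)
    w = np.ascontiguousarray(
        w.transpose(2, 0, 1, 3).reshape(len(centers), n_s, n_ch * window),
        dtype=np.float32,
    )
    return centers, w


def decode_timecourse(
    epochs: EpochedEEG,
    window: int = 3,
    chunk_size: int = 5,
    n_iter: int = 50,
    C: float = 1.0,
    seed: int = 0,
    time_step: int = 1,
) -> DecodingTimeseries:
    """Pairwise decoding timeseries for all condition pairs.

    ``time_step`` decimates the decoded time grid (features still use the
    full-rate window); the default decodes every sample.
    """
    categories = _condition_categories(epochs)
    pairs = _pair_frame(categories)
    pa = pairs["i"].to_numpy(np.int64)
    pb = pairs["j"].to_numpy(np.int64)
    rng = _rng_for(seed, "decode-timecourse")
    acc_sum = None
    centers = None
    n_pseudo = None
    for _ in range(n_iter):
        ps = make_pseudotrials(epochs, chunk_size, rng)
        n_cond, n_pseudo = ps.data.shape[0], ps.data.shape[1]
        if n_pseudo < 2:
            raise ValueError("need at least 2 pseudotrials per condition")
        stacked = ps.data.reshape(n_cond * n_pseudo, *ps.data.shape[2:])
        centers, w = _windowed(stacked, window, time_step)
        gram = np.matmul(w, w.transpose(0, 2, 1)).astype(np.float64)
        acc = _svm.pair_loso_accuracy(
            gram, pa, pb, n_pseudo, C, _svm.DEFAULT_TOL, _svm.DEFAULT_MAX_ITER
        )
        acc_sum = acc if acc_sum is None else acc_sum + acc
    return DecodingTimeseries(
        time_ms=epochs.time_ms[centers],
        accuracy=100.0 * acc_sum / n_iter,
        level="per_pair",
        n_iterations=n_iter,
        pairs=pairs,
    )


_LEVEL_TO_KIND = {
    "category": PAIR_ACROSS,
    "within_people": PAIR_WITHIN_PEOPLE,
    "within_places": PAIR_WITHIN_PLACES,
}


def aggregate_pairs(per_pair: DecodingTimeseries, mode: str) -> DecodingTimeseries:
    """Average pairwise timeseries into a category or within-category curve.

    ``category`` averages the across-category pairs (36 under the default
    design), the ``within_*`` modes the 15 pairs inside one category.
    """
    if per_pair.level != "per_pair" or per_pair.pairs is None:
        raise ValueError("aggregate_pairs needs a per-pair result")
    if mode not in _LEVEL_TO_KIND:
        raise ValueError(f"unknown mode {mode!r}")
    n_cond = int(per_pair.pairs[["i", "j"]].to_numpy().max()) + 1
    if len(per_pair.pairs) != n_cond * (n_cond - 1) // 2:
        raise ValueError("per-pair result is missing pairs")
    mask = (per_pair.pairs["kind"] == _LEVEL_TO_KIND[mode]).to_numpy()
    if not mask.any():
        raise ValueError(f"no pairs of kind {mode!r}")
    return DecodingTimeseries(
        time_ms=per_pair.time_ms,
        accuracy=per_pair.accuracy[mask].mean(axis=0),
        level=mode,
        n_iterations=per_pair.n_iterations,
    )


def time_generalize(
    epochs: EpochedEEG,
    n_iter: int = 10,
    window: int = 3,
    C: float = 1.0,
    seed: int = 0,
    time_step: int = 1,
) -> TimeGenMatrix:
    """Category-level temporal generalization matrix.

    Per iteration each condition's trials are split into two random,
    balanced halves (odd trials dropped) and averaged into one pseudotrial
    per half; a people-vs-places SVM trained at each train-time is tested
    at every test-time on the other half, both directions averaged.
    """
    categories = _condition_categories(epochs)
    y = np.where(categories == CATEGORY_PEOPLE, 1.0, -1.0)
    if len(np.unique(y)) < 2:
        raise ValueError("time generalization needs both categories")
    rng = _rng_for(seed, "time-generalize")
    n_cond = epochs.n_conditions
    n_ch, n_t = epochs.data.shape[1], epochs.data.shape[2]
    acc_sum = None
    centers = None
    for _ in range(n_iter):
        halves = np.empty((2, n_cond, n_ch, n_t), dtype=epochs.data.dtype)
        for ci in range(n_cond):
            idx = rng.permutation(epochs.condition_trials(ci + 1))
            if len(idx) < 2:
                raise ValueError("need at least 2 trials per condition")
            half_n = len(idx) // 2
            halves[0, ci] = epochs.data[idx[:half_n]].mean(axis=0)
            halves[1, ci] = epochs.data[idx[half_n : 2 * half_n]].mean(axis=0)
        centers, w0 = _windowed(halves[0], window, time_step)
        _, w1 = _windowed(halves[1], window, time_step)
        n_tt = len(centers)
        acc = np.zeros((n_tt, n_tt))
        for train_w, test_w in ((w0, w1), (w1, w0)):
            test_flat = test_w.reshape(n_tt * n_cond, -1).astype(np.float64)
            for ti in range(n_tt):
                x = train_w[ti].astype(np.float64)
                mu = x.mean(axis=0)
                wvec, bias = _svm.fit_linear_gram(x - mu, y, C)
                scores = ((test_flat - mu) @ wvec + bias).reshape(n_tt, n_cond)
                signed = scores * y
                acc[ti] += (signed > 0).mean(axis=1) + 0.5 * (signed == 0).mean(axis=1)
        acc_sum = acc / 2.0 if acc_sum is None else acc_sum + acc / 2.0
    return TimeGenMatrix(
        time_ms=epochs.time_ms[centers],
        accuracy=100.0 * acc_sum / n_iter,
        level="category",
        n_iterations=n_iter,
    )
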