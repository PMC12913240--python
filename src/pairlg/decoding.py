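"""Individual-level classification sensitivity of ERP components.

Trials of a contrast are averaged into non-overlapping blocks of consecutive
trials to raise SNR, cropped to the component's decode window (0-300 ms for
the early complex and local effects, 0-400 ms for global effects), and fed
to a linear maximum-margin classifier (SVM) under stratified fivefold
cross-validation.  Significance is established with a dual permutation
framework: a performance distribution from iterations with true labels
(re-randomized fold assignment each iteration) and a null distribution from
iterations with freshly shuffled labels.  A component counts as detected
when the mean true-label accuracy exceeds the 95th percentile of the null
distribution; the empirical p value (fraction of null iterations at or
above the observed mean) is reported alongside.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .preprocess import EpochSet

__all__ = [
    "SensitivityResult", "block_average", "crop_to_window",
    "evaluate_sensitivity", "active_passive_contrast", "prepare_samples",
]


@dataclass
class SensitivityResult:
    participant_id: str
    contrast_name: str
    true_accuracies: np.ndarray
    null_accuracies: np.ndarray
    mean_accuracy: float
    accuracy_sd: float
    threshold: float               # 95th percentile of the null distribution
    detected: bool
    p_value: float                 # fraction of null >= mean accuracy
    n_blocks: int
    trials_per_block: int


def block_average(data: np.ndarray, n_blocks: int = 50) -> np.ndarray:
    """Average consecutive trials into ``n_blocks`` equal contiguous blocks.

    Trials are partitioned in temporal order into blocks of
    ``floor(n/n_blocks)``; remainder trials at the end are dropped.  With
    fewer trials than blocks the trials are returned unchanged (single-trial
    samples) with a warning.
    """
    n = data.shape[0]
    if n < n_blocks:
        warnings.warn(f"{n} trials < {n_blocks} blocks; using single-trial samples",
                      RuntimeWarning, stacklevel=2)
        return data.copy()
    per = n // n_blocks
    used = data[: n_blocks * per]
    return used.reshape(n_blocks, per, *data.shape[1:]).mean(axis=1)


def crop_to_window(data: np.ndarray, times: np.ndarray,
                   window_ms: tuple[float, float]) -> tuple[np.ndarray, np.ndarray]:
    """Restrict the time axis to the half-open window [start, stop) ms."""
    mask = (times >= window_ms[0]) & (times < window_ms[1])
    if not mask.any():
        raise ValueError(f"empty decode window {window_ms}")
    return data[..., mask], times[mask]


def _classifier():
    # Linear maximum-margin classifier, default regularization; features
    # (channels x samples) far outnumber block samples, so the linear
    # kernel is the natural choice.  Standardization is fitted inside each
    # training fold only (pipeline), avoiding test-set leakage.
    return make_pipeline(StandardScaler(), SVC(kernel="linear"))


def _cv_accuracy(X, y, k, rng) -> float:
    """Stratified k-fold accuracy of the fold-standardized linear SVM.

    Equivalent to ``cross_val_score(_classifier(), ...)`` but with the
    linear kernel evaluated as a precomputed Gram matrix of the fold-
    standardized features, which is much faster when features outnumber
    samples by orders of magnitude.
    """
    cv = StratifiedKFold(n_splits=k, shuffle=True,
                         random_state=int(rng.integers(2**31)))
    accs = []
    for tr, te in cv.split(X, y):
        mu = X[tr].mean(axis=0)
        sd = X[tr].std(axis=0)
        sd[sd == 0] = 1.0
        x_tr = (X[tr] - mu) / sd
        x_te = (X[te] - mu) / sd
        clf = SVC(kernel="precomputed").fit(x_tr @ x_tr.T, y[tr])
        accs.append((clf.predict(x_te @ x_tr.T) == y[te]).mean())
    return float(np.mean(accs))


def evaluate_sensitivity(samples_a: np.ndarray, samples_b: np.ndarray,
                         n_iter: int = 1000, k: int = 5,
                         seed: int | None = None,
                         participant_id: str = "", contrast_name: str = "",
                         ) -> SensitivityResult:
    """Dual permutation framework on balanced block-averaged samples."""
    if samples_a.shape[0] != samples_b.shape[0]:
        raise ValueError("class imbalance: equal sample counts required")
    if samples_a.shape[0] < k:
        raise ValueError(f"need >= {k} samples per class for {k}-fold CV")
    rng = np.random.default_rng(seed)
    X = np.concatenate([samples_a.reshape(len(samples_a), -1),
                        samples_b.reshape(len(samples_b), -1)])
    y = np.repeat([1, 0], [len(samples_a), len(samples_b)])

    true_acc = np.array([_cv_accuracy(X, y, k, rng) for _ in range(n_iter)])
    null_acc = np.array([_cv_accuracy(X, rng.permutation(y), k, rng)
                         for _ in range(n_iter)])

    mean_acc = float(true_acc.mean())
    thr = float(np.percentile(null_acc, 95))
    return SensitivityResult(
        participant_id=participant_id, contrast_name=contrast_name,
        true_accuracies=true_acc, null_accuracies=null_acc,
        mean_accuracy=mean_acc, accuracy_sd=float(true_acc.std()),
        threshold=thr, detected=mean_acc > thr,
        p_value=float((null_acc >= mean_acc).mean()),
        n_blocks=len(samples_a), trials_per_block=0)


def prepare_samples(epochs: EpochSet, window_ms: tuple[float, float],
                    n_blocks: int = 50,
                    exclude_channels: tuple[str, ...] = ("M1", "M2"),
                    ) -> np.ndarray:
    """Block-average an epoch set and crop it to the decode window."""
    keep = [i for i, c in enumerate(epochs.channels) if c not in exclude_channels]
    data = epochs.data[:, keep, :]
    blocks = block_average(data, n_blocks=n_blocks)
    cropped, _ = crop_to_window(blocks, epochs.times, window_ms)
    return cropped


def participant_sensitivity(A: EpochSet, B: EpochSet,
                            window_ms: tuple[float, float],
                            n_blocks: int = 50, n_iter: int = 1000, k: int = 5,
                            seed: int | None = None) -> SensitivityResult:
    """Convenience wrapper: block-average, crop, and evaluate one contrast."""
    sa = prepare_samples(A, window_ms, n_blocks)
    sb = prepare_samples(B, window_ms, n_blocks)
    n = min(len(sa), len(sb))
    res = evaluate_sensitivity(sa[:n], sb[:n], n_iter=n_iter, k=k, seed=seed,
                               participant_id=A.participant_id,
                               contrast_name=A.contrast_name)
    res.trials_per_block = max(1, A.n_trials // n_blocks) if A.n_trials >= n_blocks else 1
    return res


def active_passive_contrast(samples_active: np.ndarray,
                            samples_passive: np.ndarray,
                            n_iter: int = 1000, k: int = 5,
                            seed: int | None = None,
                            participant_id: str = "",
                            contrast_name: str = "") -> SensitivityResult:
    """Classify session condition (active vs passive) from global-deviant
    epochs; same block/CV/permutation machinery as the within-session test."""
    return evaluate_sensitivity(samples_active, samples_passive, n_iter=n_iter,
                                k=k, seed=seed, participant_id=participant_id,
                                contrast_name=contrast_name or "active_vs_passive")
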