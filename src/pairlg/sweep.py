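"""Sensor-count x epoch-fraction factorial sweep of active-passive decoding.

Evaluates how the detectability of voluntary attention engagement degrades
when spatial coverage (8/16/32/64-sensor nested montages) or temporal
sampling (25/50/75/100% of available epochs, taken in temporal order to
emulate a shorter recording) is reduced.  Each of the 16 configurations is
scored by repeated stratified fivefold cross-validation of the active-vs-
passive classifier, averaged over participants.  The dependence of accuracy
on each factor is summarized by Spearman rank correlations over the 16
configuration means, with percentile-bootstrap confidence intervals
obtained by resampling participants.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import spearmanr

from .decoding import _cv_accuracy, block_average, crop_to_window
from .montage import Montage
from .preprocess import EpochSet

__all__ = ["SweepResult", "run_sweep", "correlate_performance"]


@dataclass
class SweepResult:
    accuracies: np.ndarray          # (participants, sensors, fractions)
    grid_mean: np.ndarray           # (sensors, fractions)
    grid_se: np.ndarray
    sensor_counts: tuple[int, ...]
    fractions: tuple[float, ...]
    n_cv_repeats: int
    contrast_name: str
    rho_epochs: float | None = None
    rho_epochs_ci: tuple[float, float] | None = None
    rho_sensors: float | None = None
    rho_sensors_ci: tuple[float, float] | None = None


def _config_samples(ep_act: EpochSet, ep_pas: EpochSet, ch_labels, fraction,
                    window_ms, n_blocks):
    """Channel-restricted, epoch-subsampled, block-averaged sample pair."""
    idx = [ep_act.channels.index(c) for c in ch_labels]
    n = min(ep_act.n_trials, ep_pas.n_trials)
    n_use = int(np.ceil(fraction * n))
    out = []
    for ep in (ep_act, ep_pas):
        data = ep.data[:n_use, idx, :]
        # At the smallest fraction the epoch budget cannot fill the blocks,
        # so raw epochs serve as samples without block averaging.
        if fraction <= 0.25 or n_use < n_blocks:
            samples = data.copy()
        else:
            samples = block_average(data, n_blocks=n_blocks)
        samples, _ = crop_to_window(samples, ep.times, window_ms)
        out.append(samples)
    return out


def run_sweep(cohort_epochs: list[tuple[EpochSet, EpochSet]],
              montage: Montage,
              sensor_counts: tuple[int, ...] = (8, 16, 32, 64),
              fractions: tuple[float, ...] = (0.25, 0.5, 0.75, 1.0),
              n_repeats: int = 500, n_blocks: int = 50, k: int = 5,
              window_ms: tuple[float, float] = (0, 400),
              seed: int | None = None, contrast_name: str = "") -> SweepResult:
    """Score every (sensors, fraction) configuration for every participant.

    ``cohort_epochs`` holds one (active, passive) pair of global-deviant
    epoch sets per participant.  Reference channels are excluded from the
    montage subsets by construction (mastoids are not decoding features).
    """
    rng = np.random.default_rng(seed)
    n_p = len(cohort_epochs)
    acc = np.zeros((n_p, len(sensor_counts), len(fractions)))
    for p, (ep_act, ep_pas) in enumerate(cohort_epochs):
        for si, n_sens in enumerate(sensor_counts):
            labels = [c for c in montage.subsets[n_sens]
                      if c not in montage.offline_reference]
            for fi, frac in enumerate(fractions):
                sa, sb = _config_samples(ep_act, ep_pas, labels, frac,
                                         window_ms, n_blocks)
                n = min(len(sa), len(sb))
                if n < k:
                    raise ValueError(
                        f"fraction {frac} leaves {n} samples per class; "
                        f"need >= {k} for {k}-fold CV")
                X = np.concatenate([sa[:n].reshape(n, -1), sb[:n].reshape(n, -1)])
                y = np.repeat([1, 0], n)
                acc[p, si, fi] = np.mean(
                    [_cv_accuracy(X, y, k, rng) for _ in range(n_repeats)])
    grid_mean = acc.mean(axis=0)
    grid_se = acc.std(axis=0, ddof=1) / np.sqrt(n_p) if n_p > 1 else np.zeros_like(grid_mean)
    return SweepResult(accuracies=acc, grid_mean=grid_mean, grid_se=grid_se,
                       sensor_counts=tuple(sensor_counts),
                       fractions=tuple(fractions), n_cv_repeats=n_repeats,
                       contrast_name=contrast_name)


def _grid_rhos(grid: np.ndarray, sensor_counts, fractions):
    s_vals = np.repeat(sensor_counts, len(fractions))
    f_vals = np.tile(fractions, len(sensor_counts))
    flat = grid.ravel()
    if np.allclose(flat, flat[0]):
        return np.nan, np.nan
    rho_f = spearmanr(flat, f_vals).statistic
    rho_s = spearmanr(flat, s_vals).statistic
    return rho_f, rho_s


def correlate_performance(result: SweepResult, n_boot: int = 1000,
                          seed: int | None = None) -> SweepResult:
    """Spearman rho of accuracy vs epoch fraction and vs sensor count.

    95% CIs are percentile bootstrap over participants: each replicate
    resamples participants with replacement, re-means the grid, and
    recomputes both correlations.  Constant grids yield rho = NaN
    (undefined ranking).
    """
    rng = np.random.default_rng(seed)
    rho_f, rho_s = _grid_rhos(result.grid_mean, result.sensor_counts,
                              result.fractions)
    n_p = result.accuracies.shape[0]
    boots_f, boots_s = [], []
    for _ in range(n_boot):
        idx = rng.integers(0, n_p, n_p)
        bf, bs = _grid_rhos(result.accuracies[idx].mean(axis=0),
                            result.sensor_counts, result.fractions)
        boots_f.append(bf)
        boots_s.append(bs)
    ci = lambda b: tuple(np.percentile([x for x in b if np.isfinite(x)], [2.5, 97.5]))  # noqa: E731
    result.rho_epochs = float(rho_f) if np.isfinite(rho_f) else None
    result.rho_sensors = float(rho_s) if np.isfinite(rho_s) else None
    result.rho_epochs_ci = ci(boots_f) if np.isfinite(boots_f).any() else None
    result.rho_sensors_ci = ci(boots_s) if np.isfinite(boots_s).any() else None
    return result
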