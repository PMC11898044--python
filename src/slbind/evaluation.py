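"""Accuracy metrics and the distribution-matched train/validation splitter.

Model accuracy is reported as root-mean-square error (kcal/mol) and
Pearson correlation between predicted and experimental binding free
energies. The splitter reserves a validation fraction whose label
distribution matches the training set: labels are quantile-binned and
sampled per bin, so both subsets span the full affinity range instead of
a random split occasionally starving one tail.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import DegenerateMetricError

__all__ = ["rmse", "pearson_r", "stratified_split", "SplitResult"]


def rmse(y_true, y_pred) -> float:
    """Root-mean-square error, in the units of the inputs (kcal/mol here)."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape:
        raise ValueError(f"shape mismatch: {y_true.shape} vs {y_pred.shape}")
    if y_true.size == 0:
        raise ValueError("rmse of empty vectors is undefined")
    return float(np.sqrt(np.mean((y_true - y_pred) ** 2)))


def pearson_r(y_true, y_pred) -> float:
    """Pearson linear correlation in [-1, 1].

    Raises DegenerateMetricError when either vector has zero variance,
    where the correlation is undefined.
    """
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape:
        raise ValueError(f"shape mismatch: {y_true.shape} vs {y_pred.shape}")
    if y_true.size < 2:
        raise DegenerateMetricError("pearson correlation needs at least 2 points")
    if np.std(y_true) == 0 or np.std(y_pred) == 0:
        raise DegenerateMetricError("pearson correlation undefined for zero-variance input")
    return float(stats.pearsonr(y_true, y_pred).statistic)


@dataclass(frozen=True)
class SplitResult:
    """Index partition of a labeled set into train and validation rows."""

    train_idx: np.ndarray
    val_idx: np.ndarray
    fraction: float
    bin_edges: np.ndarray = field(repr=False)
    seed: int = 0

    def __post_init__(self) -> None:
        overlap = np.intersect1d(self.train_idx, self.val_idx)
        if overlap.size:
            raise ValueError("train/validation indices overlap")


def stratified_split(
    y,
    fraction: float = 0.8,
    n_bins: int = 10,
    seed: int = 0,
) -> SplitResult:
    """Quantile-stratified train/validation split on a continuous label.

    The labels are cut into ``n_bins`` quantile bins; within each bin a
    seeded random share of rows goes to training and the rest to
    validation, with per-bin training counts chosen by largest-remainder
    apportionment so the overall train share is exactly
    ``round(fraction * n)``. Both subsets therefore carry (approximately)
    the same label distribution as the full set — for a Gaussian-shaped
    affinity distribution, both remain Gaussian with matching moments.
    """
    y = np.asarray(y, dtype=float)
    n = y.shape[0]
    if not 0 < fraction < 1:
        raise ValueError(f"fraction must be in (0, 1), got {fraction}")
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    if n_bins > n // 2:
        raise ValueError(f"n_bins={n_bins} too fine for n={n} (need n_bins <= n/2)")

    edges = np.quantile(y, np.linspace(0, 1, n_bins + 1))
    # right-open bins except the last; searchsorted on interior edges
    bin_of = np.searchsorted(edges[1:-1], y, side="right")

    rng = np.random.default_rng(seed)
    bins = [np.flatnonzero(bin_of == b) for b in range(n_bins)]
    sizes = np.array([rows.size for rows in bins])
    base = np.floor(fraction * sizes).astype(int)
    remainder = fraction * sizes - base
    short = int(round(fraction * n)) - base.sum()
    # largest-remainder apportionment of the leftover training slots
    for b in np.lexsort((np.arange(n_bins), -remainder)):
        if short <= 0:
            break
        if base[b] < sizes[b]:
            base[b] += 1
            short -= 1
    train, val = [], []
    for rows, n_train in zip(bins, base):
        rows = rng.permutation(rows)
        train.extend(rows[:n_train])
        val.extend(rows[n_train:])
    return SplitResult(
        train_idx=np.sort(np.asarray(train, dtype=int)),
        val_idx=np.sort(np.asarray(val, dtype=int)),
        fraction=fraction,
        bin_edges=edges,
        seed=seed,
    )
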