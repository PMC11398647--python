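"""Consistency and prediction-error metrics.

Inter-segment consistency: the Pearson correlation between the onsets of
the two 500 ms halves of a response to a repeated-noise stimulus.  If the
network responds reproducibly to the (identical) repeated input token, the
two windows correlate; the window is kept to the first 200 of each 1000
points (one fifth of a segment) because trajectories from different initial
conditions converge at different speeds and only the early part of each
segment discriminates.

Inter-trial consistency: mean pairwise Pearson correlation of responses to
the same stimulus across repeated test runs, on the same 200-point window.

Prediction error: per-time-point RMSE across test runs, and NRMSE obtained
by dividing each condition's RMSE series by the grand mean RMSE over time
and the four conditions {Hebbian, non-Hebbian} x {RN, RefRN}.

Correlations over a constant (zero-variance) window are undefined; they are
returned as NaN and excluded from aggregates (never imputed), with the
exclusion count reported alongside.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np

__all__ = [
    "SEGMENT_LENGTH",
    "DEFAULT_WINDOW",
    "inter_segment_correlation",
    "inter_segment_correlations",
    "inter_trial_consistency",
    "rmse_series",
    "rmse_per_run",
    "nrmse_series",
    "nanmean_with_count",
]

#: Samples per 500 ms stimulus segment at 2 kHz.
SEGMENT_LENGTH = 1000
#: Evaluation window: one fifth of a segment.
DEFAULT_WINDOW = 200


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a @ a) * (b @ b))
    if denom == 0.0:
        return np.nan
    return float(np.clip((a @ b) / denom, -1.0, 1.0))


def inter_segment_correlation(series: np.ndarray, window: int = DEFAULT_WINDOW,
                              offset: int = 0) -> float:
    """Pearson r between the first ``window`` points of each half.

    Windows start at the segment onsets (offset 0) by default; ``offset``
    shifts both windows for sensitivity checks.  Returns NaN when either
    window has zero variance.
    """
    series = np.asarray(series, dtype=np.float64)
    if series.shape[-1] < SEGMENT_LENGTH + offset + window:
        raise ValueError(
            f"series of length {series.shape[-1]} too short for "
            f"window={window}, offset={offset}"
        )
    a = series[..., offset:offset + window]
    b = series[..., SEGMENT_LENGTH + offset:SEGMENT_LENGTH + offset + window]
    if series.ndim == 1:
        return _pearson(a, b)
    return np.array([_pearson(ai, bi) for ai, bi in zip(a, b)])


def inter_segment_correlations(series_matrix: np.ndarray,
                               window: int = DEFAULT_WINDOW,
                               offset: int = 0) -> np.ndarray:
    """Vectorized inter-segment r for an (M, K) matrix of M series."""
    m = np.atleast_2d(np.asarray(series_matrix, dtype=np.float64))
    a = m[:, offset:offset + window]
    b = m[:, SEGMENT_LENGTH + offset:SEGMENT_LENGTH + offset + window]
    a = a - a.mean(axis=1, keepdims=True)
    b = b - b.mean(axis=1, keepdims=True)
    denom = np.sqrt(np.einsum("ij,ij->i", a, a) * np.einsum("ij,ij->i", b, b))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.einsum("ij,ij->i", a, b) / denom
    r[denom == 0.0] = np.nan
    return np.clip(r, -1.0, 1.0)


def inter_trial_consistency(series_list, window: slice | None = None
                            ) -> tuple[float, int]:
    """Mean pairwise Pearson r over all unordered pairs of M >= 2 series.

    The default window is the 200-point onset of the first segment.
    Returns (mean r, number of undefined pairs excluded).
    """
    series = [np.asarray(s, dtype=np.float64) for s in series_list]
    if len(series) < 2:
        raise ValueError("need at least two series")
    if window is None:
        window = slice(0, DEFAULT_WINDOW)
    vals = [
        _pearson(a[window], b[window]) for a, b in combinations(series, 2)
    ]
    vals = np.array(vals)
    n_undef = int(np.isnan(vals).sum())
    mean = float(np.nanmean(vals)) if n_undef < vals.size else np.nan
    return mean, n_undef


def rmse_series(outputs: np.ndarray, targets: np.ndarray) -> np.ndarray:
    """Per-time-point RMSE over trials: sqrt(mean_n (d_n(k) - y_n(k))^2)."""
    outputs = np.asarray(outputs, dtype=np.float64)
    targets = np.asarray(targets, dtype=np.float64)
    if outputs.shape != targets.shape:
        raise ValueError(
            f"shape mismatch: outputs {outputs.shape} vs targets {targets.shape}"
        )
    return np.sqrt(np.mean((targets - outputs) ** 2, axis=0))


def rmse_per_run(outputs: np.ndarray, targets: np.ndarray) -> np.ndarray:
    """Time-averaged RMSE of each trial (one value per test run)."""
    outputs = np.asarray(outputs, dtype=np.float64)
    targets = np.asarray(targets, dtype=np.float64)
    if outputs.shape != targets.shape:
        raise ValueError("shape mismatch between outputs and targets")
    return np.sqrt(np.mean((targets - outputs) ** 2, axis=1))


def nrmse_series(rmse_by_condition: dict) -> dict:
    """Normalize each condition's RMSE series by the grand mean RMSE.

    The denominator is the average of the RMSE over time and over the four
    conditions {Hebbian, non-Hebbian} x {RN, RefRN} at one spectral radius,
    so the normalized series average exactly to 1 across conditions and
    time, and rescaling all signals cancels out.
    """
    if len(rmse_by_condition) != 4:
        raise ValueError(
            f"expected the 4 plasticity-by-stimulus conditions, got "
            f"{sorted(rmse_by_condition)}"
        )
    series = {k: np.asarray(v, dtype=np.float64)
              for k, v in rmse_by_condition.items()}
    grand = float(np.mean([v.mean() for v in series.values()]))
    if grand == 0.0:
        return {k: np.full_like(v, np.nan) for k, v in series.items()}
    return {k: v / grand for k, v in series.items()}


def nanmean_with_count(values: np.ndarray) -> tuple[float, int]:
    """Mean excluding NaNs, plus the count of excluded (undefined) entries."""
    values = np.asarray(values, dtype=np.float64)
    n_undef = int(np.isnan(values).sum())
    mean = float(np.nanmean(values)) if n_undef < values.size else np.nan
    return mean, n_undef
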