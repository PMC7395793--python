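"""Performance metrics: selectivity, reconstruction, ROC, weight error, sparseness.

All metrics are pure functions of logged state; nothing here mutates a
circuit.  Because training is unsupervised, the odor each cell codes for is
first recovered by a covariance bootstrap against the true mixing matrix;
reconstruction, correlation, ROC and weight error are then computed through
that selectivity map.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "assign_selectivity",
    "reconstruct_odors",
    "performance_correlation",
    "roc_curve",
    "weight_error",
    "lifetime_sparseness",
    "mt_variance",
    "roc_thresholds",
]


def assign_selectivity(learned_w: np.ndarray, W_true: np.ndarray) -> np.ndarray:
    """Map each cell to the odor whose true affinity column it best matches.

    o(j) = argmax_m cov_i(learned_w[j, :], W_true[:, m]), with ties broken by
    the lowest odor index (np.argmax's first-maximum rule), deterministically.

    learned_w : (M, N) learned feedforward (or readout) weights, cell-major
    W_true : (N, M) true mixing matrix
    Returns an integer array of odor indices, one per cell.  The map need not
    be injective; odors claimed by no cell reconstruct to zero.
    """
    lw = learned_w - learned_w.mean(axis=-1, keepdims=True)      # center over i
    tw = W_true - W_true.mean(axis=-2, keepdims=True)
    cov = lw @ tw                                                # (M_cells, M_odors)
    return np.argmax(cov, axis=-1)


def reconstruct_odors(rates: np.ndarray, selectivity: np.ndarray,
                      M: int | None = None) -> np.ndarray:
    """Decode odor estimates as the mean rate of the cells assigned to each odor.

    c_hat_j = mean of ``rates`` over cells with o(cell) = j, and 0 for odors
    no cell claims.  ``selectivity`` should come from the weights of the
    previous trial when scoring trial-by-trial learning curves.
    """
    rates = np.asarray(rates, dtype=float)
    if M is None:
        M = selectivity.shape[-1]
    counts = np.bincount(selectivity, minlength=M).astype(float)
    sums = np.bincount(selectivity, weights=rates, minlength=M)
    out = np.zeros(M)
    claimed = counts > 0
    out[claimed] = sums[claimed] / counts[claimed]
    return out


def performance_correlation(c_est: np.ndarray, c_true: np.ndarray) -> float:
    """Pearson correlation between estimates and truth, pooled over odors x trials.

    Returns NaN (reported as missing) if either side has zero variance.
    """
    a = np.asarray(c_est, dtype=float).ravel()
    b = np.asarray(c_true, dtype=float).ravel()
    if a.std() == 0.0 or b.std() == 0.0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def roc_thresholds(lo: float = 1e-6, hi: float = 1e1, step: float = 1.2) -> np.ndarray:
    """Detection-threshold grid: geometric from ``lo`` with ~20% increments."""
    n = int(np.ceil(np.log(hi / lo) / np.log(step))) + 1
    return lo * step ** np.arange(n)


def roc_curve(c_est: np.ndarray, c_true: np.ndarray, thresholds=None):
    """Generalized ROC over an evaluation block, grouped by odors per trial.

    For each threshold, the true-positive fraction is the fraction of
    presented odors whose estimate exceeds it, and the false-positive count is
    the number of absent odors whose estimate exceeds it.  Trials are grouped
    by their number of simultaneously presented odors; curves are averaged
    within each group.

    c_est, c_true : (n_trials, M)
    Returns {k: (thresholds, mean TP fraction, mean FP count)} for each odor
    count k present in the block.
    """
    c_est = np.atleast_2d(np.asarray(c_est, dtype=float))
    c_true = np.atleast_2d(np.asarray(c_true, dtype=float))
    if thresholds is None:
        thresholds = roc_thresholds()
    present = c_true > 0.0
    n_present = present.sum(axis=1)
    out = {}
    for k in np.unique(n_present):
        if k == 0:
            continue
        sel = n_present == k
        est, pres = c_est[sel], present[sel]
        above = est[:, :, None] > thresholds[None, None, :]   # (trials, M, T)
        tp = (above & pres[:, :, None]).sum(axis=1) / k
        fp = (above & ~pres[:, :, None]).sum(axis=1)
        out[int(k)] = (thresholds, tp.mean(axis=0), fp.mean(axis=0).astype(float))
    return out


def weight_error(learned_w: np.ndarray, W_true: np.ndarray,
                 selectivity: np.ndarray, rescale: float = 1.0) -> float:
    """Normalized root-mean-square error between learned and true weights.

    d_w = (1/M) sum_j sqrt( (1/N) sum_i (w^F_ji / Z_j - W_{i,o(j)})^2 ),
    with the per-cell scale Z_j = sum_i w^F_ji / sum_i W_{i,o(j)} absorbing
    any global gain the circuit may have learned.  ``rescale`` multiplies the
    result for display conventions (e.g. the 7/3 factor used when comparing
    different sparsity settings).
    """
    matched = W_true[:, selectivity].T                 # (M_cells, N)
    denom = matched.sum(axis=-1)
    Z = learned_w.sum(axis=-1) / denom
    if np.any(Z == 0.0):
        raise FloatingPointError("zero per-cell scale in weight error")
    err = learned_w / Z[:, None] - matched
    d = np.mean(np.sqrt(np.mean(err ** 2, axis=-1)))
    return float(rescale * d)


def lifetime_sparseness(responses: np.ndarray) -> np.ndarray:
    """Lifetime sparseness S_j of each cell over single-odor presentations.

    responses : (M_odors, M_cells) array of steady-state rates, odor-major.
    S_j = (mean_m r_j^m)^2 / mean_m (r_j^m)^2; 1 for uniform tuning, 1/M for
    one-hot tuning, NaN (missing) for silent cells.
    """
    r = np.asarray(responses, dtype=float)
    mean_sq = np.mean(r ** 2, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        s = np.mean(r, axis=0) ** 2 / mean_sq
    return np.where(mean_sq > 0.0, s, np.nan)


def mt_variance(m_block: np.ndarray) -> float:
    """Pooled variance of M/T rates over both population and trials."""
    return float(np.var(np.asarray(m_block, dtype=float)))
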