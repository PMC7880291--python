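"""Sliding-window regularized LDA decoding of epoched data.

A binary (left/right) shrinkage-regularized linear discriminant is trained
in short sliding windows (40 ms windows, one-sample steps at 150 Hz) over
the analysis range −0.4 … 0.5 s.  Performance is the cross-validated ROC
area per window; the decoder's channel-space "forward model" (activation
pattern) is the normalized correlation between the single-trial decision
values and the windowed channel activity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold

from .epochs import EpochArray

log = logging.getLogger(__name__)

__all__ = [
    "WindowGrid",
    "binarize_label",
    "train_rlda",
    "train_rlda_windows",
    "window_features",
    "crossval_auc",
    "auc_from_dvals",
    "forward_model",
    "pattern_similarity",
    "DecodingResult",
]


@dataclass
class WindowGrid:
    """Sliding-window layout over a sample axis.

    ``starts`` are start-sample indices into the epoch's time vector; each
    window spans ``win_samples`` consecutive samples and windows advance by
    ``step_samples``.
    """

    starts: np.ndarray
    win_samples: int
    step_samples: int
    centers: np.ndarray

    @classmethod
    def from_times(cls, times: np.ndarray, fs: float, win_len: float = 0.040,
                   step: float = 0.0067, tmin: float = -0.4, tmax: float = 0.5
                   ) -> "WindowGrid":
        """Build the grid of all windows fully inside [tmin, tmax]."""
        win_samples = max(1, int(round(win_len * fs)))
        step_samples = max(1, int(round(step * fs)))
        eps = 0.5 / fs
        inside = np.flatnonzero((times >= tmin - eps) & (times <= tmax + eps))
        first, last = inside[0], inside[-1]
        starts = np.arange(first, last - win_samples + 2, step_samples)
        centers = np.array([times[s: s + win_samples].mean() for s in starts])
        return cls(starts=starts, win_samples=win_samples,
                   step_samples=step_samples, centers=centers)

    @property
    def n_windows(self) -> int:
        return len(self.starts)


def window_features(epochs: EpochArray, grid: WindowGrid, mode: str = "mean") -> np.ndarray:
    """Per-window features: trials × features × windows.

    ``mode='mean'`` averages the samples within each window per channel
    (features = channels); ``mode='concat'`` stacks the raw samples
    (features = channels × window samples).
    """
    d = epochs.data
    if mode == "mean":
        cs = np.concatenate([np.zeros(d.shape[:2] + (1,)), np.cumsum(d, axis=2)], axis=2)
        w = grid.win_samples
        out = (cs[:, :, grid.starts + w] - cs[:, :, grid.starts]) / w
        return out
    if mode == "concat":
        cols = [d[:, :, s: s + grid.win_samples].reshape(d.shape[0], -1)
                for s in grid.starts]
        return np.stack(cols, axis=2)
    raise ValueError(f"unknown feature mode {mode!r}")


def binarize_label(values) -> tuple[np.ndarray, np.ndarray]:
    """Map continuous values to left/right: True = right (>0), mask drops 0.

    Returns ``(labels, mask)`` where ``labels`` is boolean over the kept
    trials and ``mask`` flags trials with a strictly nonzero value.
    """
    v = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("labels must be finite")
    mask = v != 0.0
    labels = v[mask] > 0.0
    if labels.size and (labels.all() or not labels.any()):
        raise ValueError("all trials fall on one side; cannot train a classifier")
    return labels, mask


def _reg_cov(X0: np.ndarray, X1: np.ndarray, lam: float) -> np.ndarray:
    """Shrinkage-regularized pooled within-class covariance."""
    d = X0.shape[1]
    n = X0.shape[0] + X1.shape[0]
    c0 = X0 - X0.mean(axis=0)
    c1 = X1 - X1.mean(axis=0)
    pooled = (c0.T @ c0 + c1.T @ c1) / max(n - 2, 1)
    return (1.0 - lam) * pooled + lam * (np.trace(pooled) / d) * np.eye(d)


def train_rlda(X: np.ndarray, y: np.ndarray, lam: float = 0.1
               ) -> tuple[np.ndarray, float]:
    """Regularized LDA weights and bias for binary y (True = right).

    w ∝ Σ_reg⁻¹ (μ_right − μ_left) with Σ_reg = (1−λ)Σ̂ + λ(tr Σ̂/d)I; the
    bias places the decision value 0 at the midpoint of the projected class
    means, so positive decision values mean "right".
    """
    y = np.asarray(y, dtype=bool)
    if y.sum() < 2 or (~y).sum() < 2:
        raise ValueError("need at least 2 trials per class")
    mu_l, mu_r = X[~y].mean(axis=0), X[y].mean(axis=0)
    sigma = _reg_cov(X[~y], X[y], lam)
    try:
        w = np.linalg.solve(sigma, mu_r - mu_l)
    except np.linalg.LinAlgError as e:
        raise ValueError("singular regularized covariance; use lambda > 0") from e
    b = -0.5 * float(w @ (mu_r + mu_l))
    return w, b


def train_rlda_windows(Xw: np.ndarray, y: np.ndarray, lam: float = 0.1
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Batched rLDA over the window axis of trials × features × windows."""
    y = np.asarray(y, dtype=bool)
    if y.sum() < 2 or (~y).sum() < 2:
        raise ValueError("need at least 2 trials per class")
    d = Xw.shape[1]
    mu_l = Xw[~y].mean(axis=0)  # d x W
    mu_r = Xw[y].mean(axis=0)
    c0 = Xw[~y] - mu_l
    c1 = Xw[y] - mu_r
    n = Xw.shape[0]
    pooled = (np.einsum("tiw,tjw->wij", c0, c0)
              + np.einsum("tiw,tjw->wij", c1, c1)) / max(n - 2, 1)
    tr = np.trace(pooled, axis1=1, axis2=2)
    sigma = (1.0 - lam) * pooled + (lam * tr / d)[:, None, None] * np.eye(d)[None]
    diff = (mu_r - mu_l).T[:, :, None]  # W x d x 1
    w = np.linalg.solve(sigma, diff)[:, :, 0]  # W x d
    b = -0.5 * np.einsum("wd,wd->w", w, (mu_r + mu_l).T)
    return w, b


def decision_values(Xw: np.ndarray, w: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Project features onto the discriminants: trials × windows."""
    return np.einsum("tdw,wd->tw", Xw, w) + b[None, :]


def auc_from_dvals(labels: np.ndarray, dvals: np.ndarray) -> np.ndarray:
    """ROC AUC per window from decision values, via the rank statistic.

    Equivalent to the probability that a random "right" trial outranks a
    random "left" trial; ties are handled by midranks.
    """
    y = np.asarray(labels, dtype=bool)
    dv = np.atleast_2d(np.asarray(dvals, dtype=float))
    if dv.shape[0] != y.size:
        dv = dv.T
    n1, n0 = int(y.sum()), int((~y).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("need both classes to compute an AUC")
    ranks = rankdata(dv, axis=0)
    r1 = ranks[y].sum(axis=0)
    return (r1 - n1 * (n1 + 1) / 2.0) / (n1 * n0)


@dataclass
class DecodingResult:
    """Cross-validated sliding-window decoder output for one subject."""
    variable: str
    grid: WindowGrid
    lam: float
    auc: np.ndarray            # windows
    dvals: np.ndarray          # trials x windows, out-of-fold
    weights: np.ndarray        # windows x features (fit on all trials)
    bias: np.ndarray           # windows
    fwd: np.ndarray            # windows x channels
    trial_index: np.ndarray | None = None
    folds: np.ndarray | None = None

    def save(self, path: str) -> None:
        np.savez(path, variable=self.variable, lam=self.lam, auc=self.auc,
                 dvals=self.dvals, weights=self.weights, bias=self.bias,
                 fwd=self.fwd, centers=self.grid.centers, starts=self.grid.starts,
                 win_samples=self.grid.win_samples, step_samples=self.grid.step_samples,
                 trial_index=self.trial_index if self.trial_index is not None else [],
                 folds=self.folds if self.folds is not None else [])


def crossval_auc(epochs: EpochArray, values, grid: WindowGrid | None = None,
                 k: int = 6, lam: float = 0.1, seed: int = 0,
                 variable: str = "dva", feature_mode: str = "mean") -> DecodingResult:
    """Stratified k-fold sliding-window decoding with per-window ROC AUC.

    ``values`` are the continuous per-trial quantities to binarize (left/
    right); exactly-zero trials are excluded.  The AUC per window is the
    mean of the per-fold AUCs on held-out decision values; the stored
    decision values are the pooled out-of-fold projections.
    """
    labels, mask = binarize_label(np.asarray(values, dtype=float))
    ep = epochs.select(mask)
    if grid is None:
        grid = WindowGrid.from_times(ep.times, ep.fs)
    Xw = window_features(ep, grid, mode=feature_mode)
    n = Xw.shape[0]
    if labels.sum() < k or (~labels).sum() < k:
        raise ValueError(f"need at least {k} trials per class for {k}-fold CV")

    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed % (2**31))
    dvals = np.zeros((n, grid.n_windows))
    fold_of = np.zeros(n, dtype=int)
    fold_auc = np.zeros((k, grid.n_windows))
    for f, (tr, te) in enumerate(skf.split(np.zeros(n), labels)):
        w, b = train_rlda_windows(Xw[tr], labels[tr], lam)
        dv = decision_values(Xw[te], w, b)
        dvals[te] = dv
        fold_of[te] = f
        fold_auc[f] = auc_from_dvals(labels[te], dv)
    auc = fold_auc.mean(axis=0)

    w_all, b_all = train_rlda_windows(Xw, labels, lam)
    fwd = forward_model(dvals, Xw)
    return DecodingResult(variable=variable, grid=grid, lam=lam, auc=auc,
                          dvals=dvals, weights=w_all, bias=b_all, fwd=fwd,
                          trial_index=ep.trial_index, folds=fold_of)


def forward_model(dvals: np.ndarray, Xw: np.ndarray) -> np.ndarray:
    """Activation pattern: correlation of decision values with channel data.

    Per window, the Pearson correlation over trials between the decision
    value and each channel's windowed activity, normalized to unit maximum
    absolute value per window.  Zero-variance channels (or constant
    decision values) map to 0.
    """
    dv = dvals - dvals.mean(axis=0, keepdims=True)
    X = Xw - Xw.mean(axis=0, keepdims=True)
    num = np.einsum("tw,tdw->wd", dv, X)
    sd_dv = np.sqrt(np.einsum("tw,tw->w", dv, dv))
    sd_x = np.sqrt(np.einsum("tdw,tdw->wd", X, X))
    degenerate = (sd_dv[:, None] == 0) | (sd_x == 0)
    denom = np.where(degenerate, 1.0, sd_dv[:, None] * sd_x)
    corr = np.where(degenerate, 0.0, num / denom)
    if degenerate.any():
        log.warning("forward model: %d degenerate window/channel entries set to 0",
                    int(degenerate.sum()))
    peak = np.abs(corr).max(axis=1, keepdims=True)
    peak = np.where(peak == 0, 1.0, peak)
    return corr / peak


def pattern_similarity(patterns_a: np.ndarray, patterns_b: np.ndarray,
                       n_boot: int = 3000, alpha: float = 0.01, seed: int = 0):
    """Similarity of two group-level activation patterns with a bootstrap CI.

    ``patterns_a``/``patterns_b`` are per-subject patterns (subjects ×
    channels) on the same channel set.  Returns the Pearson correlation of
    the group means, the (1−alpha) bootstrap CI over the random selection
    of subjects, and the significance flag (CI excludes 0).
    """
    A = np.atleast_2d(np.asarray(patterns_a, dtype=float))
    B = np.atleast_2d(np.asarray(patterns_b, dtype=float))
    if A.shape[1] != B.shape[1]:
        raise ValueError("patterns are defined on different channel sets")

    def _corr(x, y):
        return float(np.corrcoef(x, y)[0, 1])

    r = _corr(A.mean(axis=0), B.mean(axis=0))
    rng = np.random.default_rng(seed)
    n_a, n_b = A.shape[0], B.shape[0]
    boots = np.empty(n_boot)
    for i in range(n_boot):
        ia = rng.integers(0, n_a, n_a)
        ib = ia if n_a == n_b else rng.integers(0, n_b, n_b)
        boots[i] = _corr(A[ia].mean(axis=0), B[ib].mean(axis=0))
    lo, hi = np.percentile(boots, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return {"r": r, "ci": (float(lo), float(hi)),
            "significant": bool(lo > 0 or hi < 0), "alpha": alpha}
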