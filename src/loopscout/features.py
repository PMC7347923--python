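"""Featurization of contact-map windows.

Each candidate pixel is described by the (2n+1)x(2n+1) window of counts
centred on it.  The feature vector concatenates

* the raw window values in row-major order ((2n+1)^2 features),
* the within-window rank of every pixel, scaled to (0, 1]
  ((2n+1)^2 features), and
* P2LL, the ratio of the centre pixel to the mean of the lower-left
  quadrant (1 feature),

for a total of 2*(2n+1)^2 + 1 features — 243 for the default radius n=5.
Rank features are invariant under any strictly monotone transform of the
counts, and P2LL is scale-invariant, which is what lets a model trained on
one sequencing depth transfer to another.

Row convention: window rows index the first (smaller-coordinate) anchor, so
the lower-left quadrant of a window centred at (i, j) is the n x n block at
rows i+1..i+n, columns j-n..j-1 — the region between the anchors, where a
genuine loop sits on an enriched background.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import rankdata

__all__ = ["compute_p2ll", "featurize", "featurize_batch", "n_features",
           "feature_names"]


def n_features(n: int) -> int:
    """Feature-vector length for window radius n: 2*(2n+1)^2 + 1."""
    side = 2 * n + 1
    return 2 * side * side + 1


def feature_names(n: int) -> list[str]:
    """Stable, documented feature order (models are portable across runs)."""
    side = 2 * n + 1
    names = [f"value_r{a}c{b}" for a in range(side) for b in range(side)]
    names += [f"rank_r{a}c{b}" for a in range(side) for b in range(side)]
    names.append("p2ll")
    return names


def _check_window(window: np.ndarray) -> tuple[np.ndarray, int]:
    w = np.asarray(window, dtype=np.float64)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValueError(f"window must be square, got shape {w.shape}")
    if w.shape[0] % 2 == 0:
        raise ValueError(f"window side must be odd, got {w.shape[0]}")
    return w, w.shape[0] // 2


def compute_p2ll(window: np.ndarray) -> float:
    """Peak-to-lower-left ratio: centre / mean of the lower-left quadrant.

    A zero quadrant mean is replaced by 1, so the ratio degrades to the
    centre count itself — a finite sentinel for the sparse-map case — and a
    zero centre always yields 0.
    """
    w, n = _check_window(window)
    if n < 1:
        raise ValueError("P2LL needs window radius n >= 1")
    center = w[n, n]
    quadrant_mean = w[n + 1:, :n].mean()
    if quadrant_mean <= 0:
        return float(center)
    return float(center / quadrant_mean)


def featurize(window: np.ndarray) -> np.ndarray:
    """Window -> feature vector (values, scaled average ranks, P2LL)."""
    w, n = _check_window(window)
    values = w.ravel()
    ranks = rankdata(values, method="average") / values.size
    return np.concatenate([values, ranks, [compute_p2ll(w)]])


def featurize_batch(dense: np.ndarray, ii: np.ndarray, jj: np.ndarray,
                    n: int) -> np.ndarray:
    """Vectorized featurization of many pixels of one dense matrix.

    Parameters
    ----------
    dense : symmetrized dense contact matrix.
    ii, jj : centre coordinates; every window must be in bounds
        (ii - n >= 0 and jj + n < dense.shape[0]).
    n : window radius in bins.

    Returns an (m, 2*(2n+1)^2+1) array in the same feature order as
    :func:`featurize`.
    """
    ii = np.asarray(ii, dtype=np.int64)
    jj = np.asarray(jj, dtype=np.int64)
    if ii.size == 0:
        return np.empty((0, n_features(n)))
    if ii.min() - n < 0 or jj.max() + n >= dense.shape[0]:
        raise ValueError("out-of-bounds window in batch")
    offs = np.arange(-n, n + 1)
    rows = ii[:, None, None] + offs[None, :, None]
    cols = jj[:, None, None] + offs[None, None, :]
    win = dense[rows, cols].astype(np.float64)  # (m, side, side)
    m, side = win.shape[0], win.shape[1]
    values = win.reshape(m, side * side)
    ranks = rankdata(values, method="average", axis=1) / (side * side)
    centers = win[:, n, n]
    quad = win[:, n + 1:, :n].reshape(m, -1).mean(axis=1)
    p2ll = np.where(quad > 0, centers / np.where(quad > 0, quad, 1.0), centers)
    return np.concatenate([values, ranks, p2ll[:, None]], axis=1)
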