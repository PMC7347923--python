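"""Assembly of the labeled training table.

Positives come from an orthogonal interaction list (ChIA-PET/HiChIP-style
BEDPE) mapped onto map bins and filtered by P2LL: an interaction whose
Hi-C value is below ``min_p2ll`` (default 0.1) times the mean of its
lower-left quadrant is rejected as unsupported by the map.  Negatives are
drawn in two populations — contacts distance-matched to the positives, and
long-range contacts beyond the positives' span that resemble noise — always
from pixels with nonzero counts and in-bounds windows, and never colliding
with a positive.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd

from .contactmap import ContactMap, PixelCoord
from .features import compute_p2ll, featurize_batch, n_features

__all__ = ["TrainingTable", "anchors_to_bins", "build_positive_set",
           "sample_negative_set", "assemble_training_table"]


@dataclasses.dataclass
class TrainingTable:
    """Feature matrix + labels for one classifier fit."""

    X: np.ndarray  # (n_samples, n_features)
    y: np.ndarray  # 1 = loop, 0 = background
    pixels: list[PixelCoord]

    @property
    def n_positive(self) -> int:
        return int(self.y.sum())

    @property
    def n_negative(self) -> int:
        return int((self.y == 0).sum())


def anchors_to_bins(loops: pd.DataFrame, chrom: str,
                    resolution: int) -> list[tuple[int, int]]:
    """Map BEDPE anchor intervals to bin pairs via anchor midpoints.

    Midpoints falling exactly on a bin edge round down.  Pairs are ordered
    i < j; self-pairs (both anchors in one bin) are dropped.
    """
    sub = loops[(loops["chrom1"] == chrom) & (loops["chrom2"] == chrom)]
    out: list[tuple[int, int]] = []
    for _, row in sub.iterrows():
        m1 = (int(row["start1"]) + int(row["end1"])) // 2
        m2 = (int(row["start2"]) + int(row["end2"])) // 2
        i, j = sorted((m1 // resolution, m2 // resolution))
        if i < j:
            out.append((i, j))
    return out


def build_positive_set(cmap: ContactMap, loops: pd.DataFrame, n: int = 5,
                       min_p2ll: float = 0.1) -> list[PixelCoord]:
    """P2LL-filtered positive pixels from a BEDPE interaction list.

    Keeps pixels with an in-bounds window, a nonzero centre count, and
    P2LL >= ``min_p2ll``; duplicates after binning collapse to one pixel.
    """
    seen: set[tuple[int, int]] = set()
    kept: list[PixelCoord] = []
    for i, j in anchors_to_bins(loops, cmap.chrom, cmap.resolution):
        if (i, j) in seen:
            continue
        seen.add((i, j))
        pix = PixelCoord(cmap.chrom, i, j)
        win = cmap.fetch_window(pix, n)
        if win is None or win[n, n] <= 0:
            continue
        if compute_p2ll(win) >= min_p2ll:
            kept.append(pix)
    if not kept:
        raise ValueError("no usable positives: every training interaction "
                         "was out of bounds, zero-count, or below the P2LL "
                         "threshold")
    return kept


def sample_negative_set(cmap: ContactMap, positives: list[PixelCoord],
                        n_neg: int | None = None,
                        long_range_frac: float = 0.5,
                        seed: int = 0, n: int = 5) -> list[PixelCoord]:
    """Two-population negative sample from nonzero pixels.

    ``1 - long_range_frac`` of the negatives copy the positives' genomic
    distance distribution (a positive's distance is drawn, then a random
    nonzero pixel at that distance, tolerating +/-1 bin when a distance is
    exhausted); the rest are uniform among nonzero pixels farther than the
    longest positive.  Sampling is without replacement, never returns a
    positive pixel, and is deterministic given ``seed``.  If candidates run
    out a warning is issued and fewer pixels are returned.
    """
    if not 0 <= long_range_frac <= 1:
        raise ValueError("long_range_frac must be in [0, 1]")
    if n_neg is None:
        n_neg = len(positives)
    rng = np.random.default_rng(seed)
    ii, jj, _ = cmap.nonzero()
    inb = (ii >= n) & (jj + n < cmap.n_bins) & (ii < jj)
    ii, jj = ii[inb], jj[inb]
    pos_set = {(p.i, p.j) for p in positives}
    free = np.array([(i, j) not in pos_set for i, j in zip(ii, jj)])
    ii, jj = ii[free], jj[free]
    dist = jj - ii

    pos_dists = np.array([p.j - p.i for p in positives])
    max_pd = int(pos_dists.max())

    by_dist: dict[int, list[int]] = {}
    for idx, d in enumerate(dist):
        by_dist.setdefault(int(d), []).append(idx)
    for d in by_dist:
        rng.shuffle(by_dist[d])

    n_near = int(round(n_neg * (1.0 - long_range_frac)))
    n_far = n_neg - n_near
    chosen: list[int] = []

    for _ in range(n_near):
        d = int(rng.choice(pos_dists))
        idx = None
        for dd in (d, d - 1, d + 1):
            if by_dist.get(dd):
                idx = by_dist[dd].pop()
                break
        if idx is not None:
            chosen.append(idx)

    far_pool = [idx for d, lst in by_dist.items() if d > max_pd for idx in lst]
    if far_pool and n_far > 0:
        take = min(n_far, len(far_pool))
        picks = rng.choice(len(far_pool), size=take, replace=False)
        chosen.extend(far_pool[int(k)] for k in picks)

    if len(chosen) < n_neg:
        warnings.warn(f"only {len(chosen)} of {n_neg} requested negative "
                      f"pixels could be sampled", stacklevel=2)
    return [PixelCoord(cmap.chrom, int(ii[k]), int(jj[k])) for k in chosen]


def assemble_training_table(cmap: ContactMap, positives: list[PixelCoord],
                            negatives: list[PixelCoord],
                            n: int = 5) -> TrainingTable:
    """Attach feature vectors to labeled pixels (out-of-bounds dropped)."""
    if not positives or not negatives:
        raise ValueError("both positive and negative pixel lists must be "
                         "non-empty")
    dense = cmap.dense()

    def in_bounds(p: PixelCoord) -> bool:
        return p.i - n >= 0 and p.j + n < cmap.n_bins

    pos = [p for p in positives if in_bounds(p)]
    neg = [p for p in negatives if in_bounds(p)]
    pixels = pos + neg
    if not pixels:
        raise ValueError("every pixel's window crosses the matrix boundary")
    X = featurize_batch(dense,
                        np.array([p.i for p in pixels]),
                        np.array([p.j for p in pixels]), n)
    if X.shape[1] != n_features(n):  # invariant breach, not user error
        raise AssertionError("feature length mismatch")
    y = np.concatenate([np.ones(len(pos), dtype=int),
                        np.zeros(len(neg), dtype=int)])
    return TrainingTable(X, y, pixels)
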