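"""Post-hoc evaluation of loop calls.

* Aggregate peak analysis (APA): element-wise mean of per-call windows,
  each normalized by its own window mean, with a scalar centre-enrichment
  score (aggregate centre over the mean of the four corner quadrants).
* Anchor fold enrichment against shuffled controls that preserve each
  chromosome's loop count and distance distribution while avoiding
  assembly gaps.
* Distance histograms of call sets.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .contactmap import ContactMap, LoopCall, PixelCoord

__all__ = ["APAResult", "EnrichmentResult", "apa", "shuffle_controls",
           "fold_enrichment", "distance_summary", "read_bed",
           "read_chrom_sizes"]


# ---------------------------------------------------------------------------
# small text-format readers


def read_bed(path) -> pd.DataFrame:
    """BED3+ reader (peaks, assembly gaps); extra columns ignored."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 3:
        raise ValueError("BED needs at least 3 columns")
    df = df.iloc[:, :3].copy()
    df.columns = ["chrom", "start", "end"]
    return df


def read_chrom_sizes(path) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "size"])
    return dict(zip(df["chrom"], df["size"].astype(int)))


# ---------------------------------------------------------------------------
# APA


@dataclasses.dataclass
class APAResult:
    matrix: np.ndarray  # (2k+1, 2k+1) mean of normalized windows
    center_enrichment: float
    n_used: int
    n_skipped: int


def apa(cmap: ContactMap | Mapping[str, ContactMap],
        calls: Sequence[LoopCall | PixelCoord], k: int = 5) -> APAResult:
    """Aggregate peak analysis over a set of calls.

    Each call's (2k+1)x(2k+1) window is normalized by the mean of the
    pixels within that window, then windows are averaged element-wise.
    The centre-enrichment score divides the aggregate centre by the mean
    of the four k x k corner quadrants; a flat map scores exactly 1.
    Out-of-bounds or empty windows are skipped and counted.
    """
    maps = cmap if isinstance(cmap, Mapping) else {cmap.chrom: cmap}
    side = 2 * k + 1
    acc = np.zeros((side, side))
    used = skipped = 0
    for c in calls:
        m = maps.get(c.chrom)
        win = None if m is None else m.fetch_window(
            PixelCoord(c.chrom, c.i, c.j), k)
        if win is None or win.mean() <= 0:
            skipped += 1
            continue
        acc += win / win.mean()
        used += 1
    if used == 0:
        raise ValueError("no usable calls for APA")
    agg = acc / used
    corners = np.concatenate([agg[:k, :k].ravel(), agg[:k, -k:].ravel(),
                              agg[-k:, :k].ravel(), agg[-k:, -k:].ravel()])
    score = float(agg[k, k] / corners.mean()) if corners.mean() > 0 else 0.0
    return APAResult(agg, score, used, skipped)


# ---------------------------------------------------------------------------
# shuffled controls and fold enrichment


def _build_gap_index(gaps: pd.DataFrame | None):
    by_chrom: dict[str, np.ndarray] = {}
    if gaps is not None and len(gaps):
        for chrom, sub in gaps.groupby("chrom"):
            iv = sub[["start", "end"]].to_numpy(dtype=np.int64)
            by_chrom[str(chrom)] = iv[np.argsort(iv[:, 0])]
    return by_chrom


def _overlaps_any(iv: np.ndarray, start: int, end: int) -> bool:
    # iv sorted by start; half-open interval overlap
    if iv.size == 0:
        return False
    hit = (iv[:, 0] < end) & (iv[:, 1] > start)
    return bool(hit.any())


def shuffle_controls(calls: Sequence[LoopCall], chrom_sizes: Mapping[str, int],
                     resolution: int, gaps: pd.DataFrame | None = None,
                     n_controls: int = 50, seed: int = 0,
                     max_tries: int = 1000) -> list[list[LoopCall]]:
    """Distance- and count-preserving random shuffles of a call set.

    Every control keeps, per chromosome, the multiset of loop distances;
    each loop's anchors are re-drawn uniformly, subject to the interval
    spanned by the loop avoiding assembly gaps.  A loop that cannot be
    placed within ``max_tries`` draws is dropped from that control with a
    warning.  Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    gap_ix = _build_gap_index(gaps)
    controls: list[list[LoopCall]] = []
    dropped = 0
    for _ in range(n_controls):
        ctrl: list[LoopCall] = []
        for c in calls:
            n_bins = chrom_sizes[c.chrom] // resolution
            d = c.j - c.i
            iv = gap_ix.get(c.chrom, np.empty((0, 2), dtype=np.int64))
            placed = False
            for _t in range(max_tries):
                i = int(rng.integers(0, n_bins - d))
                j = i + d
                span = (i * resolution, (j + 1) * resolution)
                if not _overlaps_any(iv, *span):
                    ctrl.append(LoopCall(c.chrom, i, j, c.probability))
                    placed = True
                    break
            if not placed:
                dropped += 1
        controls.append(ctrl)
    if dropped:
        warnings.warn(f"{dropped} control loops could not be placed outside "
                      f"gaps and were dropped", stacklevel=2)
    return controls


@dataclasses.dataclass
class EnrichmentResult:
    observed: int  # non-redundant anchors overlapping >= 1 peak
    control_counts: list[int]
    fold: float
    saturated: bool = False  # True when mean(controls) == 0 (fold is inf)


def _anchor_hits(calls: Sequence[LoopCall], peaks_by_chrom, resolution: int) -> int:
    anchors = {(c.chrom, b) for c in calls for b in (c.i, c.j)}
    hits = 0
    for chrom, b in anchors:
        iv = peaks_by_chrom.get(chrom, np.empty((0, 2), dtype=np.int64))
        if _overlaps_any(iv, b * resolution, (b + 1) * resolution):
            hits += 1
    return hits


def fold_enrichment(calls: Sequence[LoopCall], peaks: pd.DataFrame,
                    controls: Sequence[Sequence[LoopCall]],
                    resolution: int) -> EnrichmentResult:
    """Observed vs shuffled-control anchor overlap with a peak set.

    Anchors are deduplicated across calls before counting; the fold score
    is the observed hit count over the mean control hit count.
    """
    if len(peaks) == 0:
        warnings.warn("empty peak set: fold enrichment is 0", stacklevel=2)
        return EnrichmentResult(0, [0] * len(controls), 0.0)
    by_chrom = _build_gap_index(peaks)
    observed = _anchor_hits(calls, by_chrom, resolution)
    ctrl = [_anchor_hits(ctl, by_chrom, resolution) for ctl in controls]
    mean_ctrl = float(np.mean(ctrl)) if ctrl else 0.0
    if mean_ctrl == 0:
        return EnrichmentResult(observed, ctrl, float("inf"), saturated=True)
    return EnrichmentResult(observed, ctrl, observed / mean_ctrl)


# ---------------------------------------------------------------------------
# distance summaries


def distance_summary(calls: Sequence[LoopCall], resolution: int,
                     breaks: Sequence[int]) -> pd.DataFrame:
    """Counts and fractions of calls per genomic-distance stratum.

    ``breaks`` (bp, sorted) delimit the strata, e.g. (250_000, 500_000)
    gives <250 kb, 250-500 kb, >=500 kb.
    """
    breaks = list(breaks)
    if breaks != sorted(breaks):
        raise ValueError("breaks must be sorted")
    edges = [0] + breaks + [np.inf]
    dists = np.array([(c.j - c.i) * resolution for c in calls], dtype=float)
    counts, _ = np.histogram(dists, bins=edges)
    total = max(len(calls), 1)
    labels = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        labels.append(f"<{int(hi)}" if lo == 0 else
                      (f">={int(lo)}" if np.isinf(hi) else
                       f"{int(lo)}-{int(hi)}"))
    return pd.DataFrame({"stratum": labels, "count": counts,
                         "fraction": counts / total})
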