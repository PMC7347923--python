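"""Binned intrachromosomal contact maps.

A :class:`ContactMap` stores the upper triangle of a symmetric count matrix
at a fixed bin resolution and answers symmetric queries.  Maps can be loaded
from sparse triplet text (``bin1 bin2 count``) or from single-resolution
cooler (HDF5) files, optionally applying matrix-balancing weights.  The
module also provides window extraction around a pixel, binomial read
thinning to emulate shallower sequencing, and BEDPE round-tripping of loop
calls.
"""

from __future__ import annotations

import dataclasses
import warnings
from pathlib import Path
from typing import Iterable, Sequence

import h5py
import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "PixelCoord",
    "LoopCall",
    "ContactMap",
    "load_contact_map",
    "fetch_window",
    "binomial_thin",
    "write_loops",
    "read_loops",
]


@dataclasses.dataclass(frozen=True, order=True)
class PixelCoord:
    """One cell (i, j) of a contact map, with i strictly below j."""

    chrom: str
    i: int
    j: int

    def __post_init__(self) -> None:
        if not 0 <= self.i < self.j:
            raise ValueError(f"require 0 <= i < j, got ({self.i}, {self.j})")

    def distance_bins(self) -> int:
        return self.j - self.i

    def distance_bp(self, resolution: int) -> int:
        return (self.j - self.i) * resolution


@dataclasses.dataclass(frozen=True, order=True)
class LoopCall:
    """A called loop: anchor bin pair plus classifier probability."""

    chrom: str
    i: int
    j: int
    probability: float
    cluster_size: int = 1

    def __post_init__(self) -> None:
        if not 0 <= self.i < self.j:
            raise ValueError(f"require 0 <= i < j, got ({self.i}, {self.j})")

    @property
    def pixel(self) -> PixelCoord:
        return PixelCoord(self.chrom, self.i, self.j)


class ContactMap:
    """Per-chromosome sparse symmetric contact matrix.

    Counts are stored in the upper triangle (i <= j) and queried
    symmetrically; any unstored pixel reads as zero.

    Parameters
    ----------
    chrom : chromosome name.
    resolution : bin size in bp.
    n_bins : chromosome length in bins.
    bin1, bin2, count : parallel triplet arrays; entries with bin1 > bin2
        are mirrored into the upper triangle and duplicates are summed.
    weights : optional per-bin balancing factors (consumed, never computed).
    """

    def __init__(
        self,
        chrom: str,
        resolution: int,
        n_bins: int,
        bin1: Sequence[int] | np.ndarray = (),
        bin2: Sequence[int] | np.ndarray = (),
        count: Sequence[float] | np.ndarray = (),
        weights: np.ndarray | None = None,
    ) -> None:
        if resolution <= 0:
            raise ValueError("resolution must be positive")
        if n_bins <= 0:
            raise ValueError("n_bins must be positive")
        b1 = np.asarray(bin1, dtype=np.int64)
        b2 = np.asarray(bin2, dtype=np.int64)
        c = np.asarray(count, dtype=np.float64)
        if not (b1.shape == b2.shape == c.shape):
            raise ValueError("bin1/bin2/count must have equal length")
        if c.size and c.min() < 0:
            raise ValueError("negative counts are not allowed")
        if b1.size and (b1.min() < 0 or b2.min() < 0 or
                        max(b1.max(), b2.max()) >= n_bins):
            raise ValueError("bin index outside [0, n_bins)")
        # mirror lower-triangle entries, sum duplicates via COO->CSR
        lo = np.minimum(b1, b2)
        hi = np.maximum(b1, b2)
        mat = sp.coo_matrix((c, (lo, hi)), shape=(n_bins, n_bins)).tocsr()
        mat.sum_duplicates()
        mat.eliminate_zeros()
        self.chrom = str(chrom)
        self.resolution = int(resolution)
        self.n_bins = int(n_bins)
        self.matrix = mat  # upper triangle, CSR
        self.weights = None if weights is None else np.asarray(weights, float)
        self._dense: np.ndarray | None = None

    # -- queries ---------------------------------------------------------

    def query(self, i: int, j: int) -> float:
        """Symmetric count lookup; unstored pixels are 0."""
        if not (0 <= i < self.n_bins and 0 <= j < self.n_bins):
            raise IndexError(f"pixel ({i}, {j}) outside [0, {self.n_bins})")
        lo, hi = (i, j) if i <= j else (j, i)
        return float(self.matrix[lo, hi])

    def nonzero(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Upper-triangle (i, j, count) arrays of all stored pixels."""
        coo = self.matrix.tocoo()
        return coo.row.copy(), coo.col.copy(), coo.data.copy()

    def total(self) -> float:
        """Sum of upper-triangle counts (each cis pair counted once)."""
        return float(self.matrix.sum())

    def dense(self) -> np.ndarray:
        """Symmetrized dense matrix (cached); rows/cols are bins."""
        if self._dense is None:
            upper = self.matrix.toarray()
            diag = np.diag(np.diag(upper))
            self._dense = upper + upper.T - diag
        return self._dense

    def fetch_window(self, center: PixelCoord, n: int) -> np.ndarray | None:
        """(2n+1)x(2n+1) window centred on a pixel; rows index anchor 1.

        Returns ``None`` (the window-out-of-bounds sentinel) when the
        window would cross the matrix boundary; callers skip such pixels.
        """
        if n < 0:
            raise ValueError("window radius must be >= 0")
        i, j = center.i, center.j
        if i - n < 0 or j + n >= self.n_bins:
            return None
        return self.dense()[i - n:i + n + 1, j - n:j + n + 1].copy()

    # -- transforms ------------------------------------------------------

    def thin(self, alpha: float, seed: int) -> "ContactMap":
        """Binomial down-sampling: each count m becomes Binomial(m, alpha).

        Emulates a sequencing depth of ``alpha`` times the original without
        re-mapping reads.  Zero pixels stay zero; pixels thinned to zero are
        dropped from storage.  Deterministic given ``seed``.
        """
        if not 0 < alpha <= 1:
            raise ValueError("alpha must be in (0, 1]")
        i, j, c = self.nonzero()
        if not np.allclose(c, np.round(c)):
            raise ValueError("binomial thinning requires integer counts "
                             "(raw, unbalanced matrix)")
        if alpha == 1.0:
            new = c.astype(np.int64)
        else:
            rng = np.random.default_rng(seed)
            new = rng.binomial(c.astype(np.int64), alpha)
        keep = new > 0
        return ContactMap(self.chrom, self.resolution, self.n_bins,
                          i[keep], j[keep], new[keep], weights=self.weights)


# ---------------------------------------------------------------------------
# loading


def _load_triplet(path: Path, chrom: str, resolution: int,
                  n_bins: int | None) -> ContactMap:
    try:
        df = pd.read_csv(path, sep=r"\s+", header=None, comment="#",
                         names=["bin1", "bin2", "count"],
                         dtype={"bin1": np.int64, "bin2": np.int64,
                                "count": np.float64})
    except pd.errors.EmptyDataError:
        df = pd.DataFrame({"bin1": [], "bin2": [], "count": []})
    if n_bins is None:
        n_bins = int(max(df["bin1"].max(), df["bin2"].max()) + 1) if len(df) else 1
    return ContactMap(chrom, resolution, n_bins,
                      df["bin1"].to_numpy(), df["bin2"].to_numpy(),
                      df["count"].to_numpy())


def _split_cooler_uri(path: str) -> tuple[str, str]:
    if "::" in path:
        fname, grp = path.split("::", 1)
        return fname, grp
    return path, "/"


def _load_cooler(path: str, chrom: str, use_balanced: bool) -> ContactMap:
    """Read one chromosome's cis pixels from a single-resolution cooler file.

    Understands the standard cooler HDF5 layout (``chroms``, ``bins``,
    ``pixels``, ``indexes`` groups); multi-resolution files are addressed
    with the usual ``file.mcool::/resolutions/<res>`` URI syntax.
    """
    fname, grp = _split_cooler_uri(str(path))
    with h5py.File(fname, "r") as f:
        g = f[grp]
        names = [x.decode() if isinstance(x, bytes) else str(x)
                 for x in g["chroms/name"][:]]
        if chrom not in names:
            raise ValueError(
                f"chromosome {chrom!r} not in cooler file; available: {names}")
        cix = names.index(chrom)
        resolution = int(g.attrs["bin-size"])
        chrom_offset = g["indexes/chrom_offset"][:]
        lo, hi = int(chrom_offset[cix]), int(chrom_offset[cix + 1])
        n_bins = hi - lo
        bin1_offset = g["indexes/bin1_offset"][:]
        plo, phi = int(bin1_offset[lo]), int(bin1_offset[hi])
        bin1 = g["pixels/bin1_id"][plo:phi]
        bin2 = g["pixels/bin2_id"][plo:phi]
        count = g["pixels/count"][plo:phi].astype(np.float64)
        cis = bin2 < hi  # bin1 already within [lo, hi)
        bin1, bin2, count = bin1[cis] - lo, bin2[cis] - lo, count[cis]
        weights = None
        if "weight" in g["bins"]:
            weights = g["bins/weight"][lo:hi].astype(np.float64)
    if use_balanced:
        if weights is None:
            raise ValueError("balanced counts requested but the cooler file "
                             "has no 'weight' column")
        w = weights
        count = count * w[bin1] * w[bin2]
        good = np.isfinite(count)
        bin1, bin2, count = bin1[good], bin2[good], count[good]
    return ContactMap(chrom, resolution, n_bins, bin1, bin2, count,
                      weights=weights)


def load_contact_map(path: str | Path, chrom: str, resolution: int | None = None,
                     use_balanced: bool = False,
                     n_bins: int | None = None) -> ContactMap:
    """Load one chromosome's contact map from cooler or triplet text.

    Parameters
    ----------
    path : cooler HDF5 file (optionally ``::/resolutions/<res>``) or a
        whitespace-delimited ``bin1 bin2 count`` text file.
    chrom : chromosome to extract.
    resolution : bin size in bp; required for triplet text, validated
        against the file for cooler input.
    use_balanced : multiply counts by the per-bin balancing weights
        (cooler ``weight`` column); errors if no weights exist.
    n_bins : chromosome length in bins for triplet input (defaults to the
        largest index seen + 1).
    """
    fname, _ = _split_cooler_uri(str(path))
    if h5py.is_hdf5(fname):
        cmap = _load_cooler(str(path), chrom, use_balanced)
        if resolution is not None and cmap.resolution != resolution:
            raise ValueError(f"cooler resolution {cmap.resolution} != "
                             f"requested {resolution}")
        return cmap
    if use_balanced:
        raise ValueError("balanced counts requested but triplet text carries "
                         "no balancing weights")
    if resolution is None:
        raise ValueError("resolution is required for triplet text input")
    return _load_triplet(Path(path), chrom, resolution, n_bins)


# ---------------------------------------------------------------------------
# module-level operation wrappers


def fetch_window(cmap: ContactMap, center: PixelCoord, n: int) -> np.ndarray | None:
    """See :meth:`ContactMap.fetch_window`."""
    return cmap.fetch_window(center, n)


def binomial_thin(cmap: ContactMap, alpha: float, seed: int) -> ContactMap:
    """See :meth:`ContactMap.thin`."""
    return cmap.thin(alpha, seed)


# ---------------------------------------------------------------------------
# BEDPE


def write_loops(calls: Iterable[LoopCall], path: str | Path, resolution: int,
                header_lines: Iterable[str] = ()) -> None:
    """Write loop calls as BEDPE (0-based half-open one-bin anchors).

    Columns: chrom1 start1 end1 chrom2 start2 end2 name(.) probability,
    plus a cluster-size column when any call pools more than one pixel.
    Calls are written in the order given — no sorting or deduplication.
    """
    calls = list(calls)
    with_size = any(c.cluster_size != 1 for c in calls)
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        for c in calls:
            res = resolution
            fields = [c.chrom, c.i * res, (c.i + 1) * res,
                      c.chrom, c.j * res, (c.j + 1) * res,
                      ".", repr(c.probability)]
            if with_size:
                fields.append(c.cluster_size)
            fh.write("\t".join(str(x) for x in fields) + "\n")


def read_loops(path: str | Path, resolution: int) -> list[LoopCall]:
    """Read loop calls from a BEDPE written by :func:`write_loops`."""
    calls: list[LoopCall] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            chrom = f[0]
            i = int(f[1]) // resolution
            j = int(f[4]) // resolution
            prob = float(f[7]) if len(f) > 7 else float("nan")
            size = int(f[8]) if len(f) > 8 else 1
            calls.append(LoopCall(chrom, i, j, prob, size))
    return calls


def read_bedpe(path: str | Path) -> pd.DataFrame:
    """Read a generic BEDPE interaction list (training labels).

    Tolerates extra columns and comment/header lines starting with '#'.
    Returns the six coordinate columns with standard names.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 6:
        raise ValueError("BEDPE needs at least 6 columns")
    df = df.iloc[:, :6].copy()
    df.columns = ["chrom1", "start1", "end1", "chrom2", "start2", "end2"]
    return df
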