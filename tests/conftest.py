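"""Shared fixtures: simulated study data and a minimal cooler writer.

The "study" fixtures reproduce the package's reference evaluation setup —
two 400-bin chromosomes at 10 kb with 50 planted loops each, half of the
truth used as the positive training list — trained and scored once per
session so the expensive end-to-end tests can share the result.
"""

from __future__ import annotations

import dataclasses

import h5py
import numpy as np
import pandas as pd
import pytest

import loopscout as ls
from loopscout.training import anchors_to_bins

RESOLUTION = 10_000
STUDY_CHROMS = ("chrA", "chrB")
STUDY_SEED = 0


def build_study_maps(seed: int = STUDY_SEED, alpha: float | None = None):
    """Two-chromosome planted-loop fixture (optionally depth-thinned)."""
    maps, train_parts, helds = {}, [], {}
    for k, chrom in enumerate(STUDY_CHROMS):
        cfg = ls.SimulationConfig(chrom=chrom, seed=seed + k)
        cmap, train, held = ls.make_training_fixture(cfg, n_loops=50,
                                                     train_frac=0.5)
        if alpha is not None:
            cmap = cmap.thin(alpha, seed + 100 + k)
        maps[chrom] = cmap
        train_parts.append(train)
        helds[chrom] = held
    return maps, pd.concat(train_parts, ignore_index=True), helds


def run_study_pipeline(seed: int = STUDY_SEED, alpha: float | None = None):
    """Train hold-out forests, score both chromosomes, pool calls."""
    maps, loops, helds = build_study_maps(seed=seed, alpha=alpha)
    bundle = ls.train_holdout_models(maps, loops, seed=seed)
    scored, calls = {}, []
    for chrom, cmap in maps.items():
        sc = ls.score_pixels(cmap, bundle)
        scored[chrom] = sc
        calls.extend(ls.call_loops(sc, cmap.n_bins, call_threshold=0.9))
    held_pix = {(c, i, j) for c in STUDY_CHROMS
                for i, j in anchors_to_bins(helds[c], c, RESOLUTION)}
    train_pix = {(c, i, j) for c in STUDY_CHROMS
                 for i, j in anchors_to_bins(loops[loops["chrom1"] == c],
                                             c, RESOLUTION)}
    return {"maps": maps, "loops": loops, "helds": helds, "bundle": bundle,
            "scored": scored, "calls": calls,
            "held_pixels": held_pix, "truth_pixels": held_pix | train_pix}


@pytest.fixture(scope="session")
def study():
    """Full-depth end-to-end run of the reference fixture."""
    return run_study_pipeline()


@pytest.fixture(scope="session")
def study_thinned():
    """Same fixture thinned to alpha=0.5 and retrained at that depth."""
    return run_study_pipeline(alpha=0.5)


def matches_within(call, pixels, tol: int = 2) -> bool:
    """+/-tol-bin anchor matching, the field's loop-comparison convention."""
    return any(call.chrom == c and abs(call.i - i) <= tol
               and abs(call.j - j) <= tol for c, i, j in pixels)


# ---------------------------------------------------------------------------
# minimal cooler writer (test-only; files are created at test time)


def write_cooler(path, maps: dict[str, ls.ContactMap],
                 weights: dict[str, np.ndarray] | None = None) -> None:
    """Write ContactMaps as a single-resolution cooler-layout HDF5 file."""
    chroms = list(maps)
    resolution = maps[chroms[0]].resolution
    offsets = np.cumsum([0] + [maps[c].n_bins for c in chroms])
    b1_all, b2_all, cc_all = [], [], []
    for k, c in enumerate(chroms):
        i, j, v = maps[c].nonzero()
        b1_all.append(i + offsets[k])
        b2_all.append(j + offsets[k])
        cc_all.append(v)
    b1 = np.concatenate(b1_all).astype(np.int64)
    b2 = np.concatenate(b2_all).astype(np.int64)
    cc = np.concatenate(cc_all)
    order = np.lexsort((b2, b1))
    b1, b2, cc = b1[order], b2[order], cc[order]
    n_bins_total = int(offsets[-1])
    bin1_offset = np.searchsorted(b1, np.arange(n_bins_total + 1))
    with h5py.File(path, "w") as f:
        f.attrs["bin-size"] = resolution
        f.attrs["format"] = "HDF5::Cooler"
        g = f.create_group("chroms")
        g.create_dataset("name", data=np.array([c.encode() for c in chroms]))
        g.create_dataset("length", data=np.array(
            [maps[c].n_bins * resolution for c in chroms], dtype=np.int64))
        gb = f.create_group("bins")
        chrom_ids = np.concatenate([np.full(maps[c].n_bins, k)
                                    for k, c in enumerate(chroms)])
        starts = np.concatenate([np.arange(maps[c].n_bins) * resolution
                                 for c in chroms])
        gb.create_dataset("chrom", data=chrom_ids.astype(np.int32))
        gb.create_dataset("start", data=starts.astype(np.int64))
        gb.create_dataset("end", data=(starts + resolution).astype(np.int64))
        if weights is not None:
            gb.create_dataset("weight", data=np.concatenate(
                [weights[c] for c in chroms]).astype(np.float64))
        gp = f.create_group("pixels")
        gp.create_dataset("bin1_id", data=b1)
        gp.create_dataset("bin2_id", data=b2)
        gp.create_dataset("count", data=cc)
        gi = f.create_group("indexes")
        gi.create_dataset("chrom_offset", data=offsets.astype(np.int64))
        gi.create_dataset("bin1_offset", data=bin1_offset.astype(np.int64))


def random_map(seed: int = 0, n_bins: int = 80, lam: float = 4.0,
               chrom: str = "chrT") -> ls.ContactMap:
    """Small dense-ish random map for oracle-equivalence tests."""
    rng = np.random.default_rng(seed)
    iu, ju = np.triu_indices(n_bins)
    counts = rng.poisson(lam, iu.size)
    keep = counts > 0
    return ls.ContactMap(chrom, RESOLUTION, n_bins,
                         iu[keep], ju[keep], counts[keep])
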