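"""APA, shuffled-control enrichment, and distance summaries."""

import numpy as np
import pandas as pd
import pytest

import loopscout as ls
from loopscout.analysis import (apa, distance_summary, fold_enrichment,
                                shuffle_controls)
from loopscout.training import anchors_to_bins

from conftest import RESOLUTION


def constant_map(value=5.0, n_bins=60, chrom="chrT"):
    iu, ju = np.triu_indices(n_bins)
    return ls.ContactMap(chrom, RESOLUTION, n_bins, iu, ju,
                         np.full(iu.size, value))


def bed(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


class TestApa:
    def test_constant_map_scores_exactly_one(self):
        m = constant_map()
        calls = [ls.LoopCall("chrT", 10, 30, 1.0),
                 ls.LoopCall("chrT", 20, 45, 1.0)]
        res = apa(m, calls, k=5)
        assert np.allclose(res.matrix, 1.0)
        assert res.center_enrichment == 1.0

    def test_single_call_equals_its_normalized_window(self):
        rng = np.random.default_rng(0)
        iu, ju = np.triu_indices(60)
        m = ls.ContactMap("chrT", RESOLUTION, 60, iu, ju,
                          rng.poisson(6, iu.size) + 1.0)
        call = ls.LoopCall("chrT", 15, 40, 1.0)
        win = m.fetch_window(ls.PixelCoord("chrT", 15, 40), 5)
        res = apa(m, [call], k=5)
        assert np.allclose(res.matrix, win / win.mean())

    def test_scale_invariance(self):
        rng = np.random.default_rng(1)
        iu, ju = np.triu_indices(60)
        counts = rng.poisson(6, iu.size) + 1.0
        calls = [ls.LoopCall("chrT", 12, 33, 1.0),
                 ls.LoopCall("chrT", 25, 50, 1.0)]
        r1 = apa(ls.ContactMap("chrT", RESOLUTION, 60, iu, ju, counts),
                 calls)
        r2 = apa(ls.ContactMap("chrT", RESOLUTION, 60, iu, ju, 7 * counts),
                 calls)
        assert np.allclose(r1.matrix, r2.matrix)
        assert r1.center_enrichment == pytest.approx(r2.center_enrichment)

    def test_planted_truth_is_center_enriched(self, study):
        truth = [ls.LoopCall(c, i, j, 1.0)
                 for c, i, j in sorted(study["truth_pixels"])]
        res = apa(study["maps"], truth, k=5)
        assert res.center_enrichment > 1.5

    def test_no_usable_calls_is_an_error(self):
        m = constant_map(n_bins=20)
        with pytest.raises(ValueError):
            apa(m, [ls.LoopCall("chrT", 0, 19, 1.0)], k=5)


class TestShuffles:
    sizes = {"chrT": 600 * RESOLUTION}

    def test_distance_multiset_is_conserved(self):
        rng = np.random.default_rng(2)
        calls = [ls.LoopCall("chrT", int(i), int(i + d), 1.0)
                 for i, d in zip(rng.integers(0, 400, 30),
                                 rng.integers(3, 150, 30))]
        controls = shuffle_controls(calls, self.sizes, RESOLUTION,
                                    n_controls=50, seed=0)
        assert len(controls) == 50
        want = sorted(c.j - c.i for c in calls)
        for ctrl in controls:
            assert sorted(c.j - c.i for c in ctrl) == want

    def test_single_admissible_placement_is_forced(self):
        # 10-bin chromosome, loop spanning 3 bins; gaps leave only i=4
        sizes = {"chrT": 10 * RESOLUTION}
        gaps = bed([("chrT", 0, 4 * RESOLUTION),
                    ("chrT", 7 * RESOLUTION, 10 * RESOLUTION)])
        calls = [ls.LoopCall("chrT", 0, 2, 1.0)]
        controls = shuffle_controls(calls, sizes, RESOLUTION, gaps=gaps,
                                    n_controls=20, seed=1)
        assert all(ctrl == [ls.LoopCall("chrT", 4, 6, 1.0)]
                   for ctrl in controls)

    def test_deterministic_given_seed(self):
        calls = [ls.LoopCall("chrT", 5, 50, 1.0),
                 ls.LoopCall("chrT", 80, 200, 1.0)]
        c1 = shuffle_controls(calls, self.sizes, RESOLUTION, seed=9)
        c2 = shuffle_controls(calls, self.sizes, RESOLUTION, seed=9)
        assert c1 == c2


class TestFoldEnrichment:
    def test_genome_tiling_peaks_saturate_to_one(self):
        calls = [ls.LoopCall("chrT", 10, 50, 1.0)]
        peaks = bed([("chrT", 0, 600 * RESOLUTION)])
        controls = shuffle_controls(calls, {"chrT": 600 * RESOLUTION},
                                    RESOLUTION, n_controls=10, seed=0)
        res = fold_enrichment(calls, peaks, controls, RESOLUTION)
        assert res.fold == pytest.approx(1.0)

    def test_empty_peak_set_scores_zero(self):
        calls = [ls.LoopCall("chrT", 10, 50, 1.0)]
        with pytest.warns(UserWarning, match="empty peak"):
            res = fold_enrichment(calls, bed([]), [[]], RESOLUTION)
        assert res.fold == 0.0

    def test_anchor_targeted_peaks_enrich_above_one(self, study):
        truth = sorted(study["truth_pixels"])
        calls = [ls.LoopCall(c, i, j, 1.0) for c, i, j in truth]
        peaks = bed([(c, b * RESOLUTION, (b + 1) * RESOLUTION)
                     for c, i, j in truth for b in (i, j)])
        sizes = {c: 400 * RESOLUTION for c in ("chrA", "chrB")}
        controls = shuffle_controls(calls, sizes, RESOLUTION,
                                    n_controls=20, seed=3)
        res = fold_enrichment(calls, peaks, controls, RESOLUTION)
        assert res.fold > 1.0
        # brute-force oracle for the observed count
        anchors = {(c.chrom, b) for c in calls for b in (c.i, c.j)}
        brute = sum(
            any(p.chrom == ch and p.start < (b + 1) * RESOLUTION
                and p.end > b * RESOLUTION
                for p in peaks.itertuples(index=False))
            for ch, b in anchors)
        assert res.observed == brute


class TestDistanceSummary:
    def test_hand_binned_strata(self):
        calls = [ls.LoopCall("chrT", 0, d // RESOLUTION, 1.0)
                 for d in (100_000, 200_000, 300_000, 600_000)]
        df = distance_summary(calls, RESOLUTION, [250_000, 500_000])
        assert list(df["count"]) == [2, 1, 1]
        assert df["fraction"].sum() == pytest.approx(1.0)

    def test_single_distance_single_stratum(self):
        calls = [ls.LoopCall("chrT", 0, 10, 1.0)] * 4
        df = distance_summary(calls, RESOLUTION, [250_000, 500_000])
        assert list(df["count"]) == [4, 0, 0]
        assert df["fraction"].iloc[0] == 1.0
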