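"""Contact-map loading, symmetric queries, windows, thinning, BEDPE."""

import numpy as np
import pytest

import loopscout as ls
from loopscout.contactmap import read_bedpe

from conftest import RESOLUTION, random_map, write_cooler


def _write_triplets(path, rows):
    with open(path, "w") as fh:
        for r in rows:
            fh.write("\t".join(str(x) for x in r) + "\n")


class TestLoading:
    def test_mirrored_duplicates_are_summed(self, tmp_path):
        p = tmp_path / "m.txt"
        _write_triplets(p, [(0, 1, 3), (1, 0, 2), (2, 2, 5)])
        m = ls.load_contact_map(p, "chr1", RESOLUTION)
        assert m.query(0, 1) == 5 and m.query(1, 0) == 5
        assert m.query(2, 2) == 5

    def test_empty_file_gives_all_zero_map(self, tmp_path):
        p = tmp_path / "empty.txt"
        p.write_text("")
        m = ls.load_contact_map(p, "chr1", RESOLUTION, n_bins=4)
        assert all(m.query(i, j) == 0 for i in range(4) for j in range(4))

    def test_negative_counts_rejected(self, tmp_path):
        p = tmp_path / "neg.txt"
        _write_triplets(p, [(0, 1, -3)])
        with pytest.raises(ValueError, match="negative"):
            ls.load_contact_map(p, "chr1", RESOLUTION)

    def test_cooler_and_triplet_dumps_agree(self, tmp_path):
        m = random_map(seed=3, n_bins=40)
        cool = tmp_path / "t.cool"
        write_cooler(cool, {"chrT": m})
        i, j, c = m.nonzero()
        txt = tmp_path / "t.txt"
        _write_triplets(txt, zip(i, j, c.astype(int)))
        m_cool = ls.load_contact_map(cool, "chrT")
        m_txt = ls.load_contact_map(txt, "chrT", RESOLUTION, n_bins=40)
        assert np.array_equal(m_cool.dense(), m_txt.dense())

    def test_missing_chromosome_names_available(self, tmp_path):
        cool = tmp_path / "t.cool"
        write_cooler(cool, {"chrT": random_map(n_bins=10)})
        with pytest.raises(ValueError, match="chrT"):
            ls.load_contact_map(cool, "chrZ")

    def test_balanced_needs_weights(self, tmp_path):
        cool = tmp_path / "t.cool"
        m = random_map(n_bins=10)
        write_cooler(cool, {"chrT": m})
        with pytest.raises(ValueError, match="weight"):
            ls.load_contact_map(cool, "chrT", use_balanced=True)
        txt = tmp_path / "t.txt"
        _write_triplets(txt, [(0, 1, 2)])
        with pytest.raises(ValueError, match="weight"):
            ls.load_contact_map(txt, "chrT", RESOLUTION, use_balanced=True)

    def test_balanced_counts_apply_weight_product(self, tmp_path):
        m = random_map(seed=5, n_bins=12)
        w = np.linspace(0.5, 2.0, 12)
        cool = tmp_path / "w.cool"
        write_cooler(cool, {"chrT": m}, weights={"chrT": w})
        mb = ls.load_contact_map(cool, "chrT", use_balanced=True)
        i, j, _ = m.nonzero()
        k = 0
        assert mb.query(i[k], j[k]) == pytest.approx(
            m.query(i[k], j[k]) * w[i[k]] * w[j[k]])


class TestQueriesAndWindows:
    def test_query_is_symmetric_everywhere(self):
        m = random_map(seed=1, n_bins=30)
        d = m.dense()
        assert np.array_equal(d, d.T)
        for i, j in [(0, 5), (3, 3), (29, 2)]:
            assert m.query(i, j) == m.query(j, i)

    def test_window_matches_bruteforce_queries(self):
        m = random_map(seed=2, n_bins=50)
        for (ci, cj, n) in [(10, 20, 5), (6, 9, 3), (7, 12, 0)]:
            w = m.fetch_window(ls.PixelCoord("chrT", ci, cj), n)
            brute = np.array([[m.query(ci - n + a, cj - n + b)
                               for b in range(2 * n + 1)]
                              for a in range(2 * n + 1)])
            assert w.shape == (2 * n + 1, 2 * n + 1)
            assert np.array_equal(w, brute)

    def test_degenerate_radius_window_is_the_pixel(self):
        m = random_map(seed=2, n_bins=50)
        w = m.fetch_window(ls.PixelCoord("chrT", 7, 12), 0)
        assert w.shape == (1, 1) and w[0, 0] == m.query(7, 12)

    def test_boundary_violation_yields_sentinel(self):
        m = random_map(seed=2, n_bins=5)
        assert m.fetch_window(ls.PixelCoord("chrT", 0, 4), 1) is None


class TestThinning:
    def test_alpha_one_is_identity(self):
        m = random_map(seed=4)
        assert np.array_equal(m.thin(1.0, seed=9).dense(), m.dense())

    def test_thinned_counts_never_exceed_original(self):
        m = random_map(seed=4)
        for alpha in (0.1, 0.5, 0.9):
            t = m.thin(alpha, seed=11)
            assert np.all(t.dense() <= m.dense())

    def test_same_seed_reproduces(self):
        m = random_map(seed=4)
        assert np.array_equal(m.thin(0.3, seed=5).dense(),
                              m.thin(0.3, seed=5).dense())

    @pytest.mark.parametrize("alpha", [0.0, -0.2, 1.5])
    def test_invalid_alpha_rejected(self, alpha):
        with pytest.raises(ValueError):
            random_map().thin(alpha, seed=0)


class TestBedpe:
    def test_example_line_layout(self, tmp_path):
        p = tmp_path / "x.bedpe"
        ls.write_loops([ls.LoopCall("chr1", 5, 20, 0.97)], p, 10_000)
        line = p.read_text().strip()
        assert line == "chr1\t50000\t60000\tchr1\t200000\t210000\t.\t0.97"

    def test_roundtrip_random_calls_exact(self, tmp_path):
        rng = np.random.default_rng(7)
        calls = []
        for _ in range(100):
            i = int(rng.integers(0, 500))
            j = i + int(rng.integers(1, 200))
            calls.append(ls.LoopCall("chr2", i, j, float(rng.random()),
                                     int(rng.integers(1, 9))))
        p = tmp_path / "r.bedpe"
        ls.write_loops(calls, p, RESOLUTION)
        assert ls.read_loops(p, RESOLUTION) == calls

    def test_empty_roundtrip(self, tmp_path):
        p = tmp_path / "e.bedpe"
        ls.write_loops([], p, RESOLUTION, header_lines=["provenance"])
        assert ls.read_loops(p, RESOLUTION) == []

    def test_generic_bedpe_reader_tolerates_extra_columns(self, tmp_path):
        p = tmp_path / "g.bedpe"
        p.write_text("# header\nchr1\t0\t10000\tchr1\t50000\t60000\tx\t3\n")
        df = read_bedpe(p)
        assert list(df.columns) == ["chrom1", "start1", "end1",
                                    "chrom2", "start2", "end2"]
        assert len(df) == 1
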