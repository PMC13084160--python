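"""Object-based colocalization: overlaps, Mander's, line scans."""

import numpy as np
import pytest

from ncfish.coloc import (line_scan, manders, overlap_fraction, pairwise_coloc,
                          rasterize_spots, triple_coloc)
from ncfish.masks import NeuritePath
from ncfish.spots import Punctum, PunctumSet, Spot, SpotSet


def _punctum(coords):
    coords = np.asarray(coords, dtype=int)
    return Punctum(support=coords, centroid=tuple(coords.mean(axis=0)),
                   mean_intensity=1.0)


def _pset(list_of_coords, channel="x"):
    return PunctumSet(puncta=[_punctum(c) for c in list_of_coords], channel=channel)


class TestOverlapFraction:
    def test_identical_supports(self):
        p = _punctum([(0, 0), (0, 1)])
        assert overlap_fraction(p, p) == 1.0

    def test_disjoint(self):
        assert overlap_fraction(_punctum([(0, 0)]), _punctum([(5, 5)])) == 0.0

    def test_quarter_overlap_worked_example(self):
        a = _punctum([(0, 0), (0, 1), (1, 0), (1, 1)])
        b = _punctum([(1, 1), (1, 2), (2, 1), (2, 2)])
        assert overlap_fraction(a, b) == pytest.approx(0.25)

    def test_asymmetric_denominator(self):
        a = _punctum([(0, 0), (0, 1)])
        b = _punctum([(0, 1), (0, 2), (1, 1), (1, 2)])
        assert overlap_fraction(a, b) == pytest.approx(0.5)
        assert overlap_fraction(b, a) == pytest.approx(0.25)

    def test_empty_reference_errors(self):
        with pytest.raises((ValueError, TypeError)):
            overlap_fraction(Punctum(support=np.empty((0, 2), int),
                                     centroid=(0, 0), mean_intensity=0), _punctum([(0, 0)]))

    def test_matches_brute_force_on_random_pairs(self, rng):
        for _ in range(200):
            a_coords = {(int(r), int(c))
                        for r, c in rng.integers(0, 8, size=(rng.integers(1, 10), 2))}
            b_coords = {(int(r), int(c))
                        for r, c in rng.integers(0, 8, size=(rng.integers(1, 10), 2))}
            a, b = _punctum(sorted(a_coords)), _punctum(sorted(b_coords))
            expect = len(a_coords & b_coords) / len(a_coords)
            assert abs(overlap_fraction(a, b) - expect) < 1e-12


class TestPairwise:
    def test_threshold_monotonicity(self, rng):
        shape = (64, 64)
        ref = _pset([[(10, 10), (10, 11), (11, 10), (11, 11)],
                     [(30, 30), (30, 31)], [(50, 50)]], "a")
        tgt = _pset([[(10, 11), (10, 12), (11, 11)], [(30, 31)], [(40, 40)]], "b")
        c_lo = pairwise_coloc(ref, tgt, threshold=0.5, shape=shape).colocalized
        c_hi = pairwise_coloc(ref, tgt, threshold=1.0, shape=shape).colocalized
        assert c_hi <= c_lo

    def test_empty_target_zero_fraction(self):
        ref = _pset([[(5, 5)]], "a")
        rep = pairwise_coloc(ref, _pset([], "b"), shape=(16, 16))
        assert rep.fraction == 0.0 and rep.colocalized == 0

    def test_zero_reference_flags_warning(self):
        rep = pairwise_coloc(_pset([], "a"), _pset([[(5, 5)]], "b"), shape=(16, 16))
        assert rep.n_reference == 0 and rep.warning is not None

    def test_tiny_threshold_counts_touching_pairs(self, rng):
        # threshold -> 0 counts any intersecting pair: compare against a
        # brute-force all-pairs intersection test
        shape = (32, 32)
        ref_sets, tgt_sets = [], []
        for _ in range(8):
            r, c = rng.integers(2, 28, 2)
            ref_sets.append([(r + dr, c + dc) for dr in range(2) for dc in range(2)])
        for _ in range(8):
            r, c = rng.integers(2, 28, 2)
            tgt_sets.append([(r + dr, c + dc) for dr in range(2) for dc in range(2)])
        ref, tgt = _pset(ref_sets, "a"), _pset(tgt_sets, "b")
        rep = pairwise_coloc(ref, tgt, threshold=1e-9, shape=shape)
        brute = sum(
            any(set(map(tuple, a)) & set(map(tuple, b)) for b in tgt_sets)
            for a in ref_sets)
        assert rep.colocalized == brute

    def test_translation_invariance(self):
        shape = (64, 64)
        ref_sets = [[(10, 10), (10, 11)], [(30, 30)]]
        tgt_sets = [[(10, 11), (10, 12)], [(40, 40)]]
        rep1 = pairwise_coloc(_pset(ref_sets, "a"), _pset(tgt_sets, "b"), shape=shape)
        shift = lambda sets: [[(r + 7, c + 7) for r, c in s] for s in sets]
        rep2 = pairwise_coloc(_pset(shift(ref_sets), "a"),
                              _pset(shift(tgt_sets), "b"), shape=shape)
        assert rep1.colocalized == rep2.colocalized
        np.testing.assert_allclose(np.sort(rep1.per_object), np.sort(rep2.per_object))


class TestTriple:
    def test_bounded_by_pairwise(self, rng):
        shape = (64, 64)
        mk = lambda n: _pset([[(int(r) + dr, int(c) + dc)
                               for dr in range(2) for dc in range(2)]
                              for r, c in rng.integers(4, 60, size=(n, 2))])
        a, b, c = mk(10), mk(10), mk(10)
        t = triple_coloc(a, b, c, threshold=0.25, shape=shape).colocalized
        p_ab = pairwise_coloc(a, b, threshold=0.25, shape=shape).colocalized
        p_ac = pairwise_coloc(a, c, threshold=0.25, shape=shape).colocalized
        assert t <= min(p_ab, p_ac)

    def test_full_overlap_gives_one(self):
        shape = (32, 32)
        coords = [[(5, 5), (5, 6)], [(20, 20), (20, 21)]]
        a, b, c = (_pset(coords, ch) for ch in "abc")
        rep = triple_coloc(a, b, c, threshold=0.5, shape=shape)
        assert rep.fraction == 1.0


class TestManders:
    def test_identical_images(self):
        img = np.zeros((6, 6))
        img[2:4, 2:4] = 5.0
        m1, m2 = manders(img, img, 1.0, 1.0)
        assert m1 == 1.0 and m2 == 1.0

    def test_disjoint_supports(self):
        a = np.zeros((6, 6)); a[1, 1] = 2.0
        b = np.zeros((6, 6)); b[4, 4] = 3.0
        m1, m2 = manders(a, b, 0.5, 0.5)
        assert m1 == 0.0 and m2 == 0.0

    def test_worked_3x3_grid(self):
        a = np.array([[1.0, 0, 0], [0, 2.0, 0], [0, 0, 3.0]])
        b = np.zeros((3, 3)); b[1, 1] = 1.0
        m1, m2 = manders(a, b, 0.0, 0.5)
        assert m1 == pytest.approx(2.0 / 6.0)
        assert m2 == pytest.approx(1.0)

    def test_zero_intensity_errors(self):
        with pytest.raises(ValueError):
            manders(np.zeros((4, 4)), np.ones((4, 4)), 0.1, 0.1)


class TestRasterize:
    def test_disk_radius_from_sigma(self):
        spots = SpotSet(spots=[Spot(position=(16.0, 16.0), response=1, intensity=1)])
        pset = rasterize_spots(spots, (32, 32), sigma_dog=1.4975)
        support = pset.puncta[0].support
        d = np.linalg.norm(support - np.array([16.0, 16.0]), axis=1)
        assert d.max() <= np.ceil(2 * 1.4975) + 0.5
        assert len(support) > 20  # a filled disk, not a point


class TestLineScan:
    def test_constant_image_constant_profile(self):
        img = np.full((64, 64), 2.5)
        p = NeuritePath(vertices=np.array([[32.0, 5.0], [32.0, 55.0]]),
                        width_px=5, pixel_size_um=0.1)
        df = line_scan({"x": img}, p)
        np.testing.assert_allclose(df["intensity"], 2.5, atol=1e-9)

    def test_profile_length(self):
        img = np.zeros((64, 64))
        p = NeuritePath(vertices=np.array([[32.0, 5.0], [32.0, 45.0]]),
                        width_px=3, pixel_size_um=0.1)
        df = line_scan({"x": img}, p, step_px=1.0)
        assert len(df) == int(round(40.0)) + 1

    def test_spot_on_centerline_peaks_at_its_arc(self):
        img = np.full((64, 64), 0.1)
        yy, xx = np.mgrid[0:64, 0:64]
        img += np.exp(-((yy - 32.0) ** 2 + (xx - 25.0) ** 2) / (2 * 1.5 ** 2))
        p = NeuritePath(vertices=np.array([[32.0, 5.0], [32.0, 55.0]]),
                        width_px=5, pixel_size_um=0.1)
        df = line_scan({"x": img}, p)
        peak_arc = df.loc[df["intensity"].idxmax(), "arc_um"]
        assert abs(peak_arc - 2.0) <= 0.1  # spot at 20 px along = 2.0 um

    def test_channels_share_arc_grid(self):
        p = NeuritePath(vertices=np.array([[10.0, 5.0], [30.0, 40.0]]),
                        width_px=3, pixel_size_um=0.1)
        df = line_scan({"a": np.zeros((40, 50)), "b": np.ones((40, 50))}, p)
        arcs = df.groupby("channel")["arc_um"].apply(list)
        assert arcs["a"] == arcs["b"]
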