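"""Spot detection, particle analysis and compartment assignment."""

import numpy as np
import pytest
from scipy.spatial import cKDTree

from ncfish.masks import build_cell_mask, partition_neurite
from ncfish.spots import (DetectionParams, PunctumSet, SpotSet,
                          assign_to_compartments, detect_spots_dog, find_puncta)


def _gaussian_spot(img, r, c, amp=0.5, sigma=1.5):
    yy, xx = np.mgrid[0:img.shape[0], 0:img.shape[1]]
    img += amp * np.exp(-((yy - r) ** 2 + (xx - c) ** 2) / (2 * sigma ** 2))
    return img


class TestDetectSpots:
    def test_blank_image_no_spots(self):
        out = detect_spots_dog(np.full((64, 64), 0.2))
        assert len(out) == 0

    def test_single_spot_subpixel(self):
        img = _gaussian_spot(np.full((80, 80), 0.1), 30.4, 52.7)
        out = detect_spots_dog(img)
        assert len(out) == 1
        r, c = out.spots[0].position
        assert np.hypot(r - 30.4, c - 52.7) < 0.5

    def test_two_spots_10px_apart(self):
        img = np.full((80, 80), 0.1)
        _gaussian_spot(img, 40.0, 30.0)
        _gaussian_spot(img, 40.0, 40.0)
        assert len(detect_spots_dog(img)) == 2

    def test_count_nonincreasing_in_threshold(self, noisy_scene):
        img = noisy_scene.images.channels["rna"]
        counts = [len(detect_spots_dog(img, DetectionParams(dog_threshold=t,
                                                            threshold_mode="fixed")))
                  for t in (0.02, 0.05, 0.1, 0.2)]
        assert counts == sorted(counts, reverse=True)

    def test_f1_on_generated_scenes(self):
        """F1 >= 0.95 at spot amplitude 10x the noise SD (auto threshold)."""
        from ncfish.scene import generate_scene
        from tests.conftest import small_params

        for seed in (0, 1, 2):
            scene = generate_scene(small_params(noise_sd=0.05), seed=seed)
            det = detect_spots_dog(scene.images.channels["rna"],
                                   DetectionParams(threshold_mode="auto"))
            truth = scene.truth.spots["rna"]
            tree = cKDTree(truth)
            d, idx = tree.query(det.positions(), k=1)
            tp = len(set(idx[d <= 2.0]))
            fp = int((d > 2.0).sum())
            fn = len(truth) - tp
            f1 = 2 * tp / (2 * tp + fp + fn)
            assert f1 >= 0.95

    def test_min_separation_enforced(self, noisy_scene):
        out = detect_spots_dog(noisy_scene.images.channels["rna"],
                               DetectionParams(threshold_mode="auto",
                                               min_separation_px=3.0))
        pos = out.positions()
        if len(pos) > 1:
            d, _ = cKDTree(pos).query(pos, k=2)
            assert d[:, 1].min() >= 3.0


class TestFindPuncta:
    def test_two_disjoint_squares(self):
        b = np.zeros((10, 10), bool)
        b[1:3, 1:3] = True
        b[6:8, 6:8] = True
        out = find_puncta(b, np.ones((10, 10)), min_area_px=1)
        assert len(out) == 2
        assert sorted(p.area_px for p in out.puncta) == [4, 4]

    def test_diagonal_touch_is_one_punctum(self):
        b = np.zeros((6, 6), bool)
        b[1, 1] = b[2, 2] = b[3, 3] = b[4, 4] = True
        out = find_puncta(b, np.ones((6, 6)), min_area_px=1)
        assert len(out) == 1

    def test_min_area_filter(self):
        b = np.zeros((8, 8), bool)
        b[1, 1] = True           # area 1: dropped
        b[4:6, 4:6] = True       # area 4: kept
        out = find_puncta(b, np.ones((8, 8)), min_area_px=4)
        assert len(out) == 1 and out.puncta[0].area_px == 4

    def test_count_matches_flood_fill_oracle(self, rng):
        b = rng.uniform(size=(40, 40)) > 0.7
        out = find_puncta(b, np.ones_like(b, dtype=float), min_area_px=1)

        # independent 8-connectivity flood fill
        seen = np.zeros_like(b)
        count = 0
        for r in range(40):
            for c in range(40):
                if b[r, c] and not seen[r, c]:
                    count += 1
                    stack = [(r, c)]
                    seen[r, c] = True
                    while stack:
                        y, x = stack.pop()
                        for dy in (-1, 0, 1):
                            for dx in (-1, 0, 1):
                                yy, xx = y + dy, x + dx
                                if (0 <= yy < 40 and 0 <= xx < 40
                                        and b[yy, xx] and not seen[yy, xx]):
                                    seen[yy, xx] = True
                                    stack.append((yy, xx))
        assert len(out) == count

    def test_intensity_weighted_centroid(self):
        b = np.zeros((5, 5), bool)
        b[2, 1] = b[2, 2] = True
        inten = np.zeros((5, 5))
        inten[2, 1], inten[2, 2] = 1.0, 3.0
        out = find_puncta(b, inten, min_area_px=1)
        # weighted centroid col = (1*1 + 2*3) / 4 = 1.75
        assert out.puncta[0].centroid[1] == pytest.approx(1.75)


@pytest.fixture(scope="module")
def labeled(clean_scene):
    from ncfish.spots import Spot
    truth = clean_scene.truth
    mask = build_cell_mask(clean_scene.images.channels["marker"],
                           clean_scene.images.channels["nucleus"],
                           truth.soma_polygon, truth.neurite_paths,
                           corridor_only=True)
    spots = SpotSet(spots=[Spot(position=tuple(p), response=1.0, intensity=1.0)
                           for p in truth.spots["rna"]])
    return truth, mask, assign_to_compartments(spots, mask, None)


class TestAssignment:

    def test_counts_conserved(self, labeled):
        truth, mask, out = labeled
        comps = [s.compartment for s in out.spots]
        assert len(comps) == len(truth.spots["rna"])
        assert all(c in ("soma", "neurite", "outside") for c in comps)

    def test_truth_positions_in_soma_labeled_soma(self, labeled):
        truth, mask, out = labeled
        for s in out.spots:
            r, c = int(round(s.position[0])), int(round(s.position[1]))
            if mask.soma[r, c]:
                assert s.compartment == "soma"

    def test_arc_positions_within_neurite_length(self, labeled):
        truth, mask, out = labeled
        lengths = {p.name: p.arc_length_um for p in truth.neurite_paths}
        for s in out.spots:
            if s.neurite is not None:
                assert 0 <= s.arc_um <= lengths[s.neurite] + 1e-9

    def test_proximal_label_on_long_neurite(self):
        from ncfish.masks import NeuritePath
        from ncfish.spots import Spot
        # 110-um straight neurite at 1 um/px: 5 um along is proximal
        path = NeuritePath(vertices=np.array([[50.0, 10.0], [50.0, 120.0]]),
                           width_px=5, pixel_size_um=1.0, name="n0")
        corridor = np.zeros((100, 140), bool)
        corridor[48:53, 10:121] = True
        soma = np.zeros((100, 140), bool)
        soma[45:56, 0:10] = True
        from ncfish.masks import CellMask
        cm = CellMask(soma=soma, neurites=[(path, corridor)])
        part = partition_neurite(path)
        spots = SpotSet(spots=[Spot(position=(50.0, 15.0), response=1, intensity=1),
                               Spot(position=(50.0, 70.0), response=1, intensity=1),
                               Spot(position=(50.0, 115.0), response=1, intensity=1)])
        out = assign_to_compartments(spots, cm, [part])
        assert [s.compartment for s in out.spots] == ["proximal", "middle", "distal"]
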