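"""Movie I/O round-trips, translation registration against a brute-force
oracle, and ROI placement invariants."""

import json

import numpy as np
import pytest
import tifffile
from hypothesis import given, strategies as st

import knockscope as ks
from knockscope.exceptions import (
    DegenerateInputError,
    FormatError,
    ParameterError,
    PlacementError,
)
from knockscope.imaging_io import RoiSet, _full_box_topleft


class TestMovieIO:
    def test_round_trip_is_lossless(self, movie, tmp_path):
        path = ks.write_movie(movie, tmp_path / "m.tif")
        back = ks.read_movie(path)
        assert np.array_equal(back.data, movie.data)
        assert np.array_equal(back.times, movie.times)
        assert back.channel_names == movie.channel_names
        assert back.pixel_size == movie.pixel_size
        assert back.ground_truth["phi"] == movie.ground_truth["phi"]

    def test_page_count_not_divisible_by_channels(self, tmp_path):
        path = tmp_path / "bad.tif"
        tifffile.imwrite(path, np.zeros((7, 8, 8)), photometric="minisblack")
        sidecar = {"times": [0, 1, 2], "channel_names": ["target", "partner"]}
        (tmp_path / "bad.tif.json").write_text(json.dumps(sidecar))
        with pytest.raises(FormatError):
            ks.read_movie(path)

    def test_nonincreasing_sidecar_times(self, tmp_path):
        path = tmp_path / "bad.tif"
        tifffile.imwrite(path, np.zeros((4, 8, 8)), photometric="minisblack")
        sidecar = {"times": [0, 1], "channel_names": ["target", "partner"]}
        sidecar["times"] = [0, 0]
        (tmp_path / "bad.tif.json").write_text(json.dumps(sidecar))
        with pytest.raises(FormatError):
            ks.read_movie(path)

    def test_missing_sidecar(self, tmp_path):
        path = tmp_path / "orphan.tif"
        tifffile.imwrite(path, np.zeros((2, 8, 8)), photometric="minisblack")
        with pytest.raises(FormatError):
            ks.read_movie(path)


def _shift_wrap_free(img, dr, dc, rng):
    """Embed img content shifted by (dr, dc), refilling exposed borders with
    background-like noise so no wrap-around artefacts appear."""
    out = rng.normal(0, 1, img.shape)
    H, W = img.shape
    r_lo, r_hi = max(0, dr), H + min(0, dr)
    c_lo, c_hi = max(0, dc), W + min(0, dc)
    out[r_lo:r_hi, c_lo:c_hi] = img[r_lo - dr : r_hi - dr, c_lo - dc : c_hi - dc]
    return out


def _brute_force_register(ref, mov, radius=10):
    """Independent NCC maximization written from the definition."""
    H, W = ref.shape
    best, best_score = None, -np.inf
    for dr in range(-radius, radius + 1):
        for dc in range(-radius, radius + 1):
            a = ref[max(0, -dr) : H - max(0, dr), max(0, -dc) : W - max(0, dc)]
            b = mov[
                max(0, -dr) + dr : H - max(0, dr) + dr,
                max(0, -dc) + dc : W - max(0, dc) + dc,
            ]
            score = np.corrcoef(a.ravel(), b.ravel())[0, 1]
            if score > best_score:
                best, best_score = (dr, dc), score
    return best


class TestRegistration:
    def test_identity(self):
        rng = np.random.default_rng(0)
        img = rng.normal(0, 1, (64, 64))
        assert ks.register_translation(img, img) == (0, 0)

    def test_known_shift_recovered(self):
        rng = np.random.default_rng(1)
        img = rng.normal(0, 1, (64, 64))
        moved = _shift_wrap_free(img, 3, -2, rng)
        assert ks.register_translation(img, moved) == (3, -2)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(2)
        img = rng.normal(0, 1, (48, 48))
        for shift in [(0, 0), (5, 5), (-4, 7), (10, -10)]:
            moved = _shift_wrap_free(img, *shift, rng)
            assert ks.register_translation(img, moved) == _brute_force_register(
                img, moved
            )

    def test_constant_image_rejected(self):
        with pytest.raises(DegenerateInputError):
            ks.register_translation(np.zeros((64, 64)), np.ones((64, 64)))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ParameterError):
            ks.register_translation(np.zeros((64, 64)), np.zeros((32, 32)))

    @given(st.integers(-8, 8), st.integers(-8, 8))
    def test_inverse_consistency(self, dr, dc):
        rng = np.random.default_rng(5)
        img = rng.normal(0, 1, (64, 64))
        moved = _shift_wrap_free(img, dr, dc, rng)
        assert ks.register_translation(img, moved) == (dr, dc)


class TestPlaceRois:
    def test_boxes_inside_their_masks(self, scene, rois):
        masks = scene.masks()
        for comp, boxes in rois.compartments().items():
            for (r0, c0, h, w) in boxes:
                assert masks[comp][r0 : r0 + h, c0 : c0 + w].all()
        r0, c0, h, w = rois.background
        assert not scene.cell_mask[r0 : r0 + h, c0 : c0 + w].any()

    def test_boxes_pairwise_disjoint(self, rois):
        from knockscope.imaging_io import _boxes_disjoint

        boxes = rois.spindle + rois.cytoplasm + rois.mito
        for i, a in enumerate(boxes):
            for b in boxes[i + 1 :]:
                assert _boxes_disjoint(a, b)

    def test_determinism(self, scene):
        a = ks.place_rois(scene, seed=5)
        b = ks.place_rois(scene, seed=5)
        assert a.all_boxes() == b.all_boxes()

    def test_fixed_cell_31px_rois(self):
        scene = ks.generate_scene(preset="fixed", seed=3)
        rois = ks.place_rois(
            scene, roi_size=31, seed=1, compartments=("spindle", "cytoplasm")
        )
        masks = scene.masks()
        for comp, boxes in rois.compartments().items():
            assert len(boxes) == 3
            for (r0, c0, h, w) in boxes:
                assert (h, w) == (31, 31)
                assert masks[comp][r0 : r0 + h, c0 : c0 + w].all()

    def test_compartment_too_small(self):
        masks = {
            "cell": np.zeros((64, 64), dtype=bool),
            "spindle": np.zeros((64, 64), dtype=bool),
        }
        masks["cell"][10:40, 10:40] = True
        masks["spindle"][20:30, 20:30] = True  # 10x10 < 31x31
        with pytest.raises(PlacementError):
            ks.place_rois(masks, roi_size=31, seed=0,
                          compartments=("spindle",))

    def test_full_box_positions_against_direct_scan(self):
        rng = np.random.default_rng(7)
        mask = rng.random((20, 20)) > 0.4
        got = {tuple(p) for p in _full_box_topleft(mask, 3, 4)}
        expected = {
            (r, c)
            for r in range(18)
            for c in range(17)
            if mask[r : r + 3, c : c + 4].all()
        }
        assert got == expected


class TestRoiSetIO:
    def test_json_round_trip(self, rois, tmp_path):
        path = rois.to_json(tmp_path / "rois.json")
        back = RoiSet.from_json(path)
        assert back.all_boxes() == rois.all_boxes()

    def test_csv_import(self, rois, tmp_path):
        path = tmp_path / "rois.csv"
        lines = ["compartment,r0,c0,h,w"]
        for comp, boxes in [
            ("spindle", rois.spindle),
            ("cytoplasm", rois.cytoplasm),
            ("mito", rois.mito),
            ("background", [rois.background]),
            ("wholecell", [rois.wholecell]),
        ]:
            lines += [f"{comp},{r},{c},{h},{w}" for (r, c, h, w) in boxes]
        path.write_text("\n".join(lines))
        back = RoiSet.from_csv(path)
        assert back.all_boxes() == rois.all_boxes()

    def test_malformed_json(self, tmp_path):
        p = tmp_path / "bad.json"
        p.write_text('{"spindle": []')
        with pytest.raises(FormatError):
            RoiSet.from_json(p)
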