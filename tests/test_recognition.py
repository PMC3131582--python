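import numpy as np
import pytest

import chipcyto as cc
from chipcyto.recognition import (
    RecognitionConfig,
    binarize,
    compute_features,
    extract_blobs,
    process_frame,
    subtract_background,
)
from chipcyto.synthetic_imaging import make_background, render_particle, simulate_stream

from conftest import disc_mask, flood_fill_components, region_from_mask


class TestSubtractBinarize:
    def test_identical_images_give_zero_difference(self):
        img = np.random.default_rng(0).integers(0, 255, (20, 20)).astype(np.uint8)
        assert np.all(subtract_background(img, img) == 0)

    def test_constant_offset_is_preserved_signed(self):
        bg = np.full((10, 10), 100, dtype=np.uint8)
        assert np.all(subtract_background(bg + 30, bg) == 30)
        assert np.all(subtract_background(bg - 30, bg) == -30)  # no clipping

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            subtract_background(np.zeros((5, 5)), np.zeros((5, 6)))

    def test_binarize_uses_absolute_difference(self):
        cfg = RecognitionConfig(threshold=25)
        diff = np.array([[30.0, -30.0, 10.0, -10.0, 0.0]])
        assert binarize(diff, cfg).tolist() == [[True, True, False, False, False]]

    def test_threshold_above_max_gives_empty_mask(self):
        cfg = RecognitionConfig(threshold=100)
        assert not binarize(np.full((5, 5), 50.0) - 60.0, cfg).any()


class TestExtractBlobs:
    def test_empty_mask_gives_no_regions(self):
        assert extract_blobs(np.zeros((10, 10), bool), RecognitionConfig()) == []

    def test_two_separated_discs_give_two_regions(self):
        mask = np.zeros((40, 60), bool)
        mask[5:15, 5:15] = disc_mask(4.5)[1:11, 1:11]
        mask[20:30, 40:50] = disc_mask(4.5)[1:11, 1:11]
        regions = extract_blobs(mask, RecognitionConfig(min_blob_area=5))
        assert len(regions) == 2
        # raster order of the topmost-leftmost pixel
        assert regions[0].bbox[0] < regions[1].bbox[0]

    def test_min_area_filter_drops_specks(self):
        mask = np.zeros((10, 10), bool)
        mask[4, 4] = True
        assert extract_blobs(mask, RecognitionConfig(min_blob_area=2)) == []
        assert len(extract_blobs(mask, RecognitionConfig(min_blob_area=1))) == 1

    def test_edge_policy_discards_border_blobs(self):
        mask = np.zeros((10, 10), bool)
        mask[0:3, 4:7] = True
        assert extract_blobs(mask, RecognitionConfig(min_blob_area=1)) == []
        kept = extract_blobs(
            mask, RecognitionConfig(min_blob_area=1, edge_policy="keep")
        )
        assert len(kept) == 1

    def test_connectivity_choice_splits_diagonal_touch(self):
        mask = np.zeros((6, 6), bool)
        mask[1, 1] = mask[2, 2] = True
        assert len(extract_blobs(mask, RecognitionConfig(min_blob_area=1, connectivity=8))) == 1
        assert len(extract_blobs(mask, RecognitionConfig(min_blob_area=1, connectivity=4))) == 2

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_region_pixels_match_flood_fill_oracle(self, seed):
        rng = np.random.default_rng(seed)
        mask = rng.random((40, 40)) < 0.25
        mask[0, :] = mask[-1, :] = mask[:, 0] = mask[:, -1] = False
        cfg = RecognitionConfig(min_blob_area=1, edge_policy="keep")
        regions = extract_blobs(mask, cfg)
        oracle = flood_fill_components(mask, connectivity=8)
        assert len(regions) == len(oracle)
        region_sets = {frozenset(map(tuple, r.coords)) for r in regions}
        assert region_sets == {frozenset(c) for c in oracle}
        for r in regions:
            matching = [c for c in oracle if tuple(r.coords[0]) in c]
            assert r.area_px == len(matching[0])


class TestFeatures:
    @pytest.mark.parametrize("radius", [5, 8, 10, 13, 16, 20])
    def test_disc_area_and_circularity(self, radius, optics):
        mask = disc_mask(radius)
        region = region_from_mask(mask)
        det = compute_features(region, np.full(mask.shape, 60.0), optics)
        assert det.area_px == pytest.approx(np.pi * radius**2, rel=0.05)
        assert det.circularity >= 0.9
        assert det.minor_axis <= det.major_axis

    def test_two_to_one_ellipse_axis_ratio(self, optics):
        n = 64
        yy, xx = np.mgrid[:n, :n]
        mask = ((xx - 32) / 24.0) ** 2 + ((yy - 32) / 12.0) ** 2 <= 1.0
        det = compute_features(region_from_mask(mask), np.full(mask.shape, 60.0), optics)
        assert det.major_axis / det.minor_axis == pytest.approx(2.0, rel=0.10)
        # the equivalent-ellipse axes recover the true lengths in μm
        assert det.major_axis == pytest.approx(48 * optics.pixel_pitch, rel=0.10)

    def test_mean_intensity_is_mean_absolute_difference(self, optics):
        mask = np.zeros((8, 8), bool)
        mask[3:5, 3:5] = True
        diff = np.zeros((8, 8))
        diff[3:5, 3:5] = [[-40, -60], [-50, -50]]
        det = compute_features(region_from_mask(mask), diff, optics)
        assert det.mean_intensity == pytest.approx(50.0)
        assert det.area_um2 == pytest.approx(4 * optics.pixel_pitch**2)

    def test_single_pixel_region_degenerates_cleanly(self, optics):
        mask = np.zeros((5, 5), bool)
        mask[2, 2] = True
        det = compute_features(region_from_mask(mask), np.full((5, 5), 30.0), optics)
        assert det.major_axis == det.minor_axis == optics.pixel_pitch
        assert det.circularity == 1.0

    def test_features_translation_invariant(self, optics):
        mask = disc_mask(6)
        big = np.zeros((60, 60), bool)
        big[5 : 5 + mask.shape[0], 5 : 5 + mask.shape[1]] = mask
        shifted = np.zeros((60, 60), bool)
        shifted[20 : 20 + mask.shape[0], 33 : 33 + mask.shape[1]] = mask
        diff = np.full((60, 60), 50.0)
        d1 = compute_features(region_from_mask(big), diff, optics)
        d2 = compute_features(region_from_mask(shifted), diff, optics)
        assert d1.area_px == d2.area_px
        assert d1.perimeter_px == pytest.approx(d2.perimeter_px)
        assert d1.circularity == pytest.approx(d2.circularity)
        assert d2.centroid[0] - d1.centroid[0] == pytest.approx(28.0)
        assert d2.centroid[1] - d1.centroid[1] == pytest.approx(15.0)


class TestProcessFrame:
    def test_background_only_frame_yields_nothing(self, optics, recog):
        o = cc.OpticsModel(noise_sigma=0.0)
        bg = make_background(o, 1)
        assert process_frame(bg.copy(), bg, recog, o) == []

    def test_single_particle_detected_within_one_pixel(self, geometry, flow, optics, recog):
        pop = cc.ParticlePopulation(label="5um", diameter_mean=5.0, diameter_cv=0.0)
        seq = simulate_stream([pop], [1.0], flow, geometry, optics, 4e6, 0.5, seed=21)
        bg = make_background(optics, 99)
        singles = {
            f: recs[0]
            for f, recs in seq.truth_by_frame().items()
            if len(recs) == 1
        }
        assert len(singles) >= 20
        checked = 0
        for f, rec in singles.items():
            dets = process_frame(seq.frames[f], bg, recog, optics, frame_index=f)
            assert len(dets) == 1
            assert abs(dets[0].centroid[0] - rec.x_px) <= 1.0
            assert abs(dets[0].centroid[1] - rec.y_px) <= 1.0
            assert dets[0].frame_index == f
            checked += 1
            if checked >= 20:
                break

    def test_two_sizes_in_one_frame_yield_distinct_areas(self, geometry, flow, optics, recog):
        o = cc.OpticsModel(noise_sigma=0.0)
        bg = make_background(o, 1)
        frame = bg.astype(float).copy()
        from chipcyto.synthetic_imaging import _add_patch

        for x_um, d in ((22.0, 2.5), (33.0, 3.0)):
            patch, tl = render_particle((x_um, 60.0), d, o)
            _add_patch(frame, patch, tl)
        frame = np.clip(np.rint(frame), 0, 255).astype(np.uint8)
        dets = process_frame(frame, bg, recog, o)
        assert len(dets) == 2
        areas = sorted(d.area_um2 for d in dets)
        assert areas[0] < areas[1]

    def test_noiseless_recall_and_no_false_positives(self, geometry, flow, recog):
        o = cc.OpticsModel(noise_sigma=0.0)
        pop = cc.ParticlePopulation(label="3um", diameter_mean=3.0)
        seq = simulate_stream([pop], [1.0], flow, geometry, o, 4e6, 0.5, seed=8)
        bg = make_background(o, 2)
        n_det = sum(
            len(process_frame(fr, bg, recog, o, frame_index=i))
            for i, fr in enumerate(seq.frames)
        )
        # every fully visible particle found, nothing else (coincident
        # overlaps can merge, so detections never exceed truth)
        n_truth = len(seq.truth)
        merged = 0
        for recs in seq.truth_by_frame().values():
            for a in range(len(recs)):
                for b in range(a + 1, len(recs)):
                    d = np.hypot(recs[a].x_px - recs[b].x_px, recs[a].y_px - recs[b].y_px)
                    if d * o.pixel_pitch < recs[a].diameter_um / 2 + recs[b].diameter_um / 2 + 2:
                        merged += 1
        assert n_truth - merged <= n_det <= n_truth
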