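"""Background subtraction, VIA parsing, Otsu segmentation, MGI measurement."""

import inspect
import json

import numpy as np
import pytest

from gliaplex import imaging
from gliaplex.imaging import (
    RoiBox,
    UnsegmentableRoiError,
    lesion_geometry,
    measure_profile,
    measure_stack,
    otsu_threshold,
    parse_annotations,
    segment_roi,
    subtract_background,
)


def brute_force_otsu(values, nbins=256):
    """Independent oracle: exhaustive between-class variance maximization,
    tied cut points (plateaus across empty bins) averaged."""
    values = np.asarray(values, float)
    counts, edges = np.histogram(values, bins=nbins, range=(values.min(), values.max()))
    centers = (edges[:-1] + edges[1:]) / 2
    n = counts.sum()
    variances = np.full(nbins, -np.inf)
    for i in range(nbins):
        c0, c1 = counts[: i + 1].sum(), counts[i + 1 :].sum()
        if c0 == 0 or c1 == 0:
            continue
        mu0 = (counts[: i + 1] * centers[: i + 1]).sum() / c0
        mu1 = (counts[i + 1 :] * centers[i + 1 :]).sum() / c1
        variances[i] = (c0 / n) * (c1 / n) * (mu0 - mu1) ** 2
    top = variances.max()
    tied = np.flatnonzero(variances >= top - 1e-9 * abs(top))
    return float(np.mean([(centers[i] + centers[min(i + 1, nbins - 1)]) / 2 for i in tied]))


class TestSubtractBackground:
    def test_constant_image_becomes_zero(self):
        out = subtract_background(np.full((64, 64), 37.0), radius=20)
        assert np.allclose(out, 0.0)

    def test_disk_on_flat_background(self):
        img = np.full((128, 128), 10.0)
        ys, xs = np.ogrid[:128, :128]
        disk = (ys - 64) ** 2 + (xs - 64) ** 2 <= 25
        img[disk] += 100
        out = subtract_background(img, radius=30)
        interior = (ys - 64) ** 2 + (xs - 64) ** 2 <= 9
        assert np.all(np.abs(out[interior] - 100) < 2.0)
        assert np.all(np.abs(out[~disk]) < 1.0)

    def test_default_radius_is_200(self):
        assert inspect.signature(subtract_background).parameters["radius"].default == 200

    def test_oversized_radius_falls_back_to_global_minimum(self):
        img = np.arange(16.0).reshape(4, 4) + 5
        with pytest.warns(UserWarning):
            out = subtract_background(img, radius=100)
        assert np.allclose(out, img - img.min())

    def test_input_not_modified_and_output_nonnegative(self):
        rng = np.random.default_rng(0)
        img = rng.uniform(0, 100, (96, 96))
        before = img.copy()
        out = subtract_background(img, radius=25)
        assert np.array_equal(img, before)
        assert out.min() >= 0

    def test_idempotent_on_flat_background(self):
        # once the background is removed, a second pass changes little
        img = np.zeros((128, 128))
        ys, xs = np.ogrid[:128, :128]
        img[(ys - 40) ** 2 + (xs - 40) ** 2 <= 16] = 80
        once = subtract_background(img, radius=30)
        twice = subtract_background(once, radius=30)
        assert np.abs(once - twice).max() < 3.0


class TestOtsu:
    def test_bimodal_threshold_separates_modes(self):
        values = np.concatenate([np.full(50, 10.0), np.full(50, 200.0)])
        thr = otsu_threshold(values)
        assert 10 < thr < 200

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_between_class_variance(self, seed):
        rng = np.random.default_rng(seed)
        values = np.concatenate(
            [rng.normal(30, 5, 120), rng.normal(rng.uniform(80, 200), 15, 80)]
        )
        assert otsu_threshold(values) == pytest.approx(brute_force_otsu(values))

    def test_constant_sample_raises(self):
        with pytest.raises(UnsegmentableRoiError):
            otsu_threshold(np.full(20, 7.0))


class TestAnnotations:
    def _via(self, regions):
        return {"f.tif-1": {"filename": "f.tif", "size": -1, "regions": regions, "file_attributes": {}}}

    def test_parses_rect_regions_with_classes(self):
        regions = [
            {"shape_attributes": {"name": "rect", "x": 1, "y": 2, "width": 5, "height": 6},
             "region_attributes": {"type": t}}
            for t in ("astrocyte", "plaque", "NFT")
        ]
        boxes = parse_annotations(self._via(regions))
        assert [b.object_class for b in boxes] == ["astrocyte", "plaque", "NFT"]
        assert boxes[0].x == 1 and boxes[0].height == 6

    def test_polygon_regions_skipped_with_warning(self):
        regions = [
            {"shape_attributes": {"name": "polygon", "all_points_x": [1], "all_points_y": [1]},
             "region_attributes": {"type": "astrocyte"}},
            {"shape_attributes": {"name": "rect", "x": 0, "y": 0, "width": 4, "height": 4},
             "region_attributes": {"type": "microglia"}},
        ]
        with pytest.warns(UserWarning, match="non-rectangle"):
            boxes = parse_annotations(self._via(regions))
        assert len(boxes) == 1

    def test_unknown_class_raises_with_id(self):
        regions = [{"shape_attributes": {"name": "rect", "x": 0, "y": 0, "width": 4, "height": 4},
                    "region_attributes": {"type": "neuron-ish"}}]
        with pytest.raises(ValueError, match="annotation 0"):
            parse_annotations(self._via(regions))

    def test_round_trip_with_generator(self, noise_free_field):
        _, _, stack, via, truth = noise_free_field
        boxes = parse_annotations(via, stack.shape)
        assert len(boxes) == len(truth)

    def test_reads_from_file(self, tmp_path, noise_free_field):
        _, _, stack, via, _ = noise_free_field
        p = tmp_path / "via.json"
        p.write_text(json.dumps(via))
        assert len(parse_annotations(p, stack.shape)) > 0


class TestSegmentAndMeasure:
    def test_disk_roi_segments_to_disk(self, panel):
        shape = (64, 64)
        img = np.zeros(shape)
        ys, xs = np.ogrid[:64, :64]
        disk = (ys - 32) ** 2 + (xs - 32) ** 2 <= 64
        img[disk] = 150.0
        stack = imaging.ChannelStack({"ALDH1L1": img, "GFAP": img * 2}, pixel_size=0.5)
        roi = RoiBox(20, 20, 25, 25, "astrocyte", 0)
        prof = segment_roi(stack, roi, panel)
        assert abs(prof.area_px - disk.sum()) <= disk.sum() * 0.05
        cx, cy = prof.centroid_um
        assert cx == pytest.approx(32 * 0.5, abs=0.5)
        assert cy == pytest.approx(32 * 0.5, abs=0.5)

    def test_constant_crop_flagged_empty(self, panel):
        stack = imaging.ChannelStack({"ALDH1L1": np.full((32, 32), 5.0)}, pixel_size=1.0)
        prof = segment_roi(stack, RoiBox(0, 0, 10, 10, "astrocyte", 0), panel)
        assert prof.flagged_empty

    def test_measure_is_arithmetic_mean_of_masked_pixels(self, panel):
        img = np.zeros((4, 4))
        img[0, :4] = [1, 2, 3, 4]
        const = np.zeros((4, 4))
        const[0, :4] = 100.0
        channels = {"ALDH1L1": const, "TSPO": img}
        for mk in panel.phenotypic("astrocyte"):
            channels.setdefault(mk, img)
        stack = imaging.ChannelStack(channels, pixel_size=1.0)
        prof = segment_roi(stack, RoiBox(0, 0, 4, 4, "astrocyte", 0), panel)
        out = measure_profile(stack, prof, panel)
        assert out["TSPO"] == pytest.approx(2.5)

    def test_measure_invariant_to_pixels_outside_mask(self, panel):
        rng = np.random.default_rng(0)
        base = np.zeros((20, 20))
        base[5:10, 5:10] = 200.0
        channels = {"ALDH1L1": base}
        for mk in panel.phenotypic("astrocyte"):
            channels[mk] = base.copy()
        stack = imaging.ChannelStack(channels, pixel_size=1.0)
        roi = RoiBox(2, 2, 15, 15, "astrocyte", 0)
        prof = segment_roi(stack, roi, panel)
        out1 = measure_profile(stack, prof, panel)
        for mk in panel.phenotypic("astrocyte"):
            outside = stack[mk].copy()
            outside[~(outside > 0)] = rng.uniform(0, 50, (20, 20))[~(outside > 0)]
            stack.channels[mk][0:2, :] = 999.0  # outside the roi too
        out2 = measure_profile(stack, prof, panel)
        assert out1["GFAP"] == pytest.approx(out2["GFAP"])

    def test_tspo_measured_for_both_cell_types(self, panel):
        assert "TSPO" in panel.phenotypic("astrocyte")
        assert "TSPO" in panel.phenotypic("microglia")

    def test_lesion_radius_from_circular_area(self, panel):
        # r = sqrt(A/pi): a plaque of 78.5398 µm² has radius 5 µm
        rec = imaging.LesionRecord("plaque", (0.0, 0.0), 78.5398)
        assert rec.radius == pytest.approx(5.0, abs=1e-4)
        assert imaging.LesionRecord("NFT", (0.0, 0.0), 0.0).radius == 0.0

    def test_rendered_plaque_radius_recovered_within_5pct(self, noise_free_field, panel):
        sub, lesions, stack, via, truth = noise_free_field
        plaques = [l for l in lesions if l.type == "plaque"]
        if not plaques:
            pytest.skip("no plaques drawn in this field")
        rois = parse_annotations(via, stack.shape)
        recs = lesion_geometry(stack, rois, panel)
        got = sorted(r.radius for r in recs if r.type == "plaque")
        want = sorted(p.radius for p in plaques)
        assert np.allclose(got, want, rtol=0.07, atol=0.5)

    def test_noise_free_round_trip_recovers_mgi_exactly(self, noise_free_field, panel):
        sub, lesions, stack, via, truth = noise_free_field
        rois = parse_annotations(via, stack.shape)
        table, _ = measure_stack(stack, rois, panel, ball_radius=None)
        tmap = truth.set_index("annotation_id")["profile_id"]
        merged = table.assign(profile_id=table["annotation_id"].map(tmap)).merge(
            sub, on="profile_id", suffixes=("_m", "_g")
        )
        assert len(merged) == len(sub)
        for mk in panel.phenotypic("astrocyte"):
            assert np.allclose(merged[f"{mk}_m"], merged[f"{mk}_g"], rtol=1e-12)
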