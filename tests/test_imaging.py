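"""Imaging chain: DEM extraction, stitching, geometry, segmentation, porosity."""

import numpy as np
import numpy.testing as npt
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.ndimage import median_filter

from biofilmscape import imaging, synth
from biofilmscape.types import CDB, DDP, KDP, ElevationMap, PatchLabelMap


@pytest.fixture(scope="module")
def oct_bundle(small_spec):
    dem, labels = synth.gen_landscape(small_spec)
    vol = synth.gen_oct_volume(dem, labels, small_spec, axial_step_mm=0.005)
    return dem, labels, vol


class TestExtractDem:
    def test_round_trip_within_one_axial_voxel(self, small_spec, oct_bundle):
        """Surface detection errs by at most one axial voxel everywhere
        (compared against the median-filtered true DEM, since the
        extraction includes the size-4 denoising filter)."""
        dem, _, vol = oct_bundle
        rec = imaging.extract_dem(vol, small_spec.pixel_mm, 0.005)
        truth = median_filter(dem.heights, size=4, mode="nearest")
        assert np.abs(rec.heights - truth).max() <= 0.005 + 1e-12

    def test_pure_background_gives_zero_dem(self):
        rng = np.random.default_rng(0)
        vol = rng.integers(0, 60, size=(40, 10, 10), dtype=np.uint8)
        vol[0] = 255
        rec = imaging.extract_dem(vol, 0.05, 0.005)
        npt.assert_array_equal(rec.heights, 0.0)

    def test_single_column_spike_removed_by_median_filter(self):
        vol = np.zeros((60, 12, 12), dtype=np.uint8)
        vol[0] = 255
        vol[1:20, :, :] = 200  # uniform slab, 19 voxels tall
        vol[1:50, 6, 6] = 200  # one spiking column
        rec = imaging.extract_dem(vol, 0.05, 0.005)
        assert rec.heights[6, 6] == pytest.approx(rec.heights[3, 3])

    def test_substrate_plane_detected_at_bottom(self, oct_bundle):
        _, _, vol = oct_bundle
        assert imaging.find_substrate_plane(vol) == 0


class TestStitchTiles:
    def test_single_tile_identity(self):
        dem = ElevationMap(np.random.default_rng(1).random((20, 20)), 0.05)
        out = imaging.stitch_tiles([dem], (1, 1))
        npt.assert_array_equal(out.heights, dem.heights)

    def test_cut_and_restitch_recovers_original(self):
        """2x2 tiles cut with 30% overlap reassemble to the original."""
        rng = np.random.default_rng(2)
        tile = 20
        step = int(round(tile * 0.7))
        full = rng.random((step + tile, step + tile))
        tiles = [
            ElevationMap(full[r * step : r * step + tile, c * step : c * step + tile], 0.05)
            for r in range(2)
            for c in range(2)
        ]
        out = imaging.stitch_tiles(tiles, (2, 2), overlap_fraction=0.30)
        npt.assert_allclose(out.heights, full, rtol=0, atol=1e-12)

    def test_mismatched_shapes_rejected(self):
        t1 = ElevationMap(np.zeros((10, 10)), 0.05)
        t2 = ElevationMap(np.zeros((10, 12)), 0.05)
        with pytest.raises(ValueError, match="shape"):
            imaging.stitch_tiles([t1, t2], (1, 2))


class TestThicknessStats:
    def test_constant_height(self):
        dem = ElevationMap(np.full((5, 5), 0.7), 0.05)
        med, iqr = imaging.thickness_stats(dem, np.ones((5, 5), bool))
        assert med == pytest.approx(0.7)
        assert iqr == pytest.approx(0.0)

    def test_matches_brute_force_quantiles(self):
        h = np.arange(1.0, 11.0).reshape(2, 5)
        dem = ElevationMap(h, 1.0)
        med, iqr = imaging.thickness_stats(dem, np.ones_like(h, bool))
        flat = np.sort(h.ravel())
        q2, q8 = np.quantile(flat, [0.2, 0.8])
        assert med == pytest.approx(np.median(flat))
        assert iqr == pytest.approx(q8 - q2)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(shift=st.floats(0.0, 5.0))
    def test_translation_equivariance(self, shift):
        rng = np.random.default_rng(5)
        h = rng.random((6, 6))
        mask = np.ones((6, 6), bool)
        med0, iqr0 = imaging.thickness_stats(ElevationMap(h, 1.0), mask)
        med1, iqr1 = imaging.thickness_stats(ElevationMap(h + shift, 1.0), mask)
        assert med1 == pytest.approx(med0 + shift)
        assert iqr1 == pytest.approx(iqr0, abs=1e-12)

    def test_empty_mask_rejected(self):
        dem = ElevationMap(np.zeros((3, 3)), 1.0)
        with pytest.raises(ValueError, match="empty"):
            imaging.thickness_stats(dem, np.zeros((3, 3), bool))


class TestBiovolume:
    def test_unit_slab(self):
        dem = ElevationMap(np.ones((10, 10)), 1.0)
        assert imaging.biovolume(dem) == pytest.approx(100.0)

    def test_empty_mask_zero(self):
        dem = ElevationMap(np.ones((4, 4)), 1.0)
        assert imaging.biovolume(dem, np.zeros((4, 4), bool)) == 0.0

    def test_additive_over_disjoint_masks(self, oct_bundle):
        dem, labels, _ = oct_bundle
        total = sum(
            imaging.biovolume(dem, labels.labels == c) for c in (CDB, DDP, KDP)
        )
        assert total == pytest.approx(imaging.biovolume(dem))

    def test_survey_replica_volumes(self, survey_spec):
        """Per-type biovolumes of the slow-flow replica: CDB and DDP land
        within 10% of the surveyed 591 and 253 mm^3; the surveyed KDP
        volume (189 mm^3) is arithmetically inconsistent with its own
        printed area x mean height (197 x 1.09 = 215), so KDP is checked
        for internal consistency instead."""
        dem, labels = synth.gen_landscape(survey_spec)
        # replica raster is 10x10 mm; scale to the surveyed 2016 mm^2
        scale = 2016.0 / (10.0 * 10.0)
        vols = {
            c: imaging.biovolume(dem, labels.labels == c) * scale
            for c in (CDB, DDP, KDP)
        }
        assert vols[CDB] == pytest.approx(591.0, rel=0.10)
        assert vols[DDP] == pytest.approx(253.0, rel=0.10)
        area_kdp = (labels.labels == KDP).sum() * dem.pixel_area_mm2 * scale
        h_kdp = dem.heights[labels.labels == KDP].mean()
        assert vols[KDP] == pytest.approx(area_kdp * h_kdp, rel=0.02)


@pytest.fixture(scope="module")
def photo_bundle(survey_patch_params):
    from biofilmscape.types import LandscapeSpec

    spec = LandscapeSpec(
        (20.0, 20.0), 0.025, survey_patch_params, seed=3, blob_smooth_mm=2.0
    )
    dem, labels = synth.gen_landscape(spec)
    photo = synth.gen_macrophoto(dem, labels, seed=5)
    return labels, photo


class TestSegmentPatches:

    def test_recovers_classes_with_good_iou(self, photo_bundle):
        labels, photo = photo_bundle
        seg = imaging.segment_patches(photo, pixel_mm=0.025)
        for code in (CDB, DDP, KDP):
            a = labels.labels == code
            b = seg.labels == code
            iou = (a & b).sum() / (a | b).sum()
            assert iou >= 0.8, f"class {code} IoU {iou:.3f}"

    def test_uniform_image_all_cdb(self):
        img = np.full((50, 50, 3), 100, dtype=np.uint8)
        with pytest.warns(UserWarning, match="uniform"):
            seg = imaging.segment_patches(img)
        assert (seg.labels == CDB).all()

    def test_kdp_area_nondecreasing_under_dilation(self, photo_bundle):
        _, photo = photo_bundle
        a0 = (
            imaging.segment_patches(
                photo, imaging.SegmentationConfig(dilation_px=0)
            ).labels
            == KDP
        ).sum()
        a5 = (
            imaging.segment_patches(
                photo, imaging.SegmentationConfig(dilation_px=5)
            ).labels
            == KDP
        ).sum()
        assert a5 >= a0


class TestPatchGeometry:
    def test_single_class_covers_everything(self):
        dem = ElevationMap(np.full((10, 10), 0.5), 0.1)
        labels = PatchLabelMap(np.full((10, 10), CDB), 0.1)
        geo = imaging.patch_geometry(dem, labels).set_index("patch_type")
        assert geo.loc["CDB", "coverage_pct"] == pytest.approx(100.0)
        assert geo.loc["CDB", "volume_pct"] == pytest.approx(100.0)
        assert geo.loc["DDP", "area_mm2"] == 0.0

    def test_survey_kdp_coverage(self):
        """KDP covering 197 of 2016 mm^2 gives 9.8% coverage."""
        side = 120  # 12 mm at 0.1 mm pixels -> 14400 px = 144 mm^2 scaled
        n_total = side * side
        n_kdp = round(n_total * 197.0 / 2016.0)
        lab = np.full(n_total, CDB)
        lab[:n_kdp] = KDP
        labels = PatchLabelMap(lab.reshape(side, side), 0.1)
        dem = ElevationMap(np.full((side, side), 1.0), 0.1)
        geo = imaging.patch_geometry(dem, labels).set_index("patch_type")
        assert geo.loc["KDP", "coverage_pct"] == pytest.approx(9.8, abs=0.05)

    def test_percentages_normalize(self, oct_bundle):
        dem, labels, _ = oct_bundle
        geo = imaging.patch_geometry(dem, labels)
        per_patch = geo[geo["patch_type"] != "landscape"]
        assert per_patch["coverage_pct"].sum() == pytest.approx(100.0, abs=0.1)
        assert per_patch["volume_pct"].sum() == pytest.approx(100.0, abs=0.1)


class TestPorosity:
    def _slab(self, gray_fill):
        """Uniform 0.5 mm slab volume with all sub-surface voxels at a
        constant gray value (plus substrate and skin)."""
        dz = 0.005
        n_below = 100
        vol = np.zeros((n_below + 20, 8, 8), dtype=np.uint8)
        vol[0] = 255
        vol[1:n_below] = gray_fill
        vol[n_below] = 200  # surface skin
        h = np.full((8, 8), (n_below + 1) * dz)
        dem = ElevationMap(h, 0.05)
        labels = PatchLabelMap(np.full((8, 8), CDB), 0.05)
        return vol, dem, labels

    def test_all_biomass_gives_zero_porosity(self):
        vol, dem, labels = self._slab(200)
        est = imaging.porosity(vol, dem, labels, 0.005)["CDB"]
        assert est.low == est.high == 0.0

    def test_half_voids_give_half_for_both_thresholds(self):
        vol, dem, labels = self._slab(200)
        vol[1:100:2] = 0  # alternate layers at gray 0
        est = imaging.porosity(vol, dem, labels, 0.005)["CDB"]
        assert est.low == pytest.approx(0.5, abs=0.03)
        assert est.high == pytest.approx(0.5, abs=0.03)

    def test_counted_construction_29_percent(self):
        """A layer built with exactly 29% void voxels reads back 0.29
        up to voxel rounding."""
        vol, dem, labels = self._slab(200)
        layer = np.arange(1, 100)
        n_void = round(0.29 * layer.size)
        vol[layer[:n_void]] = 0
        est = imaging.porosity(
            vol, dem, labels, 0.005, layer_depths_mm=(0.495,), gray_thresholds=(120, 130)
        )["CDB"]
        assert est.mid == pytest.approx(0.29, abs=0.02)

    def test_round_trip_through_generator(self, small_spec, oct_bundle):
        """Target porosities (0.40/0.47/0.58) are recovered within 0.05."""
        dem, labels, vol = oct_bundle
        rec = imaging.extract_dem(vol, small_spec.pixel_mm, 0.005)
        est = imaging.porosity(vol, rec, labels, 0.005)
        targets = {"CDB": 0.40, "DDP": 0.47, "KDP": 0.58}
        for name, target in targets.items():
            assert est[name].mid == pytest.approx(target, abs=0.05)

    def test_tall_columns_excluded(self):
        vol, dem, labels = self._slab(200)
        dem.heights[:4, :] = 1.5  # beyond the OCT imaging depth
        est = imaging.porosity(vol, dem, labels, 0.005)["CDB"]
        assert est.n_columns == 32
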