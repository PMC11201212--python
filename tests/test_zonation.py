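"""Core detection, transects, change-point boundaries and segmentation."""

import numpy as np
import pytest

import srcamap as sm
from srcamap.errors import ZonationError
from srcamap.synthetic import NoiseModel, SyntheticScenario, generate_scan, preset
from srcamap.zonation import (
    RadialTransect,
    mean_zone_radii,
    piecewise_constant_breaks,
    validate_partition,
)

from conftest import analyse, jaccard


class TestCore:
    def test_centroid_recovers_centred_core(self, noisy_classic):
        (cx, cz), prov = sm.detect_core(noisy_classic.ratio)
        tx, tz = noisy_classic.scn.core_px()
        assert prov == "mask-centroid"
        assert abs(cx - tx) <= 2 and abs(cz - tz) <= 2

    def test_refinement_recovers_offset_core(self):
        # core 20 µm off the mask centroid: the high-Sr annulus stays
        # concentric around the true core
        scn = SyntheticScenario(
            core_xy_um=(169.75, 99.75), zone_levels_mmolmol=(4.0, 8.0, 1.5), seed=5
        )
        ca, sr, _ = generate_scan(scn)
        mask = sm.make_otolith_mask(ca)
        ratio = sm.calibrate(sm.compute_ratio_map(sr, ca, mask), sm.CalibrationModel())
        (cx, cz), prov = sm.detect_core(ratio, refine=True)
        tx, tz = scn.core_px()
        assert prov == "high-srca-centroid"
        assert np.hypot(cx - tx, cz - tz) <= 5

    def test_manual_override_returned_verbatim(self, noisy_classic):
        core, prov = sm.detect_core(noisy_classic.ratio, override=(120, 80))
        assert core == (120.0, 80.0) and prov == "manual-override"

    def test_empty_mask_rejected(self):
        ratio = sm.RatioMap(np.zeros((5, 5)), np.zeros((5, 5), bool), True, 0.5)
        with pytest.raises(ZonationError, match="empty"):
            sm.detect_core(ratio)


class TestTransect:
    def test_constant_map_gives_constant_transect(self):
        vals = np.zeros((51, 51))
        mask = np.zeros((51, 51), bool)
        yy, xx = np.mgrid[:51, :51]
        mask[(yy - 25) ** 2 + (xx - 25) ** 2 <= 20**2] = True
        vals[mask] = 4.2
        ratio = sm.RatioMap(vals, mask, True, 0.5)
        tr = sm.extract_transect(ratio, (25, 25), angle_deg=30.0)
        assert np.allclose(tr.srca[np.isfinite(tr.srca)], 4.2)

    @pytest.mark.parametrize("angle", [0.0, 45.0, 77.0, 90.0])
    def test_noise_free_transect_is_a_step_function_of_zone_levels(
        self, clean_classic, angle
    ):
        tr = sm.extract_transect(clean_classic.ratio, clean_classic.core, angle, smoothing_um=0)
        levels = set(np.unique(tr.srca[np.isfinite(tr.srca)]))
        assert levels == {2.0, 3.0, 8.0}

    def test_zero_smoothing_equals_direct_indexing_oracle(self, noisy_classic):
        ratio = noisy_classic.ratio
        cx, cz = noisy_classic.core
        tr = sm.extract_transect(ratio, (cx, cz), angle_deg=0.0, smoothing_um=0)
        # along angle 0 the samples are the pixels of row round(cz)
        row = int(round(cz))
        r0 = tr.positions_um - tr.core_position_um
        cols = np.rint(np.round(cx) + r0 / ratio.pixel_size_um).astype(int)
        expected = np.where(
            ratio.valid_mask[row, cols], ratio.values[row, cols], np.nan
        )
        assert np.allclose(tr.srca, expected, equal_nan=True)

    def test_core_outside_mask_rejected(self, noisy_classic):
        with pytest.raises(ZonationError, match="core"):
            sm.extract_transect(noisy_classic.ratio, (2, 2), 0.0)


class TestBoundaries:
    def test_noise_free_step_radii_recovered_within_one_sample(self, clean_classic):
        left, right = sm.detect_zone_boundaries(
            sm.extract_transect(clean_classic.ratio, clean_classic.core, 0.0, smoothing_um=0)
        )
        for radii in (left, right):
            assert radii[0] == pytest.approx(15.0, abs=1.0)
            assert radii[1] == pytest.approx(90.0, abs=1.0)

    def test_noisy_radii_within_5um_of_truth(self, noisy_classic):
        r1, r2 = noisy_classic.scn.zone_radii_um
        tr = sm.extract_transect(noisy_classic.ratio, noisy_classic.core, 0.0)
        for radii in sm.detect_zone_boundaries(tr):
            assert radii[0] == pytest.approx(r1, abs=5.0)
            assert radii[1] == pytest.approx(r2, abs=5.0)

    def test_constant_transect_rejected_not_silent(self):
        tr = RadialTransect(np.arange(60.0), np.full(60, 3.0), 30.0, 0.0)
        with pytest.raises(ZonationError, match="manual thresholds"):
            sm.detect_zone_boundaries(tr)

    def test_exact_dp_matches_brute_force_on_tiny_series(self):
        """The DP segmentation equals exhaustive enumeration of all
        two-break placements on a short noisy series."""
        rng = np.random.default_rng(2)
        y = np.concatenate([rng.normal(3, 0.3, 12), rng.normal(8, 0.3, 15), rng.normal(2, 0.3, 10)])

        def sse(seg):
            return ((seg - seg.mean()) ** 2).sum()

        best, best_breaks = np.inf, None
        for i in range(3, len(y) - 5):
            for j in range(i + 3, len(y) - 2):
                c = sse(y[:i]) + sse(y[i:j]) + sse(y[j:])
                if c < best:
                    best, best_breaks = c, [i, j]
        assert piecewise_constant_breaks(y, 3) == best_breaks


class TestSegmentation:
    def test_noise_free_label_accuracy_above_995(self, clean_classic):
        truth = clean_classic.truth.zone_label_map
        m = truth > 0
        acc = np.mean(clean_classic.zones.labels[m] == truth[m])
        assert acc >= 0.995  # boundary-pixel digitization costs <0.5%

    def test_noisy_per_zone_jaccard_at_least_09(self, noisy_classic):
        truth = noisy_classic.truth.zone_label_map
        for z in (1, 2, 3):
            assert jaccard(noisy_classic.zones.labels == z, truth == z) >= 0.9

    def test_weak_contrast_resident_still_three_ordered_zones(self, noisy_resident):
        labels = noisy_resident.zones.labels
        assert set(np.unique(labels)) == {0, 1, 2, 3}
        radii = mean_zone_radii(noisy_resident.zones, noisy_resident.core)
        assert radii["Z1"] < radii["Z2"] < radii["Z3"]

    def test_labels_partition_the_mask(self, noisy_classic):
        validate_partition(noisy_classic.zones, noisy_classic.mask)
        labels = noisy_classic.zones.labels
        assert (labels[~noisy_classic.mask] == 0).all()

    def test_z1_single_connected_component_contains_core(self, noisy_classic):
        from skimage.measure import label as cc_label

        z1 = noisy_classic.zones.labels == 1
        assert cc_label(z1, connectivity=2).max() == 1
        cx, cz = noisy_classic.core
        assert z1[int(round(cz)), int(round(cx))]

    def test_radial_and_threshold_methods_agree_noise_free(self, clean_classic):
        zt = sm.segment_zones(clean_classic.ratio, clean_classic.core, method="threshold")
        for z in (1, 2, 3):
            assert jaccard(clean_classic.zones.labels == z, zt.labels == z) >= 0.85

    def test_unknown_method_rejected(self, clean_classic):
        with pytest.raises(ValueError, match="unknown segmentation method"):
            sm.segment_zones(clean_classic.ratio, clean_classic.core, method="magic")


class TestGeometry:
    def test_z1_disc_equivalent_diameter(self):
        # circular otolith, Z1 disc of radius 12.5 µm -> diameter 25 µm
        scn = SyntheticScenario(
            otolith_axes_um=(90.0, 90.0),
            zone_radii_um=(12.5, 60.0),
            noise_model=NoiseModel(kind="none"),
        )
        _, _, truth = generate_scan(scn)
        zones = sm.ZoneLabelMap(truth.zone_label_map, scn.pixel_size_um)
        geom = sm.zone_geometry(zones, scn.core_px())
        assert geom["Z1"]["equivalent_diameter_um"] == pytest.approx(25.0, abs=1.0)
        assert 0.85 <= geom["Z1"]["circularity"] <= 1.0

    def test_area_equals_pixel_count_times_pixel_area(self, clean_classic):
        geom = sm.zone_geometry(clean_classic.zones, clean_classic.core)
        for z in (1, 2, 3):
            n = int((clean_classic.zones.labels == z).sum())
            assert geom[f"Z{z}"]["area_px"] == n
            assert geom[f"Z{z}"]["area_um2"] == pytest.approx(n * 0.25)

    def test_empty_zone_reports_zero_area_no_crash(self):
        labels = np.zeros((20, 20), dtype=np.uint8)
        labels[5:15, 5:15] = 1  # only Z1
        geom = sm.zone_geometry(sm.ZoneLabelMap(labels, 0.5), (10, 10))
        assert geom["Z2"]["area_um2"] == 0.0
        assert geom["Z3"]["area_px"] == 0
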