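"""Per-zone histograms, summaries, patch detection and granularity."""

import numpy as np
import pandas as pd
import pytest
from skimage.measure import label as cc_label

import srcamap as sm
from srcamap.errors import SrcaMapError
from srcamap.synthetic import generate_scan, preset

from conftest import analyse


def _ratio_zones(values, labels, pixel_size=0.5):
    valid = labels > 0
    ratio = sm.RatioMap(np.where(valid, values, 0.0), valid, True, pixel_size)
    return ratio, sm.ZoneLabelMap(labels, pixel_size)


def _three_zone_labels(shape=(12, 12)):
    labels = np.zeros(shape, dtype=np.uint8)
    labels[1:-1, 1:-1] = 3
    labels[3:-3, 3:-3] = 2
    labels[5:-5, 5:-5] = 1
    return labels


class TestHistograms:
    def test_constant_zone_single_bin_frequency_one(self):
        labels = _three_zone_labels()
        ratio, zones = _ratio_zones(np.full(labels.shape, 2.0), labels)
        stats = sm.zone_histograms(ratio, zones, bin_width=0.5)
        for name in ("Z1", "Z2", "Z3"):
            f = stats[name].frequencies
            assert f.max() == 1.0 and (f > 0).sum() == 1

    def test_two_level_zone_half_and_half(self):
        labels = np.zeros((10, 10), dtype=np.uint8)
        labels[:, :] = 2
        labels[:, :2] = 1
        labels[:, -2:] = 3
        values = np.full((10, 10), 2.0)
        values[:, 5:] = 8.0  # Z2 occupies columns 2..7 -> half 2s, half 8s
        ratio, zones = _ratio_zones(values, labels)
        h = sm.zone_histograms(ratio, zones, bin_width=0.5)["Z2"]
        assert sorted(h.frequencies[h.frequencies > 0]) == [0.5, 0.5]
        assert h.mean == pytest.approx(5.0)

    def test_raw_frequencies_sum_to_one(self, noisy_classic):
        for name in ("Z1", "Z2", "Z3"):
            assert noisy_classic.stats[name].frequencies.sum() == pytest.approx(1.0, abs=1e-9)

    def test_thresholded_view_never_gains_bins(self, noisy_classic):
        for name in ("Z1", "Z2", "Z3"):
            h = noisy_classic.stats[name]
            _, thr = h.thresholded(0.01)
            assert ((thr > 0) <= (h.frequencies > 0)).all()

    def test_union_histogram_is_pixel_weighted_mixture(self, noisy_classic):
        """Conservation: the whole-otolith histogram equals the
        area-weighted mixture of the per-zone histograms."""
        stats = noisy_classic.stats
        ratio = noisy_classic.ratio
        edges = stats["Z1"].bin_edges
        total, _ = np.histogram(ratio.valid_values(), bins=edges)
        n_total = ratio.valid_mask.sum()
        mixture = sum(
            stats[z].frequencies * stats[z].area_px for z in ("Z1", "Z2", "Z3")
        )
        assert np.allclose(mixture / n_total, total / n_total)

    def test_histogram_matches_csv_tally_oracle(self, tmp_path, noisy_classic):
        """Independent tally: binning the exported CSV reproduces every
        per-zone histogram count exactly."""
        sm.export_spatialized_csv(noisy_classic.ratio, noisy_classic.zones, tmp_path / "px.csv")
        df = pd.read_csv(tmp_path / "px.csv", comment="#").dropna()
        stats = noisy_classic.stats
        edges = stats["Z1"].bin_edges
        for name in ("Z1", "Z2", "Z3"):
            sub = df[df["zone"] == name]["srca_mmolmol"].to_numpy()
            tally, _ = np.histogram(sub, bins=edges)
            assert np.array_equal(tally, stats[name].counts)

    def test_empty_zone_missing_summaries(self):
        labels = np.zeros((10, 10), dtype=np.uint8)
        labels[2:8, 2:8] = 3
        labels[4:6, 4:6] = 1  # no Z2 anywhere
        ratio, zones = _ratio_zones(np.full((10, 10), 2.0), labels)
        stats = sm.zone_histograms(ratio, zones)
        assert stats["Z2"].empty
        summ = sm.zone_summaries(stats)
        assert np.isnan(summ["Z2"]["mode"]) and np.isnan(summ["Z2"]["max"])

    def test_nonpositive_bin_width_rejected(self, noisy_classic):
        with pytest.raises(SrcaMapError):
            sm.zone_histograms(noisy_classic.ratio, noisy_classic.zones, bin_width=0.0)


class TestSummaries:
    def test_mode_is_centre_of_maximal_bin(self):
        labels = _three_zone_labels()
        ratio, zones = _ratio_zones(np.full(labels.shape, 2.2), labels)
        stats = sm.zone_histograms(ratio, zones, bin_width=0.5)
        assert stats["Z1"].mode == pytest.approx(2.25)  # bin [2.0, 2.5)

    def test_tie_resolves_to_lower_bin_deterministically(self):
        labels = np.zeros((10, 10), dtype=np.uint8)
        labels[:] = 2
        labels[:, 0] = 1
        labels[:, -1] = 3
        values = np.full((10, 10), 2.2)
        values[:, 5:] = 7.7  # Z2: exact 40/40 split between two bins
        ratio, zones = _ratio_zones(values, labels)
        for _ in range(3):
            h = sm.zone_histograms(ratio, zones, bin_width=0.5)["Z2"]
            assert h.mode == pytest.approx(2.25)

    def test_freshwater_resident_modes_below_4(self, noisy_resident):
        summ = sm.zone_summaries(noisy_resident.stats)
        assert all(summ[z]["mode"] < 4.0 for z in ("Z1", "Z2", "Z3"))

    def test_classic_separation_z3_support_below_marine_z2(self, noisy_classic):
        """Z3 is clearly separated: its supported (>=1%) bins all sit below
        the dominant marine component of Z2."""
        stats = noisy_classic.stats
        edges, f3 = stats["Z3"].thresholded(0.01)
        z3_top = edges[1:][f3 > 0].max()
        assert z3_top < stats["Z2"].mode


class TestPatches:
    def test_marine_z2_is_one_patch_fraction_near_one(self, clean_classic, noisy_classic):
        # noise-free Z2 at 8 mmol·mol⁻¹: the whole zone is one marine patch
        p = clean_classic.patches
        assert p.z2_marine_fraction == pytest.approx(1.0, abs=0.01)
        assert len(p) == 1
        # with counting noise the fraction stays dominant
        assert noisy_classic.patches.z2_marine_fraction > 0.8

    def test_resident_has_no_patches(self, noisy_resident):
        assert len(noisy_resident.patches) == 0
        assert noisy_resident.patches.z2_marine_fraction < 0.01

    def test_five_generated_discs_recovered(self):
        """Parameter recovery: count exact at the default counting noise;
        total area within 10% of the patch-mask truth at low noise (the raw
        6-threshold erodes patch pixels in proportion to the noise at the
        patch level)."""
        scn = preset("patchy_freshwaterZ2", seed=4)
        prod = analyse(scn)
        truth_n = int(cc_label(prod.truth.patch_mask, connectivity=2).max())
        assert truth_n == 5
        assert len(prod.patches) == 5
        for p in prod.patches.patches:
            assert p.max_srca > 6.0
        from srcamap.synthetic import NoiseModel, PatchParams, SyntheticScenario

        low = analyse(
            SyntheticScenario(
                zone_levels_mmolmol=(4.2, 2.8, 1.2),
                patch_params=PatchParams(count=5, radius_um=(10.0, 10.0), level_mmolmol=8.0),
                noise_model=NoiseModel(kind="poisson", dispersion=5.0),
                seed=4,
            )
        )
        truth_area = low.truth.patch_mask.sum() * scn.pixel_size_um**2
        assert len(low.patches) == 5
        assert low.patches.total_area_um2 == pytest.approx(truth_area, rel=0.10)

    def test_patches_sorted_by_area_descending(self):
        prod = analyse(preset("patchy_amphidromous", seed=1))
        areas = [p.area_um2 for p in prod.patches.patches]
        assert areas == sorted(areas, reverse=True)

    def test_fraction_counts_subminimum_speckle(self):
        labels = _three_zone_labels((20, 20))
        values = np.full((20, 20), 2.0)
        values[4, 4] = 9.0  # a single marine pixel inside Z2: below min area
        ratio, zones = _ratio_zones(values, labels)
        p = sm.detect_patches(ratio, zones, min_patch_area_um2=10.0)
        assert len(p) == 0
        assert p.z2_marine_fraction > 0


class TestGranularity:
    def test_constant_zone_index_zero(self):
        labels = _three_zone_labels((30, 30))
        ratio, zones = _ratio_zones(np.full((30, 30), 3.0), labels)
        gi = sm.granularity_index(ratio, zones, window_um=2.0)
        assert gi["Z2"] == pytest.approx(0.0, abs=1e-12)

    def test_larger_texture_amplitude_larger_index(self):
        from srcamap.synthetic import GranularityParams, NoiseModel, SyntheticScenario

        indices = {}
        for amp in (0.1, 0.3):
            scn = SyntheticScenario(
                granularity_params=GranularityParams(amplitude=amp, corr_length_um=2.0),
                noise_model=NoiseModel(kind="none"),
                seed=6,
            )
            prod = analyse(scn)
            indices[amp] = sm.granularity_index(prod.ratio, prod.zones)["Z2"]
        assert indices[0.3] > indices[0.1]

    def test_invariant_under_global_rescaling(self, noisy_classic):
        gi = sm.granularity_index(noisy_classic.ratio, noisy_classic.zones)
        scaled = sm.RatioMap(
            noisy_classic.ratio.values * 7.0,
            noisy_classic.ratio.valid_mask,
            True,
            noisy_classic.ratio.pixel_size_um,
        )
        gi7 = sm.granularity_index(scaled, noisy_classic.zones)
        for z in ("Z1", "Z2", "Z3"):
            assert gi7[z] == pytest.approx(gi[z], rel=1e-9)

    def test_window_under_3px_rejected(self, noisy_classic):
        with pytest.raises(SrcaMapError, match="3 px"):
            sm.granularity_index(noisy_classic.ratio, noisy_classic.zones, window_um=1.0)
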