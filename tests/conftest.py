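"""Shared fixtures: synthetic scans and their pipeline products."""

from dataclasses import dataclass

import numpy as np
import pytest

import srcamap as sm
from srcamap.synthetic import NoiseModel, SyntheticScenario, generate_scan, preset


@dataclass
class PipelineProducts:
    """Everything one specimen run produces, for inspection in tests."""

    scn: SyntheticScenario
    ca: sm.ElementMap
    sr: sm.ElementMap
    truth: sm.GroundTruth
    mask: np.ndarray
    ratio: sm.RatioMap
    core: tuple
    zones: sm.ZoneLabelMap
    stats: sm.ZoneStats
    patches: sm.PatchSet
    call: sm.LifeHistoryCall


def analyse(scn, method="radial", refine=False) -> PipelineProducts:
    ca, sr, truth = generate_scan(scn)
    mask = sm.make_otolith_mask(ca)
    ratio = sm.calibrate(sm.compute_ratio_map(sr, ca, mask), sm.CalibrationModel())
    core, _ = sm.detect_core(ratio, refine=refine)
    zones = sm.segment_zones(ratio, core, method=method)
    stats = sm.zone_histograms(ratio, zones)
    patches = sm.detect_patches(ratio, zones)
    call = sm.classify(stats, patches)
    return PipelineProducts(scn, ca, sr, truth, mask, ratio, core, zones, stats, patches, call)


@pytest.fixture(scope="session")
def clean_classic():
    """Noise-free scan with levels (3, 8, 2): every value is exact."""
    scn = SyntheticScenario(
        noise_model=NoiseModel(kind="none"), zone_levels_mmolmol=(3.0, 8.0, 2.0)
    )
    return analyse(scn)


@pytest.fixture(scope="session")
def noisy_classic():
    """Seeded classic-pattern scan with the default counting noise."""
    return analyse(preset("classic_amphidromous", seed=7))


@pytest.fixture(scope="session")
def noisy_resident():
    return analyse(preset("freshwater_resident", seed=11))


def jaccard(a, b):
    return np.logical_and(a, b).sum() / np.logical_or(a, b).sum()
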