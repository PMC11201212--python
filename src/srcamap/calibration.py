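"""Pixel-wise Sr:Ca ratio computation, masking and molar calibration.

The ratio raster is the analysis' central object: every downstream step
(zonation, per-zone histograms, patch detection, classification) consumes a
:class:`RatioMap`. Division artifacts are handled by masking, never by
clipping — a pixel with zero Ca simply leaves the valid set, so infinities
can never leak into histograms or transects.

Calibration is a single multiplicative coefficient ``k`` turning the
intensity ratio into a molar Sr:Ca ratio (mmol·mol⁻¹). Full
fundamental-parameter XRF quantification is out of scope here; ``k`` comes
from the user's own spectral calibration and defaults to 1 with provenance
``"identity (uncalibrated)"``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label

from .errors import CalibrationError, DegenerateInputWarning
from .raster_io import ElementMap

__all__ = [
    "RatioMap",
    "CalibrationModel",
    "make_otolith_mask",
    "compute_ratio_map",
    "calibrate",
]


@dataclass
class RatioMap:
    """A 2D Sr:Ca ratio raster with a per-pixel validity mask.

    ``values`` are molar mmol·mol⁻¹ when ``calibrated`` is true, otherwise a
    unitless intensity ratio. Invalid pixels (background, zero-Ca) hold 0 in
    ``values`` and False in ``valid_mask`` and must never enter statistics.
    """

    values: np.ndarray
    valid_mask: np.ndarray
    calibrated: bool
    pixel_size_um: float
    provenance: str = field(default="", compare=False)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.values.shape != self.valid_mask.shape:
            raise CalibrationError("values and valid_mask shapes differ")
        v = self.values[self.valid_mask]
        if v.size and (not np.all(np.isfinite(v)) or (v < 0).any()):
            raise CalibrationError("valid ratio values must be finite and >= 0")

    @property
    def shape(self):
        return self.values.shape

    @property
    def unit(self) -> str:
        return "mmol·mol⁻¹" if self.calibrated else "intensity ratio"

    def valid_values(self) -> np.ndarray:
        return self.values[self.valid_mask]


@dataclass(frozen=True)
class CalibrationModel:
    """Linear intensity-ratio → molar-ratio conversion.

    ``k`` has units of mmol·mol⁻¹ per unit intensity ratio.
    """

    k: float = 1.0
    provenance: str = "identity (uncalibrated)"

    def __post_init__(self):
        if not self.k > 0:
            raise CalibrationError("calibration coefficient k must be > 0")


def make_otolith_mask(
    ca: ElementMap, background_quantile: float = 0.5, method: str = "otsu"
) -> np.ndarray:
    """Segment the otolith from the empty background on the Ca map.

    The Ca intensity distribution of a scan is bimodal: near-zero background
    counts versus high, near-uniform otolith counts. The default operator is
    an Otsu split; ``method="quantile"`` thresholds at the given quantile
    instead. The largest connected component above threshold is kept and its
    holes are filled.

    A degenerate (effectively constant) image has no background to separate;
    a full-frame mask is returned with a :class:`DegenerateInputWarning`.
    """
    v = ca.values
    if np.ptp(v) <= 0 or np.std(v) < 1e-12 * max(1.0, abs(float(np.mean(v)))):
        warnings.warn(
            "Ca image has no intensity contrast; using full-frame mask",
            DegenerateInputWarning,
            stacklevel=2,
        )
        return np.ones(v.shape, dtype=bool)
    if method == "otsu":
        thr = threshold_otsu(v)
    elif method == "quantile":
        thr = float(np.quantile(v, background_quantile))
    else:
        raise ValueError(f"unknown mask method '{method}' (use 'otsu' or 'quantile')")
    mask = v > thr
    frac = mask.mean()
    if frac < 1e-3 or frac > 1 - 1e-3:
        warnings.warn(
            "Ca intensity distribution looks unimodal; using full-frame mask",
            DegenerateInputWarning,
            stacklevel=2,
        )
        return np.ones(v.shape, dtype=bool)
    lab = cc_label(mask, connectivity=2)
    largest = np.argmax(np.bincount(lab.ravel())[1:]) + 1
    mask = lab == largest
    return ndimage.binary_fill_holes(mask)


def compute_ratio_map(
    sr: ElementMap, ca: ElementMap, mask: np.ndarray
) -> RatioMap:
    """Divide the Sr map by the Ca map pixel by pixel on the otolith mask.

    Pixels where Ca is exactly zero are removed from the valid mask rather
    than producing infinities. The result is uncalibrated (intensity ratio).
    """
    if sr.values.shape != ca.values.shape:
        raise CalibrationError(
            f"shape mismatch: Sr {sr.values.shape} vs Ca {ca.values.shape}"
        )
    if sr.pixel_size_um != ca.pixel_size_um:
        raise CalibrationError(
            f"pixel size mismatch: Sr {sr.pixel_size_um} vs Ca {ca.pixel_size_um} µm"
        )
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != ca.values.shape:
        raise CalibrationError("mask shape differs from the element maps")
    valid = mask & (ca.values > 0)
    values = np.zeros_like(ca.values)
    np.divide(sr.values, ca.values, out=values, where=valid)
    return RatioMap(
        values=values,
        valid_mask=valid,
        calibrated=False,
        pixel_size_um=ca.pixel_size_um,
        provenance="Sr/Ca intensity ratio",
    )


def calibrate(ratio: RatioMap, model: CalibrationModel) -> RatioMap:
    """Convert an intensity-ratio map to molar mmol·mol⁻¹ by multiplying by k.

    Calibrating an already-calibrated map is an error: the coefficient is
    not idempotent and silently stacking two would corrupt every threshold
    downstream.
    """
    if ratio.calibrated:
        raise CalibrationError("RatioMap is already calibrated")
    values = ratio.values * model.k
    values[~ratio.valid_mask] = 0.0
    return replace(
        ratio,
        values=values,
        calibrated=True,
        provenance=f"{ratio.provenance}; calibrated k={model.k:g} ({model.provenance})",
    )
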