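"""Per-zone Sr:Ca frequency distributions, summaries and marine patches.

Zones hold very different pixel counts, so all frequencies are normalized
per zone (count / valid pixels in the zone); a reporting view drops bins
below a frequency threshold (default 1%) while the raw histogram is always
retained. The mode is read from the binned frequency curve (centre of the
maximal bin, ties resolved to the lower bin); mean and max come from raw
pixel values.

Marine patches are 8-connected components of Z2 pixels above a marine
Sr:Ca threshold (default 6 mmol·mol⁻¹) — the signature of sea-water
residence inside an otherwise freshwater juvenile zone.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.measure import label as cc_label
from skimage.measure import regionprops

from .calibration import RatioMap
from .errors import SrcaMapError
from .zonation import Z1, Z2, Z3, ZoneLabelMap

__all__ = [
    "ZoneHistogram",
    "ZoneStats",
    "Patch",
    "PatchSet",
    "zone_histograms",
    "zone_summaries",
    "detect_patches",
    "granularity_index",
]

ZONES = (Z1, Z2, Z3)


@dataclass
class ZoneHistogram:
    """Raw area-normalized frequency histogram of one zone."""

    bin_edges: np.ndarray  # mmol·mol⁻¹, len nbins+1
    frequencies: np.ndarray  # sums to 1 over the zone (raw view)
    counts: np.ndarray
    area_px: int
    area_um2: float
    mode: float  # centre of maximal bin; NaN if empty
    mean: float  # from raw pixel values
    max: float

    @property
    def empty(self) -> bool:
        return self.area_px == 0

    def thresholded(self, frequency_threshold: float):
        """Reporting view: (bin_edges, frequencies) with small bins zeroed."""
        f = self.frequencies.copy()
        f[f < frequency_threshold] = 0.0
        return self.bin_edges, f


@dataclass
class ZoneStats:
    """Histograms and summaries for Z1..Z3 of one specimen."""

    zones: dict  # "Z1".."Z3" -> ZoneHistogram
    bin_width_mmolmol: float
    frequency_threshold: float = 0.01

    def __getitem__(self, key: str) -> ZoneHistogram:
        return self.zones[key]


@dataclass
class Patch:
    area_um2: float
    centroid_xz: tuple  # (x, z) pixel coordinates
    max_srca: float
    mean_srca: float


@dataclass
class PatchSet:
    """Marine-signature patches inside Z2."""

    patches: list
    marine_threshold_mmolmol: float
    min_patch_area_um2: float
    z2_marine_fraction: float  # computed before the area filter
    label_map: np.ndarray = field(default=None, compare=False)

    def __len__(self):
        return len(self.patches)

    @property
    def total_area_um2(self) -> float:
        return float(sum(p.area_um2 for p in self.patches))


def _common_edges(values: np.ndarray, bin_width: float) -> np.ndarray:
    top = float(values.max()) if values.size else bin_width
    nbins = max(int(np.ceil(top / bin_width)), 1)
    if nbins * bin_width <= top:  # max falls on an edge: keep it inside
        nbins += 1
    return np.arange(nbins + 1) * bin_width


def zone_histograms(
    ratio: RatioMap,
    zones: ZoneLabelMap,
    bin_width: float = 0.25,
    frequency_threshold: float = 0.01,
) -> ZoneStats:
    """Histogram the valid Sr:Ca values of each zone on a common bin grid.

    Bin edges are multiples of ``bin_width`` starting at 0, shared across
    zones so per-zone histograms add up (pixel-weighted) to the whole-otolith
    histogram. Frequencies are counts divided by the zone's valid pixel
    count. An empty zone yields an empty histogram with NaN summaries.
    """
    if bin_width <= 0:
        raise SrcaMapError("bin_width must be > 0")
    if ratio.values.shape != zones.labels.shape:
        raise SrcaMapError("ratio and zone maps have different shapes")
    edges = _common_edges(ratio.valid_values(), bin_width)
    centres = (edges[:-1] + edges[1:]) / 2.0
    px_area = ratio.pixel_size_um**2
    out = {}
    for zone in ZONES:
        sel = zones.zone_mask(zone) & ratio.valid_mask
        vals = ratio.values[sel]
        n = int(sel.sum())
        if n == 0:
            out[f"Z{zone}"] = ZoneHistogram(
                bin_edges=edges,
                frequencies=np.zeros(len(edges) - 1),
                counts=np.zeros(len(edges) - 1, dtype=np.int64),
                area_px=0,
                area_um2=0.0,
                mode=float("nan"),
                mean=float("nan"),
                max=float("nan"),
            )
            continue
        counts, _ = np.histogram(vals, bins=edges)
        freqs = counts / n
        mode = float(centres[int(np.argmax(freqs))])  # argmax ties -> lower bin
        out[f"Z{zone}"] = ZoneHistogram(
            bin_edges=edges,
            frequencies=freqs,
            counts=counts,
            area_px=n,
            area_um2=n * px_area,
            mode=mode,
            mean=float(vals.mean()),
            max=float(vals.max()),
        )
    return ZoneStats(
        zones=out, bin_width_mmolmol=bin_width, frequency_threshold=frequency_threshold
    )


def zone_summaries(stats: ZoneStats) -> dict:
    """(mode, mean, max) per zone; NaNs propagate for empty zones."""
    return {
        name: {"mode": h.mode, "mean": h.mean, "max": h.max}
        for name, h in stats.zones.items()
    }


def detect_patches(
    ratio: RatioMap,
    zones: ZoneLabelMap,
    marine_threshold: float = 6.0,
    min_patch_area_um2: float = 10.0,
) -> PatchSet:
    """Find marine-signature patches: above-threshold components of Z2.

    Components are 8-connected; those below ``min_patch_area_um2`` are
    dropped from the patch list (single-pixel speckle), but
    ``z2_marine_fraction`` — the fraction of valid Z2 area above threshold —
    is computed before that filter. Patches are sorted by area, largest
    first.
    """
    z2 = zones.zone_mask(Z2) & ratio.valid_mask
    above = z2 & (ratio.values > marine_threshold)
    n_z2 = int(z2.sum())
    fraction = float(above.sum() / n_z2) if n_z2 else 0.0
    px_area = ratio.pixel_size_um**2
    lab = cc_label(above, connectivity=2)
    patches = []
    for rp in regionprops(lab, intensity_image=ratio.values):
        area = rp.area * px_area
        if area < min_patch_area_um2:
            continue
        cz, cx = rp.centroid
        patches.append(
            Patch(
                area_um2=float(area),
                centroid_xz=(float(cx), float(cz)),
                max_srca=float(rp.intensity_max),
                mean_srca=float(rp.intensity_mean),
            )
        )
    patches.sort(key=lambda p: (-p.area_um2, p.centroid_xz))
    return PatchSet(
        patches=patches,
        marine_threshold_mmolmol=marine_threshold,
        min_patch_area_um2=min_patch_area_um2,
        z2_marine_fraction=fraction,
        label_map=lab,
    )


def granularity_index(
    ratio: RatioMap, zones: ZoneLabelMap, window_um: float = 5.0
) -> dict:
    """Median local coefficient of variation per zone.

    The local CV (stdev/mean over a square window of the stated physical
    width) quantifies granular texture; it is invariant to global rescaling
    of the map. Window must span at least 3 pixels.
    """
    w = int(round(window_um / ratio.pixel_size_um))
    if w < 3:
        raise SrcaMapError(
            f"granularity window {window_um} µm is under 3 px at "
            f"{ratio.pixel_size_um} µm/px"
        )
    valid = ratio.valid_mask.astype(float)
    v = np.where(ratio.valid_mask, ratio.values, 0.0)
    den = ndimage.uniform_filter(valid, size=w)
    m = np.zeros_like(v)
    np.divide(ndimage.uniform_filter(v, size=w), den, out=m, where=den > 0)
    m2 = np.zeros_like(v)
    np.divide(ndimage.uniform_filter(v * v, size=w), den, out=m2, where=den > 0)
    var = np.maximum(m2 - m * m, 0.0)
    cv = np.zeros_like(v)
    np.divide(np.sqrt(var), m, out=cv, where=m > 0)
    out = {}
    for zone in ZONES:
        sel = zones.zone_mask(zone) & ratio.valid_mask
        out[f"Z{zone}"] = float(np.median(cv[sel])) if sel.any() else float("nan")
    return out
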