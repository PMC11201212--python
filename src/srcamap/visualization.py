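"""False-colour rendering of Sr:Ca maps and the 3-3-2 RGB bit conversion.

Two renderings are produced. The first scales the molar ratio to 8-bit
indices against a cohort-wide maximum (so colours are comparable between
specimens) and applies a red→yellow→brown→cyan→slate-grey lookup table; the
background is anchored at the top index, mimicking the practice of painting
a few background pixels at the cohort maximum before applying the LUT. The
second is the 3-3-2 RGB conversion: the 8-bit index is bit-sliced into 3
red, 3 green and 2 blue bits, which turns small local value offsets into
abrupt colour changes and exposes granular texture and fine rings.

The exact published palette colours are not available; the default LUT is
a 5-anchor linear gradient approximating the named progression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .calibration import RatioMap
from .errors import SrcaMapError
from .zone_stats import ZoneStats

__all__ = [
    "ColourLUT",
    "default_lut",
    "normalize_for_display",
    "apply_lut",
    "convert_332_rgb",
    "render_map_png",
    "plot_zone_frequencies",
]

#: Anchor colours of the default palette, low Sr:Ca to high.
PALETTE_ANCHORS = (
    (170, 15, 15),    # red
    (235, 200, 40),   # yellow
    (130, 80, 30),    # brown
    (70, 200, 210),   # cyan
    (112, 128, 144),  # slate grey
)


@dataclass(frozen=True)
class ColourLUT:
    """A total mapping from 8-bit index to RGB, plus the normalization max."""

    table: np.ndarray  # (256, 3) uint8
    global_max_mmolmol: float

    def __post_init__(self):
        t = np.asarray(self.table)
        if t.shape != (256, 3):
            raise SrcaMapError("LUT table must have shape (256, 3)")
        if np.array_equal(t[0], t[255]):
            raise SrcaMapError("LUT endpoints must be distinct")


def default_lut(global_max_mmolmol: float) -> ColourLUT:
    """Linear interpolation through the 5 palette anchors."""
    anchors = np.asarray(PALETTE_ANCHORS, dtype=float)
    pos = np.linspace(0, 255, len(anchors))
    idx = np.arange(256)
    table = np.stack(
        [np.interp(idx, pos, anchors[:, c]) for c in range(3)], axis=1
    )
    return ColourLUT(
        table=np.round(table).astype(np.uint8),
        global_max_mmolmol=float(global_max_mmolmol),
    )


def normalize_for_display(ratio: RatioMap, global_max: float) -> np.ndarray:
    """Scale Sr:Ca values linearly onto 8-bit indices [0, 255].

    ``global_max`` is the cohort-wide maximum ratio: using the same value
    for every specimen makes their colours directly comparable. Values
    above it are clipped with a warning. Background (invalid) pixels are
    set to index 255, anchoring the background at the top of the scale.
    """
    if not global_max > 0:
        raise SrcaMapError("global_max must be > 0")
    vmax = float(ratio.valid_values().max()) if ratio.valid_mask.any() else 0.0
    if vmax > global_max:
        warnings.warn(
            f"map maximum {vmax:.3g} exceeds global_max {global_max:.3g}; clipping",
            stacklevel=2,
        )
    idx = np.clip(ratio.values / global_max, 0.0, 1.0) * 255.0
    out = np.round(idx).astype(np.uint8)
    out[~ratio.valid_mask] = 255
    return out


def apply_lut(index_raster: np.ndarray, lut: ColourLUT) -> np.ndarray:
    """Pure per-pixel table lookup; returns an (H, W, 3) uint8 image."""
    idx = np.asarray(index_raster)
    if idx.dtype != np.uint8:
        raise SrcaMapError("apply_lut expects an 8-bit index raster")
    return lut.table[idx]


def convert_332_rgb(index_raster: np.ndarray) -> np.ndarray:
    """3-3-2 RGB conversion of an 8-bit raster.

    For a value v: R = bits 7–5, G = bits 4–2, B = bits 1–0 (high bits to
    red, the Fiji convention). Channels are rescaled to the full 8-bit
    range (R, G × 255/7; B × 255/3) for visibility. Adjacent values differ
    in low-order bits only, so near-equal neighbours render smoothly while
    sustained granularity produces strong colour contrast.
    """
    idx = np.asarray(index_raster)
    if idx.dtype != np.uint8:
        raise SrcaMapError("convert_332_rgb expects an 8-bit index raster")
    r = (idx >> 5) & 0b111
    g = (idx >> 2) & 0b111
    b = idx & 0b11
    out = np.empty(idx.shape + (3,), dtype=np.uint8)
    out[..., 0] = np.round(r * (255.0 / 7.0)).astype(np.uint8)
    out[..., 1] = np.round(g * (255.0 / 7.0)).astype(np.uint8)
    out[..., 2] = np.round(b * (255.0 / 3.0)).astype(np.uint8)
    return out


def render_map_png(
    ratio: RatioMap,
    path,
    global_max: float | None = None,
    mode: str = "lut",
    scale_bar_um: float | None = 50.0,
) -> np.ndarray:
    """Render a ratio map to PNG and return the RGB array.

    ``mode``: "lut" for the false-colour palette, "332" for the 3-3-2 RGB
    conversion. An optional scale bar of the given physical length is burnt
    into the lower-left corner.
    """
    if global_max is None:
        global_max = float(ratio.valid_values().max())
    idx = normalize_for_display(ratio, global_max)
    if mode == "lut":
        rgb = apply_lut(idx, default_lut(global_max))
    elif mode == "332":
        rgb = convert_332_rgb(idx)
    else:
        raise SrcaMapError(f"unknown render mode '{mode}'")
    rgb = rgb.copy()
    if scale_bar_um:
        bar_px = int(round(scale_bar_um / ratio.pixel_size_um))
        h, w = rgb.shape[:2]
        y0 = max(h - 12, 0)
        x0 = 8
        if x0 + bar_px < w:
            rgb[y0 : min(y0 + 4, h), x0 : x0 + bar_px] = (255, 255, 255)
    plt.imsave(str(path), rgb)
    return rgb


def plot_zone_frequencies(stats: ZoneStats, path, title: str = "") -> None:
    """Area plot of per-zone normalized Sr:Ca frequencies above threshold."""
    fig, ax = plt.subplots(figsize=(6, 3.2))
    colours = {"Z1": "#c23b22", "Z2": "#e0a800", "Z3": "#2c7fb8"}
    for name, hist in stats.zones.items():
        if hist.empty:
            continue
        edges, freq = hist.thresholded(stats.frequency_threshold)
        centres = (edges[:-1] + edges[1:]) / 2.0
        ax.fill_between(centres, freq, step="mid", alpha=0.45, color=colours[name])
        ax.plot(centres, freq, drawstyle="steps-mid", color=colours[name], label=name)
    ax.set_xlabel("Sr:Ca (mmol·mol$^{-1}$)")
    ax.set_ylabel("normalized frequency")
    if title:
        ax.set_title(title)
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(str(path), dpi=120)
    plt.close(fig)
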