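"""Read/write elemental intensity rasters and export spatialized pixel values.

Rasters are single-channel TIFFs. 32-bit float is the native interchange
format: XRF count maps need the full dynamic range, and integer 8/16-bit
inputs are accepted only with a warning. Coordinates follow the image
convention used throughout the package: pixel (0, 0) at the top-left,
``x`` = column index, ``z`` = row index, both 0-based.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field

import numpy as np
import tifffile

from .errors import DynamicRangeWarning, RasterIOError

__all__ = [
    "ElementMap",
    "read_element_map",
    "write_element_map",
    "export_spatialized_csv",
]

#: Text of the comment line written at the top of spatialized CSV exports.
CSV_COORDINATE_NOTE = (
    "# coordinates: x = column, z = row, 0-based, origin at top-left pixel"
)


@dataclass
class ElementMap:
    """A single-element XRF intensity raster.

    Parameters
    ----------
    values : ndarray
        2D array of non-negative intensities (arbitrary counts), float64.
    element : str
        Element label, e.g. ``"Ca"`` or ``"Sr"``.
    pixel_size_um : float
        Physical edge length of one (square) pixel in micrometres.
    """

    values: np.ndarray
    element: str
    pixel_size_um: float
    source: str = field(default="", compare=False)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise RasterIOError(
                f"ElementMap expects a 2D array, got ndim={self.values.ndim}"
            )
        if not np.all(np.isfinite(self.values)):
            raise RasterIOError("ElementMap values must all be finite")
        if (self.values < 0).any():
            raise RasterIOError("ElementMap values must be non-negative")
        if not self.pixel_size_um > 0:
            raise RasterIOError("pixel_size_um must be > 0")

    @property
    def shape(self):
        return self.values.shape


def read_element_map(path, element: str, pixel_size_um: float) -> ElementMap:
    """Load a single-channel TIFF intensity map.

    Values are taken as stored, with no rescaling. Multi-channel images are
    rejected; integer images narrower than 32 bits load but emit a
    :class:`DynamicRangeWarning` because quantisation may have destroyed the
    high dynamic range the ratio analysis relies on.
    """
    path = str(path)
    try:
        arr = tifffile.imread(path)
    except Exception as exc:  # noqa: BLE001 - re-raise with file context
        raise RasterIOError(f"cannot read TIFF '{path}': {exc}") from exc
    if arr.ndim != 2:
        raise RasterIOError(
            f"expected single-channel raster in '{path}', got shape {arr.shape}"
        )
    if np.issubdtype(arr.dtype, np.integer) and arr.dtype.itemsize < 4:
        warnings.warn(
            f"'{path}' is {8 * arr.dtype.itemsize}-bit integer; "
            "32-bit dynamic range is not preserved",
            DynamicRangeWarning,
            stacklevel=2,
        )
    if (arr < 0).any():
        raise RasterIOError(f"negative intensities in '{path}'")
    return ElementMap(arr, element=element, pixel_size_um=pixel_size_um, source=path)


def write_element_map(emap: ElementMap, path) -> None:
    """Write an :class:`ElementMap` as a 32-bit float single-channel TIFF."""
    tifffile.imwrite(str(path), emap.values.astype(np.float32))


def export_spatialized_csv(ratio, zones, path) -> int:
    """Write one CSV row per non-background pixel: ``x,z,srca_mmolmol,zone``.

    ``ratio`` is a :class:`~srcamap.calibration.RatioMap` and ``zones`` a
    :class:`~srcamap.zonation.ZoneLabelMap` of the same shape. Pixels inside
    a zone but invalid in the ratio map (e.g. zero-Ca) are exported with an
    empty value field. Returns the number of data rows written.
    """
    if ratio.values.shape != zones.labels.shape:
        raise RasterIOError(
            f"shape mismatch: ratio {ratio.values.shape} vs zones {zones.labels.shape}"
        )
    zz, xx = np.nonzero(zones.labels > 0)
    order = np.lexsort((xx, zz))  # row-major, deterministic
    zz, xx = zz[order], xx[order]
    labels = zones.labels[zz, xx]
    valid = ratio.valid_mask[zz, xx]
    vals = ratio.values[zz, xx]
    with open(path, "w", newline="", encoding="utf-8") as fh:
        fh.write(CSV_COORDINATE_NOTE + "\n")
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["x", "z", "srca_mmolmol", "zone"])
        for x, z, v, ok, lab in zip(xx, zz, vals, valid, labels):
            writer.writerow(
                [int(x), int(z), repr(float(v)) if ok else "", f"Z{int(lab)}"]
            )
    return int(len(xx))
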