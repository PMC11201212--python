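"""Per-specimen and cohort orchestration of the full analysis workflow.

One specimen runs: otolith mask → Sr/Ca ratio → molar calibration → core →
zone segmentation → per-zone statistics → marine patches → life-history
call → renderings. A cohort runs in two passes so the display normalization
uses the cohort-wide maximum Sr:Ca (pass 1 streams per-specimen maxima,
pass 2 renders and classifies) — rendering parameters never reach the
classifier, so the call is invariant to display normalization.

Every run writes a machine-readable report (JSON, no timestamps) that is
byte-identical when re-run on the same inputs and config.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import __version__
from .calibration import CalibrationModel, calibrate, compute_ratio_map, make_otolith_mask
from .classification import ClassifierConfig, LifeHistoryCall, classify, classify_batch
from .errors import PipelineStageError, SrcaMapError
from .raster_io import export_spatialized_csv, read_element_map
from .visualization import plot_zone_frequencies, render_map_png
from .zonation import detect_core, segment_zones, zone_geometry
from .zone_stats import detect_patches, granularity_index, zone_histograms, zone_summaries

log = logging.getLogger("srcamap")

DEFAULT_CONFIG = {
    "calibration": {"k": 1.0, "provenance": "identity (uncalibrated)"},
    "mask": {"method": "otsu", "background_quantile": 0.5},
    "zonation": {
        "method": "radial",
        "n_zones": 3,
        "n_angles": 16,
        "smoothing_um": 2.5,
        "core": "auto",  # "auto" | "refine" | [x, z]
    },
    "stats": {
        "bin_width": 0.25,
        "frequency_threshold": 0.01,
        "marine_threshold": 6.0,
        "min_patch_area_um2": 10.0,
        "granularity_window_um": 5.0,
    },
    "classify": {
        "fw_upper": 4.0,
        "marine_lower": 6.0,
        "estuarine_z1": 5.0,
        "patch_fraction_min": 0.05,
    },
    "display": {"global_max": None, "scale_bar_um": 50.0},
    "pixel_size_um": 0.5,
}


def resolve_config(config=None) -> dict:
    """Merge a partial config (dict or YAML path) over the defaults."""
    merged = json.loads(json.dumps(DEFAULT_CONFIG))
    if config is None:
        return merged
    if isinstance(config, (str, Path)):
        with open(config, encoding="utf-8") as fh:
            config = yaml.safe_load(fh) or {}
    for section, values in config.items():
        if isinstance(values, dict) and isinstance(merged.get(section), dict):
            merged[section].update(values)
        else:
            merged[section] = values
    return merged


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True).encode("utf-8")
    ).hexdigest()[:16]


@dataclass
class SpecimenReport:
    """Machine-readable result of one specimen run."""

    specimen_id: str
    ca_path: str
    sr_path: str
    ratio_summary: dict
    zone_areas: dict
    zone_summaries: dict
    granularity: dict
    patches: dict
    call: LifeHistoryCall
    boundary_fractions: tuple
    core_xz: tuple
    config_hash: str
    version: str
    output_dir: str = field(default="", compare=False)

    def to_json(self) -> str:
        d = {
            "specimen_id": self.specimen_id,
            "inputs": {"ca": self.ca_path, "sr": self.sr_path},
            "ratio_summary": self.ratio_summary,
            "zone_areas": self.zone_areas,
            "zone_summaries": self.zone_summaries,
            "granularity": self.granularity,
            "patches": self.patches,
            "call": {
                "category": self.call.category,
                "estuarine_hatch": self.call.estuarine_hatch,
                "evidence": asdict(self.call.evidence),
                "config": asdict(self.call.config),
            },
            "boundary_fractions": list(self.boundary_fractions),
            "core_xz": list(self.core_xz),
            "provenance": {"config_hash": self.config_hash, "version": self.version},
        }
        return json.dumps(d, sort_keys=True, indent=1, allow_nan=True)


def _stage(name, fn, *args, **kwargs):
    t0 = time.perf_counter()
    try:
        out = fn(*args, **kwargs)
    except SrcaMapError as exc:
        raise PipelineStageError(name, exc) from exc
    log.info("stage %-12s done in %.2f s", name, time.perf_counter() - t0)
    return out


def run_specimen(
    ca_path,
    sr_path,
    config=None,
    output_dir=None,
    specimen_id: str = "specimen",
    global_max: float | None = None,
) -> SpecimenReport:
    """Run the full per-specimen workflow; optionally write artifacts.

    ``global_max`` overrides the display normalization maximum (used by
    cohort runs); it affects renderings only, never the classification.
    """
    cfg = resolve_config(config)
    px = float(cfg["pixel_size_um"])

    ca = _stage("raster_io", read_element_map, ca_path, "Ca", px)
    sr = _stage("raster_io", read_element_map, sr_path, "Sr", px)
    mask = _stage(
        "mask",
        make_otolith_mask,
        ca,
        background_quantile=cfg["mask"]["background_quantile"],
        method=cfg["mask"]["method"],
    )
    ratio_raw = _stage("ratio", compute_ratio_map, sr, ca, mask)
    model = CalibrationModel(
        k=float(cfg["calibration"]["k"]), provenance=cfg["calibration"]["provenance"]
    )
    ratio = _stage("calibrate", calibrate, ratio_raw, model)

    core_cfg = cfg["zonation"]["core"]
    if isinstance(core_cfg, (list, tuple)):
        (core, core_prov) = _stage("core", detect_core, ratio, override=tuple(core_cfg))
    else:
        (core, core_prov) = _stage(
            "core", detect_core, ratio, refine=(core_cfg == "refine")
        )
    zones = _stage(
        "segment",
        segment_zones,
        ratio,
        core,
        method=cfg["zonation"]["method"],
        n_zones=int(cfg["zonation"]["n_zones"]),
        n_angles=int(cfg["zonation"]["n_angles"]),
        smoothing_um=float(cfg["zonation"]["smoothing_um"]),
    )
    stats = _stage(
        "stats",
        zone_histograms,
        ratio,
        zones,
        bin_width=float(cfg["stats"]["bin_width"]),
        frequency_threshold=float(cfg["stats"]["frequency_threshold"]),
    )
    patches = _stage(
        "patches",
        detect_patches,
        ratio,
        zones,
        marine_threshold=float(cfg["stats"]["marine_threshold"]),
        min_patch_area_um2=float(cfg["stats"]["min_patch_area_um2"]),
    )
    grain = _stage(
        "granularity",
        granularity_index,
        ratio,
        zones,
        window_um=float(cfg["stats"]["granularity_window_um"]),
    )
    clf_cfg = ClassifierConfig(**cfg["classify"])
    call = _stage("classify", classify, stats, patches, clf_cfg)

    vv = ratio.valid_values()
    report = SpecimenReport(
        specimen_id=specimen_id,
        ca_path=str(ca_path),
        sr_path=str(sr_path),
        ratio_summary={
            "valid_px": int(ratio.valid_mask.sum()),
            "min": float(vv.min()),
            "max": float(vv.max()),
            "mean": float(vv.mean()),
            "unit": ratio.unit,
        },
        zone_areas=zone_geometry(zones, core),
        zone_summaries=zone_summaries(stats),
        granularity=grain,
        patches={
            "n_patches": len(patches),
            "total_area_um2": patches.total_area_um2,
            "z2_marine_fraction": patches.z2_marine_fraction,
            "marine_threshold_mmolmol": patches.marine_threshold_mmolmol,
        },
        call=call,
        boundary_fractions=zones.boundary_fractions,
        core_xz=(float(core[0]), float(core[1])),
        config_hash=config_hash(cfg),
        version=__version__,
    )

    if output_dir is not None:
        outdir = Path(output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        report.output_dir = str(outdir)
        (outdir / "report.json").write_text(report.to_json(), encoding="utf-8")
        (outdir / "config.yaml").write_text(yaml.safe_dump(cfg), encoding="utf-8")
        tifffile.imwrite(str(outdir / "zones.tif"), zones.labels)
        write_element_map_like(ratio, outdir / "ratio.tif")
        export_spatialized_csv(ratio, zones, outdir / "spatialized.csv")
        gmax = global_max or cfg["display"]["global_max"] or report.ratio_summary["max"]
        render_map_png(
            ratio,
            outdir / "srca_map.png",
            global_max=float(gmax),
            mode="lut",
            scale_bar_um=cfg["display"]["scale_bar_um"],
        )
        render_map_png(
            ratio,
            outdir / "srca_332rgb.png",
            global_max=float(gmax),
            mode="332",
            scale_bar_um=None,
        )
        plot_zone_frequencies(stats, outdir / "zone_frequencies.png", title=specimen_id)
    return report


def write_element_map_like(ratio, path):
    tifffile.imwrite(str(path), ratio.values.astype(np.float32))


def run_cohort(manifest, config=None, output_dir=None):
    """Two-pass cohort run: shared display maximum, then per-specimen runs.

    ``manifest`` is a CSV path or DataFrame with columns id, ca_path,
    sr_path (unique IDs). Returns (cohort table, category counts, reports).
    """
    if isinstance(manifest, (str, Path)):
        manifest = pd.read_csv(manifest)
    required = {"id", "ca_path", "sr_path"}
    if not required.issubset(manifest.columns):
        raise SrcaMapError(f"manifest must have columns {sorted(required)}")
    if len(manifest) == 0:
        raise SrcaMapError("manifest lists no specimens")
    ids = manifest["id"].astype(str).tolist()
    if len(set(ids)) != len(ids):
        raise SrcaMapError("duplicate specimen IDs in manifest")
    missing = [
        p
        for p in list(manifest["ca_path"]) + list(manifest["sr_path"])
        if not Path(p).exists()
    ]
    if missing:
        raise SrcaMapError(f"missing input files: {missing}")

    cfg = resolve_config(config)
    px = float(cfg["pixel_size_um"])
    # pass 1: streaming cohort-wide Sr:Ca maximum
    global_max = 0.0
    for _, row in manifest.iterrows():
        ca = read_element_map(row["ca_path"], "Ca", px)
        sr = read_element_map(row["sr_path"], "Sr", px)
        mask = make_otolith_mask(ca, method=cfg["mask"]["method"])
        ratio = calibrate(
            compute_ratio_map(sr, ca, mask),
            CalibrationModel(k=float(cfg["calibration"]["k"])),
        )
        vv = ratio.valid_values()
        if vv.size:
            global_max = max(global_max, float(vv.max()))
    log.info("cohort global max Sr:Ca = %.3g", global_max)

    # pass 2
    reports = []
    for _, row in manifest.iterrows():
        sid = str(row["id"])
        outdir = None if output_dir is None else Path(output_dir) / sid
        reports.append(
            run_specimen(
                row["ca_path"],
                row["sr_path"],
                config=cfg,
                output_dir=outdir,
                specimen_id=sid,
                global_max=global_max,
            )
        )
    table, counts = classify_batch(reports)
    table.attrs["global_max_mmolmol"] = global_max
    if output_dir is not None:
        Path(output_dir).mkdir(parents=True, exist_ok=True)
        table.to_csv(Path(output_dir) / "cohort.csv", index=False)
    return table, counts, reports
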