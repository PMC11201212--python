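"""Threshold-based life-history classification from per-zone evidence.

The ecological reading of the concentric zones: Z1 records hatching, Z2 the
juvenile growth phase (marine for amphidromous fish), Z3 adult freshwater
life. Sr:Ca thresholds follow the standard salinity proxy ranges — roughly
2–4 mmol·mol⁻¹ in freshwater, above 6 in estuarine/sea water — and are all
explicit and configurable.

Decision rules, applied in order:

1. ``amphidromous_classic``  — Z2 mode ≥ marine_lower and Z3 mode ≤ fw_upper
   (the juvenile zone is dominantly marine).
2. ``amphidromous_patchy``   — Z2 mode < marine_lower, but the marine patch
   fraction of Z2 is at least ``patch_fraction_min`` and Z3 mode ≤ fw_upper
   (marine passage recorded only in patches).
3. ``freshwater_resident``   — Z2 and Z3 modes ≤ fw_upper and the patch
   fraction is below ``patch_fraction_min``.
4. ``indeterminate``         — anything else (the classifier abstains).

Z1 never enters the main category: hatching can legitimately happen under
estuarine influence in an otherwise freshwater-resident fish, so an
elevated Z1 sets the ``estuarine_hatch`` flag rather than blocking the
resident call.

Independently of the category, ``estuarine_hatch`` is flagged when the Z1
maximum reaches ``estuarine_z1`` while the call is not classic — a hatching
phase under higher-salinity (estuarine) influence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .errors import ClassificationError
from .zone_stats import PatchSet, ZoneStats

__all__ = [
    "ClassifierConfig",
    "Evidence",
    "LifeHistoryCall",
    "classify",
    "classify_evidence",
    "classify_batch",
    "CATEGORIES",
]

CATEGORIES = (
    "amphidromous_classic",
    "amphidromous_patchy",
    "freshwater_resident",
    "indeterminate",
)


@dataclass(frozen=True)
class ClassifierConfig:
    """Sr:Ca thresholds (mmol·mol⁻¹) and the patch-fraction rule.

    ``patch_fraction_min`` has no published value; 0.05 requires a small but
    unmistakable marine-patch footprint before calling marine passage.
    """

    fw_upper: float = 4.0
    marine_lower: float = 6.0
    estuarine_z1: float = 5.0
    patch_fraction_min: float = 0.05

    def __post_init__(self):
        if not (0 < self.fw_upper <= self.estuarine_z1 <= self.marine_lower):
            raise ClassificationError(
                "thresholds must satisfy 0 < fw_upper <= estuarine_z1 <= marine_lower"
            )


@dataclass(frozen=True)
class Evidence:
    """The per-zone numbers the classifier sees (mmol·mol⁻¹, fraction)."""

    z1_mode: float
    z1_max: float
    z2_mode: float
    z2_mean: float
    z3_mode: float
    z2_marine_fraction: float


@dataclass(frozen=True)
class LifeHistoryCall:
    category: str
    estuarine_hatch: bool
    evidence: Evidence
    config: ClassifierConfig = field(default_factory=ClassifierConfig)


def _require(value: float, name: str) -> float:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        raise ClassificationError(f"cannot classify: {name} is missing")
    return value


def classify_evidence(ev: Evidence, cfg: ClassifierConfig = ClassifierConfig()) -> LifeHistoryCall:
    """Pure decision function: identical evidence + config ⇒ identical call."""
    z2_mode = _require(ev.z2_mode, "Z2 mode")
    z3_mode = _require(ev.z3_mode, "Z3 mode")
    frac = ev.z2_marine_fraction
    z1_max = ev.z1_max
    if z2_mode >= cfg.marine_lower and z3_mode <= cfg.fw_upper:
        category = "amphidromous_classic"
    elif (
        z2_mode < cfg.marine_lower
        and frac >= cfg.patch_fraction_min
        and z3_mode <= cfg.fw_upper
    ):
        category = "amphidromous_patchy"
    elif (
        z2_mode <= cfg.fw_upper
        and z3_mode <= cfg.fw_upper
        and frac < cfg.patch_fraction_min
    ):
        category = "freshwater_resident"
    else:
        category = "indeterminate"
    estuarine = (
        category != "amphidromous_classic"
        and not math.isnan(z1_max)
        and z1_max >= cfg.estuarine_z1
    )
    return LifeHistoryCall(
        category=category, estuarine_hatch=estuarine, evidence=ev, config=cfg
    )


def classify(
    stats: ZoneStats, patches: PatchSet, cfg: ClassifierConfig = ClassifierConfig()
) -> LifeHistoryCall:
    """Classify a specimen from its :class:`ZoneStats` and :class:`PatchSet`."""
    z1, z2, z3 = stats["Z1"], stats["Z2"], stats["Z3"]
    if z2.empty or z3.empty:
        raise ClassificationError("cannot classify: Z2 or Z3 is empty")
    ev = Evidence(
        z1_mode=z1.mode,
        z1_max=z1.max,
        z2_mode=z2.mode,
        z2_mean=z2.mean,
        z3_mode=z3.mode,
        z2_marine_fraction=patches.z2_marine_fraction,
    )
    return classify_evidence(ev, cfg)


def classify_batch(reports) -> tuple[pd.DataFrame, dict]:
    """Cohort table from per-specimen reports.

    ``reports`` is an iterable of objects (or mappings) carrying
    ``specimen_id`` and ``call``. Returns (table, category counts); the
    table has one row per specimen, ordered by ID. Duplicate IDs and empty
    input are errors.
    """
    rows = []
    for rep in reports:
        get = rep.get if isinstance(rep, dict) else lambda k, r=rep: getattr(r, k)
        sid = str(get("specimen_id"))
        call: LifeHistoryCall = get("call")
        rows.append(
            {
                "specimen_id": sid,
                "category": call.category,
                "estuarine_hatch": call.estuarine_hatch,
                "z1_max": call.evidence.z1_max,
                "z2_mode": call.evidence.z2_mode,
                "z3_mode": call.evidence.z3_mode,
                "z2_marine_fraction": call.evidence.z2_marine_fraction,
            }
        )
    if not rows:
        raise ClassificationError("classify_batch needs at least one report")
    ids = [r["specimen_id"] for r in rows]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ClassificationError(f"duplicate specimen IDs: {dupes}")
    table = pd.DataFrame(rows).sort_values("specimen_id").reset_index(drop=True)
    counts = {c: int((table["category"] == c).sum()) for c in CATEGORIES}
    return table, counts
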