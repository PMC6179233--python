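"""Probability x precision combination maps and zonal area accounting.

Within the footprint of each probability threshold (low / moderate /
high), the CoV surface is classed into terciles — empirical 1/3 and 2/3
quantiles of the CoV values inside that footprint — giving cumulative
precision cutoffs: high precision keeps only cells at or below the first
tercile, moderate at or below the second, low keeps the entire footprint
(cutoff = the footprint maximum).  Crossing three probability levels with
three precision levels yields nine presence/absence maps, whose areas are
then accounted inside and outside management-zone polygons.

A grid cell belongs to a zone iff its centre falls inside the polygon;
zones must not overlap, so inside areas plus the outside remainder sum
exactly to each map's total.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grids import GridSurface, ZoneSet, require_aligned

logger = logging.getLogger(__name__)

__all__ = [
    "PrecisionClassing",
    "ComboMap",
    "precision_terciles",
    "combo_maps",
    "zonal_area",
    "sensitivity_report",
    "PROBABILITY_LEVELS",
    "PRECISION_LEVELS",
]

PROBABILITY_LEVELS = ("low", "moderate", "high")
PRECISION_LEVELS = ("low", "moderate", "high")


@dataclass
class PrecisionClassing:
    """Cumulative CoV cutoffs inside one probability footprint."""

    probability_threshold: float
    q33: float
    q67: float
    max: float

    def __post_init__(self) -> None:
        if not self.q33 <= self.q67 <= self.max:
            raise ValueError("tercile breakpoints must be ordered q33 <= q67 <= max")

    def cutoff(self, precision_level: str) -> float:
        return {"high": self.q33, "moderate": self.q67, "low": self.max}[precision_level]


@dataclass
class ComboMap:
    """One of the nine probability x precision presence masks."""

    probability_level: str
    precision_level: str
    probability_threshold: float
    cov_cutoff: float
    mask: GridSurface  # 1 presence, 0 absence, NaN nodata
    area_m2: float

    @property
    def name(self) -> str:
        return f"p_{self.probability_level}_prec_{self.precision_level}"


def precision_terciles(cov: GridSurface, footprint: GridSurface) -> PrecisionClassing:
    """Tercile breakpoints of CoV values inside a probability footprint.

    Quantiles use linear interpolation of order statistics (position
    1 + (n-1)p); the third cutoff is the footprint maximum, so the
    low-precision class reproduces the footprint exactly.
    """
    require_aligned(cov, footprint)
    inside = (footprint.values == 1) & cov.mask
    vals = cov.values[inside]
    if vals.size == 0:
        raise ValueError("footprint is empty (or CoV is nodata everywhere inside it)")
    q33, q67 = np.quantile(vals, [1 / 3, 2 / 3])
    return PrecisionClassing(
        probability_threshold=np.nan, q33=float(q33), q67=float(q67), max=float(vals.max())
    )


def combo_maps(
    prob: GridSurface,
    cov: GridSurface,
    prob_thresholds: tuple[float, float, float],
) -> list[ComboMap]:
    """The nine presence maps from three probability thresholds x terciles.

    ``prob_thresholds`` is (low, moderate, high), ordered ascending;
    footprints are ``prob >= t`` and precision cutoffs are computed within
    each footprint separately.
    """
    require_aligned(prob, cov)
    t_low, t_mod, t_high = prob_thresholds
    if not t_low <= t_mod <= t_high:
        raise ValueError("probability thresholds must be ordered low <= moderate <= high")
    out: list[ComboMap] = []
    cell_area = prob.cell_area
    for level, t in zip(PROBABILITY_LEVELS, (t_low, t_mod, t_high)):
        foot_vals = np.where(prob.values >= t, 1.0, 0.0)
        foot_vals[~prob.mask] = np.nan
        footprint = prob.like(foot_vals)
        if np.nansum(foot_vals) == 0:
            logger.warning("probability level %r (t=%.3g): empty footprint", level, t)
            for plevel in PRECISION_LEVELS:
                out.append(
                    ComboMap(level, plevel, t, np.nan, footprint.copy(), 0.0)
                )
            continue
        classing = precision_terciles(cov, footprint)
        classing.probability_threshold = t
        for plevel in PRECISION_LEVELS:
            cutoff = classing.cutoff(plevel)
            mask_vals = np.where(
                (foot_vals == 1) & (cov.values <= cutoff), 1.0, 0.0
            )
            mask_vals[~prob.mask] = np.nan
            area = float(np.nansum(mask_vals) * cell_area)
            out.append(ComboMap(level, plevel, t, cutoff, prob.like(mask_vals), area))
    return out


def zonal_area(combo: ComboMap, zones: ZoneSet, cell_size: float | None = None) -> pd.DataFrame:
    """Predicted-presence area inside each zone and outside all zones.

    Returns one row per zone plus an ``outside`` row, with columns
    ``combo, zone_id, zone_type, area_m2``.  Zones must not overlap.
    """
    zones.check_non_overlapping()
    grid = combo.mask
    if cell_size is not None and not np.isclose(cell_size, grid.cell_size):
        raise ValueError("cell_size disagrees with the mask's cell size")
    cell_area = grid.cell_area
    present = combo.mask.values == 1
    membership = zones.contains_centers(grid)
    rows = []
    claimed = np.zeros(grid.shape, dtype=bool)
    for z in zones:
        inside = membership[z.zone_id]
        claimed |= inside
        rows.append(
            {
                "combo": combo.name,
                "zone_id": z.zone_id,
                "zone_type": z.zone_type,
                "area_m2": float(np.sum(present & inside) * cell_area),
            }
        )
    rows.append(
        {
            "combo": combo.name,
            "zone_id": "outside",
            "zone_type": "outside",
            "area_m2": float(np.sum(present & ~claimed) * cell_area),
        }
    )
    return pd.DataFrame(rows)


def sensitivity_report(reports: list[pd.DataFrame], combos: list[ComboMap]) -> dict:
    """Summaries across the nine combination maps.

    Emits total area per combo, inside/outside splits per zone type, the
    number of zones with any predicted presence per combo, and pairwise
    area ratios between combos (e.g. the low/low map against the
    high/high map).
    """
    if len(reports) != len(combos):
        raise ValueError("one zonal report per combo map is required")
    per_combo: dict[str, dict] = {}
    for combo, rep in zip(combos, reports):
        inside = rep[rep.zone_id != "outside"]
        by_type = inside.groupby("zone_type")["area_m2"].sum().to_dict()
        per_combo[combo.name] = {
            "probability_level": combo.probability_level,
            "precision_level": combo.precision_level,
            "total_area_m2": float(rep.area_m2.sum()),
            "inside_area_m2": float(inside.area_m2.sum()),
            "outside_area_m2": float(rep.loc[rep.zone_id == "outside", "area_m2"].sum()),
            "area_by_zone_type_m2": {k: float(v) for k, v in by_type.items()},
            "zones_with_presence": int((inside.area_m2 > 0).sum()),
        }
    totals = {name: d["total_area_m2"] for name, d in per_combo.items()}
    ratios = {}
    names = list(totals)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            if totals[b] > 0:
                ratios[f"{a}/{b}"] = totals[a] / totals[b]
    return {"per_combo": per_combo, "area_ratios": ratios}
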