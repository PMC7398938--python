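"""Suitability classification, class-area tabulation, and the change /
vulnerability indicators.

The consensus probability surface is cut into four classes — 0 not
suitable, 1 low, 2 moderate, 3 high — at breaks (b1, b2, b3), default
(0.25, 0.5, 0.75): class 0 for values <= b1, 1 for (b1, b2], 2 for
(b2, b3], 3 above b3.  Class shares are percentages of valid cells,
optionally cell-area weighted (cos-latitude approximation to geodesic
cell area).

Two indicators compare a class's current share Ac with its future share
Af under a scenario/horizon:

    AC = (Af - Ac) / Ac x 100     (change relative to the current area)
    CH = (Af - Ac) / Af x 100     (gain or loss relative to the future area)

Both share the sign of Af - Ac and satisfy AC * Ac = CH * Af exactly.
Reported values are rounded to one decimal, half away from zero.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError, NumericError
from .grids import Grid

CLASS_NAMES = ("not_suitable", "low", "moderate", "high")
DEFAULT_BREAKS = (0.25, 0.5, 0.75)


def round1(x: float) -> float:
    """Round to 1 decimal, halves away from zero (table convention)."""
    return float(Decimal(repr(float(x))).quantize(Decimal("0.1"),
                                                  rounding=ROUND_HALF_UP))


@dataclass
class SuitabilityClassGrid:
    grid: Grid  # codes 0..3 as floats, NaN nodata
    class_breaks: tuple


@dataclass
class SuitabilitySummary:
    """Percent of (optionally area-weighted) valid cells in each class."""

    percents: dict  # class name -> percent, sums to 100
    scenario: str = "current"
    area_ha: dict | None = None

    def as_tuple(self) -> tuple:
        return tuple(self.percents[c] for c in CLASS_NAMES)


@dataclass
class ChangeReport:
    """AC and CH per class per future scenario, raw and rounded."""

    current: SuitabilitySummary
    rows: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "current": self.current.percents,
            "rows": self.rows,
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def classify_suitability(surface: Grid,
                         breaks: tuple = DEFAULT_BREAKS) -> SuitabilityClassGrid:
    """Cut a probability surface into the four suitability classes."""
    b1, b2, b3 = breaks
    if not (0.0 < b1 < b2 < b3 < 1.0):
        raise ConfigError(f"breaks must satisfy 0 < b1 < b2 < b3 < 1, "
                          f"got {breaks}")
    v = surface.values
    codes = np.full(surface.shape, np.nan)
    m = surface.mask
    codes[m] = np.digitize(v[m], [b1, b2, b3], right=True)
    return SuitabilityClassGrid(grid=surface.with_values(codes),
                                class_breaks=tuple(breaks))


def class_percentages(classes: SuitabilityClassGrid,
                      cell_area_weighted: bool = False,
                      scenario: str = "current") -> SuitabilitySummary:
    """Share of each class among valid cells, summing to 100."""
    g = classes.grid
    m = g.mask
    if not m.any():
        raise DataError("class grid has no valid cells")
    if cell_area_weighted:
        _, lat = g.cell_centers()
        w = np.cos(np.radians(lat))
        # geodesic cell area (cos-latitude approx), km^2 -> hectares
        cell_km = 111.19492664455873 * g.cell_size  # mean-radius arc length
        area = w * cell_km * cell_km * 100.0
    else:
        w = np.ones(g.shape)
        area = None
    codes = g.values
    totals = np.array([float(w[m & (codes == k)].sum()) for k in range(4)])
    percents = 100.0 * totals / totals.sum()
    summary = SuitabilitySummary(
        percents=dict(zip(CLASS_NAMES, percents)), scenario=scenario)
    if area is not None:
        summary.area_ha = {c: float(area[m & (codes == k)].sum())
                           for k, c in enumerate(CLASS_NAMES)}
    return summary


def change_indicator_CH(Ac: float, Af: float) -> float:
    """Gain/loss relative to the future area: (Af - Ac) / Af x 100."""
    if Af <= 0:
        raise NumericError("CH undefined for non-positive future area Af")
    return (Af - Ac) / Af * 100.0


def change_indicator_AC(Ac: float, Af: float) -> float:
    """Change relative to the current area: (Af - Ac) / Ac x 100."""
    if Ac <= 0:
        raise NumericError("AC undefined for non-positive current area Ac")
    return (Af - Ac) / Ac * 100.0


def change_report(current: SuitabilitySummary,
                  futures: list[SuitabilitySummary]) -> ChangeReport:
    """AC/CH for every class x future scenario, with the internal
    consistency check AC*Ac = CH*Af."""
    report = ChangeReport(current=current)
    for fut in futures:
        for cname in CLASS_NAMES:
            ac_cur = current.percents[cname]
            af = fut.percents[cname]
            row = {"scenario": fut.scenario, "class": cname,
                   "Ac": ac_cur, "Af": af,
                   "CH": None, "AC": None, "CH_raw": None, "AC_raw": None}
            if af > 0:
                row["CH_raw"] = change_indicator_CH(ac_cur, af)
                row["CH"] = round1(row["CH_raw"])
            if ac_cur > 0:
                row["AC_raw"] = change_indicator_AC(ac_cur, af)
                row["AC"] = round1(row["AC_raw"])
            if row["CH_raw"] is not None and row["AC_raw"] is not None:
                lhs = row["AC_raw"] * ac_cur
                rhs = row["CH_raw"] * af
                if abs(lhs - rhs) > 1e-9 * max(1.0, abs(lhs)):
                    raise NumericError(
                        f"indicator identity violated for {cname}: "
                        f"AC*Ac={lhs} vs CH*Af={rhs}")
            report.rows.append(row)
    return report


def zonal_summary(classes: SuitabilityClassGrid, zones) -> dict:
    """Per-zone class percentages and dominant-class risk label.

    ``zones`` is either an integer zone-mask :class:`Grid` (NaN outside
    all zones) or a mapping of zone name to shapely polygon; polygons are
    evaluated against cell centres.  Zones without valid cells are
    flagged and excluded from the summaries.
    """
    g = classes.grid
    if isinstance(zones, Grid):
        g.require_same_geometry(zones)
        zvals = zones.values
        zone_ids = sorted(int(z) for z in np.unique(zvals[~np.isnan(zvals)]))
        membership = {f"zone_{z}": (zvals == z) for z in zone_ids}
    else:
        from shapely import contains_xy

        lon, lat = g.cell_centers()
        membership = {name: contains_xy(poly, lon, lat)
                      for name, poly in zones.items()}
    out = {"zones": {}, "empty_zones": []}
    for name, member in membership.items():
        sel = member & g.mask
        if not sel.any():
            out["empty_zones"].append(name)
            continue
        codes = g.values[sel]
        counts = np.array([(codes == k).sum() for k in range(4)], dtype=float)
        percents = 100.0 * counts / counts.sum()
        label = CLASS_NAMES[int(np.argmax(counts))]
        out["zones"][name] = {
            "percents": dict(zip(CLASS_NAMES, percents)),
            "n_cells": int(sel.sum()),
            "risk_label": label,
        }
    if not out["zones"]:
        raise DataError("no zone overlaps the class grid")
    return out
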