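"""Predictor stacks, point-value extraction, and collinearity filtering.

Collinearity among candidate predictors is screened with variance
inflation factors: VIF_j = 1/(1 - R2_j), with R2_j from an ordinary
least-squares regression (with intercept) of predictor j on all other
continuous predictors.  Screening is stepwise: while any VIF exceeds the
threshold (default 3), the single worst predictor is removed and VIFs
are recomputed.  Categorical layers (land cover) never enter the VIF
computation and are always retained.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError
from .grids import Grid

META_COLUMNS = ["id", "label", "partition"]


@dataclass
class PredictorStack:
    """Ordered, geometry-aligned set of named predictor layers."""

    names: list
    grids: list
    kinds: list  # "continuous" | "categorical", parallel to names

    def __post_init__(self) -> None:
        if not (len(self.names) == len(self.grids) == len(self.kinds)):
            raise ConfigError("names, grids and kinds must be parallel lists")
        if len(set(self.names)) != len(self.names):
            raise ConfigError("layer names must be unique")
        for k in self.kinds:
            if k not in ("continuous", "categorical"):
                raise ConfigError(f"unknown layer kind {k!r}")
        for g in self.grids[1:]:
            self.grids[0].require_same_geometry(g)

    @property
    def domain(self) -> Grid:
        """Valid-data intersection of all layers, as a 0/1 grid."""
        mask = np.ones(self.grids[0].shape, dtype=bool)
        for g in self.grids:
            mask &= g.mask
        vals = np.where(mask, 1.0, np.nan)
        return self.grids[0].with_values(vals)

    def continuous_names(self) -> list:
        return [n for n, k in zip(self.names, self.kinds)
                if k == "continuous"]

    def categorical_names(self) -> list:
        return [n for n, k in zip(self.names, self.kinds)
                if k == "categorical"]

    def layer(self, name: str) -> Grid:
        return self.grids[self.names.index(name)]

    def subset(self, names: list) -> "PredictorStack":
        keep = [self.names.index(n) for n in names]
        return PredictorStack([self.names[i] for i in keep],
                              [self.grids[i] for i in keep],
                              [self.kinds[i] for i in keep])


@dataclass
class VifReport:
    """Trace of the stepwise VIF screen."""

    threshold: float
    iterations: list = field(default_factory=list)  # {removed, vif_values}
    selected: list = field(default_factory=list)
    categorical_retained: list = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "threshold": self.threshold,
            "iterations": [
                {"removed": it["removed"],
                 "vif_values": {k: (None if np.isinf(v) else float(v))
                                for k, v in it["vif_values"].items()}}
                for it in self.iterations
            ],
            "selected": list(self.selected),
            "categorical_retained": list(self.categorical_retained),
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def extract_values(stack: PredictorStack, points: pd.DataFrame):
    """Feature table: one row per point, one column per layer.

    Each point takes the value of the cell containing it.  Points outside
    the grid or hitting nodata in any layer are dropped; returns
    ``(table, dropped)`` with dropped counts by reason.
    """
    g0 = stack.grids[0]
    lon = points["lon"].to_numpy(dtype=float)
    lat = points["lat"].to_numpy(dtype=float)
    inside = g0.contains(lon, lat)
    dropped = {"out_of_bounds": int((~inside).sum()), "nodata": 0}
    pts = points.loc[inside].reset_index(drop=True)
    r, c = g0.locate(pts["lon"].to_numpy(), pts["lat"].to_numpy())
    cols = {}
    valid = np.ones(len(pts), dtype=bool)
    for name, grid in zip(stack.names, stack.grids):
        v = grid.values[r, c]
        valid &= ~np.isnan(v)
        cols[name] = v
    dropped["nodata"] = int((~valid).sum())
    meta = {k: pts[k].to_numpy() for k in META_COLUMNS if k in pts}
    table = pd.DataFrame({**meta, **cols}).loc[valid].reset_index(drop=True)
    if table.empty:
        raise DataError("no points with complete predictor values remain")
    return table, dropped


def feature_columns(table: pd.DataFrame) -> list:
    return [c for c in table.columns if c not in META_COLUMNS]


def compute_vif(table: pd.DataFrame, variables: list) -> dict:
    """Variance inflation factor of each listed variable.

    VIF_j = 1 / (1 - R2_j) with R2_j the coefficient of determination of
    an OLS fit (with intercept) of variable j on the other listed
    variables.  Perfect collinearity is reported as +inf.
    """
    if len(variables) < 2:
        raise ConfigError("VIF needs at least 2 variables")
    X = table[list(variables)].to_numpy(dtype=float)
    n = X.shape[0]
    if n < len(variables) + 2:
        raise DataError(
            f"{n} rows is too few for VIF over {len(variables)} variables")
    sds = X.std(axis=0)
    for name, sd in zip(variables, sds):
        if sd == 0:
            raise DataError(f"variable {name!r} is constant")
    out = {}
    for j, name in enumerate(variables):
        y = X[:, j]
        others = np.delete(X, j, axis=1)
        A = np.column_stack([np.ones(n), others])
        beta, *_ = np.linalg.lstsq(A, y, rcond=None)
        resid = y - A @ beta
        ss_res = float(resid @ resid)
        ss_tot = float(((y - y.mean()) ** 2).sum())
        r2 = 1.0 - ss_res / ss_tot
        if r2 >= 1.0 - 1e-12:
            out[name] = np.inf
        else:
            out[name] = 1.0 / (1.0 - r2)
    return out


def stepwise_vif_select(table: pd.DataFrame, threshold: float = 3.0,
                        continuous: list | None = None,
                        categorical: list | None = None) -> VifReport:
    """Iteratively drop the worst-VIF variable until all VIFs <= threshold.

    Ties are broken by earliest column order.  With fewer than two
    continuous variables remaining the screen terminates with everything
    retained.  Categorical variables bypass the screen entirely.
    """
    if threshold <= 1:
        raise ConfigError("threshold must exceed 1")
    if continuous is None:
        continuous = feature_columns(table)
        if categorical:
            continuous = [c for c in continuous if c not in categorical]
    categorical = list(categorical or [])
    remaining = list(continuous)
    report = VifReport(threshold=threshold,
                       categorical_retained=categorical)
    while len(remaining) >= 2:
        vifs = compute_vif(table, remaining)
        worst = max(remaining, key=lambda v: (vifs[v],))  # earliest-first ties
        if vifs[worst] > threshold:
            report.iterations.append({"removed": worst, "vif_values": vifs})
            remaining.remove(worst)
        else:
            report.iterations.append({"removed": None, "vif_values": vifs})
            break
    report.selected = remaining
    return report
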