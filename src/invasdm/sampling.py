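"""Occurrence handling: cleaning, pseudo-absence generation, 70/30 split.

Occurrence tables are pandas DataFrames with columns
``id, lon, lat, label, partition`` where label is 1 for presences and 0
for pseudo-absences and partition is one of train/test/unassigned.

Pseudo-absences are background points drawn uniformly from valid cells
of the study domain, subject to a great-circle exclusion buffer around
every presence (default 10 km) so that cells immediately around known
occurrences are never treated as absences.  Distances use the haversine
formula on the WGS84 mean-radius sphere.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import CapacityError, ConfigError, DataError
from .grids import Grid, haversine_km

OCCURRENCE_COLUMNS = ["id", "lon", "lat", "label", "partition"]


def _as_occurrences(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    if "partition" not in out:
        out["partition"] = "unassigned"
    if "id" not in out:
        out["id"] = [f"r{i}" for i in range(len(out))]
    missing = [c for c in OCCURRENCE_COLUMNS if c not in out]
    if missing:
        raise DataError(f"occurrence table missing columns {missing}")
    bad_lon = (out["lon"] < -180) | (out["lon"] > 180)
    bad_lat = (out["lat"] < -90) | (out["lat"] > 90)
    if bad_lon.any() or bad_lat.any():
        raise DataError("coordinates outside WGS84 bounds")
    if not out["label"].isin([0, 1]).all():
        raise DataError("labels must be 0 (pseudo-absence) or 1 (presence)")
    return out[OCCURRENCE_COLUMNS]


def clean_occurrences(raw: pd.DataFrame, domain: Grid):
    """Drop duplicate and unusable records.

    Collapses exact (lon, lat, label) duplicates to their first record,
    drops records outside the domain grid and records falling on nodata
    cells.  Returns ``(cleaned, dropped)`` where dropped is a dict of
    counts by reason: duplicate / out_of_bounds / nodata.
    """
    occ = _as_occurrences(raw)
    dropped = {"duplicate": 0, "out_of_bounds": 0, "nodata": 0}

    dup = occ.duplicated(subset=["lon", "lat", "label"], keep="first")
    dropped["duplicate"] = int(dup.sum())
    occ = occ[~dup]

    inside = domain.contains(occ["lon"].to_numpy(), occ["lat"].to_numpy())
    dropped["out_of_bounds"] = int((~inside).sum())
    occ = occ[inside]

    if len(occ):
        r, c = domain.locate(occ["lon"].to_numpy(), occ["lat"].to_numpy())
        valid = domain.mask[r, c]
        dropped["nodata"] = int((~valid).sum())
        occ = occ[valid]

    if occ.empty:
        raise DataError("no occurrence records survived cleaning")
    return occ.reset_index(drop=True), dropped


def _eligible_cells(domain: Grid, presences: pd.DataFrame,
                    min_distance_km: float) -> np.ndarray:
    """Flat indices of valid cells >= min_distance_km from every presence."""
    rr, cc = np.meshgrid(np.arange(domain.rows), np.arange(domain.cols),
                         indexing="ij")
    lon, lat = domain.cell_center(rr.ravel(), cc.ravel())
    ok = domain.mask.ravel().copy()
    plon = presences["lon"].to_numpy()
    plat = presences["lat"].to_numpy()
    # chunk over presences to bound memory on big grids
    for start in range(0, len(plon), 256):
        pl = plon[start:start + 256]
        pa = plat[start:start + 256]
        d = haversine_km(lon[:, None], lat[:, None], pl[None, :], pa[None, :])
        ok &= (d >= min_distance_km).all(axis=1)
    # the cell containing a presence is never an absence, even at buffer 0
    pr, pc = domain.locate(plon, plat)
    inb = (pr >= 0) & (pr < domain.rows) & (pc >= 0) & (pc < domain.cols)
    ok[pr[inb] * domain.cols + pc[inb]] = False
    return np.flatnonzero(ok)


def generate_pseudo_absences(domain: Grid, presences: pd.DataFrame, n: int,
                             min_distance_km: float = 10.0, seed: int = 0,
                             mode: str = "generation") -> pd.DataFrame:
    """Sample ``n`` background points respecting the presence buffer.

    mode="generation" (default): rejection-sample batches of valid cells
    (oversampling factor 10, at most 100 batches) and keep those beyond
    the buffer until ``n`` distinct cells are collected.
    mode="posthoc": draw ``n`` cells first, then remove the ones inside
    the buffer — may therefore return fewer than ``n`` points.

    Both modes sample cells without replacement, uniformly over valid
    cells, and are deterministic per seed.  A :class:`CapacityError`
    reporting the eligible-cell count is raised when fewer than ``n``
    cells can ever satisfy the buffer (generation mode only).
    """
    if n < 1:
        raise ConfigError("n must be >= 1")
    if min_distance_km < 0:
        raise ConfigError("min_distance_km must be non-negative")
    if mode not in ("generation", "posthoc"):
        raise ConfigError(f"unknown pseudo-absence mode {mode!r}")
    pres = _as_occurrences(presences)
    pres = pres[pres["label"] == 1]
    valid_idx = np.flatnonzero(domain.mask.ravel())
    if valid_idx.size == 0:
        raise CapacityError("domain has no valid cells", eligible=0)
    rng = np.random.default_rng(seed)
    plon = pres["lon"].to_numpy()
    plat = pres["lat"].to_numpy()

    def far_enough(idx: np.ndarray) -> np.ndarray:
        rows, cols = np.unravel_index(idx, domain.shape)
        lon, lat = domain.cell_center(rows, cols)
        d = haversine_km(lon[:, None], lat[:, None],
                         plon[None, :], plat[None, :])
        ok = (d >= min_distance_km).all(axis=1)
        if min_distance_km == 0:  # still exclude the presence cells
            pr, pc = domain.locate(plon, plat)
            pres_cells = set((pr * domain.cols + pc).tolist())
            ok &= np.array([i not in pres_cells for i in idx])
        return ok

    if mode == "posthoc":
        take = min(n, valid_idx.size)
        drawn = rng.choice(valid_idx, size=take, replace=False)
        kept = drawn[far_enough(drawn)]
        return _cells_to_occurrences(domain, kept)

    chosen: list[int] = []
    seen: set[int] = set()
    for _ in range(100):
        batch = rng.choice(valid_idx, size=min(10 * n, valid_idx.size),
                           replace=False)
        batch = batch[far_enough(batch)]
        for i in batch.tolist():
            if i not in seen:
                seen.add(i)
                chosen.append(i)
                if len(chosen) == n:
                    return _cells_to_occurrences(domain, np.array(chosen))
    eligible = _eligible_cells(domain, pres, min_distance_km)
    raise CapacityError(
        f"requested {n} pseudo-absences but only {eligible.size} cells lie "
        f">= {min_distance_km} km from all presences",
        eligible=int(eligible.size))


def _cells_to_occurrences(domain: Grid, idx: np.ndarray) -> pd.DataFrame:
    rows, cols = np.unravel_index(idx.astype(int), domain.shape)
    lon, lat = domain.cell_center(rows, cols)
    return pd.DataFrame({
        "id": [f"a{i}" for i in range(len(idx))],
        "lon": lon, "lat": lat, "label": 0, "partition": "unassigned",
    })


def split_train_test(data: pd.DataFrame, train_fraction: float = 0.7,
                     seed: int = 0) -> pd.DataFrame:
    """Stratified random train/test partition.

    Within each label, round(train_fraction * count) records go to train
    (round-half-up) and the rest to test, so label proportions are
    preserved to within one record.  Deterministic per seed.
    """
    if not 0 < train_fraction < 1:
        raise ConfigError("train_fraction must be in (0, 1)")
    occ = _as_occurrences(data)
    labels = sorted(occ["label"].unique())
    if len(labels) < 2:
        raise DataError("both labels are required for a stratified split")
    rng = np.random.default_rng(seed)
    out = occ.copy()
    for lab in labels:
        pos = np.flatnonzero((occ["label"] == lab).to_numpy())
        if pos.size < 2:
            raise DataError(
                f"label {lab} has {pos.size} record(s); need >= 2 to place "
                "one in each partition")
        n_train = int(np.floor(train_fraction * pos.size + 0.5))
        n_train = min(max(n_train, 1), pos.size - 1)  # both sides non-empty
        perm = rng.permutation(pos)
        out.iloc[perm[:n_train], out.columns.get_loc("partition")] = "train"
        out.iloc[perm[n_train:], out.columns.get_loc("partition")] = "test"
    return out
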