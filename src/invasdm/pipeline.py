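"""End-to-end orchestration: simulate -> prepare -> select-vars -> fit ->
evaluate -> ensemble -> classify -> change -> zones.

A run lives in a single directory.  Every stage reads its inputs from
and writes its outputs to that directory, so stages can be run one at a
time (the CLI exposes each) or all at once with :func:`run_pipeline`,
which also writes a manifest recording every parameter, seed and
artifact checksum.  Reruns with identical config produce byte-identical
numeric artifacts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .change import (DEFAULT_BREAKS, change_report, class_percentages,
                     classify_suitability, zonal_summary)
from .errors import InvasdmError
from .evaluation import (build_ensemble, evaluate_model, evaluation_table,
                         variable_importance)
from .grids import Grid, read_ascii_grid, write_ascii_grid
from .models import (ALGORITHMS, ModelSpec, fit_model, load_model,
                     predict_surface, save_model)
from .predictors import (PredictorStack, VifReport, extract_values,
                         stepwise_vif_select)
from .sampling import (clean_occurrences, generate_pseudo_absences,
                       split_train_test)
from .synthetic import VirtualSpeciesConfig, simulate_virtual_species

SCENARIOS = ("RCP4.5-2050", "RCP8.5-2050", "RCP4.5-2070", "RCP8.5-2070")


@dataclass
class RunConfig:
    """All pipeline parameters.

    Defaults follow the reference protocol: 500 pseudo-absences with a
    10 km exclusion buffer, a stratified 70/30 train/test split, VIF
    threshold 3, TSS consensus gate 0.75 and quartile class breaks.
    """

    species: VirtualSpeciesConfig = field(
        default_factory=VirtualSpeciesConfig)
    n_pseudo_absences: int = 500
    min_distance_km: float = 10.0
    pa_mode: str = "generation"
    train_fraction: float = 0.7
    vif_threshold: float = 3.0
    algorithms: tuple = ALGORITHMS
    tss_gate: float = 0.75
    tss_weighted: bool = False
    class_breaks: tuple = DEFAULT_BREAKS
    cell_area_weighted: bool = False
    seed: int = 0
    version: str = __version__

    def validate(self) -> None:
        from .errors import ConfigError

        if self.n_pseudo_absences < 1:
            raise ConfigError("n_pseudo_absences must be positive")
        if self.min_distance_km < 0:
            raise ConfigError("min_distance_km must be non-negative")
        if not 0 < self.train_fraction < 1:
            raise ConfigError("train_fraction must be in (0, 1)")
        if self.vif_threshold <= 1:
            raise ConfigError("vif_threshold must exceed 1")
        unknown = [a for a in self.algorithms if a not in ALGORITHMS]
        if unknown:
            raise ConfigError(f"unknown algorithm(s) {unknown}")
        b1, b2, b3 = self.class_breaks
        if not (0 < b1 < b2 < b3 < 1):
            raise ConfigError("class_breaks must be strictly increasing "
                              "within (0, 1)")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["species"] = dataclasses.asdict(self.species)
        d["algorithms"] = list(self.algorithms)
        d["class_breaks"] = list(self.class_breaks)
        d["species"]["coefficients"] = list(self.species.coefficients)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        sp = d.pop("species", {})
        cfg = cls(species=VirtualSpeciesConfig(**sp), **{
            k: v for k, v in d.items() if k != "version"})
        cfg.algorithms = tuple(cfg.algorithms)
        cfg.class_breaks = tuple(cfg.class_breaks)
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(),
                                             sort_keys=True))


class PipelineError(InvasdmError):
    """Stage failure wrapper: remembers which stage broke."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


# ---------------------------------------------------------------------------
# run-directory helpers

def _p(rundir, *parts) -> Path:
    path = Path(rundir).joinpath(*parts)
    path.parent.mkdir(parents=True, exist_ok=True)
    return path


def _load_stack(rundir, scenario: str | None, selected: list | None = None
                ) -> PredictorStack:
    """Predictor stack from inputs/ (current) or inputs/future/<tag>/."""
    rundir = Path(rundir)
    meta = json.loads((rundir / "inputs" / "layers.json").read_text())
    names, kinds, grids = [], [], []
    for name, kind in zip(meta["names"], meta["kinds"]):
        if selected is not None and name not in selected:
            continue
        if kind == "categorical" or scenario is None:
            path = rundir / "inputs" / f"{name}.asc"
        else:
            path = rundir / "inputs" / "future" / scenario / f"{name}.asc"
        names.append(name)
        kinds.append(kind)
        grids.append(read_ascii_grid(path))
    return PredictorStack(names, grids, kinds)


def _selected_variables(rundir) -> tuple[list, list]:
    rep = json.loads((Path(rundir) / "vif_report.json").read_text())
    return rep["selected"], rep["categorical_retained"]


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# stages

def stage_simulate(config: RunConfig, rundir) -> None:
    """Generate the virtual-species inputs into <rundir>/inputs/."""
    sim = simulate_virtual_species(config.species)
    inputs = _p(rundir, "inputs", "layers.json")
    names = sim["names"] + ["landcover"]
    kinds = sim["kinds"] + ["categorical"]
    inputs.write_text(json.dumps({"names": names, "kinds": kinds},
                                 indent=2))
    for name, grid in zip(sim["names"], sim["covariates"]):
        write_ascii_grid(grid, _p(rundir, "inputs", f"{name}.asc"))
    write_ascii_grid(sim["landcover"], _p(rundir, "inputs", "landcover.asc"))
    write_ascii_grid(sim["truth"], _p(rundir, "inputs", "truth.asc"))
    _write_csv(sim["presences"], _p(rundir, "inputs", "presences.csv"))
    for tag, grids in sim["future"].items():
        for name, grid in zip(sim["names"], grids):
            write_ascii_grid(grid, _p(rundir, "inputs", "future", tag,
                                      f"{name}.asc"))
    write_ascii_grid(_default_zone_mask(sim["landcover"]),
                     _p(rundir, "inputs", "zones.asc"))


def _default_zone_mask(template: Grid) -> Grid:
    """Three rectangular 'protected areas' spanning the suitability
    gradient, used when no real zone polygons exist."""
    rows, cols = template.shape
    z = np.full(template.shape, np.nan)
    r4, c4 = rows // 4, cols // 4
    z[r4 // 2:r4 // 2 + r4, c4 // 2:c4 // 2 + c4] = 1
    z[2 * r4:3 * r4, 2 * c4:3 * c4] = 2
    z[r4 // 2:r4 // 2 + r4, 2 * c4 + c4 // 2:3 * c4 + c4 // 2] = 3
    return template.with_values(z)


def stage_prepare(config: RunConfig, rundir) -> pd.DataFrame:
    """Clean presences, add pseudo-absences, split, extract features."""
    rundir = Path(rundir)
    stack = _load_stack(rundir, scenario=None)
    domain = stack.domain
    presences = pd.read_csv(rundir / "inputs" / "presences.csv")
    presences, dropped = clean_occurrences(presences, domain)
    absences = generate_pseudo_absences(
        domain, presences, config.n_pseudo_absences,
        config.min_distance_km, seed=config.seed + 1, mode=config.pa_mode)
    occ = pd.concat([presences, absences], ignore_index=True)
    occ = split_train_test(occ, config.train_fraction, seed=config.seed + 2)
    _write_csv(occ, _p(rundir, "occurrences.csv"))
    table, extract_dropped = extract_values(stack, occ)
    _write_csv(table, _p(rundir, "features.csv"))
    _p(rundir, "prepare_log.json").write_text(json.dumps(
        {"cleaning_dropped": dropped, "extract_dropped": extract_dropped,
         "n_presences": int((occ["label"] == 1).sum()),
         "n_pseudo_absences": int((occ["label"] == 0).sum())}, indent=2))
    return table


def stage_select_vars(config: RunConfig, rundir) -> VifReport:
    rundir = Path(rundir)
    table = pd.read_csv(rundir / "features.csv")
    meta = json.loads((rundir / "inputs" / "layers.json").read_text())
    categorical = [n for n, k in zip(meta["names"], meta["kinds"])
                   if k == "categorical"]
    continuous = [n for n, k in zip(meta["names"], meta["kinds"])
                  if k == "continuous"]
    report = stepwise_vif_select(table, config.vif_threshold,
                                 continuous=continuous,
                                 categorical=categorical)
    report.to_json(_p(rundir, "vif_report.json"))
    return report


def stage_fit(config: RunConfig, rundir) -> dict:
    rundir = Path(rundir)
    table = pd.read_csv(rundir / "features.csv")
    selected, categorical = _selected_variables(rundir)
    keep = ["id", "label", "partition"] + selected + categorical
    train = table.loc[table["partition"] == "train", keep]
    fitted = {}
    for alg in config.algorithms:
        spec = ModelSpec(algorithm_id=alg, seed=config.seed + 3)
        model = fit_model(spec, train, categorical=categorical)
        fitted[alg] = model
        save_model(model, _p(rundir, "models", f"{alg}.joblib"))
    return fitted


def _load_models(config: RunConfig, rundir) -> dict:
    return {alg: load_model(Path(rundir) / "models" / f"{alg}.joblib")
            for alg in config.algorithms}


def stage_evaluate(config: RunConfig, rundir, fitted: dict | None = None
                   ) -> pd.DataFrame:
    rundir = Path(rundir)
    fitted = fitted or _load_models(config, rundir)
    table = pd.read_csv(rundir / "features.csv")
    test = table[table["partition"] == "test"]
    labels = test["label"].to_numpy()
    results = [evaluate_model(alg, fitted[alg].predict(test), labels)
               for alg in config.algorithms]
    ev = evaluation_table(results)
    _write_csv(ev, _p(rundir, "evaluation.csv"))
    imp = variable_importance(list(fitted.values()), test,
                              seed=config.seed + 4)
    _p(rundir, "variable_importance.json").write_text(
        json.dumps({k: round(v, 6) for k, v in imp.items()}, indent=2))
    return ev


def stage_ensemble(config: RunConfig, rundir, fitted: dict | None = None
                   ) -> None:
    """Member surfaces for every scenario and the TSS-gated consensus."""
    rundir = Path(rundir)
    fitted = fitted or _load_models(config, rundir)
    selected, categorical = _selected_variables(rundir)
    test = pd.read_csv(rundir / "features.csv")
    test = test[test["partition"] == "test"]
    evals = {alg: evaluate_model(alg, fitted[alg].predict(test),
                                 test["label"].to_numpy())
             for alg in config.algorithms}
    layer_names = selected + categorical
    member_ids = None
    for scenario in (None,) + tuple(SCENARIOS):
        tag = scenario or "current"
        stack = _load_stack(rundir, scenario, selected=layer_names)
        surfaces = {alg: predict_surface(fitted[alg], stack)
                    for alg in config.algorithms}
        for alg, surf in surfaces.items():
            write_ascii_grid(surf, _p(rundir, "model_surfaces",
                                      f"{alg}_{tag}.asc"))
        ens = build_ensemble(surfaces, evals, tss_gate=config.tss_gate,
                             tss_weighted=config.tss_weighted)
        if member_ids is None:
            member_ids = ens.member_ids
            _p(rundir, "ensemble_members.json").write_text(json.dumps(
                {"members": ens.member_ids,
                 "member_tss": {k: round(v, 6)
                                for k, v in ens.member_tss.items()},
                 "excluded": ens.excluded}, indent=2))
        write_ascii_grid(ens.surface, _p(rundir, f"ensemble_{tag}.asc"))


def stage_classify(config: RunConfig, rundir) -> None:
    rundir = Path(rundir)
    for tag in ("current",) + tuple(SCENARIOS):
        surface = read_ascii_grid(rundir / f"ensemble_{tag}.asc")
        classes = classify_suitability(surface, config.class_breaks)
        write_ascii_grid(classes.grid, _p(rundir, "class_grids",
                                          f"{tag}.asc"))


def stage_change(config: RunConfig, rundir) -> None:
    rundir = Path(rundir)
    summaries = {}
    for tag in ("current",) + tuple(SCENARIOS):
        grid = read_ascii_grid(rundir / "class_grids" / f"{tag}.asc")
        from .change import SuitabilityClassGrid

        scg = SuitabilityClassGrid(grid=grid,
                                   class_breaks=config.class_breaks)
        summaries[tag] = class_percentages(
            scg, cell_area_weighted=config.cell_area_weighted, scenario=tag)
    report = change_report(summaries["current"],
                           [summaries[t] for t in SCENARIOS])
    report.to_json(_p(rundir, "change_report.json"))
    _write_csv(report.to_frame(), _p(rundir, "change_report.csv"))


def stage_zones(config: RunConfig, rundir) -> None:
    rundir = Path(rundir)
    from .change import SuitabilityClassGrid

    grid = read_ascii_grid(rundir / "class_grids" / "current.asc")
    zones = read_ascii_grid(rundir / "inputs" / "zones.asc")
    scg = SuitabilityClassGrid(grid=grid, class_breaks=config.class_breaks)
    out = zonal_summary(scg, zones)
    _p(rundir, "zonal_report.json").write_text(json.dumps(out, indent=2))


# ---------------------------------------------------------------------------

STAGES = ("simulate", "prepare", "select-vars", "fit", "evaluate",
          "ensemble", "classify", "change", "zones")

#: artifact name -> glob patterns relative to the run directory
ARTIFACTS = {
    "occurrences": ["occurrences.csv"],
    "features": ["features.csv"],
    "vif_report": ["vif_report.json"],
    "evaluation": ["evaluation.csv", "variable_importance.json"],
    "model_surfaces": ["model_surfaces/*.asc"],
    "ensemble_surfaces": ["ensemble_*.asc", "ensemble_members.json"],
    "class_grids": ["class_grids/*.asc"],
    "change_report": ["change_report.json", "change_report.csv"],
    "zonal_report": ["zonal_report.json"],
}


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_manifest(config: RunConfig, rundir) -> dict:
    rundir = Path(rundir)
    artifacts = []
    for name, patterns in ARTIFACTS.items():
        files = sorted(str(f.relative_to(rundir))
                       for pat in patterns for f in rundir.glob(pat))
        artifacts.append({
            "name": name,
            "files": {f: _sha256(rundir / f) for f in files},
        })
    inputs = sorted(str(f.relative_to(rundir))
                    for f in rundir.glob("inputs/**/*") if f.is_file())
    manifest = {
        "version": __version__,
        "config": config.to_dict(),
        "input_checksums": {f: _sha256(rundir / f) for f in inputs},
        "artifacts": artifacts,
    }
    _p(rundir, "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def run_pipeline(config: RunConfig, rundir) -> dict:
    """Run every stage in order; halt on the first failure with its
    stage name (partial artifacts are retained).  Returns the manifest."""
    config.validate()
    rundir = Path(rundir)
    rundir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(rundir / "config.yml")
    state: dict = {}
    plan = [
        ("simulate", lambda: stage_simulate(config, rundir)),
        ("prepare", lambda: stage_prepare(config, rundir)),
        ("select-vars", lambda: stage_select_vars(config, rundir)),
        ("fit", lambda: state.update(fitted=stage_fit(config, rundir))),
        ("evaluate", lambda: stage_evaluate(config, rundir,
                                            state.get("fitted"))),
        ("ensemble", lambda: stage_ensemble(config, rundir,
                                            state.get("fitted"))),
        ("classify", lambda: stage_classify(config, rundir)),
        ("change", lambda: stage_change(config, rundir)),
        ("zones", lambda: stage_zones(config, rundir)),
    ]
    for name, fn in plan:
        try:
            fn()
        except InvasdmError as exc:
            raise PipelineError(name, exc) from exc
    return write_manifest(config, rundir)
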