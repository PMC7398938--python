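"""Model evaluation (AUC, TSS), the TSS-gated consensus, and
permutation variable importance.

AUC is the probability that a randomly chosen presence outscores a
randomly chosen absence (ties count half) — computed by midranks,
equivalent to exhaustive pair counting.  TSS = sensitivity +
specificity - 1 at a threshold; the threshold is chosen by scanning all
distinct score values and maximizing TSS (smallest threshold on ties).
The consensus surface is the unweighted cellwise mean of the member
surfaces whose TSS exceeds the gate (default 0.75); members at or below
the gate are excluded and reported.  An optional TSS-weighted mean is
available but off by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import ConfigError, DataError, GateError
from .grids import Grid
from .models import FittedModel
from .predictors import feature_columns


@dataclass
class EvaluationResult:
    algorithm_id: str
    auc: float
    threshold: float
    sensitivity: float
    specificity: float
    tss: float
    performance_band: str


@dataclass
class EnsembleResult:
    member_ids: list
    member_tss: dict
    surface: Grid
    excluded: dict = field(default_factory=dict)  # id -> reason


def _check_labels(labels: np.ndarray) -> tuple[int, int]:
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise DataError("AUC/TSS need both presences and absences")
    return n_pos, n_neg


def compute_auc(scores, labels) -> float:
    """Rank-based (Mann-Whitney) AUC with midrank tie handling."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    n_pos, n_neg = _check_labels(labels)
    ranks = rankdata(scores)  # midranks
    rank_sum_pos = ranks[labels == 1].sum()
    u = rank_sum_pos - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def select_threshold_max_tss(scores, labels):
    """Threshold maximizing TSS; classify positive when score >= threshold.

    All distinct score values are candidate thresholds; ties in TSS are
    broken toward the smallest threshold.  Returns
    (threshold, sensitivity, specificity, tss).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    n_pos, n_neg = _check_labels(labels)
    thresholds = np.unique(scores)  # ascending
    # At threshold t: predicted positive <=> score >= t
    ge = scores[None, :] >= thresholds[:, None]
    tp = (ge & (labels == 1)[None, :]).sum(axis=1)
    fp = (ge & (labels == 0)[None, :]).sum(axis=1)
    sens = tp / n_pos
    spec = 1.0 - fp / n_neg
    tss = sens + spec - 1.0
    best = int(np.argmax(tss))  # argmax -> first (smallest) on ties
    return (float(thresholds[best]), float(sens[best]), float(spec[best]),
            float(tss[best]))


def performance_band(auc: float) -> str:
    """AUC performance class: >0.9 high, (0.7, 0.9] moderate,
    (0.5, 0.7] low, <=0.5 no better than random."""
    if not 0.0 <= auc <= 1.0:
        raise ConfigError(f"AUC {auc} outside [0, 1]")
    if auc > 0.9:
        return "high"
    if auc > 0.7:
        return "moderate"
    if auc > 0.5:
        return "low"
    return "random"


def evaluate_model(algorithm_id: str, scores, labels) -> EvaluationResult:
    """Full threshold-independent + threshold-dependent evaluation."""
    auc = compute_auc(scores, labels)
    thr, sens, spec, tss = select_threshold_max_tss(scores, labels)
    return EvaluationResult(algorithm_id=algorithm_id, auc=auc,
                            threshold=thr, sensitivity=sens,
                            specificity=spec, tss=tss,
                            performance_band=performance_band(auc))


def evaluation_table(results: list[EvaluationResult]) -> pd.DataFrame:
    return pd.DataFrame([{
        "algorithm": r.algorithm_id, "auc": r.auc, "threshold": r.threshold,
        "sensitivity": r.sensitivity, "specificity": r.specificity,
        "tss": r.tss, "band": r.performance_band,
    } for r in results])


def build_ensemble(surfaces: dict, evals: dict, tss_gate: float = 0.75,
                   tss_weighted: bool = False) -> EnsembleResult:
    """Consensus surface: mean of member surfaces with TSS > gate."""
    if not surfaces:
        raise DataError("no member surfaces supplied")
    ids = list(surfaces)
    ref = surfaces[ids[0]]
    for i in ids[1:]:
        ref.require_same_geometry(surfaces[i])
    member_tss = {i: evals[i].tss for i in ids}
    members = [i for i in ids if member_tss[i] > tss_gate]
    excluded = {i: f"tss {member_tss[i]:.3f} <= gate {tss_gate}"
                for i in ids if i not in members}
    if not members:
        raise GateError(
            f"no model passed the TSS gate {tss_gate} "
            f"(member TSS: { {k: round(v, 3) for k, v in member_tss.items()} })")
    stackvals = np.stack([surfaces[i].values for i in members])
    if tss_weighted:
        w = np.array([member_tss[i] for i in members], dtype=float)
        mean = np.tensordot(w / w.sum(), stackvals, axes=1)
    else:
        mean = stackvals.mean(axis=0)
    return EnsembleResult(member_ids=members,
                          member_tss={i: member_tss[i] for i in members},
                          surface=ref.with_values(mean), excluded=excluded)


def variable_importance(models: list[FittedModel], test: pd.DataFrame,
                        seed: int = 0, n_permutations: int = 10) -> dict:
    """Permutation importance as mean relative contribution (percent).

    Per model and variable: importance = max(0, AUC_original - mean AUC
    over ``n_permutations`` shuffles of that variable's column);
    per-model importances are normalized to sum to 100, then averaged
    across models and renormalized.  Variables the response does not
    depend on therefore score near zero.
    """
    if not models:
        raise ConfigError("need at least one model")
    labels = test["label"].to_numpy()
    _check_labels(labels)
    variables = feature_columns(test)
    rng = np.random.default_rng(seed)
    per_model = []
    for model in models:
        auc0 = compute_auc(model.predict(test), labels)
        drops = {}
        for var in variables:
            aucs = []
            for _ in range(n_permutations):
                shuffled = test.copy()
                shuffled[var] = rng.permutation(shuffled[var].to_numpy())
                aucs.append(compute_auc(model.predict(shuffled), labels))
            drops[var] = max(0.0, auc0 - float(np.mean(aucs)))
        total = sum(drops.values())
        if total == 0:  # uninformative model: flat profile
            per_model.append({v: 100.0 / len(variables) for v in variables})
        else:
            per_model.append({v: 100.0 * d / total
                              for v, d in drops.items()})
    mean_imp = {v: float(np.mean([m[v] for m in per_model]))
                for v in variables}
    total = sum(mean_imp.values())
    return {v: 100.0 * x / total for v, x in mean_imp.items()}
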