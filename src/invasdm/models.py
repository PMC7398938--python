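"""The five suitability learners and their prediction surfaces.

All learners consume the same feature table (presence=1 /
pseudo-absence=0 labels, one column per selected predictor) and emit a
probability of presence in [0, 1]:

* GLM  — binomial logistic regression, linear terms, no penalty.
* SVM  — RBF-kernel support vector classifier with Platt-calibrated
         probabilities, on standardized features.
* RF   — random forest, 500 trees.
* BRT  — gradient-boosted trees, learning rate 0.01, depth 3, early
         stopping on a 20% holdout of the training rows.
* MARS — piecewise-linear hinge-basis logistic model fitted by greedy
         forward basis selection (an adaptive regression-spline
         surrogate on the logit scale).

Categorical predictors (land cover) are one-hot encoded for every
learner; encoding categories are frozen at fit time.  Fits are
deterministic given the spec seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .errors import ConfigError, DataError
from .grids import Grid
from .predictors import META_COLUMNS, PredictorStack, feature_columns

ALGORITHMS = ("GLM", "SVM", "RF", "BRT", "MARS")


@dataclass
class ModelSpec:
    algorithm_id: str
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.algorithm_id not in ALGORITHMS:
            raise ConfigError(
                f"unknown algorithm {self.algorithm_id!r}; "
                f"expected one of {ALGORITHMS}")


class HingeLogisticMARS:
    """Adaptive piecewise-linear logistic model.

    Candidate basis functions are reflected hinge pairs
    ``max(0, x - t), max(0, t - x)`` with knots at training-data
    quantiles of each feature.  Pairs are added greedily — each step
    refits the logistic model with every remaining candidate pair and
    keeps the pair with the largest deviance reduction — until
    ``max_terms`` basis functions are reached or the best reduction
    falls below ``min_improvement`` per observation.
    """

    def __init__(self, n_knots: int = 5, max_terms: int = 21,
                 min_improvement: float = 1e-4):
        self.n_knots = n_knots
        self.max_terms = max_terms
        self.min_improvement = min_improvement

    @staticmethod
    def _hinges(x: np.ndarray, knot: float) -> np.ndarray:
        return np.column_stack([np.maximum(0.0, x - knot),
                                np.maximum(0.0, knot - x)])

    def _candidates(self, X: np.ndarray):
        qs = np.linspace(0.1, 0.9, self.n_knots)
        cands = []
        for j in range(X.shape[1]):
            for t in np.quantile(X[:, j], qs):
                if (X[:, j] > t).any() and (X[:, j] < t).any():
                    cands.append((j, float(t)))
        # dedupe identical (feature, knot) pairs from ties in quantiles
        return sorted(set(cands))

    @staticmethod
    def _deviance(model, H: np.ndarray, y: np.ndarray) -> float:
        p = np.clip(model.predict_proba(H)[:, 1], 1e-12, 1 - 1e-12)
        return -2.0 * float(y @ np.log(p) + (1 - y) @ np.log(1 - p))

    def fit(self, X: np.ndarray, y: np.ndarray) -> "HingeLogisticMARS":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        n = len(y)

        def fit_lr(H):
            lr = LogisticRegression(C=np.inf, max_iter=1000,
                                    solver="lbfgs")
            lr.fit(H, y)
            return lr

        self.terms_: list[tuple[int, float]] = []
        H = np.zeros((n, 0))
        base = np.full(n, y.mean())
        base = np.clip(base, 1e-12, 1 - 1e-12)
        current_dev = -2.0 * float(y @ np.log(base)
                                   + (1 - y) @ np.log(1 - base))
        remaining = self._candidates(X)
        while remaining and H.shape[1] < self.max_terms:
            best = None
            for cand in remaining:
                j, t = cand
                Htry = np.hstack([H, self._hinges(X[:, j], t)])
                lr = fit_lr(Htry)
                dev = self._deviance(lr, Htry, y)
                if best is None or dev < best[0]:
                    best = (dev, cand, lr)
            dev, cand, lr = best
            if current_dev - dev < self.min_improvement * n:
                break
            j, t = cand
            H = np.hstack([H, self._hinges(X[:, j], t)])
            self.terms_.append(cand)
            self.model_ = lr
            current_dev = dev
            remaining.remove(cand)
        if not self.terms_:  # no useful split: intercept-only fallback
            self.model_ = fit_lr(np.ones((n, 1)))
            self.terms_ = []
        return self

    def _design(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if not self.terms_:
            return np.ones((X.shape[0], 1))
        return np.hstack([self._hinges(X[:, j], t) for j, t in self.terms_])

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return self.model_.predict_proba(self._design(X))


@dataclass
class FittedModel:
    """A trained learner plus everything needed to reproduce its inputs."""

    spec: ModelSpec
    feature_names: list
    categorical_levels: dict  # name -> sorted training categories
    estimator: object
    n_train: int = 0

    def encode(self, table: pd.DataFrame) -> np.ndarray:
        """Design matrix in training column order (one-hot categoricals)."""
        missing = [v for v in self.feature_names if v not in table.columns]
        if missing:
            raise DataError(f"feature table lacks variable(s) {missing}")
        blocks = []
        for name in self.feature_names:
            col = table[name].to_numpy(dtype=float)
            if name in self.categorical_levels:
                levels = self.categorical_levels[name]
                blocks.append(np.column_stack(
                    [(col == lv).astype(float) for lv in levels]))
            else:
                blocks.append(col[:, None])
        return np.hstack(blocks)

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        """Probability of presence for each row, clipped to [0, 1]."""
        X = self.encode(table)
        p = self.estimator.predict_proba(X)[:, 1]
        return np.clip(p, 0.0, 1.0)


def _build_estimator(spec: ModelSpec):
    hp = dict(spec.hyperparameters)
    seed = spec.seed
    if spec.algorithm_id == "GLM":
        return make_pipeline(StandardScaler(), LogisticRegression(
            C=np.inf, max_iter=hp.pop("max_iter", 1000)))
    if spec.algorithm_id == "SVM":
        svc = SVC(kernel="rbf", random_state=seed,
                  C=hp.pop("C", 1.0), gamma=hp.pop("gamma", "scale"))
        return make_pipeline(StandardScaler(), CalibratedClassifierCV(
            svc, method="sigmoid", ensemble=False, cv=5))
    if spec.algorithm_id == "RF":
        return RandomForestClassifier(
            n_estimators=hp.pop("n_estimators", 500), random_state=seed,
            n_jobs=1)
    if spec.algorithm_id == "BRT":
        return GradientBoostingClassifier(
            learning_rate=hp.pop("learning_rate", 0.01),
            max_depth=hp.pop("max_depth", 3),
            n_estimators=hp.pop("n_estimators", 1000),
            validation_fraction=0.2, n_iter_no_change=20,
            random_state=seed)
    if spec.algorithm_id == "MARS":
        return HingeLogisticMARS(
            n_knots=hp.pop("n_knots", 5),
            max_terms=hp.pop("max_terms", 21))
    raise ConfigError(f"unknown algorithm {spec.algorithm_id!r}")


def fit_model(spec: ModelSpec, train: pd.DataFrame,
              categorical: list | None = None) -> FittedModel:
    """Fit one learner on the training feature table."""
    y = train["label"].to_numpy(dtype=int)
    if len(np.unique(y)) < 2:
        raise DataError("training data contains a single class")
    names = feature_columns(train)
    categorical = [c for c in (categorical or []) if c in names]
    levels = {c: sorted(pd.unique(train[c])) for c in categorical}
    model = FittedModel(spec=spec, feature_names=names,
                        categorical_levels=levels, estimator=None,
                        n_train=len(train))
    X = model.encode(train)
    est = _build_estimator(spec)
    est.fit(X, y)
    model.estimator = est
    return model


def predict_surface(model: FittedModel, stack: PredictorStack) -> Grid:
    """Per-cell probability surface; nodata in any layer propagates."""
    missing = [v for v in model.feature_names if v not in stack.names]
    if missing:
        raise DataError(f"predictor stack lacks layer(s) {missing}")
    domain = stack.domain
    mask = domain.mask
    r, c = np.nonzero(mask)
    table = pd.DataFrame({name: stack.layer(name).values[r, c]
                          for name in model.feature_names})
    probs = model.predict(table)
    out = np.full(domain.shape, np.nan)
    out[r, c] = probs
    return domain.with_values(out)


def save_model(model: FittedModel, path: str | Path) -> None:
    """Persist a fitted model (joblib container with spec and version)."""
    from . import __version__

    joblib.dump({"version": __version__, "spec": model.spec,
                 "model": model}, path)


def load_model(path: str | Path) -> FittedModel:
    return joblib.load(path)["model"]
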