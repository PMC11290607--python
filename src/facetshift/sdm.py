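"""Presence-background species distribution models.

Three learner families — an additive logistic model with smooth spline terms
(GAM-like), a regularized log-linear presence-background classifier with
linear + quadratic + pairwise-product features (a maximum-entropy-style
model), and stochastic gradient-boosted trees — plus their unweighted-mean
ensemble.  All are sklearn-style estimators (``fit`` / ``predict_proba`` /
``get_params``) so they compose with sklearn tooling.

Workflow per species: a 75/25 class-stratified holdout evaluates each learner
(AUC and continuous Boyce index on the test split); species whose best model
scores AUC < 0.7 or Boyce < 0.4 are flagged low-quality; the best-performing
learner (the ensemble competes too) is refitted on all data, a
max(sensitivity+specificity) threshold is chosen, and the final model is
projected to current and future predictor stacks — binary maps are suitability
>= threshold restricted to the buffered accessible area.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import shapely
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.ensemble import GradientBoostingClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import train_test_split
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import MinMaxScaler, PolynomialFeatures, SplineTransformer, StandardScaler

from .evaluation import auc, boyce_index, select_threshold
from .grids import PredictorStack, RasterGrid
from .occurrences import AccessibleArea

logger = logging.getLogger(__name__)

__all__ = [
    "SdmDataset", "build_dataset",
    "AdditiveLogisticSDM", "MaxentLikeSDM", "BoostedTreesSDM", "EnsembleSDM",
    "SuitabilityModelSet", "fit_learners", "evaluate_and_finalize", "project",
    "AUC_GATE", "BOYCE_GATE",
]

AUC_GATE = 0.7
BOYCE_GATE = 0.4


# ------------------------------------------------------------------ learners

class _SuitabilityMixin:
    def suitability(self, X) -> np.ndarray:
        """Predicted habitat suitability in [0, 1]."""
        return self.predict_proba(X)[:, 1]


class AdditiveLogisticSDM(_SuitabilityMixin, ClassifierMixin, BaseEstimator):
    """Additive logistic model: per-predictor smooth spline terms feeding a
    ridge-penalised logistic regression (the GAM family member)."""

    def __init__(self, n_knots: int = 5, degree: int = 3, C: float = 1.0,
                 random_state: int | None = None):
        self.n_knots = n_knots
        self.degree = degree
        self.C = C
        self.random_state = random_state

    def fit(self, X, y):
        self.pipeline_ = make_pipeline(
            StandardScaler(),
            SplineTransformer(n_knots=self.n_knots, degree=self.degree),
            LogisticRegression(C=self.C, max_iter=2000),
        )
        self.pipeline_.fit(np.asarray(X, dtype=float), np.asarray(y, dtype=int))
        self.classes_ = self.pipeline_[-1].classes_
        return self

    def predict_proba(self, X):
        return self.pipeline_.predict_proba(np.asarray(X, dtype=float))

    def predict(self, X):
        return self.pipeline_.predict(np.asarray(X, dtype=float))


class MaxentLikeSDM(_SuitabilityMixin, ClassifierMixin, BaseEstimator):
    """Maximum-entropy-style model: L1-regularized log-linear classifier on
    linear + quadratic + pairwise-product features of min-max-scaled
    predictors (the standard presence-background equivalent of a MaxEnt model
    with linear/quadratic/product feature classes)."""

    def __init__(self, C: float = 1.0, random_state: int | None = None):
        self.C = C
        self.random_state = random_state

    def fit(self, X, y):
        self.pipeline_ = make_pipeline(
            MinMaxScaler(),
            PolynomialFeatures(degree=2, include_bias=False),
            LogisticRegression(l1_ratio=1.0, C=self.C, solver="liblinear",
                               max_iter=2000, random_state=self.random_state),
        )
        self.pipeline_.fit(np.asarray(X, dtype=float), np.asarray(y, dtype=int))
        self.classes_ = self.pipeline_[-1].classes_
        return self

    def predict_proba(self, X):
        return self.pipeline_.predict_proba(np.asarray(X, dtype=float))

    def predict(self, X):
        return self.pipeline_.predict(np.asarray(X, dtype=float))


class BoostedTreesSDM(_SuitabilityMixin, ClassifierMixin, BaseEstimator):
    """Stochastic gradient-boosted regression trees."""

    def __init__(self, n_estimators: int = 300, learning_rate: float = 0.05,
                 max_depth: int = 3, subsample: float = 0.75,
                 random_state: int | None = None):
        self.n_estimators = n_estimators
        self.learning_rate = learning_rate
        self.max_depth = max_depth
        self.subsample = subsample
        self.random_state = random_state

    def fit(self, X, y):
        self.model_ = GradientBoostingClassifier(
            n_estimators=self.n_estimators, learning_rate=self.learning_rate,
            max_depth=self.max_depth, subsample=self.subsample,
            random_state=self.random_state,
        )
        self.model_.fit(np.asarray(X, dtype=float), np.asarray(y, dtype=int))
        self.classes_ = self.model_.classes_
        return self

    def predict_proba(self, X):
        return self.model_.predict_proba(np.asarray(X, dtype=float))

    def predict(self, X):
        return self.model_.predict(np.asarray(X, dtype=float))


class EnsembleSDM(_SuitabilityMixin, ClassifierMixin, BaseEstimator):
    """Unweighted mean of the component learners' suitabilities."""

    def __init__(self, components: list | None = None):
        self.components = components

    def fit(self, X, y):
        self.fitted_components_ = []
        for comp in self.components or []:
            self.fitted_components_.append(clone(comp).fit(X, y))
        self.classes_ = np.array([0, 1])
        return self

    @classmethod
    def from_fitted(cls, fitted: list) -> "EnsembleSDM":
        obj = cls(components=None)
        obj.fitted_components_ = list(fitted)
        obj.classes_ = np.array([0, 1])
        return obj

    def predict_proba(self, X):
        p1 = np.mean([m.predict_proba(X)[:, 1] for m in self.fitted_components_], axis=0)
        return np.column_stack([1 - p1, p1])

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)


# ------------------------------------------------------------------- dataset

@dataclass
class SdmDataset:
    """Per-species design matrices with a stratified 75/25 holdout."""

    species_id: str
    feature_names: list[str]
    x_presence: np.ndarray
    x_background: np.ndarray
    train_idx: np.ndarray = None
    test_idx: np.ndarray = None
    presence_cells: set = field(default_factory=set)

    def __post_init__(self) -> None:
        if np.isnan(self.x_presence).any() or np.isnan(self.x_background).any():
            raise ValueError("predictor matrices contain missing values")

    @property
    def x(self) -> np.ndarray:
        return np.vstack([self.x_presence, self.x_background])

    @property
    def y(self) -> np.ndarray:
        return np.concatenate([np.ones(len(self.x_presence), dtype=int),
                               np.zeros(len(self.x_background), dtype=int)])

    def split(self, seed: int, test_size: float = 0.25) -> None:
        idx = np.arange(len(self.x))
        tr, te = train_test_split(idx, test_size=test_size, random_state=seed,
                                  stratify=self.y)
        self.train_idx, self.test_idx = tr, te


def build_dataset(species_id: str, occ, background, stack: PredictorStack,
                  background_ratio: int = 2) -> SdmDataset:
    """Extract predictor values at presence and background cells.

    Presences are mapped to their containing grid cell; records falling off
    the grid are dropped.  Background rows must number ``background_ratio``
    times the presence rows (the sampler guarantees this).
    """
    grid = stack.grid
    pr, pc = grid.indices_of(occ["lon"].to_numpy(), occ["lat"].to_numpy())
    ok = pr >= 0
    pr, pc = pr[ok], pc[ok]
    if pr.size == 0:
        raise ValueError(f"no presence records on the grid for {species_id!r}")
    xp = stack.as_matrix(pr, pc)
    if {"row", "col"}.issubset(background.columns):
        br = background["row"].to_numpy()
        bc = background["col"].to_numpy()
    else:
        br, bc = grid.indices_of(background["lon"].to_numpy(), background["lat"].to_numpy())
    xb = stack.as_matrix(br, bc)
    if len(xb) != background_ratio * len(xp):
        logger.warning("%s: background rows (%d) != %d x presences (%d)",
                       species_id, len(xb), background_ratio, len(xp))
    return SdmDataset(species_id, stack.names, xp, xb,
                      presence_cells=set(zip(pr.tolist(), pc.tolist())))


# ------------------------------------------------------------------- fitting

@dataclass
class SuitabilityModelSet:
    """Fitted learners with their holdout scores and the final model."""

    species_id: str
    feature_names: list[str]
    learners: dict[str, object]
    auc_scores: dict[str, float]
    boyce_scores: dict[str, float]
    best_learner: str
    low_quality: bool = False
    final_model: object = None
    threshold: float | None = None
    dropped_features: list[str] = field(default_factory=list)

    @property
    def best_auc(self) -> float:
        return self.auc_scores[self.best_learner]

    @property
    def best_boyce(self) -> float:
        return self.boyce_scores[self.best_learner]


def _make_learners(seed: int, brt_estimators: int = 300) -> dict[str, object]:
    return {
        "gam": AdditiveLogisticSDM(random_state=seed),
        "maxent": MaxentLikeSDM(random_state=seed),
        "brt": BoostedTreesSDM(n_estimators=brt_estimators, random_state=seed),
    }


def fit_learners(data: SdmDataset, seed: int = 0,
                 min_presences: int = 15,
                 boyce_windows: int = 101,
                 boyce_window_fraction: float = 0.1,
                 brt_estimators: int = 300) -> SuitabilityModelSet:
    """Fit the three learner families and their ensemble on the train split
    and score every candidate on the holdout.

    Species with fewer than ``min_presences`` presences are rejected
    (mirroring the omission of low-occurrence species).  Predictors constant
    on the training rows are dropped from this species' model.

    The holdout Boyce uses the classic wide smoothing (window = one tenth of
    the range): with small test sets the narrow-window estimate is too noisy
    to gate on.
    """
    n_pres = len(data.x_presence)
    if n_pres < min_presences:
        raise ValueError(f"{data.species_id}: {n_pres} presences < minimum {min_presences}")
    if data.train_idx is None:
        data.split(seed)

    x, y = data.x, data.y
    xtr, ytr = x[data.train_idx], y[data.train_idx]
    xte, yte = x[data.test_idx], y[data.test_idx]

    keep = np.ptp(xtr, axis=0) > 0
    dropped = [n for n, k in zip(data.feature_names, keep) if not k]
    if dropped:
        logger.warning("%s: dropping constant predictors %s", data.species_id, dropped)
    xtr, xte = xtr[:, keep], xte[:, keep]

    learners = _make_learners(seed, brt_estimators)
    fitted: dict[str, object] = {}
    for name, est in learners.items():
        fitted[name] = est.fit(xtr, ytr)
    fitted["ensemble"] = EnsembleSDM.from_fitted(list(fitted.values()))

    aucs, boyces = {}, {}
    for name, est in fitted.items():
        s = est.suitability(xte)
        aucs[name] = auc(s, yte)
        try:
            boyces[name] = boyce_index(s[yte == 1], s[yte == 0], n_windows=boyce_windows,
                                       window_fraction=boyce_window_fraction)
        except ValueError:
            boyces[name] = float("nan")
    best = max(aucs, key=lambda k: aucs[k])
    return SuitabilityModelSet(
        species_id=data.species_id,
        feature_names=[n for n, k in zip(data.feature_names, keep) if k],
        learners=fitted, auc_scores=aucs, boyce_scores=boyces,
        best_learner=best, dropped_features=dropped,
    )


def evaluate_and_finalize(data: SdmDataset, model_set: SuitabilityModelSet,
                          seed: int = 0,
                          auc_gate: float = AUC_GATE,
                          boyce_gate: float = BOYCE_GATE,
                          brt_estimators: int = 300) -> SuitabilityModelSet:
    """Apply the quality gates, refit the best learner on all occurrences and
    pick the binarisation threshold.

    A species is flagged low-quality when its best holdout AUC < ``auc_gate``
    or Boyce < ``boyce_gate`` (flagged species keep a final model but are
    excluded from the stacked diversity metrics downstream).
    """
    best_boyce = model_set.best_boyce
    model_set.low_quality = (model_set.best_auc < auc_gate
                             or (np.isnan(best_boyce) or best_boyce < boyce_gate))

    keep_cols = [data.feature_names.index(n) for n in model_set.feature_names]
    x_all = data.x[:, keep_cols]
    y_all = data.y
    best = model_set.best_learner
    fresh = _make_learners(seed, brt_estimators)
    if best == "ensemble":
        final = EnsembleSDM.from_fitted(
            [clone(fresh[n]).fit(x_all, y_all) for n in ("gam", "maxent", "brt")])
    else:
        final = clone(fresh[best]).fit(x_all, y_all)
    s = final.suitability(x_all)
    model_set.final_model = final
    model_set.threshold = select_threshold(s[y_all == 1], s[y_all == 0])
    return model_set


# ---------------------------------------------------------------- projection

def project(model_set: SuitabilityModelSet, stack: PredictorStack,
            area: AccessibleArea) -> tuple[RasterGrid, RasterGrid]:
    """Project the final model onto a predictor stack.

    Returns (suitability map, binary range map).  The binary map is True
    where suitability >= the species threshold *and* the cell centre lies in
    the buffered accessible area.
    """
    if model_set.final_model is None or model_set.threshold is None:
        raise ValueError("model set is not finalized")
    missing = [n for n in model_set.feature_names if n not in stack]
    if missing:
        raise KeyError(f"stack lacks predictors {missing}")
    grid = stack.grid
    x = stack.subset(model_set.feature_names).as_matrix()
    suit = model_set.final_model.suitability(x).reshape(grid.shape)
    lons, lats = np.meshgrid(grid.lon_centers(), grid.lat_centers())
    accessible = shapely.contains_xy(area.buffered, lons.ravel(), lats.ravel()).reshape(grid.shape)
    binary = (suit >= model_set.threshold) & accessible
    tag = f"{model_set.species_id}_{stack.scenario}_{stack.period}"
    return (grid.like(suit, name=f"suitability_{tag}"),
            grid.like(binary.astype(float), name=f"binary_{tag}"))
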