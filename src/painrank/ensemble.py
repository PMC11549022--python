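"""Imbalance-aware tree ensembles for pain-gene classification.

Four probabilistic base learners — XGBoost, gradient boosting, AdaBoost
and a random forest, in that fixed member order — are combined by
weighted soft voting: class probabilities are multiplied by per-learner
weights and averaged, and the hard label is the argmax at threshold
0.5. The voting weights are chosen by exhaustively permuting a weight
multiset (default {4, 2, 1, 3}) over the members and keeping the
permutation with the best geometric-mean score on out-of-fold
predictions. A stacking variant feeds the out-of-fold base
probabilities to a logistic meta-model instead.

With ~1 positive per 40 negatives, each member trains on all positives
plus its own random negative subsample of equal size (random
undersampling, the standard imbalance remedy), topped up with balanced
class weighting for any residual skew. Balanced training keeps
probability threshold 0.5 a meaningful operating point: on
chance-level data the members' probabilities straddle 0.5 instead of
collapsing to the majority class, and each member's distinct negative
subsample lets the ensemble collectively cover far more of the
negative class than any single learner.

Feature selection is backward elimination guided by tree-path
attribution: at each step the feature with the smallest mean absolute
attribution is dropped and the cross-validated metrics are re-measured;
the subset with the highest GM (MCC as tie-break) wins.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import (
    AdaBoostClassifier,
    GradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.utils.class_weight import compute_sample_weight
from xgboost import XGBClassifier

from .attribution import combine_attributions, rank_features, tree_path_attribution
from .metrics import MetricSet, confusion_from_predictions, metric_set

__all__ = [
    "DEFAULT_SEED",
    "BaseLearnerSpec",
    "WeightVector",
    "default_learner_specs",
    "make_estimator",
    "fit_base_learners",
    "predict_proba_matrix",
    "soft_vote",
    "weight_search",
    "oof_probabilities",
    "VotingEnsemble",
    "StackingEnsemble",
    "fit_voting",
    "fit_stacking",
    "CrossValResult",
    "cross_validate",
    "shap_weighted",
    "backward_eliminate",
    "random_search_tuner",
]

DEFAULT_SEED = 20240101

# voting member order is fixed; weights [4, 2, 1, 3] map onto it
MEMBER_ORDER = ["xgb", "gb", "ada", "rf"]
DEFAULT_WEIGHT_MULTISET = (4, 2, 1, 3)


@dataclass(frozen=True)
class BaseLearnerSpec:
    """One base learner: family name, hyperparameters, seed."""

    name: str
    family: str  # xgb | gb | ada | rf
    hyperparameters: dict = field(default_factory=dict)
    seed: int = DEFAULT_SEED


@dataclass(frozen=True)
class WeightVector:
    """Non-negative voting weights in fixed member order."""

    weights: tuple

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if (w < 0).any() or w.sum() <= 0:
            raise ValueError("weights must be non-negative with a positive sum")

    def normalized(self) -> np.ndarray:
        w = np.asarray(self.weights, dtype=float)
        return w / w.sum()


def default_learner_specs(seed: int = DEFAULT_SEED) -> list[BaseLearnerSpec]:
    """The four voting members with modest, CPU-friendly settings."""
    return [
        BaseLearnerSpec("xgb", "xgb", {"n_estimators": 200, "max_depth": 4,
                                       "learning_rate": 0.1}, seed),
        BaseLearnerSpec("gb", "gb", {"n_estimators": 100, "max_depth": 3,
                                     "learning_rate": 0.1}, seed),
        BaseLearnerSpec("ada", "ada", {"n_estimators": 100,
                                       "learning_rate": 0.5}, seed),
        BaseLearnerSpec("rf", "rf", {"n_estimators": 200,
                                     "min_samples_leaf": 2}, seed),
    ]


def make_estimator(spec: BaseLearnerSpec, y=None):
    """Instantiate the sklearn/xgboost estimator for a spec.

    ``y`` (training labels) sets the positive-class weighting for
    families that take it as a constructor argument.
    """
    hp = dict(spec.hyperparameters)
    if spec.family == "xgb":
        spw = hp.pop("scale_pos_weight", None)
        if spw is None and y is not None:
            y = np.asarray(y)
            pos = max(int(y.sum()), 1)
            spw = (len(y) - pos) / pos
        return XGBClassifier(
            random_state=spec.seed, n_jobs=1, tree_method="hist",
            eval_metric="logloss", scale_pos_weight=spw or 1.0, **hp,
        )
    if spec.family == "gb":
        return GradientBoostingClassifier(random_state=spec.seed, **hp)
    if spec.family == "ada":
        return AdaBoostClassifier(random_state=spec.seed, **hp)
    if spec.family == "rf":
        return RandomForestClassifier(
            random_state=spec.seed, n_jobs=1,
            class_weight=hp.pop("class_weight", "balanced_subsample"), **hp,
        )
    raise ValueError(f"unknown learner family {spec.family!r}")


def _fit_one(spec: BaseLearnerSpec, X, y, neg_pos_ratio: float | None = 1.0,
             member_index: int = 0):
    """Fit one learner, undersampling negatives to ``neg_pos_ratio`` x
    the positive count (None disables undersampling).

    Each member draws its own negative subsample (seeded by the spec
    seed and its position), so the ensemble collectively sees far more
    of the negative class than any single member.
    """
    if neg_pos_ratio is not None:
        pos = np.where(y == 1)[0]
        neg = np.where(y == 0)[0]
        n_keep = min(len(neg), max(int(round(neg_pos_ratio * len(pos))), 1))
        if n_keep < len(neg):
            rng = np.random.default_rng([spec.seed, member_index])
            keep = rng.choice(neg, size=n_keep, replace=False)
            idx = np.sort(np.concatenate([pos, keep]))
            X, y = X[idx], y[idx]
    est = make_estimator(spec, y)
    if spec.family in ("gb", "ada"):
        # these families take no class_weight argument; balance per-sample
        est.fit(X, y, sample_weight=compute_sample_weight("balanced", y))
    else:
        est.fit(X, y)
    return est


def fit_base_learners(X, y, specs: list[BaseLearnerSpec],
                      neg_pos_ratio: float | None = 1.0) -> dict:
    """Fit every spec on (X, y); rejects single-class training data."""
    if not specs:
        raise ValueError("specs must be non-empty")
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("training data contains a single class")
    return {
        spec.name: _fit_one(spec, np.asarray(X, float), y, neg_pos_ratio, i)
        for i, spec in enumerate(specs)
    }


def predict_proba_matrix(learners: dict, X) -> np.ndarray:
    """Class-1 probabilities, one column per learner (fixed dict order)."""
    X = np.asarray(X, float)
    return np.column_stack([m.predict_proba(X)[:, 1] for m in learners.values()])


def soft_vote(probas, w: WeightVector | tuple) -> np.ndarray:
    """Weighted average of per-learner class-1 probability vectors."""
    if not isinstance(w, WeightVector):
        w = WeightVector(tuple(w))
    if isinstance(probas, np.ndarray) and probas.ndim == 2:
        P = probas.astype(float)  # columns are learners
    else:
        P = np.column_stack([np.asarray(p, float) for p in probas])
    wn = w.normalized()
    if P.shape[1] != wn.size:
        raise ValueError(f"{P.shape[1]} probability vectors but {wn.size} weights")
    return P @ wn


def weight_search(probas, truth, weight_multiset=DEFAULT_WEIGHT_MULTISET) -> WeightVector:
    """Exhaustive permutation search of the weight multiset.

    Evaluates the GM of the soft-vote hard predictions (threshold 0.5)
    for every distinct permutation, in lexicographic order, and returns
    the first argmax.
    """
    P = np.asarray(probas, float)
    truth = np.asarray(truth)
    if P.shape[1] != len(weight_multiset):
        raise ValueError("one weight per learner required")
    best, best_gm = None, -1.0
    for perm in sorted(set(itertools.permutations(weight_multiset))):
        combined = soft_vote(P, WeightVector(perm))
        g = metric_set(confusion_from_predictions(truth, (combined >= 0.5).astype(int))).gm
        if g > best_gm:
            best, best_gm = perm, g
    return WeightVector(best)


def oof_probabilities(X, y, specs, folds: int = 5, seed: int = DEFAULT_SEED,
                      neg_pos_ratio: float | None = 1.0) -> np.ndarray:
    """Out-of-fold class-1 probabilities per learner (n x k)."""
    X = np.asarray(X, float)
    y = np.asarray(y)
    out = np.zeros((len(y), len(specs)))
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    for tr, te in skf.split(X, y):
        learners = fit_base_learners(X[tr], y[tr], specs, neg_pos_ratio)
        out[te] = predict_proba_matrix(learners, X[te])
    return out


class VotingEnsemble:
    """Weighted soft-voting ensemble over the four base learners."""

    def __init__(self, specs=None, weight_multiset=DEFAULT_WEIGHT_MULTISET,
                 tune_weights: bool = True, oof_folds: int = 5,
                 seed: int = DEFAULT_SEED, neg_pos_ratio: float | None = 1.0):
        self.specs = specs
        self.weight_multiset = tuple(weight_multiset)
        self.tune_weights = tune_weights
        self.oof_folds = oof_folds
        self.seed = seed
        self.neg_pos_ratio = neg_pos_ratio

    def fit(self, X, y):
        specs = self.specs or default_learner_specs(self.seed)
        X = np.asarray(X, float)
        y = np.asarray(y)
        if self.tune_weights:
            oof = oof_probabilities(X, y, specs, self.oof_folds, self.seed,
                                    self.neg_pos_ratio)
            self.weights_ = weight_search(oof, y, self.weight_multiset)
        else:
            self.weights_ = WeightVector(self.weight_multiset)
        self.learners_ = fit_base_learners(X, y, specs, self.neg_pos_ratio)
        self.specs_ = specs
        return self

    def predict_proba(self, X) -> np.ndarray:
        p1 = soft_vote(predict_proba_matrix(self.learners_, X), self.weights_)
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)

    def attributions(self, X) -> np.ndarray:
        """Weight-combined per-feature path attributions."""
        mats = [tree_path_attribution(m, X)[0] for m in self.learners_.values()]
        return shap_weighted(mats, self.weights_)


class StackingEnsemble:
    """Base learners stacked under a logistic-regression meta-model.

    The meta-model is fitted on out-of-fold base probabilities so it
    never sees a base learner's training-set fit of the same rows.
    """

    def __init__(self, specs=None, oof_folds: int = 5, seed: int = DEFAULT_SEED,
                 neg_pos_ratio: float | None = 1.0):
        self.specs = specs
        self.oof_folds = oof_folds
        self.seed = seed
        self.neg_pos_ratio = neg_pos_ratio

    def fit(self, X, y):
        specs = self.specs or default_learner_specs(self.seed)
        X = np.asarray(X, float)
        y = np.asarray(y)
        oof = oof_probabilities(X, y, specs, self.oof_folds, self.seed,
                                self.neg_pos_ratio)
        self.meta_ = LogisticRegression(max_iter=1000, random_state=self.seed)
        self.meta_.fit(oof, y)
        self.learners_ = fit_base_learners(X, y, specs, self.neg_pos_ratio)
        self.specs_ = specs
        return self

    def predict_proba(self, X) -> np.ndarray:
        return self.meta_.predict_proba(predict_proba_matrix(self.learners_, X))

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)

    def attributions(self, X) -> np.ndarray:
        """Chain-rule approximation: base attributions weighted by the
        meta-model's coefficient magnitudes."""
        mats = [tree_path_attribution(m, X)[0] for m in self.learners_.values()]
        coefs = np.abs(self.meta_.coef_[0])
        if coefs.sum() == 0:
            coefs = np.ones_like(coefs)
        return shap_weighted(mats, coefs)


def fit_voting(X, y, specs=None, weight_multiset=DEFAULT_WEIGHT_MULTISET,
               seed: int = DEFAULT_SEED) -> VotingEnsemble:
    return VotingEnsemble(specs, weight_multiset, seed=seed).fit(X, y)


def fit_stacking(X, y, specs=None, seed: int = DEFAULT_SEED) -> StackingEnsemble:
    return StackingEnsemble(specs, seed=seed).fit(X, y)


@dataclass
class CrossValResult:
    """Per-fold metrics with stored held-out predictions."""

    folds: list[MetricSet]
    predictions: list[tuple] = field(default_factory=list)  # (idx, truth, proba)

    def mean(self) -> MetricSet:
        return MetricSet(**{k: float(np.mean([f.as_dict()[k] for f in self.folds]))
                            for k in ("mcc", "gm", "f1", "ba")})

    def sd(self) -> MetricSet:
        return MetricSet(**{k: float(np.std([f.as_dict()[k] for f in self.folds], ddof=1))
                            for k in ("mcc", "gm", "f1", "ba")})

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame([f.as_dict() for f in self.folds])


def cross_validate(X, y, model_factory, folds: int = 10,
                   seed: int = DEFAULT_SEED) -> CrossValResult:
    """Stratified k-fold CV of any fit/predict_proba model factory."""
    X = np.asarray(X, float)
    y = np.asarray(y)
    if int(y.sum()) < folds:
        raise ValueError(
            f"{int(y.sum())} positives cannot stratify into {folds} folds"
        )
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    fold_metrics, preds = [], []
    for tr, te in skf.split(X, y):
        model = model_factory()
        model.fit(X[tr], y[tr])
        proba = model.predict_proba(X[te])[:, 1]
        c = confusion_from_predictions(y[te], (proba >= 0.5).astype(int))
        fold_metrics.append(metric_set(c))
        preds.append((te, y[te].copy(), proba))
    return CrossValResult(fold_metrics, preds)


def shap_weighted(matrices, weights) -> np.ndarray:
    """Weight-normalized combination of per-learner attribution matrices."""
    if isinstance(weights, WeightVector):
        weights = weights.weights
    return combine_attributions(matrices, weights)


def backward_eliminate(X: pd.DataFrame, y, model_factory, folds: int = 5,
                       seed: int = DEFAULT_SEED, strategy: str = "attribution"):
    """Attribution-guided backward elimination down to one feature.

    At each step the cross-validated GM/MCC of the current subset is
    recorded, then the least important feature is dropped — by mean
    absolute path attribution (``strategy="attribution"``) or by
    re-fitting every leave-one-out candidate and keeping the best
    (``strategy="refit"``). Returns ``(selected, trajectory)`` where
    ``selected`` maximizes GM with MCC as tie-break.
    """
    if X.shape[1] < 2:
        raise ValueError("need at least 2 features to eliminate")
    X = X.copy()
    y = np.asarray(y)
    current = list(X.columns)
    records = []
    while current:
        try:
            cv = cross_validate(X[current].to_numpy(), y, model_factory, folds, seed)
            mean = cv.mean()
            records.append({"n_features": len(current),
                            "features": tuple(current),
                            "gm": mean.gm, "mcc": mean.mcc,
                            "ba": mean.ba, "f1": mean.f1, "failed": False})
        except ValueError:
            records.append({"n_features": len(current), "features": tuple(current),
                            "gm": np.nan, "mcc": np.nan, "ba": np.nan,
                            "f1": np.nan, "failed": True})
        if len(current) == 1:
            break
        if strategy == "attribution":
            model = model_factory()
            model.fit(X[current].to_numpy(), y)
            if hasattr(model, "attributions"):
                contrib = model.attributions(X[current].to_numpy())
            else:
                contrib, _ = tree_path_attribution(model, X[current].to_numpy())
            ranked = rank_features(contrib, current)
            current.remove(ranked[-1])
        elif strategy == "refit":
            best_gm, victim = -np.inf, current[-1]
            for cand in current:
                rest = [c for c in current if c != cand]
                try:
                    g = cross_validate(X[rest].to_numpy(), y, model_factory,
                                       folds, seed).mean().gm
                except ValueError:
                    continue
                if g > best_gm:
                    best_gm, victim = g, cand
            current.remove(victim)
        else:
            raise ValueError(f"unknown strategy {strategy!r}")
    trajectory = pd.DataFrame(records)
    ok = trajectory[~trajectory["failed"]]
    if ok.empty:
        raise RuntimeError("every elimination step failed; nothing to select")
    best = ok.sort_values(["gm", "mcc", "n_features"],
                          ascending=[False, False, True], kind="stable").iloc[0]
    return list(best["features"]), trajectory


def random_search_tuner(X, y, family: str, param_space: dict, budget: int = 20,
                        folds: int = 5, seed: int = DEFAULT_SEED):
    """Seeded random-search tuner optimizing summed GM + MCC + BA + F1.

    ``param_space`` maps hyperparameter name to a list of candidate
    values. Returns ``(best_hyperparameters, best_objective)``. This is
    the pluggable tuning contract; any optimizer with the same
    signature and objective can stand in.
    """
    rng = np.random.default_rng(seed)
    names = sorted(param_space)
    best_hp, best_obj = {}, -np.inf
    for _ in range(budget):
        hp = {n: param_space[n][rng.integers(len(param_space[n]))] for n in names}
        spec = BaseLearnerSpec("cand", family, hp, seed)
        cv = cross_validate(
            np.asarray(X, float), np.asarray(y),
            lambda: _TunableSingle(spec), folds, seed,
        )
        m = cv.mean()
        obj = m.gm + m.mcc + m.ba + m.f1
        if obj > best_obj:
            best_hp, best_obj = hp, obj
    return best_hp, best_obj


class _TunableSingle:
    """Single-learner wrapper giving specs a fit/predict_proba surface."""

    def __init__(self, spec: BaseLearnerSpec):
        self.spec = spec

    def fit(self, X, y):
        self.model_ = _fit_one(self.spec, np.asarray(X, float), np.asarray(y))
        return self

    def predict_proba(self, X):
        return self.model_.predict_proba(np.asarray(X, float))
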