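"""Per-APOE-group classifier training and the gate decision logic.

Each APOE group gets its own classifier, chosen by ten-fold stratified
cross-validated grid search over six standard families (KNN, SVM, Gaussian
process, feed-forward network, random forest, logistic regression). The
selection criterion is the F_{1/10} score of the group's designated majority
class (amyloid-negative in non-carriers, amyloid-positive in carriers),
which weights precision ten times over recall. The best configuration per
family is a *transition model*; the transition model with the best mean
validation score, rounded to a full percent, becomes the *final model* —
rounded-score ties are broken by raw performance on the held-out test set,
and the whole selection trail is recorded.

The gate itself: carriers are always referred for explicit amyloid testing;
non-carriers are spared testing only on an amyloid-negative prediction.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.gaussian_process import GaussianProcessClassifier
from sklearn.gaussian_process.kernels import RBF
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.ensemble import RandomForestClassifier
from sklearn.svm import SVC

from .config import ABETA_NEG, ABETA_POS, APOE4_C, APOE4_NC
from .metrics import balanced_accuracy, f_beta, precision_recall, round_percent
from .preprocess import ScalerParams, apply_scaler

FAMILY_ORDER = ("KNN", "SVM", "GPC", "DNN", "RFC", "LR")

SPARE = "spare_amyloid_testing"
RECOMMEND = "recommend_amyloid_testing"

#: Designated (majority) amyloid class per APOE group.
MAJORITY_CLASS = {APOE4_NC: ABETA_NEG, APOE4_C: ABETA_POS}


def default_grids() -> dict[str, list[dict]]:
    """Shipped hyperparameter lattices, one ordered list of points per family.

    Deliberately modest so a full grid search runs quickly on a desktop;
    lattices are configuration, not a fixed part of the method.
    """
    return {
        "KNN": [{"n_neighbors": k} for k in (3, 5, 11, 21)],
        "SVM": [{"C": c, "kernel": "rbf", "gamma": "scale"} for c in (0.1, 1.0, 10.0)]
        + [{"C": 1.0, "kernel": "linear"}],
        "GPC": [{"length_scale": 1.0}],
        "DNN": [{"hidden_layer_sizes": (32,)}, {"hidden_layer_sizes": (64, 32)}],
        "RFC": [{"n_estimators": 100, "max_depth": None}, {"n_estimators": 100, "max_depth": 5}],
        "LR": [{"C": c} for c in (0.1, 1.0, 10.0)],
    }


def make_estimator(family: str, params: Mapping, seed: int = 0):
    """Instantiate a scikit-learn classifier for one lattice point."""
    params = dict(params)
    if family == "KNN":
        return KNeighborsClassifier(**params)
    if family == "SVM":
        return SVC(random_state=seed, **params)
    if family == "GPC":
        length_scale = params.pop("length_scale", 1.0)
        return GaussianProcessClassifier(
            kernel=1.0 * RBF(length_scale=length_scale), random_state=seed, **params
        )
    if family == "DNN":
        # early stopping off for determinism; plain small feed-forward net
        return MLPClassifier(
            max_iter=400, early_stopping=False, random_state=seed, **params
        )
    if family == "RFC":
        return RandomForestClassifier(random_state=seed, n_jobs=1, **params)
    if family == "LR":
        return LogisticRegression(max_iter=2000, **params)
    raise ValueError(f"unknown classifier family {family!r}; known: {FAMILY_ORDER}")


@dataclasses.dataclass(frozen=True)
class ScorerSpec:
    """Model-selection criterion: F_beta (default) or balanced accuracy of
    the designated class."""

    target_class: str
    beta: float = 0.1
    metric: str = "f_beta"  # or "balanced_accuracy"

    def __post_init__(self) -> None:
        if self.beta <= 0:
            raise ValueError("beta must be > 0")
        if self.metric not in ("f_beta", "balanced_accuracy"):
            raise ValueError(f"unknown metric {self.metric!r}")

    def score(self, y_true, y_pred) -> float:
        y_true = np.asarray(y_true)
        y_pred = np.asarray(y_pred)
        p, r = precision_recall(y_true, y_pred, self.target_class)
        if self.metric == "f_beta":
            return f_beta(p, r, self.beta)
        neg = y_true != self.target_class
        spec = float(np.sum(neg & (y_pred != self.target_class)) / neg.sum()) if neg.sum() else 0.0
        return balanced_accuracy(r, spec)


@dataclasses.dataclass(frozen=True)
class TransitionModel:
    """Best hyperparameter configuration of one classifier family."""

    family: str
    params: dict
    cv_mean_f: float
    cv_fold_scores: tuple[float, ...]

    def __post_init__(self) -> None:
        if abs(self.cv_mean_f - float(np.mean(self.cv_fold_scores))) > 1e-12:
            raise ValueError("cv_mean_f must equal the mean of cv_fold_scores")


def grid_search_cv(
    X: pd.DataFrame,
    y: pd.Series,
    family: str,
    lattice: Sequence[Mapping],
    scorer: ScorerSpec,
    folds: int = 10,
    seed: int = 0,
) -> TransitionModel:
    """Exhaustive grid search with stratified k-fold cross-validation.

    Every lattice point is evaluated; its score is the mean of the scorer
    over the validation folds. Returns the argmax as a transition model;
    ties go to the earlier lattice point. Fold assignment is deterministic
    per seed and shared across lattice points.
    """
    if not lattice:
        raise ValueError(f"empty hyperparameter lattice for {family}")
    y_arr = np.asarray(y)
    classes, counts = np.unique(y_arr, return_counts=True)
    if len(classes) < 2:
        raise ValueError("grid search needs both classes present")
    if counts.min() < folds:
        raise ValueError(
            f"need >= {folds} subjects per class for {folds}-fold stratified CV; "
            f"counts {dict(zip(classes, counts))}"
        )
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(skf.split(X, y_arr))
    X_np = X.to_numpy(dtype=float)
    best: TransitionModel | None = None
    for params in lattice:
        fold_scores = []
        for tr_idx, va_idx in splits:
            if len(np.unique(y_arr[tr_idx])) < 2 or len(np.unique(y_arr[va_idx])) < 2:
                raise RuntimeError(
                    "degenerate CV fold with a single class; stratification failed"
                )
            est = make_estimator(family, params, seed=seed)
            est.fit(X_np[tr_idx], y_arr[tr_idx])
            fold_scores.append(scorer.score(y_arr[va_idx], est.predict(X_np[va_idx])))
        tm = TransitionModel(
            family=family,
            params=dict(params),
            cv_mean_f=float(np.mean(fold_scores)),
            cv_fold_scores=tuple(float(s) for s in fold_scores),
        )
        if best is None or tm.cv_mean_f > best.cv_mean_f:
            best = tm
    assert best is not None
    return best


class TieBreakNeeded(ValueError):
    """Raised when several transition models tie on the rounded validation
    score and no holdout scores were supplied to break the tie."""

    def __init__(self, tied_families: list[str]):
        self.tied_families = tied_families
        super().__init__(
            "transition models tied on rounded validation score "
            f"({tied_families}); supply holdout_scores to break the tie"
        )


def select_final_model(
    transition_models: Sequence[TransitionModel],
    holdout_scores: Mapping[str, float] | None = None,
    expected: int = len(FAMILY_ORDER),
) -> tuple[TransitionModel, dict]:
    """Pick the final model among transition models.

    Validation scores are rounded to a full percent; the unique maximum
    wins. On a rounded tie the raw holdout (primary test set) score among
    the tied models decides — holdout scores are consulted only then, and
    the returned selection trail records whether and how the tie-break was
    used.
    """
    models = list(transition_models)
    if len(models) != expected:
        raise ValueError(f"expected {expected} transition models, got {len(models)}")
    rounded = [round_percent(m.cv_mean_f) for m in models]
    best_rounded = max(rounded)
    tied_idx = [i for i, r in enumerate(rounded) if r == best_rounded]
    trail: dict = {
        "candidates": [
            {
                "family": m.family,
                "params": m.params,
                "cv_mean_f": m.cv_mean_f,
                "rounded_percent": r,
            }
            for m, r in zip(models, rounded)
        ],
        "tie_break": {"used": False, "tied_families": [], "holdout_scores": None},
    }
    if len(tied_idx) == 1:
        return models[tied_idx[0]], trail
    tied_families = [models[i].family for i in tied_idx]
    if holdout_scores is None:
        raise TieBreakNeeded(tied_families)
    missing = [f for f in tied_families if f not in holdout_scores]
    if missing:
        raise ValueError(f"holdout_scores missing tied families {missing}")
    winner = max(tied_idx, key=lambda i: (holdout_scores[models[i].family], -i))
    trail["tie_break"] = {
        "used": True,
        "tied_families": tied_families,
        "holdout_scores": {f: float(holdout_scores[f]) for f in tied_families},
    }
    return models[winner], trail


@dataclasses.dataclass
class GateModel:
    """Fitted per-APOE-group artifact of the gatekeeping system."""

    apoe_group: str  # APOE4-nc or APOE4-c
    majority_class: str
    scaler: ScalerParams
    transition: TransitionModel
    classifier: object
    selection_trail: dict
    feature_spec: dict  # kwargs for preprocess.feature_matrix + chosen columns
    beta: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        # pooled (non-gated) models carry a free target class; per-APOE
        # models must follow the group convention
        if self.apoe_group in MAJORITY_CLASS and (
            MAJORITY_CLASS[self.apoe_group] != self.majority_class
        ):
            raise ValueError(
                f"majority_class {self.majority_class} inconsistent with "
                f"group {self.apoe_group}"
            )

    def features(self, cohort) -> pd.DataFrame:
        """Raw (unscaled) feature table for this model from a cohort."""
        from .preprocess import feature_matrix

        return feature_matrix(
            cohort,
            include_apoe=self.feature_spec.get("include_apoe", False),
            exclude=self.feature_spec.get("exclude", ()),
        )


def predict(gate_model: GateModel, features: pd.DataFrame):
    """Predict amyloid status for raw feature rows.

    The model's training-set scaler is applied internally; a schema mismatch
    (missing feature columns) raises. Returns ``(labels, proba)`` where
    ``proba`` is the probability of the majority class when the family
    supports it, else ``None``.
    """
    Xs = apply_scaler(gate_model.scaler, features)
    clf = gate_model.classifier
    labels = np.asarray(clf.predict(Xs.to_numpy(dtype=float)))
    proba = None
    if hasattr(clf, "predict_proba"):
        probs = clf.predict_proba(Xs.to_numpy(dtype=float))
        j = list(clf.classes_).index(gate_model.majority_class)
        proba = probs[:, j]
    return labels, proba


def gate_decision(apoe4_carrier: bool, prediction: str | None = None) -> str:
    """Route one subject through the gate.

    Carriers are always referred for explicit amyloid testing. Non-carriers
    require a classifier prediction: amyloid-negative spares testing,
    amyloid-positive refers.
    """
    if apoe4_carrier:
        return RECOMMEND
    if prediction is None:
        raise ValueError("non-carriers require a classifier prediction")
    if prediction not in (ABETA_NEG, ABETA_POS):
        raise ValueError(f"unknown prediction {prediction!r}")
    return SPARE if prediction == ABETA_NEG else RECOMMEND
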