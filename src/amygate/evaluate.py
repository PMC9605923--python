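"""Evaluation protocol: test metrics, balanced-downsample audit, permutation
importance, mutual-information feature ranking, and the ablation study.

The balanced-downsample audit exposes prevalence-driven classifiers:
repeated evaluation on subsets where the majority class is randomly reduced
to minority size drives the precision of a classifier that merely predicts
the majority class to the balanced base rate of 0.5. Permutation importance
(delta) is the baseline score minus the mean score after shuffling one
feature column across subjects.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.feature_selection import mutual_info_classif

from .cohort import Cohort
from .config import ABETA_NEG, ABETA_POS, APOE4_C, APOE4_NC
from .gatekeeper import GateModel, ScorerSpec, predict
from .metrics import MetricSet, f_beta, precision_recall
from .preprocess import apply_scaler, labels_of


def test_metrics(gate_model: GateModel, test: Cohort) -> MetricSet:
    """Designated-class precision/recall/F_{1/10}/balanced accuracy on a
    held-out cohort (the model's scaler is applied internally)."""
    if len(test) == 0:
        raise ValueError("empty test cohort")
    X = gate_model.features(test)
    y = labels_of(test).to_numpy()
    y_hat, _ = predict(gate_model, X)
    return MetricSet.from_predictions(y, y_hat, gate_model.majority_class, gate_model.beta)


@dataclasses.dataclass
class BalancedAudit:
    """Average performance over randomly downsampled balanced test subsets."""

    subset_size: int  # minority-class count: each subset has 2x this
    n_repeats: int
    per_repeat: pd.DataFrame  # columns precision, recall, f_1_10, balanced_accuracy
    mean: MetricSet
    seed: int


def balanced_downsample_eval(
    gate_model: GateModel,
    test: Cohort,
    n_repeats: int | None = None,
    seed: int = 0,
    repeat_cap: int = 10_000,
) -> BalancedAudit:
    """Overfitting audit on balanced subsets of the test set.

    Every repeat keeps all minority-class subjects and a uniform random
    equally-sized subset of the majority class (if the two classes are
    already equal the subset is the full test set). ``n_repeats`` defaults
    to the square of the balanced subset size, capped at ``repeat_cap``.
    The mean metric set recomputes F_{1/10} from the mean precision and
    recall.
    """
    y = labels_of(test).to_numpy()
    maj = gate_model.majority_class
    maj_idx = np.flatnonzero(y == maj)
    min_idx = np.flatnonzero(y != maj)
    n = min(len(maj_idx), len(min_idx))
    if n == 0:
        raise ValueError("a class is empty in the test cohort; audit undefined")
    if n_repeats is None:
        n_repeats = min(n * n, repeat_cap)
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    X = gate_model.features(test)
    y_hat, _ = predict(gate_model, X)  # predictions fixed; only the subset varies
    rng = np.random.default_rng(seed)

    def _side(idx: np.ndarray) -> np.ndarray:
        return idx if len(idx) == n else rng.choice(idx, size=n, replace=False)

    rows = []
    for _ in range(n_repeats):
        sub = np.concatenate([_side(min_idx), _side(maj_idx)])
        m = MetricSet.from_predictions(y[sub], y_hat[sub], maj, gate_model.beta)
        rows.append(
            {
                "precision": m.precision,
                "recall": m.recall,
                "f_1_10": m.f_1_10,
                "balanced_accuracy": m.balanced_accuracy,
            }
        )
    per_repeat = pd.DataFrame(rows)
    mp, mr = float(per_repeat["precision"].mean()), float(per_repeat["recall"].mean())
    mean = MetricSet(
        precision=mp,
        recall=mr,
        f_1_10=f_beta(mp, mr, gate_model.beta),
        balanced_accuracy=float(per_repeat["balanced_accuracy"].mean()),
        target_class=maj,
        n_test=2 * n,
    )
    return BalancedAudit(
        subset_size=n, n_repeats=n_repeats, per_repeat=per_repeat, mean=mean, seed=seed
    )


def permutation_importance(
    gate_model: GateModel,
    test: Cohort,
    n_perm: int = 1000,
    seed: int = 0,
    chunk: int = 64,
) -> pd.DataFrame:
    """Permutation importance (delta) of every input feature.

    Each feature column is shuffled across test subjects ``n_perm`` times;
    the score (F_{1/10} of the designated class, the model-selection metric)
    is recomputed each time, and delta = baseline - mean permuted score.
    Deterministic per seed. Returns a table ``feature, delta, baseline,
    mean_permuted, n_perm`` sorted by descending delta.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if len(test) == 0:
        raise ValueError("empty test cohort")
    scorer = ScorerSpec(target_class=gate_model.majority_class, beta=gate_model.beta)
    X = gate_model.features(test)
    Xs = apply_scaler(gate_model.scaler, X).to_numpy(dtype=float)
    y = labels_of(test).to_numpy()
    clf = gate_model.classifier
    baseline = scorer.score(y, np.asarray(clf.predict(Xs)))
    rng = np.random.default_rng(seed)
    n_test, n_feat = Xs.shape
    feature_names = list(apply_scaler(gate_model.scaler, X).columns)
    rows = []
    for j in range(n_feat):
        scores = np.empty(n_perm)
        done = 0
        while done < n_perm:
            b = min(chunk, n_perm - done)
            block = np.tile(Xs, (b, 1))
            for k in range(b):
                perm = rng.permutation(n_test)
                block[k * n_test : (k + 1) * n_test, j] = Xs[perm, j]
            preds = np.asarray(clf.predict(block))
            for k in range(b):
                scores[done + k] = scorer.score(
                    y, preds[k * n_test : (k + 1) * n_test]
                )
            done += b
        mean_perm = float(scores.mean())
        rows.append(
            {
                "feature": feature_names[j],
                "delta": baseline - mean_perm,
                "baseline": baseline,
                "mean_permuted": mean_perm,
                "n_perm": n_perm,
            }
        )
    table = pd.DataFrame(rows).sort_values("delta", ascending=False, kind="stable")
    return table.reset_index(drop=True)


def mutual_info_rank(X: pd.DataFrame, y, seed: int = 0) -> list[str]:
    """Features ordered by decreasing estimated mutual information with the
    outcome (nearest-neighbour estimator for continuous features)."""
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("outcome is constant; mutual information undefined")
    discrete = np.array([X[c].nunique() <= 2 for c in X.columns])
    mi = mutual_info_classif(
        X.to_numpy(dtype=float), y, discrete_features=discrete, random_state=seed
    )
    order = np.lexsort((np.arange(len(mi)), -mi))
    return [X.columns[i] for i in order]


def select_top(ranked: Sequence[str], fraction: float) -> list[str]:
    """Top ceil(fraction * n) features of a ranked list."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    return list(ranked[: math.ceil(fraction * len(ranked))])


_VARIANTS = ("full", "-APOE", "-FDG", "-age", "-sex", "sub10", "sub50")


@dataclasses.dataclass(frozen=True)
class AblationSpec:
    """One row of the ablation grid.

    mode: ``CL`` (pooled classification, APOE carriership as an input
    feature) or ``GK`` (gated per-APOE-group classification). objective:
    the model-selection metric. variant: which feature block is removed, or
    ``sub10``/``sub50`` for the mutual-information-ranked top fraction.
    """

    mode: str  # CL | GK
    objective: str = "f_beta"  # f_beta | balanced_accuracy
    variant: str = "full"

    def __post_init__(self) -> None:
        if self.mode not in ("CL", "GK"):
            raise ValueError(f"mode must be CL or GK, got {self.mode!r}")
        if self.objective not in ("f_beta", "balanced_accuracy"):
            raise ValueError(f"unknown objective {self.objective!r}")
        if self.variant not in _VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; known {_VARIANTS}")
        if self.variant == "-APOE" and self.mode != "CL":
            raise ValueError("-APOE variant is only valid for CL mode")

    @property
    def mi_fraction(self) -> float | None:
        return {"sub10": 0.10, "sub50": 0.50}.get(self.variant)

    @property
    def exclude(self) -> tuple[str, ...]:
        return {
            "-APOE": ("apoe",),
            "-FDG": ("fdg",),
            "-age": ("age",),
            "-sex": ("sex",),
        }.get(self.variant, ())


def run_ablation(
    cohort: Cohort,
    specs: Sequence[AblationSpec],
    seed: int = 0,
    families: Sequence[str] | None = None,
    grids: dict | None = None,
    split_fraction: float = 0.7,
    cv_folds: int = 10,
    beta: float = 0.1,
) -> pd.DataFrame:
    """Refit the pipeline under each ablation spec and tabulate test metrics.

    GK rows report each APOE group's designated class on that group's test
    set; CL rows report both classes of a single pooled classifier on the
    pooled test set (with the F_{1/10} objective, one pooled fit per target
    class). Returns one row per (spec, class) with columns ``mode,
    objective, variant, target_class, f_1_10, precision, recall, n_test,
    n_features, family``.
    """
    from .model import GatekeeperModel, fit_pooled_classifier

    rows = []
    for spec in specs:
        if spec.mode == "GK":
            gm = GatekeeperModel(
                cohort,
                beta=beta,
                split_fraction=split_fraction,
                cv_folds=cv_folds,
                seed=seed,
                families=families,
                grids=grids,
                scorer_metric=spec.objective,
                feature_exclude=spec.exclude,
                mi_fraction=spec.mi_fraction,
            )
            res = gm.fit()
            for group in (APOE4_C, APOE4_NC):
                m = res.test_metrics(group)
                rows.append(_row(spec, m, res.models[group]))
        else:
            targets = (
                [ABETA_POS, ABETA_NEG]
                if spec.objective == "f_beta"
                else [ABETA_POS]  # one balanced-accuracy fit covers both classes
            )
            for target in targets:
                gate, test = fit_pooled_classifier(
                    cohort,
                    target_class=target,
                    beta=beta,
                    split_fraction=split_fraction,
                    cv_folds=cv_folds,
                    seed=seed,
                    families=families,
                    grids=grids,
                    scorer_metric=spec.objective,
                    feature_exclude=spec.exclude,
                    mi_fraction=spec.mi_fraction,
                )
                X = gate.features(test)
                y = labels_of(test).to_numpy()
                y_hat, _ = predict(gate, X)
                report_classes = (
                    [target]
                    if spec.objective == "f_beta"
                    else [ABETA_POS, ABETA_NEG]
                )
                for cls in report_classes:
                    m = MetricSet.from_predictions(y, y_hat, cls, beta)
                    rows.append(_row(spec, m, gate))
    return pd.DataFrame(rows)


def _row(spec: AblationSpec, m: MetricSet, gate: GateModel) -> dict:
    return {
        "mode": spec.mode,
        "objective": spec.objective,
        "variant": spec.variant,
        "target_class": m.target_class,
        "f_1_10": m.f_1_10,
        "precision": m.precision,
        "recall": m.recall,
        "n_test": m.n_test,
        "n_features": len(gate.scaler.feature_names),
        "family": gate.transition.family,
    }
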