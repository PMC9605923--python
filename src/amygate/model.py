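"""Model/results interface of the gatekeeping pipeline.

:class:`GatekeeperModel` is built from a cohort and a handful of pipeline
settings; :meth:`GatekeeperModel.fit` runs the full chain — PET/CSF
concordance filter, 3xIQR outlier filter, APOE grouping, stratified 70/30
split, per-group standardization, minority upsampling, six-family
cross-validated grid search and rounded-percent final-model selection — and
returns a :class:`GatekeeperResults` carrying the fitted per-group gate
models, the exclusion log, the train/test splits, and evaluation methods
(test metrics, balanced-downsample audit, permutation importance, gate
decisions, summary table).
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import Cohort
from .config import ABETA_NEG, ABETA_POS, APOE4_C, APOE4_NC, CutoffTable, DEFAULT_CUTOFFS
from .gatekeeper import (
    FAMILY_ORDER,
    GateModel,
    MAJORITY_CLASS,
    ScorerSpec,
    TieBreakNeeded,
    TransitionModel,
    default_grids,
    gate_decision,
    grid_search_cv,
    make_estimator,
    predict,
    select_final_model,
)
from .metrics import MetricSet, round_percent
from .preprocess import (
    SplitResult,
    apoe_split,
    apply_scaler,
    concordance_filter,
    feature_matrix,
    fit_scaler,
    iqr_outlier_filter,
    labels_of,
    stratified_split,
    upsample_frame,
)


def _fit_gate(
    train: Cohort,
    test: Cohort | None,
    group: str,
    target_class: str,
    *,
    families: Sequence[str],
    grids: Mapping[str, list],
    beta: float,
    cv_folds: int,
    seed: int,
    scorer_metric: str = "f_beta",
    include_apoe: bool = False,
    feature_exclude: tuple[str, ...] = (),
    mi_fraction: float | None = None,
    upsample_within_folds: bool = False,
) -> GateModel:
    """Train one gate model on a training cohort.

    Order matches the reference pipeline: features assembled, scaled
    (training parameters only), minority class upsampled, then grid-search
    CV per family; rounded-percent selection with lazy holdout tie-break.
    """
    X = feature_matrix(train, include_apoe=include_apoe, exclude=feature_exclude)
    y = labels_of(train)
    if mi_fraction is not None:
        from .evaluate import mutual_info_rank, select_top

        ranked = mutual_info_rank(X, y, seed=seed)
        X = X[select_top(ranked, mi_fraction)]
    scaler = fit_scaler(X)
    Xs = apply_scaler(scaler, X)
    if not upsample_within_folds:
        Xs, y = upsample_frame(Xs, y, seed=seed)
    scorer = ScorerSpec(target_class=target_class, beta=beta, metric=scorer_metric)
    transitions = [
        grid_search_cv(Xs, y, fam, grids[fam], scorer, folds=cv_folds, seed=seed)
        for fam in families
    ]

    def _refit(tm: TransitionModel):
        est = make_estimator(tm.family, tm.params, seed=seed)
        est.fit(Xs.to_numpy(dtype=float), np.asarray(y))
        return est

    try:
        chosen, trail = select_final_model(transitions, expected=len(families))
    except TieBreakNeeded as tie:
        if test is None or len(test) == 0:
            raise
        # holdout scores computed only for the tied families, only on a tie
        holdout: dict[str, float] = {}
        X_test = feature_matrix(test, include_apoe=include_apoe, exclude=feature_exclude)
        Xs_test = apply_scaler(scaler, X_test)
        y_test = labels_of(test).to_numpy()
        for tm in transitions:
            if tm.family in tie.tied_families:
                est = _refit(tm)
                holdout[tm.family] = scorer.score(
                    y_test, est.predict(Xs_test.to_numpy(dtype=float))
                )
        chosen, trail = select_final_model(
            transitions, holdout_scores=holdout, expected=len(families)
        )
    classifier = _refit(chosen)
    return GateModel(
        apoe_group=group,
        majority_class=target_class,
        scaler=scaler,
        transition=chosen,
        classifier=classifier,
        selection_trail=trail,
        feature_spec={
            "include_apoe": include_apoe,
            "exclude": feature_exclude,
            "selected_features": list(X.columns),
        },
        beta=beta,
        seed=seed,
    )


def fit_pooled_classifier(
    cohort: Cohort,
    target_class: str,
    *,
    beta: float = 0.1,
    split_fraction: float = 0.7,
    cv_folds: int = 10,
    seed: int = 0,
    families: Sequence[str] | None = None,
    grids: Mapping[str, list] | None = None,
    scorer_metric: str = "f_beta",
    feature_exclude: tuple[str, ...] = (),
    mi_fraction: float | None = None,
    cutoffs: CutoffTable = DEFAULT_CUTOFFS,
) -> tuple[GateModel, Cohort]:
    """Non-gated reference fit: one classifier on the pooled training set,
    with APOE carriership as a binary input feature (unless excluded).

    Returns the fitted model (apoe_group ``pooled``) and the pooled test
    cohort.
    """
    families = tuple(families) if families else FAMILY_ORDER
    grids = dict(grids) if grids else default_grids()
    kept, _ = concordance_filter(cohort, cutoffs)
    kept, _ = iqr_outlier_filter(kept)
    split = stratified_split(kept, split_fraction, seed)
    gate = _fit_gate(
        split.train,
        split.test,
        group="pooled",
        target_class=target_class,
        families=families,
        grids=grids,
        beta=beta,
        cv_folds=cv_folds,
        seed=seed,
        scorer_metric=scorer_metric,
        include_apoe="apoe" not in feature_exclude,
        feature_exclude=feature_exclude,
        mi_fraction=mi_fraction,
    )
    return gate, split.test


class GatekeeperModel:
    """APOE-gated amyloid-status classification system.

    Parameters
    ----------
    cohort
        Labeled MCI cohort (gold amyloid status from tracer cutoffs).
    beta
        F-beta weight of the selection criterion; 0.1 weights precision ten
        times over recall.
    split_fraction
        Training fraction of the stratified split (per APOE group).
    cv_folds
        Folds of the stratified grid-search cross-validation.
    seed
        Drives the split, fold assignment, upsampling and any stochastic
        classifier; fixed seed means a bit-identical selection trail.
    families, grids
        Classifier families to search and their hyperparameter lattices
        (defaults: all six shipped families).
    iqr_k
        Multiplier of the per-region IQR outlier fences.
    feature_exclude, mi_fraction, scorer_metric, upsample_within_folds
        Ablation hooks: drop feature blocks, restrict to the top
        mutual-information fraction, switch the selection metric, or move
        upsampling inside CV folds (leakage-safe variant, off by default —
        the reference pipeline upsamples before cross-validation).
    """

    def __init__(
        self,
        cohort: Cohort,
        *,
        beta: float = 0.1,
        split_fraction: float = 0.7,
        cv_folds: int = 10,
        seed: int = 0,
        families: Sequence[str] | None = None,
        grids: Mapping[str, list] | None = None,
        iqr_k: float = 3.0,
        cutoffs: CutoffTable = DEFAULT_CUTOFFS,
        scorer_metric: str = "f_beta",
        feature_exclude: tuple[str, ...] = (),
        mi_fraction: float | None = None,
        upsample_within_folds: bool = False,
    ):
        self.cohort = cohort
        self.beta = beta
        self.split_fraction = split_fraction
        self.cv_folds = cv_folds
        self.seed = seed
        self.families = tuple(families) if families else FAMILY_ORDER
        self.grids = dict(grids) if grids else default_grids()
        self.iqr_k = iqr_k
        self.cutoffs = cutoffs
        self.scorer_metric = scorer_metric
        self.feature_exclude = tuple(feature_exclude)
        self.mi_fraction = mi_fraction
        self.upsample_within_folds = upsample_within_folds

    @classmethod
    def from_dataframe(
        cls,
        data: pd.DataFrame,
        followups: pd.DataFrame | None = None,
        region_names: Sequence[str] | None = None,
        **kwargs,
    ) -> "GatekeeperModel":
        """Build from a subject table (and optional follow-up table) using
        the standard column schema."""
        from .cohort import FOLLOWUP_COLUMNS, REGION_PREFIX

        if region_names is None:
            region_names = [
                c[len(REGION_PREFIX):] for c in data.columns if c.startswith(REGION_PREFIX)
            ]
        if followups is None:
            followups = pd.DataFrame(columns=FOLLOWUP_COLUMNS)
        cohort = Cohort(data.reset_index(drop=True), list(region_names), followups)
        return cls(cohort, **kwargs)

    def fit(self) -> "GatekeeperResults":
        """Run the full pipeline and return fitted results."""
        kept, exc_conc = concordance_filter(self.cohort, self.cutoffs)
        kept, exc_iqr = iqr_outlier_filter(kept, self.iqr_k)
        exclusions = pd.concat(
            [exc_conc.assign(stage="concordance"), exc_iqr.assign(stage="iqr")],
            ignore_index=True,
        )[["subject_id", "stage", "reason"]]
        nc, c = apoe_split(kept)
        splits: dict[str, SplitResult] = {}
        models: dict[str, GateModel] = {}
        for group, sub in ((APOE4_NC, nc), (APOE4_C, c)):
            split = stratified_split(sub, self.split_fraction, self.seed)
            splits[group] = split
            models[group] = _fit_gate(
                split.train,
                split.test,
                group=group,
                target_class=MAJORITY_CLASS[group],
                families=self.families,
                grids=self.grids,
                beta=self.beta,
                cv_folds=self.cv_folds,
                seed=self.seed,
                scorer_metric=self.scorer_metric,
                include_apoe=False,
                feature_exclude=self.feature_exclude,
                mi_fraction=self.mi_fraction,
                upsample_within_folds=self.upsample_within_folds,
            )
        return GatekeeperResults(
            model=self, models=models, splits=splits, exclusions=exclusions
        )


@dataclasses.dataclass
class GatekeeperResults:
    """Fitted gatekeeping system with its evaluation protocol."""

    model: GatekeeperModel
    models: dict[str, GateModel]
    splits: dict[str, SplitResult]
    exclusions: pd.DataFrame

    @property
    def groups(self) -> list[str]:
        return list(self.models)

    def test_cohort(self, group: str) -> Cohort:
        return self.splits[group].test

    def test_metrics(self, group: str) -> MetricSet:
        """Designated-class metrics of a group's final model on its
        held-out test set."""
        from .evaluate import test_metrics

        return test_metrics(self.models[group], self.splits[group].test)

    def balanced_audit(self, group: str, n_repeats: int | None = None, seed: int = 0):
        """Balanced-downsample overfitting audit on the group's test set."""
        from .evaluate import balanced_downsample_eval

        return balanced_downsample_eval(
            self.models[group], self.splits[group].test, n_repeats=n_repeats, seed=seed
        )

    def permutation_importance(
        self, group: str, n_perm: int = 1000, seed: int = 0
    ) -> pd.DataFrame:
        from .evaluate import permutation_importance

        return permutation_importance(
            self.models[group], self.splits[group].test, n_perm=n_perm, seed=seed
        )

    def predict_astatus(self, cohort: Cohort) -> pd.Series:
        """Predicted amyloid status per subject, routing each subject to its
        APOE group's gate model."""
        out = pd.Series(index=cohort.data["subject_id"], dtype=object, name="predicted")
        carrier = cohort.data["apoe4"].astype(bool).to_numpy()
        for group, mask in ((APOE4_NC, ~carrier), (APOE4_C, carrier)):
            if not mask.any():
                continue
            sub = cohort.subset(cohort.data.loc[mask, "subject_id"])
            labels, _ = predict(self.models[group], self.models[group].features(sub))
            out.loc[sub.data["subject_id"]] = labels
        return out

    def gate_decisions(self, cohort: Cohort | None = None) -> pd.DataFrame:
        """Route subjects through the gate: carriers are referred for
        amyloid testing; non-carriers are spared on a negative prediction.

        Defaults to the pooled held-out test sets of both groups.
        """
        if cohort is None:
            ids = pd.concat(
                [self.splits[g].test.data["subject_id"] for g in self.groups]
            )
            base = Cohort(
                pd.concat(
                    [self.splits[g].test.data for g in self.groups], ignore_index=True
                ),
                list(self.model.cohort.region_names),
                self.model.cohort.followups[
                    self.model.cohort.followups["subject_id"].isin(set(ids))
                ].reset_index(drop=True),
            )
            cohort = base
        predicted = self.predict_astatus(cohort)
        rows = []
        for sid, carrier in zip(
            cohort.data["subject_id"], cohort.data["apoe4"].astype(bool)
        ):
            pred = predicted.loc[sid]
            rows.append(
                {
                    "subject_id": sid,
                    "apoe_group": APOE4_C if carrier else APOE4_NC,
                    "predicted": pred,
                    "decision": gate_decision(bool(carrier), pred),
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        """Plain-text summary of selection and held-out performance."""
        lines = [
            "APOE-gated amyloid-status gatekeeping system",
            "=" * 60,
            f"cohort: {self.model.cohort.n_subjects} subjects "
            f"({len(self.exclusions)} excluded upstream of grouping)",
            f"selection: F_1/{int(round(1 / self.model.beta))} grid-search CV, "
            f"{self.model.cv_folds} folds, seed {self.model.seed}",
            "",
        ]
        for group in self.groups:
            gm = self.models[group]
            split = self.splits[group]
            m = self.test_metrics(group)
            tie = gm.selection_trail["tie_break"]
            lines += [
                f"{group}  (majority class {gm.majority_class})",
                "-" * 60,
                f"  train/test: {len(split.train)}/{len(split.test)} subjects",
                f"  final model: {gm.transition.family} {gm.transition.params}",
                f"  CV mean F_1/10: {gm.transition.cv_mean_f:.3f} "
                f"({round_percent(gm.transition.cv_mean_f)}%)"
                + ("  [tie-break used]" if tie["used"] else ""),
                f"  test precision {m.precision:.3f}  recall {m.recall:.3f}  "
                f"F_1/10 {m.f_1_10:.3f}  balanced acc {m.balanced_accuracy:.3f}",
                "",
            ]
        return "\n".join(lines)
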