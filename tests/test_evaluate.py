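"""Evaluation protocol: test metrics, balanced audit, permutation
importance, mutual-information ranking and the ablation grid."""

import numpy as np
import pandas as pd
import pytest

from amygate import GeneratorConfig, generate_cohort
from amygate.config import ABETA_NEG, ABETA_POS, APOE4_C, APOE4_NC
from amygate.evaluate import (
    AblationSpec,
    balanced_downsample_eval,
    mutual_info_rank,
    permutation_importance,
    run_ablation,
    select_top,
    test_metrics as designated_metrics,
)
from amygate.gatekeeper import GateModel, TransitionModel
from amygate.metrics import f_beta
from amygate.model import GatekeeperModel
from amygate.preprocess import feature_matrix, fit_scaler

from conftest import FAST_KWARGS, make_cohort


class _ConstantClassifier:
    """Always predicts one class; stands in for a prevalence-driven model."""

    def __init__(self, label):
        self.label = label

    def fit(self, X, y):
        return self

    def predict(self, X):
        return np.array([self.label] * len(X))


def _gate_with(classifier, cohort, group=APOE4_C, majority=ABETA_POS):
    X = feature_matrix(cohort)
    scaler = fit_scaler(X)
    return GateModel(
        apoe_group=group,
        majority_class=majority,
        scaler=scaler,
        transition=TransitionModel("KNN", {}, 1.0, (1.0,)),
        classifier=classifier,
        selection_trail={"candidates": [], "tie_break": {"used": False}},
        feature_spec={"include_apoe": False, "exclude": ()},
    )


class TestTestMetrics:
    def test_perfect_predictor_scores_one(self, fitted_small):
        gm = fitted_small.models[APOE4_C]
        test = fitted_small.splits[APOE4_C].test

        class Oracle:
            def predict(self, X):  # matches gold labels by construction
                return test.data["astatus"].to_numpy()

        oracle_gate = _gate_with(Oracle(), test)
        m = designated_metrics(oracle_gate, test)
        assert (m.precision, m.recall, m.f_1_10) == (1.0, 1.0, 1.0)

    def test_constant_majority_on_balanced_test(self):
        labels = [ABETA_POS] * 30 + [ABETA_NEG] * 30
        co = make_cohort(60, labels=labels, seed=1)
        gate = _gate_with(_ConstantClassifier(ABETA_POS), co)
        m = designated_metrics(gate, co)
        assert m.precision == 0.5 and m.recall == 1.0
        assert m.f_1_10 == pytest.approx(f_beta(0.5, 1.0, 0.1), abs=1e-12)
        assert m.f_1_10 == pytest.approx(0.50248756, abs=1e-6)

    def test_never_majority_gives_zero_by_convention(self):
        co = make_cohort(20, labels=[ABETA_POS] * 10 + [ABETA_NEG] * 10)
        gate = _gate_with(_ConstantClassifier(ABETA_NEG), co)
        m = designated_metrics(gate, co)
        assert m.precision == 0.0 and m.recall == 0.0 and m.f_1_10 == 0.0

    def test_empty_test_rejected(self, fitted_small, base_cohort):
        gm = fitted_small.models[APOE4_NC]
        with pytest.raises(ValueError, match="empty"):
            designated_metrics(gm, base_cohort.subset([]))


class TestBalancedAudit:
    def test_prevalence_classifier_converges_to_half_precision(self):
        labels = [ABETA_POS] * 80 + [ABETA_NEG] * 20
        co = make_cohort(100, labels=labels, seed=2)
        gate = _gate_with(_ConstantClassifier(ABETA_POS), co)
        audit = balanced_downsample_eval(gate, co, n_repeats=200, seed=0)
        assert audit.subset_size == 20
        assert audit.mean.recall == 1.0
        assert audit.mean.precision == pytest.approx(0.5, abs=1e-12)  # exact per subset
        assert (audit.per_repeat["precision"] == 0.5).all()

    def test_balanced_test_set_reduces_to_plain_metrics(self, fitted_small):
        labels = [ABETA_POS] * 25 + [ABETA_NEG] * 25
        co = make_cohort(50, labels=labels, seed=3)
        gm = _gate_with(_ConstantClassifier(ABETA_POS), co)
        audit = balanced_downsample_eval(gm, co, n_repeats=5, seed=1)
        plain = designated_metrics(gm, co)
        assert audit.mean.precision == plain.precision
        assert audit.mean.recall == plain.recall

    def test_single_repeat_reproducible(self, fitted_small):
        gm = fitted_small.models[APOE4_C]
        test = fitted_small.splits[APOE4_C].test
        a = balanced_downsample_eval(gm, test, n_repeats=1, seed=7)
        b = balanced_downsample_eval(gm, test, n_repeats=1, seed=7)
        pd.testing.assert_frame_equal(a.per_repeat, b.per_repeat)

    def test_default_repeats_are_subset_size_squared(self, fitted_small):
        gm = fitted_small.models[APOE4_C]
        test = fitted_small.splits[APOE4_C].test
        audit = balanced_downsample_eval(gm, test, seed=0, repeat_cap=50)
        assert audit.n_repeats == min(audit.subset_size**2, 50)


def _one_signal_cohort(n=260, n_regions=12, seed=0, effect=1.2):
    return generate_cohort(
        GeneratorConfig(
            n_subjects=n,
            n_regions=n_regions,
            signal_regions=(4,),
            effect_size=effect,
            region_correlation=0.0,
            seed=seed,
        )
    )


class TestPermutationImportance:
    def test_planted_signal_region_ranks_first(self):
        co = _one_signal_cohort(seed=5)
        res = GatekeeperModel(co, seed=5, **FAST_KWARGS).fit()
        table = res.permutation_importance(APOE4_C, n_perm=150, seed=0)
        assert table.iloc[0]["feature"] == "region_R004"

    def test_label_independent_feature_has_null_delta(self):
        co = _one_signal_cohort(seed=6)
        res = GatekeeperModel(co, seed=6, **FAST_KWARGS).fit()
        table = res.permutation_importance(APOE4_NC, n_perm=300, seed=1)
        null_delta = table.loc[table["feature"] == "sex", "delta"].iloc[0]
        assert abs(null_delta) < 0.02

    def test_delta_identity_and_determinism(self, fitted_small):
        gm = fitted_small.models[APOE4_C]
        test = fitted_small.splits[APOE4_C].test
        a = permutation_importance(gm, test, n_perm=20, seed=2)
        b = permutation_importance(gm, test, n_perm=20, seed=2)
        pd.testing.assert_frame_equal(a, b)
        np.testing.assert_allclose(
            a["delta"], a["baseline"] - a["mean_permuted"], atol=1e-12
        )

    def test_zero_permutations_rejected(self, fitted_small):
        gm = fitted_small.models[APOE4_C]
        with pytest.raises(ValueError, match="n_perm"):
            permutation_importance(gm, fitted_small.splits[APOE4_C].test, n_perm=0)


class TestMutualInformation:
    def test_planted_signal_ranks_first(self):
        co = _one_signal_cohort(n=500, seed=7, effect=1.5)
        # rank within the carrier training features, where prevalence is high
        X = feature_matrix(co)
        y = co.data["astatus"]
        ranked = mutual_info_rank(X, y, seed=0)
        assert ranked[0] == "region_R004"

    def test_select_top_ceiling(self):
        ranked = [f"f{i}" for i in range(93)]
        assert len(select_top(ranked, 0.10)) == 10
        assert select_top(ranked, 1.0) == ranked
        with pytest.raises(ValueError):
            select_top(ranked, 0.0)

    def test_constant_outcome_rejected(self):
        X = pd.DataFrame({"a": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match="constant"):
            mutual_info_rank(X, np.array([1, 1, 1]), seed=0)


class TestAblation:
    def test_spec_validation(self):
        with pytest.raises(ValueError, match="-APOE"):
            AblationSpec("GK", "f_beta", "-APOE")
        with pytest.raises(ValueError, match="variant"):
            AblationSpec("CL", "f_beta", "-MRI")

    def test_feature_set_audit(self, base_cohort):
        specs = [
            AblationSpec("GK", "f_beta", "-FDG"),
            AblationSpec("GK", "f_beta", "sub10"),
            AblationSpec("CL", "f_beta", "full"),
            AblationSpec("CL", "f_beta", "-APOE"),
        ]
        table = run_ablation(
            base_cohort, specs, seed=1, cv_folds=4, families=("LR",),
            grids={"LR": [{"C": 1.0}]},
        )
        no_fdg = table[table["variant"] == "-FDG"]
        assert (no_fdg["n_features"] == 2).all()  # age + sex only
        sub10 = table[table["variant"] == "sub10"]
        assert (sub10["n_features"] == 10).all()  # ceil(0.10 * 92)
        cl_full = table[(table["mode"] == "CL") & (table["variant"] == "full")]
        assert (cl_full["n_features"] == 93).all()  # age + sex + APOE + 90 regions
        cl_noapoe = table[(table["mode"] == "CL") & (table["variant"] == "-APOE")]
        assert (cl_noapoe["n_features"] == 92).all()

    def test_gatekeeping_beats_pooled_precision_on_apoe_structured_data(self):
        """With prevalence strongly structured by APOE, the gated models'
        designated-class precision is at least the pooled classifier's."""
        co = generate_cohort(GeneratorConfig(n_subjects=700, seed=13))
        specs = [AblationSpec("GK", "f_beta", "full"), AblationSpec("CL", "f_beta", "full")]
        table = run_ablation(
            co, specs, seed=2, cv_folds=5, families=("LR", "KNN"),
            grids={"LR": [{"C": 1.0}], "KNN": [{"n_neighbors": 11}]},
        )
        for cls in (ABETA_POS, ABETA_NEG):
            gk = table[(table["mode"] == "GK") & (table["target_class"] == cls)]
            cl = table[(table["mode"] == "CL") & (table["target_class"] == cls)]
            assert gk["precision"].iloc[0] >= cl["precision"].iloc[0] - 0.05

    def test_ablation_table_seed_deterministic(self, base_cohort):
        spec = [AblationSpec("GK", "f_beta", "full")]
        kw = dict(cv_folds=4, families=("LR",), grids={"LR": [{"C": 1.0}]})
        a = run_ablation(base_cohort, spec, seed=3, **kw)
        b = run_ablation(base_cohort, spec, seed=3, **kw)
        pd.testing.assert_frame_equal(a, b)

    def test_balanced_accuracy_objective_reports_both_classes(self, base_cohort):
        table = run_ablation(
            base_cohort,
            [AblationSpec("CL", "balanced_accuracy", "full")],
            seed=1,
            cv_folds=4,
            families=("LR",),
            grids={"LR": [{"C": 1.0}]},
        )
        assert set(table["target_class"]) == {ABETA_POS, ABETA_NEG}
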