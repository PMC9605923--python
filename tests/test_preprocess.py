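"""Data-preparation chain: labeling, filters, split, scaling, upsampling."""

import numpy as np
import pandas as pd
import pytest

from amygate import GeneratorConfig, generate_cohort
from amygate.config import ABETA_NEG, ABETA_POS
from amygate.preprocess import (
    apoe_split,
    apply_scaler,
    concordance_filter,
    feature_matrix,
    fit_scaler,
    iqr_outlier_filter,
    label_astatus,
    stratified_split,
    upsample_minority,
)

from conftest import make_cohort


@pytest.mark.parametrize(
    "tracer,suvr,expected",
    [
        ("AV45", 1.37, ABETA_POS),
        ("AV45", 1.11, ABETA_POS),  # boundary inclusive
        ("AV45", 1.109, ABETA_NEG),
        ("PiB", 1.41, ABETA_POS),
        ("FBB", 1.079, ABETA_NEG),
        ("FBB", 1.08, ABETA_POS),
    ],
)
def test_label_astatus_cutoffs(tracer, suvr, expected):
    assert label_astatus(tracer, suvr) == expected


def test_label_astatus_unknown_tracer():
    with pytest.raises(ValueError, match="tracer"):
        label_astatus("NAV4694", 1.5)


class TestConcordanceFilter:
    def test_discordant_subjects_excluded_with_reason(self):
        labels = [ABETA_NEG, ABETA_POS, ABETA_NEG, ABETA_POS]
        # csf 150 => CSF-positive; 250 => CSF-negative
        csf = [150.0, 250.0, np.nan, 150.0]
        co = make_cohort(4, labels=labels, csf=csf)
        kept, excluded = concordance_filter(co)
        assert set(excluded["subject_id"]) == {"T0000", "T0001"}
        reasons = dict(zip(excluded["subject_id"], excluded["reason"]))
        assert reasons["T0000"] == "csf-pos/pet-neg"
        assert reasons["T0001"] == "csf-neg/pet-pos"
        assert len(kept) == 2  # no-CSF and concordant subjects pass

    def test_boundary_value_is_csf_positive(self):
        co = make_cohort(2, labels=[ABETA_POS, ABETA_NEG], csf=[192.0, 192.0])
        kept, excluded = concordance_filter(co)
        assert list(excluded["subject_id"]) == ["T0001"]

    def test_concordant_synthetic_cohort_passes_whole(self):
        co = generate_cohort(
            GeneratorConfig(n_subjects=300, seed=11, p_csf_available=1.0, p_csf_discordant=0.0)
        )
        kept, excluded = concordance_filter(co)
        assert len(excluded) == 0 and len(kept) == 300


class TestIqrFilter:
    def test_injected_spike_is_the_only_exclusion(self):
        rng = np.random.default_rng(0)
        vals = np.exp(rng.normal(np.log(1.25), 0.05, (100, 4)))
        vals[17, 2] *= 2.5
        co = make_cohort(100, region_values=vals)
        kept, excluded = iqr_outlier_filter(co, k=3.0)
        assert list(excluded["subject_id"]) == ["T0017"]
        assert "R02" in excluded["reason"].iloc[0]
        assert len(kept) == 99

    def test_identical_values_produce_no_exclusions(self):
        vals = np.full((10, 3), 1.3)
        co = make_cohort(10, n_regions=3, region_values=vals)
        kept, excluded = iqr_outlier_filter(co)
        assert len(excluded) == 0  # IQR = 0; values on the fence are kept

    def test_infinite_k_keeps_everyone(self):
        co = make_cohort(50, seed=3)
        kept, excluded = iqr_outlier_filter(co, k=np.inf)
        assert len(excluded) == 0

    def test_too_few_subjects(self):
        with pytest.raises(ValueError, match=">= 4"):
            iqr_outlier_filter(make_cohort(3))

    def test_exclusion_set_matches_fence_oracle(self):
        """Exclusions equal an independently computed single-pass fence
        check on the full input cohort."""
        rng = np.random.default_rng(12)
        vals = np.exp(rng.normal(np.log(1.25), 0.3, (60, 5)))
        co = make_cohort(60, n_regions=5, region_values=vals)
        kept, excluded = iqr_outlier_filter(co, k=1.0)
        q1, q3 = np.percentile(vals, [25, 75], axis=0)
        lo, hi = q1 - (q3 - q1), q3 + (q3 - q1)
        expect = {
            co.data["subject_id"].iloc[i]
            for i in range(60)
            if ((vals[i] < lo) | (vals[i] > hi)).any()
        }
        assert set(excluded["subject_id"]) == expect
        assert len(kept) == 60 - len(expect)


class TestStratifiedSplit:
    def test_reported_class_sizes_round_correctly(self):
        labels = [ABETA_NEG] * 117 + [ABETA_POS] * 57
        co = make_cohort(174, labels=labels, seed=1)
        split = stratified_split(co, 0.7, seed=0)
        train_labels = split.train.data["astatus"]
        assert (train_labels == ABETA_NEG).sum() == 82
        assert (train_labels == ABETA_POS).sum() == 40
        assert len(split.train) + len(split.test) == 174
        assert set(split.train.data["subject_id"]).isdisjoint(
            set(split.test.data["subject_id"])
        )

    def test_fraction_one_returns_everything_as_train(self, base_cohort):
        split = stratified_split(base_cohort, 1.0, seed=0)
        assert len(split.test) == 0 and len(split.train) == len(base_cohort)

    def test_seeds_change_partition_not_counts(self):
        labels = [ABETA_NEG] * 60 + [ABETA_POS] * 40
        co = make_cohort(100, labels=labels, seed=2)
        s1 = stratified_split(co, 0.7, seed=1)
        s2 = stratified_split(co, 0.7, seed=2)
        assert sorted(s1.train.data["astatus"].value_counts()) == sorted(
            s2.train.data["astatus"].value_counts()
        )
        assert set(s1.train.data["subject_id"]) != set(s2.train.data["subject_id"])
        # deterministic per seed
        s1b = stratified_split(co, 0.7, seed=1)
        assert list(s1.train.data["subject_id"]) == list(s1b.train.data["subject_id"])

    def test_tiny_class_rejected(self):
        co = make_cohort(10, labels=[ABETA_POS] + [ABETA_NEG] * 9)
        with pytest.raises(ValueError):
            stratified_split(co, 0.7, seed=0)


class TestScaler:
    def test_hand_computed_standardization(self):
        df = pd.DataFrame({"age": [1.0, 2.0, 3.0], "sex": [0, 1, 0]})
        params = fit_scaler(df)
        out = apply_scaler(params, df)
        np.testing.assert_allclose(
            out["age"], [-1.224744871391589, 0.0, 1.224744871391589], atol=1e-12
        )
        assert list(out["sex"]) == [0, 1, 0]  # binary pass-through

    def test_train_columns_standardized(self, base_cohort):
        X = feature_matrix(base_cohort)
        params = fit_scaler(X)
        out = apply_scaler(params, X)
        cont = [c for c in out.columns if c != "sex"]
        assert np.abs(out[cont].mean()).max() < 1e-9
        assert np.abs(out[cont].std(ddof=0) - 1).max() < 1e-9

    def test_constant_column_named_in_error(self):
        df = pd.DataFrame({"age": [70.0, 70.0, 70.0], "x": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match="age"):
            fit_scaler(df, passthrough=())

    def test_test_rows_do_not_leak_into_params(self, base_cohort):
        """Scaler parameters are computed on the training partition only:
        perturbing test-subject values leaves them bit-identical."""
        split = stratified_split(base_cohort, 0.7, seed=4)
        params = fit_scaler(feature_matrix(split.train))
        perturbed = base_cohort.data.copy()
        test_ids = set(split.test.data["subject_id"])
        mask = perturbed["subject_id"].isin(test_ids)
        perturbed.loc[mask, "age"] += 100.0
        from amygate.cohort import Cohort

        co2 = Cohort(perturbed, base_cohort.region_names, base_cohort.followups)
        split2 = stratified_split(co2, 0.7, seed=4)
        params2 = fit_scaler(feature_matrix(split2.train))
        pd.testing.assert_series_equal(params.means, params2.means)
        pd.testing.assert_series_equal(params.sds, params2.sds)


class TestUpsampling:
    def test_counts_match_majority(self):
        labels = [ABETA_NEG] * 117 + [ABETA_POS] * 57
        co = make_cohort(174, labels=labels, seed=5)
        up = upsample_minority(co, seed=0)
        counts = up.data["astatus"].value_counts()
        assert counts[ABETA_NEG] == counts[ABETA_POS] == 117

    def test_added_rows_are_duplicates_and_majority_untouched(self):
        labels = [ABETA_NEG] * 20 + [ABETA_POS] * 5
        co = make_cohort(25, labels=labels, seed=6)
        up = upsample_minority(co, seed=1)
        region_cols = co.region_columns
        minority_rows = {
            tuple(r) for r in co.data.loc[co.data["astatus"] == ABETA_POS, region_cols].to_numpy()
        }
        added = up.data.iloc[25:]
        assert (added["astatus"] == ABETA_POS).all()
        for r in added[region_cols].to_numpy():
            assert tuple(r) in minority_rows
        pd.testing.assert_frame_equal(up.data.iloc[:25], co.data)
        # support unchanged: no new unique minority feature rows
        up_rows = {
            tuple(r) for r in up.data.loc[up.data["astatus"] == ABETA_POS, region_cols].to_numpy()
        }
        assert up_rows == minority_rows

    def test_balanced_input_unchanged(self):
        co = make_cohort(20, labels=[ABETA_NEG] * 10 + [ABETA_POS] * 10)
        assert upsample_minority(co, seed=0).data.equals(co.data)

    def test_single_minority_row_replicated(self):
        co = make_cohort(6, labels=[ABETA_NEG] * 5 + [ABETA_POS])
        up = upsample_minority(co, seed=0)
        assert (up.data["astatus"] == ABETA_POS).sum() == 5

    def test_deterministic_per_seed(self):
        labels = [ABETA_NEG] * 20 + [ABETA_POS] * 7
        co = make_cohort(27, labels=labels, seed=8)
        assert upsample_minority(co, seed=3).data.equals(upsample_minority(co, seed=3).data)


def test_apoe_split_partitions(base_cohort):
    nc, c = apoe_split(base_cohort)
    assert len(nc) + len(c) == len(base_cohort)
    assert not nc.data["apoe4"].any()
    assert c.data["apoe4"].all()


def test_apoe_split_empty_group_warns():
    co = make_cohort(6, apoe=[True] * 6)
    with pytest.warns(UserWarning, match="empty"):
        apoe_split(co)
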