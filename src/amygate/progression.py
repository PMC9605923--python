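"""Progression-to-dementia comparison between gold and predicted status.

Subjects with at least two follow-up diagnoses spanning at least six months
are eligible. The fraction progressing to dementia is compared between
gold-standard and classifier-predicted amyloid groups with a Pearson
chi-square test (alpha = 0.05, no continuity correction by default).
Dementia outcomes are sub-categorized by follow-up amyloid PET: probable AD
(PET-positive at or before diagnosis), non-AD dementia (PET-negative at or
after diagnosis), possible AD (no PET available around diagnosis).

Caveat recorded in every comparison: the gold and predicted groups overlap
in membership, so the two proportions are not from independent samples; the
test is reported exactly as the study protocol specifies, with this
annotation.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import Cohort
from .config import ABETA_NEG, ABETA_POS
from .metrics import round_percent

DEMENTIA = "dementia"
MIN_SPAN_MONTHS = 6.0


def eligible_subjects(cohort: Cohort, min_span_months: float = MIN_SPAN_MONTHS) -> Cohort:
    """Subjects with >= 2 follow-up diagnoses whose first and last visits
    are at least ``min_span_months`` apart."""
    if len(cohort.followups) == 0:
        return cohort.subset([])
    g = cohort.followups.groupby("subject_id")["months"]
    span = g.max() - g.min()
    count = g.count()
    ok = count[(count >= 2) & (span >= min_span_months)].index
    return cohort.subset(list(ok))


@dataclasses.dataclass
class ProgressionTable:
    """Progression counts of one amyloid group under one label source."""

    group: str  # e.g. APOE4-nc
    label_source: str  # gold | predicted
    target_class: str
    n_eligible: int
    n_progressed: int
    percent: int
    subcategories: dict  # probable_ad / non_ad / possible_ad counts

    def __post_init__(self) -> None:
        if self.n_progressed > self.n_eligible:
            raise ValueError("n_progressed cannot exceed n_eligible")
        if sum(self.subcategories.values()) != self.n_progressed:
            raise ValueError("subcategory counts must sum to n_progressed")
        expected = round_percent(
            self.n_progressed / self.n_eligible if self.n_eligible else 0.0
        )
        if self.percent != expected:
            raise ValueError(
                f"percent {self.percent} inconsistent with counts "
                f"{self.n_progressed}/{self.n_eligible} ({expected}%)"
            )


def _progressed_ids(cohort: Cohort) -> list[str]:
    fups = cohort.followups
    prog = fups.loc[fups["diagnosis"] == DEMENTIA, "subject_id"].unique()
    return list(prog)


def subcategorize_dementia(cohort: Cohort, progressed_ids) -> dict:
    """Partition progressed subjects into probable AD / non-AD dementia /
    possible AD by amyloid-PET status around the dementia diagnosis.

    Probable AD: amyloid-PET positive at or before the (first) dementia
    diagnosis. Non-AD dementia: PET negative at or after it. Possible AD:
    no PET available. The partition is exhaustive and mutually exclusive,
    applied in that order.
    """
    counts = {"probable_ad": 0, "non_ad": 0, "possible_ad": 0}
    fups = cohort.followups
    for sid in progressed_ids:
        f = fups[fups["subject_id"] == sid]
        t_dx = f.loc[f["diagnosis"] == DEMENTIA, "months"].min()
        pos_before = (
            (f["amyloid_pet_status"] == ABETA_POS) & (f["months"] <= t_dx)
        ).any()
        neg_after = (
            (f["amyloid_pet_status"] == ABETA_NEG) & (f["months"] >= t_dx)
        ).any()
        if pos_before:
            counts["probable_ad"] += 1
        elif neg_after:
            counts["non_ad"] += 1
        else:
            counts["possible_ad"] += 1
    return counts


def progression_rate(
    subset: Cohort,
    target_class: str,
    labels: pd.Series | None = None,
    label_source: str = "gold",
    group: str = "",
) -> ProgressionTable:
    """Progression table for subjects labeled ``target_class``.

    ``labels`` maps subject_id to an amyloid label (defaults to the gold
    column); a subject counts as progressed if any follow-up diagnosis is
    dementia. Percent is rounded to the nearest integer.
    """
    if labels is None:
        labels = pd.Series(
            subset.data["astatus"].to_numpy(),
            index=pd.Index(subset.data["subject_id"]),
        )
    ids = [sid for sid in subset.data["subject_id"] if labels.loc[sid] == target_class]
    if not ids:
        raise ValueError(f"no eligible subjects labeled {target_class}")
    sub = subset.subset(ids)
    progressed = _progressed_ids(sub)
    return ProgressionTable(
        group=group,
        label_source=label_source,
        target_class=target_class,
        n_eligible=len(ids),
        n_progressed=len(progressed),
        percent=round_percent(len(progressed) / len(ids)),
        subcategories=subcategorize_dementia(sub, progressed),
    )


@dataclasses.dataclass
class ChiSquareResult:
    """Pearson chi-square comparison of two progression proportions."""

    statistic: float
    df: int
    p_value: float
    alpha: float = 0.05
    significant: bool = False
    note: str = (
        "gold and predicted groups overlap in membership; proportions are "
        "not from independent samples"
    )

    def __post_init__(self) -> None:
        if not 0 <= self.p_value <= 1:
            raise ValueError("p_value outside [0,1]")
        self.significant = self.p_value < self.alpha


def chi_square_compare(
    table_a: ProgressionTable,
    table_b: ProgressionTable,
    alpha: float = 0.05,
    continuity_correction: bool = False,
) -> ChiSquareResult:
    """Pearson chi-square on the 2x2 (progressed vs not) x (label source)
    contingency table, df = 1, no continuity correction by default."""
    for t in (table_a, table_b):
        if t.n_eligible == 0:
            raise ValueError("degenerate progression table (n_eligible = 0)")
    obs = np.array(
        [
            [table_a.n_progressed, table_a.n_eligible - table_a.n_progressed],
            [table_b.n_progressed, table_b.n_eligible - table_b.n_progressed],
        ],
        dtype=float,
    )
    expected = stats.contingency.expected_freq(obs)
    if (expected == 0).any():
        raise ValueError(
            "expected cell count of zero; use an exact test for these counts"
        )
    stat, p, df, _ = stats.chi2_contingency(obs, correction=continuity_correction)
    return ChiSquareResult(statistic=float(stat), df=int(df), p_value=float(p), alpha=alpha)


def compare_progression(
    results,
    group: str,
    seed: int = 0,
) -> tuple[ProgressionTable, ProgressionTable, ChiSquareResult]:
    """End-to-end comparison on a fitted system's test set for one APOE
    group: gold vs predicted designated class, chi-square at 0.05."""
    test = results.splits[group].test
    eligible = eligible_subjects(test)
    target = results.models[group].majority_class
    gold = progression_rate(eligible, target, label_source="gold", group=group)
    predicted_labels = results.predict_astatus(eligible)
    pred = progression_rate(
        eligible, target, labels=predicted_labels, label_source="predicted", group=group
    )
    return gold, pred, chi_square_compare(gold, pred)
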