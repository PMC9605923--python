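"""Data-preparation chain for the gatekeeping analysis.

Stages, in the order the pipeline applies them: amyloid-status labeling from
tracer cutoffs, PET/CSF concordance filtering, per-region 3xIQR outlier
exclusion, APOE grouping, stratified train/test splitting, feature
standardization (train parameters applied to test), and minority-class
upsampling with replacement.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort import Cohort, REGION_PREFIX
from .config import ABETA_NEG, ABETA_POS, CutoffTable, DEFAULT_CUTOFFS


def label_astatus(
    amyloid_tracer: str,
    amyloid_global_suvr: float,
    cutoffs: CutoffTable = DEFAULT_CUTOFFS,
) -> str:
    """Amyloid status from the tracer-specific global SUVr cutoff.

    Positive iff the global SUVr is >= the tracer's threshold (boundary
    inclusive).
    """
    try:
        cut = cutoffs.suvr_cutoffs[amyloid_tracer]
    except KeyError:
        raise ValueError(
            f"unknown tracer {amyloid_tracer!r}; known: "
            f"{sorted(cutoffs.suvr_cutoffs)}"
        ) from None
    return ABETA_POS if amyloid_global_suvr >= cut else ABETA_NEG


def csf_label(csf_ab42: float, cutoffs: CutoffTable = DEFAULT_CUTOFFS) -> str:
    """CSF amyloid status: values at or below the cutoff (pg/ml) are positive."""
    return ABETA_POS if csf_ab42 <= cutoffs.csf_cutoff else ABETA_NEG


def concordance_filter(
    cohort: Cohort, cutoffs: CutoffTable = DEFAULT_CUTOFFS
) -> tuple[Cohort, pd.DataFrame]:
    """Exclude subjects whose CSF amyloid label contradicts the PET label.

    Subjects without a CSF measurement pass through. Returns the kept cohort
    and an exclusion table ``subject_id, reason`` with reason one of
    ``csf-neg/pet-pos`` or ``csf-pos/pet-neg``.
    """
    reasons = []
    keep = np.ones(len(cohort.data), dtype=bool)
    for i, (_, row) in enumerate(cohort.data.iterrows()):
        csf = row["csf_ab42"]
        if pd.isna(csf):
            continue
        c_label = csf_label(float(csf), cutoffs)
        p_label = row["astatus"]
        if c_label != p_label:
            keep[i] = False
            reason = (
                "csf-neg/pet-pos" if c_label == ABETA_NEG else "csf-pos/pet-neg"
            )
            reasons.append({"subject_id": row["subject_id"], "reason": reason})
    excluded = pd.DataFrame(reasons, columns=["subject_id", "reason"])
    kept = cohort.subset(cohort.data.loc[keep, "subject_id"])
    return kept, excluded


def iqr_outlier_filter(
    cohort: Cohort, k: float = 3.0
) -> tuple[Cohort, pd.DataFrame]:
    """Exclude subjects with any regional SUVr outside the k x IQR fences.

    Fences ``[Q1 - k*IQR, Q3 + k*IQR]`` are computed per region on the full
    input cohort in a single pass (not recomputed after exclusion); quartiles
    use linear interpolation. Values exactly on a fence are kept — exclusion
    requires falling strictly outside.
    """
    if len(cohort) < 4:
        raise ValueError(
            f"iqr_outlier_filter needs >= 4 subjects to define quartiles, got {len(cohort)}"
        )
    X = cohort.data[cohort.region_columns].to_numpy(dtype=float)
    q1, q3 = np.percentile(X, [25, 75], axis=0)  # linear interpolation
    iqr = q3 - q1
    lo, hi = q1 - k * iqr, q3 + k * iqr
    with np.errstate(invalid="ignore"):
        outside = (X < lo) | (X > hi)
    bad = outside.any(axis=1)
    reasons = []
    region_names = np.array(cohort.region_names)
    for i in np.flatnonzero(bad):
        regions = region_names[outside[i]]
        reasons.append(
            {
                "subject_id": cohort.data.iloc[i]["subject_id"],
                "reason": "iqr-outlier:" + ",".join(regions[:3]),
            }
        )
    excluded = pd.DataFrame(reasons, columns=["subject_id", "reason"])
    kept = cohort.subset(cohort.data.loc[~bad, "subject_id"])
    return kept, excluded


def apoe_split(cohort: Cohort) -> tuple[Cohort, Cohort]:
    """Partition into (non-carriers, carriers) of the APOE-e4 allele."""
    carrier = cohort.data["apoe4"].astype(bool).to_numpy()
    nc = cohort.subset(cohort.data.loc[~carrier, "subject_id"])
    c = cohort.subset(cohort.data.loc[carrier, "subject_id"])
    for name, group in (("non-carrier", nc), ("carrier", c)):
        if len(group) == 0:
            warnings.warn(f"APOE {name} group is empty", stacklevel=2)
    return nc, c


@dataclasses.dataclass
class SplitResult:
    """A stratified train/test partition of a cohort."""

    train: Cohort
    test: Cohort
    fraction: float
    seed: int


def _train_counts(class_sizes: list[int], fraction: float) -> list[int]:
    """Per-class train counts: floors plus largest-remainder top-up so the
    total equals round-half-up(fraction * n)."""
    n = sum(class_sizes)
    target = int(math.floor(fraction * n + 0.5))
    raw = [fraction * s for s in class_sizes]
    base = [int(math.floor(r)) for r in raw]
    short = target - sum(base)
    # distribute remaining slots by largest fractional remainder; break ties
    # toward the larger class, then class order
    order = sorted(
        range(len(class_sizes)),
        key=lambda i: (-(raw[i] - base[i]), -class_sizes[i], i),
    )
    counts = list(base)
    for i in order[: max(short, 0)]:
        counts[i] += 1
    counts = [min(c, s) for c, s in zip(counts, class_sizes)]
    return counts


def stratified_split(
    cohort: Cohort, fraction: float = 0.7, seed: int = 0
) -> SplitResult:
    """Random train/test split stratified on amyloid status.

    Per-class train counts follow the global fraction (largest-remainder
    rounding); the partition is deterministic for a fixed seed. Requires both
    classes present with at least two members each (unless fraction == 1.0,
    which returns the full cohort as train).
    """
    labels = cohort.data["astatus"].to_numpy()
    classes = [ABETA_NEG, ABETA_POS]
    sizes = [int(np.sum(labels == c)) for c in classes]
    if fraction >= 1.0:
        empty = cohort.subset([])
        return SplitResult(train=cohort, test=empty, fraction=fraction, seed=seed)
    if any(s == 0 for s in sizes):
        raise ValueError(f"both classes required for a stratified split; sizes {sizes}")
    if any(s < 2 for s in sizes):
        raise ValueError(f"each class needs >= 2 members to split; sizes {sizes}")
    rng = np.random.default_rng(seed)
    counts = _train_counts(sizes, fraction)
    train_ids: list[str] = []
    for cls, n_train in zip(classes, counts):
        ids = cohort.data.loc[labels == cls, "subject_id"].to_numpy()
        chosen = rng.choice(ids, size=n_train, replace=False)
        train_ids.extend(chosen.tolist())
    train_set = set(train_ids)
    test_ids = [s for s in cohort.data["subject_id"] if s not in train_set]
    return SplitResult(
        train=cohort.subset(train_ids),
        test=cohort.subset(test_ids),
        fraction=fraction,
        seed=seed,
    )


@dataclasses.dataclass(frozen=True)
class ScalerParams:
    """Per-feature standardization parameters estimated on a training set.

    Continuous features are centered and scaled to unit variance (population
    SD, i.e. divide by n); features in ``passthrough`` (binary codes such as
    sex or APOE carriership) are left untouched.
    """

    means: pd.Series
    sds: pd.Series
    passthrough: tuple[str, ...]

    @property
    def feature_names(self) -> list[str]:
        return list(self.means.index) + list(self.passthrough)


def fit_scaler(
    features: pd.DataFrame, passthrough: Sequence[str] = ("sex", "apoe4")
) -> ScalerParams:
    """Estimate standardization parameters on training features.

    Raises ``ValueError`` naming any zero-variance continuous feature.
    """
    passthrough = tuple(c for c in passthrough if c in features.columns)
    cont = [c for c in features.columns if c not in passthrough]
    means = features[cont].mean()
    sds = features[cont].std(ddof=0)
    zero = sds.index[sds <= 0].tolist()
    if zero:
        raise ValueError(f"zero-variance features cannot be standardized: {zero}")
    return ScalerParams(means=means, sds=sds, passthrough=passthrough)


def apply_scaler(params: ScalerParams, features: pd.DataFrame) -> pd.DataFrame:
    """Apply training-set standardization to a feature table."""
    missing = [c for c in params.feature_names if c not in features.columns]
    if missing:
        raise ValueError(f"feature table missing columns: {missing}")
    out = features.copy()
    cont = list(params.means.index)
    out[cont] = (features[cont] - params.means) / params.sds
    return out[params.feature_names]


def feature_matrix(
    cohort: Cohort,
    include_apoe: bool = False,
    exclude: Sequence[str] = (),
    regions: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Assemble the classifier input table: age, sex and regional SUVr.

    ``include_apoe`` adds binary APOE-e4 carriership (used by non-gated
    classification). ``exclude`` drops feature blocks by name: ``age``,
    ``sex``, ``fdg`` (all regions) or ``apoe``. ``regions`` restricts the
    SUVr block to a subset of region names.
    """
    cols: dict[str, pd.Series] = {}
    if "age" not in exclude:
        cols["age"] = cohort.data["age"].astype(float)
    if "sex" not in exclude:
        cols["sex"] = cohort.data["sex"].astype(int)
    if include_apoe and "apoe" not in exclude:
        cols["apoe4"] = cohort.data["apoe4"].astype(int)
    if "fdg" not in exclude:
        names = cohort.region_names if regions is None else list(regions)
        for name in names:
            cols[REGION_PREFIX + name] = cohort.data[REGION_PREFIX + name].astype(float)
    out = pd.DataFrame(cols)
    out.index = pd.Index(cohort.data["subject_id"], name="subject_id")
    return out


def labels_of(cohort: Cohort) -> pd.Series:
    """Gold-standard amyloid-status labels indexed by subject id."""
    s = pd.Series(
        cohort.data["astatus"].to_numpy(),
        index=pd.Index(cohort.data["subject_id"], name="subject_id"),
        name="astatus",
    )
    return s


def upsample_minority(cohort: Cohort, seed: int = 0) -> Cohort:
    """Balance a training cohort by duplicating minority-class rows.

    Minority rows are sampled with replacement until the class counts match;
    majority rows are untouched. Duplicated rows get a ``#r<k>`` suffix on
    the subject id to keep ids unique. Deterministic per seed; a cohort that
    is already balanced is returned unchanged.
    """
    labels = cohort.data["astatus"].to_numpy()
    n_neg = int(np.sum(labels == ABETA_NEG))
    n_pos = int(np.sum(labels == ABETA_POS))
    if n_neg == 0 or n_pos == 0:
        raise ValueError("both classes required for upsampling")
    if n_neg == n_pos:
        return cohort
    minority = ABETA_POS if n_pos < n_neg else ABETA_NEG
    deficit = abs(n_neg - n_pos)
    rng = np.random.default_rng(seed)
    pool = cohort.data.index[labels == minority].to_numpy()
    picks = rng.choice(pool, size=deficit, replace=True)
    dup = cohort.data.loc[picks].copy()
    dup["subject_id"] = [
        f"{sid}#r{k}" for k, sid in enumerate(dup["subject_id"], start=1)
    ]
    data = pd.concat([cohort.data, dup], ignore_index=True)
    return Cohort(data, list(cohort.region_names), cohort.followups, dict(cohort.provenance))


def upsample_frame(
    X: pd.DataFrame, y: pd.Series, seed: int = 0
) -> tuple[pd.DataFrame, pd.Series]:
    """Minority upsampling on a feature table / label series pair.

    Same mechanism as :func:`upsample_minority`, applied after scaling inside
    the training pipeline.
    """
    counts = y.value_counts()
    if len(counts) < 2:
        raise ValueError("both classes required for upsampling")
    if counts.iloc[0] == counts.iloc[-1]:
        return X, y
    minority = counts.idxmin()
    deficit = int(counts.max() - counts.min())
    rng = np.random.default_rng(seed)
    pool = np.flatnonzero((y == minority).to_numpy())
    picks = rng.choice(pool, size=deficit, replace=True)
    X_up = pd.concat([X, X.iloc[picks]], ignore_index=False)
    y_up = pd.concat([y, y.iloc[picks]], ignore_index=False)
    return X_up, y_up
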