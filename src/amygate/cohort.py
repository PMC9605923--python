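"""Cohort container and plain-CSV serialization.

A :class:`Cohort` holds one row per MCI subject in a pandas DataFrame
(demographics, APOE carriership, the regional FDG SUVr vector, amyloid
measurements, optional CSF) plus a long-format follow-up table. It is the
object every pipeline stage consumes and emits.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .config import ABETA_NEG, ABETA_POS

REGION_PREFIX = "region_"

#: Non-region columns of the subject table, in serialization order.
BASE_COLUMNS = [
    "subject_id",
    "age",
    "sex",
    "apoe4",
    "tracer",
    "amyloid_suvr",
    "csf_ab42",
    "astatus",
]

FOLLOWUP_COLUMNS = ["subject_id", "months", "diagnosis", "amyloid_pet_status"]


@dataclasses.dataclass
class SubjectRecord:
    """One MCI subject, as a plain record."""

    subject_id: str
    age: float
    sex: int  # male = 0, female = 1
    apoe4_carrier: bool
    fdg_suvr: np.ndarray
    amyloid_tracer: str
    amyloid_global_suvr: float
    csf_ab42: float | None
    astatus_gold: str
    followups: list[tuple[float, str, str]]  # (months, diagnosis, amyloid_pet_status)


@dataclasses.dataclass
class Cohort:
    """An ordered collection of subjects sharing a region schema.

    Attributes
    ----------
    data
        One row per subject; columns ``subject_id, age, sex, apoe4, tracer,
        amyloid_suvr, csf_ab42, astatus`` followed by one ``region_<name>``
        column per region.
    region_names
        Region labels, without the ``region_`` prefix.
    followups
        Long-format table ``subject_id, months, diagnosis,
        amyloid_pet_status``; may be empty.
    provenance
        ``{"source": "synthetic", "seed": ...}`` or ``{"source": "file",
        "path": ...}``.
    """

    data: pd.DataFrame
    region_names: list[str]
    followups: pd.DataFrame = dataclasses.field(
        default_factory=lambda: pd.DataFrame(columns=FOLLOWUP_COLUMNS)
    )
    provenance: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in BASE_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"cohort table missing columns: {missing}")
        missing_regions = [
            name for name in self.region_names
            if REGION_PREFIX + name not in self.data.columns
        ]
        if missing_regions:
            raise ValueError(f"cohort table missing region columns: {missing_regions}")
        ids = self.data["subject_id"]
        if ids.duplicated().any():
            dupes = ids[ids.duplicated()].unique().tolist()
            raise ValueError(f"duplicate subject_ids: {dupes[:5]}")
        if len(self.data) and (self.data[self.region_columns].to_numpy() <= 0).any():
            raise ValueError("fdg_suvr values must be strictly positive")
        bad_status = set(self.data["astatus"]) - {ABETA_NEG, ABETA_POS}
        if bad_status:
            raise ValueError(f"unknown astatus labels: {sorted(bad_status)}")
        if len(self.followups):
            months = self.followups.groupby("subject_id")["months"]
            if (months.apply(lambda m: not m.is_monotonic_increasing)).any():
                raise ValueError("followups must be strictly increasing in time")

    # -- basic API -----------------------------------------------------

    @property
    def region_columns(self) -> list[str]:
        return [REGION_PREFIX + name for name in self.region_names]

    @property
    def n_subjects(self) -> int:
        return len(self.data)

    def __len__(self) -> int:
        return len(self.data)

    def subset(self, mask_or_ids) -> "Cohort":
        """Return a new cohort restricted to a boolean mask or id sequence."""
        if isinstance(mask_or_ids, (pd.Series, np.ndarray)) and getattr(
            mask_or_ids, "dtype", None
        ) == bool:
            data = self.data.loc[np.asarray(mask_or_ids)]
        else:
            ids = set(mask_or_ids)
            data = self.data[self.data["subject_id"].isin(ids)]
        fups = self.followups[
            self.followups["subject_id"].isin(set(data["subject_id"]))
        ]
        return Cohort(
            data.reset_index(drop=True),
            list(self.region_names),
            fups.reset_index(drop=True),
            dict(self.provenance),
        )

    def subjects(self) -> Iterator[SubjectRecord]:
        """Iterate subjects as plain records."""
        fups_by_id: dict[str, list] = {}
        for _, row in self.followups.iterrows():
            fups_by_id.setdefault(row["subject_id"], []).append(
                (row["months"], row["diagnosis"], row["amyloid_pet_status"])
            )
        region_cols = self.region_columns
        for _, row in self.data.iterrows():
            csf = row["csf_ab42"]
            yield SubjectRecord(
                subject_id=row["subject_id"],
                age=float(row["age"]),
                sex=int(row["sex"]),
                apoe4_carrier=bool(row["apoe4"]),
                fdg_suvr=row[region_cols].to_numpy(dtype=float),
                amyloid_tracer=row["tracer"],
                amyloid_global_suvr=float(row["amyloid_suvr"]),
                csf_ab42=None if pd.isna(csf) else float(csf),
                astatus_gold=row["astatus"],
                followups=fups_by_id.get(row["subject_id"], []),
            )


def _followup_path(path: Path) -> Path:
    return path.with_name(path.stem + "_followups" + path.suffix)


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    """Write a cohort to ``path`` (subjects CSV) plus a companion
    ``<stem>_followups.csv`` long-format table."""
    path = Path(path)
    cols = BASE_COLUMNS + cohort.region_columns
    # pandas' default float formatting is the shortest round-trip repr,
    # so write-then-read reproduces every value exactly
    cohort.data[cols].to_csv(path, index=False)
    cohort.followups[FOLLOWUP_COLUMNS].to_csv(_followup_path(path), index=False)


def read_cohort(path: str | Path, region_names: Sequence[str] | None = None) -> Cohort:
    """Read a cohort written by :func:`write_cohort`.

    Region names are inferred from the ``region_`` columns unless given.
    Raises ``ValueError`` naming any missing schema column.
    """
    path = Path(path)
    data = pd.read_csv(
        path,
        dtype={"subject_id": str, "tracer": str, "astatus": str},
        float_precision="round_trip",
    )
    missing = [c for c in BASE_COLUMNS if c not in data.columns]
    if missing:
        raise ValueError(f"cohort file {path} missing columns: {missing}")
    if region_names is None:
        region_names = [
            c[len(REGION_PREFIX):] for c in data.columns if c.startswith(REGION_PREFIX)
        ]
    else:
        missing_regions = [
            REGION_PREFIX + r for r in region_names
            if REGION_PREFIX + r not in data.columns
        ]
        if missing_regions:
            raise ValueError(f"cohort file {path} missing columns: {missing_regions}")
    fpath = _followup_path(path)
    if fpath.exists():
        followups = pd.read_csv(
            fpath,
            dtype={"subject_id": str, "diagnosis": str, "amyloid_pet_status": str},
            float_precision="round_trip",
        )
    else:
        followups = pd.DataFrame(columns=FOLLOWUP_COLUMNS)
    data["apoe4"] = data["apoe4"].astype(bool)
    data["sex"] = data["sex"].astype(int)
    return Cohort(
        data,
        list(region_names),
        followups,
        provenance={"source": "file", "path": str(path)},
    )
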