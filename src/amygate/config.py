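"""Configuration objects: tracer cutoffs and the synthetic-cohort generator.

All probabilities, rates and distribution parameters that define a synthetic
MCI cohort live in :class:`GeneratorConfig`. Defaults reproduce the
statistical structure of the ADNI-style training sample the gatekeeping
analysis assumes: APOE-e4-dependent amyloid prevalence (~33% positive in
non-carriers, ~83% in carriers), an age shift in the amyloid-positive groups,
a network-structured hypometabolism signal in regional FDG SUVr, and
tracer-specific global amyloid SUVr distributions around the published
positivity cutoffs.
"""

from __future__ import annotations

import math
from typing import Mapping

from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

from .regions import AAL90, DEFAULT_SIGNAL_REGIONS

# Amyloid-status labels used throughout the package.
ABETA_POS = "Abeta+"
ABETA_NEG = "Abeta-"

# APOE-e4 group labels.
APOE4_NC = "APOE4-nc"
APOE4_C = "APOE4-c"

TRACERS = ("AV45", "PiB", "FBB")


class CutoffTable(BaseModel):
    """Tracer-specific global amyloid SUVr positivity thresholds.

    A subject is amyloid positive when the global SUVr is greater than or
    equal to the tracer's threshold. On CSF, amyloid-beta 1-42 values at or
    below ``csf_cutoff`` (pg/ml) indicate positivity.
    """

    model_config = ConfigDict(frozen=True)

    suvr_cutoffs: Mapping[str, float] = Field(
        default={"AV45": 1.11, "PiB": 1.41, "FBB": 1.08}
    )
    csf_cutoff: float = 192.0

    @field_validator("suvr_cutoffs")
    @classmethod
    def _positive_thresholds(cls, v: Mapping[str, float]) -> Mapping[str, float]:
        for tracer, cut in v.items():
            if cut <= 0:
                raise ValueError(f"cutoff for {tracer} must be > 0, got {cut}")
        return dict(v)

    @field_validator("csf_cutoff")
    @classmethod
    def _positive_csf(cls, v: float) -> float:
        if v <= 0:
            raise ValueError("csf_cutoff must be > 0")
        return v


DEFAULT_CUTOFFS = CutoffTable()


class MeanSD(BaseModel):
    """A (mean, SD) pair for a normal distribution."""

    model_config = ConfigDict(frozen=True)

    mean: float
    sd: float = Field(gt=0)


class FollowupConfig(BaseModel):
    """Longitudinal follow-up process of the synthetic cohort.

    Visits occur every ``visit_interval_months`` up to ``horizon_months``.
    Progression to dementia is geometric over visits, with the per-visit
    hazard solved so that the cumulative conversion probability over the
    horizon equals ``p_progress_given_astatus`` for each amyloid status.
    At the visit of a dementia diagnosis an amyloid PET reflecting the gold
    standard status is available with probability ``p_followup_pet``.
    """

    model_config = ConfigDict(frozen=True)

    p_has_followups: float = Field(default=0.8, ge=0, le=1)
    visit_interval_months: int = Field(default=6, gt=0)
    horizon_months: int = Field(default=60, gt=0)
    p_progress_given_astatus: Mapping[str, float] = Field(
        default={ABETA_POS: 0.43, ABETA_NEG: 0.12}
    )
    p_followup_pet: float = Field(default=0.3, ge=0, le=1)

    @field_validator("p_progress_given_astatus")
    @classmethod
    def _valid_progress(cls, v: Mapping[str, float]) -> Mapping[str, float]:
        missing = {ABETA_POS, ABETA_NEG} - set(v)
        if missing:
            raise ValueError(f"p_progress_given_astatus missing keys {sorted(missing)}")
        for k, p in v.items():
            if not 0 <= p <= 1:
                raise ValueError(f"p_progress_given_astatus[{k}] outside [0,1]: {p}")
        return dict(v)


def _default_age_params() -> dict:
    # Training-sample demographics: mean age (SD) per APOE group x A-status.
    return {
        "noncarrier": {
            ABETA_NEG: MeanSD(mean=70.6, sd=7.65),
            ABETA_POS: MeanSD(mean=74.5, sd=7.25),
        },
        "carrier": {
            ABETA_NEG: MeanSD(mean=67.1, sd=8.08),
            ABETA_POS: MeanSD(mean=72.4, sd=6.59),
        },
    }


def _default_amyloid_suvr_params() -> dict:
    # AV45 means/SDs follow the training-sample demographics; PiB and FBB are
    # plausible distributions straddling the published cutoffs (1.41, 1.08).
    return {
        "AV45": {ABETA_NEG: MeanSD(mean=1.00, sd=0.05), ABETA_POS: MeanSD(mean=1.37, sd=0.17)},
        "PiB": {ABETA_NEG: MeanSD(mean=1.20, sd=0.10), ABETA_POS: MeanSD(mean=1.70, sd=0.20)},
        "FBB": {ABETA_NEG: MeanSD(mean=0.95, sd=0.05), ABETA_POS: MeanSD(mean=1.40, sd=0.18)},
    }


class GeneratorConfig(BaseModel):
    """Full parameterization of a synthetic MCI cohort.

    Parameters
    ----------
    n_subjects
        Cohort size.
    p_apoe4
        Probability of APOE-e4 carriership (>= 1 e4 allele).
    p_abeta_pos_given_apoe
        Amyloid-positive prevalence per APOE group, keys ``carrier`` /
        ``noncarrier``. Defaults 0.83 / 0.33.
    age_means_sds
        Mean/SD of age (years) per APOE group and amyloid status.
    p_female
        Probability of female sex (coded 1).
    n_regions, region_names
        Size and labels of the regional FDG SUVr vector (AAL-90 by default).
    signal_regions
        0-based indices of regions carrying the amyloid-status effect.
    effect_size
        Standardized mean decrease of SUVr in signal regions for
        amyloid-positive subjects (Cohen's d on the log scale).
    region_correlation
        Exchangeable correlation of regional noise within a network block,
        in [0, 1).
    network_size
        Number of regions per correlated network block.
    tracer_mix
        Proportions of amyloid tracers over {AV45, PiB, FBB}; must sum to 1.
    amyloid_suvr_params
        Mean/SD of global amyloid SUVr per tracer and amyloid status.
    p_csf_available, p_csf_discordant
        Probability that CSF amyloid-beta 1-42 was measured, and that a
        measured CSF label contradicts the PET label.
    followup
        Longitudinal follow-up process, see :class:`FollowupConfig`.
    outlier_rate
        Per-subject probability of one extreme (x2.5) region value.
    seed
        Seed of the generator; identical configs produce identical cohorts.
    """

    model_config = ConfigDict(frozen=True)

    n_subjects: int = Field(default=500, gt=0)
    p_apoe4: float = Field(default=0.49, ge=0, le=1)
    p_abeta_pos_given_apoe: Mapping[str, float] = Field(
        default={"carrier": 0.83, "noncarrier": 0.33}
    )
    age_means_sds: Mapping[str, Mapping[str, MeanSD]] = Field(
        default_factory=_default_age_params
    )
    p_female: float = Field(default=0.46, ge=0, le=1)
    n_regions: int = Field(default=90, gt=0)
    region_names: tuple[str, ...] | None = None
    signal_regions: tuple[int, ...] = DEFAULT_SIGNAL_REGIONS
    effect_size: float = Field(default=0.8, ge=0)
    region_correlation: float = Field(default=0.3, ge=0, lt=1)
    network_size: int = Field(default=10, gt=0)
    log_suvr_mean: float = math.log(1.25)
    log_suvr_sd: float = Field(default=0.08, gt=0)
    tracer_mix: Mapping[str, float] = Field(
        default={"AV45": 0.86, "PiB": 0.024, "FBB": 0.116}
    )
    amyloid_suvr_params: Mapping[str, Mapping[str, MeanSD]] = Field(
        default_factory=_default_amyloid_suvr_params
    )
    p_csf_available: float = Field(default=0.5, ge=0, le=1)
    p_csf_discordant: float = Field(default=0.09, ge=0, le=1)
    csf_params: Mapping[str, MeanSD] = Field(
        default={ABETA_POS: MeanSD(mean=140.0, sd=25.0), ABETA_NEG: MeanSD(mean=230.0, sd=30.0)}
    )
    followup: FollowupConfig = Field(default_factory=FollowupConfig)
    outlier_rate: float = Field(default=0.0, ge=0, le=1)
    outlier_factor: float = Field(default=2.5, gt=0)
    cutoffs: CutoffTable = Field(default_factory=lambda: DEFAULT_CUTOFFS)
    seed: int = 0

    @field_validator("p_abeta_pos_given_apoe")
    @classmethod
    def _valid_prevalence(cls, v: Mapping[str, float]) -> Mapping[str, float]:
        missing = {"carrier", "noncarrier"} - set(v)
        if missing:
            raise ValueError(f"p_abeta_pos_given_apoe missing keys {sorted(missing)}")
        for k, p in v.items():
            if not 0 <= p <= 1:
                raise ValueError(f"p_abeta_pos_given_apoe[{k}] outside [0,1]: {p}")
        return dict(v)

    @field_validator("tracer_mix")
    @classmethod
    def _valid_mix(cls, v: Mapping[str, float]) -> Mapping[str, float]:
        unknown = set(v) - set(TRACERS)
        if unknown:
            raise ValueError(f"tracer_mix has unknown tracers {sorted(unknown)}")
        total = sum(v.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"tracer_mix must sum to 1 (got {total})")
        if any(p < 0 for p in v.values()):
            raise ValueError("tracer_mix proportions must be >= 0")
        return dict(v)

    @model_validator(mode="after")
    def _cross_field(self) -> "GeneratorConfig":
        if self.region_names is not None and len(self.region_names) != self.n_regions:
            raise ValueError(
                f"region_names has {len(self.region_names)} entries, "
                f"n_regions is {self.n_regions}"
            )
        bad = [i for i in self.signal_regions if not 0 <= i < self.n_regions]
        if bad:
            raise ValueError(f"signal_regions indices out of range: {bad}")
        for group, per_status in self.age_means_sds.items():
            missing = {ABETA_POS, ABETA_NEG} - set(per_status)
            if missing:
                raise ValueError(f"age_means_sds[{group}] missing {sorted(missing)}")
        return self

    def resolved_region_names(self) -> list[str]:
        if self.region_names is not None:
            return list(self.region_names)
        if self.n_regions == 90:
            return list(AAL90)
        return [f"R{i:03d}" for i in range(self.n_regions)]
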