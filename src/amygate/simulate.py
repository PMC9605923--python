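"""Seeded synthetic MCI cohort generator.

Emulates the statistical structure the gatekeeping analysis assumes, without
any image synthesis:

* APOE-e4-dependent amyloid-positive prevalence (defaults ~83% in carriers,
  ~33% in non-carriers) and an age shift in the positive groups;
* a network-structured hypometabolism signal: regional FDG SUVr is
  log-normal with exchangeable within-network correlation, and
  amyloid-positive subjects have their mean lowered by a configurable
  standardized effect in a designated set of signal regions;
* tracer-specific global amyloid SUVr drawn on the correct side of the
  published positivity cutoff, so gold label and value always agree;
* optional CSF amyloid-beta 1-42 values with a configurable PET/CSF
  discordance rate;
* longitudinal follow-up visits with amyloid-status-dependent progression
  to dementia (geometric over visits).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cohort import Cohort, FOLLOWUP_COLUMNS, REGION_PREFIX
from .config import ABETA_NEG, ABETA_POS, GeneratorConfig


def _truncated_normal(
    rng: np.random.Generator,
    mean: np.ndarray,
    sd: np.ndarray,
    lower: np.ndarray,
    upper: np.ndarray,
    max_iter: int = 1000,
) -> np.ndarray:
    """Elementwise normal draws restricted to [lower, upper] by resampling."""
    x = rng.normal(mean, sd)
    for _ in range(max_iter):
        bad = (x < lower) | (x > upper)
        if not bad.any():
            return x
        x = np.where(bad, rng.normal(mean, sd), x)
    return np.clip(x, lower, upper)


def _regional_suvr(
    rng: np.random.Generator, cfg: GeneratorConfig, apos: np.ndarray
) -> np.ndarray:
    """Log-normal regional SUVr with block-exchangeable correlation.

    Within each network block of ``network_size`` consecutive regions, the
    standardized log-SUVr shares a common factor with loading
    sqrt(region_correlation). Amyloid-positive subjects have the mean of
    each signal region lowered by ``effect_size`` standardized units.
    """
    n, p = len(apos), cfg.n_regions
    rho = cfg.region_correlation
    n_blocks = int(np.ceil(p / cfg.network_size))
    block_of = np.minimum(np.arange(p) // cfg.network_size, n_blocks - 1)
    factors = rng.standard_normal((n, n_blocks))
    noise = rng.standard_normal((n, p))
    z = np.sqrt(rho) * factors[:, block_of] + np.sqrt(1.0 - rho) * noise
    shift = np.zeros(p)
    if cfg.signal_regions:
        shift[list(cfg.signal_regions)] = cfg.effect_size
    log_suvr = cfg.log_suvr_mean + cfg.log_suvr_sd * (
        z - np.outer(apos.astype(float), shift)
    )
    return np.exp(log_suvr)


def generate_cohort(config: GeneratorConfig, seed: int | None = None) -> Cohort:
    """Generate a synthetic MCI cohort.

    Deterministic for a fixed config (the config's ``seed`` field, unless
    overridden by the ``seed`` argument). Gold amyloid status is drawn from
    the APOE-conditional prevalence and the global amyloid SUVr is then
    sampled on the matching side of the tracer cutoff, so label and value
    agree exactly.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    n = cfg.n_subjects
    region_names = cfg.resolved_region_names()

    apoe = rng.random(n) < cfg.p_apoe4
    p_pos = np.where(
        apoe,
        cfg.p_abeta_pos_given_apoe["carrier"],
        cfg.p_abeta_pos_given_apoe["noncarrier"],
    )
    apos = rng.random(n) < p_pos
    status = np.where(apos, ABETA_POS, ABETA_NEG)

    # age per (APOE group x amyloid status)
    age = np.empty(n)
    for carrier in (False, True):
        gkey = "carrier" if carrier else "noncarrier"
        for st in (ABETA_NEG, ABETA_POS):
            mask = (apoe == carrier) & (status == st)
            ms = cfg.age_means_sds[gkey][st]
            age[mask] = rng.normal(ms.mean, ms.sd, size=int(mask.sum()))
    age = np.clip(age, 40.0, 100.0)

    sex = (rng.random(n) < cfg.p_female).astype(int)

    fdg = _regional_suvr(rng, cfg, apos)
    # multiplicative spikes in one random region per affected subject
    spiked = rng.random(n) < cfg.outlier_rate
    if spiked.any():
        which = rng.integers(0, cfg.n_regions, size=int(spiked.sum()))
        fdg[np.flatnonzero(spiked), which] *= cfg.outlier_factor

    # amyloid tracer and global SUVr on the correct side of the cutoff
    tracers = sorted(cfg.tracer_mix)
    probs = np.array([cfg.tracer_mix[t] for t in tracers])
    tracer = rng.choice(tracers, size=n, p=probs / probs.sum())
    mean = np.empty(n)
    sd = np.empty(n)
    cut = np.empty(n)
    for t in tracers:
        tm = tracer == t
        cut[tm] = cfg.cutoffs.suvr_cutoffs[t]
        for st in (ABETA_NEG, ABETA_POS):
            m = tm & (status == st)
            ms = cfg.amyloid_suvr_params[t][st]
            mean[m], sd[m] = ms.mean, ms.sd
    eps = 1e-9
    lower = np.where(apos, cut, 0.0 + eps)
    upper = np.where(apos, np.inf, cut - eps)
    amyloid_suvr = _truncated_normal(rng, mean, sd, lower, upper)

    # CSF: concordant component unless flagged discordant
    has_csf = rng.random(n) < cfg.p_csf_available
    discordant = rng.random(n) < cfg.p_csf_discordant
    csf_pos = np.where(discordant, ~apos, apos)  # CSF-positive component?
    csf_cut = cfg.cutoffs.csf_cutoff
    cm = np.where(csf_pos, cfg.csf_params[ABETA_POS].mean, cfg.csf_params[ABETA_NEG].mean)
    cs = np.where(csf_pos, cfg.csf_params[ABETA_POS].sd, cfg.csf_params[ABETA_NEG].sd)
    clo = np.where(csf_pos, 1.0, csf_cut + eps)
    chi = np.where(csf_pos, csf_cut, np.inf)
    csf = _truncated_normal(rng, cm, cs, clo, chi)
    csf = np.where(has_csf, csf, np.nan)

    ids = [f"S{i:05d}" for i in range(n)]
    data = {
        "subject_id": ids,
        "age": age,
        "sex": sex,
        "apoe4": apoe,
        "tracer": tracer,
        "amyloid_suvr": amyloid_suvr,
        "csf_ab42": csf,
        "astatus": status,
    }
    for j, name in enumerate(region_names):
        data[REGION_PREFIX + name] = fdg[:, j]
    table = pd.DataFrame(data)

    followups = _generate_followups(rng, cfg, ids, status)
    return Cohort(
        table,
        region_names,
        followups,
        provenance={"source": "synthetic", "seed": int(cfg.seed if seed is None else seed)},
    )


def _generate_followups(
    rng: np.random.Generator,
    cfg: GeneratorConfig,
    ids: list[str],
    status: np.ndarray,
) -> pd.DataFrame:
    fu = cfg.followup
    n = len(ids)
    visits = np.arange(
        fu.visit_interval_months,
        fu.horizon_months + 1,
        fu.visit_interval_months,
        dtype=float,
    )
    k = len(visits)
    has = rng.random(n) < fu.p_has_followups
    # per-visit hazard so cumulative conversion over the horizon matches
    hazard = {
        st: 1.0 - (1.0 - fu.p_progress_given_astatus[st]) ** (1.0 / k)
        for st in (ABETA_NEG, ABETA_POS)
    }
    rows: list[tuple] = []
    u = rng.random((n, k))
    pet_avail = rng.random(n) < fu.p_followup_pet
    for i in range(n):
        if not has[i]:
            continue
        h = hazard[status[i]]
        conv = np.flatnonzero(u[i] < h)
        t_conv = conv[0] if len(conv) else k  # visit index of first dementia dx
        for v in range(k):
            dx = "dementia" if v >= t_conv else "MCI"
            pet = "unavailable"
            if dx == "dementia" and v == t_conv and pet_avail[i]:
                pet = status[i]
            rows.append((ids[i], visits[v], dx, pet))
    return pd.DataFrame(rows, columns=FOLLOWUP_COLUMNS)
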