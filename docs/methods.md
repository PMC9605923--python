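# Methods

## The gatekeeping model

The system is a two-stage decision architecture for amyloid-status (A-status)
approximation in MCI. Stage one is a deterministic OR gate on APOE-ε4
carriership. Stage two is a per-group binary classifier predicting the
group's designated majority class — Aβ- in non-carriers (APOE4-nc), Aβ+ in
carriers (APOE4-c) — from 92 features: age (years), sex (male = 0,
female = 1) and 90 AAL-region mean FDG SUVr values (pons-normalized,
computed upstream; image processing is outside the package's scope). The
clinical rule emitted per subject: carriers are always referred for explicit
amyloid testing; non-carriers are spared testing only when predicted Aβ-.

Key assumptions: amyloid positivity is dichotomized by tracer-specific
global SUVr cutoffs (AV45 ≥ 1.11, PiB ≥ 1.41, FBB ≥ 1.08; CSF Aβ1-42
≤ 192 pg/ml when used for validation); the APOE groups have strongly
different Aβ+ base rates, which the designated-class design deliberately
exploits; and a prediction is clinically useful only when precise, which
motivates the F_{1/10} selection criterion (precision weighted 10× over
recall; F_{β}(0,0) is defined as 0).

## Pipeline order and conventions

The preparation chain runs in a fixed order: PET/CSF concordance filter →
per-region 3×IQR outlier filter → APOE grouping → stratified 70/30 split →
per-group standardization → minority upsampling. Conventions that were
genuinely open and had to be fixed:

* **Standardization** uses the population SD (divide by n); binary codes
  (sex, APOE) pass through. Test data are always transformed with training
  parameters; scaling is fit per APOE group, inside the group pipeline.
* **IQR fences** use linear-interpolation quartiles computed once on the
  full input cohort (single pass); exclusion requires a value strictly
  outside [Q1 − 3·IQR, Q3 + 3·IQR], so fence-exact values and
  zero-IQR regions exclude nobody.
* **Stratified split** allocates per-class training counts by floor plus
  largest-remainder top-up so the total matches round-half-up of
  fraction × n; the partition is uniform at random given the counts,
  deterministic per seed.
* **Upsampling** duplicates minority rows with replacement until class
  counts match, after scaling and before cross-validation, replicating the
  reference pipeline order. This leaks duplicated rows across CV folds by
  design; a leakage-safe within-fold variant exists behind
  `upsample_within_folds=True` (default off, because the reference
  behaviour is the object of study).
* **Grid search** evaluates every lattice point of every family with
  stratified 10-fold CV on a fold assignment shared across points; the
  argmax ties break to the earlier lattice point. Shipped default lattices
  are deliberately small (≤ 4 points per family) so a full six-family
  search runs in about a minute per 1000 subjects on one CPU; lattices are
  configuration, not method.
* **Final-model selection** rounds mean validation scores to a full percent
  (half away from zero) *only* at the between-family comparison; rounded
  ties are broken by raw F_{1/10} on the held-out test set, computed lazily
  and only for tied families, and the selection trail records candidates,
  rounded scores and any tie-break inputs. Class predictions use the
  families' default 0.5 probability threshold; no calibration.

## Evaluation protocol

* **Designated-class metrics**: precision/recall of the majority class with
  the zero-division convention precision = recall = 0 (keeps audit averages
  defined).
* **Balanced-downsample audit**: each repeat keeps the smaller class whole
  and draws an equal-sized uniform subset of the larger class; the number
  of repeats defaults to the squared balanced subset size, capped at
  10,000 (recorded in the audit). The mean metric set recomputes F_{1/10}
  from mean precision and mean recall. For a label-independent classifier
  the audit's mean precision converges to 0.5.
* **Permutation importance**: δ = baseline − mean score over n_perm = 1000
  shuffles of one feature column on the test set, scored with the
  model-selection metric (F_{1/10} of the designated class); the scored
  metric is configurable since nothing forces this choice.
* **Mutual information** ranking uses the k-nearest-neighbour estimator
  (seeded); sub10/sub50 ablation variants keep the top ceil(10%/50%) of
  features.
* **Ablation grid**: GK rows refit the gated pipeline per variant and
  report each group's designated class on that group's test set; CL rows
  fit one pooled classifier with APOE carriership as a binary feature
  (unless ablated) and evaluate on the pooled test set — with the F_{1/10}
  objective one pooled fit per target class, with the balanced-accuracy
  objective a single fit reported for both classes.
* **Progression comparison**: eligibility requires ≥ 2 follow-up diagnoses
  with first and last ≥ 6 months apart (the span interpretation of an
  ambiguous rule); a subject progresses if any follow-up diagnosis is
  dementia (first occurrence counts). Dementia outcomes sub-categorize as
  probable AD (amyloid-PET positive at or before diagnosis), non-AD
  dementia (PET negative at or after), else possible AD — applied in that
  order, so the partition is exhaustive and exclusive. The χ² comparison is
  Pearson without continuity correction (flag available), df = 1,
  α = 0.05. The gold and predicted arms share members, so the test is not
  between independent samples; every result carries that annotation.

## Synthetic cohort generator

The generator emulates the joint structure the analysis needs, not images:

| parameter | default | rationale |
|---|---|---|
| p_apoe4 | 0.49 | carrier share of the study population |
| Aβ+ given APOE | 0.83 carrier / 0.33 non-carrier | group base rates |
| age (years) | e.g. Aβ- non-carrier 70.6 (7.65), Aβ+ carrier 72.4 (6.59) | group demographics |
| p_female | 0.46 | cohort composition |
| effect_size | 0.8 SD | standardized hypometabolism deficit in signal regions |
| signal regions | 10 temporoparietal/limbic AAL regions | AD-vulnerable network |
| region_correlation | 0.3 within blocks of 10 | network-structured noise |
| amyloid SUVr | AV45 Aβ- 1.00 (0.05), Aβ+ 1.37 (0.17); PiB/FBB analogous around their cutoffs | tracer distributions |
| tracer mix | AV45 0.86, FBB 0.116, PiB 0.024 | tracer availability |
| p_csf_discordant | 0.09 | PET/CSF label disagreement rate |
| progression | 0.43 Aβ+ / 0.12 Aβ- over 60 months, visits every 6 | conversion rates |

Regional SUVr is log-normal (guaranteeing positivity) with a common factor
per block of ten consecutive regions — the simplest structure in which
*networks*, rather than single regions, carry signal; Aβ+ subjects have the
log-mean of each signal region lowered by `effect_size` standardized units.
The global amyloid SUVr is drawn truncated to the correct side of the
tracer cutoff, so gold label and value agree exactly by construction. CSF
values come from a two-component normal around 192 pg/ml; discordance flips
the component, not the PET value. Follow-up visits are regular (6-month
interval, 60-month horizon ≈ the reported mean follow-up), with a geometric
per-visit conversion hazard solved to hit the target cumulative rates; an
amyloid PET reflecting gold status is available at the conversion visit
with probability 0.3. Injected outliers are ×2.5 multiplicative spikes in
one random region, guaranteed to trip the 3×IQR fence at realistic spreads.
PiB and FBB amyloid-SUVr parameters are not published for this population
and were chosen as plausible distributions straddling the cutoffs.

What the generator does **not** emulate: scanner/site effects, realistic
PET noise or partial-volume structure, longitudinal FDG change, cognitive
scores, missing regions, or any spatial correlation beyond the exchangeable
blocks. Passing tests therefore demonstrate that the pipeline recovers the
structure it assumes — not that the clinical performance numbers transfer
to real ADNI or memory-clinic data, which are access-restricted.

## Problem sizes used in the test suite

End-to-end parameter recovery runs the full six-family pipeline on a
1500-subject cohort (effect 0.8 in ten regions, prevalences 0.83/0.33) and
requires ≥ 0.80 designated-class precision per group. The null audit uses
1000 subjects with no regional effect and balanced prevalence; a
logistic-regression-only fit there is the canonical majority-prone model.
Planted-signal recovery uses twenty 800-subject one-signal cohorts (twelve
regions, effect 1.2, no residual correlation, age shift left at its default)
with n_perm = 200, sized so a single informative region reliably dominates
the importance ranking of an adequate (linear) classifier. The χ² oracle
check is exhaustive over all non-degenerate 2×2 tables with group sizes up
to 18 and randomized up to 50, at 10⁻⁹ agreement.

## Known limitations

* The designated-class architecture presumes the group base rates of the
  study population; under different APOE-prevalence structure the majority
  classes may differ and the gate logic would need re-derivation.
* Upsampling before CV (the reference behaviour) optimistically biases
  validation scores; the balanced audit exists precisely to expose the
  consequence, and the within-fold variant quantifies it.
* The progression χ² treats overlapping arms as independent; it is
  reported for comparability, annotated, not corrected.
* Hyperparameter lattices are small by default; richer searches are a
  configuration change and were not explored.
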