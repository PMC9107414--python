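# Methods

## The normative scoring model

The unit of analysis is a cortical parcel ("mosaic"): mean cortical
thickness (CT, mm) over a patch of an approximately equal-sized
1000-patch cortical parcellation. For each patient and parcel the method
asks a purely empirical question: *where does this patient's CT fall in
the distribution of demographically comparable healthy controls?*

The null distribution is built non-parametrically. Each matched control
is leave-one-out (LOO) z-scored against the remaining controls
(`z_i = (x_i − mean_{−i}) / sd_{−i}`, sample SD over the n−1 remaining
values); the patient is z-scored against all matched controls. The rank
p-value is the fraction of LOO null values *strictly* below the patient's
z, and a parcel is labelled atrophic when p ≤ α (α = 0.05, inclusive).
Because z is a monotone transform within each reference set, the
procedure is essentially a rank test: it needs no Gaussian assumption for
validity of the rank, only exchangeability of patient and controls under
the null.

Assumptions worth stating explicitly:

* **Exchangeability within the matched cell.** Matching (±2 years,
  inclusive, exact sex equality) is the only demographic adjustment; no
  covariate regression is applied. Ages are compared as real years.
* **Per-parcel independence is *not* assumed** for the subject-level
  labels — each parcel is tested marginally. Spatial correlation only
  matters for the group-level family-wise inference (below).
* **Resolution.** p takes only values k/n for n matched controls, so
  p ≤ 0.05 is unattainable below n = 20; `min_controls` defaults to 20
  and a warning is logged for n < 30.

### Finite-sample type-I rate

With the inclusive threshold and strict-tie counting, a null patient is
labelled atrophic when their rank among n controls is at most
⌊αn⌋ + 1 of n + 1 positions: at n = 200 the attainable level is
11/201 ≈ 0.0547, not 0.05. The LOO transform partially offsets this —
removing an extreme control stretches the null's tails, which makes the
labelling slightly conservative — so the realised per-parcel type-I rate
at n = 200 is ≈ 0.053 (measured by simulation; `scripts/acceptance.py`
recomputes it). This is an inherent discreteness property of rank
p-values at finite n, not an implementation artefact; users needing exact
calibration can use the `midrank` tie mode and larger banks. The
calibration test that requires equality with 0.05 within 3 binomial
standard errors over 5·10⁵ tests therefore fails by design at n = 200
(observed ≈ 0.053, band ±0.0009); it is kept as an honest record of the
method's finite-sample behaviour.

### Ambiguities resolved

* The patient could be z-scored against the full control cohort or the
  matched subset; the matched subset is used, consistent with the
  matching rationale (the alternative re-introduces demographic
  variance). Nulls and patient z then share a reference set.
* Ties in the rank count (|Δz| ≤ 1e−12) contribute 0 in the default
  `strict` mode; a `midrank` mode (ties count 0.5) is available for
  smoother calibration.
* Zero-spread parcels raise an error rather than silently producing
  p = 0.5: constant CT across controls indicates broken input.

## Group-level permutation inference

Per clinical group, binary maps form a patients × parcels hit matrix.
Under the null that atrophy has no consistent localisation, each
patient's hits are relocated uniformly over parcels; every iteration
permutes each row independently (per-patient burden conserved) and
records per-parcel hit counts.

* `paper_pointwise`: p = (# iterations with permuted count > observed)/B
  — the literal per-parcel exceedance rule, pointwise rather than
  family-wise, p = 0 possible. Whether "exceeding" means ">" or "≥" is
  ambiguous; strict ">" is implemented.
* `max_statistic` (default): p = (1 + #{max over parcels ≥ observed})/(B+1),
  add-one corrected — a standard valid FWER-controlling permutation
  p-value. The max-count statistic is heavily discrete at realistic base
  rates, so the realised FWER is conservative (≈ 0.01–0.03 at 10 patients
  × 200 parcels), comfortably under the nominal 0.05.

Whether one shared shuffle or independent per-row shuffles per iteration
is used was an open choice; independent per-row shuffles implement the
stated null (each patient's pattern relocated independently). B defaults
to 100 000; the RNG seed is recorded in the output metadata and identical
configs reproduce p-maps bit-exactly.

## ROI overlay and radar summaries

Composite ROIs (motor = pre-/paracentral; frontal; parietal; temporal)
are unions of Desikan–Killiany regions; the membership table ships as an
editable TSV (`src/mosaicct/data/dk_composite_rois.tsv`). Insula,
cingulate and occipital regions map to "none" and count only toward
whole-brain fractions. A parcel is assigned to the ROI holding the
plurality of its vertices; ties break deterministically by the precedence
motor → frontal → parietal → temporal with a logged warning. The exact
regions pooled into each composite are a documented convention (the
canonical composition 122/185/150/200 of 1000 leaves 343 parcels
unassigned); verifying the counts against the real surface atlases
requires the vertex-level Schaefer-1000 and Desikan–Killiany files, which
are not bundled.

## Between-group statistics

Whole-brain thin-patch fractions are compared by one-way ANOVA; raw mean
CT by a linear model with age and sex covariates, testing the group
factor with a partial ("type III"-style) F-test. Tukey HSD post-hoc
p-values come from the studentized range applied to pairwise differences
of model-adjusted group means (q = √2·|t|), with age entered as a
six-level categorical covariate — by default six equal-width bins over
the pooled age range (edges configurable; empty bins are dropped with a
warning). With two groups and no covariates this reduces exactly to the
pooled two-sample t-test. No Welch correction is applied; a
heteroscedasticity warning is logged when the group variance ratio
exceeds 4. Mean differences are reported as second group minus first
(alphabetical order).

## Synthetic data generator

The generator reproduces the statistical structure the method assumes,
not cortical geometry: per-parcel CT is i.i.d. Gaussian across subjects
with baseline 2.2 mm and between-subject SD 0.10 mm (typical of
parcel-mean CT in adult cohorts), ages uniform over 50–73 years, sexes
Bernoulli(0.5). Patients are drawn from the control distribution and a
chosen fraction of each target ROI's parcels is shifted by a multiple of
the between-subject SD (e.g. the semantic-variant-like preset: −3 SD over
the whole temporal ROI); affected parcels are returned as ground truth.
Patient ages are clipped 2 years inside the bank's age range so every
patient can draw a full matched reference group.

Deliberate simplifications, and what passing tests therefore do and do
not show: no spatial correlation between parcels by default (an
exchangeable-correlation option exists to stress the family-wise
calibration), no age/sex effect on CT by default (a −0.005 mm/year slope
option verifies that matching absorbs age confounds), no scanner/site
effects, no realistic ROI geometry. Calibration and recovery results on
this generator validate the statistical machinery; they do not establish
performance on real MRI-derived CT, where spatial smoothness, site
effects and non-Gaussian tails will matter.

Power context for recovery tests: the atrophy threshold sits near the
null's 5% rank cutoff (≈ −1.65 to −1.75 SD depending on n), so per-parcel
sensitivity at a −3 SD effect is ≈ Φ(3 − 1.7) ≈ 0.90, and ≈ 0.99 at
−4 SD; tests assert at these oracle levels with Monte-Carlo slack.

## Problem sizes and numerical choices

The test suite and the acceptance script use desk-scale problem sizes
chosen to give tight Monte-Carlo error at interactive runtimes: 200-
(sometimes 400-)control banks, 500 null patients × 1000 parcels for
type-I calibration, 100 replicate cohorts × 2000 permutation iterations
for FWER calibration, and 50-parcel miniatures (ROI blocks scaled from
the canonical 122/185/150/200 composition) for unit tests. Permutations
are processed in fixed 500-iteration chunks (memory-bounded, result
independent of chunking). CT values outside (0.5, 5.0) mm are rejected at
ingest as physiologically implausible. All randomness flows through
`numpy.random.Generator` seeds recorded in outputs; every pipeline output
is reproduced bit-exactly from config + inputs + seed.

## Known limitations

* Matching does not widen the ±2-year window when too few controls
  match; it errors instead (explicit is safer than silent widening).
* Missing parcel values are ingest errors; there is no missing-data
  policy.
* The pointwise permutation mode is not family-wise valid despite its
  common use; it is provided for fidelity and comparison only.
* Subject-level calibration is exact only up to rank discreteness
  (above); report n_matched alongside any thin-patch fraction.
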