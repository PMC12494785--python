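# Methods

## Tumor-fraction model

A somatic variant observed in plasma at allele frequency `VAF` is modelled
as arising from a two-component mixture: a tumor fraction `f` of the cfDNA
carrying `M` mutated of `CN` total allele copies at the locus, and a
non-tumor remainder that is diploid and unmutated. The forward model

```
VAF = M·f / (CN·f + 2·(1 − f))
```

assumes the mutation is clonal within the tumor compartment and that the
allelic composition is homogeneous (no copy-number heterogeneity across
tumor subclones). Inverting it at the anchor locus gives the copy-number
corrected ctDNA fraction `f = 2 / (M/VAF − CN + 2)`; the equivalent
mutated-sample-fraction map `MSF = VAF·(CN·f + 2(1−f))/M` is kept as an
independent implementation so the identity `MSF(expected_vaf(f)) = f` can
be tested to 1e-12 rather than assumed.

The anchor is the **maximum non-amplified VAF** in the sample. Amplified
loci are excluded because focal amplification inflates VAF beyond the
mixture model's range; a locus counts as amplified when the copy-number
source flags it, or as a fallback when `CN ≥ 5` (configurable), which
covers simulated data where only integer states exist. If every candidate
locus is amplified, the lowest-CN locus is used and a warning logged,
rather than declaring the sample unassessable — samples with amplified
KRAS still deserve a fraction estimate. Fractions implied above 1 by
sampling noise are clamped to 1 with a warning. When no copy-number call
covers the anchor locus the background is assumed disomic with one mutated
allele, recorded per sample in a `disomic_fallback` flag.

Absolute burden converts fraction to mutated genome equivalents per ml
plasma at 6 pg per diploid genome: `mGE/ml = f · conc · 1000/6`. Negative
samples are quantified as exactly 0 mGE/ml (not missing), so longitudinal
trajectories carry them at the floor.

## Variant inclusion rules

* **Tissue somatic**: kept iff called by ≥2 callers, high/moderate impact
  and VAF strictly > 3%; a variant confirmed in ctDNA or another tumor
  sample of the same patient is rescued with a single caller (impact rule
  stands), so cross-sample comparisons do not manufacture heterogeneity.
* **Germline**: analysis set = primary-caller calls, high/moderate impact,
  VAF > 25%, gnomAD AF < 3%; reported subset additionally ClinVar
  pathogenic/likely pathogenic, conflict-free, neoplastically associated.
* **Plasma**: kept iff ≥5 duplex-consensus reads, no evidence in the
  matched normal, canonical transcript; variants confirmed in tissue or
  another plasma sample, or on KRAS hotspot codons (G12/G13/Q61), are
  rescued down to `rescue_min_reads` (default 1). The assay's limit of
  detection is not quantified as a VAF, so rescue is parameterized by
  consensus-read support instead. Rescued variants are exempt from the
  canonical requirement (the corroboration itself is the evidence).
* **Matched-normal override**: a normal-detected variant is retained when
  its plasma VAF exceeds 5% while the normal VAF stays below 0.2% — at
  that asymmetry the trace in the normal is more plausibly low-level
  contamination or clonal hematopoiesis background than germline origin.
  Encoded as a rule rather than a per-patient exception so it is auditable
  and configurable.

Boundary semantics are literal: "above 3%/25%" strict, "minimum of five"
inclusive. All filters are idempotent, order-independent and monotone in
their thresholds (property-tested).

## Cutpoint discovery and survival summaries

Maximally selected rank statistics: candidates are midpoints between
consecutive distinct baseline burden values (midpoints rather than observed
values, so the returned threshold never coincides with a patient);
admissible splits leave at least `ceil(minprop·n)` patients on each side
(`minprop` defaults to 0.1, the conventional default for this procedure).
Each candidate is scored with the standardized log-rank statistic
`(O−E)/√V`, implemented directly from the pooled risk-set tabulation;
the search maximizes `|z|` with ties broken toward the smaller cutpoint so
results are deterministic. The full per-candidate profile is exposed; no
multiple-testing correction of the maximal statistic is computed, but the
profile supports permutation calibration by the user.

Boundary assignment: a patient whose baseline burden equals the cutpoint
goes to the low group; missing baselines stay unassigned (an
`exclude_from_search` flag supports patients assigned post hoc from later
samples without influencing discovery).

Kaplan–Meier medians and Cox fits delegate to lifelines. Continuous burden
enters Cox models per 1000 mGE/ml; confidence intervals are Wald-type on
the log-HR. ECOG levels 2 and 3 are combined in multivariable fits (too few
patients separate them). Non-convergence (e.g. separation) raises an
explicit error rather than returning a degenerate estimate.

## Δ-ctDNA events

One event per consecutive pair of assessable samples bracketing a dated
workup (nearest sample strictly before, first at/after; multiple workups in
one bracket collapse to the earliest). Patients need ≥2 assessable samples
and ≥1 positive. High-group events are classified only by where the burden
lands relative to the cutoff; low-group events by a ±25 mGE/ml band, open
on the stable side (a change of exactly 25 counts as movement, the only
reading under which "stable within 25" and "increase greater than 25"
partition the line; a drop of ≥25 is a decrease by symmetry). Disease
status is progression-or-death when the workup read progression or the
patient died within 3 months of the *next sample's* date — the sample date
rather than the workup date, since the burden measurement is what the
event interprets. Cutoff and band are parameters (the cutoff is
cohort-derived, not universal).

## Concordance

Presence matrices use variant identity (chrom, pos, ref, alt) so distinct
variants in one gene stay separate. Absences in a sample whose tumor
content is below the detectability floor are flagged not-assessable and
can never create discrepancies; the floor defaults to 2%, reusing the
eligibility threshold (at least one plasma sample with ctDNA fraction
strictly above 2%) per sample — the suppression is reported in the output
metadata since it is a modelling choice, not a measured sensitivity.
Tissue samples without a tumor-content estimate are treated as assessable.
Discrepancy calls require at least one assessable sample on the silent
side. The actionability table (KRAS G12C → sotorasib, BRCA1/2 → olaparib,
PIK3CA → alpelisib) is a static lookup emitted for orientation and carries
no clinical authority.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes, not
any individual patient:

* cohort mix 75% palliative / 25% adjuvant; baseline ctDNA negativity 26%
  (palliative) and 80% (adjuvant), i.e. a zero-inflated Beta(0.8, 8)
  baseline fraction;
* cfDNA concentration lognormal(ln 20, 0.9) ng/ml — median ≈ 20 ng/ml with
  a long right tail, the familiar shape of clinical cfDNA yields;
* 1–5 plasma draws per patient (median 3) on ~28-day cycles; tumor-fraction
  trajectories follow a geometric random walk with drift −0.25 and step SD
  0.5 per cycle (a generic on-treatment decline; no published generative
  model exists for these trajectories);
* per-locus allelic composition: disomic by default, 30% non-disomic
  (LOH and low-gain states), 8% amplified; anchor variants are clonal and
  non-amplified (KRAS with probability 0.9), passengers subclonal with
  clonality capped so they cannot systematically out-vote the anchor;
* allele frequencies are Binomial(depth 1400, forward-model VAF) draws —
  1400× reflects UMI-collapsed consensus coverage — so detection dropout
  at low fractions emerges naturally rather than being imposed;
* overall survival is exponential with median 3.7 months above and 11.9
  months below a 350 mGE/ml baseline threshold, with independent
  exponential censoring (median 60 months; the emulated study does not
  describe its censoring process);
* covariates (age, ECOG, M-stage, regimen, CA19-9, CEA, CRP, albumin) are
  drawn with group-dependent shifts in the directions observed clinically
  (higher inflammation markers and lower albumin in high-burden patients);
* workups sit between consecutive draws; their status tracks the truth
  trajectory with a 15% label-flip probability.

One RNG stream per table, all spawned from the master seed, so adding or
re-parameterizing one table never perturbs the others, and a fixed seed
reproduces every table bit for bit.

What the generator does **not** emulate: sequencing error profiles, UMI
family statistics, clonal hematopoiesis beyond a flat 2% contamination
flag rate, copy-number log-ratio tracks, non-exponential survival shapes,
and informative censoring. Passing tests therefore demonstrate the
pipeline's correctness and calibration under the stated generative
assumptions, not assay-level sensitivity on real plasma.

Focused generators (pure exponential survival; a loglinear continuous
burden effect; a confounded binary group effect with correlated
ECOG/CRP/albumin; a hazard change-point cohort) back the parameter-recovery
studies. Their sizes — 25 replicates at n=200–2000 — were chosen so that
the Monte-Carlo error of a replicate median is a few percent of the target
quantity.

## Numerical choices and degenerate inputs

* Roundtrip identity fraction↔VAF holds to 1e-12 across CN 1–6.
* Log-rank variance uses the hypergeometric form per distinct event time;
  a zero total variance (degenerate grouping) is an error, not a zero.
* Cutpoint search: all-identical values, or no split satisfying minprop,
  raise domain errors naming the condition.
* Empty variant sets quantify as ctDNA-negative (fraction and burden 0);
  non-assessable samples propagate as missing, never as zero.
* Table IO is TSV with a stable column order and `%.10g` floats, so
  re-running a pipeline with the same configuration is byte-identical.

## Known limitations

* The anchor-MAF estimator inherits binomial noise: at 1400× and a 5%
  tumor fraction the relative error of a single estimate is ~15%.
* Subclonal variants on LOH backgrounds can occasionally exceed the anchor
  VAF and bias the fraction estimate downward slightly; the quantifier
  takes the observed maximum and cannot distinguish clonality.
* The maxstat p-value is not corrected for the maximal selection; treat
  the statistic as a ranking criterion, not a calibrated test.
* Cox models assume proportional hazards; the change-point generative
  model satisfies it within strata but real cohorts may not.
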