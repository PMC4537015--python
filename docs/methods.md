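# Methods

This note documents the statistical procedures, the defaults and the
numerical choices behind `mirmet`, and what the synthetic-data tests do
and do not establish about real data.

## Cq model and normalisation

A qPCR run reports, per well, a quantification cycle Cq; lower Cq means
higher abundance, and a transcript that has not amplified by the end of
the 40-cycle run is *undetected*. `mirmet` keeps detection as an explicit
boolean grid beside the Cq values: "not expressed" is always a flag-based
notion, never `Cq == 40` numerically, so the imputation ceiling can be
changed without altering filter semantics.

* **Imputation** (`impute_undetected`): undetected wells receive the
  ceiling, 40 cycles by default. A ceiling at or below the largest
  detected Cq triggers a warning but is permitted.
* **Replicate aggregation** (`aggregate_replicates`): the aggregate of a
  replicate group is the *median of its detected wells* — robust to a
  single failed well; a group with no detected well stays undetected.
  Aggregation is optional per dataset, since card-format runs are
  single-well while validation plates are typically run in triplicate.
* **Normalisation** (`delta_cq`): ΔCq(m, s) = Cq(m, s) − Cq(U6, s); the U6
  small nuclear RNA is the single endogenous reference. U6 undetected in
  any sample is a hard error — normalisation is undefined without the
  reference and silently imputing it would corrupt every ΔCq in that
  sample. Relative expression is log₁₀ 2^(−ΔCq), assuming perfect
  doubling per cycle; higher ΔCq = lower expression throughout.

## The screen

Each miRNA is compared between the two groups with the two-sided
Mann-Whitney rank test on per-sample ΔCq (imputed values included — the
ceiling is a legitimate, if censored, low-expression observation, and
missingness is handled separately by the first filter):

* exact null distribution when the combined sample size is ≤ 20 and there
  are no ties; otherwise the normal approximation with tie correction and
  continuity correction. A row whose values are all equal (e.g. every
  well at the ceiling) gets p = 1 directly.
* Benjamini-Hochberg step-up adjustment across all miRNAs (delegated to
  `statsmodels`; an independent brute-force implementation cross-checks
  it in the tests); significance is `p_adj < alpha` with `alpha = 0.05`.

Two selection filters are then evaluated **for significant records only**
(they are reported as missing for the rest):

1. **Missingness asymmetry**: keep a miRNA that is detected in all
   samples of at least one group, or whose larger undetected count is at
   least `ratio` (default 2) times the smaller. This removes miRNAs whose
   significance is driven by scattered dropout in both groups rather than
   a real group difference.
2. **Quartile separation**: keep only miRNAs with Q1 of one group
   strictly above Q3 of the other. Quartiles use linear interpolation
   between order statistics (numpy's default, "type 7"). The convention
   is fixed and exposed because PASS/FAIL can flip between quartile
   estimators at n = 12; strict inequality is required.

Direction is read from group medians on the ΔCq scale:
`median_a > median_b` ⇒ `lower_in_group_a` (an exact tie, which cannot
occur for a significant record, falls to `higher_in_group_a`).

## Validation and pairing

* **Cross-set confirmation**: candidates are re-tested in an independent
  sample set with the same rank test; BH adjustment is applied *across
  the candidate panel only* (the panel is the family of hypotheses
  actually re-tested). Confirmation requires adjusted p < alpha **and**
  the same direction as discovery. The procedure is symmetric under
  relabeling the groups together with flipping the direction codes.
* **Paired analysis**: within-pair differences d_i = ΔCq(metastasis
  member) − ΔCq(primary member) are tested with the two-sided one-sample
  t test; a signed-rank alternative is available behind
  `method="wilcoxon"`. Degenerate guards: all d_i = 0 gives p = 1 and no
  direction; constant non-zero d_i gives an infinite-t sentinel with
  p = 0. Both raw and BH-adjusted p are reported — with typical designs
  of ~4 pairs the stage is severely under-powered, and the pipeline's
  candidate intersection deliberately uses the *raw* p for paired
  membership while discovery and validation use adjusted p.
* **Intersection**: all pairwise and k-way intersections of the named
  candidate sets, with per-id provenance. The pipeline nominates miRNAs
  in the three-way intersection.

## Perturbation analysis

Input is a probe × condition table of normalised log-intensities for two
cell lines, each with mimic, inhibitor and matched negative controls.
With the transfection experiments pooled before hybridisation there is
one array per condition, so per-probe effects are condition-minus-control
contrasts and replication comes from the two cell lines:

* per line, the inverse-modulation contrast d_l = (lfc_inhibitor −
  lfc_mimic)/2; the per-probe effect is the mean of d₁, d₂ and its
  variance s² across the two lines has 1 residual degree of freedom;
* the variance prior s² ~ s₀²·F(d, d₀) is fitted across probes by
  matching the mean and variance of log sample variances (the trigamma
  inverse is solved by Newton iteration). When the spread of log
  variances does not exceed pure sampling noise, the prior degrees of
  freedom are reported as an infinite-d₀ sentinel and s₀² is the mean
  variance (for identical inputs, exactly that value);
* the moderated statistic uses the shrunk variance
  s̃² = (d₀s₀² + d·s²)/(d₀ + d) with d₀ + d degrees of freedom (normal
  when d₀ is infinite). In the d₀ → 0 limit this is the ordinary t.

A probe is **inversely modified** iff (i) mimic and inhibitor contrasts
are strictly sign-opposed within each line, (ii) each arm's sign is
consistent across lines, (iii) the moderated p is below alpha and the
mean |lfc| reaches `min_abs_lfc` in both arms. The thresholds default to
alpha = 0.05 and min_abs_lfc = log₂ 1.5 and are exposed as configuration:
the size of a published "inversely modified" probe list depends on
unstated cutoffs, so no particular count is a target of this package.

The merge with metastasis DE genes encodes the suppression logic of a
miRNA that is *low* in metastatic cells: a gene up in metastasis must be
up under the inhibitor (miRNA suppressed) and down under the mimic;
a gene down in metastasis must behave oppositely. `concordant` requires
the probe to be inversely modified *and* to match this direction rule.

## Motif scanners

The four canonical seed-site patterns of a mature miRNA (5'→3') are: 6mer
= reverse complement of nucleotides 2–7; 7mer-m8 = reverse complement of
2–8; 7mer-A1 = 6mer + A; 8mer = 7mer-m8 + A. Scanning enumerates every
occurrence of the core 6mer and upgrades each locus by the flanking m8
match and/or the A opposite position 1, so nested patterns yield exactly
one site of the most specific type per locus (8mer > 7mer-m8 > 7mer-A1 >
6mer); overlapping loci are each reported. AU-rich elements are maximal
runs of AUUUA pentamers overlapping at step 4 (AUUUAUUUA = 2 pentamers),
with a cluster class of min(5, count). Coordinates in all reports are
1-based inclusive on the UTR; internally the code is 0-based half-open.
DNA-alphabet inputs are converted T→U with a warning.

These scanners are local stand-ins for web-database lookups whose UTR
databases and versions are unrecorded; gene lists produced on real data
therefore depend on the user-supplied UTR FASTA and cannot be expected to
reproduce any particular published list.

## Synthetic data

`gen_cq_dataset` emulates a miRNA card run: per-miRNA latent baselines
~ N(28, 3²) cycles (a wide between-miRNA abundance spread), a planted
group shift of `effect_delta_cq` = 8 cycles for `n_true_positives` = 20
of 670 miRNAs (direction random per miRNA), well noise ~ N(0, 2²), and
logistic dropout: a well of latent Cq c is undetected with probability
1/(1 + exp(−(c − 35)·slope)), slope 1/cycle; any well with latent Cq ≥ 40
is deterministically undetected. U6 is generated low and stable
(N(20, 0.15²)) and always detected. Defaults mirror the study design
(12 vs 12 discovery, 10 vs 10 validation, 4 pairs); the noise and
abundance distributions are the package's own choices — no published
values exist for them — and are all exposed in `SimConfig`, none
hard-coded. A truth table can be reused across sets so discovery,
validation and paired data share the same planted effects.

`gen_perturbation_dataset` plants targets at −lfc (mimic) and +lfc
(inhibitor) against matched controls, consistently in two lines, with
per-well noise (defaults 5000 probes, 50 targets, lfc 1, noise 0.2).
`gen_sequences` plants seed sites and ARE runs into uniform-ACGU random
UTRs (a neutral null for motif statistics), adjusting flanking bases so a
planted site scans as exactly its planted type and a planted ARE run is
maximal as planted.

What the generator does **not** model: card/batch effects,
pre-amplification bias, amplification-efficiency differences,
inter-miRNA correlation, clinical covariates, and realistic UTR base
composition. Passing tests therefore demonstrate the correctness and
calibration of the *procedures* under the stated generative model, not
performance on real tissue data.

## Problem sizes and reproducibility

Each generator draws from a single `numpy` Generator seeded from its
config, so identical config + seed reproduces outputs byte for byte; the
pipeline manifest records a config hash (path basenames + parameters) and
per-report checksums. The test suite exercises: 500 null replicates at
full study scale for FDR control; 10 replicates for planted-effect
recovery; 1000-case oracle comparisons for the rank test, BH, quartile
filter and both sequence scanners; 10,000 probes for moderation-prior
recovery; and 5000-probe perturbation simulations. The demonstration
bundle is scaled to 100 miRNAs / 8 vs 8 / 500 probes / 20 UTRs with 6
sample pairs so a full pipeline run completes in about a second.

## Known limitations

* Single-reference normalisation only; no multi-reference or global
  normalisation, no efficiency correction, no inter-card calibration.
* The perturbation module consumes already-normalised log-intensities;
  array background correction and normalisation are out of scope.
* The missingness filter's "twice the other group" rule is scale-free
  but ignores group size imbalance; it is applied as stated.
* With 4 pairs the paired t test has low power and its raw-p gating in
  the nomination step trades specificity for sensitivity — both raw and
  adjusted p are always reported so users can choose otherwise.
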