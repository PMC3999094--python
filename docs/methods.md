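# Methods

## The problem

Azathioprine (AZA) is an immunosuppressive pro-drug whose active
metabolites, 6-thioguanine nucleotides (6-TGN), accumulate in
erythrocytes; efficacy and leukopenia both track their level. Co-medication
with 5-aminosalicylic acid (5-ASA) inhibits thiopurine S-methyltransferase
and raises 6-TGN. The package implements a two-arm design for finding
germline SNPs that predict 6-TGN exposure:

* a **clinical arm** correlating additively coded genotypes with the
  dose-normalised exposure `RR = [6-TGN] / dose_AZA` in a patient cohort,
  and
* an **in-vitro arm** detecting drug-induced expression allelic imbalance
  (EAI) of premature RNA at heterozygous SNPs in a lymphoblastoid
  cell-line panel exposed to drug vs vehicle,

followed by an intersection of the two evidence streams.

## Clinical screen

For each patient with AZA dose `d > 0` and 6-TGN level `c > 0`, the risk
ratio is `c / d` (pmol per 8×10⁸ RBCs per mg/day). Patients with 5-ASA
below 2000 mg/day are excluded before analysis (configurable `min_dose`);
the exclusion report preserves input order. Genotypes are coded AA=0,
AB=1, BB=2; NoCall is missing and is removed pairwise per SNP. A SNP is
analysable when every genotype class appears in at least `min_per_class`
(default 2) retained patients. The test statistic is the Pearson
product-moment correlation of code against risk ratio, with the two-sided
p-value from the t distribution on n−2 degrees of freedom; Spearman is
available behind `method="spearman"`. The decision rule is
`r² ≥ r2_min (0.4)` and `p < alpha (0.01)` on raw p-values — no
multiple-testing correction is part of the rule, but a Benjamini–Hochberg
column is emitted for information. Whether the 0.4 floor applies to r² or
to |r| is genuinely ambiguous in the field's usage, so both are supported
(`threshold_on="r2"` default, `"abs_r"` optional); |r| ≥ 0.4 is the weaker
rule. Output is sorted by descending r², ties broken lexicographically by
SNP id, which makes the screen invariant to input row order.

MCV and WBC, when present, are correlated with 6-TGN by plain pairwise-
complete Pearson (macrocytosis gives the positive MCV sign, myelotoxicity
the negative WBC sign); no dose adjustment is applied.

## EAI statistics

All ratio statistics are computed on signals that are strictly positive
(an optional background floor is applied first). Per heterozygous
(line, SNP) pair and condition, the folded allelic ratio is
`EAI(max) = max(A/B, B/A) ≥ 1`; the orientation is taken independently per
condition, matching the printed formula (a fixed per-SNP orientation is a
documented alternative, not implemented). The per-line detection rule is
`EAI ratio = drug EAI(max) / vehicle EAI(max) ≥ 2`, boundary inclusive.
Only lines with an AB call at SNPs in genic regions (3'UTR, 5'UTR, CDS,
exon, intron) are evaluated; pairs with an Absent detection call or a
missing condition are skipped and counted in the drop log.

The cohort analysis runs per SNP over its heterozygous lines (≥ `min_het`,
default 3; fewer yields a non-responsive row flagged `insufficient_het`):

* **ANCOVA arm.** Two rows per line (one per allele):
  `log2(drug signal) ~ allele + log2(vehicle signal)`; the reported
  p-value is the allele-factor coefficient's two-sided t-test. Adjusting
  for the same allele's baseline signal targets exactly the
  drug-conditional allelic difference the EAI ratio measures. Cell line is
  not modelled as a blocking factor; the paired t-test arm carries the
  within-line pairing instead. The OLS solve is closed-form (3-column
  design) for speed over thousands of SNPs and is verified against
  statsmodels OLS in the test suite.
* **t-test arm.** One-sample two-sided t-test of the per-line paired
  differences `log2 drug EAI(max) − log2 vehicle EAI(max)` against zero.
  Under the null these differences are symmetric about zero (difference of
  two identically distributed folded variables), so the test is close to
  nominal; simulation puts its type-I error at α = 0.01 within Monte-Carlo
  error of 0.01 across realistic heterozygote counts.
* **Fold requirement.** `max_fold ≥ fold_min (2)`, by default the largest
  drug-condition EAI(max) across het lines (`fold_rule="drug_abs"` —
  an absolute-imbalance reading); `"ratio_of_ratios"` applies the floor to
  the drug/vehicle quotient instead.

A SNP is **responsive** when `n_het ≥ min_het`, either arm has p < α, and
the fold requirement holds. Log base 2 is used throughout. Because every
statistic is a ratio, rescaling all signals of one condition by a common
constant changes nothing, and swapping the allele labels everywhere
(signals and genotype calls) is an exact invariance; both are enforced by
tests.

## Intersection

A clinically passing SNP is **coincident** when the panel supports it:
`any_line` (≥ 1 line with a detected EAI ratio), `cohort_responsive`, or
`either` (default — a single supporting line can carry the signal, as in
the motivating single-line/single-SNP case). Tightening any upstream
threshold can only shrink the coincident set. A gene-level rollup flags a
gene when any of its SNPs is coincident.

## Expression filter

Probe-level total mRNA signals are scale-normalised per condition so the
2%-symmetric-trimmed mean equals 100 (the trim fraction approximates
array target-signal scaling and is configurable); scaling is linear, hence
idempotent. Probes need a Present detection call in at least one condition
(configurable to both). The drug/vehicle ratio uses a denominator floored
at ε = 1 normalised unit — implemented as `max(vehicle, ε)` so the
boundary cases (ratio exactly 2 or 0.5) behave as stated while background
denominators cannot blow up. Up-regulated: ratio ≥ 2; down: ≤ 0.5;
boundaries inclusive; gene rollups count distinct genes.

## Synthetic data

The generators define the study conditions: 30 cell lines and 38 patients
by default, one shared SNP panel per config. Genotypes are Hardy-Weinberg
at a single MAF (default 0.3, the value used for the imbalance
recovery studies); there is no linkage disequilibrium, population
structure or per-SNP frequency variation. Baseline expression per SNP is
lognormal(μ=6, σ=0.8) on the log scale (median ≈ 400 intensity units);
the absent allele of a homozygote reports a background mean of 5 so ratio
statistics stay defined. Measurement noise is multiplicative lognormal
with σ = 0.3 by default ("low noise" studies use 0.2). Planted EAI SNPs
multiply exactly one allele's mean by `eai_effect` (default 4) in
heterozygous lines under drug only, and are forced into genic regions so
the region filter cannot mask them. Patients' latent risk ratio is
`baseline (4) + beta_risk × Σ codes + N(0, risk_noise_sd=1.5)`, truncated
at 0.05, and 6-TGN is ratio × dose, so the generator identity
`6-TGN/dose = latent ratio` holds exactly; AZA doses come from
{25, 50, 75, 100} mg/day and 5-ASA doses from a grid spanning 0–4000
mg/day weighted so a minority falls below the 2000 mg/day exclusion.
MCV and WBC are built from the standardised 6-TGN with target correlations
+0.7 and −0.5. Drug-induced EAI magnitudes in real cells are unknown, so
`eai_effect` is a free parameter. What passing tests show is that the
screens recover effects of the planted form at the configured sizes — not
that real arrays are free of batch effects, cross-hybridisation or
genotype-calling error, none of which are simulated.

For the clinical power study the target is a population r² of 0.6 at
n = 32 retained patients; `beta_risk` follows in closed form from
`r² = β²·2pq / (β²·2pq + σ²)`. MAF 0.5 is used there so the
three-genotype class filter is essentially never the binding constraint in
a 32-patient draw (at MAF 0.3 the rarest homozygote class fails the
≥ 2-per-class rule in roughly a fifth of draws, which would measure the
filter, not the correlation rule). Problem sizes in the routine study
scripts — 2500 null SNPs for the calibration check, 300 SNPs/30 planted
for recovery, 500 replicates for power — give Monte-Carlo standard errors
comfortably below the margins being checked.

## Numerical choices and degenerate inputs

Zero-variance vectors (constant risk ratios, constant genotype codes,
constant MCV) raise a typed `ZeroVarianceError` and are skipped with a
logged reason rather than propagating NaNs. Correlations need ≥ 3 complete
pairs. Non-positive signals are a caller error for `eai_max`
(`background_floor` exists for raw inputs). All decision boundaries
(EAI ratio ≥ 2, fold ≥ 2, r² ≥ 0.4) are inclusive; p-value comparisons are
strict (<). Seeds are mandatory in `SimConfig`; every generator stream is
derived from the single seed, so equal configs give byte-identical
outputs.

## Known limitations

* The genome-scale hit counts reported for the original arrays are not
  reproducible from public data (the raw arrays were never deposited);
  the package's claims are therefore about operating characteristics on
  synthetic cohorts with known truth, plus exact reproduction of the
  packaged 38-patient clinical table.
* The ANCOVA formulation of "analysis of covariance of expression values"
  is one defensible reading (allele factor, baseline covariate);
  alternatives (e.g. line as a blocking factor) are noted but not
  implemented.
* Star-allele (TPMT*2/*3B/*3C/*4) nomenclature, array physics, genotype
  calling and GO-term enrichment are out of scope.
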