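# Methods

## Background and model

MeD-seq profiles DNA methylation with the LpnPI restriction enzyme,
which cuts only at methylated CpG-containing recognition sites and
releases 32 bp fragments centred on the methylated CpG. After
sequencing, the number of fragments attributable to each LpnPI site is
a proxy for that site's methylation level. `meddx` implements the full
downstream analysis — fragment filtering, site counting, region
scoring, differentially-methylated-region (DMR) calling, cumulative
methylation scores, qMSP panel positivity and combined clinical
classifiers — together with a synthetic-data module that emulates a
two-phase study design: marker discovery in liver tissue (hepatocellular
carcinoma vs cirrhosis) followed by evaluation of those markers in
plasma cell-free DNA (cfDNA), where tumor-derived DNA is heavily diluted
by DNA from other cell types.

## Fragment filtering and QC (`meddx.reads`)

A read is kept when at least one LpnPI site lies 13–17 bp (both bounds
inclusive; configurable) from its 5' or 3' end. Each kept read is
attributed to exactly one site — the 5'-most qualifying one — so that
assigned + unassigned reads always equal the kept total. Sample QC
follows the strict rule: pass iff total reads exceed the floor AND the
fraction of CpG-containing reads exceeds 20%. The sequencing-scale
floor is 20 million reads (`PAPER_QC_MIN_READS`); a toy-scale default
of 2,000 (`TOY_QC_MIN_READS`) ships alongside for simulated libraries.
Alignment is out of scope: reads carry mapped positions, and
externally produced per-site count tables can be loaded from TSV.

## Region scores (`meddx.regions`)

Three region classes are built from the gene annotation: TSS windows
(1 kb before to 1 kb after the transcription start site), gene bodies
(1 kb downstream of the TSS to the transcription end site, strand-aware;
on the minus strand the body is `[tes, tss - flank)`), and CpG islands.
All coordinates are 0-based half-open (BED convention); windows are
clipped at chromosome ends, and bodies shorter than 1 bp are omitted.
Overlapping genes yield overlapping regions — counts may contribute to
more than one region, i.e. scoring is region-wise, not partition-wise.
A region score is the reads-per-million (RPM) sum of site counts with
`start <= pos < end`.

## DMR calling (`meddx.dmr`)

Counts are pooled within each group at every site and compared with a
2×2 chi-square test without continuity correction — the table is
[site reads, all other reads] × [case, control], which is how a count
test absorbs library-size (coverage) differences; RPM means provide the
direction (hyper/hypo relative to the case group) and fold change.
Significance is `p < alpha / n_tests` with `n_tests` the number of
testable sites (nonzero pooled coverage, sex chromosomes removed — the
Bonferroni correction is genome-wide, not per region class). Runs of
significant sites with a common direction and consecutive gaps of at
most `max_gap` are binned into one DMR spanning the first site to 2 bp
past the last (covering the final CpG dinucleotide). DMRs must then
clear `min_sites` (default 4), `min_size` (100 bp) and `min_fold` (2,
applied to max(fc, 1/fc)); `max_gap` defaults to 1,000 bp. These
defaults are package choices — thresholds of this kind are standard in
restriction-enzyme methylation analysis but no canonical values exist.

A note on calibration: pooled counts from overdispersed
(negative-binomial) libraries inflate the chi-square statistic relative
to its nominal null, so per-site Bonferroni alone is not exactly
calibrated under overdispersion. The run-binning requirement
(>= 4 same-direction significant neighbours) and the fold-change filter
make the *family-wise* DMR false-positive rate conservative in
practice; the null-calibration test measures this directly on 100
replicate null simulations.

Sex chromosomes are removed before testing (configurable list), since
X/Y methylation differences between sex-imbalanced groups would
masquerade as disease DMRs.

## Cumulative methylation scores (`meddx.signature`)

Each DMR gets an ROC-optimal RPM threshold learned on training labels:
the Youden-J maximizer (`sensitivity + specificity − 1`), ties broken
toward the larger threshold; `closest01` (nearest to the (0,1) ROC
corner) is available as an alternative criterion. A sample scores 1
per DMR it is positive for — strictly above the threshold for
hypermethylated DMRs, strictly below for hypomethylated — and the sum
over the signature is its DNA methylation score. Fit and apply are
separate calls, so thresholds never see held-out data. Score vectors
are compared between groups with a two-sided Mann–Whitney U test per
signature plus Benjamini–Hochberg correction across signatures
(flagged at q < 0.01). A negative-binomial count-model comparison
(DESeq2-style) is deliberately not used here: the inputs are small
integer counts of positive markers, not sequencing count matrices with
a mean–dispersion relationship. Infinite fold changes (control mean 0)
are capped at 1e6 and flagged.

## qMSP panel (`meddx.qmsp`)

Relative methylation is `2^-(Ct_target − Ct_ACTB)` (comparative Ct
against the unmethylated beta-actin reference). An undetermined target
Ct (no amplification) maps to level 0 rather than missing, matching
qMSP semantics. Positivity thresholds are the control group's
empirical 95th percentile per marker, computed with linear
interpolation between order statistics (the interpolation rule is a
documented choice; other rules shift borderline calls). A sample is
positive iff its level strictly exceeds the threshold, so ~5% of
held-out null controls are called positive by construction. Group
comparisons use the Mann–Whitney U test: exact enumeration for
tie-free groups of at most 25, the tie-corrected normal approximation
otherwise.

## Diagnostics (`meddx.diagnostics`)

The ASAP score is evaluated exactly as printed:
`Z = −6.836 + 0.042·age + 0.989·sex + 1.841·log10(AFP) + 0.949·log10(PIVKA-II)`.
Biomarkers are clipped to the assay detection windows (AFP 0.5–2000
ng/mL, PIVKA-II 5–75000 mAU/mL) at cohort ingestion; `asap_score`
itself lifts only non-positive inputs to the floor so the logarithms
are defined. Combined classifiers are binary logistic regressions:
`enter` keeps all features, `backward` removes the largest Wald
p-value iteratively until all remaining p <= 0.05 (SPSS-style
likelihood-ratio removal would be an alternative criterion). AIC is
`2k − 2 ln L` with k counting the intercept; under this convention AIC
is positive for any Bernoulli likelihood, so externally reported
negative AIC values for such models must follow some other convention
and are not comparable. Perfect separation triggers a flagged
L2-penalized fallback rather than an error. AUC uses the rank
(Mann–Whitney, midrank) formulation; the operating point at a fixed
specificity s is the smallest threshold whose training specificity is
>= s (positive = strictly above), and validation cohorts reuse the
frozen training threshold, so validation specificity may drift. Paired
AUC curves are compared with the DeLong structural-components test.

## Synthetic data (`meddx.synthetic`)

The generator defines the simulated study conditions:

- **Genome**: `n_chroms` chromosomes; genes and CpG islands placed with
  Poisson counts at the requested densities; LpnPI sites are point CpG
  positions with exponential spacing — mean gap 100 bp genome-wide and
  20 bp inside islands, giving island-dense site structure.
- **Counts**: negative binomial with `Var = m + phi*m^2` (Poisson as
  `phi -> 0`). Defaults: mean depth 50 reads/site and dispersion
  `phi = 0.05`. No per-site depth distribution is published for real
  MeD-seq libraries, so these defaults are placeholders chosen to be
  plausible for bulk sequencing; conclusions that depend on absolute
  depth should be re-checked against real data.
- **Planted DMRs**: inside a planted hyper region the case-group mean
  is multiplied by the fold change (divided, for hypo); default fold 4
  over runs of 8 consecutive sites.
- **cfDNA**: expected counts are the convex mixture
  `tf*tumor + (1−tf)*background`, NB-sampled. The default tumor
  fraction 0.02 reflects the reported 1–3% hepatocyte contribution to
  plasma cfDNA. This one-parameter dilution is the mechanism behind
  the package's central qualitative result: markers with near-perfect
  tissue separation become uninformative (AUC → 0.5) in cfDNA as the
  fraction drops.
- **qMSP / cohorts**: Ct values are Gaussian around group delta-Ct
  means; AFP/PIVKA-II are log10-normal per group (HCC higher and more
  dispersed) and clipped to the detection limits.

What the generator does *not* emulate: real genome sequence and motif
context, bisulfite chemistry, read quality and mapping error,
per-patient tumor heterogeneity, and covariate correlations between
clinical variables and methylation. Passing tests therefore
demonstrate the correctness and calibration of the computational
pipeline under its stated statistical model, not clinical performance
on real cohorts.

All public generator APIs take explicit seeds; identical seed and
design give byte-identical outputs.

## Pipeline (`meddx.pipeline`, CLI `meddx`)

`run_discovery` chains genome generation, planting, tissue simulation,
per-site testing, sex-chromosome removal, DMR calling, annotation,
per-DMR threshold fitting and top-k selection by training AUC (default
k = 5). `run_blood_evaluation` simulates independent training and
validation cfDNA cohorts plus matched clinical covariates, fits
DMM-only, ASAP-only, ASAP+DMM and ASAP+best-DMM logistic models on
training data and applies the frozen models and operating thresholds to
validation (default fixed specificity 0.857). Validation labels are
never read before the final evaluation call. `dilution_curve` sweeps
the tumor fraction and reports the cumulative-score AUC at each value.

Problem sizes in the shipped tests and acceptance script (one 300–500 kb
chromosome, ~2–10k sites, 10+10 tissue and up to 400+400 cfDNA samples,
100 null replicates) were chosen so the full suite runs in minutes on a
single core while keeping Monte-Carlo error well inside the asserted
tolerances; all of them are ordinary function arguments and scale up
freely.

## Known limitations

- The run-binning DMR formulation is one consistent reading of a
  "sliding window" over sequentially tested sites; a fixed-width
  window with a step size would be a different geometry.
- Backward elimination uses Wald p-values; likelihood-ratio removal
  can differ near the boundary.
- The percentile interpolation rule and the inclusive 13–17 bp filter
  bounds are documented choices where conventions differ.
- No covariate adjustment or per-sample dispersion modelling in the
  site test; groups are pooled.
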