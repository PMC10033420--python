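# Methods

This note documents the models and procedures implemented in `sbbc`, the
defaults and the reasoning behind them, what the synthetic cohort does and
does not emulate, and the numerical choices that matter for reproducing
results.

## Somatic variant processing

Mutation tables are MAF-like: one row per call with sample, genomic key
(chrom, pos, ref, alt — 1-based inclusive), gene, consequence class, VAF,
population allele frequency (the maximum of dbSNP/ExAC-style frequencies), a
somatic confidence score in [0, 1] and a 96-channel trinucleotide class.

**Somatic filter.** Calls with population AF strictly above 0.2 are removed
as presumed germline (the boundary value 0.2 is retained), and calls with a
somatic score strictly below 0.5 are removed as low-confidence.  The score
direction deserves a note: published filter descriptions of this style are
sometimes ambiguous about whether a score threshold retains or removes;
since the score is higher-is-more-confident, this package removes the
low-scoring calls, and both thresholds are explicit arguments.

**Driver annotation.** A call is a putative driver when its consequence is
splice-site, nonsense, frameshift or non-synonymous (missense or in-frame
indel) *and* its gene is in the supplied cancer gene census.  Synonymous and
unclassified consequences never qualify.

**Residual-disease QC.** The relative burden difference is `|PT − RD| / PT`
— the pre-treatment specimen is the reference denominator.  By default a
sample is discarded only when *both* criteria fire (purity < 0.3 AND
relative difference > 25%); the conjunction is configurable to OR because
prose statements of such rules are often ambiguous about the connective.
The decision reports which criteria fired.

**Clones.** Per-variant CCF = VAF · (purity·CN + (1 − purity)·2) / purity,
clipped to [0, 1], assuming one mutated copy per carrying cell (CN defaults
to 2).  Clones are 1-D agglomerations of CCF: a sorted sweep opens a new
cluster when the next value is ≥ `gap` (default 0.15) above the running
cluster mean; clone CCF is the member median; the highest-CCF clone is the
trunk and parents are assigned by descending CCF.  This is deliberately a
desk-scale stand-in, not a Bayesian subclonal reconstruction: it recovers
well-separated clones (tests require separation ≥ 3× within-clone spread)
and is not meant to resolve overlapping clusters.  PT→RD tracking matches
clones by maximal Jaccard overlap of member mutations (threshold 0.5, one RD
clone per PT clone, best match first); unmatched PT clones are extinct,
unmatched RD clones emergent, and the output table (clone, CCF_PT, CCF_RD,
status, ΔCCF) is directly fish-plot-ready.

## Pair relatedness

**Shared mutations.** `100 · 2|A∩B| / (|A|+|B|)` on (chrom, pos, ref, alt)
keys — mutation identity, not gene identity, because two tumors hitting the
same gene with different variants is evidence of *independence*.  The
statistic is symmetric, bounded in [0, 100] and equals 100 iff the sets are
identical; it is undefined (error) when both sets are empty.

**Copy number.** Gene-level total-copy-number profiles have the diploid
reference (2) subtracted before the cosine, so the shared diploid background
cannot manufacture similarity; a profile entirely at reference has no
direction and raises.  Distance = 1 − similarity.

**Signatures.** Spectra are counts over the 96 pyrimidine-centred
trinucleotide substitution classes in COSMIC order.  Exposures minimise
`‖spectrum/Σ − catalogue·e‖²` with e ≥ 0, Σe = 1, solved by SLSQP on the
exact quadratic objective (tolerance 1e-14, ≤ 500 iterations) — equivalent
at this scale to the quadratic-programming refitters used in signature
software.  The package ships a deterministic synthetic 13-column catalogue
(`toy_breast_catalogue`) named after the signatures recurrently seen in
breast cancer, with APOBEC-, clock- and HRD-like accents; real COSMIC
matrices are accepted anywhere a catalogue is taken.  Cohort-level
percentages average multicentric foci of one patient-side first, then
average across patient-sides and multiply by 100, so a patient with several
sampled foci cannot dominate the cohort profile.

**Classification.** A pair is called clonal when shared-mutation count ≥ 2
or shared percentage ≥ 10%; both thresholds are explicit configuration, as
no formal decision rule is standard — the defaults reflect the convention
that two independently recurrent identical mutations are already unlikely.
Copy-number similarity is reported as context but does not enter the rule.

## Immune contexture and TCR repertoires

The dissimilarity index between two samples is the sum over the 22 LM22
subsets of squared abundance differences (absolute-mode deconvolution
output).  It is computed pairwise between samples; no cohort-size
normalisation is applied (this affects scale only, not ordering).  Block
means summarise within-PT, within-RD, cross, left–right-pair and
PT–RD-pair dissimilarity, with Wilcoxon rank-sum p-values for the stated
contrasts; singleton blocks are reported as missing.

TIL change categories compare pre/post levels after rounding to the nearest
integer percent (TILs are recorded in whole percent in practice): equal →
stable, lower → decreased, higher → increased; incomplete records are
excluded from denominators.

Chao-1 is `S_obs + f1²/(2 f2)`, switching to the bias-corrected
`S_obs + f1(f1−1)/2` when there are no doubletons (avoids division by
zero).  D50 is the minimal number of clonotypes, in decreasing count order
(ties broken by CDR3 sequence for determinism), whose cumulative frequency
reaches 50% of reads.  Sharing statistics count distinct CDR3 sequences
common to sample pairs; *public* clonotypes are sequences seen in samples of
at least two distinct patients when a sample→patient map is supplied.

## Expression

Counts are normalised with median-of-ratios size factors (geometric-mean
reference over genes expressed in every sample; total-count fallback with a
warning) followed by log2(x + 1).  This is a variance-stabilising surrogate
for a regularised-log transform: the downstream analyses use only
correlation structure and rank-based gene variability, which the surrogate
preserves, and it needs no fitted dispersion model.

Variable genes: per-gene IQR on the normalised matrix, sorted ascending;
the knee is the point of the curve farthest (perpendicular distance) from
the chord joining the first and last points, first index on ties —
deterministic and conservative (keeps more genes); selection is IQR
strictly above the knee's IQR.  A perfectly linear curve has all distances
zero, so the knee degenerates to the first point and all genes above it are
kept (documented behaviour); an all-equal curve raises and suggests a
fixed-count fallback.  The IQR is computed after transformation.

Clustering uses d = 1 − Pearson r between samples over the selected genes
with Ward linkage; Ward on a correlation distance violates Ward's Euclidean
assumption but is the conventional pairing for expression profiles, and is
used here knowingly.  Samples are sorted by label before linkage so merge
order is deterministic under ties.  PCA takes the 3,000 most-IQR-variable
genes (all genes, with a warning, when fewer exist), gene-centres, and
projects samples via SVD with a deterministic sign convention.

The PT–RD co-pairing rate is the fraction of residual-disease samples whose
nearest neighbour in the distance matrix is their own primary tumor; the
fraction nearest the contralateral tumor is reported alongside.

## Clinical statistics

pCR is ypT0 or ypTis together with ypN0.  The axillary response rate
defaults to the node-negative proportion (zero residual positive nodes);
a `strict_literal` mode computes the proportion of patients with more than
one positive node, reproducing a published figure-legend wording that
conflicts with the term "pCR" — both modes are explicit so either
convention can be reproduced, never silently.

Concordance between left and right tumors uses Cohen's kappa
(multi-category, marginal-product expected agreement) for categorical
variables and Kendall tau-b (tie-corrected) for numeric ones.

The interaction models fit
`outcome ~ subtype + concordance + subtype:concordance (+ covariates)` with
luminal and concordant as reference levels (the largest cell) against the
reduced model without the interaction; linear by least squares for TIL
levels, logistic by IRLS (tol 1e-8, ≤ 100 iterations) for pCR.  The
interaction p-value is the likelihood-ratio chi-square with df = number of
interaction columns, flagged significant at 0.10 — the conventional level
for low-powered interaction tests.  Design matrices are built explicitly;
interaction columns for empty subtype × concordance cells are dropped with
a warning (estimable contrasts only), and apparent separation in the
logistic fit (|coefficient| > 15) raises with a suggestion to penalise.
Group comparisons use Fisher's exact test for 2×2 tables, chi-square
otherwise and Wilcoxon rank-sum for continuous outcomes; a `prefer`
argument forces a specific convention where needed (a continuity-corrected
chi-square on a 2×2, for instance).  Forward stepwise selection adds, per
round, the candidate with the smallest likelihood-ratio p ≤ 0.05, ties
broken by candidate order.

Null calibration: with an iid Gaussian outcome the interaction LRT rejects
at ~9–10% at the 0.10 level.  On cohorts from the default generator the
rate is ~12%: truncating TIL noise to [0, 100] makes residual variance
subtype-dependent, and with heavily unbalanced cells this mildly inflates
the pooled-variance test.  This is a property of the simulated data, not of
the test, and is left as-is.

## The synthetic cohort

The generator's defaults are the study conditions the analyses assume.
Clinical layer: 313 pairs, 84.7% subtype-concordant; subtype weights
luminal 0.876 / TNBC 0.072 / HER2+ 0.052; concordant pairs draw one subtype
for both tumors, discordant pairs two distinct subtypes, so the label is
consistent by construction.  Stromal TIL baselines 15/35/25% for
luminal/TNBC/HER2+ (chosen so TNBC > HER2+ > luminal, as no per-subtype
means are published to reproduce), Gaussian noise sd 12, truncation to
[0, 100]; luminal tumors in discordant pairs receive +12 TIL points — the
interaction the inference stage is asked to recover.  pCR follows a
logistic model calibrated so luminal-concordant ≈ 6%, luminal-discordant
≈ 22%, TNBC ≈ 35%, HER2+ ≈ 30%, with no concordance effect outside
luminal; staging (ypT/ypN, residual positive nodes) is generated
consistently with the drawn pCR.

Sequenced sub-cohort (default 6 of the pairs, mirroring a
20-sample-scale sequencing study): each patient gets 30 germline variants
(population AF 0.25–0.6, emitted in every sample so the somatic filter is
exercised end-to-end), per-tumor somatic mutations (Poisson, mean 151.5)
with channels drawn from the tumor's signature mixture (Dirichlet per
genotype; BRCA carriers, prevalence 13/313, weight the HRD-like signature),
5 low-score artifact calls per sample, and purity uniform on [0.4, 0.9].
Clones: trunk CCF 1 holding 60% of mutations plus stick-broken subclones;
VAF = CCF·purity/2 + Gaussian noise (sd 0.01).  In `independent` mode left
and right share no somatic mutation; in `clonal` mode both sides carry the
same burden and share exactly the configured trunk fraction, so the
shared-mutation percentage equals that fraction by construction.  RD
samples drop each non-trunk clone with probability 1 − retention (default
0.7) and gain 25 private mutations as one emergent clone.  Two right-side
RD samples are planted with purity 0.10–0.28 and ~45% mutation loss so the
QC rule discards exactly them.  Arm-level CNA events favour gains at
1q/8q/17q and losses at 4p/8p/6q/13q/16q (probability 0.5 vs 0.08
background); RD inherits PT events with a 5% flip probability, sides draw
independently.

Expression: per-sample latent = patient component (weight
√leftright_correlation, default √0.3) + tumor component shared by a PT and
its RD (weight √ptrd_correlation, default √0.9) + noise, scaled into a
log-rate around a lognormal gene baseline, with subtype-shifted
hormone/proliferation/immune modules (100 genes each of 1,500); counts are
Poisson.  Immune: Dirichlet over the 22 LM22 subsets times a Gamma total
mass; the PT concentration peaks at M2, resting CD4 memory and M1; the RD
concentration shifts mass toward M2/M0/CD4-resting *and* is rescaled to a
lower total (14), so post-treatment profiles are both shifted and more
dispersed.  TCR: per sample 150 clonotypes drawn 90/7/3% from
private/patient/public pools with Zipf(a = 2) counts.

Every layer draws from its own seed substream of the single config seed, so
layers are reproducible independently of generation order, and all outputs
are byte-deterministic under a fixed seed.

**What the generator does not emulate** — and hence what passing tests do
not establish about real data: sequencing noise and coverage structure (no
read-level simulation), focal or allele-specific copy number, subclonal CNA,
signature profiles of real COSMIC shape (the toy catalogue is synthetic),
real LM22 correlation structure between subsets, V/J gene usage, survival
endpoints, and missing clinical data.  Tests demonstrate internal
consistency and statistical calibration of the methods, not biological
validity on patient cohorts.

## Problem sizes and numerics

The test suite and the acceptance script run simulation-based checks at
sizes chosen to keep Monte-Carlo noise well inside the asserted bands on a
single CPU: 100 random instances per metric-oracle comparison (tolerances
1e-12 for dot-product metrics, 1e-9 otherwise), 20 three-signature mixtures
at 5,000 mutations for exposure recovery (mean RMSE < 0.05), 400 null
cohorts of 500 pairs for the type-I-error estimate and 200 cohorts of 400
pairs for CI coverage, and a 20-pair sequenced cohort for burden medians.
Floating-point values are written to bundles with 17 significant digits;
missing values as `.`; all tables with fixed column order and row sort so
repeated writes are checksum-identical.
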