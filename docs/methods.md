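# Methods

`sccprog` re-implements, as a tested pipeline over synthetic data, the
genomic analysis of cutaneous squamous cell carcinoma (cuSCC)
development across its preneoplastic sequence: chronically sun-exposed
normal skin (NS; the mouse analogue is chronically irradiated skin,
CHR) to actinic keratosis (AK; mouse papilloma, PAP) to invasive SCC.
This note documents the statistical models, defaults, numerical
choices, and what the synthetic generators do and do not emulate.

## Mutation spectra and overlap (`spectrum`)

Somatic SNVs are placed in trinucleotide context and tabulated in the
standard 96-class pyrimidine-centric catalog (six substitution types x
sixteen flanking-base contexts; purine-reference variants are
reverse-complemented).  Adjacent same-sample SNVs are collapsed
left-to-right into multi-nucleotide records before spectrum summaries;
the CC->TT fraction — the UVB photoproduct hallmark — is reported over
the dinucleotide denominator and is NaN (not 0) when no dinucleotide
events exist.  Mutational load is variants per megabase over an
explicitly supplied callable footprint; no footprint is ever built in.
The significantly-mutated-gene rule retains genes mutated in at least
`min_pairings` tumour/control pairings (default 7) that are either on
a prior-evidence list or exceed a COSMIC recurrence count threshold
(default 400, interpreted as total recorded mutations for the gene).
Site-specific overlap between two samples is the size of their
`(chrom, pos, alt)` intersection; cohort means average over
within-patient comparison rows, so a patient with two SCCs contributes
two AK/SCC comparisons — this is the aggregation that reproduces the
reference cohort's means (0.75, 3.4, 1.8) from its per-patient counts.

## Non-smooth NMF (`nsnmf`)

Catalogs X (96 x samples) are factorised as X ~ W S(theta) H with
S(theta) = (1-theta) I + (theta/k) J.  The smoothing operator blends
each signature with the uniform mixture during the partner update,
which absorbs flat noise and drives both W and H towards sparser, less
correlated solutions; theta = 0 is classical KL-NMF exactly.  Updates
are multiplicative Kullback-Leibler steps applied alternately (H
against the effective basis W S, W against the effective coefficients
S H), each of which is monotone in the KL objective, so the recorded
divergence history is non-increasing.  Defaults: theta 0.5 (always
logged in outputs), 10 restarts, convergence at relative divergence
change < 1e-6 or 2,000 iterations, epsilon floor 1e-12 in all
quotients.

Scale fixing: signatures are meaningful only up to column scale, so W
is column-normalised to unit sums at the end of each restart with the
compensating rescale of H, followed by H-only polish updates against
the fixed normalised basis.  An exact reconstruction-preserving
compensation would be H <- S^-1 D S H, which can produce negative
entries for theta > 0; the polish step instead re-converges the
exposures, leaving the reconstruction divergence unchanged to within
the convergence tolerance.  Model order k is caller-supplied; selecting
k is out of scope.  Exposure attribution of a catalog against a fixed
signature set minimises KL divergence by the same multiplicative
update (nonnegative least squares is available as an option) and
reports proportions; recovery experiments match estimated to true
signatures by Hungarian assignment on cosine similarity.

Identifiability caveat: without near-pure samples (separability) the
factorisation is not unique and no algorithm can guarantee recovering
planted signatures; the recovery tests use sparse Dirichlet exposures,
which provide approximately pure samples.

## Expression processing (`expression`)

Size factors use the median-of-ratios (scaling factor) method over
genes expressed in every sample, rescaled to geometric mean 1, with a
total-count fallback.  The variance-stabilising transform is the
stand-in `log2(count / size_factor + 1)`, named `vst_standin` in
outputs: downstream steps need only monotone variance flattening, not
a fitted dispersion trend.  Batch alignment shifts each batch per gene
so all batch medians equal the gene's global median (an additive shift
on the log scale; the operation is idempotent).  The differential
expression stand-in is a per-gene Welch t-test on transformed values
(paired mode uses within-subject differences), with
Benjamini-Hochberg control; this deliberately diverges from
negative-binomial Wald pipelines and is documented as such.  The
integration cutoff q < 0.25 with fold change > 1.25x is exposed as
`DEResult.significant`.  Clustering uses 1 - Pearson r with complete
linkage; PCA components are sign-fixed so the largest-magnitude
loading is positive.  The CIN70 chromosomal-instability score sums
size-factor-normalised counts over a caller-supplied gene set (the
70-gene list belongs to its original publication and ships as an input
fixture, not embedded), transforms as log2(x+1), and adjusts by
least-squares residuals on subject and batch indicator covariates.

## Progression model (`progression`)

For each gene, transformed expression is modelled as stage fixed
effects plus a per-subject random intercept, restricted to subjects
with complete three-stage sets, and fitted by exact maximum likelihood:
the variance ratio lambda = tau^2/sigma^2 is profiled out (per-group
Sherman-Morrison inverses give closed-form GLS estimates for each
lambda) and maximised by bounded one-dimensional search.  The boundary
lambda = 0 is a legitimate ML solution and is not treated as a
convergence failure — this matters, because generic mixed-model
optimisers flag a large fraction of boundary genes as failed and would
silently exclude them.  Models are genuinely refitted under both the
normal-skin and the intermediate-lesion reference parameterisations
(the reparameterization identity, coefficient negation under reference
swap, is then a real test of the fitter).  Wald tests use the normal
approximation; no per-gene degrees-of-freedom correction is applied,
and nominal p (not q) gates the designation, though q-values are
emitted alongside.

Designation rule (alpha = 0.05 nominal): the full-span (SCC vs NS)
contrast must be significant; *early* additionally requires the AK-NS
contrast significant with matching sign, *late* the SCC-AK contrast,
*stepwise* both.  Per-species false designation under this rule runs
at roughly 4-6% of null genes (the gate and second test are strongly
correlated); the cross-species intersection is what drives the false
rate to ~0.2%, since a null must be designated identically with
matching sign in two independent cohorts.  Fold changes are computed
in a paired manner: per subject, the ratio of anti-log2 values, then
the arithmetic mean of those per-subject ratios.

Cross-species sets keep homolog pairs with identical designation and
full-span coefficient sign after restricting the homology map to
one-to-one pairs (any feature in more than one pair is discarded with
all its pairs).  Motif overrepresentation in the resulting sets
reports a one-sided Fisher exact p together with a conjugate-Dirichlet
2x2 Bayes factor (uniform Dirichlet priors on the association model's
four cells versus independent uniform priors on the margins; the
multinomial coefficient cancels), with BF > 3 flagged.

## Enrichment (`enrichment`)

The running-sum statistic is the weighted Kolmogorov-Smirnov form: hit
increments proportional to |score|^p (default p=1), miss decrements
1/(N-m); ES is the signed maximum deviation.  Significance permutes
gene labels — on a fixed ranked list this is the only permutable unit —
with NES = ES / mean(|null ES| of the same sign), empirical p against
the same-sign null, and BH q within each enrichment direction.  The
transcription-factor concordance filter selects factors whose targets
are significantly enriched (q < 0.25) in the same direction in both
species in an adjacent stage comparison and in the full NS-to-SCC
comparison, labelling the factor early/late/global by which
transitions fired; opposite-direction transitions are recorded
separately.  The co-target network links selected factors whose
target-set overlap has one-sided Fisher p below 1e-4 within the
regulated-gene universe.

## miRNA pipeline (`mirna`)

Usable small-RNA reads are those of length >= 10 nt whose terminal
single-base run is <= 8 nt.  The read-to-miRNA matcher is an
exact-prefix stand-in for alignment-based mapping: a read matches a
reference it equals or prefixes with at most one mismatch; reads
matching several references at the same best mismatch count are split
fractionally.  Abundances are parts per million of usable reads.
Differential expression per stage comparison uses a t-test on
log2(ppm+1) with a 1.5x fold-change threshold at P < 0.05; the
recurrence call requires significance in at least two of three
comparisons *with consistent direction* (the direction-consistency
requirement is this package's explicit choice).  Functional pairs:
for each significantly changed miRNA, a one-sided Fisher test of its
predicted-target set against the opposite-direction significant gene
set (q < 0.25, FC > 1.25) within the tested-gene universe, BH across
miRNAs per comparison; passing miRNAs are paired with each
anti-directional significant predicted target, ranked by the number of
significant comparisons.  Conservation requires the miRNA (via a
family name map) and the target (via the one-to-one homolog map) to
appear with the same direction pattern in both species.

## Scoring and survival (`scoring`)

Cohort signatures take genes at |FC| > 2 and P < 0.05 split by sign.
Cohort ranking scores each cohort by the sum of squared NES over its
significant (q < 0.25) signature directions minus lambda times the
number of non-significant directions; the penalty lambda defaults to 0
and is recorded with the output, as the original penalty form is not
specified.  The survival signature replaces each gene by its z-score
within the cohort and scores each sample as the sum over upregulated
genes minus the sum over downregulated genes; zero-variance genes
contribute 0.  Samples are sorted by score with ties broken by sample
identifier, and the top quartile (floor(n/4) samples) is compared with
the bottom quartile by the standard two-group log-rank chi-square with
Kaplan-Meier curves; a fully censored selection yields a NaN sentinel
with a message rather than an exception.

## Synthetic data (`simulate`)

All generators are pure functions of `SimConfig`; the seed fully
determines every output, and ground truth sufficient to score each
downstream stage is returned alongside the data.

Mutation cohorts: the reference is uniform-random A/C/G/T (default
1 Mb); `footprint_mb` (default 64.05, the value implied by 2,927
variants at 45.7/Mb) is a separate scalar because exome capture
footprints are not equal to reference length.  Six patients carry one
sample per lesion class with Poisson totals around class means
372/1,186/2,927.  Each mutation draws a signature from the class's
exposure mixture — UVB-dominated in AK/SCC (0.80/0.85 weight),
more even in NS (0.45) — and a 96-channel context from that
signature, and is placed at a uniformly chosen reference position with
the matching trinucleotide (reverse-complement placement for
purine-centred sites), with a 1,000-retry cap and a hard error rather
than silent bias when contexts are exhausted.  VAFs are Beta draws
whose shapes shift towards higher frequencies from NS to SCC,
mimicking emerging clonal dominance.  `shared_clone_fraction` copies
that fraction of a later lesion's variants site-identically from the
preceding lesion (default 0: the observed within-patient overlaps are
near chance level).  Note that on a 1-Mb reference the
context-restricted placement makes random collisions between
high-count samples non-negligible; overlap-counting tests that require
near-zero chance overlap use smaller counts or longer references.

Expression pairs: counts are negative binomial with variance
mu + alpha mu^2 (alpha default 0.1) around
mu = 2^(baseline + stage effect + subject intercept + batch shift),
baseline Uniform(3,8) log2, subject intercepts N(0, 0.5^2), a 0.3-log2
batch shift on the second batch.  Early genes shift at the first
transition only, late at the second only, stepwise at both, with
random signs concordant across species; planted fractions default to
10%/2%/3% (changes concentrated in the early transition).  70% of
genes are one-to-one homologs; 10% are embedded in many-to-many groups
so the homolog filter has something to discard; the rest are unmapped.

miRNA pairs: a subset of miRNAs (default 15 of 120) moves
monotonically across stages (half up, half down, 2-log2 full-span
effect); each mapped target of a regulated miRNA moves oppositely with
probability `penetrance`.  Target-gene baselines are drawn
Uniform(5,9) log2 — the generator emulates the expression-filtered
tested gene space, since a planted 4x repression of a gene with ~8
counts is statistically invisible at n=6 and no pipeline would test
such genes.

Survival: signature genes track a latent per-sample factor (up genes
positively, down genes negatively, unit noise); event times are
exponential with rate baseline_hazard x exp(hazard_coef x standardised
signature score); censoring is independent with the configured
probability, censoring times drawn uniformly before the event.

What the generators do not emulate: sequencing error and alignment
artifacts, copy-number and indel variation, isoform structure, GC and
length biases, dispersion trends varying with expression, miRNA
isomiRs, informative censoring, and correlated gene-gene noise.
Passing tests therefore demonstrate correctness of the statistical
machinery under the stated generative models, not robustness to every
artifact of real sequencing data.

## Problem sizes used in the checks

The test suite exercises the documented study-scale regimes directly:
signature recovery at k=4 with 200 samples of 2,000 mutations;
progression recovery at 2,000 genes with 6 subjects per species (the
recovery check plants strong, 1.5-log2 effects, as weaker 2-fold
effects are genuinely underpowered at this cohort size); GSEA
calibration over 200 random sets at 200-1,000 permutations; survival
calibration over 200 null cohorts and 100 powered cohorts of 200
samples.  The cohort-scale spectrum statistics run on the full default
cohort (~27,000 variants).

## Known limitations

The DE stand-in lacks shrinkage, so its q-values are better calibrated
at moderate counts than for very low-count genes.  The theta behind the
original pan-cancer 21-signature basis is not on record, and that
basis itself (derived from >6,000 tumour exomes) is not re-derivable
here; theta is therefore an explicit, logged parameter.
The GATHER Bayes factor is a documented conjugate-Dirichlet stand-in;
the Fisher p is always reported alongside.  The mixed model supports a
single random intercept; crossed or nested random effects are out of
scope.
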