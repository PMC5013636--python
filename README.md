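# sccprog

Cross-species genomic analysis of cutaneous squamous cell carcinoma
(cuSCC) development through its preneoplastic stages: chronically
sun-exposed normal skin (NS; mouse analogue CHR) → actinic keratosis
(AK; mouse papilloma) → invasive SCC.  The package is for
computational biologists studying premalignant progression who need a
tested, reusable implementation of the full analysis chain over
matched-lesion cohorts — with a synthetic-data generator carrying
known ground truth in place of protected patient sequencing data.

## What it computes

- **Mutation spectra and overlap** (`sccprog.spectrum`): 96-class
  trinucleotide catalogs (pyrimidine-centric SBS convention), DNP
  collapsing and the CC→TT UVB hallmark fraction, per-Mb mutational
  loads, the recurrence + prior-evidence rule for significantly
  mutated genes, and within-patient site-specific overlap counts
  between lesion classes.
- **Non-smooth NMF** (`sccprog.nsnmf`): sparse signature
  deconvolution X ≈ W·S(θ)·H with the smoothing operator
  S(θ) = (1−θ)I + (θ/k)J between basis and exposures, multiplicative
  KL updates, best-of-restarts, and exposure refitting of new catalogs
  against a fixed signature set.
- **Expression processing** (`sccprog.expression`): median-of-ratios
  normalisation, a documented log2 VST stand-in, per-gene batch-median
  alignment, t-test differential expression with BH control,
  Pearson/complete-linkage clustering with PCA, and covariate-adjusted
  CIN70 chromosomal-instability scores.
- **Progression model** (`sccprog.progression`): per-gene linear mixed
  models (stage fixed effects, subject random intercept, exact
  profiled ML) fitted under two reference parameterisations; genes
  designated *early*, *late*, *stepwise* or *none* by the nominal-p
  gating rule; one-to-one homolog filtering and cross-species
  conserved sets; motif overrepresentation with Fisher p and a
  conjugate-Dirichlet Bayes factor.
- **Enrichment** (`sccprog.enrichment`): weighted KS running-sum GSEA
  with gene-label permutation NES/q, the cross-species transcription
  factor concordance filter, and the Fisher-exact TF co-target
  network.
- **miRNA functional pairs** (`sccprog.mirna`): small-RNA read
  filtering, prefix-match ppm quantification, ≥2-of-3
  direction-consistent recurrence calls, and miRNA–mRNA
  anti-correlated functional pairs with cross-species conservation.
- **Scoring and survival** (`sccprog.scoring`): FC>2/P<0.05 cohort
  signatures, penalised sum-of-squared-NES cohort ranking, z-score-sum
  signature scores, and top-vs-bottom quartile Kaplan–Meier/log-rank
  comparison.
- **Synthetic cohorts** (`sccprog.simulate`): seed-deterministic
  generators for every input above, returning ground truth that scores
  each downstream stage.

## Worked example

Simulate the default mutation cohort (6 patients, class mean counts
372/1,186/2,927, 64.05-Mb callable footprint), compute loads and
spectra, and deconvolve signatures:

```python
from sccprog import simulate as sim, spectrum, nsnmf

cfg = sim.SimConfig(seed=1)
reference, variants, truth = sim.simulate_mutation_cohort(cfg)
variants = spectrum.collapse_dnps(variants)
per_sample, per_class = spectrum.mutation_load(variants, cfg.footprint_mb)
print(per_class.round(1))

summary = spectrum.spectrum_summary(variants, reference)
print("C>T fraction:", round(summary.six_class_fractions["C>T"], 3))

catalog = spectrum.build_catalog96(variants, reference)
model = nsnmf.nsnmf_factorize(catalog.to_numpy(), k=3, theta=0.5,
                              n_restarts=5, seed=1)
perm, cos = nsnmf.match_signatures(model.W, cfg.truth_signatures)
print("signature recovery cosines:", cos.round(3))

props = nsnmf.fit_exposures(model.W[:, perm], catalog["P1_SCC"].to_numpy())
print("P1_SCC exposures:", props.round(3))
```

Output:

```
              mean_n  mean_load  min_load  max_load
lesion_class
AK            1173.8       18.3      18.1      18.6
NS             369.8        5.8       5.5       6.0
SCC           2925.0       45.7      44.9      46.8
C>T fraction: 0.917
signature recovery cosines: [0.996 0.955 0.305]
P1_SCC exposures: [0.762 0.074 0.164]
```

The per-class mean loads land on the cohort figures the generator is
parameterised to mimic (5.8 / 18.5 / 45.7 variants per Mb), and the
spectrum is dominated by C→T transitions as expected under UVB
mutagenesis.  The two concentrated truth signatures (UVB-like and
CpG-like C→T) are recovered at cosine ≥0.95; the third, flat
background signature is only weakly identified (cosine 0.31) — a
diffuse signature carried at low exposure by 18 samples is close to
unidentifiable, which is exactly the behaviour the sparseness-seeking
smoothing is meant to expose rather than hide.  The SCC sample's
refit exposures put 76% of mutations on the UVB-like signature
(truth: 85% of draws, with the background absorbing part of the
remainder).

The same operations are scriptable from a shell:

```bash
sccprog simulate mutations --seed 1 --out-dir cohort/
sccprog spectrum load --variants cohort/variants.tsv --footprint-mb 64.05 --out loads.tsv
sccprog nsnmf fit --catalog catalog.tsv --k 3 --theta 0.5 --seed 1 --out-dir nmf/
```

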