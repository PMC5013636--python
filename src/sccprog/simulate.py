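"""Synthetic cohorts with known ground truth for every pipeline stage.

Generates (i) signature-mixture somatic mutation cohorts with
patient/lesion-class structure and optionally shared clones, placed on
a random reference sequence so trinucleotide contexts are genuine;
(ii) paired two-species negative-binomial expression studies with
subject random intercepts, batch shifts and planted early/late/stepwise
progression genes linked by a partly one-to-one homology map;
(iii) miRNA/mRNA count pairs in which chosen miRNAs move across stages
and their mapped targets move oppositely with configurable penetrance;
and (iv) survival cohorts whose event hazard depends on a z-score-sum
gene-signature score.  Every generator is a pure function of
:class:`SimConfig` - the seed fully determines all outputs - and
returns ground-truth objects sufficient to score the downstream stage.

Defaults mirror the study conditions: six patients with lesion classes
NS/AK/SCC at mean somatic variant counts 372/1,186/2,927 over a
64.05-Mb callable footprint, a UVB-dominated signature mixture for
AK/SCC with a more even mixture in NS, and progression effects
concentrated in the early (NS to AK) transition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .scoring import zscore_signature_score
from .spectrum import BASES, CONTEXT_LABELS, VariantRecord, revcomp

DEFAULT_CLASS_MEANS = {"NS": 372, "AK": 1186, "SCC": 2927}
#: callable footprint implied by 2,927 variants at 45.7 per Mb
DEFAULT_FOOTPRINT_MB = 64.05


def default_signatures() -> np.ndarray:
    """Three 96-channel truth signatures: UVB-like, CpG-like, flat.

    The UVB-like signature concentrates on C>T at dipyrimidine contexts
    (pyrimidine 5' neighbour), the CpG-like one on C>T at NpCpG
    contexts, and the third is flat background.  Columns sum to 1.
    """
    w = np.zeros((96, 3))
    for i, label in enumerate(CONTEXT_LABELS):
        five, sub, three = label[0], label[2:5], label[6]
        if sub == "C>T" and five in "CT":
            w[i, 0] = 1.0
        if sub == "C>T" and three == "G":
            w[i, 1] = 1.0
    w[:, 2] = 1.0
    return w / w.sum(axis=0)


DEFAULT_CLASS_EXPOSURES = {
    # UVB-dominant in lesions, more even mixture in chronically exposed skin
    "NS": (0.45, 0.25, 0.30),
    "AK": (0.80, 0.10, 0.10),
    "SCC": (0.85, 0.08, 0.07),
}

#: VAF beta parameters per lesion class: NS skewed to low-frequency
#: subclones, SCC towards emerging dominant clones.
DEFAULT_VAF_BETA = {"NS": (1.5, 8.0), "AK": (2.0, 6.0), "SCC": (3.0, 5.0)}


@dataclass
class SimConfig:
    """Configuration for all synthetic generators.

    The seed fully determines every output.  Proportion-valued fields
    must lie in [0, 1]; ``frac_early + frac_late + frac_stepwise`` must
    not exceed 1; truth signature columns must sum to 1.
    """

    seed: int = 0
    # mutation cohort
    n_patients: int = 6
    lesion_classes: tuple[str, ...] = ("NS", "AK", "SCC")
    class_mean_counts: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_MEANS)
    )
    shared_clone_fraction: float = 0.0
    footprint_mb: float = DEFAULT_FOOTPRINT_MB
    reference_length: int = 1_000_000
    truth_signatures: np.ndarray = field(default_factory=default_signatures)
    truth_exposures: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_EXPOSURES)
    )
    max_placement_retries: int = 1000
    # expression pair
    genes_total: int = 2000
    frac_early: float = 0.10
    frac_late: float = 0.02
    frac_stepwise: float = 0.03
    effect_size_log2: float = 1.0
    subject_sd: float = 0.5
    batch_shift: float = 0.3
    nb_dispersion: float = 0.1
    n_batches: int = 2
    one_to_one_fraction: float = 0.7
    many_to_many_fraction: float = 0.1
    # miRNA pairs
    n_mirna: int = 120
    n_de_mirna: int = 15
    targets_per_mirna: int = 20
    penetrance: float = 1.0
    mirna_effect_log2: float = 2.0
    mirna_target_map: dict[str, set[str]] | None = None
    # survival
    n_survival_samples: int = 200
    hazard_coef: float = 1.0
    censor_rate: float = 0.3
    baseline_hazard: float = 0.1

    def __post_init__(self) -> None:
        for name in (
            "shared_clone_fraction",
            "frac_early",
            "frac_late",
            "frac_stepwise",
            "penetrance",
            "censor_rate",
            "one_to_one_fraction",
            "many_to_many_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.frac_early + self.frac_late + self.frac_stepwise > 1.0:
            raise ValueError("planted gene fractions must sum to <= 1")
        w = np.asarray(self.truth_signatures, dtype=float)
        if w.ndim != 2 or w.shape[0] != 96:
            raise ValueError("truth_signatures must be 96 x k")
        if not np.allclose(w.sum(axis=0), 1.0, atol=1e-9):
            raise ValueError("truth signature columns must sum to 1 within 1e-9")
        k = w.shape[1]
        for cls, exp in self.truth_exposures.items():
            if len(exp) != k:
                raise ValueError(
                    f"exposures for class {cls} have {len(exp)} entries, "
                    f"but truth_signatures has k={k}"
                )
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if self.footprint_mb <= 0:
            raise ValueError("footprint_mb must be positive")
        if not np.isfinite(self.hazard_coef):
            raise ValueError("hazard_coef must be finite")


@dataclass
class MutationTruth:
    """Ground truth for a simulated mutation cohort."""

    exposures: pd.DataFrame  # samples x signatures, proportions
    shared_sites: pd.DataFrame  # patient, donor/recipient samples, chrom, pos, alt
    class_mean_counts: dict[str, float]


def _context_positions(sequence: str) -> dict[str, np.ndarray]:
    """1-based centre positions of each pyrimidine-centric trinucleotide.

    A genomic site whose forward-strand trinucleotide has a purine
    centre is indexed under the reverse complement, so every interior
    position appears under exactly one pyrimidine-centred context.
    """
    positions: dict[str, list[int]] = {}
    for i in range(1, len(sequence) - 1):
        tri = sequence[i - 1 : i + 2]
        key = tri if tri[1] in "CT" else revcomp(tri)
        positions.setdefault(key, []).append(i + 1)
    return {k: np.asarray(v) for k, v in positions.items()}


def simulate_mutation_cohort(
    cfg: SimConfig,
) -> tuple[dict[str, str], list[VariantRecord], MutationTruth]:
    """Signature-mixture mutation cohort on a random reference sequence.

    Per patient and lesion class, a Poisson total around the class mean
    is drawn; each mutation draws a signature from the sample's truth
    exposure mixture and a 96-channel context from that signature, and
    is placed at a reference position whose trinucleotide matches the
    drawn context (reverse-complemented placement for purine-centred
    sites).  Within a patient, a fraction ``shared_clone_fraction`` of
    each later lesion's variants is copied site-identically from the
    preceding lesion class, emulating shared clones.

    Returns (reference, variants, truth); truth carries realised
    per-sample exposure proportions and the shared-site list.
    """
    rng = np.random.default_rng(cfg.seed)
    seq = "".join(rng.choice(list(BASES), size=cfg.reference_length))
    reference = {"chr_sim": seq}
    ctx_positions = _context_positions(seq)
    w = np.asarray(cfg.truth_signatures, dtype=float)
    k = w.shape[1]

    variants: list[VariantRecord] = []
    shared_rows = []
    exposure_rows = {}
    for p in range(1, cfg.n_patients + 1):
        patient = f"P{p}"
        prev_sample_variants: list[VariantRecord] | None = None
        for cls in cfg.lesion_classes:
            sample = f"{patient}_{cls}"
            n_total = int(rng.poisson(cfg.class_mean_counts[cls]))
            mix = np.asarray(cfg.truth_exposures[cls], dtype=float)
            mix = mix / mix.sum()
            n_shared = 0
            sample_variants: list[VariantRecord] = []
            used_positions: set[int] = set()
            if prev_sample_variants is not None and cfg.shared_clone_fraction > 0:
                n_shared = min(
                    int(round(cfg.shared_clone_fraction * n_total)),
                    len(prev_sample_variants),
                )
                donor_idx = rng.choice(
                    len(prev_sample_variants), size=n_shared, replace=False
                )
                a, b = DEFAULT_VAF_BETA.get(cls, (2.0, 5.0))
                for idx in donor_idx:
                    d = prev_sample_variants[idx]
                    sample_variants.append(
                        VariantRecord(
                            patient=patient,
                            sample=sample,
                            lesion_class=cls,
                            chrom=d.chrom,
                            pos=d.pos,
                            ref=d.ref,
                            alt=d.alt,
                            vaf=float(rng.beta(a, b)),
                            gene=d.gene,
                            cosmic_count=d.cosmic_count,
                        )
                    )
                    used_positions.add(d.pos)
                    shared_rows.append(
                        {
                            "patient": patient,
                            "donor": d.sample,
                            "recipient": sample,
                            "chrom": d.chrom,
                            "pos": d.pos,
                            "alt": d.alt,
                        }
                    )
            n_new = n_total - n_shared
            sig_draws = rng.choice(k, size=n_new, p=mix)
            realised = np.bincount(sig_draws, minlength=k) / max(n_total, 1)
            exposure_rows[sample] = realised
            a, b = DEFAULT_VAF_BETA.get(cls, (2.0, 5.0))
            for sig in sig_draws:
                channel = rng.choice(96, p=w[:, sig])
                label = CONTEXT_LABELS[channel]
                tri = label[0] + label[2] + label[6]
                alt_pyr = label[4]
                pool = ctx_positions.get(tri)
                if pool is None or pool.size == 0:
                    raise RuntimeError(
                        f"context {tri} absent from the generated reference; "
                        "increase reference_length"
                    )
                pos = None
                for _ in range(cfg.max_placement_retries):
                    cand = int(pool[rng.integers(pool.size)])
                    if cand not in used_positions:
                        pos = cand
                        break
                if pos is None:
                    raise RuntimeError(
                        f"could not place context {tri} after "
                        f"{cfg.max_placement_retries} retries (sample {sample})"
                    )
                used_positions.add(pos)
                ref_base = seq[pos - 1]
                if ref_base in "CT":
                    alt = alt_pyr
                else:  # purine-centred site: emit the complementary event
                    alt = revcomp(alt_pyr)
                variants.append(
                    VariantRecord(
                        patient=patient,
                        sample=sample,
                        lesion_class=cls,
                        chrom="chr_sim",
                        pos=pos,
                        ref=ref_base,
                        alt=alt,
                        vaf=float(rng.beta(a, b)),
                        gene=f"G{pos // 1000:04d}",
                        cosmic_count=0,
                    )
                )
            variants.extend(sample_variants)
            prev_sample_variants = [v for v in variants if v.sample == sample]
    truth = MutationTruth(
        exposures=pd.DataFrame.from_dict(
            exposure_rows, orient="index", columns=[f"sig{j}" for j in range(k)]
        ),
        shared_sites=pd.DataFrame(
            shared_rows,
            columns=["patient", "donor", "recipient", "chrom", "pos", "alt"],
        ),
        class_mean_counts=dict(cfg.class_mean_counts),
    )
    return reference, variants, truth


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, alpha: float) -> np.ndarray:
    """Negative binomial with variance mean + alpha * mean^2."""
    size = 1.0 / alpha
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


_STAGE_LABELS = {"human": ("NS", "AK", "SCC"), "mouse": ("CHR", "PAP", "SCC")}


def _simulate_expression_species(
    cfg: SimConfig,
    rng: np.random.Generator,
    species: str,
    gene_ids: list[str],
    labels: pd.Series,
    signs: pd.Series,
):
    stages = _STAGE_LABELS[species]
    n_sub = cfg.n_patients
    baseline = rng.uniform(3.0, 8.0, size=len(gene_ids))
    subject_fx = rng.normal(0.0, cfg.subject_sd, size=n_sub)
    stage_step = {
        "none": (0.0, 0.0),
        "early": (1.0, 0.0),
        "late": (0.0, 1.0),
        "stepwise": (1.0, 1.0),
    }
    step1 = np.array([stage_step[l][0] for l in labels]) * signs.to_numpy()
    step2 = np.array([stage_step[l][1] for l in labels]) * signs.to_numpy()
    columns = {}
    meta_rows = []
    for s in range(n_sub):
        subject = f"{species[0]}S{s + 1}"
        batch = f"batch{s % cfg.n_batches}"
        for stage_idx, stage in enumerate(stages):
            sample = f"{subject}_{stage}"
            log_mu = (
                baseline
                + cfg.effect_size_log2
                * (step1 * (stage_idx >= 1) + step2 * (stage_idx >= 2))
                + subject_fx[s]
                + (cfg.batch_shift if batch == "batch1" else 0.0)
            )
            mu = 2.0 ** log_mu
            columns[sample] = _nb_draw(rng, mu, cfg.nb_dispersion)
            meta_rows.append(
                {
                    "sample": sample,
                    "stage": stage,
                    "subject": subject,
                    "batch": batch,
                    "species": species,
                }
            )
    counts = pd.DataFrame(columns, index=gene_ids)
    metadata = pd.DataFrame(meta_rows).set_index("sample")
    return counts, metadata


def simulate_expression_pair(cfg: SimConfig):
    """Two-species expression studies with planted progression genes.

    Counts are negative binomial around mu = 2^(baseline + stage effect
    + subject intercept + batch shift).  Early genes shift only at the
    first transition, late genes only at the second, stepwise genes at
    both; signs are randomised per gene but concordant across species
    for one-to-one homologs.  A fraction of genes map one-to-one across
    species; ``many_to_many_fraction`` of them are embedded in
    many-to-many groups (and are therefore absent from the filtered
    truth set), and the remainder are unmapped.

    Returns (study_human, study_mouse, homology, truth) where homology
    has columns [feature_a, feature_b] (human, mouse; possibly
    many-to-many) and truth is indexed by human gene with columns
    [label, sign, mouse_gene, one_to_one].
    """
    from .expression import ExpressionStudy

    rng = np.random.default_rng(cfg.seed + 1)
    n = cfg.genes_total
    human_genes = [f"hg{i:05d}" for i in range(n)]
    mouse_genes = [f"mg{i:05d}" for i in range(n)]

    n_early = int(cfg.frac_early * n)
    n_late = int(cfg.frac_late * n)
    n_step = int(cfg.frac_stepwise * n)
    labels = np.array(["none"] * n, dtype=object)
    order = rng.permutation(n)
    labels[order[:n_early]] = "early"
    labels[order[n_early : n_early + n_late]] = "late"
    labels[order[n_early + n_late : n_early + n_late + n_step]] = "stepwise"
    if cfg.effect_size_log2 == 0:
        labels[:] = "none"
    signs = rng.choice([-1.0, 1.0], size=n)
    labels_h = pd.Series(labels, index=human_genes)
    signs_h = pd.Series(signs, index=human_genes)
    labels_m = pd.Series(labels, index=mouse_genes)
    signs_m = pd.Series(signs, index=mouse_genes)

    counts_h, meta_h = _simulate_expression_species(
        cfg, rng, "human", human_genes, labels_h, signs_h
    )
    counts_m, meta_m = _simulate_expression_species(
        cfg, rng, "mouse", mouse_genes, labels_m, signs_m
    )

    # homology structure: one-to-one, many-to-many, unmapped
    idx = rng.permutation(n)
    n_oto = int(cfg.one_to_one_fraction * n)
    n_mm = int(cfg.many_to_many_fraction * n)
    oto = set(idx[:n_oto])
    mm = list(idx[n_oto : n_oto + n_mm])
    pairs = [(human_genes[i], mouse_genes[i]) for i in sorted(oto)]
    for j in range(0, len(mm) - 1, 2):
        a, b = mm[j], mm[j + 1]
        # two human genes sharing one mouse partner (and vice versa)
        pairs.append((human_genes[a], mouse_genes[b]))
        pairs.append((human_genes[b], mouse_genes[b]))
        pairs.append((human_genes[a], mouse_genes[a]))
    homology = pd.DataFrame(pairs, columns=["feature_a", "feature_b"])

    truth = pd.DataFrame(
        {
            "label": labels_h,
            "sign": signs_h,
            "mouse_gene": mouse_genes,
            "one_to_one": [i in oto for i in range(n)],
        },
        index=human_genes,
    )
    study_h = ExpressionStudy(counts=counts_h, metadata=meta_h)
    study_m = ExpressionStudy(counts=counts_m, metadata=meta_m)
    return study_h, study_m, homology, truth


def default_target_map(cfg: SimConfig, rng: np.random.Generator) -> dict[str, set[str]]:
    """Random miRNA -> target-gene-set map over the simulated gene pool."""
    genes = [f"hg{i:05d}" for i in range(cfg.genes_total)]
    return {
        f"mir{j:03d}": set(
            rng.choice(genes, size=cfg.targets_per_mirna, replace=False)
        )
        for j in range(cfg.n_mirna)
    }


def simulate_mirna_and_pairs(cfg: SimConfig):
    """miRNA and mRNA counts with planted anti-correlated functional pairs.

    A chosen subset of miRNAs moves monotonically across stages (half
    up, half down); each mapped target of a regulated miRNA moves in
    the opposite direction with probability ``penetrance``.  Non-pair
    genes are null.  Returns (mirna_study, mrna_study, target_map,
    truth_pairs) with truth_pairs columns [mirna, gene,
    mirna_direction, gene_direction].
    """
    from .expression import ExpressionStudy

    rng = np.random.default_rng(cfg.seed + 2)
    target_map = (
        {k: set(v) for k, v in cfg.mirna_target_map.items()}
        if cfg.mirna_target_map
        else default_target_map(cfg, rng)
    )
    if not target_map:
        raise ValueError("mirna_target_map must be nonempty")
    mirnas = sorted(target_map)
    n_de = min(cfg.n_de_mirna, len(mirnas))
    de_mirnas = list(rng.choice(mirnas, size=n_de, replace=False))
    mir_dir = {m: (1.0 if i % 2 == 0 else -1.0) for i, m in enumerate(de_mirnas)}

    genes = sorted({g for t in target_map.values() for g in t})
    gene_dir: dict[str, float] = {}
    truth_rows = []
    for m in de_mirnas:
        for g in sorted(target_map[m]):
            if g in gene_dir:
                continue
            if rng.random() < cfg.penetrance:
                gene_dir[g] = -mir_dir[m]
                truth_rows.append(
                    {
                        "mirna": m,
                        "gene": g,
                        "mirna_direction": "up" if mir_dir[m] > 0 else "down",
                        "gene_direction": "up" if gene_dir[g] > 0 else "down",
                    }
                )

    stages = ("NS", "AK", "SCC")
    mir_baseline = rng.uniform(4.0, 9.0, size=len(mirnas))
    # target genes emulate the expression-filtered tested gene space:
    # baselines start high enough that a planted repression is visible
    # above counting noise, as after standard low-count filtering
    gene_baseline = rng.uniform(5.0, 9.0, size=len(genes))
    mir_cols = {}
    gene_cols = {}
    meta_rows = []
    for s in range(cfg.n_patients):
        subject = f"S{s + 1}"
        for stage_idx, stage in enumerate(stages):
            sample = f"{subject}_{stage}"
            mir_mu = 2.0 ** (
                mir_baseline
                + np.array(
                    [
                        mir_dir.get(m, 0.0) * cfg.mirna_effect_log2 * stage_idx / 2.0
                        for m in mirnas
                    ]
                )
            )
            gene_mu = 2.0 ** (
                gene_baseline
                + np.array(
                    [
                        gene_dir.get(g, 0.0) * cfg.mirna_effect_log2 * stage_idx / 2.0
                        for g in genes
                    ]
                )
            )
            mir_cols[sample] = _nb_draw(rng, mir_mu, cfg.nb_dispersion)
            gene_cols[sample] = _nb_draw(rng, gene_mu, cfg.nb_dispersion)
            meta_rows.append(
                {
                    "sample": sample,
                    "stage": stage,
                    "subject": subject,
                    "batch": f"batch{s % cfg.n_batches}",
                    "species": "human",
                }
            )
    metadata = pd.DataFrame(meta_rows).set_index("sample")
    mirna_study = ExpressionStudy(
        counts=pd.DataFrame(mir_cols, index=mirnas), metadata=metadata
    )
    mrna_study = ExpressionStudy(
        counts=pd.DataFrame(gene_cols, index=genes), metadata=metadata.copy()
    )
    truth_pairs = pd.DataFrame(
        truth_rows, columns=["mirna", "gene", "mirna_direction", "gene_direction"]
    )
    return mirna_study, mrna_study, target_map, truth_pairs


def simulate_survival_cohort(
    cfg: SimConfig,
    up_genes: list[str],
    down_genes: list[str],
    n_null_genes: int = 50,
):
    """Survival cohort whose hazard follows a gene-signature score.

    Expression of signature genes tracks a per-sample latent factor u
    (up genes positively, down genes negatively, unit noise); event
    times are exponential with rate baseline_hazard *
    exp(hazard_coef * standardised signature score); censoring is
    independent with probability ``censor_rate`` (censoring times drawn
    uniformly before the event).  Returns (survival table indexed by
    sample with [time, event], expression matrix genes x samples).
    """
    if not up_genes and not down_genes:
        raise ValueError("empty gene sets")
    rng = np.random.default_rng(cfg.seed + 3)
    n = cfg.n_survival_samples
    samples = [f"T{i:04d}" for i in range(n)]
    u = rng.normal(size=n)
    rows = {}
    for g in up_genes:
        rows[g] = u + rng.normal(size=n)
    for g in down_genes:
        rows[g] = -u + rng.normal(size=n)
    for j in range(n_null_genes):
        rows[f"null{j:03d}"] = rng.normal(size=n)
    expression = pd.DataFrame(rows, index=samples).T
    score = zscore_signature_score(expression, set(up_genes), set(down_genes))
    z = (score - score.mean()) / (score.std(ddof=0) or 1.0)
    rate = cfg.baseline_hazard * np.exp(cfg.hazard_coef * z)
    times = rng.exponential(1.0 / rate)
    event = np.ones(n, dtype=int)
    censor = rng.random(n) < cfg.censor_rate
    times = np.where(censor, rng.uniform(0, times), times)
    event[censor] = 0
    survival = pd.DataFrame({"time": times, "event": event}, index=samples)
    survival.index.name = "sample"
    return survival, expression
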