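"""Mutation-spectrum statistics for somatic variant cohorts.

Builds pyrimidine-centric 96-class trinucleotide catalogs from somatic
SNVs, collapses adjacent substitutions into dinucleotide (and longer)
events, and computes the cohort-level statistics used to characterise
UVR-driven progression: six-class substitution fractions, the CC->TT
dinucleotide fraction (the UVB hallmark), per-megabase mutational loads,
the recurrence + prior-evidence rule for significantly mutated genes,
and within-patient site-specific overlap counts between lesion classes.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SUBSTITUTION_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: The 96 context labels, ordered by substitution class, then 5' base,
#: then 3' base (e.g. "A[C>A]A", "A[C>A]C", ...).
CONTEXT_LABELS = tuple(
    f"{five}[{sub}]{three}"
    for sub in SUBSTITUTION_CLASSES
    for five in BASES
    for three in BASES
)

_CONTEXT_INDEX = {label: i for i, label in enumerate(CONTEXT_LABELS)}


def revcomp(seq: str) -> str:
    """Reverse complement of an ACGT string."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class VariantRecord:
    """One somatic substitution call (SNV or collapsed multi-nucleotide).

    Coordinates are 1-based and fully closed, MAF-style.  ``ref`` and
    ``alt`` must have equal length; length-1 records are SNVs, length-2
    records are DNPs produced by :func:`collapse_dnps`.
    """

    patient: str
    sample: str
    lesion_class: str
    chrom: str
    pos: int
    ref: str
    alt: str
    vaf: float | None = None
    gene: str | None = None
    cosmic_count: int | None = None

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")
        if len(self.ref) != len(self.alt):
            raise ValueError(
                f"ref/alt length mismatch at {self.chrom}:{self.pos}: "
                f"{self.ref}>{self.alt}"
            )

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1

    @property
    def is_dnp(self) -> bool:
        return len(self.ref) == 2

    def site_key(self) -> tuple[str, int, str]:
        """(chrom, pos, alt): the identity used for overlap counting."""
        return (self.chrom, self.pos, self.alt)


def collapse_dnps(variants: Sequence[VariantRecord]) -> list[VariantRecord]:
    """Merge adjacent same-sample SNVs into multi-nucleotide records.

    Runs of SNVs at consecutive positions within one sample are merged
    left-to-right into a single record whose ref/alt are the
    concatenated alleles, anchored at the leftmost position.  Runs of
    length two yield DNPs (e.g. two C>T at pos 10 and 11 become one
    CC>TT at pos 10).  The VAF of a merged record is the mean of the
    available member VAFs.

    Raises
    ------
    ValueError
        If a sample carries two records at the same (chrom, pos).
    """
    ordered = sorted(variants, key=lambda v: (v.sample, v.chrom, v.pos))
    seen: set[tuple[str, str, int]] = set()
    for v in ordered:
        key = (v.sample, v.chrom, v.pos)
        if key in seen:
            raise ValueError(
                f"duplicate position within sample {v.sample}: {v.chrom}:{v.pos}"
            )
        seen.add(key)

    out: list[VariantRecord] = []
    run: list[VariantRecord] = []

    def flush() -> None:
        if not run:
            return
        if len(run) == 1:
            out.append(run[0])
        else:
            first = run[0]
            vafs = [v.vaf for v in run if v.vaf is not None]
            out.append(
                replace(
                    first,
                    ref="".join(v.ref for v in run),
                    alt="".join(v.alt for v in run),
                    vaf=float(np.mean(vafs)) if vafs else None,
                )
            )
        run.clear()

    for v in ordered:
        if (
            run
            and v.is_snv
            and run[-1].is_snv
            and v.sample == run[-1].sample
            and v.chrom == run[-1].chrom
            and v.pos == run[-1].pos + 1
        ):
            run.append(v)
            continue
        flush()
        if v.is_snv:
            run.append(v)
        else:
            out.append(v)
    flush()
    return out


def _context_bin(ref: str, alt: str, context: str) -> int:
    """96-bin index for an SNV with its reference trinucleotide context.

    Purine-reference variants are reverse-complemented into the
    pyrimidine-centric convention.
    """
    if context[1] != ref:
        raise ValueError(f"context {context} does not have ref base {ref} centred")
    if ref in "GA":
        context = revcomp(context)
        ref = context[1]
        alt = alt.translate(_COMPLEMENT)
    sub = f"{ref}>{alt}"
    return _CONTEXT_INDEX[f"{context[0]}[{sub}]{context[2]}"]


def build_catalog96(
    variants: Iterable[VariantRecord],
    reference: Mapping[str, str],
) -> pd.DataFrame:
    """Per-sample 96-class catalogs from SNVs placed in trinucleotide context.

    Parameters
    ----------
    variants
        Variant records; only SNVs with ACGT ref/alt contribute.  DNPs
        and longer records are excluded (collapse first if desired).
    reference
        chrom -> sequence mapping used for flanking-base lookup.

    Returns
    -------
    DataFrame indexed by :data:`CONTEXT_LABELS` with one column per
    sample (all samples observed in the input, even if they contribute
    zero SNVs).  Column totals equal each sample's included SNV count.

    Raises
    ------
    ValueError
        If the reference base at a variant position does not match the
        record's ref allele, naming the offending record.
    """
    samples: list[str] = []
    counts: dict[str, np.ndarray] = {}
    for v in variants:
        if v.sample not in counts:
            counts[v.sample] = np.zeros(96, dtype=int)
            samples.append(v.sample)
        if not v.is_snv or v.ref not in BASES or v.alt not in BASES:
            continue
        seq = reference[v.chrom]
        if v.pos < 2 or v.pos > len(seq) - 1:
            raise ValueError(
                f"variant {v.sample} {v.chrom}:{v.pos} lacks flanking context"
            )
        context = seq[v.pos - 2 : v.pos + 1]
        if context[1] != v.ref:
            raise ValueError(
                f"reference mismatch for {v.sample} {v.chrom}:{v.pos} "
                f"{v.ref}>{v.alt}: reference has {context[1]!r}"
            )
        counts[v.sample][_context_bin(v.ref, v.alt, context)] += 1
    data = {s: counts[s] for s in samples}
    return pd.DataFrame(data, index=list(CONTEXT_LABELS), dtype=int)


@dataclass
class SpectrumSummary:
    """Cohort substitution-spectrum summary.

    ``cc_tt_fraction`` is NaN (undefined) when the input has no DNPs;
    ``cpg_ct_fraction`` is NaN when no reference was supplied or no C>T
    SNVs exist.
    """

    six_class_fractions: pd.Series
    cpg_ct_fraction: float
    cc_tt_fraction: float
    n_snv: int
    n_dnp: int
    vaf_hist_counts: np.ndarray
    vaf_bin_edges: np.ndarray


def _pyrimidine_class(ref: str, alt: str) -> str:
    if ref in "GA":
        ref = ref.translate(_COMPLEMENT)
        alt = alt.translate(_COMPLEMENT)
    return f"{ref}>{alt}"


def spectrum_summary(
    variants: Sequence[VariantRecord],
    reference: Mapping[str, str] | None = None,
    vaf_bin_width: float = 0.05,
) -> SpectrumSummary:
    """Six-class fractions, CC->TT DNP fraction, CpG C>T fraction, VAF histogram.

    Expects DNPs to be already collapsed (:func:`collapse_dnps`).  The
    six-class fractions have the SNV count as denominator and sum to 1
    whenever at least one SNV is present; the CC->TT fraction has the
    DNP count as denominator (GG>AA counts as CC>TT on the opposite
    strand).  The CpG fraction is the share of C>T SNVs whose
    pyrimidine-strand 3' neighbour is G, and needs a reference.
    """
    snvs = [v for v in variants if v.is_snv and v.ref in BASES and v.alt in BASES]
    dnps = [v for v in variants if v.is_dnp]

    frac = pd.Series(0.0, index=list(SUBSTITUTION_CLASSES))
    for v in snvs:
        frac[_pyrimidine_class(v.ref, v.alt)] += 1
    if snvs:
        frac /= len(snvs)

    if dnps:
        n_cctt = sum(
            1 for v in dnps if (v.ref, v.alt) in {("CC", "TT"), ("GG", "AA")}
        )
        cc_tt = n_cctt / len(dnps)
    else:
        cc_tt = float("nan")

    cpg = float("nan")
    if reference is not None:
        ct = [v for v in snvs if _pyrimidine_class(v.ref, v.alt) == "C>T"]
        if ct:
            at_cpg = 0
            for v in ct:
                seq = reference[v.chrom]
                context = seq[v.pos - 2 : v.pos + 1]
                if v.ref == "G":
                    context = revcomp(context)
                if context[2] == "G":
                    at_cpg += 1
            cpg = at_cpg / len(ct)

    edges = np.arange(0.0, 1.0 + vaf_bin_width / 2, vaf_bin_width)
    vafs = [v.vaf for v in variants if v.vaf is not None]
    hist, edges = np.histogram(vafs, bins=edges)

    return SpectrumSummary(
        six_class_fractions=frac,
        cpg_ct_fraction=cpg,
        cc_tt_fraction=cc_tt,
        n_snv=len(snvs),
        n_dnp=len(dnps),
        vaf_hist_counts=hist,
        vaf_bin_edges=edges,
    )


def mutation_load(
    variants: Sequence[VariantRecord],
    footprint_mb: float,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Variants per megabase per sample, with per-lesion-class summaries.

    ``footprint_mb`` is the callable territory in megabases and is
    always explicit input; no built-in footprint exists.

    Returns
    -------
    (per_sample, per_class)
        ``per_sample`` has columns [patient, lesion_class, n_variants,
        load]; ``per_class`` has columns [mean_n, mean_load, min_load,
        max_load] indexed by lesion class.
    """
    if footprint_mb <= 0:
        raise ValueError(f"footprint_mb must be positive, got {footprint_mb}")
    rows: dict[str, dict] = {}
    for v in variants:
        r = rows.setdefault(
            v.sample,
            {"patient": v.patient, "lesion_class": v.lesion_class, "n_variants": 0},
        )
        r["n_variants"] += 1
    per_sample = pd.DataFrame.from_dict(rows, orient="index")
    per_sample.index.name = "sample"
    if per_sample.empty:
        per_sample = pd.DataFrame(
            columns=["patient", "lesion_class", "n_variants", "load"]
        )
        per_class = pd.DataFrame(
            columns=["mean_n", "mean_load", "min_load", "max_load"]
        )
        return per_sample, per_class
    per_sample["load"] = per_sample["n_variants"] / footprint_mb
    per_class = per_sample.groupby("lesion_class").agg(
        mean_n=("n_variants", "mean"),
        mean_load=("load", "mean"),
        min_load=("load", "min"),
        max_load=("load", "max"),
    )
    return per_sample, per_class


def smg_filter(
    variants: Sequence[VariantRecord],
    known_genes: Iterable[str],
    min_pairings: int = 7,
    cosmic_threshold: int = 400,
) -> list[str]:
    """Significantly-mutated-gene rule: recurrence plus prior evidence.

    A gene is retained iff it is mutated in at least ``min_pairings``
    tumour/control pairings (distinct samples) AND it is either in
    ``known_genes`` or its COSMIC mutation count exceeds
    ``cosmic_threshold``.  Missing COSMIC annotations are treated as 0
    and logged, not raised.
    """
    known = set(known_genes)
    pairings: dict[str, set[str]] = {}
    cosmic: dict[str, int] = {}
    for v in variants:
        if v.gene is None:
            continue
        pairings.setdefault(v.gene, set()).add(v.sample)
        if v.cosmic_count is None:
            logger.debug(
                "missing cosmic_count for %s at %s:%d treated as 0",
                v.gene,
                v.chrom,
                v.pos,
            )
            count = 0
        else:
            count = v.cosmic_count
        cosmic[v.gene] = max(cosmic.get(v.gene, 0), count)
    return sorted(
        g
        for g, samples in pairings.items()
        if len(samples) >= min_pairings
        and (g in known or cosmic.get(g, 0) > cosmic_threshold)
    )


@dataclass
class OverlapSummary:
    """Within-patient site-specific overlap counts.

    ``pairwise`` has one row per within-patient comparison of two
    samples from different (or duplicated) lesion classes, with columns
    [patient, pair, sample_a, sample_b, overlap, flagged]; ``flagged``
    marks comparisons arising from a duplicated lesion class within the
    patient (e.g. a patient with two SCCs).  ``higher_order`` holds the
    3-way/4-way intersections.  ``class_pair_means`` averages the
    pairwise overlap over comparison rows per class pair.
    """

    pairwise: pd.DataFrame
    higher_order: pd.DataFrame = field(default_factory=pd.DataFrame)
    class_pair_means: pd.Series = field(default_factory=pd.Series)


def summarize_overlap_rows(pairwise: pd.DataFrame) -> pd.Series:
    """Cohort mean overlap per class pair, averaged over comparison rows."""
    if pairwise.empty:
        return pd.Series(dtype=float)
    return pairwise.groupby("pair")["overlap"].mean()


def site_overlap(
    variants: Sequence[VariantRecord],
    class_order: Sequence[str] = ("NS", "AK", "SCC"),
) -> OverlapSummary:
    """Site-specific variant overlap between lesion classes within patients.

    Two samples overlap at a site when they share an identical
    (chrom, pos, alt) tuple; ref is implied by position.  Collapsed
    DNPs participate as their merged records.  Every within-patient
    class pair present is counted; patients with duplicated classes
    contribute one row per sample combination, flagged.  Higher-order
    (3-way and 4-way) intersections are reported where the samples
    exist.
    """
    sites: dict[str, set[tuple[str, int, str]]] = {}
    sample_info: dict[str, tuple[str, str]] = {}
    for v in variants:
        sites.setdefault(v.sample, set()).add(v.site_key())
        sample_info[v.sample] = (v.patient, v.lesion_class)

    by_patient: dict[str, list[str]] = {}
    for s, (patient, _) in sample_info.items():
        by_patient.setdefault(patient, []).append(s)

    rank = {c: i for i, c in enumerate(class_order)}
    pair_rows = []
    higher_rows = []
    for patient, samples in sorted(by_patient.items()):
        samples = sorted(samples, key=lambda s: (rank.get(sample_info[s][1], 99), s))
        classes = [sample_info[s][1] for s in samples]
        duplicated = {c for c in classes if classes.count(c) > 1}
        if duplicated:
            logger.warning(
                "patient %s has duplicated lesion classes %s; reporting all "
                "sample combinations flagged",
                patient,
                sorted(duplicated),
            )
        for sa, sb in itertools.combinations(samples, 2):
            ca, cb = sample_info[sa][1], sample_info[sb][1]
            pair_rows.append(
                {
                    "patient": patient,
                    "pair": f"{ca}/{cb}" if ca != cb else f"{ca}1/{ca}2",
                    "sample_a": sa,
                    "sample_b": sb,
                    "overlap": len(sites[sa] & sites[sb]),
                    "flagged": ca in duplicated or cb in duplicated,
                }
            )
        for order in (3, 4):
            for combo in itertools.combinations(samples, order):
                inter = set.intersection(*(sites[s] for s in combo))
                higher_rows.append(
                    {
                        "patient": patient,
                        "pair": "/".join(sample_info[s][1] for s in combo),
                        "samples": ",".join(combo),
                        "overlap": len(inter),
                    }
                )

    pairwise = pd.DataFrame(
        pair_rows,
        columns=["patient", "pair", "sample_a", "sample_b", "overlap", "flagged"],
    )
    higher = pd.DataFrame(
        higher_rows, columns=["patient", "pair", "samples", "overlap"]
    )
    return OverlapSummary(
        pairwise=pairwise,
        higher_order=higher,
        class_pair_means=summarize_overlap_rows(pairwise),
    )
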