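"""Small-RNA quantification and miRNA-mRNA functional-pair analysis.

Small-RNA reads (adapter-trimmed) are filtered by length and terminal
homopolymer content, assigned to miRNA reference sequences by an
exact-prefix matcher with a configurable mismatch budget, and
quantified as parts per million (ppm) of usable reads.  Differential
miRNA expression uses a t-test on log2(ppm + 1) with a fold-change
threshold, and a recurrence call requires direction-consistent
significance in at least two of the three pairwise stage comparisons.
Functional pairs link differentially expressed miRNAs to
opposite-direction differentially expressed predicted targets via a
one-sided Fisher enrichment of the target set in the gene signature,
and are intersected across species through homolog and miRNA-family
maps.
"""

from __future__ import annotations

import logging
import warnings
from collections import Counter
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .expression import benjamini_hochberg

logger = logging.getLogger(__name__)


def _terminal_homopolymer_length(seq: str) -> int:
    if not seq:
        return 0
    last = seq[-1]
    i = len(seq) - 1
    while i >= 0 and seq[i] == last:
        i -= 1
    return len(seq) - 1 - i


def filter_small_rna_reads(
    reads: list[str],
    min_length: int = 10,
    max_terminal_homopolymer: int = 8,
) -> tuple[list[str], Counter]:
    """Usable-read filter for adapter-trimmed small-RNA reads.

    A read is kept iff its length is at least ``min_length`` and its
    terminal run of one repeated base is at most
    ``max_terminal_homopolymer`` nucleotides (discarding reads ending
    in homopolymers of 9 nt or more, by default).  Returns the usable
    reads and a Counter of discarded reads by reason.
    """
    usable: list[str] = []
    discarded: Counter = Counter()
    for read in reads:
        if len(read) < min_length:
            discarded["too_short"] += 1
        elif _terminal_homopolymer_length(read) > max_terminal_homopolymer:
            discarded["terminal_homopolymer"] += 1
        else:
            usable.append(read)
    if not reads:
        warnings.warn("empty read input: zero usable reads", stacklevel=2)
    return usable, discarded


@dataclass
class MirnaProfile:
    """Per-sample miRNA quantification: counts and ppm of usable reads."""

    sample: str
    usable_reads: int
    counts: pd.Series
    ppm: pd.Series


def quantify_mirna(
    usable_reads: list[str],
    reference: dict[str, str],
    max_mismatch: int = 1,
    sample: str = "sample",
) -> MirnaProfile:
    """Assign usable reads to miRNA references and express them as ppm.

    A read matches a reference iff it equals the reference, or is a
    prefix of it, allowing up to ``max_mismatch`` mismatches.  Reads
    matching several references equally well (same minimal mismatch
    count) are split fractionally among them.  ppm_i = count_i /
    usable * 1e6, so the ppm total never exceeds 1e6.
    """
    ids = list(reference)
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate reference ids")
    counts = pd.Series(0.0, index=ids)
    n_usable = len(usable_reads)
    for read in usable_reads:
        best: list[str] = []
        best_mm = max_mismatch + 1
        for rid in ids:
            ref = reference[rid]
            if len(read) > len(ref):
                continue
            mm = sum(a != b for a, b in zip(read, ref))
            if mm > max_mismatch:
                continue
            if mm < best_mm:
                best, best_mm = [rid], mm
            elif mm == best_mm:
                best.append(rid)
        if best:
            share = 1.0 / len(best)
            for rid in best:
                counts[rid] += share
    ppm = counts / n_usable * 1e6 if n_usable else counts * 0.0
    return MirnaProfile(sample=sample, usable_reads=n_usable, counts=counts, ppm=ppm)


def de_mirna_recurrent(
    ppm: pd.DataFrame,
    metadata: pd.DataFrame,
    stages: tuple[str, str, str] = ("NS", "AK", "SCC"),
    fc_min: float = 1.5,
    p_max: float = 0.05,
    stage_col: str = "stage",
) -> pd.DataFrame:
    """Per-comparison miRNA differential expression with recurrence call.

    For each of the three pairwise stage comparisons, a two-sided
    t-test on log2(ppm + 1) with a linear fold-change threshold of
    ``fc_min``; miRNAs that are all-zero in a comparison are excluded
    from it.  A miRNA is *recurrent* iff it is significant in at least
    two of the three comparisons with a consistent direction.

    Returns a DataFrame indexed by miRNA with per-comparison
    ``log2_fc_*``/``p_*``/``sig_*`` columns and a ``recurrent`` flag.
    """
    logp = np.log2(ppm + 1.0)
    comps = list(combinations(stages, 2))
    out = pd.DataFrame(index=ppm.index)
    directions = pd.DataFrame(index=ppm.index, columns=[f"{a}_{b}" for a, b in comps])
    for a, b in comps:
        label = f"{a}_{b}"
        cols_a = metadata.index[metadata[stage_col] == a].intersection(logp.columns)
        cols_b = metadata.index[metadata[stage_col] == b].intersection(logp.columns)
        if len(cols_a) < 2 or len(cols_b) < 2:
            raise ValueError(f"need >=2 samples per group for {label}")
        va = logp[cols_a].to_numpy()
        vb = logp[cols_b].to_numpy()
        all_zero = (ppm[cols_a].to_numpy().sum(axis=1) == 0) & (
            ppm[cols_b].to_numpy().sum(axis=1) == 0
        )
        with np.errstate(invalid="ignore", divide="ignore"):
            _, p = stats.ttest_ind(vb, va, axis=1, equal_var=False)
        p = np.where(np.isnan(p), 1.0, p)
        lfc = vb.mean(axis=1) - va.mean(axis=1)
        sig = (p < p_max) & (np.abs(lfc) > np.log2(fc_min)) & ~all_zero
        out[f"log2_fc_{label}"] = lfc
        out[f"p_{label}"] = np.where(all_zero, np.nan, p)
        out[f"sig_{label}"] = sig
        directions[label] = np.where(sig, np.sign(lfc), np.nan)

    def _recurrent(row: pd.Series) -> bool:
        signs = row.dropna()
        return len(signs) >= 2 and signs.nunique() == 1

    out["recurrent"] = directions.apply(_recurrent, axis=1)
    out["direction"] = directions.apply(
        lambda r: (
            "up"
            if _recurrent(r) and r.dropna().iloc[0] > 0
            else ("down" if _recurrent(r) else "none")
        ),
        axis=1,
    )
    return out


def functional_pairs(
    mirna_de: pd.DataFrame,
    gene_de: dict[str, pd.DataFrame],
    target_map: dict[str, set[str]],
    universe: set[str],
    q_max: float = 0.25,
    fc_min: float = 1.25,
) -> pd.DataFrame:
    """miRNA-mRNA functional pairs by one-sided Fisher target enrichment.

    For every comparison shared between ``mirna_de`` (output of
    :func:`de_mirna_recurrent`) and ``gene_de`` (comparison label ->
    per-gene table with ``log2_fc``/``q`` columns over the tested-gene
    ``universe``), each significantly changed miRNA is tested for
    enrichment of its predicted targets within the opposite-direction
    differentially expressed gene set (q < q_max, |FC| > fc_min);
    Fisher p-values are BH-corrected across miRNAs per comparison.
    miRNAs passing q < q_max are paired with each anti-directional
    significant predicted target, and pairs are ranked by the number
    of comparisons in which they are significant.

    Returns a DataFrame with columns [mirna, gene, mirna_direction,
    gene_direction, n_comparisons, comparisons, enrichment_q].
    """
    if not universe:
        raise ValueError("empty gene universe")
    pair_hits: dict[tuple[str, str], dict] = {}
    for label, table in gene_de.items():
        sig_col = f"sig_{label}"
        if sig_col not in mirna_de.columns:
            continue
        genes = table.loc[table.index.intersection(universe)]
        de_mask = (genes["q"] < q_max) & (2.0 ** genes["log2_fc"].abs() > fc_min)
        up_genes = set(genes.index[de_mask & (genes["log2_fc"] > 0)])
        down_genes = set(genes.index[de_mask & (genes["log2_fc"] < 0)])

        candidates = mirna_de.index[mirna_de[sig_col].fillna(False)]
        fisher_rows = []
        for mir in candidates:
            direction = np.sign(mirna_de.loc[mir, f"log2_fc_{label}"])
            opposite = down_genes if direction > 0 else up_genes
            targets = target_map.get(mir, set()) & universe
            overlap = targets & opposite
            table22 = [
                [len(overlap), len(opposite) - len(overlap)],
                [
                    len(targets) - len(overlap),
                    len(universe) - len(opposite) - len(targets) + len(overlap),
                ],
            ]
            if not targets:
                p = 1.0
            else:
                _, p = stats.fisher_exact(table22, alternative="greater")
            fisher_rows.append((mir, direction, float(p), overlap))
        if not fisher_rows:
            continue
        qvals = benjamini_hochberg(np.array([r[2] for r in fisher_rows]))
        for (mir, direction, _p, overlap), q in zip(fisher_rows, qvals):
            if q >= q_max:
                continue
            for gene in overlap:
                key = (mir, gene)
                rec = pair_hits.setdefault(
                    key,
                    {
                        "mirna_direction": "up" if direction > 0 else "down",
                        "gene_direction": "down" if direction > 0 else "up",
                        "comparisons": [],
                        "enrichment_q": float(q),
                    },
                )
                rec["comparisons"].append(label)
                rec["enrichment_q"] = min(rec["enrichment_q"], float(q))

    rows = [
        {
            "mirna": mir,
            "gene": gene,
            "mirna_direction": rec["mirna_direction"],
            "gene_direction": rec["gene_direction"],
            "n_comparisons": len(rec["comparisons"]),
            "comparisons": ",".join(sorted(rec["comparisons"])),
            "enrichment_q": rec["enrichment_q"],
        }
        for (mir, gene), rec in pair_hits.items()
    ]
    out = pd.DataFrame(
        rows,
        columns=[
            "mirna",
            "gene",
            "mirna_direction",
            "gene_direction",
            "n_comparisons",
            "comparisons",
            "enrichment_q",
        ],
    )
    return out.sort_values(
        ["n_comparisons", "mirna", "gene"], ascending=[False, True, True]
    ).reset_index(drop=True)


def conserve_pairs(
    pairs_a: pd.DataFrame,
    pairs_b: pd.DataFrame,
    homology: pd.DataFrame,
    mirna_name_map: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Cross-species conserved functional pairs (bipartite network rows).

    A species-A pair is conserved iff its miRNA (translated through the
    family name map, identity by default) and its target gene
    (translated through the filtered one-to-one homolog map,
    feature_a -> feature_b) both appear in species B with the same
    direction pattern.  The output is symmetric in species order up to
    the identifier convention: it lists species-A identifiers alongside
    their species-B counterparts and can serve directly as a bipartite
    edge list.
    """
    name = (lambda m: mirna_name_map.get(m, m)) if mirna_name_map else (lambda m: m)
    gene_map = dict(zip(homology["feature_a"], homology["feature_b"]))
    b_keys = {
        (r.mirna, r.gene, r.mirna_direction, r.gene_direction)
        for r in pairs_b.itertuples()
    }
    rows = []
    for r in pairs_a.itertuples():
        partner_gene = gene_map.get(r.gene)
        if partner_gene is None:
            continue
        if (name(r.mirna), partner_gene, r.mirna_direction, r.gene_direction) in b_keys:
            rows.append(
                {
                    "mirna": r.mirna,
                    "gene": r.gene,
                    "partner_gene": partner_gene,
                    "mirna_direction": r.mirna_direction,
                    "gene_direction": r.gene_direction,
                    "n_comparisons": r.n_comparisons,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "mirna",
            "gene",
            "partner_gene",
            "mirna_direction",
            "gene_direction",
            "n_comparisons",
        ],
    )
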