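"""Ranked-list gene-set enrichment and TF motif-target selection.

Implements the weighted Kolmogorov-Smirnov running-sum enrichment
statistic on a fold-change-ranked gene list, a gene-label permutation
null for normalised enrichment scores (NES) with BH q-values computed
within each enrichment direction, the cross-species transcription
factor concordance filter (targets enriched in the same direction in
both species in an adjacent stage comparison, and in the full
normal-to-SCC comparison), and the Fisher-exact TF co-target network.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .expression import benjamini_hochberg

ADJACENT_COMPARISONS = ("NS_AK", "AK_SCC")
FULL_COMPARISON = "NS_SCC"


def _es_from_hits(
    hit_positions: np.ndarray,
    hit_weights: np.ndarray,
    n_genes: int,
) -> float:
    """ES from sorted 0-based hit positions and their weights.

    The running sum rises by w_i / sum(w) at each hit and falls by
    1 / (N - m) at each miss; between hits it is monotone, so the
    signed maximum deviation is attained immediately after or
    immediately before a hit.
    """
    m = hit_positions.size
    n_miss = n_genes - m
    w_total = hit_weights.sum()
    if w_total <= 0:
        # all-zero weights: fall back to unweighted hits
        hit_weights = np.ones(m)
        w_total = float(m)
    cum_hit = np.cumsum(hit_weights) / w_total
    if n_miss == 0:
        return 0.0
    miss_before = (hit_positions - np.arange(m)) / n_miss
    after = cum_hit - miss_before
    before = np.concatenate(([0.0], cum_hit[:-1])) - miss_before
    hi = after.max()
    lo = min(before.min(), 0.0)
    return float(hi if hi >= -lo else lo)


def gsea_running_sum(
    ranked_genes: list[str],
    scores: np.ndarray,
    gene_set: set[str],
    weight_exponent: float = 1.0,
) -> tuple[float, np.ndarray]:
    """Weighted KS running sum over a ranked gene list.

    ``ranked_genes`` must contain unique identifiers ordered by the
    ranking statistic (``scores`` aligned).  Hit increments are
    proportional to |score|^weight_exponent; with exponent 0 the
    statistic depends only on hit positions.  Returns the signed
    maximum deviation (ES) and the full running-sum profile.  An empty
    intersection returns (nan, zeros).
    """
    n = len(ranked_genes)
    if len(set(ranked_genes)) != n:
        raise ValueError("ranked gene list has duplicate identifiers")
    scores = np.asarray(scores, dtype=float)
    hits = np.fromiter(
        (g in gene_set for g in ranked_genes), dtype=bool, count=n
    )
    m = int(hits.sum())
    if m == 0:
        return float("nan"), np.zeros(n)
    if m == n:
        return 0.0, np.zeros(n)
    weights = np.abs(scores) ** weight_exponent
    w_hit = weights * hits
    w_total = w_hit.sum()
    if w_total <= 0:
        w_hit = hits.astype(float)
        w_total = float(m)
    steps = np.where(hits, w_hit / w_total, -1.0 / (n - m))
    profile = np.cumsum(steps)
    es = profile[np.argmax(np.abs(profile))]
    return float(es), profile


@dataclass
class EnrichmentResult:
    name: str
    es: float
    nes: float
    p: float
    q: float
    direction: str  # "up" or "down"
    n_hits: int


def gsea_significance(
    ranked_genes: list[str],
    scores: np.ndarray,
    gene_sets: dict[str, set[str]],
    n_perm: int = 1000,
    seed: int = 0,
    weight_exponent: float = 1.0,
) -> pd.DataFrame:
    """Permutation significance of gene-set enrichment on a ranked list.

    The null permutes gene labels: for each set, null ES values are
    recomputed with the same number of hits placed at random positions
    of the fixed ranked list.  The empirical p uses the same-sign null
    portion; NES divides ES by the mean |null ES| of the same sign; BH
    q-values are computed within each direction.  Fully seeded and
    reproducible.

    Returns a DataFrame indexed by set name with columns
    [es, nes, p, q, direction, n_hits].
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    n = len(ranked_genes)
    scores = np.asarray(scores, dtype=float)
    weights = np.abs(scores) ** weight_exponent
    rng = np.random.default_rng(seed)
    rows = []
    gene_index = {g: i for i, g in enumerate(ranked_genes)}
    for name, gs in gene_sets.items():
        positions = np.array(sorted(gene_index[g] for g in gs if g in gene_index))
        m = positions.size
        if m == 0 or m == n:
            rows.append(
                {
                    "name": name,
                    "es": float("nan"),
                    "nes": float("nan"),
                    "p": float("nan"),
                    "direction": "none",
                    "n_hits": m,
                }
            )
            continue
        es = _es_from_hits(positions, weights[positions], n)
        null_es = np.empty(n_perm)
        perm_pos = np.argsort(rng.random((n_perm, n)), axis=1)[:, :m]
        perm_pos.sort(axis=1)
        for i in range(n_perm):
            null_es[i] = _es_from_hits(perm_pos[i], weights[perm_pos[i]], n)
        same_sign = null_es * np.sign(es) > 0
        n_same = int(same_sign.sum())
        if n_same == 0:
            nes = float("nan")
            p = 1.0 / (n_perm + 1)
        else:
            mean_abs = np.abs(null_es[same_sign]).mean()
            nes = float(es / mean_abs) if mean_abs > 0 else float("nan")
            p = (1 + int(np.sum(np.abs(null_es[same_sign]) >= abs(es)))) / (
                1 + n_same
            )
        rows.append(
            {
                "name": name,
                "es": es,
                "nes": nes,
                "p": float(p),
                "direction": "up" if es >= 0 else "down",
                "n_hits": m,
            }
        )
    table = pd.DataFrame(rows).set_index("name")
    table["q"] = np.nan
    for direction in ("up", "down"):
        mask = (table["direction"] == direction) & table["p"].notna()
        if mask.any():
            table.loc[mask, "q"] = benjamini_hochberg(table.loc[mask, "p"].to_numpy())
    return table[["es", "nes", "p", "q", "direction", "n_hits"]]


def tf_concordance_filter(
    enrichment_tables: dict[tuple[str, str], pd.DataFrame],
    species: tuple[str, str] = ("human", "mouse"),
    q_max: float = 0.25,
) -> pd.DataFrame:
    """Cross-species concordance selection of transcription factors.

    ``enrichment_tables`` maps (species, comparison) to a table indexed
    by motif/factor with ``nes`` (or ``es``) and ``q`` columns, for the
    comparisons NS_AK, AK_SCC and NS_SCC (or the species analogues
    relabelled to these keys).  A factor is selected iff some adjacent
    comparison shows significant (q < q_max) same-direction enrichment
    in both species AND the full NS_SCC comparison is significant in
    the same direction in both species.  The stage label records which
    adjacent comparison(s) fired: early, late, or global (both).  A
    factor firing in opposite directions at the two transitions gets
    one row per transition with its direction.

    Returns a DataFrame with columns [factor, stage, direction,
    comparisons], one row per (factor, fired transition).
    """
    sp_a, sp_b = species

    def _status(table: pd.DataFrame, factor: str) -> tuple[bool, float]:
        if factor not in table.index:
            return False, 0.0
        row = table.loc[factor]
        score = row["nes"] if "nes" in row else row["es"]
        return bool(row["q"] < q_max) and np.isfinite(score), float(np.sign(score))

    factors: set[str] = set()
    for tab in enrichment_tables.values():
        factors |= set(tab.index)

    rows = []
    for factor in sorted(factors):
        full_a = _status(enrichment_tables[(sp_a, FULL_COMPARISON)], factor)
        full_b = _status(enrichment_tables[(sp_b, FULL_COMPARISON)], factor)
        full_ok = full_a[0] and full_b[0] and full_a[1] == full_b[1]
        if not full_ok:
            continue
        fired = []
        for comp, stage in zip(ADJACENT_COMPARISONS, ("early", "late")):
            adj_a = _status(enrichment_tables[(sp_a, comp)], factor)
            adj_b = _status(enrichment_tables[(sp_b, comp)], factor)
            if adj_a[0] and adj_b[0] and adj_a[1] == adj_b[1]:
                fired.append((stage, "up" if adj_a[1] > 0 else "down", comp))
        if not fired:
            continue
        stage_label = "global" if len(fired) == 2 else fired[0][0]
        for stage, direction, comp in fired:
            rows.append(
                {
                    "factor": factor,
                    "stage": stage_label if len(fired) == 1 else stage,
                    "global": len(fired) == 2,
                    "direction": direction,
                    "comparison": comp,
                }
            )
    return pd.DataFrame(
        rows, columns=["factor", "stage", "global", "direction", "comparison"]
    )


def tf_cotarget_network(
    selected_factors: list[str],
    motif_target_sets: dict[str, set[str]],
    universe: set[str],
    p_threshold: float = 1e-4,
) -> nx.Graph:
    """TF co-target network: edges where target-set overlap is significant.

    Nodes are the selected factors; an edge joins two factors when the
    one-sided Fisher exact p of their target-set overlap within the
    regulated-gene universe falls below ``p_threshold``.  Edge
    attributes: ``overlap`` (shared target count) and ``p``.  Factors
    with no targets in the universe remain isolated nodes.
    """
    if len(selected_factors) < 2:
        g = nx.Graph()
        g.add_nodes_from(selected_factors)
        return g
    g = nx.Graph()
    g.add_nodes_from(selected_factors)
    n_u = len(universe)
    targets = {
        f: motif_target_sets.get(f, set()) & universe for f in selected_factors
    }
    for i, fa in enumerate(selected_factors):
        for fb in selected_factors[i + 1 :]:
            ta, tb = targets[fa], targets[fb]
            if not ta or not tb:
                continue
            overlap = len(ta & tb)
            table = [
                [overlap, len(ta) - overlap],
                [len(tb) - overlap, n_u - len(ta) - len(tb) + overlap],
            ]
            _, p = stats.fisher_exact(table, alternative="greater")
            if p < p_threshold:
                g.add_edge(fa, fb, overlap=overlap, p=float(p))
    return g
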