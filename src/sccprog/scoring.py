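"""Cohort signatures, cross-cohort ranking and survival scoring.

Derives tumour-vs-normal cohort signatures (up/down gene sets at
FC > 2, P < 0.05), ranks external cohorts against a progression-ranked
gene list by a penalised sum of squared significant NES values, scores
samples with the z-score-sum signature (sum of per-gene z-scores over
upregulated genes minus the sum over downregulated genes), and compares
the top against the bottom score quartile with a Kaplan-Meier/log-rank
analysis.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test

from .enrichment import gsea_significance
from .expression import differential_expression

logger = logging.getLogger(__name__)


@dataclass
class CohortSignature:
    """Up/down gene sets characterising one cohort's tumour response."""

    cohort: str
    up: set[str]
    down: set[str]
    fc_min: float = 2.0
    p_max: float = 0.05

    def __post_init__(self) -> None:
        if self.up & self.down:
            raise ValueError("up and down sets must be disjoint")


def derive_cohort_signature(
    transformed: pd.DataFrame,
    metadata: pd.DataFrame,
    normal_label: str,
    tumour_label: str,
    cohort: str,
    fc_min: float = 2.0,
    p_max: float = 0.05,
    stage_col: str = "stage",
) -> CohortSignature:
    """Tumour-progression signature: genes with |FC| > fc_min at P < p_max.

    Thresholds are applied to the transformed-scale test (nominal p,
    not q, mirroring signature derivation conventions).  Empty
    signatures are allowed with a warning.
    """
    de = differential_expression(
        transformed, metadata, normal_label, tumour_label, stage_col=stage_col
    )
    t = de.table
    sig = (t["p"] < p_max) & (2.0 ** t["log2_fc"].abs() > fc_min)
    up = set(t.index[sig & (t["log2_fc"] > 0)])
    down = set(t.index[sig & (t["log2_fc"] < 0)])
    if not up and not down:
        warnings.warn(f"empty signature for cohort {cohort}", stacklevel=2)
    return CohortSignature(cohort=cohort, up=up, down=down, fc_min=fc_min, p_max=p_max)


def rank_cohorts_by_enrichment(
    ranked_genes: list[str],
    scores: np.ndarray,
    signatures: list[CohortSignature],
    n_perm: int = 1000,
    seed: int = 0,
    penalty_lambda: float = 0.0,
    q_max: float = 0.25,
) -> pd.DataFrame:
    """Rank cohorts by the sum of squared significant NES values.

    Each cohort contributes its up and down signature directions;
    score(cohort) = sum over directions of NES^2 * 1[q < q_max] minus
    ``penalty_lambda`` times the number of non-significant directions.
    Cohorts with no computable NES are ranked last and flagged.
    Deterministic given the seed and invariant to cohort input order.
    """
    gene_sets: dict[str, set[str]] = {}
    owner: dict[str, str] = {}
    for sig in sorted(signatures, key=lambda s: s.cohort):
        for direction, genes in (("up", sig.up), ("down", sig.down)):
            if genes:
                key = f"{sig.cohort}::{direction}"
                gene_sets[key] = genes
                owner[key] = sig.cohort
    enr = gsea_significance(ranked_genes, scores, gene_sets, n_perm=n_perm, seed=seed)
    rows = []
    for sig in signatures:
        keys = [k for k, c in owner.items() if c == sig.cohort]
        nes = enr.loc[[k for k in keys if k in enr.index]]
        computable = nes["nes"].notna()
        if not keys or not computable.any():
            rows.append(
                {"cohort": sig.cohort, "score": -np.inf, "n_significant": 0,
                 "flagged": True}
            )
            continue
        significant = computable & (nes["q"] < q_max)
        score = float((nes.loc[significant, "nes"] ** 2).sum())
        score -= penalty_lambda * int((~significant).sum())
        rows.append(
            {
                "cohort": sig.cohort,
                "score": score,
                "n_significant": int(significant.sum()),
                "flagged": False,
            }
        )
    table = pd.DataFrame(rows).sort_values(
        ["score", "cohort"], ascending=[False, True]
    )
    table["rank"] = np.arange(1, len(table) + 1)
    return table.set_index("cohort")


def zscore_signature_score(
    expression: pd.DataFrame,
    up_genes: set[str],
    down_genes: set[str],
) -> pd.Series:
    """z-score-sum signature score per sample.

    Each gene's expression is replaced by its z-score within the cohort
    (across samples); the sample score adds the z-scores of
    upregulated-signature genes and subtracts those of downregulated
    ones.  Zero-variance genes contribute 0 (logged).  Swapping the up
    and down sets negates the score exactly.
    """
    up = [g for g in up_genes if g in expression.index]
    down = [g for g in down_genes if g in expression.index]
    if not up and not down:
        raise ValueError("no signature gene present in the expression matrix")
    sub = expression.loc[up + down]
    mean = sub.mean(axis=1)
    sd = sub.std(axis=1, ddof=0)
    zero_var = sd == 0
    if zero_var.any():
        logger.info(
            "zero-variance signature genes contribute 0: %s",
            list(sub.index[zero_var]),
        )
    z = sub.sub(mean, axis=0).div(sd.where(~zero_var, np.inf), axis=0)
    score = z.loc[up].sum(axis=0) - z.loc[down].sum(axis=0)
    score.name = "signature_score"
    return score


@dataclass
class LogrankResult:
    """Top-vs-bottom score-quartile survival comparison."""

    statistic: float
    p: float
    n_per_group: int
    km_curves: pd.DataFrame = field(default_factory=pd.DataFrame)
    degenerate: bool = False
    message: str = ""


def quartile_logrank(
    scores: pd.Series,
    survival: pd.DataFrame,
    time_col: str = "time",
    event_col: str = "event",
) -> LogrankResult:
    """Log-rank test between the top and bottom 25% of signature scores.

    Samples are sorted by (score, sample id) for deterministic quartile
    membership; the two extreme quartiles (floor(n/4) samples each,
    minimum 1) are compared with the standard two-group log-rank
    chi-square (1 df), and Kaplan-Meier step functions are returned for
    both groups.  If every selected record is censored the result is a
    NaN sentinel with an explanatory message.
    """
    common = scores.index.intersection(survival.index)
    if len(common) < 4:
        raise ValueError("need >=4 samples with both score and survival data")
    ordered = (
        pd.DataFrame({"score": scores.loc[common]})
        .assign(sample=lambda d: d.index)
        .sort_values(["score", "sample"])
        .index
    )
    n_q = max(len(ordered) // 4, 1)
    bottom = ordered[:n_q]
    top = ordered[-n_q:]
    surv_top = survival.loc[top]
    surv_bot = survival.loc[bottom]
    n_events = int(surv_top[event_col].sum() + surv_bot[event_col].sum())
    if n_events == 0:
        return LogrankResult(
            statistic=float("nan"),
            p=float("nan"),
            n_per_group=n_q,
            degenerate=True,
            message="all selected records are censored; log-rank undefined",
        )
    result = logrank_test(
        surv_top[time_col],
        surv_bot[time_col],
        event_observed_A=surv_top[event_col],
        event_observed_B=surv_bot[event_col],
    )
    curves = []
    for label, sub in (("top_quartile", surv_top), ("bottom_quartile", surv_bot)):
        km = KaplanMeierFitter()
        km.fit(sub[time_col], sub[event_col], label=label)
        step = km.survival_function_.reset_index()
        step.columns = ["time", "survival"]
        step["group"] = label
        curves.append(step)
    return LogrankResult(
        statistic=float(result.test_statistic),
        p=float(result.p_value),
        n_per_group=n_q,
        km_curves=pd.concat(curves, ignore_index=True),
    )
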