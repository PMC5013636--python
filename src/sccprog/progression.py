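"""Per-gene mixed-effects progression modelling across lesion stages.

For each gene, transformed expression is modelled as a function of
lesion stage (fixed effect) with a per-subject random intercept, fitted
by maximum likelihood.  Models are fitted twice, once with the normal
(NS/CHR) stage as reference and once with the intermediate (AK/PAP)
stage, yielding the three stage contrasts AK-NS, SCC-NS and SCC-AK with
Wald tests (normal approximation).  Genes are designated *early*
(change concentrated in the NS->AK transition), *late* (AK->SCC),
*stepwise* (both) or *none* according to the nominal-p gating rule, and
per-species designations are intersected through one-to-one homologs.
A conjugate-Dirichlet 2x2 Bayes factor with a one-sided Fisher test
serves motif-overrepresentation queries on the resulting gene sets.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize_scalar
from scipy.special import gammaln

logger = logging.getLogger(__name__)

DESIGNATIONS = ("early", "late", "stepwise", "none")


@dataclass
class GeneFit:
    """One mixed-model fit of a gene under a given reference stage.

    ``coefficients``/``pvalues`` map contrast labels like ``"AK-NS"``
    (non-reference stage minus reference) to estimates and Wald
    normal-approximation p-values.
    """

    reference_stage: str
    converged: bool
    coefficients: dict[str, float]
    pvalues: dict[str, float]
    random_intercept_var: float = float("nan")


_LAMBDA_MAX = 1e4  # upper bound on the variance ratio tau^2 / sigma^2


def _profiled_ml_random_intercept(
    y: np.ndarray,
    X: np.ndarray,
    group_index: list[np.ndarray],
) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Exact ML fit of y = X beta + u_group + e by profiling.

    The marginal covariance is sigma^2 (I + lambda Z Z') with
    lambda = tau^2 / sigma^2; for a given lambda, beta and sigma^2 have
    closed GLS forms (per-group Sherman-Morrison inverses), leaving a
    one-dimensional profiled log-likelihood maximised over lambda >= 0
    by bounded scalar search.  The boundary lambda = 0 (no subject
    variance) is a legitimate ML solution, not a failure.

    Returns (beta, se, tau2, sigma2).
    """
    n, p = X.shape

    def neg_profile(lam: float):
        XtVX = np.zeros((p, p))
        XtVy = np.zeros(p)
        logdet = 0.0
        for ii in group_index:
            m = ii.size
            c = lam / (1.0 + m * lam)
            Xi, yi = X[ii], y[ii]
            xs = Xi.sum(axis=0)
            XtVX += Xi.T @ Xi - c * np.outer(xs, xs)
            XtVy += Xi.T @ yi - c * xs * yi.sum()
            logdet += np.log1p(m * lam)
        beta = np.linalg.solve(XtVX, XtVy)
        rss = 0.0
        for ii in group_index:
            m = ii.size
            c = lam / (1.0 + m * lam)
            ri = y[ii] - X[ii] @ beta
            rss += ri @ ri - c * ri.sum() ** 2
        sigma2 = rss / n
        nll = 0.5 * (n * np.log(max(sigma2, 1e-300)) + logdet)
        return nll, beta, sigma2, XtVX

    res = minimize_scalar(
        lambda t: neg_profile(np.expm1(t))[0],
        bounds=(0.0, np.log1p(_LAMBDA_MAX)),
        method="bounded",
        options={"xatol": 1e-10},
    )
    lam = max(float(np.expm1(res.x)), 0.0)
    if neg_profile(0.0)[0] <= res.fun:
        lam = 0.0
    _, beta, sigma2, XtVX = neg_profile(lam)
    cov = sigma2 * np.linalg.inv(XtVX)
    se = np.sqrt(np.diag(cov))
    return beta, se, lam * sigma2, sigma2


def fit_gene_lme(
    values: np.ndarray,
    stage: np.ndarray,
    subject: np.ndarray,
    reference_stage: str,
    stage_order: tuple[str, ...] | None = None,
) -> GeneFit:
    """Random-intercept ML fit of one gene's expression on lesion stage.

    Requires >=3 subjects, each contributing every stage (complete
    sets).  Wald p-values use the normal approximation.  Numerical
    failure (including zero-variance genes) returns ``converged=False``
    rather than raising.
    """
    values = np.asarray(values, dtype=float)
    stage = np.asarray(stage)
    subject = np.asarray(subject)
    stages = list(stage_order) if stage_order else sorted(set(stage))
    if reference_stage not in stages:
        raise ValueError(f"reference stage {reference_stage!r} not present")
    uniq_subjects = sorted(set(subject))
    if len(uniq_subjects) < 3:
        raise ValueError("need >=3 subjects")
    others = [s for s in stages if s != reference_stage]
    exog = np.column_stack(
        [np.ones(values.size)] + [(stage == s).astype(float) for s in others]
    )
    labels = [f"{s}-{reference_stage}" for s in others]
    if np.std(values) == 0:
        return GeneFit(reference_stage, False, {}, {})
    group_index = [np.where(subject == g)[0] for g in uniq_subjects]
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            beta, se, tau2, _sigma2 = _profiled_ml_random_intercept(
                values, exog, group_index
            )
        coefs = beta[1 : 1 + len(others)]
        ses = se[1 : 1 + len(others)]
        if not np.all(np.isfinite(coefs)) or not np.all(np.isfinite(ses)) or np.any(
            ses <= 0
        ):
            return GeneFit(reference_stage, False, {}, {})
        z = coefs / ses
        p = 2.0 * stats.norm.sf(np.abs(z))
        return GeneFit(
            reference_stage=reference_stage,
            converged=True,
            coefficients=dict(zip(labels, coefs.astype(float))),
            pvalues=dict(zip(labels, p.astype(float))),
            random_intercept_var=float(tau2),
        )
    except (np.linalg.LinAlgError, ValueError, ZeroDivisionError):
        return GeneFit(reference_stage, False, {}, {})


def paired_fold_change(
    values_a: pd.Series,
    values_b: pd.Series,
    subjects_a: pd.Series,
    subjects_b: pd.Series,
) -> float:
    """Mean within-subject linear-scale fold change b/a.

    Values are log2-transformed expression; each subject contributes
    the ratio of its anti-log2 values, and the cohort fold change is
    the arithmetic mean of those per-subject ratios.
    """
    a_by = {}
    b_by = {}
    for v, s in zip(values_a, subjects_a):
        a_by.setdefault(s, []).append(v)
    for v, s in zip(values_b, subjects_b):
        b_by.setdefault(s, []).append(v)
    shared = sorted(set(a_by) & set(b_by))
    if not shared:
        return float("nan")
    ratios = [
        2.0 ** float(np.mean(b_by[s])) / 2.0 ** float(np.mean(a_by[s]))
        for s in shared
    ]
    return float(np.mean(ratios))


def fit_progression_models(
    transformed: pd.DataFrame,
    metadata: pd.DataFrame,
    stages: tuple[str, str, str] = ("NS", "AK", "SCC"),
    subject_col: str = "subject",
    stage_col: str = "stage",
) -> pd.DataFrame:
    """Dual-reference mixed-model fits for every gene.

    Restricts to subjects possessing all three stages, fits each gene
    once with ``stages[0]`` and once with ``stages[1]`` as reference,
    and tabulates the three contrasts plus paired fold changes.

    Returns a DataFrame indexed by gene with columns
    ``converged``, ``coef_early``/``p_early`` (AK-NS), ``coef_full``/
    ``p_full`` (SCC-NS), ``coef_late``/``p_late`` (SCC-AK) and
    ``fc_early``/``fc_full``/``fc_late`` (paired linear-scale ratios).
    """
    s0, s1, s2 = stages
    meta = metadata.loc[metadata[stage_col].isin(stages)]
    per_subject = meta.groupby(subject_col)[stage_col].agg(lambda x: set(x))
    complete = [s for s, st in per_subject.items() if st >= set(stages)]
    if len(complete) < 3:
        raise ValueError("need >=3 subjects with complete stage sets")
    keep = meta.index[meta[subject_col].isin(complete)]
    cols = transformed.columns.intersection(keep)
    mat = transformed[cols]
    stage_arr = metadata.loc[cols, stage_col].to_numpy()
    subj_arr = metadata.loc[cols, subject_col].to_numpy()

    rows = []
    for gene in mat.index:
        values = mat.loc[gene].to_numpy(dtype=float)
        fit0 = fit_gene_lme(values, stage_arr, subj_arr, s0, stages)
        fit1 = fit_gene_lme(values, stage_arr, subj_arr, s1, stages)
        converged = fit0.converged and fit1.converged
        row = {"gene": gene, "converged": converged}
        if converged:
            row["coef_early"] = fit0.coefficients[f"{s1}-{s0}"]
            row["p_early"] = fit0.pvalues[f"{s1}-{s0}"]
            row["coef_full"] = fit0.coefficients[f"{s2}-{s0}"]
            row["p_full"] = fit0.pvalues[f"{s2}-{s0}"]
            row["coef_late"] = fit1.coefficients[f"{s2}-{s1}"]
            row["p_late"] = fit1.pvalues[f"{s2}-{s1}"]
        else:
            for key in ("coef_early", "p_early", "coef_full", "p_full",
                        "coef_late", "p_late"):
                row[key] = float("nan")
        rows.append(row)

    table = pd.DataFrame(rows).set_index("gene")
    # paired fold changes, vectorised over genes per contrast
    for label, (num, den) in {
        "fc_early": (s1, s0),
        "fc_full": (s2, s0),
        "fc_late": (s2, s1),
    }.items():
        num_cols = cols[stage_arr == num]
        den_cols = cols[stage_arr == den]
        num_sub = metadata.loc[num_cols, subject_col]
        den_sub = metadata.loc[den_cols, subject_col]
        shared = sorted(set(num_sub) & set(den_sub))
        num_by = {
            s: mat[num_cols[(num_sub == s).to_numpy()]].mean(axis=1) for s in shared
        }
        den_by = {
            s: mat[den_cols[(den_sub == s).to_numpy()]].mean(axis=1) for s in shared
        }
        ratios = [
            2.0 ** (num_by[s] - den_by[s]) for s in shared
        ]
        table[label] = pd.concat(ratios, axis=1).mean(axis=1)
    return table


def classify_progression(calls: pd.DataFrame, alpha: float = 0.05) -> pd.Series:
    """Early/late/stepwise designation from the dual-reference contrasts.

    Gate: the full-span (SCC-NS) contrast must have nominal p < alpha.
    Among gated genes, *early* requires the AK-NS contrast significant
    with a sign matching the full-span coefficient, *late* the same for
    SCC-AK, *stepwise* both.  Non-converged genes and genes with any
    missing contrast get *none*.  No multiplicity correction is applied
    at this step (nominal p by design).
    """
    designation = pd.Series("none", index=calls.index, dtype=object)
    ok = calls["converged"].fillna(False).astype(bool)
    needed = ["p_full", "coef_full", "p_early", "coef_early", "p_late", "coef_late"]
    ok &= calls[needed].notna().all(axis=1)
    gate = ok & (calls["p_full"] < alpha)
    sign_full = np.sign(calls["coef_full"])
    early = gate & (calls["p_early"] < alpha) & (np.sign(calls["coef_early"]) == sign_full)
    late = gate & (calls["p_late"] < alpha) & (np.sign(calls["coef_late"]) == sign_full)
    designation[early & ~late] = "early"
    designation[late & ~early] = "late"
    designation[early & late] = "stepwise"
    return designation


def one_to_one_homologs(mapping: pd.DataFrame) -> pd.DataFrame:
    """Retain only homolog pairs forming a cross-species bijection.

    ``mapping`` needs columns ``feature_a`` and ``feature_b`` (one row
    per candidate pair).  Any feature participating in more than one
    pair is discarded together with all its pairs, so the result is a
    bijection on its retained features.  May be empty.
    """
    m = mapping.drop_duplicates(subset=["feature_a", "feature_b"])
    a_counts = m["feature_a"].value_counts()
    b_counts = m["feature_b"].value_counts()
    keep = m["feature_a"].map(a_counts).eq(1) & m["feature_b"].map(b_counts).eq(1)
    return m.loc[keep].reset_index(drop=True)


def cross_species_sets(
    calls_a: pd.DataFrame,
    calls_b: pd.DataFrame,
    homology: pd.DataFrame,
) -> dict[str, pd.DataFrame]:
    """Conserved early/late/stepwise homolog pairs.

    ``calls_a``/``calls_b`` are per-gene tables with ``designation``
    and ``coef_full`` columns (see :func:`fit_progression_models` plus
    :func:`classify_progression`); ``homology`` is a filtered
    one-to-one map with columns feature_a/feature_b.  A pair is
    conserved when both species give the identical non-none designation
    with the same full-span coefficient sign.  Returns per-designation
    DataFrames of pairs, plus the merged table under ``"merged"``.
    """
    merged = homology.merge(
        calls_a[["designation", "coef_full"]],
        left_on="feature_a",
        right_index=True,
    ).merge(
        calls_b[["designation", "coef_full"]],
        left_on="feature_b",
        right_index=True,
        suffixes=("_a", "_b"),
    )
    conserved = merged[
        (merged["designation_a"] == merged["designation_b"])
        & (merged["designation_a"] != "none")
        & (np.sign(merged["coef_full_a"]) == np.sign(merged["coef_full_b"]))
    ]
    out: dict[str, pd.DataFrame] = {"merged": merged}
    for d in ("early", "late", "stepwise"):
        out[d] = conserved[conserved["designation_a"] == d][
            ["feature_a", "feature_b", "coef_full_a", "coef_full_b"]
        ].reset_index(drop=True)
    return out


def dirichlet_2x2_bayes_factor(table: np.ndarray) -> float:
    """Bayes factor for association vs independence in a 2x2 table.

    Both models use uniform Dirichlet priors: the association model
    places Dirichlet(1,1,1,1) on the four cell probabilities; the
    independence model places independent Dirichlet(1,1) priors on the
    row and column margins.  The multinomial coefficient cancels in the
    ratio.  Values > 1 favour association.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or np.any(t < 0):
        raise ValueError("need a nonnegative 2x2 table")
    n = t.sum()
    cells = t.ravel()
    log_m1 = gammaln(4.0) - gammaln(n + 4.0) + np.sum(gammaln(cells + 1.0))
    rows = t.sum(axis=1)
    cols = t.sum(axis=0)
    log_m0 = (
        gammaln(2.0)
        - gammaln(n + 2.0)
        + np.sum(gammaln(rows + 1.0))
        + gammaln(2.0)
        - gammaln(n + 2.0)
        + np.sum(gammaln(cols + 1.0))
    )
    return float(np.exp(log_m1 - log_m0))


def gather_style_overrepresentation(
    gene_set: set[str],
    motif_target_sets: dict[str, set[str]],
    universe: set[str],
    bf_threshold: float = 3.0,
) -> pd.DataFrame:
    """Motif-target overrepresentation in a gene set: Fisher p and Bayes factor.

    For each motif, a 2x2 table (in gene set x in target set) over the
    universe is scored with a one-sided Fisher exact test and the
    conjugate-Dirichlet Bayes factor; motifs with BF > ``bf_threshold``
    are flagged significant.  Motifs with no targets in the universe
    get NaN sentinels; a degenerate table where the gene set and target
    set both equal the universe is flagged in the ``degenerate``
    column.
    """
    if not gene_set <= universe:
        raise ValueError("gene_set must be a subset of universe")
    rows = []
    n_u = len(universe)
    n_s = len(gene_set)
    for motif, targets in motif_target_sets.items():
        t_in = targets & universe
        n_t = len(t_in)
        if n_t == 0:
            rows.append(
                {
                    "motif": motif,
                    "overlap": 0,
                    "set_size": n_s,
                    "target_size": 0,
                    "p": float("nan"),
                    "bayes_factor": float("nan"),
                    "significant": False,
                    "degenerate": False,
                }
            )
            continue
        overlap = len(gene_set & t_in)
        table = np.array(
            [
                [overlap, n_s - overlap],
                [n_t - overlap, n_u - n_s - n_t + overlap],
            ]
        )
        degenerate = n_s == n_u or n_t == n_u
        if degenerate:
            logger.warning("degenerate 2x2 table for motif %s", motif)
        _, p = stats.fisher_exact(table, alternative="greater")
        bf = dirichlet_2x2_bayes_factor(table)
        rows.append(
            {
                "motif": motif,
                "overlap": overlap,
                "set_size": n_s,
                "target_size": n_t,
                "p": float(p),
                "bayes_factor": bf,
                "significant": bool(bf > bf_threshold) and not degenerate,
                "degenerate": degenerate,
            }
        )
    return pd.DataFrame(rows).set_index("motif")
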