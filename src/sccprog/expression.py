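"""Bulk RNA-seq count processing for the progression cohorts.

Covers median-of-ratios size-factor normalisation, a documented
variance-stabilising-transform stand-in (log2 of size-factor-scaled
counts), per-gene batch-median alignment, a transformed-scale Welch
t-test for differential expression with Benjamini-Hochberg control,
Pearson/complete-linkage clustering with PCA summaries, and the CIN70
chromosomal-instability score with covariate adjustment.

The VST stand-in and the t-test DE are deliberate simplifications of
dispersion-modelling pipelines: downstream progression analysis depends
only on a monotone variance-flattening transform and a calibrated
per-gene test, both of which these provide.  Outputs label the
transform "vst_standin".
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import complete, leaves_list
from scipy.spatial.distance import squareform
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

#: metadata columns every ExpressionStudy carries
METADATA_COLUMNS = ("stage", "subject", "batch", "species")


@dataclass
class ExpressionStudy:
    """Gene x sample count matrix with per-sample metadata.

    ``counts`` is genes x samples; ``metadata`` is indexed by sample and
    must provide stage, subject, batch and species columns.
    ``size_factors`` is filled by :func:`normalize`.
    """

    counts: pd.DataFrame
    metadata: pd.DataFrame
    size_factors: pd.Series | None = None

    def __post_init__(self) -> None:
        missing = set(self.counts.columns) - set(self.metadata.index)
        if missing:
            raise ValueError(f"metadata missing for samples: {sorted(missing)}")
        for col in METADATA_COLUMNS:
            if col not in self.metadata.columns:
                raise ValueError(f"metadata lacks required column {col!r}")
        if self.size_factors is not None and (self.size_factors <= 0).any():
            raise ValueError("size factors must be positive")

    @property
    def samples(self) -> pd.Index:
        return self.counts.columns

    @property
    def genes(self) -> pd.Index:
        return self.counts.index


def size_factors_median_of_ratios(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios (scaling factor) normalisation factors.

    For genes expressed in every sample, each sample's factor is the
    median of its count ratios to the per-gene geometric mean; factors
    are then rescaled to geometric mean 1.  If no gene is expressed in
    all samples, falls back to total-count scaling with a warning.
    """
    mat = counts.to_numpy(dtype=float)
    expressed = (mat > 0).all(axis=1)
    if expressed.any():
        sub = mat[expressed]
        log_geo = np.mean(np.log(sub), axis=1)
        ratios = np.log(sub) - log_geo[:, None]
        factors = np.exp(np.median(ratios, axis=0))
    else:
        warnings.warn(
            "no gene expressed in all samples; falling back to total-count scaling",
            stacklevel=2,
        )
        totals = mat.sum(axis=0)
        if (totals <= 0).any():
            raise ValueError("cannot normalise samples with zero total counts")
        factors = totals
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def normalize(study: ExpressionStudy) -> ExpressionStudy:
    """Attach median-of-ratios size factors to a study."""
    study.size_factors = size_factors_median_of_ratios(study.counts)
    return study


def vst_standin(counts: pd.DataFrame, size_factors: pd.Series) -> pd.DataFrame:
    """Variance-stabilising-transform stand-in: log2(count / factor + 1)."""
    return np.log2(counts.div(size_factors, axis=1) + 1.0)


def batch_align(matrix: pd.DataFrame, batches: pd.Series) -> pd.DataFrame:
    """Per-gene batch-median alignment on the transformed scale.

    Each batch's values are shifted per gene so that every batch median
    equals the gene's global median.  Idempotent; identity for a single
    batch.  Single-sample batches are allowed (their median is the
    value) and logged.
    """
    batches = batches.reindex(matrix.columns)
    if batches.isna().any():
        raise ValueError("batch labels missing for some samples")
    aligned = matrix.copy()
    global_median = matrix.median(axis=1)
    for batch, cols in matrix.columns.to_series().groupby(batches):
        if len(cols) == 1:
            logger.info("batch %s has a single sample", batch)
        cols = list(cols)
        shift = global_median - matrix[cols].median(axis=1)
        aligned[cols] = matrix[cols].add(shift, axis=0)
    return aligned


def vst_and_batch_align(
    counts: pd.DataFrame,
    size_factors: pd.Series,
    batches: pd.Series,
) -> pd.DataFrame:
    """Transform counts and align batch medians in one step."""
    return batch_align(vst_standin(counts, size_factors), batches)


def benjamini_hochberg(pvalues: np.ndarray) -> np.ndarray:
    """BH step-up q-values (monotone in p-rank)."""
    return multipletests(pvalues, method="fdr_bh")[1]


@dataclass
class DEResult:
    """Per-gene differential expression table for one comparison.

    ``table`` columns: log2_fc, p, q; log2 fold change is group_b minus
    group_a on the transformed scale.
    """

    comparison: str
    table: pd.DataFrame

    def significant(self, q_max: float = 0.25, fc_min: float = 1.25) -> pd.DataFrame:
        """Genes passing the integration cutoff (q < q_max, |FC| > fc_min)."""
        t = self.table
        return t[(t["q"] < q_max) & (2.0 ** t["log2_fc"].abs() > fc_min)]


def differential_expression(
    transformed: pd.DataFrame,
    metadata: pd.DataFrame,
    group_a: str,
    group_b: str,
    stage_col: str = "stage",
    paired: bool = False,
    subject_col: str = "subject",
) -> DEResult:
    """Welch t-test per gene on transformed values, BH-corrected.

    ``group_b`` is the test condition: log2 fold change is
    mean(group_b) - mean(group_a).  With ``paired=True`` the test is a
    one-sample t-test on within-subject differences (subjects present
    in both groups only).  Genes with zero variance in both groups get
    p = 1 when the means are equal, p = 0 otherwise.
    """
    in_a = metadata.index[metadata[stage_col] == group_a]
    in_b = metadata.index[metadata[stage_col] == group_b]
    a = transformed[transformed.columns.intersection(in_a)]
    b = transformed[transformed.columns.intersection(in_b)]
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise ValueError("need >=2 samples per group")

    if paired:
        subj_a = metadata.loc[a.columns, subject_col]
        subj_b = metadata.loc[b.columns, subject_col]
        common = sorted(set(subj_a) & set(subj_b))
        if len(common) < 2:
            raise ValueError("paired mode needs >=2 shared subjects")
        da = a[[subj_a.index[subj_a.tolist().index(s)] for s in common]]
        db = b[[subj_b.index[subj_b.tolist().index(s)] for s in common]]
        diffs = db.to_numpy() - da.to_numpy()
        with np.errstate(invalid="ignore", divide="ignore"), \
                warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            tstat, p = stats.ttest_1samp(diffs, 0.0, axis=1)
        lfc = diffs.mean(axis=1)
        zero_var = diffs.std(axis=1) == 0
        p = np.where(zero_var & (lfc == 0), 1.0, p)
        p = np.where(zero_var & (lfc != 0), 0.0, p)
    else:
        av, bv = a.to_numpy(), b.to_numpy()
        with np.errstate(invalid="ignore", divide="ignore"), \
                warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            tstat, p = stats.ttest_ind(bv, av, axis=1, equal_var=False)
        lfc = bv.mean(axis=1) - av.mean(axis=1)
        zero_var = (av.std(axis=1) == 0) & (bv.std(axis=1) == 0)
        p = np.where(zero_var & (lfc == 0), 1.0, p)
        p = np.where(zero_var & (lfc != 0), 0.0, p)

    p = np.where(np.isnan(p), 1.0, p)
    table = pd.DataFrame(
        {"log2_fc": lfc, "p": p, "q": benjamini_hochberg(p)},
        index=transformed.index,
    )
    return DEResult(comparison=f"{group_a}_vs_{group_b}", table=table)


@dataclass
class ClusterSummary:
    correlation: pd.DataFrame
    linkage: np.ndarray
    dendrogram_order: list[str]
    pca_coordinates: pd.DataFrame
    explained_variance_ratio: np.ndarray
    excluded_samples: list[str] = field(default_factory=list)


def correlation_cluster_pca(
    matrix: pd.DataFrame,
    gene_subset: list[str] | None = None,
    n_components: int = 2,
) -> ClusterSummary:
    """Pearson correlation, complete-linkage clustering and PCA of samples.

    Distance is 1 - Pearson r between sample profiles.  Constant sample
    vectors have undefined correlation and are excluded with a warning.
    Each principal component is oriented so its largest-magnitude
    loading is positive, making signs deterministic.
    """
    if gene_subset is not None:
        matrix = matrix.loc[matrix.index.intersection(gene_subset)]
    constant = matrix.std(axis=0) == 0
    excluded = list(matrix.columns[constant])
    if excluded:
        warnings.warn(
            f"excluding constant samples from clustering: {excluded}", stacklevel=2
        )
        matrix = matrix.loc[:, ~constant]
    if matrix.shape[1] < 3:
        raise ValueError("need >=3 non-constant samples")
    # stable order for tie-breaking
    matrix = matrix[sorted(matrix.columns)]
    corr = matrix.corr(method="pearson")
    dist = 1.0 - corr.to_numpy()
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    Z = complete(squareform(dist, checks=False))
    order = [corr.columns[i] for i in leaves_list(Z)]

    n_comp = min(n_components, matrix.shape[1] - 1)
    pca = PCA(n_components=n_comp)
    coords = pca.fit_transform(matrix.to_numpy().T - matrix.to_numpy().T.mean(axis=0))
    for j in range(n_comp):
        loading = pca.components_[j]
        if loading[np.argmax(np.abs(loading))] < 0:
            pca.components_[j] *= -1
            coords[:, j] *= -1
    pca_df = pd.DataFrame(
        coords,
        index=matrix.columns,
        columns=[f"PC{i + 1}" for i in range(n_comp)],
    )
    return ClusterSummary(
        correlation=corr,
        linkage=Z,
        dendrogram_order=order,
        pca_coordinates=pca_df,
        explained_variance_ratio=pca.explained_variance_ratio_,
        excluded_samples=excluded,
    )


@dataclass
class CINScore:
    """Per-sample chromosomal-instability score.

    ``table`` columns: raw (sum of normalised counts over the CIN gene
    set), transformed (log2(raw+1)), adjusted (residual of a linear fit
    on the covariate design).
    """

    table: pd.DataFrame
    genes_used: list[str]
    genes_missing: list[str]


def cin70_score(
    study: ExpressionStudy,
    cin_genes: list[str],
    covariates: tuple[str, ...] = ("subject", "batch"),
) -> CINScore:
    """CIN70-style score: summed normalised counts, covariate-adjusted.

    The raw score sums size-factor-normalised counts over the CIN genes
    present; the transformed score is log2(raw + 1); the adjusted score
    is the residual of a least-squares fit of the transformed score on
    indicator columns for the requested covariates (redundant columns
    dropped with a warning on rank deficiency).  With no covariates the
    adjusted score is simply the centred transformed score.
    """
    if study.size_factors is None:
        normalize(study)
    present = [g for g in cin_genes if g in study.counts.index]
    missing = [g for g in cin_genes if g not in study.counts.index]
    if not present:
        raise ValueError("no CIN gene present in the study")
    if missing:
        logger.info("CIN genes missing from study: %s", missing)
    norm = study.counts.loc[present].div(study.size_factors, axis=1)
    raw = norm.sum(axis=0)
    transformed = np.log2(raw + 1.0)

    design_cols = [np.ones(len(raw))]
    for cov in covariates:
        values = study.metadata.loc[raw.index, cov]
        levels = sorted(values.unique())[1:]  # drop first level per covariate
        for lv in levels:
            design_cols.append((values == lv).to_numpy(dtype=float))
    design = np.column_stack(design_cols)
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        warnings.warn(
            "rank-deficient covariate design; redundant columns resolved by "
            "least squares",
            stacklevel=2,
        )
    beta, *_ = np.linalg.lstsq(design, transformed.to_numpy(), rcond=None)
    adjusted = transformed.to_numpy() - design @ beta
    table = pd.DataFrame(
        {"raw": raw, "transformed": transformed, "adjusted": adjusted},
        index=raw.index,
    )
    return CINScore(table=table, genes_used=present, genes_missing=missing)
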