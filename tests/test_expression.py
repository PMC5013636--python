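"""Normalisation, batch alignment, DE stand-in, clustering and CIN70."""

import numpy as np
import pandas as pd
import pytest

from sccprog import expression as expr


def make_study(counts, stages=None, subjects=None, batches=None):
    counts = pd.DataFrame(
        counts,
        index=[f"g{i}" for i in range(np.shape(counts)[0])],
        columns=[f"s{j}" for j in range(np.shape(counts)[1])],
    )
    n = counts.shape[1]
    meta = pd.DataFrame(
        {
            "stage": stages or ["NS"] * n,
            "subject": subjects or [f"sub{j}" for j in range(n)],
            "batch": batches or ["b0"] * n,
            "species": ["human"] * n,
        },
        index=counts.columns,
    )
    return expr.ExpressionStudy(counts=counts, metadata=meta)


class TestSizeFactors:
    def test_identical_columns_unit_factors(self):
        counts = pd.DataFrame(np.tile([[4], [9], [25]], (1, 3)))
        assert np.allclose(expr.size_factors_median_of_ratios(counts), 1.0)

    def test_doubled_column_relative_factor_two(self):
        base = np.array([[10, 10, 20], [4, 4, 8], [100, 100, 200]])
        f = expr.size_factors_median_of_ratios(pd.DataFrame(base))
        assert f.iloc[2] / f.iloc[0] == pytest.approx(2.0)

    def test_hand_computed_five_by_three(self):
        counts = pd.DataFrame(
            [[2, 4, 8], [3, 6, 12], [5, 10, 20], [7, 14, 28], [11, 22, 44]]
        )
        # each gene's ratios to its geometric mean are identical per
        # column: col j factor proportional to 1, 2, 4 -> geo-mean 2
        f = expr.size_factors_median_of_ratios(counts)
        assert np.allclose(f, [0.5, 1.0, 2.0])

    def test_scale_equivariance(self, rng):
        counts = pd.DataFrame(rng.poisson(50, size=(30, 4)) + 1)
        f = expr.size_factors_median_of_ratios(counts)
        scaled = counts.copy()
        scaled[2] = counts[2] * 3
        f2 = expr.size_factors_median_of_ratios(scaled)
        ratio = (f2 / f).to_numpy()
        assert ratio[2] / ratio[0] == pytest.approx(3.0, rel=1e-9)

    def test_fallback_total_count_with_warning(self):
        counts = pd.DataFrame([[0, 5], [5, 0]])
        with pytest.warns(UserWarning, match="total-count"):
            f = expr.size_factors_median_of_ratios(counts)
        assert np.allclose(f, 1.0)


class TestBatchAlign:
    def test_single_batch_identity(self, rng):
        mat = pd.DataFrame(rng.normal(size=(10, 4)))
        batches = pd.Series(["b0"] * 4, index=mat.columns)
        pd.testing.assert_frame_equal(expr.batch_align(mat, batches), mat)

    def test_constant_offset_removed(self, rng):
        mat = pd.DataFrame(rng.normal(size=(10, 6)))
        delta = 1.7
        shifted = mat.copy()
        shifted.iloc[:, 3:] += delta
        batches = pd.Series(["b0"] * 3 + ["b1"] * 3, index=mat.columns)
        aligned = expr.batch_align(shifted, batches)
        for _, row in aligned.iterrows():
            assert abs(row.iloc[:3].median() - row.iloc[3:].median()) < 1e-12

    def test_idempotent(self, rng):
        mat = pd.DataFrame(rng.normal(size=(8, 6)))
        batches = pd.Series(["b0", "b0", "b1", "b1", "b2", "b2"],
                            index=mat.columns)
        once = expr.batch_align(mat, batches)
        twice = expr.batch_align(once, batches)
        pd.testing.assert_frame_equal(once, twice)


class TestDifferentialExpression:
    def test_bh_matches_bruteforce_stepup(self, rng):
        p = rng.uniform(size=10)
        q = expr.benjamini_hochberg(p)
        m = len(p)
        order = np.argsort(p)
        brute = np.empty(m)
        running = 1.0
        for rank in range(m - 1, -1, -1):
            i = order[rank]
            running = min(running, p[i] * m / (rank + 1))
            brute[i] = running
        assert np.allclose(q, brute)

    def test_type_one_error_calibrated_on_null(self):
        rng = np.random.default_rng(5)
        mat = pd.DataFrame(
            rng.normal(size=(5000, 12)),
            index=[f"g{i}" for i in range(5000)],
            columns=[f"s{j}" for j in range(12)],
        )
        meta = pd.DataFrame(
            {
                "stage": ["A"] * 6 + ["B"] * 6,
                "subject": list(range(12)),
                "batch": "b0",
                "species": "human",
            },
            index=mat.columns,
        )
        de = expr.differential_expression(mat, meta, "A", "B")
        frac = (de.table["p"] < 0.05).mean()
        assert frac == pytest.approx(0.05, abs=0.02)

    def test_planted_two_fold_recovered(self):
        rng = np.random.default_rng(6)
        n_genes, n_planted = 500, 100
        base = rng.uniform(4, 8, size=n_genes)
        mat = np.tile(base[:, None], (1, 12)) + rng.normal(
            0, np.sqrt(0.05), size=(n_genes, 12)
        )
        mat[:n_planted, 6:] += 1.0  # 2x on log2 scale
        frame = pd.DataFrame(
            mat,
            index=[f"g{i}" for i in range(n_genes)],
            columns=[f"s{j}" for j in range(12)],
        )
        meta = pd.DataFrame(
            {
                "stage": ["A"] * 6 + ["B"] * 6,
                "subject": list(range(12)),
                "batch": "b0",
                "species": "human",
            },
            index=frame.columns,
        )
        de = expr.differential_expression(frame, meta, "A", "B")
        hits = de.significant(q_max=0.25, fc_min=1.25).index
        recovered = sum(1 for g in hits if int(g[1:]) < n_planted)
        assert recovered / n_planted >= 0.8

    def test_zero_variance_equal_means_p_one(self):
        frame = pd.DataFrame(
            [[1.0, 1.0, 1.0, 1.0]], index=["g0"], columns=list("abcd")
        )
        meta = pd.DataFrame(
            {
                "stage": ["A", "A", "B", "B"],
                "subject": list(range(4)),
                "batch": "b0",
                "species": "human",
            },
            index=frame.columns,
        )
        de = expr.differential_expression(frame, meta, "A", "B")
        assert de.table.loc["g0", "p"] == 1.0

    def test_threshold_monotonicity(self, rng):
        mat = pd.DataFrame(
            rng.normal(size=(300, 10)) + np.linspace(0, 2, 300)[:, None],
            index=[f"g{i}" for i in range(300)],
        )
        mat.iloc[:50, 5:] += 1.5
        mat.columns = [f"s{j}" for j in range(10)]
        meta = pd.DataFrame(
            {
                "stage": ["A"] * 5 + ["B"] * 5,
                "subject": list(range(10)),
                "batch": "b0",
                "species": "human",
            },
            index=mat.columns,
        )
        de = expr.differential_expression(mat, meta, "A", "B")
        n_loose = len(de.significant(q_max=0.25, fc_min=1.25))
        n_tight_q = len(de.significant(q_max=0.1, fc_min=1.25))
        n_tight_fc = len(de.significant(q_max=0.25, fc_min=2.0))
        assert n_tight_q <= n_loose and n_tight_fc <= n_loose


class TestClusterPca:
    def test_duplicated_sample_perfect_correlation_merged_first(self, rng):
        mat = pd.DataFrame(rng.normal(size=(50, 4)), columns=list("abcd"))
        mat["d"] = mat["a"]
        out = expr.correlation_cluster_pca(mat)
        assert out.correlation.loc["a", "d"] == pytest.approx(1.0)
        first_merge = out.linkage[0, :2].astype(int)
        names = [out.correlation.columns[i] for i in first_merge]
        assert set(names) == {"a", "d"}

    def test_two_classes_separated_by_pc1(self, rng):
        a = rng.normal(0, 1, size=(100, 5))
        b = rng.normal(4, 1, size=(100, 5))
        mat = pd.DataFrame(np.hstack([a, b]),
                           columns=[f"s{j}" for j in range(10)])
        out = expr.correlation_cluster_pca(mat)
        pc1 = out.pca_coordinates["PC1"]
        ga, gb = pc1.iloc[:5], pc1.iloc[5:]
        # silhouette-style separation of the leading component
        gap = abs(ga.mean() - gb.mean())
        spread = max(ga.std(), gb.std(), 1e-9)
        assert gap / (gap + spread) > 0.5

    def test_correlation_symmetric_unit_diagonal(self, rng):
        mat = pd.DataFrame(rng.normal(size=(30, 5)))
        mat.columns = [f"s{j}" for j in range(5)]
        out = expr.correlation_cluster_pca(mat)
        c = out.correlation.to_numpy()
        assert np.allclose(c, c.T)
        assert np.allclose(np.diag(c), 1.0)

    def test_constant_sample_excluded_with_warning(self, rng):
        mat = pd.DataFrame(rng.normal(size=(30, 4)))
        mat.columns = [f"s{j}" for j in range(4)]
        mat["s3"] = 2.0
        with pytest.warns(UserWarning, match="constant"):
            out = expr.correlation_cluster_pca(mat)
        assert out.excluded_samples == ["s3"]


class TestCin70:
    def _study(self, rng, n_samples=8, boost=None):
        counts = rng.poisson(100, size=(20, n_samples))
        if boost is not None:
            counts[:5, boost] *= 4
        study = make_study(
            counts,
            subjects=[f"sub{j // 2}" for j in range(n_samples)],
            batches=[f"b{j % 2}" for j in range(n_samples)],
        )
        return study

    def test_covariate_free_equals_centred(self, rng):
        study = self._study(rng)
        score = expr.cin70_score(study, [f"g{i}" for i in range(5)], covariates=())
        t = score.table
        assert np.allclose(t["adjusted"], t["transformed"] - t["transformed"].mean())

    def test_residuals_orthogonal_to_design(self, rng):
        study = self._study(rng)
        score = expr.cin70_score(study, [f"g{i}" for i in range(5)])
        adj = score.table["adjusted"].to_numpy()
        for cov in ("subject", "batch"):
            for level in study.metadata[cov].unique():
                col = (study.metadata[cov] == level).to_numpy(dtype=float)
                assert abs(adj @ col) < 1e-8

    def test_boosted_samples_rank_top(self, rng):
        study = self._study(rng, n_samples=8, boost=[0, 1])
        score = expr.cin70_score(
            study, [f"g{i}" for i in range(5)], covariates=("batch",)
        )
        ranked = score.table["adjusted"].rank(ascending=False)
        assert ranked.iloc[0] <= 2 and ranked.iloc[1] <= 2

    def test_batch_constant_invariance(self, rng):
        """Adding a per-batch constant on the transformed scale does not
        change adjusted scores when batch is a covariate -- checked via
        the residual property on counts scaled per batch."""
        study = self._study(rng)
        base = expr.cin70_score(study, [f"g{i}" for i in range(5)],
                                covariates=("batch",))
        shifted = study.counts.copy()
        b1 = study.metadata.index[study.metadata["batch"] == "b1"]
        shifted[b1] = shifted[b1] * 4  # 2 log2-units per batch
        study2 = expr.ExpressionStudy(
            counts=shifted, metadata=study.metadata,
            size_factors=study.size_factors,
        )
        study2.size_factors = None
        score2 = expr.cin70_score(study2, [f"g{i}" for i in range(5)],
                                  covariates=("batch",))
        # residuals unchanged up to normalisation effects
        corr = np.corrcoef(base.table["adjusted"], score2.table["adjusted"])[0, 1]
        assert corr > 0.99

    def test_missing_all_genes_rejected(self, rng):
        study = self._study(rng)
        with pytest.raises(ValueError):
            expr.cin70_score(study, ["absent1", "absent2"])
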