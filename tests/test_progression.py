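"""Mixed-effects progression fits, designations, homologs, Bayes factors."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats

from sccprog import progression as prog


def simulate_gene(rng, n_sub=6, effects=(0.0, 0.0), subject_sd=0.5, noise=0.3):
    """One gene over n_sub subjects x 3 stages; effects are cumulative
    shifts at the first and second transition."""
    stage = np.tile(["NS", "AK", "SCC"], n_sub)
    subject = np.repeat([f"S{i}" for i in range(n_sub)], 3)
    u = rng.normal(0, subject_sd, n_sub)
    shift = {"NS": 0.0, "AK": effects[0], "SCC": effects[0] + effects[1]}
    y = (
        5.0
        + np.array([shift[s] for s in stage])
        + np.repeat(u, 3)
        + rng.normal(0, noise, 3 * n_sub)
    )
    return y, stage, subject


class TestFitGeneLme:
    def test_reference_swap_negates_coefficient(self, rng):
        y, stage, subject = simulate_gene(rng, effects=(0.8, 0.4))
        fit_ns = prog.fit_gene_lme(y, stage, subject, "NS", ("NS", "AK", "SCC"))
        fit_ak = prog.fit_gene_lme(y, stage, subject, "AK", ("NS", "AK", "SCC"))
        assert abs(
            fit_ns.coefficients["AK-NS"] + fit_ak.coefficients["NS-AK"]
        ) < 1e-6
        assert abs(
            fit_ns.pvalues["AK-NS"] - fit_ak.pvalues["NS-AK"]
        ) < 1e-6

    def test_no_subject_variance_reduces_to_stage_means(self, rng):
        y, stage, subject = simulate_gene(rng, n_sub=10, effects=(1.0, 0.5),
                                          subject_sd=0.0)
        fit = prog.fit_gene_lme(y, stage, subject, "NS", ("NS", "AK", "SCC"))
        mean_ns = y[stage == "NS"].mean()
        assert fit.coefficients["AK-NS"] == pytest.approx(
            y[stage == "AK"].mean() - mean_ns, abs=1e-6
        )
        assert fit.coefficients["SCC-NS"] == pytest.approx(
            y[stage == "SCC"].mean() - mean_ns, abs=1e-6
        )

    def test_constant_gene_not_converged(self):
        stage = np.tile(["NS", "AK", "SCC"], 4)
        subject = np.repeat(list("abcd"), 3)
        fit = prog.fit_gene_lme(np.ones(12), stage, subject, "NS")
        assert not fit.converged

    def test_matches_statsmodels_mixedlm(self, rng):
        """Cross-check the profiled-ML fitter against statsmodels."""
        from statsmodels.regression.mixed_linear_model import MixedLM

        for _ in range(5):
            y, stage, subject = simulate_gene(rng, effects=(0.5, 0.3),
                                              subject_sd=0.6)
            fit = prog.fit_gene_lme(y, stage, subject, "NS", ("NS", "AK", "SCC"))
            exog = np.column_stack(
                [np.ones(y.size), (stage == "AK").astype(float),
                 (stage == "SCC").astype(float)]
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = MixedLM(y, exog, groups=subject).fit(reml=False)
            if not res.converged:
                continue
            assert fit.coefficients["AK-NS"] == pytest.approx(res.params[1],
                                                              abs=1e-4)
            assert fit.coefficients["SCC-NS"] == pytest.approx(res.params[2],
                                                               abs=1e-4)

    def test_designation_invariant_to_constant_shift(self, rng):
        y, stage, subject = simulate_gene(rng, effects=(1.0, 0.0))
        f1 = prog.fit_gene_lme(y, stage, subject, "NS", ("NS", "AK", "SCC"))
        f2 = prog.fit_gene_lme(y + 100.0, stage, subject, "NS",
                               ("NS", "AK", "SCC"))
        for key in f1.coefficients:
            assert f1.coefficients[key] == pytest.approx(
                f2.coefficients[key], abs=1e-6
            )


class TestClassify:
    def _calls(self, p_full, c_full, p_early, c_early, p_late, c_late):
        return pd.DataFrame(
            {
                "converged": [True],
                "p_full": [p_full],
                "coef_full": [c_full],
                "p_early": [p_early],
                "coef_early": [c_early],
                "p_late": [p_late],
                "coef_late": [c_late],
            },
            index=["g"],
        )

    @pytest.mark.parametrize(
        "calls_args, expected",
        [
            ((0.2, 1.0, 0.01, 1.0, 0.01, 1.0), "none"),  # gate fails
            ((0.01, 1.0, 0.01, 1.0, 0.3, 1.0), "early"),
            ((0.01, 1.0, 0.01, -1.0, 0.3, 1.0), "none"),  # sign mismatch
            ((0.01, 1.0, 0.01, -1.0, 0.02, 1.0), "late"),
            ((0.01, 1.0, 0.01, 1.0, 0.02, 1.0), "stepwise"),
            ((0.01, -1.0, 0.01, -1.0, 0.02, -1.0), "stepwise"),
        ],
    )
    def test_rule_table(self, calls_args, expected):
        calls = self._calls(*calls_args)
        assert prog.classify_progression(calls).loc["g"] == expected

    def test_unconverged_gets_none(self):
        calls = self._calls(0.01, 1.0, 0.01, 1.0, 0.3, 1.0)
        calls["converged"] = False
        assert prog.classify_progression(calls).loc["g"] == "none"


class TestHomologs:
    def test_many_to_many_removed(self):
        m = pd.DataFrame(
            {"feature_a": ["a", "b", "c"], "feature_b": ["x", "x", "y"]}
        )
        out = prog.one_to_one_homologs(m)
        assert out.to_dict("records") == [{"feature_a": "c", "feature_b": "y"}]

    def test_clean_bijection_unchanged(self):
        m = pd.DataFrame(
            {"feature_a": ["a", "b"], "feature_b": ["x", "y"]}
        )
        pd.testing.assert_frame_equal(prog.one_to_one_homologs(m), m)

    def test_empty_result_allowed(self):
        m = pd.DataFrame(
            {"feature_a": ["a", "a"], "feature_b": ["x", "y"]}
        )
        assert prog.one_to_one_homologs(m).empty


class TestCrossSpecies:
    def _calls(self, genes, designations, coefs):
        return pd.DataFrame(
            {"designation": designations, "coef_full": coefs}, index=genes
        )

    def test_mismatched_designation_excluded(self):
        a = self._calls(["a1"], ["early"], [1.0])
        b = self._calls(["b1"], ["late"], [1.0])
        hom = pd.DataFrame({"feature_a": ["a1"], "feature_b": ["b1"]})
        sets = prog.cross_species_sets(a, b, hom)
        assert sets["early"].empty and sets["late"].empty

    def test_sign_mismatch_excluded(self):
        a = self._calls(["a1"], ["early"], [1.0])
        b = self._calls(["b1"], ["early"], [-1.0])
        hom = pd.DataFrame({"feature_a": ["a1"], "feature_b": ["b1"]})
        assert prog.cross_species_sets(a, b, hom)["early"].empty

    def test_concordant_pair_conserved(self):
        a = self._calls(["a1", "a2"], ["early", "none"], [1.0, 0.5])
        b = self._calls(["b1", "b2"], ["early", "early"], [2.0, 0.5])
        hom = pd.DataFrame(
            {"feature_a": ["a1", "a2"], "feature_b": ["b1", "b2"]}
        )
        out = prog.cross_species_sets(a, b, hom)["early"]
        assert out["feature_a"].tolist() == ["a1"]


def bf_numerical_oracle(table):
    """Bayes factor by direct numerical integration of both marginal
    likelihoods (association: Dirichlet(1,1,1,1) over the 3-simplex;
    independence: product of two Beta(1,1) margins)."""
    n11, n12 = table[0]
    n21, n22 = table[1]
    n = n11 + n12 + n21 + n22

    def assoc_integrand(p3, p2, p1):
        p4 = 1.0 - p1 - p2 - p3
        if p4 <= 0:
            return 0.0
        return (
            math.gamma(4.0)
            * p1 ** n11 * p2 ** n12 * p3 ** n21 * p4 ** n22
        )

    m1, _ = integrate.tplquad(
        assoc_integrand,
        0, 1,
        lambda p1: 0, lambda p1: 1 - p1,
        lambda p1, p2: 0, lambda p1, p2: 1 - p1 - p2,
    )

    def indep_integrand(c, r):
        return (
            (r * c) ** n11
            * (r * (1 - c)) ** n12
            * ((1 - r) * c) ** n21
            * ((1 - r) * (1 - c)) ** n22
        )

    m0, _ = integrate.dblquad(indep_integrand, 0, 1, 0, 1)
    return m1 / m0


class TestGatherOverrepresentation:
    def test_bayes_factor_matches_numerical_integration(self):
        for table in ([[3, 1], [1, 4]], [[2, 2], [2, 2]], [[5, 0], [0, 4]]):
            closed = prog.dirichlet_2x2_bayes_factor(np.array(table))
            numeric = bf_numerical_oracle(table)
            assert closed == pytest.approx(numeric, rel=1e-4)

    def test_independent_table_bf_below_one(self):
        # overlap exactly at chance level in a balanced table
        assert prog.dirichlet_2x2_bayes_factor(np.array([[4, 4], [4, 4]])) < 1.0

    def test_fisher_matches_hypergeometric_enumeration(self, rng):
        universe = {f"g{i}" for i in range(20)}
        gene_set = set(rng.choice(sorted(universe), size=7, replace=False))
        targets = set(rng.choice(sorted(universe), size=8, replace=False))
        out = prog.gather_style_overrepresentation(
            gene_set, {"m": targets}, universe
        )
        k_obs = len(gene_set & targets)
        N, K, n = len(universe), len(targets), len(gene_set)
        tail = sum(
            math.comb(K, k) * math.comb(N - K, n - k) / math.comb(N, n)
            for k in range(k_obs, min(K, n) + 1)
        )
        assert out.loc["m", "p"] == pytest.approx(tail, rel=1e-10)

    def test_empty_target_set_nan_sentinel(self):
        out = prog.gather_style_overrepresentation(
            {"a"}, {"m": set()}, {"a", "b"}
        )
        assert np.isnan(out.loc["m", "p"])

    def test_degenerate_table_flagged(self):
        universe = {"a", "b"}
        out = prog.gather_style_overrepresentation(
            universe, {"m": universe}, universe
        )
        assert out.loc["m", "degenerate"]

    def test_gene_set_outside_universe_rejected(self):
        with pytest.raises(ValueError):
            prog.gather_style_overrepresentation({"z"}, {"m": {"a"}}, {"a"})


class TestFitProgressionModels:
    def test_planted_early_gene_designated(self, rng):
        n_sub = 6
        stage = np.tile(["NS", "AK", "SCC"], n_sub)
        subject = np.repeat([f"S{i}" for i in range(n_sub)], 3)
        genes = {}
        y_early, *_ = simulate_gene(rng, n_sub=n_sub, effects=(1.5, 0.0),
                                    noise=0.2)
        genes["early_gene"] = y_early
        y_null, *_ = simulate_gene(rng, n_sub=n_sub, effects=(0.0, 0.0),
                                   noise=0.2)
        genes["null_gene"] = y_null
        mat = pd.DataFrame(genes, index=[f"{s}_{i}" for i, s in enumerate(stage)]).T
        meta = pd.DataFrame(
            {
                "stage": stage,
                "subject": subject,
                "batch": "b0",
                "species": "human",
            },
            index=mat.columns,
        )
        calls = prog.fit_progression_models(mat, meta, ("NS", "AK", "SCC"))
        calls["designation"] = prog.classify_progression(calls)
        assert calls.loc["early_gene", "designation"] == "early"
        # paired fold change tracks the planted 1.5-log2 early shift
        assert calls.loc["early_gene", "fc_early"] == pytest.approx(
            2 ** 1.5, rel=0.3
        )

    def test_requires_complete_sets(self, rng):
        mat = pd.DataFrame(rng.normal(size=(3, 6)),
                           index=["g0", "g1", "g2"],
                           columns=[f"s{j}" for j in range(6)])
        meta = pd.DataFrame(
            {
                "stage": ["NS", "AK", "SCC", "NS", "AK", "NS"],
                "subject": ["a", "a", "a", "b", "b", "c"],
                "batch": "b0",
                "species": "human",
            },
            index=mat.columns,
        )
        with pytest.raises(ValueError, match="complete"):
            prog.fit_progression_models(mat, meta, ("NS", "AK", "SCC"))
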