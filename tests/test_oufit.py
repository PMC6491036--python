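"""Hansen model machinery: weights, covariance, likelihood, fitting, ICs."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import multivariate_normal

from phylofoot.oufit import (
    HansenDesign,
    OUParams,
    build_hypotheses,
    compare_models,
    fit_bm,
    fit_hansen,
    hansen_loglik,
    information_criteria,
    ou_vcv,
    ou_weight_matrix,
    refit_noiseless,
)
from phylofoot.synthetic import make_tree, simulate_traits
from phylofoot.tree import paint_regimes


def brute_force_mean_cov(tree, painting, alpha, sigma_sq, theta_by_regime, root):
    """Independent construction of the Hansen mean and covariance.

    Mean by explicit per-segment integration of the OU expectation down
    each root-to-tip path; covariance from the closed-form fixed-root OU
    using recursively computed depths.  Shares no code with HansenDesign.
    """
    tips = tree.tip_indices
    depths = tree.depths
    n = len(tips)
    mean = np.zeros(n)
    for i, t in enumerate(tips):
        path = [t] + [a for a in tree.ancestors(t) if a != 0]
        path = path[::-1]  # root-adjacent first
        m = root
        for node in path:
            t0, t1 = depths[tree.parent(node)], depths[node]
            dt = t1 - t0
            th = theta_by_regime[painting.edge_regime[node]]
            if alpha == 0:
                pass
            else:
                e = np.exp(-alpha * dt)
                m = m * e + th * (1 - e)
        mean[i] = m
    cov = np.zeros((n, n))
    for a in range(n):
        for b in range(n):
            anc_a = set([tips[a]] + tree.ancestors(tips[a]))
            anc_b = set([tips[b]] + tree.ancestors(tips[b]))
            s = max(depths[j] for j in anc_a & anc_b)
            d = depths[tips[a]] + depths[tips[b]] - 2 * s
            if alpha == 0:
                cov[a, b] = sigma_sq * s
            else:
                cov[a, b] = (
                    sigma_sq
                    / (2 * alpha)
                    * np.exp(-alpha * d)
                    * (1 - np.exp(-2 * alpha * s))
                )
    return mean, cov


def random_two_regime(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(3, 7))
    tree = make_tree(n, "birth-death", seed=seed)
    tip = tree.tip_labels[int(rng.integers(n))]
    painting = paint_regimes(tree, [({tip}, "a")], background="b")
    alpha = float(rng.uniform(0.05, 3.0))
    sigma_sq = float(rng.uniform(0.2, 2.0))
    theta = {r: float(rng.normal(0, 2)) for r in painting.regimes}
    return tree, painting, alpha, sigma_sq, theta


class TestWeights:
    def test_rows_sum_to_one(self, fixture_tree, study):
        painting = study.paintings["H4"]
        for alpha in (0.01, 0.5, 5.0):
            W = ou_weight_matrix(fixture_tree, painting, alpha)
            assert np.allclose(W.sum(axis=1), 1.0, atol=1e-10)

    def test_hand_integrated_segments(self, tree3):
        painting = paint_regimes(tree3, [({"A", "B"}, "x")], background="bg")
        W = ou_weight_matrix(tree3, painting, 1.0)
        k_x = painting.regimes.index("x")
        k_bg = painting.regimes.index("bg")
        # tip A sits in regime x for its whole 2-Myr path
        assert W[0, k_x] == pytest.approx(1 - np.exp(-2))
        assert W[0, k_bg] == pytest.approx(np.exp(-2))
        # tip C never leaves the background
        assert W[2, k_bg] == pytest.approx(1.0)

    def test_strong_selection_indicator(self, tree3):
        painting = paint_regimes(tree3, [({"A", "B"}, "x")], background="bg")
        W = ou_weight_matrix(tree3, painting, 100.0)
        k_x = painting.regimes.index("x")
        assert W[0, k_x] == pytest.approx(1.0, abs=1e-12)

    def test_alpha_zero_root_indicator(self, tree3):
        painting = paint_regimes(tree3, [({"A", "B"}, "x")], background="bg")
        W = ou_weight_matrix(tree3, painting, 0.0)
        k_bg = painting.regimes.index("bg")
        assert np.allclose(W[:, k_bg], 1.0)


class TestOuVcv:
    def test_bm_limit(self, bd20):
        from phylofoot.tree import vcv_bm

        assert np.allclose(ou_vcv(bd20, 0.0, 2.0), 2.0 * vcv_bm(bd20))
        rel = np.abs(ou_vcv(bd20, 1e-8, 1.0) - vcv_bm(bd20)) / np.abs(
            vcv_bm(bd20) + 1e-12
        )
        assert np.nanmax(rel[vcv_bm(bd20) > 0]) < 1e-6

    def test_two_tip_closed_form(self):
        from phylofoot.tree import read_newick

        t = read_newick("((A:1,B:1):1,C:2);")
        V = ou_vcv(t, 1.0, 2.0)
        assert V[0, 1] == pytest.approx(np.exp(-2) * (1 - np.exp(-2)))

    def test_strong_selection_stationary_diagonal(self, bd20):
        V = ou_vcv(bd20, 40.0, 2.0)
        assert np.allclose(np.diag(V), 2.0 / 80.0, rtol=1e-6)
        off = V - np.diag(np.diag(V))
        assert np.abs(off).max() < 1e-3 * V[0, 0]


class TestLoglik:
    @pytest.mark.parametrize("seed", range(25))
    def test_matches_brute_force_oracle(self, seed):
        tree, painting, alpha, sigma_sq, theta = random_two_regime(seed)
        root = theta[painting.root_regime]
        mean, cov = brute_force_mean_cov(
            tree, painting, alpha, sigma_sq, theta, root
        )
        rng = np.random.default_rng(seed + 999)
        y = mean + np.linalg.cholesky(cov) @ rng.standard_normal(len(mean))
        params = OUParams(
            [alpha], [sigma_sq],
            np.array([[theta[r]] for r in painting.regimes]),
            painting.regimes, painting.root_regime,
        )
        yd = pd.DataFrame({"trait1": y}, index=tree.tip_labels)
        mine = hansen_loglik(yd, tree, painting, params)
        oracle = multivariate_normal(mean, cov, allow_singular=False).logpdf(y)
        assert mine == pytest.approx(oracle, abs=1e-8)

    def test_alpha_zero_reduces_to_bm(self, bd20):
        rng = np.random.default_rng(0)
        y = pd.DataFrame(
            {"trait1": rng.standard_normal(20)}, index=bd20.tip_labels
        )
        painting = paint_regimes(bd20, [], background="g")
        mu = 0.3
        params = OUParams([0.0], [1.3], [[mu]], ["g"], "g")
        from phylofoot.tree import vcv_bm

        ll = hansen_loglik(y, bd20, painting, params)
        oracle = multivariate_normal(
            np.full(20, mu), 1.3 * vcv_bm(bd20)
        ).logpdf(y["trait1"])
        assert ll == pytest.approx(oracle, abs=1e-8)

    def test_translation_invariance(self, bd20):
        tree, painting, alpha, sigma_sq, theta = random_two_regime(4)
        params = OUParams(
            [alpha], [sigma_sq],
            np.array([[theta[r]] for r in painting.regimes]),
            painting.regimes, painting.root_regime,
        )
        y = simulate_traits(tree, painting, params, seed=1)
        c = 17.3
        params_shift = OUParams(
            [alpha], [sigma_sq],
            np.array([[theta[r] + c] for r in painting.regimes]),
            painting.regimes, painting.root_regime,
        )
        assert hansen_loglik(y + c, tree, painting, params_shift) == pytest.approx(
            hansen_loglik(y, tree, painting, params), abs=1e-9
        )

    def test_taxa_order_invariance(self, bd20):
        painting = paint_regimes(bd20, [], background="g")
        params = OUParams([0.5], [1.0], [[0.0]], ["g"], "g")
        y = simulate_traits(bd20, painting, params, seed=2)
        shuffled = y.sample(frac=1.0, random_state=0)
        assert hansen_loglik(shuffled, bd20, painting, params) == pytest.approx(
            hansen_loglik(y, bd20, painting, params), abs=1e-10
        )


class TestFit:
    def test_noiseless_recovery(self, bd20):
        painting = paint_regimes(
            bd20, [(bd20.clade_tips(bd20.children(0)[0]), "s")], background="b"
        )
        K = painting.regimes
        th = np.array([[0.0 if r == "b" else 3.0] for r in K])
        params = OUParams([1.5], [0.8], th, K, painting.root_regime)
        y = simulate_traits(bd20, painting, params, seed=3)
        fit = fit_hansen(y, bd20, painting, "OU2")
        fit2 = refit_noiseless(fit, bd20)
        assert np.allclose(fit2.params.theta, fit.params.theta, atol=1e-4)

    def test_nesting_loglik_ordering(self, study_pc_means, fixture_tree, study):
        fb = fit_bm(study_pc_means, fixture_tree)
        f1 = fit_hansen(study_pc_means, fixture_tree, study.paintings["H2"], "H2")
        f4 = fit_hansen(study_pc_means, fixture_tree, study.paintings["H4"], "H4")
        assert f1.logL >= fb.logL - 1e-6
        assert f4.logL >= f1.logL - 1e-6

    def test_information_criteria_formulas(self):
        crit = information_criteria(-100.0, 5, 45)
        assert crit["AIC"] == pytest.approx(210.0)
        assert crit["AICc"] == pytest.approx(210.0 + 2 * 5 * 6 / 39)
        assert crit["SIC"] == pytest.approx(200.0 + 5 * np.log(45))

    def test_aicc_approaches_aic_large_n(self):
        for p in (2, 10, 20):
            crit = information_criteria(-50.0, p, 10**7)
            assert abs(crit["AICc"] - crit["AIC"]) < 1e-4


class TestCompare:
    def test_penalty_ordering_on_equal_loglik(self, study_pc_means):
        a = fit_bm(study_pc_means, make_tree(45, "packaged"))
        rows = [a.summary_row(), a.summary_row()]
        # construct directly: equal logL, different p
        import dataclasses

        b = dataclasses.replace(a, label="rich", n_params=a.n_params + 2)
        crit = information_criteria(b.logL, b.n_params, b.n_taxa)
        b = dataclasses.replace(
            b, AIC=crit["AIC"], AICc=crit["AICc"], SIC=crit["SIC"]
        )
        tab = compare_models([b, a])
        assert tab.iloc[0]["model"] == a.label
        assert tab.iloc[0]["dAICc"] == 0.0

    def test_mismatched_data_rejected(self, fixture_tree, study_pc_means):
        a = fit_bm(study_pc_means, fixture_tree)
        b = fit_bm(study_pc_means + 1.0, fixture_tree)
        with pytest.raises(ValueError, match="different data"):
            compare_models([a, b])


class TestHypotheses:
    def test_regime_counts(self, fixture_tree):
        hyps = dict(build_hypotheses(fixture_tree))
        assert hyps["H1"] is None
        assert hyps["H2"].n_regimes == 1
        assert hyps["H3"].n_regimes == 3
        assert hyps["H4"].n_regimes == 4
        assert hyps["H5"].n_regimes == 5
        assert hyps["H6"].n_regimes == 6

    def test_fossil_regime_default_african_ape(self, fixture_tree):
        hyps = dict(build_hypotheses(fixture_tree))
        fossil_edge = fixture_tree.tip_index("Ardipithecus_ramidus")
        assert hyps["H3"].edge_regime[fossil_edge] == "terrestrial"
        assert hyps["H4"].edge_regime[fossil_edge] == "plantigrade"
        homo_edge = fixture_tree.tip_index("Homo_sapiens")
        assert hyps["H4"].edge_regime[homo_edge] == "bipedal"

    def test_fossil_regime_bipedal_option(self, fixture_tree):
        hyps = dict(build_hypotheses(fixture_tree, fossil_regime="bipedal"))
        fossil_edge = fixture_tree.tip_index("Ardipithecus_ramidus")
        assert hyps["H4"].edge_regime[fossil_edge] == "bipedal"

    def test_works_without_fossil(self):
        from phylofoot.synthetic import packaged_tree

        t = packaged_tree(with_fossil=False)
        hyps = dict(build_hypotheses(t, fossil=None))
        assert hyps["H6"].n_regimes == 6

    def test_missing_genus_rejected(self, bd20):
        with pytest.raises(KeyError):
            build_hypotheses(bd20, fossil=None)


class TestRecoverySmall:
    def test_ou2_selected_over_bm_and_ou1(self, fixture_tree):
        homininae = {
            t
            for t in fixture_tree.tip_labels
            if t.split("_")[0] in ("Pan", "Gorilla", "Homo", "Ardipithecus")
        }
        pp = paint_regimes(fixture_tree, [(homininae, "shift")], background="base")
        th = np.array(
            [[3.0 if r == "shift" else 0.0] for r in pp.regimes]
        )
        params = OUParams([2.0], [1.0], th, pp.regimes, pp.root_regime)
        ou1 = paint_regimes(fixture_tree, [], background="g")
        wins = 0
        errs = []
        for r in range(20):
            y = simulate_traits(fixture_tree, pp, params, seed=700 + r)
            fits = [
                fit_bm(y, fixture_tree),
                fit_hansen(y, fixture_tree, ou1, "OU1"),
                fit_hansen(y, fixture_tree, pp, "OU2"),
            ]
            tab = compare_models(fits)
            wins += tab.iloc[0]["model"] == "OU2"
            est = dict(zip(fits[2].params.regimes, fits[2].params.theta[:, 0]))
            errs.append(abs(est["shift"] - 3.0))
        assert wins >= 18
        assert np.median(errs) < 0.3
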