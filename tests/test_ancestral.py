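"""Ancestral states: Brownian closed form, stable MCMC, PSRF, BPIC."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import levy_stable

from phylofoot._stable import StableDensity
from phylofoot.ancestral import (
    bm_ancestral,
    bpic_compare,
    phylomorphospace,
    psrf,
    stable_mcmc,
)
from phylofoot.tree import read_newick


class TestStableDensity:
    @pytest.mark.parametrize("index", [1.1, 1.3, 1.5, 1.8, 1.95])
    def test_matches_scipy_levy_stable(self, index):
        d = StableDensity(index)
        ref = levy_stable(alpha=index, beta=0)
        body = np.linspace(0, 5, 21)
        assert np.abs(d.logpdf(body) - ref.logpdf(body)).max() < 1e-3
        tail = np.array([8.0, 20.0, 60.0, 120.0])
        assert np.abs(d.logpdf(tail) - ref.logpdf(tail)).max() < 0.05

    def test_gaussian_boundary_exact(self):
        d = StableDensity(2.0)
        x = np.linspace(-6, 6, 41)
        expect = -(x**2) / 4.0 - 0.5 * np.log(4 * np.pi)
        assert np.allclose(d.logpdf(x), expect)

    def test_scaled_density_normalisation(self):
        d = StableDensity(1.6)
        # numeric integral of pdf over a wide window is close to 1
        x = np.linspace(-200, 200, 200001)
        p = np.exp(d.logpdf(x))
        assert np.trapezoid(p, x) == pytest.approx(1.0, abs=5e-3)


class TestBmAncestral:
    def test_star_root_is_tip_mean(self, star8):
        y = pd.DataFrame(
            {"trait1": np.arange(8, dtype=float)}, index=star8.tip_labels
        )
        est = bm_ancestral(y, star8)
        assert est.table.loc[0, ("trait1", "median")] == pytest.approx(3.5)

    def test_two_tip_weighted_mean(self):
        t = read_newick("(A:2,B:0.5);")
        ya, yb = 1.0, 3.0
        y = pd.DataFrame({"trait1": [ya, yb]}, index=t.tip_labels)
        est = bm_ancestral(y, t)
        expect = (ya / 2 + yb / 0.5) / (1 / 2 + 1 / 0.5)
        assert est.table.loc[0, ("trait1", "median")] == pytest.approx(expect)

    def test_constant_traits_zero_width(self, balanced8):
        y = pd.DataFrame(
            {"trait1": np.full(8, 2.5)}, index=balanced8.tip_labels
        )
        est = bm_ancestral(y, balanced8)
        med = est.table.xs("median", axis=1, level=1)
        lo = est.table.xs("lower", axis=1, level=1)
        hi = est.table.xs("upper", axis=1, level=1)
        assert np.allclose(med, 2.5)
        assert np.allclose(hi - lo, 0.0, atol=1e-8)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_joint_gaussian_bruteforce(self, seed):
        """Conditional mean of internals given tips, full joint solve."""
        from phylofoot.synthetic import make_tree

        tree = make_tree(5, "birth-death", seed=seed)
        rng = np.random.default_rng(seed)
        y = pd.DataFrame(
            {"trait1": rng.standard_normal(5)}, index=tree.tip_labels
        )
        est = bm_ancestral(y, tree)

        tips, internals = tree.tip_indices, tree.internal_indices
        depths = tree.depths
        anc = {i: {i} | set(tree.ancestors(i)) for i in range(tree.n_nodes)}

        def mrca_d(u, v):
            return max(depths[j] for j in anc[u] & anc[v])

        C_tt = np.array([[mrca_d(a, b) for b in tips] for a in tips])
        C_nt = np.array([[mrca_d(u, b) for b in tips] for u in internals])
        Ci = np.linalg.inv(C_tt)
        ones = np.ones(len(tips))
        yv = y["trait1"].to_numpy()
        mu = ones @ Ci @ yv / (ones @ Ci @ ones)
        expect = mu + C_nt @ Ci @ (yv - mu)
        got = est.table[("trait1", "median")].loc[internals].to_numpy()
        assert np.abs(got - expect).max() < 1e-8


class TestPsrf:
    def test_identical_chains_exactly_one(self):
        x = np.sin(np.arange(200.0))
        assert psrf([x, x.copy()]) == 1.0

    def test_disjoint_chains_much_greater(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 1, 500)
        b = rng.normal(100, 1, 500)
        assert psrf([a, b]) > 1.1 * 10

    def test_iid_same_distribution_near_one(self):
        rng = np.random.default_rng(1)
        chains = [rng.standard_normal(10_000) for _ in range(2)]
        assert 1.0 <= psrf(chains) <= 1.05

    def test_single_chain_rejected(self):
        with pytest.raises(ValueError):
            psrf([np.arange(100.0)])


@pytest.fixture(scope="module")
def star_run(star8):
    rng = np.random.default_rng(0)
    y = pd.DataFrame({"trait1": rng.normal(0, 1, 8)}, index=star8.tip_labels)
    bm = bm_ancestral(y, star8)
    run, est = stable_mcmc(
        y, star8, iterations=20_000, thinning=20, burn_in=6_000,
        seed=1, fixed_index=2.0,
    )
    return y, bm, run, est


class TestStableMcmc:
    def test_gaussian_limit_matches_bm_root(self, star_run):
        y, bm, run, est = star_run
        x = run.kept("trait1", "x")[:, :, 0].ravel()
        # Monte-Carlo s.e. with a conservative autocorrelation inflation
        mc_se = 3.0 * x.std() / np.sqrt(len(x) / 10)
        assert abs(
            est.table.loc[0, ("trait1", "median")]
            - bm.table.loc[0, ("trait1", "median")]
        ) <= 3 * mc_se

    def test_converged_at_test_scale(self, star_run):
        _, _, run, _ = star_run
        assert run.max_psrf < 1.1
        assert run.converged

    def test_sample_bookkeeping(self, star_run):
        _, _, run, _ = star_run
        x = run.samples["trait1"]["x"]
        assert x.shape[:2] == (2, 20_000 // 20)

    def test_identical_seeds_psrf_one(self, star8):
        rng = np.random.default_rng(2)
        y = pd.DataFrame({"trait1": rng.normal(0, 1, 8)}, index=star8.tip_labels)
        run, _ = stable_mcmc(
            y, star8, iterations=2_000, thinning=10, burn_in=500,
            seed=[7, 7], fixed_index=2.0,
        )
        assert run.max_psrf == 1.0

    def test_outlier_attenuation(self, balanced8):
        vals = {"A": 0.1, "B": -0.1, "C": 0.05, "D": -0.05,
                "E": 0.1, "F": 0.0, "G": -0.1, "H": 8.0}
        y = pd.DataFrame(
            {"trait1": [vals[l] for l in balanced8.tip_labels]},
            index=balanced8.tip_labels,
        )
        bm = bm_ancestral(y, balanced8)
        run, est = stable_mcmc(
            y, balanced8, iterations=30_000, thinning=20, burn_in=10_000, seed=3
        )
        bm_root = bm.table.loc[0, ("trait1", "median")]
        st_root = est.table.loc[0, ("trait1", "median")]
        assert bm_root > 0.5  # dragged toward the outlier lineage
        assert abs(st_root) < abs(bm_root) / 2  # heavy tails attenuate it

    def test_shift_equivariance(self, star8):
        rng = np.random.default_rng(4)
        y = pd.DataFrame({"trait1": rng.normal(0, 1, 8)}, index=star8.tip_labels)
        kw = dict(iterations=10_000, thinning=10, burn_in=3_000,
                  seed=5, fixed_index=2.0)
        _, est0 = stable_mcmc(y, star8, **kw)
        _, est1 = stable_mcmc(y + 10.0, star8, **kw)
        d = (
            est1.table.xs("median", axis=1, level=1)
            - est0.table.xs("median", axis=1, level=1)
        )
        assert np.abs(d.to_numpy() - 10.0).max() < 0.15

    def test_iteration_precondition(self, star8):
        y = pd.DataFrame({"trait1": np.arange(8.0)}, index=star8.tip_labels)
        with pytest.raises(ValueError):
            stable_mcmc(y, star8, iterations=50, thinning=10, burn_in=10)


class TestBpic:
    def test_identical_runs_tie(self, star8):
        rng = np.random.default_rng(6)
        y = pd.DataFrame({"trait1": rng.normal(0, 1, 8)}, index=star8.tip_labels)
        kw = dict(iterations=5_000, thinning=10, burn_in=1_500, seed=8,
                  fixed_index=2.0)
        run_a, _ = stable_mcmc(y, star8, **kw)
        run_b, _ = stable_mcmc(y, star8, **kw)
        diff, label = bpic_compare(run_a, run_b)
        assert diff == pytest.approx(0.0, abs=1e-9)
        assert label == "tie"

    def test_jump_data_prefers_stable(self, balanced8):
        wins = 0
        reps = 5
        for r in range(reps):
            rng = np.random.default_rng(50 + r)
            vals = 0.2 * rng.standard_normal(8)
            vals[-1] += 10.0  # one lineage with an extreme jump
            y = pd.DataFrame({"trait1": vals}, index=balanced8.tip_labels)
            kw = dict(iterations=12_000, thinning=10, burn_in=4_000, seed=r)
            run_bm, _ = stable_mcmc(y, balanced8, fixed_index=2.0, **kw)
            run_st, _ = stable_mcmc(y, balanced8, **kw)
            diff, label = bpic_compare(run_bm, run_st)
            wins += label == "stable"
        assert wins > reps / 2

    def test_bm_data_prefers_bm_or_tie(self, balanced8):
        ok = 0
        reps = 5
        for r in range(reps):
            rng = np.random.default_rng(70 + r)
            y = pd.DataFrame(
                {"trait1": rng.standard_normal(8)}, index=balanced8.tip_labels
            )
            kw = dict(iterations=12_000, thinning=10, burn_in=4_000, seed=r)
            run_bm, _ = stable_mcmc(y, balanced8, fixed_index=2.0, **kw)
            run_st, _ = stable_mcmc(y, balanced8, **kw)
            _, label = bpic_compare(run_bm, run_st)
            ok += label in ("BM", "tie")
        assert ok > reps / 2


class TestPhylomorphospace:
    def test_counts_on_three_tip_tree(self, tree3):
        y = pd.DataFrame(
            {"PC1": [0.0, 1.0, 2.0], "PC2": [1.0, 0.0, -1.0]},
            index=tree3.tip_labels,
        )
        est = bm_ancestral(y, tree3)
        space = phylomorphospace(tree3, y, est, focal_node=0)
        assert len(space["nodes"]) == 2
        assert len(space["tips"]) == 3
        assert len(space["edges"]) == 4

    def test_tip_coordinates_passthrough(self, tree3):
        y = pd.DataFrame(
            {"PC1": [0.2, 1.1, 2.5], "PC2": [0.4, -0.3, 0.9]},
            index=tree3.tip_labels,
        )
        est = bm_ancestral(y, tree3)
        space = phylomorphospace(tree3, y, est, focal_node=0)
        assert (space["tips"].loc[tree3.tip_labels, "PC1"] == y["PC1"]).all()

    def test_missing_focal_rejected(self, tree3):
        y = pd.DataFrame(
            {"PC1": [0.0, 1.0, 2.0], "PC2": [0.0, 1.0, 2.0]},
            index=tree3.tip_labels,
        )
        est = bm_ancestral(y, tree3)
        with pytest.raises(KeyError):
            phylomorphospace(tree3, y, est, focal_node=999)

    def test_focal_box_bounds_ordered(self, study_pc_means, fixture_tree):
        est = bm_ancestral(study_pc_means[["PC1", "PC2"]], fixture_tree)
        focal = fixture_tree.mrca(["Homo_sapiens", "Pan_troglodytes"])
        space = phylomorphospace(
            fixture_tree, study_pc_means[["PC1", "PC2"]], est, focal
        )
        for lo, hi in space["focal_box"].values():
            assert lo <= hi
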