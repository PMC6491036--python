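"""Standardization, PCA, species means, UPGMA with cophenetic validation."""

import itertools

import numpy as np
import pandas as pd
import pytest

from phylofoot.morphometrics import (
    SHAPE_COLUMNS,
    derive_talar_neck,
    geomean_standardize,
    pca,
    species_means,
    upgma_cophenetic,
)


def shape_table(X, taxa=None):
    df = pd.DataFrame(np.asarray(X, float), columns=SHAPE_COLUMNS)
    df.insert(0, "taxon", taxa if taxa is not None else [f"t{i}" for i in range(len(df))])
    return df


class TestTalarNeck:
    def test_simple_subtraction(self):
        assert derive_talar_neck(50, 30) == 20

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError):
            derive_talar_neck(30, 30)

    def test_batch_matches_vector_subtraction(self):
        rng = np.random.default_rng(0)
        troch = rng.uniform(10, 30, 50)
        art = troch + rng.uniform(1, 20, 50)
        assert np.allclose(derive_talar_neck(art, troch), art - troch)


class TestStandardize:
    def test_hand_computed_row(self):
        row = shape_table([[1, 2, 4, 8, 16, 32]])
        out = geomean_standardize(row)
        gm = 2 ** 2.5
        assert out["geomean"].iloc[0] == pytest.approx(gm)
        assert out[SHAPE_COLUMNS].iloc[0, 0] == pytest.approx(1 / gm)
        assert out[SHAPE_COLUMNS].iloc[0, 0] == pytest.approx(0.1768, abs=1e-4)

    def test_constant_row_all_ones(self):
        out = geomean_standardize(shape_table([[7] * 6]))
        assert np.allclose(out[SHAPE_COLUMNS], 1.0)

    def test_scale_invariance(self):
        base = np.array([[12.0, 5.0, 20.0, 31.0, 28.0, 22.0]])
        a = geomean_standardize(shape_table(base))
        b = geomean_standardize(shape_table(base * 3.0))
        assert np.allclose(a[SHAPE_COLUMNS], b[SHAPE_COLUMNS])

    def test_row_products_equal_one(self, study):
        out = geomean_standardize(study.measurements)
        assert np.allclose(out[SHAPE_COLUMNS].prod(axis=1), 1.0, atol=1e-10)

    def test_idempotence(self, study):
        once = geomean_standardize(study.measurements)
        twice = geomean_standardize(once[["taxon"] + SHAPE_COLUMNS])
        assert np.allclose(once[SHAPE_COLUMNS], twice[SHAPE_COLUMNS], atol=1e-12)

    def test_nonpositive_value_names_row(self):
        bad = shape_table([[1, 2, 3, 4, 5, 6], [1, -2, 3, 4, 5, 6]])
        with pytest.raises(ValueError, match="1"):
            geomean_standardize(bad)

    def test_raw_table_derives_neck(self):
        raw = pd.DataFrame(
            {
                "taxon": ["a"],
                "max_talar_articular": [50.0],
                "talar_trochlea": [30.0],
                "cuboid": [20.0],
                "mt1": [40.0],
                "mt5": [45.0],
                "pp4": [25.0],
            }
        )
        out = geomean_standardize(raw)
        vals = np.array([30, 20, 20, 40, 45, 25], float)
        gm = np.exp(np.log(vals).mean())
        assert np.allclose(out[SHAPE_COLUMNS].iloc[0], vals / gm)


class TestPCA:
    def test_rank_one_data(self):
        X = np.ones((10, 6))
        X[:, 3] = np.linspace(1, 2, 10)
        res = pca(shape_table(X))
        assert res.percent_variance[0] == pytest.approx(100.0)

    def test_eigenvalues_match_svd_oracle(self):
        rng = np.random.default_rng(1)
        X = rng.lognormal(0, 0.2, (100, 6))
        res = pca(shape_table(X))
        Xc = X - X.mean(axis=0)
        s = np.linalg.svd(Xc, compute_uv=False)
        assert np.allclose(res.eigenvalues, s**2 / 99, atol=1e-10)
        assert res.percent_variance.sum() == pytest.approx(100.0, abs=1e-6)

    def test_loadings_orthonormal_and_sign_convention(self):
        rng = np.random.default_rng(2)
        res = pca(shape_table(rng.lognormal(0, 0.3, (60, 6))))
        L = res.loadings.to_numpy()
        assert np.allclose(L.T @ L, np.eye(6), atol=1e-8)
        for j in range(6):
            k = np.argmax(np.abs(L[:, j]))
            assert L[k, j] > 0

    def test_scores_covariance_diagonal(self):
        rng = np.random.default_rng(3)
        res = pca(shape_table(rng.lognormal(0, 0.3, (80, 6))))
        S = res.scores[[f"PC{i+1}" for i in range(6)]].to_numpy()
        C = np.cov(S.T)
        off = C - np.diag(np.diag(C))
        assert np.abs(off).max() < 1e-8
        assert np.allclose(np.diag(C), res.eigenvalues, atol=1e-8)

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError):
            pca(shape_table(np.ones((5, 6))))


class TestSpeciesMeans:
    def test_single_individual_passthrough(self):
        df = pd.DataFrame({"taxon": ["a", "b"], "PC1": [1.0, 2.0]})
        out = species_means(df)
        assert out.loc["a", "PC1"] == 1.0

    def test_two_individual_mean(self):
        df = pd.DataFrame({"taxon": ["a", "a"], "PC1": [1.0, 3.0]})
        assert species_means(df).loc["a", "PC1"] == 2.0

    def test_fixture_recovers_generator_means(self, study):
        from phylofoot.synthetic import expected_standardized_shape, log_mass_table

        std = geomean_standardize(study.measurements)
        means = species_means(std[["taxon"] + SHAPE_COLUMNS])
        lm = log_mass_table(study.tree, include_fossil=True)
        gen = expected_standardized_shape(study.species_log_shape, lm)
        diff = np.log(means.loc[gen.index, SHAPE_COLUMNS]) - np.log(gen)
        # lognormal noise sd 0.05 over 8 individuals -> se about 0.018
        assert np.abs(diff.to_numpy()).max() < 0.1


def upgma_oracle(D):
    """Exhaustive UPGMA agglomeration; lowest-index pair on ties."""
    clusters = {i: [i] for i in range(len(D))}
    D = {(i, j): D[i, j] for i in range(len(D)) for j in range(len(D)) if i < j}
    merges = []
    nxt = len(clusters)
    while len(clusters) > 1:
        (i, j), h = min(D.items(), key=lambda kv: (kv[1], kv[0]))
        merges.append((i, j, h, len(clusters[i]) + len(clusters[j])))
        clusters[nxt] = clusters[i] + clusters[j]
        ni, nj = len(clusters[i]), len(clusters[j])
        del clusters[i], clusters[j]
        newD = {}
        for (a, b), d in D.items():
            if {a, b} & {i, j}:
                continue
            newD[(a, b)] = d
        for k in clusters:
            if k == nxt:
                continue
            dik = D.get((min(i, k), max(i, k)))
            djk = D.get((min(j, k), max(j, k)))
            newD[(min(k, nxt), max(k, nxt))] = (ni * dik + nj * djk) / (ni + nj)
        D = newD
        nxt += 1
    return merges


class TestUPGMA:
    def test_hand_example_heights(self):
        pts = pd.DataFrame({"x": [0.0, 1.0, 5.0]}, index=["A", "B", "C"])
        res = upgma_cophenetic(pts)
        heights = sorted(res.linkage[:, 2])
        assert heights[0] == pytest.approx(1.0)
        assert heights[1] == pytest.approx(4.5)

    def test_equilateral_tie_flagged_degenerate(self):
        # three points at mutual distance 2
        pts = pd.DataFrame(
            {"x": [0.0, 2.0, 1.0], "y": [0.0, 0.0, np.sqrt(3)]},
            index=["A", "B", "C"],
        )
        res = upgma_cophenetic(pts)
        assert res.degenerate
        assert np.isnan(res.cophenetic_r)
        assert res.linkage[0, 2] == pytest.approx(2.0)

    def test_heights_nondecreasing_and_r_range(self, study):
        std = geomean_standardize(study.measurements)
        means = species_means(std[["taxon"] + SHAPE_COLUMNS])
        res = upgma_cophenetic(means)
        h = res.linkage[:, 2]
        assert np.all(np.diff(h) >= -1e-12)
        assert -1.0 <= res.cophenetic_r <= 1.0

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 7))
        X = rng.normal(0, 1, (n, 3))
        pts = pd.DataFrame(X, index=[f"t{i}" for i in range(n)])
        res = upgma_cophenetic(pts)
        from scipy.spatial.distance import squareform, pdist

        D = squareform(pdist(X))
        oracle = upgma_oracle(D)
        for row, (_, _, h, size) in zip(res.linkage, oracle):
            assert row[2] == pytest.approx(h)
            assert int(row[3]) == size

    def test_dendrogram_newick_roundtrip(self, study):
        std = geomean_standardize(study.measurements)
        means = species_means(std[["taxon"] + SHAPE_COLUMNS])
        res = upgma_cophenetic(means)
        from phylofoot.tree import read_newick

        t = read_newick(res.to_newick())
        assert set(t.tip_labels) == set(means.index)
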