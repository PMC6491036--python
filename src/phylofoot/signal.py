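"""Multivariate phylogenetic signal: the Kmult statistic.

Kmult generalises Blomberg's K to a species x traits matrix: the ratio
of the observed to the Brownian-expected ratio of mean squared error
around the phylogenetic mean (MSE0) to phylogenetically corrected mean
squared error (MSE), with traces taken across traits.  Expectation is
about 1 under Brownian motion; values well below 1 indicate less signal
than Brownian motion predicts.  Significance comes from permuting the
rows of the trait matrix across the tips.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, solve_triangular

from .tree import PhyloTree, vcv_bm

__all__ = ["SignalResult", "kmult"]


@dataclasses.dataclass
class SignalResult:
    K_mult: float
    p_value: float
    n_perm: int
    perm_K: np.ndarray

    def summary_row(self) -> dict:
        return {"K_mult": self.K_mult, "p": self.p_value, "n_perm": self.n_perm}


def _k_stat(Y: np.ndarray, L: np.ndarray, Cinv_sum, ones_t, trC, n) -> float:
    """K for one permutation; L is the Cholesky factor of C."""
    Yt = solve_triangular(L, Y, lower=True)
    a = (ones_t @ Yt) / (ones_t @ ones_t)  # phylogenetic mean per trait
    R = Y - a[None, :]
    Rt = Yt - np.outer(ones_t, a)
    mse0 = np.einsum("ij,ij->", R, R) / (n - 1)
    mse = np.einsum("ij,ij->", Rt, Rt) / (n - 1)
    expected = (trC - n / Cinv_sum) / (n - 1)
    return float((mse0 / mse) / expected)


def kmult(
    traits,
    tree: PhyloTree,
    n_perm: int = 999,
    seed: int | None = None,
) -> SignalResult:
    """Kmult with a permutation test of tip-trait association.

    ``traits``: taxon-indexed DataFrame or array in tip order, n x T.
    The p-value is (1 + #{perm K >= observed K}) / (n_perm + 1).
    """
    if n_perm < 99:
        raise ValueError("use at least 99 permutations")
    if isinstance(traits, pd.DataFrame):
        Y = traits.loc[tree.tip_labels].to_numpy(float)
    else:
        Y = np.asarray(traits, float)
        if Y.ndim == 1:
            Y = Y[:, None]
    n = tree.n_tips
    if Y.shape[0] != n:
        raise ValueError("trait rows must match tip count")
    if np.allclose(Y, Y[0]):
        raise ValueError("constant trait matrix: K undefined")

    C = vcv_bm(tree)
    c, low = cho_factor(C, lower=True)
    L = np.tril(c)
    ones = np.ones(n)
    ones_t = solve_triangular(L, ones, lower=True)
    Cinv_sum = float(ones @ cho_solve((c, low), ones))
    trC = float(np.trace(C))

    k_obs = _k_stat(Y, L, Cinv_sum, ones_t, trC, n)
    rng = np.random.default_rng(seed)
    perm = np.empty(n_perm)
    for i in range(n_perm):
        perm[i] = _k_stat(Y[rng.permutation(n)], L, Cinv_sum, ones_t, trC, n)
    p = (1.0 + np.sum(perm >= k_obs)) / (n_perm + 1.0)
    return SignalResult(k_obs, float(p), n_perm, perm)
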