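"""Hansen (multi-optima Ornstein-Uhlenbeck) model fitting on painted trees.

The model for one trait X along a lineage is the stochastic differential
equation dX(t) = alpha (theta - X(t)) dt + sigma dB(t), where theta is
the optimum of the selective regime the branch carries, alpha (1/Myr) the
strength of the restraining force, and sigma^2 (trait^2/Myr) the
diffusion.  Brownian motion is the alpha = 0 special case.  Traits
(typically PC1-PC3) are fitted as independent univariate processes
sharing one regime painting; their log-likelihoods are summed and their
parameter counts added, so alternative paintings remain comparable by
information criteria.

Conventions (documented because the literature varies):

* root state = optimum of the root regime (no separate root parameter);
* AICc/SIC sample size n = number of taxa;
* parameters per trait: alpha + sigma^2 + one theta per regime
  (Brownian motion: sigma^2 + root state, i.e. 2).
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, solve_triangular
from scipy.optimize import minimize_scalar

from .tree import PhyloTree, RegimePainting, mrca_depth_matrix

__all__ = [
    "OUParams",
    "OUFitResult",
    "HansenDesign",
    "ou_weight_matrix",
    "ou_vcv",
    "hansen_loglik",
    "fit_bm",
    "fit_hansen",
    "build_hypotheses",
    "compare_models",
    "information_criteria",
]

logger = logging.getLogger(__name__)

ALPHA_MIN = 1e-6
#: upper bound on the restraining force; avoids degenerate stationary fits
ALPHA_MAX = 50.0
_BM_ALPHA_EPS = 1e-12


@dataclasses.dataclass
class OUParams:
    """Per-trait OU parameters tied to one regime painting.

    ``theta`` is a (regimes x traits) array ordered like ``regimes``.
    Root convention: the ancestral state equals the root regime's theta.
    """

    alpha: np.ndarray  # (T,), 1/Myr, >= 0
    sigma_sq: np.ndarray  # (T,), trait^2/Myr, > 0
    theta: np.ndarray  # (K, T)
    regimes: list[str]
    root_regime: str

    def __post_init__(self):
        self.alpha = np.atleast_1d(np.asarray(self.alpha, float))
        self.sigma_sq = np.atleast_1d(np.asarray(self.sigma_sq, float))
        self.theta = np.atleast_2d(np.asarray(self.theta, float))
        if np.any(self.alpha < 0):
            raise ValueError("alpha must be >= 0")
        if np.any(self.sigma_sq <= 0):
            raise ValueError("sigma_sq must be > 0")
        if not np.all(np.isfinite(self.theta)):
            raise ValueError("theta must be finite")
        if self.theta.shape != (len(self.regimes), len(self.alpha)):
            raise ValueError("theta must be (n_regimes, n_traits)")
        if self.root_regime not in self.regimes:
            raise ValueError("root_regime missing from regimes")

    @property
    def n_traits(self) -> int:
        return len(self.alpha)

    def theta_table(self) -> pd.DataFrame:
        cols = [f"trait{j + 1}" for j in range(self.n_traits)]
        return pd.DataFrame(self.theta, index=self.regimes, columns=cols)


class HansenDesign:
    """Precomputed geometry of (tree, painting) for fast repeated fits.

    Stores the root-to-tip path incidence of every edge, the start/end
    depth of each edge, the shared-path (MRCA depth) matrix, and the
    regime indicator of each edge, so that the Hansen weight matrix and
    the OU correlation matrix are closed-form functions of alpha.
    """

    def __init__(self, tree: PhyloTree, painting: RegimePainting | None):
        self.tree = tree
        self.painting = painting
        tips = tree.tip_indices
        self.n = len(tips)
        self.tip_labels = tree.tip_labels
        depths = tree.depths
        self.T = depths[tips].astype(float)  # tip depths
        self.S = mrca_depth_matrix(tree)  # shared path time
        self.D = self.T[:, None] + self.T[None, :] - 2.0 * self.S

        edges = tree.edge_indices
        self.edges = edges
        e_start = np.array([depths[tree.parent(e)] for e in edges])
        e_end = np.array([depths[e] for e in edges])
        self.e_start, self.e_end = e_start, e_end
        # path incidence: P[i, b] True iff edge b lies on root->tip i path
        P = np.zeros((self.n, len(edges)), dtype=bool)
        epos = {e: b for b, e in enumerate(edges)}
        for i, t in enumerate(tips):
            j = t
            while j != 0:
                P[i, epos[j]] = True
                j = tree.parent(j)
        self.P = P

        if painting is None:
            self.regimes = ["root"]
            self.root_col = 0
            self.M = np.zeros((len(edges), 1))
        else:
            painting.validate(tree)
            self.regimes = painting.regimes
            rpos = {r: k for k, r in enumerate(self.regimes)}
            self.root_col = rpos[painting.root_regime]
            M = np.zeros((len(edges), len(self.regimes)))
            for b, e in enumerate(edges):
                M[b, rpos[painting.edge_regime[e]]] = 1.0
            self.M = M

    @property
    def n_regimes(self) -> int:
        return len(self.regimes)

    def weights(self, alpha: float) -> np.ndarray:
        """Tips x regimes matrix of exponentially discounted regime times.

        Entry (i, k) integrates alpha * exp(-alpha (T_i - t)) over the
        times t at which lineage i sat in regime k, plus the residual
        root weight exp(-alpha T_i) credited to the root regime (root
        state = root optimum).  Rows sum to 1 exactly (telescoping).
        At alpha = 0 the matrix degenerates to the root-regime indicator:
        the Brownian limit, where optima are unidentifiable.
        """
        if alpha < 0:
            raise ValueError("alpha must be >= 0")
        W = np.zeros((self.n, self.n_regimes))
        if alpha <= _BM_ALPHA_EPS:
            W[:, self.root_col] = 1.0
            return W
        Ti = self.T[:, None]
        seg = np.exp(-alpha * (Ti - self.e_end[None, :])) - np.exp(
            -alpha * (Ti - self.e_start[None, :])
        )
        seg = np.where(self.P, seg, 0.0)
        W = seg @ self.M
        W[:, self.root_col] += np.exp(-alpha * self.T)
        return W

    def corr(self, alpha: float) -> np.ndarray:
        """OU covariance for sigma^2 = 1, fixed-root convention.

        cov(i, j) = exp(-alpha d_ij) (1 - exp(-2 alpha s_ij)) / (2 alpha)
        with s_ij the shared path time and d_ij the patristic separation;
        the alpha -> 0 limit is the Brownian matrix s_ij.  Valid for
        non-contemporaneous (fossil) tips.
        """
        if alpha <= _BM_ALPHA_EPS:
            return self.S.copy()
        return np.exp(-alpha * self.D) * (-np.expm1(-2.0 * alpha * self.S)) / (
            2.0 * alpha
        )


def ou_weight_matrix(
    tree: PhyloTree, painting: RegimePainting, alpha: float
) -> np.ndarray:
    return HansenDesign(tree, painting).weights(alpha)


def ou_vcv(tree: PhyloTree, alpha: float, sigma_sq: float = 1.0) -> np.ndarray:
    if sigma_sq <= 0:
        raise ValueError("sigma_sq must be > 0")
    return sigma_sq * HansenDesign(tree, None).corr(alpha)


# ------------------------------------------------------------------ likelihood


def _as_trait_array(traits, design: HansenDesign) -> np.ndarray:
    """Coerce traits to an (n_tips, T) array aligned with tree tip order."""
    if isinstance(traits, pd.DataFrame):
        missing = [t for t in design.tip_labels if t not in traits.index]
        if missing:
            raise KeyError(f"taxa missing from trait table: {missing}")
        Y = traits.loc[design.tip_labels].to_numpy(dtype=float)
    else:
        Y = np.asarray(traits, dtype=float)
        if Y.ndim == 1:
            Y = Y[:, None]
        if Y.shape[0] != design.n:
            raise ValueError("trait rows do not match tip count")
    return Y


def _gaussian_loglik(y: np.ndarray, mean: np.ndarray, cov: np.ndarray) -> float:
    n = len(y)
    try:
        c, low = cho_factor(cov, lower=True)
    except np.linalg.LinAlgError as exc:
        raise ValueError("non-positive-definite OU covariance") from exc
    r = y - mean
    alpha_v = cho_solve((c, low), r)
    logdet = 2.0 * np.sum(np.log(np.diag(c)))
    return float(-0.5 * (n * np.log(2 * np.pi) + logdet + r @ alpha_v))


def hansen_loglik(
    traits,
    tree: PhyloTree,
    painting: RegimePainting | None,
    params: OUParams,
) -> float:
    """Exact Gaussian log-likelihood of the Hansen model, summed over traits."""
    design = HansenDesign(tree, painting)
    Y = _as_trait_array(traits, design)
    if Y.shape[1] != params.n_traits:
        raise ValueError("trait count mismatch with params")
    if painting is not None and params.regimes != design.regimes:
        raise ValueError("params regime order does not match painting")
    total = 0.0
    for t in range(params.n_traits):
        W = design.weights(params.alpha[t])
        mean = W @ params.theta[:, t]
        cov = params.sigma_sq[t] * design.corr(params.alpha[t])
        total += _gaussian_loglik(Y[:, t], mean, cov)
    return total


# ------------------------------------------------------------------ fitting


def information_criteria(logL: float, p: int, n: int) -> dict[str, float]:
    aic = -2.0 * logL + 2.0 * p
    aicc = aic + (2.0 * p * (p + 1) / (n - p - 1)) if n - p - 1 > 0 else np.inf
    sic = -2.0 * logL + p * np.log(n)
    return {"AIC": aic, "AICc": aicc, "SIC": sic}


@dataclasses.dataclass
class OUFitResult:
    label: str
    params: OUParams
    logL: float
    n_params: int
    n_taxa: int
    AIC: float
    AICc: float
    SIC: float
    painting: RegimePainting | None
    per_trait_logL: np.ndarray
    warnings: list[str]
    data_digest: str

    def summary_row(self) -> dict:
        return {
            "model": self.label,
            "K": 1 if self.painting is None else self.painting.n_regimes,
            "logL": self.logL,
            "p": self.n_params,
            "AIC": self.AIC,
            "AICc": self.AICc,
            "SIC": self.SIC,
        }


def _digest(Y: np.ndarray) -> str:
    return hashlib.sha1(np.ascontiguousarray(Y).tobytes()).hexdigest()[:12]


def _concentrated(design: HansenDesign, y: np.ndarray, alpha: float):
    """Profile out theta (GLS) and sigma^2 (ML) at fixed alpha.

    Returns (logL, theta_hat, sigma2_hat).  Rank-deficient weight columns
    (e.g. the Brownian limit where every non-root optimum loses weight)
    are handled by least squares on the whitened design.
    """
    n = design.n
    V0 = design.corr(alpha)
    W = design.weights(alpha)
    c, low = cho_factor(V0, lower=True)
    L = np.tril(c) if low else np.triu(c).T
    Wt = solve_triangular(L, W, lower=True)
    yt = solve_triangular(L, y, lower=True)
    theta, *_ = np.linalg.lstsq(Wt, yt, rcond=None)
    r = yt - Wt @ theta
    sigma2 = max(float(r @ r) / n, 1e-12)
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    logL = -0.5 * (n * (np.log(2 * np.pi) + np.log(sigma2) + 1.0) + logdet)
    return float(logL), theta, sigma2


def _fit_one_trait(design: HansenDesign, y: np.ndarray, n_grid: int = 25):
    """ML fit of (alpha, sigma^2, theta) for one trait by a deterministic
    log-alpha grid scan followed by bounded local refinement.

    The exact Brownian boundary alpha = 0 is always a candidate, so a
    model that nests Brownian motion never scores below it.
    """
    lo, hi = np.log(ALPHA_MIN), np.log(ALPHA_MAX)
    grid = np.linspace(lo, hi, n_grid)
    vals = np.array([_concentrated(design, y, np.exp(g))[0] for g in grid])
    i = int(np.argmax(vals))
    a, b = grid[max(i - 1, 0)], grid[min(i + 1, n_grid - 1)]
    res = minimize_scalar(
        lambda g: -_concentrated(design, y, np.exp(g))[0],
        bounds=(a, b),
        method="bounded",
        options={"xatol": 1e-8},
    )
    if not res.success:  # pragma: no cover - bounded Brent rarely fails
        raise RuntimeError(f"alpha optimisation failed: {res}")
    g_best = res.x if -res.fun >= vals[i] else grid[i]
    alpha = float(np.exp(g_best))
    logL, theta, sigma2 = _concentrated(design, y, alpha)
    ll0, theta0, sigma0 = _concentrated(design, y, 0.0)
    if ll0 > logL:
        alpha, logL, theta, sigma2 = 0.0, ll0, theta0, sigma0
    return alpha, sigma2, theta, logL


def fit_hansen(
    traits,
    tree: PhyloTree,
    painting: RegimePainting | None,
    label: str = "OU",
    ic_sample_size: int | None = None,
) -> OUFitResult:
    """Maximum-likelihood Hansen fit (or Brownian motion if painting is None).

    Per trait, theta is profiled by GLS given alpha and sigma^2 by its ML
    plug-in, leaving a one-dimensional concentrated likelihood in alpha
    maximised deterministically (grid + bounded refinement).
    """
    design = HansenDesign(tree, painting)
    Y = _as_trait_array(traits, design)
    n, T = Y.shape
    warns: list[str] = []

    if painting is None:
        return fit_bm(traits, tree, label=label, ic_sample_size=ic_sample_size)

    K = design.n_regimes
    alphas = np.empty(T)
    sig = np.empty(T)
    theta = np.empty((K, T))
    per_logL = np.empty(T)
    for t in range(T):
        a, s2, th, lL = _fit_one_trait(design, Y[:, t])
        alphas[t], sig[t], theta[:, t], per_logL[t] = a, s2, th, lL
        if a >= ALPHA_MAX * 0.999:
            warns.append(f"trait {t + 1}: alpha at upper bound {ALPHA_MAX}/Myr")
        W = design.weights(a)
        weak = [
            design.regimes[k]
            for k in range(K)
            if W[:, k].max() < 1e-8 and k != design.root_col
        ]
        if weak:
            warns.append(
                f"trait {t + 1}: unidentifiable regime(s) {weak} "
                "(no lineage retains weight)"
            )
    for w in warns:
        logger.info("%s: %s", label, w)

    logL = float(per_logL.sum())
    p = T * (2 + K)
    crit = information_criteria(logL, p, ic_sample_size or n)
    params = OUParams(alphas, sig, theta, design.regimes, painting.root_regime)
    return OUFitResult(
        label, params, logL, p, n, crit["AIC"], crit["AICc"], crit["SIC"],
        painting, per_logL, warns, _digest(Y),
    )


def fit_bm(
    traits,
    tree: PhyloTree,
    label: str = "BM",
    ic_sample_size: int | None = None,
) -> OUFitResult:
    """ML Brownian-motion fit: GLS root state and ML sigma^2 per trait.

    ``ic_sample_size`` overrides the AICc/SIC sample size (default: the
    number of taxa; stepwise regime discovery uses taxa x traits).
    """
    design = HansenDesign(tree, None)
    Y = _as_trait_array(traits, design)
    n, T = Y.shape
    C = design.S
    c, low = cho_factor(C, lower=True)
    L = np.tril(c)
    ones_t = solve_triangular(L, np.ones(n), lower=True)
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    alphas = np.zeros(T)
    sig = np.empty(T)
    theta = np.empty((1, T))
    per_logL = np.empty(T)
    for t in range(T):
        yt = solve_triangular(L, Y[:, t], lower=True)
        mu = float(ones_t @ yt / (ones_t @ ones_t))
        r = yt - mu * ones_t
        s2 = max(float(r @ r) / n, 1e-12)
        per_logL[t] = -0.5 * (n * (np.log(2 * np.pi) + np.log(s2) + 1.0) + logdet)
        sig[t] = s2
        theta[0, t] = mu
    logL = float(per_logL.sum())
    p = T * 2
    crit = information_criteria(logL, p, ic_sample_size or n)
    params = OUParams(alphas, sig, theta, ["root"], "root")
    return OUFitResult(
        label, params, logL, p, n, crit["AIC"], crit["AICc"], crit["SIC"],
        None, per_logL, [], _digest(Y),
    )


def refit_noiseless(fit: OUFitResult, tree: PhyloTree) -> OUFitResult:
    """Refit a Hansen model on its own fitted expectation (sanity check)."""
    design = HansenDesign(tree, fit.painting)
    cols = [f"trait{j + 1}" for j in range(fit.params.n_traits)]
    mu = np.column_stack(
        [
            design.weights(fit.params.alpha[t]) @ fit.params.theta[:, t]
            for t in range(fit.params.n_traits)
        ]
    )
    noiseless = pd.DataFrame(mu, index=design.tip_labels, columns=cols)
    return fit_hansen(noiseless, tree, fit.painting, label=fit.label + "_noiseless")


# ------------------------------------------------------------------ hypotheses


def _genus_tips(tree: PhyloTree, genus: str) -> list[str]:
    tips = [t for t in tree.tip_labels if t.split("_")[0] == genus]
    if not tips:
        raise KeyError(f"no tips of genus {genus!r} in tree")
    return tips


def build_hypotheses(
    tree: PhyloTree,
    fossil: str | None = "Ardipithecus_ramidus",
    fossil_regime: str | dict[str, str] | None = "african_ape",
) -> list[tuple[str, RegimePainting | None]]:
    """The a-priori adaptive hypotheses H1-H6 for the anthropoid foot.

    H1 Brownian motion; H2 single global optimum; H3 bipedal /
    terrestrial / arboreal; H4 splits terrestrial into heel-strike
    plantigrade (African apes) vs semiplantigrade (terrestrial
    cercopithecins); H5 adds a climbing-plus-hindlimb-suspension regime
    (Pongo, atelids); H6 splits active climbing (hylobatids, Alouatta,
    Lagothrix by default) from suspension (Pongo, Ateles).

    ``fossil_regime`` fixes which regime the fossil's branch carries in
    H3-H6: the default ``"african_ape"`` places it with the terrestrial
    (H3) / plantigrade (H4-H6) African-ape regime; ``"bipedal"`` places
    it with *Homo*; a dict maps hypothesis label to regime choice.
    """
    from .tree import paint_regimes

    labels = set(tree.tip_labels)
    has_fossil = fossil is not None and fossil in labels

    homo = _genus_tips(tree, "Homo")
    pan = _genus_tips(tree, "Pan")
    gorilla = _genus_tips(tree, "Gorilla")
    pongo = _genus_tips(tree, "Pongo")
    papio = _genus_tips(tree, "Papio")
    thero = _genus_tips(tree, "Theropithecus")
    eryth = _genus_tips(tree, "Erythrocebus")
    chloro = _genus_tips(tree, "Chlorocebus")
    ateles = _genus_tips(tree, "Ateles")
    alouatta = _genus_tips(tree, "Alouatta")
    lagothrix = _genus_tips(tree, "Lagothrix")
    hylobatids = [
        x
        for x in tree.tip_labels
        if x.split("_")[0] in ("Hylobates", "Hoolock", "Symphalangus")
    ]

    def fossil_choice(h: str, ape_label: str) -> str:
        if isinstance(fossil_regime, dict):
            return fossil_regime.get(h, ape_label)
        if fossil_regime == "bipedal":
            return "bipedal"
        return ape_label

    def bipedal_pieces(h: str, ape_label: str):
        """Pieces painting the hominin clade; order matters (override)."""
        if not has_fossil:
            return [(set(homo), "bipedal")]
        choice = fossil_choice(h, ape_label)
        if choice == "bipedal":
            return [(set(homo) | {fossil}, "bipedal")]
        # fossil with the African-ape regime: hominin stem + fossil keep
        # the ape regime, only the Homo terminal edge is bipedal
        return [(set(homo) | {fossil}, ape_label), (set(homo), "bipedal")]

    terr_pieces = [(set(g), "terrestrial") for g in (pan, gorilla, papio, thero, eryth, chloro)]
    plant_pieces = [(set(g), "plantigrade") for g in (pan, gorilla)]
    semi_pieces = [(set(g), "semiplantigrade") for g in (papio, thero, eryth, chloro)]
    susp_all = [(set(g), "suspension") for g in (pongo, ateles, alouatta, lagothrix)]
    climb_pieces = [(set(hylobatids), "climbing"), (set(alouatta), "climbing"),
                    (set(lagothrix), "climbing")]
    susp_pieces = [(set(g), "suspension") for g in (pongo, ateles)]

    out: list[tuple[str, RegimePainting | None]] = [("H1", None)]
    out.append(("H2", paint_regimes(tree, [], background="global")))
    out.append(
        (
            "H3",
            paint_regimes(
                tree,
                terr_pieces + bipedal_pieces("H3", "terrestrial"),
                background="arboreal",
            ),
        )
    )
    out.append(
        (
            "H4",
            paint_regimes(
                tree,
                plant_pieces + semi_pieces + bipedal_pieces("H4", "plantigrade"),
                background="arboreal",
            ),
        )
    )
    out.append(
        (
            "H5",
            paint_regimes(
                tree,
                plant_pieces + semi_pieces + susp_all
                + bipedal_pieces("H5", "plantigrade"),
                background="arboreal",
            ),
        )
    )
    out.append(
        (
            "H6",
            paint_regimes(
                tree,
                plant_pieces + semi_pieces + climb_pieces + susp_pieces
                + bipedal_pieces("H6", "plantigrade"),
                background="arboreal",
            ),
        )
    )
    return out


def compare_models(fits: list[OUFitResult]) -> pd.DataFrame:
    """Rank fitted models by AICc (ascending) with delta-AICc.

    All fits must be on identical data (checked by digest).
    """
    if len(fits) < 2:
        raise ValueError("need >= 2 fits to compare")
    digests = {f.data_digest for f in fits}
    if len(digests) > 1:
        raise ValueError("fits were computed on different data")
    rows = [f.summary_row() for f in fits]
    tab = pd.DataFrame(rows).sort_values("AICc", kind="stable").reset_index(drop=True)
    tab["dAICc"] = tab["AICc"] - tab["AICc"].iloc[0]
    return tab
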