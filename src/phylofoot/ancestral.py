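"""Ancestral-state estimation: Brownian closed form and stable-model MCMC.

Under constant-rate Brownian motion the joint distribution of tip and
node states is Gaussian, so node estimates are a GLS/conditional-mean
solve.  Because that model assumes one rate everywhere, exceptionally
derived lineages drag ancestral estimates toward themselves (the
"averaging effect").  The stable model relaxes gradualism: branch
increments follow a symmetric alpha-stable distribution whose stability
index is learned from the data.  Heavy tails let individual branches
carry large jumps without inflating everyone else's implied rate, which
attenuates the pull of outlier lineages on ancestral nodes.

Model sampled by Metropolis-within-Gibbs, per trait:

* internal node states x (flat prior),
* global rate scale c (log-uniform on [1e-6, 1e3], bounded away from 0),
* stability index in (1, 2] (uniform; 2 = Gaussian/Brownian).

Each branch increment x_child - x_parent has a symmetric stable density
with scale c * t^(1/index), t the branch length in Myr.  Two chains are
run by default; convergence is monitored with the Gelman-Rubin PSRF and
models are compared with a posterior-mean plug-in BPIC (lower better).
"""

from __future__ import annotations

import dataclasses
import logging
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve

from ._stable import StableDensity
from .tree import PhyloTree

__all__ = [
    "AncestralEstimate",
    "McmcRun",
    "bm_ancestral",
    "stable_mcmc",
    "psrf",
    "bpic_compare",
    "phylomorphospace",
]

logger = logging.getLogger(__name__)

PSRF_FLAG = 1.2
_LOG_C_LO, _LOG_C_HI = np.log(1e-6), np.log(1e3)
_IDX_LO, _IDX_HI = 1.0, 2.0


@dataclasses.dataclass
class AncestralEstimate:
    """Per internal node and trait: median and 95% credibility interval.

    ``table`` is indexed by internal node id with columns
    ``(trait, {median, lower, upper})``.
    """

    table: pd.DataFrame
    method: str

    def node(self, node_id: int) -> pd.DataFrame:
        return self.table.loc[node_id].unstack()

    def medians(self) -> pd.DataFrame:
        return self.table.xs("median", axis=1, level=1)


def _node_cov_blocks(tree: PhyloTree):
    """MRCA-depth covariance blocks between internal nodes and tips."""
    tips = tree.tip_indices
    internals = tree.internal_indices
    depths = tree.depths
    anc: dict[int, set[int]] = {}
    for i in range(tree.n_nodes):
        anc[i] = {i} | set(tree.ancestors(i))

    def mrca_depth(u, v):
        return max(depths[j] for j in (anc[u] & anc[v]))

    C_tt = np.array([[mrca_depth(a, b) for b in tips] for a in tips])
    C_nt = np.array([[mrca_depth(u, b) for b in tips] for u in internals])
    C_nn_diag = depths[internals]
    return internals, tips, C_tt, C_nt, C_nn_diag


def _trait_frame(traits, tree: PhyloTree) -> pd.DataFrame:
    if isinstance(traits, pd.DataFrame):
        missing = [t for t in tree.tip_labels if t not in traits.index]
        if missing:
            raise KeyError(f"taxa missing from trait table: {missing}")
        return traits.loc[tree.tip_labels].astype(float)
    Y = np.asarray(traits, float)
    if Y.ndim == 1:
        Y = Y[:, None]
    cols = [f"trait{j + 1}" for j in range(Y.shape[1])]
    return pd.DataFrame(Y, index=tree.tip_labels, columns=cols)


def bm_ancestral(traits, tree: PhyloTree) -> AncestralEstimate:
    """GLS ancestral states under constant-rate Brownian motion.

    Point estimates are the conditional means given the tips with the
    root treated as an unknown GLS mean; intervals are Gaussian with the
    conditional variance plus the root-mean uncertainty, using the ML
    plug-in rate.  On a star tree the root equals the phylogenetic
    (here arithmetic) tip mean.
    """
    Y = _trait_frame(traits, tree)
    internals, tips, C_tt, C_nt, C_nn_diag = _node_cov_blocks(tree)
    n = len(tips)
    c, low = cho_factor(C_tt, lower=True)
    ones = np.ones(n)
    Ci1 = cho_solve((c, low), ones)
    s11 = float(ones @ Ci1)

    rows = []
    for col in Y.columns:
        y = Y[col].to_numpy()
        mu = float(Ci1 @ y / s11)
        r = y - mu
        Cir = cho_solve((c, low), r)
        sigma2 = max(float(r @ Cir) / n, 0.0)
        est = mu + C_nt @ Cir
        CiCtn = cho_solve((c, low), C_nt.T)
        cond_var = C_nn_diag - np.einsum("ij,ji->i", C_nt, CiCtn)
        mean_adj = (1.0 - C_nt @ Ci1) ** 2 / s11
        var = sigma2 * np.clip(cond_var + mean_adj, 0.0, None)
        half = 1.959963984540054 * np.sqrt(var)
        for u, e, h in zip(internals, est, half):
            rows.append((u, col, e, e - h, e + h))

    tab = pd.DataFrame(rows, columns=["node", "trait", "median", "lower", "upper"])
    tab = tab.set_index(["node", "trait"]).unstack("trait")
    tab = tab.reorder_levels([1, 0], axis=1).sort_index(axis=1)
    return AncestralEstimate(tab, method="BM")


# ------------------------------------------------------------------ PSRF


def psrf(chains) -> float:
    """Gelman-Rubin potential scale reduction factor for one parameter.

    ``chains``: sequence of >= 2 equal-length post-burn-in sample arrays.
    Identical chains give exactly 1.0 (the estimate is clamped from
    below at 1, its asymptotic floor).
    """
    arrs = [np.asarray(ch, float) for ch in chains]
    if len(arrs) < 2:
        raise ValueError("PSRF needs >= 2 chains")
    n = min(len(a) for a in arrs)
    if n < 10:
        raise ValueError("chains too short for PSRF")
    X = np.stack([a[:n] for a in arrs])
    m = X.shape[0]
    means = X.mean(axis=1)
    W = X.var(axis=1, ddof=1).mean()
    B = n * means.var(ddof=1)
    if W <= 0:
        return 1.0
    var_hat = (n - 1) / n * W + B / n
    return float(max(1.0, np.sqrt(var_hat / W)))


# ------------------------------------------------------------------ MCMC


@dataclasses.dataclass
class McmcRun:
    """Two-chain stable-model run for one trait matrix.

    ``samples`` maps trait -> dict with per-chain arrays: ``x`` of shape
    (chains, n_samples, n_internal), ``log_c``, ``index``, ``loglik``.
    """

    samples: dict
    internals: list[int]
    iterations: int
    thinning: int
    burn_in: int
    n_chains: int
    psrf_table: pd.DataFrame
    bpic: float
    converged: bool
    fixed_index: float | None

    @property
    def max_psrf(self) -> float:
        return float(self.psrf_table["psrf"].max())

    def kept(self, trait: str, key: str) -> np.ndarray:
        """Post-burn-in samples, shape (chains, kept, ...)."""
        keep_from = self.burn_in // self.thinning
        return self.samples[trait][key][:, keep_from:]


_ZERO_EDGE_TOL = 1e-9


@lru_cache(maxsize=256)
def _density(index_q: float) -> StableDensity:
    """Stable densities cached on the quantized index grid.

    The sampler proposes the stability index on a 0.01 grid (far finer
    than the posterior spread of the index) so the FFT inversion (about
    2 ms) is amortised across proposals instead of being rebuilt for
    every Metropolis step.
    """
    return StableDensity(index_q)


def _quantize_index(value: float) -> float:
    return float(np.clip(round(value, 2), _IDX_LO + 0.01, _IDX_HI))


class _ContractedTree:
    """Tree geometry with zero-length edges contracted.

    Zero-length internal edges (arbitrarily resolved polytomies) would
    glue node states together through a zero-variance increment, which
    freezes single-node Metropolis updates; contracting them restores
    the intended polytomy.  Each node gets a representative; a
    representative that is (or absorbs) a tip is pinned at its datum.
    """

    def __init__(self, tree: PhyloTree):
        self.tree = tree
        n = tree.n_nodes
        rep = np.arange(n)

        def find(i):
            while rep[i] != i:
                rep[i] = rep[rep[i]]
                i = rep[i]
            return i

        tipset = set(tree.tip_indices)
        for e in tree.edge_indices:
            if tree.branch_length(e) < _ZERO_EDGE_TOL:
                a, b = find(tree.parent(e)), find(e)
                if a == b:
                    continue
                # prefer a tip as representative (its state is data)
                if b in tipset:
                    a, b = b, a
                rep[b] = a
        self.rep = np.array([find(i) for i in range(n)])

        eff = [
            (self.rep[tree.parent(e)], self.rep[e], tree.branch_length(e))
            for e in tree.edge_indices
            if tree.branch_length(e) >= _ZERO_EDGE_TOL
        ]
        self.par = np.array([p for p, _, _ in eff], dtype=int)
        self.chi = np.array([c for _, c, _ in eff], dtype=int)
        self.t_b = np.array([t for _, _, t in eff])
        # free nodes: internal representatives (not pinned to a tip)
        self.free = np.array(
            sorted(
                {self.rep[u] for u in tree.internal_indices}
                - {self.rep[t] for t in tree.tip_indices}
            ),
            dtype=int,
        )
        # BFS levels on the contracted tree (still a tree, so bipartite)
        adj: dict[int, list[int]] = {}
        for p, q in zip(self.par, self.chi):
            adj.setdefault(int(p), []).append(int(q))
            adj.setdefault(int(q), []).append(int(p))
        root = int(self.rep[0])
        lev = {root: 0}
        frontier = [root]
        while frontier:
            nxt = []
            for u in frontier:
                for v in adj.get(u, []):
                    if v not in lev:
                        lev[v] = lev[u] + 1
                        nxt.append(v)
            frontier = nxt
        self.level = lev

    def fill_values(self, y: np.ndarray, x_free: np.ndarray) -> np.ndarray:
        """Node-value vector from tip data and free-node states."""
        tree = self.tree
        val = np.zeros(tree.n_nodes)
        for t, v in zip(tree.tip_indices, y):
            val[t] = v
        for u, v in zip(self.free, x_free):
            val[u] = v
        return val[self.rep]


def _run_chain(
    geo: _ContractedTree,
    y: np.ndarray,
    iterations: int,
    thinning: int,
    rng: np.random.Generator,
    x0_free: np.ndarray,
    log_c0: float,
    fixed_index: float | None,
    adapt_until: int,
):
    tree = geo.tree
    internals = tree.internal_indices
    n_int = len(internals)
    par, chi, t_b = geo.par, geo.chi, geo.t_b
    free = geo.free
    n_free = len(free)
    pos_of = {int(u): k for k, u in enumerate(free)}

    # values indexed by representative node; tips fixed at data
    val = np.zeros(tree.n_nodes)
    for t, lab_y in zip(tree.tip_indices, y):
        val[int(geo.rep[t])] = lab_y
    val[free] = x0_free

    colors = [
        np.array([u for u in free if geo.level[int(u)] % 2 == par_ity], dtype=int)
        for par_ity in (0, 1)
    ]
    # per color: edges with an endpoint in the block and the owning node
    color_edges, color_owner = [], []
    for block in colors:
        bset = set(block.tolist())
        eids, owner = [], []
        for b in range(len(par)):
            if par[b] in bset:
                eids.append(b)
                owner.append(pos_of[int(par[b])])
            elif chi[b] in bset:
                eids.append(b)
                owner.append(pos_of[int(chi[b])])
        color_edges.append(np.array(eids, dtype=int))
        color_owner.append(np.array(owner, dtype=int))
    block_pos = [np.array([pos_of[int(u)] for u in block]) for block in colors]

    # joint-translation blocks: the free representatives inside each free
    # node's subtree (any symmetric block proposal is valid; blocks that
    # are whole subtrees are the ones that match the posterior geometry)
    freeset = set(free.tolist())
    subtree_blocks = []
    for u in free:
        if int(u) == int(geo.rep[0]):
            continue
        nodes = {int(geo.rep[v]) for v in tree.subtree_nodes(int(u))} & freeset
        if 2 <= len(nodes) < len(freeset):
            subtree_blocks.append(np.array(sorted(nodes), dtype=int))

    idx_cur = _quantize_index(1.9 if fixed_index is None else float(fixed_index))
    dens = _density(idx_cur)
    log_c = float(log_c0)

    def edge_ll(values, d, lc, stab_idx):
        scale = np.exp(lc) * t_b ** (1.0 / stab_idx)
        return d.logpdf_scaled(values[chi] - values[par], scale)

    cur_ll = edge_ll(val, dens, log_c, idx_cur)

    step_x = np.full(n_free, 0.5)
    step_c, step_idx, step_g = 0.4, 0.1, 0.5
    acc_x = np.zeros(n_free)
    try_x = np.zeros(n_free)
    acc_c = try_c = acc_i = try_i = acc_g = try_g = 0

    n_keep = iterations // thinning
    out_x = np.empty((n_keep, n_int))
    out_c = np.empty(n_keep)
    out_idx = np.empty(n_keep)
    out_ll = np.empty(n_keep)
    kept = 0

    scale_all = np.exp(log_c) * t_b ** (1.0 / idx_cur)

    for it in range(1, iterations + 1):
        # --- node blocks
        for cidx in (0, 1):
            block = colors[cidx]
            if block.size == 0:
                continue
            bpos = block_pos[cidx]
            eids = color_edges[cidx]
            owner = color_owner[cidx]
            prop = val[block] + step_x[bpos] * rng.standard_normal(block.size)
            val_prop = val.copy()
            val_prop[block] = prop
            new_ll = dens.logpdf_scaled(
                val_prop[chi[eids]] - val_prop[par[eids]], scale_all[eids]
            )
            owner_block_index = np.searchsorted(bpos, owner)
            delta = np.zeros(block.size)
            np.add.at(delta, owner_block_index, new_ll - cur_ll[eids])
            accept = np.log(rng.random(block.size)) < delta
            if np.any(accept):
                val[block[accept]] = prop[accept]
                upd = accept[owner_block_index]
                cur_ll[eids[upd]] = new_ll[upd]
            try_x[bpos] += 1
            np.add.at(acc_x, bpos, accept.astype(float))

        # --- joint translation moves: all free nodes, or a random free
        # subtree.  The overall level of the internal states (and of any
        # deep subtree) is the softest posterior direction; shifting a
        # block as one unit decorrelates it far faster than node-wise
        # updates can.
        try_g += 1
        shift = step_g * rng.standard_normal()
        if subtree_blocks and rng.random() < 0.5:
            block_nodes = subtree_blocks[rng.integers(len(subtree_blocks))]
        else:
            block_nodes = free
        val_prop = val.copy()
        val_prop[block_nodes] += shift
        new_ll = dens.logpdf_scaled(
            val_prop[chi] - val_prop[par], scale_all
        )
        if np.log(rng.random()) < new_ll.sum() - cur_ll.sum():
            val = val_prop
            cur_ll = new_ll
            acc_g += 1

        # --- rate scale c
        try_c += 1
        lc_prop = log_c + step_c * rng.standard_normal()
        if _LOG_C_LO <= lc_prop <= _LOG_C_HI:
            new_ll = edge_ll(val, dens, lc_prop, idx_cur)
            if np.log(rng.random()) < new_ll.sum() - cur_ll.sum():
                log_c = lc_prop
                cur_ll = new_ll
                scale_all = np.exp(log_c) * t_b ** (1.0 / idx_cur)
                acc_c += 1

        # --- stability index
        if fixed_index is None:
            try_i += 1
            idx_prop = round(idx_cur + step_idx * rng.standard_normal(), 2)
            if _IDX_LO < idx_prop <= _IDX_HI:
                dens_prop = _density(idx_prop)
                new_ll = edge_ll(val, dens_prop, log_c, idx_prop)
                if np.log(rng.random()) < new_ll.sum() - cur_ll.sum():
                    idx_cur = idx_prop
                    dens = dens_prop
                    cur_ll = new_ll
                    scale_all = np.exp(log_c) * t_b ** (1.0 / idx_cur)
                    acc_i += 1

        # --- adapt proposal scales during burn-in only
        if it <= adapt_until and it % 100 == 0:
            with np.errstate(invalid="ignore", divide="ignore"):
                rate = np.where(try_x > 0, acc_x / try_x, 0.3)
            step_x *= np.exp(np.clip(rate - 0.3, -0.5, 0.5))
            step_x = np.clip(step_x, 1e-4, 50.0)
            if try_c:
                step_c = float(np.clip(step_c * np.exp((acc_c / try_c) - 0.3), 1e-4, 5.0))
            if try_i:
                step_idx = float(np.clip(step_idx * np.exp((acc_i / try_i) - 0.3), 1e-4, 0.5))
            if try_g:
                step_g = float(np.clip(step_g * np.exp((acc_g / try_g) - 0.3), 1e-4, 50.0))
            acc_x[:] = 0
            try_x[:] = 0
            acc_c = try_c = acc_i = try_i = acc_g = try_g = 0

        if it % thinning == 0:
            out_x[kept] = val[geo.rep[internals]]
            out_c[kept] = log_c
            out_idx[kept] = idx_cur
            out_ll[kept] = cur_ll.sum()
            kept += 1

    return {"x": out_x, "log_c": out_c, "index": out_idx, "loglik": out_ll}


def _chain_loglik_at(geo: _ContractedTree, y, x_free, log_c, stab_idx):
    """Data log-likelihood at a single parameter point (for BPIC)."""
    val = geo.fill_values(y, x_free)
    dens = _density(_quantize_index(stab_idx))
    scale = np.exp(log_c) * geo.t_b ** (1.0 / stab_idx)
    return float(dens.logpdf_scaled(val[geo.chi] - val[geo.par], scale).sum())


def stable_mcmc(
    traits,
    tree: PhyloTree,
    iterations: int = 2_000_000,
    thinning: int = 200,
    burn_in: int = 600_000,
    chains: int = 2,
    seed: int | list[int] = 0,
    fixed_index: float | None = None,
) -> tuple[McmcRun, AncestralEstimate]:
    """Stable-model ancestral states by Metropolis-within-Gibbs MCMC.

    Defaults mirror the full protocol (2,000,000 iterations, thinning
    200, 600,000 burn-in, two chains); tests and pipelines scale these
    down together.  ``fixed_index=2.0`` pins the Gaussian (Brownian)
    boundary, giving the Bayesian BM model used in BPIC comparison.
    ``seed`` may be one master seed (chain seeds derived) or an explicit
    per-chain list (identical seeds give identical chains, PSRF 1).
    Node estimates are medians with 95% credibility intervals from the
    pooled post-burn-in samples of all chains.
    """
    if iterations < 10 * thinning:
        raise ValueError("iterations must be >= 10 * thinning")
    if burn_in >= iterations:
        raise ValueError("burn_in must be < iterations")
    Y = _trait_frame(traits, tree)
    internals = tree.internal_indices
    bm = bm_ancestral(Y, tree)
    geo = _ContractedTree(tree)
    free_pos = [internals.index(int(u)) for u in geo.free]

    if isinstance(seed, (list, tuple)):
        if len(seed) != chains:
            raise ValueError("need one seed per chain")
        chain_seeds = [int(s) for s in seed]
    else:
        ss = np.random.SeedSequence(int(seed)).spawn(chains)
        chain_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss]

    keep_from = burn_in // thinning
    samples: dict = {}
    psrf_rows = []
    bpic_total = 0.0

    for col in Y.columns:
        y = Y[col].to_numpy()
        x0 = bm.table[(col, "median")].loc[internals].to_numpy()
        x0_free = x0[free_pos]
        # crude initial rate from the BM increments on contracted edges
        val0 = geo.fill_values(y, x0_free)
        incr = val0[geo.chi] - val0[geo.par]
        c0 = float(np.sqrt(np.mean(incr**2 / geo.t_b)) / np.sqrt(2.0)) or 1e-3
        log_c0 = float(np.clip(np.log(max(c0, 1e-6)), _LOG_C_LO, _LOG_C_HI))

        runs = []
        for ch in range(chains):
            rng = np.random.default_rng(chain_seeds[ch])
            jitter = 0.0 if chain_seeds.count(chain_seeds[0]) == chains else 0.1 * ch
            runs.append(
                _run_chain(
                    geo, y, iterations, thinning, rng,
                    x0_free + jitter, log_c0 + jitter, fixed_index,
                    adapt_until=burn_in,
                )
            )
        st = {
            k: np.stack([r[k] for r in runs]) for k in ("x", "log_c", "index", "loglik")
        }
        samples[col] = st

        for j, u in enumerate(internals):
            psrf_rows.append(
                (col, f"node{u}", psrf([st["x"][c, keep_from:, j] for c in range(chains)]))
            )
        psrf_rows.append((col, "log_c", psrf([st["log_c"][c, keep_from:] for c in range(chains)])))
        if fixed_index is None:
            psrf_rows.append((col, "index", psrf([st["index"][c, keep_from:] for c in range(chains)])))

        # BPIC: posterior-mean plug-in variant
        ll_kept = st["loglik"][:, keep_from:].ravel()
        mean_ll = float(ll_kept.mean())
        x_hat = st["x"][:, keep_from:].reshape(-1, len(internals)).mean(axis=0)
        lc_hat = float(st["log_c"][:, keep_from:].mean())
        idx_hat = (
            float(fixed_index)
            if fixed_index is not None
            else float(st["index"][:, keep_from:].mean())
        )
        ll_hat = _chain_loglik_at(geo, y, x_hat[free_pos], lc_hat, idx_hat)
        p_d = 2.0 * (ll_hat - mean_ll)
        bpic_total += -2.0 * mean_ll + 2.0 * p_d

    psrf_tab = pd.DataFrame(psrf_rows, columns=["trait", "param", "psrf"])
    converged = bool((psrf_tab["psrf"] <= PSRF_FLAG).all())
    if not converged:
        logger.warning(
            "PSRF > %.2f on %d parameter(s); run flagged non-converged",
            PSRF_FLAG, int((psrf_tab["psrf"] > PSRF_FLAG).sum()),
        )

    rows = []
    for col in Y.columns:
        xs = samples[col]["x"][:, keep_from:].reshape(-1, len(internals))
        med = np.median(xs, axis=0)
        lo = np.percentile(xs, 2.5, axis=0)
        hi = np.percentile(xs, 97.5, axis=0)
        for u, m, a, b in zip(internals, med, lo, hi):
            rows.append((u, col, m, a, b))
    tab = pd.DataFrame(rows, columns=["node", "trait", "median", "lower", "upper"])
    tab = tab.set_index(["node", "trait"]).unstack("trait")
    tab = tab.reorder_levels([1, 0], axis=1).sort_index(axis=1)
    est = AncestralEstimate(tab, method="stable" if fixed_index is None else f"stable(index={fixed_index:g})")

    run = McmcRun(
        samples, internals, iterations, thinning, burn_in, chains,
        psrf_tab, float(bpic_total), converged, fixed_index,
    )
    return run, est


def bpic_compare(run_bm: McmcRun, run_stable: McmcRun) -> tuple[float, str]:
    """BPIC difference (stable minus BM) and the preferred model label.

    Lower BPIC is better; |difference| below 2 is reported as a tie.
    Non-converged runs propagate a warning.
    """
    for name, run in (("BM", run_bm), ("stable", run_stable)):
        if not run.converged:
            logger.warning("%s run flagged non-converged; BPIC unreliable", name)
    diff = run_stable.bpic - run_bm.bpic
    if abs(diff) < 2.0:
        label = "tie"
    else:
        label = "stable" if diff < 0 else "BM"
    return float(diff), label


# ---------------------------------------------------------- phylomorphospace


def phylomorphospace(
    tree: PhyloTree,
    tip_scores: pd.DataFrame,
    node_estimates: AncestralEstimate,
    focal_node: int,
    axes: tuple[str, str] | None = None,
):
    """Assemble phylomorphospace coordinates and the focal credibility box.

    Returns a dict with tip coordinates (exactly the input scores), node
    coordinates (medians), the parent-child edge list in score space,
    and the focal node's per-axis 95% credibility rectangle.
    """
    tips = tree.tip_indices
    internals = tree.internal_indices
    if focal_node not in internals:
        raise KeyError(f"focal node {focal_node} is not an internal node")
    traits = list(node_estimates.medians().columns)
    if axes is None:
        axes = (traits[0], traits[1]) if len(traits) > 1 else (traits[0], traits[0])
    med = node_estimates.medians()

    tip_xy = tip_scores.loc[tree.tip_labels, list(dict.fromkeys(axes))]
    node_xy = med.loc[internals]

    coord = {}
    for u in internals:
        coord[u] = tuple(med.loc[u, a] for a in axes)
    for t in tips:
        lab = tree.node(t).label
        coord[t] = tuple(tip_scores.loc[lab, a] for a in axes)

    edge_list = [
        (tree.parent(i), i, coord[tree.parent(i)], coord[i])
        for i in range(1, tree.n_nodes)
    ]
    box = {
        a: (
            float(node_estimates.table.loc[focal_node, (a, "lower")]),
            float(node_estimates.table.loc[focal_node, (a, "upper")]),
        )
        for a in axes
    }
    return {
        "axes": axes,
        "tips": tip_xy,
        "nodes": node_xy,
        "edges": edge_list,
        "focal_node": focal_node,
        "focal_box": box,
    }


def plot_phylomorphospace(space: dict, path: str | None = None):
    """Render the phylomorphospace with the focal credibility box."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ax_x, ax_y = space["axes"]
    fig, ax = plt.subplots(figsize=(6, 5))
    for _, _, (x0, y0), (x1, y1) in space["edges"]:
        ax.plot([x0, x1], [y0, y1], color="0.7", lw=0.8, zorder=1)
    ax.scatter(
        space["tips"][ax_x], space["tips"][ax_y], s=18, color="tab:blue", zorder=3
    )
    ax.scatter(
        space["nodes"][ax_x], space["nodes"][ax_y], s=10, color="black", zorder=2
    )
    (bx0, bx1) = space["focal_box"][ax_x]
    (by0, by1) = space["focal_box"][ax_y]
    ax.add_patch(
        plt.Rectangle(
            (bx0, by0), bx1 - bx0, by1 - by0,
            fill=False, edgecolor="goldenrod", ls="--", lw=1.5, zorder=4,
        )
    )
    ax.set_xlabel(ax_x)
    ax.set_ylabel(ax_y)
    if path:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig
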