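"""Rooted phylogenetic trees with branch lengths in millions of years.

The container supports the operations the comparative pipeline needs:
Newick round-tripping, grafting of a non-contemporaneous (fossil) tip onto
an interior edge, painting of selective regimes onto branches, Pagel's
lambda rescaling, and construction of the Brownian-motion phylogenetic
covariance matrix.  Fossil tips are first class: every covariance uses the
actual root-to-tip depth of each tip rather than forcing the tree to be
ultrametric.

Edges are identified by the index of their child node.  Node indices are
assigned in preorder and are stable for a given tree object; structural
edits (graft/prune) return a new tree with freshly assigned indices.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np

__all__ = [
    "NewickError",
    "PhyloTree",
    "RegimePainting",
    "read_newick",
    "graft_fossil_tip",
    "prune_tip",
    "paint_regimes",
    "lambda_transform",
    "vcv_bm",
]

logger = logging.getLogger(__name__)

_ULTRAMETRIC_TOL = 1e-6


class NewickError(ValueError):
    """Raised when a Newick string cannot be parsed."""


@dataclasses.dataclass
class _Node:
    index: int
    parent: int  # -1 for the root
    length: float  # branch length above this node; 0.0 for the root
    label: str | None  # tip label (None for unnamed internal nodes)
    children: list[int]

    @property
    def is_tip(self) -> bool:
        return not self.children


class PhyloTree:
    """A rooted tree with named tips and non-negative branch lengths.

    Parameters
    ----------
    nodes:
        Preorder list of `_Node`; ``nodes[0]`` is the root.
    lam:
        Pagel's lambda factor applied to off-diagonal covariance entries
        (see :func:`lambda_transform`); 1.0 means untransformed.
    """

    def __init__(self, nodes: Sequence[_Node], lam: float = 1.0):
        self._nodes = list(nodes)
        if self._nodes[0].parent != -1:
            raise ValueError("nodes[0] must be the root")
        labels = [n.label for n in self._nodes if n.is_tip]
        if any(lbl is None for lbl in labels):
            raise ValueError("every tip must carry a label")
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise ValueError(f"duplicate tip labels: {dupes}")
        for n in self._nodes:
            if n.parent != -1 and n.length < 0:
                raise ValueError(f"negative branch length on edge {n.index}")
        self.lam = float(lam)
        self._depths: np.ndarray | None = None

    # ------------------------------------------------------------------ basics

    @property
    def n_nodes(self) -> int:
        return len(self._nodes)

    @property
    def root(self) -> int:
        return 0

    def node(self, i: int) -> _Node:
        return self._nodes[i]

    def parent(self, i: int) -> int:
        return self._nodes[i].parent

    def children(self, i: int) -> list[int]:
        return self._nodes[i].children

    def branch_length(self, i: int) -> float:
        return self._nodes[i].length

    @property
    def tip_indices(self) -> list[int]:
        return [n.index for n in self._nodes if n.is_tip]

    @property
    def internal_indices(self) -> list[int]:
        return [n.index for n in self._nodes if not n.is_tip]

    @property
    def tip_labels(self) -> list[str]:
        return [self._nodes[i].label for i in self.tip_indices]  # type: ignore[misc]

    @property
    def n_tips(self) -> int:
        return len(self.tip_indices)

    @property
    def edge_indices(self) -> list[int]:
        """Every non-root node index, i.e. every edge (identified by child)."""
        return [n.index for n in self._nodes if n.parent != -1]

    def tip_index(self, label: str) -> int:
        for i in self.tip_indices:
            if self._nodes[i].label == label:
                return i
        raise KeyError(f"no tip labelled {label!r}")

    # ------------------------------------------------------------------ depths

    @property
    def depths(self) -> np.ndarray:
        """Root-to-node path length (Myr) for every node."""
        if self._depths is None:
            d = np.zeros(self.n_nodes)
            for n in self._nodes[1:]:
                d[n.index] = d[n.parent] + n.length
            self._depths = d
        return self._depths

    @property
    def tip_depths(self) -> dict[str, float]:
        d = self.depths
        return {self._nodes[i].label: float(d[i]) for i in self.tip_indices}

    @property
    def max_tip_depth(self) -> float:
        return float(max(self.tip_depths.values()))

    @property
    def is_ultrametric(self) -> bool:
        """True iff all tip depths agree within 1e-6 Myr."""
        depths = list(self.tip_depths.values())
        return max(depths) - min(depths) <= _ULTRAMETRIC_TOL

    @property
    def is_degenerate(self) -> bool:
        """A single-tip tree: accepted but useless for comparative work."""
        return self.n_tips < 2

    def ancestors(self, i: int) -> list[int]:
        """Indices from node i's parent up to (and including) the root."""
        out = []
        j = self._nodes[i].parent
        while j != -1:
            out.append(j)
            j = self._nodes[j].parent
        return out

    def mrca(self, tip_labels: Iterable[str]) -> int:
        idxs = [self.tip_index(t) for t in tip_labels]
        if len(idxs) == 1:
            return idxs[0]
        common = set([idxs[0]] + self.ancestors(idxs[0]))
        for i in idxs[1:]:
            common &= set([i] + self.ancestors(i))
        # deepest common ancestor
        return max(common, key=lambda j: self.depths[j])

    def subtree_nodes(self, i: int) -> list[int]:
        """Preorder node indices of the clade rooted at node i."""
        out, stack = [], [i]
        while stack:
            j = stack.pop()
            out.append(j)
            stack.extend(reversed(self._nodes[j].children))
        return out

    def clade_tips(self, i: int) -> set[str]:
        return {
            self._nodes[j].label
            for j in self.subtree_nodes(i)
            if self._nodes[j].is_tip
        }

    # ------------------------------------------------------------------ I/O

    def to_newick(self) -> str:
        def fmt(i: int) -> str:
            n = self._nodes[i]
            if n.is_tip:
                label = n.label
                if " " in label:
                    label = f"'{label}'"
                return f"{label}:{n.length:.10g}"
            inner = ",".join(fmt(c) for c in n.children)
            if n.parent == -1:
                return f"({inner})"
            return f"({inner}):{n.length:.10g}"

        return fmt(0) + ";"

    def copy(self) -> "PhyloTree":
        nodes = [
            _Node(n.index, n.parent, n.length, n.label, list(n.children))
            for n in self._nodes
        ]
        return PhyloTree(nodes, lam=self.lam)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        kind = "ultrametric" if self.is_ultrametric else "non-ultrametric"
        return f"<PhyloTree {self.n_tips} tips, {kind}, lam={self.lam:g}>"


# ---------------------------------------------------------------------- I/O


def _from_dendropy(dtree: dendropy.Tree) -> PhyloTree:
    n_poly = sum(
        1 for nd in dtree.preorder_node_iter() if len(nd.child_nodes()) > 2
    )
    if n_poly:
        logger.info(
            "resolving %d polytomies with zero-length internal edges", n_poly
        )
        dtree.resolve_polytomies(limit=2, update_bipartitions=False)
    nodes: list[_Node] = []
    index_of: dict[int, int] = {}
    for nd in dtree.preorder_node_iter():
        idx = len(nodes)
        index_of[id(nd)] = idx
        parent = index_of[id(nd.parent_node)] if nd.parent_node is not None else -1
        length = float(nd.edge.length) if nd.edge.length is not None else 0.0
        label = None
        if nd.is_leaf():
            if nd.taxon is not None and nd.taxon.label:
                label = str(nd.taxon.label)
            elif nd.label:
                label = str(nd.label)
        nodes.append(_Node(idx, parent, length, label, []))
        if parent != -1:
            nodes[parent].children.append(idx)
    return PhyloTree(nodes)


def read_newick(text: str) -> PhyloTree:
    """Parse a Newick string into a :class:`PhyloTree`.

    Branch lengths are required on all edges (missing ones read as 0 and
    are tolerated only at the root).  Labels containing spaces must be
    quoted.  Malformed input raises :class:`NewickError` carrying the
    parser's description of the offending position.
    """
    if not text or not text.strip():
        raise NewickError("empty Newick string")
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error classes
        raise NewickError(f"Newick parse failure: {exc}") from exc
    tree = _from_dendropy(dtree)
    if tree.is_degenerate:
        logger.warning("degenerate single-tip tree accepted")
    return tree


def write_newick(tree: PhyloTree) -> str:
    return tree.to_newick()


# ---------------------------------------------------------------- graft/prune


def graft_fossil_tip(
    tree: PhyloTree,
    stem_edge: int | str,
    stem_branch: float,
    tip_offset: float,
    label: str = "fossil",
) -> PhyloTree:
    """Insert a fossil tip on an existing edge.

    Parameters
    ----------
    stem_edge:
        Edge to attach to, named by its child-node index, or by a tip
        label (meaning that tip's terminal edge).
    stem_branch:
        Terminal branch length of the fossil (Myr), e.g. 1.4 for a stem
        lineage known from a 1.4-Myr window.
    tip_offset:
        How far before the present the fossil tip terminates (Myr); the
        fossil's depth becomes ``max extant depth - tip_offset``.

    The attachment point (fossil depth minus ``stem_branch``) must fall
    strictly inside the chosen edge's depth interval.
    """
    if stem_branch <= 0:
        raise ValueError("stem_branch must be > 0")
    if isinstance(stem_edge, str):
        stem_edge = tree.tip_index(stem_edge)
    if stem_edge <= 0 or stem_edge >= tree.n_nodes:
        raise ValueError(f"no such edge: {stem_edge}")
    if label in tree.tip_labels:
        raise ValueError(f"tip label {label!r} already present")

    depth_extant = tree.max_tip_depth
    tip_depth = depth_extant - tip_offset
    attach_depth = tip_depth - stem_branch
    child = tree.node(stem_edge)
    lo = tree.depths[child.parent]
    hi = tree.depths[stem_edge]
    if not (lo < attach_depth < hi):
        raise ValueError(
            f"attachment depth {attach_depth:.4g} Myr falls outside edge "
            f"({lo:.4g}, {hi:.4g}); the fossil cannot hang below its "
            "attachment point"
        )

    # Rebuild node list with an attachment node splitting the stem edge.
    old = tree
    new_nodes: list[_Node] = []

    def build(i: int, parent_new: int, length: float) -> int:
        idx = len(new_nodes)
        n = old.node(i)
        new_nodes.append(_Node(idx, parent_new, length, n.label, []))
        if parent_new != -1:
            new_nodes[parent_new].children.append(idx)
        for c in n.children:
            build_edge(c, idx)
        return idx

    def build_edge(child_i: int, parent_new: int) -> None:
        n = old.node(child_i)
        if child_i == stem_edge:
            upper = attach_depth - old.depths[n.parent]
            lower = old.depths[child_i] - attach_depth
            a_idx = len(new_nodes)
            new_nodes.append(_Node(a_idx, parent_new, upper, None, []))
            new_nodes[parent_new].children.append(a_idx)
            build(child_i, a_idx, lower)
            f_idx = len(new_nodes)
            new_nodes.append(_Node(f_idx, a_idx, stem_branch, label, []))
            new_nodes[a_idx].children.append(f_idx)
        else:
            build(child_i, parent_new, n.length)

    root = old.node(0)
    new_nodes.append(_Node(0, -1, 0.0, root.label, []))
    for c in root.children:
        build_edge(c, 0)
    out = PhyloTree(new_nodes, lam=tree.lam)
    assert out.n_tips == tree.n_tips + 1
    return out


def prune_tip(tree: PhyloTree, label: str) -> PhyloTree:
    """Remove a tip and suppress the resulting unary node."""
    drop = tree.tip_index(label)
    parent = tree.parent(drop)
    if parent == -1:
        raise ValueError("cannot prune the only tip of a degenerate tree")
    sibs = [c for c in tree.children(parent) if c != drop]

    new_nodes: list[_Node] = []

    def build(i: int, parent_new: int, extra: float) -> None:
        n = tree.node(i)
        if i == drop:
            return
        if i == parent and len(sibs) == 1 and tree.parent(parent) != -1:
            # unary after drop: splice the single sibling through
            build(sibs[0], parent_new, extra + n.length)
            return
        idx = len(new_nodes)
        length = n.length + extra if parent_new != -1 else 0.0
        new_nodes.append(_Node(idx, parent_new, length, n.label, []))
        if parent_new != -1:
            new_nodes[parent_new].children.append(idx)
        kids = n.children if i != parent else [c for c in n.children if c != drop]
        for c in kids:
            build(c, idx, 0.0)

    if parent == 0 and len(sibs) == 1:
        # root becomes unary: new root is the remaining child subtree
        sib = sibs[0]
        n = tree.node(sib)
        new_nodes.append(_Node(0, -1, 0.0, n.label, []))
        for c in n.children:
            build(c, 0, 0.0)
        return PhyloTree(new_nodes, lam=tree.lam)

    build(0, -1, 0.0)
    return PhyloTree(new_nodes, lam=tree.lam)


# ------------------------------------------------------------------ painting


@dataclasses.dataclass
class RegimePainting:
    """Assignment of every edge of a tree to one named selective regime.

    ``edge_regime`` maps child-node index -> regime label; ``root_regime``
    is the regime in force at the root (used as the ancestral state's
    regime under the root-optimum convention).
    """

    edge_regime: dict[int, str]
    root_regime: str

    @property
    def regimes(self) -> list[str]:
        seen: dict[str, None] = {self.root_regime: None}
        for r in self.edge_regime.values():
            seen.setdefault(r, None)
        return list(seen)

    @property
    def n_regimes(self) -> int:
        return len(self.regimes)

    def validate(self, tree: PhyloTree) -> None:
        edges = set(tree.edge_indices)
        painted = set(self.edge_regime)
        if painted != edges:
            missing = sorted(edges - painted)
            extra = sorted(painted - edges)
            raise ValueError(
                f"painting does not partition the tree: missing={missing}, "
                f"extra={extra}"
            )

    def to_table(self, tree: PhyloTree) -> "pd.DataFrame":  # noqa: F821
        import pandas as pd

        rows = []
        for e in tree.edge_indices:
            n = tree.node(e)
            rows.append(
                {
                    "edge": e,
                    "tip_label": n.label if n.is_tip else "",
                    "regime": self.edge_regime[e],
                }
            )
        return pd.DataFrame(rows)


def paint_regimes(
    tree: PhyloTree,
    clade_spec: Sequence[tuple[Iterable[str], str]],
    background: str = "background",
) -> RegimePainting:
    """Paint regimes onto a tree from crown-group specifications.

    Each ``(taxa, label)`` entry paints the crown group spanned by
    ``taxa`` — including its stem edge — with ``label``.  Entries are
    applied in order, so later entries override earlier ones on shared
    branches (nested hypotheses).  Every unclaimed edge carries
    ``background``.  A taxa set that is not monophyletic raises an error
    naming the intruding tips.
    """
    edge_regime = {e: background for e in tree.edge_indices}
    root_regime = background
    for taxa, label in clade_spec:
        taxa = set(taxa)
        missing = taxa - set(tree.tip_labels)
        if missing:
            raise KeyError(f"taxa absent from tree: {sorted(missing)}")
        m = tree.mrca(taxa)
        clade = tree.clade_tips(m) if not tree.node(m).is_tip else {tree.node(m).label}
        intruders = clade - taxa
        if intruders:
            raise ValueError(
                f"taxa set for regime {label!r} is not monophyletic; "
                f"intruding tips: {sorted(intruders)}"
            )
        for j in tree.subtree_nodes(m):
            if j == 0:
                root_regime = label
            else:
                edge_regime[j] = label
        # note: when m is the root there is no stem edge; regime shift at root
    painting = RegimePainting(edge_regime, root_regime)
    painting.validate(tree)
    return painting


def painting_from_shifts(
    tree: PhyloTree, shifts: Mapping[int, str], root_regime: str
) -> RegimePainting:
    """Build a painting from shift points at branch origins.

    A shift at edge ``e`` repaints ``e`` and all its descendants until
    overridden by a deeper shift (the SURFACE convention).
    """
    edge_regime: dict[int, str] = {}

    def walk(i: int, current: str) -> None:
        for c in tree.children(i):
            reg = shifts.get(c, current)
            edge_regime[c] = reg
            walk(c, reg)

    walk(0, root_regime)
    return RegimePainting(edge_regime, root_regime)


# ---------------------------------------------------------------- covariance


def vcv_bm(tree: PhyloTree) -> np.ndarray:
    """Brownian-motion covariance: entry (i,j) = root-to-MRCA path length.

    The diagonal holds tip depths, so fossil tips get their true (shorter)
    variances.  A Pagel's-lambda factor stored on the tree scales the
    off-diagonal entries.
    """
    tips = tree.tip_indices
    if len(tips) < 2:
        raise ValueError("vcv_bm needs >= 2 tips")
    n = len(tips)
    depths = tree.depths
    # ancestor sets (incl. self) per tip
    anc = []
    for t in tips:
        s = {t}
        s.update(tree.ancestors(t))
        anc.append(s)
    C = np.zeros((n, n))
    for a in range(n):
        C[a, a] = depths[tips[a]]
        for b in range(a + 1, n):
            shared = anc[a] & anc[b]
            C[a, b] = C[b, a] = max(depths[j] for j in shared)
    if tree.lam != 1.0:
        off = ~np.eye(n, dtype=bool)
        C[off] *= tree.lam
    return C


def lambda_transform(tree: PhyloTree, lam: float) -> PhyloTree:
    """Return a tree whose BM covariance has off-diagonals scaled by lam.

    Implemented in covariance space (the factor is stored on the tree and
    applied in :func:`vcv_bm`) so that fossil-tip variances stay exact.
    ``lam = 1`` is the identity; ``lam = 0`` removes all shared history.
    Values above 1 are admitted only while the covariance stays positive
    definite.
    """
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    out = tree.copy()
    out.lam = out.lam * lam if out.lam != 1.0 else lam
    if lam > 1.0:
        C = vcv_bm(out)
        if np.linalg.eigvalsh(C)[0] < -1e-9:
            raise ValueError(
                f"lambda={lam:g} destroys positive-definiteness of the "
                "phylogenetic covariance"
            )
    return out


def shorten_terminal_branch(
    tree: PhyloTree, label: str, new_length: float
) -> PhyloTree:
    """Set a tip's terminal branch length (e.g. shrinking *Homo sapiens*'
    terminal branch to sharpen optimum estimates).  Keeps topology."""
    if new_length < 0:
        raise ValueError("new_length must be >= 0")
    out = tree.copy()
    i = out.tip_index(label)
    out._nodes[i].length = float(new_length)
    out._depths = None
    return out


def mrca_depth_matrix(tree: PhyloTree) -> np.ndarray:
    """Shared root-to-MRCA path length between every tip pair (lam ignored)."""
    saved = tree.lam
    tree.lam = 1.0
    try:
        return vcv_bm(tree)
    finally:
        tree.lam = saved
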