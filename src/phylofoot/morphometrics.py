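"""Size standardization, ordination, and clustering of foot measurements.

The measurement table carries six linear lengths per individual (mm):
maximum talar articular length, talar trochlea length, cuboid length, MT1
length, MT5 length, and PP4 length.  Talar neck length is derived as
articular minus trochlea length, and the six variables entering the
analysis are trochlea, neck, cuboid, MT1, MT5, PP4.  Each row is divided
by its geometric mean, removing overall size, so the product of the six
standardized values per individual is 1.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "RAW_COLUMNS",
    "SHAPE_COLUMNS",
    "derive_talar_neck",
    "geomean_standardize",
    "PCAResult",
    "pca",
    "species_means",
    "UPGMAResult",
    "upgma_cophenetic",
]

#: raw caliper variables, in input order
RAW_COLUMNS = [
    "max_talar_articular",
    "talar_trochlea",
    "cuboid",
    "mt1",
    "mt5",
    "pp4",
]

#: the six variables entering the geometric mean / PCA
SHAPE_COLUMNS = ["talar_trochlea", "talar_neck", "cuboid", "mt1", "mt5", "pp4"]


def derive_talar_neck(max_articular, trochlea):
    """Talar neck length = maximum talar articular length - trochlea length.

    Accepts scalars or aligned arrays; every element must satisfy
    ``max_articular > trochlea > 0``.
    """
    a = np.asarray(max_articular, dtype=float)
    t = np.asarray(trochlea, dtype=float)
    if np.any(t <= 0):
        raise ValueError("trochlea length must be positive")
    if np.any(a <= t):
        bad = np.nonzero(np.atleast_1d(a <= t))[0]
        raise ValueError(
            f"max articular length must exceed trochlea length (rows {bad.tolist()})"
        )
    out = a - t
    return float(out) if out.ndim == 0 else out


def _require_taxon(df: pd.DataFrame) -> pd.Series:
    if "taxon" not in df.columns:
        raise ValueError("measurement table needs a 'taxon' column")
    return df["taxon"]


def geomean_standardize(table: pd.DataFrame) -> pd.DataFrame:
    """Divide each individual's six variables by their geometric mean.

    Input may carry either the raw column set (with ``max_talar_articular``,
    from which the talar neck is derived) or the shape column set directly.
    Returns a table with ``taxon``, the six standardized columns, and the
    per-row geometric mean (mm) in ``geomean``.
    """
    taxon = _require_taxon(table)
    if set(SHAPE_COLUMNS).issubset(table.columns):
        X = table[SHAPE_COLUMNS].to_numpy(dtype=float)
    elif set(RAW_COLUMNS).issubset(table.columns):
        neck = derive_talar_neck(
            table["max_talar_articular"], table["talar_trochlea"]
        )
        X = np.column_stack(
            [table["talar_trochlea"].to_numpy(float), np.atleast_1d(neck)]
            + [table[c].to_numpy(float) for c in ("cuboid", "mt1", "mt5", "pp4")]
        )
    else:
        raise ValueError(
            f"need columns {SHAPE_COLUMNS} or {RAW_COLUMNS} plus 'taxon'"
        )
    bad = np.nonzero(~np.all(X > 0, axis=1))[0]
    if bad.size:
        raise ValueError(f"non-positive measurement in rows {bad.tolist()}")
    gm = np.exp(np.mean(np.log(X), axis=1))
    Z = X / gm[:, None]
    out = pd.DataFrame(Z, columns=SHAPE_COLUMNS, index=table.index)
    out.insert(0, "taxon", taxon.values)
    out["geomean"] = gm
    return out


@dataclasses.dataclass
class PCAResult:
    """Covariance-matrix PCA of standardized variables.

    ``loadings`` columns are unit eigenvectors (variables x components),
    sign-fixed so each column's largest-magnitude entry is positive;
    ``scores`` are centered data projected on the loadings.
    """

    eigenvalues: np.ndarray
    percent_variance: np.ndarray
    loadings: pd.DataFrame
    scores: pd.DataFrame
    mean: np.ndarray

    @property
    def n_components(self) -> int:
        return len(self.eigenvalues)


def pca(standardized: pd.DataFrame, n_components: int | None = None) -> PCAResult:
    """Principal components of the standardized variables (covariance PCA).

    Requires at least one more row than variables.  Eigenvalues are the
    component variances (divisor n-1); percent variances sum to 100.
    """
    taxon = _require_taxon(standardized)
    X = standardized[SHAPE_COLUMNS].to_numpy(dtype=float)
    n, p = X.shape
    if n <= p:
        raise ValueError(f"PCA needs > {p} rows, got {n}")
    mean = X.mean(axis=0)
    Xc = X - mean
    # SVD route: eigenvalues of the covariance are s^2/(n-1)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    eig = s**2 / (n - 1)
    V = Vt.T
    # sign convention: largest |entry| of each loading column positive
    for j in range(V.shape[1]):
        k = np.argmax(np.abs(V[:, j]))
        if V[k, j] < 0:
            V[:, j] = -V[:, j]
    scores = Xc @ V
    if n_components is not None:
        eig = eig[:n_components]
        V = V[:, :n_components]
        scores = scores[:, :n_components]
    pct = 100.0 * eig / (s**2 / (n - 1)).sum()
    comp = [f"PC{i + 1}" for i in range(len(eig))]
    loadings = pd.DataFrame(V, index=SHAPE_COLUMNS, columns=comp)
    scores_df = pd.DataFrame(scores, columns=comp, index=standardized.index)
    scores_df.insert(0, "taxon", taxon.values)
    return PCAResult(eig, pct, loadings, scores_df, mean)


def species_means(scores: pd.DataFrame) -> pd.DataFrame:
    """Arithmetic mean of each numeric column per taxon.

    Returns a taxon-indexed DataFrame (one row per taxon) suitable for
    aligning against tree tips.
    """
    _require_taxon(scores)
    num = scores.select_dtypes(include=[np.number]).columns
    out = scores.groupby("taxon", sort=True)[list(num)].mean()
    return out


def align_to_tree(traits: pd.DataFrame, tree) -> pd.DataFrame:
    """Reorder a taxon-indexed trait table to the tree's tip order."""
    missing = [t for t in tree.tip_labels if t not in traits.index]
    if missing:
        raise KeyError(f"taxa in tree missing from trait table: {missing}")
    return traits.loc[tree.tip_labels]


@dataclasses.dataclass
class UPGMAResult:
    linkage: np.ndarray  # scipy linkage matrix
    labels: list[str]
    cophenetic_r: float
    degenerate: bool  # cophenetic r undefined (all distances tied)

    def to_newick(self) -> str:
        """Dendrogram as a Newick string with branch lengths from heights."""
        tree = hierarchy.to_tree(self.linkage)

        def fmt(node, parent_height):
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{self.labels[node.id]}:{length:.10g}"
            inner = ",".join(fmt(c, node.dist) for c in (node.left, node.right))
            return f"({inner}):{length:.10g}"

        root = tree
        inner = ",".join(fmt(c, root.dist) for c in (root.left, root.right))
        return f"({inner});"


def upgma_cophenetic(traits: pd.DataFrame) -> UPGMAResult:
    """UPGMA clustering on Euclidean distances with cophenetic validation.

    The cophenetic correlation is the Pearson correlation between the
    original pairwise distances and the dendrogram's cophenetic
    distances; when all input distances are tied it is undefined and the
    result is flagged degenerate (r reported as nan).
    """
    X = traits.select_dtypes(include=[np.number]).to_numpy(dtype=float)
    labels = [str(t) for t in traits.index]
    if len(labels) < 3:
        raise ValueError("UPGMA needs >= 3 taxa")
    d = pdist(X, metric="euclidean")
    if np.any(d == 0):
        warnings.warn(
            "duplicate taxon rows at zero distance; merged at height 0",
            stacklevel=2,
        )
    Z = hierarchy.linkage(d, method="average")
    coph = hierarchy.cophenet(Z)
    degenerate = np.allclose(d, d[0]) or np.allclose(coph, coph[0])
    if degenerate:
        r = float("nan")
    else:
        r = float(np.corrcoef(d, coph)[0, 1])
    return UPGMAResult(Z, labels, r, degenerate)
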