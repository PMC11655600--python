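"""Diet-breadth diversity statistics and ordination.

Implements the abundance-based Morisita–Horn dissimilarity between the
plant-visit profiles of two bee species, classical principal-coordinates
ordination of the resulting dissimilarity matrix, the inverse Simpson
diversity (Hill number of order q = 2), and its phylogenetic
generalisation qPD, in which branch lengths of the plant phylogeny weight
how distantly related the visited genera are.
"""

from __future__ import annotations

from typing import Mapping, Optional, Tuple

import numpy as np
import pandas as pd

from .trees import GenusTree


def morisita_horn_dissimilarity(x, y) -> float:
    """1 − C_MH for two nonnegative count vectors of equal length.

    C_MH = 2 Σ xᵢyᵢ / ((d_x + d_y) · X · Y) with X = Σxᵢ, Y = Σyᵢ,
    d_x = Σxᵢ²/X², d_y = Σyᵢ²/Y². Zero for identical relative profiles,
    one for disjoint supports.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    if (x < 0).any() or (y < 0).any():
        raise ValueError("counts must be nonnegative")
    X, Y = x.sum(), y.sum()
    if X <= 0 or Y <= 0:
        raise ValueError("zero-sum count vector")
    dx = (x**2).sum() / X**2
    dy = (y**2).sum() / Y**2
    c = 2.0 * (x * y).sum() / ((dx + dy) * X * Y)
    return float(min(1.0, max(0.0, 1.0 - c)))


def morisita_horn_matrix(counts: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Morisita–Horn dissimilarities between the rows of a
    species × taxon count matrix."""
    M = counts.to_numpy(dtype=float)
    if (M.sum(axis=1) <= 0).any():
        bad = counts.index[M.sum(axis=1) <= 0].tolist()
        raise ValueError(f"rows with zero total counts: {bad}")
    X = M.sum(axis=1)
    d = (M**2).sum(axis=1) / X**2
    cross = M @ M.T
    C = 2.0 * cross / ((d[:, None] + d[None, :]) * X[:, None] * X[None, :])
    D = np.clip(1.0 - C, 0.0, 1.0)
    D = (D + D.T) / 2.0  # exact symmetry despite float association order
    np.fill_diagonal(D, 0.0)
    return pd.DataFrame(D, index=counts.index, columns=counts.index)


def ordination_scores(
    D: pd.DataFrame, n_axes: int = 2, method: str = "pcoa"
) -> pd.DataFrame:
    """First ``n_axes`` ordination axes of a dissimilarity matrix.

    ``method="pcoa"`` (default): classical principal-coordinates analysis —
    Gower double-centering of −½D², eigendecomposition, coordinates scaled
    by √eigenvalue, axes in descending eigenvalue order. Axes with negative
    eigenvalues (possible because Morisita–Horn is not Euclidean-embeddable
    in general) are excluded before the first ``n_axes`` are taken.

    ``method="raw"``: unscaled eigenvectors of D itself, for comparison.

    Sign convention for both: each axis is flipped so its largest-magnitude
    loading is positive, making the output reproducible.
    """
    Dm = D.to_numpy(dtype=float)
    if np.isnan(Dm).any():
        raise ValueError("dissimilarity matrix contains NaN")
    if not np.allclose(Dm, Dm.T, atol=1e-10):
        raise ValueError("dissimilarity matrix must be symmetric")
    n = Dm.shape[0]

    if method == "pcoa":
        A = -0.5 * Dm**2
        J = np.eye(n) - np.ones((n, n)) / n
        G = J @ A @ J
        vals, vecs = np.linalg.eigh((G + G.T) / 2.0)
        order = np.argsort(vals)[::-1]
        vals, vecs = vals[order], vecs[:, order]
        pos = vals > max(1e-12, 1e-9 * abs(vals).max(initial=1.0))
        vals, vecs = vals[pos], vecs[:, pos]
        coords = vecs * np.sqrt(vals)
    elif method == "raw":
        vals, vecs = np.linalg.eigh((Dm + Dm.T) / 2.0)
        order = np.argsort(np.abs(vals))[::-1]
        coords = vecs[:, order]
    else:
        raise ValueError(f"unknown ordination method: {method!r}")

    out = np.zeros((n, n_axes))
    k = min(n_axes, coords.shape[1])
    out[:, :k] = coords[:, :k]
    for j in range(k):
        i_max = np.argmax(np.abs(out[:, j]))
        if out[i_max, j] < 0:
            out[:, j] = -out[:, j]
    return pd.DataFrame(
        out, index=D.index, columns=[f"axis{i+1}" for i in range(n_axes)]
    )


def inverse_simpson(counts) -> float:
    """Effective number of equally common taxa: 1 / Σ pᵢ²."""
    c = np.asarray(counts, dtype=float)
    if (c < 0).any():
        raise ValueError("counts must be nonnegative")
    total = c.sum()
    if total <= 0:
        raise ValueError("zero total count")
    p = c / total
    return float(1.0 / (p**2).sum())


def _branch_abundances(tree: GenusTree, props: Mapping[str, float]):
    """(length, abundance) per edge: abundance = summed tip proportions
    descending through the edge."""
    out = []
    node_ab = {}
    t = tree.tree
    for node in t.postorder_node_iter():
        if node.is_leaf():
            ab = props.get(node.taxon.label, 0.0)
        else:
            ab = sum(node_ab[id(ch)] for ch in node.child_nodes())
        node_ab[id(node)] = ab
        length = node.edge.length or 0.0
        if node.parent_node is not None and length > 0 and ab > 0:
            out.append((length, ab))
    return out


def phylo_simpson(tree: GenusTree, counts: Mapping[str, float]) -> float:
    """Phylogenetic Hill–Simpson diversity qPD at q = 2.

    With branch lengths Lᵢ, branch abundances aᵢ (tip proportions summed
    through each branch), and mean depth T̄ = Σ Lᵢaᵢ:

        qPD = 1 / Σ (Lᵢ/T̄) aᵢ²

    Reduces to the inverse Simpson index on a star tree with equal branch
    lengths, and to 1.0 when a single genus is visited.
    """
    counts = {k: float(v) for k, v in counts.items() if v > 0}
    if not counts:
        raise ValueError("no positive counts")
    tips = set(tree.family_map)
    missing = sorted(set(counts) - tips)
    if missing:
        raise KeyError(f"counted taxa missing from tree: {missing}")
    total = sum(counts.values())
    props = {k: v / total for k, v in counts.items()}
    branches = _branch_abundances(tree, props)
    tbar = sum(L * a for L, a in branches)
    if tbar <= 0:
        return 1.0
    s = sum((L / tbar) * a * a for L, a in branches)
    return float(1.0 / s)


def faith_pd(tree: GenusTree, counts: Mapping[str, float]) -> float:
    """Faith's phylogenetic richness: total branch length spanning the
    visited tips. Computed only for the collinearity report, never used as
    a model predictor."""
    counts = {k: v for k, v in counts.items() if v > 0}
    props = {k: 1.0 for k in counts}
    return float(sum(L for L, a in _branch_abundances(tree, props)))
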