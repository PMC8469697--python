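"""Multivariate comparison of ligand bias profiles.

Bias factors for one cell model are assembled into a ligands x
readout-pairs matrix (the reference ligand's row is identically 0 by
definition; non-determined entries are imputed to 0 and masked, or the
ligand row dropped).  Ligand profiles are then compared by principal
component analysis — column-mean-centered, unscaled by default since all
entries share log10-bias units — followed by Ward-linkage hierarchical
clustering on the retained principal-component scores (components
covering >= 95% of the variance, at least two), cut at k clusters.

Caveat inherited from the imputation rule: a ligand with no determined
bias value gets an all-zero row and lands exactly on the reference in
every projection, which signals missing information, not pharmacological
equivalence.  The mask records which entries were imputed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from sklearn.decomposition import PCA

from .types import BiasMatrix, PCAResult

__all__ = ["build_bias_matrix", "run_pca", "cluster_pca", "linkage_to_newick"]


def build_bias_matrix(bias_table: pd.DataFrame, cell_model: str,
                      impute: str = "zero", reference: str | None = None) -> BiasMatrix:
    """Assemble the ligands x pairs ΔΔLogBF matrix for one cell model.

    ``impute="zero"`` replaces nd / non-identifiable entries with 0 and
    masks them; ``impute="drop"`` removes ligands having any such entry.
    """
    if impute not in ("zero", "drop"):
        raise ValueError(f"unknown imputation policy {impute!r}")
    sub = bias_table[bias_table["cell_model"] == cell_model]
    if sub.empty:
        raise ValueError(f"bias table has no rows for cell model {cell_model!r}")
    pairs = list(dict.fromkeys(zip(sub["response1"], sub["response2"])))
    ligands = list(dict.fromkeys(sub["ligand"]))
    if reference is None:
        reference = "reference"
    values = np.zeros((len(ligands) + 1, len(pairs)))
    mask = np.zeros_like(values, dtype=bool)
    for i, lig in enumerate(ligands, start=1):
        for j, (r1, r2) in enumerate(pairs):
            row = sub[(sub["ligand"] == lig) & (sub["response1"] == r1) & (sub["response2"] == r2)]
            if row.empty:
                mask[i, j] = True
                continue
            val = float(row["ddlogbf"].iloc[0])
            usable = row["display"].iloc[0] != "nd" and np.isfinite(val)
            if usable:
                values[i, j] = val
            else:
                mask[i, j] = True  # imputed to 0
    all_ligands = [reference] + ligands
    all_nd = [all_ligands[i] for i in range(1, len(all_ligands)) if mask[i].all()]
    if all_nd:
        import warnings

        warnings.warn(f"ligand(s) {all_nd} have no determined bias value; "
                      "their zero rows coincide with the reference", stacklevel=2)
    if impute == "drop":
        keep = [0] + [i for i in range(1, len(all_ligands)) if not mask[i].any()]
        all_ligands = [all_ligands[i] for i in keep]
        values, mask = values[keep], mask[keep]
    return BiasMatrix(cell_model=cell_model, ligands=all_ligands, pairs=pairs,
                      values=values, mask=mask, reference=reference)


def run_pca(m: BiasMatrix, scale: bool = False) -> PCAResult:
    """Column-mean-centered (optionally standardized) PCA of a bias matrix.

    Deterministic up to the documented sign convention: each component is
    oriented so its largest-magnitude loading is positive.  A rank-0
    matrix (all rows identical) yields a degenerate result with zero
    scores and variance fractions, not an exception.
    """
    X = np.asarray(m.values, dtype=float)
    if X.shape[0] < 3 or X.shape[1] < 2:
        raise ValueError("PCA needs at least 3 ligands and 2 readout pairs")
    if not np.all(np.isfinite(X)):
        raise ValueError("unmasked missing values in bias matrix")
    if scale:
        sd = X.std(axis=0, ddof=0)
        X = X / np.where(sd > 0, sd, 1.0)
    n_comp = min(X.shape[0] - 1, X.shape[1])
    if np.allclose(X, X[0], atol=1e-15):
        return PCAResult(ligands=list(m.ligands),
                         scores=np.zeros((X.shape[0], n_comp)),
                         loadings=np.zeros((n_comp, X.shape[1])),
                         explained_variance_ratio=np.zeros(n_comp),
                         degenerate=True)
    pca = PCA(n_components=n_comp, svd_solver="full")
    scores = pca.fit_transform(X)
    loadings = pca.components_
    # sign convention: largest-|loading| positive per component
    for k in range(loadings.shape[0]):
        j = int(np.argmax(np.abs(loadings[k])))
        if loadings[k, j] < 0:
            loadings[k] *= -1.0
            scores[:, k] *= -1.0
    return PCAResult(ligands=list(m.ligands), scores=scores, loadings=loadings,
                     explained_variance_ratio=pca.explained_variance_ratio_.copy())


def cluster_pca(p: PCAResult, k: int = 3, variance_target: float = 0.95):
    """Ward clustering on retained PC scores, cut at ``k`` clusters.

    Retains the leading components covering at least ``variance_target``
    of the variance (minimum 2).  Returns ``(labels, linkage, newick)``;
    labels are renumbered in order of first appearance so they are stable
    under row permutation up to renaming.
    """
    n = p.scores.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds number of ligands ({n})")
    if p.degenerate:
        keep = p.scores.shape[1]
    else:
        cum = np.cumsum(p.explained_variance_ratio)
        keep = max(2, int(np.searchsorted(cum, variance_target - 1e-12) + 1))
        keep = min(keep, p.scores.shape[1])
    X = p.scores[:, :keep]
    Z = hierarchy.linkage(X, method="ward")
    raw = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    relabel: dict[int, int] = {}
    labels = np.array([relabel.setdefault(c, len(relabel) + 1) for c in raw])
    return labels, Z, linkage_to_newick(Z, p.ligands)


def linkage_to_newick(Z: np.ndarray, names: list[str]) -> str:
    """Serialize a scipy linkage matrix as a Newick tree string."""
    tree = hierarchy.to_tree(Z)

    def walk(node, parent_dist: float) -> str:
        length = max(parent_dist - node.dist, 0.0)
        if node.is_leaf():
            return f"{names[node.id]}:{length:.6g}"
        left = walk(node.left, node.dist)
        right = walk(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return walk(tree, tree.dist) + ";"
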