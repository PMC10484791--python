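"""Diffusion pseudotime on unperturbed cells and kNN transfer to perturbed cells.

Pseudotime is computed only on the non-targeting-control (NTC) population,
where no knockout perturbs the trajectory, using a diffusion-map kernel on a
kNN graph in PCA space; it is then transferred to perturbed cells as the
mean pseudotime of their k = 15 nearest NTC cells in the first 8 principal
components. Reference 2-D coordinates are likewise projected onto query
cells by kNN averaging with k = 20. Branch labels are inputs; per-branch
pseudotime is rescaled to the unit interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.sparse.linalg import eigsh
from sklearn.neighbors import NearestNeighbors

__all__ = [
    "PCAModel",
    "EmbeddingBundle",
    "PseudotimeVector",
    "pca_embed",
    "diffusion_pseudotime",
    "knn_pseudotime_transfer",
    "scale_branch",
    "knn_project_coordinates",
]


@dataclass
class PCAModel:
    """Frozen PCA basis: per-gene means and component loadings, so query
    cells can be projected into the reference basis."""

    mean_: np.ndarray
    components_: np.ndarray  # n_pcs x n_genes
    explained_variance_ratio_: np.ndarray

    def transform(self, x: np.ndarray) -> np.ndarray:
        return (np.asarray(x, dtype=float) - self.mean_) @ self.components_.T


@dataclass
class EmbeddingBundle:
    """Row-aligned embeddings for one set of cells."""

    cell_ids: pd.Index
    pca: np.ndarray
    diffusion: np.ndarray | None = None
    coords: np.ndarray | None = None  # reference 2-D coordinates
    branch: pd.Series | None = None
    pca_model: PCAModel | None = None


@dataclass
class PseudotimeVector:
    """Pseudotime per cell; the root maps to 0. When ``scaled`` the values
    lie in [0, 1] within each branch."""

    values: pd.Series
    root_cell: str | None = None
    scaled: bool = False


def pca_embed(
    expr: np.ndarray | pd.DataFrame, n_pcs: int = 8
) -> tuple[EmbeddingBundle, PCAModel]:
    """Deterministic PCA of a cells x genes matrix.

    Centering is per gene; the sign of each component is fixed so that its
    largest-magnitude loading is positive. Raises if ``n_pcs`` exceeds the
    matrix rank.
    """
    if isinstance(expr, pd.DataFrame):
        ids = expr.index
        x = expr.to_numpy(dtype=float)
    else:
        x = np.asarray(expr, dtype=float)
        ids = pd.RangeIndex(len(x))
    mean = x.mean(axis=0)
    xc = x - mean
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    rank = int(np.sum(s > s[0] * 1e-10)) if s.size else 0
    if n_pcs > rank:
        raise ValueError(f"n_pcs={n_pcs} exceeds matrix rank {rank}")
    vt = vt[:n_pcs]
    s = s[:n_pcs]
    u = u[:, :n_pcs]
    # sign convention: largest-|loading| entry of each component positive
    for i in range(n_pcs):
        j = int(np.argmax(np.abs(vt[i])))
        if vt[i, j] < 0:
            vt[i] *= -1.0
            u[:, i] *= -1.0
    total_var = (xc ** 2).sum()
    evr = (s ** 2) / total_var if total_var > 0 else np.zeros(n_pcs)
    model = PCAModel(mean_=mean, components_=vt.copy(),
                     explained_variance_ratio_=evr)
    scores = u * s
    return EmbeddingBundle(cell_ids=pd.Index(ids), pca=scores, pca_model=model), model


def _diffusion_operator(x: np.ndarray, k: int):
    """Symmetrized, density-normalized diffusion kernel on the kNN graph.

    Returns the symmetric conjugate A = D^{-1/2} K D^{-1/2} of the
    row-stochastic transition matrix, together with D^{-1/2}.
    """
    n = len(x)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(x)
    dist, idx = nn.kneighbors(x)
    dist, idx = dist[:, 1:], idx[:, 1:]  # drop self
    # adaptive bandwidth: distance to the ceil(k/2)-th neighbor
    sigma = dist[:, int(np.ceil(k / 2)) - 1]
    sigma = np.maximum(sigma, 1e-12)
    rows = np.repeat(np.arange(n), k)
    cols = idx.ravel()
    w = np.exp(-(dist.ravel() ** 2) / (sigma[rows] * sigma[cols]))
    kmat = coo_matrix((w, (rows, cols)), shape=(n, n)).tocsr()
    kmat = kmat.maximum(kmat.T)  # symmetric union graph
    ncomp, labels = connected_components(kmat, directed=False)
    if ncomp > 1:
        sizes = np.bincount(labels)
        raise ValueError(
            f"kNN graph is disconnected ({ncomp} components, sizes {sizes.tolist()}); "
            "increase k"
        )
    # density normalization (alpha = 1) removes sampling-density bias
    q = np.asarray(kmat.sum(axis=1)).ravel()
    dq = 1.0 / q
    kmat = kmat.multiply(dq[:, None]).multiply(dq[None, :]).tocsr()
    d = np.asarray(kmat.sum(axis=1)).ravel()
    dinv_sqrt = 1.0 / np.sqrt(d)
    a = kmat.multiply(dinv_sqrt[:, None]).multiply(dinv_sqrt[None, :]).tocsr()
    return a, dinv_sqrt


def diffusion_pseudotime(
    ref: EmbeddingBundle,
    root: str | int,
    n_dcs: int = 10,
    k: int = 30,
) -> tuple[PseudotimeVector, np.ndarray]:
    """Diffusion pseudotime of the reference (NTC) cells from a root cell.

    A Gaussian kernel with per-cell adaptive bandwidth (distance to the
    ceil(k/2)-th neighbor) is built on the symmetrized kNN graph,
    density-normalized, and row-normalized into a transition operator. The
    pseudotime of cell x is its diffusion distance from the root accumulated
    over the top ``n_dcs`` non-trivial eigencomponents,
    dpt(x) = || sum_i (lambda_i / (1 - lambda_i)) psi_i (x - root) ||.
    Eigenvector signs are fixed for determinism; the root maps to 0.

    Returns the pseudotime vector and the diffusion-component matrix.
    """
    n = len(ref.pca)
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of cells ({n})")
    if isinstance(root, (int, np.integer)) and root not in ref.cell_ids:
        root_pos = int(root)
    else:
        if root not in ref.cell_ids:
            raise ValueError(f"root cell {root!r} not in reference")
        root_pos = int(ref.cell_ids.get_loc(root))
    a, dinv_sqrt = _diffusion_operator(np.asarray(ref.pca, dtype=float), k)
    n_eig = min(n_dcs + 1, n - 1)
    # fixed start vector keeps the Lanczos iteration bit-reproducible
    v0 = np.full(n, 1.0 / np.sqrt(n))
    # largest-algebraic: diffusion components are the slow modes near 1,
    # not large-magnitude oscillatory (negative) modes
    evals, evecs = eigsh(a, k=n_eig, which="LA", v0=v0)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    # psi: right eigenvectors of the row-stochastic operator, unit norm
    psi = evecs * dinv_sqrt[:, None]
    psi /= np.linalg.norm(psi, axis=0, keepdims=True)
    # deterministic sign: largest-|entry| coordinate positive
    for i in range(psi.shape[1]):
        j = int(np.argmax(np.abs(psi[:, i])))
        if psi[j, i] < 0:
            psi[:, i] *= -1.0
    lam = np.clip(evals[1:], None, 1.0 - 1e-10)
    comps = psi[:, 1:]
    g = comps * (lam / (1.0 - lam))[None, :]
    diff = g - g[root_pos]
    pt = np.sqrt((diff ** 2).sum(axis=1))
    values = pd.Series(pt, index=ref.cell_ids, name="pseudotime")
    return PseudotimeVector(values=values, root_cell=str(ref.cell_ids[root_pos])), comps


def _knn_mean(
    ref_x: np.ndarray, ref_values: np.ndarray, query_x: np.ndarray, k: int
) -> np.ndarray:
    if k > len(ref_x):
        raise ValueError(f"k={k} exceeds reference size {len(ref_x)}")
    nn = NearestNeighbors(n_neighbors=k).fit(ref_x)
    _, idx = nn.kneighbors(query_x)
    return ref_values[idx].mean(axis=1)


def knn_pseudotime_transfer(
    ref: EmbeddingBundle,
    ref_pt: PseudotimeVector,
    query_pca: np.ndarray | pd.DataFrame,
    k: int = 15,
    n_pcs: int = 8,
) -> PseudotimeVector:
    """Assign each perturbed cell the mean pseudotime of its k nearest
    reference (NTC) cells, by Euclidean distance in the first ``n_pcs``
    principal components of the shared basis."""
    if isinstance(query_pca, pd.DataFrame):
        q_ids = query_pca.index
        q = query_pca.to_numpy(dtype=float)
    else:
        q = np.asarray(query_pca, dtype=float)
        q_ids = pd.RangeIndex(len(q))
    ref_x = np.asarray(ref.pca, dtype=float)[:, :n_pcs]
    vals = ref_pt.values.loc[ref.cell_ids].to_numpy()
    out = _knn_mean(ref_x, vals, q[:, :n_pcs], k)
    return PseudotimeVector(
        values=pd.Series(out, index=q_ids, name="pseudotime"),
        root_cell=ref_pt.root_cell,
    )


def scale_branch(pt: PseudotimeVector, branches: pd.Series) -> PseudotimeVector:
    """Rescale pseudotime to the unit interval within each branch;
    a degenerate branch (max == min) maps to 0."""
    branches = branches.loc[pt.values.index]
    out = pt.values.astype(float).copy()
    for _, idx in out.groupby(branches).groups.items():
        v = out.loc[idx]
        lo, hi = v.min(), v.max()
        out.loc[idx] = 0.0 if hi == lo else (v - lo) / (hi - lo)
    return PseudotimeVector(values=out, root_cell=pt.root_cell, scaled=True)


def knn_project_coordinates(
    ref: EmbeddingBundle,
    query_pca: np.ndarray | pd.DataFrame,
    k: int = 20,
    n_pcs: int | None = None,
) -> pd.DataFrame:
    """Predict reference 2-D coordinates for query cells as the mean of the
    k nearest reference cells' coordinates in the shared PCA basis."""
    if ref.coords is None:
        raise ValueError("reference bundle carries no 2-D coordinates")
    if isinstance(query_pca, pd.DataFrame):
        q_ids = query_pca.index
        q = query_pca.to_numpy(dtype=float)
    else:
        q = np.asarray(query_pca, dtype=float)
        q_ids = pd.RangeIndex(len(q))
    ref_x = np.asarray(ref.pca, dtype=float)
    if n_pcs is not None:
        ref_x = ref_x[:, :n_pcs]
        q = q[:, :n_pcs]
    if k > len(ref_x):
        raise ValueError(f"k={k} exceeds reference size {len(ref_x)}")
    nn = NearestNeighbors(n_neighbors=k).fit(ref_x)
    _, idx = nn.kneighbors(q)
    coords = np.asarray(ref.coords, dtype=float)[idx].mean(axis=1)
    return pd.DataFrame(coords, index=q_ids, columns=["coord1", "coord2"])
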