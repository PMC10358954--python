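"""Tree-guided multi-task spectral clustering of diffused gene networks.

Each cell type's similarity matrix S is spectrally embedded with the
regularized graph Laplacian L_tau = I - D_tau^{-1/2} A D_tau^{-1/2}, where
D_tau = D + mu_D adds the mean degree to the degree diagonal.  Cluster
identities are matched across cell types by a tree-guided warm-start scheme:
all embeddings are aligned to a reference embedding (built from the
leaf-averaged similarity) by orthogonal Procrustes, k-means is seeded at the
tree root with k-means++ on the reference, and every tree node's k-means is
warm-started from its parent's centroids, so label c means the same cluster
in every cell type by construction.  This is a variant reconstruction of
tree-guided multi-task clustering from its two contracts: per-cell-type
spectral clustering on L_tau and cross-cell-type cluster correspondence
guided by the cell-type tree.

The cluster count is selected from a grid (default {6, 7, 8, 9}) by average
Newman modularity subject to a minimum cluster size.  Gene sets that change
cluster membership coherently within a subtree ("transitioning" sets) are
found by average-linkage clustering of the genes' label vectors under
Hamming-fraction distance, cut at height 0.1, keeping sets of >= 5 genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from scipy.stats import hypergeom
from sklearn.cluster import KMeans
from sklearn.decomposition import NMF

from .loops import bh_qvalues
from .networks import CellTypeTree

K_GRID = (6, 7, 8, 9)
DEFAULT_K = 7
MIN_SET_SIZE = 5
CUT_HEIGHT = 0.1


def spectral_embed(S, k: int) -> np.ndarray:
    """Rows of the k bottom eigenvectors of the regularized Laplacian,
    normalized to unit length (all-zero rows are left zero)."""
    A = np.asarray(S, dtype=float).copy()
    if A.shape[0] != A.shape[1]:
        raise ValueError("similarity matrix must be square")
    if k >= A.shape[0]:
        raise ValueError("k must be smaller than the number of nodes")
    if not np.allclose(A, A.T, atol=1e-8):
        raise ValueError("similarity matrix must be symmetric")
    if A.min() < 0:
        raise ValueError("similarity matrix must be non-negative")
    np.fill_diagonal(A, 0.0)
    deg = A.sum(axis=1)
    d_tau = deg + deg.mean()
    inv = 1.0 / np.sqrt(d_tau)
    L = np.eye(len(A)) - inv[:, None] * A * inv[None, :]
    _, vec = linalg.eigh(L, subset_by_index=[0, k - 1])
    norms = np.linalg.norm(vec, axis=1)
    out = vec.copy()
    nz = norms > 0
    out[nz] = vec[nz] / norms[nz, None]
    return out


def _align(E: np.ndarray, E_ref: np.ndarray) -> np.ndarray:
    """Orthogonal Procrustes rotation of an embedding onto the reference."""
    R, _ = linalg.orthogonal_procrustes(E, E_ref)
    return E @ R


@dataclass
class ClusterAssignment:
    """Genes x cell types cluster labels (1..k), identities matched across
    cell types."""

    labels: pd.DataFrame
    k: int
    embeddings: dict[str, np.ndarray] = field(default_factory=dict)


def multitask_cluster(similarities: dict[str, pd.DataFrame], tree: CellTypeTree,
                      k: int = DEFAULT_K, seed: int = 0,
                      root_restarts: int = 50) -> ClusterAssignment:
    """Cluster every cell type with tree-guided warm-started k-means."""
    if set(tree.labels) != set(similarities):
        raise ValueError("tree leaves must equal the cell-type set")
    genes = sorted(set().union(*(list(s.index) for s in similarities.values())))
    aligned: dict[str, np.ndarray] = {}
    mats = {}
    for ct, S in similarities.items():
        M = S.reindex(index=genes, columns=genes).fillna(0.0)
        vals = M.to_numpy()
        np.fill_diagonal(vals, 1.0)
        mats[ct] = vals
    S_ref = np.mean([mats[ct] for ct in sorted(mats)], axis=0)
    E_ref = spectral_embed(S_ref, k)
    for ct in similarities:
        aligned[ct] = _align(spectral_embed(mats[ct], k), E_ref)

    root_km = KMeans(n_clusters=k, n_init=root_restarts, random_state=seed)
    root_km.fit(E_ref)

    label_cols: dict[str, np.ndarray] = {}

    def leaf_mean(node) -> np.ndarray:
        names = tree.leaves_under(node)
        return np.mean([aligned[n] for n in names], axis=0)

    def descend(node, parent_centroids: np.ndarray) -> None:
        E = aligned[tree.labels[node.id]] if node.is_leaf() else leaf_mean(node)
        km = KMeans(n_clusters=k, init=parent_centroids, n_init=1,
                    random_state=seed)
        km.fit(E)
        if node.is_leaf():
            label_cols[tree.labels[node.id]] = km.labels_ + 1
        else:
            descend(node.left, km.cluster_centers_)
            descend(node.right, km.cluster_centers_)

    root = tree.to_tree()
    descend(root, root_km.cluster_centers_)
    labels = pd.DataFrame(label_cols, index=genes)[sorted(label_cols)]
    return ClusterAssignment(labels=labels, k=k, embeddings=aligned)


def independent_cluster(similarities: dict[str, pd.DataFrame], k: int,
                        seed: int = 0, n_init: int = 50) -> ClusterAssignment:
    """Per-cell-type spectral clustering with no cross-cell-type coupling
    (comparison baseline; labels are *not* matched across cell types)."""
    genes = sorted(set().union(*(list(s.index) for s in similarities.values())))
    label_cols: dict[str, np.ndarray] = {}
    embeddings = {}
    for ct in sorted(similarities):
        M = similarities[ct].reindex(index=genes, columns=genes).fillna(0.0)
        vals = M.to_numpy()
        np.fill_diagonal(vals, 1.0)
        E = spectral_embed(vals, k)
        km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(E)
        label_cols[ct] = km.labels_ + 1
        embeddings[ct] = E
    labels = pd.DataFrame(label_cols, index=genes)[sorted(label_cols)]
    return ClusterAssignment(labels=labels, k=k, embeddings=embeddings)


def weighted_modularity(S, labels: np.ndarray) -> float:
    """Newman modularity sum_c [e_c/m - (d_c/(2m))^2] on an S-weighted graph
    (diagonal excluded)."""
    W = np.asarray(S, dtype=float).copy()
    np.fill_diagonal(W, 0.0)
    m = W.sum() / 2.0
    if m == 0:
        return 0.0
    q = 0.0
    for c in np.unique(labels):
        mask = labels == c
        e_c = W[np.ix_(mask, mask)].sum() / 2.0
        d_c = W[mask].sum()
        q += e_c / m - (d_c / (2 * m)) ** 2
    return float(q)


def select_k(similarities: dict[str, pd.DataFrame], tree: CellTypeTree,
             grid=K_GRID, seed: int = 0,
             min_cluster_size: int = MIN_SET_SIZE) -> tuple[int, pd.DataFrame]:
    """Pick k by maximum average modularity subject to every cluster holding
    at least ``min_cluster_size`` genes in every cell type; reports the full
    sweep table."""
    rows = []
    for k in grid:
        assignment = multitask_cluster(similarities, tree, k=k, seed=seed)
        mods = []
        min_size = np.inf
        for ct, S in similarities.items():
            genes = list(assignment.labels.index)
            M = S.reindex(index=genes, columns=genes).fillna(0.0).to_numpy()
            lab = assignment.labels[ct].to_numpy()
            mods.append(weighted_modularity(M, lab))
            sizes = pd.Series(lab).value_counts()
            min_size = min(min_size, sizes.min() if len(sizes) == k else 0)
        rows.append({"k": k, "modularity": float(np.mean(mods)),
                     "min_cluster_size": int(min_size)})
    table = pd.DataFrame(rows)
    ok = table[table["min_cluster_size"] >= min_cluster_size]
    pick_from = ok if len(ok) else table
    k_star = int(pick_from.sort_values(["modularity", "k"],
                                       ascending=[False, True]).iloc[0]["k"])
    return k_star, table


@dataclass
class TransitioningGeneSet:
    genes: list[str]
    majority_labels: dict[str, int]
    status: str  # "conserved" or "transitioning"
    snp_associated: bool = False


def transitioning_gene_sets(labels: pd.DataFrame,
                            direct_hits: dict[str, set] | None = None,
                            cut_height: float = CUT_HEIGHT,
                            min_genes: int = MIN_SET_SIZE
                            ) -> list[TransitioningGeneSet]:
    """Group genes by their cluster-assignment profiles.

    Pairwise gene distance is the Hamming fraction of the label vectors;
    average-linkage clustering with optimal leaf ordering is cut at
    ``cut_height``; sets smaller than ``min_genes`` are dropped.  A set is
    conserved when all members carry one identical label in every cell type,
    transitioning otherwise.
    """
    X = labels.to_numpy()
    genes = list(labels.index)
    if len(genes) < 2:
        return []
    d = pdist(X, metric="hamming")
    Z = hierarchy.linkage(d, method="average", optimal_ordering=True)
    flat = hierarchy.fcluster(Z, t=cut_height, criterion="distance")
    out = []
    for c in np.unique(flat):
        members = [g for g, f in zip(genes, flat) if f == c]
        if len(members) < min_genes:
            continue
        sub = labels.loc[members]
        majority = {ct: int(sub[ct].mode().iloc[0]) for ct in labels.columns}
        conserved = sub.nunique().eq(1).all() and sub.iloc[0].nunique() == 1
        snp = False
        if direct_hits:
            snp = any(set(members) & set(h) for h in direct_hits.values())
        out.append(TransitioningGeneSet(
            genes=members, majority_labels=majority,
            status="conserved" if conserved else "transitioning",
            snp_associated=snp))
    return out


def hypergeom_enrichment(gene_set: set[str], annotation: dict[str, set[str]],
                         background: set[str], alpha: float = 0.05
                         ) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of a gene set per annotation
    term, BH-corrected across terms."""
    if not gene_set <= background:
        raise ValueError("gene set must be a subset of the background")
    N, n = len(background), len(gene_set)
    rows = []
    for term, term_genes in sorted(annotation.items()):
        K = len(term_genes & background)
        if K == 0:
            continue
        k = len(term_genes & gene_set)
        p = float(hypergeom.sf(k - 1, N, K, n))
        rows.append({"term": term, "overlap": k, "term_size": K, "p": p})
    df = pd.DataFrame(rows, columns=["term", "overlap", "term_size", "p"])
    if len(df):
        df["q"] = bh_qvalues(df["p"].to_numpy())
        df["significant"] = df["q"] < alpha
    return df


@dataclass
class NMFSummary:
    W: pd.DataFrame  # terms x factors
    H: pd.DataFrame  # factors x gene lists
    explained_variance: float
    top_terms: dict[int, list[str]]
    top_lists: dict[int, list[str]]


def nmf_summarize(X: pd.DataFrame, k: int = 7, seed: int = 0,
                  max_iter: int = 5000, tol: float = 1e-6,
                  n_top_terms: int = 10, n_top_lists: int = 5) -> NMFSummary:
    """Rank-k NMF of a non-negative enrichment matrix (-log q values,
    terms x gene lists), with explained variance EV = 1 - var(x - x_hat)/var(x)
    and the top terms/lists per factor from the factor matrices."""
    vals = X.to_numpy(dtype=float)
    if (vals < 0).any():
        raise ValueError("NMF input must be non-negative")
    model = NMF(n_components=k, init="nndsvda", solver="mu",
                max_iter=max_iter, tol=tol, random_state=seed)
    W = model.fit_transform(vals)
    H = model.components_
    resid = vals - W @ H
    ev = float(1.0 - np.var(resid) / np.var(vals))
    top_terms = {f: list(X.index[np.argsort(-W[:, f])][:n_top_terms])
                 for f in range(k)}
    top_lists = {f: list(X.columns[np.argsort(-H[f])][:n_top_lists])
                 for f in range(k)}
    return NMFSummary(
        W=pd.DataFrame(W, index=X.index, columns=range(k)),
        H=pd.DataFrame(H, index=range(k), columns=X.columns),
        explained_variance=ev, top_terms=top_terms, top_lists=top_lists)
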