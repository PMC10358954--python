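"""Cell-type-specific molecular networks and the cell-type relationship tree.

Each cell type's network merges three unweighted undirected edge classes:

* **ppi** — protein-protein interactions kept at a confidence score > 0.95;
* **proximal** — TF-gene edges supported by an accessible motif (purity
  score > 0.9) inside the gene's TSS +/-2500 bp promoter window;
* **distal** — TF-gene edges where a significant loop connects the promoter
  window to a bin carrying a qualifying motif for the TF.

Within the proximal and distal classes separately, only the top 5% of
candidate edges by motif purity are retained (ties at the cutoff included).
Edges are unweighted; diffusion downstream operates on plain adjacency.

The cell-type relationship tree is built by UPGMA, either on Euclidean
distances of promoter H3K4me3 signal profiles or on the F-score profiles of
shared significant interactions.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from Bio import Phylo
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform
from sklearn.metrics import fowlkes_mallows_score

from .core_io import TSS_WINDOW, IntervalSet
from .snplink import gene_bins

PPI_MIN_SCORE = 0.95
MOTIF_MIN_PURITY = 0.9
TOP_EDGE_FRACTION = 0.05


# ---------------------------------------------------------------------------
# cell-type tree
# ---------------------------------------------------------------------------


@dataclass
class CellTypeTree:
    """Rooted tree over cell types, stored as a scipy linkage matrix plus the
    leaf labels in linkage order."""

    labels: list[str]
    linkage: np.ndarray

    def __post_init__(self) -> None:
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("duplicate cell-type names")

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def cut(self, k: int) -> dict[str, int]:
        """Flat clustering of the leaves into k clusters."""
        flat = hierarchy.fcluster(self.linkage, t=k, criterion="maxclust")
        return dict(zip(self.labels, (int(c) for c in flat)))

    def to_tree(self) -> hierarchy.ClusterNode:
        """Root node for root-to-leaf traversal; leaf ids index ``labels``."""
        return hierarchy.to_tree(self.linkage)

    def leaves_under(self, node: hierarchy.ClusterNode) -> list[str]:
        return [self.labels[i] for i in node.pre_order(lambda n: n.id) ]

    def to_newick(self) -> str:
        def fmt(node: hierarchy.ClusterNode, parent_height: float) -> str:
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{self.labels[node.id]}:{length:g}"
            left = fmt(node.left, node.dist)
            right = fmt(node.right, node.dist)
            return f"({left},{right}):{length:g}"
        root = self.to_tree()
        inner = fmt(root, root.dist)
        # strip the root's zero-length suffix
        return inner.rsplit(":", 1)[0] + ";"

    @classmethod
    def from_newick(cls, text: str) -> "CellTypeTree":
        """Rebuild a tree from Newick via UPGMA on its leaf-to-leaf path
        distances (exact for ultrametric trees)."""
        tree = Phylo.read(io.StringIO(text), "newick")
        leaves = sorted(tree.get_terminals(), key=lambda c: c.name)
        names = [c.name for c in leaves]
        n = len(names)
        dm = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                d = tree.distance(leaves[i], leaves[j])
                dm[i, j] = dm[j, i] = d
        Z = hierarchy.linkage(squareform(dm), method="average")
        return cls(labels=names, linkage=Z)


def upgma_tree(dist_condensed: np.ndarray, labels: list[str]) -> CellTypeTree:
    Z = hierarchy.linkage(dist_condensed, method="average")
    return CellTypeTree(labels=list(labels), linkage=Z)


def infer_tree_signal(signal: pd.DataFrame) -> CellTypeTree:
    """UPGMA on Euclidean distances of per-cell-type promoter signal rows.

    ``signal``: cell types x promoter bins.  Rows are sorted by cell-type
    name first so ties in the linkage are broken lexicographically.
    """
    if signal.index.duplicated().any():
        raise ValueError("duplicate cell-type names")
    if len(signal) < 2:
        raise ValueError("need at least two cell types")
    signal = signal.sort_index()
    d = pdist(signal.to_numpy(dtype=float), metric="euclidean")
    return upgma_tree(d, list(signal.index))


def interaction_fscore_matrix(loop_sets: dict[str, set]) -> pd.DataFrame:
    """Pairwise F-score (2|A∩B| / (|A|+|B|)) of shared loop pairs."""
    names = sorted(loop_sets)
    F = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            sa, sb = loop_sets[a], loop_sets[b]
            denom = len(sa) + len(sb)
            f = 2 * len(sa & sb) / denom if denom else 1.0
            F.loc[a, b] = F.loc[b, a] = f
    return F


def interaction_fscore_tree(loop_sets: dict[str, set]) -> CellTypeTree:
    """UPGMA on Euclidean distances between cell types' F-score profiles."""
    if len(loop_sets) < 2:
        raise ValueError("need at least two loop sets")
    F = interaction_fscore_matrix(loop_sets)
    d = pdist(F.to_numpy(), metric="euclidean")
    return upgma_tree(d, list(F.index))


def fowlkes_mallows(tree1: CellTypeTree, tree2: CellTypeTree, k: int,
                    n_permutations: int = 1000, seed: int = 0
                    ) -> tuple[float, float]:
    """Fowlkes-Mallows index B_k between two trees cut at k clusters, with a
    leaf-label permutation null.  Returns (index, permutation p-value)."""
    if set(tree1.labels) != set(tree2.labels):
        raise ValueError("trees must share their leaf sets")
    n = tree1.n_leaves
    if not 2 <= k <= n - 1:
        raise ValueError(f"k must be in [2, {n - 1}]")
    names = sorted(tree1.labels)
    c1 = tree1.cut(k)
    c2 = tree2.cut(k)
    l1 = np.array([c1[x] for x in names])
    l2 = np.array([c2[x] for x in names])
    observed = float(fowlkes_mallows_score(l1, l2))
    rng = np.random.default_rng(seed)
    null_ge = 0
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        if fowlkes_mallows_score(l1, l2[perm]) >= observed:
            null_ge += 1
    p = (1 + null_ge) / (1 + n_permutations)
    return observed, p


# ---------------------------------------------------------------------------
# network assembly
# ---------------------------------------------------------------------------


def _top_fraction(edges: dict[tuple[str, str], float],
                  top_frac: float) -> list[tuple[str, str, float]]:
    """Keep the top ``top_frac`` of candidate edges by purity; ties at the
    cutoff are all retained."""
    if not edges:
        return []
    items = sorted(edges.items(), key=lambda kv: (-kv[1], kv[0]))
    keep = math.ceil(top_frac * len(items))
    cutoff = items[keep - 1][1]
    return [(tf, g, s) for (tf, g), s in items if s >= cutoff]


def build_proximal_network(motif_hits: dict[str, IntervalSet], tss: IntervalSet,
                           purity_min: float = MOTIF_MIN_PURITY,
                           top_frac: float = TOP_EDGE_FRACTION
                           ) -> list[tuple[str, str, float]]:
    """TF-gene edges from accessible motifs inside promoter windows."""
    candidates: dict[tuple[str, str], float] = {}
    for tf, hits in motif_hits.items():
        for hit in hits:
            if hit.score is None or not hit.score > purity_min:
                continue
            for gene_rec in tss.df[tss.df["chrom"] == hit.chrom].itertuples(index=False):
                lo = gene_rec.start - TSS_WINDOW
                hi = gene_rec.start + TSS_WINDOW
                if lo <= hit.start < hi:
                    key = (tf, str(gene_rec.name))
                    candidates[key] = max(candidates.get(key, -np.inf),
                                          float(hit.score))
    return _top_fraction(candidates, top_frac)


def build_distal_network(motif_hits: dict[str, IntervalSet], tss: IntervalSet,
                         loops, purity_min: float = MOTIF_MIN_PURITY,
                         top_frac: float = TOP_EDGE_FRACTION
                         ) -> list[tuple[str, str, float]]:
    """TF-gene edges supported by a significant loop joining a promoter bin
    and a motif-carrying bin.  A motif sharing the anchor with the TSS makes
    no distal edge (that is proximal territory)."""
    from .core_io import RESOLUTION  # local import to avoid a cycle at module load

    genes_at: dict[tuple[str, int], list[str]] = {}
    for rec in tss.df.itertuples(index=False):
        for b in gene_bins(int(rec.start)):
            genes_at.setdefault((rec.chrom, b), []).append(str(rec.name))

    hits_at: dict[tuple[str, int], dict[str, float]] = {}
    for tf, hits in motif_hits.items():
        for hit in hits:
            if hit.score is None or not hit.score > purity_min:
                continue
            key = (hit.chrom, int(hit.start) // RESOLUTION)
            hits_at.setdefault(key, {})
            hits_at[key][tf] = max(hits_at[key].get(tf, -np.inf), float(hit.score))

    candidates: dict[tuple[str, str], float] = {}
    for rec in loops.frame.itertuples(index=False):
        a, b = int(rec.bin_i), int(rec.bin_j)
        for g_bin, m_bin in ((a, b), (b, a)):
            genes = genes_at.get((rec.chrom, g_bin), [])
            motifs = hits_at.get((rec.chrom, m_bin), {})
            for gene in genes:
                for tf, purity in motifs.items():
                    key = (tf, gene)
                    candidates[key] = max(candidates.get(key, -np.inf), purity)
    return _top_fraction(candidates, top_frac)


def merge_networks(ppi: list, proximal: list, distal: list) -> nx.Graph:
    """Union of the three edge classes into one unweighted graph; provenance
    per edge records which classes contributed; self-loops are dropped."""
    g = nx.Graph()
    for cls, edges in (("ppi", ppi), ("proximal", proximal), ("distal", distal)):
        for edge in edges:
            a, b = str(edge[0]), str(edge[1])
            if a == b:
                continue
            if g.has_edge(a, b):
                g[a][b]["provenance"].add(cls)
            else:
                g.add_edge(a, b, weight=1.0, provenance={cls})
    return g
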