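"""Two-step graph diffusion of SNP-derived gene scores.

Step one (node diffusion) spreads the direct-hit scores Q over the network
with the regularized Laplacian kernel K_L = (I + lambda*L)^-1, where
L = I - D^{-1/2} A D^{-1/2} is the symmetric normalized Laplacian, giving
diffused node scores V = K_L . Q.  Step two (edge diffusion) reweights edges
with the insulated heat kernel K_H = beta (I - (1-beta) W)^-1 over the
column-stochastic transition matrix W = A D^{-1}, and forms
H = K_H . diag(V).  The submatrix of H over the direct hits plus the top 1%
of diffused scores is converted into the diffusion-state distance (DSD)
matrix P (L1 distance between rows of H) and finally into a similarity
matrix S = exp(-P^2 / (2 sigma_P^2)) via a Gaussian kernel whose width is the
standard deviation of all entries of P.

All kernels are applied through linear solves, never explicit inverses.
The kernel width defaults to lambda = 1 (selected by leave-one-out
cross-validation over {0.1, 0.5, 1, 5, 10}); the retention rate defaults to
beta = 0.3.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import linalg
from scipy.spatial.distance import cdist
from sklearn.metrics import roc_auc_score

from .snplink import GeneScoreVector

LAMBDA_GRID = (0.1, 0.5, 1.0, 5.0, 10.0)
DEFAULT_LAMBDA = 1.0
DEFAULT_BETA = 0.3
TOP_NODE_FRACTION = 0.01


def _graph_arrays(graph: nx.Graph) -> tuple[list[str], np.ndarray, np.ndarray]:
    nodes = sorted(graph.nodes)
    if not nodes:
        raise ValueError("empty graph")
    A = nx.to_numpy_array(graph, nodelist=nodes, weight="weight")
    deg = A.sum(axis=1)
    return nodes, A, deg


def _normalized_laplacian(A: np.ndarray, deg: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore"):
        dinv = np.where(deg > 0, 1.0 / np.sqrt(deg), 0.0)
    return np.eye(len(deg)) - dinv[:, None] * A * dinv[None, :]


def _score_array(scores, nodes: list[str]) -> np.ndarray:
    if isinstance(scores, GeneScoreVector):
        return np.array([scores.score(n) for n in nodes])
    if isinstance(scores, pd.Series):
        return scores.reindex(nodes).fillna(0.0).to_numpy(dtype=float)
    return np.array([float(scores.get(n, 0.0)) for n in nodes])


def node_diffusion(graph: nx.Graph, scores, lam: float = DEFAULT_LAMBDA) -> pd.Series:
    """Diffused node scores V = (I + lambda*L)^-1 Q, by symmetric solve."""
    if lam <= 0:
        raise ValueError("lambda must be positive")
    nodes, A, deg = _graph_arrays(graph)
    L = _normalized_laplacian(A, deg)
    Q = _score_array(scores, nodes)
    V = linalg.solve(np.eye(len(nodes)) + lam * L, Q, assume_a="pos")
    return pd.Series(V, index=nodes)


def select_lambda_loocv(graph: nx.Graph, scores: GeneScoreVector,
                        grid=LAMBDA_GRID) -> tuple[float, pd.DataFrame]:
    """Choose the kernel width by leave-one-out cross-validation.

    For each lambda and each held-out direct hit, scores are diffused from
    the remaining hits and the held-out gene's diffused score is ranked
    against the non-hit genes; performance is the AUROC with hits as
    positives (non-hit scores averaged over folds).  Ties go to the smaller
    lambda.
    """
    nodes, A, deg = _graph_arrays(graph)
    hits = sorted(h for h in scores.direct_hits if h in set(nodes))
    if len(hits) < 3:
        raise ValueError("need at least 3 direct hits for LOOCV")
    non_hits = [n for n in nodes if n not in set(hits)]
    idx = {n: i for i, n in enumerate(nodes)}
    Q_full = _score_array(scores, nodes)
    L = _normalized_laplacian(A, deg)
    eye = np.eye(len(nodes))

    rows = []
    for lam in grid:
        cho = linalg.cho_factor(eye + lam * L)
        held_scores = []
        non_hit_acc = np.zeros(len(non_hits))
        for h in hits:
            Q = Q_full.copy()
            Q[idx[h]] = 0.0
            V = linalg.cho_solve(cho, Q)
            held_scores.append(V[idx[h]])
            non_hit_acc += V[[idx[n] for n in non_hits]]
        y = np.concatenate([np.ones(len(hits)), np.zeros(len(non_hits))])
        s = np.concatenate([held_scores, non_hit_acc / len(hits)])
        rows.append({"lambda": lam, "auroc": float(roc_auc_score(y, s))})
    table = pd.DataFrame(rows)
    best = table.sort_values(["auroc", "lambda"], ascending=[False, True]).iloc[0]
    return float(best["lambda"]), table


def edge_diffusion(graph: nx.Graph, V: pd.Series,
                   beta: float = DEFAULT_BETA) -> pd.DataFrame:
    """Edge-diffused weighted adjacency H = K_H . diag(V).

    K_H = beta (I - (1-beta) W)^-1 with W = A D^{-1}; a degree-zero node's
    transition column is the unit vector on itself (it retains its own
    heat)."""
    if not 0 < beta <= 1:
        raise ValueError("beta must be in (0, 1]")
    nodes, A, deg = _graph_arrays(graph)
    with np.errstate(divide="ignore"):
        dinv = np.where(deg > 0, 1.0 / deg, 0.0)
    W = A * dinv[None, :]
    for j in np.nonzero(deg == 0)[0]:
        W[j, j] = 1.0
    n = len(nodes)
    K = beta * linalg.solve(np.eye(n) - (1 - beta) * W, np.eye(n))
    v = V.reindex(nodes).fillna(0.0).to_numpy(dtype=float)
    H = K * v[None, :]
    return pd.DataFrame(H, index=nodes, columns=nodes)


@dataclass
class DiffusionResult:
    V: pd.Series
    H: pd.DataFrame
    selected: list[str]
    P: pd.DataFrame
    sigma: float
    S: pd.DataFrame
    lam: float = DEFAULT_LAMBDA
    beta: float = DEFAULT_BETA


def select_nodes_and_dsd(H: pd.DataFrame, direct_hits: set[str], V: pd.Series,
                         top_frac: float = TOP_NODE_FRACTION,
                         dsd_rows: str = "selected") -> DiffusionResult:
    """Select direct hits plus the top fraction of diffused scores, then build
    the DSD matrix P and Gaussian similarity S over the selected nodes.

    With ``dsd_rows="selected"`` (default) the diffusion state of a node is
    its row of H restricted to the selected columns; ``"all"`` uses full rows.
    """
    nodes = list(H.index)
    v = V.reindex(nodes).to_numpy(dtype=float)
    k = max(1, math.ceil(top_frac * len(nodes)))
    thresh = np.sort(v)[::-1][k - 1]
    top = {n for n, s in zip(nodes, v) if s >= thresh}
    selected = sorted((set(direct_hits) & set(nodes)) | top)
    if len(selected) < 3:
        raise ValueError("fewer than 3 selected nodes")
    if dsd_rows == "selected":
        U = H.loc[selected, selected].to_numpy(dtype=float)
    elif dsd_rows == "all":
        U = H.loc[selected, :].to_numpy(dtype=float)
    else:
        raise ValueError("dsd_rows must be 'selected' or 'all'")
    P = cdist(U, U, metric="cityblock")
    sigma = float(np.std(P))  # population standard deviation of all entries
    if sigma > 0:
        S = np.exp(-(P ** 2) / (2 * sigma ** 2))
    else:
        S = np.ones_like(P)
    return DiffusionResult(
        V=V, H=H, selected=selected,
        P=pd.DataFrame(P, index=selected, columns=selected),
        sigma=sigma,
        S=pd.DataFrame(S, index=selected, columns=selected),
    )


def diffuse_network(graph: nx.Graph, scores, lam: float = DEFAULT_LAMBDA,
                    beta: float = DEFAULT_BETA,
                    top_frac: float = TOP_NODE_FRACTION,
                    dsd_rows: str = "selected") -> DiffusionResult:
    """Full two-step diffusion: node scores -> V -> H -> (P, S)."""
    V = node_diffusion(graph, scores, lam=lam)
    H = edge_diffusion(graph, V, beta=beta)
    hits = scores.direct_hits if isinstance(scores, GeneScoreVector) else {
        n for n, s in _as_mapping(scores).items() if s > 0
    }
    res = select_nodes_and_dsd(H, hits, V, top_frac=top_frac, dsd_rows=dsd_rows)
    res.lam, res.beta = lam, beta
    return res


def _as_mapping(scores) -> dict[str, float]:
    if isinstance(scores, pd.Series):
        return {str(k): float(v) for k, v in scores.items()}
    return dict(scores)
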