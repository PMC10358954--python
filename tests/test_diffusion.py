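"""Laplacian and heat kernels, DSD, Gaussian similarity, LOOCV width."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

import chromalink as cl
from chromalink.diffusion import (diffuse_network, edge_diffusion,
                                  node_diffusion, select_lambda_loocv,
                                  select_nodes_and_dsd)
from chromalink.snplink import GeneScoreVector

from conftest import random_graph


def path_graph(n=3):
    g = nx.path_graph(n)
    g = nx.relabel_nodes(g, {i: f"n{i}" for i in g.nodes})
    nx.set_edge_attributes(g, 1.0, "weight")
    return g


class TestNodeDiffusion:
    def test_small_lambda_recovers_input(self):
        g = path_graph(5)
        q = {f"n{i}": float(i) for i in range(5)}
        v = node_diffusion(g, q, lam=1e-8)
        np.testing.assert_allclose(v.to_numpy(), [q[n] for n in sorted(q)], atol=1e-6)

    def test_zero_scores_stay_zero(self):
        v = node_diffusion(path_graph(4), {}, lam=1.0)
        assert (v == 0).all()

    def test_matches_dense_inverse_oracle_on_path(self):
        g = path_graph(3)
        q = np.array([1.0, 0.0, 0.0])
        v = node_diffusion(g, {"n0": 1.0}, lam=1.0)
        A = nx.to_numpy_array(g, nodelist=["n0", "n1", "n2"])
        d = A.sum(1)
        L = np.eye(3) - A / np.sqrt(np.outer(d, d))
        oracle = np.linalg.inv(np.eye(3) + L) @ q
        np.testing.assert_allclose(v.to_numpy(), oracle, atol=1e-8)

    def test_solve_residual_is_tiny_on_random_graph(self):
        g = random_graph(80, 0.1, seed=1)
        rng = np.random.default_rng(2)
        q = {n: float(rng.uniform()) for n in g.nodes}
        lam = 1.0
        v = node_diffusion(g, q, lam=lam)
        nodes = sorted(g.nodes)
        A = nx.to_numpy_array(g, nodelist=nodes)
        d = A.sum(1)
        with np.errstate(divide="ignore"):
            dinv = np.where(d > 0, 1 / np.sqrt(d), 0.0)
        L = np.eye(len(nodes)) - dinv[:, None] * A * dinv[None, :]
        resid = (np.eye(len(nodes)) + lam * L) @ v.to_numpy() - [q[n] for n in nodes]
        assert np.abs(resid).max() < 1e-10

    def test_isolated_node_keeps_its_score(self):
        g = path_graph(3)
        g.add_node("iso")
        v = node_diffusion(g, {"iso": 2.0}, lam=1.0)
        # (I + lambda*I_row)^-1 on an isolated node halves the score at lam=1
        assert v["iso"] == pytest.approx(1.0)

    def test_nonpositive_lambda_rejected(self):
        with pytest.raises(ValueError):
            node_diffusion(path_graph(3), {}, lam=0.0)


class TestEdgeDiffusion:
    def test_beta_one_gives_diag_v(self):
        g = path_graph(3)
        V = pd.Series([1.0, 2.0, 3.0], index=["n0", "n1", "n2"])
        H = edge_diffusion(g, V, beta=1.0)
        np.testing.assert_allclose(H.to_numpy(), np.diag([1.0, 2.0, 3.0]), atol=1e-12)

    def test_kernel_columns_sum_to_one(self):
        g = random_graph(60, 0.1, seed=3)
        V = pd.Series(1.0, index=sorted(g.nodes))
        H = edge_diffusion(g, V, beta=0.3)  # V=1 so H == K_H
        np.testing.assert_allclose(H.to_numpy().sum(axis=0), 1.0, atol=1e-10)

    def test_matches_truncated_series_on_two_nodes(self):
        g = path_graph(2)
        beta = 0.3
        V = pd.Series(1.0, index=["n0", "n1"])
        H = edge_diffusion(g, V, beta=beta)
        W = np.array([[0.0, 1.0], [1.0, 0.0]])
        series = sum(beta * (1 - beta) ** t * np.linalg.matrix_power(W, t)
                     for t in range(200))
        np.testing.assert_allclose(H.to_numpy(), series, atol=1e-10)

    def test_beta_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            edge_diffusion(path_graph(2), pd.Series(1.0, index=["n0", "n1"]), beta=0.0)


class TestDsdSelection:
    def test_identity_h_gives_l1_distance_two(self):
        H = pd.DataFrame(np.eye(3), index=list("abc"), columns=list("abc"))
        V = pd.Series([1.0, 1.0, 1.0], index=list("abc"))
        res = select_nodes_and_dsd(H, {"a", "b", "c"}, V, top_frac=1.0)
        off = res.P.loc["a", "b"]
        assert off == pytest.approx(2.0)
        assert res.P.values.diagonal().max() == 0.0
        assert res.S.loc["a", "a"] == 1.0

    def test_identical_rows_give_zero_distance_unit_similarity(self):
        H = pd.DataFrame([[1.0, 2.0, 0.0], [1.0, 2.0, 0.0], [0.0, 0.0, 5.0]],
                         index=list("abc"), columns=list("abc"))
        V = pd.Series(1.0, index=list("abc"))
        res = select_nodes_and_dsd(H, {"a", "b", "c"}, V, top_frac=1.0)
        assert res.P.loc["a", "b"] == 0.0
        assert res.S.loc["a", "b"] == 1.0

    def test_selection_is_hits_union_top_fraction(self):
        g = random_graph(100, 0.08, seed=4)
        nodes = sorted(g.nodes)
        hits = set(nodes[:3])
        scores = GeneScoreVector(scores={h: 3.0 for h in hits}, direct_hits=hits)
        res = diffuse_network(g, scores)
        assert hits <= set(res.selected)
        k = int(np.ceil(0.01 * len(nodes)))
        assert len(res.selected) >= max(k, len(hits))

    def test_too_few_selected_rejected(self):
        H = pd.DataFrame(np.eye(2), index=list("ab"), columns=list("ab"))
        V = pd.Series([1.0, 0.0], index=list("ab"))
        with pytest.raises(ValueError, match="3"):
            select_nodes_and_dsd(H, {"a"}, V, top_frac=0.01)


class TestLambdaSelection:
    def test_planted_module_hits_are_recoverable(self, network_fixture):
        g = network_fixture.graphs["ct02"]
        module = network_fixture.modules[0]
        rng = np.random.default_rng(5)
        hits = set(rng.choice(module, size=12, replace=False))
        sv = GeneScoreVector(scores={h: 2.0 for h in hits}, direct_hits=hits)
        lam, table = select_lambda_loocv(g, sv)
        assert table["auroc"].max() > 0.9
        assert lam in {0.1, 0.5, 1.0, 5.0, 10.0}

    def test_random_hits_give_chance_auroc(self, network_fixture):
        # single draws are noisy (only ~15 positives), so average over draws
        g = network_fixture.graphs["ct02"]
        rng = np.random.default_rng(6)
        vals = []
        for _ in range(8):
            hits = set(rng.choice(sorted(g.nodes), size=15, replace=False))
            sv = GeneScoreVector(scores={h: 2.0 for h in hits}, direct_hits=hits)
            _, table = select_lambda_loocv(g, sv, grid=(1.0,))
            vals.append(table["auroc"].iloc[0])
        assert abs(np.mean(vals) - 0.5) < 0.1

    def test_fewer_than_three_hits_rejected(self):
        g = path_graph(5)
        sv = GeneScoreVector(scores={"n0": 1.0, "n1": 1.0},
                             direct_hits={"n0", "n1"})
        with pytest.raises(ValueError, match="3"):
            select_lambda_loocv(g, sv)
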