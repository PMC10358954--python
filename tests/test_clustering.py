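"""Spectral embedding, multi-task clustering, gene sets, enrichment, NMF."""

from math import comb

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

import chromalink as cl
from chromalink.clustering import (hypergeom_enrichment, independent_cluster,
                                   multitask_cluster, nmf_summarize, select_k,
                                   spectral_embed, transitioning_gene_sets,
                                   weighted_modularity)


def block_similarity(sizes, p_in=1.0, p_out=0.0, seed=None):
    n = sum(sizes)
    labels = np.repeat(np.arange(len(sizes)), sizes)
    S = np.where(labels[:, None] == labels[None, :], p_in, p_out).astype(float)
    if seed is not None:
        rng = np.random.default_rng(seed)
        noise = rng.uniform(0, 0.05, size=(n, n))
        S = S + (noise + noise.T) / 2
    np.fill_diagonal(S, 1.0)
    return S, labels


class TestSpectralEmbed:
    def test_blocks_separate_in_embedding(self):
        S, labels = block_similarity([10, 10, 10])
        E = spectral_embed(S, 3)
        from sklearn.cluster import KMeans
        pred = KMeans(3, n_init=10, random_state=0).fit_predict(E)
        assert adjusted_rand_score(labels, pred) == 1.0

    def test_eigen_residuals_vanish(self):
        S, _ = block_similarity([8, 8], seed=1)
        A = S.copy()
        np.fill_diagonal(A, 0.0)
        deg = A.sum(1)
        inv = 1 / np.sqrt(deg + deg.mean())
        L = np.eye(len(A)) - inv[:, None] * A * inv[None, :]
        from scipy.linalg import eigh
        w, v = eigh(L, subset_by_index=[0, 1])
        for i in range(2):
            assert np.linalg.norm(L @ v[:, i] - w[i] * v[:, i]) < 1e-8

    def test_permutation_equivariance(self):
        S, _ = block_similarity([6, 6], seed=2)
        perm = np.random.default_rng(0).permutation(len(S))
        E = spectral_embed(S, 2)
        Ep = spectral_embed(S[np.ix_(perm, perm)], 2)
        # compare via pairwise row distances (eigenvectors have sign freedom)
        from scipy.spatial.distance import pdist, squareform
        D = squareform(pdist(E))
        Dp = squareform(pdist(Ep))
        np.testing.assert_allclose(Dp, D[np.ix_(perm, perm)], atol=1e-8)

    def test_invalid_inputs_rejected(self):
        S, _ = block_similarity([4, 4])
        with pytest.raises(ValueError, match="k"):
            spectral_embed(S, 8)
        with pytest.raises(ValueError, match="symmetric"):
            spectral_embed(np.triu(S), 2)


class TestModularity:
    def test_two_disconnected_cliques_score_half(self):
        S, labels = block_similarity([10, 10])
        np.fill_diagonal(S, 0.0)
        assert weighted_modularity(S, labels) == pytest.approx(0.5)

    def test_single_cluster_scores_zero(self):
        S, _ = block_similarity([10, 10])
        assert weighted_modularity(S, np.zeros(20)) == pytest.approx(0.0)

    def test_matches_direct_double_sum_oracle(self):
        rng = np.random.default_rng(3)
        n = 30
        W = rng.uniform(0, 1, size=(n, n))
        W = (W + W.T) / 2
        np.fill_diagonal(W, 0.0)
        labels = rng.integers(0, 4, size=n)
        m = W.sum() / 2
        oracle = sum((W[i, j] - W[i].sum() * W[j].sum() / (2 * m)) / (2 * m)
                     for i in range(n) for j in range(n)
                     if labels[i] == labels[j])
        assert weighted_modularity(W, labels) == pytest.approx(oracle, abs=1e-10)


class TestMultitask:
    def test_identical_similarities_give_identical_columns(self, network_fixture):
        S, _ = block_similarity([20, 20, 20], seed=4)
        genes = [f"g{i:03d}" for i in range(60)]
        frame = pd.DataFrame(S, index=genes, columns=genes)
        sims = {ct: frame for ct in network_fixture.tree.labels}
        asgn = multitask_cluster(sims, network_fixture.tree, k=3, seed=0)
        cols = [asgn.labels[c] for c in asgn.labels.columns]
        for c in cols[1:]:
            assert (c == cols[0]).all()

    def test_planted_modules_recovered_with_matched_labels(self, network_fixture,
                                                           similarity_panel):
        asgn = multitask_cluster(similarity_panel, network_fixture.tree,
                                 k=6, seed=0)
        for ct in similarity_panel:
            ari = adjusted_rand_score(network_fixture.labels[ct], asgn.labels[ct])
            assert ari >= 0.9
        sets = transitioning_gene_sets(asgn.labels)
        trans = set().union(*(set(s.genes) for s in sets
                              if s.status == "transitioning"), set())
        recall = len(trans & network_fixture.transitioning_genes) / len(
            network_fixture.transitioning_genes)
        assert recall >= 0.9

    def test_same_seed_reproduces_labels(self, network_fixture, similarity_panel):
        a = multitask_cluster(similarity_panel, network_fixture.tree, k=6, seed=3)
        b = multitask_cluster(similarity_panel, network_fixture.tree, k=6, seed=3)
        assert a.labels.equals(b.labels)

    def test_tree_leaf_mismatch_rejected(self, network_fixture, similarity_panel):
        sims = dict(similarity_panel)
        sims.pop(sorted(sims)[0])
        with pytest.raises(ValueError, match="leaves"):
            multitask_cluster(sims, network_fixture.tree, k=4)

    def test_select_k_prefers_planted_module_count(self, network_fixture,
                                                   similarity_panel):
        k_star, table = select_k(similarity_panel, network_fixture.tree,
                                 grid=(4, 5, 6, 7, 8), seed=0)
        assert k_star == 6
        assert table.loc[table["k"] == 6, "modularity"].iloc[0] == table["modularity"].max()


class TestTransitioningSets:
    def test_constant_profiles_form_one_conserved_set(self):
        labels = pd.DataFrame({"ct0": [1] * 8, "ct1": [1] * 8},
                              index=[f"g{i}" for i in range(8)])
        sets = transitioning_gene_sets(labels)
        assert len(sets) == 1
        assert sets[0].status == "conserved"

    def test_small_sets_are_dropped(self):
        labels = pd.DataFrame({
            "ct0": [1] * 8 + [2] * 4,
            "ct1": [1] * 8 + [3] * 4,
        }, index=[f"g{i}" for i in range(12)])
        sets = transitioning_gene_sets(labels)
        assert len(sets) == 1 and len(sets[0].genes) == 8

    def test_relabeling_clusters_consistently_is_invariant(self, network_fixture,
                                                           similarity_panel):
        asgn = multitask_cluster(similarity_panel, network_fixture.tree, k=6, seed=0)
        perm = {1: 4, 2: 6, 3: 1, 4: 5, 5: 2, 6: 3}
        relabeled = asgn.labels.replace(perm)
        a = transitioning_gene_sets(asgn.labels)
        b = transitioning_gene_sets(relabeled)
        sets_a = sorted(tuple(sorted(s.genes)) for s in a)
        sets_b = sorted(tuple(sorted(s.genes)) for s in b)
        assert sets_a == sets_b
        assert sorted(s.status for s in a) == sorted(s.status for s in b)

    def test_snp_association_flag(self):
        labels = pd.DataFrame({"ct0": [1] * 6, "ct1": [1] * 6},
                              index=[f"g{i}" for i in range(6)])
        sets = transitioning_gene_sets(labels, direct_hits={"ct0": {"g2"}})
        assert sets[0].snp_associated


class TestEnrichment:
    def test_exact_enumeration_example(self):
        background = {f"g{i}" for i in range(10)}
        term = {f"g{i}" for i in range(5)}
        out = hypergeom_enrichment(term, {"T": term}, background)
        assert out.iloc[0]["p"] == pytest.approx(1 / comb(10, 5))

    def test_central_overlap_is_not_significant(self):
        background = {f"g{i}" for i in range(100)}
        term = {f"g{i}" for i in range(50)}
        gene_set = {f"g{i}" for i in range(45, 55)}  # overlap 5 of 10: expected
        out = hypergeom_enrichment(gene_set, {"T": term}, background)
        assert out.iloc[0]["p"] > 0.3
        assert not out.iloc[0]["significant"]

    def test_set_equal_background_gives_p_one(self):
        background = {f"g{i}" for i in range(10)}
        out = hypergeom_enrichment(background, {"T": {"g0", "g1"}}, background)
        assert out.iloc[0]["p"] == pytest.approx(1.0)

    def test_non_subset_rejected_and_empty_terms_skipped(self):
        background = {"a", "b"}
        with pytest.raises(ValueError):
            hypergeom_enrichment({"z"}, {}, background)
        out = hypergeom_enrichment({"a"}, {"T": {"x", "y"}}, background)
        assert len(out) == 0


class TestNMF:
    def test_low_rank_matrix_is_faithfully_represented(self):
        rng = np.random.default_rng(9)
        W = rng.uniform(0, 1, size=(40, 5))
        H = rng.uniform(0, 1, size=(5, 21))
        X = pd.DataFrame(W @ H, index=[f"t{i}" for i in range(40)],
                         columns=[f"l{i}" for i in range(21)])
        res = nmf_summarize(X, k=7, seed=0)
        assert res.explained_variance >= 0.999
        assert (res.W.to_numpy() >= 0).all() and (res.H.to_numpy() >= 0).all()
        assert len(res.top_terms[0]) == 10 and len(res.top_lists[0]) == 5

    def test_ev_formula_matches_direct_recomputation(self):
        rng = np.random.default_rng(10)
        X = pd.DataFrame(rng.uniform(0, 1, size=(30, 15)))
        res = nmf_summarize(X, k=4, seed=0)
        xhat = res.W.to_numpy() @ res.H.to_numpy()
        ev = 1 - np.var(X.to_numpy() - xhat) / np.var(X.to_numpy())
        assert res.explained_variance == pytest.approx(ev, abs=1e-12)

    def test_negative_input_rejected(self):
        X = pd.DataFrame([[1.0, -0.1], [0.2, 0.3]])
        with pytest.raises(ValueError, match="non-negative"):
            nmf_summarize(X, k=1)
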