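"""Correlation AUC, fold enrichment, eQTL precision/recall, expression test."""

import numpy as np
import pandas as pd
import pytest

import chromalink as cl
from chromalink.core_io import ContactMatrix, IntervalSet
from chromalink.loops import SignificantInteractionSet
from chromalink.metrics import (eqtl_precision_recall, expression_interacting_vs_not,
                                fold_enrichment, nearest_gene_baseline,
                                stratified_correlation_auc)


def random_matrix(n_bins, seed, transform=None):
    rng = np.random.default_rng(seed)
    cm = ContactMatrix("chr1", n_bins=n_bins)
    for d in range(1, min(200, n_bins - 1) + 1):
        for i in range(n_bins - d):
            v = float(rng.lognormal())
            cm.set(i, i + d, transform(v) if transform else v)
    return cm


class TestStratifiedAUC:
    def test_identity_gives_auc_one(self):
        cm = random_matrix(60, seed=0)
        curve, auc = stratified_correlation_auc(cm, cm)
        assert auc == pytest.approx(1.0)
        assert (curve["r"] > 0.999999).all()

    def test_shift_invariance(self):
        truth = random_matrix(60, seed=1)
        shifted = ContactMatrix("chr1", n_bins=60)
        for (i, j), c in truth.items():
            shifted.set(i, j, c + 7.0)
        _, auc = stratified_correlation_auc(shifted, truth)
        assert auc == pytest.approx(1.0)

    def test_independent_predictions_have_near_zero_auc(self):
        truth = random_matrix(100, seed=2)
        noise = random_matrix(100, seed=3)
        _, auc = stratified_correlation_auc(noise, truth)
        assert abs(auc) < 0.1

    def test_constant_strata_are_skipped(self):
        truth = random_matrix(30, seed=4)
        flat = ContactMatrix("chr1", n_bins=30)
        for (i, j), _ in truth.items():
            flat.set(i, j, 1.0)
        curve, auc = stratified_correlation_auc(flat, truth)
        assert len(curve) == 0 and np.isnan(auc)


class TestFoldEnrichment:
    def test_worked_arithmetic(self):
        pred = {(0, i) for i in range(1, 11)}
        gold = {(0, i) for i in range(6, 56)}
        assert fold_enrichment(pred, gold, 1000) == pytest.approx(10.0)

    def test_self_enrichment_is_universe_over_gold(self):
        gold = {(0, i) for i in range(1, 21)}
        assert fold_enrichment(gold, gold, 500) == pytest.approx(500 / 20)

    def test_random_predictions_enrich_near_one(self):
        rng = np.random.default_rng(5)
        universe = [(0, i) for i in range(2000)]
        gold = set(map(tuple, rng.choice(universe, size=200, replace=False)))
        vals = []
        for _ in range(200):
            pred = set(map(tuple, rng.choice(universe, size=100, replace=False)))
            vals.append(fold_enrichment(pred, gold, len(universe)))
        se = np.std(vals) / np.sqrt(len(vals))
        assert np.mean(vals) == pytest.approx(1.0, abs=3 * se + 0.02)

    def test_degenerate_inputs(self):
        assert np.isnan(fold_enrichment(set(), {(0, 1)}, 10))
        with pytest.raises(ValueError):
            fold_enrichment({(0, 1)}, {(0, 1)}, 0)


class TestEqtlPrecisionRecall:
    def frame(self, pairs):
        return pd.DataFrame(pairs, columns=["snp_id", "gene", "distance"])

    def test_identity_gives_unit_precision_recall(self):
        pred = self.frame([("rs1", "g1", 50_000), ("rs2", "g2", 450_000)])
        out = eqtl_precision_recall(pred, pred)
        filled = out.dropna(subset=["precision"])
        assert (filled["precision"] == 1.0).all()
        assert (filled["recall"] == 1.0).all()

    def test_disjoint_sets_score_zero_where_defined(self):
        pred = self.frame([("rs1", "g1", 50_000)])
        eqtl = self.frame([("rs2", "g2", 50_000)])
        row = eqtl_precision_recall(pred, eqtl).iloc[0]
        assert row["precision"] == 0.0 and row["recall"] == 0.0

    def test_empty_bins_are_missing_not_zero(self):
        pred = self.frame([("rs1", "g1", 50_000)])
        out = eqtl_precision_recall(pred, pred)
        assert np.isnan(out.iloc[5]["precision"])


class TestNearestGene:
    def test_basic_tie_and_single_gene(self):
        tss = IntervalSet.from_records([("chr1", 9000, 9001, "gA"),
                                        ("chr1", 12_000, 12_001, "gB")])
        snps = IntervalSet.from_records([("chr1", 10_000, 10_001, "rs1"),
                                         ("chr1", 10_500, 10_501, "rs2")])
        mapping = nearest_gene_baseline(snps, tss)
        assert mapping["rs1"] == "gA"        # 1000 < 2000
        assert mapping["rs2"] == "gA"        # equidistant: lower coordinate
        only = IntervalSet.from_records([("chr1", 100, 101, "gX")])
        assert set(nearest_gene_baseline(snps, only).values()) == {"gX"}


class TestExpressionComparison:
    def loops_at(self, bins):
        frame = pd.DataFrame({"chrom": "chr1", "bin_i": [b[0] for b in bins],
                              "bin_j": [b[1] for b in bins],
                              "count": 1.0, "p": 0.001, "q": 0.01})
        return SignificantInteractionSet(frame=frame)

    def genes(self, n):
        return IntervalSet.from_records(
            [("chr1", 5000 * i + 2500, 5000 * i + 2501, f"g{i}") for i in range(n)])

    def test_planted_high_expression_is_detected(self):
        rng = np.random.default_rng(6)
        tss = self.genes(400)
        loops = self.loops_at([(i, i + 40) for i in range(200)])
        inter = cl.metrics.interacting_genes(loops, tss)
        expr = {f"g{i}": float(rng.lognormal(mean=(1.0 if f"g{i}" in inter else 0.3)))
                for i in range(400)}
        t, p = expression_interacting_vs_not(loops, tss, expr)
        assert p < 0.05 and t > 0

    def test_null_gives_large_p_on_average(self):
        rng = np.random.default_rng(7)
        tss = self.genes(400)
        loops = self.loops_at([(i, i + 40) for i in range(200)])
        ps = []
        for k in range(20):
            expr = {f"g{i}": float(rng.lognormal()) for i in range(400)}
            ps.append(expression_interacting_vs_not(loops, tss, expr)[1])
        assert np.mean(ps) > 0.2

    def test_zero_rpkm_is_shielded_and_empty_group_raises(self):
        tss = self.genes(10)
        loops = self.loops_at([(0, 40)])
        expr = {f"g{i}": 0.0 for i in range(10)}
        t, p = expression_interacting_vs_not(loops, tss, expr)
        assert np.isfinite(t) or np.isnan(t)  # no -inf from log(0)
        with pytest.raises(ValueError):
            expression_interacting_vs_not(self.loops_at([(100, 140)]), tss, expr)
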