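"""Evaluation statistics for predicted contact maps and SNP-gene links.

* distance-stratified Pearson correlation of predicted vs measured counts,
  summarized by its area under the curve (mean of per-stratum r);
* fold enrichment (q/k)/(m/S) of predicted loops against an experimental
  gold standard mapped onto the 5 kb pair universe;
* precision/recall of predicted SNP-gene links against eQTL pairs, stratified
  by SNP-TSS distance, with a nearest-gene baseline;
* expression comparison (t-test on log RPKM) between genes that participate
  in significant interactions and genes that do not.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import MAX_SPAN_BINS, RESOLUTION, TSS_WINDOW, ContactMatrix, IntervalSet

logger = logging.getLogger(__name__)


def stratified_correlation_auc(pred: ContactMatrix, truth: ContactMatrix,
                               min_pairs: int = 3,
                               max_span_bins: int = MAX_SPAN_BINS
                               ) -> tuple[pd.DataFrame, float]:
    """Per-distance Pearson r of predicted vs measured counts and its AUC.

    For every 5 kb distance stratum up to 1 Mb, r is computed over all
    candidate pairs at that distance (missing entries are 0).  Strata with
    fewer than ``min_pairs`` pairs or zero variance in either vector are
    skipped.  The AUC is the mean of r over retained strata (the trapezoid
    rule over a uniform grid reduces to the mean).
    """
    if pred.chrom != truth.chrom:
        raise ValueError("matrices must share a chromosome")
    n = max(pred.n_bins, truth.n_bins)
    dense_p = np.zeros((n, n))
    dense_t = np.zeros((n, n))
    for (i, j), c in pred.items():
        dense_p[i, j] = c
    for (i, j), c in truth.items():
        dense_t[i, j] = c
    rows = []
    for d in range(1, min(max_span_bins, n - 1) + 1):
        i = np.arange(n - d)
        x = dense_p[i, i + d]
        y = dense_t[i, i + d]
        if len(i) < min_pairs:
            continue
        # relative threshold: np.std of N identical floats is ~1 ulp, not 0
        tol_x = 1e-12 * max(1.0, float(np.abs(x).max(initial=0.0)))
        tol_y = 1e-12 * max(1.0, float(np.abs(y).max(initial=0.0)))
        if np.std(x) <= tol_x or np.std(y) <= tol_y:
            logger.debug("stratum %d skipped: zero variance", d)
            continue
        r = float(np.corrcoef(x, y)[0, 1])
        rows.append({"distance_bp": d * RESOLUTION, "n_pairs": len(i), "r": r})
    curve = pd.DataFrame(rows, columns=["distance_bp", "n_pairs", "r"])
    auc = float(curve["r"].mean()) if len(curve) else float("nan")
    return curve, auc


def fold_enrichment(predicted: set, gold: set, universe_size: int) -> float:
    """(q/k) / (m/S): enrichment of predicted pairs for a gold standard.

    ``gold`` must already be mapped onto the candidate pair universe.
    Returns NaN when either set is empty (undefined).
    """
    if universe_size <= 0:
        raise ValueError("universe size must be positive")
    q = len(predicted & gold)
    k, m = len(predicted), len(gold)
    if q > k:
        raise AssertionError("overlap exceeds prediction count")
    if k == 0 or m == 0:
        return float("nan")
    return (q / k) / (m / universe_size)


def eqtl_precision_recall(pred: pd.DataFrame, eqtl: pd.DataFrame,
                          bin_width: int = 100_000, max_dist: int = 1_000_000
                          ) -> pd.DataFrame:
    """Per-distance-bin precision/recall of predicted SNP-gene pairs vs eQTL.

    Both inputs need columns ``snp_id``, ``gene`` and ``distance`` (SNP-TSS
    distance in bp).  Precision = |pred ∩ eqtl| / |pred| and
    recall = |pred ∩ eqtl| / |eqtl| within each bin; empty denominators give
    NaN.
    """
    edges = np.arange(0, max_dist + bin_width, bin_width)
    pred_keys = set(zip(pred["snp_id"], pred["gene"]))
    eqtl_keys = set(zip(eqtl["snp_id"], eqtl["gene"]))
    rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        p_bin = {k for k, d in zip(zip(pred["snp_id"], pred["gene"]),
                                   pred["distance"]) if lo <= d < hi}
        e_bin = {k for k, d in zip(zip(eqtl["snp_id"], eqtl["gene"]),
                                   eqtl["distance"]) if lo <= d < hi}
        inter = len(p_bin & e_bin)
        rows.append({
            "dist_lo": lo, "dist_hi": hi,
            "n_pred": len(p_bin), "n_eqtl": len(e_bin),
            "precision": inter / len(p_bin) if p_bin else float("nan"),
            "recall": inter / len(e_bin) if e_bin else float("nan"),
        })
    return pd.DataFrame(rows)


def overall_precision_recall(pred: pd.DataFrame, eqtl: pd.DataFrame) -> tuple[float, float]:
    """Unstratified precision/recall of predicted SNP-gene pairs vs eQTL."""
    p = set(zip(pred["snp_id"], pred["gene"]))
    e = set(zip(eqtl["snp_id"], eqtl["gene"]))
    inter = len(p & e)
    prec = inter / len(p) if p else float("nan")
    rec = inter / len(e) if e else float("nan")
    return prec, rec


def nearest_gene_baseline(snps: IntervalSet, tss: IntervalSet) -> dict[str, str]:
    """Map each SNP to the gene with the nearest TSS (ties to the lower
    coordinate).  SNP position = interval start; TSS position = interval
    start of the TSS record."""
    out: dict[str, str] = {}
    tss_df = tss.df
    for chrom, snp_sub in snps.df.groupby("chrom"):
        genes = tss_df[tss_df["chrom"] == chrom].sort_values(["start", "name"])
        if genes.empty:
            logger.warning("no TSS on %s; SNPs left unmapped", chrom)
            continue
        pos = genes["start"].to_numpy()
        names = genes["name"].to_numpy()
        for rec in snp_sub.itertuples(index=False):
            dist = np.abs(pos - rec.start)
            # ties broken toward the lower coordinate: argmin takes the first
            out[rec.name] = str(names[int(np.argmin(dist))])
    return out


def interacting_genes(loops, tss: IntervalSet) -> set[str]:
    """Genes whose TSS +/-2500 bp window overlaps any anchor of a
    significant loop."""
    anchor_bins: dict[str, set[int]] = {}
    for rec in loops.frame.itertuples(index=False):
        anchor_bins.setdefault(rec.chrom, set()).update((int(rec.bin_i), int(rec.bin_j)))
    hit = set()
    for rec in tss.df.itertuples(index=False):
        bins = anchor_bins.get(rec.chrom, set())
        lo = max(0, rec.start - TSS_WINDOW) // RESOLUTION
        hi = (rec.start + TSS_WINDOW - 1) // RESOLUTION
        if any(b in bins for b in range(lo, hi + 1)):
            hit.add(str(rec.name))
    return hit


def expression_interacting_vs_not(loops, tss: IntervalSet,
                                  expression: dict[str, float],
                                  pseudocount: float = 0.1) -> tuple[float, float]:
    """Two-sample t-test of log(RPKM + pseudocount) between interacting and
    non-interacting genes.  Raises if either group is empty."""
    inter = interacting_genes(loops, tss)
    x = [np.log(expression[g] + pseudocount) for g in expression if g in inter]
    y = [np.log(expression[g] + pseudocount) for g in expression if g not in inter]
    if not x or not y:
        raise ValueError("one of the gene groups is empty")
    t, p = stats.ttest_ind(x, y)
    return float(t), float(p)
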