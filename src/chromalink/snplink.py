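"""Linking non-coding SNPs to genes through significant interactions.

A SNP (GWAS lead or LD proxy at R^2 >= 0.8, supplied as input) sits in the
5 kb bin of its position; a gene claims every bin overlapping its TSS
+/-2500 bp window.  A SNP-gene pair is emitted whenever the (snp_bin,
gene_bin) pair is a significant loop in the cell type at hand.  Gene scores —
the diffusion inputs downstream — are the average -log10(q) over a gene's
significant SNP interactions; genes with at least one such interaction are
the phenotype's "direct hits".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import RESOLUTION, TSS_WINDOW, IntervalSet

Q_FLOOR = 1e-300  # clamp before taking logs


def gene_bins(tss_start: int) -> range:
    """Bins overlapped by the promoter window [tss-2500, tss+2500)."""
    lo = max(0, tss_start - TSS_WINDOW)
    hi = tss_start + TSS_WINDOW  # half-open
    return range(lo // RESOLUTION, (hi - 1) // RESOLUTION + 1)


def link_snps_to_genes(snps: IntervalSet, loops, tss: IntervalSet) -> pd.DataFrame:
    """Emit every (SNP, gene) pair connected by a significant loop.

    Returns a frame with snp_id, gene, snp_bin, gene_bin, q and the SNP-TSS
    distance in bp; each distinct (SNP, gene) pair appears once, keeping its
    smallest q.
    """
    loop_q: dict[tuple[str, int, int], float] = {}
    for rec in loops.frame.itertuples(index=False):
        a, b = int(rec.bin_i), int(rec.bin_j)
        key = (rec.chrom, min(a, b), max(a, b))
        loop_q[key] = min(loop_q.get(key, 1.0), float(rec.q))

    gene_by_bin: dict[tuple[str, int], list] = {}
    tss_pos: dict[str, int] = {}
    for rec in tss.df.itertuples(index=False):
        tss_pos[str(rec.name)] = int(rec.start)
        for b in gene_bins(int(rec.start)):
            gene_by_bin.setdefault((rec.chrom, b), []).append(str(rec.name))

    partners: dict[tuple[str, int], list[tuple[int, float]]] = {}
    for (chrom, a, b), q in loop_q.items():
        partners.setdefault((chrom, a), []).append((b, q))
        partners.setdefault((chrom, b), []).append((a, q))

    rows = {}
    for rec in snps.df.itertuples(index=False):
        snp_bin = int(rec.start) // RESOLUTION
        snp_id = str(rec.name)
        for partner, q in partners.get((rec.chrom, snp_bin), []):
            for gene in gene_by_bin.get((rec.chrom, partner), []):
                key = (snp_id, gene)
                dist = abs(int(rec.start) - tss_pos[gene])
                prev = rows.get(key)
                if prev is None or q < prev["q"]:
                    rows[key] = {"snp_id": snp_id, "gene": gene,
                                 "snp_bin": snp_bin, "gene_bin": partner,
                                 "q": q, "distance": dist}
    return pd.DataFrame(list(rows.values()),
                        columns=["snp_id", "gene", "snp_bin", "gene_bin",
                                 "q", "distance"])


@dataclass
class GeneScoreVector:
    """gene -> average -log10(q) over its significant SNP interactions."""

    scores: dict[str, float] = field(default_factory=dict)
    direct_hits: set[str] = field(default_factory=set)

    def score(self, gene: str) -> float:
        return self.scores.get(gene, 0.0)

    def as_series(self, genes: list[str]) -> pd.Series:
        return pd.Series({g: self.score(g) for g in genes}, dtype=float)[genes]


def score_genes(pairs: pd.DataFrame) -> GeneScoreVector:
    """Per-gene mean of -log10(q) over its SNP-gene pairs; every gene with at
    least one pair is flagged a direct hit."""
    out = GeneScoreVector()
    if len(pairs) == 0:
        return out
    neglog = -np.log10(np.maximum(pairs["q"].to_numpy(dtype=float), Q_FLOOR))
    df = pd.DataFrame({"gene": pairs["gene"], "s": neglog})
    means = df.groupby("gene")["s"].mean()
    out.scores = {str(g): float(v) for g, v in means.items()}
    out.direct_hits = set(out.scores)
    return out
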