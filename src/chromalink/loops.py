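"""Distance-stratified binomial test for significant interactions.

Following the ligation-frequency model of Duan et al., each distance stratum
(pairs separated by exactly d bins, d = 1..200, i.e. 5 kb steps up to 1 Mb)
is tested separately: within a stratum the probability that a given candidate
pair carries any one interaction is uniform, m_d = 1 / (#candidate pairs at
distance d), and with n_d total interactions observed in the stratum, the
p-value of a pair observed k times is the upper binomial tail
P(K >= k | n_d, m_d).  The Benjamini-Hochberg q-value is the minimal FDR at
which the pair is called significant; the default significance threshold is
q < 0.05.

The candidate universe per stratum is *all* bin pairs at that distance on the
chromosome, not just the nonzero ones.  Real-valued (predicted) counts are
rounded half-to-even before testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import binom
from statsmodels.stats.multitest import multipletests

from .core_io import MAX_SPAN_BINS, ContactMatrix


@dataclass
class StratumTest:
    """One distance stratum: n total interactions, uniform per-pair
    probability m = 1/#candidates, and per-pair integer counts."""

    distance_bins: int
    n_candidates: int
    n_total: int
    m: float
    pairs: pd.DataFrame  # bin_i, bin_j, count (int), p


@dataclass
class LoopTestContext:
    chrom: str
    n_bins: int
    strata: dict[int, StratumTest] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        if not self.strata:
            return pd.DataFrame(columns=["chrom", "bin_i", "bin_j", "count", "p"])
        frames = [s.pairs.assign(distance_bins=d) for d, s in sorted(self.strata.items())]
        out = pd.concat(frames, ignore_index=True)
        out.insert(0, "chrom", self.chrom)
        return out


@dataclass
class SignificantInteractionSet:
    """Loop calls at q < alpha; ``frame`` columns:
    chrom, bin_i, bin_j, count, p, q."""

    frame: pd.DataFrame
    alpha: float = 0.05

    def __len__(self) -> int:
        return len(self.frame)

    def pair_set(self) -> set[tuple[int, int]]:
        return set(zip(self.frame["bin_i"].astype(int), self.frame["bin_j"].astype(int)))


def binomial_pvalues(matrix: ContactMatrix, n_bins: int | None = None,
                     max_span_bins: int = MAX_SPAN_BINS) -> LoopTestContext:
    """Upper-tail binomial p-value per pair, stratified by distance.

    Counts are rounded half-to-even to integers.  Candidate pairs with zero
    counts have p = 1 and are carried implicitly (only observed pairs are
    materialized; the stratum records n_candidates for the universe).
    """
    n = n_bins if n_bins is not None else matrix.n_bins
    ctx = LoopTestContext(chrom=matrix.chrom, n_bins=n)
    by_d: dict[int, list] = {}
    for (i, j), c in matrix.items():
        by_d.setdefault(j - i, []).append((i, j, c))
    for d in range(1, min(max_span_bins, n - 1) + 1):
        n_cand = n - d
        if n_cand <= 0:
            continue
        m = 1.0 / n_cand
        recs = by_d.get(d, [])
        k = np.rint([c for _, _, c in recs]).astype(int)
        n_total = int(k.sum())
        # P(K >= k) = sf(k-1); k = 0 gives p = 1
        p = binom.sf(k - 1, n_total, m) if len(k) else np.array([])
        pairs = pd.DataFrame({
            "bin_i": [r[0] for r in recs],
            "bin_j": [r[1] for r in recs],
            "count": k,
            "p": p,
        })
        ctx.strata[d] = StratumTest(distance_bins=d, n_candidates=n_cand,
                                    n_total=n_total, m=m, pairs=pairs)
    return ctx


def bh_qvalues(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values), in input order."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_significant(context: LoopTestContext, alpha: float = 0.05,
                     global_fdr: bool = False) -> SignificantInteractionSet:
    """Apply BH within each distance stratum (or pooled with
    ``global_fdr=True``) and keep records with q < alpha.

    Zero-count candidate pairs enter the correction with p = 1: the BH
    denominator per stratum is the full candidate universe, implemented by
    adjusting the materialized pairs with M = n_candidates (p = 1 entries
    cannot change any other pair's q under step-up BH).
    """
    frames = []
    strata = sorted(context.strata.items())
    if global_fdr:
        all_pairs = [s.pairs for _, s in strata if len(s.pairs)]
        M = sum(s.n_candidates for _, s in strata)
        if all_pairs:
            pooled = pd.concat(all_pairs, ignore_index=True)
            pooled["q"] = _bh_with_universe(pooled["p"].to_numpy(), M)
            frames.append(pooled)
    else:
        for _, s in strata:
            if not len(s.pairs):
                continue
            sub = s.pairs.copy()
            sub["q"] = _bh_with_universe(sub["p"].to_numpy(), s.n_candidates)
            frames.append(sub)
    if frames:
        out = pd.concat(frames, ignore_index=True)
        out = out[out["q"] < alpha].reset_index(drop=True)
    else:
        out = pd.DataFrame(columns=["bin_i", "bin_j", "count", "p", "q"])
    out.insert(0, "chrom", context.chrom)
    out = out.sort_values(["bin_i", "bin_j"]).reset_index(drop=True)
    return SignificantInteractionSet(frame=out[["chrom", "bin_i", "bin_j",
                                                "count", "p", "q"]], alpha=alpha)


def _bh_with_universe(p: np.ndarray, M: int) -> np.ndarray:
    """Step-up BH where the total test count M includes implicit p = 1 tests
    beyond the materialized ones."""
    n_extra = M - len(p)
    if n_extra < 0:
        raise ValueError("universe smaller than number of materialized pairs")
    if n_extra == 0:
        return bh_qvalues(p)
    q_full = bh_qvalues(np.concatenate([p, np.ones(n_extra)]))
    return q_full[: len(p)]


def call_loops(matrix: ContactMatrix, alpha: float = 0.05,
               n_bins: int | None = None,
               global_fdr: bool = False) -> SignificantInteractionSet:
    """End-to-end loop calling: binomial p-values then BH at q < alpha."""
    return call_significant(binomial_pvalues(matrix, n_bins=n_bins),
                            alpha=alpha, global_fdr=global_fdr)
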