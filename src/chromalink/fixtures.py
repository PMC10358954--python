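"""Synthetic-data generators with recorded ground truth.

Every downstream stage of the package gets a testable input from here:
block-structured contact matrices with power-law distance decay, signal
panels whose features determine the counts through a recorded generating
function, multi-cell-type stochastic-block-model gene networks with planted
conserved and transitioning modules on a known cell-type tree, and SNP
studies with planted SNP-gene links and eQTL support.

All generators are pure functions of a :class:`SyntheticSpec` (whose seed
fully determines the output), and the returned ground-truth records suffice
to score every downstream metric without re-deriving structure.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist

from .core_io import MAX_SPAN_BINS, RESOLUTION, ContactMatrix, IntervalSet, SignalTrack
from .features import (MOTIF_LABELS, SIGNAL_LABELS, build_pair_features,
                       discretize, fit_discretization)
from .networks import CellTypeTree, upgma_tree


@dataclass
class SyntheticSpec:
    """Conditions for the synthetic study.

    Defaults give a 3 Mb chromosome (600 bins) with 6 equal TADs,
    3 cell types and 300 genes in 6 network modules — small enough for
    seconds-scale tests while preserving the statistical structure the
    methods assume.
    """

    n_bins: int = 600
    n_tads: int = 6
    decay_exponent: float = 1.0
    noise_sd: float = 0.2
    seed: int = 0
    chrom: str = "chrS"
    base_count: float = 100.0
    tad_boost: float = 1.0
    #: per-1Mb-segment (base_count, tad_boost) overrides; None = homogeneous
    segment_params: list[tuple[float, float]] | None = None

    n_cell_types: int = 3
    n_genes: int = 300
    n_modules: int = 6
    p_within: float = 0.30
    p_between: float = 0.02
    #: plant a transitioning event (a minority of module 0 joins module 1
    #: inside the designated subtree)
    transition: bool = True
    n_transition: int = 20


# ---------------------------------------------------------------------------
# contact matrix
# ---------------------------------------------------------------------------


def tad_blocks(spec: SyntheticSpec) -> np.ndarray:
    """Block id per bin; blocks are equal-width tiles."""
    width = spec.n_bins // spec.n_tads
    return np.minimum(np.arange(spec.n_bins) // width, spec.n_tads - 1)


def planted_boundaries(spec: SyntheticSpec) -> list[int]:
    width = spec.n_bins // spec.n_tads
    return [k * width for k in range(1, spec.n_tads)]


def count_law(spec: SyntheticSpec, i: np.ndarray, j: np.ndarray,
              same_block: np.ndarray) -> np.ndarray:
    """Noise-free expected count for pairs (i, j).

    count = base * (j-i)^(-decay) * (1 + boost * same_block); when
    ``segment_params`` is set, base and boost come from the 1 Mb segment of
    each anchor, averaged over the pair's (one or two) segments.
    """
    d = (j - i).astype(float)
    if spec.segment_params is None:
        return spec.base_count * d ** (-spec.decay_exponent) * (1 + spec.tad_boost * same_block)
    bins_per_seg = 1_000_000 // RESOLUTION
    params = np.array(spec.segment_params, dtype=float)
    si = np.minimum(i // bins_per_seg, len(params) - 1)
    sj = np.minimum(j // bins_per_seg, len(params) - 1)
    out = np.zeros(len(d))
    for s, anchor_seg in ((0, si), (1, sj)):
        base = params[anchor_seg, 0]
        boost = params[anchor_seg, 1]
        out += base * d ** (-spec.decay_exponent) * (1 + boost * same_block)
    return out / 2.0


def synth_contact_matrix(spec: SyntheticSpec) -> tuple[ContactMatrix, list[int]]:
    """Block-structured contact matrix with power-law decay and log-normal
    multiplicative noise; returns the matrix and the planted TAD boundaries."""
    if spec.decay_exponent <= 0:
        raise ValueError("decay exponent must be positive")
    if spec.n_bins < 2 * MAX_SPAN_BINS:
        raise ValueError(f"n_bins must be at least {2 * MAX_SPAN_BINS}")
    rng = np.random.default_rng(spec.seed)
    block = tad_blocks(spec)
    cm = ContactMatrix(spec.chrom, n_bins=spec.n_bins)
    for d in range(1, min(MAX_SPAN_BINS, spec.n_bins - 1) + 1):
        i = np.arange(spec.n_bins - d)
        j = i + d
        mu = count_law(spec, i, j, (block[i] == block[j]).astype(float))
        noise = np.exp(rng.normal(0.0, spec.noise_sd, size=len(i))) if spec.noise_sd > 0 else 1.0
        counts = mu * noise
        for a, b, c in zip(i, j, counts):
            cm.set(int(a), int(b), float(c))
    return cm, planted_boundaries(spec)


# ---------------------------------------------------------------------------
# signal panel
# ---------------------------------------------------------------------------


def synth_signal_panel(spec: SyntheticSpec, matrix: ContactMatrix,
                       shape_seed: int | None = None
                       ) -> tuple[list[SignalTrack], dict]:
    """Ten per-bin tracks (7 signal-like, 3 motif-count-like) for the
    chromosome of ``matrix``.

    The informative tracks are the boundary-marker motif tracks (CTCF- and
    RAD21-like, peaking exactly at the planted TAD boundaries): together with
    genomic distance they determine the noise-free counts through
    :func:`count_law` (a pair is cross-block iff a boundary lies in
    ``(i, j]``, visible in the motif window or the downstream anchor).  The
    other tracks are smooth nuisance signals; one mirrors the matrix's
    per-bin contact activity.  The generating function is recorded in the
    returned description.

    ``shape_seed`` fixes the deterministic shapes of the nuisance tracks
    independently of the measurement noise, so two cell types can share
    track shapes while differing in their noise realizations.
    """
    n = spec.n_bins
    rng = np.random.default_rng(spec.seed + 1 if shape_seed is None else shape_seed)
    noise_rng = np.random.default_rng(spec.seed + 1009)
    boundaries = planted_boundaries(spec)
    tracks: list[SignalTrack] = []

    activity = np.zeros(n)
    for (i, j), c in matrix.items():
        activity[i] += c
        activity[j] += c
    activity = np.log1p(activity)

    for label in SIGNAL_LABELS:
        freq = rng.uniform(1.0, 4.0)
        phase = rng.uniform(0.0, 2 * np.pi)
        s = 2.0 + np.sin(2 * np.pi * freq * np.arange(n) / n + phase)
        if label == "H3K27ac":
            s = activity / max(activity.max(), 1.0) + 1.0
        if spec.noise_sd > 0:
            s = np.clip(s + noise_rng.normal(0.0, spec.noise_sd / 2, size=n), 0.0, None)
        tracks.append(SignalTrack(values={spec.chrom: s}, label=label))

    for label, peak in zip(MOTIF_LABELS, (3.0, 2.0, 0.0)):
        counts = np.zeros(n)
        if peak > 0:
            counts[boundaries] = peak
        else:  # TBP-like: unstructured counts
            counts = rng.poisson(0.3, size=n).astype(float)
        if spec.noise_sd > 0 and peak > 0:
            counts += noise_rng.binomial(1, min(0.05, spec.noise_sd / 10), size=n)
        tracks.append(SignalTrack(values={spec.chrom: counts}, label=label))

    description = {
        "law": "base * d^-decay * (1 + boost * same_block)",
        "base_count": spec.base_count,
        "decay_exponent": spec.decay_exponent,
        "tad_boost": spec.tad_boost,
        "segment_params": spec.segment_params,
        "boundary_tracks": ["CTCF", "RAD21"],
        "boundaries": boundaries,
    }
    return tracks, description


def synth_regression_dataset(spec: SyntheticSpec, test_seed_offset: int = 101,
                             k_levels: int = 20) -> dict:
    """Train/test pair-feature tables for cross-cell-type count regression.

    The "test cell type" shares the generating law and TAD structure but has
    its own noise realization and nuisance tracks.  Discretization models are
    fitted on the training tracks and applied unchanged to the test tracks.
    """
    train_matrix, boundaries = synth_contact_matrix(spec)
    test_spec = SyntheticSpec(**{**spec.__dict__, "seed": spec.seed + test_seed_offset})
    test_matrix, _ = synth_contact_matrix(test_spec)

    shape_seed = spec.seed + 1  # both cell types share track shapes
    train_tracks, law = synth_signal_panel(spec, train_matrix, shape_seed=shape_seed)
    test_tracks, _ = synth_signal_panel(test_spec, test_matrix, shape_seed=shape_seed)

    n_sig = len(SIGNAL_LABELS)
    models = [fit_discretization(t, k=k_levels, seed=spec.seed)
              for t in train_tracks[:n_sig]]
    train_levels = [discretize(t, m) for t, m in zip(train_tracks[:n_sig], models)]
    test_levels = [discretize(t, m) for t, m in zip(test_tracks[:n_sig], models)]

    train_table = build_pair_features(train_levels, train_tracks[n_sig:],
                                      spec.chrom, counts=train_matrix)
    test_table = build_pair_features(test_levels, test_tracks[n_sig:],
                                     spec.chrom, counts=test_matrix)
    return {
        "train_table": train_table, "test_table": test_table,
        "train_matrix": train_matrix, "test_matrix": test_matrix,
        "boundaries": boundaries, "models": models, "law": law,
    }


# ---------------------------------------------------------------------------
# multi-cell-type networks
# ---------------------------------------------------------------------------


@dataclass
class MultiCellTypeFixture:
    graphs: dict[str, nx.Graph]
    tree: CellTypeTree
    labels: pd.DataFrame  # planted community id per gene (rows) x cell type
    transitioning_genes: set[str]
    designated: list[str]  # cell types of the designated subtree
    modules: list[list[str]]


def synth_multi_celltype_networks(spec: SyntheticSpec) -> MultiCellTypeFixture:
    """Stochastic-block-model gene networks sharing module structure across
    cell types, with a planted transitioning event in a designated subtree.

    The transitioning event moves a minority of module 0 (``n_transition``
    genes) into module 1's community inside the designated subtree.  Keeping
    the movers a minority leaves every module anchored by a majority of its
    original members, so cluster identities stay resolvable across cell
    types and the cluster count is unchanged.
    """
    if spec.n_cell_types < 2:
        raise ValueError("need at least two cell types")
    if spec.n_genes < spec.n_modules:
        raise ValueError("module sizes exceed the gene count")
    rng = np.random.default_rng(spec.seed + 2)
    genes = [f"g{ix:04d}" for ix in range(spec.n_genes)]
    base_membership = np.arange(spec.n_genes) % spec.n_modules  # interleaved, equal sizes
    # reorder so modules are contiguous for readability
    order = np.argsort(base_membership, kind="stable")
    base_membership = base_membership[order]

    cts = [f"ct{ix:02d}" for ix in range(spec.n_cell_types)]
    coords = np.array([0.0, 1.0] + [5.0 * ix for ix in range(2, spec.n_cell_types)])
    tree = upgma_tree(pdist(coords[:, None]), cts)
    designated = cts[:2] if spec.n_cell_types > 2 else cts[:1]

    m0 = np.nonzero(base_membership == 0)[0]
    if spec.transition and spec.n_transition >= len(m0):
        raise ValueError("transitioning genes must be a minority of module 0")
    movers = m0[len(m0) - spec.n_transition:]
    transitioning = set()
    if spec.transition and spec.n_modules >= 2:
        transitioning = {genes[ix] for ix in movers}

    label_cols = {}
    graphs = {}
    for ct in cts:
        membership = base_membership.copy()
        if spec.transition and spec.n_modules >= 2 and ct in designated:
            membership[movers] = 1
        P = np.where(membership[:, None] == membership[None, :],
                     spec.p_within, spec.p_between)
        upper = np.triu(rng.random((spec.n_genes, spec.n_genes)) < P, k=1)
        g = nx.Graph()
        g.add_nodes_from(genes)
        ii, jj = np.nonzero(upper)
        g.add_edges_from((genes[a], genes[b], {"weight": 1.0}) for a, b in zip(ii, jj))
        graphs[ct] = g
        label_cols[ct] = membership + 1
    labels = pd.DataFrame(label_cols, index=genes)
    modules = [[genes[ix] for ix in np.nonzero(base_membership == m)[0]]
               for m in range(spec.n_modules)]
    return MultiCellTypeFixture(graphs=graphs, tree=tree, labels=labels,
                                transitioning_genes=transitioning,
                                designated=designated, modules=modules)


# ---------------------------------------------------------------------------
# SNP study
# ---------------------------------------------------------------------------


@dataclass
class SnpStudyFixture:
    snps: IntervalSet
    tss: IntervalSet
    ld: pd.DataFrame          # lead_id, proxy_id, r2
    eqtl: pd.DataFrame        # snp_id, gene, distance
    planted_links: pd.DataFrame  # the complete derivable (snp_id, gene) set


def synth_snp_study(spec: SyntheticSpec, loops, n_snps: int = 40,
                    planted_fraction: float = 0.8,
                    eqtl_fraction: float = 0.5) -> SnpStudyFixture:
    """Place SNPs and gene TSSs relative to a significant-interaction set.

    A ``planted_fraction`` of SNPs lands inside loop anchors whose partner
    bin hosts a gene promoter (TSS centered in the bin, so its +/-2500 bp
    window is exactly that bin); the rest land in bins touching no loop.
    The complete derivable SNP-gene link set is recorded, and an exact
    ``eqtl_fraction`` subsample of it is emitted as eQTL support.
    """
    frame = loops.frame
    if not len(frame):
        raise ValueError("loop set is empty")
    rng = np.random.default_rng(spec.seed + 3)
    chrom = str(frame["chrom"].iloc[0])
    loop_pairs = list(zip(frame["bin_i"].astype(int), frame["bin_j"].astype(int),
                          frame["q"].astype(float)))
    anchor_bins = {b for i, j, _ in loop_pairs for b in (i, j)}

    n_planted = int(round(planted_fraction * n_snps))
    chosen = rng.choice(len(loop_pairs), size=n_planted, replace=True)

    gene_of_bin: dict[int, str] = {}
    snp_rows, tss_rows = [], []
    snp_bins: list[int] = []
    for s_ix, l_ix in enumerate(chosen):
        i, j, _ = loop_pairs[l_ix]
        gene_bin, snp_bin = (j, i) if rng.random() < 0.5 else (i, j)
        if gene_bin not in gene_of_bin:
            gene = f"gene_b{gene_bin}"
            gene_of_bin[gene_bin] = gene
            tss = gene_bin * RESOLUTION + RESOLUTION // 2
            tss_rows.append((chrom, tss, tss + 1, gene, None))
        pos = snp_bin * RESOLUTION + int(rng.integers(0, RESOLUTION))
        snp_rows.append((chrom, pos, pos + 1, f"rs{s_ix:04d}", None))
        snp_bins.append(snp_bin)

    # bins that cannot link to any gene: none of their looped partners hosts one
    partner_map: dict[int, set[int]] = {}
    for i, j, _ in loop_pairs:
        partner_map.setdefault(i, set()).add(j)
        partner_map.setdefault(j, set()).add(i)
    n_extent = int(frame[["bin_i", "bin_j"]].to_numpy().max()) + 1
    free_bins = [b for b in range(n_extent)
                 if not (partner_map.get(b, set()) & set(gene_of_bin))]
    if not free_bins and n_planted < n_snps:
        raise ValueError("no gene-free bins available for unlinked SNPs")
    for s_ix in range(n_planted, n_snps):
        b = int(rng.choice(free_bins))
        pos = b * RESOLUTION + int(rng.integers(0, RESOLUTION))
        snp_rows.append((chrom, pos, pos + 1, f"rs{s_ix:04d}", None))
        snp_bins.append(b)

    # LD proxies share the lead's bin (and therefore its links)
    ld_rows = []
    for rec, b in zip(list(snp_rows), snp_bins):
        if rng.random() < 0.3:
            pos = b * RESOLUTION + int(rng.integers(0, RESOLUTION))
            proxy_id = rec[3].replace("rs", "ld")
            ld_rows.append({"lead_id": rec[3], "proxy_id": proxy_id,
                            "r2": float(rng.uniform(0.8, 1.0))})
            snp_rows.append((chrom, pos, pos + 1, proxy_id, None))
            snp_bins.append(b)

    # complete derivable link set: every (snp, gene) joined by a loop
    partners: dict[int, list[tuple[int, float]]] = {}
    for i, j, q in loop_pairs:
        partners.setdefault(i, []).append((j, q))
        partners.setdefault(j, []).append((i, q))
    links = {}
    for rec, b in zip(snp_rows, snp_bins):
        for partner, q in partners.get(b, []):
            gene = gene_of_bin.get(partner)
            if gene is None:
                continue
            tss = partner * RESOLUTION + RESOLUTION // 2
            links[(rec[3], gene)] = {"snp_id": rec[3], "gene": gene,
                                     "distance": abs(rec[1] - tss), "q": q}
    planted_links = pd.DataFrame(list(links.values()),
                                 columns=["snp_id", "gene", "distance", "q"])

    n_eqtl = int(round(eqtl_fraction * len(planted_links)))
    eqtl_ix = rng.choice(len(planted_links), size=n_eqtl, replace=False) \
        if len(planted_links) else []
    eqtl = planted_links.iloc[sorted(eqtl_ix)][["snp_id", "gene", "distance"]]
    eqtl = eqtl.reset_index(drop=True)

    return SnpStudyFixture(
        snps=IntervalSet.from_records(snp_rows),
        tss=IntervalSet.from_records(tss_rows),
        ld=pd.DataFrame(ld_rows, columns=["lead_id", "proxy_id", "r2"]),
        eqtl=eqtl,
        planted_links=planted_links[["snp_id", "gene", "distance", "q"]],
    )
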