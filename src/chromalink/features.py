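"""Discretized pair features for contact-count regression.

Each 5 kb bin is described by a 10-dimensional feature vector: seven
ChIP-seq/accessibility signals discretized into 20 levels by 1-D k-means, and
three accessible-motif count tracks (CTCF, RAD21, TBP; hits filtered at a
purity score > 0.50).  A pair (i, j) is represented by the features of the
two anchor bins plus the window between them — 30 values — with the genomic
distance in bp appended, for 31 columns total.

Discretization levels are fitted once on the training cell type and the same
cluster centers are applied to every test cell type, so levels are comparable
across cell types.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .core_io import MAX_SPAN_BINS, RESOLUTION, IntervalSet, SignalTrack

#: canonical assay order of the 10 per-bin features
SIGNAL_LABELS = ["DNase", "H3K27ac", "H3K27me3", "H3K36me3", "H3K4me1",
                 "H3K4me3", "H3K9me3"]
MOTIF_LABELS = ["CTCF", "RAD21", "TBP"]
ALL_LABELS = SIGNAL_LABELS + MOTIF_LABELS


def normalize_and_collapse(tracks: list[SignalTrack], label: str = "",
                           cell_type: str = "") -> SignalTrack:
    """Depth-normalize replicate tracks and collapse them by the per-bin median.

    Each replicate is scaled by ``1e6 / total signal`` (counts per million),
    then replicates are collapsed bin-wise with the median.
    """
    if not tracks:
        raise ValueError("need at least one replicate")
    chroms = tracks[0].chroms()
    scaled = []
    for t in tracks:
        total = sum(float(np.sum(t.values[c])) for c in t.chroms())
        if total == 0:
            raise ValueError(f"all-zero replicate track {t.label!r}")
        scaled.append({c: t.values[c] * (1e6 / total) for c in t.chroms()})
    out = SignalTrack(label=label or tracks[0].label, cell_type=cell_type)
    for c in chroms:
        stack = np.vstack([s[c] for s in scaled])
        out.values[c] = np.median(stack, axis=0)
    return out


@dataclass
class DiscretizationModel:
    """Sorted 1-D k-means cluster centers; the level of a value is the index
    of its nearest center (ties to the lower level)."""

    centers: np.ndarray  # strictly increasing

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=float)
        if np.any(np.diff(self.centers) <= 0):
            raise ValueError("cluster centers must be strictly increasing")

    @property
    def n_levels(self) -> int:
        return len(self.centers)

    def assign(self, values: np.ndarray) -> np.ndarray:
        """Level of each value = index of the nearest center."""
        values = np.asarray(values, dtype=float)
        if self.n_levels == 1:
            return np.zeros(values.shape, dtype=int)
        mids = (self.centers[:-1] + self.centers[1:]) / 2.0
        # a value exactly at a midpoint belongs to the lower level
        return np.searchsorted(mids, values, side="left").astype(int)


def fit_discretization(track: SignalTrack, k: int = 20, seed: int = 0) -> DiscretizationModel:
    """Fit 1-D k-means with ``k`` clusters on all bin values of a track.

    If the track has fewer than ``k`` distinct values, ``k`` is reduced to
    that count (a constant track yields a single level).
    """
    values = np.concatenate([track.values[c] for c in track.chroms()])
    if values.size == 0:
        raise ValueError("empty signal track")
    distinct = np.unique(values)
    k_eff = min(k, len(distinct))
    if k_eff == len(distinct):
        centers = distinct
    else:
        km = KMeans(n_clusters=k_eff, n_init=10, random_state=seed)
        km.fit(values.reshape(-1, 1))
        centers = np.sort(np.unique(km.cluster_centers_.ravel()))
    return DiscretizationModel(centers=centers)


def discretize(track: SignalTrack, model: DiscretizationModel) -> SignalTrack:
    out = SignalTrack(label=track.label, cell_type=track.cell_type)
    for c in track.chroms():
        out.values[c] = model.assign(track.values[c]).astype(float)
    return out


def motif_bin_counts(hits: IntervalSet, n_bins: int, chrom: str | None = None,
                     purity_min: float = 0.50, label: str = "") -> SignalTrack:
    """Per-5kb-bin count of motif hits with purity score strictly > ``purity_min``.

    A hit is assigned to the bin of its start coordinate (half-open bins, so a
    hit starting exactly at 5000 lands in bin 1).
    """
    df = hits.df
    if chrom is not None:
        df = df[df["chrom"] == chrom]
        chroms = [chrom]
    else:
        chroms = sorted(df["chrom"].unique()) or ["chr"]
    track = SignalTrack(label=label)
    for c in chroms:
        sub = df[df["chrom"] == c]
        counts = np.zeros(n_bins)
        if len(sub):
            keep = sub["score"].astype(float) > purity_min
            bins = (sub.loc[keep, "start"].astype(int) // RESOLUTION).to_numpy()
            bins = bins[bins < n_bins]
            np.add.at(counts, bins, 1.0)
        track.values[c] = counts
    if chrom is not None and chrom not in track.values:
        track.values[chrom] = np.zeros(n_bins)
    return track


# ---------------------------------------------------------------------------
# pair feature construction
# ---------------------------------------------------------------------------


@dataclass
class PairFeatureTable:
    """Rows of 31 pair features (10 region1 + 10 window + 10 region2 + distance)
    with optional target counts.  ``frame`` columns: ``bin_i``, ``bin_j``, the
    31 feature columns in fixed order, and optionally ``count``."""

    frame: pd.DataFrame
    feature_columns: list[str] = field(default_factory=list)
    chrom: str = ""

    def X(self) -> np.ndarray:
        return self.frame[self.feature_columns].to_numpy(dtype=float)

    def y(self) -> np.ndarray:
        return self.frame["count"].to_numpy(dtype=float)

    def __len__(self) -> int:
        return len(self.frame)


def _window_stats(values: np.ndarray, n: int, d: int, kind: str) -> np.ndarray:
    """Window feature for all pairs (i, i+d): mean of intervening values for
    signals, total/(d-1) for motif counts; adjacent pairs use the mean of the
    two anchors."""
    i = np.arange(n - d)
    if d == 1:
        return (values[i] + values[i + 1]) / 2.0
    cs = np.concatenate([[0.0], np.cumsum(values)])
    inner = cs[i + d] - cs[i + 1]  # sum over bins i+1 .. i+d-1
    return inner / (d - 1)  # mean for signals == total / #window-bins for motifs


def build_pair_features(
    signal_levels: list[SignalTrack],
    motif_counts: list[SignalTrack],
    chrom: str,
    counts=None,
    signal_raw: list[SignalTrack] | None = None,
    models: list[DiscretizationModel] | None = None,
    window_mode: str = "levels",
    max_span_bins: int = MAX_SPAN_BINS,
) -> PairFeatureTable:
    """Build the 31-column pair feature table for one chromosome.

    Pairs span 1..``max_span_bins`` bins (5 kb .. 1 Mb).  For ChIP/DNase
    tracks the window feature is the mean of the discretized levels over the
    intervening bins (``window_mode="levels"``, the default); with
    ``window_mode="raw"`` the raw signal is averaged over the window and then
    discretized with the fitted model.  For motif tracks the window feature is
    the total motif count divided by the number of intervening bins.  Adjacent
    pairs (no intervening bin) use the mean of the two anchor values.

    ``counts`` may be a :class:`~chromalink.core_io.ContactMatrix` supplying
    regression targets.
    """
    if window_mode not in ("levels", "raw"):
        raise ValueError("window_mode must be 'levels' or 'raw'")
    if window_mode == "raw" and (signal_raw is None or models is None):
        raise ValueError("window_mode='raw' requires raw tracks and models")

    tracks = signal_levels + motif_counts
    labels = [t.label or f"f{ix}" for ix, t in enumerate(tracks)]
    n = min(len(t.values[chrom]) for t in tracks)
    n_sig = len(signal_levels)

    blocks = []
    for d in range(1, min(max_span_bins, n - 1) + 1):
        i = np.arange(n - d)
        cols: dict[str, np.ndarray] = {"bin_i": i, "bin_j": i + d}
        for ix, t in enumerate(tracks):
            v = t.values[chrom][:n]
            lab = labels[ix]
            cols[f"{lab}_r1"] = v[i]
            if ix < n_sig and window_mode == "raw":
                raw = signal_raw[ix].values[chrom][:n]
                w = _window_stats(raw, n, d, "signal")
                cols[f"{lab}_win"] = models[ix].assign(w).astype(float)
            else:
                cols[f"{lab}_win"] = _window_stats(v, n, d, "any")
            cols[f"{lab}_r2"] = v[i + d]
        cols["distance"] = np.full(n - d, d * RESOLUTION, dtype=float)
        blocks.append(pd.DataFrame(cols))
    frame = pd.concat(blocks, ignore_index=True)

    feature_columns = (
        [f"{lab}_r1" for lab in labels]
        + [f"{lab}_win" for lab in labels]
        + [f"{lab}_r2" for lab in labels]
        + ["distance"]
    )
    order = ["bin_i", "bin_j"] + feature_columns
    frame = frame[order]

    if counts is not None:
        frame["count"] = [
            counts.get(int(a), int(b)) for a, b in zip(frame["bin_i"], frame["bin_j"])
        ]
    return PairFeatureTable(frame=frame, feature_columns=feature_columns, chrom=chrom)
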