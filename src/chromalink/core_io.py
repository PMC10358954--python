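"""Domain types, coordinate conventions, and on-disk formats.

Conventions used throughout the package:

* all coordinates are 0-based, half-open (the native BED/bedGraph convention);
* the genomic unit is a fixed-width 5 kb bin, ``index = floor(position/5000)``;
* contact matrices are intra-chromosomal, stored upper-triangular
  (``i < j``) and restricted to pair spans of 5 kb .. 1 Mb (1..200 bins);
* counts are stored as reals, since normalized and predicted counts are
  non-integer;
* strand is ignored.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

#: width of a genomic bin in bp
RESOLUTION = 5000
#: maximum pair span in bins (1 Mb)
MAX_SPAN_BINS = 200
#: half-width of a promoter window around a TSS in bp
TSS_WINDOW = 2500


def bin_of(position: int, resolution: int = RESOLUTION) -> int:
    """Bin index of a genomic position (0-based, half-open bins)."""
    return int(position) // resolution


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenomicBin:
    """A fixed-width 5 kb genomic interval ``[index*5000, index*5000+5000)``."""

    chrom: str
    index: int

    def __post_init__(self) -> None:
        if self.index < 0:
            raise ValueError("bin index must be non-negative")

    @property
    def start(self) -> int:
        return self.index * RESOLUTION

    @property
    def end(self) -> int:
        return self.start + RESOLUTION


@dataclass
class SignalTrack:
    """Per-bin real-valued signal for one assay in one cell type."""

    values: dict[str, np.ndarray] = field(default_factory=dict)
    label: str = ""
    cell_type: str = ""

    def chroms(self) -> list[str]:
        return sorted(self.values)

    def n_bins(self, chrom: str) -> int:
        return len(self.values[chrom])


class ContactMatrix:
    """Sparse intra-chromosomal 5 kb contact counts, upper-triangular.

    Entries are keyed ``(i, j)`` with ``i < j`` and ``1 <= j - i <= 200``
    (pair span 5 kb .. 1 Mb).  ``n_bins`` records the chromosome extent in
    bins and defines the candidate-pair universe for statistics downstream.
    """

    def __init__(self, chrom: str, n_bins: int | None = None):
        self.chrom = chrom
        self.resolution = RESOLUTION
        self.max_span_bins = MAX_SPAN_BINS
        self._data: dict[tuple[int, int], float] = {}
        self._n_bins = n_bins

    # -- construction -------------------------------------------------------

    def add(self, i: int, j: int, count: float) -> None:
        """Accumulate ``count`` onto the canonical ``(min, max)`` key."""
        if count < 0:
            raise ValueError(f"negative contact count for pair ({i},{j})")
        if i == j:
            raise ValueError(f"self-pair ({i},{i}) is not a valid contact")
        a, b = (i, j) if i < j else (j, i)
        if a < 0:
            raise ValueError("negative bin index")
        if b - a > self.max_span_bins:
            raise ValueError(
                f"pair span {b - a} bins exceeds the {self.max_span_bins}-bin limit"
            )
        self._data[(a, b)] = self._data.get((a, b), 0.0) + float(count)

    def set(self, i: int, j: int, count: float) -> None:
        a, b = (i, j) if i < j else (j, i)
        self._data.pop((a, b), None)
        self.add(i, j, count)

    # -- access -------------------------------------------------------------

    @property
    def n_bins(self) -> int:
        if self._n_bins is not None:
            return self._n_bins
        if not self._data:
            return 0
        return max(j for _, j in self._data) + 1

    @n_bins.setter
    def n_bins(self, value: int) -> None:
        self._n_bins = int(value)

    def get(self, i: int, j: int, default: float = 0.0) -> float:
        a, b = (i, j) if i < j else (j, i)
        return self._data.get((a, b), default)

    def items(self) -> Iterator[tuple[tuple[int, int], float]]:
        return iter(self._data.items())

    def __len__(self) -> int:
        return len(self._data)

    def __contains__(self, key: tuple[int, int]) -> bool:
        a, b = key
        if a > b:
            a, b = b, a
        return (a, b) in self._data

    def to_frame(self) -> pd.DataFrame:
        keys = sorted(self._data)
        return pd.DataFrame(
            {
                "chrom": self.chrom,
                "bin_i": [k[0] for k in keys],
                "bin_j": [k[1] for k in keys],
                "count": [self._data[k] for k in keys],
            }
        )

    def to_dense(self) -> np.ndarray:
        """Full symmetric matrix of shape (n_bins, n_bins)."""
        n = self.n_bins
        m = np.zeros((n, n))
        for (i, j), c in self._data.items():
            m[i, j] = c
            m[j, i] = c
        return m

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, chrom: str, n_bins: int | None = None) -> "ContactMatrix":
        cm = cls(chrom, n_bins=n_bins)
        for i, j, c in zip(frame["bin_i"], frame["bin_j"], frame["count"]):
            cm.add(int(i), int(j), float(c))
        return cm


@dataclass
class IntervalSet:
    """A list of ``(chrom, start, end, name, score)`` records, 0-based half-open.

    Used for TSS windows, SNPs, motif hits and TADs alike.
    """

    df: pd.DataFrame

    COLUMNS = ["chrom", "start", "end", "name", "score"]

    @classmethod
    def from_records(cls, records: Iterable[tuple]) -> "IntervalSet":
        rows = []
        for rec in records:
            rec = tuple(rec) + (None,) * (5 - len(rec))
            chrom, start, end, name, score = rec[:5]
            if not int(start) < int(end):
                raise ValueError(f"interval start must be < end: {rec[:3]}")
            rows.append((chrom, int(start), int(end), name, score))
        df = pd.DataFrame(rows, columns=cls.COLUMNS)
        return cls(df)

    def __len__(self) -> int:
        return len(self.df)

    def __iter__(self):
        return self.df.itertuples(index=False)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def read_signal_track(path, resolution: int = RESOLUTION, label: str = "",
                      cell_type: str = "") -> SignalTrack:
    """Read a 4-column bedGraph into per-bin values.

    Each record contributes its value weighted by its bp overlap with every
    bin it touches; a bin's value is the length-weighted mean over the full
    bin width, i.e. uncovered base pairs count as 0.  Overlapping records are
    rejected.
    """
    per_chrom: dict[str, dict] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split()
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: expected 4 bedGraph columns")
            chrom = fields[0]
            try:
                start, end, value = int(fields[1]), int(fields[2]), float(fields[3])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed bedGraph record") from exc
            if start >= end:
                raise ValueError(f"{path}:{lineno}: start must be < end")
            per_chrom.setdefault(chrom, {"recs": []})["recs"].append((start, end, value))

    track = SignalTrack(label=label, cell_type=cell_type)
    for chrom, info in per_chrom.items():
        recs = sorted(info["recs"])
        for (s1, e1, _), (s2, _, _) in zip(recs, recs[1:]):
            if s2 < e1:
                raise ValueError(
                    f"overlapping bedGraph records on {chrom} at {s2} < {e1}"
                )
        extent = recs[-1][1]
        n = -(-extent // resolution)
        acc = np.zeros(n)
        for start, end, value in recs:
            for b in range(start // resolution, -(-end // resolution)):
                lo = max(start, b * resolution)
                hi = min(end, (b + 1) * resolution)
                acc[b] += value * (hi - lo)
        track.values[chrom] = acc / resolution
    return track


def read_pairs(path, n_bins: int | None = None) -> dict[str, ContactMatrix]:
    """Read a ``chrom<TAB>start1<TAB>start2<TAB>count`` pairs file.

    Keys are canonicalized to ``i < j``; duplicate pairs are summed.
    Returns one :class:`ContactMatrix` per chromosome.
    """
    try:
        df = pd.read_csv(path, sep="\t", header=None,
                         names=["chrom", "start1", "start2", "count"],
                         float_precision="round_trip")
    except pd.errors.EmptyDataError:
        return {}
    if df.empty:
        return {}
    for col in ("start1", "start2"):
        bad = df[col] % RESOLUTION != 0
        if bad.any():
            raise ValueError(
                f"{path}: start {df.loc[bad, col].iloc[0]} is not a multiple of {RESOLUTION}"
            )
    if (df["count"] < 0).any():
        raise ValueError(f"{path}: negative contact count")
    out: dict[str, ContactMatrix] = {}
    for chrom, sub in df.groupby("chrom", sort=True):
        cm = ContactMatrix(str(chrom), n_bins=n_bins)
        for s1, s2, c in zip(sub["start1"], sub["start2"], sub["count"]):
            cm.add(int(s1) // RESOLUTION, int(s2) // RESOLUTION, float(c))
        out[str(chrom)] = cm
    return out


def write_pairs(matrices, path) -> None:
    """Write one or more contact matrices to a pairs TSV (no header)."""
    if isinstance(matrices, ContactMatrix):
        matrices = {matrices.chrom: matrices}
    with open(path, "w") as fh:
        for chrom in sorted(matrices):
            cm = matrices[chrom]
            for (i, j) in sorted(dict(cm.items())):
                fh.write(f"{chrom}\t{i * RESOLUTION}\t{j * RESOLUTION}\t{cm.get(i, j)!r}\n")


def read_edge_list(path, min_score: float) -> list[tuple[str, str, float]]:
    """Read a ``nodeA<TAB>nodeB<TAB>score`` TSV, keeping edges with
    score strictly greater than ``min_score``; self-loops are dropped and
    duplicate edges keep their maximum score."""
    try:
        df = pd.read_csv(path, sep="\t", header=None, names=["a", "b", "score"])
    except pd.errors.EmptyDataError:
        return []
    if df.empty:
        return []
    score = pd.to_numeric(df["score"], errors="coerce")
    if score.isna().any():
        bad = df.loc[score.isna(), "score"].iloc[0]
        raise ValueError(f"{path}: non-numeric edge score {bad!r}")
    edges: dict[tuple[str, str], float] = {}
    for a, b, s in zip(df["a"].astype(str), df["b"].astype(str), score):
        if a == b or not s > min_score:
            continue
        key = (a, b) if a < b else (b, a)
        edges[key] = max(edges.get(key, -np.inf), float(s))
    return [(a, b, s) for (a, b), s in sorted(edges.items())]


def read_intervals(path) -> IntervalSet:
    """Read a BED3+ file; optional column 4 is a name, column 5 a real score."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 BED columns")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            if start >= end:
                raise ValueError(f"{path}:{lineno}: interval start must be < end")
            name = fields[3] if len(fields) > 3 else None
            score = float(fields[4]) if len(fields) > 4 else None
            rows.append((chrom, start, end, name, score))
    return IntervalSet(pd.DataFrame(rows, columns=IntervalSet.COLUMNS))


def write_intervals(intervals: IntervalSet, path) -> None:
    with open(path, "w") as fh:
        for rec in intervals:
            fields = [rec.chrom, str(rec.start), str(rec.end)]
            if rec.name is not None:
                fields.append(str(rec.name))
                if rec.score is not None:
                    fields.append(repr(float(rec.score)))
            fh.write("\t".join(fields) + "\n")
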