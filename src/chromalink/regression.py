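"""Local 1 Mb-segment random-forest regression of Hi-C contact counts.

A chromosome is tiled into non-overlapping 1 Mb segments and a separate
regression forest is trained per segment on every 5 kb pair with at least one
anchor inside the segment.  At prediction time a pair whose anchors fall in
two different segments receives the average of the two segment models'
predictions.  Training in one cell type and predicting in another is the
intended use: the discretized features are comparable across cell types.

Two baselines are provided: *transfer count* (the training cell type's
measured counts used verbatim as predictions) and a single *global* forest
trained on all pairs of the chromosome.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestRegressor

from .core_io import RESOLUTION, ContactMatrix
from .features import PairFeatureTable

logger = logging.getLogger(__name__)

SEGMENT_SIZE = 1_000_000  # bp


@dataclass
class ForestParams:
    """Regression-forest hyperparameters (not pinned down by the method
    itself; recorded in model metadata for reproducibility)."""

    n_trees: int = 100
    max_features: int | None = None  # default ceil(p/3), set at fit time
    max_depth: int | None = None
    min_samples_leaf: int = 1

    def resolved_max_features(self, p: int) -> int:
        if self.max_features is not None:
            return self.max_features
        return math.ceil(p / 3)


@dataclass
class LocalModelEnsemble:
    chrom: str
    segment_size: int
    models: dict[int, RandomForestRegressor]
    feature_columns: list[str]
    params: ForestParams
    seed: int
    cell_type: str = ""
    empty_segments: list[int] = field(default_factory=list)


def segment_of(bin_index: int, segment_size: int = SEGMENT_SIZE) -> int:
    return (bin_index * RESOLUTION) // segment_size


def assign_training_pairs(table: PairFeatureTable,
                          segment_size: int = SEGMENT_SIZE) -> dict[int, np.ndarray]:
    """Map each 1 Mb segment to the row indices of pairs touching it.

    A pair (i, j) belongs to every segment containing bin i or bin j, so it
    is assigned to exactly one segment (both anchors inside) or two
    (spanning pair).
    """
    if len(table) == 0:
        raise ValueError("empty feature table")
    bins_per_seg = segment_size // RESOLUTION
    si = table.frame["bin_i"].to_numpy() // bins_per_seg
    sj = table.frame["bin_j"].to_numpy() // bins_per_seg
    out: dict[int, list] = {}
    for seg in np.unique(np.concatenate([si, sj])):
        rows = np.nonzero((si == seg) | (sj == seg))[0]
        out[int(seg)] = rows
    return out


def _make_forest(params: ForestParams, p: int, seed: int) -> RandomForestRegressor:
    return RandomForestRegressor(
        n_estimators=params.n_trees,
        max_features=params.resolved_max_features(p),
        max_depth=params.max_depth,
        min_samples_leaf=params.min_samples_leaf,
        random_state=seed,
        n_jobs=1,
    )


def train_local(table: PairFeatureTable,
                assignment: dict[int, np.ndarray] | None = None,
                params: ForestParams | None = None,
                seed: int = 0,
                segment_size: int = SEGMENT_SIZE,
                cell_type: str = "") -> LocalModelEnsemble:
    """Train one regression forest per 1 Mb segment on its assigned pairs."""
    params = params or ForestParams()
    if "count" not in table.frame.columns:
        raise ValueError("feature table has no target counts")
    if assignment is None:
        assignment = assign_training_pairs(table, segment_size)
    X = table.X()
    y = table.y()
    models: dict[int, RandomForestRegressor] = {}
    empty = []
    n_segments = max(assignment) + 1 if assignment else 0
    for seg in range(n_segments):
        rows = assignment.get(seg)
        if rows is None or len(rows) == 0:
            empty.append(seg)
            continue
        forest = _make_forest(params, X.shape[1], seed)
        forest.fit(X[rows], y[rows])
        models[seg] = forest
    return LocalModelEnsemble(
        chrom=table.chrom, segment_size=segment_size, models=models,
        feature_columns=list(table.feature_columns), params=params, seed=seed,
        cell_type=cell_type, empty_segments=empty,
    )


def _nearest_model(ensemble: LocalModelEnsemble, seg: int) -> int:
    trained = np.array(sorted(ensemble.models))
    return int(trained[np.argmin(np.abs(trained - seg))])


def predict_counts(ensemble: LocalModelEnsemble, table: PairFeatureTable,
                   n_bins: int | None = None) -> ContactMatrix:
    """Predict counts for every pair of a feature table.

    Within-segment pairs use that segment's model; spanning pairs average the
    two segment models.  Negative predictions are clamped to zero.  A pair in
    a segment without a trained model falls back to the nearest trained
    segment (with a warning).
    """
    if list(table.feature_columns) != list(ensemble.feature_columns):
        raise ValueError("feature columns do not match training metadata")
    X = table.X()
    bins_per_seg = ensemble.segment_size // RESOLUTION
    si = table.frame["bin_i"].to_numpy() // bins_per_seg
    sj = table.frame["bin_j"].to_numpy() // bins_per_seg

    def resolve(seg: int) -> int:
        if seg in ensemble.models:
            return seg
        near = _nearest_model(ensemble, seg)
        logger.warning("segment %d has no model; falling back to segment %d", seg, near)
        return near

    si = np.array([resolve(int(s)) for s in si])
    sj = np.array([resolve(int(s)) for s in sj])

    pred_sum = np.zeros(len(X))
    pred_n = np.zeros(len(X))
    for seg, model in ensemble.models.items():
        for arr in (si, sj):
            rows = np.nonzero(arr == seg)[0]
            if len(rows):
                pred_sum[rows] += model.predict(X[rows])
                pred_n[rows] += 1
    same = si == sj  # both anchors in one segment: count the model once
    pred_n[same] = pred_n[same] / 2
    pred_sum[same] = pred_sum[same] / 2
    pred = np.clip(pred_sum / pred_n, 0.0, None)

    cm = ContactMatrix(table.chrom, n_bins=n_bins)
    bi = table.frame["bin_i"].to_numpy()
    bj = table.frame["bin_j"].to_numpy()
    for i, j, c in zip(bi, bj, pred):
        cm.set(int(i), int(j), float(c))
    return cm


def baseline_transfer_count(train_matrix: ContactMatrix) -> ContactMatrix:
    """Use the training cell type's measured counts verbatim as the
    prediction for the test cell type (missing pairs predict 0)."""
    cm = ContactMatrix(train_matrix.chrom, n_bins=train_matrix.n_bins)
    for (i, j), c in train_matrix.items():
        cm.set(i, j, c)
    return cm


@dataclass
class GlobalModel:
    chrom: str
    model: RandomForestRegressor
    feature_columns: list[str]


def train_global(table: PairFeatureTable, params: ForestParams | None = None,
                 seed: int = 0) -> GlobalModel:
    """Train a single forest on all pairs of the chromosome (whole-chromosome
    comparator to the local ensemble)."""
    params = params or ForestParams()
    X, y = table.X(), table.y()
    forest = _make_forest(params, X.shape[1], seed)
    forest.fit(X, y)
    return GlobalModel(chrom=table.chrom, model=forest,
                       feature_columns=list(table.feature_columns))


def predict_global(model: GlobalModel, table: PairFeatureTable,
                   n_bins: int | None = None) -> ContactMatrix:
    if list(table.feature_columns) != list(model.feature_columns):
        raise ValueError("feature columns do not match training metadata")
    pred = np.clip(model.model.predict(table.X()), 0.0, None)
    cm = ContactMatrix(table.chrom, n_bins=n_bins)
    for i, j, c in zip(table.frame["bin_i"], table.frame["bin_j"], pred):
        cm.set(int(i), int(j), float(c))
    return cm


def baseline_global_model(table: PairFeatureTable, test_table: PairFeatureTable,
                          params: ForestParams | None = None, seed: int = 0,
                          n_bins: int | None = None) -> ContactMatrix:
    """Train the whole-chromosome forest and predict the test table."""
    return predict_global(train_global(table, params, seed), test_table, n_bins=n_bins)
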