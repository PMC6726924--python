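"""Observation-interval records, attractor features and the tracking matrix.

The measurement is cut into records long enough to characterize the fast-time
attractor but short against the slow damage time scale.  Each record's
embedded trajectory is summarized by a characteristic-distance feature vector
(mean distance of the record's points to K fixed reference points chosen once
from the first, healthiest record); the vectors are stacked into the tracking
matrix X, whose temporal derivative V is the second ingredient of the smooth
orthogonal decomposition.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .embed import EmbeddedRecord, TimeSeries
from .errors import DimensionError, InsufficientDataError, ParameterError
from .rng import stream

__all__ = [
    "RecordingPlan",
    "ReferenceSet",
    "TrackingMatrix",
    "partition_records",
    "choose_references",
    "characteristic_distance",
    "build_tracking",
]

MIN_RECORDS = 4


@dataclass(frozen=True)
class RecordingPlan:
    record_length: int  # samples
    overlap: int = 0  # samples

    def __post_init__(self):
        if self.record_length < 2:
            raise ParameterError("record_length must be >= 2 samples")
        if not 0 <= self.overlap < self.record_length:
            raise ParameterError("need 0 <= overlap < record_length")

    @property
    def stride(self) -> int:
        return self.record_length - self.overlap

    def n_records(self, n_samples: int) -> int:
        if n_samples < self.record_length:
            return 0
        return (n_samples - self.record_length) // self.stride + 1


@dataclass(frozen=True)
class ReferenceSet:
    """K fixed points in embedded space, drawn from the reference record."""

    points: np.ndarray  # (K, d)
    record_index: int
    seed: int

    @property
    def size(self) -> int:
        return self.points.shape[0]

    @property
    def dimension(self) -> int:
        return self.points.shape[1]


@dataclass(frozen=True)
class TrackingMatrix:
    X: np.ndarray  # (m, K), column-centered feature values
    V: np.ndarray  # (m, K), temporal derivative of X
    timestamps: np.ndarray  # (m,) record times
    column_means: np.ndarray  # (K,) removed means

    def __post_init__(self):
        if self.X.shape != self.V.shape:
            raise DimensionError("X and V must have identical shapes")
        if not np.all(np.isfinite(self.X)):
            raise DimensionError("X must be finite")

    @property
    def n_records(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]


def partition_records(series: TimeSeries, plan: RecordingPlan
                      ) -> tuple[list[TimeSeries], np.ndarray]:
    """Cut the series into records; trailing partial segment is dropped.

    Returns the segments and their start times (seconds).  Raises when fewer
    than 4 records fit.
    """
    n = len(series)
    m = plan.n_records(n)
    if m < MIN_RECORDS:
        raise InsufficientDataError(
            f"plan yields {m} records; need at least {MIN_RECORDS}")
    starts = np.arange(m) * plan.stride
    segments = [TimeSeries(series.values[s: s + plan.record_length],
                           series.sample_rate) for s in starts]
    return segments, starts / series.sample_rate


def choose_references(first_record: EmbeddedRecord, k: int, seed: int) -> ReferenceSet:
    """Greedy farthest-point sampling of K reference points.

    The initial point is drawn from the seeded "references" stream; each
    subsequent point maximizes its minimum distance to the points already
    chosen (ties broken by lowest index).  Deterministic given (inputs, seed).
    """
    pts = first_record.points
    n = pts.shape[0]
    if k < 1:
        raise ParameterError("K must be >= 1")
    if k > n:
        raise ParameterError(f"K = {k} exceeds the record's {n} embedded points")
    rng = stream(seed, "references")
    chosen = [int(rng.integers(n))]
    min_dist = np.linalg.norm(pts - pts[chosen[0]], axis=1)
    while len(chosen) < k:
        nxt = int(np.argmax(min_dist))
        chosen.append(nxt)
        min_dist = np.minimum(min_dist, np.linalg.norm(pts - pts[nxt], axis=1))
    return ReferenceSet(points=pts[np.array(chosen)].copy(),
                        record_index=0, seed=seed)


def characteristic_distance(record: EmbeddedRecord, refs: ReferenceSet) -> np.ndarray:
    """Feature vector: component k = mean distance of the record's embedded
    points to reference point k.  Permutation-invariant within the record."""
    if record.dimension != refs.dimension:
        raise DimensionError(
            f"record dimension {record.dimension} != reference dimension "
            f"{refs.dimension}")
    return cdist(refs.points, record.points).mean(axis=1)


def build_tracking(features: Sequence[np.ndarray],
                   timestamps: Optional[np.ndarray] = None,
                   center: bool = True) -> TrackingMatrix:
    """Stack feature vectors into X and differentiate to get V.

    V uses central differences at interior records and first-order one-sided
    differences at the two boundary records, over the supplied timestamps
    (default: record indices 0, 1, 2, ..., i.e. unit record spacing).
    Columns of X are mean-centered by default; the removed means are kept.
    """
    m = len(features)
    if m < MIN_RECORDS:
        raise InsufficientDataError(f"need >= {MIN_RECORDS} records, got {m}")
    widths = {np.asarray(f).shape for f in features}
    if len(widths) != 1 or len(next(iter(widths))) != 1:
        raise DimensionError(f"ragged or non-1-D feature vectors: {widths}")
    X = np.asarray(features, dtype=float)
    if timestamps is None:
        timestamps = np.arange(m, dtype=float)
    else:
        timestamps = np.asarray(timestamps, dtype=float)
        if timestamps.shape != (m,):
            raise DimensionError("timestamps must have one entry per record")
    means = X.mean(axis=0) if center else np.zeros(X.shape[1])
    Xc = X - means
    V = np.gradient(Xc, timestamps, axis=0, edge_order=1)
    return TrackingMatrix(X=Xc, V=V, timestamps=timestamps, column_means=means)
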