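"""Delay-coordinate embedding with automatic parameter selection.

Delay is chosen at the first local minimum of the average mutual information
(AMI) of the series with its lagged copy; dimension is chosen as the smallest
dimension whose false-nearest-neighbor (FNN) fraction falls below a threshold.
Both criteria operate in integer samples; conversion to seconds happens only
at reporting time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.spatial import cKDTree

from .errors import (
    DegenerateInputError,
    DimensionError,
    InsufficientDataError,
    ParameterError,
)

__all__ = [
    "TimeSeries",
    "EmbeddingParams",
    "EmbeddedRecord",
    "EmbeddingOptions",
    "EmbeddingSelection",
    "FirstMinimum",
    "average_mutual_information",
    "first_minimum",
    "false_nearest_neighbors",
    "select_embedding",
    "delay_embed",
]


@dataclass(frozen=True)
class TimeSeries:
    """Uniformly sampled scalar measurement."""

    values: np.ndarray
    sample_rate: float

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 1 or values.size < 2:
            raise DegenerateInputError("need a 1-D series with at least 2 samples")
        if not np.all(np.isfinite(values)):
            raise DegenerateInputError("series contains non-finite values")
        if self.sample_rate <= 0:
            raise DegenerateInputError("sample_rate must be > 0")

    def __len__(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class EmbeddingParams:
    delay: int  # samples
    dimension: int

    def __post_init__(self):
        if self.delay < 1:
            raise ParameterError("delay must be >= 1 sample")
        if self.dimension < 1:
            raise ParameterError("dimension must be >= 1")

    @property
    def window(self) -> int:
        return (self.dimension - 1) * self.delay


@dataclass(frozen=True)
class EmbeddedRecord:
    """Delay-vector trajectory of one observation-interval record."""

    points: np.ndarray  # (n_points, dimension)
    params: EmbeddingParams

    @property
    def n_points(self) -> int:
        return self.points.shape[0]

    @property
    def dimension(self) -> int:
        return self.points.shape[1]


def _hist_mi(a: np.ndarray, b: np.ndarray, edges: np.ndarray) -> float:
    """Mutual information (nats) from an equal-width 2-D histogram."""
    joint, _, _ = np.histogram2d(a, b, bins=[edges, edges])
    n = joint.sum()
    p = joint / n
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    mask = p > 0
    return float(np.sum(p[mask] * np.log(p[mask] / (px @ py)[mask])))


def average_mutual_information(series: TimeSeries, max_lag: int,
                               n_bins: int = 64) -> np.ndarray:
    """AMI(k) for k = 0..max_lag, in nats.

    Estimated from the 2-D equal-width histogram of (y_n, y_{n+k}) over the
    full series range.  AMI(0) is the marginal entropy estimate.
    """
    y = series.values
    n = y.size
    if max_lag >= n / 2:
        raise ParameterError(f"max_lag ({max_lag}) must be < N/2 ({n / 2:g})")
    if n_bins < 2:
        raise ParameterError("n_bins must be >= 2")
    lo, hi = float(y.min()), float(y.max())
    if hi == lo:
        raise DegenerateInputError("constant series: zero-width histogram bins")
    edges = np.linspace(lo, hi, n_bins + 1)
    edges[-1] = np.nextafter(hi, np.inf)  # include the max in the last bin
    return np.array([_hist_mi(y[: n - k], y[k:], edges)
                     for k in range(max_lag + 1)])


@dataclass(frozen=True)
class FirstMinimum:
    lag: int
    converged: bool  # False when falling back to the global minimum

    def __index__(self) -> int:
        return self.lag


def first_minimum(curve: np.ndarray) -> FirstMinimum:
    """First local minimum of an AMI curve, with plateau skipping.

    A candidate at lag k requires a strict decrease into the (possibly
    length-1) plateau starting at k and a strict increase out of it.  When no
    interior minimum exists the global minimum is returned flagged
    ``converged=False``.
    """
    curve = np.asarray(curve, dtype=float)
    if curve.size < 3:
        raise ParameterError("curve must have length >= 3")
    k = 1
    n = curve.size
    while k < n:
        if curve[k] < curve[k - 1]:
            j = k
            while j + 1 < n and curve[j + 1] == curve[j]:
                j += 1
            if j + 1 < n and curve[j + 1] > curve[j]:
                return FirstMinimum(lag=k, converged=True)
            k = j + 1
        else:
            k += 1
    return FirstMinimum(lag=int(np.argmin(curve[1:]) + 1), converged=False)


def _delay_matrix(y: np.ndarray, tau: int, dim: int) -> np.ndarray:
    n_pts = y.size - (dim - 1) * tau
    idx = np.arange(n_pts)[:, None] + tau * np.arange(dim)[None, :]
    return y[idx]


def _nearest_with_exclusion(points: np.ndarray, theiler: int) -> np.ndarray:
    """Index of the Euclidean nearest neighbor of each point, excluding
    temporal neighbors within ``theiler`` samples.  Exact (KD-tree)."""
    n = points.shape[0]
    tree = cKDTree(points)
    nn = np.full(n, -1, dtype=int)
    k = min(n, 2 * theiler + 3)
    remaining = np.arange(n)
    while remaining.size:
        _, idx = tree.query(points[remaining], k=k)
        if idx.ndim == 1:
            idx = idx[:, None]
        unresolved = []
        for row, i in enumerate(remaining):
            cand = idx[row]
            ok = cand[np.abs(cand - i) > theiler]
            if ok.size:
                nn[i] = ok[0]
            else:
                unresolved.append(i)
        remaining = np.array(unresolved, dtype=int)
        if remaining.size:
            if k == n:
                # pathological: everything inside the exclusion window
                raise InsufficientDataError(
                    "Theiler exclusion leaves no admissible neighbors")
            k = min(n, 2 * k)
    return nn


def false_nearest_neighbors(series: TimeSeries, tau: int, max_dim: int,
                            r_tol: float = 15.0, a_tol: float = 2.0) -> np.ndarray:
    """Kennel-style FNN fraction for dimensions 1..max_dim.

    A neighbor pair is false in dimension d if the extra (d+1)-th coordinate
    either grows the distance by more than ``r_tol`` (ratio test) or pushes the
    (d+1)-distance beyond ``a_tol`` times the series standard deviation
    (attractor-size test).  Neighbor search is exact with a Theiler exclusion
    of ``tau`` samples.
    """
    y = series.values
    n = y.size
    if max_dim * tau >= n:
        raise ParameterError("max_dim * tau must be < N")
    sigma = float(y.std())
    fractions = np.empty(max_dim)
    for d in range(1, max_dim + 1):
        n_pts = n - d * tau  # points that possess a (d+1)-th coordinate
        if n_pts < 10:
            raise InsufficientDataError(
                f"only {n_pts} embeddable points at dimension {d}")
        emb = _delay_matrix(y, tau, d)[:n_pts]
        nn = _nearest_with_exclusion(emb, theiler=tau)
        diff = emb - emb[nn]
        dist_d = np.sqrt(np.einsum("ij,ij->i", diff, diff))
        extra = np.abs(y[np.arange(n_pts) + d * tau] - y[nn + d * tau])
        # floor the denominator at machine-noise scale so exact recurrences
        # (periodic orbits) are not flagged false by ulp-level ratios
        denom = np.maximum(dist_d, 1e-9 * sigma)
        dist_d1 = np.sqrt(dist_d ** 2 + extra ** 2)
        false = (extra / denom > r_tol) | (dist_d1 > a_tol * sigma)
        fractions[d - 1] = false.mean()
    return fractions


@dataclass(frozen=True)
class EmbeddingOptions:
    max_lag: Optional[int] = None  # default: N // 4 capped at 200
    n_bins: int = 64
    max_dim: int = 8
    r_tol: float = 15.0
    a_tol: float = 2.0
    fnn_threshold: float = 0.01
    delay: Optional[int] = None  # user override
    dimension: Optional[int] = None  # user override


@dataclass(frozen=True)
class EmbeddingSelection:
    params: EmbeddingParams
    ami: Optional[np.ndarray]
    fnn: Optional[np.ndarray]
    delay_converged: bool
    dimension_converged: bool


def select_embedding(series: TimeSeries,
                     options: EmbeddingOptions = EmbeddingOptions()) -> EmbeddingSelection:
    """Choose (delay, dimension) by first-AMI-minimum + FNN threshold.

    User-supplied overrides in ``options`` short-circuit the corresponding
    search.  ``dimension_converged`` is False when the FNN fraction never
    drops below the threshold (e.g. white noise), in which case the dimension
    saturates at ``max_dim``.
    """
    n = len(series)
    ami_curve = None
    delay_ok = True
    if options.delay is not None:
        tau = int(options.delay)
    else:
        max_lag = options.max_lag if options.max_lag is not None \
            else max(3, min(n // 4, 200))
        ami_curve = average_mutual_information(series, max_lag, options.n_bins)
        fm = first_minimum(ami_curve)
        tau, delay_ok = fm.lag, fm.converged

    fnn_curve = None
    dim_ok = True
    if options.dimension is not None:
        dim = int(options.dimension)
    else:
        max_dim = options.max_dim
        while max_dim * tau >= n and max_dim > 1:
            max_dim -= 1
        fnn_curve = false_nearest_neighbors(series, tau, max_dim,
                                            options.r_tol, options.a_tol)
        below = np.nonzero(fnn_curve < options.fnn_threshold)[0]
        if below.size:
            dim = int(below[0]) + 1
        else:
            dim = max_dim
            dim_ok = False

    params = EmbeddingParams(delay=tau, dimension=dim)
    if params.window >= n:
        raise DimensionError(
            f"(d-1)*tau = {params.window} >= N = {n}: series too short")
    return EmbeddingSelection(params=params, ami=ami_curve, fnn=fnn_curve,
                              delay_converged=delay_ok,
                              dimension_converged=dim_ok)


def delay_embed(series: TimeSeries, params: EmbeddingParams) -> EmbeddedRecord:
    """Exact delay embedding: rows [y_n, y_{n+tau}, ..., y_{n+(d-1)tau}].

    No interpolation, no normalization; every coordinate is bit-identical to
    a source sample.
    """
    n = len(series)
    if params.window >= n:
        raise DimensionError(
            f"(d-1)*tau = {params.window} must be < N = {n}")
    return EmbeddedRecord(points=_delay_matrix(series.values, params.delay,
                                               params.dimension),
                          params=params)
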