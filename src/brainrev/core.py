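"""Shift-asymmetry (irreversibility) statistics on multivariate time series.

The central construction compares lag-``T`` Pearson correlations of a signal
with those of its time-reversed copy.  Each correlation is mapped through the
Gaussian mutual-information transform ``-0.5 * ln(1 - r**2)``; the elementwise
squared difference of the forward and reversal matrices quantifies how far the
process is from detailed balance, and its mean over all entries is the global
irreversibility ``I``.

Two correlation estimators are available:

``segment_normalized`` (default)
    Sample Pearson correlation of the ``L - T`` overlapping pairs, with means
    and standard deviations computed on the two overlapping segments.  Under
    this estimator the reversal matrix is *exactly* the transpose of the
    forward matrix (reversing both series enumerates the same pairs with the
    roles of the rows swapped), so the squared-difference matrix is symmetric
    with zero diagonal.

``full_window``
    Means and standard deviations taken over the whole window; the transpose
    identity then holds only up to edge terms of order ``1/L``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .exceptions import DegenerateInputError, SeriesTooShortError, ValidationError

logger = logging.getLogger(__name__)

Estimator = Literal["segment_normalized", "full_window"]
Direction = Literal["forward", "reversal"]
ZeroVariancePolicy = Literal["error", "zero"]

#: r**2 is clipped to at most 1 - _R2_CLIP before the logarithm.
_R2_CLIP = 1e-12


@dataclass(frozen=True)
class TimeSeriesMatrix:
    """A parcellated multivariate signal, regions x timepoints.

    Parameters
    ----------
    region_ids
        Ordered unique identifiers, one per row of ``values``.
    values
        Array of shape ``(n_regions, n_timepoints)``; all entries finite.
    sampling_interval
        Optional sampling interval in seconds (metadata only).
    """

    region_ids: tuple[str, ...]
    values: np.ndarray
    sampling_interval: float | None = None

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "region_ids", tuple(str(r) for r in self.region_ids))
        if values.ndim != 2:
            raise ValidationError(f"values must be 2-D, got shape {values.shape}")
        n, length = values.shape
        if len(self.region_ids) != n:
            raise ValidationError(
                f"{len(self.region_ids)} region ids for {n} rows of data"
            )
        if len(set(self.region_ids)) != n:
            raise ValidationError("region ids must be unique")
        if length < 2:
            raise ValidationError(f"need at least 2 timepoints, got {length}")
        if not np.all(np.isfinite(values)):
            bad = np.argwhere(~np.isfinite(values))[0]
            raise ValidationError(
                f"non-finite value at region {self.region_ids[bad[0]]!r}, "
                f"timepoint {bad[1]}"
            )
        if self.sampling_interval is not None and self.sampling_interval <= 0:
            raise ValidationError("sampling_interval must be positive")

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[1]

    def window(self, start: int, stop: int) -> "TimeSeriesMatrix":
        """Restriction to the half-open timepoint range ``[start, stop)``."""
        return TimeSeriesMatrix(
            self.region_ids, self.values[:, start:stop], self.sampling_interval
        )


@dataclass(frozen=True)
class FSMatrix:
    """Mutual-information-transformed lag-``shift`` correlation matrix (nats)."""

    values: np.ndarray
    shift: int
    direction: Direction

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 2 or values.shape[0] != values.shape[1]:
            raise ValidationError(f"FSMatrix must be square, got {values.shape}")
        if not np.all(np.isfinite(values)) or np.any(values < 0):
            raise ValidationError("FSMatrix entries must be finite and >= 0")
        if self.shift < 0:
            raise ValidationError("shift must be non-negative")
        if self.direction not in ("forward", "reversal"):
            raise ValidationError(f"unknown direction {self.direction!r}")


@dataclass(frozen=True)
class ReversibilityMatrix:
    """Elementwise squared forward/reversal difference (nats**2)."""

    values: np.ndarray
    shift: int

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 2 or values.shape[0] != values.shape[1]:
            raise ValidationError(
                f"ReversibilityMatrix must be square, got {values.shape}"
            )
        if np.any(values < 0):
            raise ValidationError("squared differences must be >= 0")

    def mean(self, include_diagonal: bool = True) -> float:
        """Mean over entries; the global irreversibility when computed from
        full FS matrices."""
        v = self.values
        if include_diagonal:
            return float(v.mean())
        n = v.shape[0]
        if n < 2:
            return 0.0
        off = ~np.eye(n, dtype=bool)
        return float(v[off].mean())


def time_reverse(ts: TimeSeriesMatrix) -> TimeSeriesMatrix:
    """Invert the temporal order of every row; ids and metadata unchanged."""
    return TimeSeriesMatrix(
        ts.region_ids, ts.values[:, ::-1].copy(), ts.sampling_interval
    )


def _check_segment_length(length: int, shift: int) -> None:
    if length - shift < 3:
        raise SeriesTooShortError(
            f"need at least shift + 3 timepoints, got L={length} with shift={shift}"
        )


def shifted_pearson(
    x: Sequence[float],
    y: Sequence[float],
    shift: int,
    *,
    zero_variance: ZeroVariancePolicy = "error",
) -> float:
    """Sample Pearson correlation of the pairs ``(x(t), y(t + shift))``.

    Means and standard deviations are computed on the two overlapping
    segments (segment-normalized estimator).  ``shift=0`` reduces to the
    ordinary Pearson correlation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be 1-D sequences of equal length")
    if shift < 0:
        raise ValidationError("shift must be non-negative")
    length = x.size
    _check_segment_length(length, shift)
    a = x[: length - shift]
    b = y[shift:]
    a = a - a.mean()
    b = b - b.mean()
    na = np.sqrt(a @ a)
    nb = np.sqrt(b @ b)
    if na == 0.0 or nb == 0.0:
        if zero_variance == "zero":
            warnings.warn("zero-variance segment; returning correlation 0")
            return 0.0
        raise DegenerateInputError("zero-variance segment in shifted correlation")
    r = float((a @ b) / (na * nb))
    # guard tiny floating excursions outside [-1, 1]
    return min(1.0, max(-1.0, r))


def pairwise_irreversibility(
    x: Sequence[float], y: Sequence[float], shift: int = 1
) -> float:
    """Absolute difference between forward and time-reversed lag-``shift``
    correlations of a pair of series.

    The reversed correlation is computed by explicitly reversing both
    sequences and applying :func:`shifted_pearson`; correlations keep their
    signs and only the final difference is taken in absolute value.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    c_forward = shifted_pearson(x, y, shift)
    c_reversed = shifted_pearson(x[::-1], y[::-1], shift)
    return abs(c_forward - c_reversed)


def mutual_info_of_correlation(r):
    """Gaussian mutual information ``-0.5 * ln(1 - r**2)`` of a correlation.

    ``r**2`` is clipped to ``1 - 1e-12`` before the logarithm, so ``|r| = 1``
    maps to ``-0.5 * ln(1e-12) ~= 13.8155``.  Accepts scalars or arrays.
    """
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) > 1.0):
        raise ValidationError("correlation magnitude exceeds 1")
    r2 = np.minimum(r * r, 1.0 - _R2_CLIP)
    out = -0.5 * np.log1p(-r2)
    return float(out) if out.ndim == 0 else out


def _shifted_correlation_matrix(
    X: np.ndarray,
    shift: int,
    *,
    estimator: Estimator = "segment_normalized",
    zero_variance: ZeroVariancePolicy = "error",
    region_ids: tuple[str, ...] | None = None,
) -> np.ndarray:
    """All-pairs lag-``shift`` correlations: entry (i, j) correlates row i at
    time t with row j at time t + shift."""
    n, length = X.shape
    _check_segment_length(length, shift)
    m = length - shift
    A = X[:, :m]
    B = X[:, shift:]
    if estimator == "segment_normalized":
        Ac = A - A.mean(axis=1, keepdims=True)
        Bc = B - B.mean(axis=1, keepdims=True)
        na = np.linalg.norm(Ac, axis=1)
        nb = np.linalg.norm(Bc, axis=1)
    elif estimator == "full_window":
        mu = X.mean(axis=1, keepdims=True)
        sd = X.std(axis=1)
        Ac = A - mu
        Bc = B - mu
        na = sd * np.sqrt(m)
        nb = na
    else:
        raise ValidationError(f"unknown estimator {estimator!r}")

    bad = (na == 0.0) | (nb == 0.0)
    if np.any(bad):
        idx = int(np.flatnonzero(bad)[0])
        name = region_ids[idx] if region_ids is not None else f"row {idx}"
        if zero_variance == "zero":
            warnings.warn(f"zero-variance segment for region {name}; using 0")
            # centered zero-variance rows are identically zero, so a dummy
            # norm of 1 yields correlation 0 for every pair involving them
            na = np.where(na == 0.0, 1.0, na)
            nb = np.where(nb == 0.0, 1.0, nb)
        else:
            raise DegenerateInputError(
                f"zero-variance segment for region {name} at shift {shift}"
            )
    C = (Ac @ Bc.T) / np.outer(na, nb)
    # full-window normalization can overshoot [-1, 1] by O(1/L) edge terms
    return np.clip(C, -1.0, 1.0)


def fs_matrix(
    ts: TimeSeriesMatrix,
    shift: int = 1,
    direction: Direction = "forward",
    *,
    estimator: Estimator = "segment_normalized",
    zero_variance: ZeroVariancePolicy = "error",
) -> FSMatrix:
    """N x N matrix of mutual-information-transformed lag-``shift``
    correlations; for ``direction='reversal'`` both rows are first
    time-reversed.  Not generally symmetric."""
    X = ts.values
    if direction == "reversal":
        X = X[:, ::-1]
    elif direction != "forward":
        raise ValidationError(f"unknown direction {direction!r}")
    C = _shifted_correlation_matrix(
        X,
        shift,
        estimator=estimator,
        zero_variance=zero_variance,
        region_ids=ts.region_ids,
    )
    return FSMatrix(mutual_info_of_correlation(C), shift, direction)


def reversibility_matrix(fs_f: FSMatrix, fs_r: FSMatrix) -> ReversibilityMatrix:
    """Elementwise squared difference of forward and reversal FS matrices."""
    if fs_f.values.shape != fs_r.values.shape:
        raise ValidationError(
            f"shape mismatch: {fs_f.values.shape} vs {fs_r.values.shape}"
        )
    if fs_f.shift != fs_r.shift:
        raise ValidationError(f"shift mismatch: {fs_f.shift} vs {fs_r.shift}")
    diff = fs_f.values - fs_r.values
    return ReversibilityMatrix(diff * diff, fs_f.shift)


def global_irreversibility(
    ts: TimeSeriesMatrix,
    shift: int = 1,
    *,
    estimator: Estimator = "segment_normalized",
    zero_variance: ZeroVariancePolicy = "error",
    include_diagonal: bool = True,
) -> float:
    """Global irreversibility ``I``: mean over all N**2 entries of the squared
    forward/reversal FS difference.

    Invariant under region permutation, per-region positive affine rescaling,
    and time reversal of the input.
    """
    fs_f = fs_matrix(
        ts, shift, "forward", estimator=estimator, zero_variance=zero_variance
    )
    fs_r = fs_matrix(
        ts, shift, "reversal", estimator=estimator, zero_variance=zero_variance
    )
    return reversibility_matrix(fs_f, fs_r).mean(include_diagonal=include_diagonal)
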