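"""Sliding-window dynamics of the global irreversibility statistic.

The window count follows ``n = floor((L - W) / step)`` — note this is one
*fewer* than the usual ``floor((L - W) / step) + 1`` convention: the last
admissible window is dropped.  This convention is forced by the two reference
counts the defaults must reproduce (L=195 -> 21 windows and L=175 -> 17
windows with W=90, step=5).  Pass ``include_final_window=True`` to restore
the usual convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import Estimator, TimeSeriesMatrix, ZeroVariancePolicy, global_irreversibility
from .exceptions import InsufficientWindowsError, SeriesTooShortError, ValidationError


@dataclass(frozen=True)
class WindowingScheme:
    """Sliding-window geometry: length ``window_length``, step
    ``window_length - overlap``."""

    window_length: int = 90
    overlap: int = 85

    def __post_init__(self) -> None:
        if self.window_length < 1:
            raise ValidationError("window_length must be positive")
        if not 0 <= self.overlap < self.window_length:
            raise ValidationError(
                f"overlap must be in [0, window_length), got {self.overlap}"
            )

    @property
    def step(self) -> int:
        return self.window_length - self.overlap


@dataclass(frozen=True)
class SubjectProfile:
    """Per-subject summary of windowed global irreversibility.

    ``average_reversibility`` is the arithmetic mean of the per-window values
    and ``deviation_reversibility`` their sample (n-1) standard deviation —
    the latter measures non-stationarity of the asymmetry over time.
    """

    subject_id: str
    window_values: np.ndarray
    average_reversibility: float
    deviation_reversibility: float

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "window_values", np.asarray(self.window_values, dtype=float)
        )

    @property
    def n_windows(self) -> int:
        return self.window_values.size


def make_windows(
    L: int, scheme: WindowingScheme, *, include_final_window: bool = False
) -> list[tuple[int, int]]:
    """Ordered half-open index ranges ``[k*step, k*step + W)`` covering a
    series of length ``L``.

    Raises :class:`SeriesTooShortError` if ``L <= W``.
    """
    W = scheme.window_length
    if L <= W:
        raise SeriesTooShortError(
            f"series length {L} must exceed window length {W}"
        )
    n = (L - W) // scheme.step
    if include_final_window:
        n += 1
    return [(k * scheme.step, k * scheme.step + W) for k in range(n)]


def window_irreversibility(
    ts: TimeSeriesMatrix,
    scheme: WindowingScheme,
    shift: int = 1,
    *,
    estimator: Estimator = "segment_normalized",
    zero_variance: ZeroVariancePolicy = "error",
    include_diagonal: bool = True,
    include_final_window: bool = False,
) -> np.ndarray:
    """Global irreversibility evaluated on every sliding window."""
    spans = make_windows(
        ts.n_timepoints, scheme, include_final_window=include_final_window
    )
    return np.array(
        [
            global_irreversibility(
                ts.window(start, stop),
                shift,
                estimator=estimator,
                zero_variance=zero_variance,
                include_diagonal=include_diagonal,
            )
            for start, stop in spans
        ]
    )


def subject_profile(
    ts: TimeSeriesMatrix,
    scheme: WindowingScheme,
    shift: int = 1,
    *,
    subject_id: str = "subject",
    estimator: Estimator = "segment_normalized",
    zero_variance: ZeroVariancePolicy = "error",
    include_diagonal: bool = True,
    include_final_window: bool = False,
) -> SubjectProfile:
    """Windowed irreversibility trace plus its mean (average reversibility)
    and sample standard deviation (deviation reversibility).

    Requires at least two windows (a standard deviation is undefined
    otherwise).
    """
    values = window_irreversibility(
        ts,
        scheme,
        shift,
        estimator=estimator,
        zero_variance=zero_variance,
        include_diagonal=include_diagonal,
        include_final_window=include_final_window,
    )
    if values.size < 2:
        raise InsufficientWindowsError(
            f"need >= 2 windows for a profile, got {values.size} "
            f"(L={ts.n_timepoints}, W={scheme.window_length}, step={scheme.step})"
        )
    return SubjectProfile(
        subject_id=subject_id,
        window_values=values,
        average_reversibility=float(values.mean()),
        deviation_reversibility=float(values.std(ddof=1)),
    )
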