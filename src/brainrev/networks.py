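"""Within- and between-network irreversibility.

Each entry of the squared forward/reversal FS difference depends only on its
own pair of rows, so restricting the statistic to a pair of networks is the
same as taking the block mean of the full-series squared-difference matrix
over rows in one network and columns in the other.  Within-network blocks
include the (zero) diagonal in their mean, mirroring the global definition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import (
    Estimator,
    TimeSeriesMatrix,
    ZeroVariancePolicy,
    fs_matrix,
    reversibility_matrix,
)
from .exceptions import InsufficientWindowsError, ValidationError
from .synthetic import ParcelAtlas
from .windows import WindowingScheme, make_windows


@dataclass(frozen=True)
class NetworkProfile:
    """Per-subject windowed irreversibility for every unordered network pair.

    ``average`` and ``deviation`` are square lower-triangular matrices over
    the atlas's networks (canonical order); entry (a, b) with a >= b holds the
    mean / sample standard deviation across windows of the (a, b) block
    statistic.  The diagonal holds within-network values.  Upper-triangular
    entries are NaN.
    """

    subject_id: str
    networks: tuple[str, ...]
    window_values: np.ndarray  # (n_pairs, n_windows), pairs in lower-tri order
    average: np.ndarray
    deviation: np.ndarray

    @property
    def n_windows(self) -> int:
        return self.window_values.shape[1]

    def pair_index(self, net_a: str, net_b: str) -> int:
        """Row of ``window_values`` holding the (net_a, net_b) trace."""
        ia, ib = self.networks.index(net_a), self.networks.index(net_b)
        a, b = max(ia, ib), min(ia, ib)
        return a * (a + 1) // 2 + b


def _reversibility_values(
    ts: TimeSeriesMatrix,
    shift: int,
    estimator: Estimator,
    zero_variance: ZeroVariancePolicy,
) -> np.ndarray:
    fs_f = fs_matrix(ts, shift, "forward", estimator=estimator, zero_variance=zero_variance)
    fs_r = fs_matrix(ts, shift, "reversal", estimator=estimator, zero_variance=zero_variance)
    return reversibility_matrix(fs_f, fs_r).values


def submatrix_irreversibility(
    ts: TimeSeriesMatrix,
    atlas: ParcelAtlas,
    net_a: str,
    net_b: str,
    shift: int = 1,
    *,
    estimator: Estimator = "segment_normalized",
    zero_variance: ZeroVariancePolicy = "error",
) -> float:
    """Mean squared forward/reversal FS difference over the block with rows
    restricted to ``net_a`` regions and columns to ``net_b`` regions.

    Symmetric in (net_a, net_b); for an atlas assigning every region to one
    network the within-network value equals the global irreversibility.
    """
    if len(atlas.region_ids) != ts.n_regions or atlas.region_ids != ts.region_ids:
        raise ValidationError("atlas region ids must match the time series")
    rows = atlas.indices(net_a)
    cols = atlas.indices(net_b)
    R = _reversibility_values(ts, shift, estimator, zero_variance)
    return float(R[np.ix_(rows, cols)].mean())


def network_profile(
    ts: TimeSeriesMatrix,
    atlas: ParcelAtlas,
    scheme: WindowingScheme,
    shift: int = 1,
    *,
    subject_id: str = "subject",
    estimator: Estimator = "segment_normalized",
    zero_variance: ZeroVariancePolicy = "error",
    include_final_window: bool = False,
) -> NetworkProfile:
    """Windowed block statistics for every unordered network pair, averaged
    (and sd'ed, n-1 denominator) across windows.

    The squared-difference matrix is computed once per window and all block
    means are read off it.
    """
    if len(atlas.region_ids) != ts.n_regions or atlas.region_ids != ts.region_ids:
        raise ValidationError("atlas region ids must match the time series")
    networks = atlas.networks
    idx = [atlas.indices(n) for n in networks]
    spans = make_windows(
        ts.n_timepoints, scheme, include_final_window=include_final_window
    )
    if len(spans) < 2:
        raise InsufficientWindowsError(
            f"need >= 2 windows for a profile, got {len(spans)}"
        )
    n_pairs = len(networks) * (len(networks) + 1) // 2
    values = np.empty((n_pairs, len(spans)))
    for w, (start, stop) in enumerate(spans):
        R = _reversibility_values(ts.window(start, stop), shift, estimator, zero_variance)
        p = 0
        for a in range(len(networks)):
            for b in range(a + 1):
                values[p, w] = R[np.ix_(idx[a], idx[b])].mean()
                p += 1
    k = len(networks)
    average = np.full((k, k), np.nan)
    deviation = np.full((k, k), np.nan)
    p = 0
    for a in range(k):
        for b in range(a + 1):
            average[a, b] = values[p].mean()
            deviation[a, b] = values[p].std(ddof=1)
            p += 1
    return NetworkProfile(
        subject_id=subject_id,
        networks=networks,
        window_values=values,
        average=average,
        deviation=deviation,
    )
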