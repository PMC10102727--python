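"""Synthetic cohorts with a controllable degree of time-irreversibility.

The generative family is a lag-1 Gaussian vector autoregression
``x(t) = W x(t-1) + eps(t)``.  With a symmetric coupling matrix ``W`` and
isotropic noise the stationary process satisfies detailed balance and is
time-reversible; making ``W`` directed breaks detailed balance.  The
``asymmetry`` parameter (kappa) interpolates between the symmetrized coupling
(kappa = 0, reversible) and fully independent directed weights (kappa = 1),
so cohorts with graded kappa exhibit graded temporal asymmetry.

Non-stationarity of the asymmetry is produced by modulating the coupling
scale with a slow multiplicative envelope (one full period per series) whose
relative amplitude is the ``nonstationarity`` parameter; the per-window
irreversibility then fluctuates window to window, which the deviation
reversibility summarizes.

All generators are pure functions of their arguments including the seed.
Per-subject seeds are derived as ``SeedSequence([base_seed, crc32(group),
subject_index])`` so reproducibility does not depend on iteration order.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .core import TimeSeriesMatrix
from .exceptions import PartitionError, StationarityError, ValidationError

#: Canonical resting-state network names, in canonical order.
CANONICAL_NETWORKS = (
    "Visual",
    "Somatomotor",
    "DorsalAttention",
    "VentralAttention",
    "Limbic",
    "Control",
    "Default",
)


@dataclass(frozen=True)
class ParcelAtlas:
    """Assignment of each region to one of up to 7 canonical networks."""

    region_ids: tuple[str, ...]
    network_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "region_ids", tuple(str(r) for r in self.region_ids))
        object.__setattr__(
            self, "network_labels", tuple(str(n) for n in self.network_labels)
        )
        if len(self.region_ids) != len(self.network_labels):
            raise ValidationError("one network label per region required")
        if len(set(self.region_ids)) != len(self.region_ids):
            raise ValidationError("region ids must be unique")
        unknown = set(self.network_labels) - set(CANONICAL_NETWORKS)
        if unknown:
            raise ValidationError(f"unknown network labels: {sorted(unknown)}")

    @property
    def n_regions(self) -> int:
        return len(self.region_ids)

    @property
    def networks(self) -> tuple[str, ...]:
        """Distinct labels present, in canonical order."""
        present = set(self.network_labels)
        return tuple(n for n in CANONICAL_NETWORKS if n in present)

    def indices(self, network: str) -> np.ndarray:
        """Row indices of the regions belonging to ``network``."""
        if network not in set(self.network_labels):
            raise ValidationError(f"network {network!r} not present in atlas")
        return np.flatnonzero(
            np.asarray([lbl == network for lbl in self.network_labels])
        )


@dataclass(frozen=True)
class CouplingGraph:
    """Directed lag-1 coupling coefficients with zero diagonal and spectral
    radius < 1."""

    weights: np.ndarray
    asymmetry: float

    def __post_init__(self) -> None:
        weights = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", weights)
        if weights.ndim != 2 or weights.shape[0] != weights.shape[1]:
            raise ValidationError("weights must be square")
        if np.any(np.diag(weights) != 0.0):
            raise ValidationError("coupling diagonal must be zero")
        if not 0.0 <= self.asymmetry <= 1.0:
            raise ValidationError("asymmetry must lie in [0, 1]")
        if spectral_radius(weights) >= 1.0:
            raise StationarityError(
                "coupling spectral radius must be < 1 for a stationary process"
            )

    @property
    def n_regions(self) -> int:
        return self.weights.shape[0]


@dataclass(frozen=True)
class GroupSpec:
    """One cohort group: label, size, series geometry, and dynamics knobs."""

    label: str
    n_subjects: int
    series_length: int
    asymmetry: float
    coupling_strength: float = 0.5
    noise_sd: float = 1.0
    nonstationarity: float = 0.0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValidationError("n_subjects must be >= 1")
        if self.series_length < 2:
            raise ValidationError("series_length must be >= 2")
        if not 0.0 <= self.asymmetry <= 1.0:
            raise ValidationError("asymmetry must lie in [0, 1]")
        if not 0.0 <= self.nonstationarity <= 1.0:
            raise ValidationError("nonstationarity must lie in [0, 1]")
        if self.noise_sd <= 0:
            raise ValidationError("noise_sd must be positive")


@dataclass(frozen=True)
class CohortSpec:
    """Ordered group definitions plus shared geometry and base seed."""

    groups: tuple[GroupSpec, ...]
    n_regions: int
    base_seed: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "groups", tuple(self.groups))
        labels = [g.label for g in self.groups]
        if len(set(labels)) != len(labels):
            raise ValidationError("group labels must be unique")
        if self.n_regions < 1:
            raise ValidationError("n_regions must be positive")


@dataclass(frozen=True)
class Subject:
    """One simulated cohort member."""

    subject_id: str
    group: str
    timeseries: TimeSeriesMatrix


def spectral_radius(matrix: np.ndarray) -> float:
    return float(np.max(np.abs(np.linalg.eigvals(matrix))))


def default_region_ids(n_regions: int) -> tuple[str, ...]:
    width = max(3, len(str(n_regions - 1)))
    return tuple(f"R{i:0{width}d}" for i in range(n_regions))


def make_default_atlas(n_regions: int, n_networks: int = 7) -> ParcelAtlas:
    """Partition ``n_regions`` into ``n_networks`` contiguous, near-equal
    blocks labelled with the canonical network names in order.

    Block sizes differ by at most 1 (the first ``n_regions % n_networks``
    blocks are one larger).
    """
    if not 1 <= n_networks <= 7:
        raise PartitionError("n_networks must be in 1..7")
    if n_networks > n_regions:
        raise PartitionError(
            f"cannot split {n_regions} regions into {n_networks} networks"
        )
    base, extra = divmod(n_regions, n_networks)
    labels: list[str] = []
    for k in range(n_networks):
        size = base + (1 if k < extra else 0)
        labels.extend([CANONICAL_NETWORKS[k]] * size)
    return ParcelAtlas(default_region_ids(n_regions), tuple(labels))


def asymmetric_coupling(
    n_regions: int,
    strength: float,
    asymmetry: float,
    seed: int | np.random.SeedSequence,
) -> CouplingGraph:
    """Random directed coupling with spectral radius exactly ``strength``.

    A matrix of i.i.d. standard-normal weights ``D`` (zero diagonal) is
    blended as ``(1 - asymmetry) * (D + D.T)/2 + asymmetry * D`` and rescaled
    so the spectral radius equals ``strength``; ``asymmetry=0`` therefore
    yields an exactly symmetric matrix.
    """
    if n_regions < 1:
        raise ValidationError("n_regions must be positive")
    if strength < 0:
        raise ValidationError("strength must be non-negative")
    if strength >= 1.0:
        raise StationarityError(
            f"coupling strength {strength} >= 1 gives a non-stationary process"
        )
    if not 0.0 <= asymmetry <= 1.0:
        raise ValidationError("asymmetry must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    D = rng.standard_normal((n_regions, n_regions))
    np.fill_diagonal(D, 0.0)
    M = (1.0 - asymmetry) * 0.5 * (D + D.T) + asymmetry * D
    rho = spectral_radius(M)
    if rho > 0.0 and strength > 0.0:
        M = M * (strength / rho)
    else:
        M = np.zeros_like(M)
    return CouplingGraph(weights=M, asymmetry=asymmetry)


def simulate_var_subject(
    coupling: CouplingGraph,
    length: int,
    noise_sd: float,
    seed: int | np.random.SeedSequence,
    nonstationarity: float = 0.0,
    *,
    region_ids: Sequence[str] | None = None,
    sampling_interval: float | None = None,
) -> TimeSeriesMatrix:
    """Simulate one subject from the lag-1 VAR ``x(t) = W x(t-1) + eps(t)``.

    A burn-in of ``10 * n_regions`` samples is discarded.  If
    ``nonstationarity > 0``, the coupling scale over the emitted samples is
    modulated by the envelope ``1 - a * (1 - cos(2*pi*t/length)) / 2`` — it
    starts at 1, dips to ``1 - a``, and completes one full period over the
    series, never raising the spectral radius (stability is preserved).
    """
    if length < 2:
        raise ValidationError("length must be >= 2")
    if noise_sd <= 0:
        raise ValidationError("noise_sd must be positive")
    if not 0.0 <= nonstationarity <= 1.0:
        raise ValidationError("nonstationarity must lie in [0, 1]")
    W = coupling.weights
    n = coupling.n_regions
    if region_ids is None:
        region_ids = default_region_ids(n)
    elif len(region_ids) != n:
        raise ValidationError("region_ids length must equal n_regions")

    rng = np.random.default_rng(seed)
    burn_in = 10 * n
    eps = rng.normal(0.0, noise_sd, size=(burn_in + length, n))
    x = np.zeros(n)
    for t in range(burn_in):
        x = W @ x + eps[t]
    out = np.empty((length, n))
    if nonstationarity > 0.0:
        phase = 2.0 * np.pi * np.arange(length) / length
        envelope = 1.0 - nonstationarity * (1.0 - np.cos(phase)) / 2.0
    else:
        envelope = np.ones(length)
    for t in range(length):
        x = (envelope[t] * W) @ x + eps[burn_in + t]
        out[t] = x
    return TimeSeriesMatrix(
        tuple(region_ids), out.T, sampling_interval=sampling_interval
    )


def subject_seed(base_seed: int, group_label: str, index: int) -> np.random.SeedSequence:
    """Stable per-subject seed: ``SeedSequence([base_seed, crc32(label),
    index])``."""
    return np.random.SeedSequence(
        [int(base_seed), zlib.crc32(group_label.encode("utf-8")), int(index)]
    )


def simulate_cohort(
    spec: CohortSpec, *, region_ids: Sequence[str] | None = None
) -> list[Subject]:
    """Simulate every subject of a cohort spec, deterministically.

    Each subject gets its own coupling draw and noise stream, both derived
    from :func:`subject_seed`, so any subject can be regenerated in isolation.
    """
    if region_ids is None:
        region_ids = default_region_ids(spec.n_regions)
    subjects: list[Subject] = []
    for group in spec.groups:
        for idx in range(group.n_subjects):
            seed = subject_seed(spec.base_seed, group.label, idx)
            coupling_seed, noise_seed = seed.spawn(2)
            coupling = asymmetric_coupling(
                spec.n_regions, group.coupling_strength, group.asymmetry, coupling_seed
            )
            ts = simulate_var_subject(
                coupling,
                group.series_length,
                group.noise_sd,
                noise_seed,
                group.nonstationarity,
                region_ids=region_ids,
            )
            subjects.append(
                Subject(f"{group.label}-{idx + 1:03d}", group.label, ts)
            )
    return subjects


def study_like_spec(
    base_seed: int,
    *,
    n_regions: int = 100,
    asymmetries: tuple[float, float, float] = (0.8, 0.4, 0.1),
    nonstationarities: tuple[float, float, float] = (0.5, 0.25, 0.1),
    coupling_strength: float = 0.95,
) -> CohortSpec:
    """Three-group cohort shaped like a typical disorders-of-consciousness
    resting-state dataset: CNT n=13 / L=195, MCS n=31 / L=175,
    UWS n=24 / L=175, with graded asymmetry and graded non-stationarity
    CNT > MCS > UWS."""
    k_cnt, k_mcs, k_uws = asymmetries
    a_cnt, a_mcs, a_uws = nonstationarities
    return CohortSpec(
        groups=(
            GroupSpec("CNT", 13, 195, k_cnt, coupling_strength, 1.0, a_cnt),
            GroupSpec("MCS", 31, 175, k_mcs, coupling_strength, 1.0, a_mcs),
            GroupSpec("UWS", 24, 175, k_uws, coupling_strength, 1.0, a_uws),
        ),
        n_regions=n_regions,
        base_seed=base_seed,
    )
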