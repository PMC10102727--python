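"""Nonparametric group comparisons with Benjamini-Hochberg FDR control.

Group differences in subject-level summaries (average / deviation
reversibility, globally and per network pair) are tested with the two-sided
Mann-Whitney U (Wilcoxon rank-sum) test.  FDR families:

* global level — the pairwise group tests within one measure form one family
  (3 tests for a three-group design);
* network level — per group pair and measure, *both* a 7-test family (the
  within-network diagonal only) and a 28-test family (all network pairs) are
  adjusted and reported, clearly labelled, since published summaries use each.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .exceptions import ValidationError
from .networks import NetworkProfile
from .windows import SubjectProfile

#: Use exact rank-sum enumeration when both samples are this small (and
#: tie-free); otherwise the tie-corrected normal approximation.
EXACT_MAX_N = 8


@dataclass(frozen=True)
class ComparisonResult:
    """One two-sided rank-sum comparison, raw and FDR-adjusted."""

    group_a: str
    group_b: str
    measure: str  # "average" | "deviation"
    level: str  # "global" or "<net_a>|<net_b>"
    u_statistic: float
    p_raw: float
    p_fdr: float
    fdr_family: str = "global-pairwise"


@dataclass(frozen=True)
class SignificanceTriangle:
    """Lower-triangular p-value matrices for one group pair and measure.

    ``p_fdr_all`` is adjusted over all populated cells (28 for 7 networks);
    ``p_fdr_within`` is adjusted over the diagonal (within-network) cells
    only and is NaN off-diagonal.  Upper-triangular entries are NaN.
    """

    group_a: str
    group_b: str
    measure: str
    networks: tuple[str, ...]
    p_raw: np.ndarray
    p_fdr_all: np.ndarray
    p_fdr_within: np.ndarray

    def binarized(self, alpha: float, family: str = "all") -> np.ndarray:
        return binarize_significance(self, alpha, family=family)


def ranksum_test(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; returns (U for sample ``a``, p).

    Uses exact enumeration when both samples have at most ``EXACT_MAX_N``
    observations and there are no ties, and the tie-corrected normal
    approximation (without continuity correction) otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("rank-sum test requires two non-empty samples")
    pooled = np.concatenate([a, b])
    ties = np.unique(pooled).size < pooled.size
    if a.size <= EXACT_MAX_N and b.size <= EXACT_MAX_N and not ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = sps.mannwhitneyu(
        a, b, alternative="two-sided", method=method, use_continuity=False
    )
    return float(res.statistic), float(min(res.pvalue, 1.0))


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    Sort ascending, set ``q_(k) = p_(k) * m / k``, enforce monotonicity from
    the largest rank down, cap at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValidationError("p_values must be a non-empty 1-D sequence")
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValidationError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out


def _group_values(
    profiles: Mapping[str, Sequence[SubjectProfile]], group: str, measure: str
) -> np.ndarray:
    attr = f"{measure}_reversibility"
    return np.array([getattr(p, attr) for p in profiles[group]])


def compare_global(
    profiles: Mapping[str, Sequence[SubjectProfile]],
) -> list[ComparisonResult]:
    """All unordered group pairs x {average, deviation}, with BH adjustment
    over the pairwise tests within each measure."""
    groups = list(profiles)
    if len(groups) < 2:
        raise ValidationError("need at least 2 groups")
    for g in groups:
        if len(profiles[g]) < 2:
            raise ValidationError(f"group {g!r} has fewer than 2 subjects")
    results: list[ComparisonResult] = []
    for measure in ("average", "deviation"):
        batch: list[ComparisonResult] = []
        for ga, gb in combinations(groups, 2):
            u, p = ranksum_test(
                _group_values(profiles, ga, measure),
                _group_values(profiles, gb, measure),
            )
            batch.append(
                ComparisonResult(ga, gb, measure, "global", u, p, p_fdr=np.nan)
            )
        adjusted = bh_adjust([r.p_raw for r in batch])
        results.extend(
            replace(r, p_fdr=float(q)) for r, q in zip(batch, adjusted)
        )
    return results


def _network_pair_values(
    profiles: Sequence[NetworkProfile], a: int, b: int, measure: str
) -> np.ndarray:
    matrix = "average" if measure == "average" else "deviation"
    return np.array([getattr(p, matrix)[a, b] for p in profiles])


def compare_networks(
    profiles: Mapping[str, Sequence[NetworkProfile]],
) -> list[SignificanceTriangle]:
    """Per group pair and measure, rank-sum tests for every unordered network
    pair, FDR-adjusted both over the 7 within-network tests and over all 28."""
    groups = list(profiles)
    if len(groups) < 2:
        raise ValidationError("need at least 2 groups")
    for g in groups:
        if len(profiles[g]) < 2:
            raise ValidationError(f"group {g!r} has fewer than 2 subjects")
    networks = profiles[groups[0]][0].networks
    for g in groups:
        for p in profiles[g]:
            if p.networks != networks:
                raise ValidationError("all profiles must share one network set")
    k = len(networks)
    triangles: list[SignificanceTriangle] = []
    for ga, gb in combinations(groups, 2):
        for measure in ("average", "deviation"):
            p_raw = np.full((k, k), np.nan)
            for a in range(k):
                for b in range(a + 1):
                    _, p = ranksum_test(
                        _network_pair_values(profiles[ga], a, b, measure),
                        _network_pair_values(profiles[gb], a, b, measure),
                    )
                    p_raw[a, b] = p
            tri = np.tril_indices(k)
            p_fdr_all = np.full((k, k), np.nan)
            p_fdr_all[tri] = bh_adjust(p_raw[tri])
            diag = np.arange(k)
            p_fdr_within = np.full((k, k), np.nan)
            p_fdr_within[diag, diag] = bh_adjust(p_raw[diag, diag])
            triangles.append(
                SignificanceTriangle(
                    ga, gb, measure, networks, p_raw, p_fdr_all, p_fdr_within
                )
            )
    return triangles


def binarize_significance(
    triangle: SignificanceTriangle, alpha: float, *, family: str = "all"
) -> np.ndarray:
    """1 where the chosen family's adjusted p is below ``alpha``, 0 elsewhere
    in the populated triangle, NaN above the diagonal."""
    if not 0.0 < alpha <= 1.0:
        raise ValidationError("alpha must lie in (0, 1]")
    if family == "all":
        p = triangle.p_fdr_all
    elif family == "within":
        p = triangle.p_fdr_within
    else:
        raise ValidationError(f"unknown family {family!r}")
    out = np.where(np.isnan(p), np.nan, (p < alpha).astype(float))
    return out
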