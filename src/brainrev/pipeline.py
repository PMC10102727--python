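"""End-to-end orchestration: profiles -> network profiles -> statistics ->
report tables, all as TSV/JSON artifacts."""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .config import AnalysisConfig
from .core import TimeSeriesMatrix
from .exceptions import BrainrevError
from .networks import NetworkProfile, network_profile
from .stats import SignificanceTriangle, compare_global, compare_networks
from .synthetic import ParcelAtlas
from .windows import SubjectProfile, WindowingScheme, subject_profile

logger = logging.getLogger(__name__)


class PipelineStageError(BrainrevError):
    """An orchestration stage failed; the message names the stage."""


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineStageError:
                raise
            except Exception as exc:
                raise PipelineStageError(f"stage {name!r} failed: {exc}") from exc
        wrapper.__name__ = fn.__name__
        wrapper.__doc__ = fn.__doc__
        return wrapper
    return deco


def _scheme(config: AnalysisConfig) -> WindowingScheme:
    return WindowingScheme(config.window_length, config.overlap)


@_stage("subject-profiles")
def compute_subject_profiles(
    subjects: Sequence[tuple[str, str, TimeSeriesMatrix]], config: AnalysisConfig
) -> dict[str, list[SubjectProfile]]:
    """Windowed global irreversibility profile per subject, keyed by group."""
    scheme = _scheme(config)
    out: dict[str, list[SubjectProfile]] = {}
    for subject_id, group, ts in subjects:
        prof = subject_profile(
            ts,
            scheme,
            config.shift,
            subject_id=subject_id,
            estimator=config.estimator,
            zero_variance=config.zero_variance_policy,
            include_diagonal=config.include_diagonal,
            include_final_window=config.include_final_window,
        )
        out.setdefault(group, []).append(prof)
    return out


@_stage("network-profiles")
def compute_network_profiles(
    subjects: Sequence[tuple[str, str, TimeSeriesMatrix]],
    atlas: ParcelAtlas,
    config: AnalysisConfig,
) -> dict[str, list[NetworkProfile]]:
    """Windowed network-pair profiles per subject, keyed by group."""
    scheme = _scheme(config)
    out: dict[str, list[NetworkProfile]] = {}
    for subject_id, group, ts in subjects:
        prof = network_profile(
            ts,
            atlas,
            scheme,
            config.shift,
            subject_id=subject_id,
            estimator=config.estimator,
            zero_variance=config.zero_variance_policy,
            include_final_window=config.include_final_window,
        )
        out.setdefault(group, []).append(prof)
    return out


def subject_profiles_frame(
    profiles: Mapping[str, Sequence[SubjectProfile]]
) -> pd.DataFrame:
    rows = [
        {
            "subject_id": p.subject_id,
            "group": group,
            "n_windows": p.n_windows,
            "average_reversibility": p.average_reversibility,
            "deviation_reversibility": p.deviation_reversibility,
        }
        for group, plist in profiles.items()
        for p in plist
    ]
    return pd.DataFrame(rows)


def window_values_frame(
    profiles: Mapping[str, Sequence[SubjectProfile]]
) -> pd.DataFrame:
    rows = [
        {"subject_id": p.subject_id, "group": group, "window_index": w,
         "irreversibility": v}
        for group, plist in profiles.items()
        for p in plist
        for w, v in enumerate(p.window_values)
    ]
    return pd.DataFrame(rows)


def network_profiles_frame(
    profiles: Mapping[str, Sequence[NetworkProfile]]
) -> pd.DataFrame:
    rows = []
    for group, plist in profiles.items():
        for p in plist:
            for a in range(len(p.networks)):
                for b in range(a + 1):
                    rows.append(
                        {
                            "subject_id": p.subject_id,
                            "group": group,
                            "net_a": p.networks[a],
                            "net_b": p.networks[b],
                            "average": p.average[a, b],
                            "deviation": p.deviation[a, b],
                        }
                    )
    return pd.DataFrame(rows)


def load_subject_profiles(
    subjects_tsv: str | Path, windows_tsv: str | Path | None = None
) -> dict[str, list[SubjectProfile]]:
    """Rebuild grouped profiles from the serialized tables (window traces
    restored when the long table is given)."""
    df = pd.read_csv(subjects_tsv, sep="\t")
    traces: dict[str, np.ndarray] = {}
    if windows_tsv is not None:
        wdf = pd.read_csv(windows_tsv, sep="\t")
        for sid, sub in wdf.groupby("subject_id"):
            traces[sid] = sub.sort_values("window_index")["irreversibility"].to_numpy()
    out: dict[str, list[SubjectProfile]] = {}
    for _, row in df.iterrows():
        values = traces.get(row["subject_id"], np.array([]))
        out.setdefault(row["group"], []).append(
            SubjectProfile(
                subject_id=row["subject_id"],
                window_values=values,
                average_reversibility=row["average_reversibility"],
                deviation_reversibility=row["deviation_reversibility"],
            )
        )
    return out


def load_network_profiles(
    networks_tsv: str | Path,
) -> dict[str, list[NetworkProfile]]:
    """Rebuild grouped network profiles from the long-format table (window
    traces are not serialized and come back empty)."""
    df = pd.read_csv(networks_tsv, sep="\t")
    networks = tuple(pd.unique(df["net_a"]))
    k = len(networks)
    index = {n: i for i, n in enumerate(networks)}
    out: dict[str, list[NetworkProfile]] = {}
    for (sid, group), sub in df.groupby(["subject_id", "group"], sort=False):
        average = np.full((k, k), np.nan)
        deviation = np.full((k, k), np.nan)
        for _, row in sub.iterrows():
            a, b = index[row["net_a"]], index[row["net_b"]]
            average[a, b] = row["average"]
            deviation[a, b] = row["deviation"]
        out.setdefault(group, []).append(
            NetworkProfile(
                subject_id=sid,
                networks=networks,
                window_values=np.zeros((k * (k + 1) // 2, 0)),
                average=average,
                deviation=deviation,
            )
        )
    return out


@_stage("group-statistics")
def compute_statistics(
    subject_profiles: Mapping[str, Sequence[SubjectProfile]],
    net_profiles: Mapping[str, Sequence[NetworkProfile]],
) -> tuple[pd.DataFrame, pd.DataFrame, list[SignificanceTriangle]]:
    global_results = compare_global(subject_profiles)
    gdf = pd.DataFrame(
        [
            {
                "group_a": r.group_a,
                "group_b": r.group_b,
                "measure": r.measure,
                "level": r.level,
                "u_statistic": r.u_statistic,
                "p_raw": r.p_raw,
                "p_fdr": r.p_fdr,
            }
            for r in global_results
        ]
    )
    triangles = compare_networks(net_profiles)
    rows = []
    for t in triangles:
        for a in range(len(t.networks)):
            for b in range(a + 1):
                rows.append(
                    {
                        "group_a": t.group_a,
                        "group_b": t.group_b,
                        "measure": t.measure,
                        "net_a": t.networks[a],
                        "net_b": t.networks[b],
                        "p_raw": t.p_raw[a, b],
                        "p_fdr_all": t.p_fdr_all[a, b],
                        "p_fdr_within": t.p_fdr_within[a, b],
                    }
                )
    ndf = pd.DataFrame(rows)
    return gdf, ndf, triangles


def write_triangles(
    outdir: Path, triangles: Sequence[SignificanceTriangle], alpha: float
) -> None:
    for t in triangles:
        binary = t.binarized(alpha)
        df = pd.DataFrame(binary, index=t.networks, columns=t.networks)
        df.to_csv(
            outdir / f"binarized_{t.group_a}_vs_{t.group_b}_{t.measure}.tsv",
            sep="\t",
        )


def report_frame(subjects_df: pd.DataFrame) -> pd.DataFrame:
    """Per-group medians of average and deviation reversibility."""
    return (
        subjects_df.groupby("group", sort=False)
        .agg(
            n=("subject_id", "size"),
            median_average_reversibility=("average_reversibility", "median"),
            median_deviation_reversibility=("deviation_reversibility", "median"),
        )
        .reset_index()
    )


def run_pipeline(
    config: AnalysisConfig,
    subjects: Sequence[tuple[str, str, TimeSeriesMatrix]],
    atlas: ParcelAtlas,
    outdir: str | Path,
) -> dict[str, Path]:
    """Full analysis on loaded subjects; writes every artifact under
    ``outdir`` and returns a name -> path map.

    Rerunning with identical inputs produces identical tables.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sprofiles = compute_subject_profiles(subjects, config)
    nprofiles = compute_network_profiles(subjects, atlas, config)
    sdf = subject_profiles_frame(sprofiles)
    wdf = window_values_frame(sprofiles)
    ndf = network_profiles_frame(nprofiles)
    gstats, nstats, triangles = compute_statistics(sprofiles, nprofiles)
    rdf = report_frame(sdf)

    paths = {
        "subjects": outdir / "subjects.tsv",
        "windows": outdir / "windows.tsv",
        "networks": outdir / "networks.tsv",
        "global_stats": outdir / "global_stats.tsv",
        "network_stats": outdir / "network_stats.tsv",
        "report": outdir / "report.tsv",
        "metadata": outdir / "run_metadata.json",
    }
    sdf.to_csv(paths["subjects"], sep="\t", index=False)
    wdf.to_csv(paths["windows"], sep="\t", index=False)
    ndf.to_csv(paths["networks"], sep="\t", index=False)
    gstats.to_csv(paths["global_stats"], sep="\t", index=False)
    nstats.to_csv(paths["network_stats"], sep="\t", index=False)
    rdf.to_csv(paths["report"], sep="\t", index=False)
    write_triangles(outdir, triangles, config.alpha)

    metadata = {
        "package_version": __version__,
        "config": config.to_dict(),
        "n_subjects": len(subjects),
        "groups": sorted({g for _, g, _ in subjects}),
        "n_regions": atlas.n_regions,
        "versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    paths["metadata"].write_text(json.dumps(metadata, indent=2, sort_keys=True))
    logger.info("pipeline complete: %d subjects -> %s", len(subjects), outdir)
    return paths
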