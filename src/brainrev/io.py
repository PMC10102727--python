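"""Plain-text file formats.

* time series TSV — header row of region ids, one row per timepoint (one
  column per region); transposed to regions x timepoints in memory
* atlas TSV — columns ``region_id``, ``network``
* manifest TSV — columns ``subject_id``, ``group``, ``path`` (paths resolved
  relative to the manifest's directory)
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core import TimeSeriesMatrix
from .exceptions import ValidationError
from .synthetic import CANONICAL_NETWORKS, ParcelAtlas

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.17g"  # round-trips IEEE doubles exactly


@dataclass(frozen=True)
class CohortFiles:
    """Resolved manifest: one (subject_id, group, path) triple per subject."""

    entries: tuple[tuple[str, str, Path], ...]

    def load(self, atlas: ParcelAtlas) -> list[tuple[str, str, TimeSeriesMatrix]]:
        out = []
        for subject_id, group, path in self.entries:
            ts = read_timeseries(path)
            if ts.region_ids != atlas.region_ids:
                raise ValidationError(
                    f"region ids of subject {subject_id!r} ({path}) do not match "
                    "the atlas (same ids, same order, required)"
                )
            out.append((subject_id, group, ts))
        return out


def write_timeseries(path: str | Path, ts: TimeSeriesMatrix) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("\t".join(ts.region_ids) + "\n")
        np.savetxt(fh, ts.values.T, fmt=_FLOAT_FMT, delimiter="\t")


def read_timeseries(path: str | Path) -> TimeSeriesMatrix:
    """Parse and validate a time series TSV; errors name the offending cell."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"time series file not found: {path}")
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
    if len(set(header)) != len(header):
        dupes = sorted({h for h in header if header.count(h) > 1})
        raise ValidationError(f"duplicate region ids in {path}: {dupes}")
    try:
        # np.loadtxt parses floats with correct rounding (bit-exact round trip)
        values = np.loadtxt(path, skiprows=1, delimiter="\t", ndmin=2).T
    except ValueError:
        # re-scan with pandas to point at the offending cell
        raw = pd.read_csv(path, sep="\t", header=0, names=header, dtype=str)
        numeric = raw.apply(pd.to_numeric, errors="coerce")
        bad = numeric.isna() & raw.notna()
        if bad.any().any():
            col = bad.any(axis=0).idxmax()
            row = int(bad[col].idxmax())
            raise ValidationError(
                f"non-numeric token {raw.at[row, col]!r} at data row {row}, "
                f"column {col!r} in {path}"
            ) from None
        raise ValidationError(f"ragged or malformed rows in {path}") from None
    if values.shape[0] != len(header):
        raise ValidationError(
            f"{path}: {len(header)} header columns but {values.shape[0]} data columns"
        )
    if not np.all(np.isfinite(values)):
        i, j = np.argwhere(~np.isfinite(values))[0]
        raise ValidationError(
            f"non-finite value at data row {j}, column {header[i]!r} in {path}"
        )
    return TimeSeriesMatrix(tuple(header), values)


def write_atlas(path: str | Path, atlas: ParcelAtlas) -> None:
    pd.DataFrame(
        {"region_id": atlas.region_ids, "network": atlas.network_labels}
    ).to_csv(path, sep="\t", index=False)


def read_atlas(path: str | Path) -> ParcelAtlas:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"atlas file not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns) != ["region_id", "network"]:
        raise ValidationError(
            f"atlas {path} must have columns region_id, network; got {list(df.columns)}"
        )
    atlas = ParcelAtlas(tuple(df["region_id"]), tuple(df["network"]))
    missing = set(CANONICAL_NETWORKS) - set(atlas.network_labels)
    if missing:
        logger.warning(
            "atlas %s uses %d of 7 canonical networks (missing: %s)",
            path, 7 - len(missing), ", ".join(sorted(missing)),
        )
    return atlas


def write_manifest(
    path: str | Path, entries: list[tuple[str, str, str | Path]]
) -> None:
    pd.DataFrame(
        [(s, g, str(p)) for s, g, p in entries],
        columns=["subject_id", "group", "path"],
    ).to_csv(path, sep="\t", index=False)


def read_manifest_and_atlas(
    manifest_path: str | Path, atlas_path: str | Path
) -> tuple[CohortFiles, ParcelAtlas]:
    """Parse the manifest and atlas; verify every referenced file exists."""
    manifest_path = Path(manifest_path)
    if not manifest_path.exists():
        raise FileNotFoundError(f"manifest file not found: {manifest_path}")
    atlas = read_atlas(atlas_path)
    df = pd.read_csv(manifest_path, sep="\t", dtype=str)
    if list(df.columns) != ["subject_id", "group", "path"]:
        raise ValidationError(
            f"manifest {manifest_path} must have columns subject_id, group, path"
        )
    if df["subject_id"].duplicated().any():
        dupes = sorted(df.loc[df["subject_id"].duplicated(), "subject_id"])
        raise ValidationError(f"duplicate subject ids in manifest: {dupes}")
    entries = []
    for _, row in df.iterrows():
        p = Path(row["path"])
        if not p.is_absolute():
            p = manifest_path.parent / p
        if not p.exists():
            raise ValidationError(
                f"manifest references missing file {p} (subject {row['subject_id']!r})"
            )
        entries.append((row["subject_id"], row["group"], p))
    return CohortFiles(tuple(entries)), atlas
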