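"""File formats: the track-table CSV dialect and TIFF stack helpers.

The track table holds one row per (cell_id, frame) with a fixed header,
UTF-8 encoding and '.' decimal separators.  Validation is strict and
errors name the offending line (1-based, counting the header as line 1).
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile

from .lineage import CellTrack, link_generations

__all__ = [
    "TRACK_COLUMNS",
    "TrackTableError",
    "read_track_table",
    "read_track_frame",
    "write_track_table",
    "tracks_to_frame",
    "read_stack",
    "write_stack",
]

TRACK_COLUMNS = (
    "cell_id",
    "frame",
    "time_min",
    "area_um2",
    "centroid_x_um",
    "centroid_y_um",
    "pole1_x",
    "pole1_y",
    "pole2_x",
    "pole2_y",
    "mother_id",
    "has_stalk",
    "sep_event",
    "cyto_event",
)

_NUMERIC = (
    "frame",
    "time_min",
    "area_um2",
    "centroid_x_um",
    "centroid_y_um",
    "pole1_x",
    "pole1_y",
    "pole2_x",
    "pole2_y",
    "has_stalk",
    "sep_event",
    "cyto_event",
)


class TrackTableError(ValueError):
    """Schema violation in a track-table CSV, with the offending line number."""


def read_track_frame(path: str | Path) -> pd.DataFrame:
    """Read and validate a track table as a DataFrame (cell_id/mother_id as str)."""
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False, encoding="utf-8")
    if tuple(df.columns) != TRACK_COLUMNS:
        missing = set(TRACK_COLUMNS) - set(df.columns)
        extra = set(df.columns) - set(TRACK_COLUMNS)
        raise TrackTableError(
                f"{path.name}: bad header (missing {sorted(missing)}, unexpected {sorted(extra)})"
        )
    for col in _NUMERIC:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & (df[col] != "")
        if bad.any():
            line = int(bad.idxmax()) + 2
            raise TrackTableError(
                f"{path.name}: line {line}: non-numeric value {df[col][bad.idxmax()]!r} in column {col!r}"
            )
        if converted.isna().any():
            line = int(converted.isna().idxmax()) + 2
            raise TrackTableError(f"{path.name}: line {line}: empty value in column {col!r}")
        df[col] = converted
    dup = df.duplicated(subset=["cell_id", "frame"])
    if dup.any():
        line = int(dup.idxmax()) + 2
        raise TrackTableError(
            f"{path.name}: line {line}: duplicated (cell_id, frame) = "
            f"({df.loc[dup.idxmax(), 'cell_id']!r}, {int(df.loc[dup.idxmax(), 'frame'])})"
        )
    df["frame"] = df["frame"].astype(int)
    for col in ("has_stalk", "sep_event", "cyto_event"):
        df[col] = df[col].astype(int)
    return df


def read_track_table(path: str | Path) -> dict[str, CellTrack]:
    """Read a track-table CSV into linked :class:`CellTrack` objects."""
    df = read_track_frame(path)
    return link_generations(df.to_dict("records"))


def tracks_to_frame(tracks: Mapping[str, CellTrack] | pd.DataFrame) -> pd.DataFrame:
    """Normalise either a table or linked tracks to the CSV dialect DataFrame."""
    if isinstance(tracks, pd.DataFrame):
        df = tracks.loc[:, list(TRACK_COLUMNS)].copy()
        return df
    rows = []
    for cid in sorted(tracks):
        tr = tracks[cid]
        for i, f in enumerate(tr.frames):
            rows.append(
                dict(
                    cell_id=tr.cell_id,
                    frame=int(f),
                    time_min=float(tr.times[i]),
                    area_um2=float(tr.areas[i]),
                    centroid_x_um=float(tr.centroids[i, 0]),
                    centroid_y_um=float(tr.centroids[i, 1]),
                    pole1_x=float(tr.poles[i, 0, 0]),
                    pole1_y=float(tr.poles[i, 0, 1]),
                    pole2_x=float(tr.poles[i, 1, 0]),
                    pole2_y=float(tr.poles[i, 1, 1]),
                    mother_id=tr.mother_id or "",
                    has_stalk=int(tr.has_stalk),
                    sep_event=int(f == tr.sep_event_frame) if tr.sep_event_frame is not None else 0,
                    cyto_event=int(f == tr.cyto_event_frame) if tr.cyto_event_frame is not None else 0,
                )
            )
    return pd.DataFrame(rows, columns=list(TRACK_COLUMNS))


def write_track_table(tracks: Mapping[str, CellTrack] | pd.DataFrame, path: str | Path) -> None:
    """Write tracks (or a dialect DataFrame) as a track-table CSV."""
    df = tracks_to_frame(tracks)
    df.to_csv(path, index=False, encoding="utf-8", lineterminator="\n")


def read_stack(path: str | Path) -> np.ndarray:
    """Read a (frames, rows, cols) TIFF stack."""
    arr = tifffile.imread(path)
    return arr[None] if arr.ndim == 2 else arr


def write_stack(frames: Sequence[np.ndarray], path: str | Path) -> None:
    """Write frames as a uint16 TIFF stack (values clipped to the uint16 range)."""
    arr = np.stack([np.asarray(f) for f in frames])
    arr = np.clip(np.round(arr), 0, np.iinfo(np.uint16).max).astype(np.uint16)
    tifffile.imwrite(path, arr, photometric="minisblack")
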