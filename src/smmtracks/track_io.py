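"""Reading, writing and validation of track tables, geometries and foci.

All tables are plain delimited text (tab-separated on write; tab or comma
accepted on read) with a header row.  Coordinates are in μm in the lab
frame, frame indices are 0-based integers.

Table schemas
-------------
tracks     : ``cell_id, track_id, channel, frame, x_um, y_um``
geometry   : ``cell_id, length_um, radius_um, cx_um, cy_um, theta_rad``
foci       : ``cell_id, focus_id, x_um, y_um``
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import CellGeometry

logger = logging.getLogger(__name__)

TRACK_COLUMNS = ["cell_id", "track_id", "channel", "frame", "x_um", "y_um"]
GEOMETRY_COLUMNS = ["cell_id", "length_um", "radius_um", "cx_um", "cy_um", "theta_rad"]
FOCI_COLUMNS = ["cell_id", "focus_id", "x_um", "y_um"]


@dataclass
class TrackSet:
    """A collection of single-molecule tracks.

    ``df`` holds one row per localization with the track-table schema,
    sorted by (cell_id, track_id, frame); ``delta_t`` is the frame
    interval in seconds shared by all tracks.
    """

    df: pd.DataFrame
    delta_t: float

    def __post_init__(self) -> None:
        if self.delta_t <= 0:
            raise ValueError("delta_t must be positive")
        missing = [c for c in TRACK_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"track table missing columns: {missing}")

    @property
    def n_tracks(self) -> int:
        if self.df.empty:
            return 0
        return self.df.groupby(["cell_id", "track_id", "channel"]).ngroups

    @property
    def n_localizations(self) -> int:
        return len(self.df)

    def n_steps(self) -> pd.Series:
        """Adjacent-frame displacement count per track (gaps excluded)."""
        if self.df.empty:
            return pd.Series(dtype=int)

        def _steps(g: pd.DataFrame) -> int:
            return int((np.diff(g["frame"].to_numpy()) == 1).sum())

        return self.df.groupby(["cell_id", "track_id", "channel"]).apply(
            _steps, include_groups=False
        )

    def groupby_tracks(self):
        return self.df.groupby(["cell_id", "track_id", "channel"], sort=True)


def _read_table(path) -> pd.DataFrame:
    # accepts comma- or tab-separated text
    return pd.read_csv(path, sep=None, engine="python")


def read_tracks(path, delta_t: float) -> TrackSet:
    """Read a track table, validate it and return a :class:`TrackSet`.

    Rows are grouped by (cell_id, track_id, channel) and sorted by frame.
    Duplicated (track, frame) rows and non-finite coordinates are errors.
    """
    df = _read_table(path)
    missing = [c for c in TRACK_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    n_read = len(df)
    if n_read:
        for col in ("x_um", "y_um"):
            vals = pd.to_numeric(df[col], errors="coerce")
            if vals.isna().any():
                bad = df.loc[vals.isna()].index[0]
                raise ValueError(f"{path}: non-numeric {col} at row {bad}")
            df[col] = vals.astype(float)
        df["frame"] = pd.to_numeric(df["frame"], errors="raise").astype(int)
        if (df["frame"] < 0).any():
            raise ValueError(f"{path}: negative frame indices")
        key = ["cell_id", "track_id", "channel"]
        dup = df.duplicated(subset=key + ["frame"])
        if dup.any():
            tid = df.loc[dup.idxmax(), "track_id"]
            raise ValueError(f"{path}: duplicated frame in track {tid}")
        df = df.sort_values(key + ["frame"], kind="mergesort").reset_index(drop=True)
    logger.info("read %d localizations from %s", n_read, path)
    return TrackSet(df=df[TRACK_COLUMNS].copy(), delta_t=delta_t)


def write_tracks(tracks: TrackSet, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tracks.df.to_csv(path, sep="\t", index=False, float_format="%.6f")


def filter_min_steps(tracks: TrackSet, min_steps: int = 5,
                     count: str = "steps") -> TrackSet:
    """Keep tracks of sufficient length.

    With ``count="steps"`` (default) a track must have at least
    ``min_steps`` adjacent-frame displacements, i.e. ``min_steps + 1``
    gap-free localizations; ``count="points"`` instead requires
    ``min_steps`` localizations.  The filter is idempotent.
    """
    if min_steps < 1:
        raise ValueError("min_steps must be >= 1")
    if count not in ("steps", "points"):
        raise ValueError("count must be 'steps' or 'points'")
    if tracks.df.empty:
        return TrackSet(tracks.df.copy(), tracks.delta_t)
    key = ["cell_id", "track_id", "channel"]
    if count == "steps":
        sizes = tracks.df.groupby(key)["frame"].transform(
            lambda f: (np.diff(f.to_numpy()) == 1).sum()
        )
    else:
        sizes = tracks.df.groupby(key)["frame"].transform("size")
    keep = sizes >= min_steps
    n_tracks = tracks.n_tracks
    out = TrackSet(tracks.df.loc[keep].reset_index(drop=True), tracks.delta_t)
    logger.info(
        "min-steps filter (%s >= %d): kept %d/%d tracks",
        count, min_steps, out.n_tracks, n_tracks,
    )
    return out


# ---- geometry tables ------------------------------------------------------

def geometries_to_frame(geoms: dict[int, CellGeometry]) -> pd.DataFrame:
    rows = [
        {
            "cell_id": cid,
            "length_um": g.length,
            "radius_um": g.radius,
            "cx_um": g.center[0],
            "cy_um": g.center[1],
            "theta_rad": g.orientation,
        }
        for cid, g in geoms.items()
    ]
    return pd.DataFrame(rows, columns=GEOMETRY_COLUMNS)


def frame_to_geometries(df: pd.DataFrame) -> dict[int, CellGeometry]:
    return {
        row.cell_id: CellGeometry(
            length=row.length_um,
            radius=row.radius_um,
            center=(row.cx_um, row.cy_um),
            orientation=row.theta_rad,
        )
        for row in df.itertuples(index=False)
    }


def read_geometries(path) -> dict[int, CellGeometry]:
    df = _read_table(path)
    missing = [c for c in GEOMETRY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    return frame_to_geometries(df)


def write_geometries(geoms: dict[int, CellGeometry], path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    geometries_to_frame(geoms).to_csv(path, sep="\t", index=False,
                                      float_format="%.6f")


# ---- foci tables ----------------------------------------------------------

def read_foci(path) -> pd.DataFrame:
    df = _read_table(path)
    missing = [c for c in FOCI_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    return df[FOCI_COLUMNS].copy()


def write_foci(foci: pd.DataFrame, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    foci[FOCI_COLUMNS].to_csv(path, sep="\t", index=False, float_format="%.6f")


# ---- result tables --------------------------------------------------------

def write_results(tables: dict[str, pd.DataFrame], out_dir) -> list[Path]:
    """Write named result tables as tab-separated text, one file per table."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, table in tables.items():
        p = out_dir / f"{name}.tsv"
        table.to_csv(p, sep="\t", index=False)
        paths.append(p)
    return paths


def read_result(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
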