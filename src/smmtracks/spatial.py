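"""Spatial statistics: standardized-cell maps, dwelling tracks, foci and
focus-proximity histograms.

The standardized cell projects localizations from many cells into one
normalized frame (long axis and short axis both in [−0.5, 0.5]) for
pooled track-density heat maps.  Dwelling (static) tracks of the
replisome marker DnaX define focus reference points; crRNP track points
are then scored by their distance to the nearest focus in the same cell,

    D = sqrt((x_focus − x_i)² + (y_focus − y_i)²),

summarized as a probability histogram.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.ndimage import gaussian_filter

from .geometry import CellGeometry
from .track_io import FOCI_COLUMNS, TrackSet

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class StandardizedCellMap:
    """Pooled track-density grid over normalized cell coordinates."""

    x_edges: np.ndarray   # long axis, spanning [-0.5, 0.5]
    y_edges: np.ndarray   # short axis, spanning [-0.5, 0.5]
    density: np.ndarray   # shape (nx, ny), sums to 1
    n_cells: int
    n_points: int


@dataclass(frozen=True)
class DistanceHistogram:
    """Probability histogram of nearest-focus distances."""

    bin_edges: np.ndarray    # μm
    probability: np.ndarray  # sums to 1
    distances: np.ndarray    # underlying per-(track, point) distances, μm


def standardize(points: np.ndarray, geometry: CellGeometry,
                tol: float = 0.1) -> tuple[np.ndarray, int]:
    """Normalize lab-frame points into the standardized cell frame.

    The cell frame is rotated/translated so the long axis is x; the
    long-axis coordinate is divided by the cell length and the short-axis
    coordinate by the cell diameter, putting the pole tips at (±0.5, 0).
    Points farther than ``tol`` μm outside the wall are dropped (count
    returned); the rest are kept as-is (localization noise may place
    them slightly outside ±0.5).
    """
    pts = np.atleast_2d(np.asarray(points, float))
    if pts.size == 0:
        return np.empty((0, 2)), 0
    local = geometry.to_local(pts)
    keep = geometry.signed_distance_local(local) <= tol
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("standardize: dropped %d/%d points outside the cell",
                    n_dropped, len(pts))
    local = local[keep]
    out = np.column_stack([local[:, 0] / geometry.length,
                           local[:, 1] / (2.0 * geometry.radius)])
    return out, n_dropped


def density_map(tracks: TrackSet, geometries: dict[int, CellGeometry],
                grid_shape: tuple[int, int] = (50, 26),
                smooth_sigma_bins: float = 1.0,
                tol: float = 0.1) -> StandardizedCellMap:
    """Pooled standardized-cell track-density map over all cells.

    All localizations of all tracks are projected into the normalized
    frame, histogrammed on a ``grid_shape`` = (long, short) grid over
    [−0.5, 0.5]², optionally Gaussian-smoothed, and normalized so the
    map sums to 1.
    """
    if tracks.df.empty:
        raise ValueError("density_map requires at least one track")
    nx, ny = grid_shape
    x_edges = np.linspace(-0.5, 0.5, nx + 1)
    y_edges = np.linspace(-0.5, 0.5, ny + 1)
    hist = np.zeros((nx, ny))
    n_points = 0
    cells = 0
    for cid, sub in tracks.df.groupby("cell_id"):
        geom = geometries.get(cid)
        if geom is None:
            logger.warning("density_map: no geometry for cell %r, skipped", cid)
            continue
        norm, _ = standardize(sub[["x_um", "y_um"]].to_numpy(), geom, tol=tol)
        if len(norm) == 0:
            continue
        h, _, _ = np.histogram2d(
            np.clip(norm[:, 0], -0.5, 0.5), np.clip(norm[:, 1], -0.5, 0.5),
            bins=[x_edges, y_edges])
        hist += h
        n_points += len(norm)
        cells += 1
    if n_points == 0:
        raise ValueError("no localizations fell inside any provided geometry")
    if smooth_sigma_bins > 0:
        hist = gaussian_filter(hist, smooth_sigma_bins, mode="constant")
    density = hist / hist.sum()
    return StandardizedCellMap(x_edges=x_edges, y_edges=y_edges,
                               density=density, n_cells=cells,
                               n_points=n_points)


def classify_dwelling(track_xy: np.ndarray, confinement_radius: float = 0.09,
                      min_fraction: float = 0.8) -> str:
    """Label a track ``"static"`` (dwelling) or ``"mobile"``.

    Static iff at least ``min_fraction`` of its localizations lie within
    ``confinement_radius`` of the track centroid.  The default radius is
    three times the default localization noise (3 × 0.03 μm).
    """
    xy = np.atleast_2d(np.asarray(track_xy, float))
    if len(xy) < 2:
        raise ValueError("track must have at least 2 localizations")
    centroid = xy.mean(axis=0)
    r = np.hypot(xy[:, 0] - centroid[0], xy[:, 1] - centroid[1])
    frac = np.mean(r <= confinement_radius)
    return "static" if frac >= min_fraction else "mobile"


def classify_tracks(tracks: TrackSet, confinement_radius: float = 0.09,
                    min_fraction: float = 0.8) -> pd.DataFrame:
    """Per-track dwelling labels: ``cell_id, track_id, channel, label``."""
    rows = []
    for (cid, tid, ch), g in tracks.groupby_tracks():
        lab = classify_dwelling(g[["x_um", "y_um"]].to_numpy(),
                                confinement_radius, min_fraction)
        rows.append((cid, tid, ch, lab))
    return pd.DataFrame(rows, columns=["cell_id", "track_id", "channel",
                                       "label"])


def foci_from_dwelling(tracks: TrackSet, labels: pd.DataFrame | None = None,
                       merge_radius: float = 0.15,
                       confinement_radius: float = 0.09,
                       min_fraction: float = 0.8) -> pd.DataFrame:
    """Derive focus reference points from dwelling (static) tracks.

    Each static track contributes its centroid; within a cell, centroids
    closer than ``merge_radius`` (single linkage) are merged by
    averaging, and each merged cluster becomes a single fixed reference
    point.  Returns the track_io foci schema; empty input gives an
    empty table.
    """
    if labels is None:
        labels = classify_tracks(tracks, confinement_radius, min_fraction)
    static = labels[labels["label"] == "static"]
    rows = []
    for cid, sub in static.groupby("cell_id"):
        cents = []
        for tid in sub["track_id"]:
            g = tracks.df[(tracks.df["cell_id"] == cid)
                          & (tracks.df["track_id"] == tid)]
            cents.append(g[["x_um", "y_um"]].to_numpy().mean(axis=0))
        cents = np.asarray(cents)
        if len(cents) == 1:
            merged = cents
        else:
            cl = fcluster(linkage(cents, method="single"),
                          t=merge_radius, criterion="distance")
            merged = np.array([cents[cl == k].mean(axis=0)
                               for k in np.unique(cl)])
        # deterministic ordering: by long-axis then short-axis position
        merged = merged[np.lexsort((merged[:, 1], merged[:, 0]))]
        for i, (x, y) in enumerate(merged):
            rows.append((cid, i, x, y))
    return pd.DataFrame(rows, columns=FOCI_COLUMNS)


def nearest_focus_distances(tracks: TrackSet, foci: pd.DataFrame,
                            points_per_track: int = 5,
                            point_rule: str = "first") -> pd.DataFrame:
    """Distance from track points to the nearest focus in the same cell.

    For each track, ``points_per_track`` localizations are taken —
    the first ones (default) or evenly spaced (``point_rule="spread"``) —
    and each is scored by its minimum Euclidean distance over the cell's
    foci (ties broken by lowest focus_id).  Tracks in cells without foci
    are skipped with a log message.  Returns one row per (track, point):
    ``cell_id, track_id, channel, point_index, focus_id, distance_um``.
    """
    if point_rule not in ("first", "spread"):
        raise ValueError("point_rule must be 'first' or 'spread'")
    foci_by_cell = {
        cid: sub.sort_values("focus_id")
        for cid, sub in foci.groupby("cell_id")
    }
    rows = []
    n_skipped = 0
    for (cid, tid, ch), g in tracks.groupby_tracks():
        cell_foci = foci_by_cell.get(cid)
        if cell_foci is None or cell_foci.empty:
            n_skipped += 1
            continue
        xy = g[["x_um", "y_um"]].to_numpy()
        n = min(points_per_track, len(xy))
        if point_rule == "first":
            idx = np.arange(n)
        else:
            idx = np.unique(np.linspace(0, len(xy) - 1, n).round().astype(int))
        fxy = cell_foci[["x_um", "y_um"]].to_numpy()
        fids = cell_foci["focus_id"].to_numpy()
        for pi in idx:
            d = np.hypot(fxy[:, 0] - xy[pi, 0], fxy[:, 1] - xy[pi, 1])
            j = int(np.argmin(d))  # first minimum -> lowest focus_id
            rows.append((cid, tid, ch, int(pi), int(fids[j]), float(d[j])))
    if n_skipped:
        logger.info("nearest_focus_distances: skipped %d tracks in cells "
                    "without foci", n_skipped)
    return pd.DataFrame(rows, columns=["cell_id", "track_id", "channel",
                                       "point_index", "focus_id",
                                       "distance_um"])


def distance_probability_histogram(distances: np.ndarray,
                                   bin_width: float = 0.1) -> DistanceHistogram:
    """Probability-normalized histogram of nearest-focus distances."""
    d = np.asarray(distances, float).ravel()
    if len(d) == 0:
        raise ValueError("need at least one distance")
    if (d < 0).any():
        raise ValueError("distances must be non-negative")
    hi = max(d.max(), bin_width)
    n_bins = int(np.ceil(hi / bin_width))
    edges = np.arange(n_bins + 1) * bin_width
    if edges[-1] < hi:
        edges = np.append(edges, edges[-1] + bin_width)
    counts, _ = np.histogram(d, bins=edges)
    return DistanceHistogram(bin_edges=edges,
                             probability=counts / len(d),
                             distances=d)
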