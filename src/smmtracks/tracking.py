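"""Minimal spot detection and frame-to-frame linking.

A deliberately simple image-to-track path: band-pass (difference of
Gaussians) filtering with local-maximum detection and sub-pixel Gaussian
refinement, followed by greedy nearest-neighbour linking with optional
gap closing.  Adequate at the sparse emitter densities reached after
photobleaching; correctness is validated against simulator ground truth
rather than against a multi-hypothesis tracker.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.optimize import least_squares
from skimage.feature import peak_local_max

from .track_io import TRACK_COLUMNS, TrackSet


@dataclass(frozen=True)
class Spot:
    x_px: float
    y_px: float
    amplitude: float
    snr: float


def _refine_gaussian(img: np.ndarray, row: int, col: int, sigma: float,
                     half: int) -> tuple[float, float, float] | None:
    """Sub-pixel refinement: LSQ fit of a fixed-σ 2D Gaussian + offset."""
    h, w = img.shape
    r0, r1 = max(row - half, 0), min(row + half + 1, h)
    c0, c1 = max(col - half, 0), min(col + half + 1, w)
    win = img[r0:r1, c0:c1].astype(float)
    if win.size < 9:
        return None
    yy, xx = np.mgrid[r0:r1, c0:c1]
    bg0 = win.min()
    a0 = win.max() - bg0

    # parameters: amplitude, col-centre, row-centre, background
    def res(p):
        a, cx, cy, bg = p
        g = a * np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * sigma**2)) + bg
        return (g - win).ravel()

    try:
        sol = least_squares(res, x0=[a0, float(col), float(row), bg0],
                            method="lm", max_nfev=500)
    except Exception:
        return None
    a, cx, cy, bg = sol.x
    if not (c0 - 1 <= cx <= c1 and r0 - 1 <= cy <= r1) or a <= 0:
        return None
    return float(cx), float(cy), float(a)


def detect_spots(frame: np.ndarray, expected_psf_sigma: float,
                 snr_threshold: float = 5.0,
                 refine: str = "gaussian") -> list[Spot]:
    """Detect diffraction-limited spots in one 2D frame.

    Candidates are local maxima of a difference-of-Gaussians band-pass
    (σ and 2.5σ); the noise scale is the median absolute deviation of
    the filtered image, and candidates below ``snr_threshold`` are
    discarded.  Positions are refined to sub-pixel precision by a 2D
    Gaussian fit (``refine="gaussian"``) or intensity-weighted centroid
    (``refine="centroid"``).  Returned x/y are in pixels (x = column).
    """
    img = np.asarray(frame, float)
    if img.ndim != 2:
        raise ValueError("frame must be a 2D image")
    sigma = float(expected_psf_sigma)
    if sigma < 1.0:
        raise ValueError("expected_psf_sigma must be >= 1 pixel")
    if refine not in ("gaussian", "centroid"):
        raise ValueError("refine must be 'gaussian' or 'centroid'")

    bp = gaussian_filter(img, sigma) - gaussian_filter(img, 2.5 * sigma)
    mad = np.median(np.abs(bp - np.median(bp)))
    noise = 1.4826 * mad if mad > 0 else max(bp.std(), 1e-12)
    peaks = peak_local_max(bp, min_distance=max(int(np.ceil(2 * sigma)), 1),
                           threshold_abs=snr_threshold * noise,
                           exclude_border=False)
    half = max(int(np.ceil(3 * sigma)), 2)
    spots: list[Spot] = []
    for row, col in peaks:
        snr = float(bp[row, col] / noise)
        if refine == "gaussian":
            fit = _refine_gaussian(img, row, col, sigma, half)
            if fit is None:
                continue
            cx, cy, amp = fit
        else:
            r0, r1 = max(row - half, 0), min(row + half + 1, img.shape[0])
            c0, c1 = max(col - half, 0), min(col + half + 1, img.shape[1])
            win = img[r0:r1, c0:c1] - img[r0:r1, c0:c1].min()
            tot = win.sum()
            if tot <= 0:
                continue
            yy, xx = np.mgrid[r0:r1, c0:c1]
            cx = float((win * xx).sum() / tot)
            cy = float((win * yy).sum() / tot)
            amp = float(img[row, col])
        spots.append(Spot(x_px=cx, y_px=cy, amplitude=amp, snr=snr))
    spots.sort(key=lambda s: (s.y_px, s.x_px))
    return spots


def detect_stack(stack: np.ndarray, expected_psf_sigma: float,
                 snr_threshold: float = 5.0,
                 refine: str = "gaussian") -> list[np.ndarray]:
    """Per-frame (n_i, 2) arrays of (x_px, y_px) detections."""
    out = []
    for frame in stack:
        spots = detect_spots(frame, expected_psf_sigma, snr_threshold, refine)
        out.append(np.array([[s.x_px, s.y_px] for s in spots]).reshape(-1, 2))
    return out


def link(detections: list[np.ndarray], max_disp: float, delta_t: float,
         max_gap: int = 0, min_steps: int = 5, pixel_size: float = 1.0,
         cell_id: int = 0, channel: str = "green") -> TrackSet:
    """Greedy nearest-neighbour linking of per-frame detections.

    ``detections[t]`` is an (n_t, 2) array of positions; positions are
    multiplied by ``pixel_size`` to yield μm.  Candidate links within
    ``max_disp`` μm (per frame of separation) are assigned greedily in
    order of ascending distance, ties broken by lowest detection index
    then lowest track id, each detection used at most once; tracks may
    bridge up to ``max_gap`` missing frames.  Output tracks must have at
    least ``min_steps`` displacements (localizations − 1).
    """
    if max_disp <= 0:
        raise ValueError("max_disp must be positive")
    tracks: list[dict] = []   # {"frames": [...], "xy": [...]}
    active: list[int] = []    # indices into tracks
    for t, det in enumerate(detections):
        det = np.asarray(det, float).reshape(-1, 2) * pixel_size
        # candidate (distance, det_idx, track_idx) for active tracks
        cands = []
        for ti in active:
            tr = tracks[ti]
            gap = t - tr["frames"][-1]
            if gap > max_gap + 1:
                continue
            last = tr["xy"][-1]
            for di in range(len(det)):
                d = float(np.hypot(det[di, 0] - last[0], det[di, 1] - last[1]))
                if d <= max_disp * gap:
                    cands.append((d, di, ti))
        cands.sort(key=lambda c: (c[0], c[1], c[2]))
        used_det: set[int] = set()
        used_trk: set[int] = set()
        for d, di, ti in cands:
            if di in used_det or ti in used_trk:
                continue
            used_det.add(di)
            used_trk.add(ti)
            tracks[ti]["frames"].append(t)
            tracks[ti]["xy"].append(det[di])
        for di in range(len(det)):
            if di not in used_det:
                tracks.append({"frames": [t], "xy": [det[di]]})
        active = [ti for ti in range(len(tracks))
                  if t - tracks[ti]["frames"][-1] <= max_gap]

    rows = []
    tid = 0
    for tr in tracks:
        if len(tr["frames"]) - 1 < min_steps:
            continue
        xy = np.asarray(tr["xy"])
        for f, (x, y) in zip(tr["frames"], xy):
            rows.append((cell_id, tid, channel, f, x, y))
        tid += 1
    df = pd.DataFrame(rows, columns=TRACK_COLUMNS)
    return TrackSet(df=df, delta_t=delta_t)
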