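"""Rod-shaped (spherocylindrical) cell geometry.

A bacterial cell is modelled in 2D projection as a *stadium*: the set of
points within ``radius`` of the central axis segment of half-length
``length/2 - radius``.  All simulation and standardization code works in a
cell-local frame (long axis along x, cell centred at the origin) and maps
to the lab frame through ``center`` and ``orientation``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class CellGeometry:
    """Spherocylinder (2D stadium) cell outline.

    Parameters
    ----------
    length : float
        Pole-to-pole length in μm.
    radius : float
        Cell radius in μm.  Must satisfy ``length >= 2 * radius``.
    center : tuple of float
        Lab-frame position of the cell centre, μm.
    orientation : float
        Angle of the long axis w.r.t. the lab x-axis, radians.
    """

    length: float
    radius: float
    center: tuple[float, float] = (0.0, 0.0)
    orientation: float = 0.0

    def __post_init__(self) -> None:
        if not self.radius > 0:
            raise ValueError(f"radius must be positive, got {self.radius}")
        if self.length < 2 * self.radius:
            raise ValueError(
                f"length ({self.length}) must be >= 2*radius ({2 * self.radius})"
            )

    @property
    def half_axis(self) -> float:
        """Half-length of the cylindrical core segment."""
        return self.length / 2.0 - self.radius

    @property
    def area(self) -> float:
        return 2 * self.half_axis * 2 * self.radius + np.pi * self.radius**2

    # ---- frame transforms -------------------------------------------------
    def to_local(self, xy: np.ndarray) -> np.ndarray:
        """Map lab-frame points (N, 2) into the cell-local frame."""
        xy = np.atleast_2d(np.asarray(xy, dtype=float))
        c, s = np.cos(self.orientation), np.sin(self.orientation)
        d = xy - np.asarray(self.center)
        return np.column_stack([c * d[:, 0] + s * d[:, 1], -s * d[:, 0] + c * d[:, 1]])

    def to_lab(self, xy: np.ndarray) -> np.ndarray:
        """Map cell-local points (N, 2) into the lab frame."""
        xy = np.atleast_2d(np.asarray(xy, dtype=float))
        c, s = np.cos(self.orientation), np.sin(self.orientation)
        return np.column_stack(
            [c * xy[:, 0] - s * xy[:, 1], s * xy[:, 0] + c * xy[:, 1]]
        ) + np.asarray(self.center)

    # ---- membership -------------------------------------------------------
    def signed_distance_local(self, xy_local: np.ndarray) -> np.ndarray:
        """Signed distance to the wall (negative inside) for local points."""
        xy = np.atleast_2d(xy_local)
        ax = np.clip(xy[:, 0], -self.half_axis, self.half_axis)
        return np.hypot(xy[:, 0] - ax, xy[:, 1]) - self.radius

    def contains(self, xy: np.ndarray, tol: float = 0.0) -> np.ndarray:
        """Boolean mask of lab-frame points inside the cell (within tol)."""
        return self.signed_distance_local(self.to_local(xy)) <= tol

    # ---- sampling & reflection -------------------------------------------
    def sample_uniform(self, rng: np.random.Generator, n: int,
                       margin: float = 0.0) -> np.ndarray:
        """Draw ``n`` points uniformly inside the cell (lab frame).

        ``margin`` shrinks the admissible region away from the wall.
        """
        if margin >= self.radius:
            raise ValueError("margin must be smaller than the cell radius")
        out = np.empty((n, 2))
        filled = 0
        hx = self.length / 2.0
        while filled < n:
            m = max(2 * (n - filled), 16)
            cand = np.column_stack([
                rng.uniform(-hx, hx, m),
                rng.uniform(-self.radius, self.radius, m),
            ])
            ok = self.signed_distance_local(cand) <= -margin
            take = min(ok.sum(), n - filled)
            out[filled:filled + take] = cand[ok][:take]
            filled += take
        return self.to_lab(out)

    def reflect_local(self, xy_local: np.ndarray, max_iter: int = 20) -> np.ndarray:
        """Specularly reflect local points that fall outside back inside.

        Iterated because a single mirror image of a long step may land
        outside again; residual violations after ``max_iter`` are clipped
        radially onto the wall.
        """
        p = np.array(np.atleast_2d(xy_local), dtype=float)
        for _ in range(max_iter):
            ax = np.clip(p[:, 0], -self.half_axis, self.half_axis)
            dx, dy = p[:, 0] - ax, p[:, 1]
            d = np.hypot(dx, dy)
            out = d > self.radius
            if not out.any():
                return p
            over = d[out] - self.radius
            p[out, 0] -= 2 * over * dx[out] / d[out]
            p[out, 1] -= 2 * over * dy[out] / d[out]
        # pathological residue: project onto the wall
        ax = np.clip(p[:, 0], -self.half_axis, self.half_axis)
        dx, dy = p[:, 0] - ax, p[:, 1]
        d = np.hypot(dx, dy)
        out = d > self.radius
        if out.any():
            scale = self.radius / d[out]
            p[out, 0] = ax[out] + dx[out] * scale
            p[out, 1] = dy[out] * scale
        return p

    def reflect(self, xy: np.ndarray) -> np.ndarray:
        """Lab-frame wrapper around :meth:`reflect_local`."""
        return self.to_lab(self.reflect_local(self.to_local(xy)))


def reflect_in_disk(xy: np.ndarray, center: np.ndarray, radius: float,
                    max_iter: int = 20) -> np.ndarray:
    """Specular reflection into a disk, used for anchored (tethered) molecules."""
    p = np.array(np.atleast_2d(xy), dtype=float)
    c = np.asarray(center, dtype=float)
    for _ in range(max_iter):
        d = np.hypot(p[:, 0] - c[0], p[:, 1] - c[1])
        out = d > radius
        if not out.any():
            return p
        over = d[out] - radius
        p[out, 0] -= 2 * over * (p[out, 0] - c[0]) / d[out]
        p[out, 1] -= 2 * over * (p[out, 1] - c[1]) / d[out]
    d = np.hypot(p[:, 0] - c[0], p[:, 1] - c[1])
    out = d > radius
    if out.any():
        scale = radius / d[out]
        p[out, 0] = c[0] + (p[out, 0] - c[0]) * scale
        p[out, 1] = c[1] + (p[out, 1] - c[1]) * scale
    return p
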