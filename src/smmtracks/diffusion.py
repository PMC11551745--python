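"""Displacement statistics and diffusion-coefficient estimation.

Implements the two estimators used for single-molecule tracking data of
cytosolic complexes in bacteria:

* a zero-mean Gaussian mixture fit to the pooled frame-to-frame x/y
  displacements (static vs mobile split), fitted by EM;
* a multi-population fit of the squared frame-to-frame displacements
  ("jump distances"): for a mixture of 2D Brownian populations with
  diffusion coefficients D_i and fractions f_i the squared jump r² is
  exponentially distributed per component, so

      P(r² <= u) = 1 - sum_i f_i * exp(-u / (4 D_i Δt [+ 4 σ_loc²]))

  which is fitted by least squares on the empirical CDF, optionally with
  a shared-D "global" variant across experimental conditions;

plus mean-squared-displacement (MSD) versus time-lag curves and the
conversion D_i = σ_i² / (2 Δt) between a population's 1D per-frame step
standard deviation and its diffusion coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .track_io import TrackSet

D_FLOOR = 1e-6  # μm²/s; fitted coefficients are clipped here with a flag


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PopulationMixture:
    """K diffusive populations with fractions f_i and coefficients D_i.

    Components are stored sorted by ascending D (slow, intermediate,
    mobile).  ``sigma`` is the per-component 1D per-frame step standard
    deviation implied by D at the frame interval ``delta_t``.
    """

    fractions: np.ndarray
    D: np.ndarray
    delta_t: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "fractions", np.asarray(self.fractions, float))
        object.__setattr__(self, "D", np.asarray(self.D, float))
        if self.fractions.shape != self.D.shape:
            raise ValueError("fractions and D must have equal length")
        if self.delta_t <= 0:
            raise ValueError("delta_t must be positive")
        if abs(self.fractions.sum() - 1.0) > 1e-9:
            raise ValueError(f"fractions must sum to 1, got {self.fractions.sum()}")
        if (self.fractions < -1e-12).any():
            raise ValueError("fractions must be non-negative")
        if (self.D < 0).any():
            raise ValueError("diffusion coefficients must be non-negative")
        order = np.argsort(self.D, kind="stable")
        object.__setattr__(self, "fractions", self.fractions[order].copy())
        object.__setattr__(self, "D", self.D[order].copy())

    @property
    def K(self) -> int:
        return len(self.D)

    @property
    def sigma(self) -> np.ndarray:
        """1D per-frame step standard deviation per component, μm."""
        return np.sqrt(2.0 * self.D * self.delta_t)


@dataclass(frozen=True)
class MSDCurve:
    """Ensemble time-averaged MSD versus time lag."""

    lags_s: np.ndarray      # τ_k = k Δt, k >= 1
    msd: np.ndarray         # μm²
    n_pairs: np.ndarray     # pair count per lag
    sem: np.ndarray         # standard error of the mean per lag
    delta_t: float

    def __len__(self) -> int:
        return len(self.lags_s)


@dataclass
class MixtureFitResult:
    """Result of a displacement-mixture fit with histogram residuals."""

    mixture: PopulationMixture
    bin_edges: np.ndarray           # jump-distance histogram binning, μm
    observed: np.ndarray            # probability per bin
    fitted: np.ndarray              # fitted probability per bin
    loss: float                     # -loglik (EM) or SSE on the CDF (LSQ)
    converged: bool
    flags: list[str] = field(default_factory=list)
    loc_sigma: float | None = None  # localization term used in the model, μm

    @property
    def residuals(self) -> np.ndarray:
        """Observed − fitted probability per histogram bin."""
        return self.observed - self.fitted

    @property
    def max_abs_residual(self) -> float:
        if len(self.observed) == 0:
            return 0.0
        return float(np.abs(self.residuals).max())


# ---------------------------------------------------------------------------
# displacement extraction
# ---------------------------------------------------------------------------

def _adjacent_steps(tracks: TrackSet) -> np.ndarray:
    """(n, 2) array of adjacent-frame (dx, dy) over all tracks.

    Only frame pairs differing by exactly one frame contribute; gapped
    pairs are excluded from all displacement statistics.
    """
    df = tracks.df
    if df.empty:
        return np.empty((0, 2))
    out = []
    for _, g in tracks.groupby_tracks():
        f = g["frame"].to_numpy()
        if len(f) < 2:
            continue
        adj = np.diff(f) == 1
        if not adj.any():
            continue
        dx = np.diff(g["x_um"].to_numpy())[adj]
        dy = np.diff(g["y_um"].to_numpy())[adj]
        out.append(np.column_stack([dx, dy]))
    if not out:
        return np.empty((0, 2))
    return np.concatenate(out)


def frame_displacements(tracks: TrackSet) -> np.ndarray:
    """Pooled signed 1D adjacent-frame displacements (x and y separately).

    The sample size is twice the number of adjacent-frame pairs: each
    pair contributes its x- and its y-displacement as independent
    observations.
    """
    steps = _adjacent_steps(tracks)
    if len(steps) == 0:
        raise ValueError("no adjacent-frame pairs in input tracks")
    return steps.T.reshape(-1)


def squared_displacements(tracks: TrackSet) -> np.ndarray:
    """Squared 2D adjacent-frame displacements r² = dx² + dy², μm²."""
    steps = _adjacent_steps(tracks)
    return (steps**2).sum(axis=1)


def sigma_to_D(sigma: float, delta_t: float) -> float:
    """D = σ² / (2 Δt): 1D step standard deviation → diffusion coefficient."""
    if delta_t <= 0:
        raise ValueError("delta_t must be positive")
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    return sigma**2 / (2.0 * delta_t)


# ---------------------------------------------------------------------------
# zero-mean Gaussian mixture on 1D displacements (EM)
# ---------------------------------------------------------------------------

def _gm_histogram(x: np.ndarray, weights: np.ndarray, sigmas: np.ndarray,
                  n_bins: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    lo, hi = np.percentile(x, [0.5, 99.5])
    if hi <= lo:
        hi = lo + max(abs(lo), 1.0) * 1e-6
    edges = np.linspace(lo, hi, n_bins + 1)
    counts, _ = np.histogram(x, bins=edges)
    observed = counts / len(x)
    from scipy.stats import norm

    cdf = np.zeros_like(edges)
    for w, s in zip(weights, sigmas):
        if s > 0:
            cdf += w * norm.cdf(edges, 0.0, s)
        else:
            cdf += w * (edges >= 0)
    fitted = np.diff(cdf)
    return edges, observed, fitted


def fit_gaussian_mixture(displacements: np.ndarray, K: int = 2,
                         delta_t: float = 0.030, n_restarts: int = 5,
                         max_iter: int = 500, tol: float = 1e-10,
                         n_bins: int = 50) -> MixtureFitResult:
    """Fit K zero-mean Gaussian components to 1D displacements by EM.

    Means are fixed at zero (Brownian steps are symmetric); the free
    parameters are the component weights and standard deviations.  The
    best of ``n_restarts`` deterministically seeded starts is kept, and
    D_i = σ_i²/(2Δt) is reported per component, sorted ascending.
    """
    x = np.asarray(displacements, float).ravel()
    if K < 1:
        raise ValueError("K must be >= 1")
    if len(x) < 10 * K:
        raise ValueError(f"need >= {10 * K} displacements for K={K}")

    if np.ptp(x) == 0.0:
        # degenerate sample: all identical values
        s = abs(float(x[0]))  # zero-mean model: constant c has sd |c|
        mix = PopulationMixture([1.0], [sigma_to_D(s, delta_t)], delta_t)
        edges = np.array([x[0] - 0.5, x[0] + 0.5])
        return MixtureFitResult(
            mixture=mix, bin_edges=edges, observed=np.array([1.0]),
            fitted=np.array([1.0]), loss=0.0, converged=True,
            flags=["degenerate_sample"],
        )

    x2 = x**2
    rng = np.random.default_rng(20230915)
    # quantile-spread σ seeds: K geometric quantiles of |x|
    absx = np.abs(x[x != 0])
    if len(absx) == 0:
        absx = np.array([np.std(x)])
    qs = np.linspace(0.15, 0.95, K)
    base_sigma = np.maximum(np.quantile(absx, qs), 1e-6)

    best = None
    for r in range(n_restarts):
        if r == 0:
            sig2 = base_sigma**2
        else:
            sig2 = (base_sigma * np.exp(rng.normal(0, 0.5, K)))**2
        w = np.full(K, 1.0 / K)
        ll_prev = -np.inf
        converged = False
        for _ in range(max_iter):
            # E-step in log space
            logp = (np.log(w)[:, None]
                    - 0.5 * np.log(2 * np.pi * sig2)[:, None]
                    - x2[None, :] / (2 * sig2[:, None]))
            m = logp.max(axis=0)
            lse = m + np.log(np.exp(logp - m).sum(axis=0))
            ll = lse.sum()
            gamma = np.exp(logp - lse)
            # M-step (means fixed at 0)
            nk = gamma.sum(axis=1)
            w = nk / len(x)
            sig2 = np.maximum((gamma * x2).sum(axis=1) / np.maximum(nk, 1e-300),
                              1e-12)
            if abs(ll - ll_prev) < tol * (1 + abs(ll)):
                converged = True
                break
            ll_prev = ll
        if best is None or ll > best[0]:
            best = (ll, w.copy(), np.sqrt(sig2), converged)

    ll, w, sig, converged = best
    flags = []
    D = np.array([sigma_to_D(s, delta_t) for s in sig])
    low = D < D_FLOOR
    if low.any():
        D = np.maximum(D, D_FLOOR)
        flags.append("D_clipped_to_floor")
    order = np.argsort(D, kind="stable")
    w, D = w[order], D[order]
    w = w / w.sum()
    mix = PopulationMixture(w, D, delta_t)
    edges, observed, fitted = _gm_histogram(x, mix.fractions, mix.sigma, n_bins)
    return MixtureFitResult(
        mixture=mix, bin_edges=edges, observed=observed, fitted=fitted,
        loss=-ll, converged=converged, flags=flags,
    )


# ---------------------------------------------------------------------------
# squared-displacement (jump-distance) mixture, least squares on the ECDF
# ---------------------------------------------------------------------------

def _sqd_scales(D: np.ndarray, delta_t: float, loc_sigma: float | None) -> np.ndarray:
    s = 4.0 * D * delta_t
    if loc_sigma is not None:
        s = s + 4.0 * loc_sigma**2
    return s


def sqd_mixture_cdf(u: np.ndarray, fractions: np.ndarray, D: np.ndarray,
                    delta_t: float, loc_sigma: float | None = None) -> np.ndarray:
    """Model CDF of squared jumps: 1 − Σ f_i exp(−u / (4 D_i Δt + 4 σ_loc²))."""
    scales = _sqd_scales(np.asarray(D, float), delta_t, loc_sigma)
    u = np.asarray(u, float)
    return 1.0 - np.exp(-u[..., None] / scales).dot(np.asarray(fractions, float))


def _ecdf_grid(r2: np.ndarray, n_grid: int) -> tuple[np.ndarray, np.ndarray]:
    u = np.sort(r2)
    n = len(u)
    if n <= n_grid:
        idx = np.arange(n)
    else:
        idx = np.unique(np.linspace(0, n - 1, n_grid).round().astype(int))
    return u[idx], (idx + 0.5) / n


def _softmax(b: np.ndarray) -> np.ndarray:
    z = np.concatenate([b, [0.0]])
    z = z - z.max()
    e = np.exp(z)
    return e / e.sum()


def _jump_histogram(r2: np.ndarray, fractions: np.ndarray, D: np.ndarray,
                    delta_t: float, loc_sigma: float | None,
                    n_bins: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Probability histogram of jump distances r plus fitted bin masses.

    Binning convention: ``n_bins`` equal-width bins spanning
    [0, 99.5th percentile of r]; observed probabilities are counts over
    the *total* sample size, fitted masses are model-CDF differences.
    """
    r = np.sqrt(r2)
    hi = np.percentile(r, 99.5)
    if hi <= 0:
        hi = max(r.max(), 1e-6)
    edges = np.linspace(0.0, hi, n_bins + 1)
    counts, _ = np.histogram(r, bins=edges)
    observed = counts / len(r)
    cdf = sqd_mixture_cdf(edges**2, fractions, D, delta_t, loc_sigma)
    fitted = np.diff(cdf)
    return edges, observed, fitted


def _sqd_inits(r2: np.ndarray, K: int, delta_t: float,
               loc_sigma: float | None, n_restarts: int) -> list[np.ndarray]:
    """Deterministic multi-start D initializations from quantile spread."""
    rng = np.random.default_rng(20240130)
    qs = np.linspace(0.2, 0.9, K)
    scale0 = np.maximum(np.quantile(r2, qs), 1e-8)
    if loc_sigma is not None:
        scale0 = np.maximum(scale0 - 4.0 * loc_sigma**2, 1e-8)
    D0 = np.sort(scale0 / (4.0 * delta_t))
    inits = [D0]
    for _ in range(max(n_restarts - 1, 0)):
        inits.append(np.sort(D0 * np.exp(rng.normal(0, 0.7, K))))
    return inits


def fit_sqd_mixture(r2: np.ndarray, K: int = 3, delta_t: float = 0.030,
                    loc_sigma: float | None = None, n_restarts: int = 5,
                    n_bins: int = 50, n_grid: int = 800) -> MixtureFitResult:
    """Fit a K-population jump-distance model on the empirical CDF of r².

    Least-squares on the ECDF (bin-independent); the histogram residuals
    reported alongside use ``n_bins`` equal-width jump-distance bins up to
    the 99.5th percentile, matching the convention used for figure
    residual panels.  ``loc_sigma`` optionally adds a 4σ² localization
    term to each component's scale (default off).
    """
    r2 = np.asarray(r2, float).ravel()
    if K < 1:
        raise ValueError("K must be >= 1")
    if len(r2) < 10 * K:
        raise ValueError(f"need >= {10 * K} squared displacements for K={K}")
    if (r2 < 0).any():
        raise ValueError("squared displacements must be non-negative")

    flags: list[str] = []
    if np.ptp(r2) == 0.0:
        D_val = max(float(r2[0]) / (4.0 * delta_t), D_FLOOR)
        mix = PopulationMixture([1.0], [D_val], delta_t)
        return MixtureFitResult(
            mixture=mix, bin_edges=np.array([0.0, np.sqrt(r2[0]) + 1e-6]),
            observed=np.array([1.0]), fitted=np.array([1.0]), loss=0.0,
            converged=True, flags=["degenerate_sample"], loc_sigma=loc_sigma,
        )

    u_grid, ecdf = _ecdf_grid(r2, n_grid)

    def unpack(theta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        D = np.exp(np.clip(theta[:K], -40.0, 40.0))
        f = _softmax(theta[K:]) if K > 1 else np.array([1.0])
        return f, D

    def resid(theta: np.ndarray) -> np.ndarray:
        f, D = unpack(theta)
        return sqd_mixture_cdf(u_grid, f, D, delta_t, loc_sigma) - ecdf

    best = None
    for D0 in _sqd_inits(r2, K, delta_t, loc_sigma, n_restarts):
        theta0 = np.concatenate([np.log(np.maximum(D0, 1e-9)), np.zeros(K - 1)])
        try:
            sol = least_squares(resid, theta0, method="lm", xtol=1e-12,
                                ftol=1e-12, max_nfev=20000)
        except Exception:
            continue
        sse = float(np.sum(sol.fun**2))
        if best is None or sse < best[0]:
            best = (sse, sol)
    if best is None:
        raise RuntimeError("squared-displacement fit failed in all restarts")
    sse, sol = best
    if not sol.success:
        flags.append("optimizer_not_converged")
    f, D = unpack(sol.x)
    if (D < D_FLOOR).any():
        D = np.maximum(D, D_FLOOR)
        flags.append("D_clipped_to_floor")
    order = np.argsort(D, kind="stable")
    f, D = f[order], D[order]
    mix = PopulationMixture(f / f.sum(), D, delta_t)
    edges, observed, fitted = _jump_histogram(
        r2, mix.fractions, mix.D, delta_t, loc_sigma, n_bins)
    return MixtureFitResult(
        mixture=mix, bin_edges=edges, observed=observed, fitted=fitted,
        loss=sse, converged=sol.success, flags=flags, loc_sigma=loc_sigma,
    )


def fit_sqd_global(samples: dict[str, np.ndarray], K: int = 3,
                   delta_t: float = 0.030, loc_sigma: float | None = None,
                   n_restarts: int = 5, n_bins: int = 50,
                   n_grid: int = 400) -> dict[str, MixtureFitResult]:
    """Joint jump-distance fit across conditions with shared D_i.

    The diffusion coefficients are common to all conditions while the
    population fractions are condition-specific — the "global diffusion
    constants" convention that makes per-condition population sizes
    directly comparable.
    """
    if len(samples) < 2:
        raise ValueError("global fit requires >= 2 conditions")
    conds = list(samples.keys())
    data = {}
    for c in conds:
        r2 = np.asarray(samples[c], float).ravel()
        if len(r2) < 10 * K:
            raise ValueError(f"condition {c!r}: need >= {10 * K} displacements")
        data[c] = _ecdf_grid(r2, n_grid)

    n_cond = len(conds)

    def unpack(theta):
        D = np.exp(np.clip(theta[:K], -40.0, 40.0))
        fs = []
        for j in range(n_cond):
            b = theta[K + j * (K - 1): K + (j + 1) * (K - 1)]
            fs.append(_softmax(b) if K > 1 else np.array([1.0]))
        return fs, D

    def resid(theta):
        fs, D = unpack(theta)
        parts = []
        for j, c in enumerate(conds):
            u, e = data[c]
            parts.append(sqd_mixture_cdf(u, fs[j], D, delta_t, loc_sigma) - e)
        return np.concatenate(parts)

    pooled = np.concatenate([np.asarray(samples[c], float) for c in conds])
    best = None
    for D0 in _sqd_inits(pooled, K, delta_t, loc_sigma, n_restarts):
        theta0 = np.concatenate([
            np.log(np.maximum(D0, 1e-9)), np.zeros(n_cond * (K - 1))])
        try:
            sol = least_squares(resid, theta0, method="lm", xtol=1e-12,
                                ftol=1e-12, max_nfev=40000)
        except Exception:
            continue
        sse = float(np.sum(sol.fun**2))
        if best is None or sse < best[0]:
            best = (sse, sol)
    if best is None:
        raise RuntimeError("global squared-displacement fit failed")
    sse, sol = best
    fs, D = unpack(sol.x)
    flags = [] if sol.success else ["optimizer_not_converged"]
    if (D < D_FLOOR).any():
        D = np.maximum(D, D_FLOOR)
        flags = flags + ["D_clipped_to_floor"]
    order = np.argsort(D, kind="stable")
    D = D[order]
    results = {}
    for j, c in enumerate(conds):
        f = fs[j][order]
        mix = PopulationMixture(f / f.sum(), D, delta_t)
        r2 = np.asarray(samples[c], float).ravel()
        edges, observed, fitted = _jump_histogram(
            r2, mix.fractions, mix.D, delta_t, loc_sigma, n_bins)
        results[c] = MixtureFitResult(
            mixture=mix, bin_edges=edges, observed=observed, fitted=fitted,
            loss=sse, converged=sol.success, flags=list(flags),
            loc_sigma=loc_sigma,
        )
    return results


# ---------------------------------------------------------------------------
# MSD
# ---------------------------------------------------------------------------

def msd(tracks: TrackSet, max_lag_frames: int = 10) -> MSDCurve:
    """Ensemble time-averaged MSD over all valid pairs in all tracks.

    For lag k, every pair of localizations in the same track whose frame
    indices differ by exactly k contributes its squared 2D displacement;
    the per-lag SEM is over pairs.
    """
    if max_lag_frames < 1:
        raise ValueError("max_lag_frames must be >= 1")
    sums = np.zeros(max_lag_frames)
    sums2 = np.zeros(max_lag_frames)
    counts = np.zeros(max_lag_frames, dtype=int)
    for _, g in tracks.groupby_tracks():
        f = g["frame"].to_numpy()
        x = g["x_um"].to_numpy()
        y = g["y_um"].to_numpy()
        pos = {fi: i for i, fi in enumerate(f)}
        for k in range(1, max_lag_frames + 1):
            for fi, i in pos.items():
                j = pos.get(fi + k)
                if j is None:
                    continue
                d2 = (x[j] - x[i])**2 + (y[j] - y[i])**2
                sums[k - 1] += d2
                sums2[k - 1] += d2 * d2
                counts[k - 1] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
        var = np.where(counts > 1,
                       (sums2 - counts * mean**2) / np.maximum(counts - 1, 1),
                       0.0)
        sem = np.where(counts > 0, np.sqrt(np.maximum(var, 0.0) /
                                           np.maximum(counts, 1)), np.nan)
    lags = np.arange(1, max_lag_frames + 1) * tracks.delta_t
    return MSDCurve(lags_s=lags, msd=mean, n_pairs=counts, sem=sem,
                    delta_t=tracks.delta_t)


def d_from_msd(curve: MSDCurve, n_fit_points: int = 4
               ) -> tuple[float, float, dict]:
    """Weighted linear fit MSD(τ) = 4 D τ + b on the first lags.

    The intercept b absorbs the (static) localization-error offset.
    Returns (D, b, info) where info carries R², the number of points used
    and a ``negative_D`` flag when the slope came out negative (D is then
    reported as 0).
    """
    if len(curve) < n_fit_points:
        raise ValueError(
            f"MSD curve has {len(curve)} lags, need {n_fit_points}")
    tau = curve.lags_s[:n_fit_points]
    y = curve.msd[:n_fit_points]
    sem = curve.sem[:n_fit_points]
    if np.isnan(y).any():
        raise ValueError("MSD undefined (no pairs) within the fit range")
    good = np.isfinite(sem) & (sem > 0)
    if good.all():
        w = 1.0 / sem**2
    else:
        w = np.ones_like(tau)
    W = np.sum(w)
    tbar = np.sum(w * tau) / W
    ybar = np.sum(w * y) / W
    denom = np.sum(w * (tau - tbar)**2)
    slope = np.sum(w * (tau - tbar) * (y - ybar)) / denom
    b = ybar - slope * tbar
    yhat = slope * tau + b
    ss_res = np.sum(w * (y - yhat)**2)
    ss_tot = np.sum(w * (y - ybar)**2)
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    D = slope / 4.0
    info = {"r_squared": float(r2), "n_fit_points": n_fit_points,
            "negative_D": D < 0}
    if D < 0:
        D = 0.0
    return float(D), float(b), info
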