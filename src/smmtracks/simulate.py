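"""Synthetic single-molecule microscopy (SMM) datasets with ground truth.

Emulates slimfield tracking data of fluorescently tagged CRISPR effector
complexes (crRNPs, green channel) and replisome clamp-loader DnaX foci
(red channel) in rod-shaped bacteria: a mixture of 2–4 Brownian
populations diffusing inside a spherocylindrical cell with specular wall
reflection, isotropic localization noise, per-frame photobleaching, a
discarded pre-bleaching phase and an optional fraction of slow-population
molecules tethered near a replication-fork focus.

Every dataset carries its generative truth (per-molecule population
label, anchor focus, true positions) so downstream estimators can be
validated against it.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .diffusion import PopulationMixture
from .geometry import CellGeometry, reflect_in_disk
from .track_io import FOCI_COLUMNS, TRACK_COLUMNS, TrackSet

DEFAULT_GEOMETRY = CellGeometry(length=2.5, radius=0.5)


@dataclass
class SimulationConfig:
    """Parameters of one simulated SMM acquisition.

    ``n_frames`` counts recorded frames (after the discarded
    pre-bleaching phase); ``n_molecules`` is the fluorophore count per
    cell at the *start of the pre-phase*, so the number of molecules
    entering the recording is thinned by survival through
    ``bleach_phase_frames``.  ``anchor_fraction`` tethers that fraction
    of slow-population (first component) molecules within
    ``anchor_radius`` of a randomly assigned focus.
    """

    mixture: PopulationMixture
    delta_t: float = 0.030
    n_frames: int = 300
    n_cells: int = 60
    n_molecules: int = 40
    loc_noise_sigma: float = 0.030
    survival_prob: float = 0.98
    bleach_phase_frames: int = 100
    n_foci: int = 2
    anchor_fraction: float = 0.0
    anchor_radius: float = 0.075
    polar_bias: float = 0.0
    geometry: CellGeometry = field(default_factory=lambda: DEFAULT_GEOMETRY)
    channel: str = "green"
    min_track_steps: int = 5
    seed: int = 0

    def validate(self) -> None:
        if self.delta_t <= 0:
            raise ValueError("delta_t must be positive")
        if self.n_frames < 6:
            raise ValueError("n_frames must be >= 6")
        if not (0.0 <= self.survival_prob <= 1.0):
            raise ValueError("survival_prob must lie in [0, 1]")
        if not (0.0 <= self.anchor_fraction <= 1.0):
            raise ValueError("anchor_fraction must lie in [0, 1]")
        if not (0.0 <= self.polar_bias <= 1.0):
            raise ValueError("polar_bias must lie in [0, 1]")
        if self.anchor_fraction > 0 and self.n_foci == 0:
            raise ValueError("anchor_fraction > 0 requires n_foci > 0")
        if self.anchor_fraction > 0 and self.anchor_radius >= self.geometry.radius * 2:
            raise ValueError(
                "geometry cannot contain anchor_radius "
                f"({self.anchor_radius} vs radius {self.geometry.radius})")
        if self.n_cells < 1 or self.n_molecules < 0:
            raise ValueError("n_cells >= 1 and n_molecules >= 0 required")
        if self.loc_noise_sigma < 0:
            raise ValueError("loc_noise_sigma must be non-negative")
        if abs(self.mixture.delta_t - self.delta_t) > 1e-12:
            raise ValueError("mixture.delta_t must equal config.delta_t")


@dataclass
class GroundTruth:
    """Generative truth for one simulated dataset.

    ``molecules``: one row per emitted track — ``cell_id, track_id,
    population, D_true, anchor_focus_id, lifetime_frames`` (focus id −1
    means free).  ``positions``: noiseless trajectory per localization.
    ``foci``: the true focus table (track_io foci schema).
    """

    molecules: pd.DataFrame
    positions: pd.DataFrame
    foci: pd.DataFrame


def _cell_rng(seed: int, cell: int, stream: int) -> np.random.Generator:
    # deterministic per-cell substreams of one master seed
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(cell, stream)))


def _sample_foci_cell(cfg: SimulationConfig, rng: np.random.Generator,
                      n: int) -> np.ndarray:
    """Focus positions in one cell; ``polar_bias`` is the probability a
    focus is drawn inside a polar cap instead of uniformly in the cell."""
    g = cfg.geometry
    pts = g.sample_uniform(rng, n)
    if cfg.polar_bias > 0 and n > 0:
        polar = rng.random(n) < cfg.polar_bias
        n_p = int(polar.sum())
        if n_p:
            # rejection-sample inside the two spherical caps (|x| > half_axis)
            cap = np.empty((n_p, 2))
            filled = 0
            while filled < n_p:
                m = max(4 * (n_p - filled), 16)
                cand = np.column_stack([
                    rng.choice([-1.0, 1.0], m) * rng.uniform(
                        g.half_axis, g.length / 2, m),
                    rng.uniform(-g.radius, g.radius, m)])
                ok = g.signed_distance_local(cand) <= 0
                take = min(ok.sum(), n_p - filled)
                cap[filled:filled + take] = cand[ok][:take]
                filled += take
            pts[polar] = g.to_lab(cap)
    return pts


def simulate_foci(config: SimulationConfig) -> pd.DataFrame:
    """Simulate DnaX-focus positions for every cell (track_io foci schema)."""
    config.validate()
    if config.n_foci < 0:
        raise ValueError("n_foci must be >= 0")
    rows = []
    for c in range(config.n_cells):
        rng = _cell_rng(config.seed, c, 0)
        pts = _sample_foci_cell(config, rng, config.n_foci)
        for i in range(config.n_foci):
            rows.append((c, i, pts[i, 0], pts[i, 1]))
    return pd.DataFrame(rows, columns=FOCI_COLUMNS)


def simulate_tracks(config: SimulationConfig,
                    foci: pd.DataFrame | None = None
                    ) -> tuple[TrackSet, GroundTruth]:
    """Simulate an SMM dataset: tracks plus full generative truth.

    Per cell: molecules are assigned a mixture component by its fraction
    and start uniformly inside the cell (anchored molecules start inside
    their tether disk); each frame every coordinate advances by a
    zero-mean Gaussian step of sd sqrt(2 D Δt) with specular reflection
    at the cell wall (anchored molecules additionally reflect at the
    tether-disk boundary); reported positions add isotropic Gaussian
    localization noise.  Molecules bleach with probability
    1 − survival_prob per frame; survival through the discarded
    pre-bleaching phase thins the starting population.  Tracks shorter
    than ``min_track_steps`` displacements are dropped.

    ``foci`` optionally injects an external focus table (track_io foci
    schema) instead of drawing fresh ones — used to emulate a second
    imaging channel in the *same* cells, e.g. crRNP molecules anchored
    at the DnaX foci of a paired red-channel simulation.  Cells without
    a focus get no anchored molecules.
    """
    config.validate()
    if foci is None:
        foci = simulate_foci(config)
    else:
        missing = [c for c in FOCI_COLUMNS if c not in foci.columns]
        if missing:
            raise ValueError(f"external foci table missing columns {missing}")
        foci = foci[FOCI_COLUMNS].copy()
    p = config.survival_prob
    track_rows: list[pd.DataFrame] = []
    truth_rows: list[pd.DataFrame] = []
    mol_rows = []
    next_track_id = 0
    sigmas = config.mixture.sigma  # per-component 1D step sd

    for c in range(config.n_cells):
        rng = _cell_rng(config.seed, c, 1)
        # pre-phase bleaching: thin the initial population
        if config.bleach_phase_frames > 0 and p < 1.0:
            n_start = rng.binomial(config.n_molecules,
                                   p**config.bleach_phase_frames)
        else:
            n_start = config.n_molecules
        if n_start == 0:
            continue
        comp = rng.choice(config.mixture.K, size=n_start,
                          p=config.mixture.fractions)
        # recorded lifetime in frames (localizations), capped at n_frames
        if p < 1.0:
            life = np.minimum(rng.geometric(1.0 - p, n_start), config.n_frames)
        else:
            life = np.full(n_start, config.n_frames)
        cell_foci = (foci[foci["cell_id"] == c]
                     .sort_values("focus_id")[["x_um", "y_um"]].to_numpy())
        anchored = np.full(n_start, -1, dtype=int)
        if config.anchor_fraction > 0 and len(cell_foci):
            slow = comp == 0
            tether = slow & (rng.random(n_start) < config.anchor_fraction)
            anchored[tether] = rng.integers(0, len(cell_foci), tether.sum())

        pos = config.geometry.sample_uniform(rng, n_start)
        for i in np.flatnonzero(anchored >= 0):
            ctr = cell_foci[anchored[i]]
            # start inside tether disk ∩ cell
            for _ in range(200):
                u = rng.uniform(-1, 1, 2) * config.anchor_radius
                cand = ctr + u
                if (np.hypot(*u) <= config.anchor_radius
                        and config.geometry.contains(cand)[0]):
                    pos[i] = cand
                    break
            else:
                pos[i] = ctr

        n_max = int(life.max())
        traj = np.empty((n_start, n_max, 2))
        traj[:, 0] = pos
        cur = pos.copy()
        for t in range(1, n_max):
            idx = np.flatnonzero(life > t)
            if len(idx) == 0:
                break
            steps = rng.normal(0.0, 1.0, (n_start, 2)) * sigmas[comp][:, None]
            nxt = cur[idx] + steps[idx]
            # tethered molecules: reflect at the tether disk first
            for j, i in enumerate(idx):
                if anchored[i] >= 0:
                    nxt[j] = reflect_in_disk(nxt[j], cell_foci[anchored[i]],
                                             config.anchor_radius)[0]
            nxt = config.geometry.reflect(nxt)
            cur[idx] = nxt
            traj[idx, t] = nxt

        noise = rng.normal(0.0, config.loc_noise_sigma, traj.shape)
        for i in range(n_start):
            L = int(life[i])
            n_steps = L - 1
            if n_steps < config.min_track_steps:
                continue
            tid = next_track_id
            next_track_id += 1
            frames = np.arange(L)
            true_xy = traj[i, :L]
            obs_xy = true_xy + noise[i, :L]
            track_rows.append(pd.DataFrame({
                "cell_id": c, "track_id": tid, "channel": config.channel,
                "frame": frames, "x_um": obs_xy[:, 0], "y_um": obs_xy[:, 1],
            }))
            truth_rows.append(pd.DataFrame({
                "cell_id": c, "track_id": tid, "frame": frames,
                "x_true_um": true_xy[:, 0], "y_true_um": true_xy[:, 1],
            }))
            mol_rows.append((c, tid, int(comp[i]),
                             float(config.mixture.D[comp[i]]),
                             int(anchored[i]), L))

    if track_rows:
        df = pd.concat(track_rows, ignore_index=True)[TRACK_COLUMNS]
        truth_pos = pd.concat(truth_rows, ignore_index=True)
    else:
        df = pd.DataFrame(columns=TRACK_COLUMNS)
        truth_pos = pd.DataFrame(
            columns=["cell_id", "track_id", "frame", "x_true_um", "y_true_um"])
    molecules = pd.DataFrame(
        mol_rows, columns=["cell_id", "track_id", "population", "D_true",
                           "anchor_focus_id", "lifetime_frames"])
    tracks = TrackSet(df=df, delta_t=config.delta_t)
    return tracks, GroundTruth(molecules=molecules, positions=truth_pos,
                               foci=foci)


# ---------------------------------------------------------------------------
# image rendering
# ---------------------------------------------------------------------------

def render_frames(tracks: TrackSet, psf_sigma: float = 0.15,
                  photon_rate: float = 2000.0, background: float = 20.0,
                  pixel_size: float = 0.1, fov_px: tuple[int, int] | None = None,
                  seed: int = 0) -> np.ndarray:
    """Render tracks as a multi-frame 16-bit image stack.

    Each localization becomes a pixel-integrated 2D Gaussian spot of
    total intensity ``photon_rate`` photons; Poisson shot noise is
    applied to spot + constant ``background`` (counts/pixel).  The field
    of view defaults to the bounding box of all localizations plus a
    4-σ margin; coordinates must fit inside an explicit ``fov_px``.
    """
    from scipy.special import erf

    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")
    if psf_sigma <= 0:
        raise ValueError("psf_sigma must be positive")
    df = tracks.df
    n_frames = int(df["frame"].max()) + 1 if len(df) else 1
    margin = 4.0 * psf_sigma
    if len(df):
        x0 = df["x_um"].min() - margin
        y0 = df["y_um"].min() - margin
        if fov_px is None:
            w = int(np.ceil((df["x_um"].max() + margin - x0) / pixel_size)) + 1
            h = int(np.ceil((df["y_um"].max() + margin - y0) / pixel_size)) + 1
            fov_px = (h, w)
        else:
            h, w = fov_px
            if (df["x_um"].max() - x0 > w * pixel_size
                    or df["y_um"].max() - y0 > h * pixel_size):
                raise ValueError("localizations do not fit in the field of view")
    else:
        x0 = y0 = 0.0
        if fov_px is None:
            fov_px = (32, 32)
        h, w = fov_px
    h, w = fov_px

    rng = np.random.default_rng(seed)
    stack = np.empty((n_frames, h, w), dtype=np.uint16)
    xe = x0 + np.arange(w + 1) * pixel_size
    ye = y0 + np.arange(h + 1) * pixel_size
    s = psf_sigma * np.sqrt(2.0)
    for t in range(n_frames):
        img = np.full((h, w), float(background))
        sub = df[df["frame"] == t]
        for row in sub.itertuples(index=False):
            fx = 0.5 * (erf((xe - row.x_um) / s))
            fy = 0.5 * (erf((ye - row.y_um) / s))
            img += photon_rate * np.outer(np.diff(fy), np.diff(fx))
        stack[t] = np.clip(rng.poisson(img), 0, 65535).astype(np.uint16)
    return stack


def write_stack(stack: np.ndarray, path) -> None:
    import tifffile

    tifffile.imwrite(path, stack, photometric="minisblack")


# ---------------------------------------------------------------------------
# condition presets
# ---------------------------------------------------------------------------

def _mix(fractions, D, delta_t=0.030) -> PopulationMixture:
    return PopulationMixture(np.asarray(fractions), np.asarray(D), delta_t)

# Printed coefficients: slow 0.023 μm²/s, intermediate 0.128 μm²/s.  The
# mobile coefficient (0.6) and all per-condition fractions are declared
# defaults — the originals were only shown graphically.
_WT_D = (0.023, 0.128, 0.60)

_PRESETS: dict[str, dict] = {
    # native system: chromosomal target present, ~1/3 slow
    "wildtype": dict(mixture=_mix((0.34, 0.36, 0.30), _WT_D)),
    # native system + untargeted high-copy plasmid: slow pool drains into
    # the intermediate (scanning) pool
    "high_copy_plasmid": dict(mixture=_mix((0.12, 0.56, 0.32), _WT_D)),
    # recombinant E. coli host conditions (crRNP green channel)
    "genome_target": dict(mixture=_mix((0.35, 0.35, 0.30), _WT_D),
                          anchor_fraction=0.3, n_foci=2),
    "nontarget_plasmid": dict(mixture=_mix((0.15, 0.55, 0.30), _WT_D),
                              anchor_fraction=0.0, n_foci=2),
    "target_plasmid": dict(mixture=_mix((0.45, 0.35, 0.20), _WT_D),
                           anchor_fraction=0.6, n_foci=2, polar_bias=0.6),
    # DnaX-mScarlet (red channel): replisome-bound vs free clamp loader
    "dnax_nontarget": dict(mixture=_mix((0.55, 0.45), (0.012, 0.35)),
                           channel="red", anchor_fraction=0.7, n_foci=2),
    # polar bias: replicating high-copy plasmids concentrate toward the poles
    "dnax_target": dict(mixture=_mix((0.70, 0.30), (0.008, 0.25)),
                        channel="red", anchor_fraction=0.8, n_foci=2,
                        polar_bias=0.5),
}

PRESET_NAMES = tuple(_PRESETS)


def preset(name: str, seed: int = 0, **overrides) -> SimulationConfig:
    """Fully populated :class:`SimulationConfig` for a named condition.

    Conditions mirror the experimental design: wild type, wild type with
    a high-copy plasmid, and the recombinant-host genome-target /
    non-target-plasmid / target-plasmid strains for the crRNP channel,
    plus the two DnaX conditions.  Keyword overrides replace any field.
    """
    if name not in _PRESETS:
        raise ValueError(
            f"unknown preset {name!r}; choose from {sorted(_PRESETS)}")
    kwargs = copy.deepcopy(_PRESETS[name])
    kwargs.update(overrides)
    cfg = SimulationConfig(seed=seed, **kwargs)
    cfg.validate()
    return cfg
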