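# smmtracks

Simulation and analysis of single-molecule microscopy (SMM) tracking
data of fluorescently tagged complexes in rod-shaped bacteria — built
around the question of how Type IV-A CRISPR effector complexes (crRNPs,
tagged with mNeonGreen) behave relative to the DNA replisome (DnaX-
mScarlet foci) when they do or do not have a plasmid target.

The package is for people who work with single-particle tracking data
in bacteria and want a tested, reproducible pipeline for the standard
analyses of such experiments:

* **synthetic data with ground truth** — multi-population Brownian
  motion inside a spherocylindrical cell with wall reflection,
  localization noise, photobleaching, replisome foci and optional
  tethering of bound molecules at foci;
* **population structure** — jump-distance (squared-displacement)
  mixture fits and zero-mean Gaussian mixture fits of frame-to-frame
  displacements, single-condition or global (shared diffusion
  coefficients across conditions);
* **MSD-versus-time-lag** curves and diffusion-coefficient extraction;
* **spatial statistics** — standardized-cell track-density maps,
  dwelling (static) track classification, focus detection from
  dwelling tracks, nearest-focus distance-probability histograms;
* a minimal **image path** (spot detection + greedy linking) for
  starting from rendered or real TIFF stacks.

## The model

Each molecule belongs to one of K diffusive populations with fractions
f_i and diffusion coefficients D_i.  For 2D Brownian motion the 1D
frame-to-frame step has standard deviation σ_i with D_i = σ_i²/2Δt,
and the squared 2D jump r² is exponential per population, giving the
mixture CDF

    P(r² ≤ u) = 1 − Σ_i f_i · exp(−u / (4 D_i Δt [+ 4 σ_loc²]))

which is fitted by least squares on the empirical CDF (the σ_loc term
is an optional localization-error correction).  Histogram residual
panels use 50 jump-distance bins up to the 99.5th percentile.  MSD
analysis fits MSD(τ) = 4Dτ + b over the first lags.  Proximity to the
replisome uses D = sqrt((x_focus − x_i)² + (y_focus − y_i)²) for the
first five points of each track against the nearest DnaX focus in the
same cell.  See `docs/methods.md` for the full account.

## Worked example

Simulate the wild-type condition (three populations at Δt = 30 ms,
tracks of at least five steps) and fit the three-component
jump-distance mixture with the known localization precision:

```python
from smmtracks import (preset, simulate_tracks, squared_displacements,
                       fit_sqd_mixture)

cfg = preset("wildtype", seed=1, n_cells=120)
tracks, truth = simulate_tracks(cfg)
r2 = squared_displacements(tracks)
fit = fit_sqd_mixture(r2, K=3, delta_t=cfg.delta_t,
                      loc_sigma=cfg.loc_noise_sigma)
print(f"{tracks.n_tracks} tracks, {len(r2)} adjacent-frame jumps")
for i, (f, D) in enumerate(zip(fit.mixture.fractions, fit.mixture.D)):
    print(f"population {i}: fraction {f:.3f}, D = {D:.4f} um^2/s")
print(f"max |histogram residual| = {fit.max_abs_residual:.4f}")
```

prints

```
605 tracks, 33805 adjacent-frame jumps
population 0: fraction 0.327, D = 0.0231 um^2/s
population 1: fraction 0.358, D = 0.1221 um^2/s
population 2: fraction 0.315, D = 0.5207 um^2/s
max |histogram residual| = 0.0022
```

The generative truth here is fractions (0.34, 0.36, 0.30) with
D = (0.023, 0.128, 0.6) μm²/s: the slow and intermediate populations —
the two coefficients that anchor the biology (target-bound vs
DNA-scanning complexes) — come back within a few per cent, while the
mobile coefficient is biased low because wall reflections in a
0.5-μm-radius cell compress the largest jumps.  The residual bound
shows the three-component model describes the jump-distance histogram
to within ±0.02 per bin.

## Command line

```sh
smmtracks simulate --preset wildtype --seed 1 --out runs/wt
smmtracks analyze --tracks runs/wt/tracks.tsv \
    --geometry runs/wt/geometry.tsv --foci runs/wt/foci.tsv \
    --k 3 --out runs/wt/analysis
smmtracks report --results runs/wt/analysis
```

`simulate` writes the interface tables (tracks, foci, geometry, truth,
provenance record; `--render` adds a 16-bit TIFF stack); `analyze` runs
filter → mixture fits (`--global` shares D across conditions, passed as
repeated `label=path` arguments) → MSD → density maps → dwelling/foci →
distance histograms; `report` renders the figure set (jump-distance
histograms with residual panels, fraction-vs-D bubble plot, MSD curves,
standardized-cell heat maps, distance histograms).

## Analysis scripts

Numbered drivers under `analysis/` rebuild the full study on synthetic
data, writing tables under `results/`: `01_simulate_conditions.py`
(all condition presets; the plasmid conditions as two-channel cells
sharing replisome foci), `02_diffusion_fits.py` (global mixture fits
and MSD summaries), `03_spatial_maps.py` (standardized-cell densities),
`04_focus_proximity.py` (dwelling foci and nearest-focus histograms),
`05_recovery_benchmark.py` (parameter-recovery spread over seeds).

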