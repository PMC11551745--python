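#!/usr/bin/env python
"""Simulate the experimental conditions with known ground truth.

Generates one synthetic SMM dataset per condition preset — the crRNP
(green-channel) conditions wildtype / high_copy_plasmid /
nontarget_plasmid / target_plasmid and the DnaX (red-channel) conditions
dnax_nontarget / dnax_target — and writes the standard interface tables
(tracks, foci, geometry, generative truth) under results/sim/<condition>/.

The two recombinant plasmid conditions are simulated as two-channel
cells: the DnaX (red) channel is simulated first and its true focus
positions are injected into the paired crRNP (green) simulation, so
anchored green complexes sit at the red channel's replisome foci as
they do in a real cell.
"""

from pathlib import Path

from smmtracks import preset, simulate_tracks, write_foci, write_geometries, write_tracks

SEED = 1
N_CELLS = 60
SINGLE = ["wildtype", "high_copy_plasmid"]
PAIRS = {"nontarget_plasmid": "dnax_nontarget",
         "target_plasmid": "dnax_target"}
OUT = Path(__file__).resolve().parent.parent / "results" / "sim"


def _write(out, cfg, tracks, truth, red_tracks=None):
    out.mkdir(parents=True, exist_ok=True)
    write_tracks(tracks, out / "tracks.tsv")
    write_foci(truth.foci, out / "foci.tsv")
    write_geometries({c: cfg.geometry for c in range(cfg.n_cells)},
                     out / "geometry.tsv")
    truth.molecules.to_csv(out / "truth_molecules.tsv", sep="\t", index=False)
    if red_tracks is not None:
        write_tracks(red_tracks, out / "dnax_tracks.tsv")


def _report(name, cfg, tracks):
    n_steps = int(tracks.n_steps().sum())
    print(f"{name:18s} {tracks.n_tracks:4d} tracks, "
          f"{n_steps:6d} adjacent-frame steps "
          f"(slow fraction truth {cfg.mixture.fractions[0]:.2f})")


def main() -> None:
    seed = SEED
    for name in SINGLE:
        cfg = preset(name, seed=seed, n_cells=N_CELLS)
        tracks, truth = simulate_tracks(cfg)
        _write(OUT / name, cfg, tracks, truth)
        _report(name, cfg, tracks)
        seed += 1
    for green_name, red_name in PAIRS.items():
        red_cfg = preset(red_name, seed=seed, n_cells=N_CELLS)
        red_tracks, red_truth = simulate_tracks(red_cfg)
        _write(OUT / red_name, red_cfg, red_tracks, red_truth)
        _report(red_name, red_cfg, red_tracks)
        green_cfg = preset(green_name, seed=seed + 1, n_cells=N_CELLS)
        green_tracks, green_truth = simulate_tracks(green_cfg,
                                                    foci=red_truth.foci)
        _write(OUT / green_name, green_cfg, green_tracks, green_truth,
               red_tracks=red_tracks)
        _report(green_name, green_cfg, green_tracks)
        seed += 2


if __name__ == "__main__":
    main()
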