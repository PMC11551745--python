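#!/usr/bin/env python
"""Standardized-cell track-density maps per condition.

Projects every simulated localization into the normalized cell frame and
pools a track-density histogram per condition.  Reports how much
probability mass sits in the polar caps (|long axis| > 0.3) versus the
mid-cell (nucleoid) region — the qualitative contrast between anchored
(plasmid-target) and scanning conditions — and writes
results/spatial/density_map.tsv plus one heat-map figure per condition.
"""

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from smmtracks import density_map, read_geometries, read_tracks

BASE = Path(__file__).resolve().parent.parent / "results"
CONDITIONS = ["wildtype", "high_copy_plasmid", "nontarget_plasmid",
              "target_plasmid"]
DT = 0.030


def main() -> None:
    out = BASE / "spatial"
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for cond in CONDITIONS:
        sim = BASE / "sim" / cond
        tracks = read_tracks(sim / "tracks.tsv", DT)
        geoms = read_geometries(sim / "geometry.tsv")
        cmap = density_map(tracks, geoms, grid_shape=(40, 20))
        xc = 0.5 * (cmap.x_edges[:-1] + cmap.x_edges[1:])
        polar = cmap.density[(abs(xc) > 0.3), :].sum()
        print(f"{cond:18s} polar-cap mass {polar:.3f} "
              f"({cmap.n_points} localizations, {cmap.n_cells} cells)")
        yc = 0.5 * (cmap.y_edges[:-1] + cmap.y_edges[1:])
        for i, x in enumerate(xc):
            for j, y in enumerate(yc):
                rows.append({"condition": cond, "x_norm": x, "y_norm": y,
                             "density": cmap.density[i, j]})
        fig, ax = plt.subplots(figsize=(5, 2.5))
        ax.imshow(cmap.density.T, origin="lower", aspect="auto",
                  extent=[-0.5, 0.5, -0.5, 0.5], cmap="inferno")
        ax.set_xlabel("long axis (normalized)")
        ax.set_ylabel("short axis")
        ax.set_title(f"track density: {cond}")
        fig.tight_layout()
        fig.savefig(out / f"density_{cond}.png", dpi=150)
        plt.close(fig)
    pd.DataFrame(rows).to_csv(out / "density_map.tsv", sep="\t", index=False)
    print(f"tables and figures written to {out}")


if __name__ == "__main__":
    main()
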