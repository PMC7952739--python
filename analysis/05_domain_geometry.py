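"""Domain-conformation analytics of the selected model ensembles.

Computes per-model (theta1, theta2, phi, D) tables for the open- and
closed-state selections, 1-d histograms, 2-d frequency and difference maps,
and the b-b'-superposed averaged COM models with the per-domain shift
between states.  Tables go to results/, figures to results/figures/.
"""

import argparse
import json
from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from cgsaxs.cg_builder import assign_charges
from cgsaxs.cg_simulator import Trajectory, merge_trajectories
from cgsaxs.domain_geometry import (GEOMETRY_COLUMNS, averaged_com_model,
                                    com_shift, frequency_maps, geometry_table)
from cgsaxs.synthetic_data import ToySpec, make_toy_protein


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", default="results")
    args = ap.parse_args()
    out = Path(args.out)
    figdir = out / "figures"
    figdir.mkdir(parents=True, exist_ok=True)

    _, chain, _ = make_toy_protein(ToySpec(seed=args.seed))
    chain = assign_charges(chain)
    trajectories = [Trajectory.load(str(p.with_suffix("")))
                    for p in sorted((out / "trajectories").glob("*.npz"))]
    pool = merge_trajectories(trajectories)

    tables, models = {}, {}
    for name in ("open", "closed"):
        screen = pd.read_csv(out / f"screen_{name}.csv")
        picked = np.nonzero(screen["selected"].to_numpy())[0]
        frames = pool.frames[picked]
        table = geometry_table(chain, frames)
        table.to_csv(out / f"geometry_{name}.csv", index=False)
        tables[name] = table
        models[name] = averaged_com_model(chain, frames, chain.coord)
        summary = table.attrs["summary"]
        print(f"{name} ({len(table)} models): " + ", ".join(
            f"{c} = {m:.1f} +- {s:.1f}" for c, (m, s) in summary.items()))

    shifts = {lbl: com_shift(models["open"], models["closed"], lbl)
              for lbl in ("a", "ap")}
    print(f"averaged-COM shift open vs closed: a {shifts['a']:.1f} A, "
          f"a' {shifts['ap']:.1f} A")
    with open(out / "com_shifts.json", "w") as fh:
        json.dump({k: round(v, 2) for k, v in shifts.items()}, fh, indent=1)

    # 1-d histograms
    fig, axes = plt.subplots(2, 2, figsize=(9, 7))
    bins = {"theta1": 5.0, "theta2": 5.0, "phi": 10.0, "D": 1.0}
    for ax, col in zip(axes.ravel(), GEOMETRY_COLUMNS):
        lo = min(t[col].min() for t in tables.values())
        hi = max(t[col].max() for t in tables.values())
        edges = np.arange(np.floor(lo), hi + bins[col], bins[col])
        for name, color in (("open", "tab:red"), ("closed", "tab:blue")):
            w = np.full(len(tables[name]), 1.0 / len(tables[name]))
            ax.hist(tables[name][col], bins=edges, weights=w, alpha=0.5,
                    color=color, label=name)
        ax.set_xlabel(col)
        ax.set_ylabel("frequency")
        ax.legend()
    fig.tight_layout()
    fig.savefig(figdir / "geometry_histograms.png", dpi=150)

    # 2-d maps and difference
    map_o, map_c, diff, xe, ye = frequency_maps(tables["open"],
                                                tables["closed"])
    np.savetxt(out / "freq_diff_theta2_D.csv", diff, delimiter=",")
    fig, axes = plt.subplots(1, 3, figsize=(13, 4), sharey=True)
    for ax, (m, title) in zip(axes, ((map_o, "open"), (map_c, "closed"),
                                     (diff, "open - closed"))):
        im = ax.pcolormesh(xe, ye, m.T,
                           cmap="RdBu_r" if "-" in title else "viridis")
        ax.set_title(title)
        ax.set_xlabel("theta2 [deg]")
        fig.colorbar(im, ax=ax)
    axes[0].set_ylabel("D [A]")
    fig.tight_layout()
    fig.savefig(figdir / "frequency_maps.png", dpi=150)
    print(f"tables, shifts and figures written under {out}/")


if __name__ == "__main__":
    main()
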