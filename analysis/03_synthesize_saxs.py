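"""Synthesize aggregate-contaminated SAXS observations and refine them.

For each sub-state ensemble this script builds the noisy "observed" profile
(96/3/1 wt% monomer/dimer/trimer mixture), applies the aggregate correction
to recover the monomer curve, and tabulates Guinier radii before/after the
correction against the known truth.
"""

import argparse
from pathlib import Path

import pandas as pd

from cgsaxs.cg_builder import assign_charges
from cgsaxs.cg_simulator import Trajectory
from cgsaxs.saxs_calc import extract_monomer_profile, guinier_fit
from cgsaxs.structure_io import write_saxs
from cgsaxs.synthetic_data import ExperimentSpec, ToySpec, make_toy_protein, \
    synthesize_experiment


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", default="results")
    args = ap.parse_args()
    out = Path(args.out)
    traj_dir = out / "trajectories"

    _, chain, _ = make_toy_protein(ToySpec(seed=args.seed))
    chain = assign_charges(chain)

    rows = []
    for k, name in enumerate(("open", "closed")):
        traj = Trajectory.load(str(traj_dir / name))
        spec = ExperimentSpec(seed=args.seed + 1 + k)
        observed, truth, mixture = synthesize_experiment(traj, chain, spec)
        corrected = extract_monomer_profile(observed, mixture,
                                            guinier_fit(observed).rg)
        for tag, prof in (("observed", observed), ("truth", truth),
                          ("corrected", corrected)):
            write_saxs(prof, str(out / f"saxs_{name}_{tag}.dat"))
        rg_t = guinier_fit(truth).rg
        rg_o = guinier_fit(observed).rg
        rg_c = guinier_fit(corrected).rg
        rows.append({"state": name, "rg_truth": rg_t, "rg_contaminated": rg_o,
                     "rg_corrected": rg_c,
                     "recovery_error_pct": 100 * (rg_c - rg_t) / rg_t})
        print(f"{name}: Rg truth {rg_t:.2f} A, contaminated {rg_o:.2f} A, "
              f"corrected {rg_c:.2f} A "
              f"({100 * (rg_c - rg_t) / rg_t:+.2f}% vs truth)")
    pd.DataFrame(rows).to_csv(out / "guinier_summary.csv", index=False)
    print(f"profiles and guinier_summary.csv written under {out}/")


if __name__ == "__main__":
    main()
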