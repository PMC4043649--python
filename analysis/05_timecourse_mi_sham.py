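#!/usr/bin/env python
"""Post-operative monocyte kinetics: infarction vs sham vs sampling control.

Simulates the sequential study (15 MI, 7 sham, 4 non-operated sampling
controls, sampled at days 0-7, 14, 21), computes each animal's
baseline-subtracted (delta) kinetics, and tests MI against sham day by day
with Bonferroni correction.

What it finds: an early dip (most pronounced for non-classical monocytes
and eosinophils) followed by classical and non-classical monocytosis - but
MI and sham trajectories are statistically indistinguishable at these group
sizes because the generator gives both groups the same surgery-driven
kinetics, while the sampling controls stay flat.  The systemic monocyte
response is a sham-surgery effect, not an infarct-size readout.

Writes results/delta_kinetics.csv and results/mi_sham_tests.csv.
"""

import argparse
import os
import sys

sys.path.insert(0, os.path.join(os.path.dirname(__file__), "..", "src"))

from cytovar.experiments import mi_sham_ctrl_experiment  # noqa: E402

RESULTS = os.path.join(os.path.dirname(__file__), "..", "results")


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--acquisition-fraction", type=float, default=0.5,
                        help="fraction of each tube acquired (counts are invariant)")
    args = parser.parse_args()
    os.makedirs(RESULTS, exist_ok=True)

    out = mi_sham_ctrl_experiment(
        seed=args.seed, acquisition_fraction=args.acquisition_fraction
    )
    out["group_kinetics"].to_csv(
        os.path.join(RESULTS, "delta_kinetics.csv"), index=False
    )
    out["tests"].to_csv(os.path.join(RESULTS, "mi_sham_tests.csv"), index=False)

    kin = out["group_kinetics"]
    cl = kin[(kin["subset"] == "classical_mono")]
    print("Classical-monocyte delta (cells/ul) by group and day:")
    print(
        cl.pivot(index="day", columns="group", values="mean").round(1).to_string()
    )
    tests = out["tests"]
    n_sig = int((tests["p_adjusted"] < 0.05).sum())
    print(f"\nMI vs SHAM per-day tests (Bonferroni): {n_sig} of {len(tests)} "
          "significant at alpha = 0.05")
    print(f"min adjusted p = {tests['p_adjusted'].min():.3f}")


if __name__ == "__main__":
    main()
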