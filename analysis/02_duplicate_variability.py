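#!/usr/bin/env python
"""Technical (inter-assay) variability from duplicate acquisitions.

Simulates 12 animals whose blood draw is stained and acquired twice with
independent technical noise, runs all 24 acquisitions through the full
pipeline, and reports the per-subset inter-assay CV (mean over animals of
the per-pair CVs).

What it finds: duplicate-level CVs of a few percent (about 2% for
classical monocytes, 4-5% for the sparser non-classical subset and
eosinophils) - an order of magnitude below the between-animal biological
CVs of analysis 01, so the cohort dispersion is biological, not assay
instability.

Writes results/inter_assay_cv.csv.
"""

import argparse
import os
import sys

sys.path.insert(0, os.path.join(os.path.dirname(__file__), "..", "src"))

from cytovar.experiments import duplicate_cv_experiment  # noqa: E402

RESULTS = os.path.join(os.path.dirname(__file__), "..", "results")


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--replicates", type=int, default=4,
                        help="replicate 12-pair experiments averaged for the report")
    args = parser.parse_args()
    os.makedirs(RESULTS, exist_ok=True)

    out = duplicate_cv_experiment(seed=args.seed, n_pairs=12,
                                  n_replicates=args.replicates)
    frame = out["per_replicate"].mean().rename("inter_assay_cv_pct").to_frame()
    frame.index.name = "subset"
    frame.to_csv(os.path.join(RESULTS, "inter_assay_cv.csv"))

    print(f"12 duplicate pairs x {args.replicates} replicate experiments "
          f"(seed {args.seed}).")
    print("\nInter-assay CV (%), mean of per-pair CVs:")
    print(frame.round(2).to_string())


if __name__ == "__main__":
    main()
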