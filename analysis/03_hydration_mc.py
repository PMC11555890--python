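#!/usr/bin/env python
"""Reduced-scale Monte Carlo hydration structure of the pristine tube.

Runs the multi-seed Metropolis campaign (TIP3P water, 0.993 g/cm3, 298 K,
+-0.13 A / +-10 deg production moves) around the fixed (9,0) nanotube and
computes the cylindrical water RDF: location of the first exterior shell and
convergence of g(r) to the bulk limit beyond 12 A.

Writes results/hydration/rdf_pooled.csv, per-seed RDFs, and a summary.
"""

import json
from pathlib import Path

import numpy as np

from nanosolv.pipeline import hydration_study

OUT = Path(__file__).resolve().parents[1] / "results" / "hydration"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    study = hydration_study(seeds=(1, 2, 3, 4))
    pooled = study["pooled_profile"]
    pooled.to_frame().to_csv(OUT / "rdf_pooled.csv", index=False)
    for seed, run in zip((1, 2, 3, 4), study["runs"]):
        run["profile"].to_frame().to_csv(OUT / f"rdf_seed{seed}.csv", index=False)

    far = pooled.bin_centers > 12.0
    summary = {
        "tube_radius": study["tube_radius"],
        "per_seed_peaks": study["per_seed_peaks"],
        "majority_peak": study["majority_peak"],
        "pooled_peak": study["pooled_peak"],
        "pooled_peak_g": study["pooled_peak_g"],
        "bulk_converged_beyond_12A": bool(study["bulk_converged"]),
        "far_field_mean_abs_dev": float(np.mean(np.abs(pooled.g_values[far] - 1))),
        "acceptance_ratios": [r["result"].acceptance_ratio for r in study["runs"]],
        "n_waters": [r["system"].n_waters for r in study["runs"]],
    }
    (OUT / "summary.json").write_text(json.dumps(summary, indent=2))

    print(f"tube radius {summary['tube_radius']:.2f} A")
    print(f"first exterior shell per seed: {summary['per_seed_peaks']} A")
    print(f"majority peak: {summary['majority_peak']} A from the axis "
          f"({summary['majority_peak'] - summary['tube_radius']:.2f} A above the wall)")
    print(f"g(r) flat at 1 +- 0.1 beyond 12 A: {summary['bulk_converged_beyond_12A']}"
          f" (mean |g-1| = {summary['far_field_mean_abs_dev']:.3f})")
    print(f"production acceptance ratios: "
          f"{[round(a, 3) for a in summary['acceptance_ratios']]}")
    print(f"outputs in {OUT}")


if __name__ == "__main__":
    main()
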