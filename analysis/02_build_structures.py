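#!/usr/bin/env python
"""Generate every structure the simulations consume and write them out.

Builds the (9,0) nanotube, its OH- and COOH-functionalized variants, the
rigid drug surrogate with its Mulliken charge map, the four drug-carrier
complexes, and a solvated example system, reporting the key geometric
checks (atom counts, tube radius, contact distances, water counts).

Writes results/structures/*.{xyz,pdb}.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from nanosolv.io import write_structure
from nanosolv.pipeline import RunConfig, build_system, bundled_table
from nanosolv.structures import (
    SimulationBox,
    assign_charges,
    build_drug_surrogate,
    build_zigzag_cnt,
    functionalize,
    make_complex,
    water_count_for_density,
    zigzag_radius,
)

OUT = Path(__file__).resolve().parents[1] / "results" / "structures"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cnt = build_zigzag_cnt(9, 5)
    length = cnt.positions[:, 2].max() - cnt.positions[:, 2].min()
    print(f"(9,0) tube: {cnt.n_atoms} atoms, radius "
          f"{zigzag_radius(9, 1.455):.3f} A, realized length {length:.2f} A")
    write_structure(cnt, OUT / "cnt.xyz")

    charges = pd.read_csv(bundled_table("mulliken_charges.csv")).set_index("species")
    site = int(np.argmin(np.abs(cnt.positions[:, 2])))
    drug = build_drug_surrogate()

    for group, species in (("OH", "CNT-OH"), ("COOH", "CNT-COOH")):
        carrier = functionalize(cnt, group, site)
        print(f"{species}: {carrier.n_atoms} atoms")
        write_structure(carrier, OUT / f"{species.lower()}.xyz")
        for bind in ("CO", "PY"):
            row = charges.loc[f"{species}-D({bind})"]
            posed = assign_charges(
                drug, {"O4": row["q_O4"], "N_py": row["q_N"]}, neutralize=True
            )
            cx = make_complex(posed, carrier, bind)
            tag = "O4" if bind == "CO" else "N_py"
            d = np.linalg.norm(cx.labeled_position(tag) - cx.labeled_position("H3"))
            print(f"  {species}-D({bind}): {cx.n_atoms} atoms, "
                  f"{tag}...H3 = {d:.2f} A")
            write_structure(cx, OUT / f"{species.lower()}-d{bind.lower()}.pdb")

    box = SimulationBox.cubic(50.0)
    print(f"50 A cube at 0.993 g/cm3 holds "
          f"{water_count_for_density(box, 0.993)} waters (closed form)")

    system = build_system(RunConfig(carrier="cnt", box_edge=30.0, seed=1))
    print(f"solvated 30 A example: {system.n_waters} waters around the tube")
    write_structure(system, OUT / "cnt_solvated.pdb")
    print(f"structures written to {OUT}")


if __name__ == "__main__":
    main()
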