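#!/usr/bin/env python
"""Projection-approximation + TJM-scaled CCS of SOD1 structures.

Run with locally downloaded PDB files (e.g. 1E9P for the holo-dimer
crystal structure, 1L3N for the NMR ensemble, 1RK7 for the apo monomer);
coordinate files are not redistributed with this repository.  For each
structure the orientation-averaged projected area of the atom-sphere union
is estimated by Monte-Carlo sampling, scaled to a trajectory-method-like
value, and compared with the reported measured CCS.

Example:  python analysis/06_structure_ccs.py path/to/1E9P.pdb
"""

import argparse
import json
from pathlib import Path

import numpy as np

from sodims.structure import pa_ccs, read_structure
from sodims.unfolding import percent_difference

#: reported platform CCS values to compare against, per structure
REFERENCE_MEASURED = {
    "1E9P": [("DTIMS holo-dimer 10+", 2693.5), ("TIMS holo-dimer 10+", 2629.0)],
    "1L3N": [("DTIMS holo-dimer 10+", 2693.5), ("TIMS holo-dimer 10+", 2629.0)],
    "1RK7": [("DTIMS apo-monomer 7+", 1711.0)],
}


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("pdb_files", nargs="+", type=Path)
    ap.add_argument("--model", default="first",
                    help="'first', 'all' (ensemble average), or model index")
    ap.add_argument("--orientations", type=int, default=64)
    ap.add_argument("--samples", type=int, default=8000)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    for path in args.pdb_files:
        models = read_structure(path.read_text(), model_selection=args.model)
        if not isinstance(models, list):
            models = [models]
        estimates = [
            pa_ccs(m, n_orientations=args.orientations, n_samples=args.samples,
                   seed=args.seed)
            for m in models
        ]
        pa = float(np.mean([e.pa_ccs for e in estimates]))
        tjm = float(np.mean([e.tjm_ccs for e in estimates]))
        sd = float(np.hypot.reduce([e.sd for e in estimates]) / len(estimates))
        stem = path.stem.upper()
        print(f"{stem}: {len(models)} model(s), "
              f"{len(models[0].elements)} atoms -> PA {pa:,.0f} A^2, "
              f"TJM {tjm:,.0f} +- {1.14 * sd:,.0f} A^2")
        for label, measured in REFERENCE_MEASURED.get(stem, []):
            diff = percent_difference(tjm, measured)
            print(f"  vs {label} ({measured:,.1f} A^2): {diff:.1f} % difference")
        (args.out / f"structure_ccs_{stem}.json").write_text(
            json.dumps([json.loads(e.to_json()) for e in estimates], indent=1)
        )


if __name__ == "__main__":
    main()
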