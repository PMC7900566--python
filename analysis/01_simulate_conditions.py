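#!/usr/bin/env python
"""Simulate the tune-mix calibrant frame and the three SOD1 solution
conditions (native / intermediate / harsh), writing frames + truth tables
under results/frames/.

The three conditions emulate increasing acid/organic denaturation: the
native buffer keeps the holo-dimer envelope (10+-12+), the intermediate
condition adds extended dimers, higher-charge holo-monomers, and the
single-metal monomer, and the harsh condition is dominated by the
apo-monomer up to 16+.
"""

import argparse
from pathlib import Path

from sodims.calibration import load_reference_calibrants
from sodims.synthetic import (
    InstrumentTruth,
    condition_presets,
    synth_calibrant_frame,
    synth_protein_frame,
)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--noise-sd", type=float, default=0.0)
    ap.add_argument("--out", type=Path, default=Path("results/frames"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    truth = InstrumentTruth()
    cals = load_reference_calibrants()
    frame, tt = synth_calibrant_frame(
        truth, [(c.mz, c.charge, c.reference_ccs) for c in cals],
        noise_sd=args.noise_sd, seed=args.seed,
    )
    frame.to_csv(args.out / "tunemix.csv")
    tt.to_csv(args.out / "tunemix_truth.csv", index=False)
    print(f"tune mix: {len(cals)} calibrant ions, arrival times "
          f"{tt.arrival_time_ms.min():.1f}-{tt.arrival_time_ms.max():.1f} ms")

    for i, cond in enumerate(condition_presets()):
        cond.noise_sd = args.noise_sd
        frame, tt = synth_protein_frame(cond, truth, seed=args.seed + 1 + i)
        frame.to_csv(args.out / f"{cond.name}.csv")
        tt.to_csv(args.out / f"{cond.name}_truth.csv", index=False)
        species = ", ".join(sorted(tt.form.unique()))
        print(f"{cond.name}: {len(tt)} conformer peaks over "
              f"{tt.charge.nunique()} charge states ({species})")


if __name__ == "__main__":
    main()
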