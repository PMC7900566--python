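#!/usr/bin/env python
"""Fit the single-field CCS calibration line from the simulated tune-mix
frame and report its diagnostics.

Measured calibrant arrival times are regressed on the Mason-Schamp
abscissa (gamma * CCS / z); the slope/intercept (beta, t_fix) then convert
protein arrival times to CCS in later steps.
"""

import argparse
import json
from pathlib import Path

from sodims.calibration import (
    calibration_report,
    extract_calibrant_times,
    fit_single_field,
    load_reference_calibrants,
)
from sodims.frames import MobilityFrame


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--frames", type=Path, default=Path("results/frames"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    frame = MobilityFrame.from_csv(args.frames / "tunemix.csv")
    cals = load_reference_calibrants()
    measured = extract_calibrant_times(frame, cals)
    calib = fit_single_field(measured)
    report = calibration_report(calib, measured)

    args.out.mkdir(parents=True, exist_ok=True)
    calib.to_json(args.out / "calibration.json")
    (args.out / "calibration_report.json").write_text(
        json.dumps(report, indent=1)
    )
    print(f"beta = {calib.beta:.6f} ms per (A^2 sqrt(Da)/z), "
          f"t_fix = {calib.t_fix:.4f} ms, R^2 = {calib.r_squared:.8f}")
    print(f"max |residual| = {report['max_abs_residual_ms']:.2e} ms; "
          f"max back-calculated CCS error = "
          f"{max(abs(e) for e in report['ccs_back_error_percent']):.2e} %")
    print("fit OK" if report["fit_ok"] else "fit FLAGGED (R^2 below threshold)")


if __name__ == "__main__":
    main()
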