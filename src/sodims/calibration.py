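"""Single-field CCS calibration for drift-tube IMS.

The Mason-Schamp equation at a single fixed field reduces to a linear
relation between arrival time and a mass/charge-scaled CCS term:

    t_A = (beta / z) * sqrt(m_i / (m_i + m_beta)) * CCS + t_fix

where ``m_i`` is the ion mass, ``m_beta`` the drift-gas mass, ``beta`` the
mobility slope and ``t_fix`` the mobility-independent transit time.  A set
of well-characterised tune-mix calibrant ions with reference nitrogen CCS
values is fit by ordinary least squares, and the resulting line converts
measured arrival times of analyte ions into CCS.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path

import numpy as np
from scipy import stats

from .constants import N2_MASS, PROTON_MASS
from .frames import MobilityFrame, refine_apex

__all__ = [
    "CalibrantIon",
    "SingleFieldCalibration",
    "SingularFitError",
    "fit_single_field",
    "drift_to_ccs",
    "ccs_to_drift",
    "calibration_report",
    "extract_calibrant_times",
    "load_reference_calibrants",
    "read_calibrant_table",
]


class SingularFitError(ValueError):
    """Too few or degenerate calibrants for a regression."""


@dataclass(frozen=True)
class CalibrantIon:
    """One tune-mix ion: m/z, charge, reference N2 CCS and measured time."""

    mz: float
    charge: int
    reference_ccs: float  # A^2 in N2
    arrival_time: float = float("nan")  # ms

    def __post_init__(self) -> None:
        if self.mz <= 0 or self.charge < 1 or self.reference_ccs <= 0:
            raise ValueError("mz, charge and reference_ccs must be positive")
        if self.ion_mass <= 0:
            raise ValueError("implied ion mass is non-positive")

    @property
    def ion_mass(self) -> float:
        # positive mode, protonation only: m = z * (mz - m_p)
        return self.charge * (self.mz - PROTON_MASS)


@dataclass
class SingleFieldCalibration:
    beta: float  # ms per (A^2 * sqrt(Da ratio) / charge)
    t_fix: float  # ms
    gas_mass: float  # Da
    r_squared: float
    residuals_ms: list[float] = field(default_factory=list)

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(asdict(self), indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, text_or_path: str | Path) -> "SingleFieldCalibration":
        p = Path(str(text_or_path))
        text = p.read_text() if p.exists() else str(text_or_path)
        return cls(**json.loads(text))


def _gamma(ion_mass: float | np.ndarray, gas_mass: float) -> float | np.ndarray:
    """Reduced-mass factor sqrt(m/(m+m_beta)); in (0,1), increasing in m."""
    return np.sqrt(ion_mass / (ion_mass + gas_mass))


def _abscissa(c: CalibrantIon, gas_mass: float) -> float:
    return _gamma(c.ion_mass, gas_mass) * c.reference_ccs / c.charge


def fit_single_field(
    calibrants: list[CalibrantIon],
    gas_mass: float = N2_MASS,
    weights: np.ndarray | None = None,
) -> SingleFieldCalibration:
    """Least squares of arrival time on the scaled-CCS abscissa.

    Unweighted OLS by default, matching the standardized single-field
    protocol; per-ion ``weights`` enable a weighted fit.
    """
    if len(calibrants) < 2:
        raise SingularFitError("need >= 2 calibrants")
    x = np.array([_abscissa(c, gas_mass) for c in calibrants])
    t = np.array([c.arrival_time for c in calibrants])
    if np.any(~np.isfinite(t)):
        raise ValueError("calibrants have unmeasured (NaN) arrival times")
    if np.ptp(x) == 0.0:
        raise SingularFitError("degenerate abscissae: all calibrants identical")
    if weights is None:
        res = stats.linregress(x, t)
        slope, intercept = float(res.slope), float(res.intercept)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != x.shape or np.any(w < 0) or w.sum() == 0:
            raise ValueError("weights must be nonnegative, one per calibrant")
        slope, intercept = np.polyfit(x, t, 1, w=np.sqrt(w))
        slope, intercept = float(slope), float(intercept)
    fitted = slope * x + intercept
    ss_res = float(np.sum((t - fitted) ** 2))
    ss_tot = float(np.sum((t - t.mean()) ** 2))
    return SingleFieldCalibration(
        beta=slope,
        t_fix=intercept,
        gas_mass=float(gas_mass),
        r_squared=max(0.0, 1.0 - ss_res / ss_tot) if ss_tot > 0 else 1.0,
        residuals_ms=list(t - fitted),
    )


def drift_to_ccs(
    arrival_time: float,
    ion_mass: float,
    charge: int,
    calib: SingleFieldCalibration,
) -> float:
    """Invert the calibration line: arrival time (ms) -> CCS (A^2).

    An arrival time below ``t_fix`` would imply negative mobility; it is
    flagged with a warning and returned as NaN rather than a silent
    negative CCS.
    """
    if ion_mass <= 0 or charge < 1:
        raise ValueError("ion_mass and charge must be positive")
    if arrival_time < calib.t_fix:
        warnings.warn(
            f"arrival time {arrival_time:.3f} ms < t_fix {calib.t_fix:.3f} ms: "
            "negative mobility; returning NaN",
            stacklevel=2,
        )
        return float("nan")
    return (
        (arrival_time - calib.t_fix)
        * charge
        / (calib.beta * _gamma(ion_mass, calib.gas_mass))
    )


def ccs_to_drift(
    ccs: float, ion_mass: float, charge: int, calib: SingleFieldCalibration
) -> float:
    """Forward calibration line: CCS (A^2) -> arrival time (ms)."""
    if ion_mass <= 0 or charge < 1:
        raise ValueError("ion_mass and charge must be positive")
    if ccs < 0:
        raise ValueError("ccs must be >= 0")
    return calib.beta / charge * _gamma(ion_mass, calib.gas_mass) * ccs + calib.t_fix


def calibration_report(
    calib: SingleFieldCalibration,
    calibrants: list[CalibrantIon],
    r_squared_threshold: float = 0.999,
) -> dict:
    """Fit diagnostics: residuals, per-ion back-calculated CCS errors, flags.

    The report is JSON-serialisable and round-trips through ``json``.
    """
    back_errors = []
    for c in calibrants:
        ccs_back = drift_to_ccs(c.arrival_time, c.ion_mass, c.charge, calib)
        back_errors.append(100.0 * (ccs_back - c.reference_ccs) / c.reference_ccs)
    resid = np.abs(calib.residuals_ms)
    worst = int(np.argmax(resid)) if len(calibrants) else -1
    return {
        "r_squared": calib.r_squared,
        "beta": calib.beta,
        "t_fix": calib.t_fix,
        "gas_mass": calib.gas_mass,
        "n_calibrants": len(calibrants),
        "max_abs_residual_ms": float(resid.max()) if len(calibrants) else 0.0,
        "max_residual_ion_mz": calibrants[worst].mz if len(calibrants) else None,
        "ccs_back_error_percent": back_errors,
        "fit_ok": bool(calib.r_squared >= r_squared_threshold),
        "r_squared_threshold": r_squared_threshold,
    }


def extract_calibrant_times(
    frame: MobilityFrame,
    calibrants: list[CalibrantIon],
    mz_half_width: float | None = None,
) -> list[CalibrantIon]:
    """Measure calibrant arrival times from a tune-mix frame.

    For each calibrant the drift trace in a narrow m/z window around its
    m/z is extracted and the apex refined to sub-bin precision by 3-point
    Gaussian interpolation (exact for noiseless Gaussian peaks).
    """
    out = []
    for c in calibrants:
        if mz_half_width is None:
            res = frame.metadata.get("instrument", {}).get("resolution_mz", 500.0)
            half = 1.2 * c.mz / res
        else:
            half = mz_half_width
        sel = (frame.mz_axis >= c.mz - half) & (frame.mz_axis <= c.mz + half)
        if not sel.any():
            raise ValueError(f"calibrant m/z {c.mz} outside frame m/z axis")
        trace = frame.intensity[:, sel].sum(axis=1)
        i = int(np.argmax(trace))
        apex, _ = refine_apex(frame.drift_axis, trace, i)
        out.append(CalibrantIon(c.mz, c.charge, c.reference_ccs, apex))
    return out


# ------------------------------------------------------------------ tables


def read_calibrant_table(path: str | Path) -> list[CalibrantIon]:
    """Read a calibrant CSV with header ``mz,charge,ccs_n2``."""
    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            out.append(
                CalibrantIon(
                    mz=float(row["mz"]),
                    charge=int(row["charge"]),
                    reference_ccs=float(row["ccs_n2"]),
                )
            )
    if not out:
        raise ValueError(f"no calibrants found in {path}")
    return out


def load_reference_calibrants() -> list[CalibrantIon]:
    """Packaged tune-mix reference table (hexakis-fluoroalkoxy-phosphazene
    ions; single-field nitrogen CCS values from the multi-laboratory
    standardisation of the method).  Used here as a realistic calibrant set
    for synthetic frames; verify against your own tune-mix lot before use
    on real data."""
    ref = resources.files("sodims.data").joinpath("tunemix_ccs_n2.csv")
    with resources.as_file(ref) as path:
        return read_calibrant_table(path)
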