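"""Arrival-time-distribution extraction and conformer analysis.

An ATD is the drift-time trace in a narrow m/z window around one assigned
(species, charge).  Local maxima of the lightly smoothed trace are conformer
candidates; apexes are refined to sub-bin precision, abundances come from
valley-to-valley integration, and apex times convert to CCS through the
single-field calibration.  A valley that stays well above baseline between
two conformers indicates unresolved intermediate structures.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

from .calibration import SingleFieldCalibration, drift_to_ccs
from .frames import MobilityFrame, refine_apex

__all__ = [
    "ATD",
    "ConformerPeak",
    "extract_atd",
    "detect_conformers",
    "intermediates_present",
    "atd_to_ccs",
]


@dataclass
class ATD:
    species: str
    charge: int
    drift_axis: np.ndarray  # ms
    intensity: np.ndarray  # >= 0
    mz_window: tuple[float, float]

    def __post_init__(self) -> None:
        self.drift_axis = np.asarray(self.drift_axis, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.drift_axis.shape != self.intensity.shape:
            raise ValueError("drift axis and intensity must have equal length")

    def to_csv(self, path) -> None:
        """Export as ``drift_time_ms,intensity`` CSV."""
        import pandas as pd

        pd.DataFrame(
            {"drift_time_ms": self.drift_axis, "intensity": self.intensity}
        ).to_csv(path, index=False)


@dataclass
class ConformerPeak:
    apex_time: float  # ms
    height: float
    fwhm_ms: float
    relative_abundance: float  # in (0, 1]; sums to <= 1 over an ATD
    ccs: float = float("nan")  # filled by atd_to_ccs
    label: str = ""  # compact / extended / intermediate-region
    flags: set[str] = field(default_factory=set)


def extract_atd(
    frame: MobilityFrame,
    mz_center: float,
    half_width: float,
    species: str = "",
    charge: int = 0,
) -> ATD:
    """Extracted-ion mobilogram: sum over m/z bins in the window."""
    sel = (frame.mz_axis >= mz_center - half_width) & (
        frame.mz_axis <= mz_center + half_width
    )
    if not sel.any():
        raise ValueError(
            f"m/z window {mz_center}+-{half_width} does not intersect the frame"
        )
    return ATD(
        species=species,
        charge=charge,
        drift_axis=frame.drift_axis.copy(),
        intensity=frame.intensity[:, sel].sum(axis=1),
        mz_window=(mz_center - half_width, mz_center + half_width),
    )


def _baseline(trace: np.ndarray) -> float:
    # constant baseline: 5th percentile of the trace
    return float(np.percentile(trace, 5.0))


def detect_conformers(
    atd: ATD,
    min_prominence_frac: float = 0.05,
    smoothing_window: int = 3,
) -> list[ConformerPeak]:
    """Detect conformer peaks in an ATD.

    The trace is smoothed with a short moving average; local maxima with
    prominence >= ``min_prominence_frac`` x the global maximum are kept.
    Apexes are refined by 3-point Gaussian interpolation and abundances are
    baseline-subtracted valley-to-valley areas, normalised to sum to 1.
    An all-zero trace yields an empty list.
    """
    y = atd.intensity.astype(float)
    if y.size == 0 or y.max() <= 0:
        return []
    if smoothing_window > 1:
        kernel = np.ones(smoothing_window) / smoothing_window
        y = np.convolve(y, kernel, mode="same")
    base = _baseline(y)
    ys = y - base
    idx, props = signal.find_peaks(ys, prominence=min_prominence_frac * ys.max())
    if idx.size == 0:
        return []
    widths = signal.peak_widths(ys, idx, rel_height=0.5)[0]
    dt = atd.drift_axis[1] - atd.drift_axis[0]
    # valley-to-valley integration boundaries: minima between adjacent apexes
    bounds = [0]
    for a, b in zip(idx, idx[1:]):
        bounds.append(a + int(np.argmin(ys[a:b])))
    bounds.append(ys.size - 1)
    areas = np.array(
        [np.trapezoid(np.clip(ys[lo : hi + 1], 0, None)) for lo, hi in zip(bounds, bounds[1:])]
    )
    total = areas.sum()
    peaks = []
    for k, i in enumerate(idx):
        apex, height = refine_apex(atd.drift_axis, ys, int(i))
        peaks.append(
            ConformerPeak(
                apex_time=apex,
                height=height,
                fwhm_ms=float(widths[k] * dt),
                relative_abundance=float(areas[k] / total) if total > 0 else 0.0,
            )
        )
    return peaks


def intermediates_present(
    atd: ATD,
    peaks: list[ConformerPeak],
    valley_threshold_frac: float = 0.10,
) -> tuple[bool, dict]:
    """Do the valleys between conformers stay above baseline?

    True iff the minimum (baseline-subtracted) intensity between some pair
    of adjacent apexes exceeds ``valley_threshold_frac`` x the smaller apex
    height.  With fewer than two peaks the question is undefined; returns
    ``(False, {"reason": ...})``.
    """
    if len(peaks) < 2:
        return False, {"reason": "fewer than two conformer peaks", "valleys": []}
    base = _baseline(atd.intensity)
    ys = atd.intensity - base
    order = sorted(peaks, key=lambda p: p.apex_time)
    valleys = []
    present = False
    for p1, p2 in zip(order, order[1:]):
        sel = (atd.drift_axis > p1.apex_time) & (atd.drift_axis < p2.apex_time)
        if not sel.any():
            continue
        vmin = float(ys[sel].min())
        smaller = min(p1.height, p2.height)
        ratio = vmin / smaller if smaller > 0 else 0.0
        above = ratio > valley_threshold_frac
        present = present or above
        valleys.append(
            {
                "between_ms": (p1.apex_time, p2.apex_time),
                "valley_min": vmin,
                "valley_to_apex_ratio": ratio,
                "above_threshold": above,
            }
        )
    return present, {"reason": "", "valleys": valleys}


def atd_to_ccs(
    peaks: list[ConformerPeak],
    ion_mass: float,
    charge: int,
    calib: SingleFieldCalibration,
) -> list[ConformerPeak]:
    """Fill conformer CCS from apex times via the calibration line.

    At fixed mass and charge the CCS ordering equals the apex-time
    ordering (the relation is affine and increasing).
    """
    return [
        replace(p, ccs=drift_to_ccs(p.apex_time, ion_mass, charge, calib))
        for p in peaks
    ]
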