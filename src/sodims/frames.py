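"""Nested drift-time x m/z mobility frames and their on-disk format.

A :class:`MobilityFrame` is the canonical in-memory container for one
acquisition: a dense intensity grid over a uniform arrival-time axis (ms)
and a uniform m/z axis, plus free-form metadata (instrument parameters,
provenance).  On disk a frame is a long-format CSV with header
``drift_time_ms,mz,intensity`` sorted by drift time then m/z, with a JSON
sidecar for the metadata.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["MobilityFrame", "refine_apex"]


@dataclass
class MobilityFrame:
    """Dense 2D intensity map over arrival time (rows) x m/z (columns)."""

    drift_axis: np.ndarray  # ms, shape (n_drift,)
    mz_axis: np.ndarray  # shape (n_mz,)
    intensity: np.ndarray  # shape (n_drift, n_mz), nonnegative
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.drift_axis = np.asarray(self.drift_axis, dtype=float)
        self.mz_axis = np.asarray(self.mz_axis, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.shape != (self.drift_axis.size, self.mz_axis.size):
            raise ValueError(
                f"intensity shape {self.intensity.shape} does not match axes "
                f"({self.drift_axis.size}, {self.mz_axis.size})"
            )

    @property
    def drift_step(self) -> float:
        return float(self.drift_axis[1] - self.drift_axis[0])

    @property
    def mz_step(self) -> float:
        return float(self.mz_axis[1] - self.mz_axis[0])

    def mass_spectrum(self) -> np.ndarray:
        """Marginal m/z spectrum (sum over the drift axis)."""
        return self.intensity.sum(axis=0)

    def mobilogram(self) -> np.ndarray:
        """Marginal arrival-time trace (sum over the m/z axis)."""
        return self.intensity.sum(axis=1)

    # ---------------------------------------------------------------- I/O
    def to_csv(self, path: str | Path, sidecar: bool = True) -> None:
        """Write the long-format CSV (and a metadata JSON sidecar)."""
        path = Path(path)
        n_d, n_m = self.intensity.shape
        df = pd.DataFrame(
            {
                "drift_time_ms": np.repeat(self.drift_axis, n_m),
                "mz": np.tile(self.mz_axis, n_d),
                "intensity": self.intensity.ravel(),
            }
        )
        df.to_csv(path, index=False)
        if sidecar:
            meta = dict(self.metadata)
            meta["drift_axis"] = {
                "start": float(self.drift_axis[0]),
                "step": self.drift_step,
                "n": int(n_d),
            }
            meta["mz_axis"] = {
                "start": float(self.mz_axis[0]),
                "step": self.mz_step,
                "n": int(n_m),
            }
            path.with_suffix(".meta.json").write_text(
                json.dumps(meta, indent=1, sort_keys=True)
            )

    @classmethod
    def from_csv(cls, path: str | Path) -> "MobilityFrame":
        path = Path(path)
        df = pd.read_csv(path)
        drift = np.unique(df["drift_time_ms"].to_numpy())
        mz = np.unique(df["mz"].to_numpy())
        inten = (
            df.sort_values(["drift_time_ms", "mz"])["intensity"]
            .to_numpy()
            .reshape(drift.size, mz.size)
        )
        meta: dict = {}
        sidecar = path.with_suffix(".meta.json")
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
            meta.pop("drift_axis", None)
            meta.pop("mz_axis", None)
        return cls(drift, mz, inten, meta)


def refine_apex(axis: np.ndarray, trace: np.ndarray, i: int) -> tuple[float, float]:
    """Sub-bin apex of a peak whose maximum bin is ``i``.

    Fits the three samples around the maximum with a Gaussian (a parabola in
    log intensity), which is exact for noiseless Gaussian peaks.  Falls back
    to a plain parabola when a flanking sample is non-positive, and to the
    bin centre when the peak sits on the trace boundary.

    Returns ``(position, height)`` in axis units.
    """
    axis = np.asarray(axis, dtype=float)
    trace = np.asarray(trace, dtype=float)
    if i <= 0 or i >= trace.size - 1:
        return float(axis[i]), float(trace[i])
    y0, y1, y2 = trace[i - 1], trace[i], trace[i + 1]
    h = axis[i] - axis[i - 1]
    if min(y0, y1, y2) > 0.0:
        l0, l1, l2 = np.log((y0, y1, y2))
        denom = l0 - 2.0 * l1 + l2
        if denom >= 0.0:  # not locally concave in log space
            return float(axis[i]), float(y1)
        delta = 0.5 * (l0 - l2) / denom
        height = float(np.exp(l1 - 0.25 * (l0 - l2) * delta))
    else:
        denom = y0 - 2.0 * y1 + y2
        if denom >= 0.0:
            return float(axis[i]), float(y1)
        delta = 0.5 * (y0 - y2) / denom
        height = float(y1 - 0.25 * (y0 - y2) * delta)
    delta = float(np.clip(delta, -0.5, 0.5))
    return float(axis[i] + delta * h), height
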