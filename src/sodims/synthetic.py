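"""Forward simulation of nested DTIMS-MS frames with known ground truth.

The generator produces calibrant and protein mobility frames whose peak
positions follow the single-field drift relation

    t_A = (beta / z) * sqrt(m_i / (m_i + m_beta)) * CCS + t_fix

so that every downstream stage — calibration, species assignment, ATD
conformer analysis, unfolding profiling — can be tested against an exact
truth table without any instrument data.

Three condition presets emulate the acid/organic denaturation series used
to unfold bovine Cu/Zn-superoxide dismutase (SOD1):

``native``
    30 mM ammonium acetate.  Dominated by the 10+-12+ holo-dimer envelope
    with a small 6+-8+ holo-monomer population; the 12+ dimer and 6+
    monomer coincide at 2,620 m/z and are separable only by mobility.
``intermediate``
    30% acetonitrile + 100 uM formic acid.  Extended 11+ dimer appears,
    the holo-monomer envelope extends to higher charge states with
    unresolved intermediates, and a single-metal monomer forms.
``harsh``
    30% acetonitrile + 25 mM formic acid.  The apo-monomer dominates with
    the widest charge-state range (7+-16+), reaching 3,608 A^2 at 16+;
    the 11+ dimer shows three conformers (2,735 / 3,237 / 3,556 A^2).

All configured conformer CCS values that the source measurements report
are used verbatim; the remainder are plausible interpolations documented
in docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .constants import N2_MASS
from .frames import MobilityFrame
from .species import SpeciesDefinition, neutral_mass, theoretical_mz

__all__ = [
    "InstrumentTruth",
    "ConformerSpec",
    "ChargeStateSpec",
    "SpeciesMix",
    "ConditionSpec",
    "forward_arrival_time",
    "synth_calibrant_frame",
    "synth_protein_frame",
    "condition_presets",
    "default_hypotheses",
    "APO_MONOMER_MASS",
]

#: Default apo-monomer chain mass (Da).  Chosen so that the holo forms under
#: the charge-neutral metal-substitution convention (k = 2) reproduce the
#: printed native m/z ladder: dimer 3,144 / 2,858 / 2,620; monomer 2,620 /
#: 2,246 / 1,965.
APO_MONOMER_MASS = 15_588.5


@dataclass
class InstrumentTruth:
    """Ground-truth instrument model for the forward simulation.

    ``beta`` and ``t_fix`` are the slope/intercept of the single-field drift
    relation; ``resolution_mz`` is m/FWHM for m/z peaks; ``resolution_drift``
    is t/FWHM for arrival-time peaks (FWHM_drift = t / resolution_drift,
    i.e. the default 33.3 gives a 3% -of-arrival-time FWHM, typical of a
    resolving-power ~50 drift tube).
    """

    beta: float = 0.15  # ms per (A^2 * sqrt(Da ratio) / charge)
    t_fix: float = 0.5  # ms
    gas_mass: float = N2_MASS  # Da
    drift_time_range: tuple[float, float] = (10.0, 70.0)  # ms
    mz_range: tuple[float, float] = (900.0, 3300.0)
    resolution_mz: float = 500.0
    resolution_drift: float = 33.33
    drift_step: float = 0.1  # ms
    mz_step: float = 1.0

    def __post_init__(self) -> None:
        if self.beta <= 0:
            raise ValueError("beta must be > 0")
        if self.t_fix < 0:
            raise ValueError("t_fix must be >= 0")
        if self.gas_mass <= 0:
            raise ValueError("gas_mass must be > 0")
        for name, (lo, hi) in (
            ("drift_time_range", self.drift_time_range),
            ("mz_range", self.mz_range),
        ):
            if not hi > lo:
                raise ValueError(f"{name} must be a nonempty (min, max) interval")

    def drift_axis(self) -> np.ndarray:
        lo, hi = self.drift_time_range
        n = int(round((hi - lo) / self.drift_step)) + 1
        return lo + self.drift_step * np.arange(n)

    def mz_axis(self) -> np.ndarray:
        lo, hi = self.mz_range
        n = int(round((hi - lo) / self.mz_step)) + 1
        return lo + self.mz_step * np.arange(n)

    def sigma_drift(self, t: float) -> float:
        return (t / self.resolution_drift) / 2.354820045

    def sigma_mz(self, mz: float) -> float:
        return (mz / self.resolution_mz) / 2.354820045


@dataclass
class ConformerSpec:
    ccs: float  # A^2
    weight: float  # relative abundance within the charge state

    def __post_init__(self) -> None:
        if self.ccs <= 0:
            raise ValueError("conformer CCS must be > 0")
        if self.weight < 0:
            raise ValueError("conformer weight must be >= 0")


@dataclass
class ChargeStateSpec:
    charge: int
    weight: float  # relative abundance of this charge state
    conformers: list[ConformerSpec]
    #: Fraction in [0, 1) of the smaller flanking apex filled in as a plateau
    #: between adjacent conformers, emulating ATDs that fail to return to
    #: baseline (unresolved intermediate structures).
    valley_fill: float = 0.0

    def __post_init__(self) -> None:
        if self.charge < 1:
            raise ValueError("charge must be >= 1")
        if not 0.0 <= self.valley_fill < 1.0:
            raise ValueError("valley_fill must be in [0, 1)")
        if not self.conformers:
            raise ValueError("charge state needs at least one conformer")


@dataclass
class SpeciesMix:
    species: SpeciesDefinition
    charge_states: list[ChargeStateSpec]

    def __post_init__(self) -> None:
        if not self.charge_states:
            raise ValueError(f"species {self.species.name!r} has zero charge states")


@dataclass
class ConditionSpec:
    """One solution condition: a species mix plus noise settings."""

    name: str
    mixes: list[SpeciesMix]
    baseline: float = 0.0  # constant additive offset
    noise_sd: float = 0.0  # Gaussian sd as a fraction of the tallest peak apex
    total_intensity: float = 1.0e4  # summed counts shared by all peaks

    def __post_init__(self) -> None:
        if not self.mixes:
            raise ValueError("condition needs at least one species")
        w = [cs.weight for mix in self.mixes for cs in mix.charge_states]
        if min(w) < 0 or sum(w) == 0:
            raise ValueError("charge-state weights must be >= 0 and not all zero")


def forward_arrival_time(
    ccs: float, ion_mass: float, charge: int, truth: InstrumentTruth
) -> float:
    """Arrival time (ms) of an ion under the single-field drift relation.

    Strictly increasing in CCS and strictly decreasing in charge at fixed
    CCS and mass; equals ``t_fix`` for a zero-CCS ion.
    """
    if ion_mass <= 0:
        raise ValueError("ion_mass must be > 0")
    if charge < 1:
        raise ValueError("charge must be a positive integer")
    if ccs < 0:
        raise ValueError("ccs must be >= 0")
    gamma = np.sqrt(ion_mass / (ion_mass + truth.gas_mass))
    return truth.beta / charge * gamma * ccs + truth.t_fix


def _add_peak_2d(
    inten: np.ndarray,
    drift_axis: np.ndarray,
    mz_axis: np.ndarray,
    t0: float,
    mz0: float,
    area: float,
    sigma_t: float,
    sigma_mz: float,
) -> None:
    """Add a separable 2D Gaussian whose summed counts equal ``area``."""
    dt = drift_axis[1] - drift_axis[0]
    dm = mz_axis[1] - mz_axis[0]
    # local windows (+-6 sigma) keep generation fast on large grids
    i0 = np.searchsorted(drift_axis, t0 - 6 * sigma_t)
    i1 = np.searchsorted(drift_axis, t0 + 6 * sigma_t)
    j0 = np.searchsorted(mz_axis, mz0 - 6 * sigma_mz)
    j1 = np.searchsorted(mz_axis, mz0 + 6 * sigma_mz)
    if i0 >= i1 or j0 >= j1:
        return
    gt = np.exp(-0.5 * ((drift_axis[i0:i1] - t0) / sigma_t) ** 2)
    gt *= dt / (sigma_t * np.sqrt(2 * np.pi))
    gm = np.exp(-0.5 * ((mz_axis[j0:j1] - mz0) / sigma_mz) ** 2)
    gm *= dm / (sigma_mz * np.sqrt(2 * np.pi))
    inten[i0:i1, j0:j1] += area * np.outer(gt, gm)


def _add_noise(inten: np.ndarray, noise_sd: float, seed: int | None) -> None:
    """Additive Gaussian noise, seeded, scaled per m/z column.

    The sd in each m/z column is ``noise_sd`` x that column's maximum, so
    the per-bin noise amplitude at every peak's apex is ``noise_sd`` x the
    apex height (signal-tracking detector noise); signal-free columns stay
    clean.  Intensities are clipped at zero afterwards.
    """
    if noise_sd <= 0:
        return
    rng = np.random.default_rng(seed)
    col_sd = noise_sd * inten.max(axis=0)
    inten += rng.standard_normal(inten.shape) * col_sd[np.newaxis, :]
    np.clip(inten, 0.0, None, out=inten)


def synth_calibrant_frame(
    truth: InstrumentTruth,
    calibrants: list[tuple[float, int, float]],
    noise_sd: float = 0.0,
    seed: int | None = 0,
    peak_area: float = 1.0e3,
    proton_mass: float = 1.00728,
) -> tuple[MobilityFrame, pd.DataFrame]:
    """Simulate a tune-mix acquisition.

    ``calibrants`` are ``(mz, charge, reference_ccs)`` triples.  One 2D
    Gaussian peak is placed per calibrant at its forward-model arrival time;
    the returned truth table records the exact centres.  Identical seeds
    yield identical frames.
    """
    if not calibrants:
        raise ValueError("calibrant list must not be empty")
    mzs = np.array([c[0] for c in calibrants], dtype=float)
    lo = min(200.0, mzs.min() - 50.0)
    hi = mzs.max() + 100.0
    drift_axis = truth.drift_axis()
    n_mz = int(round((hi - lo) / truth.mz_step)) + 1
    mz_axis = lo + truth.mz_step * np.arange(n_mz)
    inten = np.zeros((drift_axis.size, mz_axis.size))
    rows = []
    for mz, z, ccs in calibrants:
        ion_mass = z * (mz - proton_mass)
        t0 = forward_arrival_time(ccs, ion_mass, z, truth)
        _add_peak_2d(
            inten,
            drift_axis,
            mz_axis,
            t0,
            mz,
            peak_area,
            truth.sigma_drift(t0),
            truth.sigma_mz(mz),
        )
        rows.append(
            {
                "species": f"calibrant_{mz:.3f}",
                "form": "calibrant",
                "charge": z,
                "ccs": ccs,
                "mz": mz,
                "arrival_time_ms": t0,
                "abundance": 1.0 / len(calibrants),
            }
        )
    _add_noise(inten, noise_sd, seed)
    meta = {"kind": "calibrant", "seed": seed, "instrument": asdict(truth)}
    return MobilityFrame(drift_axis, mz_axis, inten, meta), pd.DataFrame(rows)


def synth_protein_frame(
    condition: ConditionSpec,
    truth: InstrumentTruth,
    seed: int | None = 0,
) -> tuple[MobilityFrame, pd.DataFrame]:
    """Simulate one solution condition as a nested DTIMS-MS frame.

    Every (species, charge, conformer) becomes a separable 2D Gaussian at
    (theoretical m/z, forward arrival time).  ``valley_fill`` adds a plateau
    between adjacent conformers of the same charge state so the ATD fails to
    return to baseline.  The truth table is exhaustive: one row per
    conformer peak, with arrival times computed exactly by
    :func:`forward_arrival_time`.
    """
    drift_axis = truth.drift_axis()
    mz_axis = truth.mz_axis()
    inten = np.zeros((drift_axis.size, mz_axis.size))
    rows = []
    total_w = sum(cs.weight for mix in condition.mixes for cs in mix.charge_states)
    for mix in condition.mixes:
        mass = neutral_mass(mix.species)
        for cs in mix.charge_states:
            mz0 = theoretical_mz(mass, cs.charge)
            sigma_mz = truth.sigma_mz(mz0)
            conf_w = sum(c.weight for c in cs.conformers)
            if conf_w == 0:
                raise ValueError(
                    f"{mix.species.name} {cs.charge}+ has all-zero conformer weights"
                )
            apexes = []
            for conf in sorted(cs.conformers, key=lambda c: c.ccs):
                t0 = forward_arrival_time(conf.ccs, mass, cs.charge, truth)
                area = (
                    condition.total_intensity
                    * (cs.weight / total_w)
                    * (conf.weight / conf_w)
                )
                sigma_t = truth.sigma_drift(t0)
                _add_peak_2d(
                    inten, drift_axis, mz_axis, t0, mz0, area, sigma_t, sigma_mz
                )
                apex_height = (
                    area
                    * truth.drift_step
                    * truth.mz_step
                    / (2 * np.pi * sigma_t * sigma_mz)
                )
                apexes.append((t0, apex_height))
                rows.append(
                    {
                        "species": mix.species.name,
                        "form": mix.species.form,
                        "charge": cs.charge,
                        "ccs": conf.ccs,
                        "mz": mz0,
                        "arrival_time_ms": t0,
                        "abundance": conf.weight / conf_w,
                        "charge_weight": cs.weight / total_w,
                    }
                )
            if cs.valley_fill > 0 and len(apexes) > 1:
                # plateau between conformers applied as a pointwise max so the
                # flanking peak shapes (and hence their apexes) are untouched
                # and the fill is a local *minimum* region, never a spurious
                # local maximum
                gm = np.exp(-0.5 * ((mz_axis - mz0) / sigma_mz) ** 2)
                for (t1, h1), (t2, h2) in zip(apexes, apexes[1:]):
                    level = cs.valley_fill * min(h1, h2)
                    sel = (drift_axis > t1) & (drift_axis < t2)
                    inten[sel] = np.maximum(inten[sel], level * gm[np.newaxis, :])
    if condition.baseline > 0:
        inten += condition.baseline
    _add_noise(inten, condition.noise_sd, seed)
    meta = {
        "kind": "protein",
        "condition": condition.name,
        "seed": seed,
        "instrument": asdict(truth),
    }
    truth_df = pd.DataFrame(rows)
    bad = ~truth_df["arrival_time_ms"].between(*truth.drift_time_range)
    if bad.any():
        raise ValueError(
            "configured conformers fall outside the drift-time range:\n"
            f"{truth_df[bad]}"
        )
    return MobilityFrame(drift_axis, mz_axis, inten, meta), truth_df


# --------------------------------------------------------------------------
# Condition presets emulating the three-solution SOD1 denaturation series
# --------------------------------------------------------------------------


def default_hypotheses(
    apo_monomer_mass: float = APO_MONOMER_MASS,
    proton_displacement_per_metal: int = 2,
) -> dict[str, SpeciesDefinition]:
    """The SOD1 species hypothesis set used by presets and the pipeline.

    The single-metal monomer is represented by both Cu-only and Zn-only
    hypotheses (1.83 Da apart), which is what makes the missing-metal
    identity ambiguous at native-protein mass resolution.
    """
    k = proton_displacement_per_metal
    m = apo_monomer_mass

    def sp(name, form, n, ncu, nzn):
        return SpeciesDefinition(
            name=name,
            form=form,
            oligomer_order=n,
            apo_monomer_mass=m,
            n_cu=ncu,
            n_zn=nzn,
            proton_displacement_per_metal=k,
        )

    return {
        "holo-dimer": sp("holo-dimer", "holo-dimer", 2, 2, 2),
        "holo-monomer": sp("holo-monomer", "holo-monomer", 1, 1, 1),
        "single-metal-monomer-cu": sp(
            "single-metal-monomer-cu", "single-metal monomer", 1, 1, 0
        ),
        "single-metal-monomer-zn": sp(
            "single-metal-monomer-zn", "single-metal monomer", 1, 0, 1
        ),
        "apo-monomer": sp("apo-monomer", "apo-monomer", 1, 0, 0),
    }


def _cs(charge, weight, conformers, fill=0.0):
    return ChargeStateSpec(
        charge=charge,
        weight=weight,
        conformers=[ConformerSpec(ccs=c, weight=w) for c, w in conformers],
        valley_fill=fill,
    )


def condition_presets(
    apo_monomer_mass: float = APO_MONOMER_MASS,
) -> list[ConditionSpec]:
    """The three solution-condition presets, ordered native -> harsh.

    Measured conformer CCS values are used verbatim (e.g. 10+ dimer
    2,693.5 A^2; harsh 11+ dimer 2,735 / 3,237 / 3,556 A^2; 16+ apo
    3,608 A^2); unreported high-charge monomer values are interpolations
    chosen so the monomer profile shows four gap-separated elongation
    regions (see docs/methods.md).
    """
    hyp = default_hypotheses(apo_monomer_mass)
    dimer = hyp["holo-dimer"]
    holo = hyp["holo-monomer"]
    sm = hyp["single-metal-monomer-cu"]
    apo = hyp["apo-monomer"]

    native = ConditionSpec(
        name="native",
        mixes=[
            SpeciesMix(
                dimer,
                [
                    _cs(10, 0.26, [(2693.5, 1.0)]),
                    _cs(11, 0.32, [(2743.0, 1.0)]),
                    _cs(12, 0.22, [(2790.0, 1.0)]),
                ],
            ),
            SpeciesMix(
                holo,
                [
                    _cs(6, 0.08, [(1610.0, 1.0)]),
                    _cs(7, 0.07, [(1653.0, 1.0)]),
                    _cs(8, 0.05, [(1700.0, 1.0)]),
                ],
            ),
        ],
    )

    intermediate = ConditionSpec(
        name="intermediate",
        mixes=[
            SpeciesMix(
                dimer,
                [
                    _cs(10, 0.10, [(2700.0, 1.0)]),
                    _cs(11, 0.12, [(2743.0, 0.6), (3237.0, 0.4)]),
                    _cs(12, 0.08, [(2790.0, 1.0)]),
                ],
            ),
            SpeciesMix(
                holo,
                [
                    _cs(6, 0.07, [(1610.0, 1.0)]),
                    _cs(7, 0.08, [(1670.0, 1.0)]),
                    _cs(8, 0.07, [(1700.0, 1.0)]),
                    _cs(9, 0.06, [(1767.0, 0.55), (2267.0, 0.45)], fill=0.30),
                    _cs(10, 0.05, [(1790.0, 0.40), (2300.0, 0.60)]),
                    _cs(11, 0.04, [(2650.0, 1.0)]),
                    _cs(12, 0.035, [(2720.0, 1.0)]),
                    _cs(14, 0.025, [(3120.0, 1.0)]),
                ],
            ),
            SpeciesMix(
                sm,
                [
                    _cs(7, 0.07, [(1697.0, 1.0)]),
                    _cs(8, 0.06, [(1740.0, 0.5), (2220.0, 0.5)]),
                    _cs(9, 0.05, [(1800.0, 0.40), (2290.0, 0.60)], fill=0.25),
                    _cs(10, 0.05, [(2310.0, 1.0)]),
                    _cs(14, 0.04, [(3125.0, 1.0)]),
                ],
            ),
        ],
    )

    harsh = ConditionSpec(
        name="harsh",
        mixes=[
            SpeciesMix(
                dimer,
                [
                    _cs(10, 0.05, [(2716.0, 1.0)]),
                    _cs(11, 0.05, [(2735.0, 0.40), (3237.0, 0.33), (3556.0, 0.27)]),
                    _cs(12, 0.03, [(2800.0, 1.0)]),
                ],
            ),
            SpeciesMix(
                holo,
                [
                    _cs(6, 0.05, [(1615.0, 1.0)]),
                    _cs(7, 0.06, [(1656.0, 0.45), (2105.0, 0.55)]),
                    _cs(8, 0.05, [(1700.0, 0.5), (2160.0, 0.5)]),
                ],
            ),
            SpeciesMix(
                apo,
                [
                    _cs(7, 0.09, [(1711.0, 0.5), (2230.0, 0.5)], fill=0.30),
                    _cs(8, 0.08, [(1730.0, 0.45), (2260.0, 0.55)], fill=0.30),
                    _cs(9, 0.08, [(1775.0, 0.40), (2290.0, 0.60)], fill=0.25),
                    _cs(10, 0.07, [(1785.0, 0.30), (2320.0, 0.70)]),
                    _cs(11, 0.07, [(1795.0, 0.50), (2780.0, 0.50)]),
                    _cs(12, 0.07, [(3060.0, 1.0)]),
                    _cs(13, 0.06, [(3190.0, 1.0)]),
                    _cs(14, 0.06, [(3330.0, 1.0)]),
                    _cs(15, 0.05, [(3470.0, 1.0)]),
                    _cs(16, 0.08, [(3608.0, 1.0)]),
                ],
            ),
        ],
    )
    return [native, intermediate, harsh]
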