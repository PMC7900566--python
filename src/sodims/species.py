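"""Species hypotheses, charge-state inference, and peak assignment.

A species hypothesis fixes an oligomer order and metalation state; its
neutral mass follows from the apo-monomer chain mass, the average metal
masses, and a proton-displacement convention (a divalent metal binding at a
native site displaces ``k`` protons; the default k = 2 is the
charge-neutral substitution).  Observed m/z peaks are matched against the
hypotheses, charge-state ladders are solved jointly for charge and neutral
mass, and m/z-coincident species (a dimer at charge 2z coincides exactly
with its monomer at z) are separated by mobility.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .constants import CU_AVG, PROTON_MASS, ZN_AVG

__all__ = [
    "SpeciesDefinition",
    "PeakAssignment",
    "neutral_mass",
    "theoretical_mz",
    "infer_charge_and_mass",
    "assign_peaks",
    "resolve_mz_coincidence",
    "hypotheses_to_json",
    "hypotheses_from_json",
    "LadderError",
]


class LadderError(ValueError):
    """Charge-state ladder is underdetermined or internally inconsistent."""


@dataclass(frozen=True)
class SpeciesDefinition:
    """One oligomer + metalation hypothesis."""

    name: str
    oligomer_order: int
    apo_monomer_mass: float  # Da
    n_cu: int = 0
    n_zn: int = 0
    proton_displacement_per_metal: int = 2
    #: report-level family label ("holo-dimer", "apo-monomer", ...); defaults
    #: to the hypothesis name.
    form: str = ""
    max_metals_per_monomer: int = 2  # 1 Cu + 1 Zn

    def __post_init__(self) -> None:
        if self.oligomer_order < 1:
            raise ValueError("oligomer_order must be >= 1")
        if self.apo_monomer_mass <= 0:
            raise ValueError("apo_monomer_mass must be > 0")
        if min(self.n_cu, self.n_zn, self.proton_displacement_per_metal) < 0:
            raise ValueError("metal counts and proton displacement must be >= 0")
        if self.n_cu + self.n_zn > self.max_metals_per_monomer * self.oligomer_order:
            raise ValueError(
                f"{self.name!r}: {self.n_cu + self.n_zn} metals exceeds "
                f"{self.max_metals_per_monomer} per monomer"
            )
        if not self.form:
            object.__setattr__(self, "form", self.name)


@dataclass
class PeakAssignment:
    observed_mz: float
    intensity: float
    charge: int
    species: str
    theoretical_mz: float
    mass_error_da: float  # neutral-mass scale (m/z error * z)
    ambiguity_flags: set[str] = field(default_factory=set)


def neutral_mass(species: SpeciesDefinition) -> float:
    """Neutral average mass (Da) of a species hypothesis.

    M = n * M_apo + n_cu * (M_Cu - k * m_p) + n_zn * (M_Zn - k * m_p)
    with k protons displaced per bound metal.
    """
    k = species.proton_displacement_per_metal
    m = (
        species.oligomer_order * species.apo_monomer_mass
        + species.n_cu * (CU_AVG - k * PROTON_MASS)
        + species.n_zn * (ZN_AVG - k * PROTON_MASS)
    )
    if m <= 0:
        raise ValueError(f"species {species.name!r} has non-positive neutral mass")
    return m


def theoretical_mz(mass: float, charge: int) -> float:
    """m/z of [M + zH]^z+ in positive mode."""
    if mass <= 0:
        raise ValueError("mass must be > 0")
    if charge < 1:
        raise ValueError("charge must be a positive integer")
    return (mass + charge * PROTON_MASS) / charge


def infer_charge_and_mass(
    peaks_mz: list[float] | np.ndarray,
    mass_spread_tolerance_da: float = 5.0,
) -> tuple[list[int], float]:
    """Solve a consecutive charge-state ladder for charges and neutral mass.

    ``peaks_mz`` must be strictly descending m/z assumed to carry
    consecutive charges z, z+1, ....  For the top adjacent pair (p1 > p2)
    the charge of p1 is z1 = round((p2 - m_p) / (p1 - p2)); the neutral
    mass is the mean of z_i * (p_i - m_p) over all peaks.

    Raises :class:`LadderError` for a single peak (underdetermined) or when
    the per-peak mass estimates spread beyond the tolerance (inconsistent
    ladder).
    """
    p = np.asarray(peaks_mz, dtype=float)
    if p.size < 2:
        raise LadderError("charge inference needs >= 2 peaks (underdetermined)")
    if not np.all(np.diff(p) < 0):
        raise LadderError("peaks must be strictly descending in m/z")
    z1 = int(round((p[1] - PROTON_MASS) / (p[0] - p[1])))
    if z1 < 1:
        raise LadderError("inferred charge is non-positive; not a consecutive ladder")
    charges = [z1 + i for i in range(p.size)]
    masses = np.array([z * (mz - PROTON_MASS) for z, mz in zip(charges, p)])
    spread = float(masses.max() - masses.min())
    if spread > mass_spread_tolerance_da:
        raise LadderError(
            f"inconsistent ladder: per-peak neutral masses spread {spread:.2f} Da "
            f"(> {mass_spread_tolerance_da} Da); estimates: {np.round(masses, 2)}"
        )
    return charges, float(masses.mean())


def assign_peaks(
    peaks: list[tuple[float, float]],
    hypotheses: list[SpeciesDefinition],
    z_range: tuple[int, int] | dict[str, tuple[int, int]] = (1, 20),
    tolerance_da: float = 1.0,
    mass_resolution_da: float = 4.0,
) -> list[PeakAssignment]:
    """Match observed (m/z, intensity) peaks to (species, charge) hypotheses.

    A peak matches when |observed - theoretical| m/z <= tolerance_da / z
    (the tolerance is specified on the neutral-mass scale).  ``z_range`` may
    be a global (lo, hi) or a per-species-name mapping.

    Flags:

    ``metal_identity_ambiguous``
        another hypothesis of the same oligomer order and total metal count
        but different metalation lies within ``mass_resolution_da`` of the
        matched hypothesis (Cu-only vs Zn-only differ by ~1.83 Da on
        average masses, 0.999545 Da for 63Cu vs 64Zn).
    ``mz_coincident``
        two or more hypotheses match the same observed peak.
    """
    if not hypotheses:
        raise ValueError("need at least one species hypothesis")
    if tolerance_da <= 0:
        raise ValueError("tolerance_da must be > 0")
    masses = {h.name: neutral_mass(h) for h in hypotheses}
    assignments: list[PeakAssignment] = []
    for mz_obs, inten in peaks:
        matched: list[PeakAssignment] = []
        for h in hypotheses:
            lo, hi = z_range[h.name] if isinstance(z_range, dict) else z_range
            for z in range(lo, hi + 1):
                mz_th = theoretical_mz(masses[h.name], z)
                err_da = (mz_obs - mz_th) * z
                if abs(err_da) <= tolerance_da:
                    flags: set[str] = set()
                    for other in hypotheses:
                        if (
                            other.name != h.name
                            and other.oligomer_order == h.oligomer_order
                            and other.n_cu + other.n_zn == h.n_cu + h.n_zn
                            and (other.n_cu, other.n_zn) != (h.n_cu, h.n_zn)
                            and abs(masses[other.name] - masses[h.name])
                            < mass_resolution_da
                        ):
                            flags.add("metal_identity_ambiguous")
                    matched.append(
                        PeakAssignment(
                            observed_mz=mz_obs,
                            intensity=inten,
                            charge=z,
                            species=h.name,
                            theoretical_mz=mz_th,
                            mass_error_da=err_da,
                            ambiguity_flags=flags,
                        )
                    )
        if len(matched) > 1:
            for a in matched:
                a.ambiguity_flags.add("mz_coincident")
        assignments.extend(matched)
    return assignments


def hypotheses_to_json(hypotheses: list[SpeciesDefinition]) -> str:
    """Serialise a hypothesis list to the config-JSON dialect."""
    import dataclasses
    import json

    return json.dumps([dataclasses.asdict(h) for h in hypotheses], indent=1)


def hypotheses_from_json(text: str) -> list[SpeciesDefinition]:
    """Load a hypothesis list from config JSON (inverse of
    :func:`hypotheses_to_json`)."""
    import json

    return [SpeciesDefinition(**entry) for entry in json.loads(text)]


def resolve_mz_coincidence(
    assignments: list[PeakAssignment],
    frame,
    calib,
    hypotheses: list[SpeciesDefinition],
    expected_ccs: dict[str, float],
    mz_half_width: float | None = None,
    detection_threshold: float = 0.05,
    min_prominence_frac: float = 0.05,
    smoothing_window: int = 3,
):
    """Attribute ATD components of an m/z-coincident peak to hypotheses.

    For assignments sharing one observed m/z, the arrival-time distribution
    in that window is split into conformer components; each component is
    attributed to the hypothesis whose predicted arrival time (from its
    expected CCS prior, by default the species' compact value) is nearest.
    A hypothesis survives only if its attributed components exceed
    ``detection_threshold`` x the tallest component.

    Returns ``(surviving assignments, attribution table)``.
    """
    from .atd import detect_conformers, extract_atd
    from .calibration import ccs_to_drift

    if calib is None:
        raise ValueError("cannot resolve m/z coincidence without a calibration")
    if not assignments:
        return [], []
    mz0 = float(np.mean([a.observed_mz for a in assignments]))
    by_name = {h.name: h for h in hypotheses}
    if mz_half_width is None:
        res = frame.metadata.get("instrument", {}).get("resolution_mz", 500.0)
        mz_half_width = 1.2 * mz0 / res
    atd = extract_atd(frame, mz0, mz_half_width)
    comps = detect_conformers(
        atd,
        min_prominence_frac=min_prominence_frac,
        smoothing_window=smoothing_window,
    )
    if not comps:
        return [], []
    predicted = {}
    for a in assignments:
        sp = by_name[a.species]
        predicted[(a.species, a.charge)] = ccs_to_drift(
            expected_ccs[a.species], neutral_mass(sp), a.charge, calib
        )
    attribution = []
    best_height = max(c.height for c in comps)
    strength: dict[tuple[str, int], float] = {}
    for c in comps:
        key = min(predicted, key=lambda k: abs(predicted[k] - c.apex_time))
        attribution.append((c, key))
        strength[key] = max(strength.get(key, 0.0), c.height)
    survivors = [
        a
        for a in assignments
        if strength.get((a.species, a.charge), 0.0)
        >= detection_threshold * best_height
    ]
    if len(survivors) < len(assignments):
        dropped = {a.species for a in assignments} - {a.species for a in survivors}
        warnings.warn(
            f"m/z {mz0:.1f}: no ATD component above threshold for {sorted(dropped)}",
            stacklevel=2,
        )
    for a in survivors:
        if len(survivors) == 1:
            a.ambiguity_flags.discard("mz_coincident")
    return survivors, attribution
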