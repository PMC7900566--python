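"""End-to-end orchestration: generate -> calibrate -> assign -> ATD -> profile.

:class:`RunConfig` collects every tunable with its default; ``run_pipeline``
executes the full analysis on synthetic presets (or user-supplied frames),
writing calibration JSON, assignment CSV, conformer CSV, profile CSV,
regions JSON, pathway JSON, optional comparison CSV and a run log.  Output
is deterministic for a fixed config + seed.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, ValidationError

from . import __version__
from .atd import atd_to_ccs, detect_conformers, extract_atd, intermediates_present
from .calibration import (
    calibration_report,
    extract_calibrant_times,
    fit_single_field,
    load_reference_calibrants,
    read_calibrant_table,
)
from .frames import MobilityFrame, refine_apex
from .species import (
    PeakAssignment,
    assign_peaks,
    neutral_mass,
    resolve_mz_coincidence,
)
from .synthetic import (
    InstrumentTruth,
    condition_presets,
    default_hypotheses,
    synth_calibrant_frame,
    synth_protein_frame,
)
from .unfolding import (
    build_profile,
    comparison_table,
    find_elongation_regions,
    pathway_summary,
)

__all__ = ["RunConfig", "validate_config", "run_pipeline", "analyze_condition"]

MONOMER_FORMS = ["holo-monomer", "single-metal monomer", "apo-monomer"]


class RunConfig(BaseModel):
    """All pipeline parameters with defaults; the effective config is dumped
    into the run log so every numeric output is traceable."""

    seed: int = 0
    synthetic: bool = True
    noise_sd: float = 0.0  # fraction of tallest apex, synthetic frames
    out_dir: str = "results/run"
    # paths for non-synthetic input (long-format frame CSVs per condition)
    frame_paths: dict[str, str] = Field(default_factory=dict)
    calibrant_table: str | None = None  # CSV mz,charge,ccs_n2; None = packaged
    condition_order: list[str] = Field(
        default_factory=lambda: ["native", "intermediate", "harsh"]
    )
    # species hypotheses: per-species charge windows (observed ranges)
    z_range: dict[str, tuple[int, int]] = Field(
        default_factory=lambda: {
            "holo-dimer": (9, 13),
            "holo-monomer": (6, 16),
            "single-metal-monomer-cu": (6, 16),
            "single-metal-monomer-zn": (6, 16),
            "apo-monomer": (6, 16),
        }
    )
    tolerance_da: float = Field(default=1.0, gt=0)
    mass_resolution_da: float = Field(default=4.0, gt=0)
    ms_peak_prominence_frac: float = Field(default=0.004, gt=0, lt=1)
    atd_prominence_frac: float = Field(default=0.05, gt=0, lt=1)
    atd_smoothing_window: int = Field(default=3, ge=1)
    valley_threshold_frac: float = Field(default=0.10, ge=0)
    min_region_gap: float = Field(default=150.0, gt=0)
    compact_band: float = Field(default=0.03, ge=0)
    # optional theoretical CCS entries for the comparison table
    theoretical_ccs: list[tuple[str, str, float]] = Field(default_factory=list)
    measured_ccs: list[tuple[str, str, float | None]] = Field(default_factory=list)


def validate_config(config: dict | RunConfig) -> list[str]:
    """Schema + semantic checks; returns a list of violations (empty = ok)."""
    violations: list[str] = []
    if isinstance(config, dict):
        known = set(RunConfig.model_fields)
        for k in config:
            if k not in known:
                violations.append(f"unknown field: {k}")
        try:
            config = RunConfig(**{k: v for k, v in config.items() if k in known})
        except ValidationError as e:
            violations.extend(
                f"{'.'.join(str(p) for p in err['loc'])}: {err['msg']}"
                for err in e.errors()
            )
            return violations
    for name, (lo, hi) in config.z_range.items():
        if lo < 1 or hi < lo:
            violations.append(f"z_range[{name}]: invalid charge window ({lo}, {hi})")
    if not config.condition_order:
        violations.append("condition_order: must not be empty")
    if not config.synthetic:
        for cond in config.condition_order:
            if cond not in config.frame_paths:
                violations.append(f"frame_paths: missing frame for {cond!r}")
        if config.calibrant_table is None:
            violations.append(
                "calibrant_table: required when CCS computation is requested "
                "on real frames"
            )
    return violations


def detect_ms_peaks(
    frame: MobilityFrame, prominence_frac: float = 0.004
) -> list[tuple[float, float]]:
    """Peak-pick the marginal mass spectrum.

    Candidate maxima come from a prominence filter; each apex is refined by
    a windowed Gaussian least-squares fit (+-2.5 sigma), which averages the
    marginal's summed noise down far enough to hold the +-1 Da neutral-mass
    matching tolerance even at dimer charge states, with a 3-point
    interpolation fallback.
    """
    from scipy import signal
    from scipy.optimize import curve_fit

    spec = frame.mass_spectrum()
    if spec.max() <= 0:
        return []
    res = frame.metadata.get("instrument", {}).get("resolution_mz", 500.0)
    step = frame.mz_step
    idx, _ = signal.find_peaks(spec, prominence=prominence_frac * spec.max())
    peaks = []
    for i in idx:
        mz0, height = refine_apex(frame.mz_axis, spec, int(i))
        sigma0 = (frame.mz_axis[i] / res) / 2.354820045
        w = max(2, int(np.ceil(2.5 * sigma0 / step)))
        lo, hi = max(0, i - w), min(spec.size - 1, i + w)
        # truncate at the valley on each side so a close neighbouring peak
        # cannot contaminate the fit
        lo = lo + int(np.argmin(spec[lo : i + 1]))
        hi = i + int(np.argmin(spec[i : hi + 1]))
        xs, ys = frame.mz_axis[lo : hi + 1], spec[lo : hi + 1]
        try:
            popt, _ = curve_fit(
                lambda x, a, mu, sig, c: a * np.exp(-0.5 * ((x - mu) / sig) ** 2) + c,
                xs,
                ys,
                p0=[float(ys.max()), float(frame.mz_axis[i]), sigma0, 0.0],
                maxfev=400,
            )
            if abs(popt[1] - frame.mz_axis[i]) < 2 * sigma0:
                mz0, height = float(popt[1]), float(popt[0])
        except RuntimeError:
            pass
        peaks.append((mz0, height))
    return peaks


def analyze_condition(
    frame: MobilityFrame,
    condition: str,
    calib,
    hypotheses: dict,
    config: RunConfig,
) -> tuple[pd.DataFrame, list[PeakAssignment], list[dict]]:
    """Assign peaks and extract per-(species, charge) conformers for one frame.

    Returns (conformer table, assignments, intermediate-structure flags).
    """
    hyp_list = list(hypotheses.values())
    ms_peaks = detect_ms_peaks(frame, config.ms_peak_prominence_frac)
    assignments = assign_peaks(
        ms_peaks,
        hyp_list,
        z_range=config.z_range,
        tolerance_da=config.tolerance_da,
        mass_resolution_da=config.mass_resolution_da,
    )
    compact_priors = {
        name: min(
            (row.ccs for row in _PRIOR_TABLE if row.species == name),
            default=2000.0,
        )
        for name in hypotheses
    }
    res_mz = frame.metadata.get("instrument", {}).get("resolution_mz", 500.0)

    # group coincident assignments by observed m/z and resolve by mobility
    by_mz: dict[float, list[PeakAssignment]] = {}
    for a in assignments:
        by_mz.setdefault(a.observed_mz, []).append(a)

    rows = []
    valley_flags = []
    surviving: list[PeakAssignment] = []
    for mz_obs, group in by_mz.items():
        half = 1.2 * mz_obs / res_mz
        if len(group) > 1:
            group, attribution = resolve_mz_coincidence(
                group,
                frame,
                calib,
                hyp_list,
                expected_ccs=compact_priors,
                mz_half_width=half,
                min_prominence_frac=config.atd_prominence_frac,
                smoothing_window=config.atd_smoothing_window,
            )
            comps_by_key: dict[tuple[str, int], list] = {}
            for comp, key in attribution:
                comps_by_key.setdefault(key, []).append(comp)
        else:
            comps_by_key = None
        surviving.extend(group)
        for a in group:
            mass = neutral_mass(hypotheses[a.species])
            atd = extract_atd(frame, mz_obs, half, species=a.species, charge=a.charge)
            peaks = detect_conformers(
                atd,
                min_prominence_frac=config.atd_prominence_frac,
                smoothing_window=config.atd_smoothing_window,
            )
            if comps_by_key is not None:
                mine = comps_by_key.get((a.species, a.charge), [])
                apexes = {round(c.apex_time, 6) for c in mine}
                peaks = [p for p in peaks if round(p.apex_time, 6) in apexes]
            present, stats = intermediates_present(
                atd, peaks, config.valley_threshold_frac
            )
            if present:
                valley_flags.append(
                    {"condition": condition, "species": a.species,
                     "charge": a.charge, "valleys": stats["valleys"]}
                )
            peaks = atd_to_ccs(peaks, mass, a.charge, calib)
            conf_total = sum(p.relative_abundance for p in peaks) or 1.0
            for p in peaks:
                rows.append(
                    {
                        "condition": condition,
                        "species": a.species,
                        "form": hypotheses[a.species].form,
                        "charge": a.charge,
                        "observed_mz": mz_obs,
                        "apex_ms": p.apex_time,
                        "ccs": p.ccs,
                        "fwhm_ms": p.fwhm_ms,
                        "abundance": a.intensity
                        * p.relative_abundance
                        / conf_total,
                        "intermediates": present,
                        "flags": ";".join(sorted(a.ambiguity_flags)),
                    }
                )
    table = pd.DataFrame(rows)
    if not table.empty:
        table["abundance"] /= table["abundance"].sum()
    return table, surviving, valley_flags


class _Prior:
    def __init__(self, species, ccs):
        self.species, self.ccs = species, ccs


#: compact-CCS priors per hypothesis (each species' lowest-charge compact
#: value) used to attribute m/z-coincident ATD components.
_PRIOR_TABLE = [
    _Prior("holo-dimer", 2693.5),
    _Prior("holo-monomer", 1610.0),
    _Prior("single-metal-monomer-cu", 1697.0),
    _Prior("single-metal-monomer-zn", 1697.0),
    _Prior("apo-monomer", 1711.0),
]


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full pipeline and write all artifacts under ``out_dir``.

    Returns a summary record (also written as ``run_log.json``).
    """
    violations = validate_config(config)
    if violations:
        raise ValueError("invalid config: " + "; ".join(violations))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    truth = InstrumentTruth()
    hypotheses = default_hypotheses()

    # ---- calibration -----------------------------------------------------
    if config.calibrant_table:
        calibrants = read_calibrant_table(config.calibrant_table)
    else:
        calibrants = load_reference_calibrants()
    cal_frame, _ = synth_calibrant_frame(
        truth,
        [(c.mz, c.charge, c.reference_ccs) for c in calibrants],
        noise_sd=config.noise_sd,
        seed=config.seed,
    )
    measured = extract_calibrant_times(cal_frame, calibrants)
    calib = fit_single_field(measured, truth.gas_mass)
    calib.to_json(out / "calibration.json")
    report = calibration_report(calib, measured)
    (out / "calibration_report.json").write_text(json.dumps(report, indent=1))

    # ---- per-condition frames -------------------------------------------
    presets = {c.name: c for c in condition_presets()}
    conformer_tables, all_assignments, all_valleys = [], [], []
    truth_tables = {}
    for i, cond in enumerate(config.condition_order):
        if config.synthetic:
            if cond not in presets:
                raise ValueError(f"no synthetic preset named {cond!r}")
            spec = presets[cond]
            spec.noise_sd = config.noise_sd
            frame, truth_df = synth_protein_frame(
                spec, truth, seed=config.seed + 1 + i
            )
            truth_tables[cond] = truth_df
            truth_df.to_csv(out / f"truth_{cond}.csv", index=False)
        else:
            frame = MobilityFrame.from_csv(config.frame_paths[cond])
        table, assignments, valleys = analyze_condition(
            frame, cond, calib, hypotheses, config
        )
        conformer_tables.append(table)
        all_valleys.extend(valleys)
        for a in assignments:
            all_assignments.append(
                {
                    "condition": cond,
                    "observed_mz": a.observed_mz,
                    "charge": a.charge,
                    "species": a.species,
                    "theoretical_mz": a.theoretical_mz,
                    "mass_error_da": a.mass_error_da,
                    "flags": ";".join(sorted(a.ambiguity_flags)),
                }
            )

    pd.DataFrame(all_assignments).to_csv(out / "assignments.csv", index=False)
    conformers = pd.concat(conformer_tables, ignore_index=True)
    conformers.to_csv(out / "conformers.csv", index=False)

    # ---- profile, regions, pathway --------------------------------------
    profile = build_profile(conformer_tables, compact_band=config.compact_band)
    profile.rows.to_csv(out / "profile.csv", index=False)
    regions = find_elongation_regions(
        profile, min_gap=config.min_region_gap, forms=MONOMER_FORMS
    )
    (out / "regions.json").write_text(json.dumps(regions.to_dict(), indent=1))
    pathway = pathway_summary(profile, config.condition_order)
    (out / "pathway.json").write_text(json.dumps(pathway, indent=1))
    (out / "intermediates.json").write_text(json.dumps(all_valleys, indent=1))

    if config.theoretical_ccs and config.measured_ccs:
        comparison_table(config.measured_ccs, config.theoretical_ccs).to_csv(
            out / "comparison.csv", index=False
        )

    summary = {
        "version": __version__,
        "seed": config.seed,
        "config": json.loads(config.model_dump_json()),
        "calibration": {"beta": calib.beta, "t_fix": calib.t_fix,
                        "r_squared": calib.r_squared},
        "n_assignments": len(all_assignments),
        "n_conformers": int(len(conformers)),
        "compact_reference": profile.compact_reference,
        "elongation_regions": regions.labels,
        "first_appearance_order": pathway["first_appearance_order"],
    }
    (out / "run_log.json").write_text(json.dumps(summary, indent=1))
    return summary
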