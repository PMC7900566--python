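"""CCS-vs-charge unfolding profiles, elongation regions, and comparisons.

Conformer tables from several solution conditions are assembled into a
single profile per species form; the lowest observed charge state defines
the compact reference, conformers more than a small band above it are
"extended", and 1-D gap clustering of the extended CCS values yields the
discrete elongation regions (E1, E2, ...) through which the protein
unfolds.  Percent differences between platforms and theory use the
symmetric mean-denominator convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "UnfoldingProfile",
    "ElongationRegions",
    "build_profile",
    "find_elongation_regions",
    "percent_difference",
    "comparison_table",
    "pathway_summary",
    "plot_profile",
]

PROFILE_COLUMNS = ["condition", "form", "charge", "ccs", "abundance", "label"]


@dataclass
class UnfoldingProfile:
    """Long-format conformer table plus per-form compact references."""

    rows: pd.DataFrame  # PROFILE_COLUMNS
    compact_reference: dict[str, float]  # form -> CCS at lowest observed charge


@dataclass
class ElongationRegions:
    """Ordered elongation regions E1..Ek with disjoint CCS intervals."""

    labels: list[str]
    intervals: list[tuple[float, float]]
    members: list[pd.DataFrame]  # rows of the profile belonging to each region

    def __len__(self) -> int:
        return len(self.labels)

    def to_dict(self) -> dict:
        return {
            label: {
                "ccs_interval": list(interval),
                "members": mem[["condition", "form", "charge", "ccs"]].to_dict(
                    "records"
                ),
            }
            for label, interval, mem in zip(self.labels, self.intervals, self.members)
        }


def build_profile(
    conformer_tables: list[pd.DataFrame],
    compact_band: float = 0.03,
) -> UnfoldingProfile:
    """Assemble per-condition conformer tables into an unfolding profile.

    Each input table needs columns ``condition, form, charge, ccs,
    abundance``.  Duplicate (condition, form, charge, ccs) rows are merged
    with an abundance-weighted mean and a warning.  The compact reference of
    each form is the smallest CCS at its lowest observed charge state;
    conformers above ``reference * (1 + compact_band)`` are labelled
    extended, the rest compact.
    """
    if not conformer_tables:
        raise ValueError("need at least one conformer table")
    df = pd.concat(conformer_tables, ignore_index=True)
    if df.empty:
        raise ValueError("conformer tables are empty")
    key = ["condition", "form", "charge"]
    # merge near-duplicate rows (same key, CCS within 0.1%)
    df = df.sort_values(key + ["ccs"]).reset_index(drop=True)
    merged = []
    for _, grp in df.groupby(key, sort=False):
        grp = grp.reset_index(drop=True)
        cluster_id = (grp["ccs"].diff() / grp["ccs"] > 1e-3).cumsum()
        for _, cl in grp.groupby(cluster_id):
            if len(cl) > 1:
                warnings.warn(
                    f"merging {len(cl)} duplicate rows for "
                    f"{tuple(cl.iloc[0][key])} with abundance-weighted mean",
                    stacklevel=2,
                )
            w = cl["abundance"].to_numpy()
            w = w / w.sum() if w.sum() > 0 else np.full(len(cl), 1 / len(cl))
            row = cl.iloc[0].copy()
            row["ccs"] = float(np.dot(cl["ccs"], w))
            row["abundance"] = float(cl["abundance"].sum())
            merged.append(row)
    df = pd.DataFrame(merged).reset_index(drop=True)
    reference = {}
    for form, grp in df.groupby("form"):
        zmin = grp["charge"].min()
        reference[form] = float(grp.loc[grp["charge"] == zmin, "ccs"].min())
    df["label"] = [
        "extended"
        if row.ccs > reference[row.form] * (1.0 + compact_band)
        else "compact"
        for row in df.itertuples()
    ]
    return UnfoldingProfile(rows=df[PROFILE_COLUMNS], compact_reference=reference)


def find_elongation_regions(
    profile: UnfoldingProfile,
    min_gap: float = 150.0,
    forms: list[str] | None = None,
) -> ElongationRegions:
    """Gap-cluster extended-conformer CCS values into elongation regions.

    Single-linkage in one dimension: sort the extended CCS values and split
    wherever the gap between consecutive values exceeds ``min_gap`` (A^2).
    Regions are labelled E1..Ek in ascending CCS.  ``forms`` restricts the
    clustering (e.g. to the monomer forms); default is all forms.
    """
    df = profile.rows
    if forms is not None:
        df = df[df["form"].isin(forms)]
    ext = df[df["label"] == "extended"].sort_values("ccs").reset_index(drop=True)
    if ext.empty:
        return ElongationRegions(labels=[], intervals=[], members=[])
    region_id = (ext["ccs"].diff() > min_gap).cumsum()
    labels, intervals, members = [], [], []
    for k, (_, grp) in enumerate(ext.groupby(region_id), start=1):
        labels.append(f"E{k}")
        intervals.append((float(grp["ccs"].min()), float(grp["ccs"].max())))
        members.append(grp.reset_index(drop=True))
    return ElongationRegions(labels=labels, intervals=intervals, members=members)


def percent_difference(a: float, b: float, convention: str = "mean") -> float:
    """Symmetric percent difference between two CCS values.

    Default convention divides by the mean of the two values:
    ``100 * |a - b| / ((a + b) / 2)``; ``convention`` may also be
    ``"first"`` or ``"second"`` to divide by one of the inputs.  Report
    layers round to 1 decimal.
    """
    if a <= 0 or b <= 0:
        raise ValueError("percent_difference requires positive inputs")
    denom = {"mean": (a + b) / 2.0, "first": a, "second": b}[convention]
    return 100.0 * abs(a - b) / denom


def comparison_table(
    measured: list[tuple[str, str, float | None]],
    theoretical: list[tuple[str, str, float]],
    convention: str = "mean",
) -> pd.DataFrame:
    """Cross measured (label, platform, CCS) against theoretical
    (structure id, method, CCS) values; missing measurements render "N.D."."""
    if not measured or not theoretical:
        raise ValueError("measured and theoretical lists must be nonempty")
    rows = []
    for struct_id, method, ccs_th in theoretical:
        for label, platform, ccs_meas in measured:
            if ccs_meas is None or (
                isinstance(ccs_meas, float) and np.isnan(ccs_meas)
            ):
                meas_repr, diff_repr = "N.D.", "N.D."
            else:
                meas_repr = f"{ccs_meas:g}"
                diff_repr = f"{percent_difference(ccs_th, ccs_meas, convention):.1f}"
            rows.append(
                {
                    "structure": struct_id,
                    "method": method,
                    "ccs_theoretical": ccs_th,
                    "measurement": label,
                    "platform": platform,
                    "ccs_measured": meas_repr,
                    "percent_diff": diff_repr,
                }
            )
    return pd.DataFrame(rows)


def pathway_summary(
    profiles: dict[str, UnfoldingProfile] | UnfoldingProfile,
    condition_order: list[str],
    presence_threshold: float = 0.0,
) -> dict:
    """Order species forms along the unfolding pathway.

    For each condition (in the given harshness order) the species forms are
    ranked by summed abundance; the first-appearance ordering lists forms by
    the first condition in which their summed abundance exceeds the
    threshold, breaking ties by abundance at that condition.  Monotone
    abundance trends across conditions are flagged per form.
    """
    if isinstance(profiles, UnfoldingProfile):
        df = profiles.rows
    else:
        df = pd.concat([p.rows for p in profiles.values()], ignore_index=True)
    missing = set(df["condition"]) - set(condition_order)
    if missing:
        raise ValueError(f"conditions {sorted(missing)} not in condition_order")
    # total abundance of a form = sum over its conformers of
    # charge-level abundance
    totals = (
        df.groupby(["condition", "form"])["abundance"].sum().unstack(fill_value=0.0)
    )
    totals = totals.reindex(condition_order, fill_value=0.0)
    ranking = {
        cond: list(totals.loc[cond].sort_values(ascending=False).index)
        for cond in condition_order
    }
    first_seen = []
    for form in totals.columns:
        present = totals[form] > presence_threshold
        if present.any():
            ci = int(np.argmax(present.to_numpy()))
            first_seen.append((ci, -totals[form].iloc[ci], form))
    first_seen.sort()
    trends = {}
    for form in totals.columns:
        v = totals[form].to_numpy()
        if np.all(np.diff(v) >= 0) and v[-1] > v[0]:
            trends[form] = "increasing"
        elif np.all(np.diff(v) <= 0) and v[-1] < v[0]:
            trends[form] = "decreasing"
        else:
            trends[form] = "non-monotone"
    return {
        "condition_order": list(condition_order),
        "ranking_by_condition": ranking,
        "first_appearance_order": [f for _, _, f in first_seen],
        "abundance_by_condition": {
            c: totals.loc[c].to_dict() for c in condition_order
        },
        "trends": trends,
    }


def plot_profile(
    profile: UnfoldingProfile,
    regions: ElongationRegions | None = None,
    ax=None,
):
    """CCS vs charge state, one marker set per form, with optional region
    bands.  Returns the matplotlib axes."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 5))
    for form, grp in profile.rows.groupby("form"):
        ax.scatter(grp["charge"], grp["ccs"], s=18 + 120 * grp["abundance"],
                   alpha=0.75, label=form)
    for form, ref in profile.compact_reference.items():
        ax.axhline(ref, lw=0.6, ls="--", color="grey")
    if regions is not None:
        for label, (lo, hi) in zip(regions.labels, regions.intervals):
            ax.axhspan(lo, hi, alpha=0.08, color="tab:orange")
            ax.annotate(label, xy=(ax.get_xlim()[1], (lo + hi) / 2), fontsize=8)
    ax.set_xlabel("charge state")
    ax.set_ylabel("CCS (A$^2$)")
    ax.legend(fontsize=8)
    return ax
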