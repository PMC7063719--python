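"""Dose-volume histogram analysis and plan comparison.

The metric set mirrors what is clinically reported for interstitial liver
HDR treatments: liver V5Gy/V10Gy (% of liver volume), OAR D1cc (Gy), CTV
V150/V100/V95/V90 (% of CTV volume, thresholds in % of prescription) and
D95/D90 (reported in % of prescription).  Deltas are model-based minus
water-reference values, in each parameter's native unit, and cohorts are
summarised by median/min/max.

Conventions: "volume receiving at least D" uses an inclusive threshold
(>=); D_V is the dose of the marginal voxel of the hottest-V subvolume
(descending-dose accumulation; fractional volume bookkeeping, no upward
dose interpolation -- this keeps v_at_dose(d_at_volume(V)) >= V exact).
Parameters are computed directly from voxel doses; binned DVH curves are
for reporting only.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from importlib.resources import files

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .geometry import VoxelGrid

__all__ = [
    "DVHCurve",
    "compute_dvh",
    "v_at_dose",
    "d_at_volume",
    "structure_parameters",
    "compare_doses",
    "summarize_cohort",
    "load_tolerances",
    "check_tolerances",
    "deviation_vs_volume",
    "CTV_V_LEVELS",
    "CTV_D_LEVELS",
]

CTV_V_LEVELS = (150, 100, 95, 90)  # % of prescription
CTV_D_LEVELS = (95, 90)  # % of structure volume


@dataclass(frozen=True)
class DVHCurve:
    """Cumulative DVH: fraction of structure volume receiving >= dose."""

    dose_bins: np.ndarray  # Gy, ascending
    cum_volume_fraction: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.cum_volume_fraction, dtype=float)
        if np.any(np.diff(v) > 1e-12):
            raise ValueError("cumulative DVH must be non-increasing")
        if abs(v[0] - 1.0) > 1e-12:
            raise ValueError("cumulative DVH must start at 1 at 0 Gy")


def _masked_doses(dose: VoxelGrid, mask: VoxelGrid) -> np.ndarray:
    if not mask.same_geometry(dose):
        raise ValueError("mask is not aligned with the dose grid")
    sel = np.asarray(mask.values, dtype=bool)
    if not np.any(sel):
        raise ValueError("empty structure mask")
    return np.asarray(dose.values, dtype=float)[sel]


def compute_dvh(dose: VoxelGrid, mask: VoxelGrid,
                bin_width_gy: float = 0.05) -> DVHCurve:
    """Cumulative DVH with equal voxel-volume weights."""
    d = _masked_doses(dose, mask)
    top = max(d.max(), bin_width_gy)
    edges = np.arange(0.0, top + 2 * bin_width_gy, bin_width_gy)
    frac = (d[None, :] >= edges[:, None]).mean(axis=1)
    frac[0] = 1.0  # every voxel receives >= 0 Gy
    return DVHCurve(edges, frac)


def v_at_dose(dose: VoxelGrid, mask: VoxelGrid, threshold_gy: float) -> float:
    """Percent of the structure receiving at least ``threshold_gy``."""
    if threshold_gy < 0:
        raise ValueError("threshold must be non-negative")
    d = _masked_doses(dose, mask)
    return 100.0 * float(np.count_nonzero(d >= threshold_gy)) / d.size


def v_at_dose_cm3(dose: VoxelGrid, mask: VoxelGrid,
                  threshold_gy: float) -> float:
    """Absolute volume (cm^3) of the structure receiving >= threshold."""
    d = _masked_doses(dose, mask)
    return float(np.count_nonzero(d >= threshold_gy)) * dose.voxel_volume_cm3


def d_at_volume(dose: VoxelGrid, mask: VoxelGrid, volume,
                unit: str = "cm3") -> float:
    """Minimum dose received by the hottest ``volume`` of the structure.

    ``unit`` is ``"cm3"`` (e.g. D1cc) or ``"pct"`` (e.g. D95 = hottest
    95% of the structure volume).  Accumulates voxels in descending dose;
    the returned dose is that of the marginal voxel.
    """
    d = _masked_doses(dose, mask)
    voxvol = dose.voxel_volume_cm3
    total = d.size * voxvol
    if unit == "pct":
        volume_cm3 = volume / 100.0 * total
    elif unit == "cm3":
        volume_cm3 = float(volume)
    else:
        raise ValueError("unit must be 'cm3' or 'pct'")
    if volume_cm3 <= 0:
        raise ValueError("requested volume must be positive")
    if volume_cm3 > total * (1 + 1e-9):
        raise ValueError(f"requested volume {volume_cm3:.3g} cm^3 exceeds "
                         f"structure volume {total:.3g} cm^3")
    d_sorted = np.sort(d)[::-1]
    k = min(int(np.ceil(volume_cm3 / voxvol - 1e-9)), d.size)
    return float(d_sorted[k - 1])


def structure_parameters(dose: VoxelGrid, mask: VoxelGrid, role: str,
                         prescription_gy: float) -> dict:
    """The reported DVH parameter set for one structure.

    Liver: V5Gy/V10Gy in % plus the absolute V5Gy in cm^3; OARs: D1cc in
    Gy; CTVs: V150..V90 in % of volume and D95/D90 in Gy and % of
    prescription.
    """
    out = {}
    if role == "liver":
        out["V5Gy_pct"] = v_at_dose(dose, mask, 5.0)
        out["V10Gy_pct"] = v_at_dose(dose, mask, 10.0)
        out["V5Gy_cm3"] = v_at_dose_cm3(dose, mask, 5.0)
    elif role.startswith("OAR"):
        out["D1cc_Gy"] = d_at_volume(dose, mask, 1.0, "cm3")
    elif role == "CTV":
        for lvl in CTV_V_LEVELS:
            out[f"V{lvl}_pct"] = v_at_dose(
                dose, mask, lvl / 100.0 * prescription_gy)
        for lvl in CTV_D_LEVELS:
            d = d_at_volume(dose, mask, lvl, "pct")
            out[f"D{lvl}_Gy"] = d
            out[f"D{lvl}_pct"] = 100.0 * d / prescription_gy
    else:
        raise ValueError(f"unknown structure role {role!r}")
    return out


def compare_doses(params_ref: dict, params_mbdc: dict) -> dict:
    """Per-parameter delta: model-based value minus water-reference value.

    Both inputs map structure -> {parameter -> value} and must describe
    the same structures.  Deltas keep each parameter's native unit.
    """
    if set(params_ref) != set(params_mbdc):
        raise ValueError("structure sets differ between the two dose modes")
    deltas = {}
    for s in params_ref:
        if set(params_ref[s]) != set(params_mbdc[s]):
            raise ValueError(f"parameter sets differ for structure {s!r}")
        deltas[s] = {k: params_mbdc[s][k] - params_ref[s][k]
                     for k in params_ref[s]}
    return deltas


def summarize_cohort(per_case_values) -> pd.DataFrame:
    """Median/min/max per parameter over cases.

    ``per_case_values`` is a sequence of {parameter -> value} dicts (one
    per case or per structure instance).
    """
    if len(per_case_values) == 0:
        raise ValueError("need at least one case")
    frame = pd.DataFrame(list(per_case_values))
    return pd.DataFrame({
        "median": frame.median(),
        "min": frame.min(),
        "max": frame.max(),
    })


def load_tolerances() -> dict:
    """Bundled clinical tolerance limits (liver V% and OAR D1cc)."""
    data = files("liverbrachy") / "data" / "tolerances.json"
    return json.loads(data.read_text())


def check_tolerances(params: dict, structure_type: str,
                     tolerances: dict = None) -> dict:
    """Flag parameters exceeding their clinical tolerance.

    ``params`` maps parameter name -> value for one structure;
    ``structure_type`` is ``"liver"`` or an OAR type such as
    ``"stomach"``.  Kidney D1cc has no clinical limit and is never
    flagged.  Unknown structure types warn and return no flags.
    """
    if tolerances is None:
        tolerances = load_tolerances()
    flags = {}
    if structure_type == "liver":
        for key, limit_key in (("V5Gy_pct", "V5Gy_pct"),
                               ("V10Gy_pct", "V10Gy_pct")):
            if key in params:
                limit = tolerances["liver"][limit_key]
                flags[key] = "exceed" if params[key] > limit else "pass"
    elif structure_type in tolerances["oar_d1cc_Gy"]:
        limit = tolerances["oar_d1cc_Gy"][structure_type]
        if "D1cc_Gy" in params and limit is not None:
            flags["D1cc_Gy"] = ("exceed" if params["D1cc_Gy"] > limit
                                else "pass")
    else:
        warnings.warn(f"no tolerance entry for structure type "
                      f"{structure_type!r}; skipped", stacklevel=2)
    return flags


def deviation_vs_volume(v5_ref_cm3, v5_mbdc_cm3):
    """Relative V5Gy deviation paired with the absolute reference volume.

    Returns ``(pairs, rho)`` where ``pairs`` is an (n, 2) array of
    (V5Gy_ref in cm^3, relative deviation) and ``rho`` the Spearman rank
    correlation between them (NaN for fewer than two usable cases).
    Cases with zero reference volume are excluded with a warning.
    """
    ref = np.asarray(v5_ref_cm3, dtype=float)
    mbdc = np.asarray(v5_mbdc_cm3, dtype=float)
    if ref.shape != mbdc.shape:
        raise ValueError("case lists must have equal length")
    ok = ref > 0
    if not np.all(ok):
        warnings.warn(f"{np.count_nonzero(~ok)} case(s) with zero reference "
                      f"V5Gy excluded", stacklevel=2)
    ref, mbdc = ref[ok], mbdc[ok]
    rel = (mbdc - ref) / ref
    pairs = np.column_stack([ref, rel])
    if len(ref) < 2 or np.ptp(rel) <= 1e-12:
        return pairs, float("nan")  # degenerate: correlation undefined
    rho, _ = spearmanr(ref, rel)
    return pairs, float(rho)
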