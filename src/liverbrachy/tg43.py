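"""Analytic TG-43-style dose calculation in unbounded water.

Implements the 2-D formalism

    Ddot(r, theta) = S_K * Lambda * G(r, theta)/G(1 cm, 90 deg)
                     * g(r) * F(r, theta)

with a line-source geometry function available and a point-source mode
(G = 1/r^2, F = 1) as the default.  The bundled parameter set is a
generic Ir-192 HDR point-source fixture (see ``data/tg43``): g(r) built
from the classic Meisberger attenuation/buildup polynomial, Lambda a
point-source consensus-style value of 1.12 cGy/(h U), and a synthetic
anisotropy table for exercising the 2-D code path.

The module is normalised through Lambda, independently of the Monte Carlo
engine's air-kerma-strength calibration, so agreement between the two is
a genuine cross-check of the transport physics.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from functools import lru_cache
from importlib.resources import files

import numpy as np

from .geometry import VoxelGrid

__all__ = [
    "TG43Parameters",
    "load_default_parameters",
    "geometry_function",
    "radial_dose_function",
    "anisotropy",
    "tg43_dose_rate",
    "tg43_dose_grid",
]

_TG43 = files("liverbrachy") / "data" / "tg43"


@dataclass(frozen=True)
class TG43Parameters:
    """Source parameter set: Lambda, active length, g(r), F(r, theta)."""

    dose_rate_constant: float  # cGy / (h * U)
    active_length_mm: float
    g_radii_cm: np.ndarray
    g_values: np.ndarray
    f_radii_cm: np.ndarray = None
    f_thetas_deg: np.ndarray = None
    f_values: np.ndarray = None  # (n_r, n_theta)

    def __post_init__(self):
        if self.dose_rate_constant <= 0:
            raise ValueError("dose rate constant must be positive")
        g1 = np.interp(1.0, self.g_radii_cm, self.g_values)
        if abs(g1 - 1.0) > 1e-6:
            raise ValueError(f"g(1 cm) = {g1}, must be 1")
        if self.f_values is not None:
            i90 = np.searchsorted(self.f_thetas_deg, 90.0)
            if not np.allclose(self.f_values[:, i90], 1.0, atol=1e-6):
                raise ValueError("F(r, 90 deg) must be 1")


@lru_cache(maxsize=1)
def load_default_parameters() -> TG43Parameters:
    """The bundled generic Ir-192 point-source fixture."""
    meta = json.loads((_TG43 / "meta.json").read_text())
    g_rows = [ln.split(",") for ln in
              (_TG43 / "g.csv").read_text().strip().splitlines()[1:]]
    g = np.array(g_rows, dtype=float)
    f_lines = (_TG43 / "anisotropy_synthetic.csv").read_text().strip().splitlines()
    thetas = np.array(f_lines[0].split(",")[1:], dtype=float)
    f_rows = np.array([ln.split(",") for ln in f_lines[1:]], dtype=float)
    return TG43Parameters(
        dose_rate_constant=meta["dose_rate_constant_cGy_per_h_U"],
        active_length_mm=meta["active_length_mm"],
        g_radii_cm=g[:, 0], g_values=g[:, 1],
        f_radii_cm=f_rows[:, 0], f_thetas_deg=thetas,
        f_values=f_rows[:, 1:],
    )


def geometry_function(r_cm, theta_deg=90.0, active_length_mm=None):
    """Line-source geometry function G_L(r, theta) in cm^-2.

    With ``active_length_mm`` omitted (or zero) the point-source form
    1/r^2 is returned.  On the source axis (theta = 0 or 180 deg) the
    closed-form limit 1/(r^2 - L^2/4) applies.
    """
    r = np.asarray(r_cm, dtype=float)
    if np.any(r <= 0):
        raise ValueError("r must be positive")
    if not active_length_mm:
        out = 1.0 / r**2
        return float(out) if np.isscalar(r_cm) else out
    L = active_length_mm / 10.0  # cm
    theta = np.deg2rad(np.asarray(theta_deg, dtype=float))
    r, theta = np.broadcast_arrays(r, theta)
    sin_t, cos_t = np.sin(theta), np.cos(theta)
    # angle subtended by the line source at the field point
    x1, y1 = r * cos_t - L / 2, r * sin_t
    x2, y2 = r * cos_t + L / 2, r * sin_t
    beta = np.arctan2(y1, x1) - np.arctan2(y2, x2)
    beta = np.abs(beta)
    with np.errstate(divide="ignore", invalid="ignore"):
        g_line = beta / (L * r * sin_t)
    on_axis = np.abs(sin_t) < 1e-9
    g_axis = 1.0 / np.clip(r**2 - L**2 / 4.0, 1e-12, None)
    out = np.where(on_axis, g_axis, g_line)
    return float(out) if np.isscalar(r_cm) and np.isscalar(theta_deg) else out


def radial_dose_function(params: TG43Parameters, r_cm):
    """g(r), linearly interpolated; no extrapolation."""
    r = np.asarray(r_cm, dtype=float)
    lo, hi = params.g_radii_cm[0], params.g_radii_cm[-1]
    if np.any(r < lo) or np.any(r > hi):
        raise ValueError(f"r outside g(r) table range [{lo}, {hi}] cm")
    out = np.interp(r, params.g_radii_cm, params.g_values)
    return float(out) if np.isscalar(r_cm) else out


def anisotropy(params: TG43Parameters, r_cm, theta_deg):
    """F(r, theta) by bilinear interpolation; 1 if no table is loaded."""
    if params.f_values is None:
        return np.ones_like(np.asarray(r_cm, dtype=float))
    r = np.clip(np.asarray(r_cm, dtype=float),
                params.f_radii_cm[0], params.f_radii_cm[-1])
    t = np.clip(np.asarray(theta_deg, dtype=float),
                params.f_thetas_deg[0], params.f_thetas_deg[-1])
    ri = np.clip(np.searchsorted(params.f_radii_cm, r) - 1, 0,
                 len(params.f_radii_cm) - 2)
    ti = np.clip(np.searchsorted(params.f_thetas_deg, t) - 1, 0,
                 len(params.f_thetas_deg) - 2)
    wr = (r - params.f_radii_cm[ri]) / (
        params.f_radii_cm[ri + 1] - params.f_radii_cm[ri])
    wt = (t - params.f_thetas_deg[ti]) / (
        params.f_thetas_deg[ti + 1] - params.f_thetas_deg[ti])
    v = params.f_values
    out = ((1 - wr) * (1 - wt) * v[ri, ti]
           + wr * (1 - wt) * v[ri + 1, ti]
           + (1 - wr) * wt * v[ri, ti + 1]
           + wr * wt * v[ri + 1, ti + 1])
    return float(out) if np.isscalar(r_cm) and np.isscalar(theta_deg) else out


def tg43_dose_rate(r_cm, theta_deg, air_kerma_strength_U,
                   params: TG43Parameters = None, line_source: bool = False):
    """Dose rate in water, cGy/h, at polar coordinates (r, theta)."""
    if params is None:
        params = load_default_parameters()
    if line_source:
        L = params.active_length_mm
        g_ratio = (geometry_function(r_cm, theta_deg, L)
                   / geometry_function(1.0, 90.0, L))
        f = anisotropy(params, r_cm, theta_deg)
    else:
        g_ratio = geometry_function(r_cm)  # 1/r^2, G(1 cm) = 1
        f = 1.0
    return (air_kerma_strength_U * params.dose_rate_constant
            * g_ratio * radial_dose_function(params, r_cm) * f)


def tg43_dose_grid(plan, grid: VoxelGrid, params: TG43Parameters = None,
                   line_source: bool = False) -> VoxelGrid:
    """Superpose TG-43 dose (Gy) over all dwell positions onto a grid.

    Voxels closer to a dwell than the g(r) table minimum (or farther than
    its maximum) are evaluated at the clamped radius, with a warning.
    """
    if params is None:
        params = load_default_parameters()
    xs = grid.axis_coords(0)[:, None, None]
    ys = grid.axis_coords(1)[None, :, None]
    zs = grid.axis_coords(2)[None, None, :]
    dose = np.zeros(grid.shape)
    lo, hi = params.g_radii_cm[0], params.g_radii_cm[-1]
    clamped = False
    for pos, t_s in zip(plan.dwell_positions, plan.dwell_times):
        if t_s == 0:
            continue
        r = np.sqrt((xs - pos[0]) ** 2 + (ys - pos[1]) ** 2
                    + (zs - pos[2]) ** 2) / 10.0  # cm
        if line_source:
            dz = (zs - pos[2]) / 10.0 + np.zeros_like(r)
            with np.errstate(invalid="ignore"):
                theta = np.degrees(np.arccos(np.clip(dz / np.maximum(r, 1e-9),
                                                     -1, 1)))
        else:
            theta = 90.0
        rc = np.clip(r, max(lo, 1e-3), hi)
        clamped = clamped or np.any(rc != r)
        rate = tg43_dose_rate(rc, theta, plan.source_strength_U, params,
                              line_source)
        # correct the geometry factor back to the true radius where only
        # the table lookup needed clamping
        rate = rate * (rc / np.maximum(r, 1e-3)) ** 2
        dose += rate * (t_s / 3600.0) / 100.0  # cGy/h * h -> Gy
    if clamped:
        warnings.warn("voxels outside the g(r) table range were evaluated "
                      "at the clamped radius", stacklevel=2)
    return grid.with_values(dose)
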