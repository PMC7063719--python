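"""Physics validation experiments.

Self-contained numerical experiments exercising the transport engine
against independent references: inverse-square fall-off in near-vacuum,
primary transmission through a water slab versus exp(-mu d), Compton
kinematics, scoring-mode coefficient ratios, MC-versus-TG-43 agreement
in water (the central cross-check: the two sides use independent
normalisations), and the 1/sqrt(N) convergence of the batch uncertainty.

Each experiment returns plain numbers so the same code backs the unit
tests, the ``validate-physics`` CLI command and the acceptance script.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .geometry import VoxelGrid
from .mc_engine import (
    TreatmentPlan,
    run_simulation,
    uniform_phantom,
    water_phantom_like,
)
from .physics_data import (
    build_material,
    coefficient,
    load_ir192_spectrum,
    load_material,
)
from .tg43 import load_default_parameters, tg43_dose_rate

__all__ = [
    "centered_grid",
    "single_dwell_plan",
    "inverse_square_ratio",
    "woodcock_slab_transmission",
    "scoring_mode_ratio",
    "mc_vs_tg43_water",
    "dwm_vs_dww_in_liver",
    "convergence_ratio",
    "physics_suite",
]


def centered_grid(n: int = 64, spacing_mm: float = 1.0) -> VoxelGrid:
    """A cubic grid centred on the origin."""
    spacing = np.full(3, float(spacing_mm))
    origin = -(n - 1) / 2.0 * spacing
    return VoxelGrid(np.zeros((n, n, n), dtype=np.int16), spacing, origin)


def single_dwell_plan(time_s: float = 300.0, s_k: float = 40700.0,
                      prescription: float = 15.0) -> TreatmentPlan:
    return TreatmentPlan(np.zeros((1, 3)), np.array([time_s]),
                         source_strength_U=s_k, prescription_Gy=prescription)


def _radius_grid(grid: VoxelGrid) -> np.ndarray:
    xs = grid.axis_coords(0)[:, None, None]
    ys = grid.axis_coords(1)[None, :, None]
    zs = grid.axis_coords(2)[None, None, :]
    return np.sqrt(xs**2 + ys**2 + zs**2) / 10.0  # cm


def _shell_mean(values, r, r0, half_width_cm):
    sel = np.abs(r - r0) <= half_width_cm
    return float(values[sel].mean())


def inverse_square_ratio(n_histories: int = 10**6, seed: int = 1,
                         r_inner: float = 1.0, r_outer: float = 2.0):
    """Kerma ratio between thin shells in near-vacuum vs the 1/r^2 law.

    Returns ``(ratio, sigma_ratio, expected)`` with the MC standard error
    propagated from batch statistics.
    """
    thin_air = build_material(
        "near_vacuum", load_material("air").composition, 1e-9)
    grid = centered_grid(n=64, spacing_mm=1.0)
    phantom = uniform_phantom(grid, thin_air)
    plan = single_dwell_plan()
    dose, batches = run_simulation(
        phantom, plan, mode="w,m", n_histories=n_histories, n_batches=10,
        seed=seed, return_batches=True)
    r = _radius_grid(grid)
    hw = 0.05  # cm
    means_in = np.array([_shell_mean(b, r, r_inner, hw) for b in batches])
    means_out = np.array([_shell_mean(b, r, r_outer, hw) for b in batches])
    ratio = means_in.mean() / means_out.mean()
    k = len(batches)
    rel_in = means_in.std(ddof=1) / np.sqrt(k) / means_in.mean()
    rel_out = means_out.std(ddof=1) / np.sqrt(k) / means_out.mean()
    sigma = ratio * np.hypot(rel_in, rel_out)
    # The 1/r^2 law evaluated on the same discrete voxels: the finite
    # lattice shifts the thin-shell ratio by ~1% from the ideal
    # (r2/r1)^2, identically for MC and analytic, so compare like with
    # like and rescale so the ideal law reads as the expected value.
    # The track-length tally estimates the *volume average* of
    # 1/(4 pi r^2) per voxel, so the reference is volume-averaged too
    # (2-point Gauss rule per axis, exact through cubic terms).
    inv_r2 = np.zeros_like(r)
    gauss = grid.spacing / 10.0 / (2.0 * np.sqrt(3.0))  # cm offsets
    xs = grid.axis_coords(0)[:, None, None] / 10.0
    ys = grid.axis_coords(1)[None, :, None] / 10.0
    zs = grid.axis_coords(2)[None, None, :] / 10.0
    for sx in (-1, 1):
        for sy in (-1, 1):
            for sz in (-1, 1):
                inv_r2 += 1.0 / ((xs + sx * gauss[0]) ** 2
                                 + (ys + sy * gauss[1]) ** 2
                                 + (zs + sz * gauss[2]) ** 2)
    inv_r2 /= 8.0
    lattice = (_shell_mean(inv_r2, r, r_inner, hw)
               / _shell_mean(inv_r2, r, r_outer, hw))
    ideal = (r_outer / r_inner) ** 2
    ratio = ratio * ideal / lattice
    sigma = sigma * ideal / lattice
    return float(ratio), float(sigma), ideal


@njit(cache=False)
def _woodcock_count(n, seed, mu, mu_majorant, depth_cm):
    """Photons surviving ``depth_cm`` of a medium without real collision,
    sampled exactly as the engine does (majorant flights + rejection)."""
    np.random.seed(seed)
    survived = 0
    for _ in range(n):
        x = 0.0
        while True:
            x += -np.log(np.random.random()) / mu_majorant
            if x >= depth_cm:
                survived += 1
                break
            if np.random.random() * mu_majorant < mu:
                break
    return survived


def woodcock_slab_transmission(n: int = 2 * 10**5, seed: int = 1,
                               depth_cm: float = 5.0,
                               energy_mev: float = 0.316506):
    """Primary transmission through a water slab vs exp(-mu d).

    The majorant is deliberately larger than mu (cortical bone level) so
    the virtual-collision rejection is exercised.  Returns
    ``(observed_fraction, expected, binomial_sigma)``.
    """
    water = load_material("water")
    bone = load_material("cortical_bone")
    mu = coefficient(water, energy_mev, "mu") * water.density
    mu_maj = coefficient(bone, energy_mev, "mu") * bone.density
    survived = _woodcock_count(n, seed, mu, mu_maj, depth_cm)
    observed = survived / n
    expected = float(np.exp(-mu * depth_cm))
    sigma = float(np.sqrt(expected * (1 - expected) / n))
    return observed, expected, sigma


def scoring_mode_ratio(energy_mev: float = 0.316506):
    """(m,m)/(w,m) tally ratio for one segment in a pure-liver voxel,
    versus the muen/rho ratio of liver to water at that energy."""
    from .mc_engine import score_kerma

    liver = load_material("liver")
    water = load_material("water")
    grid = centered_grid(n=3, spacing_mm=2.0)
    phantom = uniform_phantom(grid, liver)
    segments = [((1, 1, 1), 0.7, energy_mev)]
    t_wm = score_kerma(segments, "w,m", phantom)[1, 1, 1]
    t_mm = score_kerma(segments, "m,m", phantom)[1, 1, 1]
    expected = (coefficient(liver, energy_mev, "muen")
                / coefficient(water, energy_mev, "muen"))
    return t_mm / t_wm, expected


def mc_vs_tg43_water(n_histories: int = 5 * 10**6, seed: int = 1,
                     radii_cm=(1.0, 2.0, 3.0, 5.0)):
    """MC water dose vs the analytic TG-43 point-source calculation.

    Both sides are averaged over the same thin spherical shells of voxel
    centres, so voxel-volume averaging bias cancels.  The phantom spans
    +-11.2 cm, leaving a >= 6 cm full-scatter margin beyond the outermost
    shell (the analytic reference assumes unbounded water, so missing
    backscatter would otherwise depress the MC dose at large radii).
    Returns a list of ``(r, mc_over_tg43, rel_sigma_mc)`` tuples.
    """
    grid = centered_grid(n=112, spacing_mm=2.0)
    phantom = water_phantom_like(grid)
    plan = single_dwell_plan(time_s=600.0)
    dose, batches = run_simulation(
        phantom, plan, mode="w,w", n_histories=n_histories, n_batches=10,
        seed=seed, return_batches=True)
    r = _radius_grid(grid)
    params = load_default_parameters()
    t_h = plan.total_time_s / 3600.0
    out = []
    hw = 0.1
    for r0 in radii_cm:
        sel = np.abs(r - r0) <= hw
        mc = dose.dose.values[sel].mean()
        tg = (tg43_dose_rate(r[sel], 90.0, plan.source_strength_U, params)
              * t_h / 100.0).mean()
        shell = np.array([b[sel].mean() for b in batches])
        rel_sigma = shell.std(ddof=1) / np.sqrt(len(batches)) / shell.mean()
        out.append((r0, mc / tg, float(rel_sigma)))
    return out


def dwm_vs_dww_in_liver(n_histories: int = 2 * 10**6, seed: int = 1,
                        r_cm: float = 5.0):
    """Directional check: in an all-liver phantom, dose-to-water scored in
    medium beyond 3 cm falls below the all-water dose.

    The effect is small in an unbounded medium -- scatter buildup almost
    fully compensates the denser liver's extra attenuation at short range
    -- so the shell sits at 5 cm, where the net attenuation term wins,
    and the phantom keeps a full-scatter margin beyond it.  Returns
    ``(dwm_shell, dww_shell, combined_sigma)``.
    """
    grid = centered_grid(n=112, spacing_mm=2.0)
    plan = single_dwell_plan()
    liver = load_material("liver")
    dwm, b_wm = run_simulation(uniform_phantom(grid, liver), plan,
                               mode="w,m", n_histories=n_histories,
                               n_batches=10, seed=seed, return_batches=True)
    dww, b_ww = run_simulation(water_phantom_like(grid), plan,
                               mode="w,w", n_histories=n_histories,
                               n_batches=10, seed=seed, return_batches=True)
    r = _radius_grid(grid)
    hw = 0.1
    m_wm = np.array([_shell_mean(b, r, r_cm, hw) for b in b_wm])
    m_ww = np.array([_shell_mean(b, r, r_cm, hw) for b in b_ww])
    k = len(b_wm)
    sigma = np.hypot(m_wm.std(ddof=1), m_ww.std(ddof=1)) / np.sqrt(k)
    return float(m_wm.mean()), float(m_ww.mean()), float(sigma)


def convergence_ratio(n_histories: int = 2 * 10**5, seed: int = 1):
    """Median rel. uncertainty ratio when histories are quadrupled.

    The batch estimator should scale as 1/sqrt(N), i.e. the ratio should
    be close to 2.
    """
    grid = centered_grid(n=48, spacing_mm=2.0)
    phantom = water_phantom_like(grid)
    plan = single_dwell_plan()
    d1 = run_simulation(phantom, plan, mode="w,w", n_histories=n_histories,
                        n_batches=10, seed=seed)
    d4 = run_simulation(phantom, plan, mode="w,w",
                        n_histories=4 * n_histories, n_batches=10,
                        seed=seed + 1)
    sel = d1.dose.values >= 0.3 * plan.prescription_Gy
    r1 = d1.rel_uncertainty.values[sel]
    r4 = d4.rel_uncertainty.values[sel]
    ok = (r1 > 0) & (r4 > 0)
    return float(np.median(r1[ok] / r4[ok]))


def physics_suite(seed: int = 1, n: int = 10**6):
    """The oracle suite as (name, value, note) rows for the CLI."""
    from .physics_data import compton_scattered_energy

    rows = []
    ratio, sigma, expected = inverse_square_ratio(n_histories=n, seed=seed)
    rows.append(("inverse_square_ratio", ratio,
                 f"expected {expected} +- {3 * sigma:.3f} (3 sigma)"))
    obs, exp, bsig = woodcock_slab_transmission(seed=seed)
    rows.append(("slab_transmission", obs,
                 f"expected {exp:.5f} +- {3 * bsig:.5f} (3 sigma)"))
    e180 = compton_scattered_energy(0.316506, -1.0)
    rows.append(("compton_180_energy_MeV", e180,
                 "closed form E/(1+2E/m_e c^2)"))
    got, want = scoring_mode_ratio()
    rows.append(("liver_over_water_muen_ratio", got, f"table value {want:.6f}"))
    for r0, rat, rsig in mc_vs_tg43_water(n_histories=max(n, 10**6),
                                          seed=seed):
        rows.append((f"mc_over_tg43_r{r0:g}cm", rat,
                     f"MC shell noise {rsig:.4f} (1 sigma)"))
    return rows
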