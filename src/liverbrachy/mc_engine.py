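"""Collision-kerma Monte Carlo photon transport on voxel phantoms.

Model
-----
Each dwell position is an isotropic point source emitting the bundled
Ir-192 line spectrum.  Photons are transported by Woodcock (delta)
tracking against the energy-dependent global majorant; at real collisions
the interaction is photoelectric absorption or Compton scattering off a
free electron (Klein-Nishina), with the channel probability taken from
the bundled cross sections.  Rayleigh scattering is omitted (the bundled
mu/rho is the coherent-free total, so transport and tables are
consistent).  Secondary electrons are not transported: dose is
approximated as collision kerma under charged-particle equilibrium, via a
track-length fluence estimator -- every flight segment (real or virtual
collision) adds  weight * E * (muen/rho)(E) * length / V  to its voxel,
scored simultaneously with the water coefficient (modes "w,w"/"w,m") and
the voxel medium's coefficient (mode "m,m").  Photons below 10 keV are
absorbed on the spot.

Normalisation is analytic: the emission rate follows from the air-kerma
strength S_K as  photons/s = S_K / k_air, with k_air the air kerma at 1 m
per emitted photon summed over the spectrum.  This is independent of the
TG-43 dose-rate constant, so MC vs TG-43 agreement is a genuine two-sided
check.

Uncertainty uses the batch method: the run is split into batches with
counter-derived sub-seeds; the voxel-wise standard error of the batch
mean, divided by the mean, is the relative uncertainty, and its maximum
inside the 30%-isodose line (>= 0.30 x prescription) is the per-run
summary statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as dc_replace

import numpy as np
from numba import njit

from .geometry import SegmentedPhantom, VoxelGrid
from .physics_data import (
    PhotonSpectrum,
    coefficient,
    kn_compton_mu_rho,
    load_ir192_spectrum,
    load_material,
)

__all__ = [
    "TreatmentPlan",
    "DoseGrid",
    "run_simulation",
    "run_modes",
    "run_to_uncertainty",
    "transport_photon",
    "score_kerma",
    "air_kerma_per_photon_at_1m",
    "emission_rate",
    "normalize_dose",
    "estimate_uncertainty",
    "apply_dose_cutoff",
    "water_phantom_like",
    "uniform_phantom",
]

MEV_PER_G_TO_GY = 1.602176634e-10
ENERGY_CUTOFF_MEV = 0.010
DEFAULT_DOSE_CAP_GY = 200.0
MODES = ("w,w", "w,m", "m,m")
_N_ENERGY = 512


@dataclass
class TreatmentPlan:
    """Dwell positions/times, source strength and prescription."""

    dwell_positions: np.ndarray  # (n, 3) mm
    dwell_times: np.ndarray  # s
    source_strength_U: float  # air-kerma strength, uGy m^2/h
    prescription_Gy: float

    def __post_init__(self):
        self.dwell_positions = np.atleast_2d(
            np.asarray(self.dwell_positions, dtype=float))
        self.dwell_times = np.atleast_1d(
            np.asarray(self.dwell_times, dtype=float))
        if self.dwell_positions.shape[0] == 0:
            raise ValueError("plan needs at least one dwell position")
        if self.dwell_positions.shape[1] != 3:
            raise ValueError("dwell positions must be (n, 3) mm")
        if self.dwell_times.shape[0] != self.dwell_positions.shape[0]:
            raise ValueError("one dwell time per dwell position required")
        if np.any(self.dwell_times < 0):
            raise ValueError("dwell times must be non-negative")
        if self.source_strength_U <= 0:
            raise ValueError("source strength must be positive")
        if self.prescription_Gy <= 0:
            raise ValueError("prescription dose must be positive")

    @property
    def total_time_s(self) -> float:
        return float(self.dwell_times.sum())


@dataclass
class DoseGrid:
    """Absorbed dose (Gy) with relative 1-sigma uncertainty and metadata."""

    dose: VoxelGrid
    rel_uncertainty: VoxelGrid
    mode: str
    histories: int
    seed: int
    max_rel_unc_30pct: float = np.nan

    def __post_init__(self):
        if self.mode not in MODES and self.mode != "w,w-analytic":
            raise ValueError(f"unknown scoring mode {self.mode!r}")
        if np.any(self.dose.values < 0):
            raise ValueError("dose must be non-negative")


# ----------------------------------------------------------------------
# engine tables: everything the kernel needs, on a fine log-energy grid
# ----------------------------------------------------------------------

class EngineTables:
    """Per-material cross sections resampled onto a fine log-energy grid."""

    def __init__(self, materials, e_min=ENERGY_CUTOFF_MEV, e_max=1.5,
                 n=_N_ENERGY):
        self.e_grid = np.exp(np.linspace(np.log(e_min), np.log(e_max), n))
        self.loge0 = np.log(e_min)
        self.inv_dloge = (n - 1) / (np.log(e_max) - np.log(e_min))
        water = load_material("water")
        nm = len(materials)
        self.mu_lin = np.empty((nm, n))
        self.muen_m = np.empty((nm, n))
        self.p_pe = np.empty((nm, n))
        self.rho = np.array([m.density for m in materials])
        for i, mat in enumerate(materials):
            mu_rho = coefficient(mat, self.e_grid, "mu")
            self.mu_lin[i] = mu_rho * mat.density
            self.muen_m[i] = coefficient(mat, self.e_grid, "muen")
            kn = kn_compton_mu_rho(mat, self.e_grid)
            self.p_pe[i] = np.clip(1.0 - kn / mu_rho, 0.0, 1.0)
        self.muen_w = coefficient(water, self.e_grid, "muen")
        self.mu_majorant = self.mu_lin.max(axis=0)


# ----------------------------------------------------------------------
# numba kernels
# ----------------------------------------------------------------------

@njit(cache=False, inline="always")
def _interp(arr, f):
    i = int(f)
    w = f - i
    return arr[i] * (1.0 - w) + arr[i + 1] * w


@njit(cache=False)
def _track_one(x, y, z, ux, uy, uz, energy,
               mat, gx0, gy0, gz0, sx, sy, sz,
               mu_lin, p_pe, muen_w, muen_m, rho,
               mu_maj, loge0, inv_dloge, ne,
               inv_voxvol, tally_w, tally_m,
               record, seg_vox, seg_len, seg_e):
    """Transport one photon; tally inline and optionally record segments.

    Returns the number of recorded segments (0 when record is False).
    """
    nx, ny, nz = mat.shape
    nseg = 0
    cap = seg_len.shape[0]
    while True:
        if energy < ENERGY_CUTOFF_MEV:
            break
        f = (np.log(energy) - loge0) * inv_dloge
        if f < 0.0:
            f = 0.0
        if f > ne - 1.000001:
            f = ne - 1.000001
        mumaj = _interp(mu_maj, f)
        muen_w_e = _interp(muen_w, f)
        s = -np.log(np.random.random()) / mumaj

        # voxel marching along the flight segment of length s
        ix = int(np.floor((x - gx0) / sx))
        iy = int(np.floor((y - gy0) / sy))
        iz = int(np.floor((z - gz0) / sz))
        if ix < 0 or ix >= nx or iy < 0 or iy >= ny or iz < 0 or iz >= nz:
            return nseg
        if ux > 0.0:
            tmx = ((gx0 + (ix + 1) * sx) - x) / ux
            tdx = sx / ux
            stx = 1
        elif ux < 0.0:
            tmx = ((gx0 + ix * sx) - x) / ux
            tdx = -sx / ux
            stx = -1
        else:
            tmx = 1e30
            tdx = 1e30
            stx = 0
        if uy > 0.0:
            tmy = ((gy0 + (iy + 1) * sy) - y) / uy
            tdy = sy / uy
            sty = 1
        elif uy < 0.0:
            tmy = ((gy0 + iy * sy) - y) / uy
            tdy = -sy / uy
            sty = -1
        else:
            tmy = 1e30
            tdy = 1e30
            sty = 0
        if uz > 0.0:
            tmz = ((gz0 + (iz + 1) * sz) - z) / uz
            tdz = sz / uz
            stz = 1
        elif uz < 0.0:
            tmz = ((gz0 + iz * sz) - z) / uz
            tdz = -sz / uz
            stz = -1
        else:
            tmz = 1e30
            tdz = 1e30
            stz = 0

        t = 0.0
        inside = True
        while True:
            tnext = tmx
            axis = 0
            if tmy < tnext:
                tnext = tmy
                axis = 1
            if tmz < tnext:
                tnext = tmz
                axis = 2
            end = tnext if tnext < s else s
            seg = end - t
            if seg > 0.0:
                m = mat[ix, iy, iz]
                c = energy * seg * inv_voxvol
                tally_w[ix, iy, iz] += c * muen_w_e
                tally_m[ix, iy, iz] += c * _interp(muen_m[m], f)
                if record and nseg < cap:
                    seg_vox[nseg, 0] = ix
                    seg_vox[nseg, 1] = iy
                    seg_vox[nseg, 2] = iz
                    seg_len[nseg] = seg
                    seg_e[nseg] = energy
                    nseg += 1
            if s <= tnext:
                break
            t = tnext
            if axis == 0:
                ix += stx
                tmx += tdx
                if ix < 0 or ix >= nx:
                    inside = False
                    break
            elif axis == 1:
                iy += sty
                tmy += tdy
                if iy < 0 or iy >= ny:
                    inside = False
                    break
            else:
                iz += stz
                tmz += tdz
                if iz < 0 or iz >= nz:
                    inside = False
                    break
        if not inside:
            return nseg

        x += s * ux
        y += s * uy
        z += s * uz

        m = mat[ix, iy, iz]
        mu_here = _interp(mu_lin[m], f)
        if np.random.random() * mumaj >= mu_here:
            continue  # virtual collision: direction and energy unchanged

        if np.random.random() < _interp(p_pe[m], f):
            return nseg  # photoelectric absorption (kerma already tallied)

        # Compton: sample x = E'/E from Klein-Nishina by rejection
        a = energy / 0.51099895
        xmin = 1.0 / (1.0 + 2.0 * a)
        fmax = xmin + 1.0 / xmin
        while True:
            xr = xmin + (1.0 - xmin) * np.random.random()
            cost = 1.0 - (1.0 / xr - 1.0) / a
            val = xr + 1.0 / xr - (1.0 - cost * cost)
            if np.random.random() * fmax <= val:
                break
        energy *= xr
        sint = np.sqrt(max(0.0, 1.0 - cost * cost))
        phi = 2.0 * np.pi * np.random.random()
        cphi = np.cos(phi)
        sphi = np.sin(phi)
        if abs(uz) < 0.99999:
            den = np.sqrt(1.0 - uz * uz)
            nux = ux * cost + sint * (ux * uz * cphi - uy * sphi) / den
            nuy = uy * cost + sint * (uy * uz * cphi + ux * sphi) / den
            nuz = uz * cost - den * sint * cphi
        else:
            sign = 1.0 if uz > 0 else -1.0
            nux = sint * cphi
            nuy = sign * sint * sphi
            nuz = sign * cost
        norm = np.sqrt(nux * nux + nuy * nuy + nuz * nuz)
        ux, uy, uz = nux / norm, nuy / norm, nuz / norm

        if energy < ENERGY_CUTOFF_MEV:
            # absorb the residual photon locally as kerma
            m = mat[ix, iy, iz]
            d = energy * inv_voxvol / rho[m]
            tally_w[ix, iy, iz] += d
            tally_m[ix, iy, iz] += d
            return nseg
    return nseg


@njit(cache=False)
def _run_batch(n_photons, seed,
               mat, gx0, gy0, gz0, sx, sy, sz,
               mu_lin, p_pe, muen_w, muen_m, rho,
               mu_maj, loge0, inv_dloge,
               spec_e, spec_cdf, dwell_pos, dwell_cdf,
               inv_voxvol, tally_w, tally_m):
    np.random.seed(seed)
    ne = mu_maj.shape[0]
    seg_vox = np.empty((1, 3), dtype=np.int64)
    seg_len = np.empty(1)
    seg_e = np.empty(1)
    for _ in range(n_photons):
        r = np.random.random()
        j = np.searchsorted(dwell_cdf, r)
        x = dwell_pos[j, 0]
        y = dwell_pos[j, 1]
        z = dwell_pos[j, 2]
        r = np.random.random()
        k = np.searchsorted(spec_cdf, r)
        energy = spec_e[k]
        cost = 2.0 * np.random.random() - 1.0
        sint = np.sqrt(1.0 - cost * cost)
        phi = 2.0 * np.pi * np.random.random()
        ux = sint * np.cos(phi)
        uy = sint * np.sin(phi)
        uz = cost
        _track_one(x, y, z, ux, uy, uz, energy,
                   mat, gx0, gy0, gz0, sx, sy, sz,
                   mu_lin, p_pe, muen_w, muen_m, rho,
                   mu_maj, loge0, inv_dloge, ne,
                   inv_voxvol, tally_w, tally_m,
                   False, seg_vox, seg_len, seg_e)


@njit(cache=False)
def _track_recorded(seed, x, y, z, ux, uy, uz, energy,
                    mat, gx0, gy0, gz0, sx, sy, sz,
                    mu_lin, p_pe, muen_w, muen_m, rho,
                    mu_maj, loge0, inv_dloge,
                    inv_voxvol, tally_w, tally_m,
                    seg_vox, seg_len, seg_e):
    np.random.seed(seed)
    ne = mu_maj.shape[0]
    return _track_one(x, y, z, ux, uy, uz, energy,
                      mat, gx0, gy0, gz0, sx, sy, sz,
                      mu_lin, p_pe, muen_w, muen_m, rho,
                      mu_maj, loge0, inv_dloge, ne,
                      inv_voxvol, tally_w, tally_m,
                      True, seg_vox, seg_len, seg_e)


@njit(cache=False)
def _count_uncollided(n, seed, energy, mu, depth):
    """Photons of a pencil beam crossing ``depth`` cm without collision."""
    np.random.seed(seed)
    count = 0
    for _ in range(n):
        s = -np.log(np.random.random()) / mu
        if s > depth:
            count += 1
    return count


# ----------------------------------------------------------------------
# python-level operations
# ----------------------------------------------------------------------

def _grid_geometry_cm(grid: VoxelGrid):
    s = grid.spacing / 10.0
    lower = grid.origin / 10.0 - s / 2.0
    return lower, s


def _kernel_args(phantom: SegmentedPhantom, tables: EngineTables):
    grid = phantom.material_index
    lower, s = _grid_geometry_cm(grid)
    mat = np.ascontiguousarray(phantom.material_index.values.astype(np.int16))
    inv_voxvol = 1.0 / grid.voxel_volume_cm3
    return (mat, lower[0], lower[1], lower[2], s[0], s[1], s[2],
            tables.mu_lin, tables.p_pe, tables.muen_w, tables.muen_m,
            tables.rho, tables.mu_majorant, tables.loge0, tables.inv_dloge,
            inv_voxvol)


def water_phantom_like(grid: VoxelGrid) -> SegmentedPhantom:
    """An all-water phantom on the given grid (the TG-43 surrogate)."""
    water = load_material("water")
    idx = grid.with_values(np.zeros(grid.shape, dtype=np.int16))
    dens = grid.with_values(np.full(grid.shape, water.density))
    return SegmentedPhantom(idx, dens, [water])


def uniform_phantom(grid: VoxelGrid, material) -> SegmentedPhantom:
    """A phantom filled with a single material."""
    idx = grid.with_values(np.zeros(grid.shape, dtype=np.int16))
    dens = grid.with_values(np.full(grid.shape, material.density))
    return SegmentedPhantom(idx, dens, [material])


def air_kerma_per_photon_at_1m(spectrum: PhotonSpectrum) -> float:
    """Air kerma at 1 m per emitted photon, Gy (vacuum attenuation)."""
    air = load_material("air")
    p = spectrum.probabilities
    e = spectrum.energies
    muen = coefficient(air, e, "muen")
    fluence = 1.0 / (4.0 * np.pi * 100.0**2)  # cm^-2 at 1 m per photon
    return float(np.sum(p * e * muen) * fluence * MEV_PER_G_TO_GY)


def emission_rate(plan: TreatmentPlan, spectrum: PhotonSpectrum) -> float:
    """Photons emitted per second for the plan's air-kerma strength."""
    k_air = air_kerma_per_photon_at_1m(spectrum)
    sk_gy_per_h = plan.source_strength_U * 1e-6  # U -> Gy m^2/h at 1 m
    return sk_gy_per_h / k_air / 3600.0


def normalize_dose(tally_per_history: np.ndarray, plan: TreatmentPlan,
                   spectrum: PhotonSpectrum) -> np.ndarray:
    """Convert a per-history kerma tally (MeV/g) to absorbed dose in Gy."""
    photons_total = emission_rate(plan, spectrum) * plan.total_time_s
    return tally_per_history * photons_total * MEV_PER_G_TO_GY


def _validate_run(phantom, plan, n_histories, n_batches):
    if n_batches < 2 or n_histories < n_batches:
        raise ValueError("need n_histories >= n_batches >= 2")
    if plan.total_time_s <= 0:
        raise ValueError("total dwell time is zero")
    grid = phantom.material_index
    lower, s = _grid_geometry_cm(grid)
    upper = lower + s * np.array(grid.shape)
    pos = plan.dwell_positions / 10.0
    if np.any(pos < lower) or np.any(pos >= upper):
        raise ValueError("dwell position outside the phantom grid")


def _sub_seed(seed: int, counter: int) -> int:
    return int((seed * 2654435761 + 97531 * (counter + 1)) % (2**31 - 1))


class _BatchAccumulator:
    def __init__(self, shape):
        self.n = 0
        self.s1 = np.zeros(shape)
        self.s2 = np.zeros(shape)

    def add(self, batch_dose):
        self.n += 1
        self.s1 += batch_dose
        self.s2 += batch_dose**2

    def mean(self):
        return self.s1 / self.n

    def rel_uncertainty(self):
        mean = self.mean()
        var = np.maximum(self.s2 / self.n - mean**2, 0.0)
        # standard error of the batch mean
        se = np.sqrt(var / max(self.n - 1, 1))
        with np.errstate(divide="ignore", invalid="ignore"):
            rel = np.where(mean > 0, se / mean, 0.0)
        return rel


def _max_rel_unc_30pct(dose, rel_unc, prescription):
    sel = dose >= 0.30 * prescription
    if not np.any(sel):
        return float("nan")
    return float(rel_unc[sel].max())


def _run_batches(phantom, plan, spectrum, n_histories, n_batches, seed,
                 keep_batches=False):
    tables = EngineTables(phantom.materials)
    args = _kernel_args(phantom, tables)
    spec_cdf = np.cumsum(spectrum.probabilities)
    spec_cdf[-1] = 1.0
    t = plan.dwell_times / plan.total_time_s
    dwell_cdf = np.cumsum(t)
    dwell_cdf[-1] = 1.0
    dwell_pos = np.ascontiguousarray(plan.dwell_positions / 10.0)

    shape = phantom.material_index.shape
    per_batch = n_histories // n_batches
    photons_total = emission_rate(plan, spectrum) * plan.total_time_s
    acc_w = _BatchAccumulator(shape)
    acc_m = _BatchAccumulator(shape)
    batches_w, batches_m = [], []
    for b in range(n_batches):
        tally_w = np.zeros(shape)
        tally_m = np.zeros(shape)
        _run_batch(per_batch, _sub_seed(seed, b), *args[:15],
                   spectrum.energies, spec_cdf, dwell_pos, dwell_cdf,
                   args[15], tally_w, tally_m)
        dose_w = tally_w / per_batch * photons_total * MEV_PER_G_TO_GY
        dose_m = tally_m / per_batch * photons_total * MEV_PER_G_TO_GY
        acc_w.add(dose_w)
        acc_m.add(dose_m)
        if keep_batches:
            batches_w.append(dose_w)
            batches_m.append(dose_m)
    return acc_w, acc_m, per_batch * n_batches, batches_w, batches_m


def _make_dose_grid(phantom, plan, acc, mode, histories, seed):
    grid = phantom.material_index
    dose = acc.mean()
    rel = acc.rel_uncertainty()
    return DoseGrid(
        dose=grid.with_values(dose),
        rel_uncertainty=grid.with_values(rel),
        mode=mode,
        histories=histories,
        seed=seed,
        max_rel_unc_30pct=_max_rel_unc_30pct(dose, rel, plan.prescription_Gy),
    )


def run_simulation(phantom: SegmentedPhantom, plan: TreatmentPlan,
                   spectrum: PhotonSpectrum = None, mode: str = "m,m",
                   n_histories: int = 10**6, n_batches: int = 10,
                   seed: int = 0, return_batches: bool = False):
    """Run the MC engine and return the dose in one scoring mode.

    Mode "w,w" replaces the whole phantom by water before transport (the
    TG-43 surrogate); "w,m" transports in medium and scores with the
    water coefficient; "m,m" scores with the medium coefficient.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    if spectrum is None:
        spectrum = load_ir192_spectrum()
    if mode == "w,w":
        phantom = water_phantom_like(phantom.material_index)
    _validate_run(phantom, plan, n_histories, n_batches)
    acc_w, acc_m, histories, bw, bm = _run_batches(
        phantom, plan, spectrum, n_histories, n_batches, seed,
        keep_batches=return_batches)
    acc = acc_m if mode == "m,m" else acc_w
    out = _make_dose_grid(phantom, plan, acc, mode, histories, seed)
    if return_batches:
        return out, (bm if mode == "m,m" else bw)
    return out


def run_modes(phantom: SegmentedPhantom, plan: TreatmentPlan,
              spectrum: PhotonSpectrum = None, modes=MODES,
              n_histories: int = 10**6, n_batches: int = 10,
              seed: int = 0) -> dict:
    """Compute several scoring modes efficiently.

    One transport pass through the heterogeneous phantom yields both
    "w,m" and "m,m"; "w,w" needs its own pass on the water-substituted
    phantom.  All passes share the same seed (common random numbers, so
    mode differences are not noise-dominated).
    """
    if spectrum is None:
        spectrum = load_ir192_spectrum()
    out = {}
    medium_modes = [m for m in modes if m in ("w,m", "m,m")]
    if medium_modes:
        _validate_run(phantom, plan, n_histories, n_batches)
        acc_w, acc_m, hist, _, _ = _run_batches(
            phantom, plan, spectrum, n_histories, n_batches, seed)
        if "w,m" in medium_modes:
            out["w,m"] = _make_dose_grid(phantom, plan, acc_w, "w,m", hist, seed)
        if "m,m" in medium_modes:
            out["m,m"] = _make_dose_grid(phantom, plan, acc_m, "m,m", hist, seed)
    if "w,w" in modes:
        wp = water_phantom_like(phantom.material_index)
        _validate_run(wp, plan, n_histories, n_batches)
        acc_w, _, hist, _, _ = _run_batches(
            wp, plan, spectrum, n_histories, n_batches, seed)
        out["w,w"] = _make_dose_grid(wp, plan, acc_w, "w,w", hist, seed)
    return out


def run_to_uncertainty(phantom: SegmentedPhantom, plan: TreatmentPlan,
                       spectrum: PhotonSpectrum = None, mode: str = "w,w",
                       target_max_rel_unc: float = 0.008,
                       batch_histories: int = 10**5, min_batches: int = 4,
                       max_batches: int = 64, seed: int = 0) -> DoseGrid:
    """Add batches until the 30%-isodose uncertainty drops below target.

    Mirrors the study design of choosing the number of histories so the
    maximum relative standard deviation inside the 30%-isodose line stays
    below a threshold.  Stops at ``max_batches`` regardless.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    if spectrum is None:
        spectrum = load_ir192_spectrum()
    if mode == "w,w":
        phantom = water_phantom_like(phantom.material_index)
    _validate_run(phantom, plan, batch_histories * min_batches, min_batches)
    tables = EngineTables(phantom.materials)
    args = _kernel_args(phantom, tables)
    spec_cdf = np.cumsum(spectrum.probabilities)
    spec_cdf[-1] = 1.0
    dwell_cdf = np.cumsum(plan.dwell_times / plan.total_time_s)
    dwell_cdf[-1] = 1.0
    dwell_pos = np.ascontiguousarray(plan.dwell_positions / 10.0)
    photons_total = emission_rate(plan, spectrum) * plan.total_time_s
    shape = phantom.material_index.shape
    acc = _BatchAccumulator(shape)
    summary = float("inf")
    for b in range(max_batches):
        tally_w = np.zeros(shape)
        tally_m = np.zeros(shape)
        _run_batch(batch_histories, _sub_seed(seed, b), *args[:15],
                   spectrum.energies, spec_cdf, dwell_pos, dwell_cdf,
                   args[15], tally_w, tally_m)
        tally = tally_m if mode == "m,m" else tally_w
        acc.add(tally / batch_histories * photons_total * MEV_PER_G_TO_GY)
        if acc.n >= min_batches:
            summary = _max_rel_unc_30pct(acc.mean(), acc.rel_uncertainty(),
                                         plan.prescription_Gy)
            if summary < target_max_rel_unc:
                break
    dose = acc.mean()
    rel = acc.rel_uncertainty()
    grid = phantom.material_index
    return DoseGrid(grid.with_values(dose), grid.with_values(rel), mode,
                    acc.n * batch_histories, seed,
                    max_rel_unc_30pct=summary)


def transport_photon(phantom: SegmentedPhantom, position_mm, direction,
                     energy_mev: float, seed: int = 0, max_segments=65536):
    """Transport a single photon and return its voxel segments.

    Returns a list of ``((ix, iy, iz), track_length_cm, energy_MeV)``
    covering every voxel traversal (real and virtual-collision flights).
    """
    direction = np.asarray(direction, dtype=float)
    norm = np.linalg.norm(direction)
    if norm == 0:
        raise ValueError("direction must be a non-zero vector")
    direction = direction / norm
    tables = EngineTables(phantom.materials)
    args = _kernel_args(phantom, tables)
    shape = phantom.material_index.shape
    tally_w = np.zeros(shape)
    tally_m = np.zeros(shape)
    seg_vox = np.zeros((max_segments, 3), dtype=np.int64)
    seg_len = np.zeros(max_segments)
    seg_e = np.zeros(max_segments)
    pos = np.asarray(position_mm, dtype=float) / 10.0
    n = _track_recorded(seed, pos[0], pos[1], pos[2],
                        direction[0], direction[1], direction[2],
                        float(energy_mev), *args[:15], args[15],
                        tally_w, tally_m, seg_vox, seg_len, seg_e)
    return [((int(seg_vox[i, 0]), int(seg_vox[i, 1]), int(seg_vox[i, 2])),
             float(seg_len[i]), float(seg_e[i])) for i in range(n)]


def score_kerma(segments, mode: str, phantom: SegmentedPhantom,
                weight: float = 1.0) -> np.ndarray:
    """Track-length kerma tally (MeV/g per history) from explicit segments.

    Reference-path implementation of the estimator the fused kernel
    applies inline: each segment contributes
    ``weight * E * (muen/rho)(E) * L / V`` to its voxel, with the water
    coefficient in modes "w,w"/"w,m" and the voxel material's own
    coefficient in mode "m,m".
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    grid = phantom.material_index
    tally = np.zeros(grid.shape)
    inv_v = 1.0 / grid.voxel_volume_cm3
    water = load_material("water")
    for (ix, iy, iz), length, energy in segments:
        if mode == "m,m":
            mat = phantom.materials[grid.values[ix, iy, iz]]
        else:
            mat = water
        mu_en = coefficient(mat, energy, "muen")
        tally[ix, iy, iz] += weight * energy * mu_en * length * inv_v
    return tally


def estimate_uncertainty(batch_doses, prescription_Gy: float = None):
    """Voxel-wise relative standard error of the batch mean.

    ``batch_doses`` is a sequence of equally sized dose arrays (one per
    batch).  Returns ``(mean, rel_uncertainty, max_within_30pct)``; the
    summary is NaN when no prescription is given or no voxel reaches 30%
    of it.  Zero-dose voxels have undefined uncertainty and are reported
    as 0 and excluded from the summary.
    """
    stack = np.stack([np.asarray(b, dtype=float) for b in batch_doses])
    k = stack.shape[0]
    if k < 2:
        raise ValueError("need at least two batches")
    mean = stack.mean(axis=0)
    se = stack.std(axis=0, ddof=1) / np.sqrt(k)
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.where(mean > 0, se / mean, 0.0)
    summary = (np.nan if prescription_Gy is None
               else _max_rel_unc_30pct(mean, rel, prescription_Gy))
    return mean, rel, summary


def apply_dose_cutoff(dose_grid: DoseGrid,
                      cap_gy: float = DEFAULT_DOSE_CAP_GY) -> DoseGrid:
    """Clip the dose at ``cap_gy`` (clinical TPS convention); idempotent."""
    if cap_gy <= 0:
        raise ValueError("dose cap must be positive")
    capped = np.minimum(dose_grid.dose.values, cap_gy)
    return dc_replace(dose_grid, dose=dose_grid.dose.with_values(capped))
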