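"""Seeded generator of synthetic liver brachytherapy cases.

Emulates the study mix of CT-guided interstitial HDR liver cases with no
patient data: an abdominal HU phantom (air background, soft-tissue body,
lung cap, liver, optional ribs), delineated structures (body, liver,
spherical CTVs, adjacent OARs), straight implant catheters with dwell
positions, and dwell times fitted so the analytic water-kernel dose
covers each CTV surface at the prescription.

Emulated study conditions: single-fraction prescriptions of 12/15/20/25
Gy, CTV volumes from under 1 cm^3 to ~280 cm^3 (radius 6-40 mm), fewer
than 10 up to ~100 dwell positions per CTV, one to five CTVs per case,
and an OAR mix in which the stomach is the most frequent organ.

Everything is deterministic under the configured seed; HU noise can be
switched off for exact-count segmentation tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import nnls

from .geometry import StructureSet, VoxelGrid
from .mc_engine import TreatmentPlan
from .tg43 import load_default_parameters, radial_dose_function

__all__ = [
    "CaseConfig",
    "SyntheticCase",
    "generate_case",
    "assign_dwell_times",
    "generate_cohort",
    "PRESCRIPTIONS_GY",
    "OAR_FREQUENCIES",
]

PRESCRIPTIONS_GY = (12.0, 15.0, 20.0, 25.0)

#: Sampling frequency of each OAR type in the default cohort mix; the
#: stomach leads, mirroring its dominance in clinical liver implants.
OAR_FREQUENCIES = {
    "stomach": 0.70, "heart": 0.40, "bowel": 0.35, "colon": 0.35,
    "kidney": 0.25, "duodenum": 0.25, "esophagus": 0.20,
    "bile_duct": 0.15, "gall_bladder": 0.05,
}

# Unit offset directions (relative to the liver ellipsoid) and radii (mm)
# for the OAR library; spheres are placed just outside the liver surface.
_OAR_GEOMETRY = {
    "stomach": ((-1.0, 0.3, 0.1), 26.0),
    "heart": ((-0.3, -0.2, 1.0), 28.0),
    "bowel": ((-0.4, 0.5, -1.0), 24.0),
    "colon": ((0.4, 0.6, -1.0), 22.0),
    "kidney": ((0.5, -0.8, -0.8), 22.0),
    "duodenum": ((-0.7, 0.5, -0.8), 14.0),
    "esophagus": ((-0.9, -0.4, 0.8), 10.0),
    "bile_duct": ((-0.3, 0.3, -0.9), 8.0),
    "gall_bladder": ((0.3, 0.7, -0.6), 14.0),
}

_HU = {  # mean, sigma
    "air": (-1000.0, 0.0),
    "lung": (-700.0, 50.0),
    "soft": (40.0, 15.0),
    "liver": (55.0, 10.0),
    "rib": (700.0, 150.0),
}


@dataclass
class CaseConfig:
    """Parameters of one synthetic case."""

    shape: tuple = (96, 96, 96)
    spacing_mm: tuple = (2.0, 2.0, 2.0)
    body_semiaxes_mm: tuple = (88.0, 75.0, 92.0)
    liver_center_mm: tuple = (18.0, 8.0, -8.0)
    liver_semiaxes_mm: tuple = (58.0, 48.0, 52.0)
    include_lung: bool = True
    include_ribs: bool = False
    n_ctvs: int = 1
    ctv_radius_range_mm: tuple = (6.0, 40.0)
    prescription_Gy: float = 15.0
    oars: tuple = ("stomach",)
    dwell_spacing_mm: float = 10.0
    catheter_spacing_mm: float = 20.0
    source_strength_U: float = 40700.0  # ~10 Ci Ir-192
    patient_sex: str = "male"
    hu_noise: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.prescription_Gy <= 0:
            raise ValueError("prescription must be positive")
        if self.dwell_spacing_mm <= 0 or self.catheter_spacing_mm <= 0:
            raise ValueError("dwell/catheter spacing must be positive")
        if self.n_ctvs < 1:
            raise ValueError("need at least one CTV")


@dataclass
class SyntheticCase:
    """A generated case: HU phantom, structures, plan, CTV geometry."""

    config: CaseConfig
    hu: VoxelGrid
    structures: StructureSet
    plan: TreatmentPlan
    ctv_spheres: list = field(default_factory=list)  # (center_mm, radius_mm)

    @property
    def patient_sex(self) -> str:
        return self.config.patient_sex


def _ellipsoid(coords, center, semiaxes):
    x, y, z = coords
    return (((x - center[0]) / semiaxes[0]) ** 2
            + ((y - center[1]) / semiaxes[1]) ** 2
            + ((z - center[2]) / semiaxes[2]) ** 2) <= 1.0


def _sphere(coords, center, radius):
    x, y, z = coords
    return ((x - center[0]) ** 2 + (y - center[1]) ** 2
            + (z - center[2]) ** 2) <= radius**2


def _place_ctvs(rng, config):
    """Sample CTV centres/radii fully inside the liver (5 mm clearance)."""
    lo, hi = config.ctv_radius_range_mm
    c = np.array(config.liver_center_mm)
    ax = np.array(config.liver_semiaxes_mm)
    spheres = []
    for _ in range(config.n_ctvs):
        radius = float(rng.uniform(lo, hi))
        shrunk = ax - radius - 5.0  # centre must stay in this ellipsoid
        if np.any(shrunk <= 0):
            raise ValueError(
                f"CTV of radius {radius:.1f} mm cannot be contained in "
                f"the liver (semiaxes {tuple(ax)})")
        for _attempt in range(2000):
            u = rng.uniform(-1, 1, size=3)
            center = c + u * shrunk
            if np.sum(((center - c) / shrunk) ** 2) <= 1.0:
                spheres.append((center, radius))
                break
        else:
            raise ValueError("CTV placement failed: liver too small")
    return spheres


def _catheter_dwells(center, radius, config):
    """Dwell positions on a rectangular grid of straight z-catheters.

    Catheters run along z through the CTV cross-section; dwells sit at
    ``dwell_spacing`` steps inside the sphere plus a 5 mm margin.
    """
    cs = config.catheter_spacing_mm
    ds = config.dwell_spacing_mm
    n_side = int(np.floor(radius / cs))
    offsets = np.arange(-n_side, n_side + 1) * cs
    dwells = []
    for ox in offsets:
        for oy in offsets:
            d2 = ox**2 + oy**2
            if d2 > radius**2:
                continue
            half = np.sqrt(radius**2 - d2) + 5.0  # mm, CTV + margin
            n_dw = max(int(np.floor(2 * half / ds)) + 1, 1)
            zs = (np.arange(n_dw) - (n_dw - 1) / 2.0) * ds
            for oz in zs:
                dwells.append([center[0] + ox, center[1] + oy,
                               center[2] + oz])
    return np.array(dwells)


def _sphere_surface_points(center, radius, n=200):
    """Deterministic Fibonacci-lattice points on the CTV surface."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + 5**0.5) * i
    pts = np.column_stack([
        np.sin(phi) * np.cos(theta),
        np.sin(phi) * np.sin(theta),
        np.cos(phi),
    ])
    return center + radius * pts


def assign_dwell_times(dwell_positions_mm, surface_points_mm,
                       prescription_gy: float, source_strength_U: float,
                       coverage_quantile: float = 0.10) -> np.ndarray:
    """Fit non-negative dwell times to cover the CTV surface.

    A non-negative least-squares fit drives the analytic point-source
    dose (inverse square times the radial dose function) at the surface
    sample points to the prescription; times are then rescaled so the
    ``coverage_quantile`` of surface doses equals the prescription
    (i.e. 90% of the surface is at or above it by default).
    """
    pos = np.atleast_2d(np.asarray(dwell_positions_mm, dtype=float))
    pts = np.atleast_2d(np.asarray(surface_points_mm, dtype=float))
    params = load_default_parameters()
    r_cm = np.linalg.norm(pts[:, None, :] - pos[None, :, :], axis=2) / 10.0
    r_cm = np.clip(r_cm, params.g_radii_cm[0], params.g_radii_cm[-1])
    # Gy per second of dwell time at each surface point
    rate = (source_strength_U * params.dose_rate_constant
            * radial_dose_function(params, r_cm) / r_cm**2) / 3600.0 / 100.0
    target = np.full(pts.shape[0], prescription_gy)
    times, _ = nnls(rate, target)
    achieved = rate @ times
    ref = np.quantile(achieved[achieved > 0], coverage_quantile)
    if ref <= 0:
        raise ValueError("dwell-time fit produced zero dose everywhere")
    return times * (prescription_gy / ref)


def generate_case(config: CaseConfig) -> SyntheticCase:
    """Build one synthetic case; deterministic under ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    shape = tuple(config.shape)
    spacing = np.asarray(config.spacing_mm, dtype=float)
    origin = -(np.array(shape) - 1) / 2.0 * spacing
    grid = VoxelGrid(np.zeros(shape, dtype=np.float32), spacing, origin)
    xs = grid.axis_coords(0)[:, None, None]
    ys = grid.axis_coords(1)[None, :, None]
    zs = grid.axis_coords(2)[None, None, :]
    coords = (xs, ys, zs)

    body = _ellipsoid(coords, (0.0, 0.0, 0.0), config.body_semiaxes_mm)
    liver = _ellipsoid(coords, config.liver_center_mm,
                       config.liver_semiaxes_mm) & body
    lung = np.zeros(shape, dtype=bool)
    if config.include_lung:
        lung_center = (config.liver_center_mm[0] - 10.0, 0.0,
                       config.liver_center_mm[2]
                       + config.liver_semiaxes_mm[2] + 28.0)
        lung = (_ellipsoid(coords, lung_center, (60.0, 55.0, 34.0))
                & body & ~liver)
    ribs = np.zeros(shape, dtype=bool)
    if config.include_ribs:
        a, b, _ = config.body_semiaxes_mm
        for zc in np.arange(-80.0, 81.0, 24.0):
            shell = (((xs / (a - 6.0)) ** 2 + (ys / (b - 6.0)) ** 2 >= 0.94)
                     & (np.abs(zs - zc) < 5.0))
            ribs |= shell & body
        ribs &= ~liver & ~lung

    def _hu(name, size):
        mean, sigma = _HU[name]
        if config.hu_noise and sigma > 0:
            return mean + rng.normal(0.0, sigma, size=size)
        return np.full(size, mean)

    hu = np.full(shape, _HU["air"][0], dtype=np.float32)
    hu[body] = _hu("soft", int(body.sum()))
    hu[lung] = _hu("lung", int(lung.sum()))
    hu[liver] = _hu("liver", int(liver.sum()))
    hu[ribs] = _hu("rib", int(ribs.sum()))
    hu_grid = grid.with_values(hu.astype(np.float32))

    masks = {
        "body": grid.with_values(body),
        "liver": grid.with_values(liver),
    }
    roles = {"body": "body", "liver": "liver"}

    ctv_spheres = _place_ctvs(rng, config)
    for i, (center, radius) in enumerate(ctv_spheres, start=1):
        name = f"ctv_{i}"
        masks[name] = grid.with_values(_sphere(coords, center, radius))
        roles[name] = "CTV"

    liver_c = np.array(config.liver_center_mm)
    liver_ax = np.array(config.liver_semiaxes_mm)
    for oar in config.oars:
        direction, radius = _OAR_GEOMETRY[oar]
        d = np.asarray(direction, dtype=float)
        d = d / np.linalg.norm(d)
        t_surface = 1.0 / np.sqrt(np.sum((d / liver_ax) ** 2))
        center = liver_c + d * (t_surface + radius + 2.0)
        center = center + rng.uniform(-4.0, 4.0, size=3)
        m = _sphere(coords, center, radius) & body & ~liver
        if not np.any(m):  # pushed outside the body: hug the surface
            center = liver_c + d * (t_surface + radius * 0.5)
            m = _sphere(coords, center, radius) & body & ~liver
        masks[oar] = grid.with_values(m)
        roles[oar] = f"OAR:{oar}"

    all_pos, all_times = [], []
    for center, radius in ctv_spheres:
        pos = _catheter_dwells(center, radius, config)
        times = assign_dwell_times(
            pos, _sphere_surface_points(center, radius),
            config.prescription_Gy, config.source_strength_U)
        keep = times > 1e-9
        all_pos.append(pos[keep])
        all_times.append(times[keep])
    plan = TreatmentPlan(
        dwell_positions=np.vstack(all_pos),
        dwell_times=np.concatenate(all_times),
        source_strength_U=config.source_strength_U,
        prescription_Gy=config.prescription_Gy,
    )
    structures = StructureSet(masks=masks, roles=roles)
    return SyntheticCase(config=config, hu=hu_grid, structures=structures,
                         plan=plan, ctv_spheres=ctv_spheres)


def volume_trend_configs(master_seed: int = 100) -> list:
    """Five single-CTV cases with increasing liver V5Gy volumes.

    CTV radii step from 8 to 24 mm with prescriptions from 12 to 20 Gy,
    so the 5-Gy isodose grows from ~10 to ~350 cm^3 while staying inside
    the liver (once the isodose saturates the organ, the water/medium
    difference collapses and the deviation-versus-volume trend with it).
    Used for the deviation-vs-volume scatter analysis.
    """
    radii = (8.0, 12.0, 16.0, 20.0, 24.0)
    prescriptions = (12.0, 12.0, 15.0, 15.0, 20.0)
    return [CaseConfig(ctv_radius_range_mm=(r, r), prescription_Gy=p,
                       seed=master_seed + i)
            for i, (r, p) in enumerate(zip(radii, prescriptions))]


def generate_cohort(n_cases: int, master_seed: int = 0,
                    mix: dict = None) -> list:
    """Draw a cohort of cases with varied prescriptions, CTVs and OARs.

    ``mix`` can override any ``CaseConfig`` field for every case (e.g.
    ``{"n_ctvs": 1}`` forces single-CTV cases).  Reproducible under the
    master seed; each case gets an independent child seed.
    """
    if n_cases < 1:
        raise ValueError("need at least one case")
    mix = dict(mix or {})
    ss = np.random.SeedSequence(master_seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31 - 1))
                   for s in ss.spawn(n_cases + 1)]
    rng = np.random.default_rng(child_seeds[-1])
    cases = []
    for i in range(n_cases):
        fields = {
            "prescription_Gy": float(rng.choice(PRESCRIPTIONS_GY)),
            "n_ctvs": int(rng.integers(1, 6)),
            "patient_sex": "female" if rng.random() < 3 / 18 else "male",
            "seed": child_seeds[i],
        }
        oars = [name for name, p in OAR_FREQUENCIES.items()
                if rng.random() < p]
        if not oars:  # at least one OAR was delineated for every case
            oars = ["stomach"]
        fields["oars"] = tuple(oars)
        # multi-CTV cases use smaller targets so all of them fit
        if fields["n_ctvs"] > 1:
            fields["ctv_radius_range_mm"] = (6.0, 22.0)
        fields.update(mix)
        cases.append(generate_case(CaseConfig(**fields)))
    return cases
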