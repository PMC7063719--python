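"""Bundled photon physics: the Ir-192 line spectrum, elemental photon
coefficients and reference tissue materials.

The data files live under ``liverbrachy/data`` and are plain CSV/JSON:

* ``ir192_spectrum.csv`` -- discrete photon emission lines (gamma plus
  Pt/Os K X-rays) of the Ir-192 decay, energies in MeV, intensities in
  photons per decay.  Lines below 10 keV are dropped.
* ``elements/<sym>.csv`` -- per-element mass attenuation (coherent-free)
  and mass energy-absorption coefficients on a 0.01-1.5 MeV grid.  See
  ``scripts/build_physics_tables.py`` for how these are constructed and
  validated.
* ``materials.json`` -- reference tissue compositions and densities
  (air, lung, adipose, male/female soft tissue, liver, cortical bone)
  plus water.

Mixture coefficients are mass-fraction-weighted sums of the elemental
coefficients; single-energy lookups use log-log interpolation and refuse
to extrapolate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from functools import lru_cache
from importlib.resources import files

import numpy as np

__all__ = [
    "PhotonSpectrum",
    "CoefficientTable",
    "Material",
    "load_ir192_spectrum",
    "load_element_tables",
    "build_material",
    "load_material",
    "load_all_materials",
    "coefficient",
    "sample_energy",
    "klein_nishina_cross_section",
    "compton_scattered_energy",
    "kn_compton_mu_rho",
    "TG186_DENSITIES",
]

_DATA = files("liverbrachy") / "data"

R_E_CM = 2.8179403262e-13
MEC2_MEV = 0.51099895
AVOGADRO = 6.02214076e23

#: Reference densities (g/cm^3) of the segmentation tissue set.
TG186_DENSITIES = {
    "air": 0.0012,
    "lung": 0.26,
    "adipose": 0.95,
    "soft_tissue_female": 1.02,
    "soft_tissue_male": 1.03,
    "liver": 1.06,
    "cortical_bone": 1.92,
}


@dataclass(frozen=True)
class PhotonSpectrum:
    """Discrete photon line spectrum of a radionuclide."""

    energies: np.ndarray  # MeV, ascending
    intensities: np.ndarray  # photons per decay

    def __post_init__(self):
        e = np.asarray(self.energies, dtype=float)
        p = np.asarray(self.intensities, dtype=float)
        if e.shape != p.shape or e.ndim != 1 or e.size == 0:
            raise ValueError("energies/intensities must be matching 1-D arrays")
        if np.any(e <= 0.005) or np.any(e >= 1.5):
            raise ValueError("line energies must lie in (0.005, 1.5) MeV")
        if np.any(p <= 0):
            raise ValueError("line intensities must be positive")
        object.__setattr__(self, "energies", e)
        object.__setattr__(self, "intensities", p)

    @property
    def total_intensity(self) -> float:
        """Photons emitted per decay."""
        return float(self.intensities.sum())

    @property
    def probabilities(self) -> np.ndarray:
        """Per-line sampling probabilities (normalised intensities)."""
        return self.intensities / self.intensities.sum()

    @property
    def mean_energy(self) -> float:
        """Intensity-weighted mean photon energy, MeV."""
        return float(np.average(self.energies, weights=self.intensities))


@dataclass(frozen=True)
class CoefficientTable:
    """Photon mass coefficients on an ascending energy grid (cm^2/g)."""

    energies: np.ndarray
    mu_rho: np.ndarray
    muen_rho: np.ndarray

    def __post_init__(self):
        e = np.asarray(self.energies, dtype=float)
        mu = np.asarray(self.mu_rho, dtype=float)
        men = np.asarray(self.muen_rho, dtype=float)
        if not (e.shape == mu.shape == men.shape):
            raise ValueError("table columns must have equal length")
        if np.any(np.diff(e) <= 0):
            raise ValueError("energy grid must be strictly increasing")
        if np.any(mu <= 0) or np.any(men <= 0):
            raise ValueError("coefficients must be positive")
        if np.any(men > mu * (1 + 1e-12)):
            raise ValueError("muen/rho must not exceed mu/rho")
        object.__setattr__(self, "energies", e)
        object.__setattr__(self, "mu_rho", mu)
        object.__setattr__(self, "muen_rho", men)

    def lookup(self, energy, kind: str):
        """Log-log interpolated coefficient; no extrapolation."""
        e = np.asarray(energy, dtype=float)
        if np.any(e < self.energies[0]) or np.any(e > self.energies[-1]):
            raise ValueError(
                f"energy outside table range "
                f"[{self.energies[0]}, {self.energies[-1]}] MeV")
        col = {"mu": self.mu_rho, "muen": self.muen_rho}[kind]
        out = np.exp(np.interp(np.log(e), np.log(self.energies), np.log(col)))
        return float(out) if np.isscalar(energy) else out


@dataclass(frozen=True)
class Material:
    """A named tissue: density, elemental mass fractions, mixture table."""

    name: str
    density: float  # g/cm^3
    composition: dict = field(compare=False)
    table: CoefficientTable = field(compare=False)
    z_over_a: float = 0.0  # mass-fraction-weighted <Z/A>

    def __post_init__(self):
        if self.density <= 0:
            raise ValueError(f"density must be positive, got {self.density}")
        total = sum(self.composition.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"mass fractions sum to {total}, not 1")


def _read_csv(resource) -> np.ndarray:
    text = resource.read_text()
    rows = [line.split(",") for line in text.strip().splitlines()[1:]]
    return np.array(rows, dtype=float)


@lru_cache(maxsize=1)
def load_ir192_spectrum() -> PhotonSpectrum:
    """The bundled Ir-192 photon line spectrum."""
    try:
        arr = _read_csv(_DATA / "ir192_spectrum.csv")
    except (FileNotFoundError, ValueError) as exc:  # pragma: no cover
        raise RuntimeError("bundled Ir-192 spectrum missing or corrupt") from exc
    order = np.argsort(arr[:, 0])
    return PhotonSpectrum(arr[order, 0], arr[order, 1])


@lru_cache(maxsize=1)
def load_element_tables() -> dict:
    """Elemental coefficient tables plus Z and A, keyed by symbol."""
    meta = json.loads((_DATA / "elements.json").read_text())
    out = {}
    for sym, za in meta.items():
        arr = _read_csv(_DATA / "elements" / f"{sym}.csv")
        out[sym] = {
            "table": CoefficientTable(arr[:, 0], arr[:, 1], arr[:, 2]),
            "Z": za["Z"],
            "A": za["A"],
        }
    return out


def build_material(name: str, composition: dict, density: float) -> Material:
    """Mix elemental coefficients into a material table.

    Fractions are renormalised if they sum to 1 within 1e-4; a larger
    discrepancy or an element without a bundled table is an error.
    """
    if density <= 0:
        raise ValueError(f"density must be positive, got {density}")
    elements = load_element_tables()
    unknown = sorted(set(composition) - set(elements))
    if unknown:
        raise KeyError(f"no bundled coefficient table for element(s): "
                       f"{', '.join(unknown)}")
    total = sum(composition.values())
    if abs(total - 1.0) > 1e-4:
        raise ValueError(f"mass fractions sum to {total:.6f}; expected 1")
    comp = {sym: w / total for sym, w in composition.items()}

    # All bundled element tables share one grid; the merge below keeps the
    # mixture rule correct even if a future table used a different grid.
    grid = np.unique(np.concatenate(
        [elements[sym]["table"].energies for sym in comp]))
    mu = np.zeros_like(grid)
    muen = np.zeros_like(grid)
    zoa = 0.0
    for sym, w in comp.items():
        tab = elements[sym]["table"]
        mu += w * tab.lookup(grid, "mu")
        muen += w * tab.lookup(grid, "muen")
        zoa += w * elements[sym]["Z"] / elements[sym]["A"]
    return Material(name=name, density=density, composition=comp,
                    table=CoefficientTable(grid, mu, muen), z_over_a=zoa)


@lru_cache(maxsize=None)
def load_material(name: str) -> Material:
    """A bundled reference material by name (e.g. ``liver``, ``water``)."""
    mats = json.loads((_DATA / "materials.json").read_text())
    if name not in mats:
        raise KeyError(f"unknown bundled material {name!r}; "
                       f"available: {', '.join(sorted(mats))}")
    spec = mats[name]
    return build_material(name, spec["composition"], spec["density"])


def load_all_materials() -> dict:
    mats = json.loads((_DATA / "materials.json").read_text())
    return {name: load_material(name) for name in mats}


def coefficient(material: Material, energy, kind: str = "muen"):
    """mu/rho or muen/rho of a material at the given energy (MeV)."""
    if kind not in ("mu", "muen"):
        raise ValueError("kind must be 'mu' or 'muen'")
    return material.table.lookup(energy, kind)


def sample_energy(spectrum: PhotonSpectrum, rng: np.random.Generator,
                  size=None):
    """Draw line energies with probability proportional to intensity."""
    idx = rng.choice(spectrum.energies.size, size=size,
                     p=spectrum.probabilities)
    return spectrum.energies[idx]


def klein_nishina_cross_section(energy_mev) -> np.ndarray:
    """Total Klein-Nishina cross section per free electron, cm^2."""
    a = np.asarray(energy_mev, dtype=float) / MEC2_MEV
    t1 = (1 + a) / a**2 * (2 * (1 + a) / (1 + 2 * a) - np.log1p(2 * a) / a)
    t2 = np.log1p(2 * a) / (2 * a)
    t3 = (1 + 3 * a) / (1 + 2 * a) ** 2
    return 2 * np.pi * R_E_CM**2 * (t1 + t2 - t3)


def kn_compton_mu_rho(material: Material, energy_mev):
    """Free-electron Compton mass attenuation of a material, cm^2/g."""
    return (AVOGADRO * material.z_over_a
            * klein_nishina_cross_section(energy_mev))


def compton_scattered_energy(energy_mev, cos_theta):
    """Photon energy after Compton scattering through angle theta."""
    return energy_mev / (1.0 + energy_mev / MEC2_MEV * (1.0 - cos_theta))
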