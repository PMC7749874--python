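"""Photon interaction data for the materials the dose engine transports through.

The package ships mass attenuation (``mu/rho``, coherent included) and mass
energy-absorption (``mu_en/rho``) coefficients for air, water, ICRU-44 soft
tissue, PMMA, cortical bone and aluminum on the standard 10-150 keV grid,
interpolated log-log.  Total attenuation always comes straight from the
table; the split into interaction channels used by the Monte Carlo engine is
semi-empirical:

* incoherent scattering is the free-electron Klein-Nishina cross-section
  times the electron density (``Z/A``) of the material;
* the remainder (photoelectric + coherent) is split by fitting
  ``A (E/50)^-3 + B (E/50)^-2`` shapes (photoelectric ~ E^-3, coherent
  ~ E^-2 over this range) to the tabulated remainder.

Only the total governs free paths and transmission, so this split never
perturbs attenuation; it only decides how often an interaction absorbs the
photon locally versus scatters it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy.optimize import nnls

ELECTRON_REST_KEV = 510.99895
CLASSICAL_ELECTRON_RADIUS_CM = 2.8179403262e-13
AVOGADRO = 6.02214076e23

MATERIAL_NAMES = ("air", "water", "soft_tissue", "pmma", "bone", "aluminum")
# integer ids used in voxel material maps (aluminum never appears in phantoms)
MATERIAL_IDS = {"air": 0, "lung": 1, "soft_tissue": 2, "pmma": 3, "bone": 4, "water": 5}
# the soft-tissue/water class carries water coefficients: the HU-to-density
# conversion is anchored on water, so a 0 HU voxel must attenuate as water;
# lung-like tissue (fluid-filled in utero) uses the ICRU soft-tissue table
ID_TO_TABLE_NAME = {0: "air", 1: "soft_tissue", 2: "water", 3: "pmma", 4: "bone", 5: "water"}


def klein_nishina_total_cm2(energy_keV):
    """Total Klein-Nishina cross-section per electron (cm^2)."""
    k = np.asarray(energy_keV, dtype=float) / ELECTRON_REST_KEV
    re2 = CLASSICAL_ELECTRON_RADIUS_CM**2
    t1 = (1.0 + k) / k**2 * (2.0 * (1.0 + k) / (1.0 + 2.0 * k) - np.log1p(2.0 * k) / k)
    t2 = np.log1p(2.0 * k) / (2.0 * k)
    t3 = (1.0 + 3.0 * k) / (1.0 + 2.0 * k) ** 2
    return 2.0 * np.pi * re2 * (t1 + t2 - t3)


@dataclass
class Material:
    """One material's coefficient grids plus the fitted channel split."""

    name: str
    density_g_cm3: float
    z_over_a: float
    energy_keV: np.ndarray
    mu_rho: np.ndarray
    mu_en_rho: np.ndarray
    _pe_amp: float = field(default=0.0, repr=False)
    _coh_amp: float = field(default=0.0, repr=False)

    def __post_init__(self):
        # fit the photoelectric/coherent shapes to the non-Compton remainder
        inc = klein_nishina_total_cm2(self.energy_keV) * AVOGADRO * self.z_over_a
        remainder = np.clip(self.mu_rho - inc, 0.0, None)
        basis = np.column_stack([(self.energy_keV / 50.0) ** -3.0, (self.energy_keV / 50.0) ** -2.0])
        # weight relative to remainder so small high-E values still constrain B
        w = 1.0 / np.maximum(remainder, 1e-4)
        amps, _ = nnls(basis * w[:, None], remainder * w)
        self._pe_amp, self._coh_amp = float(amps[0]), float(amps[1])

    def _loglog(self, table: np.ndarray, energy_keV) -> np.ndarray:
        e = np.clip(np.asarray(energy_keV, dtype=float), self.energy_keV[0], self.energy_keV[-1])
        return np.exp(np.interp(np.log(e), np.log(self.energy_keV), np.log(table)))

    def mu_rho_at(self, energy_keV):
        """Mass attenuation coefficient (cm^2/g), coherent included."""
        return self._loglog(self.mu_rho, energy_keV)

    def mu_en_rho_at(self, energy_keV):
        """Mass energy-absorption coefficient (cm^2/g)."""
        return self._loglog(self.mu_en_rho, energy_keV)

    def mu_at(self, energy_keV, density_g_cm3=None):
        """Linear attenuation coefficient (1/cm) at the nominal or given density."""
        rho = self.density_g_cm3 if density_g_cm3 is None else density_g_cm3
        return self.mu_rho_at(energy_keV) * rho

    def branch_fractions(self, energy_keV):
        """(photoelectric, incoherent, coherent) probability shares at energy.

        The shares sum to 1 and are consistent with the tabulated total.
        """
        e = np.asarray(energy_keV, dtype=float)
        total = self.mu_rho_at(e)
        inc = np.minimum(klein_nishina_total_cm2(e) * AVOGADRO * self.z_over_a, total)
        remainder = total - inc
        pe_shape = self._pe_amp * (e / 50.0) ** -3.0
        coh_shape = self._coh_amp * (e / 50.0) ** -2.0
        shape_sum = np.maximum(pe_shape + coh_shape, 1e-300)
        pe = remainder * pe_shape / shape_sum
        coh = remainder - pe
        return pe / total, inc / total, coh / total


class MaterialTable:
    """Registry of the shipped materials, keyed by name and by voxel id."""

    def __init__(self):
        pkg = resources.files("oemdose") / "data"
        meta = json.loads((pkg / "materials.json").read_text())
        df = pd.read_csv(pkg / "mass_attenuation.csv", comment="#")
        self._materials: dict[str, Material] = {}
        for name, grp in df.groupby("material"):
            grp = grp.sort_values("energy_keV")
            self._materials[name] = Material(
                name=name,
                density_g_cm3=meta[name]["density_g_cm3"],
                z_over_a=meta[name]["z_over_a"],
                energy_keV=grp["energy_keV"].to_numpy(float),
                mu_rho=grp["mu_rho"].to_numpy(float),
                mu_en_rho=grp["mu_en_rho"].to_numpy(float),
            )

    def __getitem__(self, name: str) -> Material:
        return self._materials[name]

    def by_id(self, material_id: int) -> Material:
        return self._materials[ID_TO_TABLE_NAME[material_id]]

    @property
    def names(self):
        return tuple(self._materials)


_DEFAULT: MaterialTable | None = None


def default_materials() -> MaterialTable:
    """Shared instance of the shipped coefficient tables."""
    global _DEFAULT
    if _DEFAULT is None:
        _DEFAULT = MaterialTable()
    return _DEFAULT
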