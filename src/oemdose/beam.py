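"""X-ray source model: energy spectrum, beam quality and bowtie filter.

The scanner's spectrum is not published; what is published is its beam
quality — the aluminum half-value layer (HVL) and the equivalent
monoenergetic ("effective") energy.  This module therefore builds a
semi-empirical spectrum (Kramers-type bremsstrahlung with tungsten K lines,
hardened by aluminum filtration) and calibrates the filtration thickness so
the computed HVL reproduces the measured one.  Air kerma is always the
weighting quantity: ``K ~ sum_i w_i E_i (mu_en/rho)_air(E_i)``.

The bowtie filter is "virtual": a lateral free-in-air kerma profile is
inverted, position by position, into the equivalent aluminum thickness that
reproduces the measured kerma reduction at the corresponding fan angle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
import warnings

import numpy as np

from .errors import CalibrationError, InvalidInputError
from .materials import MaterialTable, default_materials

# tungsten K lines (keV, relative intensity); the Kbeta2 energy follows the
# source characterization this package reproduces (literature value ~69.1)
TUNGSTEN_K_EDGE_KEV = 69.5
DEFAULT_W_LINES = ((59.32, 100.0), (57.98, 57.0), (67.24, 22.0), (67.42, 5.0))


@dataclass(frozen=True)
class Spectrum:
    """Discrete photon-fluence spectrum (0.5 keV bins plus line energies)."""

    energies_keV: np.ndarray
    weights: np.ndarray
    tube_voltage_kV: float
    characteristic_lines: tuple[tuple[float, float], ...] = ()

    def __post_init__(self):
        e = np.asarray(self.energies_keV, dtype=float)
        w = np.asarray(self.weights, dtype=float)
        if e.shape != w.shape or e.ndim != 1 or e.size == 0:
            raise InvalidInputError("energies and weights must be matching 1-D arrays")
        if np.any(w < 0) or not np.all(np.isfinite(w)):
            raise InvalidInputError("weights must be finite and non-negative")
        total = w.sum()
        if total <= 0:
            raise InvalidInputError("spectrum has no fluence")
        if np.any(e[w > 0] > self.tube_voltage_kV + 1e-9):
            raise InvalidInputError("fluence above the tube voltage")
        object.__setattr__(self, "energies_keV", e)
        object.__setattr__(self, "weights", w / total)

    @classmethod
    def monoenergetic(cls, energy_keV: float) -> "Spectrum":
        return cls(np.array([energy_keV]), np.array([1.0]), tube_voltage_kV=energy_keV)

    @property
    def mean_energy_keV(self) -> float:
        return float(np.sum(self.energies_keV * self.weights))

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        """Draw ``n`` photon energies proportional to fluence."""
        cdf = np.cumsum(self.weights)
        return self.energies_keV[np.searchsorted(cdf, rng.random(n) * cdf[-1])]

    def attenuated(self, al_thickness_mm: float, materials: MaterialTable | None = None) -> "Spectrum":
        materials = materials or default_materials()
        mu = materials["aluminum"].mu_at(self.energies_keV)
        return Spectrum(
            self.energies_keV,
            self.weights * np.exp(-mu * al_thickness_mm / 10.0),
            self.tube_voltage_kV,
            self.characteristic_lines,
        )


def generate_spectrum(
    tube_voltage_kV: float,
    al_filtration_mm: float,
    materials: MaterialTable | None = None,
    k_lines: tuple[tuple[float, float], ...] = DEFAULT_W_LINES,
) -> Spectrum:
    """Semi-empirical tube spectrum at a voltage and total Al filtration.

    Bremsstrahlung follows Kramers' law, ``N(E) ~ (kV - E)/E``, filtered by
    the given aluminum thickness; tungsten K fluorescence is added when the
    voltage exceeds the K edge (69.5 keV), with a line fraction growing as
    ``0.3 (kV/69.5 - 1)^1.5`` of total fluence before filtration.
    """
    if not 40.0 <= tube_voltage_kV <= 150.0:
        raise InvalidInputError("tube voltage must lie in [40, 150] kV")
    if al_filtration_mm < 0:
        raise InvalidInputError("filtration must be non-negative")
    materials = materials or default_materials()
    centers = np.arange(5.0, tube_voltage_kV, 0.5) + 0.25
    centers = centers[centers < tube_voltage_kV]
    brems = (tube_voltage_kV - centers) / centers
    energies, weights = centers, brems / brems.sum()
    lines: tuple[tuple[float, float], ...] = ()
    if tube_voltage_kV > TUNGSTEN_K_EDGE_KEV:
        frac = 0.3 * (tube_voltage_kV / TUNGSTEN_K_EDGE_KEV - 1.0) ** 1.5
        line_e = np.array([e for e, _ in k_lines])
        line_i = np.array([i for _, i in k_lines])
        keep = line_e < tube_voltage_kV
        line_e, line_i = line_e[keep], line_i[keep]
        energies = np.concatenate([energies, line_e])
        weights = np.concatenate([(1.0 - frac) * weights, frac * line_i / line_i.sum()])
        lines = tuple((float(e), float(i)) for e, i in zip(line_e, line_i))
    spec = Spectrum(energies, weights, tube_voltage_kV, lines)
    return spec.attenuated(al_filtration_mm, materials) if al_filtration_mm > 0 else spec


def _air_kerma_vs_al(spectrum: Spectrum, thickness_mm, materials: MaterialTable):
    """Relative air kerma behind aluminum of the given thickness(es)."""
    e = spectrum.energies_keV
    kerma_w = spectrum.weights * e * materials["air"].mu_en_rho_at(e)
    mu = materials["aluminum"].mu_at(e)
    t = np.atleast_1d(np.asarray(thickness_mm, dtype=float))
    k = np.sum(kerma_w[None, :] * np.exp(-mu[None, :] * t[:, None] / 10.0), axis=1)
    return k / kerma_w.sum()


def compute_hvl(spectrum: Spectrum, materials: MaterialTable | None = None) -> float:
    """Aluminum half-value layer (mm) of a spectrum, air-kerma weighted."""
    materials = materials or default_materials()
    lo, hi = 0.0, 200.0
    if _air_kerma_vs_al(spectrum, hi, materials)[0] > 0.5:
        raise CalibrationError("HVL beyond 200 mm Al; spectrum unphysically hard")
    for _ in range(100):
        mid = 0.5 * (lo + hi)
        k = _air_kerma_vs_al(spectrum, mid, materials)[0]
        if abs(k - 0.5) < 1e-10:
            return mid
        if k > 0.5:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def calibrate_filtration_to_hvl(
    tube_voltage_kV: float,
    target_hvl_mmAl: float,
    materials: MaterialTable | None = None,
    max_filtration_mm: float = 20.0,
    tol_mm: float = 0.005,
) -> float:
    """Total Al filtration whose spectrum reproduces a measured HVL.

    Bisection on filtration thickness; raises with bracketing diagnostics
    when the target is unreachable within [0, ``max_filtration_mm``].
    """
    materials = materials or default_materials()

    def hvl_of(f):
        return compute_hvl(generate_spectrum(tube_voltage_kV, f, materials), materials)

    lo, hi = 0.0, max_filtration_mm
    h_lo, h_hi = hvl_of(lo), hvl_of(hi)
    if not h_lo <= target_hvl_mmAl <= h_hi:
        raise CalibrationError(
            f"target HVL {target_hvl_mmAl} mm Al outside attainable range "
            f"[{h_lo:.3f}, {h_hi:.3f}] at {tube_voltage_kV} kV"
        )
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        h = hvl_of(mid)
        if abs(h - target_hvl_mmAl) < 0.2 * tol_mm or hi - lo < 1e-6:
            return mid
        if h < target_hvl_mmAl:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def effective_energy(hvl_mmAl: float, materials: MaterialTable | None = None) -> float:
    """Monoenergetic energy (keV) with the same aluminum HVL.

    Inverts ``mu/rho`` of aluminum (log-log) at ``ln 2 / HVL / rho``.
    """
    if hvl_mmAl <= 0:
        raise InvalidInputError("HVL must be positive")
    materials = materials or default_materials()
    al = materials["aluminum"]
    target = np.log(2.0) / (hvl_mmAl / 10.0) / al.density_g_cm3
    grid_mu = al.mu_rho  # strictly decreasing on 10-150 keV
    if not grid_mu[-1] <= target <= grid_mu[0]:
        raise InvalidInputError(f"HVL {hvl_mmAl} mm Al outside the table-representable range")
    log_e = np.interp(np.log(target), np.log(grid_mu[::-1]), np.log(al.energy_keV[::-1]))
    return float(np.exp(log_e))


@dataclass(frozen=True)
class BowtieFilter:
    """Fan-angle dependent equivalent aluminum thickness."""

    fan_angles_deg: np.ndarray
    al_thickness_mm: np.ndarray
    materials: MaterialTable = field(default_factory=default_materials, repr=False, compare=False)

    def __post_init__(self):
        a = np.asarray(self.fan_angles_deg, dtype=float)
        t = np.asarray(self.al_thickness_mm, dtype=float)
        if a.shape != t.shape or a.ndim != 1 or a.size == 0:
            raise InvalidInputError("angle and thickness grids must match")
        if np.any(a < 0) or np.any(np.diff(a) <= 0):
            raise InvalidInputError("store the one-sided |angle| grid, increasing from 0")
        if np.any(t < 0):
            raise InvalidInputError("thickness must be non-negative")
        object.__setattr__(self, "fan_angles_deg", a)
        object.__setattr__(self, "al_thickness_mm", t)

    @classmethod
    def flat(cls) -> "BowtieFilter":
        return cls(np.array([0.0, 30.0]), np.array([0.0, 0.0]))

    def thickness_at(self, gamma_deg) -> np.ndarray:
        return np.interp(np.abs(np.asarray(gamma_deg, dtype=float)),
                         self.fan_angles_deg, self.al_thickness_mm)

    def transmission(self, gamma_deg, energy_keV) -> np.ndarray:
        mu = self.materials["aluminum"].mu_at(energy_keV)
        return np.exp(-mu * self.thickness_at(gamma_deg) / 10.0)


def bowtie_from_airkerma_profile(
    lateral_positions_mm,
    relative_kerma,
    spectrum: Spectrum,
    source_to_iso_mm: float = 600.0,
    materials: MaterialTable | None = None,
) -> BowtieFilter:
    """Invert a lateral air-kerma profile into a virtual bowtie filter.

    Each lateral position maps to the fan angle ``atan(x / SID)``; the
    equivalent Al thickness there solves the spectrum-weighted kerma ratio.
    The result is symmetrized (averaging +/- angles) and forced monotone
    non-decreasing in |angle|.
    """
    materials = materials or default_materials()
    x = np.asarray(lateral_positions_mm, dtype=float)
    k = np.asarray(relative_kerma, dtype=float)
    if x.shape != k.shape or x.ndim != 1 or x.size < 2:
        raise InvalidInputError("positions and kerma must be matching 1-D arrays")
    if np.any(k <= 0):
        raise InvalidInputError("relative kerma must be positive")
    order = np.argsort(x)
    x, k = x[order], k[order]
    k = k / np.interp(0.0, x, k)  # normalize to the central ray
    if np.any(k > 1.0 + 1e-9):
        warnings.warn("relative kerma exceeds the central value; clamping to 1")
        k = np.minimum(k, 1.0)
    # vectorized bisection for the thickness at every position
    lo = np.zeros_like(x)
    hi = np.full_like(x, 200.0)
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        ratio = _air_kerma_vs_al(spectrum, mid, materials)
        too_thick = ratio < k
        hi = np.where(too_thick, mid, hi)
        lo = np.where(too_thick, lo, mid)
    t = 0.5 * (lo + hi)
    gamma = np.degrees(np.arctan(x / source_to_iso_mm))
    # symmetrize onto the one-sided grid
    g_abs = np.unique(np.round(np.abs(gamma), 6))
    t_sym = np.array([
        0.5 * (np.interp(g, gamma, t) + np.interp(-g, gamma, t)) for g in g_abs
    ])
    t_sym = np.maximum.accumulate(t_sym)
    t_sym[g_abs == 0.0] = 0.0
    return BowtieFilter(g_abs, t_sym, materials)


def write_spectrum_csv(path, spectrum: Spectrum) -> None:
    lines = [f"# tube_voltage_kV: {spectrum.tube_voltage_kV}", "energy_keV,relative_fluence"]
    lines += [f"{e:.6g},{w:.9g}" for e, w in zip(spectrum.energies_keV, spectrum.weights)]
    Path(path).write_text("\n".join(lines) + "\n")


def read_spectrum_csv(path) -> Spectrum:
    kv, energies, weights = None, [], []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line.startswith("#"):
            if "tube_voltage_kV" in line:
                kv = float(line.split(":")[1])
        elif line and not line[0].isalpha():
            e, _, w = line.partition(",")
            energies.append(float(e))
            weights.append(float(w))
    if not energies:
        raise InvalidInputError(f"no spectrum samples in {path}")
    e = np.asarray(energies)
    return Spectrum(e, np.asarray(weights), kv if kv is not None else float(e.max()))


def write_bowtie_csv(path, bowtie: BowtieFilter) -> None:
    lines = ["fan_angle_deg,al_thickness_mm"]
    lines += [f"{a:.6g},{t:.6g}" for a, t in zip(bowtie.fan_angles_deg, bowtie.al_thickness_mm)]
    Path(path).write_text("\n".join(lines) + "\n")


def read_bowtie_csv(path) -> BowtieFilter:
    angles, thick = [], []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#") and not line[0].isalpha():
            a, _, t = line.partition(",")
            angles.append(float(a))
            thick.append(float(t))
    if not angles:
        raise InvalidInputError(f"no bowtie samples in {path}")
    return BowtieFilter(np.asarray(angles), np.asarray(thick))


def synthetic_airkerma_profile(
    lateral_positions_mm=None, edge_relative_kerma: float = 0.30
) -> tuple[np.ndarray, np.ndarray]:
    """Synthetic stand-in for the measured lateral air-kerma profile.

    Gaussian-shaped falloff reaching ``edge_relative_kerma`` at 180 mm,
    emulating the measured shape of a body bowtie; used when no measurement
    file is supplied.
    """
    if lateral_positions_mm is None:
        lateral_positions_mm = np.arange(-180.0, 181.0, 10.0)
    x = np.asarray(lateral_positions_mm, dtype=float)
    rel = np.exp(np.log(edge_relative_kerma) * (x / 180.0) ** 2)
    return x, rel
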