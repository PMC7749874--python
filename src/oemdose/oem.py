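"""Calibrated behaviour of the organ-effective modulation (OEM) feature.

Three measured facts drive this module: the console shows a reduced tube
current when OEM is switched on (the embedded calibration table), the
modulation rates plateau at DM_Max = 63.5 % / DM_Total = 16.0 % for
requested currents of 200 mA and above and vanish at 80 mA and below, and
the dip spans a 160 degree gantry arc centred on the anterior (front mode)
or posterior (back mode) side.

The scanner never reveals the dip's shape, only its extremum (DM_Max) and
its rotation integral (DM_Total).  We close the model with a raised-cosine
taper ``w(u) = cos^p(pi u / 2)`` on the arc, solving the exponent ``p`` so
the integral constraint holds.  A small relative floor at the arc edges
(default 5 % of full depth) gives the dip the abrupt onset seen in measured
profiles and keeps the 1 %-threshold window detection sharp; the exponent is
re-solved so DM_Total is still met exactly.

Angle convention (shared package-wide): gantry angle 0 deg at the patient's
anterior (12 o'clock), increasing clockwise viewed from the couch foot.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.integrate import quad

from .errors import InfeasibleShapeError, InvalidInputError

#: requested (OEM_OFF) console current -> displayed OEM_ON current, as
#: measured on the scanner console (identical at 80 kV and 100 kV)
DEFAULT_CALIBRATION_ENTRIES = (
    (40, 40), (50, 50), (60, 60), (70, 70), (80, 80), (90, 88), (100, 95),
    (130, 118), (150, 133), (200, 170), (250, 213), (300, 255), (400, 340),
    (500, 425),
)


@dataclass(frozen=True)
class OEMCalibrationTable:
    """Requested vs displayed tube current anchors for OEM_ON."""

    entries: tuple[tuple[float, float], ...] = DEFAULT_CALIBRATION_ENTRIES

    def __post_init__(self):
        entries = tuple(sorted((float(r), float(d)) for r, d in self.entries))
        object.__setattr__(self, "entries", entries)
        req = np.array([r for r, _ in entries])
        disp = np.array([d for _, d in entries])
        if len(req) < 2 or np.any(np.diff(req) <= 0):
            raise InvalidInputError("calibration anchors must have distinct requested currents")
        if np.any(disp > req):
            raise InvalidInputError("displayed current cannot exceed requested current")

    @property
    def requested(self) -> np.ndarray:
        return np.array([r for r, _ in self.entries])

    @property
    def displayed(self) -> np.ndarray:
        return np.array([d for _, d in self.entries])

    @classmethod
    def from_csv(cls, path) -> "OEMCalibrationTable":
        rows = []
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#") or line[0].isalpha():
                continue
            r, _, d = line.partition(",")
            rows.append((float(r), float(d)))
        return cls(tuple(rows))

    def to_csv(self, path) -> None:
        lines = ["requested_mA,displayed_mA"]
        lines += [f"{r:g},{d:g}" for r, d in self.entries]
        Path(path).write_text("\n".join(lines) + "\n")


@dataclass(frozen=True)
class OEMParameters:
    """Plateau characterization of the modulation feature."""

    theta_deg: float = 160.0
    dm_max_plateau_pct: float = 63.5
    dm_total_plateau_pct: float = 16.0
    plateau_onset_mA: float = 200.0
    no_modulation_below_mA: float = 80.0

    def __post_init__(self):
        if not 0.0 < self.dm_total_plateau_pct <= self.dm_max_plateau_pct <= 100.0:
            raise InvalidInputError("need 0 < DM_Total <= DM_Max <= 100")
        if not 0.0 < self.theta_deg <= 360.0:
            raise InvalidInputError("theta must lie in (0, 360]")


def oem_displayed_current(requested_mA: float, table: OEMCalibrationTable | None = None) -> int:
    """Console current shown during OEM_ON for a requested (OFF) current.

    Piecewise-linear interpolation between the calibration anchors, rounded
    half-up to an integer mA; identity below the smallest anchor and
    constant-ratio extrapolation above the largest (both with a warning).
    """
    table = table or OEMCalibrationTable()
    if requested_mA <= 0:
        raise InvalidInputError("requested current must be positive")
    req, disp = table.requested, table.displayed
    if requested_mA < req[0]:
        warnings.warn("requested current below calibrated range; assuming no modulation")
        value = float(requested_mA)
    elif requested_mA > req[-1]:
        warnings.warn("requested current above calibrated range; extrapolating last ratio")
        value = requested_mA * disp[-1] / req[-1]
    else:
        value = float(np.interp(requested_mA, req, disp))
    return int(math.floor(value + 0.5))


def modulation_rates(
    requested_mA: float,
    params: OEMParameters | None = None,
    table: OEMCalibrationTable | None = None,
) -> tuple[float, float]:
    """(DM_Max %, DM_Total %) for a requested tube current.

    Zero at and below 80 mA, the measured plateau at and above 200 mA, and
    in between both plateau values scaled by the current-reduction ratio the
    calibration table implies relative to its plateau-onset ratio.
    """
    params = params or OEMParameters()
    table = table or OEMCalibrationTable()
    if requested_mA <= 0:
        raise InvalidInputError("requested current must be positive")
    if requested_mA <= params.no_modulation_below_mA:
        return 0.0, 0.0
    if requested_mA >= params.plateau_onset_mA:
        return params.dm_max_plateau_pct, params.dm_total_plateau_pct
    ref = 1.0 - oem_displayed_current(params.plateau_onset_mA, table) / params.plateau_onset_mA
    here = 1.0 - oem_displayed_current(requested_mA, table) / requested_mA
    s = min(max(here / ref, 0.0), 1.0)
    return s * params.dm_max_plateau_pct, s * params.dm_total_plateau_pct


def _cos_power_mean(p: float) -> float:
    """Mean of cos^p(pi u / 2) over u in [-1, 1]."""
    value, _ = quad(lambda u: math.cos(0.5 * math.pi * u) ** p, 0.0, 1.0, limit=200)
    return value


def _solve_cos_power_mean(target_mean: float, lo: float = 1e-3, hi: float = 50.0) -> float:
    """Exponent p with mean(cos^p) = target, by bisection (residual < 1e-8)."""
    m_lo, m_hi = _cos_power_mean(lo), _cos_power_mean(hi)
    if not m_hi <= target_mean <= m_lo:
        raise InfeasibleShapeError(
            f"target taper mean {target_mean:.4f} outside attainable range "
            f"[{m_hi:.4f}, {m_lo:.4f}] for p in [{lo}, {hi}]"
        )
    a, b = lo, hi
    for _ in range(200):
        mid = 0.5 * (a + b)
        m = _cos_power_mean(mid)
        if abs(m - target_mean) < 1e-10:
            return mid
        if m > target_mean:  # mean decreases with p
            a = mid
        else:
            b = mid
        if b - a < 1e-12:
            break
    return 0.5 * (a + b)


def solve_taper_exponent(dm_max_pct: float, dm_total_pct: float, arc_deg: float) -> float:
    """Cosine-taper exponent matching both modulation rates over an arc.

    The dip depth profile ``w(u) = cos^p(pi u / 2)`` must average, over the
    arc, to ``DM_Total * 360 / (DM_Max * arc)`` so that a dip of depth
    DM_Max/100 integrates to DM_Total/100 over the full rotation.
    """
    if not 0.0 < dm_total_pct <= dm_max_pct:
        raise InvalidInputError("need 0 < DM_Total <= DM_Max")
    if not 0.0 < arc_deg <= 360.0:
        raise InvalidInputError("arc must lie in (0, 360] degrees")
    required = dm_total_pct * 360.0 / (dm_max_pct * arc_deg)
    if required > 1.0:
        raise InfeasibleShapeError(
            "requested rotation integral exceeds a rectangular dip of the same depth"
        )
    return _solve_cos_power_mean(required)


class AngularOutputProfile:
    """Relative tube output r(phi) over one gantry rotation.

    ``r(phi) = 1`` outside the modulation arc; inside, the output drops to
    ``1 - DM_Max/100`` at the arc centre following the floored cosine-power
    taper.  ``mean_relative_output`` equals ``1 - DM_Total/100`` exactly.
    """

    def __init__(
        self,
        mode: str,
        dm_max_pct: float = 0.0,
        dm_total_pct: float = 0.0,
        arc_deg: float = 160.0,
        edge_floor: float = 0.05,
    ):
        if mode not in ("off", "front", "back"):
            raise InvalidInputError("mode must be one of off/front/back")
        self.mode = mode
        self.center_deg = 0.0 if mode in ("off", "front") else 180.0
        self.arc_deg = float(arc_deg)
        self.dm_max_pct = float(dm_max_pct)
        self.dm_total_pct = float(dm_total_pct)
        if mode == "off" or dm_max_pct == 0.0:
            self.mode = mode
            self.dm_max_pct = 0.0
            self.dm_total_pct = 0.0
            self.edge_floor = 0.0
            self.taper_exponent = float("nan")
            return
        required = dm_total_pct * 360.0 / (dm_max_pct * arc_deg)
        if required > 1.0:
            raise InfeasibleShapeError("DM_Total incompatible with DM_Max over this arc")
        # shrink the floor if the dip is nearly rectangular; allow larger
        # exponents than the plain solver for very narrow-integral dips
        self.edge_floor = min(edge_floor, 0.5 * required)
        self.taper_exponent = _solve_cos_power_mean(
            (required - self.edge_floor) / (1.0 - self.edge_floor), hi=400.0
        )

    def relative_output(self, phi_deg) -> np.ndarray:
        phi = np.asarray(phi_deg, dtype=float)
        if self.dm_max_pct == 0.0:
            return np.ones_like(phi)
        u = ((phi - self.center_deg + 180.0) % 360.0 - 180.0) / (0.5 * self.arc_deg)
        inside = np.abs(u) <= 1.0
        w = np.zeros_like(phi)
        cu = np.cos(0.5 * np.pi * np.clip(u, -1.0, 1.0))
        w[inside] = self.edge_floor + (1.0 - self.edge_floor) * cu[inside] ** self.taper_exponent
        return 1.0 - (self.dm_max_pct / 100.0) * w

    @property
    def mean_relative_output(self) -> float:
        return 1.0 - self.dm_total_pct / 100.0

    def tabulate(self, step_deg: float = 0.5) -> tuple[np.ndarray, np.ndarray]:
        """(angles, relative output) lookup at a fixed angular step."""
        phi = np.arange(0.0, 360.0, step_deg)
        return phi, self.relative_output(phi)

    def rotated(self, delta_deg: float) -> "AngularOutputProfile":
        """Copy with the dip centre shifted by ``delta_deg``."""
        out = AngularOutputProfile.__new__(AngularOutputProfile)
        out.__dict__.update(self.__dict__)
        out.center_deg = (self.center_deg + delta_deg) % 360.0
        return out


def build_angular_profile(
    mode: str,
    requested_mA: float,
    params: OEMParameters | None = None,
    table: OEMCalibrationTable | None = None,
    edge_floor: float = 0.05,
) -> AngularOutputProfile:
    """Angular output model for a scan mode at a requested tube current."""
    params = params or OEMParameters()
    if mode == "off":
        return AngularOutputProfile("off")
    d_max, d_tot = modulation_rates(requested_mA, params, table)
    return AngularOutputProfile(mode, d_max, d_tot, params.theta_deg, edge_floor)
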