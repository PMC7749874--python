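"""Dose-rate profile analysis for organ-effective modulation (OEM).

A CT scanner with OEM enabled dips its tube output over an angular arc of
the rotation.  Measuring the dose rate at the isocenter of a PMMA phantom
with OEM off and on gives two time profiles; comparing them yields the
three characterization numbers used throughout the package:

* the modulation angle ``theta = 360 * T_drr / T_1rot`` where ``T_drr`` is
  the duration of the dose-rate reduction and ``T_1rot`` the rotation time;
* ``DM_Max = 100 * (1 - min(DR_on / DR_off))``, the deepest instantaneous
  output reduction;
* ``DM_Total = 100 * (1 - integral(DR_on) / integral(DR_off))``, the
  rotation-integrated reduction, both evaluated over exactly one rotation
  after the start-up overhead.

The module also synthesizes profiles from an angular output model, which is
how every analysis routine here is exercised without scanner hardware.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import TYPE_CHECKING

import numpy as np

from .errors import DegenerateProfileError, InvalidInputError

if TYPE_CHECKING:  # pragma: no cover
    from .oem import AngularOutputProfile

#: start-up output not used for image reconstruction (measured total output
#: ran ~25 ms longer than the 500 ms rotation setting)
DEFAULT_STARTUP_OVERHEAD_MS = 25.0


@dataclass(frozen=True)
class DoseRateProfile:
    """Time-sampled tube output (mGy/s) over one volume-scan exposure."""

    times_ms: np.ndarray
    dose_rates: np.ndarray
    rotation_period_ms: float = 500.0
    label: str = ""

    def __post_init__(self):
        t = np.asarray(self.times_ms, dtype=float)
        d = np.asarray(self.dose_rates, dtype=float)
        object.__setattr__(self, "times_ms", t)
        object.__setattr__(self, "dose_rates", d)
        if t.ndim != 1 or t.size < 2 or d.shape != t.shape:
            raise InvalidInputError("profile needs matching 1-D time and dose-rate arrays")
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise InvalidInputError("times must be strictly increasing")
        if not np.allclose(dt, dt[0], rtol=1e-9, atol=0.0):
            raise InvalidInputError("times must be uniformly sampled")
        if not np.all(np.isfinite(d)) or np.any(d < 0):
            raise InvalidInputError("dose rates must be finite and non-negative")
        if self.rotation_period_ms <= 0:
            raise InvalidInputError("rotation period must be positive")
        if t[-1] - t[0] < self.rotation_period_ms - 1e-9:
            raise InvalidInputError("profile must cover at least one rotation period")

    @property
    def dt_ms(self) -> float:
        return float(self.times_ms[1] - self.times_ms[0])

    @property
    def duration_ms(self) -> float:
        return float(self.times_ms[-1] - self.times_ms[0])

    def output_start_ms(self, fraction: float = 0.01) -> float:
        """Time of the first sample exceeding ``fraction`` of the peak rate."""
        peak = float(self.dose_rates.max())
        if peak <= 0.0:
            raise DegenerateProfileError("profile has no output")
        idx = np.argmax(self.dose_rates > fraction * peak)
        return float(self.times_ms[idx])


@dataclass(frozen=True)
class ModulationWindow:
    """Interval of the ON profile where output is measurably reduced."""

    t_start_ms: float
    t_end_ms: float

    def __post_init__(self):
        if self.t_end_ms < self.t_start_ms:
            raise InvalidInputError("window end precedes start")

    @property
    def t_drr_ms(self) -> float:
        return self.t_end_ms - self.t_start_ms


@dataclass(frozen=True)
class ModulationMetrics:
    """The (theta, DM_Max, DM_Total) triple characterizing one ON/OFF pair."""

    theta_deg: float
    dm_max_pct: float
    dm_total_pct: float

    def __post_init__(self):
        if not 0.0 <= self.theta_deg <= 360.0:
            raise InvalidInputError("theta must lie in [0, 360] degrees")
        if not 0.0 <= self.dm_max_pct <= 100.0:
            raise InvalidInputError("DM_Max must lie in [0, 100] %")
        if not -1e-9 <= self.dm_total_pct <= self.dm_max_pct + 1e-9:
            raise InvalidInputError("DM_Total must lie in [0, DM_Max]")


def _ratio_on_off(on: DoseRateProfile, off: DoseRateProfile):
    """ON/OFF dose-rate ratio on the ON grid (OFF linearly resampled)."""
    if off.dose_rates.max() <= 0.0:
        raise DegenerateProfileError("OFF profile is all zero")
    lo = max(on.times_ms[0], off.times_ms[0])
    hi = min(on.times_ms[-1], off.times_ms[-1])
    if hi <= lo:
        raise InvalidInputError("profiles do not overlap in time")
    mask = (on.times_ms >= lo) & (on.times_ms <= hi)
    t = on.times_ms[mask]
    off_r = np.interp(t, off.times_ms, off.dose_rates)
    valid = off_r > 1e-12 * off.dose_rates.max()
    ratio = np.full(t.shape, np.nan)
    ratio[valid] = on.dose_rates[mask][valid] / off_r[valid]
    return t, ratio


def detect_modulation_window(
    on: DoseRateProfile,
    off: DoseRateProfile,
    threshold_fraction: float = 0.01,
    peak_search_ms: float = 50.0,
) -> ModulationWindow:
    """Locate the dose-rate reduction window of an OEM_ON profile.

    The window spans the earliest to the latest time at which the ON/OFF
    ratio falls below ``1 - threshold_fraction`` of the local pre/post-dip
    peak ratio (the peak is searched within ``peak_search_ms`` of each
    provisional edge, which makes the rule robust to the start-up ramp).
    Returns a zero-length window when no sample qualifies.
    """
    if not 0.0 < threshold_fraction < 1.0:
        raise InvalidInputError("threshold fraction must lie in (0, 1)")
    t, ratio = _ratio_on_off(on, off)
    finite = np.isfinite(ratio)
    if not finite.any():
        raise DegenerateProfileError("no usable ON/OFF ratio samples")
    work = np.where(finite, ratio, np.inf)
    i_min = int(np.argmin(work))
    baseline = float(np.nanmedian(ratio))
    if baseline <= 0.0:
        raise DegenerateProfileError("non-positive baseline ratio")

    def _edges(reference_left: float, reference_right: float):
        below_l = work < (1.0 - threshold_fraction) * reference_left
        below_r = work < (1.0 - threshold_fraction) * reference_right
        if not (below_l[i_min] or below_r[i_min]):
            return None
        left = i_min
        while left > 0 and below_l[left - 1]:
            left -= 1
        right = i_min
        while right < len(t) - 1 and below_r[right + 1]:
            right += 1
        return left, right

    first = _edges(baseline, baseline)
    if first is None:
        t_flat = float(t[i_min])
        return ModulationWindow(t_flat, t_flat)
    left, right = first
    # refine once against the local peaks adjacent to the provisional edges
    near_l = finite & (np.abs(t - t[left]) <= peak_search_ms)
    near_r = finite & (np.abs(t - t[right]) <= peak_search_ms)
    ref_l = float(np.nanmax(np.where(near_l, ratio, np.nan)))
    ref_r = float(np.nanmax(np.where(near_r, ratio, np.nan)))
    refined = _edges(ref_l, ref_r)
    if refined is not None:
        left, right = refined
    return ModulationWindow(float(t[left]), float(t[right]))


def modulation_angle(t_drr_ms: float, t_1rot_ms: float) -> float:
    """Gantry arc (degrees) equivalent to a dose-rate reduction time."""
    if t_1rot_ms <= 0:
        raise InvalidInputError("rotation period must be positive")
    if not 0.0 <= t_drr_ms <= t_1rot_ms:
        raise InvalidInputError("T_drr must lie in [0, T_1rot]")
    return 360.0 * t_drr_ms / t_1rot_ms


def _rotation_mask(t: np.ndarray, on: DoseRateProfile, startup_overhead_ms: float):
    """Mask (on grid ``t``) covering exactly one rotation after start-up."""
    start = on.output_start_ms() + startup_overhead_ms
    stop = start + on.rotation_period_ms
    if stop > t[-1] + 0.5 * on.dt_ms:
        raise InvalidInputError("profile too short for one rotation after start-up")
    return (t >= start - 1e-9) & (t <= stop + 1e-9)


def dm_max(
    on: DoseRateProfile,
    off: DoseRateProfile,
    startup_overhead_ms: float = DEFAULT_STARTUP_OVERHEAD_MS,
) -> float:
    """Maximum instantaneous output reduction (%), over one rotation."""
    t, ratio = _ratio_on_off(on, off)
    window = ratio[_rotation_mask(t, on, startup_overhead_ms)]
    if np.isnan(window).any():
        raise DegenerateProfileError("OFF profile vanishes inside the rotation window")
    return 100.0 * (1.0 - float(window.min()))


def dm_total(
    on: DoseRateProfile,
    off: DoseRateProfile,
    startup_overhead_ms: float = DEFAULT_STARTUP_OVERHEAD_MS,
) -> float:
    """Rotation-integrated output reduction (%), trapezoid quadrature."""
    t, _ = _ratio_on_off(on, off)
    mask = _rotation_mask(t, on, startup_overhead_ms)
    t_w = t[mask]
    on_w = np.interp(t_w, on.times_ms, on.dose_rates)
    off_w = np.interp(t_w, off.times_ms, off.dose_rates)
    total_off = np.trapezoid(off_w, t_w)
    if total_off <= 0.0:
        raise DegenerateProfileError("OFF profile integrates to zero over the rotation")
    total_on = np.trapezoid(on_w, t_w)
    return 100.0 * (1.0 - total_on / total_off)


def analyze_pair(
    on: DoseRateProfile,
    off: DoseRateProfile,
    threshold_fraction: float = 0.01,
    startup_overhead_ms: float = DEFAULT_STARTUP_OVERHEAD_MS,
) -> tuple[ModulationMetrics, ModulationWindow]:
    """Full characterization of one ON/OFF profile pair."""
    window = detect_modulation_window(on, off, threshold_fraction)
    theta = modulation_angle(min(window.t_drr_ms, on.rotation_period_ms), on.rotation_period_ms)
    d_max = max(dm_max(on, off, startup_overhead_ms), 0.0)
    d_tot = min(max(dm_total(on, off, startup_overhead_ms), 0.0), d_max)
    return ModulationMetrics(theta, d_max, d_tot), window


def synthesize_profile(
    t_1rot_ms: float = 500.0,
    base_rate: float = 10.0,
    dip: "AngularOutputProfile | None" = None,
    startup_overhead_ms: float = DEFAULT_STARTUP_OVERHEAD_MS,
    noise_sd: float = 0.0,
    seed: int | None = 0,
    dt_ms: float = 1.0,
    start_angle_deg: float = 180.0,
    label: str = "",
) -> DoseRateProfile:
    """Generate a dose-rate profile from an angular output model.

    Output runs from t = 0 to ``startup_overhead_ms + t_1rot_ms``; the
    imaging rotation is the final ``t_1rot_ms``, during which the gantry
    angle advances from ``start_angle_deg`` through one full turn and the
    dip's relative output multiplies the base rate.  The default start angle
    (180 deg) places a front-centered dip in the middle of the rotation.
    Deterministic for a fixed seed.
    """
    if base_rate <= 0:
        raise InvalidInputError("base rate must be positive")
    if noise_sd < 0:
        raise InvalidInputError("noise SD must be non-negative")
    if t_1rot_ms <= 0 or startup_overhead_ms < 0:
        raise InvalidInputError("invalid timing parameters")
    duration = startup_overhead_ms + t_1rot_ms
    n = int(round(duration / dt_ms)) + 1
    times = np.arange(n) * dt_ms
    rates = np.full(n, float(base_rate))
    if dip is not None:
        in_rot = times >= startup_overhead_ms
        phi = (start_angle_deg + 360.0 * (times[in_rot] - startup_overhead_ms) / t_1rot_ms) % 360.0
        rates[in_rot] *= dip.relative_output(phi)
    if noise_sd > 0.0:
        rng = np.random.default_rng(seed)
        rates = np.clip(rates + rng.normal(0.0, noise_sd, size=n), 0.0, None)
    return DoseRateProfile(times, rates, rotation_period_ms=t_1rot_ms, label=label)


def write_profile_csv(path, profile: DoseRateProfile, **metadata) -> None:
    """Two-column CSV with '#'-prefixed metadata headers."""
    lines = [f"# label: {profile.label}", f"# rotation_period_ms: {profile.rotation_period_ms}"]
    lines += [f"# {k}: {v}" for k, v in metadata.items()]
    lines.append("time_ms,dose_rate_mGy_per_s")
    lines += [f"{t:.6g},{d:.9g}" for t, d in zip(profile.times_ms, profile.dose_rates)]
    Path(path).write_text("\n".join(lines) + "\n")


def read_profile_csv(path) -> DoseRateProfile:
    meta: dict[str, str] = {}
    times, rates = [], []
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            key, _, value = line[1:].partition(":")
            meta[key.strip()] = value.strip()
        elif not line[0].isalpha():
            t, _, d = line.partition(",")
            times.append(float(t))
            rates.append(float(d))
    if not times:
        raise InvalidInputError(f"no samples found in {path}")
    return DoseRateProfile(
        np.asarray(times),
        np.asarray(rates),
        rotation_period_ms=float(meta.get("rotation_period_ms", 500.0)),
        label=meta.get("label", ""),
    )
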