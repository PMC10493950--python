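"""Minimum shoot conductance (g_min) from branch drydown mass series, and
the phase-transition temperature (T_P) from a segmented fit of g_min against
temperature.

A detached, wax-sealed branchlet drying in an oven loses water first through
closing stomata and then, at a steady rate, through the cuticle.  The steady
mass-loss slope gives the transpiration rate

    R = dw / (dt * A)        [mmol m^-2 s^-1, A the double-sided leaf area]

which converts to a diffusive conductance via the vapor pressure deficit:

    SVP(T) = (610.7 * 10^(7.5 T / (237.3 + T))) / 1000      [kPa, Buck]
    VPD(T, RH) = (1 - RH/100) * SVP(T)                      [kPa]
    g = R / VPD * P_atm,  P_atm = 101.6 kPa.

g_min stays roughly flat at low temperature and rises sharply above a
breakpoint; that breakpoint — fitted by a continuous two-segment linear
model — is the phase transition temperature T_P.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize

__all__ = [
    "MOLAR_MASS_WATER",
    "P_ATM_KPA",
    "saturation_vapor_pressure",
    "vapor_pressure_deficit",
    "leaf_area",
    "MassSeries",
    "detect_steady_state",
    "transpiration_rate",
    "ConductancePoint",
    "gmin_at_temperature",
    "SegmentedRegression",
    "SegmentedResults",
    "fit_breakpoint",
    "BreakpointNotIdentifiableError",
    "NoSteadyStateError",
]

MOLAR_MASS_WATER = 18.015  # g mol^-1
P_ATM_KPA = 101.6          # sea-level atmospheric pressure used in g = R/VPD * P_atm


class NoSteadyStateError(RuntimeError):
    """The drydown never settles to a steady mass-loss rate."""


class BreakpointNotIdentifiableError(RuntimeError):
    """SSE is flat across candidate breakpoints (e.g. globally linear data)."""


def saturation_vapor_pressure(T):
    """Saturation vapor pressure in kPa at temperature ``T`` (deg C), Buck form."""
    T = np.asarray(T, dtype=float)
    if np.any(T <= -237.3):
        raise ValueError("temperature out of range for the Buck formula")
    out = (610.7 * 10.0 ** (7.5 * T / (237.3 + T))) / 1000.0
    return float(out) if out.ndim == 0 else out


def vapor_pressure_deficit(T, rh):
    """Vapor pressure deficit in kPa at ``T`` (deg C) and relative humidity ``rh`` (%)."""
    rh = np.asarray(rh, dtype=float)
    if np.any((rh < 0) | (rh > 100)):
        raise ValueError("relative humidity must be in [0, 100] %")
    out = (1.0 - rh / 100.0) * saturation_vapor_pressure(T)
    return float(out) if np.ndim(out) == 0 else out


def leaf_area(leaf_dry_mass_g: float, sla_m2_per_kg: float,
              double_sided: bool = True) -> float:
    """Branchlet leaf area (m^2) from total leaf dry mass (g) and SLA (m^2 kg^-1).

    SLA is conventionally projected (single-sided); ``double_sided=True``
    (default) doubles it, matching the double-sided area used in the
    transpiration-rate denominator.
    """
    if leaf_dry_mass_g <= 0 or sla_m2_per_kg <= 0:
        raise ValueError("leaf dry mass and SLA must be positive")
    area = leaf_dry_mass_g / 1000.0 * sla_m2_per_kg
    return 2.0 * area if double_sided else area


@dataclass
class MassSeries:
    """One branchlet drydown record at a single oven temperature."""
    times: np.ndarray          # s, strictly increasing
    masses: np.ndarray         # g
    temperature: float         # deg C
    rh: float                  # %
    leaf_dry_mass: float       # g
    sla: float                 # m^2 kg^-1

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.masses = np.asarray(self.masses, dtype=float)
        if self.times.size != self.masses.size or self.times.size < 10:
            raise ValueError("mass series needs >= 10 matched samples")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if not (0.0 < self.temperature < 60.0):
            raise ValueError("temperature must be in (0, 60) deg C")
        if not (0.0 <= self.rh < 100.0):
            raise ValueError("relative humidity must be in [0, 100) %")


def _window_slopes(times: np.ndarray, masses: np.ndarray, window: int) -> np.ndarray:
    n = times.size
    slopes = np.empty(n - window + 1)
    for i in range(n - window + 1):
        t = times[i:i + window]
        m = masses[i:i + window]
        slopes[i] = np.polyfit(t, m, 1)[0]
    return slopes


def detect_steady_state(series: MassSeries, window: int = 5,
                        rel_tol: float = 0.15) -> tuple[int, int]:
    """Terminal steady-rate index range ``(start, stop)`` of a drydown.

    Rolling least-squares slopes over ``window``-point windows are compared
    with the final window's slope; the longest terminal run of windows whose
    slope deviates by at most ``rel_tol`` (relative) is returned as a
    half-open index range.  The run must contain at least two windows —
    a single self-matching final window (as on a still-curving, purely
    exponential series) raises :class:`NoSteadyStateError`.
    """
    if window < 3:
        raise ValueError("window must be >= 3 points")
    slopes = _window_slopes(series.times, series.masses, window)
    ref = slopes[-1]
    denom = abs(ref) if ref != 0 else np.finfo(float).tiny
    ok = np.abs(slopes - ref) <= rel_tol * denom if ref != 0 else (
        np.abs(slopes) <= 1e-12 * np.max(np.abs(series.masses)))
    start_w = len(ok)
    for i in range(len(ok) - 1, -1, -1):
        if ok[i]:
            start_w = i
        else:
            break
    if start_w >= len(ok) - 1:
        raise NoSteadyStateError(
            f"no steady state at T={series.temperature} deg C: slope still "
            f"changing by more than {rel_tol:.0%} up to the final window")
    return int(start_w), int(series.times.size)


def transpiration_rate(series: MassSeries, index_range: tuple[int, int],
                       area_m2: float) -> float:
    """Steady transpiration rate R in mmol m^-2 s^-1 over an index range.

    Least-squares slope of mass (g) vs time (s), converted to a molar water
    flux per unit leaf area; sign-flipped so mass loss gives R >= 0.  A
    non-negative mass slope warns and returns 0.
    """
    lo, hi = index_range
    if hi - lo < 3:
        raise ValueError("transpiration rate needs >= 3 points")
    if area_m2 <= 0:
        raise ValueError("leaf area must be positive")
    slope_g_per_s = np.polyfit(series.times[lo:hi], series.masses[lo:hi], 1)[0]
    if slope_g_per_s >= 0:
        warnings.warn("non-negative mass slope in steady window; R set to 0")
        return 0.0
    return float(-slope_g_per_s / MOLAR_MASS_WATER * 1000.0 / area_m2)


@dataclass
class ConductancePoint:
    """g_min at one oven temperature."""
    temperature: float           # deg C
    gmin: float                  # mmol m^-2 s^-1
    r_flux: float                # mmol m^-2 s^-1
    vpd: float                   # kPa
    steady_window: tuple[int, int]


def gmin_at_temperature(series: MassSeries, window: int = 5,
                        rel_tol: float = 0.15, double_sided: bool = True,
                        p_atm: float = P_ATM_KPA) -> ConductancePoint:
    """Minimum conductance from one drydown: steady window -> R -> g = R/VPD * P_atm."""
    vpd = vapor_pressure_deficit(series.temperature, series.rh)
    if vpd == 0:
        raise ZeroDivisionError(
            "VPD is zero (RH = 100%): conductance undefined, no vapour gradient")
    rng_idx = detect_steady_state(series, window=window, rel_tol=rel_tol)
    area = leaf_area(series.leaf_dry_mass, series.sla, double_sided=double_sided)
    R = transpiration_rate(series, rng_idx, area)
    g = R / vpd * p_atm
    return ConductancePoint(series.temperature, g, R, vpd, rng_idx)


# ---------------------------------------------------------------------------
# segmented (breakpoint) regression for T_P

class SegmentedRegression:
    """Continuous two-segment linear model g(T) = b0 + b1 T + b2 (T - psi)+.

    The breakpoint psi is found by an exhaustive 0.1 deg C grid search
    strictly between the second and penultimate observed temperatures,
    refined by bounded scalar minimisation of the profile SSE; b0, b1, b2
    are ordinary least squares at each candidate psi.  psi is the phase
    transition temperature T_P.
    """

    def __init__(self, temperature, g):
        self.T = np.asarray(temperature, dtype=float)
        self.g = np.asarray(g, dtype=float)
        if self.T.size != self.g.size:
            raise ValueError("temperature and g must have equal length")
        if self.T.size < 5:
            raise ValueError("breakpoint fit needs >= 5 temperature points")
        order = np.argsort(self.T)
        self.T, self.g = self.T[order], self.g[order]

    @classmethod
    def from_points(cls, points: Sequence[ConductancePoint]) -> "SegmentedRegression":
        return cls([p.temperature for p in points], [p.gmin for p in points])

    def _sse(self, psi: float) -> tuple[float, np.ndarray]:
        X = np.column_stack([np.ones_like(self.T), self.T,
                             np.clip(self.T - psi, 0.0, None)])
        beta, *_ = np.linalg.lstsq(X, self.g, rcond=None)
        resid = self.g - X @ beta
        return float(resid @ resid), beta

    def fit(self, grid_step: float = 0.1, flat_tol: float = 1e-6) -> "SegmentedResults":
        Ts = np.unique(self.T)
        lo, hi = Ts[1], Ts[-2]
        grid = np.arange(lo + grid_step, hi, grid_step)
        if grid.size == 0:
            raise ValueError("temperature range too narrow for a breakpoint grid")
        sse = np.array([self._sse(psi)[0] for psi in grid])
        spread = sse.max() - sse.min()
        # flatness is judged against the scale of the data (total sum of
        # squares), so exactly-linear inputs (all SSE ~ 0) are flagged
        tss = float(np.sum((self.g - self.g.mean()) ** 2))
        if spread <= flat_tol * max(tss, np.finfo(float).tiny):
            raise BreakpointNotIdentifiableError(
                "SSE is flat across candidate breakpoints; "
                "the g(T) relationship has no identifiable kink")
        best = grid[int(np.argmin(sse))]
        res = optimize.minimize_scalar(
            lambda p: self._sse(p)[0],
            bounds=(max(lo, best - grid_step), min(hi, best + grid_step)),
            method="bounded", options={"xatol": 1e-4})
        psi = float(res.x)
        sse_hat, beta = self._sse(psi)
        fitted = beta[0] + beta[1] * self.T + beta[2] * np.clip(self.T - psi, 0, None)
        return SegmentedResults(
            tp=psi, intercept=float(beta[0]),
            slope_below=float(beta[1]), slope_above=float(beta[1] + beta[2]),
            sse=sse_hat, temperature=self.T, g=self.g, fitted=fitted)


@dataclass
class SegmentedResults:
    """Fitted breakpoint model; ``tp`` is the phase transition temperature."""
    tp: float
    intercept: float
    slope_below: float
    slope_above: float
    sse: float
    temperature: np.ndarray = field(repr=False)
    g: np.ndarray = field(repr=False)
    fitted: np.ndarray = field(repr=False)

    def predict(self, T):
        T = np.asarray(T, dtype=float)
        b2 = self.slope_above - self.slope_below
        return self.intercept + self.slope_below * T + b2 * np.clip(T - self.tp, 0, None)

    def summary(self) -> str:
        return (
            "Segmented g_min(T) fit\n"
            f"  T_P (breakpoint)  {self.tp:.2f} deg C\n"
            f"  slope below T_P   {self.slope_below:.4f} mmol m^-2 s^-1 K^-1\n"
            f"  slope above T_P   {self.slope_above:.4f} mmol m^-2 s^-1 K^-1\n"
            f"  intercept         {self.intercept:.4f}\n"
            f"  SSE               {self.sse:.6g}\n"
        )

    def plot(self, ax=None):
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        ax.scatter(self.temperature, self.g, label="g_min")
        Tg = np.linspace(self.temperature.min(), self.temperature.max(), 200)
        ax.plot(Tg, self.predict(Tg), color="C1", label="segmented fit")
        ax.axvline(self.tp, ls=":", color="0.4")
        ax.set_xlabel("temperature (deg C)")
        ax.set_ylabel("g_min (mmol m$^{-2}$ s$^{-1}$)")
        ax.legend()
        return ax


def fit_breakpoint(points: Sequence[ConductancePoint] | tuple) -> SegmentedResults:
    """Functional wrapper: fit T_P from per-temperature conductance points."""
    if len(points) and isinstance(points[0], ConductancePoint):
        model = SegmentedRegression.from_points(points)
    else:
        T, g = points
        model = SegmentedRegression(T, g)
    return model.fit()
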