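"""Enzyme kinetics and growth-rate analysis.

Covers the quantitative enzymology of an amylose-degrading
glucanotransferase assayed by the iodine method:

* conversion of iodine-complex absorbance loss (A660) into specific
  amylose-degradation activity (mg amylose per minute per mg enzyme),
* transglycosylation factors (fold-activation of amylose degradation by an
  added acceptor sugar, relative to no acceptor), with first-order error
  propagation,
* Michaelis-Menten fitting of acceptor-concentration / initial-velocity data
  via the Lineweaver-Burk double-reciprocal plot (the reported method), with
  a direct nonlinear fit available as a cross-check,
* Vmax -> kcat conversion given the enzyme load (mg/ml) and molar mass (Da),
* specific growth rate by log-linear regression over the exponential phase
  of a growth curve.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize, stats

__all__ = [
    "ActivityMeasurement",
    "RatePoint",
    "KineticDataset",
    "KineticFit",
    "GrowthCurve",
    "GrowthFit",
    "FitFailureError",
    "absorbance_to_specific_activity",
    "transglycosylation_factor",
    "fit_lineweaver_burk",
    "fit_michaelis_menten",
    "vmax_to_kcat",
    "enzyme_molar_concentration",
    "efficiency_ratio",
    "fit_growth_rate",
]


class FitFailureError(ValueError):
    """The data are inconsistent with the Michaelis-Menten model."""


@dataclass
class ActivityMeasurement:
    """Specific amylose-degradation activity under one acceptor condition."""

    condition: str
    specific_activity: float  # mg amylose / (min * mg enzyme)
    acceptor_concentration: float = 0.0  # mM
    sd: float | None = None
    clipped: bool = False

    def __post_init__(self) -> None:
        if self.specific_activity < 0:
            raise ValueError("specific_activity must be >= 0")


@dataclass
class RatePoint:
    acceptor_concentration: float  # mM
    velocity: float  # assay-native velocity units (uM product / min here)

    def __post_init__(self) -> None:
        if self.acceptor_concentration <= 0:
            raise ValueError("acceptor concentration must be positive")
        if self.velocity < 0:
            raise ValueError("velocity must be >= 0")


@dataclass
class KineticDataset:
    """Initial-velocity points for one acceptor, plus optional ground truth."""

    acceptor: str
    points: list[RatePoint]
    ground_truth: dict = field(default_factory=dict)

    def concentrations(self) -> np.ndarray:
        return np.array([p.acceptor_concentration for p in self.points])

    def velocities(self) -> np.ndarray:
        return np.array([p.velocity for p in self.points])


@dataclass
class KineticFit:
    KM: float  # mM
    Vmax: float  # velocity units
    kcat: float | None = None  # min^-1
    efficiency: float | None = None  # min^-1 mM^-1
    r_squared: float | None = None
    enzyme_concentration: float | None = None  # mg/ml
    enzyme_molar_mass: float | None = None  # Da
    method: str = "lineweaver_burk"


@dataclass
class GrowthCurve:
    times: np.ndarray  # h
    densities: np.ndarray  # cells/ml
    exponential_window: tuple[float, float] | None = None
    ground_truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.densities = np.asarray(self.densities, dtype=float)
        if self.times.shape != self.densities.shape:
            raise ValueError("times and densities must align")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")


@dataclass
class GrowthFit:
    k: float  # h^-1, slope of ln(density) vs time
    r_squared: float
    window: tuple[float, float]
    n_points: int


def absorbance_to_specific_activity(
    delta_A660: float,
    calibration_slope: float,
    reaction_minutes: float,
    enzyme_mg: float,
    condition: str = "",
    acceptor_concentration: float = 0.0,
) -> ActivityMeasurement:
    """Convert an A660 drop into specific activity.

    ``calibration_slope`` is the iodine standard curve, ug amylose per
    absorbance unit. One activity unit is 1 ug amylose hydrolysed per
    minute; specific activity is reported as mg amylose / (min * mg enzyme).
    Negative absorbance changes are clipped to zero and flagged.
    """
    if calibration_slope <= 0:
        raise ValueError("calibration_slope must be positive")
    if reaction_minutes <= 0:
        raise ValueError("reaction_minutes must be positive")
    if enzyme_mg <= 0:
        raise ValueError("enzyme_mg must be positive")
    clipped = delta_A660 < 0
    delta = max(delta_A660, 0.0)
    ug_per_min_per_mg = delta * calibration_slope / reaction_minutes / enzyme_mg
    return ActivityMeasurement(
        condition=condition,
        specific_activity=ug_per_min_per_mg / 1000.0,  # ug -> mg
        acceptor_concentration=acceptor_concentration,
        clipped=clipped,
    )


def transglycosylation_factor(
    with_acceptor: ActivityMeasurement,
    without_acceptor: ActivityMeasurement,
) -> tuple[float, float | None]:
    """Fold-activation of amylose degradation by the acceptor.

    Returns (factor, sd); the SD is first-order propagated when both inputs
    carry one, else None.
    """
    if without_acceptor.specific_activity <= 0:
        raise ZeroDivisionError("baseline (no acceptor) activity must be positive")
    factor = with_acceptor.specific_activity / without_acceptor.specific_activity
    sd = None
    if with_acceptor.sd is not None and without_acceptor.sd is not None:
        rel = math.sqrt(
            (with_acceptor.sd / with_acceptor.specific_activity) ** 2
            + (without_acceptor.sd / without_acceptor.specific_activity) ** 2
        )
        sd = factor * rel
    return factor, sd


def fit_lineweaver_burk(data: KineticDataset | Sequence[RatePoint]) -> KineticFit:
    """Michaelis-Menten parameters from the double-reciprocal plot.

    Unweighted ordinary least squares of 1/v on 1/[S]; slope = KM/Vmax,
    intercept = 1/Vmax. A non-positive intercept or slope means the data are
    inconsistent with saturation kinetics (except the exact-saturation limit
    slope == 0, which returns KM = 0, Vmax = mean v).
    """
    points = data.points if isinstance(data, KineticDataset) else list(data)
    if len({p.acceptor_concentration for p in points}) < 3:
        raise ValueError("need >= 3 points with distinct concentrations")
    if any(p.velocity <= 0 for p in points):
        raise ValueError("all velocities must be positive for the reciprocal fit")
    s = np.array([p.acceptor_concentration for p in points])
    v = np.array([p.velocity for p in points])
    res = stats.linregress(1.0 / s, 1.0 / v)
    slope, intercept = res.slope, res.intercept
    if intercept <= 0:
        raise FitFailureError(
            "non-positive Lineweaver-Burk intercept: data inconsistent "
            "with Michaelis-Menten kinetics"
        )
    KM = slope / intercept
    if KM < 0:
        if KM > -1e-9:  # saturation limit: v constant over [S], slope ~ 0
            KM = 0.0
        else:
            raise FitFailureError(
                "negative Lineweaver-Burk slope: data inconsistent with "
                "Michaelis-Menten kinetics"
            )
    Vmax = 1.0 / intercept
    r2 = float(res.rvalue**2) if np.isfinite(res.rvalue) else 1.0
    return KineticFit(KM=float(KM), Vmax=float(Vmax), r_squared=r2)


def fit_michaelis_menten(data: KineticDataset | Sequence[RatePoint]) -> KineticFit:
    """Direct nonlinear Michaelis-Menten fit (cross-check for the LB route)."""
    points = data.points if isinstance(data, KineticDataset) else list(data)
    if len({p.acceptor_concentration for p in points}) < 3:
        raise ValueError("need >= 3 points with distinct concentrations")
    s = np.array([p.acceptor_concentration for p in points])
    v = np.array([p.velocity for p in points])
    vmax0 = float(v.max()) or 1.0
    km0 = float(np.median(s))
    popt, _ = optimize.curve_fit(
        lambda x, vmax, km: vmax * x / (km + x), s, v, p0=(vmax0, km0), maxfev=10000
    )
    vmax, km = popt
    if vmax <= 0 or km < 0:
        raise FitFailureError("nonlinear fit produced non-physical parameters")
    resid = v - vmax * s / (km + s)
    ss_tot = float(np.sum((v - v.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    return KineticFit(KM=float(km), Vmax=float(vmax), r_squared=r2, method="nonlinear")


def enzyme_molar_concentration(
    enzyme_concentration: float, enzyme_molar_mass: float
) -> float:
    """Enzyme load in uM from mg/ml and Da: (g/l) / (g/mol) * 1e6."""
    if enzyme_concentration <= 0 or enzyme_molar_mass <= 0:
        raise ValueError("enzyme concentration and molar mass must be positive")
    return enzyme_concentration / enzyme_molar_mass * 1e6


def vmax_to_kcat(
    Vmax: float, enzyme_concentration: float, enzyme_molar_mass: float
) -> float:
    """Turnover number (min^-1) from Vmax in uM/min and enzyme load.

    kcat = Vmax / [E], with [E] in uM from mg/ml and Da.
    """
    if Vmax < 0:
        raise ValueError("Vmax must be >= 0")
    return Vmax / enzyme_molar_concentration(enzyme_concentration, enzyme_molar_mass)


def complete_fit(
    fit: KineticFit, enzyme_concentration: float, enzyme_molar_mass: float
) -> KineticFit:
    """Fill kcat and kcat/KM on a fit, given the enzyme load."""
    kcat = vmax_to_kcat(fit.Vmax, enzyme_concentration, enzyme_molar_mass)
    fit.kcat = kcat
    fit.efficiency = efficiency_ratio(fit, kcat=kcat)
    fit.enzyme_concentration = enzyme_concentration
    fit.enzyme_molar_mass = enzyme_molar_mass
    return fit


def efficiency_ratio(fit: KineticFit, kcat: float | None = None) -> float:
    """Catalytic efficiency kcat/KM in min^-1 mM^-1."""
    kcat = fit.kcat if kcat is None else kcat
    if kcat is None:
        raise ValueError("fit carries no kcat; convert Vmax first")
    if kcat == 0:
        return 0.0
    if fit.KM <= 0:
        raise ValueError("KM must be positive for an efficiency ratio")
    return kcat / fit.KM


def _window_regression(t: np.ndarray, log_n: np.ndarray) -> tuple[float, float]:
    res = stats.linregress(t, log_n)
    ss_tot = float(np.sum((log_n - log_n.mean()) ** 2))
    if ss_tot == 0:
        # perfectly flat log-density: zero slope fits exactly
        return 0.0, 1.0
    return float(res.slope), float(res.rvalue**2)


def fit_growth_rate(
    curve: GrowthCurve,
    window: tuple[float, float] | None = None,
    min_points: int = 4,
    r2_threshold: float = 0.99,
) -> GrowthFit:
    """Specific growth rate k (h^-1) by OLS of ln(density) on time.

    With an explicit ``window`` (t_start, t_end) the regression uses the
    points inside it (>= 3 required). Otherwise the longest contiguous run of
    at least ``min_points`` points whose log-linear fit reaches
    ``r2_threshold`` is selected as the exponential phase; among equally long
    windows the earlier one wins.
    """
    if window is None:
        window = curve.exponential_window
    t, n = curve.times, curve.densities
    if window is not None:
        mask = (t >= window[0]) & (t <= window[1])
        if mask.sum() < 3:
            raise ValueError("need >= 3 points inside the window")
        if np.any(n[mask] <= 0):
            raise ValueError("densities in the window must be positive")
        slope, r2 = _window_regression(t[mask], np.log(n[mask]))
        return GrowthFit(k=slope, r_squared=r2, window=window,
                         n_points=int(mask.sum()))

    if np.any(n <= 0):
        raise ValueError("densities must be positive for automatic window selection")
    log_n = np.log(n)
    m = len(t)
    best: GrowthFit | None = None
    for length in range(m, min_points - 1, -1):
        for start in range(0, m - length + 1):
            sl = slice(start, start + length)
            slope, r2 = _window_regression(t[sl], log_n[sl])
            if r2 >= r2_threshold:
                best = GrowthFit(
                    k=slope,
                    r_squared=r2,
                    window=(float(t[sl][0]), float(t[sl][-1])),
                    n_points=length,
                )
                break
        if best is not None:
            break
    if best is None:
        raise FitFailureError(
            f"no contiguous window of >= {min_points} points reaches "
            f"r^2 >= {r2_threshold}"
        )
    return best
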