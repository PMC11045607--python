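"""Specific-rate estimation from batch fermentation time courses.

The specific growth rate mu is the slope of ln(biomass) versus time in an
exponential window.  Metabolite yields are slopes of concentration versus
biomass concentration (dS/dX, mmol/gDCW), and specific rates follow as

    r_i = mu * (dS/dX) = mu / Y_i,x

where Y_i,x = dX/dS is the biomass-per-metabolite yield (gDCW/mmol).
Negative rates denote uptake, positive rates production.  Biphasic batch
cultures (a first nitrogen source consumed and depleted, a second one
consumed afterwards) are split into lag / phase A / phase B windows from
the depletion of a marker metabolite.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats


class FitError(ValueError):
    """Raised when a regression window is unusable (too few/degenerate points)."""


@dataclass
class TimeCourse:
    """Timestamped biomass and metabolite concentrations.

    ``time`` in h (strictly increasing), ``biomass`` in gDCW/L, metabolite
    concentrations in mmol/L.
    """

    time: np.ndarray
    biomass: np.ndarray
    metabolites: Dict[str, np.ndarray] = field(default_factory=dict)
    replicate_id: str = ""

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.biomass = np.asarray(self.biomass, dtype=float)
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        if self.biomass.shape != self.time.shape:
            raise ValueError("biomass and time lengths differ")
        self.metabolites = {
            k: np.asarray(v, dtype=float) for k, v in self.metabolites.items()
        }
        for name, values in self.metabolites.items():
            if values.shape != self.time.shape:
                raise ValueError(f"metabolite {name}: length mismatch")

    def window_mask(self, window: "PhaseWindow") -> np.ndarray:
        return (self.time >= window.t_start - 1e-12) & (
            self.time <= window.t_end + 1e-12
        )

    def to_frame(self) -> pd.DataFrame:
        data = {"time_h": self.time, "biomass_gdcw_l": self.biomass}
        for name, values in self.metabolites.items():
            data[f"{name}_mmol_l"] = values
        return pd.DataFrame(data)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, replicate_id: str = "") -> "TimeCourse":
        mets = {}
        for col in df.columns:
            if col.endswith("_mmol_l"):
                mets[col[: -len("_mmol_l")]] = df[col].to_numpy()
        return cls(
            time=df["time_h"].to_numpy(),
            biomass=df["biomass_gdcw_l"].to_numpy(),
            metabolites=mets,
            replicate_id=replicate_id,
        )


@dataclass(frozen=True)
class PhaseWindow:
    label: str  # "lag", "A" or "B"
    t_start: float
    t_end: float


@dataclass(frozen=True)
class GrowthRateFit:
    mu: float  # 1/h
    se: float
    n_points: int
    window: PhaseWindow


@dataclass(frozen=True)
class YieldFit:
    """Slope of metabolite concentration vs biomass: dS/dX, mmol/gDCW.

    The biomass-per-metabolite yield is Y_i,x = 1/slope (signed); the
    magnitude convention used in fermentation tables is |Y_i,x|.
    """

    metabolite: str
    slope: float
    se: float
    n_points: int
    window: PhaseWindow

    @property
    def yield_xs(self) -> float:
        """Y_i,x = dX/dS in gDCW/mmol (inf for a flat metabolite)."""
        if self.slope == 0.0:
            return math.inf
        return 1.0 / self.slope


@dataclass(frozen=True)
class RateEstimate:
    metabolite: str
    rate: float  # mmol/(gDCW*h); negative = uptake
    se: float
    flag: str = ""


def fit_growth_rate(tc: TimeCourse, window: PhaseWindow) -> GrowthRateFit:
    """OLS of ln(biomass) on time within the window."""
    mask = tc.window_mask(window)
    t = tc.time[mask]
    x = tc.biomass[mask]
    if t.size < 3:
        raise FitError(
            f"window {window.label} [{window.t_start}, {window.t_end}] has "
            f"{t.size} points; need >= 3"
        )
    if np.any(x <= 0):
        raise FitError("biomass must be positive for a log-linear fit")
    res = stats.linregress(t, np.log(x))
    se = float(res.stderr) if np.isfinite(res.stderr) else 0.0
    return GrowthRateFit(mu=float(res.slope), se=se, n_points=int(t.size),
                         window=window)


def fit_yield(tc: TimeCourse, metabolite: str, window: PhaseWindow) -> YieldFit:
    """OLS slope of metabolite concentration on biomass concentration."""
    if metabolite not in tc.metabolites:
        raise FitError(f"metabolite {metabolite!r} not in time course")
    mask = tc.window_mask(window)
    x = tc.biomass[mask]
    s = tc.metabolites[metabolite][mask]
    if x.size < 3:
        raise FitError(f"window has {x.size} points; need >= 3")
    if np.ptp(x) <= 0:
        raise FitError("biomass does not vary within the window")
    res = stats.linregress(x, s)
    se = float(res.stderr) if np.isfinite(res.stderr) else 0.0
    return YieldFit(metabolite=metabolite, slope=float(res.slope), se=se,
                    n_points=int(x.size), window=window)


def specific_rate(
    mu: float,
    yield_xs: float,
    mu_se: float = 0.0,
    yield_se: float = 0.0,
    metabolite: str = "",
) -> RateEstimate:
    """r_i = mu / Y_i,x with first-order error propagation.

    ``yield_xs`` is the signed biomass-per-metabolite yield dX/dS in
    gDCW/mmol.  A zero yield is interpreted as "metabolite not turned
    over" and reported as a zero rate with a flag; an infinite yield
    (flat concentration profile) likewise gives rate zero.
    """
    if yield_xs == 0.0:
        return RateEstimate(metabolite, 0.0, 0.0, flag="non-consumed")
    if math.isinf(yield_xs):
        return RateEstimate(metabolite, 0.0, 0.0, flag="non-consumed")
    rate = mu / yield_xs
    rel = 0.0
    if mu != 0.0:
        rel += (mu_se / mu) ** 2
    rel += (yield_se / yield_xs) ** 2
    return RateEstimate(metabolite, rate, abs(rate) * math.sqrt(rel))


def rate_from_fits(growth: GrowthRateFit, yield_fit: YieldFit) -> RateEstimate:
    """Combine a growth-rate and a yield fit: r = mu * dS/dX."""
    if yield_fit.slope == 0.0:
        return RateEstimate(yield_fit.metabolite, 0.0, 0.0, flag="non-consumed")
    return specific_rate(
        growth.mu, yield_fit.yield_xs,
        mu_se=growth.se,
        # SE of 1/slope by first-order propagation: se/slope^2.
        yield_se=yield_fit.se / yield_fit.slope**2,
        metabolite=yield_fit.metabolite,
    )


def split_phases(
    tc: TimeCourse,
    marker_metabolite: str,
    depletion_threshold: Optional[float] = None,
    noise_sd: Optional[float] = None,
) -> List[PhaseWindow]:
    """Split a biphasic batch culture on depletion of a marker metabolite.

    Lag ends at the first sample where the marker has declined by more
    than twice its measurement SD and keeps declining; phase A ends when
    the marker falls below the depletion threshold (default 2% of its
    initial concentration); phase B covers the remainder.
    """
    if marker_metabolite not in tc.metabolites:
        raise FitError(f"marker {marker_metabolite!r} not in time course")
    s = tc.metabolites[marker_metabolite]
    t = tc.time
    s0 = s[0]
    if depletion_threshold is None:
        depletion_threshold = 0.02 * s0
    sd = (noise_sd * s0) if noise_sd else max(1e-9, 1e-6 * max(abs(s0), 1.0))

    if s0 <= depletion_threshold:  # marker already depleted at start
        return [PhaseWindow("B", t[0], t[-1])]

    depleted = np.nonzero(s < depletion_threshold)[0]
    if depleted.size == 0:
        if np.ptp(s) <= 2 * sd:
            warnings.warn(
                f"marker {marker_metabolite} constant; no phase split",
                stacklevel=2,
            )
            return [PhaseWindow("A", t[0], t[-1])]
        warnings.warn(
            f"marker {marker_metabolite} never depleted; single phase A",
            stacklevel=2,
        )
        a_end_idx = len(s) - 1
        t_b_start = None
    else:
        # The sample at which the marker first reads depleted belongs to
        # phase B; the clamped reading itself would bias phase-A fits.
        a_end_idx = max(int(depleted[0]) - 1, 0)
        t_b_start = t[depleted[0]]

    # Lag: earliest sample where the marker has declined by more than 2 sd
    # below its initial level and the decline persists at the next sample.
    # The level is a median over the first samples so a single noisy
    # initial reading cannot trigger a false onset.
    level = float(np.median(s[: min(3, len(s))]))
    first_decline = None
    for i in range(1, len(s)):
        sustained = i + 1 >= len(s) or level - s[i + 1] > 2 * sd
        if level - s[i] > 2 * sd and sustained:
            first_decline = i
            break
    windows: List[PhaseWindow] = []
    if first_decline is None or first_decline <= 1:
        a_start_idx = 0  # consumption under way from the first interval
    else:
        # The last flat sample closes the lag; phase A starts at the first
        # sample that already shows consumption.
        windows.append(PhaseWindow("lag", t[0], t[first_decline - 1]))
        a_start_idx = first_decline
    if a_start_idx <= a_end_idx:
        windows.append(PhaseWindow("A", t[a_start_idx], t[a_end_idx]))
    if t_b_start is not None and t_b_start < t[-1]:
        windows.append(PhaseWindow("B", t_b_start, t[-1]))
    return windows


def estimate_rates(
    tc: TimeCourse,
    marker_metabolite: str,
    metabolites: Optional[Sequence[str]] = None,
    depletion_threshold: Optional[float] = None,
    noise_sd: Optional[float] = None,
) -> pd.DataFrame:
    """Per-phase growth rates and specific consumption/production rates.

    Returns a long-form table (phase, quantity, metabolite, value, se)
    mirroring the layout of fermentation rate tables: growth rate first,
    then one specific rate per metabolite, uptake negative.
    """
    windows = [
        w for w in split_phases(tc, marker_metabolite, depletion_threshold,
                                noise_sd)
        if w.label != "lag"
    ]
    if metabolites is None:
        metabolites = sorted(tc.metabolites)
    rows = []
    for window in windows:
        try:
            growth = fit_growth_rate(tc, window)
        except FitError:
            continue
        rows.append({
            "phase": window.label, "quantity": "growth_rate", "metabolite": "",
            "value": growth.mu, "se": growth.se, "flag": "",
        })
        for met in metabolites:
            try:
                yf = fit_yield(tc, met, window)
            except FitError:
                continue
            est = rate_from_fits(growth, yf)
            rows.append({
                "phase": window.label, "quantity": "specific_rate",
                "metabolite": met, "value": est.rate, "se": est.se,
                "flag": est.flag,
            })
    return pd.DataFrame(rows, columns=["phase", "quantity", "metabolite",
                                       "value", "se", "flag"])
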