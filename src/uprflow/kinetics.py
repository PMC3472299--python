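"""Batch-culture growth kinetics: specific growth rate, phase shift, yield.

During balanced exponential growth, biomass follows X(t) = x0·e^(μt), so
the maximum specific growth rate μ (h⁻¹) is the OLS slope of ln X vs t.
Alkali dosing for pH control tracks biomass formation, so μ can also be
read from the log of the alkali *addition rate* (the finite-difference
rate of the cumulative titrant trace is proportional to dX/dt ∝ e^(μt),
making its log exactly linear on a uniform sampling grid).  A shift from
exponential to linear growth is located by a grid search over candidate
breakpoints with an exponential fit before and a continuous straight
line after, scored by SSE on the original scale.  The biomass yield on
substrate Y_xs (g dry weight per g glucose, density 1 kg/L) is the
ratio of biomass formed to glucose consumed over a time window.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CultureTimeSeries",
    "GrowthFit",
    "fit_exponential_mu",
    "detect_breakpoint",
    "compute_yield",
]


@dataclass
class CultureTimeSeries:
    """Bioreactor observations; sparse signals carry NaN where unobserved."""

    data: pd.DataFrame  # columns time_h, biomass_gdw_kg, alkali_cum_mol, glucose_g_l

    def __post_init__(self) -> None:
        required = {"time_h"}
        if not required <= set(self.data.columns):
            raise ValueError("culture data needs a time_h column")
        t = self.data["time_h"].to_numpy(dtype=float)
        if np.any(np.diff(t) <= 0):
            raise ValueError("time must be strictly increasing")
        for col in ("biomass_gdw_kg", "glucose_g_l"):
            if col in self.data:
                vals = self.data[col].dropna().to_numpy(dtype=float)
                if vals.size and vals.min() < 0:
                    raise ValueError(f"{col} must be non-negative")
        if "alkali_cum_mol" in self.data:
            alk = self.data["alkali_cum_mol"].dropna().to_numpy(dtype=float)
            if np.any(np.diff(alk) < -1e-12):
                raise ValueError("cumulative alkali must be non-decreasing")

    def observed(self, signal: str) -> tuple[np.ndarray, np.ndarray]:
        col = {"biomass": "biomass_gdw_kg", "alkali": "alkali_cum_mol",
               "glucose": "glucose_g_l"}[signal]
        mask = self.data[col].notna().to_numpy()
        return (
            self.data.loc[mask, "time_h"].to_numpy(dtype=float),
            self.data.loc[mask, col].to_numpy(dtype=float),
        )


@dataclass
class GrowthFit:
    mu: float | None = None
    mu_se: float | None = None
    r_squared: float | None = None
    fit_window: tuple[float, float] | None = None
    t_break: float | None = None
    linear_rate: float | None = None
    yield_xs: float | None = None
    model: str | None = None

    def to_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items()}


def _exp_signal(ts: CultureTimeSeries, signal: str) -> tuple[np.ndarray, np.ndarray]:
    """Times and values whose log is linear in time during exponential growth."""
    if signal == "biomass":
        return ts.observed("biomass")
    if signal == "alkali":
        # cumulative alkali ∝ X - x0; its finite-difference rate ∝ dX/dt
        # ∝ e^(μt), so regress on rates at interval midpoints.  Any
        # constant baseline cancels in the differencing.
        t, a = ts.observed("alkali")
        if len(t) < 2:
            return np.empty(0), np.empty(0)
        rates = np.diff(a) / np.diff(t)
        mid = 0.5 * (t[1:] + t[:-1])
        keep = rates > 0
        return mid[keep], rates[keep]
    raise ValueError(f"signal must be 'biomass' or 'alkali', got {signal!r}")


def fit_exponential_mu(
    ts: CultureTimeSeries,
    signal: str = "biomass",
    window: tuple[float, float] | None = None,
) -> tuple[float, float, float]:
    """OLS slope of ln(signal) vs time: (mu, standard error, R²)."""
    t, y = _exp_signal(ts, signal)
    if window is not None:
        keep = (t >= window[0]) & (t <= window[1])
        t, y = t[keep], y[keep]
    keep = y > 0
    t, y = t[keep], y[keep]
    if len(t) < 3:
        raise ValueError(f"need >= 3 positive observations to fit mu, have {len(t)}")
    res = stats.linregress(t, np.log(y))
    return float(res.slope), float(res.stderr), float(res.rvalue**2)


def _exp_fit_sse(t, y):
    """Exponential fit by log-OLS; returns (params, SSE on original scale)."""
    res = stats.linregress(t, np.log(y))
    pred = np.exp(res.intercept + res.slope * t)
    return res, float(((y - pred) ** 2).sum())


def detect_breakpoint(
    ts: CultureTimeSeries,
    signal: str = "biomass",
    min_points_per_phase: int = 4,
    sse_margin: float = 0.10,
) -> GrowthFit:
    """Locate an exponential-to-linear phase shift by grid search.

    Every interior observation time with at least ``min_points_per_phase``
    points on each side is a candidate breakpoint: the earlier points get
    a log-OLS exponential fit, the later points a straight line anchored
    at the exponential's value at the breakpoint (continuity), and the
    candidate minimizing total SSE on the original scale wins.  The
    two-phase model is reported only when it beats the single-exponential
    SSE by more than ``sse_margin`` (fractional reduction); otherwise the
    culture is called pure-exponential with no breakpoint.
    """
    t, y = _exp_signal(ts, signal)
    keep = y > 0
    t, y = t[keep], y[keep]
    n = len(t)
    if n < 8:
        raise ValueError(f"need >= 8 observations to assess a phase shift, have {n}")
    res_exp, sse_exp = _exp_fit_sse(t, y)
    best = None  # (sse, i, exp fit, slope)
    for i in range(min_points_per_phase - 1, n - min_points_per_phase):
        tb = t[i]
        pre_t, pre_y = t[: i + 1], y[: i + 1]
        post_t, post_y = t[i + 1 :], y[i + 1 :]
        res_pre, sse_pre = _exp_fit_sse(pre_t, pre_y)
        anchor = math.exp(res_pre.intercept + res_pre.slope * tb)
        dt = post_t - tb
        slope = float((dt * (post_y - anchor)).sum() / (dt * dt).sum())
        sse_post = float(((post_y - (anchor + slope * dt)) ** 2).sum())
        total = sse_pre + sse_post
        if best is None or total < best[0]:
            best = (total, i, res_pre, slope)
    two_phase = best is not None and best[0] < (1.0 - sse_margin) * sse_exp
    if not two_phase:
        return GrowthFit(
            mu=float(res_exp.slope),
            mu_se=float(res_exp.stderr),
            r_squared=float(res_exp.rvalue**2),
            fit_window=(float(t[0]), float(t[-1])),
            t_break=None,
            model="pure-exponential",
        )
    sse, i, res_pre, slope = best
    return GrowthFit(
        mu=float(res_pre.slope),
        mu_se=float(res_pre.stderr),
        r_squared=float(res_pre.rvalue**2),
        fit_window=(float(t[0]), float(t[i])),
        t_break=float(t[i]),
        linear_rate=slope,
        model="exponential-then-linear",
    )


def _interp_at(ts: CultureTimeSeries, signal: str, when: float) -> float:
    t, y = ts.observed(signal)
    if not (t.min() <= when <= t.max()):
        raise ValueError(f"{signal} not observed around t={when}")
    return float(np.interp(when, t, y))


def compute_yield(
    ts: CultureTimeSeries, window: tuple[float, float]
) -> float:
    """Biomass yield on glucose over a window: ΔX / (−ΔS), g_DW per g.

    Biomass (g_DW/kg broth) and glucose (g/L) are interpolated to the
    window endpoints; broth density 1 kg/L makes the units commensurate.
    """
    t0, t1 = window
    x0, x1 = _interp_at(ts, "biomass", t0), _interp_at(ts, "biomass", t1)
    s0, s1 = _interp_at(ts, "glucose", t0), _interp_at(ts, "glucose", t1)
    if s1 >= s0:
        raise ValueError("glucose does not decrease over the window")
    return (x1 - x0) / (s0 - s1)
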