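"""Least-squares curve fits for mechanotransduction data.

Four families: single/two-component Boltzmann activation (open probability
vs displacement), logistic dose-response (Hill block), bi-exponential
current decay, and the linear current-voltage regression.  Nonlinear fits
use bounded trust-region least squares with a deterministic multistart; the
I-V line is closed-form ordinary least squares.
"""
from __future__ import annotations

import dataclasses
import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from . import models
from .core_io import Trace, register_result

__all__ = [
    "FitError", "BoltzmannFit", "DoseResponseFit", "BiExpFit", "IVFit",
    "fit_boltzmann", "fit_dose_response", "fit_biexp", "fit_iv",
]


class FitError(RuntimeError):
    """A fit failed to converge or the data cannot constrain the model."""


@register_result
@dataclass
class BoltzmannFit:
    """Boltzmann activation fit.

    x_half (um) and slope_s (1/um) describe the dominant component; z is the
    gating force in newtons derived via z = slope * kT at the configured
    temperature.  ``components`` lists (x_half, slope, weight) per component.
    """

    x_half: float
    slope_s: float
    z: float
    components: list
    rss: float
    n_points: int

    def __post_init__(self):
        self.components = [tuple(c) for c in self.components]

    def predict(self, x):
        return models.boltzmann_mixture(x, self.components)


@register_result
@dataclass
class DoseResponseFit:
    """Logistic (Hill) dose-response fit: I(C) = (Ii-If)/(1+(C/C50)^p) + If."""

    i_initial: float
    i_final: float
    c_half: float
    hill_p: float
    rss: float
    n_points: int

    def predict(self, c):
        return models.dose_response(c, self.i_initial, self.i_final,
                                    self.c_half, self.hill_p)

    def block_fraction(self, c):
        """Fractional reduction of the initial current at concentration c."""
        return (self.i_initial - self.predict(c)) / self.i_initial


@register_result
@dataclass
class BiExpFit:
    """Bi-exponential decay fit with components ordered tau1 < tau2."""

    a1: float
    a2: float
    tau1: float
    tau2: float
    a_ss: float
    rss: float
    n_points: int
    note: str = ""

    def predict(self, t):
        return models.biexp(t, self.a1, self.tau1, self.a2, self.tau2,
                            self.a_ss)


@register_result
@dataclass
class IVFit:
    """Ordinary least-squares line I = g (V - E_rev)."""

    conductance: float
    e_rev: float
    r_squared: float
    note: str = ""

    def predict(self, v):
        return models.iv_line(v, self.conductance, self.e_rev)


def _xy(data) -> tuple:
    if isinstance(data, pd.DataFrame):
        x = data.iloc[:, 0].to_numpy(dtype=float)
        y = data.iloc[:, 1].to_numpy(dtype=float)
    else:
        x, y = data
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("expected two equal-length 1-d columns")
    return x, y


def _multistart_lsq(residual, starts, bounds):
    best = None
    for p0 in starts:
        p0 = np.clip(p0, bounds[0], bounds[1])
        try:
            sol = optimize.least_squares(residual, p0, bounds=bounds,
                                         method="trf", xtol=1e-12, ftol=1e-12,
                                         gtol=1e-12)
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise FitError("all optimizer starts failed")
    return best


def fit_boltzmann(data, n_components: int = 1, temperature: float = 295.0,
                  seed: int = 0) -> BoltzmannFit:
    """Fit p_o(X) = sum_c w_c / (1 + exp(-s_c (X - X_c))) to (X, p_o) data.

    Requires >= 4 points (one component) or >= 7 (two components) with
    p_o <= 1.05.  Deterministic: the multistart grid depends only on the
    data (the seed only jitters tied starts).
    """
    x, y = _xy(data)
    min_pts = 4 if n_components == 1 else 7
    if x.size < min_pts:
        raise FitError(f"need >= {min_pts} points, got {x.size}")
    # nominal validity band [0, 1.05] with slack for measurement noise at
    # the saturated end of normalized open probabilities
    if np.any(y > 1.25) or np.any(y < -0.25):
        raise FitError("open probabilities must lie in [0, 1.05]")
    span = float(x.max() - x.min())
    if span <= 0:
        raise FitError("displacement values are all identical")
    s_grid = [1.0 / span, 4.0 / span, 12.0 / span, 40.0 / span]
    q = np.quantile(x, [0.25, 0.5, 0.75])
    if n_components == 1:
        def residual(p):
            return models.boltzmann(x, p[0], p[1]) - y
        bounds = ([x.min() - span, 1e-3 / span],
                  [x.max() + span, 1e3 / span])
        starts = [np.array([xh, s]) for xh in (q[0], q[1], q[2])
                  for s in (s_grid[1], s_grid[2])]
        sol = _multistart_lsq(residual, starts, bounds)
        x_half, slope = sol.x
        comps = [(float(x_half), float(slope), 1.0)]
    elif n_components == 2:
        def residual(p):
            comps = [(p[0], p[1], p[4]), (p[2], p[3], 1.0 - p[4])]
            return models.boltzmann_mixture(x, comps) - y
        bounds = ([x.min() - span, 1e-3 / span, x.min() - span, 1e-3 / span, 0.0],
                  [x.max() + span, 1e3 / span, x.max() + span, 1e3 / span, 1.0])
        rng = np.random.default_rng(seed)
        starts = []
        for s1 in (s_grid[1], s_grid[2]):
            for s2 in (s_grid[1], s_grid[2]):
                starts.append(np.array([q[0], s1, q[2], s2,
                                        0.5 + 0.01 * rng.standard_normal()]))
        starts.append(np.array([q[1], s_grid[1], q[1], s_grid[3], 0.5]))
        sol = _multistart_lsq(residual, starts, bounds)
        p = sol.x
        comps = sorted([(float(p[0]), float(p[1]), float(p[4])),
                        (float(p[2]), float(p[3]), float(1.0 - p[4]))],
                       key=lambda c: c[0])
        # headline parameters from the heavier component
        x_half, slope, _ = max(comps, key=lambda c: c[2])
    else:
        raise ValueError("n_components must be 1 or 2")
    rss = float(2.0 * sol.cost)
    return BoltzmannFit(x_half=float(x_half), slope_s=float(slope),
                        z=models.gating_force(float(slope), temperature),
                        components=comps, rss=rss, n_points=int(x.size))


def fit_dose_response(data, seed: int = 0) -> DoseResponseFit:
    """Fit the logistic dose-response to a (concentration uM, current pA) table."""
    c, y = _xy(data)
    if c.size < 4:
        raise FitError(f"need >= 4 concentrations, got {c.size}")
    if np.ptp(y) == 0:
        raise FitError("all responses equal; dose-response is unconstrained")
    pos = c[c > 0]
    if pos.size == 0:
        raise FitError("need at least one positive concentration")
    y_hi, y_lo = float(y.max()), float(y.min())
    spread = y_hi - y_lo

    def residual(p):
        return models.dose_response(c, p[0], p[1], p[2], p[3]) - y

    bounds = ([y_lo - 2 * spread, y_lo - 2 * spread, pos.min() / 100.0, 0.2],
              [y_hi + 2 * spread, y_hi + 2 * spread, pos.max() * 100.0, 10.0])
    c_starts = np.geomspace(pos.min(), pos.max(), 4)
    starts = [np.array([y_hi, y_lo, ch, hp])
              for ch in c_starts for hp in (0.7, 1.0, 2.0)]
    sol = _multistart_lsq(residual, starts, bounds)
    i_i, i_f, c_half, hill_p = sol.x
    return DoseResponseFit(i_initial=float(i_i), i_final=float(i_f),
                           c_half=float(c_half), hill_p=float(hill_p),
                           rss=float(2.0 * sol.cost), n_points=int(c.size))


def fit_biexp(data, fit_window: Optional[tuple] = None,
              seed: int = 0) -> BiExpFit:
    """Fit y(t) = A1 e^{-t/tau1} + A2 e^{-t/tau2} + Ass to a decay phase.

    ``data`` is a current Trace (with ``fit_window`` in ms selecting the
    post-peak decay) or a (t, y) pair.  Time is rebased so the window starts
    at t = 0.  If the two time constants collapse (tau2/tau1 < 1.5) the fit
    falls back to a single exponential, flagged in ``note``.
    """
    if isinstance(data, Trace):
        if data.kind != "current":
            raise TypeError("fit_biexp expects a current trace")
        t = data.times()
        y = data.samples
        if fit_window is not None:
            mask = (t >= fit_window[0]) & (t <= fit_window[1])
            t, y = t[mask], y[mask]
    else:
        t, y = _xy(data)
        if fit_window is not None:
            mask = (t >= fit_window[0]) & (t <= fit_window[1])
            t, y = t[mask], y[mask]
    if t.size < 20:
        raise FitError(f"need >= 20 samples in the fit window, got {t.size}")
    t = t - t[0]
    span = float(t[-1] - t[0])
    if np.ptp(y) < 1e-12 * max(1.0, abs(float(np.mean(y)))):
        return BiExpFit(a1=0.0, a2=0.0, tau1=span / 10.0, tau2=span / 5.0,
                        a_ss=float(np.mean(y)), rss=0.0, n_points=int(t.size),
                        note="constant trace")
    a_ss0 = float(y[-1])
    amp0 = float(y[0] - y[-1])

    def residual(p):
        return models.biexp(t, p[0], p[1], p[2], p[3], p[4]) - y

    dt_min = max(span * 1e-4, float(np.min(np.diff(t))) / 4.0)
    bounds = ([-10 * abs(amp0) - 1, dt_min, -10 * abs(amp0) - 1, dt_min,
               float(y.min()) - abs(amp0) - 1],
              [10 * abs(amp0) + 1, 10 * span, 10 * abs(amp0) + 1, 10 * span,
               float(y.max()) + abs(amp0) + 1])
    tau_starts = np.geomspace(max(dt_min * 2, span / 200.0), span, 4)
    starts = [np.array([amp0 / 2, ta, amp0 / 2, min(5 * ta, 9 * span), a_ss0])
              for ta in tau_starts]
    starts.append(np.array([amp0 * 0.7, span / 20.0, amp0 * 0.3, span / 2.0,
                            a_ss0]))
    sol = _multistart_lsq(residual, starts, bounds)
    a1, tau1, a2, tau2, a_ss = sol.x
    if tau2 < tau1:
        a1, a2, tau1, tau2 = a2, a1, tau2, tau1
    note = ""
    if tau2 / tau1 < 1.5:
        warnings.warn("bi-exponential time constants collapsed; refitting a "
                      "single exponential", RuntimeWarning, stacklevel=2)

        def residual1(p):
            return p[0] * np.exp(-t / p[1]) + p[2] - y

        b1 = ([bounds[0][0], dt_min, bounds[0][4]],
              [bounds[1][0], 10 * span, bounds[1][4]])
        starts1 = [np.array([amp0, ta, a_ss0]) for ta in tau_starts]
        sol = _multistart_lsq(residual1, starts1, b1)
        a1, tau1, a_ss = sol.x
        a2, tau2 = 0.0, float("inf")
        note = "single exponential (tau collapse)"
    return BiExpFit(a1=float(a1), a2=float(a2), tau1=float(tau1),
                    tau2=float(tau2), a_ss=float(a_ss),
                    rss=float(2.0 * sol.cost), n_points=int(t.size), note=note)


def fit_iv(data) -> IVFit:
    """Ordinary least-squares I-V line; slope in nS, reversal in mV."""
    v, i = _xy(data)
    if np.unique(v).size < 3:
        raise FitError("need >= 3 distinct voltages")
    res = stats.linregress(v, i)
    slope = float(res.slope)
    if abs(slope) < 1e-12:
        return IVFit(conductance=slope, e_rev=float("nan"),
                     r_squared=float(res.rvalue ** 2),
                     note="zero slope; reversal potential undefined")
    return IVFit(conductance=slope, e_rev=float(-res.intercept / slope),
                 r_squared=float(res.rvalue ** 2))
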