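"""Closed-form response models shared by the fitting and simulation code.

All displacement arguments are in micrometres, currents in pA, voltages in
mV, times in ms and concentrations in micromolar unless stated otherwise.
"""
from __future__ import annotations

import numpy as np

BOLTZMANN_K = 1.380649e-23  # J/K
MICRON = 1e-6  # m


def boltzmann(x, x_half: float, slope: float):
    """Single-Boltzmann open probability, increasing with displacement.

    p_o(X) = 1 / (1 + exp(-slope * (X - x_half)))

    ``slope`` (1/um) relates to the channel gating force z via
    slope = z / (kT); see :func:`gating_force`.
    """
    x = np.asarray(x, dtype=float)
    return 1.0 / (1.0 + np.exp(-slope * (x - x_half)))


def boltzmann_mixture(x, components):
    """Weighted sum of single-Boltzmann terms.

    ``components`` is an iterable of (x_half, slope, weight); weights should
    be non-negative and sum to one for the result to be a probability.
    """
    x = np.asarray(x, dtype=float)
    out = np.zeros_like(x, dtype=float)
    for x_half, slope, weight in components:
        out = out + weight * boltzmann(x, x_half, slope)
    return out


def gating_force(slope: float, temperature: float = 295.0) -> float:
    """Gating force z (newtons) from a Boltzmann slope in 1/um at T kelvin."""
    return slope / MICRON * BOLTZMANN_K * temperature


def dose_response(c, i_initial: float, i_final: float, c_half: float,
                  hill_p: float = 1.0):
    """Logistic dose-response: I(C) = (Ii - If) / (1 + (C/C50)^p) + If."""
    c = np.asarray(c, dtype=float)
    return (i_initial - i_final) / (1.0 + (c / c_half) ** hill_p) + i_final


def hill_block_fraction(c, ic50: float, hill_p: float = 1.0):
    """Fraction of current blocked at concentration ``c``: r/(1+r), r=(C/IC50)^p."""
    c = np.asarray(c, dtype=float)
    r = (c / ic50) ** hill_p
    return r / (1.0 + r)


def biexp(t, a1: float, tau1: float, a2: float, tau2: float, a_ss: float):
    """Bi-exponential decay y(t) = A1 e^{-t/tau1} + A2 e^{-t/tau2} + Ass."""
    t = np.asarray(t, dtype=float)
    return a1 * np.exp(-t / tau1) + a2 * np.exp(-t / tau2) + a_ss


def iv_line(v, conductance: float, e_rev: float):
    """Ohmic current-voltage line I = g (V - E_rev); nS * mV gives pA."""
    v = np.asarray(v, dtype=float)
    return conductance * (v - e_rev)
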