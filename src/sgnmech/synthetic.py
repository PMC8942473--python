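"""Synthetic data generators and a phenomenological neuron simulator.

Everything the analysis consumes can be generated here with the statistical
structure the analysis assumes: phase-locked spike trains with von Mises
phase concentration (optionally a two-component mixture emulating
peak-splitting), noisy curve families for each fit, and a leaky
integrate-and-fire neuron carrying a mechanically activated (MA)
conductance, for combined sinusoidal current + displacement stimulation.

The MA current is

    I_MA(t) = (1 - block) * g_MA * d(t) * (E_MA - V)

where d(t) is a leak-subtracted Boltzmann drive p_o(X) - p_o(0) passed
through a two-state adaptation stage: each state u_i relaxes toward the
drive with time constant tau_i, and

    d(t) = A_ss q + A1 (q - u1) + A2 (q - u2),     q = p_o(X) - p_o(0)

so a displacement step decays bi-exponentially from q to A_ss*q, exactly
the decay form the fitting module assumes.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import models
from .core_io import (SinusoidStimulus, SpikeTrain, StepRampStimulus, Trace)

__all__ = ["PhaseLockGenSpec", "NeuronParams", "gen_phase_locked_train",
           "gen_curve_data", "simulate_neuron", "CURVE_FAMILIES"]

TWO_PI = 2.0 * math.pi

#: spike excursion painted into simulated voltage traces (detection target)
SPIKE_PEAK_MV = 20.0
SPIKE_WIDTH_MS = 1.0


@dataclass
class PhaseLockGenSpec:
    """Parameters for a phase-locked Bernoulli-per-cycle spike generator.

    components : sequence of (mean_phase rad, concentration kappa, weight);
        kappa = inf produces a delta at the mean phase, kappa = 0 uniform
        phases.  Weights must be non-negative and sum to 1.
    rate : target spikes/s; per cycle a spike is emitted with probability
        rate/frequency (capped at 1), so rates cannot exceed the stimulus
        frequency, matching physiological entrainment limits.
    """

    rate: float
    frequency: float
    duration: float
    components: Sequence[tuple] = ((0.0, 4.0, 1.0),)
    seed: int = 0

    def __post_init__(self):
        if self.rate < 0 or self.frequency <= 0 or self.duration <= 0:
            raise ValueError("rate >= 0 and frequency, duration > 0 required")
        w = np.array([c[2] for c in self.components], dtype=float)
        k = np.array([c[1] for c in self.components], dtype=float)
        if np.any(w < 0) or not math.isclose(w.sum(), 1.0, rel_tol=1e-9):
            raise ValueError("component weights must be >= 0 and sum to 1")
        if np.any(k < 0):
            raise ValueError("concentrations must be >= 0")


def gen_phase_locked_train(spec: PhaseLockGenSpec) -> SpikeTrain:
    """Draw a phase-locked spike train from a (mixture of) von Mises law(s).

    One Bernoulli trial per stimulus cycle with success probability
    rate/frequency; successful cycles place a single spike at a phase drawn
    from the mixture.  Bit-for-bit reproducible for a fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    n_cycles = int(math.floor(spec.duration * spec.frequency / 1000.0))
    p_spike = min(spec.rate / spec.frequency, 1.0)
    fire = rng.random(n_cycles) < p_spike
    cycles = np.flatnonzero(fire)
    weights = np.array([c[2] for c in spec.components], dtype=float)
    comp_idx = rng.choice(len(spec.components), size=cycles.size, p=weights)
    phases = np.empty(cycles.size)
    for j, (mu, kappa, _) in enumerate(spec.components):
        sel = comp_idx == j
        if not sel.any():
            continue
        if math.isinf(kappa):
            phases[sel] = mu
        elif kappa == 0:
            phases[sel] = rng.uniform(0.0, TWO_PI, size=int(sel.sum()))
        else:
            phases[sel] = rng.vonmises(mu, kappa, size=int(sel.sum()))
    phases = phases % TWO_PI
    times = (cycles + phases / TWO_PI) / spec.frequency * 1000.0
    stim = SinusoidStimulus(modality="displacement",
                            frequency=spec.frequency, amplitude=1.0,
                            onset=0.0, duration=spec.duration)
    return SpikeTrain(times=times, record_duration=spec.duration,
                      stimulus=stim)


CURVE_FAMILIES = {
    "boltzmann1": lambda x, p: models.boltzmann(x, **p),
    "boltzmann2": lambda x, p: models.boltzmann_mixture(x, **p),
    "dose": lambda x, p: models.dose_response(x, **p),
    "biexp": lambda x, p: models.biexp(x, **p),
    "iv": lambda x, p: models.iv_line(x, **p),
}

#: default x-grids follow the recording protocols: displacement clamp
#: 0-1.2 um in ~0.24 um steps; holding voltages -90..90 mV in 30 mV steps.
DEFAULT_GRIDS = {
    "boltzmann1": np.round(np.arange(0.0, 1.21, 0.24), 3),
    "boltzmann2": np.round(np.arange(0.0, 1.21, 0.12), 3),
    "dose": np.geomspace(0.05, 20.0, 9),
    "biexp": np.arange(0.0, 100.0, 0.05),
    "iv": np.arange(-90.0, 91.0, 30.0),
}


def gen_curve_data(family: str, true_params: dict, x=None,
                   noise_sd: float = 0.0, seed: int = 0) -> pd.DataFrame:
    """Evaluate a model family on a grid and add Gaussian noise.

    Returns a two-column DataFrame (x, y); deterministic for a fixed seed.
    """
    if family not in CURVE_FAMILIES:
        raise ValueError(f"unknown curve family {family!r}; "
                         f"choose from {sorted(CURVE_FAMILIES)}")
    x = np.asarray(DEFAULT_GRIDS[family] if x is None else x, dtype=float)
    y = np.asarray(CURVE_FAMILIES[family](x, true_params), dtype=float)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, noise_sd, size=y.shape)
    return pd.DataFrame({"x": x, "y": y})


@dataclass
class NeuronParams:
    """Integrate-and-fire neuron with a mechanically activated conductance.

    The MA pathway uses measured biophysics: reversal near 0 mV
    (e_ma = -1.4), whole-cell conductance 3.2 nS, Boltzmann midpoint
    x_half = 0.42 um, and bi-exponential adaptation with tau1 = 3.6,
    tau2 = 24 ms.  Membrane parameters (c_m, g_l, thresholds) are not
    measured quantities; they are calibration choices fixed so that the
    reference combined-stimulation conditions (50 Hz, 0.05 nA current,
    0.1 um displacement) are each subthreshold alone and suprathreshold
    in-phase together.
    """

    c_m: float = 8.0          # pF
    g_l: float = 4.0          # nS
    e_l: float = -60.0        # mV
    v_th: float = -48.6       # mV
    v_reset: float = -58.0    # mV
    refractory: float = 1.0   # ms
    g_ma: float = 3.2         # nS
    e_ma: float = -1.4        # mV
    x_half: float = 0.42      # um
    slope: float = 6.0        # 1/um
    a1: float = 0.5
    a2: float = 0.3
    a_ss: float = 0.2
    tau1: float = 3.6         # ms
    tau2: float = 24.0        # ms
    noise_sd: float = 0.0     # pA
    block_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not self.tau1 < self.tau2:
            raise ValueError("tau1 < tau2 required")
        if self.g_ma < 0:
            raise ValueError("g_ma must be >= 0")
        if not 0.0 <= self.block_fraction <= 1.0:
            raise ValueError("block_fraction must lie in [0, 1]")
        if not math.isclose(self.a1 + self.a2 + self.a_ss, 1.0, rel_tol=1e-9):
            raise ValueError("adaptation fractions a1 + a2 + a_ss must sum to 1")
        if self.c_m <= 0 or self.g_l < 0 or self.refractory < 0:
            raise ValueError("c_m > 0, g_l >= 0, refractory >= 0 required")


def simulate_neuron(params: NeuronParams,
                    current_stim=None, mech_stim=None,
                    duration: float = 1000.0, dt: float = 0.02
                    ) -> tuple[Trace, SpikeTrain]:
    """Integrate the neuron under current and/or displacement stimulation.

    Fixed-step explicit Euler integration; ``dt`` must satisfy
    dt <= 0.1 * tau1 for the adaptation states to be resolved.  Spikes are
    threshold crossings with reset and refractory period; the returned
    voltage trace carries a stereotyped triangular excursion to +20 mV at
    each spike so the detection stage can be exercised end-to-end.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if dt > 0.1 * params.tau1:
        raise ValueError(f"dt={dt} too coarse; require dt <= 0.1*tau1 "
                         f"= {0.1 * params.tau1:.4g} ms")
    n = int(round(duration / dt))
    t_grid = dt * np.arange(n)
    i_inj = (current_stim.value(t_grid) if current_stim is not None
             else np.zeros(n))
    x_disp = (mech_stim.value(t_grid) if mech_stim is not None
              else np.zeros(n))
    if params.noise_sd > 0:
        rng = np.random.default_rng(params.seed)
        noise = rng.normal(0.0, params.noise_sd, size=n)
    else:
        noise = np.zeros(n)

    slope, x_half = params.slope, params.x_half
    po_rest = 1.0 / (1.0 + math.exp(slope * x_half))
    g_eff = (1.0 - params.block_fraction) * params.g_ma
    a1, a2, a_ss = params.a1, params.a2, params.a_ss
    inv_tau1, inv_tau2 = dt / params.tau1, dt / params.tau2
    g_l, e_l, e_ma, c_inv = params.g_l, params.e_l, params.e_ma, dt / params.c_m
    v_th, v_reset, refractory = params.v_th, params.v_reset, params.refractory
    exp = math.exp

    i_list = i_inj.tolist()
    x_list = x_disp.tolist()
    n_list = noise.tolist()

    v = e_l
    u1 = 0.0
    u2 = 0.0
    refract_until = -1.0
    voltage = np.empty(n)
    spike_idx = []
    for i in range(n):
        t = i * dt
        q = 1.0 / (1.0 + exp(-slope * (x_list[i] - x_half))) - po_rest
        drive = a_ss * q + a1 * (q - u1) + a2 * (q - u2)
        i_ma = g_eff * drive * (e_ma - v)
        dv = (-g_l * (v - e_l) + i_list[i] + i_ma + n_list[i]) * c_inv
        v = v + dv
        u1 += (q - u1) * inv_tau1
        u2 += (q - u2) * inv_tau2
        if v != v or v > 1e6 or v < -1e6:
            raise RuntimeError(f"integration diverged at t = {t:.3f} ms "
                               f"(step {i}); reduce dt or stimulus amplitude")
        if t >= refract_until and v >= v_th:
            spike_idx.append(i)
            v = v_reset
            refract_until = t + refractory
        voltage[i] = v

    half = max(1, int(round(0.5 * SPIKE_WIDTH_MS / dt)))
    for si in spike_idx:
        for j in range(-half, half + 1):
            k = si + j
            if 0 <= k < n:
                frac = abs(j) / half
                voltage[k] = SPIKE_PEAK_MV * (1 - frac) + v_th * frac
    times = dt * np.array(spike_idx, dtype=float)
    trace = Trace(dt=dt, samples=voltage, kind="voltage", units="mV", t0=0.0)
    stim = current_stim if current_stim is not None else mech_stim
    train = SpikeTrain(times=times, record_duration=n * dt,
                       stimulus=stim if isinstance(stim, SinusoidStimulus)
                       else None)
    return trace, train
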