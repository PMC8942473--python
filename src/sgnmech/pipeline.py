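"""High-level experiment drivers over the simulator and analysis stages.

These functions reproduce, on synthetic neurons, the study's combined
current + displacement stimulation protocols: the subthreshold-summation
check, rate-versus-amplitude curves under a priming stimulus (with the
half-activation shift and its slope), and the eight-angle relative-phase
sweep summarized as a polar resultant.

Reference stimulus conditions follow the recordings: 50 Hz sinusoids,
0.05 nA current and 0.1 um displacement for the subthreshold-summation
check; the sweep uses a just-suprathreshold current with a near-threshold
displacement so that phase-dependent facilitation, reduction and
suppression all occur across angles.
"""
from __future__ import annotations

import dataclasses
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core_io import SinusoidStimulus, SpikeTrain
from .fits import fit_boltzmann, fit_iv
from .phaselock import (PolarSummary, count_peaks, cycle_histogram,
                        polar_summary, spike_phases, vector_strength)
from .spikes import detect_spikes, firing_rate
from .synthetic import NeuronParams, simulate_neuron

__all__ = ["combination_check", "angle_sweep", "rate_amplitude_curve",
           "half_activation_shift", "rate_vs_alignment", "SWEEP_DEFAULTS"]

#: eight-angle sweep stimulus conditions (calibrated against the default
#: neuron; see NeuronParams)
SWEEP_DEFAULTS = dict(frequency=50.0, current_amp=60.0, mech_amp=0.45,
                      noise_sd=40.0, onset=200.0, stim_duration=1000.0,
                      record_duration=1400.0, dt=0.05, n_reps=3)


def _stims(frequency, current_amp, mech_amp, angle, onset, stim_duration,
           phase_offset_current=0.0):
    cur = (SinusoidStimulus("current", frequency, current_amp,
                            phase_offset=phase_offset_current, onset=onset,
                            duration=stim_duration)
           if current_amp > 0 else None)
    # polar angle = phase lead of current relative to displacement
    mech = (SinusoidStimulus("displacement", frequency, mech_amp,
                             phase_offset=-angle, onset=onset,
                             duration=stim_duration)
            if mech_amp > 0 else None)
    return cur, mech


def combination_check(params: Optional[NeuronParams] = None,
                      frequency: float = 50.0, current_amp: float = 50.0,
                      mech_amp: float = 0.1, onset: float = 200.0,
                      stim_duration: float = 1000.0,
                      record_duration: float = 1400.0,
                      dt: float = 0.05) -> dict:
    """Spike counts for current-only, displacement-only and in-phase combined.

    With the calibrated default neuron and the reference conditions (50 Hz,
    0.05 nA, 0.1 um) each stimulus alone is subthreshold while the in-phase
    combination fires on every cycle.  Spikes are counted through the full
    detection stage on the simulated voltage trace.
    """
    params = params or NeuronParams()
    out = {}
    for label, (ia, xa) in [("current_only", (current_amp, 0.0)),
                            ("mech_only", (0.0, mech_amp)),
                            ("combined", (current_amp, mech_amp))]:
        cur, mech = _stims(frequency, ia, xa, 0.0, onset, stim_duration)
        trace, _ = simulate_neuron(params, cur, mech,
                                   duration=record_duration, dt=dt)
        out[label] = detect_spikes(trace).n
    return out


def angle_sweep(params: Optional[NeuronParams] = None, seed: int = 0,
                n_perm: int = 2000, min_spikes_for_vs: int = 5,
                **conditions) -> tuple:
    """Run the eight-angle relative-phase sweep and summarize it.

    Returns (DataFrame, PolarSummary).  The DataFrame has one row per angle
    with the repetition-averaged rate in the stimulus-overlap window, the
    pooled-phase VS (NaN when below the spike minimum), and the cycle
    histogram mode count.  Spike trains come from the detection stage run
    on the simulated voltage.
    """
    cond = {**SWEEP_DEFAULTS, **conditions}
    params = params or NeuronParams(noise_sd=cond["noise_sd"])
    angles = np.deg2rad(np.arange(0.0, 360.0, 45.0))
    window = (cond["onset"], cond["onset"] + cond["stim_duration"])
    rows = []
    polar_conditions = []
    for k, ang in enumerate(angles):
        trains = []
        pooled = []
        for rep in range(cond["n_reps"]):
            p = dataclasses.replace(params, seed=seed + 1000 * k + rep)
            cur, mech = _stims(cond["frequency"], cond["current_amp"],
                               cond["mech_amp"], ang, cond["onset"],
                               cond["stim_duration"])
            trace, _ = simulate_neuron(p, cur, mech,
                                       duration=cond["record_duration"],
                                       dt=cond["dt"])
            train = detect_spikes(trace)
            train = SpikeTrain(times=train.times,
                               record_duration=train.record_duration,
                               stimulus=cur)
            trains.append(train)
            pooled.append(spike_phases(train, stim=cur, window=window))
        polar_conditions.append((float(ang), trains))
        phases = np.concatenate(pooled)
        rate = float(np.mean([firing_rate(tr, window) for tr in trains]))
        if phases.size >= min_spikes_for_vs:
            vs = vector_strength(phases, min_spikes_for_vs).vs
            n_peaks = count_peaks(cycle_histogram(phases)).n_peaks
        else:
            vs, n_peaks = float("nan"), 0
        rows.append(dict(angle_deg=float(np.rad2deg(ang)), rate=rate,
                         vs=vs, n_spikes=int(phases.size),
                         n_peaks=int(n_peaks)))
    table = pd.DataFrame(rows)
    summary = polar_summary(polar_conditions, min_spikes_for_vs=min_spikes_for_vs,
                            n_perm=n_perm, seed=seed, window=window)
    return table, summary


def rate_vs_alignment(table: pd.DataFrame) -> float:
    """Circular distance (deg) between the rate-minimizing and
    VS-minimizing angles of an angle-sweep table.

    Angles without a measurable VS (too few spikes) count as VS = 0: where
    nothing fires, nothing phase-locks.
    """
    vs = table["vs"].to_numpy(dtype=float).copy()
    vs[~np.isfinite(vs)] = 0.0
    a_rate = table["angle_deg"].iloc[int(np.argmin(table["rate"].to_numpy()))]
    a_vs = table["angle_deg"].iloc[int(np.argmin(vs))]
    d = abs(a_rate - a_vs) % 360.0
    return float(min(d, 360.0 - d))


def rate_amplitude_curve(params: Optional[NeuronParams] = None,
                         sweep: str = "displacement",
                         amplitudes: Sequence[float] = (),
                         priming_amp: float = 0.0, frequency: float = 50.0,
                         onset: float = 200.0, stim_duration: float = 1000.0,
                         record_duration: float = 1400.0, dt: float = 0.05,
                         seed: int = 0) -> pd.DataFrame:
    """Firing rate vs stimulus amplitude under an in-phase priming stimulus.

    ``sweep`` selects which modality is swept; the other modality is held
    at ``priming_amp`` (pA for current, um for displacement).  Returns a
    DataFrame with columns (amplitude, rate).
    """
    params = params or NeuronParams()
    window = (onset, onset + stim_duration)
    rows = []
    for j, amp in enumerate(amplitudes):
        if sweep == "displacement":
            ia, xa = priming_amp, amp
        elif sweep == "current":
            ia, xa = amp, priming_amp
        else:
            raise ValueError("sweep must be 'displacement' or 'current'")
        p = dataclasses.replace(params, seed=seed + j)
        cur, mech = _stims(frequency, ia, xa, 0.0, onset, stim_duration)
        trace, _ = simulate_neuron(p, cur, mech, duration=record_duration,
                                   dt=dt)
        rows.append(dict(amplitude=float(amp),
                         rate=firing_rate(detect_spikes(trace), window)))
    return pd.DataFrame(rows)


def half_activation_shift(params: Optional[NeuronParams] = None,
                          sweep: str = "displacement",
                          amplitudes: Sequence[float] = (),
                          priming_values: Sequence[float] = (),
                          seed: int = 0, **kwargs) -> tuple:
    """Half-maximum stimulus amplitude as a function of the priming stimulus.

    For each priming level the swept rate curve is normalized to its
    maximum and fitted with a single-Boltzmann sigmoid to extract the
    half-maximum amplitude (X_0.5 when sweeping displacement under current
    priming; I_0.5 when sweeping current under displacement priming).  An
    ordinary least-squares line through (priming, half-max) gives the
    sensitivity slope: um/nA or nA/um after unit conversion by the caller.

    Returns (DataFrame with priming/half_max, slope per priming unit).
    """
    rows = []
    for j, prim in enumerate(priming_values):
        curve = rate_amplitude_curve(params, sweep=sweep,
                                     amplitudes=amplitudes,
                                     priming_amp=prim, seed=seed + 100 * j,
                                     **kwargs)
        rmax = curve["rate"].max()
        if rmax <= 0:
            rows.append(dict(priming=float(prim), half_max=float("nan")))
            continue
        norm = curve["rate"] / rmax
        fit = fit_boltzmann((curve["amplitude"].to_numpy(),
                             norm.to_numpy()))
        rows.append(dict(priming=float(prim), half_max=fit.x_half))
    table = pd.DataFrame(rows)
    ok = table.dropna()
    if len(ok) >= 3 and ok["priming"].nunique() >= 3:
        line = fit_iv((ok["priming"].to_numpy(), ok["half_max"].to_numpy()))
        slope = line.conductance  # generic OLS slope
    else:
        slope = float("nan")
    return table, float(slope)
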