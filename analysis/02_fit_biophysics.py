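#!/usr/bin/env python
"""Fit the biophysical curve families to the generated source data.

Recovers, from the synthetic series written by 01_generate_source_data.py:
the Boltzmann activation midpoint and gating force, the MA-current
conductance and reversal potential, the blocker IC50 with its Hill
coefficient (and the percent block at 1 uM), and the bi-exponential decay
time constants.  Result records go to results/fits/.
"""
import json
from pathlib import Path

import pandas as pd

from sgnmech.core_io import read_trace, write_results
from sgnmech.fits import fit_biexp, fit_boltzmann, fit_dose_response, fit_iv

BASE = Path(__file__).resolve().parent.parent / "results"
SRC = BASE / "source_data"
OUT = BASE / "fits"


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    summary = {}

    boltz = fit_boltzmann(pd.read_csv(SRC / "boltzmann1.csv"))
    write_results(boltz, OUT / "boltzmann.txt")
    summary["activation"] = dict(x_half_um=round(boltz.x_half, 3),
                                 slope_per_um=round(boltz.slope_s, 2),
                                 gating_force_fN=round(boltz.z * 1e15, 2))
    print(f"activation: X_0.5 = {boltz.x_half:.3f} um, "
          f"z = {boltz.z*1e15:.1f} fN")

    iv = fit_iv(pd.read_csv(SRC / "iv.csv"))
    write_results(iv, OUT / "iv.txt")
    summary["iv"] = dict(conductance_nS=round(iv.conductance, 3),
                         e_rev_mV=round(iv.e_rev, 2),
                         r_squared=round(iv.r_squared, 4))
    print(f"I-V: g = {iv.conductance:.2f} nS, E_MA = {iv.e_rev:.2f} mV")

    dose = fit_dose_response(pd.read_csv(SRC / "dose.csv"))
    write_results(dose, OUT / "dose.txt")
    block_1um = 100.0 * float(dose.block_fraction(1.0))
    summary["dose_response"] = dict(ic50_uM=round(dose.c_half, 3),
                                    hill=round(dose.hill_p, 3),
                                    percent_block_at_1uM=round(block_1um, 1))
    print(f"dose-response: IC50 = {dose.c_half:.2f} uM, "
          f"block at 1 uM = {block_1um:.1f}%")

    trace = read_trace(SRC / "ma_decay_trace.txt")
    decay = fit_biexp((trace.times(), -trace.samples))
    write_results(decay, OUT / "biexp.txt")
    summary["decay"] = dict(tau1_ms=round(decay.tau1, 2),
                            tau2_ms=round(decay.tau2, 2))
    print(f"decay: tau1 = {decay.tau1:.2f} ms, tau2 = {decay.tau2:.2f} ms")

    (OUT / "summary.json").write_text(json.dumps(summary, indent=2) + "\n")


if __name__ == "__main__":
    main()
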