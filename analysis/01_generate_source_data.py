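#!/usr/bin/env python
"""Generate the synthetic source-data tables for the downstream analyses.

Emulates the per-figure source data of the mechanosensitivity study:
a displacement-activation series (channel open probability vs displacement
on the 0-1.2 um displacement-clamp grid), a linear I-V series for the
mechanically activated (MA) current (-90..90 mV in 30 mV steps), a
GsMTx4 dose-response series, and an MA current decay trace.

Writes CSVs under results/source_data/ plus a generation manifest.
"""
import json
from pathlib import Path

import numpy as np

from sgnmech.cli import derive_seed
from sgnmech.core_io import Trace, write_trace
from sgnmech.synthetic import gen_curve_data
from sgnmech import models

SEED = 20260922
OUT = Path(__file__).resolve().parent.parent / "results" / "source_data"

# reference parameters: activation midpoint 0.42 um (apical neurons),
# MA conductance 3.2 nS reversing at -1.4 mV, IC50 0.9 uM, decay
# time constants 3.6 / 24 ms
TRUE = {
    "boltzmann1": dict(x_half=0.42, slope=8.0),
    "iv": dict(conductance=3.2, e_rev=-1.4),
    "dose": dict(i_initial=420.0, i_final=0.0, c_half=0.9, hill_p=1.0),
    "biexp": dict(a1=250.0, tau1=3.6, a2=120.0, tau2=24.0, a_ss=60.0),
}
NOISE = {"boltzmann1": 0.02, "iv": 8.0, "dose": 5.0, "biexp": 10.0}


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    written = []
    for family, params in TRUE.items():
        table = gen_curve_data(family, params, noise_sd=NOISE[family],
                               seed=derive_seed(SEED, f"source-{family}"))
        path = OUT / f"{family}.csv"
        table.to_csv(path, index=False)
        written.append(path.name)
        print(f"{family}: {len(table)} points -> {path}")
    # the decay series doubles as a current trace for the trace-based fit
    biexp = TRUE["biexp"]
    t = np.arange(0.0, 100.0, 0.05)
    rng = np.random.default_rng(derive_seed(SEED, "source-decay-trace"))
    y = models.biexp(t, **biexp) + rng.normal(0, NOISE["biexp"], t.size)
    trace = Trace(dt=0.05, samples=-y, kind="current", units="pA")
    write_trace(trace, OUT / "ma_decay_trace.txt")
    written.append("ma_decay_trace.txt")
    print(f"decay trace: {trace.n} samples -> {OUT/'ma_decay_trace.txt'}")
    (OUT / "manifest.json").write_text(json.dumps(
        dict(seed=SEED, true_parameters=TRUE, noise_sd=NOISE,
             files=written), indent=2) + "\n")


if __name__ == "__main__":
    main()
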