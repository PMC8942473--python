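# Methods

## Scope and units

The package analyzes electrophysiological recordings from spiral ganglion
neurons (SGNs) under mechanical and electrical stimulation, and generates
synthetic data with the same statistical structure. Canonical internal
units are ms, mV, pA, nS, µm, µM and radians (phases on [0, 2π)); the CLI
accepts injected current in nA and reports phases in degrees, matching
laboratory convention. Trace files are plain delimited text with
`# key=value` headers; proprietary acquisition formats are out of scope.

## Phase-locking statistics

Spike phase is defined as `φ = 2πf·(t − onset) mod 2π` relative to the
reference sinusoid; in the two-modality protocols the injected current is
the phase reference and the polar angle is the phase lead of the current
relative to the displacement. Vector strength is the mean resultant length
`VS = |Σ e^{iφ}|/n`. The period-histogram definition (fundamental Fourier
component of the cycle histogram divided by the spike count) is implemented
separately and used as a cross-check; the two agree to < 10⁻³ at 360 bins.

Significance uses the Rayleigh statistic `Z = n·VS²` with the standard
finite-n correction series

    p = e^{−Z} [1 + (2Z − Z²)/(4n) − (24Z − 132Z² + 76Z³ − 9Z⁴)/(288n²)],

clipped to (0, 1]. The naive `e^{−Z}` is anticonservative at small n; the
corrected form calibrates to a 5% type-I error within ±1 percentage point
at n = 50 under uniform phases (checked by simulation).

Defaults: 36 histogram bins (10°; no bin width is standard in the source
protocols), minimum 5 spikes for a valid VS (low-count entries are
reported as NA in the literature without a stated cutoff).

### Peak-splitting detector

Cycle histograms are smoothed with a wrapped Gaussian (σ = 15°); circular
local maxima at least 25% of the global maximum and separated by ≥ 60° are
counted as modes. Peak-splitting is described visually in the
electrophysiology literature without an algorithm, so these defaults are
design choices; they classify single von Mises components (κ = 4, n = 500)
as unimodal and antipodal two-component mixtures as bimodal in ≥ 95% of
seeded runs. Histograms whose smoothed max/mean ratio falls below 1.8
carry no phase structure and are flagged unreliable rather than assigned a
mode count of meaning.

### Polar summary

Per-angle rates are averaged over stimulus repetitions and normalized to
their maximum; per-angle VS pools spike phases across repetitions (pooling
stays well-defined at low counts, unlike averaging per-repetition VS).
The resultant of magnitudes `m_k` at the eight angles is
`R = Σ m_k e^{iθ_k}` with normalized magnitude `|R|/Σ m_k`. Invalid VS
entries contribute zero magnitude: where nothing fires, nothing
phase-locks, and this convention is also used when comparing the locations
of the rate and VS minima. Significance of a resultant is assessed by a
seeded permutation of the magnitudes across angles (default 10⁴ shuffles),
since no closed-form test exists for the weighted resultant.

## Curve fits

All nonlinear fits use bounded trust-region least squares
(`scipy.optimize.least_squares`, tolerances 10⁻¹²) with a deterministic
multistart grid derived from the data (quantile midpoints × log-spaced
slopes or time constants); the best cost wins, so results are reproducible
given the data. The I–V line is closed-form ordinary least squares.

- **Boltzmann activation.** Implemented with the exponent sign that makes
  open probability increase with displacement; the gating force is
  `z = s·kT` at the configured temperature (default 295 K, room
  temperature). The two-state variant is the conventional weighted sum of
  two single-Boltzmann terms — a two-state expression printed elsewhere in
  the literature is not a well-formed probability, so the weighted-sum
  form is used and the headline midpoint is taken from the
  heavier-weighted component. The nominal open-probability validity band
  is [0, 1.05], widened to 1.25 at the top to admit measurement noise on
  normalized saturated points.
- **Dose-response.** The logistic form `(I_i − I_f)/(1 + (C/C_½)^p) + I_f`
  with the Hill exponent applied to the concentration ratio (the standard
  form consistent with IC₅₀ semantics). Where a Hill coefficient is
  needed and unknown, 1 is assumed.
- **Bi-exponential decay.** Components are ordered τ₁ < τ₂. If the two
  time constants collapse (τ₂/τ₁ < 1.5) the fit warns and falls back to a
  single exponential, flagged in the result record.
- **I–V.** `I = g(V − E_rev)`; a zero slope leaves the reversal potential
  undefined and is flagged rather than divided through.

Open probabilities from displacement-step series are defined as
`p_o = I_MA(X)/I_MA,max` over the step series (the field reports P_o
without defining the normalization).

## Synthetic data

The generators' default conditions follow the recording protocols:
displacement-clamp grid 0–1.2 µm in ~0.24 µm steps, holding voltages
−90 to +90 mV in 30 mV steps, mechanical steps in ~0.14 µm increments,
relative phase stepped 45° from 0° to 315°, stimuli at 50–100 Hz.
Reference fit parameters are the measured values for apical neurons:
`X_0.5 = 0.42` µm, g = 3.2 nS, `E_MA = −1.4` mV, τ₁ = 3.6 ms,
τ₂ = 24 ms, IC₅₀ = 0.9 µM. The dose-response simulation design uses nine
log-spaced concentrations (0.05–20 µM) with Gaussian noise of ~1% of the
initial current, a realistic design for averaged peak-current
measurements under which the fit recovers IC₅₀ and the Hill coefficient
with < 5% median error.

### Phase-locked train generator

One Bernoulli trial per stimulus cycle (success probability
rate/frequency, capped at 1) places at most one spike per cycle at a phase
drawn from a (mixture of) von Mises distribution(s); κ = ∞ is a delta,
κ = 0 uniform. This matches the observed regime of rates at or below the
stimulus frequency, and the measured VS converges to the Bessel ratio
I₁(κ)/I₀(κ) as n grows. All generators are bit-reproducible under a fixed
seed.

### Neuron simulator

A leaky integrate-and-fire shell carries the measured MA pathway:

    C_m dV/dt = −g_L(V − E_L) + I_inj(t) + I_MA(t) + ξ(t)
    I_MA = (1 − b)·g_MA·d(t)·(E_MA − V)

with `b` the blocked fraction (e.g. from the Hill model at a given blocker
concentration). The drive `d(t)` is the leak-subtracted Boltzmann
activation `q = p_o(X) − p_o(0)` passed through a two-state adaptation
stage: states `u_i` relax toward `q` with time constants τ₁, τ₂ and

    d = A_ss·q + A₁(q − u₁) + A₂(q − u₂),   A₁ + A₂ + A_ss = 1,

so a displacement step decays exactly bi-exponentially from `q` to
`A_ss·q` — the literature specifies only the decay form, not the kinetic
scheme, and this is the simplest scheme that reproduces it. Leak
subtraction mirrors offline leak correction of recorded currents and makes
the zero-stimulus equilibrium exact (V ≡ E_L).

Integration is fixed-step explicit Euler with a stability guard
(non-finite voltage raises an error naming the offending step); the
default step is 0.02 ms and a step coarser than 0.1·τ₁ is rejected. The
per-step noise term ξ is white Gaussian with standard deviation
`noise_sd` per step (a phenomenological jitter, not a calibrated spectral
density — its effective voltage sd therefore depends on dt). Spikes are
threshold crossings with reset and a refractory period; a stereotyped
triangular 1-ms excursion to +20 mV is painted into the returned voltage
trace at each spike time so that the detection stage (0 mV amplitude
criterion, peak timing) can be exercised end to end.

Membrane parameters are not measured quantities in this preparation; they
are calibration choices fixed once: C_m = 8 pF, g_L = 4 nS (τ_m = 2 ms,
appropriate for these fast neurons), E_L = −60 mV, V_reset = −58 mV,
1 ms refractory, Boltzmann slope 6 µm⁻¹. The threshold −48.6 mV is set
midway between the voltage peaks reached by the reference stimuli
(50 Hz, 0.05 nA current; 0.1 µm displacement) alone and combined in
phase, so each alone is subthreshold while the in-phase pair fires on
every cycle — the subthreshold-summation phenomenon.

The eight-angle sweep defaults (60 pA current, 0.45 µm displacement,
40 pA noise, three repetitions) place the mechanical depolarization just
below threshold on its own: in-phase stimulation merges the two
depolarizations (high rate, strong locking), intermediate angles partially
cancel (reduced rate), and near-antiphase angles suppress firing almost
completely, losing measurable phase locking with it. This reproduces the
facilitation/reduction/suppression sequence and the co-location of the
rate and VS minima. It does not reproduce every in vivo feature: there is
no synaptic vesicle release, no cochlear micromechanics, no
spontaneous-rate diversity, and the suppression-angle VS collapse arises
here mainly from the loss of spikes rather than from a two-peaked
histogram, so passing tests demonstrate the analysis chain and the
qualitative interaction, not a quantitative model of the biological cell.

## Problem sizes

Test and driver simulations use dt = 0.05 ms with ~1.4 s records
(1 s stimulus overlap), three repetitions per angle; Monte-Carlo suites
use 10⁴ replicates for the Rayleigh calibration, 10⁴-spike trains for the
VS oracle, and 100 seeded replicates for parameter recovery and the
peak-splitting classifier. These sizes give sampling errors well inside
the asserted tolerances.

## Known limitations

- The simulator's noise is per-step white noise; its voltage variance is
  dt-dependent and should be treated as a phenomenological knob.
- The adaptation stage acts multiplicatively on the driving-force term
  through `d(t)`; true MA-channel kinetics (state-dependent inactivation,
  Ca²⁺ modulation) are not modeled.
- Rayleigh p-values assume independent spike phases; bursting or
  refractory correlation inflates significance, which is one reason
  tabulated p-values from recordings are not reproduction targets.
- The two-component Boltzmann fit is weakly identified on sparse grids;
  it needs ≥ 7 points and benefits from a denser design.
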