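"""Circular statistics for phase-locked spike trains.

Vector strength (VS), the mean resultant length of spike phases relative to
a periodic stimulus, runs from 0 (flat cycle histogram, no phase locking) to
1 (all spikes at one phase).  Significance uses the Rayleigh statistic
Z = n*VS^2 with a finite-n correction series; cycle histograms, a circular
peak counter for peak-splitting, and a polar resultant summary across the
eight relative phase angles (0..315 degrees in 45 degree steps) complete the
module.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

from .core_io import (TWO_PI, SinusoidStimulus, SpikeTrain, register_result)

__all__ = [
    "PhaseLockStats", "CycleHistogram", "PeakCount", "PolarSummary",
    "spike_phases", "vector_strength", "rayleigh_p", "cycle_histogram",
    "histogram_vector_strength", "count_peaks", "polar_summary",
    "POLAR_ANGLES",
]

#: the eight relative phase angles of the polar protocol, radians
POLAR_ANGLES = np.deg2rad(np.arange(0.0, 360.0, 45.0))


@register_result
@dataclass
class PhaseLockStats:
    """Vector strength, mean phase (rad), Rayleigh Z and p for one train."""

    vs: float
    mean_phase: float
    n: int
    z_stat: float
    p: float
    valid: bool


@register_result
@dataclass
class CycleHistogram:
    """Spike counts per stimulus-phase bin over [0, 2*pi)."""

    bin_edges: np.ndarray
    counts: np.ndarray
    n: int
    frequency: float

    def __post_init__(self):
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.sum() != self.n:
            raise ValueError("histogram counts do not sum to n")

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


@register_result
@dataclass
class PeakCount:
    """Mode count of a cycle histogram with a flatness reliability flag."""

    n_peaks: int
    reliable: bool
    peak_phases: np.ndarray

    def __post_init__(self):
        self.peak_phases = np.asarray(self.peak_phases, dtype=float)


@register_result
@dataclass
class PolarSummary:
    """Normalized rate and VS at the eight relative phase angles.

    ``resultant_rate`` and ``resultant_vs`` are (magnitude, angle) pairs of
    the normalized resultant R = sum(m_k exp(i theta_k)) / sum(m_k); invalid
    VS entries (NaN) contribute zero magnitude.  p-values come from a seeded
    permutation of the magnitudes across angles.
    """

    angles: np.ndarray
    rate_norm: np.ndarray
    vs_per_angle: np.ndarray
    resultant_rate: tuple
    resultant_vs: tuple
    p_rate: float
    p_vs: float
    max_rate: float = float("nan")

    def __post_init__(self):
        self.angles = np.asarray(self.angles, dtype=float)
        self.rate_norm = np.asarray(self.rate_norm, dtype=float)
        self.vs_per_angle = np.asarray(self.vs_per_angle, dtype=float)
        self.resultant_rate = tuple(self.resultant_rate)
        self.resultant_vs = tuple(self.resultant_vs)


def spike_phases(train: SpikeTrain, stim: Optional[SinusoidStimulus] = None,
                 window: Optional[tuple] = None) -> np.ndarray:
    """Phase of each spike relative to the stimulus, radians in [0, 2*pi).

    Phase of a spike at time t is 2*pi*f*(t - onset) mod 2*pi.  The window
    (ms, ms) defaults to the whole record.
    """
    stim = stim if stim is not None else train.stimulus
    if stim is None or not isinstance(stim, SinusoidStimulus):
        raise ValueError("spike_phases requires a sinusoid stimulus")
    if window is None:
        window = (0.0, train.record_duration)
    t = train.times
    t = t[(t >= window[0]) & (t < window[1])]
    return (TWO_PI * stim.frequency * (t - stim.onset) / 1000.0) % TWO_PI


def vector_strength(phases: Sequence[float],
                    min_spikes_for_vs: int = 5) -> PhaseLockStats:
    """VS = |sum(exp(i phi))| / n and the circular mean phase.

    The Rayleigh p is attached when n >= 2; ``valid`` flags whether n meets
    ``min_spikes_for_vs``.
    """
    phases = np.asarray(phases, dtype=float)
    if phases.size == 0:
        raise ValueError("vector_strength requires at least one phase")
    n = int(phases.size)
    resultant = np.exp(1j * phases).sum()
    vs = float(abs(resultant)) / n
    mean_phase = float(np.angle(resultant)) % TWO_PI
    z = n * vs * vs
    p = rayleigh_p(vs, n) if n >= 2 else float("nan")
    return PhaseLockStats(vs=vs, mean_phase=mean_phase, n=n, z_stat=z, p=p,
                          valid=n >= min_spikes_for_vs)


def rayleigh_p(vs: float, n: int) -> float:
    """Rayleigh-test p-value for circular uniformity, finite-n corrected.

    p = exp(-Z) * [1 + (2Z - Z^2)/(4n) - (24Z - 132Z^2 + 76Z^3 - 9Z^4)/(288 n^2)]

    with Z = n*VS^2, clipped to (0, 1].  The naive exp(-Z) alone is
    anticonservative at small n.
    """
    if n < 2:
        raise ValueError("rayleigh_p requires n >= 2")
    z = n * vs * vs
    correction = (1.0 + (2.0 * z - z * z) / (4.0 * n)
                  - (24.0 * z - 132.0 * z ** 2 + 76.0 * z ** 3 - 9.0 * z ** 4)
                  / (288.0 * n * n))
    p = math.exp(-z) * correction
    return float(min(1.0, max(p, 5e-324)))


def cycle_histogram(phases: Sequence[float], n_bins: int = 36,
                    frequency: float = float("nan")) -> CycleHistogram:
    """Bin spike phases into n_bins half-open bins spanning [0, 2*pi)."""
    if n_bins < 8:
        raise ValueError("n_bins must be >= 8")
    phases = np.asarray(phases, dtype=float) % TWO_PI
    edges = np.linspace(0.0, TWO_PI, n_bins + 1)
    counts, _ = np.histogram(phases, bins=edges)
    return CycleHistogram(bin_edges=edges, counts=counts,
                          n=int(phases.size), frequency=frequency)


def histogram_vector_strength(hist: CycleHistogram) -> float:
    """VS as |fundamental Fourier component of the cycle histogram| / n.

    This is the period-histogram definition of synchronization; it converges
    to the spike-wise VS as the bins become fine.
    """
    if hist.n == 0:
        raise ValueError("empty histogram")
    comp = np.sum(hist.counts * np.exp(1j * hist.centers))
    return float(abs(comp)) / hist.n


def _wrapped_smooth(counts: np.ndarray, sigma_bins: float) -> np.ndarray:
    return ndimage.gaussian_filter1d(counts.astype(float), sigma=sigma_bins,
                                     mode="wrap")


def count_peaks(hist: CycleHistogram, smooth_sd: float = np.deg2rad(15.0),
                height_frac: float = 0.25, min_sep: float = np.deg2rad(60.0),
                flatness_ratio: float = 1.8) -> PeakCount:
    """Count modes of a cycle histogram (peak-splitting detector).

    Counts are circularly smoothed with a wrapped Gaussian of ``smooth_sd``
    radians; circular local maxima at least ``height_frac`` of the global
    maximum and separated by at least ``min_sep`` are kept.  A histogram
    whose smoothed max/mean ratio falls below ``flatness_ratio`` carries no
    phase structure and is flagged unreliable.
    """
    if hist.n == 0:
        raise ValueError("count_peaks requires a non-empty histogram")
    bin_width = hist.bin_edges[1] - hist.bin_edges[0]
    smooth = _wrapped_smooth(hist.counts, smooth_sd / bin_width)
    left = np.roll(smooth, 1)
    right = np.roll(smooth, -1)
    is_max = (smooth > left) & (smooth >= right)
    if not is_max.any():          # perfectly flat after smoothing
        is_max[int(np.argmax(smooth))] = True
    candidates = np.flatnonzero(is_max & (smooth >= height_frac * smooth.max()))
    centers = hist.centers
    order = candidates[np.argsort(smooth[candidates])[::-1]]
    kept: list = []
    for idx in order:
        ang = centers[idx]
        sep_ok = all(_circ_dist(ang, centers[k]) >= min_sep for k in kept)
        if sep_ok:
            kept.append(idx)
    kept.sort()
    reliable = bool(smooth.max() / smooth.mean() >= flatness_ratio)
    return PeakCount(n_peaks=len(kept), reliable=reliable,
                     peak_phases=centers[kept])


def _circ_dist(a: float, b: float) -> float:
    d = abs(a - b) % TWO_PI
    return min(d, TWO_PI - d)


def _resultant(magnitudes: np.ndarray, angles: np.ndarray) -> tuple:
    m = np.where(np.isfinite(magnitudes), magnitudes, 0.0)
    total = m.sum()
    if total <= 0:
        return (0.0, 0.0)
    r = np.sum(m * np.exp(1j * angles)) / total
    return (float(abs(r)), float(np.angle(r)) % TWO_PI)


def _permutation_p(magnitudes: np.ndarray, angles: np.ndarray,
                   n_perm: int, rng: np.random.Generator) -> float:
    obs = _resultant(magnitudes, angles)[0]
    m = np.where(np.isfinite(magnitudes), magnitudes, 0.0)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(m)
        if _resultant(perm, angles)[0] >= obs - 1e-12:
            count += 1
    return (1 + count) / (1 + n_perm)


def polar_summary(conditions, stim: Optional[SinusoidStimulus] = None,
                  min_spikes_for_vs: int = 5, n_perm: int = 10000,
                  seed: int = 0, window: Optional[tuple] = None
                  ) -> PolarSummary:
    """Summarize rate and phase locking across the eight phase angles.

    Parameters
    ----------
    conditions : sequence of (angle_rad, list of SpikeTrain) covering exactly
        the angles 0, 45, ..., 315 degrees (any order); each angle may hold
        repeated stimulus presentations.
    stim : phase-reference sinusoid used when a train carries none.

    Per-angle rate is averaged over repetitions then normalized to its
    maximum; per-angle VS pools spike phases across repetitions.  The
    resultant of magnitudes m_k at angles theta_k is
    R = sum(m_k e^{i theta_k}) with normalized magnitude |R| / sum(m_k).
    """
    cond = sorted(conditions, key=lambda item: item[0])
    angles = np.array([c[0] for c in cond], dtype=float)
    if angles.size != 8 or not np.allclose(angles % TWO_PI, POLAR_ANGLES,
                                           atol=1e-9):
        raise ValueError("polar_summary requires exactly the 8 angles "
                         "0..315 degrees in 45 degree steps")
    rates = np.empty(8)
    vs = np.full(8, np.nan)
    for k, (_, trains) in enumerate(cond):
        if not trains:
            raise ValueError(f"no repetitions at angle index {k}")
        per_rep = []
        pooled = []
        for tr in trains:
            w = window if window is not None else (0.0, tr.record_duration)
            n_in = np.count_nonzero((tr.times >= w[0]) & (tr.times < w[1]))
            per_rep.append(n_in / (w[1] - w[0]) * 1000.0)
            pooled.append(spike_phases(tr, stim=tr.stimulus or stim, window=w))
        rates[k] = float(np.mean(per_rep))
        pooled_ph = np.concatenate(pooled) if pooled else np.empty(0)
        if pooled_ph.size >= min_spikes_for_vs:
            vs[k] = vector_strength(pooled_ph, min_spikes_for_vs).vs
    max_rate = rates.max()
    rate_norm = rates / max_rate if max_rate > 0 else np.zeros(8)
    rng = np.random.default_rng(seed)
    res_rate = _resultant(rate_norm, angles)
    res_vs = _resultant(vs, angles)
    p_rate = _permutation_p(rate_norm, angles, n_perm, rng)
    p_vs = _permutation_p(vs, angles, n_perm, rng)
    return PolarSummary(angles=angles, rate_norm=rate_norm, vs_per_angle=vs,
                        resultant_rate=res_rate, resultant_vs=res_vs,
                        p_rate=p_rate, p_vs=p_vs, max_rate=float(max_rate))
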