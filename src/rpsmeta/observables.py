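"""Oscillation observables extracted from trajectories.

Quantifies what the phase portraits show qualitatively: the dominant
oscillation frequency of a density series (spectral peak with parabolic
refinement), the phase by which one series lags another (analytic-signal
instantaneous phase, circular mean), the exponential damping rate of the
oscillation envelope, inter-node synchronization, and a coarse attractor
label (sustained cycle vs. fixed point).

All inputs are clean ODE output on a uniform time grid; no noise
robustness is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy.signal import argrelextrema, hilbert

from .dynamics import SPECIES, Trajectory

__all__ = [
    "SeriesWindow",
    "FrequencyEstimate",
    "dominant_frequency",
    "phase_difference",
    "damping_rate",
    "classify_attractor",
    "zero_lag_correlation",
    "observables_report",
]

#: Peak power must exceed this multiple of the spectral median to count
#: as a real oscillation.
_PEAK_OVER_MEDIAN = 10.0


@dataclass(frozen=True)
class SeriesWindow:
    """One scalar density time series restricted to an analysis window."""

    times: np.ndarray
    values: np.ndarray
    window_start_fraction: float = 0.0

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.shape != v.shape or t.ndim != 1:
            raise ValueError("times and values must be equal-length 1-D arrays")
        if len(t) >= 3:
            dt = np.diff(t)
            if not np.allclose(dt, dt[0], rtol=1e-8, atol=1e-12):
                raise ValueError("SeriesWindow requires a uniform time grid")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)

    @classmethod
    def from_trajectory(
        cls,
        tr: Trajectory,
        species: str,
        node: int = 1,
        start_fraction: float = 0.5,
    ) -> "SeriesWindow":
        """Take one (species, node) series, discarding the initial transient."""
        if not 0.0 <= start_fraction < 1.0:
            raise ValueError("start_fraction must be in [0, 1)")
        i0 = int(np.floor(start_fraction * len(tr.times)))
        return cls(tr.times[i0:], tr.series(species, node)[i0:], start_fraction)

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    def __len__(self) -> int:
        return len(self.times)


class FrequencyEstimate(NamedTuple):
    """Dominant frequency in cycles per unit time; 0 when non-oscillatory."""

    frequency: float
    oscillatory: bool
    peak_power: float
    median_power: float


def dominant_frequency(s: SeriesWindow) -> FrequencyEstimate:
    """Frequency of the largest spectral peak of a mean-removed series.

    Hann-windowed FFT; the peak bin is refined by parabolic
    interpolation of log power through the three bins around the
    maximum.  A series whose peak power is below 10x the spectral median
    is flagged non-oscillatory and reported as frequency 0.
    """
    if len(s) < 64:
        raise ValueError(f"need at least 64 samples, got {len(s)}")
    x = s.values - s.values.mean()
    if float(np.abs(x).max()) < 1e-12 * max(1.0, float(np.abs(s.values).max())):
        return FrequencyEstimate(0.0, False, 0.0, 0.0)
    w = np.hanning(len(x))
    power = np.abs(np.fft.rfft(x * w)) ** 2
    power = power[1:]  # drop DC
    peak = int(np.argmax(power))
    med = float(np.median(power))
    if power[peak] <= _PEAK_OVER_MEDIAN * med or power[peak] == 0.0:
        return FrequencyEstimate(0.0, False, float(power[peak]), med)
    # parabolic refinement on log power (peak-bin offset in [-0.5, 0.5])
    delta = 0.0
    if 1 <= peak < len(power) - 1:
        la, lb, lc = np.log(power[peak - 1 : peak + 2] + 1e-300)
        denom = la - 2 * lb + lc
        if denom < 0:
            delta = 0.5 * (la - lc) / denom
    freq = (peak + 1 + delta) / (len(x) * s.dt)
    return FrequencyEstimate(float(freq), True, float(power[peak]), med)


def _instantaneous_phase(values: np.ndarray) -> np.ndarray:
    return np.angle(hilbert(values - values.mean()))


def phase_difference(s1: SeriesWindow, s2: SeriesWindow) -> float:
    """Phase (radians, in [0, 2pi)) by which ``s2`` lags ``s1``.

    Both series must oscillate at matching dominant frequency (within
    2%).  The result is the circular mean of the instantaneous phase gap
    phi_1 - phi_2 from the analytic signal, with 10% of the window
    trimmed at each end against Hilbert edge effects.  Convention: if
    ``s2(t) = s1(t - tau)`` with tau a quarter period, the result is
    pi/2.
    """
    if len(s1) != len(s2) or not np.allclose(s1.times, s2.times):
        raise ValueError("phase_difference needs series on the same time grid")
    f1 = dominant_frequency(s1)
    f2 = dominant_frequency(s2)
    if not (f1.oscillatory and f2.oscillatory):
        raise ValueError("phase_difference needs oscillatory inputs")
    if abs(f1.frequency - f2.frequency) > 0.02 * max(f1.frequency, f2.frequency):
        raise ValueError(
            f"dominant frequencies differ: {f1.frequency:g} vs {f2.frequency:g}"
        )
    gap = _instantaneous_phase(s1.values) - _instantaneous_phase(s2.values)
    trim = max(1, len(gap) // 10)
    mean = np.exp(1j * gap[trim:-trim]).mean()
    return float(np.angle(mean) % (2 * np.pi))


def zero_lag_correlation(s1: SeriesWindow, s2: SeriesWindow) -> float:
    """Pearson correlation of the two series at zero lag."""
    if len(s1) != len(s2):
        raise ValueError("series length mismatch")
    return float(np.corrcoef(s1.values, s2.values)[0, 1])


def damping_rate(s: SeriesWindow, equilibrium_value: float) -> float:
    """Exponential decay rate of the oscillation envelope (per unit time).

    Least-squares slope of log |extremum - equilibrium| against
    extremum time over the successive local extrema of the series.
    Negative means decaying amplitude; values near zero mean sustained
    oscillation.
    """
    dev = s.values - equilibrium_value
    hi = argrelextrema(dev, np.greater)[0]
    lo = argrelextrema(dev, np.less)[0]
    idx = np.sort(np.concatenate([hi, lo]))
    idx = idx[np.abs(dev[idx]) > 1e-300]
    if len(idx) < 4:
        raise ValueError(f"need at least 4 extrema, found {len(idx)}")
    slope, _ = np.polyfit(s.times[idx], np.log(np.abs(dev[idx])), 1)
    return float(slope)


def classify_attractor(tr: Trajectory, tol: float) -> str:
    """Coarse late-time attractor label for a whole trajectory.

    ``fixed_point`` if every component's standard deviation over the
    final quarter of the run is below ``tol``; ``limit_cycle_or_center``
    if every appreciably oscillating component keeps a steady amplitude
    (second-half to first-half half-range ratio within [0.95, 1.05],
    measured over the post-transient second half of the run); otherwise
    ``undetermined``.
    """
    n_t = len(tr.times)
    flat = tr.states.reshape(n_t, -1)
    tail = flat[3 * n_t // 4 :]
    if float(tail.std(axis=0).max()) < tol:
        return "fixed_point"
    window = flat[n_t // 2 :]
    half = len(window) // 2
    amp1 = 0.5 * (window[:half].max(axis=0) - window[:half].min(axis=0))
    amp2 = 0.5 * (window[half:].max(axis=0) - window[half:].min(axis=0))
    active = amp1 > max(tol, 10 * float(np.finfo(float).eps))
    if not active.any():
        return "undetermined"
    ratios = amp2[active] / amp1[active]
    if ((ratios >= 0.95) & (ratios <= 1.05)).all():
        return "limit_cycle_or_center"
    return "undetermined"


def observables_report(
    tr: Trajectory,
    phase_species: str = "R",
    start_fraction: float = 0.5,
) -> dict:
    """Per-series frequency/amplitude/damping plus a pairwise phase matrix.

    The phase matrix entry [i][j] is the phase by which node j+1's
    ``phase_species`` series lags node i+1's; entries are None where a
    series is non-oscillatory.
    """
    report: dict = {"series": [], "phase_species": phase_species, "phase_matrix": None}
    windows: dict[tuple[str, int], SeriesWindow] = {}
    for sp in SPECIES:
        for node in range(1, tr.n_nodes + 1):
            win = SeriesWindow.from_trajectory(tr, sp, node, start_fraction)
            windows[(sp, node)] = win
            est = dominant_frequency(win)
            amp = 0.5 * float(win.values.max() - win.values.min())
            entry = {
                "species": sp,
                "node": node,
                "frequency": est.frequency,
                "oscillatory": est.oscillatory,
                "amplitude": amp,
                "mean": float(win.values.mean()),
            }
            try:
                full = SeriesWindow(tr.times, tr.series(sp, node))
                entry["damping_rate"] = damping_rate(full, float(win.values.mean()))
            except ValueError:
                entry["damping_rate"] = None
            report["series"].append(entry)
    mat: list[list[float | None]] = []
    for i in range(1, tr.n_nodes + 1):
        row: list[float | None] = []
        for j in range(1, tr.n_nodes + 1):
            try:
                row.append(phase_difference(windows[(phase_species, i)], windows[(phase_species, j)]))
            except ValueError:
                row.append(None)
        mat.append(row)
    report["phase_matrix"] = mat
    return report
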