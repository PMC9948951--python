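"""Periodogram PSD estimation and task-frequency bin selection.

The estimator is the plain (rectangular-window) periodogram with the sample
mean removed: one-sided PSD[k] = c_k |X_k|^2 / (fs N), c_k = 2 for interior
bins and 1 at DC and (even N) Nyquist.  For the default block design — 140
task samples at TR 3 s — the task fundamental 1/60 Hz lands exactly on bin 7
of the frequency grid, so power at that single bin carries the full
task-locked component with no leakage.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import signal as sp_signal

from .types import PowerSpectrum, RegionSignal, TaskDesign

__all__ = [
    "TargetFrequency",
    "periodogram_psd",
    "resolve_target",
    "subject_average_power",
]


@dataclass(frozen=True)
class TargetFrequency:
    """The frequency bin tested for task-locked power."""

    f0: float
    bin_index: int
    achieved_frequency: float
    leakage: bool = False


def periodogram_psd(
    signal: RegionSignal | np.ndarray, tr: float
) -> PowerSpectrum:
    """One-sided periodogram of a region signal sampled at interval ``tr``."""
    x = signal.values if isinstance(signal, RegionSignal) else np.asarray(
        signal, dtype=np.float64
    )
    if x.ndim != 1:
        raise ValueError("signal must be 1D")
    if x.size < 4:
        raise ValueError("signal too short for a periodogram (need >= 4)")
    if not np.all(np.isfinite(x)):
        raise ValueError("signal contains non-finite values")
    fs = 1.0 / tr
    freqs, psd = sp_signal.periodogram(
        x, fs=fs, window="boxcar", detrend="constant", scaling="density"
    )
    return PowerSpectrum(
        frequencies=freqs, psd=psd, n_samples=x.size, sampling_rate=fs
    )


def resolve_target(design: TaskDesign, n_samples: int) -> TargetFrequency:
    """Locate the task fundamental 1/(on+off) on the periodogram grid.

    Returns the nearest nonzero bin; the leakage flag is set when the grid
    misses the fundamental by more than 1% of the bin spacing (the task
    component then spreads over neighboring bins).  Raises when the
    fundamental exceeds Nyquist.
    """
    if n_samples < 4:
        raise ValueError("need n_samples >= 4")
    f0 = design.fundamental_frequency
    fs = 1.0 / design.tr
    nyquist = fs / 2.0
    if f0 > nyquist * (1 + 1e-12):
        raise ValueError(
            f"task frequency {f0:.4g} Hz exceeds Nyquist {nyquist:.4g} Hz "
            f"(tr={design.tr}s too coarse)"
        )
    df = fs / n_samples
    freqs = np.arange(n_samples // 2 + 1) * df
    k = 1 + int(np.argmin(np.abs(freqs[1:] - f0)))
    achieved = float(freqs[k])
    return TargetFrequency(
        f0=f0,
        bin_index=k,
        achieved_frequency=achieved,
        leakage=bool(abs(achieved - f0) > df / 100.0),
    )


def subject_average_power(
    spectra: Sequence[PowerSpectrum], target: TargetFrequency
) -> float:
    """Arithmetic mean across subjects of PSD at the target bin."""
    if not spectra:
        raise ValueError("no spectra given")
    ref = spectra[0]
    for s in spectra[1:]:
        if s.n_samples != ref.n_samples or not np.isclose(
            s.sampling_rate, ref.sampling_rate
        ):
            raise ValueError("spectra do not share a frequency grid")
    if target.bin_index >= ref.psd.size:
        raise ValueError("target bin outside the spectrum")
    return float(np.mean([s.psd[target.bin_index] for s in spectra]))
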