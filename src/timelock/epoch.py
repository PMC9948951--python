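"""Epoch-averaged block responses.

Signals are converted to percent change about the run mean, cut into
on/off cycles aligned to stimulus onset, and averaged across cycles; group
curves are the pointwise mean across subjects with individual curves kept
for plotting.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .types import RegionSignal, TaskDesign

__all__ = ["epoch_average", "group_epoch_average"]


def epoch_average(
    signal: RegionSignal | np.ndarray, design: TaskDesign
) -> np.ndarray:
    """Mean single-cycle response in percent-change units.

    The signal (dummies already removed) must span exactly
    ``n_blocks * samples_per_cycle`` samples and have a positive mean.
    """
    x = signal.values if isinstance(signal, RegionSignal) else np.asarray(
        signal, dtype=np.float64
    )
    expected = design.n_task_samples
    if x.size != expected:
        raise ValueError(
            f"signal length {x.size} does not divide into {design.n_blocks} "
            f"whole cycles of {design.samples_per_cycle} samples "
            f"(expected {expected})"
        )
    m = x.mean()
    if m <= 0:
        raise ValueError("signal mean must be positive for percent conversion")
    pct = 100.0 * (x - m) / m
    return pct.reshape(design.n_blocks, design.samples_per_cycle).mean(axis=0)


def group_epoch_average(
    curves: Sequence[np.ndarray],
) -> tuple[np.ndarray, np.ndarray]:
    """Pointwise mean across subjects; returns (mean curve, stacked curves)."""
    if not len(curves):
        raise ValueError("no epoch curves given")
    stacked = np.vstack([np.asarray(c, dtype=np.float64) for c in curves])
    return stacked.mean(axis=0), stacked
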