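"""Core domain types for block-design BOLD analysis.

The pipeline operates on four kinds of objects: acquisition descriptions
(:class:`TaskDesign`), 4D runs (:class:`BoldRun`), spatial region definitions
(:class:`RegionAtlas`), and the 1D/derived products (:class:`RegionSignal`,
:class:`PowerSpectrum`, :class:`ActivationResult`).  All volumetric objects
carry an affine so grid compatibility can be enforced before any signal is
extracted.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

__all__ = [
    "TaskDesign",
    "BoldRun",
    "RegionAtlas",
    "RegionSignal",
    "PowerSpectrum",
    "ActivationResult",
    "GridMismatchError",
    "RESTING",
]

#: Condition string marking a resting-state (no task) acquisition.
RESTING = "resting"

#: Absolute tolerance on affine entries when deciding two volumes share a grid.
AFFINE_ATOL = 1e-4


class GridMismatchError(ValueError):
    """Raised when two volumes do not share a voxel grid (shape + affine)."""


def _check_same_grid(shape_a, affine_a, shape_b, affine_b, what: str) -> None:
    if tuple(shape_a) != tuple(shape_b):
        raise GridMismatchError(
            f"{what}: shape mismatch {tuple(shape_a)} vs {tuple(shape_b)}"
        )
    if not np.allclose(affine_a, affine_b, atol=AFFINE_ATOL, rtol=0.0):
        raise GridMismatchError(f"{what}: affine mismatch beyond {AFFINE_ATOL}")


@dataclass(frozen=True)
class TaskDesign:
    """Block-design timing: ``n_blocks`` cycles of on/off stimulation.

    Parameters
    ----------
    on_seconds, off_seconds:
        Duration of the stimulation and rest halves of one cycle.  The run
        starts with an on-period.
    n_blocks:
        Number of on/off cycles.
    n_dummy:
        Volumes acquired before task onset and discarded from analysis.
    tr:
        Repetition time (sampling interval) in seconds.
    """

    on_seconds: float
    off_seconds: float
    n_blocks: int
    n_dummy: int
    tr: float

    def __post_init__(self) -> None:
        if self.on_seconds <= 0:
            raise ValueError("on_seconds must be > 0")
        if self.off_seconds < 0:
            raise ValueError("off_seconds must be >= 0")
        if self.tr <= 0:
            raise ValueError("tr must be > 0")
        if self.n_blocks < 1:
            raise ValueError("n_blocks must be >= 1")
        if self.n_dummy < 0:
            raise ValueError("n_dummy must be >= 0")
        ratio = self.cycle_seconds / self.tr
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValueError(
                f"cycle length {self.cycle_seconds}s is not an integer multiple "
                f"of tr={self.tr}s"
            )

    @property
    def cycle_seconds(self) -> float:
        return self.on_seconds + self.off_seconds

    @property
    def fundamental_frequency(self) -> float:
        """Task fundamental 1/(on+off) in Hz."""
        return 1.0 / self.cycle_seconds

    @property
    def samples_per_cycle(self) -> int:
        return int(round(self.cycle_seconds / self.tr))

    @property
    def on_samples(self) -> int:
        return int(round(self.on_seconds / self.tr))

    @property
    def n_task_samples(self) -> int:
        return self.n_blocks * self.samples_per_cycle

    @property
    def n_total_samples(self) -> int:
        return self.n_dummy + self.n_task_samples

    @property
    def duration_seconds(self) -> float:
        return self.n_total_samples * self.tr


@dataclass
class BoldRun:
    """One subject's 4D BOLD time series plus acquisition metadata."""

    data: np.ndarray
    design: TaskDesign
    subject_id: str
    condition: str
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 4:
            raise ValueError(f"not a 4D series (got {self.data.ndim}D)")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("BOLD data contains non-finite values")
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if self.condition == RESTING:
            if self.n_volumes < 2:
                raise ValueError("resting run must have >= 2 volumes")
        else:
            expected = self.design.n_total_samples
            if self.n_volumes != expected:
                raise ValueError(
                    f"task run has {self.n_volumes} volumes, design requires "
                    f"{expected} (= {self.design.n_dummy} dummies + "
                    f"{self.design.n_blocks} x {self.design.samples_per_cycle})"
                )

    @property
    def shape3d(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    def check_grid(self, shape, affine, what: str = "run vs atlas") -> None:
        _check_same_grid(self.shape3d, self.affine, shape, affine, what)


@dataclass
class RegionAtlas:
    """Gray-matter parcellation plus tract-density maps on a common grid.

    ``gm_labels`` is an integer label volume (0 = background), ``wm_density``
    maps each bundle name to a nonnegative streamline-density volume used as
    averaging weights, and ``brain_mask`` bounds everything.
    """

    gm_labels: np.ndarray
    wm_density: Mapping[str, np.ndarray]
    brain_mask: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    gm_names: Mapping[int, str] | None = None

    def __post_init__(self) -> None:
        self.gm_labels = np.asarray(self.gm_labels)
        if not np.issubdtype(self.gm_labels.dtype, np.integer):
            if not np.allclose(self.gm_labels, np.round(self.gm_labels)):
                raise ValueError("gm_labels must be an integer volume")
            self.gm_labels = np.round(self.gm_labels).astype(np.int32)
        self.brain_mask = np.asarray(self.brain_mask).astype(bool)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        shape = self.gm_labels.shape
        if self.gm_labels.ndim != 3:
            raise ValueError("gm_labels must be 3D")
        _check_same_grid(shape, self.affine, self.brain_mask.shape, self.affine,
                         "gm_labels vs brain_mask")
        if np.any((self.gm_labels > 0) & ~self.brain_mask):
            raise ValueError("gray-matter labels extend outside the brain mask")
        clean = {}
        for name, vol in self.wm_density.items():
            vol = np.asarray(vol, dtype=np.float64)
            _check_same_grid(shape, self.affine, vol.shape, self.affine,
                             f"gm_labels vs density '{name}'")
            if np.any(vol < 0):
                raise ValueError(f"density map '{name}' has negative values")
            if np.any((vol > 0) & ~self.brain_mask):
                warnings.warn(
                    f"bundle '{name}' has positive density outside the brain "
                    "mask; those voxels are ignored in weighting",
                    stacklevel=2,
                )
            clean[name] = vol
        self.wm_density = clean

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.gm_labels.shape

    @property
    def gm_label_ids(self) -> list[int]:
        ids = np.unique(self.gm_labels)
        return [int(i) for i in ids if i != 0]

    @property
    def bundle_names(self) -> list[str]:
        return sorted(self.wm_density)

    def gm_region_name(self, label_id: int) -> str:
        if self.gm_names and label_id in self.gm_names:
            return self.gm_names[label_id]
        return f"gm_{label_id:03d}"

    def check_grid(self, shape, affine, what: str = "atlas vs run") -> None:
        _check_same_grid(self.shape, self.affine, shape, affine, what)


@dataclass
class RegionSignal:
    """A region-averaged 1D time series (dummy volumes already removed)."""

    region_id: str
    tissue: str  # "GM" or "WM"
    subject_id: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 1:
            raise ValueError("signal values must be 1D")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("signal contains non-finite values")
        if self.tissue not in ("GM", "WM"):
            raise ValueError("tissue must be 'GM' or 'WM'")

    def __len__(self) -> int:
        return self.values.size


@dataclass
class PowerSpectrum:
    """One-sided periodogram: frequencies k*fs/N for k = 0..floor(N/2)."""

    frequencies: np.ndarray
    psd: np.ndarray
    n_samples: int
    sampling_rate: float

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=np.float64)
        self.psd = np.asarray(self.psd, dtype=np.float64)
        if self.frequencies.shape != self.psd.shape:
            raise ValueError("frequency grid and PSD must have equal length")
        expected = np.arange(self.frequencies.size) * (
            self.sampling_rate / self.n_samples
        )
        if not np.allclose(self.frequencies, expected, atol=1e-9):
            raise ValueError("frequencies must be k*fs/N, one-sided")
        if np.any(self.psd < -1e-12):
            raise ValueError("PSD must be nonnegative")
        np.clip(self.psd, 0.0, None, out=self.psd)


@dataclass
class ActivationResult:
    """Per-region outcome of the time-locked activation test."""

    region_id: str
    tissue: str
    observed_power: float
    p_value: float
    q_value: float
    significant: bool
    epoch_response: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.p_value <= 1.0):
            raise ValueError("p_value must lie in (0, 1]")
        if not (0.0 <= self.q_value <= 1.0):
            raise ValueError("q_value must lie in [0, 1]")
        if not math.isfinite(self.observed_power):
            raise ValueError("observed_power must be finite")
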