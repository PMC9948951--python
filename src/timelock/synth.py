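"""Synthetic BOLD data: desk-scale atlases, runs and ground-truth responses.

The generator emulates the statistical structure the analysis assumes —
block-locked responses riding on an AR(1)+drift noise floor at baseline 100 —
without attempting anatomical realism.  Gray-matter labels are contiguous
patches on an outer shell of an ellipsoidal "brain"; white-matter bundles are
tube-shaped density maps threading the interior, with density peaking at the
tube core the way streamline density peaks in deep white matter.

Ground-truth responses are built by convolving the block regressor with a
double-gamma hemodynamic kernel and applying shape modifiers (delay, sign
flip, onset/offset differencing, within-block ramp).  Baseline is fixed at
100 so percent signal change and raw units coincide numerically.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
from scipy import ndimage
from scipy.stats import gamma as gamma_dist

from .types import RESTING, BoldRun, RegionAtlas, TaskDesign

__all__ = [
    "ResponseSpec",
    "NoiseSpec",
    "Scenario",
    "make_atlas_fixture",
    "block_regressor",
    "hemodynamic_response",
    "simulate_run",
    "simulate_cohort",
]

BASELINE = 100.0
RESPONSE_SHAPES = ("sustained", "transient_onset_offset", "delayed", "negative",
                   "ramp")

#: Oversampling steps per TR when convolving with the hemodynamic kernel.
_UPSAMPLE = 30


@dataclass(frozen=True)
class ResponseSpec:
    """Ground-truth regional response.

    ``amplitude`` is the peak percent signal change relative to baseline;
    ``delay`` shifts the response in seconds (the ``delayed`` shape defaults
    to 6 s when no explicit delay is given); ``hrf_params`` are the
    double-gamma (peak time s, undershoot time s, peak/undershoot ratio).
    """

    shape: str = "sustained"
    amplitude: float = 1.0
    delay: float = 0.0
    hrf_params: tuple[float, float, float] = (6.0, 16.0, 6.0)

    def __post_init__(self) -> None:
        if self.shape not in RESPONSE_SHAPES:
            raise ValueError(
                f"unknown shape '{self.shape}'; expected one of {RESPONSE_SHAPES}"
            )
        if not np.isfinite(self.amplitude):
            raise ValueError("amplitude must be finite")
        if self.delay < 0:
            raise ValueError("delay must be >= 0")


@dataclass(frozen=True)
class NoiseSpec:
    """Additive noise model: AR(1) Gaussian plus a per-voxel linear drift.

    ``sigma`` is the marginal (stationary) standard deviation in baseline
    units, ``ar1`` the lag-1 autocorrelation, ``drift_amplitude`` the total
    drift excursion over a run.  ``spatial_fwhm_voxels`` optionally smooths
    the noise field in space to probe null robustness; the default noise is
    voxelwise independent.
    """

    sigma: float = 1.0
    ar1: float = 0.0
    drift_amplitude: float = 0.0
    spatial_fwhm_voxels: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if not (0 <= abs(self.ar1) < 1):
            raise ValueError("|ar1| must be < 1")


@dataclass(frozen=True)
class Scenario:
    """A full simulation recipe: grid, design, responders, noise, seed.

    ``responders`` maps a region key — an integer gray-matter label or a
    bundle-name string — to its :class:`ResponseSpec` (None = non-responding).
    ``amplitude_jitter`` scales each subject's amplitudes by a uniform
    factor in [1-j, 1+j] to mimic inter-subject variability.
    """

    grid_shape: tuple[int, int, int]
    design: TaskDesign
    responders: Mapping[int | str, ResponseSpec | None] = field(
        default_factory=dict
    )
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    seed: int = 0
    amplitude_jitter: float = 0.2


def make_atlas_fixture(
    grid_shape: tuple[int, int, int],
    n_gm_labels: int = 164,
    n_wm_bundles: int = 22,
    seed: int = 0,
) -> RegionAtlas:
    """Build a deterministic desk-scale atlas.

    The brain mask is an ellipsoid filling ~90% of the grid.  Gray-matter
    labels tile its outer shell as contiguous patches; each bundle is a
    Gaussian-profile tube through the deep interior whose density peaks at
    the tube axis.  Raises ``ValueError`` when the grid cannot give every
    region at least 8 voxels.
    """
    grid_shape = tuple(int(s) for s in grid_shape)
    if len(grid_shape) != 3:
        raise ValueError("grid_shape must be 3D")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xA7145]))

    center = (np.array(grid_shape) - 1) / 2.0
    radii = 0.45 * np.array(grid_shape)
    idx = np.indices(grid_shape).reshape(3, -1).T  # (V, 3)
    rel = (idx - center) / radii
    rho = np.sqrt((rel**2).sum(axis=1))
    mask_flat = rho <= 1.0
    shell_flat = mask_flat & (rho > 0.62)
    interior_flat = mask_flat & (rho <= 0.62)

    n_shell = int(shell_flat.sum())
    if n_shell < 8 * n_gm_labels:
        raise ValueError(
            f"grid too small: shell has {n_shell} voxels but "
            f"{n_gm_labels} labels need >= {8 * n_gm_labels}"
        )
    if interior_flat.sum() < 8:
        raise ValueError("grid too small: interior has fewer than 8 voxels")

    # Contiguous GM patches: order shell voxels by latitude band then azimuth
    # (after a seeded random rotation) and cut into n_gm_labels equal chunks.
    rot = _random_rotation(rng)
    shell_xyz = (idx[shell_flat] - center) @ rot.T
    r = np.linalg.norm(shell_xyz, axis=1)
    lat = shell_xyz[:, 2] / np.maximum(r, 1e-12)
    azim = np.arctan2(shell_xyz[:, 1], shell_xyz[:, 0])
    n_bands = max(1, int(round(np.sqrt(n_gm_labels))))
    band = np.minimum((0.5 * (lat + 1.0) * n_bands).astype(int), n_bands - 1)
    order = np.lexsort((azim, band))
    gm = np.zeros(idx.shape[0], dtype=np.int32)
    shell_indices = np.flatnonzero(shell_flat)[order]
    for lab, chunk in enumerate(np.array_split(shell_indices, n_gm_labels), 1):
        gm[chunk] = lab
    gm = gm.reshape(grid_shape)

    # WM bundles: Gaussian-profile tubes through the deep interior.
    interior_xyz = idx[interior_flat] - center
    interior_lin = np.flatnonzero(interior_flat)
    sigma_t = max(1.0, 0.10 * min(grid_shape))
    density: dict[str, np.ndarray] = {}
    for b in range(n_wm_bundles):
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        offset = rng.uniform(-0.25, 0.25, size=3) * radii * 0.62
        rel_xyz = interior_xyz - offset
        proj = rel_xyz @ direction
        dist = np.linalg.norm(rel_xyz - np.outer(proj, direction), axis=1)
        prof = np.exp(-(dist**2) / (2 * sigma_t**2))
        prof[dist > 2.5 * sigma_t] = 0.0
        if np.count_nonzero(prof) < 8:
            raise ValueError(
                "grid too small: a bundle tube covers fewer than 8 voxels"
            )
        vol = np.zeros(idx.shape[0], dtype=np.float64)
        vol[interior_lin] = prof
        density[f"bundle_{b:02d}"] = vol.reshape(grid_shape)

    return RegionAtlas(
        gm_labels=gm,
        wm_density=density,
        brain_mask=mask_flat.reshape(grid_shape),
        gm_names={i: f"gm_{i:03d}" for i in range(1, n_gm_labels + 1)},
    )


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random 3D rotation via QR of a Gaussian matrix."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    return q * np.sign(np.diag(r))


def block_regressor(design: TaskDesign) -> np.ndarray:
    """On/off indicator over the task samples (dummies excluded).

    Value 1 during stimulation, 0 during rest; the run starts with an
    on-period.  Length is ``n_blocks * samples_per_cycle``.
    """
    cycle = np.zeros(design.samples_per_cycle)
    cycle[: design.on_samples] = 1.0
    return np.tile(cycle, design.n_blocks)


def _double_gamma_kernel(hrf_params: tuple[float, float, float],
                         dt: float) -> np.ndarray:
    peak, undershoot, ratio = hrf_params
    t = np.arange(0.0, 32.0, dt)
    h = gamma_dist.pdf(t, a=peak, scale=1.0)
    h -= gamma_dist.pdf(t, a=undershoot, scale=1.0) / ratio
    return h


def hemodynamic_response(spec: ResponseSpec, design: TaskDesign) -> np.ndarray:
    """Noiseless ground-truth regional response in percent units.

    The block regressor (or its shape-specific variant) is oversampled,
    convolved with the double-gamma kernel, optionally delayed, sampled back
    at the TR grid and scaled so the peak absolute excursion equals
    ``spec.amplitude``.  The result is periodic with the cycle period after
    the first cycle because the kernel support (32 s) is shorter than the
    60 s default cycle.
    """
    if spec.amplitude == 0:
        return np.zeros(design.n_task_samples)
    dt = design.tr / _UPSAMPLE
    n_fine = design.n_task_samples * _UPSAMPLE
    cycle_fine = design.samples_per_cycle * _UPSAMPLE
    on_fine = design.on_samples * _UPSAMPLE

    u = np.zeros(n_fine)
    one_cycle = np.zeros(cycle_fine)
    if spec.shape in ("sustained", "delayed", "negative"):
        one_cycle[:on_fine] = 1.0
    elif spec.shape == "ramp":
        one_cycle[:on_fine] = np.linspace(0.0, 1.0, on_fine)
    elif spec.shape == "transient_onset_offset":
        # impulses (unit area) at stimulus onset and offset
        one_cycle[0] = 1.0 / dt
        one_cycle[on_fine] = 1.0 / dt
    u[:] = np.tile(one_cycle, design.n_blocks)

    kernel = _double_gamma_kernel(spec.hrf_params, dt)
    y = np.convolve(u, kernel)[:n_fine] * dt

    delay = spec.delay
    if spec.shape == "delayed" and delay == 0.0:
        delay = 6.0
    if delay > 0:
        shift = int(round(delay / dt))
        y = np.concatenate([np.zeros(shift), y])[:n_fine]
    if spec.shape == "negative":
        y = -y

    y = y[:: _UPSAMPLE]  # sample at t = k*TR, onset at sample 0
    peak = np.max(np.abs(y))
    if peak == 0:
        return np.zeros(design.n_task_samples)
    return y * (spec.amplitude / peak)


def _condition_code(condition: str) -> int:
    return zlib.crc32(condition.encode("utf-8"))


def _region_voxels(atlas: RegionAtlas, key: int | str) -> np.ndarray:
    """Boolean voxel selector for a responder key (GM label or bundle name)."""
    if isinstance(key, (int, np.integer)):
        sel = atlas.gm_labels == int(key)
        if not sel.any():
            raise ValueError(f"gray-matter label {key} not present in atlas")
    else:
        if key not in atlas.wm_density:
            raise ValueError(f"bundle '{key}' not present in atlas")
        sel = atlas.wm_density[key] > 0
    return sel


def simulate_run(
    scenario: Scenario,
    atlas: RegionAtlas,
    condition: str,
    subject_id: str = "sub-00",
    subject_index: int = 0,
) -> BoldRun:
    """Simulate one subject's run for a task or resting condition.

    Baseline is 100 in-mask; responding regions get ``100*(1+r/100)`` during
    the task samples, where ``r`` is the subject's (jittered) ground-truth
    response; dummy volumes stay at baseline.  Noise is AR(1) Gaussian plus a
    per-voxel linear drift.  Fully reproducible: the noise stream is keyed on
    (scenario seed, subject index, condition) via a counter-based generator.
    """
    if tuple(atlas.shape) != tuple(scenario.grid_shape):
        raise ValueError(
            f"atlas grid {atlas.shape} does not match scenario grid "
            f"{tuple(scenario.grid_shape)}"
        )
    design = scenario.design
    n_t = design.n_total_samples
    shape = atlas.shape
    mask = atlas.brain_mask

    ss = np.random.SeedSequence(
        [int(scenario.seed), int(subject_index), _condition_code(condition)]
    )
    rng = np.random.Generator(np.random.Philox(ss))

    # percent-response field over task samples (after dummies)
    pct = np.zeros(shape + (design.n_task_samples,))
    if condition != RESTING and scenario.responders:
        jitter = 1.0
        if scenario.amplitude_jitter > 0:
            j = scenario.amplitude_jitter
            jitter_rng = np.random.Generator(
                np.random.Philox(
                    np.random.SeedSequence(
                        [int(scenario.seed), int(subject_index), 0x9E77]
                    )
                )
            )
            jitter = 1.0 + jitter_rng.uniform(-j, j)
        for key, spec in scenario.responders.items():
            if spec is None:
                continue
            sel = _region_voxels(atlas, key)
            r = hemodynamic_response(
                replace(spec, amplitude=spec.amplitude * jitter), design
            )
            pct[sel] += r

    data = np.zeros(shape + (n_t,))
    data[mask] = BASELINE
    data[..., design.n_dummy:] *= 1.0 + pct / 100.0
    # re-zero outside mask (multiplication left zeros untouched anyway)

    noise = scenario.noise
    if noise.sigma > 0:
        eps = _ar1_noise(rng, shape, n_t, noise.sigma, noise.ar1)
        if noise.spatial_fwhm_voxels > 0:
            sd = noise.spatial_fwhm_voxels / (2.0 * np.sqrt(2.0 * np.log(2.0)))
            for t in range(n_t):
                eps[..., t] = ndimage.gaussian_filter(eps[..., t], sd)
        data[mask] += eps[mask]
    if noise.drift_amplitude != 0:
        slope = rng.uniform(-1.0, 1.0, size=shape) * noise.drift_amplitude
        ramp = np.linspace(-0.5, 0.5, n_t)
        data[mask] += slope[mask, None] * ramp[None, :]

    return BoldRun(
        data=data,
        design=design,
        subject_id=subject_id,
        condition=condition,
        affine=atlas.affine,
    )


def _ar1_noise(
    rng: np.random.Generator,
    shape: tuple[int, int, int],
    n_t: int,
    sigma: float,
    ar1: float,
) -> np.ndarray:
    """Stationary AR(1) noise, marginal std ``sigma``, independent per voxel."""
    innov_sd = sigma * np.sqrt(1.0 - ar1**2)
    eps = np.empty(shape + (n_t,))
    eps[..., 0] = rng.normal(0.0, sigma, size=shape)
    for t in range(1, n_t):
        eps[..., t] = ar1 * eps[..., t - 1] + rng.normal(
            0.0, innov_sd, size=shape
        )
    return eps


def simulate_cohort(
    scenario: Scenario,
    atlas: RegionAtlas,
    condition: str,
    n_subjects: int,
) -> list[BoldRun]:
    """Simulate one run per subject; subject ids are ``sub-00 ... sub-NN``."""
    return [
        simulate_run(scenario, atlas, condition,
                     subject_id=f"sub-{i:02d}", subject_index=i)
        for i in range(n_subjects)
    ]
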