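import numpy as np
import pytest

from timelock import (
    BoldRun,
    NoiseSpec,
    RegionAtlas,
    ResponseSpec,
    Scenario,
    TaskDesign,
    make_atlas_fixture,
)


@pytest.fixture(scope="session")
def design():
    """Default block design: 7 cycles of 30s on / 30s off, 5 dummies, TR 3s."""
    return TaskDesign(30.0, 30.0, 7, 5, 3.0)


@pytest.fixture(scope="session")
def short_design():
    """One-cycle design for cheap tests: 4 task samples, no dummies."""
    return TaskDesign(6.0, 6.0, 1, 0, 3.0)


@pytest.fixture(scope="session")
def atlas20():
    """Desk-scale atlas: 8 GM labels + 4 bundles on a 20^3 grid."""
    return make_atlas_fixture((20, 20, 20), 8, 4, seed=7)


@pytest.fixture()
def tiny_atlas():
    """Hand-built 6^3 atlas: full mask, two GM labels, two density maps."""
    shape = (6, 6, 6)
    gm = np.zeros(shape, dtype=np.int32)
    gm[0, 0, 0] = 1
    gm[1, 0:2, 0] = 2
    density_a = np.zeros(shape)
    density_a[3, 3, 3] = 2.0
    density_a[3, 3, 4] = 1.0
    density_b = np.zeros(shape)
    density_b[4, 1:4, 2] = 1.0  # uniform
    return RegionAtlas(
        gm_labels=gm,
        wm_density={"tract_a": density_a, "tract_b": density_b},
        brain_mask=np.ones(shape, dtype=bool),
    )


def make_run(data, design, condition="task", subject_id="sub-00"):
    return BoldRun(data=np.asarray(data, dtype=float), design=design,
                   subject_id=subject_id, condition=condition)


@pytest.fixture()
def random_run(design):
    """145-volume random task run on the tiny 6^3 grid."""
    rng = np.random.default_rng(42)
    data = 100.0 + rng.normal(size=(6, 6, 6, design.n_total_samples))
    return make_run(data, design)


def resting_scenario(grid, seed, sigma=1.0, ar1=0.3, design=None):
    design = design or TaskDesign(30.0, 30.0, 7, 5, 3.0)
    return Scenario(grid_shape=grid, design=design, responders={},
                    noise=NoiseSpec(sigma=sigma, ar1=ar1), seed=seed)


def responder_scenario(grid, seed, responders, sigma=1.0, ar1=0.3,
                       jitter=0.2, design=None):
    design = design or TaskDesign(30.0, 30.0, 7, 5, 3.0)
    specs = {k: (v if isinstance(v, ResponseSpec) else ResponseSpec(**v))
             for k, v in responders.items()}
    return Scenario(grid_shape=grid, design=design, responders=specs,
                    noise=NoiseSpec(sigma=sigma, ar1=ar1), seed=seed,
                    amplitude_jitter=jitter)
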