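import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import knockscope as ks

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def scene():
    """One default synthetic metaphase cell (movie preset)."""
    return ks.generate_scene(seed=11)


@pytest.fixture(scope="session")
def noiseless_scene():
    return ks.generate_scene(seed=11, noise_sd=0.0, bleach_rate=0.0)


@pytest.fixture(scope="session")
def movie(scene):
    return ks.render_timelapse(scene, [0.0, 12.0])


@pytest.fixture(scope="session")
def rois(scene):
    return ks.place_rois(scene, seed=5)


@pytest.fixture(scope="session")
def knocksideways_pipeline():
    """The full single-movie pipeline as a callable fixture."""
    return run_knocksideways_pipeline


def run_knocksideways_pipeline(seed, *, coupling=1.0, noise_sd=3.0,
                               bleach_rate=0.02, phi_max=0.95, tau=2.0,
                               times=(0.0, 12.0)):
    """Full measurement on one synthetic movie: scene → render → ROIs →
    registration + quantification → arrow records keyed by channel role."""
    scene = ks.generate_scene(
        seed=seed, coupling=coupling, noise_sd=noise_sd,
        bleach_rate=bleach_rate, phi_max=phi_max, tau=tau,
    )
    movie = ks.render_timelapse(scene, list(times))
    rois = ks.place_rois(scene, seed=seed + 10_000)
    measured = ks.measure_cell(movie, rois, cell_id=f"cell{seed}")
    records = ks.relocalization.arrow_records_from_measurements(measured)
    return scene, records
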