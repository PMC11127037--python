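import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from eegrsa.synth import (  # noqa: E402
    GeometrySchedule,
    GeometryWindow,
    SimulationConfig,
    gen_catalog,
    gen_epochs,
    random_patterns,
)


@pytest.fixture(scope="session")
def default_catalog():
    """The full 49-stimulus catalog (24 faces, 25 non-faces)."""
    return gen_catalog()


@pytest.fixture(scope="session")
def tiny_catalog():
    """8 stimuli: 3 faces + 2 objects + 3 scenes."""
    return gen_catalog(n_faces=3, n_nonfaces_per_category={"object": 2, "scene": 3}, seed=0)


def two_window_config(catalog, seed=0, noise_sd=1.0, gain=0.5, persistence_ms=0.0,
                      early=(60.0, 160.0), late=(300.0, 480.0), n_trials=30,
                      n_channels=10, sampling_rate=100.0, epoch_window=(-100.0, 500.0),
                      n_latent=6, late_gain=None):
    """Reusable two-window simulation recipe for decoding/TGM tests."""
    p1 = random_patterns(catalog.n_stimuli, n_latent, seed=seed * 101 + 1)
    p2 = random_patterns(catalog.n_stimuli, n_latent, seed=seed * 101 + 2)
    sched = GeometrySchedule(
        windows=[GeometryWindow(*early, pattern=p1, gain=gain),
                 GeometryWindow(*late, pattern=p2, gain=gain if late_gain is None else late_gain)],
        persistence_ms=persistence_ms,
        noise_sd=noise_sd,
    )
    return SimulationConfig(
        catalog=catalog, schedule=sched, n_trials_per_stimulus=n_trials,
        n_channels=n_channels, sampling_rate=sampling_rate,
        epoch_window=epoch_window, seed=seed,
    )


@pytest.fixture(scope="session")
def small_epochs(tiny_catalog):
    """One simulated subject under the two-window geometry (session-cached)."""
    return gen_epochs(two_window_config(tiny_catalog, seed=7))


@pytest.fixture(scope="session")
def noise_epochs(tiny_catalog):
    """Pure-noise epochs (all gains zero): the decoding null."""
    sched = GeometrySchedule(
        windows=[GeometryWindow(0.0, 400.0,
                                pattern=np.zeros((tiny_catalog.n_stimuli, 2)), gain=0.0)],
        noise_sd=1.0,
    )
    cfg = SimulationConfig(
        catalog=tiny_catalog, schedule=sched, n_trials_per_stimulus=24,
        n_channels=8, sampling_rate=64.0, epoch_window=(-100.0, 500.0), seed=11,
    )
    return gen_epochs(cfg)
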