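import numpy as np
import pytest

from handregard import (
    Architecture,
    Geometry,
    LearningConfig,
    Rect,
    StimulusValues,
    build_architecture,
    protocol,
)
from handregard import protocol as protocol_mod  # noqa: F401  (re-export for tests)


@pytest.fixture(scope="session")
def default_net():
    """Default 238-48-8 architecture and its connectivity mask."""
    return build_architecture()


@pytest.fixture(scope="session")
def geom9():
    """Small 9x9 workspace with a one-cell fov center at integer (4, 4)."""
    return Geometry(width=9, height=9, fov=Rect(2, 2, 6, 6),
                    fov_center=Rect(4, 4, 4, 4))


@pytest.fixture(scope="session")
def small_setup(geom9):
    """Fast closed-loop setup: 9x9 world, 125-12-8 network."""
    arch = Architecture(n_input=125, n_hidden_own=6, n_hidden_agency=6,
                        n_output=8)
    arch, mask = build_architecture(arch)
    return {
        "geometry": geom9,
        "arch": arch,
        "mask": mask,
        "stim": StimulusValues(),
        "learn": LearningConfig(),
    }


def make_toy(n_input=3, n_own=1, n_agency=1, n_output=1):
    """Tiny architecture for oracle tests; corollary = the last n_output inputs."""
    arch = Architecture(n_input=n_input, n_hidden_own=n_own,
                        n_hidden_agency=n_agency, n_output=n_output)
    return build_architecture(arch)


@pytest.fixture(scope="session")
def dynamics_runs():
    """Five scaled-down training runs (10^4 steps each, default conditions).

    Shared across the acceptance tests of the early learning dynamics; this
    is the expensive fixture of the suite (a few minutes).
    """
    geometry = Geometry()
    stim = StimulusValues()
    learn = LearningConfig()
    arch, mask = build_architecture()
    runs = [
        protocol.train(geometry, stim, learn, seed=seed, n_steps=10_000,
                       checkpoint_interval=10_000, arch=arch, mask=mask)
        for seed in range(5)
    ]
    return {"runs": runs, "arch": arch, "mask": mask, "geometry": geometry}
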