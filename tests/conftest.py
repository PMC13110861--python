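"""Shared fixtures: one small mixed system and its default archive."""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mdcz import CompressionParams, GenSpec, compress_frames, gen_system

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


SMALL_SPEC = GenSpec(n_chain_atoms=120, n_waters=30, n_ions=5, n_frames=45, seed=3)


@pytest.fixture(scope="session")
def small_system():
    """(TopologyLite, frames) with MOL + WAT + OTH segments, 45 frames."""
    return gen_system(SMALL_SPEC)


@pytest.fixture(scope="session")
def small_archive(small_system, tmp_path_factory):
    """Default-parameter archive of the small system, with its summary."""
    topo, frames = small_system
    path = tmp_path_factory.mktemp("archive") / "small.mdcz"
    summary = compress_frames(topo, frames, path, CompressionParams())
    return path, summary


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
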