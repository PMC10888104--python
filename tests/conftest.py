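"""Shared fixtures: scaled-down phantom configurations and rendered series.

The small geometry (240 x 300 px at 0.04 mm/px) keeps the same physical
layout as the default study conditions but renders ~4x faster; the
acceptance tests use the full-size defaults.
"""

from __future__ import annotations

import numpy as np
import pytest

from bruise_evolve.config import PhantomConfig, RunConfig
from bruise_evolve.phantom import render_series
from bruise_evolve.pipeline import run_phantom_series

SMALL_GEOMETRY = dict(
    image_width_px=240,
    image_height_px=300,
    pixel_scale=0.04,
    skin_row=20,
)

CLEAN = dict(noise_sd=0.0, speckle_density_rate=0.0, edge_artifact_width=0.0)


def small_config(seed: int = 11, **overrides) -> PhantomConfig:
    kwargs = dict(SMALL_GEOMETRY)
    kwargs.update(overrides)
    return PhantomConfig(seed=seed, **kwargs)


@pytest.fixture(scope="session")
def small_series():
    """Default-noise small phantom with speckle and edge artifacts."""
    return render_series(small_config(seed=11))


@pytest.fixture(scope="session")
def small_noiseless_series():
    """Noise-free small phantom, speckle and edge artifacts still present."""
    return render_series(small_config(seed=12, noise_sd=0.0))


@pytest.fixture(scope="session")
def small_clean_series():
    """Degenerate render: no noise, no speckle, no edge artifacts."""
    return render_series(small_config(seed=13, **CLEAN))


@pytest.fixture(scope="session")
def small_run():
    """Full pipeline (extract + measure) on the default-noise small phantom."""
    return run_phantom_series(small_config(seed=11))


@pytest.fixture(scope="session")
def default_run():
    """Full pipeline on one full-size default-condition phantom."""
    return run_phantom_series(PhantomConfig(seed=2))


@pytest.fixture(scope="session")
def full_noiseless_series():
    """Full-size default geometry without sensor noise (speckle and edge
    bands still present)."""
    return render_series(PhantomConfig(seed=5, noise_sd=0.0))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240602)


@pytest.fixture()
def tiny_run_config(tmp_path):
    """Fast RunConfig for pipeline/CLI tests."""
    return RunConfig(
        scenarios=["upper"],
        seeds=[3],
        out_dir=str(tmp_path / "run"),
        pixel_scale=0.04,
        phantom_overrides=dict(SMALL_GEOMETRY, n_frames=12),
    )
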