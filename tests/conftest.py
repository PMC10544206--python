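"""Shared fixtures: all test data is generated programmatically."""

from __future__ import annotations

import numpy as np
import pytest

from pulmovasc.synthdata import (
    SynthParams,
    generate_vessel_tree,
    preset_params,
    rasterize_tree,
    render_projection,
)

#: generator settings with every noise source off: geometry-only volumes
NOISE_FREE = dict(background_level=0.0, shot_noise_scale=0.0, gaussian_noise_sd=0.0)


@pytest.fixture(scope="session")
def hx_scene():
    """One chronic-hypoxia lung: params, tree, EC volume (with noise)."""
    params = preset_params("hx", seed=11)
    tree = generate_vessel_tree(params)
    volume = rasterize_tree(tree, params, "EC")
    return params, tree, volume


@pytest.fixture(scope="session")
def preset_renders():
    """Paired maximum-intensity renders of the three experimental arms grown
    from the same underlying baseline tree (seed 1)."""
    out = {}
    for name in ("normoxia", "suhx", "hx"):
        params = preset_params(name, seed=1)
        volume = rasterize_tree(generate_vessel_tree(params), params, "EC")
        out[name] = render_projection(volume)
    return out


@pytest.fixture(scope="session")
def clean_tube_params():
    """Small isotropic grid for axis-aligned phantom tubes."""
    return SynthParams(
        seed=0,
        volume_shape=(120, 41, 41),
        spacing=(2.0, 2.0, 2.0),
        **NOISE_FREE,
    )


def make_zero_noise(name: str, seed: int, **overrides) -> SynthParams:
    return preset_params(name, seed=seed, **{**NOISE_FREE, **overrides})
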