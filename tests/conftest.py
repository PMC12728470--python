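"""Shared fixtures: small, fast synthetic inputs for unit tests."""

import pytest

from tboscreen.synthetic import PhantomSpec, SyntheticCellSpec


@pytest.fixture
def tiny_spec() -> PhantomSpec:
    """Small phantom for fast unit tests (a few thousand organoid voxels)."""
    return PhantomSpec(
        n_planes=9,
        plane_shape=(32, 32),
        organoid_radius=12.0,
        n_tumor_foci=2,
        tumor_fraction=0.10,
        noise_sd=0.0,
        seed=0,
    )


@pytest.fixture
def tiny_noisy_spec(tiny_spec) -> PhantomSpec:
    from dataclasses import replace

    return replace(tiny_spec, noise_sd=10.0, seed=1)


@pytest.fixture
def small_cell_spec() -> SyntheticCellSpec:
    """Reduced cell numbers; full default state/cycling structure."""
    return SyntheticCellSpec(n_cells_per_condition=120, seed=0)
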