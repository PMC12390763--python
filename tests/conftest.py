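import numpy as np
import pytest

from stdeconv import (
    ReferenceSpec,
    SpotSimSpec,
    generate_reference,
    simulate_spots,
)


@pytest.fixture(scope="session")
def small_ref():
    """Compact 3-type reference for unit tests."""
    return generate_reference(
        ReferenceSpec(
            n_types=3, n_genes=60, cells_per_type=40, n_markers_per_type=5, seed=11
        )
    )


@pytest.fixture(scope="session")
def small_sim(small_ref):
    """150 pseudo-spots simulated from the compact reference."""
    spec = SpotSimSpec(n_spots=150, n_spatial_clusters=3, seed=7)
    ds, props, log = simulate_spots(small_ref, spec)
    return ds, props, log, spec


@pytest.fixture(scope="session")
def recovery_ref():
    """The default synthetic study reference: 4 types, 120 genes, strong markers."""
    return generate_reference(
        ReferenceSpec(
            n_types=4,
            n_genes=120,
            cells_per_type=100,
            n_markers_per_type=10,
            base_mean=2.0,
            marker_fold=5.0,
            seed=1,
        )
    )


@pytest.fixture(scope="session")
def recovery_sim(recovery_ref):
    """600 pseudo-spots with high spatial correlation (few clusters, small jitter)."""
    spec = SpotSimSpec(n_spots=600, n_spatial_clusters=4, jitter_sd=3.0, seed=1)
    ds, props, log = simulate_spots(recovery_ref, spec)
    return ds, props, log, spec


@pytest.fixture
def rng():
    return np.random.default_rng(0)
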