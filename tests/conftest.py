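from __future__ import annotations

import numpy as np
import pytest

from amplikit.fixtures import ErrorModel, build_mock_community, simulate_run


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def community():
    """Three genes, ~15% divergent, clean primer sites."""
    return build_mock_community(
        n_genes=3, length=321, divergence=0.15, seed=11
    )


@pytest.fixture(scope="session")
def clean_run(community):
    """Error-free simulated reads plus truth."""
    reads, truths = simulate_run(
        community, 120, ErrorModel(), seed=7
    )
    return reads, truths
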