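"""Shared fixtures: one moderate synthetic dataset reused across modules."""

from __future__ import annotations

import numpy as np
import pytest

from bloodtraits.synthetic_data import SimConfig, simulate_all


@pytest.fixture(scope="session")
def default_bundle():
    """Trial-sized herd (61 animals) with a small gene panel."""
    cfg = SimConfig(seed=1, n_genes=3000, n_planted=20)
    return cfg, simulate_all(cfg)


@pytest.fixture(scope="session")
def herd_meta(default_bundle):
    return default_bundle[1]["meta"]


@pytest.fixture()
def rng():
    return np.random.default_rng(20260921)
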