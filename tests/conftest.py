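from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from dnasekit.align import Alignment
from dnasekit.hmm import build_profile
from dnasekit.synthetic import SimConfig, build_synthetic_profiles, default_tree, simulate_history

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")

BUNDLE_SEED = 11


@pytest.fixture(scope="session")
def bundle():
    """Calibrated synthetic profiles for all ten orthogroups (expensive;
    built once per session)."""
    return build_synthetic_profiles(BUNDLE_SEED)


@pytest.fixture(scope="session")
def chordate_tree():
    return default_tree()


@pytest.fixture(scope="session")
def sim_truth(chordate_tree):
    cfg = SimConfig(seed=BUNDLE_SEED)
    return cfg, simulate_history(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


@pytest.fixture(scope="session")
def toy_profile():
    """Tiny 5-match-state profile over a reduced A/C/G/T residue set."""
    rows = [
        ("s1", "ACGTA"),
        ("s2", "ACGTA"),
        ("s3", "ACTTA"),
        ("s4", "ACGCA"),
    ]
    return build_profile(Alignment(rows=rows), "toy")
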