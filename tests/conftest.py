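"""Shared fixtures: benchmark trial indices and canonical chaotic series."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from pcm import PartialCrossMapping, sample_trials, simulate_three_species
from pcm._rng import child_seed

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")

#: protocol seed for all benchmark fixtures
PROTOCOL_SEED = 0

#: trial count for the benchmark protocol (reduced from the headline 100)
N_TRIALS = 30


def logistic_orbit(n: int, r: float = 3.99, x0: float = 0.37) -> np.ndarray:
    """A chaotic logistic-map orbit, the canonical 1-D test signal."""
    x = np.empty(n)
    x[0] = x0
    for t in range(1, n):
        x[t] = r * x[t - 1] * (1.0 - x[t - 1])
    return x


def benchmark_pair_indices(mode: str, n_trials: int = N_TRIALS) -> pd.DataFrame:
    """rho_C / rho_D for the X -> Y pair over the trial protocol."""
    data, _ = simulate_three_species(
        mode, seed=child_seed(PROTOCOL_SEED, 1, hash_mode(mode))
    )
    segments = sample_trials(
        data, n_trials=n_trials, segment_length=1000,
        seed=child_seed(PROTOCOL_SEED, 2, hash_mode(mode)),
    )
    rows = []
    for seg in segments:
        r = PartialCrossMapping(seg).fit_pair("X", "Y", conditioners=["Z"])
        rows.append({"rho_C": r.rho_C, "rho_D": r.rho_D[1], "decision": r.decision})
    return pd.DataFrame(rows)


def hash_mode(mode: str) -> int:
    return {"direct": 1, "chain": 2, "loop": 3}.get(mode, 9)


@pytest.fixture(scope="session")
def chain_indices() -> pd.DataFrame:
    return benchmark_pair_indices("chain")


@pytest.fixture(scope="session")
def loop_indices() -> pd.DataFrame:
    return benchmark_pair_indices("loop")


@pytest.fixture(scope="session")
def direct_indices() -> pd.DataFrame:
    return benchmark_pair_indices("direct")


@pytest.fixture(scope="session")
def chain_segment() -> pd.DataFrame:
    """One length-1000 segment of a chain-mode benchmark run."""
    data, _ = simulate_three_species("chain", seed=child_seed(PROTOCOL_SEED, 3))
    return sample_trials(data, 1, 1000, seed=child_seed(PROTOCOL_SEED, 4))[0]
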