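"""Seed fan-out.

A single user-facing integer seed is expanded into independent child
generators through :class:`numpy.random.SeedSequence` keyed by integer
stage/trial indices.  The derivation is fixed, so adding more trials or
stages never perturbs the streams of earlier ones.
"""

from __future__ import annotations

import numpy as np

__all__ = ["child_rng", "child_seed"]


def child_rng(seed: int, *key: int) -> np.random.Generator:
    """Generator for stage ``key`` of the run seeded with ``seed``."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), *map(int, key)]))


def child_seed(seed: int, *key: int) -> int:
    """A derived integer seed (< 2**31) for APIs that want a plain int."""
    return int(np.random.SeedSequence([int(seed), *map(int, key)]).generate_state(1)[0] % (2**31))
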