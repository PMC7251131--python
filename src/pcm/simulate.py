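"""Coupled noisy logistic-map benchmark generators with ground truth.

The workhorse is the n-node coupled logistic network

    x^j_t = x^j_{t-1} (alpha_j - alpha_j x^j_{t-1} - sum_i beta_ji x^i_{t-1}) + eps_j,t

with independent Gaussian noise per node per step.  ``beta[j, i]`` is the
strength of node i's influence on node j, so the ground-truth causal edge
``i -> j`` exists iff ``beta[j, i] != 0`` — the truth graph is always
derived from the coupling matrix, never stored separately.

The three-species system (growth rates 3.6 / 3.72 / 3.68, noise standard
deviation 0.005) comes in three preset interaction modes:

* ``direct``:  X -> Y                 (beta_yx active)
* ``chain``:   X -> Z -> Y            (beta_zx, beta_yz active)
* ``loop``:    X -> Z -> Y -> X       (beta_zx, beta_yz, beta_xy active)

A noise-free causal-chain variant (X autonomous, X -> Z -> Y) is provided
for transitivity demonstrations, along with a documented synthetic 8-node
sparse network (ring plus chords) for network-scale experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._rng import child_rng
from .errors import DivergenceError

__all__ = [
    "LogisticNetworkParams",
    "three_species_params",
    "eight_node_params",
    "simulate_network",
    "simulate_three_species",
    "simulate_chain_noise_free",
    "sample_trials",
    "THREE_SPECIES_ALPHA",
    "DEFAULT_NOISE_SD",
    "DEFAULT_COUPLING",
]

#: Growth rates of the three-species benchmark (X, Y, Z).
THREE_SPECIES_ALPHA: tuple[float, float, float] = (3.6, 3.72, 3.68)

#: Standard deviation of the per-step dynamical noise.
DEFAULT_NOISE_SD: float = 0.005

#: Default magnitude for every active coupling beta.
DEFAULT_COUPLING: float = 0.4

# Trajectories must stay inside this band; leaving it means divergence.
_GUARD_LO, _GUARD_HI = -0.5, 1.5


@dataclass(frozen=True)
class LogisticNetworkParams:
    """Parameters of the coupled logistic network.

    ``beta[j, i]`` couples node i into node j's equation (edge i -> j).
    ``x0 = None`` draws the initial state uniformly from (0.2, 0.8).
    """

    alpha: np.ndarray
    beta: np.ndarray
    noise_sd: float = DEFAULT_NOISE_SD
    x0: np.ndarray | None = None
    burn_in: int = 1000
    length: int = 5000
    names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        alpha = np.asarray(self.alpha, dtype=float)
        beta = np.asarray(self.beta, dtype=float)
        n = alpha.size
        if beta.shape != (n, n):
            raise ValueError(f"beta must be {n}x{n} to match alpha")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        names = self.names or tuple(f"V{i+1}" for i in range(n))
        if len(names) != n:
            raise ValueError("names must match the number of nodes")
        object.__setattr__(self, "alpha", alpha)
        object.__setattr__(self, "beta", beta)
        object.__setattr__(self, "names", tuple(names))
        if self.x0 is not None:
            x0 = np.asarray(self.x0, dtype=float)
            if x0.shape != (n,) or np.any(x0 <= 0) or np.any(x0 >= 1):
                raise ValueError("x0 must lie in (0,1)^n")
            object.__setattr__(self, "x0", x0)

    @property
    def n_nodes(self) -> int:
        return self.alpha.size

    def truth_edges(self) -> list[tuple[str, str]]:
        """Ground-truth directed edges (source, target), from beta."""
        edges = []
        for j in range(self.n_nodes):
            for i in range(self.n_nodes):
                if i != j and self.beta[j, i] != 0.0:
                    edges.append((self.names[i], self.names[j]))
        return sorted(edges)


def three_species_params(
    mode: str = "chain",
    coupling: float = DEFAULT_COUPLING,
    noise_sd: float = DEFAULT_NOISE_SD,
    length: int = 5000,
    burn_in: int = 1000,
    beta: np.ndarray | None = None,
) -> LogisticNetworkParams:
    """Preset parameters for the three-species benchmark.

    Node order is (X, Y, Z).  Besides the three headline modes
    (``direct``, ``chain``, ``loop``) the common network motifs
    ``fan_in`` (X -> Y <- Z), ``fan_out`` (X <- Z -> Y) and ``cascade``
    (chain plus the direct shortcut X -> Y) are provided for structure
    -recovery studies.  ``mode='custom'`` requires an explicit 3x3
    ``beta`` matrix.
    """
    names = ("X", "Y", "Z")
    X, Y, Z = 0, 1, 2
    b = np.zeros((3, 3))
    if mode == "direct":
        b[Y, X] = coupling
    elif mode == "chain":
        b[Z, X] = coupling
        b[Y, Z] = coupling
    elif mode == "loop":
        b[Z, X] = coupling
        b[Y, Z] = coupling
        b[X, Y] = coupling
    elif mode == "fan_in":
        b[Y, X] = coupling
        b[Y, Z] = coupling
    elif mode == "fan_out":
        b[X, Z] = coupling
        b[Y, Z] = coupling
    elif mode == "cascade":
        b[Z, X] = coupling
        b[Y, Z] = coupling
        b[Y, X] = coupling
    elif mode == "custom":
        if beta is None:
            raise ValueError("mode='custom' requires an explicit beta matrix")
        b = np.asarray(beta, dtype=float)
    else:
        raise ValueError(f"unknown mode {mode!r}; expected direct/chain/loop/custom")
    return LogisticNetworkParams(
        alpha=np.array(THREE_SPECIES_ALPHA),
        beta=b,
        noise_sd=noise_sd,
        length=length,
        burn_in=burn_in,
        names=names,
    )


def eight_node_params(
    coupling: float = 0.2,
    noise_sd: float = DEFAULT_NOISE_SD,
    length: int = 5000,
    burn_in: int = 1000,
) -> LogisticNetworkParams:
    """A synthetic sparse 8-node network: a directed ring plus two chords.

    Ten edges in total: 1->2->...->8->1 and the chords 1->5, 3->7.  This
    stands in for a network-scale benchmark topology; growth rates are
    spread over the chaotic band [3.55, 3.72].
    """
    n = 8
    alpha = np.linspace(3.55, 3.72, n)
    beta = np.zeros((n, n))
    for i in range(n):
        beta[(i + 1) % n, i] = coupling
    beta[4, 0] = coupling  # 1 -> 5
    beta[6, 2] = coupling  # 3 -> 7
    return LogisticNetworkParams(
        alpha=alpha,
        beta=beta,
        noise_sd=noise_sd,
        length=length,
        burn_in=burn_in,
        names=tuple(f"N{i+1}" for i in range(n)),
    )


def simulate_network(
    params: LogisticNetworkParams, seed: int = 0
) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """Iterate the coupled logistic network; return (series, truth edges).

    The returned DataFrame has one column per node, ``params.length`` rows
    (the burn-in is discarded), and a default RangeIndex.  Divergence —
    any state leaving the guard band (-0.5, 1.5) or turning non-finite —
    raises :class:`DivergenceError` naming the step.
    """
    rng = child_rng(seed, 0)
    n = params.n_nodes
    x = params.x0 if params.x0 is not None else rng.uniform(0.2, 0.8, n)
    x = np.array(x, dtype=float)
    total = params.burn_in + params.length
    out = np.empty((params.length, n))
    for t in range(total):
        drive = params.beta @ x
        x_new = x * (params.alpha - params.alpha * x - drive)
        if params.noise_sd > 0:
            x_new = x_new + rng.normal(0.0, params.noise_sd, n)
        if not np.all(np.isfinite(x_new)) or np.any(x_new <= _GUARD_LO) or np.any(
            x_new >= _GUARD_HI
        ):
            raise DivergenceError(
                f"trajectory left the admissible band at step {t + 1} "
                f"(state {np.array2string(x_new, precision=3)})"
            )
        x = x_new
        if t >= params.burn_in:
            out[t - params.burn_in] = x
    return pd.DataFrame(out, columns=list(params.names)), params.truth_edges()


def simulate_three_species(
    mode: str = "chain",
    params: LogisticNetworkParams | None = None,
    seed: int = 0,
    **preset_kwargs,
) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """Three-species benchmark in a preset interaction mode.

    Equivalent to :func:`simulate_network` on :func:`three_species_params`;
    with ``params`` given, ``mode`` and ``preset_kwargs`` are ignored.
    """
    p = params if params is not None else three_species_params(mode, **preset_kwargs)
    if p.n_nodes != 3:
        raise ValueError("three-species benchmark requires exactly 3 nodes")
    return simulate_network(p, seed=seed)


def simulate_chain_noise_free(
    coupling: float = DEFAULT_COUPLING,
    length: int = 5000,
    burn_in: int = 1000,
    x0: np.ndarray | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """Deterministic causal chain X -> Z -> Y (no dynamical noise).

    X iterates autonomously, Z is driven by X, and Y by Z.  The seed only
    fixes the initial state when ``x0`` is not supplied; the dynamics are
    fully deterministic.
    """
    p = replace(
        three_species_params("chain", coupling=coupling, length=length, burn_in=burn_in),
        noise_sd=0.0,
        x0=x0,
    )
    return simulate_network(p, seed=seed)


def sample_trials(
    data: pd.DataFrame, n_trials: int = 100, segment_length: int = 1000, seed: int = 0
) -> list[pd.DataFrame]:
    """Random aligned segments, the trial protocol of the benchmarks.

    Each trial uses one uniformly drawn start offset shared by all
    variables; offsets are seeded and reproducible.
    """
    L = len(data)
    if segment_length > L:
        raise ValueError(f"segment_length {segment_length} exceeds series length {L}")
    rng = child_rng(seed, 1)
    offsets = rng.integers(0, L - segment_length + 1, size=n_trials)
    return [data.iloc[o : o + segment_length].reset_index(drop=True) for o in offsets]
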