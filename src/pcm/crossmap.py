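"""Mutual cross mapping (MCM) with simplex weighting and delay scanning.

Cross mapping quantifies causation in non-separable dynamical systems: if
``U`` drives ``V``, the history of ``V`` encodes the states of ``U``, so
the neighbourhood geometry of V's shadow manifold can *estimate* ``U``.
For each time ``t`` the ``k = E_v + 1`` nearest neighbours of ``v_t`` in
M_V (the minimum number of points spanning a bounded simplex in E_v
dimensions) are located, mapped to the same-time points of M_U, and
averaged with distance-decaying weights to give the estimate ``u_hat_t``.
The causal index is ``rho_C = |Corr(u_t, u_hat_t)|`` over the common
support.

Because causal influence is transmitted with a delay in discrete-time
systems, the strongest cross map is searched over translated copies
``V_tau = {v_{t+tau}}`` of the putative effect; the reported index is the
maximum over the candidate delays.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .embedding import EmbeddingSpec, ShadowManifold, TimeSeries, delay_embed
from .errors import SupportError, UndefinedCorrelationError

__all__ = [
    "NeighborSet",
    "CrossMapResult",
    "neighbors",
    "simplex_weights",
    "cross_map",
    "cross_map_delay_scan",
    "DEFAULT_DELAYS",
]

#: Candidate delays scanned by default (symmetric around 0).
DEFAULT_DELAYS: tuple[int, ...] = tuple(range(-5, 6))

#: Minimum overlap (time points) on which a correlation is trusted.
MIN_SUPPORT = 20


@dataclass(frozen=True)
class NeighborSet:
    """Nearest neighbours of one manifold point.

    Distances are Euclidean and sorted ascending; ties are broken toward
    the smaller time index.  The query time itself and any time within the
    exclusion window never appear.
    """

    query_time: int
    neighbor_times: np.ndarray
    distances: np.ndarray


@dataclass(frozen=True)
class CrossMapResult:
    """Outcome of (delay-scanned) cross mapping of ``U`` from ``V``.

    ``estimate`` is the series ``u_hat_t`` on its support; ``rho`` is the
    absolute Pearson correlation with the true ``u_t`` there, equal to the
    maximum of ``rho_by_delay``.
    """

    estimate: TimeSeries
    rho: float
    rho_by_delay: dict[int, float]
    best_delay: int
    support: np.ndarray


def neighbors(manifold: ShadowManifold, t: int, k: int, exclusion: int = 0) -> NeighborSet:
    """The ``k`` nearest manifold points to the row at time ``t``.

    Rows with ``|t - t'| <= exclusion`` (including the query itself) are
    barred — the Theiler window guarding against trivially autocorrelated
    matches.
    """
    pos = np.flatnonzero(manifold.times == t)
    if pos.size != 1:
        raise ValueError(f"time {t} is not a row of the manifold")
    q = manifold.points[pos[0]]
    eligible = np.abs(manifold.times - t) > exclusion
    if eligible.sum() < k:
        raise SupportError(
            f"only {int(eligible.sum())} eligible points for {k} neighbours "
            f"(exclusion window {exclusion})"
        )
    d = np.linalg.norm(manifold.points[eligible] - q, axis=1)
    times = manifold.times[eligible]
    order = np.lexsort((times, d))[:k]
    return NeighborSet(query_time=int(t), neighbor_times=times[order], distances=d[order])


def simplex_weights(distances: np.ndarray) -> np.ndarray:
    """Exponential simplex weights ``w_i ∝ exp(-d_i / d_min)``.

    ``d_min`` is the smallest *nonzero* distance.  If any distance is
    exactly zero the weight mass is spread uniformly over the zero-distance
    entries only (an exact state match is a perfect predictor).  Weights
    are non-negative, sum to one, and are non-increasing in distance.
    """
    d = np.asarray(distances, dtype=float)
    if d.size < 1:
        raise ValueError("at least one distance is required")
    if np.any(d < 0):
        raise ValueError("distances must be non-negative")
    zero = d == 0.0
    if zero.any():
        w = zero.astype(float)
    else:
        with np.errstate(over="ignore"):  # d/d_min may overflow for denormal d_min
            w = np.exp(-d / d.min())
    return w / w.sum()


def _pearson_abs(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = np.std(a), np.std(b)
    if sa == 0.0 or sb == 0.0:
        raise UndefinedCorrelationError(
            "correlation undefined: zero-variance series or estimate"
        )
    r = float(np.corrcoef(a, b)[0, 1])
    return abs(r)


def cross_map(
    u: TimeSeries,
    v: TimeSeries,
    spec_u: EmbeddingSpec,
    spec_v: EmbeddingSpec,
    k: int | None = None,
    exclusion: int = 0,
    min_support: int = MIN_SUPPORT,
) -> CrossMapResult:
    """Estimate ``u`` from the shadow manifold of ``v`` (Procedure A).

    Both series are restricted to their common timeline range, embedded,
    and further restricted to times where both manifolds have rows; the
    estimate and the correlation are computed on that joint support.
    ``k`` defaults to ``E_v + 1``.
    """
    if k is None:
        k = spec_v.dim + 1
    a = max(u.start, v.start)
    b = min(u.end, v.end)
    off = max(spec_u.offset, spec_v.offset)
    n = (b - a) - off
    if n < max(min_support, k + 1):
        raise SupportError(
            f"common support of {u.name!r} and {v.name!r} has {max(n, 0)} points; "
            f"need at least {max(min_support, k + 1)}"
        )
    su = u.window(a, b)
    sv = v.window(a, b)
    mv = delay_embed(sv, spec_v)
    pts = mv.points[len(mv) - n :]  # rows valid in both manifolds
    u_vals = su.values[off:]
    tree = cKDTree(pts)
    kq = min(n, k + 1 + 2 * exclusion)
    dist, idx = tree.query(pts, k=kq)
    rows = np.arange(n)[:, None]
    allowed = np.abs(idx - rows) > exclusion
    masked = np.where(allowed, dist, np.inf)
    order = np.argsort(masked, axis=1, kind="stable")[:, :k]
    nb_d = np.take_along_axis(masked, order, axis=1)
    nb_idx = np.take_along_axis(idx, order, axis=1)
    short = ~np.isfinite(nb_d[:, -1])
    for i in np.flatnonzero(short):  # exhaustive fallback near window edges
        d_all = np.linalg.norm(pts - pts[i], axis=1)
        ok = np.abs(np.arange(n) - i) > exclusion
        if ok.sum() < k:
            raise SupportError(
                f"exclusion window {exclusion} leaves fewer than {k} neighbours"
            )
        cand = np.flatnonzero(ok)
        o = np.lexsort((cand, d_all[cand]))[:k]
        nb_idx[i], nb_d[i] = cand[o], d_all[cand][o]
    # simplex weights, vectorised: w ∝ exp(-d/d_min); exact matches take all
    zero = nb_d == 0.0
    dmin = np.where(zero, np.inf, nb_d).min(axis=1, keepdims=True)
    w = np.where(
        zero.any(axis=1, keepdims=True), zero.astype(float), np.exp(-nb_d / dmin)
    )
    w /= w.sum(axis=1, keepdims=True)
    est = np.einsum("ij,ij->i", w, u_vals[nb_idx])
    rho = _pearson_abs(u_vals, est)
    support = a + off + np.arange(n)
    estimate = TimeSeries(est, name=f"{u.name}_hat|{v.name}", start=a + off)
    return CrossMapResult(
        estimate=estimate, rho=rho, rho_by_delay={0: rho}, best_delay=0, support=support
    )


def _delay_rank(d: int) -> tuple[int, int]:
    # tie-break: smallest |delay| first, negative preferred on equal |d|
    return (abs(d), 0 if d < 0 else 1)


def cross_map_delay_scan(
    u: TimeSeries,
    v: TimeSeries,
    spec_u: EmbeddingSpec,
    spec_v: EmbeddingSpec,
    delays: tuple[int, ...] = DEFAULT_DELAYS,
    k: int | None = None,
    exclusion: int = 0,
    min_support: int = MIN_SUPPORT,
) -> CrossMapResult:
    """Cross map against every translated ``V_tau`` and keep the best.

    The translated effect series is ``V_tau = {v_{t+tau}}``; ``rho_by_delay``
    records the index at every feasible delay and the returned estimate is
    the one at the argmax (ties resolved toward the smallest ``|tau|``,
    then toward the negative candidate).
    """
    if not delays:
        raise ValueError("delays must be non-empty")
    results: dict[int, CrossMapResult] = {}
    last_err: SupportError | None = None
    for d in delays:
        try:
            results[d] = cross_map(
                u, v.shift(d), spec_u, spec_v, k=k, exclusion=exclusion, min_support=min_support
            )
        except SupportError as e:
            last_err = e
    if not results:
        raise SupportError(
            f"no candidate delay leaves enough common support between "
            f"{u.name!r} and {v.name!r} ({last_err})"
        )
    rho_by_delay = {d: r.rho for d, r in sorted(results.items())}
    best = max(results, key=lambda d: (results[d].rho, -_delay_rank(d)[0], -_delay_rank(d)[1]))
    chosen = results[best]
    return CrossMapResult(
        estimate=chosen.estimate,
        rho=chosen.rho,
        rho_by_delay=rho_by_delay,
        best_delay=best,
        support=chosen.support,
    )
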