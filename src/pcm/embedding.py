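"""Delay-coordinate embedding and automatic parameter selection.

A scalar observable ``{x_t}_{t=1}^{L}`` sampled at unit steps is turned into
a *shadow manifold*: the set of delay vectors

    (x_t, x_{t-tau}, ..., x_{t-(E-1)tau}),    t = 1+(E-1)tau, ..., L,

which, for generic observation functions of a deterministic system, is
diffeomorphic to the system's attractor (Takens/Mañé).  The embedding
dimension ``E`` is chosen by the false-nearest-neighbour (FNN) criterion and
the lag ``tau`` by the first local minimum of the delayed mutual information
(DMI).

Indices reported to users are 1-based, matching the time-series convention
``t = 1..L``; storage is 0-based internally.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import cKDTree

from .errors import DegenerateSeriesError, SeriesTooShortError

__all__ = [
    "TimeSeries",
    "EmbeddingSpec",
    "ShadowManifold",
    "delay_embed",
    "select_dim_fnn",
    "select_lag_dmi",
]


@dataclass(frozen=True)
class TimeSeries:
    """A uniformly sampled scalar series.

    Parameters
    ----------
    values : array-like of float
        The observations; must be finite and non-empty.
    name : str
        Variable label used in results and error messages.
    start : int
        Position of ``values[0]`` on a shared 0-based timeline.  Plain
        series start at 0; cross-map estimate series (which are only
        defined on a sub-range of the original timeline) carry a positive
        offset so that downstream alignment is exact.
    """

    values: np.ndarray
    name: str = ""
    start: int = 0

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size < 1:
            raise ValueError("TimeSeries requires a non-empty 1-D value array")
        if not np.all(np.isfinite(v)):
            raise ValueError(f"series {self.name!r} contains non-finite values")
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return self.values.size

    @property
    def end(self) -> int:
        """One past the last occupied timeline position."""
        return self.start + self.values.size

    def shift(self, delay: int) -> "TimeSeries":
        """The translated series ``{v_{t+delay}}`` on the same timeline."""
        return replace(self, start=self.start - int(delay))

    def window(self, start: int, stop: int) -> "TimeSeries":
        """Restriction to timeline positions ``[start, stop)``."""
        lo, hi = start - self.start, stop - self.start
        if lo < 0 or hi > len(self) or hi <= lo:
            raise ValueError("window outside the series support")
        return TimeSeries(self.values[lo:hi], name=self.name, start=start)


@dataclass(frozen=True)
class EmbeddingSpec:
    """Embedding dimension ``E`` and lag ``tau`` for one variable."""

    dim: int = 4
    lag: int = 1

    def __post_init__(self) -> None:
        if self.dim < 1 or self.lag < 1:
            raise ValueError(f"embedding needs dim >= 1 and lag >= 1, got {self}")

    @property
    def min_length(self) -> int:
        """Shortest series that admits this embedding: 1 + (E-1)*tau."""
        return 1 + (self.dim - 1) * self.lag

    @property
    def offset(self) -> int:
        """Rows consumed at the head of the series: (E-1)*tau."""
        return (self.dim - 1) * self.lag


@dataclass(frozen=True)
class ShadowManifold:
    """Delay-coordinate reconstruction of one series.

    ``points[i]`` is the vector for time ``times[i]`` (0-based timeline
    positions); ``first_valid`` is the 1-based index ``r = 1 + (E-1)*tau``
    of the first reconstructable point within the series.
    """

    points: np.ndarray
    times: np.ndarray
    spec: EmbeddingSpec
    name: str = ""
    first_valid: int = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "first_valid", 1 + self.spec.offset)

    def __len__(self) -> int:
        return self.points.shape[0]


def delay_embed(series: TimeSeries, spec: EmbeddingSpec) -> ShadowManifold:
    """Build the shadow manifold of ``series`` under ``spec``.

    The row for time ``t`` is ``(x_t, x_{t-tau}, ..., x_{t-(E-1)tau})``;
    there are ``L - (E-1)*tau`` rows.
    """
    L = len(series)
    if L < spec.min_length:
        raise SeriesTooShortError(
            f"series {series.name!r} has length {L}; embedding with E={spec.dim}, "
            f"tau={spec.lag} requires length >= {spec.min_length}"
        )
    E, tau, off = spec.dim, spec.lag, spec.offset
    n = L - off
    cols = [series.values[off - j * tau : L - j * tau] for j in range(E)]
    points = np.column_stack(cols)
    times = series.start + np.arange(off, L)
    return ShadowManifold(points=points, times=times, spec=spec, name=series.name)


def _check_varies(series: TimeSeries) -> None:
    if np.ptp(series.values) == 0.0:
        raise DegenerateSeriesError(
            f"series {series.name!r} is constant; embedding parameter selection is undefined"
        )


def select_dim_fnn(
    series: TimeSeries,
    lag: int = 1,
    max_dim: int = 10,
    rtol: float = 10.0,
    atol: float = 2.0,
    frac_threshold: float = 0.01,
) -> int:
    """Smallest embedding dimension by the false-nearest-neighbour test.

    For each candidate ``E`` the nearest neighbour of every point in the
    E-dimensional reconstruction is located; a neighbour is *false* when
    the unfolding coordinate — the next sample ``x_{t+tau}`` beyond the
    reconstruction window, the coordinate gained at E+1 — moves it away by
    more than ``rtol`` times its E-dimensional distance, or when the
    unfolded distance exceeds ``atol`` standard deviations of the series
    (the classical two-part criterion).  The forward-looking unfolding
    coordinate is essential for noninvertible dynamics (a logistic map's
    past is not a function of its present, but its future is).  The first
    ``E`` at which the false fraction drops below ``frac_threshold`` is
    returned; if none qualifies, ``max_dim`` is returned with a warning.
    """
    _check_varies(series)
    if max_dim < 2:
        raise ValueError("max_dim must be >= 2")
    spec_max = EmbeddingSpec(max_dim + 1, lag)
    if len(series) < spec_max.min_length + 1:
        raise SeriesTooShortError(
            f"series {series.name!r} too short for FNN up to E={max_dim} "
            f"(needs length >= {spec_max.min_length + 1})"
        )
    sigma = float(np.std(series.values))
    x = series.values
    L = x.size
    for E in range(1, max_dim + 1):
        m = delay_embed(series, EmbeddingSpec(E, lag))
        # keep rows whose forward unfolding coordinate x_{t+lag} exists
        keep = m.times - series.start <= L - 1 - lag
        pts = m.points[keep]
        idx = np.flatnonzero(keep)
        if pts.shape[0] < 3:
            break
        tree = cKDTree(pts)
        dist, nn = tree.query(pts, k=2)
        d = dist[:, 1]
        nn = nn[:, 1]
        t_self = m.times[idx] - series.start
        t_nn = m.times[idx[nn]] - series.start
        extra = np.abs(x[t_self + lag] - x[t_nn + lag])
        unfolded = np.sqrt(d**2 + extra**2)
        # ratio test with a rounding-noise floor so exact recurrences
        # (periodic orbits) are not flagged on 1e-16-scale distances
        false = (extra > np.maximum(rtol * d, 1e-9 * sigma)) | (unfolded / sigma > atol)
        if false.mean() < frac_threshold:
            return E
    warnings.warn(
        f"FNN fraction never fell below {frac_threshold:.2%} up to E={max_dim}; "
        "returning max_dim",
        stacklevel=2,
    )
    return max_dim


def equiprobable_labels(x: np.ndarray, n_bins: int) -> np.ndarray:
    """Discretise into (at most) ``n_bins`` marginally equiprobable bins."""
    edges = np.quantile(x, np.linspace(0, 1, n_bins + 1))
    return np.digitize(x, np.unique(edges)[1:-1])


def _mi_from_labels(a: np.ndarray, b: np.ndarray) -> float:
    """Mutual information (nats) of two integer label sequences."""
    na, nb = a.max() + 1, b.max() + 1
    joint = np.bincount(a * nb + b, minlength=na * nb).reshape(na, nb).astype(float)
    p = joint / joint.sum()
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    mask = p > 0
    return float(np.sum(p[mask] * np.log(p[mask] / (px @ py)[mask])))


def dmi_curve(series: TimeSeries, max_lag: int) -> np.ndarray:
    """Delayed mutual information at lags ``1..max_lag`` (nats)."""
    _check_varies(series)
    if max_lag < 1:
        raise ValueError("max_lag must be >= 1")
    x = series.values
    L = x.size
    if L <= max_lag + 1:
        raise SeriesTooShortError(f"series of length {L} cannot support max_lag={max_lag}")
    n_bins = int(np.ceil(np.sqrt(L)))
    lab = equiprobable_labels(x, n_bins)
    return np.array([_mi_from_labels(lab[:-k], lab[k:]) for k in range(1, max_lag + 1)])


def select_lag_dmi(series: TimeSeries, max_lag: int = 20) -> int:
    """Lag at the first local minimum of the delayed mutual information.

    Uses the equiprobable-bin histogram estimator with ``ceil(sqrt(L))``
    bins.  When the DMI curve is essentially flat — as for white noise,
    where every lag carries the same (near-zero) information — or when no
    interior local minimum exists, the fallback lag 1 is returned.
    """
    mi = dmi_curve(series, max_lag)
    # Flat-curve guard: fluctuations of the estimator on dependence-free
    # data are small relative to the estimate itself; a genuine DMI decay
    # spans a large fraction of the curve's maximum.
    if mi.max() <= 0 or (mi.max() - mi.min()) < 0.25 * mi.max():
        return 1
    for ell in range(2, max_lag):
        if mi[ell - 1] < mi[ell - 2] and mi[ell - 1] <= mi[ell]:
            return ell
    return 1
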