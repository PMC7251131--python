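"""The partial cross mapping (PCM) estimator.

Plain cross mapping cannot tell a direct causal link X -> Y from an
indirect one routed through a mediator (X -> Z -> Y): causation is
transitive, so Y's manifold encodes X either way.  PCM conditions the
cross-map consensus on the part of the information that flows through the
mediator.  For one ordered pair (X, Y) with conditioner Z the procedure is

1. delay-scan the cross map of Z from translated Y      -> Zhat^Y
2. delay-scan the cross map of X from translated Zhat^Y -> Xhat^{Zhat^Y}
3. delay-scan the cross map of X from translated Y      -> Xhat^Y
4. on the common support,
       rho_C = |Corr(X, Xhat^Y)|                       (pairwise index)
       rho_D = |Pcc (X, Xhat^Y | Xhat^{Zhat^Y})|       (direct index)

With threshold 0 << T < 1 the decision is *direct* when rho_D >= T,
*indirect* when rho_C >= T > rho_D, and *none* when rho_C < T.  With
several conditioners Z^1..Z^s the first-order index conditions jointly on
all s nested estimates; order-n indices condition on estimates routed
through every ordered chain of n distinct mediators, and the proximity
ratio gamma = (prod_n rho_Dn) / rho_C^s summarises how close the
conditioned indices stay to the pairwise one.

The module is organised around a model object, :class:`PartialCrossMapping`,
built from a DataFrame of aligned series; ``fit_pair`` returns a
:class:`PcmPairResult` and ``fit`` a :class:`PcmNetworkResult` covering
every ordered pair.  ``pcm_pair`` / ``infer_network`` are thin functional
wrappers over the same machinery.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from itertools import permutations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._rng import child_rng
from .crossmap import DEFAULT_DELAYS, CrossMapResult, cross_map_delay_scan
from .embedding import EmbeddingSpec, TimeSeries, select_dim_fnn, select_lag_dmi
from .errors import (
    CombinatorialBudgetError,
    PcmError,
    SupportError,
)
from .parcorr import corr, partial_corr

__all__ = [
    "PcmConfig",
    "PcmPairResult",
    "PcmNetworkResult",
    "PartialCrossMapping",
    "classify_link",
    "gamma_index",
    "pcm_pair",
    "pcm_higher_order",
    "infer_network",
    "surrogate_test",
]

logger = logging.getLogger("pcm")

_STRATEGIES = ("all", "top_score", "sparse_min")


@dataclass(frozen=True)
class PcmConfig:
    """Tunable parameters of a PCM run.

    ``embedding`` may be a single :class:`EmbeddingSpec` applied to every
    variable, a mapping from variable name to spec, or the string
    ``"auto"`` to select the lag by delayed mutual information and the
    dimension by false nearest neighbours per variable.
    """

    embedding: EmbeddingSpec | Mapping[str, EmbeddingSpec] | str = EmbeddingSpec(4, 1)
    delays: tuple[int, ...] = DEFAULT_DELAYS
    k: int | None = None
    exclusion: int = 0
    threshold: float = 0.5
    order: int = 1
    surrogates: int = 0
    seed: int = 0
    conditioning_strategy: str = "all"
    top_q: int = 3
    min_support: int = 20
    max_chains: int = 64
    fnn_max_dim: int = 8
    dmi_max_lag: int = 20
    standardize: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold T must lie in (0, 1)")
        if self.order < 1:
            raise ValueError("order must be >= 1")
        if self.surrogates < 0:
            raise ValueError("surrogates must be non-negative")
        if self.conditioning_strategy not in _STRATEGIES:
            raise ValueError(
                f"conditioning_strategy must be one of {_STRATEGIES}, "
                f"got {self.conditioning_strategy!r}"
            )
        if not self.delays:
            raise ValueError("delays must be non-empty")
        object.__setattr__(self, "delays", tuple(int(d) for d in self.delays))

    def spec_for(self, name: str) -> EmbeddingSpec:
        if isinstance(self.embedding, EmbeddingSpec):
            return self.embedding
        if isinstance(self.embedding, Mapping):
            return self.embedding[name]
        raise ValueError(
            "embedding='auto' must be resolved against data first "
            "(construct a PartialCrossMapping model)"
        )


@dataclass(frozen=True)
class PcmPairResult:
    """PCM indices and decision for one ordered pair."""

    source: str
    target: str
    rho_C: float
    rho_D: dict[int, float]
    gamma: float
    decision: str
    best_delays: dict[str, object]
    threshold: float
    conditioners: tuple[str, ...]
    p_value: dict[str, float] | None = None
    intermediates: dict[str, TimeSeries] = field(default_factory=dict, repr=False)
    support: tuple[int, int] = (0, 0)

    @property
    def rho_D_min(self) -> float:
        return min(self.rho_D.values())

    def summary(self) -> str:
        lines = [
            f"PCM pair {self.source} -> {self.target} "
            f"(conditioning on {', '.join(self.conditioners) or 'nothing'})",
            f"  rho_C  = {self.rho_C:.4f}",
        ]
        for n, v in sorted(self.rho_D.items()):
            lines.append(f"  rho_D{n} = {v:.4f}")
        lines.append(f"  gamma  = {self.gamma:.4f}")
        if self.p_value:
            for k, v in self.p_value.items():
                lines.append(f"  p[{k}] = {v:.4f}")
        lines.append(f"  decision at T={self.threshold:g}: {self.decision}")
        return "\n".join(lines)


def classify_link(rho_C: float, rho_D: float, T: float) -> str:
    """Three-case decision: direct / indirect / none.

    ``direct`` when rho_D >= T (the conditioned index survives),
    ``indirect`` when rho_C >= T > rho_D (pairwise signal entirely
    explained by mediators), ``none`` when rho_C < T.
    """
    for label, v in (("rho_C", rho_C), ("rho_D", rho_D)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{label} must lie in [0, 1], got {v}")
    if rho_D >= T:
        return "direct"
    if rho_C >= T:
        return "indirect"
    return "none"


def gamma_index(rho_C: float, rho_D_by_order: Mapping[int, float]) -> float:
    """Proximity ratio gamma = (prod_n rho_Dn) / rho_C**s.

    With only the first order computed this is rho_D1 / rho_C.  Values
    near 1 support a direct link when both indices hover near T.
    """
    if rho_C <= 0.0:
        raise ZeroDivisionError("gamma is undefined for rho_C = 0")
    if not rho_D_by_order:
        raise ValueError("at least one rho_D order is required")
    s = len(rho_D_by_order)
    num = math.prod(rho_D_by_order.values())
    return float(num / rho_C**s)


def _align(series: Sequence[TimeSeries], min_support: int) -> list[np.ndarray]:
    a = max(s.start for s in series)
    b = min(s.end for s in series)
    if b - a < max(min_support, 3):
        raise SupportError(
            f"aligned support has {max(b - a, 0)} points; need >= {max(min_support, 3)}"
        )
    return [s.window(a, b).values for s in series], (a, b)


class _Engine:
    """Shared cross-map machinery with memoisation over one data set."""

    def __init__(self, series: Mapping[str, TimeSeries], config: PcmConfig):
        self.series = dict(series)
        self.config = config
        self._cache: dict[tuple, CrossMapResult] = {}

    def scan_raw(self, u_name: str, v_name: str) -> CrossMapResult:
        """Delay-scanned cross map of one raw variable from another."""
        key = ("raw", u_name, v_name)
        if key not in self._cache:
            cfg = self.config
            res = cross_map_delay_scan(
                self.series[u_name],
                self.series[v_name],
                cfg.spec_for(u_name),
                cfg.spec_for(v_name),
                delays=cfg.delays,
                k=cfg.k,
                exclusion=cfg.exclusion,
                min_support=cfg.min_support,
            )
            logger.debug(
                "cross map %s from %s: rho=%.4f at delay %+d",
                u_name, v_name, res.rho, res.best_delay,
            )
            self._cache[key] = res
        return self._cache[key]

    def chain_estimate(self, chain: tuple[str, ...], y_name: str) -> CrossMapResult:
        """Nested estimate Zhat^{chain[0] <- ... <- chain[-1] <- Y}.

        ``chain[-1]`` is estimated from Y, ``chain[-2]`` from that
        estimate, and so on; each link is delay-optimised against the true
        series of the variable being estimated.
        """
        if not chain:
            raise ValueError("chain must contain at least one mediator")
        inner = chain[1:]
        if inner:
            src = self.chain_estimate(inner, y_name).estimate
        else:
            src = self.series[y_name]
        z = self.series[chain[0]]
        key = ("chain", y_name) + chain
        if key not in self._cache:
            cfg = self.config
            self._cache[key] = cross_map_delay_scan(
                z,
                src,
                cfg.spec_for(chain[0]),
                cfg.spec_for(inner[0]) if inner else cfg.spec_for(y_name),
                delays=cfg.delays,
                k=cfg.k,
                exclusion=cfg.exclusion,
                min_support=cfg.min_support,
            )
        return self._cache[key]

    def x_from_chain(self, x_name: str, chain: tuple[str, ...], y_name: str) -> CrossMapResult:
        """Xhat estimated from the nested chain estimate (stage 2)."""
        est = self.chain_estimate(chain, y_name).estimate
        key = ("xfrom", x_name, y_name) + chain
        if key not in self._cache:
            cfg = self.config
            self._cache[key] = cross_map_delay_scan(
                self.series[x_name],
                est,
                cfg.spec_for(x_name),
                cfg.spec_for(chain[0]),
                delays=cfg.delays,
                k=cfg.k,
                exclusion=cfg.exclusion,
                min_support=cfg.min_support,
            )
        return self._cache[key]

    def higher_order_rho(
        self, x_name: str, y_name: str, conditioners: tuple[str, ...], n: int
    ) -> float:
        """rho_Dn: condition on every ordered chain of n distinct mediators."""
        s = len(conditioners)
        if n > s:
            raise ValueError(f"order {n} exceeds the number of conditioners ({s})")
        n_chains = math.perm(s, n)
        if n_chains > self.config.max_chains:
            raise CombinatorialBudgetError(
                f"order {n} over {s} conditioners needs {n_chains} chain estimates, "
                f"exceeding the configured cap of {self.config.max_chains}"
            )
        xhat_y = self.scan_raw(x_name, y_name)
        ests = [
            self.x_from_chain(x_name, chain, y_name).estimate
            for chain in permutations(conditioners, n)
        ]
        (vals, _) = _align(
            [self.series[x_name], xhat_y.estimate, *ests], self.config.min_support
        )
        x_vals, xhat_vals, *cond_vals = vals
        return abs(
            partial_corr(
                x_vals,
                xhat_vals,
                cond_vals,
                names=[f"chain({','.join(c)})" for c in permutations(conditioners, n)],
            )
        )

    # ------------------------------------------------------------------
    def pair(
        self,
        x_name: str,
        y_name: str,
        conditioners: Sequence[str],
        with_surrogates: bool = True,
    ) -> PcmPairResult:
        cfg = self.config
        conditioners = tuple(conditioners)
        if not conditioners:
            raise ValueError("PCM requires at least one conditioning variable")

        def _stage(fn, stage):
            try:
                return fn()
            except PcmError as e:
                e.add_note(f"failing stage: {stage}")
                raise

        xhat_y = _stage(
            lambda: self.scan_raw(x_name, y_name), f"Xhat^Y ({x_name} from {y_name})"
        )
        zhat_delays, xz_delays, cond_ests = {}, {}, []
        for z in conditioners:
            zr = _stage(
                lambda z=z: self.chain_estimate((z,), y_name),
                f"Zhat^Y ({z} from {y_name})",
            )
            xr = _stage(
                lambda z=z: self.x_from_chain(x_name, (z,), y_name),
                f"Xhat^(Zhat^Y) ({x_name} from {z}-estimate)",
            )
            zhat_delays[z] = zr.best_delay
            xz_delays[z] = xr.best_delay
            cond_ests.append(xr.estimate)
        x = self.series[x_name]
        (vals, (a, b)) = _stage(
            lambda: _align([x, xhat_y.estimate, *cond_ests], cfg.min_support),
            "alignment of X, Xhat^Y and conditioning estimates",
        )
        x_vals, xhat_vals, *cond_vals = vals
        rho_C = abs(corr(x_vals, xhat_vals))
        rho_D = {
            1: abs(
                _stage(
                    lambda: partial_corr(x_vals, xhat_vals, cond_vals, names=list(conditioners)),
                    "partial correlation (order 1)",
                )
            )
        }
        for n in range(2, cfg.order + 1):
            if n > len(conditioners):
                break
            rho_D[n] = self.higher_order_rho(x_name, y_name, conditioners, n)
        gamma = gamma_index(rho_C, rho_D) if rho_C > 0 else float("nan")
        decision = classify_link(rho_C, min(rho_D.values()), cfg.threshold)
        p_value = None
        if with_surrogates and cfg.surrogates > 0:
            p_value = self._surrogate_p(x_name, y_name, conditioners, rho_C, rho_D[1])
        intermediates = {f"{x_name}hat^{y_name}": xhat_y.estimate}
        for z, est in zip(conditioners, cond_ests):
            intermediates[f"{z}hat^{y_name}"] = self.chain_estimate((z,), y_name).estimate
            intermediates[f"{x_name}hat^({z}hat^{y_name})"] = est
        return PcmPairResult(
            source=x_name,
            target=y_name,
            rho_C=rho_C,
            rho_D=rho_D,
            gamma=gamma,
            decision=decision,
            best_delays={
                "zhat_from_y": zhat_delays,
                "xhat_from_zhat": xz_delays,
                "xhat_from_y": xhat_y.best_delay,
            },
            threshold=cfg.threshold,
            conditioners=conditioners,
            p_value=p_value,
            intermediates=intermediates,
            support=(a, b),
        )

    def _surrogate_p(
        self,
        x_name: str,
        y_name: str,
        conditioners: tuple[str, ...],
        obs_rho_C: float,
        obs_rho_D: float | None = None,
    ) -> dict[str, float]:
        """Circular time-shift surrogate p-values.

        With an empty conditioning set only rho_C is re-scored (the
        pairwise null); otherwise the full Procedure B runs per surrogate.
        """
        cfg = self.config
        rng = child_rng(cfg.seed, 90, _stable_index(x_name, y_name))
        L = len(self.series[x_name])
        ge_C = ge_D = 0
        for _ in range(cfg.surrogates):
            shift = int(rng.integers(1, L))
            rot = dict(self.series)
            rot[x_name] = TimeSeries(
                np.roll(self.series[x_name].values, shift), name=x_name
            )
            sub = _Engine(rot, replace(cfg, surrogates=0))
            try:
                if conditioners:
                    res = sub.pair(x_name, y_name, conditioners, with_surrogates=False)
                    if res.rho_C >= obs_rho_C:
                        ge_C += 1
                    if obs_rho_D is not None and res.rho_D[1] >= obs_rho_D:
                        ge_D += 1
                else:
                    if sub.scan_raw(x_name, y_name).rho >= obs_rho_C:
                        ge_C += 1
            except PcmError:
                continue  # a failed surrogate counts as non-exceeding
        n = cfg.surrogates
        out = {"rho_C": (1 + ge_C) / (1 + n)}
        if conditioners and obs_rho_D is not None:
            out["rho_D"] = (1 + ge_D) / (1 + n)
        return out


def _stable_index(*names: str) -> int:
    # deterministic small integer derived from variable names (no hash
    # randomisation), used only to decorrelate surrogate streams per pair
    acc = 0
    for name in names:
        for ch in name:
            acc = (acc * 131 + ord(ch)) % 1_000_003
    return acc


def _series_from_frame(data: pd.DataFrame, standardize: bool = False) -> dict[str, TimeSeries]:
    out = {}
    for col in data.columns:
        v = np.asarray(data[col], dtype=float)
        if not np.all(np.isfinite(v)):
            raise ValueError(f"column {col!r} contains non-finite values")
        if np.ptp(v) == 0.0:
            raise ValueError(f"column {col!r} has zero variance")
        if standardize:
            # correlation indices are affine-invariant; this only improves
            # numerical conditioning for wildly scaled inputs
            v = (v - v.mean()) / v.std()
        out[str(col)] = TimeSeries(v, name=str(col))
    return out


class PartialCrossMapping:
    """PCM model over a set of aligned series.

    Parameters
    ----------
    data : pandas.DataFrame or mapping of name -> 1-D array
        Equal-length, finite series on a common time support, one column
        per variable.
    config : PcmConfig, optional
        Estimator settings; keyword overrides are applied on top.

    Examples
    --------
    >>> data, truth = simulate_three_species("chain", seed=7)
    >>> model = PartialCrossMapping(data.iloc[:1000])
    >>> res = model.fit_pair("X", "Y")
    >>> res.decision
    'indirect'
    """

    def __init__(self, data, config: PcmConfig | None = None, **overrides):
        if not isinstance(data, pd.DataFrame):
            data = pd.DataFrame(dict(data))
        if len(data) < 3:
            raise ValueError("need at least 3 time points")
        self.data = data
        cfg = config if config is not None else PcmConfig()
        if overrides:
            cfg = replace(cfg, **overrides)
        self._series = _series_from_frame(data, standardize=cfg.standardize)
        if cfg.embedding == "auto":
            cfg = replace(cfg, embedding=self._auto_embedding(cfg))
        self.config = cfg
        self._engine = _Engine(self._series, cfg)

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, **kwargs) -> "PartialCrossMapping":
        return cls(data, **kwargs)

    @property
    def var_names(self) -> list[str]:
        return list(self._series)

    def series(self, name: str) -> TimeSeries:
        return self._series[name]

    def _auto_embedding(self, cfg: PcmConfig) -> dict[str, EmbeddingSpec]:
        specs = {}
        for name, s in self._series.items():
            lag = select_lag_dmi(s, max_lag=cfg.dmi_max_lag)
            dim = select_dim_fnn(s, lag=lag, max_dim=cfg.fnn_max_dim)
            specs[name] = EmbeddingSpec(dim, lag)
            logger.info("auto embedding for %s: E=%d, tau=%d", name, dim, lag)
        return specs

    # ------------------------------------------------------------------
    def fit_pair(
        self, source: str, target: str, conditioners: Sequence[str] | None = None
    ) -> PcmPairResult:
        """Procedure B for one ordered pair.

        ``conditioners`` defaults to every other variable.
        """
        if conditioners is None:
            conditioners = [n for n in self.var_names if n not in (source, target)]
        return self._engine.pair(source, target, conditioners)

    def fit(self, pairs: Sequence[tuple[str, str]] | None = None) -> "PcmNetworkResult":
        """PCM over every ordered pair, per the conditioning strategy."""
        names = self.var_names
        if pairs is None:
            if len(names) < 3:
                raise ValueError("network inference requires >= 3 variables")
            pairs = [(a, b) for a in names for b in names if a != b]
        cfg = self.config
        results: dict[tuple[str, str], PcmPairResult | PcmError] = {}
        for x, y in pairs:
            others = [n for n in names if n not in (x, y)]
            try:
                results[(x, y)] = self._fit_pair_strategy(x, y, others)
            except PcmError as e:
                logger.warning("pair %s -> %s failed: %s", x, y, e)
                results[(x, y)] = e
        return PcmNetworkResult(model=self, results=results)

    def _fit_pair_strategy(self, x: str, y: str, others: list[str]) -> PcmPairResult:
        cfg, eng = self.config, self._engine
        if cfg.conditioning_strategy == "all" or len(others) <= 1:
            return eng.pair(x, y, others)
        if cfg.conditioning_strategy == "top_score":
            # rho_C^{X->Z} is |Corr(X, Xhat^Z)| i.e. scan_raw(x, z); Z->Y likewise.
            scores = {
                z: eng.scan_raw(x, z).rho + eng.scan_raw(z, y).rho for z in others
            }
            top = sorted(others, key=lambda z: (-scores[z], z))[: cfg.top_q]
            logger.debug("top_score conditioners for %s->%s: %s", x, y, top)
            return eng.pair(x, y, top)
        # sparse_min: condition on each mediator singly, keep the minimum rho_D
        best: PcmPairResult | None = None
        for z in others:
            r = eng.pair(x, y, [z])
            if best is None or r.rho_D[1] < best.rho_D[1]:
                best = r
        assert best is not None
        return best


@dataclass
class PcmNetworkResult:
    """All-pairs PCM results with decision adjacency and edge table."""

    model: PartialCrossMapping
    results: dict[tuple[str, str], PcmPairResult | PcmError]

    @property
    def threshold(self) -> float:
        return self.model.config.threshold

    def pair(self, source: str, target: str) -> PcmPairResult:
        r = self.results[(source, target)]
        if isinstance(r, PcmError):
            raise r
        return r

    @property
    def edge_table(self) -> pd.DataFrame:
        """One row per ordered pair: indices, p/q, decision.

        ``p`` is the surrogate p-value of the direct-causation index
        rho_D (absent when no surrogates were run); ``q`` its
        Benjamini-Hochberg adjustment across the table.
        """
        rows = []
        for (x, y), r in sorted(self.results.items()):
            if isinstance(r, PcmError):
                rows.append(
                    dict(
                        source=x, target=y, rho_C=np.nan, rho_D=np.nan, gamma=np.nan,
                        best_delays="", p=np.nan, q=np.nan, decision="error",
                    )
                )
                continue
            bd = r.best_delays
            bd_str = (
                "i1="
                + ",".join(f"{z}:{d:+d}" for z, d in sorted(bd["zhat_from_y"].items()))
                + ";i2="
                + ",".join(f"{z}:{d:+d}" for z, d in sorted(bd["xhat_from_zhat"].items()))
                + f";i3={bd['xhat_from_y']:+d}"
            )
            rows.append(
                dict(
                    source=x,
                    target=y,
                    rho_C=r.rho_C,
                    rho_D=r.rho_D_min,
                    gamma=r.gamma,
                    best_delays=bd_str,
                    p=r.p_value["rho_D"] if r.p_value else np.nan,
                    q=np.nan,
                    decision=r.decision,
                )
            )
        df = pd.DataFrame(rows)
        valid = df["p"].notna()
        if valid.any():
            from statsmodels.stats.multitest import multipletests

            df.loc[valid, "q"] = multipletests(df.loc[valid, "p"], method="fdr_bh")[1]
        return df

    @property
    def decision_adjacency(self) -> pd.DataFrame:
        """Boolean matrix: entry (i, j) True iff i -> j is called direct."""
        names = self.model.var_names
        adj = pd.DataFrame(False, index=names, columns=names)
        for (x, y), r in self.results.items():
            if not isinstance(r, PcmError) and r.decision == "direct":
                adj.loc[x, y] = True
        return adj

    def summary(self) -> str:
        cfg = self.model.config
        head = [
            "Partial Cross Mapping — network inference",
            "=" * 57,
            f"variables: {', '.join(self.model.var_names)}   "
            f"n_obs: {len(self.model.data)}",
            f"threshold T: {cfg.threshold:g}   delays: "
            f"{min(cfg.delays)}..{max(cfg.delays)}   strategy: {cfg.conditioning_strategy}",
            "-" * 57,
        ]
        table = self.edge_table.drop(columns=["best_delays"])
        body = table.to_string(
            index=False, float_format=lambda v: f"{v:.4f}" if v == v else "   ."
        )
        return "\n".join(head) + "\n" + body + "\n" + "=" * 57


# ----------------------------------------------------------------------
# Functional wrappers (one engine per call; the model object reuses one).


def pcm_pair(
    x: TimeSeries | np.ndarray,
    y: TimeSeries | np.ndarray,
    conditioners: Mapping[str, TimeSeries] | Sequence[TimeSeries],
    config: PcmConfig | None = None,
) -> PcmPairResult:
    """Procedure B for one ordered pair given explicit series."""
    cfg = config or PcmConfig()
    series = {}
    x = x if isinstance(x, TimeSeries) else TimeSeries(np.asarray(x, float), name="X")
    y = y if isinstance(y, TimeSeries) else TimeSeries(np.asarray(y, float), name="Y")
    if not x.name:
        x = replace(x, name="X")
    if not y.name:
        y = replace(y, name="Y")
    series[x.name] = x
    series[y.name] = y
    cond_names = []
    if isinstance(conditioners, Mapping):
        items = conditioners.items()
    else:
        items = [
            (z.name if isinstance(z, TimeSeries) and z.name else f"Z{i+1}", z)
            for i, z in enumerate(conditioners)
        ]
    for name, z in items:
        z = z if isinstance(z, TimeSeries) else TimeSeries(np.asarray(z, float), name=name)
        z = replace(z, name=name) if z.name != name else z
        series[name] = z
        cond_names.append(name)
    eng = _Engine(series, cfg)
    return eng.pair(x.name, y.name, cond_names)


def pcm_higher_order(
    x: TimeSeries,
    y: TimeSeries,
    conditioners: Mapping[str, TimeSeries],
    order: int,
    config: PcmConfig | None = None,
) -> float:
    """rho_Dn for a chosen order n over the given conditioners."""
    cfg = config or PcmConfig()
    series = {x.name: x, y.name: y, **conditioners}
    eng = _Engine(series, cfg)
    return eng.higher_order_rho(x.name, y.name, tuple(conditioners), order)


def infer_network(data: pd.DataFrame, config: PcmConfig | None = None) -> PcmNetworkResult:
    """All ordered pairs of ``data`` through the PCM decision rule."""
    return PartialCrossMapping(data, config=config).fit()


def surrogate_test(
    x: TimeSeries,
    y: TimeSeries,
    conditioners: Mapping[str, TimeSeries],
    config: PcmConfig,
) -> dict[str, float]:
    """Circular time-shift surrogate p-values for rho_C and rho_D.

    The source series is rotated by a random offset (preserving its
    autocorrelation, destroying cross-dependence), the identical pipeline
    re-scored, and ``p = (1 + #{surrogate >= observed}) / (1 + N)``.
    At least 19 surrogates are required for a 0.05-level test.  An empty
    conditioning set scores the pairwise index rho_C alone.
    """
    if config.surrogates < 1:
        raise ValueError("surrogate_test requires surrogates >= 1 in the config")
    series = {x.name: x, y.name: y, **conditioners}
    eng = _Engine(series, config)
    if conditioners:
        quiet = _Engine(series, replace(config, surrogates=0))
        obs = quiet.pair(x.name, y.name, tuple(conditioners), with_surrogates=False)
        return eng._surrogate_p(
            x.name, y.name, tuple(conditioners), obs.rho_C, obs.rho_D[1]
        )
    obs_rho = eng.scan_raw(x.name, y.name).rho
    return eng._surrogate_p(x.name, y.name, (), obs_rho)
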