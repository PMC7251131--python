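"""Cross mapping: neighbours, simplex weights, delay scanning."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from pcm import (
    EmbeddingSpec,
    TimeSeries,
    cross_map,
    cross_map_delay_scan,
    delay_embed,
    neighbors,
    simplex_weights,
    simulate_chain_noise_free,
    surrogate_test,
)
from pcm.errors import SupportError, UndefinedCorrelationError
from pcm.model import PcmConfig

from conftest import logistic_orbit


def brute_force_neighbors(manifold, t, k, exclusion=0):
    row = int(np.flatnonzero(manifold.times == t)[0])
    d = np.linalg.norm(manifold.points - manifold.points[row], axis=1)
    keep = np.abs(manifold.times - t) > exclusion
    order = sorted(np.flatnonzero(keep), key=lambda i: (d[i], manifold.times[i]))[:k]
    return manifold.times[order], d[order]


class TestNeighbors:
    def test_exact_duplicate_comes_first_with_zero_distance(self):
        vals = np.array([0.1, 0.5, 0.9, 0.1, 0.5, 0.3, 0.7])
        m = delay_embed(TimeSeries(vals), EmbeddingSpec(2, 1))
        # rows for t=1 (0.5,0.1) and t=4 (0.5,0.1) are identical
        ns = neighbors(m, t=4, k=3)
        assert ns.neighbor_times[0] == 1
        assert ns.distances[0] == 0.0

    def test_matches_brute_force_on_random_manifolds(self):
        rng = np.random.default_rng(42)
        for _ in range(30):
            n = int(rng.integers(12, 40))
            E = int(rng.integers(1, 4))
            m = delay_embed(TimeSeries(rng.normal(size=n + 5)), EmbeddingSpec(E, 1))
            t = int(rng.choice(m.times))
            k = int(rng.integers(1, 6))
            excl = int(rng.integers(0, 3))
            if (np.abs(m.times - t) > excl).sum() < k:
                continue
            ns = neighbors(m, t, k, exclusion=excl)
            bt, bd = brute_force_neighbors(m, t, k, excl)
            np.testing.assert_array_equal(ns.neighbor_times, bt)
            np.testing.assert_allclose(ns.distances, bd)

    def test_too_few_eligible_points(self):
        m = delay_embed(TimeSeries(np.arange(6.0)), EmbeddingSpec(2, 1))
        with pytest.raises(SupportError):
            neighbors(m, t=3, k=5, exclusion=2)


class TestSimplexWeights:
    def test_equal_distances_give_uniform_weights(self):
        np.testing.assert_allclose(simplex_weights([2.0, 2.0, 2.0]), np.ones(3) / 3)

    def test_zero_distance_takes_all_mass(self):
        np.testing.assert_allclose(simplex_weights([0.0, 1.0, 2.0]), [1.0, 0.0, 0.0])

    def test_two_point_hand_formula(self):
        w = simplex_weights([1.0, 2.0])
        raw = np.exp([-1.0, -2.0])
        np.testing.assert_allclose(w, raw / raw.sum())

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            simplex_weights([1.0, -0.5])

    @given(
        st.lists(st.floats(min_value=0, max_value=1e6), min_size=1, max_size=12)
    )
    def test_sum_one_and_monotone(self, ds):
        ds = np.sort(np.asarray(ds))
        w = simplex_weights(ds)
        assert np.isclose(w.sum(), 1.0)
        assert np.all(np.diff(w) <= 1e-12)
        assert np.all(w >= 0)


class TestCrossMap:
    def setup_method(self):
        self.u = TimeSeries(logistic_orbit(500), "u")
        self.spec = EmbeddingSpec(3, 1)

    def test_self_map_is_nearly_perfect(self):
        r = cross_map(self.u, self.u, self.spec, self.spec)
        assert r.rho > 0.99

    def test_default_k_is_dim_plus_one(self):
        a = cross_map(self.u, self.u, self.spec, self.spec)
        b = cross_map(self.u, self.u, self.spec, self.spec, k=self.spec.dim + 1)
        np.testing.assert_array_equal(a.estimate.values, b.estimate.values)

    def test_rho_affine_invariant(self):
        rng = np.random.default_rng(1)
        v = TimeSeries(self.u.values + 0.05 * rng.normal(size=500), "v")
        base = cross_map(self.u, v, self.spec, self.spec).rho
        scaled = cross_map(
            TimeSeries(3.0 * self.u.values - 1.0, "u"),
            TimeSeries(-2.0 * v.values + 5.0, "v"),
            self.spec,
            self.spec,
        ).rho
        assert np.isclose(base, scaled, atol=1e-10)

    def test_zero_variance_errors(self):
        flat = TimeSeries(np.zeros(100) + 0.5, "flat")
        with pytest.raises(UndefinedCorrelationError):
            cross_map(flat, self.u.window(0, 100), EmbeddingSpec(2, 1), EmbeddingSpec(2, 1))

    def test_insufficient_support_errors(self):
        short = TimeSeries(logistic_orbit(15), "s")
        with pytest.raises(SupportError):
            cross_map(short, short, self.spec, self.spec)

    def test_independent_noise_is_insignificant(self):
        rng = np.random.default_rng(9)
        x = TimeSeries(rng.normal(size=1000), "x")
        y = TimeSeries(rng.normal(size=1000), "y")
        p = surrogate_test(x, y, {}, PcmConfig(surrogates=99, seed=3))
        assert p["rho_C"] > 0.05


class TestDelayScan:
    def test_single_zero_delay_equals_plain_cross_map(self):
        u = TimeSeries(logistic_orbit(300), "u")
        spec = EmbeddingSpec(3, 1)
        a = cross_map(u, u, spec, spec)
        b = cross_map_delay_scan(u, u, spec, spec, delays=(0,))
        assert b.best_delay == 0
        assert a.rho == b.rho

    def test_recovers_known_shift(self):
        # a stochastic series is only predictable at the true alignment
        # (a deterministic orbit would be predictable at every delay)
        rng = np.random.default_rng(17)
        noise = rng.normal(size=600)
        u = TimeSeries(noise[3:], "u")
        v = TimeSeries(noise[:-3], "v")  # v_{t+3} = u_t exactly
        spec = EmbeddingSpec(3, 1)
        r = cross_map_delay_scan(u, v, spec, spec, delays=tuple(range(-5, 6)))
        assert r.best_delay == 3
        assert r.rho == max(r.rho_by_delay.values())
        assert r.rho_by_delay[3] > 2 * np.median(list(r.rho_by_delay.values()))

    def test_scan_matches_exhaustive_per_delay_evaluation(self, chain_segment):
        spec = EmbeddingSpec(4, 1)
        z = TimeSeries(chain_segment["Z"].to_numpy(), "Z")
        y = TimeSeries(chain_segment["Y"].to_numpy(), "Y")
        scan = cross_map_delay_scan(z, y, spec, spec, delays=tuple(range(-5, 6)))
        for d, rho in scan.rho_by_delay.items():
            single = cross_map(z, y.shift(d), spec, spec)
            assert single.rho == rho
        assert scan.rho == max(scan.rho_by_delay.values())

    def test_true_link_has_interior_delay_maximum(self, chain_segment):
        """For Z driven toward Y, the delay profile peaks strictly inside
        the scanned window (causal influence arrives with a finite lag)."""
        spec = EmbeddingSpec(4, 1)
        z = TimeSeries(chain_segment["Z"].to_numpy(), "Z")
        y = TimeSeries(chain_segment["Y"].to_numpy(), "Y")
        r = cross_map_delay_scan(z, y, spec, spec, delays=tuple(range(-5, 6)))
        assert -5 < r.best_delay < 5

    def test_all_delays_infeasible_errors(self):
        u = TimeSeries(logistic_orbit(40), "u")
        with pytest.raises(SupportError):
            cross_map_delay_scan(
                u, u, EmbeddingSpec(3, 1), EmbeddingSpec(3, 1), delays=(50, -50)
            )

    def test_tie_break_prefers_small_negative_delay(self):
        from pcm.crossmap import _delay_rank

        assert sorted([3, -3, 1, -1, 0], key=_delay_rank) == [0, -1, 1, -3, 3]


class TestConvergence:
    def test_rho_increases_with_library_length(self):
        """Cross-map skill grows with library length for a true link."""
        lengths = (200, 500, 1000, 3000)
        spec = EmbeddingSpec(4, 1)
        good = 0
        n_rep = 10
        for rep in range(n_rep):
            data, _ = simulate_chain_noise_free(length=3000, seed=100 + rep)
            x, z = data["X"].to_numpy(), data["Z"].to_numpy()
            rhos = [
                cross_map(
                    TimeSeries(x[:L], "x"), TimeSeries(z[:L], "z"), spec, spec
                ).rho
                for L in lengths
            ]
            if np.all(np.diff(rhos) >= -1e-6):
                good += 1
        assert good >= 0.9 * n_rep
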