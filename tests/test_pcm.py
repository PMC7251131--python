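"""The PCM estimator: decision rule, gamma, higher orders, networks."""

import numpy as np
import pandas as pd
import pytest

from pcm import (
    LogisticNetworkParams,
    PartialCrossMapping,
    PcmConfig,
    TimeSeries,
    classify_link,
    gamma_index,
    pcm_higher_order,
    pcm_pair,
    sample_trials,
    simulate_network,
    simulate_three_species,
    surrogate_test,
)
from pcm.errors import CombinatorialBudgetError, SupportError
from pcm._rng import child_rng, child_seed


class TestClassifyLink:
    @pytest.mark.parametrize(
        "rho_C,rho_D,expected",
        [(0.8, 0.7, "direct"), (0.8, 0.1, "indirect"), (0.3, 0.2, "none")],
    )
    def test_three_cases(self, rho_C, rho_D, expected):
        assert classify_link(rho_C, rho_D, 0.5) == expected

    def test_boundary_is_inclusive(self):
        assert classify_link(0.5, 0.5, 0.5) == "direct"
        assert classify_link(0.5, 0.49, 0.5) == "indirect"

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            classify_link(1.2, 0.5, 0.5)


class TestGammaIndex:
    def test_proximity_one(self):
        assert gamma_index(0.7, {1: 0.7}) == pytest.approx(1.0)

    def test_annihilation(self):
        assert gamma_index(0.7, {1: 0.0}) == 0.0

    def test_two_order_hand_value(self):
        assert gamma_index(0.8, {1: 0.6, 2: 0.4}) == pytest.approx(0.375)

    def test_zero_rho_c_undefined(self):
        with pytest.raises(ZeroDivisionError):
            gamma_index(0.0, {1: 0.5})


class TestPcmPair:
    def test_chain_is_called_indirect(self, chain_indices):
        """Mediated X->Y flow: strong pairwise index, weak conditioned one."""
        assert chain_indices["rho_C"].mean() > 0.5
        assert chain_indices["rho_D"].mean() < 0.5
        assert (chain_indices["decision"] == "indirect").mean() > 0.5

    def test_direct_link_retained_with_decoupled_third(self, direct_indices):
        """With Z decoupled, conditioning barely moves the index."""
        diff = (direct_indices["rho_C"] - direct_indices["rho_D"]).abs()
        assert (diff < 0.1 * direct_indices["rho_C"]).mean() > 0.9
        assert (direct_indices["decision"] == "direct").all()

    def test_uncoupled_system_is_called_none(self):
        from pcm import three_species_params

        p = three_species_params("custom", beta=np.zeros((3, 3)))
        data, truth = simulate_three_species(params=p, seed=child_seed(0, 30))
        assert truth == []
        seg = sample_trials(data, 1, 1000, seed=child_seed(0, 31))[0]
        res = PartialCrossMapping(seg).fit_pair("X", "Y")
        assert res.rho_C < 0.5
        assert res.decision == "none"

    def test_pure_noise_conditioner_changes_little(self):
        data, _ = simulate_three_species("direct", seed=child_seed(0, 32))
        seg = sample_trials(data, 3, 1000, seed=child_seed(0, 33))
        rng = child_rng(0, 34)
        diffs = []
        for s in seg:
            s = s.copy()
            s["W"] = rng.uniform(0.2, 0.8, len(s))
            res = PartialCrossMapping(s).fit_pair("X", "Y", conditioners=["W"])
            diffs.append(abs(res.rho_C - res.rho_D[1]))
        assert np.mean(diffs) < 0.1

    def test_bit_identical_under_fixed_config(self, chain_segment):
        a = PartialCrossMapping(chain_segment).fit_pair("X", "Y")
        b = PartialCrossMapping(chain_segment).fit_pair("X", "Y")
        assert a.rho_C == b.rho_C
        assert a.rho_D == b.rho_D
        assert a.best_delays == b.best_delays
        np.testing.assert_array_equal(
            a.intermediates["Xhat^Y"].values, b.intermediates["Xhat^Y"].values
        )

    def test_standardization_leaves_indices_unchanged(self, chain_segment):
        """The indices are correlations, hence affine-invariant; the
        z-score switch exists purely for numerical conditioning."""
        raw = PartialCrossMapping(chain_segment).fit_pair("X", "Y")
        std = PartialCrossMapping(chain_segment, standardize=True).fit_pair("X", "Y")
        assert std.rho_C == pytest.approx(raw.rho_C, abs=1e-9)
        assert std.rho_D[1] == pytest.approx(raw.rho_D[1], abs=1e-9)

    def test_stage_failures_are_annotated(self):
        rng = child_rng(0, 35)
        df = pd.DataFrame(rng.uniform(size=(60, 3)), columns=["X", "Y", "Z"])
        model = PartialCrossMapping(df, min_support=500)
        with pytest.raises(SupportError) as exc:
            model.fit_pair("X", "Y")
        assert any("failing stage" in n for n in exc.value.__notes__)


class TestHigherOrder:
    def _toy(self, n=400):
        data, _ = simulate_three_species("chain", seed=child_seed(0, 36), length=n)
        return {
            name: TimeSeries(data[name].to_numpy(), name) for name in data.columns
        }

    def test_order_one_matches_pair_rho_d(self):
        s = self._toy()
        cfg = PcmConfig()
        r1 = pcm_higher_order(s["X"], s["Y"], {"Z": s["Z"]}, order=1, config=cfg)
        rp = pcm_pair(s["X"], s["Y"], {"Z": s["Z"]}, config=cfg)
        assert r1 == pytest.approx(rp.rho_D[1], abs=1e-12)

    def test_budget_cap_enforced(self):
        s = self._toy()
        rng = child_rng(0, 37)
        conds = {"Z": s["Z"]}
        for i in range(3):
            conds[f"W{i}"] = TimeSeries(rng.uniform(0.2, 0.8, 400), f"W{i}")
        cfg = PcmConfig(max_chains=5)
        with pytest.raises(CombinatorialBudgetError, match="12 chain estimates"):
            pcm_higher_order(s["X"], s["Y"], conds, order=2, config=cfg)

    def test_two_mediator_path_suppressed_at_second_order(self):
        """X -> Z1 -> Z2 -> Y: conditioning through two-mediator chains
        removes the pairwise X->Y signal."""
        alpha = np.array([3.6, 3.72, 3.68, 3.65])
        beta = np.zeros((4, 4))
        beta[1, 0] = 0.4  # X -> Z1
        beta[2, 1] = 0.4  # Z1 -> Z2
        beta[3, 2] = 0.4  # Z2 -> Y
        params = LogisticNetworkParams(
            alpha=alpha, beta=beta, names=("X", "Z1", "Z2", "Y"), length=5000
        )
        data, truth = simulate_network(params, seed=child_seed(0, 38))
        assert ("X", "Z1") in truth and ("Z2", "Y") in truth
        segs = sample_trials(data, 6, 1000, seed=child_seed(0, 39))
        rc, rd2 = [], []
        cfg = PcmConfig(order=2)
        for seg in segs:
            series = {c: TimeSeries(seg[c].to_numpy(), c) for c in seg.columns}
            res = pcm_pair(
                series["X"], series["Y"],
                {"Z1": series["Z1"], "Z2": series["Z2"]}, config=cfg,
            )
            rc.append(res.rho_C)
            rd2.append(res.rho_D[2])
        assert np.mean(rd2) < np.mean(rc)
        assert np.mean(rd2) < 0.5 < np.mean(rc)


class TestSurrogates:
    def test_exact_copy_hits_the_p_floor(self):
        from conftest import logistic_orbit

        x = TimeSeries(logistic_orbit(500), "x")
        y = TimeSeries(x.values.copy(), "y")
        p = surrogate_test(x, y, {}, PcmConfig(surrogates=19, seed=1))
        assert p["rho_C"] == pytest.approx(1 / 20)

    def test_p_formula_at_19_surrogates(self):
        # the floor 1/(1+N) IS the formula value when nothing exceeds
        assert 1 / (1 + 19) == 0.05

    def test_zero_surrogates_is_a_configuration_error(self):
        from conftest import logistic_orbit

        x = TimeSeries(logistic_orbit(300), "x")
        with pytest.raises(ValueError):
            surrogate_test(x, x, {}, PcmConfig(surrogates=0))


class TestNetwork:
    def test_chain_adjacency_and_error_isolation(self, chain_segment):
        res = PartialCrossMapping(chain_segment).fit()
        table = res.edge_table
        assert len(table) == 6
        assert set(table["decision"]).issubset({"direct", "indirect", "none", "error"})
        # the true chain links are recovered as direct
        adj = res.decision_adjacency
        assert adj.loc["X", "Z"] and adj.loc["Z", "Y"]
        # the mediated X->Y link must not be called direct
        assert not adj.loc["X", "Y"]

    def test_sparse_min_equals_all_with_single_mediator(self, chain_segment):
        r_all = PartialCrossMapping(chain_segment, conditioning_strategy="all").fit()
        r_sp = PartialCrossMapping(
            chain_segment, conditioning_strategy="sparse_min"
        ).fit()
        for key in r_all.results:
            assert r_all.pair(*key).rho_D[1] == pytest.approx(
                r_sp.pair(*key).rho_D[1], abs=1e-12
            )

    def test_top_score_strategy_runs_and_limits_conditioners(self):
        data, _ = simulate_network(
            __import__("pcm").eight_node_params(length=1200), seed=child_seed(0, 40)
        )
        sub = data.iloc[:600, :5]
        res = PartialCrossMapping(
            sub, conditioning_strategy="top_score", top_q=2
        ).fit(pairs=[("N1", "N2")])
        assert len(res.pair("N1", "N2").conditioners) == 2

    def test_per_pair_failures_do_not_abort(self):
        rng = child_rng(0, 41)
        df = pd.DataFrame(rng.uniform(size=(80, 3)), columns=["A", "B", "C"])
        res = PartialCrossMapping(df, min_support=300).fit()
        table = res.edge_table
        assert (table["decision"] == "error").all()
        assert len(table) == 6

    def test_summary_mentions_threshold_and_variables(self, chain_segment):
        res = PartialCrossMapping(chain_segment).fit()
        text = res.summary()
        assert "threshold T: 0.5" in text
        assert "X, Y, Z" in text


class TestRhoOrdering:
    def test_rho_c_dominates_rho_d(self, chain_indices, loop_indices, direct_indices):
        """The pairwise index bounds the conditioned one in nearly all trials."""
        pooled = pd.concat([chain_indices, loop_indices, direct_indices])
        frac = (pooled["rho_C"] >= pooled["rho_D"] - 1e-12).mean()
        assert frac >= 0.95
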