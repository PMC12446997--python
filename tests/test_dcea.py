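import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cvdcea import dcea, microsim


class TestNetHealthBenefit:
    def test_zero_increments(self):
        assert dcea.incremental_net_health_benefit(0.0, 0.0, 150_000.0) == 0.0

    def test_nonpositive_wtp_rejected(self):
        with pytest.raises(ValueError):
            dcea.net_health_benefit(100.0, 1.0, 0.0)
        with pytest.raises(ValueError):
            dcea.net_health_benefit(100.0, 1.0, -5.0)

    def test_cost_saving_dominant_increment(self):
        # saving money and gaining health beats either component alone
        inhb = dcea.incremental_net_health_benefit(-2146.0, 0.028, 150_000.0)
        assert inhb > 0.028


class TestAtkinsonEde:
    def test_epsilon_zero_is_weighted_mean(self):
        h = np.array([1.0, 2.0, 5.0])
        w = np.array([0.2, 0.3, 0.5])
        assert dcea.atkinson_ede(h, w, 0.0) == pytest.approx(float(np.sum(h * w)), rel=1e-12)

    def test_equal_distribution_fixed_point(self):
        for eps in (0.0, 0.5, 1.0, 2.5):
            assert dcea.atkinson_ede([5.0, 5.0, 5.0], [0.3, 0.3, 0.4], eps) == \
                pytest.approx(5.0, rel=1e-12)

    def test_two_group_closed_form(self):
        # ((0.5*sqrt(1) + 0.5*sqrt(3)))^2
        assert dcea.atkinson_ede([1.0, 3.0], [0.5, 0.5], 0.5) == \
            pytest.approx(1.8660254, abs=5e-8)

    def test_epsilon_one_geometric_mean(self):
        assert dcea.atkinson_ede([1.0, 3.0], [0.5, 0.5], 1.0) == \
            pytest.approx(np.sqrt(3.0), rel=1e-12)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            dcea.atkinson_ede([1.0, -0.5], [0.5, 0.5], 0.5)
        with pytest.raises(ValueError):
            dcea.atkinson_ede([1.0, 2.0], [0.5, 0.6], 0.5)
        with pytest.raises(ValueError):
            dcea.atkinson_ede([1.0, 2.0], [0.5, 0.5], -0.1)

    @given(
        st.lists(st.floats(min_value=0.1, max_value=50.0), min_size=2, max_size=6),
        st.floats(min_value=0.0, max_value=3.0),
    )
    @settings(max_examples=60, deadline=None)
    def test_ede_never_exceeds_mean(self, health, eps):
        w = np.full(len(health), 1.0 / len(health))
        ede = dcea.atkinson_ede(health, w, eps)
        assert ede <= float(np.mean(health)) + 1e-9


class TestAtkinsonIndex:
    def test_no_inequality(self):
        assert dcea.atkinson_index(2.0, 2.0) == 0.0

    def test_two_group_value(self):
        assert dcea.atkinson_index(1.8660254, 2.0) == pytest.approx(0.0669873, abs=5e-8)

    def test_epsilon_zero_index_zero(self):
        h = [1.0, 4.0]
        w = [0.5, 0.5]
        ede = dcea.atkinson_ede(h, w, 0.0)
        assert dcea.atkinson_index(ede, float(np.dot(h, w))) == pytest.approx(0.0, abs=1e-12)

    def test_nonpositive_mean_is_undefined(self):
        assert np.isnan(dcea.atkinson_index(1.0, 0.0))
        assert np.isnan(dcea.atkinson_index(1.0, -2.0))


class TestEquityProperties:
    @given(st.lists(st.floats(min_value=0.5, max_value=20.0), min_size=2, max_size=5))
    @settings(max_examples=50, deadline=None)
    def test_ede_weakly_decreasing_in_epsilon(self, health):
        w = np.full(len(health), 1.0 / len(health))
        grid = [0.0, 0.5, 1.0, 1.5, 2.0, 2.5, 3.0]
        values = [dcea.atkinson_ede(health, w, e) for e in grid]
        assert all(a >= b - 1e-9 for a, b in zip(values, values[1:]))

    @given(
        st.lists(st.floats(min_value=1.0, max_value=10.0), min_size=2, max_size=5),
        st.floats(min_value=0.1, max_value=3.0),
        st.floats(min_value=0.01, max_value=0.4),
    )
    @settings(max_examples=50, deadline=None)
    def test_pigou_dalton_progressive_transfer(self, health, eps, delta_frac):
        """A mean-preserving transfer from the best-off to the worst-off group
        never lowers the equally distributed equivalent."""
        h = np.asarray(health)
        w = np.full(len(h), 1.0 / len(h))
        i, j = int(np.argmin(h)), int(np.argmax(h))
        if i == j:
            return
        delta = delta_frac * (h[j] - h[i]) / 2.0
        h2 = h.copy()
        h2[i] += delta
        h2[j] -= delta
        assert dcea.atkinson_ede(h2, w, eps) >= dcea.atkinson_ede(h, w, eps) - 1e-9


class TestBurdenAndPlane:
    def test_identical_arms_zero_change(self):
        assert dcea.inequality_burden_change(2.0, 1.9, 2.0, 1.9, 1e6) == 0.0

    def test_progressive_transfer_reduces_burden(self):
        w = np.array([0.5, 0.5])
        h_n = np.array([1.0, 3.0])
        h_e = np.array([1.5, 2.5])  # same mean, more equal
        eps = 1.5
        m = dcea.equity_metrics(h_n, h_e, w, eps, 1e6)
        assert m["burden_change"] > 0
        assert m["iedeh"] > 0

    def test_plane_coordinates(self):
        pt = dcea.equity_efficiency_point(0.003, 0.003, 10.0)
        assert pt["x"] == pytest.approx(0.0)
        assert pt["y"] == pytest.approx(0.03)
        assert dcea.equity_efficiency_point(0.01, 0.02, 1.0)["quadrant"] == "top-right"
        assert dcea.equity_efficiency_point(-0.01, 0.02, 1.0)["quadrant"] == "bottom-right"
        assert dcea.equity_efficiency_point(-0.01, -0.02, 1.0)["quadrant"] == "bottom-left"

    def test_sign_flip_of_inhb_flips_y_only(self):
        a = dcea.equity_efficiency_point(0.004, 0.001, 100.0)
        b = dcea.equity_efficiency_point(-0.004, 0.009, 100.0)
        assert b["y"] == -a["y"]


class TestBreakevenEpsilon:
    def test_root_found_when_sign_changes(self):
        w = np.array([0.5, 0.5])
        h_n = np.array([1.0, 3.0])
        h_e = np.array([1.15, 2.8])  # lower mean, more equal
        eps = dcea.breakeven_epsilon(h_n, h_e, w)
        assert eps is not None
        iedeh = dcea.atkinson_ede(h_e, w, eps) - dcea.atkinson_ede(h_n, w, eps)
        assert abs(iedeh) < 1e-3

    def test_none_when_always_enhancing(self):
        w = np.array([0.5, 0.5])
        assert dcea.breakeven_epsilon([1.0, 3.0], [1.1, 3.1], w) is None


class TestDceaSummary:
    def test_subgroup_deltas_aggregate_to_total(self, params, small_sample):
        nonexp, exp = microsim.run_pair(small_sample, params, 31)
        summ = dcea.dcea_summary(nonexp, exp, params)
        for partition in dcea.PARTITIONS:
            sub = summ.subgroups[(summ.subgroups["partition"] == partition)
                                 & (summ.subgroups["fraction"] > 0)]
            dq = float(np.sum(sub["fraction"] * sub["delta_qalys"]))
            dc = float(np.sum(sub["fraction"] * sub["delta_cost"]))
            assert dq == pytest.approx(summ.totals["delta_qalys"], rel=1e-9, abs=1e-12)
            assert dc == pytest.approx(summ.totals["delta_cost"], rel=1e-9, abs=1e-9)

    def test_equity_block_consistency(self, params, small_sample):
        nonexp, exp = microsim.run_pair(small_sample, params, 31)
        summ = dcea.dcea_summary(nonexp, exp, params)
        for partition, eq in summ.equity.items():
            assert eq["edeh_nonexp"] <= eq["nhb_nonexp"] + 1e-9
            a = eq["atkinson_nonexp"]
            assert 0.0 <= a < 1.0
            # identity A = 1 - EDEH/NHB
            assert a == pytest.approx(1.0 - eq["edeh_nonexp"] / eq["nhb_nonexp"], rel=1e-12)

    def test_empty_results(self, params):
        import pandas as pd

        from cvdcea.synthetic_population import PopulationSample
        from test_risk_engine import one_person
        empty = PopulationSample(pd.DataFrame(columns=one_person().columns), pop_scale=1.0)
        nonexp, exp = microsim.run_pair(empty, params, 1)
        summ = dcea.dcea_summary(nonexp, exp, params)
        assert summ.totals == {}
        assert len(summ.subgroups) == 0
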