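"""Gas-liquid balance: partition model, loss integration, production."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from aromaflux.balance import (
    GasTrace,
    PartitionParams,
    balance_trace,
    gas_losses,
    liquid_concentration,
    partition_coefficient,
    relative_loss,
    run_balance,
    total_production,
)


def make_trace(time, C_gas, Q=1.0, E=0.0, T=293.15, compound="x"):
    return GasTrace(compound=compound, time=np.asarray(time, float),
                    C_gas=np.asarray(C_gas, float), Q=Q, E=E, T=T)


class TestPartitionCoefficient:
    def test_reference_conditions_collapse_to_exp_f1(self):
        p = PartitionParams("x", F1=-3.0, F2=0.01, F3=10.0, F4=0.05)
        k = partition_coefficient(0.0, 293.15, p)
        assert k == pytest.approx(np.exp(-3.0), rel=1e-12)

    def test_reference_temperature_leaves_only_ethanol_term(self):
        p = PartitionParams("x", F1=-3.0, F2=0.01, F3=10.0, F4=0.05)
        for E in (0.0, 30.0, 80.0):
            assert np.log(partition_coefficient(E, 293.15, p)) == pytest.approx(
                -3.0 + 0.01 * E, rel=1e-12
            )

    def test_hand_evaluated_oracle(self):
        # independent arithmetic of the ln k model at E=50 g/L, T=303.15 K
        p = PartitionParams("x", F1=-3.0, F2=0.01, F3=10.0, F4=0.05)
        expected = np.exp(
            -3.0 + 0.01 * 50
            - ((10.0 + 0.05 * 50) / 8.314) * (1000 / 303.15 - 1000 / 293.15)
        )
        assert partition_coefficient(50.0, 303.15, p) == pytest.approx(expected, rel=1e-12)

    def test_rejects_nonfinite_and_nonpositive_inputs(self):
        p = PartitionParams("x", F1=-3.0, F2=0.0, F3=0.0, F4=0.0)
        with pytest.raises(ValueError):
            partition_coefficient(np.nan, 293.15, p)
        with pytest.raises(ValueError):
            partition_coefficient(0.0, -1.0, p)


class TestLiquidConcentration:
    def test_zero_maps_to_zero(self):
        assert liquid_concentration(0.0, 0.02) == 0.0

    def test_inverse_identity(self, rng):
        x = rng.uniform(0, 100, 20)
        k = 0.013
        assert liquid_concentration(k * x, k) == pytest.approx(x, rel=1e-12)

    def test_arithmetic_oracle(self):
        assert liquid_concentration(0.5, 0.02) == pytest.approx(25.0)

    def test_nonpositive_k_rejected(self):
        with pytest.raises(ValueError):
            liquid_concentration(1.0, 0.0)


class TestGasLosses:
    def test_zero_trace_gives_zero_loss(self):
        L = gas_losses(make_trace([0, 1, 2], [0, 0, 0]))
        assert np.all(L == 0)

    def test_constant_trace_closed_form(self):
        # constant integrand: L(T) = c0*q*T exactly under the trapezoid rule
        t = np.array([0.0, 0.7, 1.9, 3.0])
        L = gas_losses(make_trace(t, np.full(4, 2.5), Q=0.4))
        assert L[-1] == pytest.approx(2.5 * 0.4 * 3.0, rel=1e-12)

    def test_linear_trace_matches_analytic_integral_on_any_grid(self, rng):
        # integrand linear in t: trapezoid is exact regardless of spacing
        t = np.sort(rng.uniform(0, 10, 15))
        t[0] = 0.0
        a, q = 0.3, 0.8
        L = gas_losses(make_trace(t, a * t, Q=q))
        assert L[-1] == pytest.approx(a * q * t[-1] ** 2 / 2, rel=1e-12)

    def test_unsorted_times_rejected(self):
        with pytest.raises(ValueError):
            make_trace([0, 2, 1], [0, 0, 0])

    def test_grid_refinement_converges_second_order(self):
        # smooth integrand: halving h divides the quadrature error by ~4
        def loss_error(n):
            t = np.linspace(0, 10, n)
            L = gas_losses(make_trace(t, t**3, Q=1.0))
            return abs(L[-1] - 10**4 / 4)

        e1, e2 = loss_error(101), loss_error(201)
        assert e1 / e2 == pytest.approx(4.0, rel=0.1)

    @settings(max_examples=25, deadline=None)
    @given(st.lists(st.floats(0, 100), min_size=3, max_size=12))
    def test_loss_nondecreasing_for_nonnegative_traces(self, values):
        t = np.arange(len(values), dtype=float)
        L = gas_losses(make_trace(t, np.array(values)))
        assert L[0] == 0.0
        assert np.all(np.diff(L) >= 0)


class TestProductionAndRelativeLoss:
    def test_degenerate_identities(self):
        c = np.array([1.0, 2.0])
        z = np.zeros(2)
        assert np.all(total_production(c, z) == c)
        assert np.all(total_production(z, c) == c)

    def test_arithmetic(self):
        assert total_production(np.array([10.0]), np.array([2.5]))[0] == 12.5

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError):
            total_production(np.zeros(3), np.zeros(4))

    @pytest.mark.parametrize(
        "L_end, c_end, expected", [(0.0, 5.0, 0.0), (4.0, 0.0, 1.0), (1.0, 3.0, 0.25)]
    )
    def test_relative_loss_values(self, L_end, c_end, expected):
        assert relative_loss(L_end, c_end) == pytest.approx(expected)

    def test_zero_denominator_flagged(self):
        with pytest.raises(ZeroDivisionError):
            relative_loss(0.0, 0.0)

    def test_rl_invariant_to_time_rescaling_with_inverse_flow(self, rng):
        t = np.linspace(0, 10, 40)
        cg = rng.uniform(0.1, 1.0, 40)
        p = PartitionParams("x", F1=-4.0, F2=0.0, F3=0.0, F4=0.0)
        b1 = balance_trace(make_trace(t, cg, Q=0.5), p)
        b2 = balance_trace(make_trace(3 * t, cg, Q=0.5 / 3), p)
        assert b1.relative_loss == pytest.approx(b2.relative_loss, rel=1e-12)


class TestRunBalance:
    def test_noiseless_dataset_recovers_true_production(
        self, noiseless_scenario, noiseless_dataset, partition_frame
    ):
        co2 = pd.DataFrame(
            {
                "time_h": noiseless_dataset.time,
                "co2_cum": noiseless_dataset.co2_cumulative,
                "co2_rate": noiseless_dataset.co2_rate,
            }
        )
        balances = run_balance(
            noiseless_dataset.gas_traces[["compound", "time_h", "C_gas"]],
            partition_frame,
            co2,
        )
        for comp, b in balances.items():
            truth = noiseless_dataset.liquid_truth.query("compound == @comp")
            P_true = truth["P"].to_numpy()
            m = P_true > 1e-3 * P_true.max()
            rel = np.abs(b.P[m] - P_true[m]) / P_true[m]
            assert rel.max() < 5e-3
            # balance identity holds to machine precision
            assert b.P == pytest.approx(b.C_liq + b.L, abs=1e-12)
            assert np.all(np.diff(b.L) >= 0)
            assert 0 <= b.relative_loss <= 1

    def test_two_point_trace(self):
        gas = pd.DataFrame(
            {"compound": ["x", "x"], "time_h": [0.0, 1.0], "C_gas": [0.0, 0.1]}
        )
        co2 = pd.DataFrame({"time_h": [0.0, 1.0], "co2_cum": [0.0, 1.0]})
        params = {"x": PartitionParams("x", -4.0, 0.0, 0.0, 0.0)}
        (b,) = run_balance(gas, params, co2).values()
        assert b.time.size == 2 and b.L[0] == 0.0

    def test_missing_partition_parameters_named(self):
        gas = pd.DataFrame(
            {"compound": ["mystery"] * 2, "time_h": [0.0, 1.0], "C_gas": [0.0, 0.1]}
        )
        co2 = pd.DataFrame({"time_h": [0.0, 1.0], "co2_cum": [0.0, 1.0]})
        with pytest.raises(KeyError, match="mystery"):
            run_balance(gas, {}, co2)
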