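"""Unit and property tests for the closed-form variance theory."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from odnaseg import variance as v


class TestBasicStatistics:
    @pytest.mark.parametrize(
        "var_h, mean_h, expected",
        [
            (0.05, 0.5, 0.2),
            (0.0, 0.3, 0.0),
            (0.02, 0.9, 0.02 / 0.09),
        ],
    )
    def test_normalise_variance(self, var_h, mean_h, expected):
        assert v.normalise_variance(var_h, mean_h) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("mean_h", [0.0, 1.0, -0.1, 1.1])
    def test_normalise_variance_fixation_is_domain_error(self, mean_h):
        with pytest.raises(ValueError):
            v.normalise_variance(0.01, mean_h)

    @pytest.mark.parametrize(
        "nv, nb, b",
        [(0.01, 100.0, 0.99), (1.0, 1.0, 0.0), (0.002, 500.0, 0.998)],
    )
    def test_bottleneck_statistics(self, nv, nb, b):
        assert v.bottleneck_size(nv) == pytest.approx(nb)
        assert v.bottleneck_param(nv) == pytest.approx(b)

    def test_bottleneck_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            v.bottleneck_size(0.0)

    def test_summary_rejects_super_unit_variance(self):
        with pytest.raises(ValueError):
            v.VarianceSummary.from_norm_var(1.2)


class TestContributions:
    @pytest.mark.parametrize(
        "n, n_c, expected",
        [(1000, 1, 0.001), (1000, 10, 0.01), (500, 1, 0.002)],
    )
    def test_division(self, n, n_c, expected):
        assert v.division_contribution(n, n_c) == pytest.approx(expected)

    def test_division_cluster_too_large(self):
        with pytest.raises(ValueError):
            v.division_contribution(10, 11)

    @pytest.mark.parametrize(
        "nu, f, t, n, n_d, expected",
        [
            (1.0, 1.0, 1.0, 1000, 1, 0.002),  # classical 2 nu t / n
            (1.0, 0.0, 5.0, 1000, 1, 0.0),  # fully fused network
            (1.0, 0.5, 2.0, 1000, 3, 0.004),  # (1+3)*1*0.5*2/1000
        ],
    )
    def test_turnover(self, nu, f, t, n, n_d, expected):
        assert v.turnover_contribution(nu, f, t, n, n_d) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "kappa, f, t, nc, expected",
        [
            (0.002, 0.0, 1.0, 1, 0.004),
            (0.002, 1.0, 1.0, 1, 0.0),  # fully fragmented: no recombination
            (0.002, 0.3, 1.0, 1, 2 * 0.002 * 0.49),
            (0.002, 0.0, 1.0, 4, 0.001),  # plastid compartment rescaling
        ],
    )
    def test_conversion(self, kappa, f, t, nc, expected):
        assert v.conversion_contribution(kappa, f, t, nc) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "n1, n2, n_c, exact, expected",
        [
            (1000, 100, 1, False, 0.009),
            (1000, 1000, 5, False, 0.0),
            (10, 5, 1, True, 5.0 / 45.0),  # exact hypergeometric at small n
        ],
    )
    def test_subsample(self, n1, n2, n_c, exact, expected):
        assert v.subsample_contribution(n1, n2, n_c, exact) == pytest.approx(expected)

    def test_subsample_rejects_growth(self):
        with pytest.raises(ValueError):
            v.subsample_contribution(100, 200)

    @pytest.mark.parametrize(
        "n1, n2, expected",
        [(500, 100_000, 1 / 500 - 1 / 100_000), (64, 64, 0.0), (4, 8, 0.125)],
    )
    def test_amplification(self, n1, n2, expected):
        assert v.amplification_contribution(n1, n2) == pytest.approx(expected)

    def test_amplification_rejects_shrinkage(self):
        with pytest.raises(ValueError):
            v.amplification_contribution(200, 100)

    def test_exact_subsample_matches_enumeration(self):
        # enumerate the hypergeometric pmf by combinatorics for small pools
        for w, m, n_out in [(5, 5, 5), (6, 4, 3), (3, 9, 6)]:
            n1 = w + m
            probs = {}
            for k in range(max(0, n_out - w) , min(m, n_out) + 1):
                probs[k] = (
                    math.comb(m, k) * math.comb(w, n_out - k) / math.comb(n1, n_out)
                )
            hs = np.array([k / n_out for k in probs])
            ps = np.array(list(probs.values()))
            mean = float(np.sum(hs * ps))
            var = float(np.sum((hs - mean) ** 2 * ps))
            expected = var / (mean * (1 - mean))
            assert v.subsample_contribution(n1, n_out, exact=True) == pytest.approx(
                expected, rel=1e-12
            )

    @given(
        t=st.floats(0.1, 10), nu=st.floats(0, 2), f=st.floats(0, 1),
        n=st.integers(10, 10_000), n_d=st.integers(1, 5),
    )
    @settings(max_examples=50, deadline=None)
    def test_turnover_monotone_in_time_and_rates(self, t, nu, f, n, n_d):
        base = v.turnover_contribution(nu, f, t, n, n_d)
        assert v.turnover_contribution(nu, f, t * 1.5, n, n_d) >= base
        assert v.turnover_contribution(nu * 1.5, f, t, n, n_d) >= base
        assert v.turnover_contribution(nu, f, t, 2 * n, n_d) <= base
        assert v.turnover_contribution(nu, f, t, n, n_d + 1) >= base


class TestScheduleContainer:
    def test_event_requires_epoch_duration(self):
        with pytest.raises(ValueError):
            v.MechanismEvent("turnover_epoch", n1=1000, duration_days=0.0)

    def test_instantaneous_event_rejects_duration(self):
        with pytest.raises(ValueError):
            v.MechanismEvent("division", n1=1000, duration_days=1.0)

    def test_division_default_halving(self):
        ev = v.MechanismEvent("division", n1=1000)
        assert ev.n2 == 500

    def test_subsample_and_amplify_direction(self):
        with pytest.raises(ValueError):
            v.MechanismEvent("subsample", n1=100, n2=200)
        with pytest.raises(ValueError):
            v.MechanismEvent("amplify", n1=200, n2=100)

    def test_schedule_rejects_broken_chain(self):
        with pytest.raises(ValueError, match="chain"):
            v.Schedule(
                [
                    v.MechanismEvent("division", n1=1000, n2=500),
                    v.MechanismEvent("division", n1=400, n2=200),
                ]
            )

    def test_empty_schedule_total_is_zero(self):
        summary = v.total_normalised_variance(v.Schedule([]))
        assert summary.norm_var == 0.0
        assert math.isinf(summary.bottleneck_size)

    def test_two_event_total(self):
        sched = v.Schedule(
            [
                v.MechanismEvent("division", n1=1000, n2=1000),
                v.MechanismEvent(
                    "turnover_epoch", n1=1000, duration_days=1.0, turnover_rate=1.0
                ),
            ]
        )
        # division 1/1000 + turnover 2*1*1/1000
        assert v.total_normalised_variance(sched).norm_var == pytest.approx(0.003)

    def test_additivity_of_concatenation(self):
        a = v.Schedule([v.MechanismEvent("division", n1=1000, n2=500)], label="a")
        b = v.Schedule([v.MechanismEvent("amplify", n1=500, n2=1000)], label="b")
        total = v.total_normalised_variance(a + b).norm_var
        parts = (
            v.total_normalised_variance(a).norm_var
            + v.total_normalised_variance(b).norm_var
        )
        assert total == pytest.approx(parts, rel=1e-15)

    def test_saturation_warnings(self):
        epoch = v.MechanismEvent(
            "turnover_epoch", n1=1000, duration_days=400.0, turnover_rate=1.0
        )  # 2*400/1000 = 0.8
        with pytest.warns(v.SegregationWarning):
            v.total_normalised_variance(v.Schedule([epoch]))
        wild = v.Schedule([epoch, epoch])  # 1.6 > fixation bound
        with pytest.warns(v.SegregationWarning, match="capped"):
            summary = v.total_normalised_variance(wild)
        assert summary.norm_var == 1.0


def brute_force_cascade(N0, Nk, k, n_c=1):
    """Independent oracle: per cycle, amplify n -> a*n then divide a*n -> a*n/2,
    summing the corresponding single-event contributions."""
    a = 2.0 * (Nk / N0) ** (1.0 / k)
    total, n = 0.0, float(N0)
    for _ in range(k):
        total += 1.0 / n - 1.0 / (a * n)  # amplification during the cycle
        total += n_c / (a * n)  # division of a*n molecules
        n = a * n / 2.0
    return total


class TestCascade:
    @pytest.mark.parametrize(
        "N0, Nk, k, n_c",
        [
            (1000, 1000, 1, 1),
            (100_000, 670, 29, 1),
            (100_000, 670, 29, 10),
            (670, 5000, 7, 1),
            (5000, 200, 12, 3),
            (100_000, 99_999, 36, 1),
            (50, 5000, 5, 2),
        ],
    )
    def test_closed_form_equals_brute_force(self, N0, Nk, k, n_c):
        assert v.cascade_variance(N0, Nk, k, n_c) == pytest.approx(
            brute_force_cascade(N0, Nk, k, n_c), rel=1e-12
        )

    def test_constant_copy_number_single_cycle(self):
        # amplify 1000 -> 2000 (1/1000 - 1/2000) then divide (1/2000)
        assert v.cascade_variance(1000, 1000, 1, 1) == pytest.approx(1e-3, rel=1e-12)

    def test_constant_copy_number_limit(self):
        # a = 2 exactly: geometric series degenerates to k terms
        assert v.cascade_variance(1000, 1000, 7, 1) == pytest.approx(
            brute_force_cascade(1000, 1000, 7, 1), rel=1e-12
        )

    def test_equivalent_event_schedule_sums_identically(self):
        sched = v.cascade_schedule(100_000, 670, 29)
        total = sum(e.contribution() for e in sched.events)
        assert total == pytest.approx(v.cascade_variance(100_000, 670, 29), rel=1e-12)

    def test_too_fast_depletion_rejected(self):
        with pytest.raises(ValueError, match="halving"):
            v.cascade_variance(100_000, 2, 3)


class TestSelectionTheory:
    def test_mean_identity_at_t0_and_neutral(self):
        assert v.selection_mean(0.7, 0.0, 0.3) == pytest.approx(0.3)
        assert v.selection_mean(0.0, 9.0, 0.3) == pytest.approx(0.3)

    def test_mean_logistic_value(self):
        # 1/(1+e^{-1})
        assert v.selection_mean(1.0, 1.0, 0.5) == pytest.approx(0.7310585786, rel=1e-9)

    def test_mean_is_logit_shift(self):
        # logit(E) = logit(h0) + rho t, for any founder
        for h0 in (0.1, 0.42, 0.9):
            e = v.selection_mean(0.3, 4.0, h0)
            assert v.transform_heteroplasmy(e, h0) == pytest.approx(1.2, rel=1e-10)

    def test_variance_zero_at_start(self):
        assert v.selection_norm_var(0.2, 1.0, 1000, 0.0) == 0.0

    def test_neutral_limit_matches_turnover_scaling(self):
        neutral = 2.0 * 1.0 * 1.0 * 1.0 / 1000  # 2 nu f t / N
        val = v.selection_norm_var(1e-6, 1.0, 1000, 1.0)
        assert val == pytest.approx(neutral, rel=1e-4)
        params = v.SelectionParams(rho=1e-6, turnover_nu=1.0, copy_number=1000, h0=0.5)
        assert v.selection_variance(params, 1.0) == pytest.approx(
            0.25 * neutral, rel=1e-4
        )

    def test_variance_agrees_with_moment_ode_integration(self):
        from scipy.integrate import solve_ivp

        rho, nuf, N = 0.08, 0.7, 800

        def odes(t, y):
            E, V = y
            return [rho * E * (1 - E), 2 * rho * (1 - 2 * E) * V + 2 * nuf * E * (1 - E) / N]

        sol = solve_ivp(odes, (0, 12.0), [0.5, 0.0], rtol=1e-11, atol=1e-14,
                        t_eval=[3.0, 12.0])
        for t, V in zip(sol.t, sol.y[1]):
            E = v.selection_mean(rho, t, 0.5)
            assert v.selection_norm_var(rho, nuf, N, t) == pytest.approx(
                V / (E * (1 - E)), rel=1e-7
            )

    def test_selection_variance_dispatches_neutral(self):
        params = v.SelectionParams(rho=0.0, turnover_nu=0.5, copy_number=500, h0=0.3)
        expected = 0.3 * 0.7 * 2 * 0.5 * 2.0 / 500
        assert v.selection_variance(params, 2.0) == pytest.approx(expected, rel=1e-9)


class TestTransform:
    def test_identity_and_hand_value(self):
        assert v.transform_heteroplasmy(0.37, 0.37) == pytest.approx(0.0, abs=1e-14)
        assert v.transform_heteroplasmy(0.7, 0.5) == pytest.approx(
            math.log(7.0 / 3.0), rel=1e-12
        )

    def test_fixation_is_domain_error(self):
        for h in (0.0, 1.0):
            with pytest.raises(ValueError):
                v.transform_heteroplasmy(h, 0.5)

    @given(
        h=st.floats(0.01, 0.99), h0=st.floats(0.01, 0.99)
    )
    @settings(max_examples=200, deadline=None)
    def test_round_trip(self, h, h0):
        assert v.inverse_transform(v.transform_heteroplasmy(h, h0), h0) == pytest.approx(
            h, rel=1e-12, abs=1e-12
        )

    def test_vectorised(self):
        h = np.array([0.2, 0.5, 0.8])
        z = v.transform_heteroplasmy(h, 0.5)
        np.testing.assert_allclose(v.inverse_transform(z, 0.5), h, rtol=1e-12)
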