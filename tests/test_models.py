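"""One-step maps, log-rate forms, nesting identities and simulation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from andesdyn.models import (
    DivergenceError,
    ModelSpec,
    ModelVariant,
    pop_rate,
    simulate_coupled,
    simulate_trajectory,
    step,
    war_rate,
)
from andesdyn.series import ProxyTimeSeries

finite = dict(allow_nan=False, allow_infinity=False)


class TestPopRate:
    def test_direct_formula_value(self):
        # rN·(1 − N/k + α·C) at rN=0.1, k=1, N=0.5, α=0.2, C=0.3
        r = pop_rate(ModelVariant.POP_CLIMATE,
                     {"rN": 0.1, "k": 1.0, "alpha": 0.2}, 0.5, C_prev=0.3)
        assert r == pytest.approx(0.056, abs=1e-15)

    def test_logistic_equilibrium(self):
        r = pop_rate(ModelVariant.POP_CLIMATE,
                     {"rN": 0.4, "k": 2.0, "alpha": 0.5}, 2.0, C_prev=0.0)
        assert r == pytest.approx(0.0, abs=1e-15)

    @given(N=st.floats(0.01, 10, **finite))
    @settings(max_examples=50, deadline=None)
    def test_beta_zero_reduces_to_plain_logistic(self, N):
        plain = pop_rate(ModelVariant.POP_CLIMATE,
                         {"rN": 0.3, "k": 1.5, "alpha": 0.0}, N, C_prev=0.7)
        no_war = pop_rate(ModelVariant.POP_WARFARE,
                          {"rN": 0.3, "k": 1.5, "beta": 0.0}, N, W_prev=3.0)
        assert plain == pytest.approx(no_war, rel=1e-12)

    def test_monotone_decreasing_in_population(self):
        Ns = np.linspace(0.05, 5, 50)
        rates = pop_rate(ModelVariant.POP_CLIMATE,
                         {"rN": 0.3, "k": 1.0, "alpha": 0.01}, Ns, C_prev=35.0)
        assert np.all(np.diff(rates) < 0)

    def test_missing_forcing_rejected(self):
        with pytest.raises(ValueError, match="C_prev"):
            pop_rate(ModelVariant.POP_CLIMATE, {"rN": 0.1, "k": 1, "alpha": 0.2}, 0.5)

    def test_nonpositive_population_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            pop_rate(ModelVariant.POP_WARFARE,
                     {"rN": 0.1, "k": 1, "beta": 0.2}, 0.0, W_prev=1.0)


class TestWarRate:
    def test_direct_formula_value(self):
        # λ·N + ψ·C − μ at λ=0.02, N=10, ψ=0.5, C=0.4, μ=0.3
        w = war_rate(ModelVariant.WAR_ADDITIVE_CLIMATE,
                     {"lam": 0.02, "mu": 0.3, "psi": 0.5}, 1.0,
                     N_prev=10.0, C_prev=0.4)
        assert w == pytest.approx(0.1, abs=1e-12)

    def test_conflict_equilibrium(self):
        w = war_rate(ModelVariant.WAR_BASIC, {"lam": 0.5, "mu": 0.25}, 2.0,
                     N_prev=0.5)
        assert w == pytest.approx(0.0, abs=1e-15)

    @given(N=st.floats(0.01, 10, **finite), lam=st.floats(0.01, 2, **finite),
           mu=st.floats(0.01, 2, **finite))
    @settings(max_examples=50, deadline=None)
    def test_pressure_with_unit_climate_equals_basic(self, N, lam, mu):
        basic = war_rate(ModelVariant.WAR_BASIC, {"lam": lam, "mu": mu}, 1.0, N_prev=N)
        ratio = war_rate(ModelVariant.WAR_PRESSURE, {"lam": lam, "mu": mu}, 1.0,
                         N_prev=N, C_prev=1.0)
        assert basic == pytest.approx(ratio, rel=1e-12)

    def test_monotone_increasing_in_population(self):
        Ns = np.linspace(0.05, 5, 50)
        rates = war_rate(ModelVariant.WAR_BASIC, {"lam": 0.5, "mu": 0.2}, 1.0,
                         N_prev=Ns)
        assert np.all(np.diff(rates) > 0)

    def test_pressure_division_guard(self):
        with pytest.raises(ZeroDivisionError):
            war_rate(ModelVariant.WAR_PRESSURE, {"lam": 1.0, "mu": 0.1}, 1.0,
                     N_prev=1.0, C_prev=0.0)


class TestNesting:
    @given(N=st.floats(0.01, 5, **finite), C=st.floats(0.1, 50, **finite),
           W=st.floats(0.1, 6, **finite))
    @settings(max_examples=50, deadline=None)
    def test_full_model_with_gamma_zero_is_climate_model(self, N, C, W):
        full = pop_rate(ModelVariant.POP_CLIMATE_WARFARE,
                        {"rN": 0.3, "k": 1.0, "alpha": 0.01, "gamma": 0.0},
                        N, C_prev=C, W_prev=W)
        climate = pop_rate(ModelVariant.POP_CLIMATE,
                           {"rN": 0.3, "k": 1.0, "alpha": 0.01}, N, C_prev=C)
        assert full == pytest.approx(climate, rel=1e-12)

    @given(N=st.floats(0.01, 5, **finite), C=st.floats(0.1, 50, **finite))
    @settings(max_examples=50, deadline=None)
    def test_additive_with_psi_zero_is_basic(self, N, C):
        additive = war_rate(ModelVariant.WAR_ADDITIVE_CLIMATE,
                            {"lam": 0.4, "mu": 0.2, "psi": 0.0}, 1.0,
                            N_prev=N, C_prev=C)
        basic = war_rate(ModelVariant.WAR_BASIC, {"lam": 0.4, "mu": 0.2}, 1.0,
                         N_prev=N)
        assert additive == pytest.approx(basic, rel=1e-12)

    def test_warfare_rate_scale_correspondence(self):
        """The full model's −rN·γ·W term matches the mortality model's
        −β·W term when β = −rN·γ (sign convention: γ<0 harms growth)."""
        rN, k, gamma, N, W = 0.3, 1.0, -0.4, 0.6, 2.0
        beta = -rN * gamma
        full = pop_rate(ModelVariant.POP_CLIMATE_WARFARE,
                        {"rN": rN, "k": k, "alpha": 0.0, "gamma": gamma},
                        N, C_prev=0.0, W_prev=W)
        mortality = pop_rate(ModelVariant.POP_WARFARE,
                             {"rN": rN, "k": k, "beta": beta}, N, W_prev=W)
        assert full == pytest.approx(mortality, rel=1e-12)


class TestStep:
    def test_equilibrium_fixed_point(self):
        nxt = step(ModelVariant.POP_CLIMATE, {"rN": 0.4, "k": 2.0, "alpha": 0.0},
                   {"N": 2.0}, {"C": 10.0})
        assert nxt == pytest.approx(2.0, rel=1e-14)

    def test_exponential_of_rate(self):
        nxt = step(ModelVariant.POP_CLIMATE, {"rN": 0.1, "k": 1.0, "alpha": 0.2},
                   {"N": 0.5}, {"C": 0.3})
        assert nxt == pytest.approx(0.5 * np.exp(0.056), rel=1e-14)

    @pytest.mark.filterwarnings("ignore:rate exceeded")
    @given(rN=st.floats(0.01, 3, **finite), N=st.floats(0.01, 5, **finite),
           alpha=st.floats(-1, 1, **finite), C=st.floats(0.1, 50, **finite))
    @settings(max_examples=100, deadline=None)
    def test_positivity_preserved(self, rN, N, alpha, C):
        nxt = step(ModelVariant.POP_CLIMATE, {"rN": rN, "k": 1.0, "alpha": alpha},
                   {"N": N}, {"C": C})
        assert nxt > 0

    def test_extreme_rate_clipped_with_warning(self):
        with pytest.warns(RuntimeWarning, match="clipped"):
            step(ModelVariant.POP_CLIMATE, {"rN": 10.0, "k": 1.0, "alpha": 10.0},
                 {"N": 0.5}, {"C": 10.0})

    def test_beta_outside_alternative_reading(self):
        params = {"rN": 0.3, "k": 1.0, "beta": 0.05}
        inside = step(ModelVariant.POP_WARFARE, params, {"N": 0.5, "W": 2.0})
        outside = step(ModelVariant.POP_WARFARE, params, {"N": 0.5, "W": 2.0},
                       beta_outside=True)
        expected = 0.5 * np.exp(0.3 * 0.5) - 0.05 * 2.0
        assert outside == pytest.approx(expected, rel=1e-12)
        assert inside != pytest.approx(outside, rel=1e-6)


class TestModelSpec:
    def test_foreign_parameter_rejected(self):
        with pytest.raises(ValueError, match="foreign"):
            ModelSpec(ModelVariant.WAR_BASIC, fixed={"alpha": 0.0})

    def test_free_parameters_exclude_fixed(self):
        spec = ModelSpec(ModelVariant.POP_CLIMATE, fixed={"alpha": 0.0})
        assert spec.free_parameters == ("rN", "k")


class TestSimulate:
    def _climate(self, n=10, level=35.0):
        return ProxyTimeSeries(50 + 25 * np.arange(n), np.full(n, level))

    def test_constant_forcing_at_equilibrium(self):
        clim = self._climate()
        traj = simulate_trajectory(ModelVariant.POP_CLIMATE,
                                   {"rN": 0.3, "k": 1.0, "alpha": 0.0}, 1.0,
                                   {"C": clim})
        np.testing.assert_allclose(traj.values, 1.0, rtol=1e-13)

    def test_matches_manual_step_loop(self):
        clim = self._climate()
        war = ProxyTimeSeries(clim.times, np.linspace(0.5, 3.0, 10))
        params = {"rN": 0.3, "k": 1.0, "alpha": 0.005, "gamma": -0.1}
        traj = simulate_trajectory(ModelVariant.POP_CLIMATE_WARFARE, params, 0.2,
                                   {"C": clim, "W": war})
        manual = [0.2]
        for t in range(1, 10):
            manual.append(step(ModelVariant.POP_CLIMATE_WARFARE, params,
                               {"N": manual[-1]},
                               {"C": clim.values[t - 1], "W": war.values[t - 1]}))
        np.testing.assert_allclose(traj.values, manual, rtol=1e-14)
        np.testing.assert_array_equal(traj.times, clim.times)

    def test_ricker_convergence_to_carrying_capacity(self):
        """With no climate effect and rN in (0, 2) the map converges to k."""
        clim = self._climate(n=400)
        for rN in (0.1, 0.5, 1.0, 1.5, 1.9):
            for start in (0.05, 0.5, 3.0):
                traj = simulate_trajectory(
                    ModelVariant.POP_CLIMATE, {"rN": rN, "k": 1.0, "alpha": 0.0},
                    start, {"C": clim})
                assert traj.values[-1] == pytest.approx(1.0, rel=1e-6), (rN, start)

    def test_divergence_names_step(self):
        clim = self._climate(n=60)
        with pytest.warns(RuntimeWarning):
            with pytest.raises(DivergenceError) as err:
                simulate_trajectory(ModelVariant.WAR_BASIC,
                                    {"lam": 60.0, "mu": 0.0}, 1.0,
                                    {"N": ProxyTimeSeries(clim.times, np.full(60, 2.0)),
                                     "C": clim})
        assert err.value.step_index is not None

    def test_coupled_matches_separate_rates(self):
        clim = self._climate(n=15)
        params = {"rN": 0.3, "k": 1.0, "alpha": 0.004, "gamma": -0.35,
                  "lam": 0.25, "mu": 0.15}
        N, W = simulate_coupled(ModelVariant.POP_CLIMATE_WARFARE,
                                ModelVariant.WAR_BASIC, params, 0.05, 0.3, clim)
        # verify one arbitrary interior step against the one-step maps
        t = 7
        n_next = step(ModelVariant.POP_CLIMATE_WARFARE, params,
                      {"N": N.values[t - 1], "W": W.values[t - 1]},
                      {"C": clim.values[t - 1]})
        assert N.values[t] == pytest.approx(n_next, rel=1e-14)
        assert np.all(N.values > 0) and np.all(W.values > 0)
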