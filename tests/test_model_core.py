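"""Pointwise maps: sigmoid, slope, synaptic kernel, gains."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ctbgsim import (
    Connection,
    ModelSpec,
    POPULATIONS,
    PopulationParams,
    default_model,
    firing_rate,
    gains,
    loop_gain,
    rate_slope,
    rk4_step,
    synaptic_kernel,
    voltage_for_rate,
)
from ctbgsim.model import EXCITATORY_SOURCES, INHIBITORY_SOURCES, nominal_parameter_file


@pytest.fixture(scope="module")
def stn():
    return PopulationParams("z", Q_max=500.0, theta=10.0, is_excitatory=True)


class TestFiringRate:
    def test_midpoint_half_maximum(self, model):
        e = model.populations["e"]
        assert firing_rate(e.theta, e, model.sigma_p) == pytest.approx(150.0)

    def test_saturation_limits(self, stn):
        assert firing_rate(-1e3, stn, 3.3) == pytest.approx(0.0, abs=1e-12)
        assert firing_rate(+1e3, stn, 3.3) == pytest.approx(500.0)

    def test_subthalamic_evaluation(self, stn):
        # S(13 mV) for Q_max=500, theta=10, sigma'=3.3
        expected = 500.0 / (1.0 + math.exp(-3.0 / 3.3))
        assert firing_rate(13.0, stn, 3.3) == pytest.approx(expected)
        assert expected == pytest.approx(356.4, abs=0.05)

    def test_strictly_increasing_and_bounded(self, stn):
        v = np.linspace(-50, 80, 500)
        q = firing_rate(v, stn, 3.3)
        assert np.all(np.diff(q) > 0)
        assert np.all((q > 0) & (q < stn.Q_max))

    def test_nonfinite_potential_rejected(self, stn):
        with pytest.raises(ValueError):
            firing_rate(float("nan"), stn, 3.3)
        with pytest.raises(ValueError):
            firing_rate(0.0, stn, -1.0)


class TestRateSlope:
    def test_maximum_at_half_rate(self, stn):
        assert rate_slope(stn.Q_max / 2, stn, 3.3) == pytest.approx(
            stn.Q_max / (4 * 3.3)
        )

    def test_boundary_zero(self, stn):
        assert rate_slope(0.0, stn, 3.3) == 0.0
        assert rate_slope(stn.Q_max, stn, 3.3) == 0.0

    def test_subthalamic_evaluation(self, stn):
        phi = 500.0 / (1.0 + math.exp(-3.0 / 3.3))
        rho = rate_slope(phi, stn, 3.3)
        assert rho == pytest.approx(31.0, abs=0.05)

    def test_domain_error(self, stn):
        with pytest.raises(ValueError):
            rate_slope(-1.0, stn, 3.3)
        with pytest.raises(ValueError):
            rate_slope(501.0, stn, 3.3)

    @settings(derandomize=True, max_examples=50)
    @given(v=st.floats(min_value=-20.0, max_value=40.0))
    def test_consistent_with_finite_difference(self, v):
        """The slope at S(V) equals dS/dV to relative error < 1e-6."""
        stn = PopulationParams("z", Q_max=500.0, theta=10.0, is_excitatory=True)
        h = 1e-4
        fd = (firing_rate(v + h, stn, 3.3) - firing_rate(v - h, stn, 3.3)) / (2 * h)
        rho = rate_slope(firing_rate(v, stn, 3.3), stn, 3.3)
        assert rho == pytest.approx(fd, rel=1e-6)

    def test_inverse_sigmoid_roundtrip(self, stn):
        for v in (-5.0, 0.0, 13.0, 25.0):
            assert voltage_for_rate(
                firing_rate(v, stn, 3.3), stn, 3.3
            ) == pytest.approx(v, abs=1e-9)


class TestSynapticKernel:
    def test_unit_time_integral(self):
        t = np.linspace(0, 1.0, 200001)
        for a, b in ((50.0, 200.0), (30.0, 31.0), (80.0, 80.0)):
            integral = np.trapezoid(synaptic_kernel(a, b, t), t)
            assert integral == pytest.approx(1.0, abs=1e-6)

    def test_peak_time_closed_form(self):
        # extremum of the biexponential at ln(beta/alpha)/(beta-alpha)
        t_peak = math.log(200.0 / 50.0) / 150.0
        assert t_peak == pytest.approx(9.242e-3, abs=1e-5)
        t = np.linspace(0, 0.05, 50001)
        k = synaptic_kernel(50.0, 200.0, t)
        assert t[np.argmax(k)] == pytest.approx(t_peak, abs=2e-6)

    def test_equal_rate_limit_continuous(self):
        t = np.linspace(0, 0.1, 1001)
        k_limit = synaptic_kernel(50.0, 50.0, t)
        k_near = synaptic_kernel(50.0, 50.0 * (1 + 1e-7), t)
        assert np.allclose(k_near, k_limit, rtol=1e-6, atol=1e-9)

    def test_nonnegative_and_causal_domain(self):
        t = np.linspace(0, 0.5, 1000)
        assert np.all(synaptic_kernel(50.0, 200.0, t) >= 0)
        with pytest.raises(ValueError):
            synaptic_kernel(50.0, 200.0, -1e-3)
        with pytest.raises(ValueError):
            synaptic_kernel(-1.0, 200.0, 0.0)

    def test_matches_integrated_impulse_response(self):
        """Closed form equals RK4 integration of the second-order filter.

        The filter is integrated as v'' = a*b*u - (a+b)v' - a*b*v with a unit
        impulse realized as the initial condition v(0)=0, v'(0)=alpha*beta.
        """
        a, b = 50.0, 200.0
        dt = 1e-5
        n = int(0.1 / dt)
        y = np.array([0.0, a * b])

        def deriv(t, y):
            return np.array([y[1], -(a + b) * y[1] - a * b * y[0]])

        t_samples, vals = [], []
        for k in range(n):
            y = rk4_step(y, k * dt, dt, deriv)
            t_samples.append((k + 1) * dt)
            vals.append(y[0])
        vals = np.array(vals)
        ref = synaptic_kernel(a, b, np.array(t_samples))
        scale = np.max(np.abs(ref))
        assert np.max(np.abs(vals - ref)) / scale < 1e-4


class TestGains:
    def test_zero_coupling_zero_gain(self, model, operating_state):
        g = gains(operating_state, model)
        for key, val in g.G.items():
            nu = model.connection(*key).nu
            if nu == 0:
                assert val == 0.0
            assert np.sign(val) == np.sign(nu)

    def test_sign_partition_by_transmitter_class(self, model, operating_state):
        """Glutamatergic/cholinergic gains positive, GABAergic negative."""
        g = gains(operating_state, model)
        for (target, source), val in g.G.items():
            if source in EXCITATORY_SOURCES:
                assert val > 0, (target, source)
            elif source in INHIBITORY_SOURCES:
                assert val < 0, (target, source)

    def test_cortico_subthalamic_gain_composition(self, model, operating_state):
        g = gains(operating_state, model)
        rho_z = rate_slope(
            operating_state.phi0["z"], model.populations["z"], model.sigma_p
        )
        assert g.G[("z", "e")] == pytest.approx(rho_z * 1.3)

    def test_loop_gain_products(self, model, operating_state):
        g = gains(operating_state, model)
        assert loop_gain(g, []) == 1.0
        assert loop_gain(g, [("d1", "d1")]) < 0
        stn_gpe = loop_gain(g, [("p2", "z"), ("z", "p2")])
        assert stn_gpe < 0  # one excitatory leg, one inhibitory leg
        assert stn_gpe == pytest.approx(g.G[("p2", "z")] * g.G[("z", "p2")])

    def test_missing_edge_rejected(self, model, operating_state):
        g = gains(operating_state, model)
        with pytest.raises(KeyError):
            loop_gain(g, [("e", "z")])


class TestModelSpec:
    def test_packaged_default_matches_nominal_table(self, model):
        """The shipped YAML reproduces the nominal parameter set exactly."""
        packaged = ModelSpec.from_yaml(nominal_parameter_file())
        assert packaged.to_dict() == model.to_dict()

    def test_nominal_values(self, model):
        assert model.sigma_p == 3.3
        assert (model.alpha, model.beta, model.gamma_e) == (50.0, 200.0, 116.0)
        assert model.nu("p2", "z") == 2.4
        assert model.nu("z", "p2") == -0.2
        assert model.connection("s", "e").tau == 0.045
        assert model.connection("e", "s").tau == 0.035
        assert model.populations["z"].Q_max == 500.0
        assert model.populations["p2"].theta == 9.0
        assert len(model.connections) == 23

    def test_sign_invariants_enforced(self):
        with pytest.raises(ValueError):
            Connection("z", "p2", nu=+0.2)  # GABAergic source must be <= 0
        with pytest.raises(ValueError):
            Connection("s", "e", nu=-1.5)  # glutamatergic source must be >= 0
        with pytest.raises(ValueError):
            Connection("s", "e", nu=1.5, tau=-0.01)

    def test_unknown_keys_rejected(self, model):
        d = model.to_dict()
        d["typo_field"] = 1
        with pytest.raises(ValueError):
            ModelSpec.from_dict(d)

    def test_with_updates_and_roundtrip(self, model, tmp_path):
        weak = model.with_updates(p2_z=1.8)
        assert weak.nu("p2", "z") == 1.8
        assert model.nu("p2", "z") == 2.4  # original untouched
        path = tmp_path / "m.yaml"
        weak.to_yaml(path)
        assert ModelSpec.from_yaml(path).to_dict() == weak.to_dict()
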