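import json

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from antisync.model import (
    ChainSpec,
    NetworkSpec,
    NeuronParams,
    XNeuronSpec,
    assemble_network,
    build_chain,
    hr_derivatives,
)


class TestHRDerivatives:
    def test_hand_evaluated_point(self):
        # (0, 1, 0) with the standard constants and no input
        dx, dy, dz = hr_derivatives((0.0, 1.0, 0.0), NeuronParams())
        assert dx == pytest.approx(4.25)
        assert dy == pytest.approx(0.0)
        assert dz == pytest.approx(0.032)

    @given(y=st.floats(-5, 5))
    def test_slow_variable_fixed_at_rest_offset(self, y):
        # z-equation vanishes at x = x_st, z = 0 for any y
        p = NeuronParams()
        _, _, dz = hr_derivatives((p.x_st, y, 0.0), p)
        assert dz == 0.0

    def test_capacitance_scales_fast_equation_only(self):
        state = (0.3, -0.5, 1.1)
        d1 = hr_derivatives(state, NeuronParams(C=1.0))
        d2 = hr_derivatives(state, NeuronParams(C=2.0))
        assert d2[0] == pytest.approx(d1[0] / 2)
        assert d2[1:] == pytest.approx(d1[1:])

    def test_rejects_non_finite_state(self):
        with pytest.raises(ValueError, match="finite"):
            hr_derivatives((np.nan, 0.0, 0.0), NeuronParams())
        with pytest.raises(ValueError, match="finite"):
            hr_derivatives((0.0, 0.0, 0.0), NeuronParams(), coupling_input=np.inf)

    def test_rejects_invalid_params(self):
        with pytest.raises(ValueError):
            NeuronParams(C=0.0)
        with pytest.raises(ValueError):
            NeuronParams(r=-1e-3)
        with pytest.raises(ValueError):
            NeuronParams(J0=np.inf)

    def test_uncoupled_equilibrium_satisfies_all_three_equations(self):
        # independent root-finder cross-check of the vector-field algebra
        from scipy.optimize import fsolve

        p = NeuronParams()
        root, info, ier, _ = fsolve(
            lambda s: hr_derivatives(s, p), x0=[-1.5, -10.0, 1.0], full_output=True
        )
        assert ier == 1
        assert np.allclose(hr_derivatives(root, p), 0.0, atol=1e-9)


class TestBuildChain:
    def test_empty_chain(self):
        c = build_chain(0)
        assert c.C_intermediaries == ()
        assert c.k_slave == 1.7

    def test_three_intermediaries_equispaced(self):
        c = build_chain(3, C_master=1.0, C_slave=0.7)
        assert c.C_intermediaries == pytest.approx((0.925, 0.85, 0.775))

    @given(
        n=st.integers(0, 12),
        C_slave=st.floats(0.1, 2.0),
        gap=st.floats(0.05, 3.0),
        k=st.floats(-5, 5),
    )
    @settings(max_examples=60)
    def test_capacitances_strictly_decreasing_inside_open_interval(
        self, n, C_slave, gap, k
    ):
        C_master = C_slave + gap
        c = build_chain(n, C_master, C_slave, k)
        caps = (c.C_master, *c.C_intermediaries, c.C_slave)
        assert all(a > b for a, b in zip(caps, caps[1:]))

    def test_rejects_slave_not_faster(self):
        with pytest.raises(ValueError, match="anticipation"):
            build_chain(2, C_master=0.7, C_slave=0.7)
        with pytest.raises(ValueError):
            ChainSpec(1, 1.0, 0.7, (1.1,), (1.7,), 1.7)  # intermediary too slow


class TestAssembleNetwork:
    def test_state_dimension(self):
        assert assemble_network(build_chain(0)).dim == 6
        assert assemble_network(build_chain(3), XNeuronSpec()).dim == 18

    def test_zero_coupling_equals_uncoupled_blocks(self):
        chain = ChainSpec(1, 1.0, 0.7, (0.85,), (0.0,), 0.0)
        net = assemble_network(chain, XNeuronSpec(k_MX=0.0, k_SX=0.0))
        rng = np.random.default_rng(0)
        y = rng.normal(size=net.dim)
        dy = net.rhs()(0.0, y)
        for i, p in enumerate(net.neurons):
            expected = hr_derivatives(y[3 * i : 3 * i + 3], p)
            assert dy[3 * i : 3 * i + 3] == pytest.approx(expected)

    def test_identical_fast_variables_kill_coupling(self):
        net = assemble_network(build_chain(2), XNeuronSpec())
        rng = np.random.default_rng(1)
        y = rng.normal(size=net.dim)
        y[0::3] = 0.37  # same x everywhere -> diffusive terms vanish
        dy = net.rhs()(0.0, y)
        for i, p in enumerate(net.neurons):
            expected = hr_derivatives(y[3 * i : 3 * i + 3], p)
            assert dy[3 * i : 3 * i + 3] == pytest.approx(expected)

    def test_master_block_independent_of_downstream(self):
        # unidirectionality: perturbing any downstream state leaves the
        # master's derivatives unchanged
        net = assemble_network(build_chain(2), XNeuronSpec())
        f = net.rhs()
        rng = np.random.default_rng(2)
        y = rng.normal(size=net.dim)
        base = f(0.0, y)[:3]
        for j in range(3, net.dim):
            yp = y.copy()
            yp[j] += 1.234
            assert f(0.0, yp)[:3] == pytest.approx(base)

    def test_x_neuron_receives_master_and_slave_input(self):
        net = assemble_network(build_chain(0), XNeuronSpec(k_MX=3.0, k_SX=-3.0))
        i_x = net.index("X")
        f = net.rhs()
        y = np.zeros(net.dim)
        y[0] = 1.0  # master x
        y[3 * net.index("slave")] = 0.5
        dy = f(0.0, y)
        # input = 3*(1 - 0) - 3*(0.5 - 0) = 1.5, C_X = 1, rest at origin
        base = hr_derivatives((0.0, 0.0, 0.0), net.neurons[i_x])
        assert dy[3 * i_x] == pytest.approx(base[0] + 1.5)

    def test_json_round_trip(self):
        net = assemble_network(build_chain(3), XNeuronSpec(J0X=3.25, C_X=0.7))
        again = NetworkSpec.from_json(net.to_json())
        assert again == net
        doc = json.loads(net.to_json())
        assert [n["name"] for n in doc["neurons"]] == list(net.names)

    def test_edge_validation(self):
        p = NeuronParams()
        with pytest.raises(ValueError, match="out of range"):
            NetworkSpec(("a", "b"), (p, p), ((0, 5, 1.0),))
        with pytest.raises(ValueError, match="self-coupling"):
            NetworkSpec(("a", "b"), (p, p), ((1, 1, 1.0),))
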