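"""Topology, activation, net input, settling and carry-over."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import intentnet as inet
from intentnet.network import EPS, external_term


class TestTopology:
    def test_paper_dimensions(self, topo):
        assert topo.n_units == 48
        assert topo.n_visible == 28

    def test_intend_unit_connectivity(self, topo):
        m = topo.mask
        # intend unit 0 receives from intend 1..13
        assert m[0, 1:14].all()
        # paired inter-valence link, both directions
        assert m[0, 14] and m[14, 0]
        # receives from all hidden-A units, none of hidden-B
        assert m[0, 28:38].all()
        assert not m[0, 38:48].any()

    def test_no_cross_belief_cross_valence_links(self, topo):
        # intend unit 0 <-> not-intend unit 5: different belief AND valence
        assert not inet.make_topology(14, 10).mask[0, 19]
        assert not inet.make_topology(14, 10).mask[19, 0]

    def test_no_self_connections(self, topo):
        assert not np.diag(topo.mask).any()

    def test_hidden_banks_disjoint(self, topo):
        m = topo.mask
        # no hidden-hidden connections at all
        assert not m[28:, 28:].any()
        # hidden B does not touch the intend bank
        assert not m[38:48, 0:14].any()
        assert not m[0:14, 38:48].any()

    def test_degenerate_single_belief(self):
        t = inet.make_topology(1, 0)
        assert t.n_units == 2
        assert t.mask.sum() == 2  # the paired link in both directions
        assert t.fixed_mask.sum() == 2

    def test_invalid_belief_count(self):
        with pytest.raises(ValueError):
            inet.make_topology(0, 10)


class TestInitWeights:
    def test_deterministic(self, topo):
        a = inet.init_weights(topo, seed=1, scale=0.1)
        b = inet.init_weights(topo, seed=1, scale=0.1)
        assert np.array_equal(a.w, b.w) and np.array_equal(a.bias, b.bias)

    def test_inter_valence_fixed(self, topo):
        for seed in (0, 1, 99):
            w = inet.init_weights(topo, seed=seed)
            assert np.all(w.w[topo.fixed_mask] == -0.20)

    def test_zero_scale(self, topo):
        w = inet.init_weights(topo, seed=1, scale=0.0)
        assert np.all(w.w[topo.trainable_mask] == 0.0)

    def test_masked_entries_zero(self, topo):
        w = inet.init_weights(topo, seed=3, scale=0.5)
        assert np.all(w.w[~topo.mask] == 0.0)
        w.validate()

    def test_amplifier_init_valid(self, topo):
        w = inet.amplifier_init(topo, seed=5)
        w.validate()
        assert np.all(w.w[topo.fixed_mask] == -0.20)


class TestActivationFn:
    def test_midpoint(self):
        assert inet.activation_fn(0.0, gain=1.0) == 0.5

    def test_matches_closed_form_logistic(self):
        # independent evaluation of 1/(1+e^-x)
        assert inet.activation_fn(10.0, gain=1.0) == pytest.approx(
            1.0 / (1.0 + np.exp(-10.0)), abs=1e-12
        )

    @given(st.floats(-30, 30))
    def test_symmetry(self, x):
        f = inet.activation_fn
        assert f(x) + f(-x) == pytest.approx(1.0, abs=1e-9)

    @given(st.floats(-1e6, 1e6), st.floats(0.1, 10))
    def test_range_clipped(self, x, gain):
        y = inet.activation_fn(x, gain=gain)
        assert EPS <= y <= 1 - EPS

    def test_strictly_increasing(self):
        xs = np.linspace(-5, 5, 101)
        ys = inet.activation_fn(xs, gain=2.0)
        assert np.all(np.diff(ys) > 0)

    def test_invalid_gain(self):
        with pytest.raises(ValueError):
            inet.activation_fn(0.0, gain=0.0)


class TestNetInput:
    def test_clamp_only(self, tiny_topo):
        w = inet.init_weights(tiny_topo, seed=0, scale=0.0)
        w.bias[:] = 0.0
        w.w[tiny_topo.fixed_mask] = 0.0
        state = inet.ActivationState(np.full(tiny_topo.n_units, 0.5))
        x = np.array([1, 0, 1, 0, 1, 0])
        net = inet.net_input(state, w, inet.ClampedInput(x, 0.5))
        assert net[:6] == pytest.approx(0.5 * x)
        assert net[6:] == pytest.approx(0.0)  # hidden units get no external term

    def test_clamp_zero_ignores_pattern(self, tiny_weights, tiny_topo):
        state = inet.ActivationState(
            np.random.default_rng(0).uniform(0.2, 0.8, tiny_topo.n_units)
        )
        n1 = inet.net_input(state, tiny_weights, inet.ClampedInput(np.array([1, 1, 1, 0, 0, 0]), 0.0))
        n2 = inet.net_input(state, tiny_weights, inet.ClampedInput(np.array([0, 0, 0, 1, 1, 1]), 0.0))
        assert np.array_equal(n1, n2)

    def test_matches_double_loop_oracle(self, tiny_weights, tiny_topo):
        rng = np.random.default_rng(7)
        a = rng.uniform(0.1, 0.9, tiny_topo.n_units)
        x = np.array([1, 0, 0, 0, 1, 1])
        c = 0.3
        net = inet.net_input(
            inet.ActivationState(a), tiny_weights, inet.ClampedInput(x, c)
        )
        for j in range(tiny_topo.n_units):
            expected = tiny_weights.bias[j]
            for k in range(tiny_topo.n_units):
                expected += tiny_weights.w[j, k] * a[k]
            if j < tiny_topo.n_visible:
                expected += c * x[j]
            assert net[j] == pytest.approx(expected, rel=1e-12)

    def test_dimension_mismatch(self, tiny_weights, tiny_topo):
        state = inet.ActivationState(np.full(5, 0.5))
        with pytest.raises(ValueError):
            inet.net_input(state, tiny_weights, inet.ClampedInput(np.zeros(6), 0.5))


class TestSettle:
    def test_zero_network_rests_at_half(self, tiny_topo):
        w = inet.init_weights(tiny_topo, seed=0, scale=0.0)
        w.bias[:] = 0.0
        w.w[tiny_topo.fixed_mask] = 0.0
        w.inter_valence = 0.0
        traj = inet.settle(w, inet.ClampedInput(np.array([1, 0, 1, 0, 1, 0]), 0.0))
        for st_ in traj:
            assert st_.activations == pytest.approx(0.5)

    def test_trajectory_length_and_cycles(self, tiny_weights):
        traj = inet.settle(tiny_weights, inet.ClampedInput(np.array([1, 1, 0, 0, 0, 1]), 0.5), n_cycles=9)
        assert len(traj) == 9
        assert [s.cycle for s in traj] == list(range(1, 10))

    def test_deterministic(self, tiny_weights):
        inp = inet.ClampedInput(np.array([1, 0, 0, 0, 1, 1]), 0.5)
        t1 = inet.settle(tiny_weights, inp)
        t2 = inet.settle(tiny_weights, inp)
        for a, b in zip(t1, t2):
            assert np.array_equal(a.activations, b.activations)

    def test_range_invariant_under_huge_weights(self, tiny_topo):
        w = inet.init_weights(tiny_topo, seed=1, scale=50.0)
        traj = inet.settle(w, inet.ClampedInput(np.array([1, 1, 1, 0, 0, 0]), 1.0))
        for s in traj:
            assert np.all(s.activations >= EPS) and np.all(s.activations <= 1 - EPS)

    def test_bank_swap_equivariance(self, tiny_topo):
        """Relabeling intend<->not-intend (and their hidden banks) commutes
        with the whole settling computation."""
        nb, nh = tiny_topo.n_beliefs, tiny_topo.n_hidden_per_bank
        perm = np.concatenate([
            np.arange(nb, 2 * nb),          # not-intend -> intend slot
            np.arange(0, nb),               # intend -> not-intend slot
            np.arange(2 * nb + nh, 2 * nb + 2 * nh),  # hidden B -> A slot
            np.arange(2 * nb, 2 * nb + nh),           # hidden A -> B slot
        ])
        w = inet.init_weights(tiny_topo, seed=9, scale=0.4)
        w_sw = inet.WeightSet(tiny_topo, w.w[np.ix_(perm, perm)], w.bias[perm])
        x = np.array([1, 0, 1, 0, 1, 0])
        inp = inet.ClampedInput(x, 0.5)
        inp_sw = inet.ClampedInput(x[np.concatenate([np.arange(nb, 2 * nb), np.arange(nb)])], 0.5)
        rng = np.random.default_rng(4)
        init = rng.uniform(0.2, 0.8, tiny_topo.n_units)
        t = inet.settle(w, inp, init_state=inet.ActivationState(init))
        t_sw = inet.settle(w_sw, inp_sw, init_state=inet.ActivationState(init[perm]))
        for a, b in zip(t, t_sw):
            assert a.activations[perm] == pytest.approx(b.activations, abs=1e-12)

    def test_clamp_zero_invariance(self, tiny_weights):
        t1 = inet.settle(tiny_weights, inet.ClampedInput(np.array([1, 1, 1, 0, 0, 0]), 0.0))
        t2 = inet.settle(tiny_weights, inet.ClampedInput(np.array([0, 1, 0, 1, 0, 1]), 0.0))
        for a, b in zip(t1, t2):
            assert np.array_equal(a.activations, b.activations)


class TestCarryover:
    def test_zero_kappa_resets_to_rest(self):
        prev = inet.ActivationState(np.full(6, 0.9))
        s = inet.carryover_state(prev, kappa=0.0, rest=0.5)
        assert s.activations == pytest.approx(0.5)

    def test_full_kappa_copies(self):
        prev = inet.ActivationState(np.linspace(0.1, 0.9, 6))
        s = inet.carryover_state(prev, kappa=1.0)
        assert s.activations == pytest.approx(prev.activations)

    def test_partial_carryover_arithmetic(self):
        prev = inet.ActivationState(np.full(4, 0.9))
        s = inet.carryover_state(prev, kappa=0.1, rest=0.5)
        assert s.activations == pytest.approx(0.54)

    def test_no_previous_pattern(self):
        s = inet.carryover_state(None, kappa=0.1, rest=0.5, n_units=7)
        assert s.activations == pytest.approx(0.5)
        assert s.activations.size == 7


class TestSerialization:
    def test_round_trip_exact(self, topo, tmp_path):
        w = inet.amplifier_init(topo, seed=17)
        path = tmp_path / "w.json"
        inet.save_weights(w, path)
        w2 = inet.load_weights(path)
        assert np.array_equal(w.w, w2.w)
        assert np.array_equal(w.bias, w2.bias)
        assert w2.topology.n_beliefs == 14
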