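"""Unit and property tests for the firing-rate ring model."""

import numpy as np
import pytest

from conftest import decoupled_spec, random_two_unit_spec
from vipcircuit import protocols
from vipcircuit.ratenet import (
    CellClass,
    ConnectionSpec,
    RateNetworkSpec,
    StimulusTrace,
    build_ring,
    default_spec,
    fixed_point,
    gain,
    integrate,
    ring_distance,
    step_gating,
    synaptic_input,
)


class TestGain:
    @pytest.mark.parametrize(
        "x,expected",
        [(1.0, 5.33), (0.0, 0.0), (4.0, 10.66), (-3.0, 0.0), (0.25, 2.665)],
    )
    def test_square_root_transfer(self, x, expected):
        assert gain(x) == pytest.approx(expected)

    def test_vectorized_and_rectified(self):
        out = gain(np.array([-1.0, 0.0, 1.0, 4.0]))
        assert np.allclose(out, [0.0, 0.0, 5.33, 10.66])


class TestRingStructure:
    def test_periodic_ring_distance(self):
        assert ring_distance(0, 6, 7) == 1  # populations 1 and 7 are neighbours
        assert ring_distance(0, 3, 7) == 3

    def test_nearest_neighbour_pyr_pyr_targets(self, default_network):
        edges = [
            (q, p)
            for (pre, q, post, p, w) in default_network.edges()
            if pre is CellClass.PYR and post is CellClass.PYR and q != p
        ]
        targets = {q: [] for q in range(1, 8)}
        for q, p in edges:
            targets[q].append(p)
        for q, tgt in targets.items():
            assert len(tgt) == 2, "each Pyr population projects to exactly 2 others"
            assert all(ring_distance(q - 1, p - 1, 7) == 1 for p in tgt)

    def test_inter_pyr_sst_edge_count(self, default_network):
        n = sum(
            1
            for (pre, q, post, p, w) in default_network.edges()
            if pre is CellClass.PYR and post is CellClass.SST and q != p
        )
        assert n == 42  # ordered pairs excluding self on a 7-ring

    def test_ring_symmetry_of_inter_input(self, default_network):
        # total inter-population weight converging on each population is equal
        totals = np.zeros(7)
        for pre, q, post, p, w in default_network.edges():
            if q != p:
                totals[p - 1] += w
        assert np.allclose(totals, totals[0])

    def test_bad_profile_length_rejected(self):
        conns = (
            ConnectionSpec(
                CellClass.PYR, CellClass.SST, "inter", 10.0, 2.0, (1.0,)
            ),
        )
        spec = RateNetworkSpec(
            intrinsic_input={CellClass.PYR: 1.0}, connections=conns
        )
        with pytest.raises(Exception, match="distance_profile"):
            build_ring(spec)

    def test_weight_sign_convention_enforced(self):
        with pytest.raises(ValueError, match="sign"):
            ConnectionSpec(CellClass.SST, CellClass.PYR, "intra", 5.0, 6.0)
        with pytest.raises(ValueError, match="sign"):
            ConnectionSpec(CellClass.PYR, CellClass.PYR, "intra", -5.0, 2.0)


class TestSynapticInput:
    def test_zero_gating_gives_zero(self, default_network):
        S = np.zeros((default_network.n_connections, 7))
        assert np.all(synaptic_input(default_network, S) == 0)

    def test_single_edge(self):
        conns = (ConnectionSpec(CellClass.PYR, CellClass.SST, "intra", 2.0, 2.0),)
        net = build_ring(
            RateNetworkSpec(intrinsic_input={CellClass.PYR: 1.0}, connections=conns)
        )
        S = np.zeros((1, 7))
        S[0, 3] = 0.5
        syn = synaptic_input(net, S)
        assert syn[3, CellClass.SST.value] == pytest.approx(1.0)
        syn[3, CellClass.SST.value] = 0.0
        assert np.all(syn == 0)

    def test_matches_brute_force_edge_loop(self):
        rng = np.random.default_rng(7)
        spec = default_spec()
        net = build_ring(spec)
        S = rng.uniform(0, 0.5, size=(net.n_connections, 7))
        syn = synaptic_input(net, S)
        # independent oracle: loop over every (connection, pre-pop, post-pop)
        expected = np.zeros((7, 4))
        for ci, conn in enumerate(spec.connections):
            for p in range(7):
                for q in range(7):
                    if conn.scope == "intra":
                        mult = 1.0 if p == q else 0.0
                    elif p == q:
                        mult = 0.0
                    else:
                        d = ring_distance(p, q, 7)
                        mult = conn.distance_profile[d - 1]
                    expected[p, conn.post.value] += conn.weight * mult * S[ci, q]
        assert np.allclose(syn, expected, atol=1e-12)

    def test_dimension_mismatch(self, default_network):
        with pytest.raises(ValueError):
            synaptic_input(default_network, np.zeros((2, 7)))


class TestGating:
    def test_pure_decay(self):
        s = step_gating(1.0, 0.0, dt=5.0, decay_tau=10.0)
        s = step_gating(s, 0.0, dt=5.0, decay_tau=10.0)
        assert s == pytest.approx(np.exp(-1.0))

    @pytest.mark.parametrize("tau,f,expected", [(10.0, 10.0, 0.1), (20.0, 5.0, 0.1)])
    def test_steady_state(self, tau, f, expected):
        s = 0.0
        for _ in range(5000):
            s = step_gating(s, f, dt=tau / 4, decay_tau=tau)
        assert s == pytest.approx(expected, rel=1e-6)

    def test_matches_closed_form_under_constant_rate(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            tau = rng.uniform(2, 30)
            f = rng.uniform(0, 40)
            s0 = rng.uniform(0, 0.5)
            t = rng.uniform(1, 100)
            n = 200
            s = s0
            for _ in range(n):
                s = step_gating(s, f, dt=t / n, decay_tau=tau)
            closed = tau / 1000.0 * f * (1 - np.exp(-t / tau)) + s0 * np.exp(-t / tau)
            assert s == pytest.approx(closed, rel=1e-4, abs=1e-9)

    def test_oversized_step_rejected(self):
        with pytest.raises(ValueError, match="too large"):
            step_gating(0.0, 1.0, dt=6.0, decay_tau=10.0)


class TestIntegrate:
    def test_decoupled_steady_state_is_gain_of_drive(self):
        net = build_ring(decoupled_spec(intrinsic={c: 1.0 for c in CellClass}))
        traj = integrate(net, duration=500.0, dt=0.1, record_every=10)
        assert np.allclose(traj.rates[-1], 5.33, atol=1e-6)

    def test_decoupled_matches_analytic_relaxation(self):
        drive = {c: 2.0 for c in CellClass}
        net = build_ring(decoupled_spec(intrinsic=drive))
        traj = integrate(net, duration=100.0, dt=0.1, record_every=1)
        expected = gain(2.0) * (1.0 - np.exp(-traj.times / 10.0))
        assert np.allclose(traj.rates[:, 0, 0], expected, atol=1e-6)

    def test_rates_nonnegative_on_default_protocol(self, default_network):
        traj = integrate(
            default_network, protocols.static_object(), duration=1000.0, record_every=10
        )
        assert traj.rates.min() >= 0.0

    def test_steady_state_reached_within_100ms_without_ipps(self):
        # with surround suppression removed, transients last ~100 ms
        net = build_ring(default_spec(ipps=0.0))
        traj = integrate(net, protocols.static_object(), duration=500.0, record_every=10)
        late = traj.rates[(traj.times >= 400) & (traj.times < 500)].mean(axis=0)
        at_150 = traj.rates[np.searchsorted(traj.times, 150.0)]
        assert np.allclose(at_150, late, atol=0.15)

    def test_deterministic(self, default_network):
        stim = protocols.static_object()
        a = integrate(default_network, stim, duration=300.0, record_every=10)
        b = integrate(default_network, stim, duration=300.0, record_every=10)
        assert np.array_equal(a.rates, b.rates)

    def test_ring_equivariance(self):
        """Shifting the stimulated population rotates the whole response."""
        spec = default_spec()
        net = build_ring(spec)
        k = 2
        t4 = integrate(net, protocols.static_object(target_population=4),
                       duration=600.0, record_every=10)
        t6 = integrate(net, protocols.static_object(target_population=4 + k),
                       duration=600.0, record_every=10)
        assert np.allclose(np.roll(t4.rates, k, axis=1), t6.rates, atol=1e-8)

    def test_stimulus_population_mismatch_rejected(self, default_network):
        bad = StimulusTrace(np.array([0.0, 100.0]), np.zeros((1, 5)))
        with pytest.raises(ValueError):
            integrate(default_network, bad, duration=100.0)


class TestFixedPoint:
    def test_decoupled_unit_drive(self):
        net = build_ring(decoupled_spec(intrinsic={c: 1.0 for c in CellClass}))
        fp = fixed_point(net)
        assert np.allclose(fp, 5.33, atol=1e-8)

    def test_symmetric_ring_has_uniform_rates(self):
        net = build_ring(default_spec(ipps=0.0))
        fp = fixed_point(net, x0=np.full(28, 8.0))
        assert np.allclose(fp, fp[0], atol=1e-8)

    def test_agrees_with_long_integration_on_stable_draws(self):
        """Oracle agreement on >= 20 random small networks (stable ones)."""
        rng = np.random.default_rng(11)
        checked = 0
        attempts = 0
        while checked < 20 and attempts < 200:
            attempts += 1
            spec = random_two_unit_spec(rng)
            net = build_ring(spec)
            traj = integrate(net, duration=2000.0, dt=0.1, record_every=10)
            tail = traj.rates[traj.times >= 1500.0]
            if tail.std(axis=0).max() > 1e-7:  # oscillatory/unstable draw
                continue
            fp = fixed_point(net, x0=tail[-1].reshape(-1))
            assert np.allclose(fp, tail[-1], atol=1e-6)
            checked += 1
        assert checked >= 20


class TestStimulusTrace:
    def test_validation(self):
        with pytest.raises(ValueError):
            StimulusTrace(np.array([0.0, 0.0]), np.zeros((1, 7)))
        with pytest.raises(ValueError):
            StimulusTrace(np.array([0.0, 1.0]), -np.ones((1, 7)))

    def test_lookup_outside_bins_is_zero(self):
        tr = StimulusTrace(np.array([100.0, 200.0]), np.full((1, 7), 0.5))
        assert np.all(tr.at(50.0) == 0)
        assert np.all(tr.at(150.0) == 0.5)
        assert np.all(tr.at(200.0) == 0)
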