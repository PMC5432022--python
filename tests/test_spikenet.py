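"""LIF dynamics, wiring statistics and determinism of the column grid."""

import numpy as np
import pytest

from vipcircuit.ratenet import CellClass
from vipcircuit.spikenet import (
    BackgroundDrive,
    GridSpec,
    LifParams,
    SynapseRule,
    SynapseTable,
    V1Network,
    build_grid,
    default_grid_config,
    lif_fi_rate,
    set_background_state,
    simulate,
)


def quiet_background():
    return BackgroundDrive(
        rates={c: 0.0 for c in CellClass},
        weights={c: 0.0 for c in CellClass},
    )


def tiny_grid(**kw):
    return GridSpec(cells_per_column_full=80, scale=0.5, rows=2, cols=2, **kw)


def no_synapses():
    return SynapseTable(
        rules=(
            SynapseRule(CellClass.PYR, CellClass.PYR, "intra", 0.0, 0.0),
            SynapseRule(CellClass.PYR, CellClass.PV, "inter", 0.0, 0.0, reach=1),
            SynapseRule(CellClass.PYR, CellClass.SST, "inter", 0.0, 0.0, reach=2),
        ),
        thalamic_probability=0.0,
        thalamic_weight=0.0,
    )


class TestLifSingleNeuron:
    def test_subthreshold_drive_never_spikes(self):
        net = V1Network(tiny_grid(), no_synapses(), quiet_background(), wiring_seed=0)
        p = net.lif
        sd = simulate(net, None, duration=500.0, dt=0.1, seed=0,
                      external_current=0.9 * p.rheobase)
        assert len(sd.times) == 0

    def test_isi_matches_closed_form(self):
        net = V1Network(tiny_grid(), no_synapses(), quiet_background(), wiring_seed=0)
        p = net.lif
        current = 1.5 * p.rheobase
        sd = simulate(net, None, duration=1000.0, dt=0.05, seed=0,
                      external_current=current)
        one = sd.times[sd.neuron_ids == 0]
        isi = np.diff(one)
        expected = 1000.0 / lif_fi_rate(current, p)
        assert isi.std() < 1e-9  # deterministic drive -> regular firing
        assert isi.mean() == pytest.approx(expected, rel=0.02)

    def test_fi_curve_fits_square_root_gain(self):
        """The Pyr F-I curve is approximated by 5.33*sqrt(I - theta) to <10%
        over the fitting range."""
        from scipy.optimize import curve_fit

        p = LifParams()
        current = np.linspace(1.02 * p.rheobase, 2.0 * p.rheobase, 50)
        f = lif_fi_rate(current, p)
        popt, _ = curve_fit(
            lambda x, a, th: a * np.sqrt(np.maximum(x - th, 0.0)),
            current, f, p0=[5.0, p.rheobase],
        )
        slope, theta = popt
        fit = slope * np.sqrt(np.maximum(current - theta, 0.0))
        assert slope == pytest.approx(5.33, rel=0.02)
        assert np.max(np.abs(fit - f) / f) < 0.10

    def test_refractory_period_enforced(self):
        net = V1Network(tiny_grid(), no_synapses(), quiet_background(), wiring_seed=0)
        sd = simulate(net, None, duration=500.0, dt=0.1, seed=0,
                      external_current=10.0 * net.lif.rheobase)
        for nid in np.unique(sd.neuron_ids)[:5]:
            isi = np.diff(sd.times[sd.neuron_ids == nid])
            assert np.all(isi >= net.lif.t_ref - 1e-9)


@pytest.fixture(scope="module")
def small_net():
    grid = GridSpec(cells_per_column_full=400, scale=0.1)
    _, table, bg = default_grid_config()
    return V1Network(grid, table, bg, wiring_seed=7)


class TestWiring:
    @pytest.mark.parametrize(
        "pre,post,scope",
        [
            (CellClass.PYR, CellClass.PYR, "intra"),
            (CellClass.VIP, CellClass.SST, "intra"),
            (CellClass.SST, CellClass.PYR, "intra"),
            (CellClass.PYR, CellClass.SST, "inter"),
            (CellClass.PYR, CellClass.PV, "inter"),
        ],
    )
    def test_edge_counts_near_binomial_expectation(self, small_net, pre, post, scope):
        n = small_net.edge_count(pre, post, scope)
        mu = small_net.expected_edge_count(pre, post, scope)
        assert abs(n - mu) < 4 * np.sqrt(mu)

    def test_no_inhibitory_long_range_axons(self, small_net):
        """Inhibitory cells project only within their own column."""
        for pre in (CellClass.PV, CellClass.SST, CellClass.VIP):
            for post in CellClass:
                assert small_net.edge_count(pre, post, "inter") == 0

    def test_thalamus_targets_only_its_column(self, small_net):
        coo = small_net.W_lgn.tocoo()
        lgn_col = coo.row // 100
        assert np.array_equal(lgn_col, small_net.column_of[coo.col])

    def test_same_seed_reproduces_wiring(self):
        grid = tiny_grid()
        _, table, bg = default_grid_config()
        a = V1Network(grid, table, bg, wiring_seed=3)
        b = V1Network(grid, table, bg, wiring_seed=3)
        for ch in a.W:
            assert (a.W[ch] != b.W[ch]).nnz == 0
        assert (a.W_lgn != b.W_lgn).nnz == 0
        assert np.array_equal(a.recorded_mask, b.recorded_mask)

    def test_recorded_subset_is_tenth_of_pyr(self, small_net):
        n_pyr = int((small_net.class_of == CellClass.PYR.value).sum())
        assert small_net.recorded_mask.sum() == n_pyr // 10
        assert np.all(
            small_net.class_of[small_net.recorded_mask] == CellClass.PYR.value
        )

    def test_scaled_counts_validated(self):
        with pytest.raises(ValueError, match="scale"):
            GridSpec(scale=0.0)

    def test_sst_reach_exceeds_pv_reach(self):
        with pytest.raises(ValueError, match="reach"):
            SynapseTable(
                rules=(
                    SynapseRule(CellClass.PYR, CellClass.SST, "inter", 0.1, 1.0, reach=1),
                    SynapseRule(CellClass.PYR, CellClass.PV, "inter", 0.1, 1.0, reach=2),
                )
            )


class TestBackgroundState:
    def test_states_set_printed_fiber_rates(self):
        net = build_grid(tiny_grid(), no_synapses(), quiet_background(), seed=0)
        low = set_background_state(net, "low")
        high = set_background_state(net, "high")
        assert low.background.rates[CellClass.VIP] == 16.0
        assert high.background.rates[CellClass.VIP] == 20.0

    def test_only_vip_rate_changes(self):
        _, table, bg = default_grid_config()
        net = V1Network(tiny_grid(), table, bg, wiring_seed=0)
        high = set_background_state(net, "high")
        for c in (CellClass.PYR, CellClass.PV, CellClass.SST):
            assert high.background.rates[c] == net.background.rates[c]
        assert high.W is net.W  # wiring untouched

    def test_toggle_is_involution(self):
        net = build_grid(seed=0)
        back = set_background_state(set_background_state(net, "high"), "low")
        assert back.background.rates == net.background.rates

    def test_unknown_state_rejected(self):
        net = build_grid(tiny_grid(), no_synapses(), quiet_background(), seed=0)
        with pytest.raises(ValueError):
            set_background_state(net, "medium")


class TestSimulateDeterminism:
    def test_identical_seeds_identical_spikes(self):
        grid = tiny_grid()
        _, table, bg = default_grid_config()
        net = V1Network(grid, table, bg, wiring_seed=1)
        a = simulate(net, None, duration=200.0, dt=0.5, seed=5)
        b = simulate(net, None, duration=200.0, dt=0.5, seed=5)
        assert np.array_equal(a.times, b.times)
        assert np.array_equal(a.neuron_ids, b.neuron_ids)

    def test_noise_seed_changes_spikes(self):
        grid = tiny_grid()
        _, table, bg = default_grid_config()
        net = V1Network(grid, table, bg, wiring_seed=1)
        a = simulate(net, None, duration=200.0, dt=0.5, seed=5)
        b = simulate(net, None, duration=200.0, dt=0.5, seed=6)
        assert len(a.times) != len(b.times) or not np.array_equal(a.times, b.times)
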