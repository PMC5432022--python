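"""Spiking V1 model: LIF neurons on a 16x12 grid of cortical columns.

Each column holds the four cell classes (Pyr, PV, SST, VIP) in fixed
proportions; columns are wired with the same disinhibitory motif as the
firing-rate ring, plus the two inter-columnar inhibitory pathways of the
study: long-range surround suppression carried by Pyr -> SST projections
with a distance-decaying connection probability, and short-range
inhibition carried by Pyr -> PV projections to nearest-neighbour columns
(all inhibitory axons stay within their column, so cross-column inhibition
is recruited through the excitatory projections onto interneurons).
Inter-columnar connections use periodic (torus) boundary conditions.

Neurons are leaky integrate-and-fire with exponential postsynaptic
currents, advanced with exact integration at a fixed step: the subthreshold
propagators are exact for any dt, so dt only quantizes spike times.  The
membrane capacitance is set so the Pyr F-I curve is fitted by the
square-root gain 5.33*sqrt(I - theta) used in the rate model.

Thalamic input is topographic: the 100 LGN cells of image patch (i, j)
project only to neurons of column (i, j).  Background drive is a single
external Poisson fiber per neuron with a class-specific rate; locomotion
(VIP depolarization) is modelled by raising the VIP fiber rate from 16 Hz
(low state) to 20 Hz (high state).

At full scale a column has ~2000 cells; the ``scale`` factor shrinks cell
counts while connection probabilities grow inversely (capped at 1) to
preserve expected synaptic in-degree.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import sparse

from .ratenet import CellClass

__all__ = [
    "LifParams",
    "GridSpec",
    "SynapseRule",
    "SynapseTable",
    "BackgroundDrive",
    "SpikeData",
    "V1Network",
    "build_grid",
    "simulate",
    "set_background_state",
    "default_grid_config",
    "lif_fi_rate",
]

GRID_COLS = 16
GRID_ROWS = 12
N_COLUMNS = GRID_COLS * GRID_ROWS

# class composition of a column (fractions of cells per class)
CLASS_FRACTIONS = {
    CellClass.PYR: 0.80,
    CellClass.PV: 0.08,
    CellClass.SST: 0.06,
    CellClass.VIP: 0.06,
}

# synaptic current channels: excitatory, fast inhibition (PV, VIP),
# slow inhibition (SST)
CH_EXC, CH_INH_FAST, CH_INH_SLOW = 0, 1, 2
_CHANNEL_OF_PRE = {
    CellClass.PYR: CH_EXC,
    CellClass.PV: CH_INH_FAST,
    CellClass.VIP: CH_INH_FAST,
    CellClass.SST: CH_INH_SLOW,
}


@dataclass(frozen=True)
class LifParams:
    """Leaky integrate-and-fire neuron with exponential synaptic currents.

    The capacitance makes the deterministic F-I curve match the rate
    model's gain 5.33*sqrt(I - theta) to <10% over [1.02, 2] x rheobase.
    """

    tau_m: float = 10.0  # ms
    c_m: float = 206.8  # pF
    v_rest: float = -70.0  # mV
    v_reset: float = -70.0
    v_thresh: float = -50.0
    t_ref: float = 2.0  # ms
    tau_syn: tuple[float, float, float] = (2.0, 6.0, 10.0)  # exc, fast inh, slow inh

    def __post_init__(self):
        if self.v_thresh <= self.v_reset:
            raise ValueError("threshold must exceed reset")
        if self.t_ref < 0:
            raise ValueError("refractory period must be >= 0")

    @property
    def rheobase(self) -> float:
        """Minimum sustained current (pA) that elicits spiking."""
        return self.c_m * (self.v_thresh - self.v_rest) / self.tau_m


def lif_fi_rate(current_pA, params: LifParams | None = None):
    """Closed-form LIF firing rate (Hz) under constant current."""
    p = params or LifParams()
    current_pA = np.asarray(current_pA, float)
    r_mohm = p.tau_m / p.c_m * 1000.0
    v_inf = current_pA * r_mohm / 1000.0  # mV above rest
    dv = p.v_thresh - p.v_rest
    out = np.zeros_like(current_pA)
    ok = v_inf > dv
    out[ok] = 1000.0 / (p.t_ref + p.tau_m * np.log(v_inf[ok] / (v_inf[ok] - dv)))
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class GridSpec:
    """Grid geometry and per-column cell counts at a given scale."""

    cells_per_column_full: int = 2000
    scale: float = 0.05
    rows: int = GRID_ROWS
    cols: int = GRID_COLS

    def __post_init__(self):
        if not 0 < self.scale <= 1:
            raise ValueError("scale must be in (0, 1]")
        if min(self.class_counts().values()) < 1:
            raise ValueError("scaled cell count of zero for some class")

    @property
    def n_columns(self) -> int:
        return self.rows * self.cols

    def class_counts(self) -> dict:
        return {
            c: max(1, int(round(self.cells_per_column_full * self.scale * f)))
            for c, f in CLASS_FRACTIONS.items()
        }

    @property
    def cells_per_column(self) -> int:
        return sum(self.class_counts().values())


@dataclass(frozen=True)
class SynapseRule:
    """One (pre-class, post-class, scope) pathway of the grid model.

    ``probability`` is the full-scale pairwise connection probability;
    ``weight`` the PSC jump in pA (signed by pre class); ``reach`` the
    inter-columnar Chebyshev radius (0 for intra); ``decay`` an optional
    probability decay length (in columns) for long-range pathways.
    """

    pre: CellClass
    post: CellClass
    scope: str
    probability: float
    weight: float
    reach: int = 0
    decay: float | None = None
    provenance: str = "calibrated"

    def __post_init__(self):
        if not 0 <= self.probability <= 1:
            raise ValueError("probability must be in [0, 1]")
        if (self.pre is CellClass.PYR) != (self.weight >= 0):
            raise ValueError("weight sign must match presynaptic class")

    def prob_at(self, distance: int, scale: float) -> float:
        """Scaled connection probability at a column distance."""
        if self.scope == "intra":
            p = self.probability if distance == 0 else 0.0
        else:
            if distance == 0 or distance > self.reach:
                return 0.0
            p = self.probability
            if self.decay is not None:
                p = p * np.exp(-(distance - 1) / self.decay)
        return min(1.0, p / scale)


@dataclass(frozen=True)
class SynapseTable:
    rules: tuple[SynapseRule, ...]
    thalamic_probability: float = 0.05  # full-scale LGN-cell -> cortical-cell
    thalamic_weight: float = 30.0  # pA, onto Pyr
    thalamic_pv_factor: float = 1.0  # LGN->PV weight relative to LGN->Pyr

    def __post_init__(self):
        sst = [r.reach for r in self.rules
               if r.scope == "inter" and r.post is CellClass.SST]
        pv = [r.reach for r in self.rules
              if r.scope == "inter" and r.post is CellClass.PV]
        if sst and pv and max(sst) <= max(pv):
            raise ValueError("SST inter-columnar reach must exceed PV reach")

    def scaled(self, pre: CellClass, post: CellClass, scope: str, factor: float) -> "SynapseTable":
        rules = tuple(
            replace(r, probability=min(1.0, r.probability * factor), provenance="user")
            if (r.pre is pre and r.post is post and r.scope == scope)
            else r
            for r in self.rules
        )
        return replace(self, rules=rules)


@dataclass
class BackgroundDrive:
    """One external Poisson fiber per neuron; rates per class (Hz).

    The VIP rate encodes the locomotion state: 16 Hz (low) or 20 Hz (high).
    """

    rates: dict = field(
        default_factory=lambda: {
            CellClass.PYR: 3000.0,
            CellClass.PV: 2200.0,
            CellClass.SST: 1200.0,
            CellClass.VIP: 16.0,
        }
    )
    weights: dict = field(
        default_factory=lambda: {
            CellClass.PYR: 35.0,
            CellClass.PV: 35.0,
            CellClass.SST: 30.0,
            CellClass.VIP: 600.0,
        }
    )
    VIP_LOW = 16.0
    VIP_HIGH = 20.0

    def __post_init__(self):
        if any(v < 0 for v in self.rates.values()):
            raise ValueError("background rates must be >= 0")

    @property
    def vip_state(self) -> str:
        return "high" if self.rates[CellClass.VIP] >= self.VIP_HIGH else "low"


@dataclass
class SpikeData:
    """Spike events tagged by neuron, class, column and recording status."""

    times: np.ndarray  # ms, sorted
    neuron_ids: np.ndarray
    class_of: np.ndarray  # (n_neurons,) CellClass values
    column_of: np.ndarray  # (n_neurons,)
    recorded_mask: np.ndarray  # (n_neurons,) bool: 10% Pyr recording subset
    duration: float  # ms
    n_columns: int = N_COLUMNS

    def for_class(self, cell: CellClass) -> np.ndarray:
        keep = self.class_of[self.neuron_ids] == cell.value
        return self.times[keep], self.neuron_ids[keep]

    def mean_rate(self, cell: CellClass, t0: float = 0.0, t1: float | None = None) -> float:
        """Population mean rate (Hz) of one class over [t0, t1) ms."""
        t1 = self.duration if t1 is None else t1
        n_cells = int((self.class_of == cell.value).sum())
        if n_cells == 0:
            return 0.0
        times, _ = self.for_class(cell)
        n_spk = int(((times >= t0) & (times < t1)).sum())
        return n_spk / n_cells / ((t1 - t0) / 1000.0)

    def to_events(self) -> np.ndarray:
        return np.column_stack([self.times, self.neuron_ids])


def default_grid_config(scale: float = 0.05) -> tuple[GridSpec, SynapseTable, BackgroundDrive]:
    """Packaged defaults (config file ``spiking_defaults.yaml``)."""
    from . import config as _config

    cfg = _config.load_packaged("spiking_defaults")
    _config.audit_provenance(cfg)
    c = _config.resolve(cfg)
    rules = tuple(
        SynapseRule(
            pre=CellClass.from_label(e["pre"]),
            post=CellClass.from_label(e["post"]),
            scope=e["scope"],
            probability=e["probability"],
            weight=e["weight"],
            reach=int(e.get("reach", 0)),
            decay=e.get("decay"),
        )
        for e in c["connections"]
    )
    table = SynapseTable(
        rules,
        thalamic_probability=c["thalamic"]["probability"],
        thalamic_weight=c["thalamic"]["weight_pA"],
        thalamic_pv_factor=c["thalamic"]["pv_factor"],
    )
    bg = BackgroundDrive(
        rates={CellClass.from_label(k): v["rate"] for k, v in c["background"].items()},
        weights={CellClass.from_label(k): v["weight"] for k, v in c["background"].items()},
    )
    grid = GridSpec(cells_per_column_full=c["grid"]["cells_per_column_full"], scale=scale)
    return grid, table, bg


# ---------------------------------------------------------------------------
# Network construction
# ---------------------------------------------------------------------------


def _torus_offsets(reach: int):
    for di in range(-reach, reach + 1):
        for dj in range(-reach, reach + 1):
            if di == 0 and dj == 0:
                continue
            if max(abs(di), abs(dj)) <= reach:
                yield di, dj


class V1Network:
    """A realized (randomly wired) column-grid network."""

    def __init__(
        self,
        grid: GridSpec,
        synapses: SynapseTable,
        background: BackgroundDrive,
        wiring_seed: int,
        lif: LifParams | None = None,
    ):
        self.grid = grid
        self.synapses = synapses
        self.background = copy.deepcopy(background)
        self.wiring_seed = int(wiring_seed)
        self.lif = lif or LifParams()
        rng = np.random.default_rng(self.wiring_seed)

        counts = grid.class_counts()
        cpc = grid.cells_per_column
        self.n_neurons = cpc * grid.n_columns
        # layout: columns contiguous; within a column PYR, PV, SST, VIP
        class_block = np.concatenate(
            [np.full(counts[c], c.value) for c in CellClass]
        )
        self.class_of = np.tile(class_block, grid.n_columns)
        self.column_of = np.repeat(np.arange(grid.n_columns), cpc)
        offs = {}
        off = 0
        for c in CellClass:
            offs[c] = off
            off += counts[c]
        self._class_offset = offs
        self._counts = counts

        rows_list, cols_list, w_list = [], [], []

        def add_block(pre_ids, post_ids, p, w):
            if p <= 0:
                return
            mask = rng.random((pre_ids.size, post_ids.size)) < p
            pre_idx, post_idx = np.nonzero(mask)
            rows_list.append(pre_ids[pre_idx])
            cols_list.append(post_ids[post_idx])
            w_list.append(np.full(pre_idx.size, w))

        col_index = np.arange(grid.n_columns).reshape(grid.rows, grid.cols)

        def ids_of(col, cell):
            base = col * cpc + self._class_offset[cell]
            return np.arange(base, base + counts[cell])

        for rule in synapses.rules:
            if rule.scope == "intra":
                p = rule.prob_at(0, grid.scale)
                for col in range(grid.n_columns):
                    add_block(ids_of(col, rule.pre), ids_of(col, rule.post), p, rule.weight)
            else:
                for di, dj in _torus_offsets(rule.reach):
                    d = max(abs(di), abs(dj))
                    p = rule.prob_at(d, grid.scale)
                    if p <= 0:
                        continue
                    for i in range(grid.rows):
                        for j in range(grid.cols):
                            src = col_index[i, j]
                            dst = col_index[(i + di) % grid.rows, (j + dj) % grid.cols]
                            add_block(ids_of(src, rule.pre), ids_of(dst, rule.post), p, rule.weight)

        rows = np.concatenate(rows_list) if rows_list else np.empty(0, dtype=int)
        cols = np.concatenate(cols_list) if cols_list else np.empty(0, dtype=int)
        ws = np.concatenate(w_list) if w_list else np.empty(0)
        # split by channel of presynaptic class
        self.W = {}
        pre_channel = np.array([_CHANNEL_OF_PRE[CellClass(v)] for v in range(4)])
        ch_of_edge = pre_channel[self.class_of[rows]]
        for ch in (CH_EXC, CH_INH_FAST, CH_INH_SLOW):
            m = ch_of_edge == ch
            self.W[ch] = sparse.csr_matrix(
                (np.abs(ws[m]) * (1 if ch == CH_EXC else -1), (rows[m], cols[m])),
                shape=(self.n_neurons, self.n_neurons),
            )

        # thalamocortical wiring: LGN patch (i, j) -> column (i, j), onto Pyr
        # and PV, probability scaled like the cortical rules
        n_lgn_per_patch = 100
        self.n_lgn = n_lgn_per_patch * grid.n_columns
        p_th = min(1.0, synapses.thalamic_probability / grid.scale)
        lr, lc, lw = [], [], []
        for col in range(grid.n_columns):
            lgn_ids = np.arange(col * n_lgn_per_patch, (col + 1) * n_lgn_per_patch)
            for cell, wfac in (
                (CellClass.PYR, 1.0),
                (CellClass.PV, synapses.thalamic_pv_factor),
            ):
                if wfac <= 0:
                    continue
                tgt = ids_of(col, cell)
                mask = rng.random((lgn_ids.size, tgt.size)) < p_th
                a, b = np.nonzero(mask)
                lr.append(lgn_ids[a])
                lc.append(tgt[b])
                lw.append(np.full(a.size, synapses.thalamic_weight * wfac))
        lr = np.concatenate(lr) if lr else np.empty(0, dtype=int)
        lc = np.concatenate(lc) if lc else np.empty(0, dtype=int)
        lw = np.concatenate(lw) if lw else np.empty(0)
        self.W_lgn = sparse.csr_matrix(
            (lw, (lr, lc)), shape=(self.n_lgn, self.n_neurons)
        )

        # recording subset: 10% of Pyr cells
        pyr_ids = np.nonzero(self.class_of == CellClass.PYR.value)[0]
        n_rec = max(1, pyr_ids.size // 10)
        rec = rng.choice(pyr_ids, size=n_rec, replace=False)
        self.recorded_mask = np.zeros(self.n_neurons, dtype=bool)
        self.recorded_mask[rec] = True

    # -- inspection ----------------------------------------------------------

    def edge_count(self, pre: CellClass, post: CellClass, scope: str) -> int:
        """Realized edge count for one (pre, post, scope) pathway."""
        n = 0
        same_col = None
        for ch, W in self.W.items():
            coo = W.tocoo()
            m = (self.class_of[coo.row] == pre.value) & (
                self.class_of[coo.col] == post.value
            )
            same = self.column_of[coo.row] == self.column_of[coo.col]
            if scope == "intra":
                n += int((m & same).sum())
            else:
                n += int((m & ~same).sum())
        return n

    def expected_edge_count(self, pre: CellClass, post: CellClass, scope: str) -> float:
        grid = self.grid
        counts = grid.class_counts()
        total = 0.0
        for rule in self.synapses.rules:
            if rule.pre is not pre or rule.post is not post or rule.scope != scope:
                continue
            if scope == "intra":
                total += grid.n_columns * counts[pre] * counts[post] * rule.prob_at(0, grid.scale)
            else:
                for di, dj in _torus_offsets(rule.reach):
                    d = max(abs(di), abs(dj))
                    total += grid.n_columns * counts[pre] * counts[post] * rule.prob_at(d, grid.scale)
        return total


def build_grid(
    grid: GridSpec | None = None,
    synapses: SynapseTable | None = None,
    background: BackgroundDrive | None = None,
    seed: int = 0,
) -> V1Network:
    """Realize a random network; reproducible given the seed."""
    g, s, b = default_grid_config()
    return V1Network(grid or g, synapses or s, background or b, seed)


def set_background_state(network: V1Network, vip_state: str) -> V1Network:
    """Return a copy of the network with only the VIP fiber rate changed."""
    if vip_state not in ("low", "high"):
        raise ValueError("vip_state must be 'low' or 'high'")
    import copy as _copy

    out = _copy.copy(network)  # wiring shared; background replaced
    out.background = _copy.deepcopy(network.background)
    out.background.rates[CellClass.VIP] = (
        BackgroundDrive.VIP_HIGH if vip_state == "high" else BackgroundDrive.VIP_LOW
    )
    return out


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------


def simulate(
    network: V1Network,
    lgn_spikes: np.ndarray | None = None,
    duration: float = 1000.0,
    dt: float = 0.5,
    seed: int = 0,
    external_current: np.ndarray | float = 0.0,
    pv_background_factor: float = 1.0,
) -> SpikeData:
    """Simulate the LIF grid for ``duration`` ms at fixed step ``dt`` (ms).

    ``lgn_spikes``: (n, 2) array of (time_s, lgn_cell_id) rows, e.g. from
    ``scene2d.poisson_spikes``.  ``seed`` drives the background noise only
    (wiring has its own seed).  ``pv_background_factor`` scales the PV
    fiber rate (the PV-background perturbation experiment).  Synaptic
    events take effect on the following step (one-step axonal delay).
    """
    p = network.lif
    n = network.n_neurons
    rng = np.random.default_rng(seed)

    # exact-integration propagators
    decay_v = np.exp(-dt / p.tau_m)
    decay_s = np.array([np.exp(-dt / t) for t in p.tau_syn])
    # current->voltage kernel per channel over one step (mV per pA)
    def _kernel(ts):
        # pA * ms / pF = mV, so no further unit factor is needed
        if abs(ts - p.tau_m) < 1e-9:  # degenerate limit tau_syn == tau_m
            return dt * np.exp(-dt / p.tau_m) / p.c_m
        return (
            (np.exp(-dt / ts) - np.exp(-dt / p.tau_m))
            / (1.0 / p.tau_m - 1.0 / ts)
            / p.c_m
        )

    k_ch = np.array([_kernel(ts) for ts in p.tau_syn])

    n_steps = int(round(duration / dt))
    ref_steps = max(0, int(round(p.t_ref / dt)))

    # bin LGN spikes onto the step grid
    lgn_counts_by_step = None
    if lgn_spikes is not None and len(lgn_spikes):
        t_ms = lgn_spikes[:, 0] * 1000.0
        step_of = np.floor(t_ms / dt).astype(int)
        keep = (step_of >= 0) & (step_of < n_steps)
        lgn_counts_by_step = (step_of[keep], lgn_spikes[keep, 1].astype(int))
        order = np.argsort(lgn_counts_by_step[0], kind="stable")
        lgn_steps = lgn_counts_by_step[0][order]
        lgn_cells = lgn_counts_by_step[1][order]
        lgn_ptr = np.searchsorted(lgn_steps, np.arange(n_steps + 1))
    else:
        lgn_ptr = None

    bg_rate = np.array(
        [network.background.rates[CellClass(v)] for v in range(4)]
    )[network.class_of]
    bg_w = np.array(
        [network.background.weights[CellClass(v)] for v in range(4)]
    )[network.class_of]
    if pv_background_factor != 1.0:
        pv = network.class_of == CellClass.PV.value
        bg_rate = bg_rate.copy()
        bg_rate[pv] *= pv_background_factor
    bg_lam = bg_rate * dt / 1000.0

    ext = np.broadcast_to(np.asarray(external_current, float), (n,))

    V = np.full(n, p.v_rest)
    I = np.zeros((3, n))
    refrac = np.zeros(n, dtype=int)
    pending = np.zeros((3, n))  # synaptic input arriving next step

    spike_times = []
    spike_ids = []
    W = network.W
    W_lgn = network.W_lgn

    for step in range(n_steps):
        # integrate V exactly over [t, t+dt) with current currents
        syn_v = k_ch @ I  # (n,)
        V = p.v_rest + (V - p.v_rest) * decay_v + syn_v + ext * (1.0 - decay_v) * p.tau_m / p.c_m
        I *= decay_s[:, None]
        # deliver pending synaptic events (one-step delay)
        I += pending
        pending[:] = 0.0

        # refractory clamp
        in_ref = refrac > 0
        V[in_ref] = p.v_reset
        refrac[in_ref] -= 1

        # threshold crossing
        spk = np.nonzero(V >= p.v_thresh)[0]
        if spk.size:
            t_now = (step + 1) * dt
            spike_times.append(np.full(spk.size, t_now))
            spike_ids.append(spk)
            V[spk] = p.v_reset
            refrac[spk] = ref_steps
            for ch in (CH_EXC, CH_INH_FAST, CH_INH_SLOW):
                rows = W[ch][spk]
                if rows.nnz:
                    pending[ch] += np.asarray(rows.sum(axis=0)).ravel()

        # external inputs arriving during this step act from the next step
        counts = rng.poisson(bg_lam)
        nz = np.nonzero(counts)[0]
        if nz.size:
            pending[CH_EXC, nz] += bg_w[nz] * counts[nz]
        if lgn_ptr is not None:
            a, b = lgn_ptr[step], lgn_ptr[step + 1]
            if b > a:
                rows = W_lgn[lgn_cells[a:b]]
                pending[CH_EXC] += np.asarray(rows.sum(axis=0)).ravel()

        if not np.all(np.isfinite(V)):
            raise RuntimeError(f"non-finite membrane state at t = {(step + 1) * dt} ms")

    if spike_times:
        times = np.concatenate(spike_times)
        ids = np.concatenate(spike_ids)
    else:
        times = np.empty(0)
        ids = np.empty(0, dtype=int)
    return SpikeData(
        times=times,
        neuron_ids=ids,
        class_of=network.class_of,
        column_of=network.column_of,
        recorded_mask=network.recorded_mask,
        duration=duration,
        n_columns=network.grid.n_columns,
    )
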