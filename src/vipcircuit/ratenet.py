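"""Firing-rate ring model of a V1 microcircuit with four cell classes.

The model is a chain of cortical populations (default 7) on a ring, each
containing one rate unit per cell class (Pyr, PV, SST, VIP).  Rates obey

    tau_m * df/dt = -f + g(I_intrinsic + I_syn + I_stimulus),
    g(x) = gain_slope * sqrt(x)   (rectified: g(x) = 0 for x <= 0),

synaptic input is a weighted sum of gating variables, I_syn = sum_i w_i S_i,
and each gating variable low-pass filters its presynaptic rate,

    dS/dt = -S/tau + f_pre,

so the steady-state gating is tau[s] * f_pre[Hz] (dimensionless).

Within a population the four classes are wired with the canonical
disinhibitory motif (Pyr excites all classes; PV inhibits Pyr and PV;
SST inhibits Pyr, PV and VIP; VIP inhibits SST).  Across populations there
are reciprocal Pyr->Pyr connections between nearest ring neighbours only,
and Pyr->SST connections to every other population with a
distance-decaying weight profile -- the substrate of surround suppression.
The inter-population Pyr->SST weight scale is abbreviated IPPS throughout.

Units at the API: time in ms, currents in pA, rates in Hz.  Integration is
carried out internally in seconds with a fixed-step classical Runge-Kutta
scheme (default dt = 0.1 ms).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Sequence

import numpy as np

from . import config as _config

__all__ = [
    "CellClass",
    "ConnectionSpec",
    "RateNetworkSpec",
    "StimulusTrace",
    "RateTrajectory",
    "RateNetwork",
    "gain",
    "build_ring",
    "default_spec",
    "synaptic_input",
    "step_gating",
    "integrate",
    "fixed_point",
    "IntegrationError",
    "FixedPointError",
]


class CellClass(Enum):
    """The four modelled cortical cell classes; PYR is the only excitatory one."""

    PYR = 0
    PV = 1
    SST = 2
    VIP = 3

    @classmethod
    def from_label(cls, label: str) -> "CellClass":
        return cls[label.upper()]


N_CLASSES = len(CellClass)


class IntegrationError(RuntimeError):
    pass


class FixedPointError(RuntimeError):
    pass


def gain(x, gain_slope: float = 5.33):
    """Square-root transfer function, rectified at zero drive.

    Returns ``gain_slope * sqrt(x)`` (Hz) for positive drive ``x`` (pA) and
    0 for ``x <= 0``; inhibition may exceed excitation during transients, and
    the rectification keeps rates real and nonnegative.
    """
    x = np.asarray(x, dtype=float)
    out = gain_slope * np.sqrt(np.maximum(x, 0.0))
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class ConnectionSpec:
    """One cell-class-to-cell-class pathway, intra- or inter-population.

    ``weight`` is in pA per unit gating (signed: positive iff the
    presynaptic class is PYR); ``decay_tau`` is the gating decay constant
    in ms.  For ``scope='inter'`` the ``distance_profile`` gives a
    nonnegative multiplier per ring distance d = 1..max_distance
    (distance 0 is handled by the intra-scope connection).
    """

    pre: CellClass
    post: CellClass
    scope: str  # 'intra' | 'inter'
    weight: float
    decay_tau: float
    distance_profile: tuple[float, ...] | None = None
    provenance: str = "calibrated"

    def __post_init__(self):
        if self.scope not in ("intra", "inter"):
            raise ValueError(f"scope must be intra|inter, got {self.scope!r}")
        if self.decay_tau <= 0:
            raise ValueError("decay_tau must be > 0")
        if (self.pre is CellClass.PYR) != (self.weight >= 0):
            raise ValueError(
                f"{self.pre.name}->{self.post.name}: weight sign must match "
                "presynaptic class (PYR excitatory, others inhibitory)"
            )
        if self.scope == "inter":
            if self.distance_profile is None:
                raise ValueError("inter-scope connection needs a distance_profile")
            if any(v < 0 for v in self.distance_profile):
                raise ValueError("distance_profile entries must be >= 0")


@dataclass(frozen=True)
class RateNetworkSpec:
    """Full parameterization of the firing-rate ring."""

    n_populations: int = 7
    tau_m: float = 10.0  # ms
    gain_slope: float = 5.33  # Hz per sqrt(pA)
    intrinsic_input: dict = field(default_factory=dict)  # CellClass -> pA (net)
    connections: tuple[ConnectionSpec, ...] = ()
    periodic: bool = True

    def __post_init__(self):
        if self.n_populations < 3:
            raise ValueError("n_populations must be >= 3")
        if self.tau_m <= 0 or self.gain_slope <= 0:
            raise ValueError("tau_m and gain_slope must be > 0")

    @property
    def max_distance(self) -> int:
        return self.n_populations // 2

    def with_intrinsic(self, cell: CellClass, value: float) -> "RateNetworkSpec":
        intr = dict(self.intrinsic_input)
        intr[cell] = value
        return replace(self, intrinsic_input=intr)

    def scale_connection(
        self, pre: CellClass, post: CellClass, scope: str, weight: float
    ) -> "RateNetworkSpec":
        """Return a spec with the matching connection's weight replaced."""
        conns = []
        hit = False
        for c in self.connections:
            if c.pre is pre and c.post is post and c.scope == scope:
                conns.append(replace(c, weight=weight, provenance="user"))
                hit = True
            else:
                conns.append(c)
        if not hit:
            raise KeyError(f"no {scope} {pre.name}->{post.name} connection in spec")
        return replace(self, connections=tuple(conns))

    def with_decay_tau(
        self, pre: CellClass, post: CellClass, scope: str, decay_tau: float
    ) -> "RateNetworkSpec":
        conns = []
        hit = False
        for c in self.connections:
            if c.pre is pre and c.post is post and c.scope == scope:
                conns.append(replace(c, decay_tau=decay_tau, provenance="user"))
                hit = True
            else:
                conns.append(c)
        if not hit:
            raise KeyError(f"no {scope} {pre.name}->{post.name} connection in spec")
        return replace(self, connections=tuple(conns))


@dataclass(frozen=True)
class StimulusTrace:
    """Piecewise-constant stimulus current per population, delivered to Pyr only.

    ``bin_edges``: (B+1,) ms, strictly increasing; ``current``: (B, P) pA >= 0.
    """

    bin_edges: np.ndarray
    current: np.ndarray

    def __post_init__(self):
        edges = np.asarray(self.bin_edges, float)
        cur = np.asarray(self.current, float)
        object.__setattr__(self, "bin_edges", edges)
        object.__setattr__(self, "current", cur)
        if edges.ndim != 1 or np.any(np.diff(edges) <= 0):
            raise ValueError("bin_edges must be strictly increasing 1-D")
        if cur.shape[0] != edges.size - 1:
            raise ValueError("current must have one row per bin")
        if np.any(cur < 0):
            raise ValueError("stimulus current must be >= 0")

    @property
    def n_populations(self) -> int:
        return self.current.shape[1]

    def at(self, t_ms) -> np.ndarray:
        """Stimulus current per population at time(s) t (pA); 0 outside bins."""
        t = np.atleast_1d(np.asarray(t_ms, float))
        idx = np.searchsorted(self.bin_edges, t, side="right") - 1
        out = np.zeros((t.size, self.n_populations))
        ok = (idx >= 0) & (idx < self.current.shape[0]) & (t < self.bin_edges[-1])
        out[ok] = self.current[idx[ok]]
        return out if np.ndim(t_ms) else out[0]

    def to_frame(self):
        import pandas as pd

        rows = []
        for b in range(self.current.shape[0]):
            for p in range(self.n_populations):
                rows.append(
                    (self.bin_edges[b], self.bin_edges[b + 1], p + 1, self.current[b, p])
                )
        return pd.DataFrame(rows, columns=["t_start_ms", "t_end_ms", "population", "input_pA"])


def zero_stimulus(n_populations: int = 7, duration: float = 1000.0) -> StimulusTrace:
    return StimulusTrace(np.array([0.0, duration]), np.zeros((1, n_populations)))


@dataclass
class RateTrajectory:
    """Time-resolved rates and total drives, per (time, population, cell class)."""

    times: np.ndarray  # (T,) ms
    rates: np.ndarray  # (T, P, 4) Hz
    drives: np.ndarray  # (T, P, 4) pA (total input into the gain function)
    stimulus: StimulusTrace | None = None

    def class_rates(self, cell: CellClass) -> np.ndarray:
        """(T, P) rates of one cell class."""
        return self.rates[:, :, cell.value]

    def window(self, t0: float, t1: float) -> "RateTrajectory":
        m = (self.times >= t0) & (self.times < t1)
        return RateTrajectory(self.times[m], self.rates[m], self.drives[m], self.stimulus)

    def mean_rate(self, cell: CellClass, population: int, t0: float, t1: float) -> float:
        """Time-averaged rate (Hz) of one unit over [t0, t1) ms. 1-based population."""
        m = (self.times >= t0) & (self.times < t1)
        return float(self.rates[m, population - 1, cell.value].mean())

    def to_frame(self):
        import pandas as pd

        T, P, _ = self.rates.shape
        t = np.repeat(self.times, P * N_CLASSES)
        pop = np.tile(np.repeat(np.arange(1, P + 1), N_CLASSES), T)
        cls = np.tile([c.name for c in CellClass], T * P)
        return pd.DataFrame(
            {
                "time_ms": t,
                "population": pop,
                "cell_class": cls,
                "rate_hz": self.rates.reshape(-1),
            }
        )


# ---------------------------------------------------------------------------
# Network assembly
# ---------------------------------------------------------------------------


def ring_distance(i: int, j: int, n: int) -> int:
    d = abs(i - j) % n
    return min(d, n - d)


class RateNetwork:
    """Compiled form of a RateNetworkSpec: mixing matrices and flat operators.

    State layout: rates f as (P, 4); gating S as (C, P) where C indexes the
    connection specs and the column the *presynaptic* population.
    """

    def __init__(self, spec: RateNetworkSpec):
        self.spec = spec
        P = spec.n_populations
        C = len(spec.connections)
        self.n_populations = P
        self.n_connections = C
        # Mixing matrix per connection: contribution of S[c, q] to target pop p.
        self.mixing = np.zeros((C, P, P))
        for ci, conn in enumerate(spec.connections):
            if conn.scope == "intra":
                self.mixing[ci] = np.eye(P)
            else:
                prof = conn.distance_profile
                if len(prof) < spec.max_distance:
                    raise _config.ConfigError(
                        f"distance_profile for {conn.pre.name}->{conn.post.name} "
                        f"needs {spec.max_distance} entries, got {len(prof)}"
                    )
                for p in range(P):
                    for q in range(P):
                        if p == q:
                            continue
                        d = ring_distance(p, q, P) if spec.periodic else abs(p - q)
                        if d <= len(prof):
                            self.mixing[ci, p, q] = prof[d - 1]
        self.weights = np.array([c.weight for c in spec.connections])
        self.decay_tau_s = np.array([c.decay_tau for c in spec.connections]) / 1000.0
        self.pre_class = np.array([c.pre.value for c in spec.connections], dtype=int)
        self.post_class = np.array([c.post.value for c in spec.connections], dtype=int)
        self.intrinsic = np.zeros((P, N_CLASSES))
        for cell, val in spec.intrinsic_input.items():
            cell = cell if isinstance(cell, CellClass) else CellClass.from_label(cell)
            self.intrinsic[:, cell.value] = val
        # Flat operator: syn_flat (P*4) = W_big @ S_flat (C*P)
        self.W_big = np.zeros((P * N_CLASSES, C * P))
        for ci in range(C):
            block = self.weights[ci] * self.mixing[ci]  # (P, P)
            for p in range(P):
                row = p * N_CLASSES + self.post_class[ci]
                self.W_big[row, ci * P : (ci + 1) * P] = block[p]
        # f_pre gather: S_flat index (ci*P + q) reads f at (q, pre_class[ci])
        self.pre_gather = np.concatenate(
            [np.arange(P) * N_CLASSES + self.pre_class[ci] for ci in range(C)]
        )
        self.tau_flat = np.repeat(self.decay_tau_s, P)
        self.tau_m_s = spec.tau_m / 1000.0

    # -- inspection helpers (used by structural tests) ----------------------

    def edges(self) -> list[tuple[CellClass, int, CellClass, int, float]]:
        """Enumerate (pre_class, pre_pop, post_class, post_pop, weight) edges
        with nonzero weight; populations are 1-based."""
        out = []
        for ci, conn in enumerate(self.spec.connections):
            if conn.weight == 0:
                continue
            M = self.mixing[ci]
            for p in range(self.n_populations):
                for q in range(self.n_populations):
                    if M[p, q] != 0:
                        out.append(
                            (conn.pre, q + 1, conn.post, p + 1, conn.weight * M[p, q])
                        )
        return out

    def gating_steady_state(self, rates: np.ndarray) -> np.ndarray:
        """S* = tau[s] * f_pre, shape (C, P), for a given rate matrix (P, 4)."""
        return self.decay_tau_s[:, None] * rates[:, self.pre_class].T


def build_ring(spec: RateNetworkSpec) -> RateNetwork:
    """Compile a spec into an integrable network (validates the wiring)."""
    return RateNetwork(spec)


# ---------------------------------------------------------------------------
# Default (packaged) parameterization
# ---------------------------------------------------------------------------


def spec_from_config(cfg: dict, **kwargs) -> RateNetworkSpec:
    """Build a RateNetworkSpec from a (tagged) config dict.

    Keyword overrides: ``ipps`` (inter Pyr->SST weight, pA), ``vip_background``,
    ``sst_background``, ``pv_background`` (pA).
    """
    _config.audit_provenance(cfg)
    c = _config.resolve(cfg)
    cells = c["cells"]
    for key, val in kwargs.items():
        if val is None:
            continue
        if key == "ipps":
            continue
        name = {"vip_background": "VIP", "sst_background": "SST", "pv_background": "PV"}[key]
        cells[name]["background"] = val
    intrinsic = {
        CellClass.from_label(name): vals["threshold"] + vals["background"]
        for name, vals in cells.items()
    }
    conns = []
    for entry in c["connections"]:
        weight = entry["weight"]
        if (
            kwargs.get("ipps") is not None
            and entry["scope"] == "inter"
            and entry["pre"] == "PYR"
            and entry["post"] == "SST"
        ):
            weight = kwargs["ipps"]
        profile = entry.get("distance_profile")
        conns.append(
            ConnectionSpec(
                pre=CellClass.from_label(entry["pre"]),
                post=CellClass.from_label(entry["post"]),
                scope=entry["scope"],
                weight=weight,
                decay_tau=entry["decay_tau_ms"],
                distance_profile=tuple(profile) if profile else None,
                provenance=entry.get("provenance", "calibrated"),
            )
        )
    m = c["model"]
    return RateNetworkSpec(
        n_populations=m["n_populations"],
        tau_m=m["tau_m_ms"],
        gain_slope=m["gain_slope"],
        intrinsic_input=intrinsic,
        connections=tuple(conns),
        periodic=bool(m["periodic"]),
    )


def default_spec(
    ipps: float | None = None,
    vip_background: float | None = None,
    sst_background: float | None = None,
    pv_background: float | None = None,
) -> RateNetworkSpec:
    """The packaged default ring (7 populations, calibrated weights)."""
    cfg = _config.load_packaged("rate_defaults")
    return spec_from_config(
        cfg,
        ipps=ipps,
        vip_background=vip_background,
        sst_background=sst_background,
        pv_background=pv_background,
    )


# ---------------------------------------------------------------------------
# Dynamics
# ---------------------------------------------------------------------------


def synaptic_input(network: RateNetwork, gating: np.ndarray) -> np.ndarray:
    """I_syn = sum_i w_i S_i per (population, cell class); gating is (C, P)."""
    gating = np.asarray(gating, float)
    if gating.shape != (network.n_connections, network.n_populations):
        raise ValueError(
            f"gating shape {gating.shape} != "
            f"({network.n_connections}, {network.n_populations})"
        )
    syn = network.W_big @ gating.reshape(-1)
    return syn.reshape(network.n_populations, N_CLASSES)


def step_gating(S, f_pre, dt: float, decay_tau: float):
    """Advance dS/dt = -S/tau + f_pre over one step (dt, decay_tau in ms).

    Exact for constant presynaptic rate over the step:
    S(t+dt) = S e^{-dt/tau} + tau[s] f_pre (1 - e^{-dt/tau}).
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if dt > decay_tau / 2:
        raise ValueError(f"dt={dt} ms too large for decay_tau={decay_tau} ms (need dt <= tau/2)")
    decay = np.exp(-dt / decay_tau)
    return S * decay + (decay_tau / 1000.0) * np.asarray(f_pre, float) * (1.0 - decay)


def _deriv_factory(network: RateNetwork):
    W = network.W_big
    intr = network.intrinsic.reshape(-1)
    slope = network.spec.gain_slope
    tau_m = network.tau_m_s
    tau_flat = network.tau_flat
    gather = network.pre_gather
    P = network.n_populations
    nf = P * N_CLASSES
    pyr_idx = np.arange(P) * N_CLASSES + CellClass.PYR.value
    sst_idx = np.arange(P) * N_CLASSES + CellClass.SST.value

    def deriv(y: np.ndarray, stim: np.ndarray, sst_extra: float = 0.0) -> np.ndarray:
        f = y[:nf]
        S = y[nf:]
        drive = intr + W @ S
        drive[pyr_idx] += stim
        if sst_extra:
            drive[sst_idx] += sst_extra
        g = slope * np.sqrt(np.maximum(drive, 0.0))
        out = np.empty_like(y)
        out[:nf] = (g - f) / tau_m
        out[nf:] = -S / tau_flat + f[gather]
        return out

    def drive_of(y: np.ndarray, stim: np.ndarray, sst_extra: float = 0.0) -> np.ndarray:
        drive = intr + W @ y[nf:]
        drive[pyr_idx] += stim
        if sst_extra:
            drive[sst_idx] += sst_extra
        return drive

    return deriv, drive_of


def integrate(
    network: RateNetwork,
    stimulus: StimulusTrace | None = None,
    duration: float = 1000.0,
    dt: float = 0.1,
    record_every: int = 1,
    initial_rates: np.ndarray | None = None,
    sst_probe: tuple[float, float, float] | None = None,
) -> RateTrajectory:
    """Integrate the ring with classical RK4 at fixed step dt (ms).

    ``sst_probe = (current_pA, t0_ms, t1_ms)`` injects an additional signed
    current into every SST unit during [t0, t1) -- the hyperpolarization probe.
    Deterministic; initial conditions are all-zero rates and gating unless
    ``initial_rates`` (P, 4) is given (gating then starts at its steady state).
    """
    P = network.n_populations
    if stimulus is None:
        stimulus = zero_stimulus(P, duration)
    if stimulus.n_populations != P:
        raise ValueError("stimulus population count does not match network")
    deriv, drive_of = _deriv_factory(network)
    nf = P * N_CLASSES
    n_steps = int(round(duration / dt))
    # Precompute per-step stimulus (value held over [t, t+dt)).
    t_grid = np.arange(n_steps) * dt
    stim_steps = stimulus.at(t_grid)  # (n_steps, P)
    if sst_probe is not None:
        amp, t0, t1 = sst_probe
        probe_steps = amp * ((t_grid >= t0) & (t_grid < t1))
    else:
        probe_steps = np.zeros(n_steps)
    y = np.zeros(nf + network.n_connections * P)
    if initial_rates is not None:
        y[:nf] = np.asarray(initial_rates, float).reshape(-1)
        y[nf:] = network.gating_steady_state(np.asarray(initial_rates, float)).reshape(-1)

    n_rec = n_steps // record_every + 1
    times = np.empty(n_rec)
    rates = np.empty((n_rec, P, N_CLASSES))
    drives = np.empty((n_rec, P, N_CLASSES))

    def record(k, step, y, stim, probe):
        times[k] = step * dt
        rates[k] = y[:nf].reshape(P, N_CLASSES)
        drives[k] = drive_of(y, stim, probe).reshape(P, N_CLASSES)

    rec = 0
    record(rec, 0, y, stim_steps[0], probe_steps[0])
    rec += 1
    dts = dt / 1000.0
    for step in range(n_steps):
        stim = stim_steps[step]
        probe = probe_steps[step]
        k1 = deriv(y, stim, probe)
        k2 = deriv(y + 0.5 * dts * k1, stim, probe)
        k3 = deriv(y + 0.5 * dts * k2, stim, probe)
        k4 = deriv(y + dts * k3, stim, probe)
        y = y + (dts / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        # Rectify: sqrt gain can overshoot to tiny negatives through RK stages.
        np.maximum(y, 0.0, out=y)
        if not np.all(np.isfinite(y)):
            raise IntegrationError(
                f"non-finite state at t = {(step + 1) * dt:.3f} ms"
            )
        if (step + 1) % record_every == 0:
            s2 = step + 1 if step + 1 < n_steps else step
            record(rec, step + 1, y, stim_steps[s2], probe_steps[s2])
            rec += 1
    return RateTrajectory(times[:rec], rates[:rec], drives[:rec], stimulus)


def integrate_with_probe(
    network: RateNetwork,
    stimulus: StimulusTrace,
    probe_current: float,
    window=(700.0, 800.0),
    duration: float = 1000.0,
    dt: float = 0.1,
    record_every: int = 1,
) -> RateTrajectory:
    """Integrate while injecting ``probe_current`` (pA, signed) into all SST
    units during ``window`` (ms) -- used to silence the Pyr-SST oscillation."""
    return integrate(
        network,
        stimulus,
        duration=duration,
        dt=dt,
        record_every=record_every,
        sst_probe=(probe_current, window[0], window[1]),
    )


def fixed_point(
    network: RateNetwork,
    stimulus_const: np.ndarray | float = 0.0,
    x0: np.ndarray | None = None,
    tol: float = 1e-10,
) -> np.ndarray:
    """Self-consistent rates (P, 4) under constant Pyr stimulus.

    Solves f = g(I_intrinsic + W tau f_pre + I_stim) with gating at its
    steady state.  Raises FixedPointError when no root is found.
    """
    from scipy import optimize

    P = network.n_populations
    stim = np.broadcast_to(np.asarray(stimulus_const, float), (P,)).copy()
    deriv, _ = _deriv_factory(network)
    nf = P * N_CLASSES

    def residual(f_flat):
        f = np.maximum(f_flat, 0.0).reshape(P, N_CLASSES)
        S = network.gating_steady_state(f)
        y = np.concatenate([f.reshape(-1), S.reshape(-1)])
        d = deriv(y, stim)
        return d[:nf] * network.tau_m_s  # g(drive) - f

    if x0 is None:
        x0 = np.full(P * N_CLASSES, 5.0)
    else:
        x0 = np.asarray(x0, float).reshape(-1)
    sol = optimize.root(residual, x0, method="hybr", tol=tol)
    f = np.maximum(sol.x, 0.0).reshape(P, N_CLASSES)
    res = np.abs(residual(f.reshape(-1))).max()
    if res > 1e-6:
        raise FixedPointError(f"no convergence; residual {res:.3e}")
    return f
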