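"""Statistics and parameter-sweep experiments on rate-model output.

The quantities here are the study's bespoke measures:

* ``snr``             -- mean Pyr rate of the stimulated population over the
  stimulus window divided by the mean Pyr rate of all other populations
  (signal-to-noise ratio of the spatial response profile).
* ``relative_change`` -- (R_stim - R_baseline) / R_baseline with default
  windows [500, 1000) ms vs [200, 500) ms.
* ``corr_or_cov``     -- Pearson correlation between a stimulus trace and a
  response trace, falling back to the raw covariance when |cov| < 1e-7
  (the quiescent-regime rule: near-zero rates make correlations spurious).
* ``oscillation_frequency`` -- dominant periodogram peak of a detrended rate
  trace, or None when no peak clears the noise floor.
* ``parameter_sweep`` / ``stability_scan`` / ``sst_hyperpolarization_probe``
  -- the sweep experiments over IPPS strength, cell-class background drives
  and gating decay constants.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import protocols
from .ratenet import (
    CellClass,
    RateTrajectory,
    StimulusTrace,
    build_ring,
    default_spec,
    integrate,
    integrate_with_probe,
)

__all__ = [
    "snr",
    "relative_change",
    "corr_or_cov",
    "CorrelationOrCovariance",
    "oscillation_frequency",
    "oscillation_amplitude",
    "input_output_correlations",
    "parameter_sweep",
    "size_tuning_curve",
    "stability_scan",
    "sst_hyperpolarization_probe",
    "SweepResult",
]

STIM_WINDOW = (500.0, 1000.0)  # ms
BASELINE_WINDOW = (200.0, 500.0)  # ms
COV_FALLBACK_THRESHOLD = 1e-7


def snr(
    trajectory: RateTrajectory, target: int = 4, window=STIM_WINDOW
) -> float:
    """Stimulated-population Pyr rate normalized to the mean of the others.

    ``target`` is 1-based.  Raises ZeroDivisionError when the other
    populations are silent over the window.
    """
    t0, t1 = window
    m = (trajectory.times >= t0) & (trajectory.times < t1)
    if not m.any():
        raise ValueError("window outside trajectory")
    pyr = trajectory.rates[m, :, CellClass.PYR.value]  # (T, P)
    means = pyr.mean(axis=0)
    others = np.delete(means, target - 1)
    if others.mean() <= 0:
        raise ZeroDivisionError("mean rate of non-target populations is zero")
    return float(means[target - 1] / others.mean())


def relative_change(r_stim: float, r_baseline: float) -> float:
    """(R_stim - R_baseline) / R_baseline."""
    if r_baseline <= 0:
        raise ZeroDivisionError("baseline rate must be > 0")
    return (r_stim - r_baseline) / r_baseline


@dataclass(frozen=True)
class CorrelationOrCovariance:
    value: float
    mode: str  # 'correlation' | 'covariance'
    threshold: float = COV_FALLBACK_THRESHOLD

    def __float__(self):
        return self.value


def corr_or_cov(x, y, threshold: float = COV_FALLBACK_THRESHOLD) -> CorrelationOrCovariance:
    """Pearson correlation with a covariance fallback for quiescent traces.

    When |cov(x, y)| < threshold the covariance itself is reported (mode
    'covariance'); correlations computed from near-zero traces are numerical
    artifacts.  Population covariance normalization (1/N) is used.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("x and y must be equal-length 1-D series (n >= 2)")
    cov = float(np.mean((x - x.mean()) * (y - y.mean())))
    if abs(cov) < threshold:
        return CorrelationOrCovariance(cov, "covariance", threshold)
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        raise ValueError("zero variance with covariance above threshold")
    return CorrelationOrCovariance(cov / (sx * sy), "correlation", threshold)


def _periodogram(series: np.ndarray, dt_s: float):
    from scipy import signal

    detrended = series - series.mean()
    window = np.hanning(detrended.size)
    freqs, power = signal.periodogram(detrended * window, fs=1.0 / dt_s, detrend=False)
    return freqs[1:], power[1:]


def oscillation_frequency(
    trajectory: RateTrajectory,
    population: int = 4,
    window=STIM_WINDOW,
    cell: CellClass = CellClass.PYR,
    peak_factor: float = 5.0,
):
    """Dominant spectral frequency (Hz) of a rate trace, or None.

    Mean-removed, Hann-tapered periodogram over the window; a peak counts as
    an oscillation only if it exceeds ``peak_factor`` times the median
    spectral power.  The window must hold at least ~10 cycles of the lowest
    detectable frequency, which the fixed 500-ms analysis windows do for the
    beta-band rhythms of interest here.
    """
    t0, t1 = window
    m = (trajectory.times >= t0) & (trajectory.times < t1)
    series = trajectory.rates[m, population - 1, cell.value]
    if series.size < 32:
        raise ValueError("window too short for spectral estimation")
    dt_s = float(np.median(np.diff(trajectory.times[m]))) / 1000.0
    freqs, power = _periodogram(series, dt_s)
    if not power.any():
        return None
    k = int(np.argmax(power))
    if power[k] < peak_factor * np.median(power):
        return None
    return float(freqs[k])


def oscillation_amplitude(
    trajectory: RateTrajectory,
    population: int = 4,
    window=STIM_WINDOW,
    cell: CellClass = CellClass.PYR,
    smooth_ms: float = 50.0,
) -> float:
    """Peak-to-trough amplitude (Hz) of the fast component of a rate trace.

    The slow trend -- a ``smooth_ms`` moving average -- is subtracted first,
    so relaxations and step transients do not count as oscillation, while a
    beta-range rhythm (period well below ``smooth_ms``... comparable to it)
    passes through essentially unattenuated.
    """
    from scipy.ndimage import uniform_filter1d

    t0, t1 = window
    m = (trajectory.times >= t0) & (trajectory.times < t1)
    series = trajectory.rates[m, population - 1, cell.value]
    t = trajectory.times[m]
    if series.size < 16:
        raise ValueError("window too short for amplitude estimation")
    dt = float(np.median(np.diff(t)))
    n = max(3, int(round(smooth_ms / dt)))
    trend = uniform_filter1d(series, size=n, mode="nearest")
    resid = series - trend
    # the first/last half-filter-widths carry boundary artifacts
    core = resid[n // 2 : resid.size - n // 2]
    if core.size < 4:
        core = resid
    return float(core.max() - core.min())


# ---------------------------------------------------------------------------
# Experiments
# ---------------------------------------------------------------------------


def _run(spec, stimulus, duration=1000.0, dt=0.1, record_every=10):
    """Integrate a spec and return the trajectory (1-ms recording grid)."""
    return integrate(
        build_ring(spec), stimulus, duration=duration, dt=dt, record_every=record_every
    )


def input_output_correlations(
    trajectory: RateTrajectory,
    threshold: float = COV_FALLBACK_THRESHOLD,
    t_start: float = 200.0,
) -> list[CorrelationOrCovariance]:
    """Per-population correlation between the Pyr stimulus input trace and
    the Pyr rate output trace (covariance fallback applied).

    The first ``t_start`` ms are excluded: the relaxation from the silent
    initial condition to the background-driven state is not a stimulus
    response, and including it swamps the input-output correlation.  The
    default matches the start of the baseline analysis window.
    """
    stim = trajectory.stimulus
    if stim is None:
        raise ValueError("trajectory carries no stimulus record")
    m = trajectory.times >= t_start
    inputs = stim.at(trajectory.times[m])  # (T, P)
    pyr = trajectory.rates[m][:, :, CellClass.PYR.value]
    return [
        corr_or_cov(inputs[:, p], pyr[:, p], threshold)
        for p in range(trajectory.rates.shape[1])
    ]


@dataclass
class SweepResult:
    """Metric evaluated per parameter value (and per population where
    applicable)."""

    parameter: str
    values: np.ndarray
    metric: dict  # value -> scalar or per-population array
    metadata: dict = field(default_factory=dict)

    def as_array(self) -> np.ndarray:
        return np.array([self.metric[v] for v in self.values])

    def to_frame(self):
        import pandas as pd

        rows = []
        for v in self.values:
            m = self.metric[v]
            if np.ndim(m) == 0:
                rows.append((v, None, float(m)))
            else:
                for p, mv in enumerate(np.atleast_1d(m), start=1):
                    rows.append((v, p, float(mv)))
        return pd.DataFrame(rows, columns=[self.parameter, "population", "metric"])


_SWEEPABLE = ("ipps", "sst_background", "vip_background")


def parameter_sweep(
    parameter: str,
    values,
    protocol: str = "static",
    metric: str = "snr",
    duration: float = 1000.0,
    dt: float = 0.1,
    spec_kwargs: dict | None = None,
) -> SweepResult:
    """Evaluate a metric while sweeping one model parameter.

    ``parameter``: 'ipps' | 'sst_background' | 'vip_background' |
    'decay:PRE->POST' (gating decay constant of one intra connection, ms).
    ``protocol``: 'static' | 'translating' | 'growing'.
    ``metric``: 'snr' | 'correlations' | 'pyr_rate'.
    Everything not swept stays at the packaged defaults (plus
    ``spec_kwargs``).  Deterministic.
    """
    spec_kwargs = dict(spec_kwargs or {})
    values = np.asarray(values, float)

    def make_spec(v):
        if parameter in _SWEEPABLE:
            kw = dict(spec_kwargs)
            kw[parameter] = v
            return default_spec(**kw)
        if parameter.startswith("decay:"):
            pre, post = parameter.split(":", 1)[1].split("->")
            spec = default_spec(**spec_kwargs)
            return spec.with_decay_tau(
                CellClass.from_label(pre), CellClass.from_label(post), "intra", v
            )
        raise KeyError(f"unknown sweep parameter {parameter!r}")

    def make_stimulus():
        if protocol == "static":
            return protocols.static_object()
        if protocol == "translating":
            return protocols.translating_object(duration=duration)
        if protocol == "growing":
            return protocols.growing_object(duration=duration)
        raise KeyError(f"unknown protocol {protocol!r}")

    stim = make_stimulus()
    out = {}
    for v in values:
        traj = _run(make_spec(v), stim, duration=duration, dt=dt)
        if metric == "snr":
            out[v] = snr(traj)
        elif metric == "correlations":
            out[v] = np.array([c.value for c in input_output_correlations(traj)])
        elif metric == "pyr_rate":
            out[v] = traj.class_rates(CellClass.PYR)[
                (traj.times >= STIM_WINDOW[0]) & (traj.times < STIM_WINDOW[1])
            ].mean(axis=0)
        else:
            raise KeyError(f"unknown metric {metric!r}")
    return SweepResult(parameter, values, out, {"protocol": protocol, "metric": metric})


def size_tuning_curve(
    vip_background: float,
    widths=(1, 3, 5, 7),
    duration: float = 1000.0,
    dt: float = 0.1,
    center: int = 4,
    normalize: bool = True,
) -> np.ndarray:
    """Population-4 Pyr response vs object width at one VIP drive.

    The response is the stimulus-evoked rate change of the center population
    (mean rate over the stimulus window minus mean rate over the baseline
    window), normalized (by default) to the width-1 response -- the standard
    surround-suppression index, reported per object size.
    """
    spec = default_spec(vip_background=vip_background)
    net = build_ring(spec)
    resp = []
    for trace in protocols.size_tuning_series(widths=widths, center=center):
        traj = integrate(net, trace, duration=duration, dt=dt, record_every=10)
        resp.append(
            traj.mean_rate(CellClass.PYR, center, *STIM_WINDOW)
            - traj.mean_rate(CellClass.PYR, center, *BASELINE_WINDOW)
        )
    resp = np.array(resp)
    if normalize:
        if resp[0] == 0:
            raise ZeroDivisionError("width-1 reference response is zero")
        resp = resp / resp[0]
    return resp


def stability_scan(
    sst_vip_taus,
    vip_sst_taus,
    duration: float = 1000.0,
    dt: float = 0.1,
    amplitude_threshold: float = 0.5,
    ipps: float = 0.0,
) -> dict:
    """Numerical stability map over the SST->VIP and VIP->SST gating decay
    constants (ms), without stimulus.

    This probes the within-population circuit, so the inter-population
    Pyr->SST pathway is removed by default (``ipps=0``).  For each grid
    point the network is relaxed and the tail (last 300 ms) of the
    population-4 Pyr rate is summarized: its mean, its detrended
    peak-to-trough amplitude, and a stable/oscillatory label (oscillatory
    when the amplitude exceeds ``amplitude_threshold`` Hz).
    """
    sst_vip_taus = np.asarray(sst_vip_taus, float)
    vip_sst_taus = np.asarray(vip_sst_taus, float)
    if np.any(sst_vip_taus <= 0) or np.any(sst_vip_taus > 100) or np.any(
        vip_sst_taus <= 0
    ) or np.any(vip_sst_taus > 100):
        raise ValueError("decay-constant grid must lie in (0, 100] ms")
    window = (duration - 300.0, duration)
    mean_rate = np.empty((sst_vip_taus.size, vip_sst_taus.size))
    amplitude = np.empty_like(mean_rate)
    oscillatory = np.zeros_like(mean_rate, dtype=bool)
    for i, ts in enumerate(sst_vip_taus):
        for j, tv in enumerate(vip_sst_taus):
            spec = default_spec(ipps=ipps).with_decay_tau(
                CellClass.SST, CellClass.VIP, "intra", ts
            ).with_decay_tau(CellClass.VIP, CellClass.SST, "intra", tv)
            traj = _run(spec, None, duration=duration, dt=dt)
            m = (traj.times >= window[0]) & (traj.times < window[1])
            mean_rate[i, j] = traj.rates[m, 3, CellClass.PYR.value].mean()
            amplitude[i, j] = oscillation_amplitude(traj, 4, window)
            oscillatory[i, j] = amplitude[i, j] > amplitude_threshold
    return {
        "sst_vip_tau_ms": sst_vip_taus,
        "vip_sst_tau_ms": vip_sst_taus,
        "mean_pyr_rate": mean_rate,
        "oscillation_amplitude": amplitude,
        "oscillatory": oscillatory,
    }


def sst_hyperpolarization_probe(
    probe_current: float = -10.0,
    ipps: float = 25.0,
    window=(700.0, 800.0),
    settle_ms: float = 50.0,
    duration: float = 1000.0,
    dt: float = 0.1,
) -> dict:
    """Oscillation amplitude in the probe window with vs without SST
    hyperpolarization, on the static protocol.

    ``probe_current`` (pA, negative = hyperpolarizing) is injected into all
    SST units during ``window``.  The sustained-rhythm amplitude is measured
    over [window start + settle_ms, window end]: silencing SST releases Pyr
    cells, and the first few tens of ms of the window contain that release
    transient rather than the rhythm being probed.  Returns both amplitudes
    and their ratio.
    """
    spec = default_spec(ipps=ipps)
    net = build_ring(spec)
    stim = protocols.static_object()
    control = integrate(net, stim, duration=duration, dt=dt, record_every=10)
    probed = integrate_with_probe(
        net, stim, probe_current, window=window, duration=duration, dt=dt, record_every=10
    )
    meas = (window[0] + settle_ms, window[1])
    a0 = oscillation_amplitude(control, 4, meas)
    a1 = oscillation_amplitude(probed, 4, meas)
    return {
        "amplitude_control": a0,
        "amplitude_probed": a1,
        "ratio": a1 / a0 if a0 > 0 else np.nan,
    }
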