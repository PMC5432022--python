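"""Reproducibility shell: run configs, seeded fixtures, run logging, figures.

A run is described by a ``RunConfig`` (model selector, protocol or scene
section, parameter overrides, seeds).  ``run_experiment`` executes it into a
fresh output directory containing the fully resolved configuration (with
its content hash), the raw outputs, and the derived metric tables, so that
any figure can be regenerated from the stored tables alone.  Two seed
streams (wiring vs noise) keep perturbation experiments seed-paired by
construction.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import config as _config
from . import metrics, protocols, scene2d, spikenet, v1metrics
from .ratenet import CellClass, build_ring, default_spec, integrate

__all__ = ["RunConfig", "run_experiment", "generate_fixtures", "make_figures"]

log = logging.getLogger("vipcircuit")

PROTOCOLS = {
    "static": protocols.static_object,
    "translating": protocols.translating_object,
    "growing": protocols.growing_object,
}


@dataclass
class RunConfig:
    """Declarative description of one experiment run."""

    model: str = "rate"  # 'rate' | 'spiking'
    protocol: str = "static"  # rate model: which stimulus schedule
    overrides: dict = field(default_factory=dict)  # rate: ipps/vip_background/...
    wiring_seed: int = 0
    noise_seed: int = 0
    scale: float = 0.05  # spiking model only
    vip_state: str = "low"  # spiking model only
    duration: float = 1000.0
    dt: float | None = None  # None -> model default

    def validate(self):
        if self.model not in ("rate", "spiking"):
            raise ValueError(f"unknown model {self.model!r}")
        if self.model == "rate" and self.protocol not in PROTOCOLS:
            raise ValueError(f"unknown protocol {self.protocol!r}")
        if self.vip_state not in ("low", "high"):
            raise ValueError("vip_state must be low|high")
        allowed = {"ipps", "vip_background", "sst_background", "pv_background"}
        bad = set(self.overrides) - allowed
        if bad:
            raise ValueError(f"unknown overrides: {sorted(bad)}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _prepare_outdir(outdir) -> Path:
    out = Path(outdir)
    if out.exists() and any(out.iterdir()):
        raise FileExistsError(f"output directory {out} exists and is not empty")
    out.mkdir(parents=True, exist_ok=True)
    return out


def run_experiment(cfg: RunConfig, outdir) -> Path:
    """Execute a run into ``outdir``; deterministic layout, bit-identical
    reruns for the deterministic (rate-model) stages."""
    cfg.validate()
    out = _prepare_outdir(outdir)
    resolved = cfg.to_dict()
    resolved["config_hash"] = _config.config_hash(resolved)
    (out / "config.json").write_text(json.dumps(resolved, indent=2, sort_keys=True))
    log.info("run %s -> %s", resolved["config_hash"], out)

    if cfg.model == "rate":
        _run_rate(cfg, out)
    else:
        _run_spiking(cfg, out)
    return out


def _run_rate(cfg: RunConfig, out: Path):
    spec = default_spec(**cfg.overrides)
    net = build_ring(spec)
    stim = PROTOCOLS[cfg.protocol](duration=cfg.duration) if cfg.protocol != "static" else protocols.static_object()
    traj = integrate(
        net, stim, duration=cfg.duration, dt=cfg.dt or 0.1, record_every=10
    )
    traj.to_frame().to_csv(out / "trajectory.csv", index=False)
    stim.to_frame().to_csv(out / "stimulus.csv", index=False)
    result = {}
    try:
        result["snr"] = metrics.snr(traj)
    except (ValueError, ZeroDivisionError):
        result["snr"] = None
    cs = metrics.input_output_correlations(traj)
    result["input_output"] = [
        {"population": p + 1, "value": c.value, "mode": c.mode}
        for p, c in enumerate(cs)
    ]
    try:
        result["oscillation_frequency_hz"] = metrics.oscillation_frequency(traj)
    except ValueError:  # run shorter than the standard analysis window
        result["oscillation_frequency_hz"] = None
    (out / "metrics.json").write_text(json.dumps(result, indent=2))


def _run_spiking(cfg: RunConfig, out: Path):
    frames = scene2d.render_frames()
    rates = scene2d.run_rates(frames)
    n_frames = int(cfg.duration // v1metrics.FRAME_MS)
    rates = rates[:n_frames]  # short smoke runs use the leading frames only
    lgn_spk = scene2d.poisson_spikes(rates, seed=cfg.noise_seed)
    grid, table, bg = spikenet.default_grid_config(scale=cfg.scale)
    net = spikenet.V1Network(grid, table, bg, wiring_seed=cfg.wiring_seed)
    net = spikenet.set_background_state(net, cfg.vip_state)
    sd = spikenet.simulate(
        net, lgn_spk, duration=cfg.duration, dt=cfg.dt or 0.5, seed=cfg.noise_seed + 1
    )
    np.savetxt(
        out / "spikes.txt",
        sd.to_events(),
        fmt="%.3f %d",
        header="time_ms neuron_id",
    )
    resp = v1metrics.bin_responses(sd)
    np.savetxt(out / "column_rates.csv", resp.rates, delimiter=",")
    lgn_tab = np.column_stack([fr.rates.reshape(-1) for fr in rates])
    np.savetxt(out / "lgn_rates.csv", lgn_tab, delimiter=",")
    mask = v1metrics.segment_target(rates)
    np.savetxt(out / "target_mask.csv", mask.inside.astype(int), delimiter=",", fmt="%d")
    cit, cot = v1metrics.cit_cot(
        resp, rates, mask, cot_frames=min(v1metrics.COT_FRAMES, n_frames)
    )
    summary = v1metrics.celltype_summary(sd)
    try:
        contrast = v1metrics.edge_surface_contrast(resp, mask)
    except ValueError:
        contrast = None
    (out / "metrics.json").write_text(
        json.dumps(
            {"CIT": cit, "COT": cot, "edge_surface_contrast": contrast,
             "class_rates": summary, "vip_state": cfg.vip_state},
            indent=2,
        )
    )


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------


def generate_fixtures(seed: int = 0) -> dict:
    """Small canned inputs for tests: a 2-unit rate net, a 3-frame mini
    scene (80x80 px, 2x2 patches), and a 4-column mini grid spec.
    Deterministic given the seed."""
    rng = np.random.default_rng(seed)
    from .ratenet import ConnectionSpec, RateNetworkSpec

    two_unit = RateNetworkSpec(
        n_populations=3,
        intrinsic_input={
            CellClass.PYR: float(rng.uniform(0.5, 2.0)),
            CellClass.PV: 0.0,
            CellClass.SST: float(rng.uniform(-0.5, 0.5)),
            CellClass.VIP: 0.0,
        },
        connections=(
            ConnectionSpec(CellClass.PYR, CellClass.PYR, "intra", float(rng.uniform(0, 15)), 4.0),
            ConnectionSpec(CellClass.PYR, CellClass.SST, "intra", float(rng.uniform(0, 20)), 4.0),
            ConnectionSpec(CellClass.SST, CellClass.PYR, "intra", -float(rng.uniform(0, 20)), 8.0),
        ),
    )

    mini_frames = []
    for k in range(3):
        img = np.zeros((80, 80))
        r = 12 + 6 * k
        yy, xx = np.mgrid[0:80, 0:80]
        img[(xx - 40.0) ** 2 + (yy - 40.0) ** 2 <= r**2] = 1.0
        mini_frames.append(img)
    mini_patches = [scene2d.patch_intensities(img) for img in mini_frames]

    mini_grid = spikenet.GridSpec(
        cells_per_column_full=400, scale=0.1, rows=2, cols=2
    )
    return {
        "two_unit_spec": two_unit,
        "mini_frames": mini_frames,
        "mini_patches": mini_patches,
        "mini_grid": mini_grid,
    }


# ---------------------------------------------------------------------------
# Figures (from stored tables only)
# ---------------------------------------------------------------------------


def make_figures(results_dir) -> list[Path]:
    """Regenerate the standard panels from a run directory's tables.

    Rate runs: per-population Pyr traces and a normalized response heat map
    (populations x 50-ms bins, scaled to the run maximum).  Sweep tables
    (snr_vs_*.csv) become SNR curves with the input-ratio reference line.
    Spiking runs: per-frame column-rate heat maps.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import pandas as pd

    res = Path(results_dir)
    if not res.exists() or not any(res.iterdir()):
        raise FileNotFoundError(f"no results in {res}")
    made = []

    traj_csv = res / "trajectory.csv"
    if traj_csv.exists():
        df = pd.read_csv(traj_csv)
        pyr = df[df.cell_class == "PYR"].pivot_table(
            index="population", columns="time_ms", values="rate_hz"
        )
        fig, (ax0, ax1) = plt.subplots(2, 1, figsize=(8, 6))
        for pop, row in pyr.iterrows():
            ax0.plot(row.index, row.values, label=f"pop {pop}", lw=0.8)
        ax0.set(xlabel="time (ms)", ylabel="Pyr rate (Hz)")
        ax0.legend(fontsize=6, ncol=4)
        # 50-ms-binned, normalized to the run maximum over all populations
        edges = np.arange(0, df.time_ms.max() + 50, 50)
        binned = np.stack([
            np.histogram(row.index, bins=edges, weights=row.values)[0]
            / np.maximum(np.histogram(row.index, bins=edges)[0], 1)
            for _, row in pyr.iterrows()
        ])
        im = ax1.imshow(
            binned / max(binned.max(), 1e-12), aspect="auto", cmap="jet",
            extent=[0, edges[-1], pyr.index.max() + 0.5, pyr.index.min() - 0.5],
        )
        ax1.set(xlabel="time (ms)", ylabel="population")
        fig.colorbar(im, ax=ax1, label="normalized Pyr response")
        path = res / "rate_panel.png"
        fig.savefig(path, dpi=110)
        plt.close(fig)
        made.append(path)

    for sweep_csv in sorted(res.glob("snr_vs_*.csv")):
        df = pd.read_csv(sweep_csv)
        param = df.columns[0]
        fig, ax = plt.subplots(figsize=(5, 4))
        ax.plot(df[param], df["metric"], "o-")
        ax.axhline(3.5 / 3.0, ls="--", c="k", label="input ratio")
        ax.set(xlabel=param, ylabel="SNR")
        ax.legend()
        path = res / f"{sweep_csv.stem}.png"
        fig.savefig(path, dpi=110)
        plt.close(fig)
        made.append(path)

    col_csv = res / "column_rates.csv"
    if col_csv.exists():
        rates = np.loadtxt(col_csv, delimiter=",")
        n_frames = rates.shape[1]
        picks = [1, n_frames // 3, 2 * n_frames // 3, n_frames - 1]
        fig, axes = plt.subplots(1, len(picks), figsize=(4 * len(picks), 3.2))
        vmax = max(rates.max(), 1e-9)
        for ax, k in zip(axes, picks):
            im = ax.imshow(
                rates[:, k].reshape(v1metrics.GRID_ROWS, v1metrics.GRID_COLS),
                cmap="jet", vmin=0, vmax=vmax,
            )
            ax.set_title(f"{int(k * 50)}-{int((k + 1) * 50)} ms", fontsize=9)
        fig.colorbar(im, ax=axes, label="Pyr rate (Hz)", shrink=0.8)
        path = res / "column_panel.png"
        fig.savefig(path, dpi=110)
        plt.close(fig)
        made.append(path)

    if not made:
        raise FileNotFoundError(f"no known tables found in {res}")
    return made
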