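"""Analysis of spiking-model output: frame-binned column responses, target
segmentation, inside/outside-target correlations (CIT/COT), cell-type
summaries, and the perturbation experiments.

Column responses CR are the firing rates of the recorded Pyr subset per
(column, 50-ms frame).  The thalamic output TO is the LGN rate per (patch,
frame).  The spatial extent of the looming target sphere is identified per
frame from the thalamic output itself; columns then split into an
inside-target and an outside-target distribution.  CIT is the Pearson
correlation between CR and TO over the inside samples of all 20 frames;
COT the same over the outside samples of the first 8 frames only (the
flanking spheres start leaving the visual field at 400 ms).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ratenet import CellClass
from .scene2d import GRID_COLS, GRID_ROWS, LGNRates
from .spikenet import SpikeData

__all__ = [
    "ColumnResponses",
    "TargetMask",
    "bin_responses",
    "segment_target",
    "pearson",
    "cit_cot",
    "celltype_summary",
    "edge_columns",
    "edge_surface_contrast",
    "scene_inputs",
    "run_scene_condition",
    "vip_state_experiment",
    "suppression_sweep",
    "pv_background_experiment",
]

FRAME_MS = 50.0
COT_FRAMES = 8  # flankers start leaving the field at 400 ms
BLANK_RATE = 20.0  # LGN rate for an empty patch (Hz)


@dataclass
class ColumnResponses:
    """Recorded-Pyr firing rate per (column, frame), Hz."""

    rates: np.ndarray  # (n_columns, n_frames)

    @property
    def n_frames(self) -> int:
        return self.rates.shape[1]

    def as_grid(self, frame: int) -> np.ndarray:
        return self.rates[:, frame].reshape(GRID_ROWS, GRID_COLS)


@dataclass
class TargetMask:
    """Per-frame boolean mask of inside-target columns (row-major order)."""

    inside: np.ndarray  # (n_columns, n_frames) bool

    def frame(self, k: int) -> np.ndarray:
        return self.inside[:, k].reshape(GRID_ROWS, GRID_COLS)


def bin_responses(spikes: SpikeData, frame_ms: float = FRAME_MS) -> ColumnResponses:
    """Rate of the recorded Pyr subset per column and 50-ms frame."""
    if spikes.duration % frame_ms:
        raise ValueError("duration must be a multiple of the frame length")
    n_frames = int(round(spikes.duration / frame_ms))
    n_col = spikes.n_columns
    rec_per_col = np.bincount(
        spikes.column_of[spikes.recorded_mask], minlength=n_col
    )
    keep = spikes.recorded_mask[spikes.neuron_ids]
    cols = spikes.column_of[spikes.neuron_ids[keep]]
    frames = np.minimum((spikes.times[keep] / frame_ms).astype(int), n_frames - 1)
    counts = np.zeros((n_col, n_frames))
    np.add.at(counts, (cols, frames), 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        rates = counts / rec_per_col[:, None] / (frame_ms / 1000.0)
    rates[rec_per_col == 0] = 0.0
    return ColumnResponses(rates)


def _connected_component(mask2d: np.ndarray, seed_rc: tuple[int, int]) -> np.ndarray:
    from scipy import ndimage

    labels, _ = ndimage.label(mask2d)  # 4-connectivity
    lab = labels[seed_rc]
    if lab == 0:
        return np.zeros_like(mask2d, dtype=bool)
    return labels == lab


def segment_target(
    lgn: list[LGNRates],
    rel_threshold: float = 0.1,
) -> TargetMask:
    """Identify the target sphere's spatial extent per frame from the LGN code.

    A patch counts as driven when its rate exceeds the blank-field rate
    (20 Hz) by ``rel_threshold`` of the frame's dynamic range; the inside
    mask is the 4-connected component of driven patches containing the
    central patch.  Blank frames yield an empty mask (flagged by the
    all-False column).
    """
    n_frames = len(lgn)
    inside = np.zeros((GRID_ROWS * GRID_COLS, n_frames), dtype=bool)
    center = (GRID_ROWS // 2, GRID_COLS // 2)
    for k, fr in enumerate(lgn):
        rates = fr.rates
        dyn = rates.max() - BLANK_RATE
        if dyn <= 0:
            continue  # blank frame -> empty mask
        driven = rates > BLANK_RATE + rel_threshold * dyn
        comp = _connected_component(driven, center)
        inside[:, k] = comp.reshape(-1)
    return TargetMask(inside)


def pearson(x, y) -> float:
    """Pearson correlation, computed from population moments.

    This is the correlation definition used for CIT/COT; it matches a naive
    two-pass mean/std computation to floating-point accuracy.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size or x.size < 2:
        raise ValueError("need two equal-length vectors (n >= 2)")
    dx = x - x.mean()
    dy = y - y.mean()
    sx = np.sqrt(np.mean(dx**2))
    sy = np.sqrt(np.mean(dy**2))
    if sx == 0 or sy == 0:
        raise ValueError("degenerate variance; correlation undefined")
    return float(np.mean(dx * dy) / (sx * sy))


def cit_cot(
    responses: ColumnResponses,
    lgn: list[LGNRates],
    mask: TargetMask,
    cot_frames: int = COT_FRAMES,
) -> tuple[float, float]:
    """Inside-target (all frames) and outside-target (first ``cot_frames``)
    correlations between column responses and thalamic outputs."""
    n_frames = responses.n_frames
    if len(lgn) != n_frames or mask.inside.shape[1] != n_frames:
        raise ValueError("responses, LGN rates and mask must share the frame axis")
    to = np.column_stack([fr.rates.reshape(-1) for fr in lgn])  # (cols, frames)
    cr = responses.rates
    ins = mask.inside
    cit = pearson(cr[ins], to[ins])
    outs = ~ins[:, :cot_frames]
    cot = pearson(cr[:, :cot_frames][outs], to[:, :cot_frames][outs])
    return cit, cot


def celltype_summary(
    spikes: SpikeData,
    mask: TargetMask | None = None,
    final_frame_ms: tuple[float, float] = (950.0, 1000.0),
    center_radius: int = 1,
) -> dict:
    """Mean rate per cell class, plus the SST rate in target-center columns
    during the final frame (the looming target dominates the field there)."""
    out = {c.name: spikes.mean_rate(c) for c in CellClass}
    rows, cols = GRID_ROWS, GRID_COLS
    ci, cj = rows // 2, cols // 2
    center_cols = [
        (ci + di) % rows * cols + (cj + dj) % cols
        for di in range(-center_radius, center_radius + 1)
        for dj in range(-center_radius, center_radius + 1)
    ]
    sst = spikes.class_of == CellClass.SST.value
    in_center = np.isin(spikes.column_of, center_cols) & sst
    n_cells = int(in_center.sum())
    t0, t1 = final_frame_ms
    ev = in_center[spikes.neuron_ids] & (spikes.times >= t0) & (spikes.times < t1)
    out["SST_center_final"] = (
        float(ev.sum()) / n_cells / ((t1 - t0) / 1000.0) if n_cells else 0.0
    )
    return out


def edge_columns(mask2d: np.ndarray) -> np.ndarray:
    """Inside-mask columns 8-adjacent to an outside column."""
    from scipy import ndimage

    inside = mask2d.astype(bool)
    eroded = ndimage.binary_erosion(
        inside, structure=np.ones((3, 3)), border_value=0
    )
    return inside & ~eroded


def edge_surface_contrast(
    responses: ColumnResponses,
    mask: TargetMask,
    frames: list[int] | None = None,
    min_inside: int = 9,
) -> float:
    """Ratio of edge-column to interior-column mean recorded-Pyr rate,
    averaged over late frames where the inside mask is large enough."""
    n_frames = responses.n_frames
    frames = frames if frames is not None else list(range(n_frames - 4, n_frames))
    ratios = []
    for k in frames:
        m2 = mask.frame(k)
        if m2.sum() < min_inside:
            continue
        edge = edge_columns(m2)
        interior = m2 & ~edge
        if not interior.any() or not edge.any():
            continue
        grid = responses.as_grid(k)
        if grid[interior].mean() <= 0:
            continue
        ratios.append(grid[edge].mean() / grid[interior].mean())
    if not ratios:
        raise ValueError("no frame with a usable interior region")
    return float(np.mean(ratios))


# ---------------------------------------------------------------------------
# Scene-driven experiments (seed-paired perturbations)
# ---------------------------------------------------------------------------

_SCENE_CACHE: dict = {}


def scene_inputs():
    """The default looming scene's LGN rates and target mask (cached)."""
    if "lgn" not in _SCENE_CACHE:
        from . import scene2d

        frames = scene2d.render_frames()
        lgn = scene2d.run_rates(frames)
        _SCENE_CACHE["lgn"] = lgn
        _SCENE_CACHE["mask"] = segment_target(lgn)
    return _SCENE_CACHE["lgn"], _SCENE_CACHE["mask"]


def run_scene_condition(
    seed: int,
    vip_state: str = "low",
    scale: float = 0.05,
    pyr_sst_inter_factor: float = 1.0,
    pv_background_factor: float = 1.0,
    dt: float = 0.5,
) -> dict:
    """Simulate the looming-scene protocol under one condition.

    The wiring seed, LGN spike seed and background-noise seed all derive
    from ``seed``, so two calls differing only in the condition arguments
    are seed-paired.  Returns CIT/COT, cell-class rates, the target-center
    SST rate in the final frame, and the edge/surface contrast.
    """
    from . import scene2d
    from .spikenet import V1Network, default_grid_config, set_background_state, simulate

    lgn, mask = scene_inputs()
    spikes_in = scene2d.poisson_spikes(lgn, seed=seed)
    grid, table, bg = default_grid_config(scale=scale)
    if pyr_sst_inter_factor != 1.0:
        table = table.scaled(CellClass.PYR, CellClass.SST, "inter", pyr_sst_inter_factor)
    net = V1Network(grid, table, bg, wiring_seed=seed)
    net = set_background_state(net, vip_state)
    sd = simulate(
        net, spikes_in, duration=1000.0, dt=dt, seed=seed + 10_000,
        pv_background_factor=pv_background_factor,
    )
    resp = bin_responses(sd)
    cit, cot = cit_cot(resp, lgn, mask)
    out = celltype_summary(sd, center_radius=2)
    out.update(CIT=cit, COT=cot)
    try:
        out["edge_surface_contrast"] = edge_surface_contrast(resp, mask)
    except ValueError:
        out["edge_surface_contrast"] = float("nan")
    return out


def vip_state_experiment(seeds, scale: float = 0.05, dt: float = 0.5) -> dict:
    """Seed-paired low/high VIP-state runs; per-seed metric dictionaries."""
    out = {"low": [], "high": []}
    for s in seeds:
        for state in ("low", "high"):
            out[state].append(run_scene_condition(s, vip_state=state, scale=scale, dt=dt))
    return out


def suppression_sweep(
    factors,
    seeds,
    vip_state: str = "low",
    scale: float = 0.05,
    dt: float = 0.5,
) -> dict:
    """CIT/COT per inter-columnar Pyr->SST probability factor, seed-paired.

    ``factors`` multiply the packaged connection probability (capped at 1
    after in-degree scaling); factor 0 removes the pathway (the weakest-
    suppression control point).
    """
    out = {}
    for f in factors:
        runs = [
            run_scene_condition(
                s, vip_state=vip_state, scale=scale, pyr_sst_inter_factor=f, dt=dt
            )
            for s in seeds
        ]
        out[f] = {
            "CIT": [r["CIT"] for r in runs],
            "COT": [r["COT"] for r in runs],
        }
    return out


def pv_background_experiment(
    reduction: float,
    seeds,
    scale: float = 0.05,
    dt: float = 0.5,
) -> dict:
    """Edge/surface contrast with vs without a PV background reduction.

    Runs in the high-depolarization (VIP high) state; ``reduction`` is the
    fractional cut of the PV fiber rate (0 = control, applied to PV only).
    """
    if not 0 <= reduction <= 1:
        raise ValueError("reduction must be in [0, 1]")
    out = {"control": [], "reduced": []}
    for s in seeds:
        out["control"].append(
            run_scene_condition(s, vip_state="high", scale=scale, dt=dt)
        )
        out["reduced"].append(
            run_scene_condition(
                s, vip_state="high", scale=scale,
                pv_background_factor=1.0 - reduction, dt=dt,
            )
        )
    return out
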