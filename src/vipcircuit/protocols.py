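"""Stimulus protocols for the 1-D firing-rate model.

Each of the 7 populations is assigned a non-overlapping unit receptive
field (RF) on the ring: population p covers the interval [p-1, p) in RF
units.  A visual object is an interval of given width; the stimulus
current a population receives is the full amplitude (default 0.5 pA)
scaled by the fraction of its RF covered by the object.  All schedules
are generated from this interval geometry, not hard-coded tables.

Protocols:

* ``static_object``      -- a 1-RF object covering population 4, on at 500 ms.
* ``size_tuning_series`` -- objects of width 1, 3, 5, 7 RF centred on
  population 4 (the classic size-tuning probe).
* ``translating_object`` -- a 3-RF object that appears over populations
  1-3 at 300 ms, steps rightward by 25% RF every 50 ms, and is removed
  from the scene at 550 ms (just after fully covering population 4).
* ``growing_object``     -- an object that looms over population 3 from
  300 ms, spreads to populations 2/4 at 400 ms and 1/5 at 500 ms, and
  disappears at 600 ms.
"""

from __future__ import annotations

import numpy as np

from .ratenet import StimulusTrace

__all__ = [
    "coverage",
    "static_object",
    "size_tuning_series",
    "translating_object",
    "growing_object",
]

DEFAULT_AMPLITUDE = 0.5  # pA, printed stimulus current
RF_WIDTH = 1.0  # RF units per population


def coverage(left: float, right: float, n_populations: int = 7) -> np.ndarray:
    """Fraction of each population's RF covered by the object [left, right].

    RFs are the unit intervals [p-1, p), p = 1..n.  No wrap-around: the
    protocols never move an object across the periodic boundary.
    """
    if right < left:
        raise ValueError("object interval reversed")
    p = np.arange(n_populations, dtype=float)
    lo = np.maximum(p, left)
    hi = np.minimum(p + RF_WIDTH, right)
    return np.clip(hi - lo, 0.0, RF_WIDTH) / RF_WIDTH


def static_object(
    target_population: int = 4,
    amplitude: float = DEFAULT_AMPLITUDE,
    onset: float = 500.0,
    end: float = 1000.0,
    n_populations: int = 7,
) -> StimulusTrace:
    """A 1-RF object over one population's RF, stepped on during [onset, end)."""
    if not 1 <= target_population <= n_populations:
        raise ValueError("target population outside the ring")
    if onset >= end:
        raise ValueError("onset must precede end")
    edges = np.array([0.0, onset, end])
    cur = np.zeros((2, n_populations))
    cur[1] = amplitude * coverage(
        target_population - 1.0, float(target_population), n_populations
    )
    return StimulusTrace(edges, cur)


def size_tuning_series(
    widths=(1, 3, 5, 7),
    center: int = 4,
    amplitude: float = DEFAULT_AMPLITUDE,
    onset: float = 500.0,
    end: float = 1000.0,
    n_populations: int = 7,
) -> list[StimulusTrace]:
    """Objects of odd RF widths centred on one population, one trace each."""
    traces = []
    for w in widths:
        if w % 2 == 0:
            raise ValueError(f"object width must be odd, got {w}")
        if w > n_populations:
            raise ValueError(f"object width {w} exceeds ring size")
        half = w / 2.0
        mid = center - 0.5  # centre of the center population's RF
        edges = np.array([0.0, onset, end])
        cur = np.zeros((2, n_populations))
        cur[1] = amplitude * coverage(mid - half, mid + half, n_populations)
        traces.append(StimulusTrace(edges, cur))
    return traces


def translating_object(
    width: float = 3.0,
    step_fraction: float = 0.25,
    step_ms: float = 50.0,
    onset: float = 300.0,
    removal: float = 550.0,
    amplitude: float = DEFAULT_AMPLITUDE,
    duration: float = 1000.0,
    n_populations: int = 7,
) -> StimulusTrace:
    """A rightward-moving object sampled on a 50-ms grid.

    The object appears at ``onset`` with its left edge at 0 (population 1
    fully covered) and advances by ``step_fraction`` RF per ``step_ms``.
    With the defaults it fully covers population 4 during [500, 550) ms and
    is removed at 550 ms.  Input per population and bin is the amplitude
    times the covered RF fraction.
    """
    if (RF_WIDTH / step_fraction) % 1 != 0:
        raise ValueError("step must divide the receptive field evenly")
    edges = np.arange(0.0, duration + step_ms / 2, step_ms)
    cur = np.zeros((edges.size - 1, n_populations))
    for b, t in enumerate(edges[:-1]):
        if t < onset or t >= removal:
            continue
        k = round((t - onset) / step_ms)
        left = k * step_fraction
        cur[b] = amplitude * coverage(left, left + width, n_populations)
    return StimulusTrace(edges, cur)


def growing_object(
    center: int = 3,
    amplitude: float = DEFAULT_AMPLITUDE,
    onset: float = 300.0,
    growth_step_ms: float = 100.0,
    offset: float = 600.0,
    max_halfwidth: int = 2,
    duration: float = 1000.0,
    n_populations: int = 7,
) -> StimulusTrace:
    """An object growing symmetrically around one population (looming).

    The object starts 1 RF wide over ``center`` at ``onset`` and widens by
    one RF on each side every ``growth_step_ms``; everything is removed at
    ``offset``.  With the defaults: population 3 is driven during
    [300, 600), populations 2 and 4 during [400, 600), populations 1 and 5
    during [500, 600) ms.
    """
    edges = sorted(
        {0.0, duration, offset}
        | {onset + k * growth_step_ms for k in range(max_halfwidth + 1)}
    )
    edges = np.array([e for e in edges if e <= duration])
    cur = np.zeros((edges.size - 1, n_populations))
    mid = center - 0.5
    for b, t in enumerate(edges[:-1]):
        if t < onset or t >= offset:
            continue
        half = 0.5 + RF_WIDTH * min(int((t - onset) // growth_step_ms), max_halfwidth)
        cur[b] = amplitude * coverage(mid - half, mid + half, n_populations)
    return StimulusTrace(edges, cur)
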