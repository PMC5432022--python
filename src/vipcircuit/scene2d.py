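"""Synthetic optic-flow scene: five spheres approached at constant speed.

A pinhole camera (the animal's eye) translates at constant speed toward a
fronto-parallel plane holding five spheres: a central *target* sphere whose
radius is 1.5x that of the four flankers, which sit at the diagonal
half-field positions.  Forward self-motion produces a linear flow field
with the focus of expansion at the image center: the target looms in place
while the flankers drift radially outward and eventually leave the frame.

Frames are rendered as filled uniform-intensity discs by exact pinhole
projection -- the downstream thalamic code only sums patch intensity, so
shading and lighting would be irrelevant detail.  Each 640x480 frame is
split into 16x12 non-overlapping 40x40-pixel patches; per-patch intensity
sums I are mapped to LGN population rates by the affine code

    R = 20 + 60 * I / I_max  [Hz],

where I_max is the maximum patch sum over the whole run, so every rate
lies in [20, 80] Hz.  Each patch drives 100 LGN cells that emit Poisson
spike trains at the patch rate, held fixed within each 50-ms frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SphereScene",
    "Frame",
    "PatchIntensities",
    "LGNRates",
    "render_frames",
    "patch_intensities",
    "lgn_rates",
    "run_rates",
    "poisson_spikes",
    "IMAGE_WIDTH",
    "IMAGE_HEIGHT",
    "PATCH_PX",
    "GRID_COLS",
    "GRID_ROWS",
]

IMAGE_WIDTH = 640
IMAGE_HEIGHT = 480
PATCH_PX = 40
GRID_COLS = IMAGE_WIDTH // PATCH_PX  # 16
GRID_ROWS = IMAGE_HEIGHT // PATCH_PX  # 12
HFOV_DEG = 80.0  # horizontal field of view


@dataclass(frozen=True)
class SphereScene:
    """Five spheres on a fronto-parallel plane, camera approaching.

    Distances are in scene units (the geometry is scale-free; only angles
    matter for the projection).  Defaults place all spheres inside the
    field of view at t = 0, have the flankers start leaving the frame at
    ~0.4 s, and keep the camera outside the target sphere for the whole
    1-s run.
    """

    target_radius: float = 1.2
    flanker_radius: float = 0.8
    plane_distance: float = 6.0
    flanker_offset: tuple[float, float] = (8.0 / 3.0, 2.0)  # (x, y), 4:3 diagonal
    speed: float = 3.875  # scene units / s toward the plane
    n_frames: int = 20
    duration: float = 1.0  # s

    def __post_init__(self):
        if not np.isclose(self.target_radius / self.flanker_radius, 1.5):
            raise ValueError("target sphere must be 1.5x the flanker radius")
        if self.plane_distance - self.speed * self.duration <= self.target_radius:
            raise ValueError("camera would penetrate the target sphere")

    @property
    def focal_px(self) -> float:
        return (IMAGE_WIDTH / 2.0) / np.tan(np.deg2rad(HFOV_DEG / 2.0))

    def sphere_centers(self) -> list[tuple[float, float]]:
        """(x, y) scene coordinates of target followed by the four flankers."""
        fx, fy = self.flanker_offset
        return [(0.0, 0.0), (fx, fy), (-fx, fy), (fx, -fy), (-fx, -fy)]

    def sphere_radii(self) -> list[float]:
        return [self.target_radius] + [self.flanker_radius] * 4

    def frame_times(self) -> np.ndarray:
        return np.arange(self.n_frames) * (self.duration / self.n_frames)

    def projected_discs(self, t: float) -> list[tuple[float, float, float]]:
        """Disc (u_px, v_px, radius_px) per sphere at time t (pinhole model)."""
        z = self.plane_distance - self.speed * t
        if z <= 0:
            raise ValueError("sphere behind camera")
        f = self.focal_px
        discs = []
        for (x, y), r in zip(self.sphere_centers(), self.sphere_radii()):
            u = f * x / z + IMAGE_WIDTH / 2.0
            v = f * y / z + IMAGE_HEIGHT / 2.0
            discs.append((u, v, f * r / z))
        return discs


@dataclass(frozen=True)
class Frame:
    """One grayscale frame: intensities in [0, 1], with its timestamp (s)."""

    image: np.ndarray
    time: float

    def __post_init__(self):
        if self.image.shape != (IMAGE_HEIGHT, IMAGE_WIDTH):
            raise ValueError("frame must be 480x640")


@dataclass(frozen=True)
class PatchIntensities:
    """Grid of per-patch pixel sums for one frame (16x12 for full scenes;
    mini test scenes may carry smaller grids)."""

    sums: np.ndarray  # (rows, cols)

    def __post_init__(self):
        if np.any(self.sums < 0):
            raise ValueError("patch sums must be >= 0")


@dataclass(frozen=True)
class LGNRates:
    """Per-patch thalamic rates (Hz) for one 50-ms frame bin."""

    rates: np.ndarray  # (rows, cols)
    cells_per_patch: int = 100
    bin_ms: float = 50.0

    def __post_init__(self):
        object.__setattr__(self, "rates", np.asarray(self.rates, float))


def render_frames(scene: SphereScene | None = None) -> list[Frame]:
    """Rasterize the scene into binary-intensity disc images, one per frame."""
    scene = scene or SphereScene()
    v_grid, u_grid = np.mgrid[0:IMAGE_HEIGHT, 0:IMAGE_WIDTH]
    u_grid = u_grid + 0.5  # pixel centers
    v_grid = v_grid + 0.5
    frames = []
    for t in scene.frame_times():
        img = np.zeros((IMAGE_HEIGHT, IMAGE_WIDTH))
        for u, v, r in scene.projected_discs(t):
            img[(u_grid - u) ** 2 + (v_grid - v) ** 2 <= r**2] = 1.0
        frames.append(Frame(img, float(t)))
    return frames


def patch_intensities(frame: Frame | np.ndarray) -> PatchIntensities:
    """Exact partition of the frame into 40x40 patch sums."""
    img = frame.image if isinstance(frame, Frame) else np.asarray(frame, float)
    h, w = img.shape
    if h % PATCH_PX or w % PATCH_PX:
        raise ValueError("frame dimensions not divisible into 40x40 patches")
    sums = img.reshape(h // PATCH_PX, PATCH_PX, w // PATCH_PX, PATCH_PX).sum(axis=(1, 3))
    return PatchIntensities(sums)


def lgn_rates(patches: PatchIntensities, i_max: float) -> LGNRates:
    """Affine thalamic rate code R = 20 + 60 I / I_max (Hz).

    ``i_max`` is the run-wide maximum patch sum.  A blank run (i_max = 0)
    yields the 20-Hz background rate everywhere, with a warning.
    """
    if i_max <= 0:
        import warnings

        warnings.warn("blank run: I_max = 0, all LGN rates at 20 Hz")
        return LGNRates(np.full_like(patches.sums, 20.0))
    return LGNRates(20.0 + 60.0 * patches.sums / i_max)


def run_rates(frames: list[Frame]) -> list[LGNRates]:
    """LGN rates for a whole run, with I_max taken over all frames' patches
    so rates are comparable across frames."""
    all_patches = [patch_intensities(f) for f in frames]
    i_max = max(p.sums.max() for p in all_patches)
    return [lgn_rates(p, i_max) for p in all_patches]


def poisson_spikes(
    rates: list[LGNRates] | LGNRates,
    n_cells: int = 100,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Poisson spike trains for every LGN cell over the frame sequence.

    Returns an array of (time_s, cell_id) rows sorted by time; cell_id =
    patch_index * n_cells + cell (patches in row-major order).  Rates are
    constant within each frame bin; spikes of independent cells are
    independent.  Reproducible given the seed.
    """
    if isinstance(rates, LGNRates):
        rates = [rates]
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    bin_s = rates[0].bin_ms / 1000.0
    events = []
    for k, fr in enumerate(rates):
        flat = fr.rates.reshape(-1)  # (192,)
        if np.any(~np.isfinite(flat)) or np.any(flat < 0):
            raise ValueError("rates must be finite and nonnegative")
        lam = np.repeat(flat, n_cells) * bin_s  # per cell
        counts = rng.poisson(lam)
        total = int(counts.sum())
        if total == 0:
            continue
        cell_ids = np.repeat(np.arange(lam.size), counts)
        times = k * bin_s + rng.uniform(0.0, bin_s, size=total)
        events.append(np.column_stack([times, cell_ids]))
    if not events:
        return np.empty((0, 2))
    out = np.concatenate(events)
    return out[np.argsort(out[:, 0], kind="stable")]
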