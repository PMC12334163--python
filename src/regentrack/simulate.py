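"""Synthetic 4D recordings of a regenerating epithelium with known lineages.

The generator emulates the statistical structure of long-term confocal
recordings of nuclei in a regenerating crustacean leg: anisotropic
voxels (0.31 × 0.31 × 1.24 µm), 10-minute intervals, four imaging
replicates per slice, cell migration toward a wound plane, a
quiescence → proliferation-burst → decline division schedule, apoptosis
rendered as bright pyknotic nuclei, depth-dependent signal attenuation,
photobleaching with step recoveries after heat shocks, and
Poisson-plus-Gaussian noise drawn independently per replicate.

Nuclei are rendered as anisotropic Gaussians (nucleus extent and PSF
combined in quadrature), which is sufficient for point-detection
tracking.  Every run is deterministic given the configuration seed, and
the emitted lineage forest always satisfies the core invariants.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, NamedTuple, Optional, Sequence, Tuple

import numpy as np
from scipy.spatial import cKDTree

from .core import LineageForest, Movie, Spot, VoxelGrid
from .track import FlowField

__all__ = [
    "SimulationConfig",
    "Event",
    "EventLog",
    "simulate_recording",
    "add_imaging_noise",
    "render_probability_map",
    "ground_truth_flow",
    "ground_truth_flow_field",
    "depth_attenuate",
    "bleach_factors",
    "add_noise",
    "burst_profile",
    "li_synth",
    "li_synth_mini",
]


class GenerationError(RuntimeError):
    """Raised when cells cannot be placed at the requested separation."""


def burst_profile(
    n_timepoints: int,
    t_on: int,
    t_off: int,
    p_burst: float,
    t_end: Optional[int] = None,
    p_decline: float = 0.0,
) -> np.ndarray:
    """Quiescence → burst → decline per-time-point division probabilities.

    Zero before ``t_on``, ``p_burst`` on ``[t_on, t_off)``, ``p_decline``
    on ``[t_off, t_end)`` and zero afterwards.
    """
    profile = np.zeros(n_timepoints, dtype=float)
    profile[t_on:t_off] = p_burst
    if t_end is not None:
        profile[t_off:t_end] = p_decline
    return profile


@dataclass
class SimulationConfig:
    """Parameters of one synthetic recording.  All lengths in µm, times in frames."""

    grid: VoxelGrid = field(
        default_factory=lambda: VoxelGrid((20, 160, 160), (1.24, 0.31, 0.31), 10.0)
    )
    n_timepoints: int = 60
    n_replicates: int = 4
    n_initial_cells: int = 40
    placement_margin: float = 3.0
    radius_mean: float = 2.0
    radius_sd: float = 0.25
    motility_sd: float = 0.5
    drift: float = 0.4
    migration_end: Optional[int] = None
    wound_axis: int = 1
    wound_plane: float = 0.0
    division_profile: Optional[np.ndarray] = None
    division_refractory: int = 5
    apoptosis_prob: float = 0.002
    pyknotic_factor: float = 3.0
    attenuation_length: float = 15.0
    bleach_rate: float = 0.002
    recovery_times: Tuple[int, ...] = (30,)
    recovery_amplitudes: Tuple[float, ...] = (0.3,)
    psf_sigma: Tuple[float, float, float] = (0.6, 0.15, 0.15)
    poisson_gain: float = 20.0
    read_noise_sd: float = 1000.0
    background: float = 200.0
    base_intensity_mean: float = 8000.0
    base_intensity_sd: float = 1200.0
    min_separation: float = 5.5
    oscillation_amplitude: float = 0.0
    oscillation_period: float = 390.0
    seed: int = 42

    def __post_init__(self) -> None:
        if self.migration_end is None:
            # wound-directed migration precedes the proliferation burst
            self.migration_end = self.n_timepoints // 4
        if self.division_profile is None:
            self.division_profile = burst_profile(
                self.n_timepoints,
                self.n_timepoints // 4,
                (self.n_timepoints * 7) // 12,
                0.04,
                (self.n_timepoints * 5) // 6,
                0.01,
            )
        self.division_profile = np.asarray(self.division_profile, dtype=float)
        if len(self.division_profile) != self.n_timepoints:
            raise ValueError("division profile length must equal n_timepoints")
        for name, p in [("division", self.division_profile), ("apoptosis", [self.apoptosis_prob])]:
            arr = np.asarray(p)
            if np.any(arr < 0) or np.any(arr > 1):
                raise ValueError(f"{name} probabilities must lie in [0, 1]")
        for name, v in [
            ("radius_mean", self.radius_mean),
            ("attenuation_length", self.attenuation_length),
            ("min_separation", self.min_separation),
            ("base_intensity_mean", self.base_intensity_mean),
        ]:
            if v <= 0:
                raise ValueError(f"{name} must be > 0")
        if len(self.recovery_times) != len(self.recovery_amplitudes):
            raise ValueError("recovery times and amplitudes must pair up")


def li_synth() -> SimulationConfig:
    """The packaged benchmark recording: 60 frames, 20 z slices, seed 42."""
    return SimulationConfig()


def li_synth_mini() -> SimulationConfig:
    """A small, fast variant of the benchmark for unit tests."""
    return SimulationConfig(
        grid=VoxelGrid((12, 120, 120), (1.24, 0.31, 0.31), 10.0),
        n_timepoints=20,
        n_initial_cells=12,
        division_profile=burst_profile(20, 6, 14, 0.06),
        recovery_times=(10,),
        seed=42,
    )


class Event(NamedTuple):
    """One lifecycle event: ``kind`` is birth, division, or apoptosis."""

    kind: str
    t: int
    cell_id: int
    parent_cell_id: Optional[int]


@dataclass
class EventLog:
    """Per-cell birth/division/apoptosis records, consistent with the forest."""

    events: List[Event] = field(default_factory=list)

    def add(self, kind: str, t: int, cell_id: int, parent: Optional[int] = None) -> None:
        self.events.append(Event(kind, t, cell_id, parent))

    def of_kind(self, kind: str) -> List[Event]:
        return [e for e in self.events if e.kind == kind]

    @property
    def n_divisions(self) -> int:
        return len(self.of_kind("division"))

    def divisions_by_time(self) -> Dict[int, int]:
        out: Dict[int, int] = {}
        for e in self.of_kind("division"):
            out[e.t] = out.get(e.t, 0) + 1
        return dict(sorted(out.items()))

    def parent_map(self) -> Dict[int, Optional[int]]:
        return {e.cell_id: e.parent_cell_id for e in self.of_kind("birth")}

    def divisions_on_path(self, cell_id: int) -> int:
        """Number of divisions separating a cell from its founding ancestor."""
        parents = self.parent_map()
        n, cid = 0, cell_id
        while parents.get(cid) is not None:
            n += 1
            cid = parents[cid]
        return n

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.events, columns=["kind", "t", "cell_id", "parent_cell_id"])


# ----------------------------------------------------------------------
# Imaging-model stages (individually callable)


def depth_attenuate(volume: np.ndarray, grid: VoxelGrid, attenuation_length: float) -> np.ndarray:
    """Scale each z slice by ``exp(-z/ℓ)``; ``ℓ = inf`` is the identity."""
    if np.any(np.asarray(volume) < 0):
        raise ValueError("intensities must be nonnegative")
    if not math.isfinite(attenuation_length):
        return np.asarray(volume, dtype=np.float32).copy()
    z = grid.axis_coords(0)
    factors = np.exp(-z / attenuation_length).astype(np.float32)
    return np.asarray(volume, dtype=np.float32) * factors[:, None, None]


def bleach_factors(
    n_exposures: int,
    rate: float,
    recovery_exposures: Sequence[int] = (),
    recovery_amplitudes: Sequence[float] = (),
) -> np.ndarray:
    """Multiplicative fluorescence trajectory over cumulative exposures.

    ``b(e) = exp(-rate·e) · Π_{e_r ≤ e} (1 + A_r)``: exponential
    photobleaching with a step recovery (heat-shock re-expression) at
    each listed exposure.
    """
    e = np.arange(n_exposures, dtype=float)
    b = np.exp(-rate * e)
    for er, amp in zip(recovery_exposures, recovery_amplitudes):
        b[e >= er] *= 1.0 + amp
    return b


def add_noise(
    volume: np.ndarray,
    rng: np.random.Generator,
    poisson_gain: float = 20.0,
    read_noise_sd: float = 100.0,
) -> np.ndarray:
    """Poisson shot noise (variance ``gain × signal``) plus Gaussian read noise."""
    clean = np.asarray(volume, dtype=np.float64)
    if np.any(clean < 0):
        raise ValueError("intensities must be nonnegative")
    noisy = rng.poisson(clean / poisson_gain).astype(np.float64) * poisson_gain
    noisy += rng.normal(0.0, read_noise_sd, size=clean.shape)
    return noisy


# ----------------------------------------------------------------------
# Scene generation


@dataclass
class _Cell:
    id: int
    pos: np.ndarray
    radius: float
    base_intensity: float
    spot_id: int = 0
    parent_spot: Optional[int] = None
    pyknotic: bool = False
    born_t: int = 0


def _place_initial_cells(cfg: SimulationConfig, rng: np.random.Generator) -> List[_Cell]:
    lo = np.full(3, cfg.placement_margin)
    hi = np.asarray(cfg.grid.extent) - cfg.placement_margin
    if np.any(hi <= lo):
        raise GenerationError("placement region is empty")
    cells: List[_Cell] = []
    positions: List[np.ndarray] = []
    attempts = 0
    while len(cells) < cfg.n_initial_cells:
        attempts += 1
        if attempts > 2000 * cfg.n_initial_cells:
            raise GenerationError(
                f"could not place {cfg.n_initial_cells} cells at separation "
                f"{cfg.min_separation} µm"
            )
        p = rng.uniform(lo, hi)
        if positions and np.min(np.linalg.norm(np.asarray(positions) - p, axis=1)) < cfg.min_separation:
            continue
        positions.append(p)
        cells.append(
            _Cell(
                id=len(cells) + 1,
                pos=p,
                radius=float(np.clip(rng.normal(cfg.radius_mean, cfg.radius_sd), 0.5, None)),
                base_intensity=float(
                    np.clip(rng.normal(cfg.base_intensity_mean, cfg.base_intensity_sd), 100.0, None)
                ),
            )
        )
    return cells


def _relax_positions(cells: List[_Cell], cfg: SimulationConfig, n_iter: int = 3) -> None:
    """Short-range repulsion: push overlapping neighbours to min_separation.

    Epithelial nuclei pack rather than interpenetrate; without this the
    wound-directed drift would pile cells into an unrealistically dense
    slab at the wound plane.
    """
    if len(cells) < 2:
        return
    lo = np.full(3, 0.5)
    hi = np.asarray(cfg.grid.extent) - 0.5
    for _ in range(n_iter):
        pos = np.array([c.pos for c in cells])
        tree = cKDTree(pos)
        pairs = sorted(tree.query_pairs(cfg.min_separation))
        if not pairs:
            break
        shift = np.zeros_like(pos)
        for i, j in pairs:
            d = pos[j] - pos[i]
            dist = float(np.linalg.norm(d))
            if dist < 1e-9:
                d, dist = np.array([0.0, 0.0, 1e-3]), 1e-3
            push = 0.5 * (cfg.min_separation - dist) * d / dist
            shift[i] -= push
            shift[j] += push
        pos = np.clip(pos + shift, lo, hi)
        for c, p in zip(cells, pos):
            c.pos = p


def _move(cell: _Cell, cfg: SimulationConfig, rng: np.random.Generator, t: int) -> np.ndarray:
    step = rng.normal(0.0, cfg.motility_sd, size=3)
    delta = cell.pos[cfg.wound_axis] - cfg.wound_plane
    if t < cfg.migration_end and abs(delta) > 2.0:
        step[cfg.wound_axis] -= math.copysign(cfg.drift, delta)
    if cfg.oscillation_amplitude > 0:
        phase = 2 * math.pi * (t * cfg.grid.time_interval) / cfg.oscillation_period
        step[cfg.wound_axis] += cfg.oscillation_amplitude * math.sin(phase)
    pos = cell.pos + step
    return np.clip(pos, 0.5, np.asarray(cfg.grid.extent) - 0.5)


def simulate_recording(
    config: SimulationConfig, return_clean: bool = False
) -> Tuple[Movie, LineageForest, EventLog]:
    """Generate a synthetic recording with its ground-truth lineage forest.

    Returns ``(movie, forest, events)``; with ``return_clean=True`` a
    fourth element carries the noiseless scene (``t, z, y, x`` float32,
    after attenuation and bleaching, before replicate noise) so that
    fresh noise realisations can be drawn with :func:`add_imaging_noise`.

    Each replicate of the movie is an independent noise realisation of
    the same noiseless scene.  Deterministic given ``config.seed``.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    cells = _place_initial_cells(cfg, rng)
    forest = LineageForest()
    events = EventLog()
    for c in cells:
        events.add("birth", 0, c.id, None)
    next_cell_id = len(cells) + 1
    next_spot_id = 1
    clean = np.zeros((cfg.n_timepoints,) + tuple(cfg.grid.shape), dtype=np.float32)
    bleach = bleach_factors(
        cfg.n_timepoints * cfg.n_replicates,
        cfg.bleach_rate,
        [t * cfg.n_replicates for t in cfg.recovery_times],
        cfg.recovery_amplitudes,
    )

    for t in range(cfg.n_timepoints):
        # emit this frame's spots (linking each to its parent's spot at t-1)
        # and render the noiseless frame
        for c in cells:
            amp = c.base_intensity * bleach[t * cfg.n_replicates]
            amp *= math.exp(-c.pos[0] / cfg.attenuation_length)
            if c.pyknotic:
                amp *= cfg.pyknotic_factor
            spot = forest.add_spot(
                Spot(
                    next_spot_id,
                    t,
                    tuple(c.pos),
                    radius=c.radius,
                    intensity=amp,
                    label="pyknotic" if c.pyknotic else None,
                )
            )
            if c.parent_spot is not None:
                forest.add_link(c.parent_spot, spot.id)
            c.spot_id = spot.id
            next_spot_id += 1
            _render_gaussian(clean[t], c.pos, c.radius, amp, cfg)
        if t == cfg.n_timepoints - 1:
            break
        # transition to t + 1
        new_cells: List[_Cell] = []
        for c in cells:
            if c.pyknotic:
                continue  # pyknotic nuclei break up after one frame
            if rng.random() < cfg.apoptosis_prob:
                events.add("apoptosis", t + 1, c.id, None)
                new_cells.append(
                    _Cell(
                        c.id,
                        _move(c, cfg, rng, t),
                        c.radius,
                        c.base_intensity,
                        parent_spot=c.spot_id,
                        pyknotic=True,
                    )
                )
                continue
            # newborn cells sit out a refractory period before dividing again
            if (
                t - c.born_t >= cfg.division_refractory
                and rng.random() < cfg.division_profile[t]
            ):
                axis = rng.normal(size=3)
                axis /= np.linalg.norm(axis)
                base = _move(c, cfg, rng, t)
                events.add("division", t, c.id, None)
                for sign in (+1.0, -1.0):
                    pos = np.clip(
                        base + sign * c.radius * axis, 0.5, np.asarray(cfg.grid.extent) - 0.5
                    )
                    events.add("birth", t + 1, next_cell_id, c.id)
                    new_cells.append(
                        _Cell(
                            next_cell_id,
                            pos,
                            c.radius,
                            c.base_intensity,
                            parent_spot=c.spot_id,
                            born_t=t + 1,
                        )
                    )
                    next_cell_id += 1
            else:
                new_cells.append(
                    _Cell(
                        c.id,
                        _move(c, cfg, rng, t),
                        c.radius,
                        c.base_intensity,
                        parent_spot=c.spot_id,
                    )
                )
        _relax_positions(new_cells, cfg)
        cells = new_cells

    movie_data = add_imaging_noise(clean, cfg, seed=int(rng.integers(2**31)))
    movie = Movie(movie_data, cfg.grid)
    forest.validate()
    if return_clean:
        return movie, forest, events, clean
    return movie, forest, events


def _render_gaussian(
    frame: np.ndarray, pos: np.ndarray, radius: float, amplitude: float, cfg: SimulationConfig
) -> None:
    """Add one nucleus to a frame: Gaussian with nucleus+PSF widths in quadrature."""
    sigma_nuc = radius / math.sqrt(2.0)
    sigmas = np.sqrt(np.square(cfg.psf_sigma) + sigma_nuc**2)
    vs = np.asarray(cfg.grid.voxel_size)
    lo = np.maximum(0, np.floor((pos - 4 * sigmas) / vs).astype(int))
    hi = np.minimum(cfg.grid.shape, np.ceil((pos + 4 * sigmas) / vs).astype(int) + 1)
    if np.any(hi <= lo):
        return
    axes = [
        (np.arange(l, h) * v - p) / s
        for l, h, v, p, s in zip(lo, hi, vs, pos, sigmas)
    ]
    gz = np.exp(-0.5 * axes[0] ** 2)[:, None, None]
    gy = np.exp(-0.5 * axes[1] ** 2)[None, :, None]
    gx = np.exp(-0.5 * axes[2] ** 2)[None, None, :]
    frame[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] += amplitude * gz * gy * gx


def add_imaging_noise(
    clean: np.ndarray, config: SimulationConfig, seed: int
) -> np.ndarray:
    """Draw per-replicate Poisson + Gaussian noise on a noiseless scene.

    Returns a uint16 array of shape ``(t, n_replicates) + grid.shape``.
    """
    rng = np.random.default_rng(seed)
    n_t = clean.shape[0]
    out = np.zeros((n_t, config.n_replicates) + clean.shape[1:], dtype=np.uint16)
    for t in range(n_t):
        base = clean[t] + config.background
        for r in range(config.n_replicates):
            noisy = add_noise(base, rng, config.poisson_gain, config.read_noise_sd)
            out[t, r] = np.clip(np.floor(noisy + 0.5), 0, 65535).astype(np.uint16)
    return out


# ----------------------------------------------------------------------
# Ground-truth auxiliaries (stand-ins for learned detector/flow outputs)


def render_probability_map(forest: LineageForest, grid: VoxelGrid, t: int) -> np.ndarray:
    """Idealised detection-probability map for the spots at time ``t``.

    Value 1 at each nucleus centre, decaying as a Gaussian of the
    nucleus radius; overlapping nuclei combine by maximum so values stay
    in ``[0, 1]``; background is exactly 0.
    """
    out = np.zeros(grid.shape, dtype=np.float32)
    vs = np.asarray(grid.voxel_size)
    for s in forest.spots_at(t):
        pos = np.asarray(s.pos)
        sigma = s.radius
        lo = np.maximum(0, np.floor((pos - 4 * sigma) / vs).astype(int))
        hi = np.minimum(grid.shape, np.ceil((pos + 4 * sigma) / vs).astype(int) + 1)
        if np.any(hi <= lo):
            continue
        axes = [
            (np.arange(l, h) * v - p) / sigma
            for l, h, v, p in zip(lo, hi, vs, pos)
        ]
        g = (
            np.exp(-0.5 * axes[0] ** 2)[:, None, None]
            * np.exp(-0.5 * axes[1] ** 2)[None, :, None]
            * np.exp(-0.5 * axes[2] ** 2)[None, None, :]
        )
        win = out[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
        np.maximum(win, g.astype(np.float32), out=win)
    return out


def ground_truth_flow(
    forest: LineageForest,
    grid: VoxelGrid,
    t: int,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Displacement field (µm) from ``t-1`` to ``t`` from the true lineage.

    Every voxel carries the displacement of the nearest tracked cell at
    time ``t`` (zero for cells without a parent), plus optional
    isotropic Gaussian noise.  Shape ``(3,) + grid.shape``.
    """
    if t < 1:
        raise ValueError("flow is defined for t >= 1")
    spots = forest.spots_at(t)
    field = np.zeros((3,) + tuple(grid.shape), dtype=np.float32)
    if spots:
        disps = []
        for s in spots:
            p = forest.parent_of(s.id)
            if p is None:
                disps.append((0.0, 0.0, 0.0))
            else:
                disps.append(tuple(np.subtract(s.pos, forest.spots[p].pos)))
        tree = cKDTree([s.pos for s in spots])
        coords = np.meshgrid(*[grid.axis_coords(a) for a in range(3)], indexing="ij")
        pts = np.stack([c.ravel() for c in coords], axis=-1)
        _, nearest = tree.query(pts)
        disps = np.asarray(disps, dtype=np.float32)
        field = disps[nearest].T.reshape((3,) + tuple(grid.shape))
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        field = field + rng.normal(0.0, noise_sd, size=field.shape).astype(np.float32)
    return field


def ground_truth_flow_field(
    forest: LineageForest, grid: VoxelGrid, noise_sd: float = 0.0, seed: int = 0
) -> FlowField:
    """Bundle :func:`ground_truth_flow` for every time step into a FlowField."""
    flow = FlowField(grid)
    times = forest.times()
    for t in times:
        if t == 0 or t - 1 not in times:
            continue
        flow.set_field(t, ground_truth_flow(forest, grid, t, noise_sd, seed + t))
    return flow
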