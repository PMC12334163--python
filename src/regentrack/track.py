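"""Nearest-neighbour linking, backtracking, and block-matching flow estimation.

Linking follows the convention of point-based tracking platforms: each
cell at time ``t+1`` is assigned to the closest available cell at ``t``
within a physical gate, with at most two daughters per parent so that
divisions can be followed.  A flow field (per-voxel displacement from
``t-1`` to ``t``) sharpens the assignment by predicting where a cell
came from: ``pos(t-1) ≈ pos(t) - flow_t(pos(t))``.

Backtracking traces a single selected cell backward in time, linking to
the nearest detection around the flow-predicted position and, where no
detection is found, interpolating a spot at the prediction — up to a
budget of consecutive interpolations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
from scipy.spatial import cKDTree

from .core import ForestError, LineageForest, Link, Spot, VoxelGrid

__all__ = [
    "FlowField",
    "LinkingParams",
    "BacktrackParams",
    "BacktrackResult",
    "link_forward",
    "backtrack",
    "estimate_flow_block_matching",
]


class FlowField:
    """Per-voxel displacement fields, one per time step.

    ``field(t)`` holds the motion (µm, ``(dz, dy, dx)`` per voxel) from
    time ``t-1`` to ``t``; backward prediction therefore subtracts the
    field sampled at the current position.
    """

    def __init__(self, grid: VoxelGrid):
        self.grid = grid
        self._fields: Dict[int, np.ndarray] = {}

    def set_field(self, t: int, field: np.ndarray) -> None:
        field = np.asarray(field, dtype=np.float32)
        if field.shape != (3,) + tuple(self.grid.shape):
            raise ValueError(
                f"flow field at t={t} has shape {field.shape}, "
                f"expected {(3,) + tuple(self.grid.shape)}"
            )
        if not np.all(np.isfinite(field)):
            raise ValueError(f"flow field at t={t} contains non-finite values")
        self._fields[t] = field

    def field(self, t: int) -> np.ndarray:
        return self._fields[t]

    @property
    def times(self) -> List[int]:
        return sorted(self._fields)

    def __contains__(self, t: int) -> bool:
        return t in self._fields

    def sample(self, t: int, pos: Sequence[float]) -> np.ndarray:
        """Displacement (µm) at the voxel nearest to a physical position."""
        if t not in self._fields:
            raise KeyError(f"no flow field stored for t={t}")
        i, j, k = self.grid.to_index(pos, clip=True)
        return self._fields[t][:, i, j, k].astype(float)


@dataclass(frozen=True)
class LinkingParams:
    """Gate and branching limits for nearest-neighbour linking.

    ``d_max`` is the maximum distance (µm) between a cell and its
    predicted origin; ``max_children`` caps the number of daughters a
    parent may accept (2 allows dividing cells to be followed).
    """

    d_max: float = 5.0
    max_children: int = 2

    def __post_init__(self) -> None:
        if self.d_max <= 0:
            raise ValueError("d_max must be > 0")
        if self.max_children < 1:
            raise ValueError("max_children must be >= 1")


@dataclass(frozen=True)
class BacktrackParams:
    """Backtracking controls.

    ``vicinity_radius`` (µm) is the linking gate around the predicted
    position; ``max_interpolation`` bounds *consecutive* interpolated
    time points; ``window_halfsize`` (µm) is the half-size of the local
    volume searched for detections when raw volumes are supplied.
    """

    vicinity_radius: float = 5.0
    max_interpolation: int = 3
    window_halfsize: float = 10.0

    def __post_init__(self) -> None:
        if self.vicinity_radius <= 0 or self.window_halfsize <= 0:
            raise ValueError("radii must be > 0")
        if self.max_interpolation < 0:
            raise ValueError("max_interpolation must be >= 0")


def _as_spots_by_time(spots: Union[Mapping[int, Sequence[Spot]], Sequence[Spot]]) -> Dict[int, List[Spot]]:
    if isinstance(spots, Mapping):
        out = {int(t): list(v) for t, v in spots.items()}
    else:
        out = {}
        for s in spots:
            out.setdefault(s.t, []).append(s)
    return dict(sorted(out.items()))


def link_forward(
    spots_by_time: Union[Mapping[int, Sequence[Spot]], Sequence[Spot]],
    flow: Optional[FlowField] = None,
    params: LinkingParams = LinkingParams(),
) -> LineageForest:
    """Link detections across consecutive frames into a lineage forest.

    For every spot ``s`` at time ``t+1`` the predicted origin is
    ``pos(s) - flow_{t+1}(pos(s))`` (or ``pos(s)`` without flow); spots
    at ``t`` within ``d_max`` of that origin are candidate parents.
    Candidate pairs are assigned greedily in ascending distance order
    (ties broken by child then parent id); a child takes one parent, a
    parent at most ``max_children`` children.  Unmatched spots start new
    tracks.
    """
    by_time = _as_spots_by_time(spots_by_time)
    times = list(by_time)
    if times and times != list(range(times[0], times[-1] + 1)):
        raise ForestError(f"spot time indices are not consecutive: {times}")
    forest = LineageForest()
    for t in times:
        for s in by_time[t]:
            forest.add_spot(s)
    for t_prev, t_next in zip(times[:-1], times[1:]):
        parents = by_time[t_prev]
        children = by_time[t_next]
        if not parents or not children:
            continue
        tree = cKDTree([p.pos for p in parents])
        candidates: List[Tuple[float, int, int]] = []
        for c in children:
            pred = np.asarray(c.pos, dtype=float)
            if flow is not None and t_next in flow:
                pred = pred - flow.sample(t_next, c.pos)
            for j in tree.query_ball_point(pred, params.d_max):
                d = float(np.linalg.norm(pred - parents[j].pos))
                candidates.append((d, c.id, parents[j].id))
        candidates.sort(key=lambda x: (x[0], x[1], x[2]))
        n_kids: Dict[int, int] = {}
        taken: set = set()
        for d, cid, pid in candidates:
            if cid in taken or n_kids.get(pid, 0) >= params.max_children:
                continue
            forest.add_link(pid, cid)
            taken.add(cid)
            n_kids[pid] = n_kids.get(pid, 0) + 1
    forest.validate()
    return forest


@dataclass
class BacktrackResult:
    """Backward trace of one cell: spots ordered from seed to earliest time.

    ``links`` point forward in time (earlier spot -> later spot);
    ``truncated`` is set when the consecutive-interpolation budget ran
    out before reaching ``t = 0``.
    """

    spots: List[Spot]
    links: List[Link]
    truncated: bool

    @property
    def n_interpolated(self) -> int:
        return sum(1 for s in self.spots if s.interpolated)

    @property
    def reached_t0(self) -> bool:
        return not self.truncated and self.spots[-1].t == 0


def backtrack(
    seed_spot: Spot,
    detections: Union[Mapping[int, Sequence[Spot]], Sequence[Spot], None] = None,
    flow: FlowField = None,
    params: BacktrackParams = BacktrackParams(),
    volumes: Optional[Sequence[np.ndarray]] = None,
    grid: Optional[VoxelGrid] = None,
    detector=None,
) -> BacktrackResult:
    """Trace a selected cell backward in time from ``seed_spot``.

    At each step the previous position is predicted by subtracting the
    flow sampled at the current position.  Detections near the
    prediction come either from ``detections`` (pre-computed spots per
    time point) or, if ``volumes`` is given, by running the centre
    detector on a local window of the previous frame.  A detection
    within ``vicinity_radius`` of the prediction is linked (closest
    first) and resets the interpolation counter; otherwise a spot
    flagged ``interpolated`` is created at the prediction.  Tracing
    stops at ``t = 0`` or, with ``truncated`` status, once the
    consecutive-interpolation budget is exhausted.
    """
    if flow is None:
        raise ValueError("backtrack requires a flow field")
    if detections is None and volumes is None:
        raise ValueError("provide either detections or volumes")
    by_time = _as_spots_by_time(detections) if detections is not None else {}

    path = [seed_spot]
    links: List[Link] = []
    next_id = 1 + max(
        [seed_spot.id] + [s.id for spots in by_time.values() for s in spots]
    )
    n_consecutive = 0
    truncated = False
    current = seed_spot
    while current.t >= 1:
        t = current.t
        pred = np.asarray(current.pos, dtype=float) - flow.sample(t, current.pos)
        cands = _local_detections(
            t - 1, pred, by_time, volumes, grid, detector, params
        )
        best, best_d = None, np.inf
        for s in cands:
            d = float(np.linalg.norm(pred - np.asarray(s.pos)))
            if d < best_d - 1e-12 or (abs(d - best_d) <= 1e-12 and (best is None or s.id < best.id)):
                best, best_d = s, d
        if best is not None and best_d <= params.vicinity_radius:
            n_consecutive = 0
            prev = best
        else:
            n_consecutive += 1
            if n_consecutive > params.max_interpolation:
                truncated = True
                break
            prev = Spot(
                next_id,
                t - 1,
                tuple(pred),
                radius=current.radius,
                intensity=0.0,
                interpolated=True,
            )
            next_id += 1
        links.append(Link(prev.id, current.id))
        path.append(prev)
        current = prev
    return BacktrackResult(spots=path, links=links, truncated=truncated)


def _local_detections(
    t: int,
    center: np.ndarray,
    by_time: Dict[int, List[Spot]],
    volumes,
    grid,
    detector,
    params: BacktrackParams,
) -> List[Spot]:
    if volumes is None:
        w = max(params.window_halfsize, params.vicinity_radius)
        return [
            s
            for s in by_time.get(t, ())
            if all(abs(a - b) <= w for a, b in zip(s.pos, center))
        ]
    # run the centre detector on a window of the previous frame
    from .detect import DetectionParams, blob_response, extract_centers

    if grid is None:
        raise ValueError("grid is required with volumes")
    det = detector if detector is not None else DetectionParams()
    vol = np.asarray(volumes[t])
    lo = [
        max(0, int(np.floor((c - params.window_halfsize) / v)))
        for c, v in zip(center, grid.voxel_size)
    ]
    hi = [
        min(n, int(np.ceil((c + params.window_halfsize) / v)) + 1)
        for c, v, n in zip(center, grid.voxel_size, grid.shape)
    ]
    window = vol[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
    if window.size == 0:
        return []
    wgrid = VoxelGrid(window.shape, grid.voxel_size, grid.time_interval)
    resp = blob_response(window, wgrid, (det.r_min, det.r_max))
    offset = np.array([l * v for l, v in zip(lo, grid.voxel_size)])
    spots = []
    for s in extract_centers(resp, wgrid, det):
        spots.append(
            Spot(s.id, t, tuple(np.asarray(s.pos) + offset), s.radius, s.intensity)
        )
    return spots


def estimate_flow_block_matching(
    frame_t: np.ndarray,
    frame_t_minus_1: np.ndarray,
    grid: VoxelGrid,
    block_halfsize: float = 5.0,
    search_radius: float = 5.0,
) -> np.ndarray:
    """Estimate a dense displacement field (µm) by block matching.

    The frame at ``t`` is tiled into blocks of physical half-size
    ``block_halfsize`` (µm); each block is located in the previous frame
    by maximising normalised cross-correlation over integer-voxel shifts
    within ``search_radius`` (µm).  Per-block displacements are linearly
    interpolated to every voxel.  Blocks with zero variance yield zero
    displacement.  Returns an array of shape ``(3,) + grid.shape``.
    """
    from skimage.feature import match_template

    a = np.asarray(frame_t, dtype=np.float64)
    b = np.asarray(frame_t_minus_1, dtype=np.float64)
    if a.shape != b.shape or a.shape != tuple(grid.shape):
        raise ValueError("frames must share the grid's shape")
    half = [max(1, int(round(block_halfsize / v))) for v in grid.voxel_size]
    srch = [max(1, int(round(search_radius / v))) for v in grid.voxel_size]
    centers = [
        np.arange(h, n, 2 * h) if n > 2 * h else np.array([n // 2])
        for h, n in zip(half, a.shape)
    ]
    disp = np.zeros((3,) + tuple(len(c) for c in centers), dtype=np.float64)
    for iz, cz in enumerate(centers[0]):
        for iy, cy in enumerate(centers[1]):
            for ix, cx in enumerate(centers[2]):
                c = (cz, cy, cx)
                lo = [max(0, ci - h) for ci, h in zip(c, half)]
                hi = [min(n, ci + h + 1) for ci, h, n in zip(c, half, a.shape)]
                tmpl = a[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
                if tmpl.size == 0 or tmpl.std() == 0:
                    continue
                rlo = [max(0, l - s) for l, s in zip(lo, srch)]
                rhi = [min(n, h + s) for h, s, n in zip(hi, srch, a.shape)]
                region = b[rlo[0] : rhi[0], rlo[1] : rhi[1], rlo[2] : rhi[2]]
                if any(rs < ts for rs, ts in zip(region.shape, tmpl.shape)) or region.std() == 0:
                    continue
                cc = match_template(region, tmpl)
                p = np.unravel_index(int(np.argmax(cc)), cc.shape)
                # template top-left in region coords when displacement is zero
                p0 = [l - rl for l, rl in zip(lo, rlo)]
                d_index = [pp0 - pp for pp0, pp in zip(p0, p)]
                disp[:, iz, iy, ix] = [di * v for di, v in zip(d_index, grid.voxel_size)]
    return _interpolate_blocks(disp, centers, grid)


def _interpolate_blocks(disp: np.ndarray, centers, grid: VoxelGrid) -> np.ndarray:
    from scipy.interpolate import RegularGridInterpolator

    out = np.zeros((3,) + tuple(grid.shape), dtype=np.float32)
    coords = np.meshgrid(*[np.arange(n) for n in grid.shape], indexing="ij")
    pts = np.stack([c.ravel() for c in coords], axis=-1).astype(float)
    for axis in range(3):
        vals = disp[axis]
        if all(len(c) > 1 for c in centers):
            itp = RegularGridInterpolator(
                [c.astype(float) for c in centers],
                vals,
                method="linear",
                bounds_error=False,
                fill_value=None,
            )
            out[axis] = itp(pts).reshape(grid.shape)
        else:
            # too few blocks along some axis: nearest-block assignment
            idx = [
                np.abs(np.subtract.outer(np.arange(n), c)).argmin(axis=1)
                for n, c in zip(grid.shape, centers)
            ]
            out[axis] = vals[np.ix_(idx[0], idx[1], idx[2])]
    return out
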