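"""Lineage-forest data model and shared containers.

A *spot* is a point-plus-radius annotation of one nucleus at one time
point; a *link* connects a parent spot at time ``t`` to a child spot at
``t + 1``.  The set of all tracks forms a *lineage forest*: an acyclic
graph in which every spot has at most one parent and at most two
children (a cell divides into at most two daughters).  Tracks are the
rooted trees of this forest, so the number of tracks always equals
``n_spots - n_links``.

Physical coordinates are microns throughout, with ``z`` measured from
the first (coverslip-proximal) slice.  Voxel index ``i`` maps to the
physical position ``i * voxel_size`` (centre-of-voxel convention,
0-based), so all distance thresholds are physical.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, Iterator, List, NamedTuple, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "Spot",
    "Link",
    "LineageForest",
    "VoxelGrid",
    "Movie",
    "ForestError",
    "count_trees",
    "reduce_time",
    "divisions_per_timepoint",
]


class ForestError(ValueError):
    """A structural violation of the lineage-forest invariants."""


@dataclass
class Spot:
    """One nucleus annotation at one time point.

    Parameters
    ----------
    id : int
        Positive identifier, unique within a forest.
    t : int
        Non-negative time index.
    pos : tuple of float
        ``(z, y, x)`` position in µm.
    radius : float
        Nucleus radius in µm, strictly positive.
    intensity : float
        Arbitrary-unit intensity (e.g. detector response), ``>= 0``.
    label : str, optional
        Categorical tag such as a marker-positive call.
    interpolated : bool
        True for spots created by flow interpolation rather than
        detection.
    """

    id: int
    t: int
    pos: Tuple[float, float, float]
    radius: float = 2.0
    intensity: float = 0.0
    label: Optional[str] = None
    interpolated: bool = False

    def __post_init__(self) -> None:
        if self.id <= 0:
            raise ForestError(f"spot id must be positive, got {self.id}")
        if self.t < 0:
            raise ForestError(f"spot {self.id}: time index {self.t} < 0")
        if self.radius <= 0:
            raise ForestError(f"spot {self.id}: radius {self.radius} <= 0")
        self.pos = tuple(float(c) for c in self.pos)
        if len(self.pos) != 3 or not all(math.isfinite(c) for c in self.pos):
            raise ForestError(f"spot {self.id}: non-finite position {self.pos}")
        if self.intensity < 0:
            raise ForestError(f"spot {self.id}: intensity {self.intensity} < 0")

    @property
    def z(self) -> float:
        return self.pos[0]

    def distance_to(self, other: "Spot") -> float:
        return float(np.linalg.norm(np.subtract(self.pos, other.pos)))


class Link(NamedTuple):
    """Directed parent -> child connection between consecutive time points."""

    source_id: int
    target_id: int


class LineageForest:
    """Acyclic forest of spots and parent->child links.

    Invariants (checked on mutation and by :meth:`validate`): every link
    endpoint exists, links advance time by exactly one step, each spot
    has at most one parent and at most two children, and there are no
    self-links.  Acyclicity follows from the unit time step.
    """

    def __init__(self, spots: Iterable[Spot] = (), links: Iterable[Link] = ()):
        self._spots: Dict[int, Spot] = {}
        self._parent: Dict[int, int] = {}
        self._children: Dict[int, List[int]] = {}
        for s in spots:
            self.add_spot(s)
        for ln in links:
            self.add_link(*ln)

    # -- construction -------------------------------------------------

    def add_spot(self, spot: Spot) -> Spot:
        if spot.id in self._spots:
            raise ForestError(f"duplicate spot id {spot.id}")
        self._spots[spot.id] = spot
        return spot

    def add_link(self, source_id: int, target_id: int) -> Link:
        if source_id == target_id:
            raise ForestError(f"self-link on spot {source_id}")
        for sid in (source_id, target_id):
            if sid not in self._spots:
                raise ForestError(f"link references unknown spot id {sid}")
        src, tgt = self._spots[source_id], self._spots[target_id]
        if tgt.t != src.t + 1:
            raise ForestError(
                f"link {source_id}->{target_id}: target time {tgt.t} "
                f"!= source time {src.t} + 1"
            )
        if target_id in self._parent:
            raise ForestError(f"spot {target_id} already has a parent")
        kids = self._children.setdefault(source_id, [])
        if len(kids) >= 2:
            raise ForestError(f"spot {source_id} already has 2 children")
        kids.append(target_id)
        self._parent[target_id] = source_id
        return Link(source_id, target_id)

    # -- access -------------------------------------------------------

    @property
    def spots(self) -> Dict[int, Spot]:
        return self._spots

    @property
    def links(self) -> List[Link]:
        return [
            Link(p, c) for p, kids in sorted(self._children.items()) for c in sorted(kids)
        ]

    @property
    def n_spots(self) -> int:
        return len(self._spots)

    @property
    def n_links(self) -> int:
        return len(self._parent)

    def __contains__(self, spot_id: int) -> bool:
        return spot_id in self._spots

    def __iter__(self) -> Iterator[Spot]:
        return iter(self._spots.values())

    def parent_of(self, spot_id: int) -> Optional[int]:
        return self._parent.get(spot_id)

    def children_of(self, spot_id: int) -> List[int]:
        return list(self._children.get(spot_id, ()))

    def roots(self) -> List[int]:
        return sorted(sid for sid in self._spots if sid not in self._parent)

    def leaves(self) -> List[int]:
        return sorted(sid for sid in self._spots if not self._children.get(sid))

    def root_of(self, spot_id: int) -> int:
        """Walk parent links up to the root of the spot's tree."""
        sid = spot_id
        if sid not in self._spots:
            raise ForestError(f"unknown spot id {sid}")
        while sid in self._parent:
            sid = self._parent[sid]
        return sid

    def path_to_root(self, spot_id: int) -> List[int]:
        """Spot ids from ``spot_id`` up to and including its root."""
        path = [spot_id]
        while path[-1] in self._parent:
            path.append(self._parent[path[-1]])
        return path

    def descendants(self, spot_id: int) -> List[int]:
        out, stack = [], [spot_id]
        while stack:
            sid = stack.pop()
            for c in self._children.get(sid, ()):
                out.append(c)
                stack.append(c)
        return out

    def times(self) -> List[int]:
        return sorted({s.t for s in self._spots.values()})

    def spots_at(self, t: int) -> List[Spot]:
        return sorted((s for s in self._spots.values() if s.t == t), key=lambda s: s.id)

    def by_time(self) -> Dict[int, List[Spot]]:
        out: Dict[int, List[Spot]] = {}
        for s in sorted(self._spots.values(), key=lambda s: s.id):
            out.setdefault(s.t, []).append(s)
        return dict(sorted(out.items()))

    def validate(self) -> None:
        """Re-check every forest invariant; raise :class:`ForestError` on failure."""
        for p, kids in self._children.items():
            if len(kids) > 2:
                raise ForestError(f"spot {p} has {len(kids)} children")
            for c in kids:
                if self._spots[c].t != self._spots[p].t + 1:
                    raise ForestError(f"link {p}->{c} does not advance time by 1")
        if self.n_links != self.n_spots - len(self.roots()):
            raise ForestError("link/spot/root arithmetic violated")

    def copy(self) -> "LineageForest":
        out = LineageForest()
        for s in self._spots.values():
            out.add_spot(replace(s))
        for ln in self.links:
            out.add_link(*ln)
        return out

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LineageForest):
            return NotImplemented
        mine = {sid: (s.t, s.pos, s.radius, s.label, s.interpolated) for sid, s in self._spots.items()}
        theirs = {sid: (s.t, s.pos, s.radius, s.label, s.interpolated) for sid, s in other._spots.items()}
        return mine == theirs and set(self.links) == set(other.links)


# ----------------------------------------------------------------------
# Forest operations


def count_trees(forest: LineageForest) -> int:
    """Number of rooted lineage trees (tracks) in the forest.

    Equals ``n_spots - n_links`` for any valid forest: every non-root
    spot consumes exactly one link.
    """
    forest.validate()
    return len(forest.roots())


def divisions_per_timepoint(forest: LineageForest) -> Dict[int, int]:
    """Count cell divisions (spots with exactly two children) per time index."""
    counts: Dict[int, int] = {t: 0 for t in forest.times()}
    for sid in forest.spots:
        if len(forest.children_of(sid)) == 2:
            counts[forest.spots[sid].t] += 1
    return counts


def reduce_time(forest: LineageForest, keep_every: int, offset: int = 0) -> LineageForest:
    """Decimate the time axis, keeping every ``keep_every``-th time point.

    Spots at kept time points (``t ≡ offset mod keep_every``) are retained
    with time re-indexed to consecutive integers; each retained spot is
    linked to its nearest retained descendants reachable through removed
    time points, so a division falling on a removed time point yields two
    links from the retained ancestor.  Retained spots whose ancestors are
    all removed become new roots.

    With ``keep_every > 2`` two successive divisions can fall inside one
    removed gap, producing more than two nearest retained descendants;
    the two earliest (ties broken by physical distance, then id) keep
    their links and the rest start new trees, preserving the two-children
    invariant.
    """
    if keep_every < 2:
        raise ValueError("keep_every must be >= 2")
    if not 0 <= offset < keep_every:
        raise ValueError("offset must satisfy 0 <= offset < keep_every")
    out = LineageForest()
    kept = {sid for sid, s in forest.spots.items() if (s.t - offset) % keep_every == 0 and s.t >= offset}
    for sid in sorted(kept):
        s = forest.spots[sid]
        out.add_spot(replace(s, t=(s.t - offset) // keep_every))
    for sid in sorted(kept):
        # nearest retained descendant on each downward branch
        targets: List[int] = []
        stack = list(forest.children_of(sid))
        while stack:
            c = stack.pop()
            if c in kept:
                targets.append(c)
            else:
                stack.extend(forest.children_of(c))
        if len(targets) > 2:
            src = forest.spots[sid]
            targets.sort(key=lambda c: (forest.spots[c].t, src.distance_to(forest.spots[c]), c))
            targets = targets[:2]
        # a chain passes through every time point, so the nearest retained
        # descendant always sits exactly one kept row below the ancestor
        for c in sorted(targets):
            out.add_link(sid, c)
    out.validate()
    return out


# ----------------------------------------------------------------------
# Image containers


@dataclass(frozen=True)
class VoxelGrid:
    """Calibrated voxel lattice for one image volume.

    ``shape`` is ``(n_z, n_y, n_x)``; ``voxel_size`` the physical edge
    lengths ``(dz, dy, dx)`` in µm; ``time_interval`` the frame spacing
    in minutes.  Index ``(i, j, k)`` sits at physical position
    ``(i*dz, j*dy, k*dx)``.
    """

    shape: Tuple[int, int, int]
    voxel_size: Tuple[float, float, float] = (1.24, 0.31, 0.31)
    time_interval: float = 10.0

    def __post_init__(self) -> None:
        if any(n <= 0 for n in self.shape):
            raise ValueError(f"non-positive grid shape {self.shape}")
        if any(v <= 0 for v in self.voxel_size) or self.time_interval <= 0:
            raise ValueError("voxel sizes and time interval must be > 0")

    @property
    def extent(self) -> Tuple[float, float, float]:
        """Physical size (µm) spanned by the voxel centres per axis."""
        return tuple((n - 1) * v for n, v in zip(self.shape, self.voxel_size))

    def to_index(self, pos: Sequence[float], clip: bool = True) -> Tuple[int, int, int]:
        """Nearest voxel index for a physical position (µm)."""
        idx = [int(round(p / v)) for p, v in zip(pos, self.voxel_size)]
        if clip:
            idx = [min(max(i, 0), n - 1) for i, n in zip(idx, self.shape)]
        return tuple(idx)

    def to_physical(self, index: Sequence[float]) -> Tuple[float, float, float]:
        return tuple(i * v for i, v in zip(index, self.voxel_size))

    def axis_coords(self, axis: int) -> np.ndarray:
        """Physical coordinates of voxel centres along one axis."""
        return np.arange(self.shape[axis]) * self.voxel_size[axis]


@dataclass
class Movie:
    """5D intensity recording: ``data[t, replicate, z, y, x]`` plus calibration.

    Replicates are repeated exposures of the same z-slice (same scene,
    independent noise); the simulator emits four by default, matching a
    four-fold frame-averaging acquisition.
    """

    data: np.ndarray
    grid: VoxelGrid

    def __post_init__(self) -> None:
        if self.data.ndim != 5:
            raise ValueError(f"movie data must be 5D (t, rep, z, y, x), got {self.data.ndim}D")
        if tuple(self.data.shape[2:]) != tuple(self.grid.shape):
            raise ValueError(
                f"data spatial shape {self.data.shape[2:]} != grid shape {self.grid.shape}"
            )

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_replicates(self) -> int:
        return self.data.shape[1]

    def frame(self, t: int, replicate: int = 0) -> np.ndarray:
        return self.data[t, replicate]

    def averaged(self, t: int, n: Optional[int] = None) -> np.ndarray:
        """Mean of the first ``n`` replicates at time ``t`` (float)."""
        n = self.n_replicates if n is None else n
        return self.data[t, :n].mean(axis=0)
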