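"""Mapping post-fixation stained nuclei onto the last live frame.

After live imaging, a specimen is fixed and stained (e.g. in situ
marker); the stained nuclei form a point cloud that must be registered
onto the nuclei of the final live frame before marker labels can be
transferred to tracked spots and lineage questions asked (which
progenitors produced the labelled cells, and through how many
divisions).  Registration is iterative-closest-point with a rigid or
affine model — slight mounting and fixation distortion is absorbed by
the affine mode and an acceptance-radius gate rather than non-rigid
warping.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .core import ForestError, LineageForest, Spot

__all__ = [
    "LabelledCloud",
    "RegistrationResult",
    "register_clouds",
    "transfer_labels",
    "progenitor_analysis",
]


@dataclass
class LabelledCloud:
    """Point cloud of nuclei with categorical labels.

    ``points`` is (n, 3) in µm (z, y, x); ``labels`` one tag per point;
    ``source`` records whether the cloud comes from fixed or live data.
    """

    points: np.ndarray
    labels: List[Optional[str]] = field(default_factory=list)
    source: str = "fixed"

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3 or len(self.points) == 0:
            raise ValueError("points must be a non-empty (n, 3) array")
        if not np.all(np.isfinite(self.points)):
            raise ValueError("points must be finite")
        if not self.labels:
            self.labels = [None] * len(self.points)
        if len(self.labels) != len(self.points):
            raise ValueError("one label per point required")

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class RegistrationResult:
    """Affine map ``x -> A @ x + b`` from fixed to live coordinates."""

    matrix: np.ndarray
    translation: np.ndarray
    residuals: np.ndarray
    converged: bool
    n_iter: int

    @property
    def mean_residual(self) -> float:
        return float(self.residuals.mean())

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=float) @ self.matrix.T + self.translation


def _fit_rigid(src: np.ndarray, dst: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Least-squares rotation + translation (Kabsch via SVD)."""
    sc, dc = src.mean(axis=0), dst.mean(axis=0)
    h = (src - sc).T @ (dst - dc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    r = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return r, dc - r @ sc


def _fit_affine(src: np.ndarray, dst: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    n = len(src)
    x = np.hstack([src, np.ones((n, 1))])
    sol, *_ = np.linalg.lstsq(x, dst, rcond=None)
    return sol[:3].T, sol[3]


def _principal_axes(points: np.ndarray) -> np.ndarray:
    c = points - points.mean(axis=0)
    _, _, vt = np.linalg.svd(c, full_matrices=False)
    return vt


def register_clouds(
    fixed: LabelledCloud,
    live: LabelledCloud,
    mode: str = "rigid",
    max_iter: int = 50,
    tol: float = 1e-8,
    trim_fraction: float = 0.0,
) -> RegistrationResult:
    """Register the fixed cloud onto the live cloud (ICP).

    Alternates nearest-neighbour correspondence with a least-squares
    rigid or affine fit, starting from centroid alignment combined with
    a principal-axes rotation (all four proper-rotation sign choices are
    tried; the best final residual wins, deterministically).  With
    ``trim_fraction > 0`` the worst correspondences are dropped from
    each fit, making the alignment robust to outlier points.
    Non-convergence within ``max_iter`` is flagged, not raised.
    """
    if mode not in ("rigid", "affine"):
        raise ValueError("mode must be 'rigid' or 'affine'")
    min_pts = 4 if mode == "affine" else 3
    if len(fixed) < min_pts or len(live) < min_pts:
        raise ValueError(f"{mode} registration needs at least {min_pts} points per cloud")

    src0 = fixed.points
    dst = live.points
    tree = cKDTree(dst)
    axes_f, axes_l = _principal_axes(src0), _principal_axes(dst)
    inits = [np.eye(3)]  # centroid-only start: robust when rotations are small
    for sz in (1.0, -1.0):
        for sy in (1.0, -1.0):
            signs = np.diag([sz, sy, sz * sy])  # keep det = +1
            inits.append(axes_l.T @ signs @ axes_f)
    best: Optional[RegistrationResult] = None
    for r0 in inits:
        t0 = dst.mean(axis=0) - r0 @ src0.mean(axis=0)
        res = _icp(src0, dst, tree, r0, t0, mode, max_iter, tol, trim_fraction)
        if best is None or res.mean_residual < best.mean_residual:
            best = res
    return best


def _icp(
    src0: np.ndarray,
    dst: np.ndarray,
    tree: cKDTree,
    a: np.ndarray,
    b: np.ndarray,
    mode: str,
    max_iter: int,
    tol: float,
    trim_fraction: float,
) -> RegistrationResult:
    fit = _fit_rigid if mode == "rigid" else _fit_affine
    prev = np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        moved = src0 @ a.T + b
        d, j = tree.query(moved)
        keep = np.arange(len(src0))
        if trim_fraction > 0:
            n_keep = max(3, int(np.ceil((1 - trim_fraction) * len(src0))))
            keep = np.argsort(d, kind="stable")[:n_keep]
        a, b = fit(src0[keep], dst[j[keep]])
        mean_res = float(np.mean(d[keep]))
        if abs(prev - mean_res) < tol:
            converged = True
            break
        prev = mean_res
    moved = src0 @ a.T + b
    d, _ = tree.query(moved)
    keep = np.arange(len(src0))
    if trim_fraction > 0:
        keep = np.argsort(d, kind="stable")[: max(3, int(np.ceil((1 - trim_fraction) * len(src0))))]
    return RegistrationResult(
        matrix=a, translation=b, residuals=d[keep], converged=converged, n_iter=it
    )


def transfer_labels(
    transform: RegistrationResult,
    fixed: LabelledCloud,
    live_spots: Sequence[Spot],
    accept_radius: float = 5.0,
) -> Tuple[List[Spot], List[int]]:
    """Carry labels from fixed points to the nearest live spots.

    Transformed fixed points are matched to live spots one-to-one in
    ascending-distance order within ``accept_radius``; the closer of two
    competing fixed points wins its spot and the other falls through to
    its next-nearest free spot.  Returns relabelled copies of the
    matched spots and the indices of unmatched fixed points.
    """
    moved = transform.apply(fixed.points)
    spot_pos = np.array([s.pos for s in live_spots])
    dist = np.linalg.norm(moved[:, None, :] - spot_pos[None, :, :], axis=2)
    cand = [
        (dist[i, j], i, j)
        for i in range(len(moved))
        for j in range(len(live_spots))
        if dist[i, j] <= accept_radius
    ]
    cand.sort()
    taken_fixed, taken_spot = set(), set()
    labelled: List[Spot] = []
    for d, i, j in cand:
        if i in taken_fixed or j in taken_spot:
            continue
        taken_fixed.add(i)
        taken_spot.add(j)
        s = live_spots[j]
        labelled.append(Spot(s.id, s.t, s.pos, s.radius, s.intensity, fixed.labels[i], s.interpolated))
    unmatched = [i for i in range(len(moved)) if i not in taken_fixed]
    return labelled, unmatched


def progenitor_analysis(
    forest: LineageForest, labelled_spots: Sequence[Spot]
) -> pd.DataFrame:
    """Trace labelled terminal cells back to their progenitors.

    Each labelled spot (at the final time point of its track) is walked
    up its parent chain to the root; labelled cells sharing a root form
    one clone.  Per clone the report gives the root (progenitor)
    position and time, the division counts along each labelled path and
    their maximum, and the split of the clone's terminal cells into
    labelled and unlabelled.
    """
    for s in labelled_spots:
        if s.id not in forest.spots:
            raise ForestError(f"labelled spot {s.id} is not in the forest")
    by_root: Dict[int, List[Spot]] = {}
    for s in labelled_spots:
        by_root.setdefault(forest.root_of(s.id), []).append(s)
    labelled_ids = {s.id for s in labelled_spots}
    records = []
    for root in sorted(by_root):
        members = by_root[root]
        per_path = []
        for s in members:
            path = forest.path_to_root(s.id)
            per_path.append(
                sum(1 for sid in path if len(forest.children_of(sid)) == 2 and sid != s.id)
            )
        subtree = [root] + forest.descendants(root)
        terminals = [sid for sid in subtree if not forest.children_of(sid)]
        n_lab = sum(1 for sid in terminals if sid in labelled_ids)
        rs = forest.spots[root]
        records.append(
            {
                "root_id": root,
                "root_t": rs.t,
                "root_z": rs.pos[0],
                "root_y": rs.pos[1],
                "root_x": rs.pos[2],
                "n_labelled_terminals": n_lab,
                "n_unlabelled_terminals": len(terminals) - n_lab,
                "divisions_per_path": per_path,
                "max_divisions": max(per_path),
            }
        )
    return pd.DataFrame(records)
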