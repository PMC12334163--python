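"""Equal-exposure acquisition conditions derived from one master recording.

A master acquisition (full z and t sampling, full lateral resolution,
four imaging replicates per slice) is subsampled into five reduced
conditions that all correspond to exactly the same total light exposure
(one quarter of the master): each condition trades z sampling, frame
rate, lateral sampling, or frame averaging against the others.
Subsampling an already-acquired recording is a proxy for acquiring at
the reduced settings — the photon budget per kept voxel is identical by
construction.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from fractions import Fraction
from typing import List, Optional, Tuple

import numpy as np

from .core import LineageForest, Movie, VoxelGrid, reduce_time

__all__ = [
    "AcquisitionCondition",
    "standard_conditions",
    "relative_exposure",
    "subsample",
    "reduce_ground_truth",
]

_HALF = Fraction(1, 2)
_ONE = Fraction(1)


@dataclass(frozen=True)
class AcquisitionCondition:
    """One subsampling recipe: kept fractions per axis plus replicates averaged.

    ``z_keep``, ``t_keep`` and ``xy_keep`` (per lateral axis) are 1 or
    1/2; ``n_average`` replicates (of ``master_replicates`` acquired)
    are averaged into the output frame.
    """

    name: str
    z_keep: Fraction = _ONE
    t_keep: Fraction = _ONE
    xy_keep: Fraction = _ONE
    n_average: int = 4
    master_replicates: int = 4

    def __post_init__(self) -> None:
        for f in (self.z_keep, self.t_keep, self.xy_keep):
            if f not in (_ONE, _HALF):
                raise ValueError(f"kept fractions must be 1 or 1/2, got {f}")
        if not 1 <= self.n_average <= self.master_replicates:
            raise ValueError("n_average must be in [1, master_replicates]")


def standard_conditions(master_replicates: int = 4) -> List[AcquisitionCondition]:
    """The five standard equal-exposure conditions (#1–#5).

    #1 halves z and t sampling (the typical acquisition); #2 keeps full
    z at half averaging; #3 keeps full t at half averaging; #4 halves
    lateral sampling on both axes; #5 keeps everything but averages a
    single replicate.
    """
    m = master_replicates
    return [
        AcquisitionCondition("#1 Standard", z_keep=_HALF, t_keep=_HALF, n_average=4, master_replicates=m),
        AcquisitionCondition("#2 Improved Z", t_keep=_HALF, n_average=2, master_replicates=m),
        AcquisitionCondition("#3 Improved T", z_keep=_HALF, n_average=2, master_replicates=m),
        AcquisitionCondition("#4 Reduced XY", xy_keep=_HALF, n_average=4, master_replicates=m),
        AcquisitionCondition("#5 Single image", n_average=1, master_replicates=m),
    ]


def relative_exposure(cond: AcquisitionCondition) -> Fraction:
    """Light exposure of the condition as a fraction of the master's.

    ``z_keep × t_keep × xy_keep² × n_average / master_replicates`` —
    exposure is proportional to illuminated voxels times replicates
    actually used.
    """
    return (
        cond.z_keep
        * cond.t_keep
        * cond.xy_keep**2
        * Fraction(cond.n_average, cond.master_replicates)
    )


def subsample(movie: Movie, cond: AcquisitionCondition) -> Movie:
    """Apply an acquisition condition to a master movie.

    Decimation keeps even indices (0, 2, 4, …) on each halved axis;
    replicate averaging takes the arithmetic mean of the *first*
    ``n_average`` replicates, rounded half-up to integers (replicates
    accumulate sequentially during a scan, so the first n correspond to
    an n-replicate acquisition).  Calibration is updated: voxel sizes
    double on decimated axes, the time interval doubles under t
    decimation.  The output movie has a single (averaged) replicate.
    """
    if movie.n_replicates != cond.master_replicates:
        raise ValueError(
            f"movie has {movie.n_replicates} replicates, condition expects "
            f"{cond.master_replicates}"
        )
    data = movie.data
    if cond.t_keep == _HALF:
        data = data[::2]
    data = data[:, : cond.n_average].astype(np.float64).mean(axis=1)
    data = np.floor(data + 0.5)
    if np.issubdtype(movie.data.dtype, np.integer):
        data = data.astype(movie.data.dtype)
    if cond.z_keep == _HALF:
        data = data[:, ::2]
    if cond.xy_keep == _HALF:
        data = data[:, :, ::2, ::2]
    dz, dy, dx = movie.grid.voxel_size
    grid = VoxelGrid(
        shape=data.shape[1:],
        voxel_size=(
            dz * (2 if cond.z_keep == _HALF else 1),
            dy * (2 if cond.xy_keep == _HALF else 1),
            dx * (2 if cond.xy_keep == _HALF else 1),
        ),
        time_interval=movie.grid.time_interval * (2 if cond.t_keep == _HALF else 1),
    )
    return Movie(data[:, None], grid)


def reduce_ground_truth(
    forest: LineageForest, cond: AcquisitionCondition
) -> LineageForest:
    """Ground truth matching a subsampled movie.

    Only the time axis affects annotations: spatial decimation does not
    move physical positions, so spot coordinates (µm) are unchanged.
    """
    if cond.t_keep == _HALF:
        return reduce_time(forest, keep_every=2, offset=0)
    return forest.copy()
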