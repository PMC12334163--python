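"""File formats: spots/links CSV, CTC-style track text, calibrated TIFF stacks.

CSV dialect is comma-separated UTF-8 with a header row and '.' decimals.
TIFF stacks are written one 16-bit file per time point and replicate,
named ``t{TTT}_r{R}.tif``, with per-axis calibration stored as ImageJ
metadata plus a JSON sidecar for the time interval.
"""

from __future__ import annotations

import json
import re
from pathlib import Path
from typing import Dict, List, Optional, Tuple, Union

import numpy as np
import pandas as pd
import tifffile

from .core import ForestError, LineageForest, Link, Movie, Spot, VoxelGrid

__all__ = [
    "spots_to_dataframe",
    "forest_from_dataframes",
    "write_spots_csv",
    "write_links_csv",
    "read_forest_csv",
    "write_forest_csv",
    "write_ctc_tracks",
    "read_ctc_tracks",
    "write_movie_tiffs",
    "read_movie_tiffs",
]

SPOT_COLUMNS = ["id", "t", "z", "y", "x", "radius", "intensity", "label", "interpolated"]
LINK_COLUMNS = ["source_id", "target_id"]


class ParseError(ForestError):
    """Malformed spots/links table; the message names the offending record."""


def spots_to_dataframe(forest: LineageForest) -> pd.DataFrame:
    rows = [
        {
            "id": s.id,
            "t": s.t,
            "z": s.pos[0],
            "y": s.pos[1],
            "x": s.pos[2],
            "radius": s.radius,
            "intensity": s.intensity,
            "label": s.label if s.label is not None else "",
            "interpolated": int(s.interpolated),
        }
        for s in sorted(forest, key=lambda s: (s.t, s.id))
    ]
    return pd.DataFrame(rows, columns=SPOT_COLUMNS)


def links_to_dataframe(forest: LineageForest) -> pd.DataFrame:
    return pd.DataFrame(forest.links, columns=LINK_COLUMNS)


def forest_from_dataframes(spots: pd.DataFrame, links: pd.DataFrame) -> LineageForest:
    """Assemble and validate a forest from spots/links tables."""
    missing = [c for c in SPOT_COLUMNS[:6] if c not in spots.columns]
    if missing:
        raise ParseError(f"spots table missing columns {missing}")
    missing = [c for c in LINK_COLUMNS if c not in links.columns]
    if missing:
        raise ParseError(f"links table missing columns {missing}")
    forest = LineageForest()
    for rec in spots.to_dict("records"):
        label = rec.get("label")
        if label is None or (isinstance(label, float) and np.isnan(label)) or label == "":
            label = None
        try:
            forest.add_spot(
                Spot(
                    id=int(rec["id"]),
                    t=int(rec["t"]),
                    pos=(float(rec["z"]), float(rec["y"]), float(rec["x"])),
                    radius=float(rec["radius"]),
                    intensity=float(rec.get("intensity", 0.0) or 0.0),
                    label=str(label) if label is not None else None,
                    interpolated=bool(int(rec.get("interpolated", 0) or 0)),
                )
            )
        except (ForestError, ValueError, TypeError) as exc:
            raise ParseError(f"bad spot record {rec!r}: {exc}") from exc
    for rec in links.to_dict("records"):
        sid, tid = int(rec["source_id"]), int(rec["target_id"])
        if sid not in forest or tid not in forest:
            raise ParseError(f"link ({sid}, {tid}) references unknown spot id")
        try:
            forest.add_link(sid, tid)
        except ForestError as exc:
            raise ParseError(f"bad link ({sid}, {tid}): {exc}") from exc
    forest.validate()
    return forest


def write_spots_csv(forest: LineageForest, path: Union[str, Path]) -> None:
    # %.17g guarantees float64 round-trip through text
    spots_to_dataframe(forest).to_csv(path, index=False, float_format="%.17g")


def write_links_csv(forest: LineageForest, path: Union[str, Path]) -> None:
    links_to_dataframe(forest).to_csv(path, index=False)


def write_forest_csv(
    forest: LineageForest, spots_path: Union[str, Path], links_path: Union[str, Path]
) -> None:
    write_spots_csv(forest, spots_path)
    write_links_csv(forest, links_path)


def read_forest_csv(
    spots_path: Union[str, Path], links_path: Union[str, Path]
) -> LineageForest:
    spots = pd.read_csv(spots_path, keep_default_na=False, float_precision="round_trip")
    links = pd.read_csv(links_path)
    return forest_from_dataframes(spots, links)


# ----------------------------------------------------------------------
# CTC-style track text: one line "L B E P" per unbranched tracklet


def _tracklets(forest: LineageForest) -> List[List[int]]:
    """Decompose into maximal unbranched spot chains (tracklets).

    A tracklet starts at a root or at a daughter of a division and runs
    until the next division or a leaf.
    """
    starts = list(forest.roots())
    for sid in sorted(forest.spots):
        if len(forest.children_of(sid)) == 2:
            starts.extend(sorted(forest.children_of(sid)))
    tracklets = []
    for start in sorted(starts, key=lambda sid: (forest.spots[sid].t, sid)):
        chain = [start]
        while True:
            kids = forest.children_of(chain[-1])
            if len(kids) != 1:
                break
            chain.append(kids[0])
        tracklets.append(chain)
    return tracklets


def write_ctc_tracks(forest: LineageForest, path: Union[str, Path]) -> None:
    """Export as Cell-Tracking-Challenge track text (``L B E P`` rows)."""
    tracklets = _tracklets(forest)
    label_of: Dict[int, int] = {}
    for lab, chain in enumerate(tracklets, start=1):
        for sid in chain:
            label_of[sid] = lab
    lines = []
    for lab, chain in enumerate(tracklets, start=1):
        b, e = forest.spots[chain[0]].t, forest.spots[chain[-1]].t
        parent_spot = forest.parent_of(chain[0])
        p = label_of[parent_spot] if parent_spot is not None else 0
        lines.append(f"{lab} {b} {e} {p}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_ctc_tracks(path: Union[str, Path]) -> LineageForest:
    """Rebuild forest *topology* from CTC track text.

    Positions are not stored in the format; spots are placed at the
    origin with unit radius, so only the graph structure round-trips.
    """
    forest = LineageForest()
    rows = []
    for lineno, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) != 4:
            raise ParseError(f"line {lineno}: expected 'L B E P', got {line!r}")
        rows.append(tuple(int(p) for p in parts))
    next_id = 1
    ends: Dict[int, int] = {}  # tracklet label -> last spot id
    starts: Dict[int, int] = {}
    for lab, b, e, _ in rows:
        prev = None
        for t in range(b, e + 1):
            sp = forest.add_spot(Spot(next_id, t, (0.0, 0.0, 0.0), radius=1.0))
            if prev is not None:
                forest.add_link(prev, sp.id)
            else:
                starts[lab] = sp.id
            prev = sp.id
            next_id += 1
        ends[lab] = prev
    for lab, b, e, p in rows:
        if p:
            if p not in ends:
                raise ParseError(f"tracklet {lab}: unknown parent label {p}")
            forest.add_link(ends[p], starts[lab])
    forest.validate()
    return forest


# ----------------------------------------------------------------------
# TIFF stacks

_TIFF_RE = re.compile(r"^t(\d+)_r(\d+)\.tif$")


def write_movie_tiffs(movie: Movie, out_dir: Union[str, Path]) -> None:
    """Write one 16-bit TIFF per time point and replicate plus calibration JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    dz, dy, dx = movie.grid.voxel_size
    data = movie.data
    if data.dtype != np.uint16:
        data = np.clip(np.floor(data + 0.5), 0, 65535).astype(np.uint16)
    for t in range(movie.n_timepoints):
        for r in range(movie.n_replicates):
            tifffile.imwrite(
                out / f"t{t:03d}_r{r}.tif",
                data[t, r],
                imagej=True,
                resolution=(1.0 / dx, 1.0 / dy),
                metadata={"spacing": dz, "unit": "um", "axes": "ZYX"},
            )
    (out / "calibration.json").write_text(
        json.dumps(
            {
                "voxel_size_um": [dz, dy, dx],
                "time_interval_min": movie.grid.time_interval,
                "shape_zyx": list(movie.grid.shape),
            },
            indent=2,
        )
    )


def read_movie_tiffs(in_dir: Union[str, Path]) -> Movie:
    in_dir = Path(in_dir)
    files: Dict[Tuple[int, int], Path] = {}
    for f in in_dir.iterdir():
        m = _TIFF_RE.match(f.name)
        if m:
            files[(int(m.group(1)), int(m.group(2)))] = f
    if not files:
        raise FileNotFoundError(f"no t*_r*.tif files in {in_dir}")
    n_t = max(t for t, _ in files) + 1
    n_r = max(r for _, r in files) + 1
    first = tifffile.imread(files[(0, 0)])
    data = np.zeros((n_t, n_r) + first.shape, dtype=first.dtype)
    for (t, r), f in files.items():
        data[t, r] = tifffile.imread(f)
    calib = json.loads((in_dir / "calibration.json").read_text())
    grid = VoxelGrid(
        shape=tuple(calib["shape_zyx"]),
        voxel_size=tuple(calib["voxel_size_um"]),
        time_interval=calib["time_interval_min"],
    )
    return Movie(data=data, grid=grid)
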