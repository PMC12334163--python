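"""Scoring predicted lineage forests against ground truth.

Vertices (spots) are matched per time point: a predicted spot is a
candidate for a ground-truth spot when it lies inside that spot's
radius, and candidates are resolved one-to-one by minimum-total-distance
assignment.  On top of the matching, the acyclic-oriented-graph matching
(AOGM) cost counts the weighted edit operations needed to turn the
prediction into the reference — vertex splits (NS), missing vertices
(FN), spurious vertices (FP), spurious edges (ED), missing edges (EA)
and edges with wrong division semantics (EC).  DET and TRA normalise
the vertex-only and full cost by the cost of building the reference
from nothing, and the raw cost doubles as a proofreading-effort
estimate: it grows with recording length at fixed per-frame quality.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .acquire import AcquisitionCondition, reduce_ground_truth, relative_exposure, standard_conditions, subsample
from .core import LineageForest, Movie, Spot
from .detect import DetectionParams, detect_volume
from .track import FlowField, LinkingParams, estimate_flow_block_matching, link_forward

__all__ = [
    "AOGMWeights",
    "SpotMatching",
    "EvaluationReport",
    "match_spots",
    "detection_scores",
    "aogm",
    "det_score",
    "tra_score",
    "linking_scores",
    "tra_on_gt",
    "proofreading_effort",
    "depth_stratified_scores",
    "evaluate_forests",
    "run_tradeoff_experiment",
    "TradeoffResult",
]

_BIG = 1e9


@dataclass(frozen=True)
class AOGMWeights:
    """Edit-operation costs (Cell-Tracking-Challenge defaults)."""

    w_NS: float = 5.0
    w_FN: float = 10.0
    w_FP: float = 1.0
    w_ED: float = 1.0
    w_EA: float = 1.5
    w_EC: float = 1.0

    def __post_init__(self) -> None:
        if any(w < 0 for w in (self.w_NS, self.w_FN, self.w_FP, self.w_ED, self.w_EA, self.w_EC)):
            raise ValueError("AOGM weights must be nonnegative")


@dataclass
class SpotMatching:
    """One-to-one vertex matching plus NS/FN/FP bookkeeping.

    ``pairs`` maps ground-truth spot id -> predicted spot id.  ``ns_ids``
    are unmatched ground-truth spots covered by an already-matched
    prediction (a vertex split would fix them); ``fn_ids`` the remaining
    unmatched ground truth; ``fp_ids`` unmatched predictions.
    """

    pairs: Dict[int, int] = field(default_factory=dict)
    ns_ids: List[int] = field(default_factory=list)
    fn_ids: List[int] = field(default_factory=list)
    fp_ids: List[int] = field(default_factory=list)

    @property
    def tp(self) -> int:
        return len(self.pairs)

    @property
    def ns(self) -> int:
        return len(self.ns_ids)

    @property
    def fn(self) -> int:
        return len(self.fn_ids)

    @property
    def fp(self) -> int:
        return len(self.fp_ids)


def match_spots(gt: LineageForest, pred: LineageForest) -> SpotMatching:
    """Match predicted to ground-truth spots, per time point.

    Candidate pairs are (g, p) with ``|pos(p) - pos(g)| <= radius(g)``;
    within each time point candidates are resolved by minimum-total-
    distance one-to-one assignment (maximum cardinality first).
    """
    out = SpotMatching()
    times = sorted(set(s.t for s in gt) | set(s.t for s in pred))
    for t in times:
        g_spots = gt.spots_at(t)
        p_spots = pred.spots_at(t)
        if not g_spots:
            out.fp_ids.extend(s.id for s in p_spots)
            continue
        if not p_spots:
            out.fn_ids.extend(s.id for s in g_spots)
            continue
        gpos = np.array([s.pos for s in g_spots])
        ppos = np.array([s.pos for s in p_spots])
        dist = np.linalg.norm(gpos[:, None, :] - ppos[None, :, :], axis=2)
        radii = np.array([s.radius for s in g_spots])
        allowed = dist <= radii[:, None]
        cost = np.where(allowed, dist, _BIG)
        rows, cols = linear_sum_assignment(cost)
        matched_g, matched_p = set(), set()
        for i, j in zip(rows, cols):
            if allowed[i, j]:
                out.pairs[g_spots[i].id] = p_spots[j].id
                matched_g.add(i)
                matched_p.add(j)
        for i, g in enumerate(g_spots):
            if i in matched_g:
                continue
            covered = any(allowed[i, j] for j in matched_p)
            (out.ns_ids if covered else out.fn_ids).append(g.id)
        out.fp_ids.extend(p_spots[j].id for j in range(len(p_spots)) if j not in matched_p)
    return out


def detection_scores(matching: SpotMatching) -> Tuple[float, float]:
    """Detection ``precision = TP/(TP+FP)`` and ``recall = TP/(TP+FN)``.

    Ground-truth spots needing a vertex split (NS) are still unrecalled
    detections and count in the recall denominator.  Empty-vs-empty
    (0/0) is defined as 1.
    """
    tp, fp, fn = matching.tp, matching.fp, matching.fn + matching.ns
    precision = 1.0 if tp + fp == 0 else tp / (tp + fp)
    recall = 1.0 if tp + fn == 0 else tp / (tp + fn)
    return precision, recall


def _is_division_link(forest: LineageForest, source_id: int) -> bool:
    return len(forest.children_of(source_id)) == 2


def aogm(
    gt: LineageForest,
    pred: LineageForest,
    weights: AOGMWeights = AOGMWeights(),
    matching: Optional[SpotMatching] = None,
) -> Tuple[Dict[str, int], float]:
    """AOGM decomposition counts and raw weighted cost.

    Vertex operations come from the matching; edge operations compare
    links through the matched-vertex map: a predicted link is redundant
    (ED) unless both endpoints are matched and their images form a
    ground-truth link; a ground-truth link with no predicted counterpart
    must be added (EA); a corresponding link whose division semantics
    differ (its source divides in one forest but not the other) needs a
    semantic change (EC).
    """
    m = matching if matching is not None else match_spots(gt, pred)
    inv = {p: g for g, p in m.pairs.items()}
    gt_links = set(gt.links)
    pred_links = set(pred.links)
    ed = ec = 0
    for (u, v) in pred_links:
        gu, gv = inv.get(u), inv.get(v)
        if gu is None or gv is None or (gu, gv) not in gt_links:
            ed += 1
        elif _is_division_link(gt, gu) != _is_division_link(pred, u):
            ec += 1
    ea = 0
    for (a, b) in gt_links:
        pa, pb = m.pairs.get(a), m.pairs.get(b)
        if pa is None or pb is None or (pa, pb) not in pred_links:
            ea += 1
    counts = {"NS": m.ns, "FN": m.fn, "FP": m.fp, "ED": ed, "EA": ea, "EC": ec}
    cost = (
        weights.w_NS * counts["NS"]
        + weights.w_FN * counts["FN"]
        + weights.w_FP * counts["FP"]
        + weights.w_ED * counts["ED"]
        + weights.w_EA * counts["EA"]
        + weights.w_EC * counts["EC"]
    )
    return counts, float(cost)


def det_score(
    gt: LineageForest,
    pred: LineageForest,
    weights: AOGMWeights = AOGMWeights(),
    matching: Optional[SpotMatching] = None,
) -> float:
    """Detection accuracy: 1 − (vertex-only cost)/(cost of an empty prediction)."""
    if gt.n_spots == 0:
        raise ValueError("DET is undefined for empty ground truth")
    counts, _ = aogm(gt, pred, weights, matching)
    cost = weights.w_NS * counts["NS"] + weights.w_FN * counts["FN"] + weights.w_FP * counts["FP"]
    denom = weights.w_FN * gt.n_spots
    return 1.0 - min(cost, denom) / denom


def tra_score(
    gt: LineageForest,
    pred: LineageForest,
    weights: AOGMWeights = AOGMWeights(),
    matching: Optional[SpotMatching] = None,
) -> float:
    """Tracking accuracy: 1 − min(AOGM, AOGM₀)/AOGM₀.

    ``AOGM₀ = w_FN·|V_gt| + w_EA·|E_gt|`` is the cost of building the
    reference from an empty prediction.
    """
    if gt.n_spots == 0:
        raise ValueError("TRA is undefined for empty ground truth")
    _, cost = aogm(gt, pred, weights, matching)
    denom = weights.w_FN * gt.n_spots + weights.w_EA * gt.n_links
    return 1.0 - min(cost, denom) / denom


def linking_scores(
    gt: LineageForest, pred: LineageForest, matching: Optional[SpotMatching] = None
) -> Tuple[float, float]:
    """Precision/recall over links.

    A predicted link is a true positive iff both endpoints are matched
    and their images form a ground-truth link.
    """
    m = matching if matching is not None else match_spots(gt, pred)
    inv = {p: g for g, p in m.pairs.items()}
    gt_links = set(gt.links)
    tp = sum(
        1
        for (u, v) in pred.links
        if u in inv and v in inv and (inv[u], inv[v]) in gt_links
    )
    n_pred, n_gt = pred.n_links, gt.n_links
    precision = 1.0 if n_pred == 0 else tp / n_pred
    recall = 1.0 if n_gt == 0 else tp / n_gt
    return precision, recall


def tra_on_gt(
    gt: LineageForest,
    flow: Optional[FlowField] = None,
    params: LinkingParams = LinkingParams(),
) -> Tuple[LineageForest, Tuple[float, float]]:
    """Re-link the ground-truth spots and score the links.

    Running the linker on perfect detections isolates linking
    performance from detection performance.  Returns the re-linked
    forest and its linking (precision, recall) against the ground truth.
    """
    spots = [
        Spot(s.id, s.t, s.pos, s.radius, s.intensity, s.label, s.interpolated)
        for s in gt
    ]
    relinked = link_forward(spots, flow, params)
    return relinked, linking_scores(gt, relinked)


def proofreading_effort(
    gt: LineageForest,
    pred: LineageForest,
    weights: AOGMWeights = AOGMWeights(),
    matching: Optional[SpotMatching] = None,
) -> float:
    """Un-normalised AOGM cost: a proxy for the manual correction workload.

    Additive over disjoint unions, so it grows with the number of time
    points even at fixed per-frame quality.
    """
    _, cost = aogm(gt, pred, weights, matching)
    return cost


def depth_stratified_scores(
    gt: LineageForest,
    pred: LineageForest,
    bin_width: float = 5.0,
    matching: Optional[SpotMatching] = None,
) -> pd.DataFrame:
    """Detection precision/recall per depth bin ([0,5), [5,10), … µm).

    Matched and missed ground-truth spots are binned by their true z;
    false positives by predicted z.  Bins without ground-truth spots are
    omitted.
    """
    m = matching if matching is not None else match_spots(gt, pred)
    rows: Dict[int, Dict[str, int]] = {}

    def bucket(z: float) -> Dict[str, int]:
        b = int(np.floor(z / bin_width))
        return rows.setdefault(b, {"n_gt": 0, "tp": 0, "fp": 0, "fn": 0, "ns": 0})

    for gid, pid in m.pairs.items():
        r = bucket(gt.spots[gid].pos[0])
        r["n_gt"] += 1
        r["tp"] += 1
    for gid in m.fn_ids:
        r = bucket(gt.spots[gid].pos[0])
        r["n_gt"] += 1
        r["fn"] += 1
    for gid in m.ns_ids:
        r = bucket(gt.spots[gid].pos[0])
        r["n_gt"] += 1
        r["ns"] += 1
    for pid in m.fp_ids:
        bucket(pred.spots[pid].pos[0])["fp"] += 1
    records = []
    for b in sorted(rows):
        r = rows[b]
        if r["n_gt"] == 0:
            continue
        tp, fp, fn = r["tp"], r["fp"], r["fn"] + r["ns"]
        records.append(
            {
                "z_lo": b * bin_width,
                "z_hi": (b + 1) * bin_width,
                "n_gt": r["n_gt"],
                "tp": tp,
                "fp": fp,
                "fn": fn,
                "precision": 1.0 if tp + fp == 0 else tp / (tp + fp),
                "recall": 1.0 if tp + fn == 0 else tp / (tp + fn),
            }
        )
    return pd.DataFrame(
        records, columns=["z_lo", "z_hi", "n_gt", "tp", "fp", "fn", "precision", "recall"]
    )


@dataclass
class EvaluationReport:
    """All scores for one predicted forest against one reference."""

    det: float
    tra: float
    detection_precision: float
    detection_recall: float
    linking_precision: float
    linking_recall: float
    aogm_counts: Dict[str, int]
    aogm_cost: float
    effort: float
    depth_table: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        for name in ("det", "tra", "detection_precision", "detection_recall", "linking_precision", "linking_recall"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0 + 1e-12:
                raise ValueError(f"{name} = {v} outside [0, 1]")
        if self.effort < 0:
            raise ValueError("effort must be >= 0")

    def to_dict(self) -> Dict[str, float]:
        d = {
            "DET": self.det,
            "TRA": self.tra,
            "detection_precision": self.detection_precision,
            "detection_recall": self.detection_recall,
            "linking_precision": self.linking_precision,
            "linking_recall": self.linking_recall,
            "effort": self.effort,
            "aogm_cost": self.aogm_cost,
        }
        d.update(self.aogm_counts)
        return d


def evaluate_forests(
    gt: LineageForest,
    pred: LineageForest,
    weights: AOGMWeights = AOGMWeights(),
    depth_bin: Optional[float] = None,
) -> EvaluationReport:
    """Score a predicted forest on every metric at once."""
    m = match_spots(gt, pred)
    counts, cost = aogm(gt, pred, weights, m)
    dp, dr = detection_scores(m)
    lp, lr = linking_scores(gt, pred, m)
    return EvaluationReport(
        det=det_score(gt, pred, weights, m),
        tra=tra_score(gt, pred, weights, m),
        detection_precision=dp,
        detection_recall=dr,
        linking_precision=lp,
        linking_recall=lr,
        aogm_counts=counts,
        aogm_cost=cost,
        effort=cost,
        depth_table=depth_stratified_scores(gt, pred, depth_bin, m) if depth_bin else None,
    )


# ----------------------------------------------------------------------
# The acquisition trade-off experiment


@dataclass
class TradeoffResult:
    """Per-condition averaged scores plus per-condition depth tables."""

    table: pd.DataFrame
    depth_tables: Dict[str, pd.DataFrame]

    def formatted(self) -> str:
        cols = [
            "condition",
            "exposure",
            "n_timepoints",
            "DET",
            "TRA",
            "detection_precision",
            "detection_recall",
            "linking_precision",
            "linking_recall",
            "gt_linking_precision",
            "gt_linking_recall",
            "effort",
        ]
        df = self.table[cols].copy()
        for c in cols[3:]:
            df[c] = df[c].map(lambda v: f"{v:.3f}" if isinstance(v, float) else v)
        return df.to_string(index=False)


def _detect_movie(
    movie: Movie, params: DetectionParams
) -> Dict[int, List[Spot]]:
    spots_by_time: Dict[int, List[Spot]] = {}
    next_id = 1
    for t in range(movie.n_timepoints):
        spots = detect_volume(movie.frame(t, 0), movie.grid, params, t=t, id_start=next_id)
        next_id += len(spots) + 1
        spots_by_time[t] = spots
    return spots_by_time


def _flow_for(
    movie: Movie, gt: LineageForest, source: Optional[str]
) -> Optional[FlowField]:
    from .simulate import ground_truth_flow_field

    if source is None:
        return None
    if source == "ground_truth":
        return ground_truth_flow_field(gt, movie.grid)
    if source == "block_matching":
        flow = FlowField(movie.grid)
        for t in range(1, movie.n_timepoints):
            flow.set_field(
                t,
                estimate_flow_block_matching(
                    movie.frame(t, 0).astype(float),
                    movie.frame(t - 1, 0).astype(float),
                    movie.grid,
                ),
            )
        return flow
    raise ValueError(f"unknown flow source {source!r}")


def run_tradeoff_experiment(
    movie: Movie,
    gt: LineageForest,
    clean: Optional[np.ndarray] = None,
    sim_config=None,
    conditions: Optional[Sequence[AcquisitionCondition]] = None,
    detect_params: DetectionParams = DetectionParams(),
    link_params: LinkingParams = LinkingParams(),
    weights: AOGMWeights = AOGMWeights(),
    flow_source: Optional[str] = "ground_truth",
    n_repeats: int = 3,
    seed: int = 0,
    depth_bin: float = 5.0,
) -> TradeoffResult:
    """Score the full pipeline under each equal-exposure condition.

    For every condition: subsample the master movie, reduce the ground
    truth to the kept time points, detect nuclei, build a flow field
    (``ground_truth``, ``block_matching`` or ``None``), link, and score
    every metric including the linking-only mode on ground-truth spots.
    Repeats draw fresh replicate noise on the noiseless scene (requires
    ``clean`` and ``sim_config``; otherwise a single repeat runs on the
    supplied movie) and scores are averaged across repeats.
    """
    from .simulate import add_imaging_noise

    if conditions is None:
        conditions = standard_conditions(movie.n_replicates)
    if n_repeats > 1 and (clean is None or sim_config is None):
        raise ValueError("n_repeats > 1 requires the noiseless scene and its config")
    seeds = np.random.SeedSequence(seed).generate_state(max(n_repeats, 1)) % (2**31)
    rows = []
    depth_tables: Dict[str, pd.DataFrame] = {}
    for cond in conditions:
        gt_c = reduce_ground_truth(gt, cond)
        sub0 = subsample(movie, cond)
        flow = _flow_for(sub0, gt_c, flow_source)
        relinked, (glp, glr) = tra_on_gt(gt_c, flow, link_params)
        per_repeat = []
        for r in range(n_repeats):
            if r == 0:
                master_r = movie
            else:
                master_r = Movie(
                    add_imaging_noise(clean, sim_config, int(seeds[r])), movie.grid
                )
            sub = sub0 if r == 0 else subsample(master_r, cond)
            spots = _detect_movie(sub, detect_params)
            pred = link_forward(spots, flow, link_params)
            report = evaluate_forests(gt_c, pred, weights, depth_bin=depth_bin)
            if r == 0:
                depth_tables[cond.name] = report.depth_table
            per_repeat.append(report.to_dict())
        mean = {k: float(np.mean([d[k] for d in per_repeat])) for k in per_repeat[0]}
        mean.update(
            condition=cond.name,
            exposure=float(relative_exposure(cond)),
            n_timepoints=sub0.n_timepoints,
            n_gt_spots=gt_c.n_spots,
            n_gt_links=gt_c.n_links,
            gt_linking_precision=glp,
            gt_linking_recall=glr,
        )
        rows.append(mean)
    table = pd.DataFrame(rows)
    front = ["condition", "exposure", "n_timepoints", "n_gt_spots", "n_gt_links"]
    table = table[front + [c for c in table.columns if c not in front]]
    return TradeoffResult(table=table, depth_tables=depth_tables)
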