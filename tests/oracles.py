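"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own algorithms: the AOGM oracle
enumerates every admissible vertex matching and takes the cheapest edit
decomposition; the instance generator builds small ground-truth/
prediction pairs with unambiguous geometry.
"""

from itertools import permutations

import numpy as np

import regentrack as rt


def enumerate_matchings(gt_by_t, pred_by_t):
    """All one-to-one partial matchings respecting the coverage rule.

    Candidate pairs per time point are (g, p) with p inside g's radius;
    yields dicts gt_id -> pred_id, built as the cartesian product of the
    per-time-point partial injections.
    """
    per_t = []
    for t in sorted(set(gt_by_t) | set(pred_by_t)):
        gs = gt_by_t.get(t, [])
        ps = pred_by_t.get(t, [])
        allowed = {
            (g.id, p.id)
            for g in gs
            for p in ps
            if np.linalg.norm(np.subtract(g.pos, p.pos)) <= g.radius
        }
        options = [{}]
        # grow partial injections one gt spot at a time
        for g in gs:
            new_options = []
            for opt in options:
                new_options.append(opt)
                used = set(opt.values())
                for p in ps:
                    if (g.id, p.id) in allowed and p.id not in used:
                        cur = dict(opt)
                        cur[g.id] = p.id
                        new_options.append(cur)
            options = new_options
        per_t.append(options)
    # cartesian product across time points
    stack = [{}]
    for options in per_t:
        stack = [{**a, **b} for a in stack for b in options]
    return stack


def edit_cost(gt, pred, pairs, weights):
    """AOGM edit decomposition cost for a given vertex matching."""
    inv = {p: g for g, p in pairs.items()}
    matched_p = set(pairs.values())
    ns = fn = 0
    for g in gt:
        if g.id in pairs:
            continue
        covered = any(
            p.id in matched_p
            and np.linalg.norm(np.subtract(g.pos, p.pos)) <= g.radius
            for p in pred
            if p.t == g.t
        )
        if covered:
            ns += 1
        else:
            fn += 1
    fp = sum(1 for p in pred if p.id not in inv)
    gt_links = set(gt.links)
    pred_links = set(pred.links)

    def divides(forest, sid):
        return len(forest.children_of(sid)) == 2

    ed = ec = 0
    for (u, v) in pred_links:
        gu, gv = inv.get(u), inv.get(v)
        if gu is None or gv is None or (gu, gv) not in gt_links:
            ed += 1
        elif divides(gt, gu) != divides(pred, u):
            ec += 1
    ea = sum(
        1
        for (a, b) in gt_links
        if pairs.get(a) is None
        or pairs.get(b) is None
        or (pairs[a], pairs[b]) not in pred_links
    )
    return (
        weights.w_NS * ns
        + weights.w_FN * fn
        + weights.w_FP * fp
        + weights.w_ED * ed
        + weights.w_EA * ea
        + weights.w_EC * ec
    )


def min_edit_cost(gt, pred, weights=None):
    """Exhaustive minimum AOGM edit cost over all admissible matchings."""
    weights = weights or rt.AOGMWeights()
    gt_by_t = {}
    for s in gt:
        gt_by_t.setdefault(s.t, []).append(s)
    pred_by_t = {}
    for s in pred:
        pred_by_t.setdefault(s.t, []).append(s)
    best = np.inf
    for pairs in enumerate_matchings(gt_by_t, pred_by_t):
        best = min(best, edit_cost(gt, pred, pairs, weights))
    return float(best)


def random_instance(rng, max_spots=8):
    """Small ground-truth forest and a perturbed prediction.

    Ground-truth tracks (possibly dividing) are far apart (≥ 14 µm for
    2 µm radii and ≤ 0.4 µm jitter), so the vertex matching is
    geometrically unambiguous; occasional isolated "twin" spots sit
    inside a neighbour's radius to exercise vertex splits.  The
    prediction jitters positions within a quarter radius and applies
    random deletions, link drops (which also flip division semantics)
    and far-away spurious spots.
    """
    radius = 2.0
    n_tracks = int(rng.integers(1, 4))
    gt = rt.LineageForest()
    sid = 1
    centers = []
    for _ in range(n_tracks):
        while True:
            c = rng.uniform(0, 40, size=3)
            if all(np.linalg.norm(c - o) >= 14.0 for o in centers):
                centers.append(c)
                break
        length = int(rng.integers(1, 4))
        t_div = int(rng.integers(0, length)) if rng.random() < 0.4 else None
        tips = [(None, np.asarray(centers[-1]))]  # (parent id, position)
        for t in range(length):
            if gt.n_spots >= max_spots - 1:
                break
            new_tips = []
            for parent, pos in tips:
                if gt.n_spots >= max_spots - 1:
                    break
                gt.add_spot(rt.Spot(sid, t, tuple(pos), radius=radius))
                if parent is not None:
                    gt.add_link(parent, sid)
                drift = np.array([0.0, 0.4, 0.0])
                if t == t_div and len(tips) == 1 and gt.n_spots <= max_spots - 2:
                    new_tips.append((sid, pos + drift + np.array([0.0, 0.0, 5.0])))
                    new_tips.append((sid, pos + drift - np.array([0.0, 0.0, 5.0])))
                else:
                    new_tips.append((sid, pos + drift))
                sid += 1
            tips = new_tips
    if rng.random() < 0.3 and gt.n_spots < max_spots:
        # isolated twin inside a neighbour's radius: forces NS bookkeeping
        s = list(gt)[int(rng.integers(0, gt.n_spots))]
        gt.add_spot(
            rt.Spot(sid, s.t, tuple(np.asarray(s.pos) + [0.0, 1.0, 0.0]), radius=radius)
        )
        sid += 1
    # prediction: copy with perturbations
    pred = rt.LineageForest()
    kept = {}
    for s in gt:
        if rng.random() < 0.15:
            continue  # deletion
        pos = np.asarray(s.pos) + rng.uniform(-0.25, 0.25, size=3)
        pred.add_spot(rt.Spot(s.id, s.t, tuple(pos), radius=radius))
        kept[s.id] = True
    for (a, b) in gt.links:
        if a in kept and b in kept and rng.random() < 0.8:
            pred.add_link(a, b)
    next_id = sid + 100
    for _ in range(int(rng.integers(0, 3))):  # spurious far spots
        t = int(rng.integers(0, 4))
        pos = rng.uniform(60, 90, size=3)
        pred.add_spot(rt.Spot(next_id, t, tuple(pos), radius=radius))
        next_id += 1
    return gt, pred
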