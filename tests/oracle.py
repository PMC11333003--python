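"""Independent brute-force recomputation of arbor statistics.

These functions recompute every pairwise/gap/zone statistic directly from
raw node coordinates and the generator's ground-truth menorah membership,
using deliberately naive algorithms (O(n^2) scans, event sweeps) that share
no code with the package's implementations.
"""

from __future__ import annotations

import math

import numpy as np


def _wrapped(dtheta: float) -> float:
    return math.atan2(math.sin(dtheta), math.cos(dtheta))


def _geodesic(graph, a: int, b: int) -> float:
    sa, ta = graph.pos(a)
    sb, tb = graph.pos(b)
    return math.sqrt((sb - sa) ** 2
                     + (graph.body.radius_um * _wrapped(tb - ta)) ** 2)


def brute_pairs(graph, truth, window_um=None):
    """All adjacent sibling-3' pairs per side: list of gap values (um)."""
    soma = graph.body.soma_s_um
    gaps = []
    for side in ("dorsal", "ventral"):
        men = [m for m in truth.menorahs
               if m.side == side and m.base_edges
               and (window_um is None
                    or soma - window_um <= m.attach_s_um <= soma)]
        items = []
        for m in men:
            nodes = sorted({n for e in m.base_edges for n in e},
                           key=graph.s)
            items.append((0.5 * (graph.s(nodes[0]) + graph.s(nodes[-1])),
                          nodes[0], nodes[-1]))
        items.sort()
        for (_, _, right_a), (_, left_b, _) in zip(items[:-1], items[1:]):
            s_gap = graph.s(left_b) - graph.s(right_a)
            gaps.append(_geodesic(graph, right_a, left_b) if s_gap > 0
                        else s_gap)
    return gaps


def brute_tbai(graph, truth, eps=0.5, window_um=None):
    soma = graph.body.soma_s_um
    M = sum(1 for m in truth.menorahs
            if m.base_edges and (window_um is None
                                 or soma - window_um <= m.attach_s_um <= soma))
    gaps = brute_pairs(graph, truth, window_um)
    G = sum(1 for g in gaps if g > eps)
    return (G / M if M else float("nan")), M, G


def brute_overlap_count(graph, truth, eps=0.5, window_um=200.0):
    return sum(1 for g in brute_pairs(graph, truth, window_um) if g <= eps)


def brute_mean_gap(graph, truth, eps=0.5, window_um=150.0):
    gaps = [g for g in brute_pairs(graph, truth, window_um) if g > eps]
    return float(np.mean(gaps)) if gaps else float("nan")


def brute_quaternary_anterior(graph, truth):
    soma = graph.body.soma_s_um
    return sum(1 for m in truth.menorahs for (att, _) in m.candle_edges
               if graph.s(att) < soma)


def _sweep_union_length(intervals, lo, hi, merge_gap=0.0,
                        minus=()) -> float:
    """Union length by event sweep on a sorted endpoint list."""
    ivs = sorted([list(iv) for iv in intervals if iv[1] > iv[0]])
    merged = []
    for a, b in ivs:
        if merged and a <= merged[-1][1] + merge_gap:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    total = 0.0
    for a, b in merged:
        pieces = [[max(a, lo), min(b, hi)]]
        for ma, mb in minus:
            nxt = []
            for pa, pb in pieces:
                if mb <= pa or ma >= pb:
                    nxt.append([pa, pb])
                    continue
                if ma > pa:
                    nxt.append([pa, ma])
                if mb < pb:
                    nxt.append([mb, pb])
            pieces = nxt
        total += sum(max(pb - pa, 0.0) for pa, pb in pieces)
    return total


def brute_zones(graph, truth, window_um=200.0, merge_gap=10.0):
    """(menorah_zone, trapped_zone), dorsal/ventral averaged."""
    soma = graph.body.soma_s_um
    lo, hi = max(soma - window_um, 0.0), soma
    from pvdarbor.core import BranchOrder
    mz, tz = [], []
    for side, sign in (("dorsal", 1), ("ventral", -1)):
        men_iv = []
        for m in truth.menorahs:
            if m.side != side:
                continue
            for u, v in m.stem_edges + m.base_edges + m.candle_edges:
                a, b = graph.s(u), graph.s(v)
                men_iv.append((min(a, b), max(a, b)))
        trap_iv = []
        for (u, v), o in truth.edge_orders.items():
            if o is not BranchOrder.TRAPPED_SECONDARY:
                continue
            arc = graph.body.radius_um * _wrapped(
                graph.theta(v) - graph.body.lateral_theta)
            if arc == 0.0:
                arc = graph.body.radius_um * _wrapped(
                    graph.theta(u) - graph.body.lateral_theta)
            if (arc > 0) != (sign > 0):
                continue
            a, b = graph.s(u), graph.s(v)
            trap_iv.append((min(a, b), max(a, b)))
        trap_clip = [(max(a, lo), min(b, hi)) for a, b in trap_iv
                     if min(b, hi) > max(a, lo)]
        # merge trapped intervals before subtracting
        trap_merged = []
        for a, b in sorted(trap_iv):
            if trap_merged and a <= trap_merged[-1][1]:
                trap_merged[-1][1] = max(trap_merged[-1][1], b)
            else:
                trap_merged.append([a, b])
        mz.append(_sweep_union_length(men_iv, lo, hi, merge_gap=merge_gap,
                                      minus=trap_merged))
        tz.append(_sweep_union_length(trap_clip, lo, hi))
    return float(np.mean(mz)), float(np.mean(tz))
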