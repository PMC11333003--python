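"""Branch-order classification of unlabeled arbors.

PVD branch orders alternate orientation: the primary dendrite runs along the
body axis (A/P) through the soma, secondaries leave it circumferentially
(D/V), tertiaries turn axial again along the sublateral lines, and
quaternary candles turn circumferential toward the nerve cords.  The
classifier exploits exactly this alternation: every edge is scored axial or
circumferential from its total displacement vector on the cylinder, the
maximal axial path through the soma becomes the primary dendrite, and a
branch leaving an order-n path orthogonally gets order n+1 while a branch
continuing in the same orientation keeps order n.

Two special cases: the single soma process reaching the ventral nerve cord
is the axon (first segment: axon initial segment), and a secondary branch
whose whole subtree stays within ``trapped_radius_um`` of the primary line
while turning axial is a *trapped* secondary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .core import ArborGraph, BranchOrder, Edge, wrap_angle


class ClassificationError(ValueError):
    pass


@dataclass(frozen=True)
class ClassifyConfig:
    """Orientation and landmark tolerances for order assignment.

    ``orientation_threshold_deg`` splits axial from circumferential edges
    (45 degrees: whichever displacement component dominates wins);
    ``trapped_radius_um`` bounds the arc distance from the primary line
    within which an axial-turning secondary counts as trapped;
    ``ventral_cord_theta`` overrides the body-derived ventral-cord angle.
    """

    orientation_threshold_deg: float = 45.0
    sublateral_offset_um: float = 20.0
    trapped_radius_um: float = 5.0
    ventral_cord_theta: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.orientation_threshold_deg < 90.0:
            raise ValueError("orientation_threshold_deg must be in (0, 90)")
        if self.trapped_radius_um < 0 or self.sublateral_offset_um < 0:
            raise ValueError("radii must be >= 0")


_AXIAL_ORDERS = {1: True, 2: False, 3: True, 4: False}


def _orientation(graph: ArborGraph, edge: Edge,
                 config: ClassifyConfig) -> str | None:
    """'axial', 'circumferential', or None for an exact tie / zero edge."""
    u, v = edge
    ds = abs(graph.s(v) - graph.s(u))
    darc = graph.body.radius_um * abs(wrap_angle(graph.theta(v) - graph.theta(u)))
    if ds == darc:
        return None
    # threshold t: axial iff angle from axis <= t, i.e. darc <= ds*tan(t)
    tan_t = math.tan(math.radians(config.orientation_threshold_deg))
    return "axial" if darc <= ds * tan_t else "circumferential"


def assign_orders(graph: ArborGraph,
                  config: ClassifyConfig = ClassifyConfig()) -> ArborGraph:
    """Return a labeled copy of the arbor (the input is not mutated)."""
    g = graph.copy()
    body = g.body
    root = g.root
    labels: dict[Edge, BranchOrder] = {}
    v_theta = (config.ventral_cord_theta if config.ventral_cord_theta is not None
               else body.ventral_cord_theta)

    def chain_edges(start_edge: Edge) -> list[Edge]:
        """Follow continuations (single-orientation main path) from an edge."""
        out = [start_edge]
        node = start_edge[1]
        while True:
            nxt = g.children(node)
            if len(nxt) != 1:
                break
            e = (node, nxt[0])
            out.append(e)
            node = nxt[0]
        return out

    # ---- axon: soma process reaching the ventral cord line ---------------
    soma_children = g.children(root)
    axon_child = None
    candidates = []
    for c in soma_children:
        if _orientation(g, (root, c), config) == "circumferential":
            sub = g.subtree_nodes(c)
            reach = min(abs(body.radius_um *
                            wrap_angle(g.theta(n) - v_theta)) for n in sub)
            if reach <= config.trapped_radius_um:
                candidates.append(c)
    if len(candidates) > 1:
        hinted = [c for c in candidates if g.g.nodes[c].get("swc_hint") == 2]
        if len(hinted) == 1:
            candidates = hinted
        else:
            raise ClassificationError(
                "ambiguous axon: multiple soma processes reach the ventral cord")
    if candidates:
        axon_child = candidates[0]
        first = True
        stack = [(root, axon_child)]
        while stack:
            e = stack.pop()
            labels[e] = BranchOrder.AIS if first else BranchOrder.AXON
            first = False
            stack.extend((e[1], c) for c in g.children(e[1]))

    # ---- primary: maximal axial path through the soma --------------------
    def axialness(e: Edge) -> float:
        u, v = e
        ds = abs(g.s(v) - g.s(u))
        darc = body.radius_um * abs(wrap_angle(g.theta(v) - g.theta(u)))
        return ds - darc

    primary_starts = [c for c in soma_children
                      if c != axon_child
                      and _orientation(g, (root, c), config) == "axial"]
    if not primary_starts:
        raise ClassificationError("no axial path through the soma")
    primary_edges: list[Edge] = []
    for c in primary_starts:
        e = (root, c)
        while True:
            primary_edges.append(e)
            kids = [(e[1], k) for k in g.children(e[1])]
            axial_kids = [k for k in kids
                          if _orientation(g, k, config) == "axial"]
            if not axial_kids:
                break
            e = max(axial_kids, key=axialness)
    for e in primary_edges:
        labels[e] = BranchOrder.PRIMARY

    # ---- alternation recursion off the primary path ----------------------
    def label_from(edge: Edge, order: int) -> None:
        stack = [(edge, order)]
        while stack:
            e, n = stack.pop()
            labels[e] = {1: BranchOrder.PRIMARY, 2: BranchOrder.SECONDARY,
                         3: BranchOrder.TERTIARY, 4: BranchOrder.QUATERNARY,
                         }.get(n, BranchOrder.UNASSIGNED)
            expected_axial = _AXIAL_ORDERS.get(n)
            for c in g.children(e[1]):
                ce = (e[1], c)
                if ce in labels:
                    continue
                ori = _orientation(g, ce, config)
                if ori is None:  # tie: alternation expectation -> next order
                    stack.append((ce, n + 1 if n < 4 else 99))
                elif expected_axial is not None and \
                        (ori == "axial") == expected_axial:
                    stack.append((ce, n))
                elif n < 4:
                    stack.append((ce, n + 1))
                else:
                    stack.append((ce, 99))

    for e in primary_edges:
        for c in g.children(e[1]):
            ce = (e[1], c)
            if ce in labels:
                continue
            ori = _orientation(g, ce, config)
            if ori == "axial":
                labels[ce] = BranchOrder.UNASSIGNED
                for n in g.subtree_nodes(c):
                    for k in g.children(n):
                        labels.setdefault((n, k), BranchOrder.UNASSIGNED)
            else:
                label_from(ce, 2)
    # soma-attached circumferential non-axon processes are secondaries too
    for c in soma_children:
        ce = (root, c)
        if ce not in labels:
            ori = _orientation(g, ce, config)
            label_from(ce, 2 if ori != "axial" else 1)

    # ---- trapped secondaries ---------------------------------------------
    lateral = body.lateral_theta
    for e, lab in list(labels.items()):
        if lab is not BranchOrder.SECONDARY:
            continue
        parent_lab = labels.get((g.parent(e[0]), e[0])) if g.parent(e[0]) else None
        if parent_lab is BranchOrder.SECONDARY:
            continue  # only subtree roots
        sub = g.subtree_nodes(e[1])
        max_arc = max(abs(body.radius_um * wrap_angle(g.theta(n) - lateral))
                      for n in sub)
        sub_edges = [(u, v) for u, v in g.g.edges(sub) if (u, v) in labels] \
            + [e]
        has_axial = any(_orientation(g, se, config) == "axial"
                        for se in sub_edges)
        if max_arc <= config.trapped_radius_um and has_axial:
            for se in set(sub_edges):
                labels[se] = BranchOrder.TRAPPED_SECONDARY

    for e in g.edges():
        g.set_order(e, labels.get(e, BranchOrder.UNASSIGNED))
    return g


def segment_menorahs(labeled: ArborGraph) -> list:
    """Group a labeled arbor into menorahs (one per 2' stem with a 3' base).

    Neighbouring menorahs whose bases abut or overlap are still counted
    separately: the unit is the stem, matching the counting rule used when
    discrete menorahs cannot be told apart by eye.
    """
    from .core import Menorah

    out = []
    body = labeled.body
    lateral = body.lateral_theta
    for e in labeled.edges_of_order(BranchOrder.SECONDARY):
        parent = labeled.parent(e[0])
        if parent is not None and \
                labeled.order((parent, e[0])) is BranchOrder.SECONDARY:
            continue  # not the stem root
        sub = labeled.subtree_nodes(e[1])
        stem, base, candles = [e], [], []
        for u, v in labeled.g.edges(sub):
            o = labeled.order((u, v))
            if o is BranchOrder.SECONDARY:
                stem.append((u, v))
            elif o is BranchOrder.TERTIARY:
                base.append((u, v))
            elif o is BranchOrder.QUATERNARY:
                candles.append((u, v))
        if not base:
            continue  # a stalled stem is secondary but not a menorah
        tip_arc = body.radius_um * wrap_angle(labeled.theta(e[1]) - lateral)
        out.append(Menorah(stem_edges=stem, base_edges=sorted(base),
                           candle_edges=sorted(candles),
                           side="dorsal" if tip_arc > 0 else "ventral",
                           attach_node=e[0],
                           attach_s_um=labeled.s(e[0])))
    out.sort(key=lambda m: (m.side, m.attach_s_um))
    return out
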