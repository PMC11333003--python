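"""Arbor-level statistics: self-avoidance indices, zones, coverage, regrowth.

The tertiary branch avoidance index (TBAI) is the number of visible gaps
between neighbouring tertiary branches divided by the number of menorahs.
Adjacency of tertiary branches follows the linear-array geometry of the
arbor: per dorsal/ventral side, menorah bases are ordered along the
sublateral line by their projected midpoints, and each consecutive pair is
scored once.  A pair whose nearest-endpoint geodesic gap exceeds the
visibility threshold ``contact_threshold_um`` counts as a gap; a pair at or
below it counts as a contact/overlap, so gaps and overlaps exactly
partition the adjacent-pair set.

The receptive-field index is the skin area innervated by the anterior
arbor (the skeleton dilated by a reach radius on the unrolled plane)
normalised by the body skin area between the soma and the mouth.

The menorah coverage zone measures the stretch of primary dendrite flanked
by menorahs — not the area of the individual branches — so neighbouring
menorah intervals separated by a small self-avoidance gap are merged before
trapped-secondary intervals are subtracted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .classify import segment_menorahs
from .core import ArborGraph, BranchOrder, Edge, Menorah, wrap_angle


class UndefinedStatisticError(ValueError):
    """The statistic has no value on this arbor (distinct from zero)."""


class InputError(ValueError):
    pass


@dataclass(frozen=True)
class MorphometricsConfig:
    """Thresholds and scoring windows (all lengths in micrometres).

    Windows measured "anterior to the soma" span ``[soma - w, soma]`` along
    the primary dendrite.  ``tbai_window_um = None`` scores the whole
    anterior + posterior arbor.
    """

    contact_threshold_um: float = 0.5
    tbai_window_um: float | None = None
    overlap_window_um: float = 200.0
    gap_window_um: float = 150.0
    zone_window_um: float = 200.0
    zone_merge_gap_um: float = 10.0
    rfi_reach_um: float = 10.0
    rfi_cell_um: float = 1.0
    site_spacing_um: float = 30.0
    defect_fraction: float = 0.5
    grade_bins: tuple[float, ...] = (0.1, 0.3, 0.6)

    def __post_init__(self) -> None:
        for name in ("contact_threshold_um", "overlap_window_um",
                     "gap_window_um", "zone_window_um", "rfi_reach_um",
                     "rfi_cell_um", "site_spacing_um"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class MorphometricsReport:
    """Per-neuron summary row (NaN marks undefined-statistic entries)."""

    tbai: float
    n_menorahs: int
    n_gaps: int
    n_overlapped_tertiary: int
    n_quaternary_anterior: int
    mean_tertiary_gap_um: float
    rfi: float
    menorah_zone_um: float
    trapped_zone_um: float
    secondary_branching_defect: bool
    defect_grade: int
    total_length_um: float

    def to_row(self) -> dict:
        return dict(vars(self))


# ---------------------------------------------------------------------------
# interval arithmetic (exposed for testing against worked examples)
# ---------------------------------------------------------------------------

Interval = tuple[float, float]


def interval_union(intervals: list[Interval],
                   merge_gap: float = 0.0) -> list[Interval]:
    """Union of closed intervals, merging neighbours separated by <= merge_gap."""
    ivs = sorted((a, b) for a, b in intervals if b > a)
    out: list[list[float]] = []
    for a, b in ivs:
        if out and a <= out[-1][1] + merge_gap:
            out[-1][1] = max(out[-1][1], b)
        else:
            out.append([a, b])
    return [(a, b) for a, b in out]


def interval_subtract(base: list[Interval],
                      minus: list[Interval]) -> list[Interval]:
    """Set difference of two unions of intervals."""
    minus = interval_union(minus)
    out: list[Interval] = []
    for a, b in interval_union(base):
        cur = a
        for ma, mb in minus:
            if mb <= cur or ma >= b:
                continue
            if ma > cur:
                out.append((cur, ma))
            cur = max(cur, mb)
            if cur >= b:
                break
        if cur < b:
            out.append((cur, b))
    return out


def interval_clip(intervals: list[Interval], lo: float,
                  hi: float) -> list[Interval]:
    return [(max(a, lo), min(b, hi)) for a, b in intervals
            if min(b, hi) > max(a, lo)]


def interval_length(intervals: list[Interval]) -> float:
    return float(sum(b - a for a, b in interval_union(intervals)))


# ---------------------------------------------------------------------------
# tertiary adjacency
# ---------------------------------------------------------------------------

@dataclass
class TertiaryPair:
    """One adjacent pair of sibling tertiary branches on a sublateral line."""

    side: str
    left_menorah: int  # indices into the menorah list
    right_menorah: int
    gap_um: float  # nearest-endpoint geodesic gap; <= 0 means overlap
    mid_s_um: float


def _base_nodes(graph: ArborGraph, m: Menorah) -> list[int]:
    nodes = {n for e in m.base_edges for n in e}
    return sorted(nodes, key=graph.s)


def tertiary_pairs(labeled: ArborGraph,
                   menorahs: list[Menorah] | None = None,
                   window_um: float | None = None) -> list[TertiaryPair]:
    """Enumerate adjacent sibling-3' pairs per side (optionally windowed).

    When ``window_um`` is given, only menorahs attaching within
    ``[soma - window, soma]`` enter the adjacency ordering, so gaps and
    overlaps computed from the result partition the same pair set.
    """
    if menorahs is None:
        menorahs = segment_menorahs(labeled)
    soma_s = labeled.body.soma_s_um
    idx = [i for i, m in enumerate(menorahs)
           if window_um is None or soma_s - window_um <= m.attach_s_um <= soma_s]
    pairs: list[TertiaryPair] = []
    for side in ("dorsal", "ventral"):
        side_idx = [i for i in idx if menorahs[i].side == side
                    and menorahs[i].base_edges]
        extents = {}
        for i in side_idx:
            nodes = _base_nodes(labeled, menorahs[i])
            extents[i] = (nodes[0], nodes[-1])  # (left node, right node)
        order = sorted(side_idx, key=lambda i: 0.5 * (
            labeled.s(extents[i][0]) + labeled.s(extents[i][1])))
        for a, b in zip(order[:-1], order[1:]):
            rn = extents[a][1]
            ln = extents[b][0]
            s_gap = labeled.s(ln) - labeled.s(rn)
            if s_gap > 0:
                gap = labeled.body.geodesic(*labeled.pos(rn), *labeled.pos(ln))
            else:
                gap = s_gap
            pairs.append(TertiaryPair(side=side, left_menorah=a,
                                      right_menorah=b, gap_um=gap,
                                      mid_s_um=0.5 * (labeled.s(rn)
                                                      + labeled.s(ln))))
    return pairs


# ---------------------------------------------------------------------------
# headline statistics
# ---------------------------------------------------------------------------

def tbai(labeled: ArborGraph,
         config: MorphometricsConfig = MorphometricsConfig(),
         menorahs: list[Menorah] | None = None) -> tuple[float, int, int]:
    """Tertiary branch avoidance index: (tbai, n_menorahs, n_gaps).

    Visible gaps (nearest-endpoint gap > ``contact_threshold_um``) divided
    by the menorah count, dorsal and ventral sides pooled.
    """
    if menorahs is None:
        menorahs = segment_menorahs(labeled)
    w = config.tbai_window_um
    soma_s = labeled.body.soma_s_um
    in_win = [m for m in menorahs
              if w is None or soma_s - w <= m.attach_s_um <= soma_s]
    M = len(in_win)
    if M == 0:
        raise UndefinedStatisticError("no menorahs in the scoring window")
    pairs = tertiary_pairs(labeled, menorahs, window_um=w)
    G = sum(1 for p in pairs if p.gap_um > config.contact_threshold_um)
    return G / M, M, G


def count_overlapped_tertiary(labeled: ArborGraph,
                              config: MorphometricsConfig = MorphometricsConfig(),
                              menorahs: list[Menorah] | None = None) -> int:
    """Adjacent 3' pairs in contact/overlap within the anterior window."""
    pairs = tertiary_pairs(labeled, menorahs,
                           window_um=config.overlap_window_um)
    return sum(1 for p in pairs if p.gap_um <= config.contact_threshold_um)


def mean_tertiary_gap(labeled: ArborGraph,
                      config: MorphometricsConfig = MorphometricsConfig(),
                      menorahs: list[Menorah] | None = None) -> float:
    """Mean visible inter-tertiary gap (um) in the anterior gap window."""
    pairs = tertiary_pairs(labeled, menorahs, window_um=config.gap_window_um)
    gaps = [p.gap_um for p in pairs if p.gap_um > config.contact_threshold_um]
    if not gaps:
        raise UndefinedStatisticError("no visible gaps in the scoring window")
    return float(np.mean(gaps))


def _side_of_edge(labeled: ArborGraph, edge: Edge) -> str:
    arc = labeled.arc(edge[1])
    if arc == 0.0:
        arc = labeled.arc(edge[0])
    return "dorsal" if arc > 0 else "ventral"


def coverage_zones(labeled: ArborGraph,
                   config: MorphometricsConfig = MorphometricsConfig(),
                   menorahs: list[Menorah] | None = None) -> tuple[float, float]:
    """(menorah_zone_um, trapped_zone_um), dorsal/ventral averaged.

    Menorah-owned edges are projected onto the primary axis, unioned
    (bridging self-avoidance gaps up to ``zone_merge_gap_um``), trapped-
    secondary intervals are subtracted, and both zones are clipped to the
    anterior window of length ``zone_window_um``.
    """
    if menorahs is None:
        menorahs = segment_menorahs(labeled)
    soma_s = labeled.body.soma_s_um
    lo = max(soma_s - config.zone_window_um, 0.0)
    hi = soma_s
    men_zone, trap_zone = [], []
    for side in ("dorsal", "ventral"):
        mv: list[Interval] = []
        for m in menorahs:
            if m.side != side:
                continue
            for e in m.edges:
                a, b = labeled.s(e[0]), labeled.s(e[1])
                mv.append((min(a, b), max(a, b)))
        tv: list[Interval] = []
        for e in labeled.edges_of_order(BranchOrder.TRAPPED_SECONDARY):
            if _side_of_edge(labeled, e) != side:
                continue
            a, b = labeled.s(e[0]), labeled.s(e[1])
            tv.append((min(a, b), max(a, b)))
        merged = interval_union(mv, merge_gap=config.zone_merge_gap_um)
        men = interval_clip(interval_subtract(merged, tv), lo, hi)
        men_zone.append(interval_length(men))
        trap_zone.append(interval_length(interval_clip(tv, lo, hi)))
    return float(np.mean(men_zone)), float(np.mean(trap_zone))


def quaternary_count(labeled: ArborGraph,
                     config: MorphometricsConfig = MorphometricsConfig()) -> int:
    """Quaternary branches whose attachment point lies anterior to the soma."""
    soma_s = labeled.body.soma_s_um
    count = 0
    for e in labeled.edges_of_order(BranchOrder.QUATERNARY):
        parent = labeled.parent(e[0])
        if parent is not None and \
                labeled.order((parent, e[0])) is BranchOrder.QUATERNARY:
            continue  # continuation within a candle, not a new branch root
        if labeled.s(e[0]) < soma_s:
            count += 1
    return count


def secondary_branching_defect(labeled: ArborGraph,
                               config: MorphometricsConfig = MorphometricsConfig(),
                               menorahs: list[Menorah] | None = None
                               ) -> tuple[bool, int]:
    """Defect call and severity grade 0-3 for secondary branching.

    Defect: the pooled menorah count in the zone window falls below
    ``defect_fraction`` of the candidate-site expectation
    (``2 * window / site_spacing``).  Severity grades the fraction of the
    window *not* covered by the menorah zone (trapped and empty stretches
    alike) into four bins.
    """
    if menorahs is None:
        menorahs = segment_menorahs(labeled)
    soma_s = labeled.body.soma_s_um
    w = config.zone_window_um
    m_win = sum(1 for m in menorahs if soma_s - w <= m.attach_s_um <= soma_s)
    expected = 2.0 * w / config.site_spacing_um
    defect = (m_win / expected) < config.defect_fraction
    men_zone, _ = coverage_zones(labeled, config, menorahs)
    severity = 1.0 - men_zone / w
    grade = int(np.searchsorted(np.asarray(config.grade_bins), severity,
                                side="right"))
    return defect, grade


def receptive_field_index(labeled: ArborGraph,
                          config: MorphometricsConfig = MorphometricsConfig()
                          ) -> float:
    """Innervated skin area of the anterior arbor over the soma-to-mouth strip.

    The dendrite skeleton is rasterised on the unrolled plane at cell size
    ``rfi_cell_um``, dilated by ``rfi_reach_um`` (Euclidean distance
    transform, periodic in the circumferential direction), clipped to the
    strip ``[mouth_s, soma_s] x [-pi r, pi r]``, and the covered cell area
    is divided by the strip area ``2 pi r (soma_s - mouth_s)``.
    """
    body = labeled.body
    if body.mouth_s_um >= body.soma_s_um:
        raise InputError("mouth must be anterior to the soma")
    cell = config.rfi_cell_um
    rho = config.rfi_reach_um
    # only the anterior arbor innervates the strip: samples are clipped at
    # the soma, and the grid pads by rho so dilation can reach the borders
    u_lo, u_hi = body.mouth_s_um - rho, body.soma_s_um
    C = body.circumference_um
    nu = max(int(math.ceil((u_hi - u_lo) / cell)), 1)
    nv = max(int(math.ceil(C / cell)), 1)
    skel = np.zeros((nu, nv), dtype=bool)
    lateral = body.lateral_theta
    any_sample = False
    for e in labeled.edges():
        if not labeled.order(e).is_dendrite:
            continue
        su, tu = labeled.pos(e[0])
        sv, tv = labeled.pos(e[1])
        if min(su, sv) >= body.soma_s_um:
            continue  # the strictly posterior arbor does not innervate the strip
        L = labeled.edge_length(e)
        n = max(int(math.ceil(L / (cell / 2))), 1)
        frac = np.linspace(0.0, 1.0, n + 1)
        ss = su + frac * (sv - su)
        vv = body.radius_um * (wrap_angle(tu - lateral)
                               + frac * wrap_angle(tv - tu))
        keep = (ss >= u_lo) & (ss <= u_hi)
        if not keep.any():
            continue
        any_sample = True
        iu = np.clip(((ss[keep] - u_lo) / cell).astype(int), 0, nu - 1)
        iv = (np.floor((vv[keep] + C / 2) / cell).astype(int)) % nv
        skel[iu, iv] = True
    if not any_sample:
        return 0.0
    tiled = np.concatenate([skel, skel, skel], axis=1)
    dist = ndimage.distance_transform_edt(~tiled, sampling=(cell, cell))
    covered = dist[:, nv:2 * nv] <= rho
    # count only columns of the strip proper
    u_centers = u_lo + (np.arange(nu) + 0.5) * cell
    strip_rows = (u_centers >= body.mouth_s_um) & (u_centers <= body.soma_s_um)
    area = float(covered[strip_rows].sum()) * cell * cell
    return area / (C * (body.soma_s_um - body.mouth_s_um))


def regrowth_length(graph_pre: ArborGraph, graph_post: ArborGraph,
                    cut_node: int) -> float:
    """Total regrown contour length after dendritomy (um).

    ``cut_node`` must lie on the primary dendrite of the labeled pre-injury
    graph and exist in the post-injury graph.  Every node of the post graph
    absent from the pre graph is regrown; the result is the sum over
    regrown terminals of the contour length from the cut site to that
    terminal, measured along the cylinder surface.
    """
    if cut_node not in graph_pre.g or cut_node not in graph_post.g:
        raise InputError("cut_node must exist in both graphs")
    incident = [(graph_pre.parent(cut_node), cut_node)] if \
        graph_pre.parent(cut_node) is not None else []
    incident += [(cut_node, c) for c in graph_pre.children(cut_node)]
    if not any(graph_pre.order(e) is BranchOrder.PRIMARY for e in incident):
        raise InputError("cut_node does not lie on the primary dendrite")
    new_nodes = set(graph_post.g.nodes) - set(graph_pre.g.nodes)
    if not new_nodes:
        return 0.0
    distal = graph_post.subtree_nodes(cut_node)
    total = 0.0
    for t in graph_post.terminals():
        if t in new_nodes and t in distal:
            total += graph_post.path_length(cut_node, t)
    return total


def compute_report(labeled: ArborGraph,
                   config: MorphometricsConfig = MorphometricsConfig()
                   ) -> MorphometricsReport:
    """Assemble the full per-neuron report (undefined statistics -> NaN)."""
    menorahs = segment_menorahs(labeled)
    try:
        tb, M, G = tbai(labeled, config, menorahs)
    except UndefinedStatisticError:
        tb, M, G = float("nan"), 0, 0
    try:
        gap = mean_tertiary_gap(labeled, config, menorahs)
    except UndefinedStatisticError:
        gap = float("nan")
    defect, grade = secondary_branching_defect(labeled, config, menorahs)
    mz, tz = coverage_zones(labeled, config, menorahs)
    return MorphometricsReport(
        tbai=tb, n_menorahs=M, n_gaps=G,
        n_overlapped_tertiary=count_overlapped_tertiary(labeled, config,
                                                        menorahs),
        n_quaternary_anterior=quaternary_count(labeled, config),
        mean_tertiary_gap_um=gap,
        rfi=receptive_field_index(labeled, config),
        menorah_zone_um=mz, trapped_zone_um=tz,
        secondary_branching_defect=defect, defect_grade=grade,
        total_length_um=labeled.total_length(
            [BranchOrder.PRIMARY, BranchOrder.SECONDARY,
             BranchOrder.TERTIARY, BranchOrder.QUATERNARY,
             BranchOrder.TRAPPED_SECONDARY]))
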