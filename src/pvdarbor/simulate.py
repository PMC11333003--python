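"""Synthetic PVD arbors, photoconversion traces, and mRNA puncta.

The generator emulates the menorah architecture of the PVD neuron: a primary
dendrite running anteriorly and posteriorly from the soma along the lateral
line, secondary stems extending dorsally and ventrally to the sublateral
lines, tertiary bases growing bidirectionally along those lines, and
quaternary candles reaching toward the dorsal/ventral nerve cords.  Sibling
tertiary tips that meet are resolved by self-avoidance with probability
``p_sa`` (both retract, leaving a gap) or persist in contact/overlap —
the knob that turns a wildtype-like arbor into a self-avoidance-defective
one.  Failed secondary sites can instead become "trapped" secondaries that
run along the primary-dendrite axis.

Every stochastic decision is recorded in a :class:`GroundTruth` so that
downstream classification and morphometrics can be validated edge by edge.
All randomness derives from a single integer seed via per-site substreams,
so identical parameters reproduce identical arbors regardless of call order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .core import ArborGraph, BranchOrder, Edge, WormBody
from .fluor import FluorTrace, PunctaSet, Punctum, puncta_positions

DEFAULT_BODY = WormBody(length_um=1000.0, radius_um=25.0,
                        soma_s_um=650.0, mouth_s_um=20.0)


class ParameterError(ValueError):
    """Simulation parameters are infeasible for the given body."""


@dataclass(frozen=True)
class ArborSimParams:
    """Knobs of the arbor generator.

    ``n_menorah_sites`` candidate secondary sites are laid out along the
    primary dendrite at mean spacing ``menorah_spacing_um`` (three quarters
    anterior to the soma, mirroring the anterior-dominant PVD arbor).  Each
    site, independently per dorsal/ventral side, branches out with
    probability ``p_branch``; a failed site instead becomes a trapped
    secondary with probability ``p_trapped``.  Neighbouring tertiary tips
    that meet retract with probability ``p_sa`` leaving a ``gap_um`` gap,
    otherwise they stay in contact with an overlap drawn uniformly on
    ``[0, menorah_spacing_um / 4]``.
    """

    n_menorah_sites: int = 16
    menorah_spacing_um: float = 30.0
    p_branch: float = 0.95
    p_trapped: float = 0.1
    p_sa: float = 0.95
    gap_um: float = 5.0
    tertiary_offset_um: float = 20.0
    quaternary_rate_per_um: float = 0.15
    jitter_um: float = 0.5
    seed: int = 0
    # secondary knobs (defaults are part of the model, rarely moved)
    max_tertiary_extent_um: float | None = None  # default: menorah_spacing_um
    trapped_offset_um: float = 1.5
    anterior_fraction: float = 0.75
    with_axon: bool = True

    def __post_init__(self) -> None:
        for name in ("p_branch", "p_trapped", "p_sa"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ParameterError(f"{name}={p} outside [0, 1]")
        for name in ("menorah_spacing_um", "gap_um", "tertiary_offset_um",
                     "quaternary_rate_per_um", "jitter_um"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        if self.n_menorah_sites < 0:
            raise ParameterError("n_menorah_sites must be >= 0")

    @property
    def tertiary_extent_um(self) -> float:
        return (self.max_tertiary_extent_um
                if self.max_tertiary_extent_um is not None
                else self.menorah_spacing_um)


PRESETS: dict[str, dict] = {
    # healthy arbor: reliable branching, reliable self-avoidance
    "wildtype_like": dict(p_branch=0.95, p_trapped=0.05, p_sa=0.95),
    # null-allele-like: secondary branching fails, stems trapped along the 1' axis
    "gk8_like": dict(p_branch=0.30, p_trapped=0.85, p_sa=0.90),
    # self-avoidance allele: branching intact, tertiary contacts persist
    "xr58_like": dict(p_branch=0.95, p_trapped=0.05, p_sa=0.25),
    # receptor over-expression: both branching and avoidance degraded
    "dma1_oe_like": dict(p_branch=0.60, p_trapped=0.30, p_sa=0.50),
}


def preset(name: str, seed: int = 0, **overrides) -> ArborSimParams:
    """Named parameter presets emulating wildtype and mutant-like phenotypes."""
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    kw = dict(PRESETS[name])
    kw.update(overrides)
    return ArborSimParams(seed=seed, **kw)


# ---------------------------------------------------------------------------
# ground truth bookkeeping
# ---------------------------------------------------------------------------

@dataclass
class ContactEvent:
    """A meeting of two sibling tertiary tips and how it was resolved."""
    side: str
    s_left_site: float
    s_right_site: float
    s_contact: float
    resolved: bool
    gap_um: float | None = None
    overlap_um: float | None = None


@dataclass
class Landmark:
    s: float
    theta: float
    kind: str  # "branch_point" | "contact_point"


@dataclass
class MenorahTruth:
    side: str
    site_index: int
    attach_node: int
    attach_s_um: float
    stem_edges: list[Edge]
    base_edges: list[Edge]
    candle_edges: list[Edge]
    left_tip_s: float
    right_tip_s: float


@dataclass
class GroundTruth:
    """Everything the generator decided, keyed to the emitted graph."""
    edge_orders: dict[Edge, BranchOrder]
    contacts: list[ContactEvent]
    menorahs: list[MenorahTruth]
    landmarks: list[Landmark]
    n_candidate_sites_per_side: int
    site_s_um: list[float]

    def resolved_fraction(self) -> float:
        """Empirical self-avoidance success rate among contact events."""
        if not self.contacts:
            raise ValueError("no contact events recorded")
        return sum(c.resolved for c in self.contacts) / len(self.contacts)

    def to_dict(self) -> dict:
        return {
            "edge_orders": {f"{u}-{v}": o.value
                            for (u, v), o in self.edge_orders.items()},
            "contacts": [vars(c) for c in self.contacts],
            "menorahs": [{**vars(m),
                          "stem_edges": [list(e) for e in m.stem_edges],
                          "base_edges": [list(e) for e in m.base_edges],
                          "candle_edges": [list(e) for e in m.candle_edges]}
                         for m in self.menorahs],
            "landmarks": [vars(l) for l in self.landmarks],
            "n_candidate_sites_per_side": self.n_candidate_sites_per_side,
            "site_s_um": list(self.site_s_um),
        }


def _rng(seed: int, *tags: int) -> np.random.Generator:
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, *tags])


# ---------------------------------------------------------------------------
# arbor generation
# ---------------------------------------------------------------------------

def candidate_sites(params: ArborSimParams, body: WormBody) -> list[float]:
    """Candidate secondary-site axial positions (anterior first, sorted)."""
    n_a = int(round(params.anterior_fraction * params.n_menorah_sites))
    n_p = params.n_menorah_sites - n_a
    soma = body.soma_s_um
    sp = params.menorah_spacing_um
    sites = sorted([soma - sp * i for i in range(1, n_a + 1)]
                   + [soma + sp * j for j in range(1, n_p + 1)])
    return sites


def generate_arbor(params: ArborSimParams,
                   body: WormBody = DEFAULT_BODY) -> tuple[ArborGraph, GroundTruth]:
    """Generate one PVD-like arbor and its decision record.

    Returns a fully built (unlabeled) :class:`ArborGraph` plus the
    :class:`GroundTruth` holding the true branch order of every edge, the
    contact events with their resolution, menorah membership, and the
    landmark list (branch points and retracted contact points).
    """
    if params.tertiary_offset_um >= math.pi * body.radius_um:
        raise ParameterError(
            f"tertiary_offset_um={params.tertiary_offset_um} exceeds the "
            f"half-circumference {math.pi * body.radius_um:.1f}")
    sp = params.menorah_spacing_um
    sites = candidate_sites(params, body)
    if sites and not (body.mouth_s_um <= sites[0] - sp / 2
                      and sites[-1] + sp / 2 <= body.length_um):
        raise ParameterError("menorah sites do not fit within [mouth_s, L]")

    lateral = body.lateral_theta
    quarter_arc = body.circumference_um / 4.0

    # --- per-side site decisions and tertiary tip bookkeeping -------------
    sides = {"dorsal": +1, "ventral": -1}
    plans: dict[str, dict] = {}
    contacts: list[ContactEvent] = []
    for side_idx, (side, sign) in enumerate(sides.items()):
        s_jit, branched, trapped, trap_dir, trap_len = [], [], [], [], []
        for i, s0 in enumerate(sites):
            r = _rng(params.seed, side_idx, i, 0)
            s_jit.append(s0 + r.normal(0.0, params.jitter_um))
            b = r.uniform() < params.p_branch
            branched.append(b)
            t = (not b) and (r.uniform() < params.p_trapped)
            trapped.append(t)
            trap_dir.append(1 if r.uniform() < 0.5 else -1)
            trap_len.append(sp * r.uniform(0.5, 1.0))
        b_idx = [i for i in range(len(sites)) if branched[i]]
        left_tip = {i: s_jit[i] - sp / 2 for i in b_idx}
        right_tip = {i: s_jit[i] + sp / 2 for i in b_idx}
        for a, b in zip(b_idx[:-1], b_idx[1:]):
            dist = s_jit[b] - s_jit[a]
            if dist / 2 > params.tertiary_extent_um:
                right_tip[a] = s_jit[a] + params.tertiary_extent_um
                left_tip[b] = s_jit[b] - params.tertiary_extent_um
                continue
            mid = 0.5 * (s_jit[a] + s_jit[b])
            rc = _rng(params.seed, side_idx, a, 1)
            if rc.uniform() < params.p_sa:
                right_tip[a] = mid - params.gap_um / 2
                left_tip[b] = mid + params.gap_um / 2
                contacts.append(ContactEvent(side, s_jit[a], s_jit[b], mid,
                                             resolved=True, gap_um=params.gap_um))
            else:
                ov = rc.uniform(0.0, sp / 4)
                right_tip[a] = mid + ov / 2
                left_tip[b] = mid - ov / 2
                contacts.append(ContactEvent(side, s_jit[a], s_jit[b], mid,
                                             resolved=False, overlap_um=ov))
        lo, hi = body.mouth_s_um, body.length_um
        for i in b_idx:
            left_tip[i] = min(max(left_tip[i], lo), s_jit[i])
            right_tip[i] = max(min(right_tip[i], hi), s_jit[i])
        plans[side] = dict(s_jit=s_jit, branched=branched, trapped=trapped,
                           trap_dir=trap_dir, trap_len=trap_len,
                           left_tip=left_tip, right_tip=right_tip, sign=sign)

    # --- build the graph ---------------------------------------------------
    graph = ArborGraph(body)
    orders: dict[Edge, BranchOrder] = {}
    menorahs: list[MenorahTruth] = []
    landmarks: list[Landmark] = []
    next_id = 1
    soma = next_id
    graph.add_node(soma, s=body.soma_s_um, theta=lateral, swc_hint=1, radius=2.0)
    next_id += 1

    def new_node(s, theta, parent, order, hint=3):
        nonlocal next_id
        nid = graph.add_node(next_id, s=s, theta=theta, parent=parent, swc_hint=hint)
        next_id += 1
        orders[(parent, nid)] = order
        return nid

    # attachments on the primary dendrite, keyed by axial position
    attachments: list[tuple[float, str, str, int]] = []  # (s, side, kind, site_idx)
    for side, plan in plans.items():
        for i in range(len(sites)):
            if plan["branched"][i]:
                attachments.append((plan["s_jit"][i], side, "stem", i))
            elif plan["trapped"][i]:
                attachments.append((plan["s_jit"][i], side, "trapped", i))

    if sites:
        ant_end = sites[0] - sp / 2
        post_end = sites[-1] + sp / 2
    else:
        ant_end = max(body.soma_s_um - sp, body.mouth_s_um)
        post_end = min(body.soma_s_um + sp, body.length_um)

    def build_primary(direction: int, end_s: float) -> None:
        nonlocal next_id
        atts = sorted((a for a in attachments
                       if (a[0] - body.soma_s_um) * direction > 0),
                      key=lambda a: a[0] * direction)
        prev = soma
        pos = body.soma_s_um
        k = 0
        while k < len(atts):
            s_here = atts[k][0]
            group = [a for a in atts if a[0] == s_here]
            k += len(group)
            node = new_node(s_here, lateral, prev, BranchOrder.PRIMARY)
            for _, side, kind, i in group:
                _attach(node, side, kind, i)
            prev, pos = node, s_here
        if (end_s - pos) * direction > 1e-9:
            new_node(end_s, lateral, prev, BranchOrder.PRIMARY)

    def _attach(node: int, side: str, kind: str, i: int) -> None:
        plan = plans[side]
        sign = plan["sign"]
        s_site = plan["s_jit"][i]
        if kind == "trapped":
            arc = sign * params.trapped_offset_um
            stub = new_node(s_site, body.theta_at_arc(arc), node,
                            BranchOrder.TRAPPED_SECONDARY)
            run_end = s_site + plan["trap_dir"][i] * plan["trap_len"][i]
            run_end = min(max(run_end, body.mouth_s_um), body.length_um)
            new_node(run_end, body.theta_at_arc(arc), stub,
                     BranchOrder.TRAPPED_SECONDARY)
            return
        # menorah: stem -> base chain (both directions) with candles
        arc = sign * params.tertiary_offset_um
        theta3 = body.theta_at_arc(arc)
        stem_tip = new_node(s_site, theta3, node, BranchOrder.SECONDARY)
        landmarks.append(Landmark(s_site, lateral, "branch_point"))
        lt, rt = plan["left_tip"][i], plan["right_tip"][i]
        rq = _rng(params.seed, 0 if side == "dorsal" else 1, i, 2)
        n_candles = rq.poisson(params.quaternary_rate_per_um * max(rt - lt, 0.0))
        cpos = np.sort(rq.uniform(lt, rt, size=n_candles))
        base_edges: list[Edge] = []
        candle_edges: list[Edge] = []
        cord_arc = sign * quarter_arc

        def build_base(positions: Sequence[float], tip_s: float) -> None:
            prev = stem_tip
            for pc in positions:
                att = new_node(pc, theta3, prev, BranchOrder.TERTIARY)
                base_edges.append((prev, att))
                term_s = pc + rq.normal(0.0, params.jitter_um)
                term_s = min(max(term_s, body.mouth_s_um), body.length_um)
                term_arc = cord_arc + rq.normal(0.0, params.jitter_um)
                term = new_node(term_s, body.theta_at_arc(term_arc), att,
                                BranchOrder.QUATERNARY)
                candle_edges.append((att, term))
                landmarks.append(Landmark(pc, theta3, "branch_point"))
                prev = att
            if abs(tip_s - graph.s(prev)) > 1e-9:
                tip = new_node(tip_s, theta3, prev, BranchOrder.TERTIARY)
                base_edges.append((prev, tip))

        build_base(sorted((p for p in cpos if p < s_site), reverse=True), lt)
        build_base(sorted(p for p in cpos if p >= s_site), rt)
        menorahs.append(MenorahTruth(
            side=side, site_index=i, attach_node=node, attach_s_um=s_site,
            stem_edges=[(node, stem_tip)], base_edges=base_edges,
            candle_edges=candle_edges, left_tip_s=lt, right_tip_s=rt))

    build_primary(-1, ant_end)
    build_primary(+1, post_end)

    if params.with_axon:
        mid = new_node(body.soma_s_um, body.theta_at_arc(-quarter_arc / 2),
                       soma, BranchOrder.AIS, hint=2)
        cord = new_node(body.soma_s_um, body.ventral_cord_theta, mid,
                        BranchOrder.AXON, hint=2)
        run = max(body.soma_s_um - 100.0, body.mouth_s_um)
        new_node(run, body.ventral_cord_theta, cord, BranchOrder.AXON, hint=2)

    for c in contacts:
        if c.resolved:
            sign = sides[c.side]
            landmarks.append(Landmark(
                c.s_contact, body.theta_at_arc(sign * params.tertiary_offset_um),
                "contact_point"))

    graph.validate()
    truth = GroundTruth(edge_orders=orders, contacts=contacts,
                        menorahs=menorahs, landmarks=landmarks,
                        n_candidate_sites_per_side=len(sites),
                        site_s_um=sites)
    return graph, truth


def labeled_from_truth(graph: ArborGraph, truth: GroundTruth) -> ArborGraph:
    """Copy of the graph carrying the ground-truth labels (for oracles)."""
    out = graph.copy()
    for e, o in truth.edge_orders.items():
        out.set_order(e, o)
    return out


# ---------------------------------------------------------------------------
# photoconversion traces
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FluorSimParams:
    """Forward model of a Kaede photoconversion-recovery experiment.

    Green signal in the distal ROI recovers as
    ``F(t) = f_0 + (f_p - f_0) * r_inf * (1 - exp(-k t)) + noise``,
    sampled every ``dt_s`` seconds (default 5 s over 6 minutes).
    """

    k_per_s: float = 0.01
    r_inf: float = 0.8
    f_p: float = 200.0
    f_0: float = 50.0
    noise_sd: float = 0.0
    dt_s: float = 5.0
    duration_s: float = 360.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.f_p > self.f_0 >= 0:
            raise ParameterError("require f_p > f_0 >= 0")
        if self.dt_s <= 0 or self.duration_s < self.dt_s:
            raise ParameterError("require dt_s > 0 and duration_s >= dt_s")


def generate_fluor_trace(params: FluorSimParams) -> FluorTrace:
    t = np.arange(0.0, params.duration_s + params.dt_s / 2, params.dt_s)
    mean = params.f_0 + (params.f_p - params.f_0) * params.r_inf * (
        1.0 - np.exp(-params.k_per_s * t))
    noise = (_rng(params.seed, 9).normal(0.0, params.noise_sd, size=t.size)
             if params.noise_sd > 0 else np.zeros_like(t))
    f = mean + noise
    return FluorTrace(t_s=t, f=f, f_p=params.f_p, f_0=float(f[0]))


# ---------------------------------------------------------------------------
# mRNA puncta
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PunctaSimParams:
    """Puncta placed along dendrites, optionally enriched at landmarks.

    ``landmark_enrichment`` multiplies the sampling density within
    ``capture_radius_um`` of any landmark; 1 means spatially uniform.
    """

    n_puncta: int = 100
    landmark_enrichment: float = 1.0
    capture_radius_um: float = 2.0
    seed: int = 0
    bin_um: float = 0.5

    def __post_init__(self) -> None:
        if self.n_puncta < 0:
            raise ParameterError("n_puncta must be >= 0")
        if self.landmark_enrichment < 1.0:
            raise ParameterError("landmark_enrichment must be >= 1")


def generate_puncta(graph: ArborGraph, truth: GroundTruth,
                    params: PunctaSimParams,
                    orders: tuple[BranchOrder, ...] | None = None) -> PunctaSet:
    """Sample puncta along dendrite edges with landmark enrichment.

    Each edge is discretised into ~``bin_um`` sub-segments; a segment within
    ``capture_radius_um`` (cylinder geodesic) of any landmark gets sampling
    weight ``landmark_enrichment``, others weight 1, both proportional to
    segment length.
    """
    if orders is None:
        dend = [e for e, o in truth.edge_orders.items() if o.is_dendrite]
    else:
        dend = [e for e, o in truth.edge_orders.items() if o in orders]
    lm = np.array([[l.s, l.theta] for l in truth.landmarks]) \
        if truth.landmarks else np.empty((0, 2))
    segs = []  # (edge, a_frac, b_frac, length, weight)
    body = graph.body
    for e in dend:
        L = graph.edge_length(e)
        if L <= 0:
            continue
        nseg = max(1, int(math.ceil(L / params.bin_um)))
        fr = np.linspace(0.0, 1.0, nseg + 1)
        mids = 0.5 * (fr[:-1] + fr[1:])
        su, tu = graph.pos(e[0])
        sv, tv = graph.pos(e[1])
        from .core import wrap_angle
        dth = wrap_angle(tv - tu)
        ms = su + mids * (sv - su)
        mt = tu + mids * dth
        if lm.size and params.landmark_enrichment > 1.0:
            dv = body.radius_um * np.abs(
                (mt[:, None] - lm[None, :, 1] + math.pi) % (2 * math.pi) - math.pi)
            d = np.sqrt((ms[:, None] - lm[None, :, 0]) ** 2 + dv ** 2)
            near = (d.min(axis=1) <= params.capture_radius_um)
        else:
            near = np.zeros(nseg, dtype=bool)
        w = np.where(near, params.landmark_enrichment, 1.0) * (L / nseg)
        for j in range(nseg):
            segs.append((e, fr[j], fr[j + 1], L, w[j]))
    if params.n_puncta > 0 and not segs:
        raise ParameterError("cannot place puncta on an arbor with zero dendrite length")

    rng = _rng(params.seed, 11)
    weights = np.array([s[4] for s in segs], dtype=float)
    puncta: list[Punctum] = []
    if params.n_puncta > 0:
        idx = rng.choice(len(segs), size=params.n_puncta, p=weights / weights.sum())
        ufrac = rng.uniform(size=params.n_puncta)
        for pid, (i, u) in enumerate(zip(idx, ufrac)):
            e, a, b, L, _ = segs[i]
            frac = a + u * (b - a)
            puncta.append(Punctum(punctum_id=pid, edge=e, offset_um=frac * L,
                                  order=truth.edge_orders[e]))
    return PunctaSet(puncta=puncta,
                     landmarks=[(l.s, l.theta, l.kind) for l in truth.landmarks])
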