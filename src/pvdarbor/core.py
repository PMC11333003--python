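"""Domain model: worm-body cylinder geometry and dendrite arbors on its surface.

The PVD neuron tiles the worm's skin, so every skeleton lives on (or very
near) a cylinder of radius ``r`` whose axis is the body centerline.  Points
are stored in cylindrical surface coordinates ``(s, theta)``: ``s`` is the
axial position along the centerline in micrometres (0 = anterior tip) and
``theta`` the circumferential angle in radians, wrapped to ``[0, 2*pi)``.
Distances between neighbouring skeleton points are geodesics on the cylinder,

    ds^2 = dS^2 + (r * dtheta)^2,

with the angular difference always taken as the shortest wrapped arc.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import networkx as nx
import numpy as np

TWO_PI = 2.0 * math.pi


class GeometryError(ValueError):
    """A coordinate or body parameter violates the cylinder model."""


class StructuralError(ValueError):
    """A skeleton is not a single rooted tree."""


def wrap_angle(delta: float) -> float:
    """Wrap an angular difference into (-pi, pi] (shortest signed arc)."""
    w = math.remainder(delta, TWO_PI)
    if w <= -math.pi:  # remainder returns [-pi, pi]; fold the open end
        w += TWO_PI
    return w


def wrap_theta(theta: float) -> float:
    """Wrap an absolute angle into [0, 2*pi)."""
    t = math.fmod(theta, TWO_PI)
    return t + TWO_PI if t < 0 else t


@dataclass(frozen=True)
class WormBody:
    """Cylindrical body geometry defining the surface metric.

    Parameters
    ----------
    length_um
        Centerline length ``L``; ``s = 0`` is the anterior tip.
    radius_um
        Body radius ``r``; the circumference ``C = 2*pi*r`` is derived.
    soma_s_um
        Axial position of the PVD soma.
    mouth_s_um
        Axial position of the mouth (anterior-most landmark); the
        receptive-field strip runs from the soma to the mouth.
    dv_reference_theta
        Angle of the dorsal midline.  The lateral line carrying the soma and
        the primary dendrite sits a quarter turn ventral of it; the ventral
        midline (ventral nerve cord) is antipodal to the dorsal midline.
    """

    length_um: float
    radius_um: float
    soma_s_um: float
    mouth_s_um: float = 0.0
    dv_reference_theta: float = math.pi / 2.0

    def __post_init__(self) -> None:
        if self.length_um <= 0 or self.radius_um <= 0:
            raise GeometryError("body length and radius must be positive")
        if not (0 <= self.mouth_s_um < self.soma_s_um <= self.length_um):
            raise GeometryError(
                "require 0 <= mouth_s_um < soma_s_um <= length_um, got "
                f"mouth={self.mouth_s_um}, soma={self.soma_s_um}, L={self.length_um}"
            )

    @property
    def circumference_um(self) -> float:
        return TWO_PI * self.radius_um

    @property
    def lateral_theta(self) -> float:
        """Angle of the lateral line (soma / primary dendrite)."""
        return wrap_theta(self.dv_reference_theta - math.pi / 2.0)

    @property
    def dorsal_cord_theta(self) -> float:
        return wrap_theta(self.dv_reference_theta)

    @property
    def ventral_cord_theta(self) -> float:
        return wrap_theta(self.dv_reference_theta + math.pi)

    def arc_from_lateral(self, theta: float) -> float:
        """Signed arc distance (um) from the lateral line; dorsal positive."""
        return self.radius_um * wrap_angle(theta - self.lateral_theta)

    def theta_at_arc(self, arc_um: float) -> float:
        """Inverse of :meth:`arc_from_lateral`."""
        return wrap_theta(self.lateral_theta + arc_um / self.radius_um)

    def geodesic(self, s1: float, theta1: float, s2: float, theta2: float) -> float:
        """Geodesic distance on the cylinder between two surface points."""
        dv = self.radius_um * wrap_angle(theta2 - theta1)
        return math.hypot(s2 - s1, dv)

    def to_dict(self) -> dict:
        return {
            "length_um": self.length_um,
            "radius_um": self.radius_um,
            "soma_s_um": self.soma_s_um,
            "mouth_s_um": self.mouth_s_um,
            "dv_reference_theta": self.dv_reference_theta,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "WormBody":
        return cls(**{k: float(d[k]) for k in (
            "length_um", "radius_um", "soma_s_um", "mouth_s_um", "dv_reference_theta")})


class BranchOrder(enum.Enum):
    """Branch-order taxonomy of PVD dendrites plus the axonal compartments.

    ``TRAPPED_SECONDARY`` is a sub-state of secondary used for zone
    accounting: a 2' branch that failed to escape the primary-dendrite zone
    and runs along the body axis instead of reaching the sublateral line.
    """

    PRIMARY = "1"
    SECONDARY = "2"
    TERTIARY = "3"
    QUATERNARY = "4"
    AXON = "axon"
    AIS = "ais"
    TRAPPED_SECONDARY = "trapped2"
    UNASSIGNED = "unassigned"

    @property
    def is_dendrite(self) -> bool:
        return self in _DENDRITE_ORDERS

    @property
    def numeric(self) -> int | None:
        """1..4 for dendritic orders (trapped counts as 2), else None."""
        return _NUMERIC.get(self)


_DENDRITE_ORDERS = {
    BranchOrder.PRIMARY, BranchOrder.SECONDARY, BranchOrder.TERTIARY,
    BranchOrder.QUATERNARY, BranchOrder.TRAPPED_SECONDARY,
}
_NUMERIC = {
    BranchOrder.PRIMARY: 1, BranchOrder.SECONDARY: 2,
    BranchOrder.TERTIARY: 3, BranchOrder.QUATERNARY: 4,
    BranchOrder.TRAPPED_SECONDARY: 2,
}

NodeKind = str  # one of {"soma", "branch_point", "continuation", "terminal"}
Edge = tuple[int, int]


class ArborGraph:
    """A rooted dendrite skeleton on a cylindrical body surface.

    Thin wrapper around a :class:`networkx.DiGraph` (edges parent -> child)
    with per-node surface coordinates and per-edge :class:`BranchOrder`
    labels.  Node attributes: ``s`` (um), ``theta`` (rad, in [0, 2*pi)),
    ``swc_hint`` (original SWC type code, informational), ``radius``.
    """

    def __init__(self, body: WormBody, graph: nx.DiGraph | None = None):
        self.body = body
        self.g = graph if graph is not None else nx.DiGraph()

    # -- construction -----------------------------------------------------
    def add_node(self, node_id: int, s: float, theta: float, *,
                 parent: int | None = None, swc_hint: int = 3,
                 radius: float = 0.5) -> int:
        if node_id in self.g:
            raise StructuralError(f"duplicate node id {node_id}")
        self.g.add_node(node_id, s=float(s), theta=wrap_theta(theta),
                        swc_hint=int(swc_hint), radius=float(radius))
        if parent is not None:
            if parent not in self.g:
                raise StructuralError(
                    f"node {node_id} references missing parent {parent}")
            self.g.add_edge(parent, node_id)
        return node_id

    def copy(self) -> "ArborGraph":
        return ArborGraph(self.body, self.g.copy())

    # -- basic queries ----------------------------------------------------
    @property
    def root(self) -> int:
        roots = [n for n in self.g if self.g.in_degree(n) == 0]
        if len(roots) != 1:
            raise StructuralError(f"expected exactly one root, found {len(roots)}")
        return roots[0]

    def __len__(self) -> int:
        return self.g.number_of_nodes()

    def nodes(self) -> Iterator[int]:
        return iter(self.g.nodes)

    def edges(self) -> Iterator[Edge]:
        return iter(self.g.edges)

    def pos(self, node: int) -> tuple[float, float]:
        d = self.g.nodes[node]
        return d["s"], d["theta"]

    def s(self, node: int) -> float:
        return self.g.nodes[node]["s"]

    def theta(self, node: int) -> float:
        return self.g.nodes[node]["theta"]

    def arc(self, node: int) -> float:
        """Signed arc distance of a node from the lateral line."""
        return self.body.arc_from_lateral(self.theta(node))

    def children(self, node: int) -> list[int]:
        return sorted(self.g.successors(node))

    def parent(self, node: int) -> int | None:
        preds = list(self.g.predecessors(node))
        return preds[0] if preds else None

    def node_kind(self, node: int) -> NodeKind:
        if self.g.in_degree(node) == 0:
            return "soma"
        out = self.g.out_degree(node)
        if out == 0:
            return "terminal"
        return "branch_point" if out >= 2 else "continuation"

    def terminals(self) -> list[int]:
        return [n for n in self.g if self.g.out_degree(n) == 0
                and self.g.in_degree(n) > 0]

    # -- edge labels ------------------------------------------------------
    def set_order(self, edge: Edge, order: BranchOrder) -> None:
        if not self.g.has_edge(*edge):
            raise StructuralError(f"no such edge {edge}")
        self.g.edges[edge]["order"] = order

    def order(self, edge: Edge) -> BranchOrder:
        return self.g.edges[edge].get("order", BranchOrder.UNASSIGNED)

    @property
    def is_labeled(self) -> bool:
        return all("order" in self.g.edges[e] for e in self.g.edges)

    def edges_of_order(self, *orders: BranchOrder) -> list[Edge]:
        wanted = set(orders)
        return [e for e in self.g.edges if self.order(e) in wanted]

    # -- metric -----------------------------------------------------------
    def edge_length(self, edge: Edge) -> float:
        """Geodesic edge length on the cylinder surface (um)."""
        u, v = edge
        if not self.g.has_edge(u, v):
            raise StructuralError(f"no such edge {edge}")
        s1, t1 = self.pos(u)
        s2, t2 = self.pos(v)
        return self.body.geodesic(s1, t1, s2, t2)

    def total_length(self, orders: Iterable[BranchOrder] | None = None) -> float:
        if orders is None:
            es: Iterable[Edge] = self.g.edges
        else:
            es = self.edges_of_order(*orders)
        return float(sum(self.edge_length(e) for e in es))

    def path_length(self, src: int, dst: int) -> float:
        """Contour length along the tree between two nodes (um)."""
        path = nx.shortest_path(self.g.to_undirected(as_view=True), src, dst)
        return float(sum(self.body.geodesic(*self.pos(a), *self.pos(b))
                         for a, b in zip(path[:-1], path[1:])))

    def subtree_nodes(self, node: int) -> set[int]:
        return {node} | nx.descendants(self.g, node)

    # -- validation -------------------------------------------------------
    def validate(self) -> None:
        """Check the single-root tree invariants; raise StructuralError."""
        if self.g.number_of_nodes() == 0:
            raise StructuralError("empty arbor")
        roots = [n for n in self.g if self.g.in_degree(n) == 0]
        if len(roots) != 1:
            raise StructuralError(f"expected one root, found {len(roots)}")
        if any(self.g.in_degree(n) > 1 for n in self.g):
            raise StructuralError("node with multiple parents")
        if not nx.is_weakly_connected(self.g):
            raise StructuralError("arbor is not connected")
        if not nx.is_directed_acyclic_graph(self.g):
            raise StructuralError("arbor contains a cycle")
        for n in self.g:
            s = self.s(n)
            if not (0.0 <= s <= self.body.length_um):
                raise GeometryError(
                    f"node {n} axial position {s:.3f} outside body [0, "
                    f"{self.body.length_um}]")

    def rotated(self, dtheta: float) -> "ArborGraph":
        """Copy with every node (and the body reference frame) rotated."""
        g = self.g.copy()
        for n in g.nodes:
            g.nodes[n]["theta"] = wrap_theta(g.nodes[n]["theta"] + dtheta)
        body = WormBody(self.body.length_um, self.body.radius_um,
                        self.body.soma_s_um, self.body.mouth_s_um,
                        wrap_theta(self.body.dv_reference_theta + dtheta))
        return ArborGraph(body, g)

    def relabeled(self, mapping: dict[int, int]) -> "ArborGraph":
        """Copy with node ids remapped (edge order labels preserved)."""
        return ArborGraph(self.body, nx.relabel_nodes(self.g, mapping, copy=True))


@dataclass
class Menorah:
    """One candelabra-shaped repeat unit of the PVD arbor.

    A menorah is a 2' stem attached to the primary dendrite, the 3' base
    branches the stem extends along the sublateral line, and the 4' candles
    standing on that base.  Stems without any 3' base are not menorahs.
    """

    stem_edges: list[Edge]
    base_edges: list[Edge]
    candle_edges: list[Edge]
    side: str  # "dorsal" | "ventral"
    attach_node: int  # node on the primary dendrite where the stem starts
    attach_s_um: float = field(default=float("nan"))

    @property
    def edges(self) -> list[Edge]:
        return self.stem_edges + self.base_edges + self.candle_edges
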