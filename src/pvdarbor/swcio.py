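"""SWC interchange for arbors on a cylindrical body surface.

SWC stores Cartesian coordinates, so the cylinder axis is laid along ``x``
(``x = s``) with ``y = r*cos(theta)``, ``z = r*sin(theta)``.  A small JSON
sidecar carries the :class:`~pvdarbor.core.WormBody` needed to interpret the
coordinates; by default it sits next to the SWC file as ``<stem>.body.json``.

Branch orders survive a round trip through the SWC *type* column:

====================  ====
label                 type
====================  ====
soma (node)              1
axon                     2
primary (1')             3
secondary (2')           4
tertiary (3')            5
quaternary (4')          6
trapped secondary        7
axon initial segment     8
unassigned               0
====================  ====

On read these codes are kept as *hints* (1 = soma, 2 = axon, 3 = dendrite in
vanilla SWC files); final labels are assigned by the classifier.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

from .core import ArborGraph, BranchOrder, GeometryError, StructuralError, WormBody

ORDER_TO_SWC = {
    BranchOrder.AXON: 2,
    BranchOrder.PRIMARY: 3,
    BranchOrder.SECONDARY: 4,
    BranchOrder.TERTIARY: 5,
    BranchOrder.QUATERNARY: 6,
    BranchOrder.TRAPPED_SECONDARY: 7,
    BranchOrder.AIS: 8,
    BranchOrder.UNASSIGNED: 0,
}
SWC_TO_ORDER = {v: k for k, v in ORDER_TO_SWC.items()}

SURFACE_TOLERANCE_FRAC = 0.02  # |dist_to_axis - r| <= 0.02 r on read
LABEL_MARKER = "pvdarbor-labels: order-coded type column"


def sidecar_path(swc_path: str | Path) -> Path:
    p = Path(swc_path)
    return p.with_suffix(".body.json") if p.suffix == ".swc" else Path(str(p) + ".body.json")


def write_body(body: WormBody, path: str | Path) -> None:
    Path(path).write_text(json.dumps(body.to_dict(), indent=2, sort_keys=True) + "\n")


def read_body(path: str | Path) -> WormBody:
    return WormBody.from_dict(json.loads(Path(path).read_text()))


def read_swc(path: str | Path,
             body_sidecar_path: str | Path | None = None) -> ArborGraph:
    """Read an SWC file plus its body sidecar into an :class:`ArborGraph`.

    Cartesian coordinates are projected onto the cylinder; a node whose
    distance to the axis deviates from ``r`` by more than 2% raises a
    :class:`GeometryError` naming the node.  Type codes are preserved as
    hints and, where they encode a full order mapping (labels written by
    :func:`write_swc` on a labeled graph), restored as edge labels.
    """
    path = Path(path)
    body = read_body(body_sidecar_path or sidecar_path(path))
    rows: list[tuple[int, int, float, float, float, float, int]] = []
    has_label_marker = False
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            if LABEL_MARKER in line:
                has_label_marker = True
            continue
        parts = line.split()
        if len(parts) != 7:
            raise StructuralError(f"{path}:{lineno}: expected 7 SWC columns")
        nid, typ, x, y, z, rad, parent = parts
        rows.append((int(nid), int(typ), float(x), float(y), float(z),
                     float(rad), int(parent)))

    graph = ArborGraph(body)
    seen: set[int] = set()
    r = body.radius_um
    for nid, typ, x, y, z, rad, parent in rows:
        axis_dist = math.hypot(y, z)
        if abs(axis_dist - r) > SURFACE_TOLERANCE_FRAC * r:
            raise GeometryError(
                f"node {nid} lies {axis_dist:.3f} um from the axis; body "
                f"radius is {r:.3f} um (tolerance {SURFACE_TOLERANCE_FRAC:.0%})")
        theta = math.atan2(z, y)
        pid = None if parent == -1 else parent
        if pid is not None and pid not in seen:
            raise StructuralError(
                f"node {nid} references parent {parent} not yet defined")
        graph.add_node(nid, s=x, theta=theta, parent=pid,
                       swc_hint=typ, radius=rad)
        seen.add(nid)
    graph.validate()

    # restore labels only for files that declare the order-coded type column;
    # vanilla SWC type codes (1/2/3) stay hints for the classifier
    if has_label_marker:
        for u, v in graph.edges():
            graph.set_order((u, v), SWC_TO_ORDER[graph.g.nodes[v]["swc_hint"]])
    return graph


def write_swc(graph: ArborGraph, path: str | Path,
              body_sidecar_path: str | Path | None = None) -> Path:
    """Write an arbor as SWC (preorder, children sorted by id) + sidecar.

    Deterministic: the same graph written twice yields byte-identical files.
    Labeled graphs store the order in the type column (see module docstring);
    unlabeled graphs fall back to the stored SWC hints.
    """
    path = Path(path)
    graph.validate()
    labeled = graph.is_labeled

    def node_type(node: int) -> int:
        if graph.parent(node) is None:
            return 1
        if labeled:
            return ORDER_TO_SWC[graph.order((graph.parent(node), node))]
        return graph.g.nodes[node].get("swc_hint", 3)

    lines = ["# SWC written by pvdarbor; cylinder axis along x",
             "# columns: id type x y z radius parent"]
    if labeled:
        lines.append(f"# {LABEL_MARKER}")
    r = graph.body.radius_um
    stack = [graph.root]
    while stack:
        n = stack.pop()
        s, theta = graph.pos(n)
        parent = graph.parent(n)
        lines.append("{} {} {:.9f} {:.9f} {:.9f} {:.3f} {}".format(
            n, node_type(n), s, r * math.cos(theta), r * math.sin(theta),
            graph.g.nodes[n].get("radius", 0.5), -1 if parent is None else parent))
        stack.extend(sorted(graph.children(n), reverse=True))
    path.write_text("\n".join(lines) + "\n")
    write_body(graph.body, body_sidecar_path or sidecar_path(path))
    return path
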