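"""Unrolling the cylindrical body surface and consolidated termini maps.

A surface point ``(s, theta)`` maps to the plane as ``u = s`` and
``v = r * wrap(theta - theta_lateral)``, the signed circumferential arc
distance from the lateral reference line (positive dorsal).  The cut seam
is antipodal to the lateral line, so the PVD arbor — which straddles the
lateral line — never wraps.  Unrolling is an isometry for paths that do not
cross the seam.

To consolidate worms of different sizes, termini scatter plots are scaled
to each worm's circumference: ``v`` is divided by ``C`` and ``u`` is
expressed in circumference units relative to the soma.  The dorsal and
ventral nerve cord annotation lines sit at +1/4 and -1/4, i.e. exactly half
a circumference apart.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import ArborGraph, BranchOrder, GeometryError, WormBody, wrap_angle

DORSAL_CORD_V = 0.25   # circumference-normalised annotation lines
VENTRAL_CORD_V = -0.25


@dataclass(frozen=True)
class UnrolledPoint:
    u_um: float
    v_um: float


def unroll_point(s: float, theta: float, body: WormBody) -> UnrolledPoint:
    """Map a surface point to the unrolled plane (v in (-pi r, pi r])."""
    if not 0.0 <= s <= body.length_um:
        raise GeometryError(f"s={s} outside [0, {body.length_um}]")
    return UnrolledPoint(u_um=s,
                         v_um=body.radius_um * wrap_angle(theta - body.lateral_theta))


def roll_point(p: UnrolledPoint, body: WormBody) -> tuple[float, float]:
    """Inverse of :func:`unroll_point`; recovers (s, theta) exactly."""
    if not 0.0 <= p.u_um <= body.length_um:
        raise GeometryError(f"u={p.u_um} outside [0, {body.length_um}]")
    return p.u_um, body.theta_at_arc(p.v_um)


@dataclass
class TerminiScatter:
    """Pooled, circumference-normalised 4' termini cloud.

    ``u_circ`` is anterior-posterior distance from each worm's soma in
    circumference units (negative = anterior); ``v_circ`` is the
    circumferential offset from the lateral line in circumference units,
    bounded by +-1/2.
    """

    worm_ids: np.ndarray
    u_circ: np.ndarray
    v_circ: np.ndarray
    dorsal_line_v: float = DORSAL_CORD_V
    ventral_line_v: float = VENTRAL_CORD_V
    u_extent_circ: float = 3.0

    @property
    def cord_separation(self) -> float:
        return self.dorsal_line_v - self.ventral_line_v

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame({"worm_id": self.worm_ids, "u_circ": self.u_circ,
                             "v_circ": self.v_circ})


def quaternary_termini(labeled: ArborGraph) -> list[tuple[float, float]]:
    """Surface coordinates (s, theta) of quaternary branch termini."""
    out = []
    for e in labeled.edges_of_order(BranchOrder.QUATERNARY):
        if not labeled.children(e[1]):
            out.append(labeled.pos(e[1]))
    return out


def make_termini_scatter(labeled_graphs: list[ArborGraph],
                         bodies: list[WormBody] | None = None,
                         u_extent_circ: float = 3.0) -> TerminiScatter:
    """Pool 4' termini across worms, scaled to each worm's circumference."""
    if bodies is None:
        bodies = [g.body for g in labeled_graphs]
    if len(bodies) != len(labeled_graphs):
        raise ValueError("need one body per graph")
    wids, us, vs = [], [], []
    for wid, (g, body) in enumerate(zip(labeled_graphs, bodies)):
        C = body.circumference_um
        for s, theta in quaternary_termini(g):
            p = unroll_point(s, theta, body)
            wids.append(wid)
            us.append((p.u_um - body.soma_s_um) / C)
            vs.append(p.v_um / C)
    if not us:
        import warnings
        warnings.warn("no quaternary termini found; scatter is empty")
    return TerminiScatter(worm_ids=np.asarray(wids, dtype=int),
                          u_circ=np.asarray(us, dtype=float),
                          v_circ=np.asarray(vs, dtype=float),
                          u_extent_circ=u_extent_circ)


def plot_termini_scatter(scatter: TerminiScatter, path=None, ax=None):
    """Publication-style scatter with the dorsal/ventral cord lines."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 2.5))
    ax.scatter(scatter.u_circ, scatter.v_circ, s=8, alpha=0.6,
               edgecolors="none")
    half = scatter.u_extent_circ / 2
    ax.axhline(scatter.dorsal_line_v, color="0.3", lw=1)
    ax.axhline(scatter.ventral_line_v, color="0.3", lw=1)
    ax.axhline(0.0, color="green", lw=1, alpha=0.5)
    ax.set_xlim(-half * 1.6, half * 0.4)
    ax.set_ylim(-0.5, 0.5)
    ax.set_xlabel("A-P position from soma (circumferences)")
    ax.set_ylabel("D-V arc (circumferences)")
    if path is not None:
        ax.figure.savefig(path, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
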