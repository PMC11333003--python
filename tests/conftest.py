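import math

import pytest

import pvdarbor as pa
from pvdarbor.core import ArborGraph, BranchOrder


@pytest.fixture(scope="session")
def body():
    return pa.DEFAULT_BODY


@pytest.fixture(scope="session")
def wt():
    """One wildtype-like arbor with its ground truth."""
    return pa.generate_arbor(pa.preset("wildtype_like", seed=7))


@pytest.fixture(scope="session")
def wt_labeled(wt):
    graph, _ = wt
    return pa.assign_orders(graph)


def build_hand_arbor(body):
    """A small arbor with exact coordinates and hand-enumerated labels.

    Three menorahs (two dorsal with one 3-um gap between their bases, one
    ventral), one trapped secondary, and an axon reaching the ventral cord.
    Returns (graph, expected_labels).
    """
    arc = body.theta_at_arc
    quarter = body.circumference_um / 4.0
    g = ArborGraph(body)
    O = BranchOrder
    exp = {}

    def add(nid, s, a, parent, order=None, hint=3):
        g.add_node(nid, s=s, theta=arc(a), parent=parent, swc_hint=hint)
        if order is not None:
            exp[(parent, nid)] = order
        return nid

    g.add_node(1, s=650.0, theta=arc(0.0), swc_hint=1)     # soma
    # primary anterior chain with attachment nodes
    add(2, 640.0, 0.0, 1, O.PRIMARY)    # dorsal menorah A
    add(3, 620.0, 0.0, 2, O.PRIMARY)    # trapped attachment
    add(4, 610.0, 0.0, 3, O.PRIMARY)    # dorsal menorah B
    add(5, 580.0, 0.0, 4, O.PRIMARY)    # ventral menorah C
    add(6, 560.0, 0.0, 5, O.PRIMARY)    # anterior end
    add(7, 680.0, 0.0, 1, O.PRIMARY)    # posterior end
    # menorah A (dorsal): stem, base [625, 652], candle at 630
    add(10, 640.0, 20.0, 2, O.SECONDARY)
    add(11, 630.0, 20.0, 10, O.TERTIARY)
    add(12, 625.0, 20.0, 11, O.TERTIARY)
    add(13, 652.0, 20.0, 10, O.TERTIARY)
    add(14, 630.0, quarter, 11, O.QUATERNARY)
    # menorah B (dorsal): base [598, 622] -> 3 um gap to A
    add(20, 610.0, 20.0, 4, O.SECONDARY)
    add(21, 598.0, 20.0, 20, O.TERTIARY)
    add(22, 622.0, 20.0, 20, O.TERTIARY)
    # menorah C (ventral): base [570, 590], candle at 585
    add(30, 580.0, -20.0, 5, O.SECONDARY)
    add(31, 570.0, -20.0, 30, O.TERTIARY)
    add(32, 585.0, -20.0, 30, O.TERTIARY)
    add(33, 590.0, -20.0, 32, O.TERTIARY)
    add(34, 585.0, -quarter, 32, O.QUATERNARY)
    # trapped secondary at 620: stub then axial run
    add(40, 620.0, 1.5, 3, O.TRAPPED_SECONDARY)
    add(41, 635.0, 1.5, 40, O.TRAPPED_SECONDARY)
    # axon: circumferential to the ventral cord, then axial
    add(50, 650.0, -19.0, 1, O.AIS, hint=2)
    add(51, 650.0, -quarter, 50, O.AXON, hint=2)
    add(52, 600.0, -quarter, 51, O.AXON, hint=2)
    g.validate()
    return g, exp


@pytest.fixture(scope="session")
def hand_arbor(body):
    return build_hand_arbor(body)
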