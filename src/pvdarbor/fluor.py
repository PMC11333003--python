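"""Photoconversion-recovery curves and dendritic mRNA-puncta statistics.

Recovery of green Kaede signal after photoconversion is normalised as
``(F_n - F_0) / (F_p - F_0)`` where ``F_0`` is the intensity immediately
after conversion, ``F_p`` the intensity right before it, and ``F_n`` the
intensity ``n`` seconds after.  A saturating exponential
``R(t) = r_inf * (1 - exp(-k t))`` summarises each curve with a rate
constant ``k`` (1/s) and a plateau ``r_inf``; cohorts are compared by
two-way ANOVA (group x time) on the raw fractions, with the fitted rates as
a secondary readout.

MS2-tagged mRNA puncta anchored to skeleton edges are summarised per
tertiary branch, and their spatial association with landmarks (branch
points, retracted contact points) is tested with a permutation null that
repositions puncta uniformly along edges of the same branch order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .core import ArborGraph, BranchOrder, Edge, wrap_angle


class DegenerateNormalizationError(ValueError):
    """F_p equals F_0; the recovery fraction is undefined."""


class FitError(RuntimeError):
    pass


@dataclass
class FluorTrace:
    """A raw photoconversion time series.

    ``f_0`` is the first post-conversion sample (t = 0); ``f_p`` the
    pre-conversion intensity (mean of pre-conversion samples if several).
    """

    t_s: np.ndarray
    f: np.ndarray
    f_p: float
    f_0: float

    def __post_init__(self) -> None:
        self.t_s = np.asarray(self.t_s, dtype=float)
        self.f = np.asarray(self.f, dtype=float)
        if self.t_s.size != self.f.size:
            raise ValueError("t_s and f must have equal length")
        if self.t_s.size == 0 or self.t_s[0] != 0.0 or np.any(np.diff(self.t_s) <= 0):
            raise ValueError("t_s must be strictly increasing and start at 0")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t_s": self.t_s, "F": self.f})


@dataclass
class RecoveryCurve:
    t_s: np.ndarray
    recovery_frac: np.ndarray
    fitted_k_per_s: float | None = None
    fitted_r_inf: float | None = None
    fit_rmse: float | None = None


def recovery_fraction(trace: FluorTrace) -> RecoveryCurve:
    """Normalise a trace to recovery fractions ``(F_n - F_0)/(F_p - F_0)``.

    Values are not clipped: noise may push individual samples below 0 or
    above 1.  The fraction at t = 0 is exactly 0 by construction.
    """
    denom = trace.f_p - trace.f_0
    if denom == 0:
        raise DegenerateNormalizationError("F_p == F_0: zero dynamic range")
    return RecoveryCurve(t_s=trace.t_s.copy(),
                         recovery_frac=(trace.f - trace.f_0) / denom)


def fit_recovery(curve: RecoveryCurve) -> tuple[float, float, float]:
    """Least-squares fit of ``R(t) = r_inf (1 - exp(-k t))``; returns (k, r_inf, rmse).

    Both parameters are constrained non-negative.  A flat all-zero curve
    fits exactly with ``r_inf = 0``.  The fitted values are also stored on
    the curve.
    """
    t = np.asarray(curve.t_s, float)
    y = np.asarray(curve.recovery_frac, float)
    if t.size < 10:
        raise FitError("need at least 10 samples to fit a recovery curve")

    def model(tt, k, r_inf):
        return r_inf * (1.0 - np.exp(-k * tt))

    if np.allclose(y, 0.0):
        k_hat, r_hat = 0.0, 0.0
    else:
        r0 = max(float(np.mean(y[-max(3, t.size // 10):])), 1e-6)
        # crude half-rise initialisation for the rate
        half_idx = int(np.argmax(y >= 0.5 * r0))
        k0 = math.log(2.0) / t[half_idx] if half_idx > 0 else 1.0 / t[-1]
        try:
            popt, _ = curve_fit(model, t, y, p0=[k0, r0],
                                bounds=([0.0, 0.0], [np.inf, np.inf]),
                                maxfev=20000)
        except RuntimeError as err:  # pragma: no cover - pathological input
            raise FitError(f"recovery fit did not converge: {err}") from err
        k_hat, r_hat = float(popt[0]), float(popt[1])
    rmse = float(np.sqrt(np.mean((model(t, k_hat, r_hat) - y) ** 2)))
    curve.fitted_k_per_s, curve.fitted_r_inf, curve.fit_rmse = k_hat, r_hat, rmse
    return k_hat, r_hat, rmse


def compare_recovery(cohort_a: list[RecoveryCurve],
                     cohort_b: list[RecoveryCurve],
                     labels: tuple[str, str] = ("A", "B")) -> dict:
    """Two-way ANOVA (group x time) on recovery fractions of two cohorts.

    Requires a common time grid.  Also reports a two-sample t-test on the
    fitted rate constants as a secondary readout.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf
    from scipy import stats as sps

    if len(cohort_a) < 2 or len(cohort_b) < 2:
        raise ValueError("need at least 2 curves per cohort")
    grid = cohort_a[0].t_s
    for c in cohort_a + cohort_b:
        if c.t_s.shape != grid.shape or not np.allclose(c.t_s, grid):
            raise ValueError("curves are not on a common time grid")

    rows = []
    for lab, cohort in zip(labels, (cohort_a, cohort_b)):
        for i, c in enumerate(cohort):
            for t, y in zip(c.t_s, c.recovery_frac):
                rows.append((lab, i, t, y))
    df = pd.DataFrame(rows, columns=["group", "curve", "t", "y"])
    # repeated-measures layout: samples within a curve are correlated (they
    # share the curve's F_0 and F_p), so the group effect is tested against
    # the between-curve mean square, not the sample residual
    fit = smf.ols("y ~ C(group) + C(group):C(curve) + C(t)", data=df).fit()
    table = sm.stats.anova_lm(fit, typ=2)
    ms_group = table.loc["C(group)", "sum_sq"] / table.loc["C(group)", "df"]
    ms_curve = (table.loc["C(group):C(curve)", "sum_sq"]
                / table.loc["C(group):C(curve)", "df"])
    f_group = float(ms_group / ms_curve)
    p_group = float(sps.f.sf(f_group, table.loc["C(group)", "df"],
                             table.loc["C(group):C(curve)", "df"]))
    ks = []
    for cohort in (cohort_a, cohort_b):
        kk = []
        for c in cohort:
            if c.fitted_k_per_s is None:
                fit_recovery(c)
            kk.append(c.fitted_k_per_s)
        ks.append(np.array(kk))
    t_stat, t_p = sps.ttest_ind(ks[0], ks[1])
    return {
        "group_F": f_group,
        "group_p": p_group,
        "time_F": float(table.loc["C(t)", "F"]),
        "time_p": float(table.loc["C(t)", "PR(>F)"]),
        "k_mean": (float(ks[0].mean()), float(ks[1].mean())),
        "k_t_stat": float(t_stat),
        "k_t_p": float(t_p),
        "anova_table": table,
    }


# ---------------------------------------------------------------------------
# puncta
# ---------------------------------------------------------------------------

@dataclass
class Punctum:
    punctum_id: int
    edge: Edge
    offset_um: float  # distance from the edge's parent endpoint
    order: BranchOrder


@dataclass
class PunctaSet:
    """Point events anchored to skeleton edges."""

    puncta: list[Punctum]
    landmarks: list[tuple[float, float, str]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.puncta)

    def counts_by_order(self) -> dict[BranchOrder, int]:
        out: dict[BranchOrder, int] = {}
        for p in self.puncta:
            out[p.order] = out.get(p.order, 0) + 1
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(p.punctum_id, f"{p.edge[0]}-{p.edge[1]}", p.offset_um,
              p.order.value) for p in self.puncta],
            columns=["punctum_id", "edge_id", "offset_um", "order"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PunctaSet":
        puncta = []
        for _, row in df.iterrows():
            u, v = (int(x) for x in str(row["edge_id"]).split("-"))
            puncta.append(Punctum(int(row["punctum_id"]), (u, v),
                                  float(row["offset_um"]),
                                  BranchOrder(str(row["order"]))))
        return cls(puncta=puncta)


def puncta_positions(graph: ArborGraph, puncta: list[Punctum]) -> np.ndarray:
    """Surface coordinates (s, theta) of puncta by interpolation along edges."""
    out = np.empty((len(puncta), 2))
    for i, p in enumerate(puncta):
        su, tu = graph.pos(p.edge[0])
        sv, tv = graph.pos(p.edge[1])
        L = graph.edge_length(p.edge)
        frac = 0.0 if L == 0 else min(max(p.offset_um / L, 0.0), 1.0)
        out[i, 0] = su + frac * (sv - su)
        out[i, 1] = tu + frac * wrap_angle(tv - tu)
    return out


def tertiary_branch_count(labeled_graph: ArborGraph) -> int:
    """Number of distinct 3' branches (maximal connected runs of 3' edges)."""
    import networkx as nx
    tert = labeled_graph.edges_of_order(BranchOrder.TERTIARY)
    if not tert:
        return 0
    sub = nx.Graph()
    sub.add_edges_from(tert)
    return nx.number_connected_components(sub)


def puncta_stats(puncta: PunctaSet, labeled_graph: ArborGraph) -> dict:
    """Per-neuron tertiary-dendrite puncta summary.

    Returns the mean punctum count per 3' branch and whether the neuron has
    any 3' punctum (the cohort-level percentage aggregates the booleans).
    """
    n3 = tertiary_branch_count(labeled_graph)
    c3 = sum(1 for p in puncta.puncta if p.order is BranchOrder.TERTIARY)
    return {
        "n_tertiary_branches": n3,
        "n_tertiary_puncta": c3,
        "mean_per_tertiary": (c3 / n3) if n3 else 0.0,
        "has_tertiary_puncta": c3 > 0,
    }


def landmark_enrichment_test(puncta: PunctaSet,
                             landmarks: list[tuple[float, float, str]],
                             labeled_graph: ArborGraph,
                             capture_radius_um: float = 2.0,
                             n_perm: int = 999,
                             seed: int = 0) -> tuple[float, float]:
    """Permutation test of puncta enrichment near landmarks.

    Observed statistic: fraction of puncta within ``capture_radius_um``
    (cylinder geodesic) of any landmark.  Null: puncta repositioned
    uniformly along edges of the same branch order (per-order counts
    preserved), ``n_perm`` times.  Returns ``(observed_fraction, p)`` with
    ``p = (1 + #{null >= observed}) / (n_perm + 1)``.
    """
    if not puncta.puncta:
        raise ValueError("no puncta to test")
    if not landmarks:
        raise ValueError("no landmarks to test against")
    body = labeled_graph.body
    lm = np.array([[s, th] for s, th, _ in landmarks])

    def near_fraction(pos: np.ndarray) -> float:
        ds = pos[:, 0:1] - lm[None, :, 0]
        dth = (pos[:, 1:2] - lm[None, :, 1] + math.pi) % (2 * math.pi) - math.pi
        d = np.sqrt(ds ** 2 + (body.radius_um * dth) ** 2)
        return float(np.mean(d.min(axis=1) <= capture_radius_um))

    observed = near_fraction(puncta_positions(labeled_graph, puncta.puncta))

    # per-order edge inventories with cumulative lengths
    by_order: dict[BranchOrder, int] = {}
    for p in puncta.puncta:
        by_order[p.order] = by_order.get(p.order, 0) + 1
    rng = np.random.default_rng([int(seed) & 0x7FFFFFFF, 13])
    exceed = np.zeros(n_perm, dtype=int)
    null_parts: dict[BranchOrder, np.ndarray] = {}
    for order, n_o in by_order.items():
        edges = labeled_graph.edges_of_order(order)
        lens = np.array([labeled_graph.edge_length(e) for e in edges])
        total = lens.sum()
        if total <= 0:
            raise ValueError(f"zero total dendrite length for order {order}")
        cum = np.concatenate([[0.0], np.cumsum(lens)])
        u = rng.uniform(0.0, total, size=(n_perm, n_o))
        idx = np.clip(np.searchsorted(cum, u, side="right") - 1, 0, len(edges) - 1)
        offs = u - cum[idx]
        frac = offs / lens[idx]
        su = np.array([labeled_graph.s(e[0]) for e in edges])
        sv = np.array([labeled_graph.s(e[1]) for e in edges])
        tu = np.array([labeled_graph.theta(e[0]) for e in edges])
        tv = np.array([labeled_graph.theta(e[1]) for e in edges])
        dth = (tv - tu + math.pi) % (2 * math.pi) - math.pi
        ps = su[idx] + frac * (sv[idx] - su[idx])
        pt = tu[idx] + frac * dth[idx]
        null_parts[order] = np.stack([ps, pt], axis=-1)
    n_total = len(puncta.puncta)
    for j in range(n_perm):
        pos = np.concatenate([null_parts[o][j] for o in null_parts], axis=0)
        assert pos.shape[0] == n_total
        if near_fraction(pos) >= observed:
            exceed[j] = 1
    p_value = (1 + int(exceed.sum())) / (n_perm + 1)
    return observed, p_value
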