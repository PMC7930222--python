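"""Linear causal effects, mediation and information-transfer measures.

Given a discovered lag-specific link graph, this module

* fits the *path coefficients* Phi(tau): for each target, one joint least
  squares regression of the target on all of its discovered parents, on
  standardized data (coefficients per standard deviation);
* accumulates the *causal effect* (CE) over all directed paths with the
  impulse-response recursion

      Psi(0) = I,   Psi(tau) = sum_{s=1}^{tau} Phi(s) Psi(tau - s),

  so ``Psi[j, i, tau]`` is the effect on component j at lag tau of a unit
  perturbation of component i — direct and indirect paths together (equal,
  by construction, to the noiseless unit-impulse response of the fitted
  linear system);
* computes the *mediated causal effect* (MCE) through a component k by
  re-running the recursion with every link INTO k removed (Phi^(k)), which
  blocks all paths through k at any lag:  MCE_k = Psi - Psi^(k);
* aggregates over the lag of maximum effect: CE^max per ordered pair, and
  per node the aggregate causal effect (ACE, mean outgoing CE^max),
  aggregate causal susceptibility (ACS, mean incoming CE^max), and average
  mediated causal effect (AMCE, mean |MCE| over the pairs that have some
  causal path through the node);
* extracts *mediation subgraphs*: the nodes and links of the time-series
  graph lying on at least one directed path between a chosen lagged pair;
* estimates *decomposed transfer entropy* (DTE): transfer entropy written
  as a sum of per-lag conditional mutual informations whose condition sets
  are read off the graph (the target's parents plus the shifted parents of
  the lagged driver), escaping the curse of dimensionality of the full
  past.

Sign is preserved throughout: a negative CE means the source counteracts
the effects of other components on the target.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .citest import CMIKnn
from .graph import TimeSeriesGraph, write_dot
from .io import ROITimeSeries

__all__ = [
    "PathCoefficients",
    "CausalEffectMatrices",
    "AggregateMeasures",
    "MediationResult",
    "CausalEffectAnalysis",
    "fit_path_coefficients",
    "causal_effect_matrices",
    "mediated_causal_effect",
    "all_mediated_effects",
    "aggregate_measures",
    "mediation_graph",
    "decomposed_transfer_entropy",
]


@dataclass
class PathCoefficients:
    """Lag-specific direct link coefficients Phi.

    ``phi[j, i, tau]`` is the coefficient of X^i_{t-tau} in the linear
    model of X^j_t on its discovered parents; exactly zero where the graph
    has no link, and zero everywhere at lag 0.
    """

    phi: np.ndarray  # (N, N, tau_max + 1)
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.phi = np.asarray(self.phi, dtype=float)
        if np.any(self.phi[:, :, 0] != 0):
            raise ValueError("contemporaneous (lag 0) coefficients must be zero")

    @property
    def n_vars(self) -> int:
        return self.phi.shape[0]

    @property
    def tau_max(self) -> int:
        return self.phi.shape[2] - 1


@dataclass
class CausalEffectMatrices:
    """Accumulated direct + indirect effects Psi per lag.

    ``psi[j, i, tau]`` is the causal effect of a unit perturbation of i on
    j after tau steps; ``psi[:, :, 0]`` is the identity.
    """

    psi: np.ndarray  # (N, N, tau_max + 1)
    labels: list[str] = field(default_factory=list)

    @property
    def tau_max(self) -> int:
        return self.psi.shape[2] - 1

    def ce(self, i: int, j: int, tau: int) -> float:
        """CE of source i on target j at lag tau."""
        return float(self.psi[j, i, tau])

    def ce_max(self) -> np.ndarray:
        """Max over lags 1..tau_max of |CE|, indexed [target, source]."""
        return np.abs(self.psi[:, :, 1:]).max(axis=2)

    def to_frame(self) -> pd.DataFrame:
        n = self.psi.shape[0]
        labels = self.labels or [f"X{i + 1}" for i in range(n)]
        rows = [
            (labels[i], labels[j], tau, self.psi[j, i, tau])
            for i in range(n)
            for j in range(n)
            for tau in range(1, self.tau_max + 1)
        ]
        return pd.DataFrame(rows, columns=["source", "target", "lag", "ce"])


@dataclass
class AggregateMeasures:
    """Per-pair and per-node summaries on the lag of maximum effect."""

    ce_max: np.ndarray  # (N, N), [target, source]
    ace: np.ndarray  # (N,) outgoing influence
    acs: np.ndarray  # (N,) susceptibility
    amce: np.ndarray  # (N,) mediation strength
    c_k_cardinality: np.ndarray  # (N,) number of pairs mediated by each node
    labels: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        n = len(self.ace)
        labels = self.labels or [f"X{i + 1}" for i in range(n)]
        return pd.DataFrame(
            {
                "roi": labels,
                "ace": self.ace,
                "acs": self.acs,
                "amce": self.amce,
                "n_mediated_pairs": self.c_k_cardinality,
            }
        )


def fit_path_coefficients(
    series: ROITimeSeries, graph: TimeSeriesGraph
) -> PathCoefficients:
    """One joint least-squares regression per target on its discovered parents.

    The series should be standardized (the pipeline does this by default)
    so coefficients are comparable across components.  Joint — not pairwise
    — regression is required for path-coefficient semantics: each
    coefficient is the direct effect holding the other parents fixed.
    """
    X = series.values
    T, N = X.shape
    L = graph.tau_max
    start = L
    phi = np.zeros((N, N, L + 1))
    for j in range(N):
        parents = graph.parents_of(j)
        if not parents:
            continue
        y = X[start:, j]
        A = np.column_stack(
            [np.ones(T - start)]
            + [X[start - tau : T - tau, i] for i, tau in parents]
        )
        coef, _, rank, _ = np.linalg.lstsq(A, y, rcond=None)
        if rank < A.shape[1]:
            names = [
                f"{graph.labels[i]}(lag {tau})" for i, tau in parents
            ]
            raise ValueError(
                f"collinear parent design for target {graph.labels[j]}: {names}"
            )
        for (i, tau), c in zip(parents, coef[1:]):
            phi[j, i, tau] = c
    return PathCoefficients(phi, list(graph.labels))


def _psi_recursion(phi: np.ndarray) -> np.ndarray:
    n, _, lp1 = phi.shape
    psi = np.zeros_like(phi)
    psi[:, :, 0] = np.eye(n)
    for tau in range(1, lp1):
        acc = np.zeros((n, n))
        for s in range(1, tau + 1):
            acc += phi[:, :, s] @ psi[:, :, tau - s]
        psi[:, :, tau] = acc
    return psi


def causal_effect_matrices(
    phi: PathCoefficients | np.ndarray, tau_max: int | None = None
) -> CausalEffectMatrices:
    """Accumulate CE over all directed paths via the impulse-response recursion.

    ``tau_max`` extends the horizon beyond the largest link lag when given
    (indirect paths can be longer than any single link).
    """
    labels = phi.labels if isinstance(phi, PathCoefficients) else []
    arr = phi.phi if isinstance(phi, PathCoefficients) else np.asarray(phi, dtype=float)
    if tau_max is not None and tau_max + 1 > arr.shape[2]:
        pad = np.zeros((arr.shape[0], arr.shape[1], tau_max + 1 - arr.shape[2]))
        arr = np.concatenate([arr, pad], axis=2)
    return CausalEffectMatrices(_psi_recursion(arr), labels)


def mediated_causal_effect(
    phi: PathCoefficients | np.ndarray, k: int, tau_max: int | None = None
) -> tuple[CausalEffectMatrices, np.ndarray]:
    """Blocked effects and MCE through component k.

    Returns ``(psi_blocked, mce)`` where ``psi_blocked`` comes from the
    recursion on Phi with every coefficient whose target is k set to zero,
    and ``mce[j, i, tau] = psi[j, i, tau] - psi_blocked[j, i, tau]`` is the
    part of the effect of i on j carried by paths through k.
    """
    labels = phi.labels if isinstance(phi, PathCoefficients) else []
    arr = phi.phi if isinstance(phi, PathCoefficients) else np.asarray(phi, dtype=float)
    if not 0 <= k < arr.shape[0]:
        raise ValueError(f"mediator index {k} out of range")
    full = causal_effect_matrices(arr, tau_max)
    blocked_phi = arr.copy()
    blocked_phi[k, :, :] = 0.0  # remove every link into k -> no path crosses k
    blocked = causal_effect_matrices(blocked_phi, tau_max)
    blocked.labels = labels
    return blocked, full.psi - blocked.psi


def all_mediated_effects(
    phi: PathCoefficients | np.ndarray, tau_max: int | None = None
) -> np.ndarray:
    """MCE for every mediator: array ``[k, j, i, tau]``."""
    arr = phi.phi if isinstance(phi, PathCoefficients) else np.asarray(phi, dtype=float)
    n = arr.shape[0]
    out = [mediated_causal_effect(arr, k, tau_max)[1] for k in range(n)]
    return np.stack(out, axis=0)


def _path_reachability(phi: np.ndarray) -> np.ndarray:
    """Boolean ``reach[j, i, tau]``: a directed path i -> j of total lag tau exists."""
    adj = (phi != 0).astype(float)
    n, _, lp1 = adj.shape
    reach = np.zeros_like(adj)
    reach[:, :, 0] = np.eye(n)
    for tau in range(1, lp1):
        acc = np.zeros((n, n))
        for s in range(1, tau + 1):
            acc += adj[:, :, s] @ reach[:, :, tau - s]
        reach[:, :, tau] = acc
    return reach > 0


def aggregate_measures(
    phi: PathCoefficients | np.ndarray, tau_max: int | None = None
) -> AggregateMeasures:
    """CE^max, ACE, ACS and AMCE from the path coefficients.

    ``ce_max[j, i] = max_{0 < tau <= tau_max} |CE_{i->j}(tau)|``;
    ``ace[i]`` averages ``ce_max`` over targets j != i, ``acs[j]`` over
    sources i != j.  ``amce[k]`` averages ``max_tau |MCE through k|`` over
    the set C_k of ordered pairs (i, j), i, j != k, that have at least one
    causal path through k within the horizon (pairs with no such path are
    excluded from the average; AMCE is 0 when C_k is empty).
    """
    labels = phi.labels if isinstance(phi, PathCoefficients) else []
    arr = phi.phi if isinstance(phi, PathCoefficients) else np.asarray(phi, dtype=float)
    n = arr.shape[0]
    if n < 2:
        raise ValueError("aggregate measures need at least 2 components")
    psi = causal_effect_matrices(arr, tau_max)
    L = psi.tau_max
    ce_max = psi.ce_max()
    off = ~np.eye(n, dtype=bool)
    ace = np.array([ce_max[:, i][off[:, i]].mean() for i in range(n)])
    acs = np.array([ce_max[j, :][off[j, :]].mean() for j in range(n)])
    reach = _path_reachability(
        np.concatenate(
            [arr, np.zeros((n, n, L + 1 - arr.shape[2]))], axis=2
        ) if arr.shape[2] < L + 1 else arr
    )
    mce_all = all_mediated_effects(arr, L)
    amce = np.zeros(n)
    card = np.zeros(n, dtype=int)
    for k in range(n):
        # i -> k at lag t1 >= 1 and k -> j at lag t2 >= 1 with t1 + t2 <= L
        to_k = reach[k, :, 1:]  # (n, L): to_k[i, t1-1]
        from_k = reach[:, k, 1:]  # (n, L): from_k[j, t2-1]
        vals = []
        for i in range(n):
            if i == k:
                continue
            t1s = np.flatnonzero(to_k[i]) + 1
            if t1s.size == 0:
                continue
            t1_min = int(t1s.min())
            for j in range(n):
                if j == k or j == i:
                    continue
                t2s = np.flatnonzero(from_k[j]) + 1
                if t2s.size and t1_min + int(t2s.min()) <= L:
                    vals.append(np.abs(mce_all[k, j, i, 1:]).max())
        card[k] = len(vals)
        amce[k] = float(np.mean(vals)) if vals else 0.0
    return AggregateMeasures(ce_max, ace, acs, amce, card, labels)


@dataclass
class MediationResult:
    """Causal paths between one lagged pair, with per-mediator effects.

    ``ts_graph`` is the time-resolved subgraph (nodes ``"ROI@t-s"``) of all
    links on at least one directed path from the source at t - lag to the
    target at t; ``summary_graph`` collapses time.  ``mce`` maps each
    intermediate component label to its mediated effect for this pair and
    lag.
    """

    source: str
    target: str
    lag: int
    total_ce: float
    mce: dict[str, float]
    ts_graph: nx.DiGraph
    summary_graph: nx.DiGraph

    @property
    def is_empty(self) -> bool:
        return self.ts_graph.number_of_edges() == 0

    def write_graphml(self, path, time_resolved: bool = True) -> None:
        nx.write_graphml(self.ts_graph if time_resolved else self.summary_graph, path)

    def write_dot(self, path, time_resolved: bool = True) -> None:
        write_dot(self.ts_graph if time_resolved else self.summary_graph, path)


def mediation_graph(
    graph: TimeSeriesGraph,
    phi: PathCoefficients,
    i: int,
    j: int,
    tau: int,
    mce_all: np.ndarray | None = None,
) -> MediationResult:
    """Subgraph of links on directed paths from X^i_{t-tau} to X^j_t.

    Nodes are annotated with their MCE for the pair (zero for the
    endpoints); edges carry the fitted link coefficient.  An empty result
    (no connecting path) is returned as such, not as an error.
    """
    n = phi.n_vars
    if not (0 <= i < n and 0 <= j < n and 1 <= tau):
        raise ValueError("invalid (source, target, lag) query")
    labels = graph.labels
    psi = causal_effect_matrices(phi, tau)
    if mce_all is None:
        mce_all = all_mediated_effects(phi, tau)
    arr = phi.phi
    G = nx.DiGraph()
    for a, b, lag in zip(*np.nonzero(arr)):
        # link source b at lag `lag` into target a; place at all offsets
        for off_b in range(tau - lag + 1):
            G.add_edge(
                (int(b), int(off_b + lag)), (int(a), int(off_b)),
                coefficient=float(arr[a, b, lag]), lag=int(lag),
            )
    src, tgt = (i, tau), (j, 0)
    nodes: set = set()
    if G.has_node(src) and G.has_node(tgt):
        desc = nx.descendants(G, src) | {src}
        anc = nx.ancestors(G, tgt) | {tgt}
        nodes = desc & anc
    sub = G.subgraph(nodes).copy() if len(nodes) >= 2 else nx.DiGraph()
    mce = {
        labels[k]: float(mce_all[k, j, i, tau])
        for k in sorted({v for v, _ in sub.nodes})
        if k not in (i, j)
    }
    ts = nx.DiGraph()
    for (v, off) in sub.nodes:
        name = f"{labels[v]}@t-{off}" if off else f"{labels[v]}@t"
        ts.add_node(name, var=labels[v], offset=off,
                    mce=mce.get(labels[v], 0.0))
    for (u, uo), (v, vo), attrs in sub.edges(data=True):
        un = f"{labels[u]}@t-{uo}" if uo else f"{labels[u]}@t"
        vn = f"{labels[v]}@t-{vo}" if vo else f"{labels[v]}@t"
        ts.add_edge(un, vn, **attrs)
    summary = nx.DiGraph()
    for (v, _off) in sub.nodes:
        summary.add_node(labels[v], mce=mce.get(labels[v], 0.0))
    for (u, _), (v, _), attrs in sub.edges(data=True):
        if summary.has_edge(labels[u], labels[v]):
            e = summary[labels[u]][labels[v]]
            e["lags"] = e["lags"] + f",{attrs['lag']}"
        else:
            summary.add_edge(
                labels[u], labels[v],
                coefficient=attrs["coefficient"], lags=str(attrs["lag"]),
            )
    return MediationResult(
        source=labels[i],
        target=labels[j],
        lag=tau,
        total_ce=psi.ce(i, j, tau),
        mce=mce,
        ts_graph=ts,
        summary_graph=summary,
    )


def decomposed_transfer_entropy(
    series: ROITimeSeries,
    graph: TimeSeriesGraph,
    i: int,
    j: int,
    tau_star: int | None = None,
    knn: CMIKnn | None = None,
    max_conds: int | None = None,
) -> tuple[float, np.ndarray]:
    """Transfer entropy i -> j decomposed into per-lag CMI terms (nats).

    Each lag term I(X^i_{t-tau}; X^j_t | S) uses the graph-derived
    condition set S = parents(j) minus the tested link, plus the parents of
    i shifted by tau — a finite sufficient subset of the infinite past.
    Returns ``(sum of terms, per-lag terms for tau = 1..tau_star)``.
    """
    if tau_star is None:
        tau_star = graph.tau_max
    if tau_star > graph.tau_max:
        raise ValueError("tau_star cannot exceed the graph's tau_max")
    knn = knn or CMIKnn()
    X = series.values
    T = X.shape[0]
    start = graph.tau_max + tau_star
    n_eff = T - start
    terms = np.zeros(tau_star)
    pj = graph.parents_of(j)
    pi = graph.parents_of(i)
    for tau in range(1, tau_star + 1):
        conds = [c for c in pj if c != (i, tau)]
        for m, s in pi:
            c = (m, s + tau)
            if c != (i, tau) and c not in conds:
                conds.append(c)
        if max_conds is not None and len(conds) > max_conds:
            conds = conds[:max_conds]
        if n_eff < len(conds) + knn.k + 2:
            raise ValueError(
                f"condition dimension {len(conds)} infeasible for n_eff={n_eff}; "
                "reduce the condition set with max_conds"
            )
        y = X[start:, j]
        xlag = X[start - tau : T - tau, i]
        Z = (
            np.column_stack([X[start - l : T - l, m] for m, l in conds])
            if conds
            else None
        )
        terms[tau - 1] = knn.estimate(xlag, y, Z)
    return float(terms.sum()), terms


class CausalEffectAnalysis(BaseEstimator):
    """Causal-effect and mediation estimator over a discovered graph.

    ``fit(series, graph)`` fits the path coefficients and derives all
    effect measures.

    Attributes
    ----------
    phi_ : PathCoefficients
    psi_ : CausalEffectMatrices
    ce_max_ : ndarray (N, N), [target, source]
    ace_, acs_, amce_ : ndarray (N,)
    mce_ : ndarray (N, N, N, tau_max + 1), [mediator, target, source, lag]
    """

    def __init__(self, tau_max: int | None = None):
        self.tau_max = tau_max

    def fit(self, X, graph: TimeSeriesGraph):
        series = X if isinstance(X, ROITimeSeries) else ROITimeSeries(
            np.asarray(X, dtype=float),
            list(graph.labels),
        )
        L = self.tau_max if self.tau_max is not None else graph.tau_max
        self.phi_ = fit_path_coefficients(series, graph)
        self.psi_ = causal_effect_matrices(self.phi_, L)
        self.mce_ = all_mediated_effects(self.phi_, L)
        agg = aggregate_measures(self.phi_, L)
        self.ce_max_ = agg.ce_max
        self.ace_ = agg.ace
        self.acs_ = agg.acs
        self.amce_ = agg.amce
        self.aggregates_ = agg
        self.labels_ = list(graph.labels)
        return self

    def mediation(self, graph: TimeSeriesGraph, i: int, j: int, tau: int) -> MediationResult:
        return mediation_graph(graph, self.phi_, i, j, tau, self.mce_)
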