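"""Two-stage time-lagged causal discovery (PCMCI).

Stage 1 (*parent pre-selection*, a PC-style condition-selection phase):
for each target, start from every lagged component as a candidate parent
and iteratively remove candidates that test conditionally independent of
the target given the ``q`` strongest remaining candidates, for condition
cardinality ``q = 0, 1, 2, ...`` — the PC1 variant with one condition set
per cardinality, keeping the test count polynomial.

Stage 2 (*momentary conditional independence*, MCI): every ordered pair
``(i, j)`` at every lag ``tau = 1..tau_max`` is tested conditional on the
pre-selected parents of the target **and** the time-shifted parents of the
lagged driver.  Conditioning on the driver's own parents is what controls
the false-positive inflation that autocorrelated series otherwise cause.

Retained links are those with raw ``p <= alpha``; alpha acts as a
regularization/model-selection parameter rather than a calibrated error
rate (optional Benjamini-Hochberg correction available).  Lag-0 links are
never tested: contemporaneous effects are excluded by assumption.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

from .citest import make_ci_test
from .graph import TimeSeriesGraph
from .io import ROITimeSeries, preprocess

__all__ = [
    "ParentSets",
    "PCMCI",
    "pc1_parent_selection",
    "mci_link_test",
    "run_pcmci",
    "count_ci_tests",
]


@dataclass
class ParentSets:
    """Per-target ordered candidate parents from the pre-selection phase.

    ``parents[j]`` lists ``(source, lag)`` pairs ordered by descending
    selection statistic; ``statistic[j][(source, lag)]`` holds the minimum
    absolute test statistic seen for that candidate across iterations.
    """

    parents: dict[int, list[tuple[int, int]]]
    statistic: dict[int, dict[tuple[int, int], float]]
    n_tests: int = 0

    def for_target(self, j: int) -> list[tuple[int, int]]:
        return list(self.parents[j])

    def total_parents(self) -> int:
        return sum(len(p) for p in self.parents.values())


def count_ci_tests(N: int, tau_max: int) -> tuple[int, int, int]:
    """Worst-case CI-test counts: (condition-selection, MCI, total).

    The condition-selection phase needs at most ``N^3 tau_max^2`` tests (a
    complete graph tested at iteratively increasing condition cardinality);
    the MCI phase always runs ``N^2 tau_max`` tests.  Any actual run's
    counters must not exceed these.
    """
    if N < 1 or tau_max < 1:
        raise ValueError("need N >= 1 and tau_max >= 1")
    pc = N**3 * tau_max**2
    mci = N**2 * tau_max
    return pc, mci, pc + mci


def _lagged_column(X: np.ndarray, var: int, lag: int, start: int) -> np.ndarray:
    """Values of component ``var`` at time t - lag, for t = start..T-1."""
    T = X.shape[0]
    return X[start - lag : T - lag, var]


def _cond_matrix(X: np.ndarray, conds, start: int) -> np.ndarray | None:
    if not conds:
        return None
    return np.column_stack([_lagged_column(X, v, l, start) for v, l in conds])


def pc1_parent_selection(
    series: ROITimeSeries,
    test=None,
    tau_max: int = 15,
    pc_alpha: float = 0.01,
    max_conds: int | None = None,
) -> ParentSets:
    """PC1 parent pre-selection for every target component.

    Candidates are removed as soon as a test conditioned on the ``q``
    strongest remaining candidates (q increasing from 0) gives
    ``p > pc_alpha``.  Ties in the strength ordering are broken by
    (source, lag) ascending for reproducibility.
    """
    if tau_max < 1:
        raise ValueError("tau_max must be >= 1")
    test = make_ci_test(test or "parcorr")
    X = series.values
    T, N = X.shape
    start = tau_max
    n_eff = T - tau_max
    if n_eff < 4:
        raise ValueError(
            f"series too short: T={T} leaves n_eff={n_eff} after cutting "
            f"tau_max={tau_max}; need T >= {tau_max + 4}"
        )
    parents: dict[int, list[tuple[int, int]]] = {}
    stats: dict[int, dict[tuple[int, int], float]] = {}
    n_tests = 0
    for j in range(N):
        cands = [(i, tau) for i in range(N) for tau in range(1, tau_max + 1)]
        stat = {c: np.inf for c in cands}
        y = _lagged_column(X, j, 0, start)
        q = 0
        while True:
            if max_conds is not None and q > max_conds:
                break
            if q > len(cands) - 1:
                break
            if q + 3 > n_eff:
                raise ValueError(
                    f"sample too short for condition cardinality {q}: "
                    f"need T >= {tau_max + q + 3}, have T = {T}"
                )
            order = sorted(cands, key=lambda c: (-stat[c], c))
            removed = set()
            tested_any = False
            for c in order:
                others = [o for o in order if o != c][:q]
                if len(others) < q:
                    continue
                res = test.run(
                    _lagged_column(X, c[0], c[1], start),
                    y,
                    _cond_matrix(X, others, start),
                )
                n_tests += 1
                tested_any = True
                stat[c] = min(stat[c], abs(res.statistic))
                if res.p_value > pc_alpha:
                    removed.add(c)
            cands = [c for c in cands if c not in removed]
            if not tested_any or not cands:
                break
            q += 1
        parents[j] = sorted(cands, key=lambda c: (-stat[c], c))
        stats[j] = {c: float(stat[c]) for c in cands}
    return ParentSets(parents, stats, n_tests)


def mci_link_test(
    series: ROITimeSeries,
    parents: ParentSets,
    test=None,
    tau_max: int = 15,
    alpha: float = 0.01,
    fdr: bool = False,
) -> TimeSeriesGraph:
    """Momentary conditional independence test for every ordered pair and lag.

    Tests X^i_{t-tau} against X^j_t conditioned on the pre-selected parents
    of j (minus the tested link) together with the parents of i shifted by
    tau.  All tests share one window of length ``T - 2 tau_max`` so every
    test uses the same effective sample size.
    """
    test = make_ci_test(test or "parcorr")
    X = series.values
    T, N = X.shape
    start = 2 * tau_max
    n_eff = T - start
    if n_eff < 4:
        raise ValueError(
            f"series too short for the MCI window: T={T} leaves n_eff={n_eff}; "
            f"need T >= {2 * tau_max + 4}"
        )
    val = np.zeros((N, N, tau_max + 1))
    p = np.ones((N, N, tau_max + 1))
    n_tests = 0
    for j in range(N):
        y = _lagged_column(X, j, 0, start)
        pj = parents.for_target(j)
        for i in range(N):
            shifted_pi = [(m, s) for m, s in parents.for_target(i)]
            for tau in range(1, tau_max + 1):
                conds = [c for c in pj if c != (i, tau)]
                for m, s in shifted_pi:
                    c = (m, s + tau)
                    if c != (i, tau) and c not in conds:
                        conds.append(c)
                res = test.run(
                    _lagged_column(X, i, tau, start),
                    y,
                    _cond_matrix(X, conds, start),
                )
                n_tests += 1
                val[j, i, tau] = res.statistic
                p[j, i, tau] = res.p_value
    if fdr:
        from scipy.stats import false_discovery_control

        mask = np.zeros_like(p, dtype=bool)
        mask[:, :, 1:] = True
        p = p.copy()
        p[mask] = false_discovery_control(p[mask], method="bh")
    return TimeSeriesGraph(
        val_matrix=val,
        p_matrix=p,
        tau_max=tau_max,
        alpha=alpha,
        labels=list(series.labels),
        n_eff=n_eff,
        n_ci_tests={"pc": parents.n_tests, "mci": n_tests,
                    "total": parents.n_tests + n_tests},
        parents=parents,
    )


def run_pcmci(
    series: ROITimeSeries,
    tau_max: int = 15,
    alpha: float = 0.01,
    ci_test="parcorr",
    pc_alpha: float | None = None,
    max_conds: int | None = None,
    knn_k: int = 10,
    knn_permutations: int = 200,
    seed: int = 0,
    fdr: bool = False,
) -> TimeSeriesGraph:
    """Run both discovery stages with the study defaults (tau_max=15, alpha=0.01).

    The returned graph carries the parent sets, the shared effective sample
    size, and the actual CI-test counters (always below the
    :func:`count_ci_tests` worst case).
    """
    if series.n_samples < 2 * (tau_max + 1):
        raise ValueError(
            f"need T >= 2 (tau_max + 1) = {2 * (tau_max + 1)} samples before "
            f"analysis; got T = {series.n_samples}"
        )
    test = make_ci_test(ci_test, knn_k=knn_k, knn_permutations=knn_permutations, seed=seed)
    parents = pc1_parent_selection(
        series, test, tau_max=tau_max,
        pc_alpha=alpha if pc_alpha is None else pc_alpha,
        max_conds=max_conds,
    )
    graph = mci_link_test(series, parents, test, tau_max=tau_max, alpha=alpha, fdr=fdr)
    bound = count_ci_tests(series.n_vars, tau_max)[2]
    assert graph.n_ci_tests["total"] <= bound, "CI-test counter exceeded worst case"
    return graph


class PCMCI(BaseEstimator):
    """Time-lagged causal graph estimator (sklearn-style).

    Fits the two-stage discovery procedure to a ``(T, N)`` array or
    :class:`~lagcausal.io.ROITimeSeries` and exposes the discovered
    lag-specific link graph.

    Parameters
    ----------
    tau_max : int, default 15
        Maximum tested lag.
    alpha : float, default 0.01
        Link-retention threshold on raw p-values (regularization knob).
    ci_test : {'parcorr', 'cmiknn'} or test instance
        Conditional-independence test.
    pc_alpha : float or None
        Pre-selection threshold; defaults to ``alpha``.
    max_conds : int or None
        Cap on the pre-selection condition cardinality (None = unlimited).
    standardize : bool, default True
        Standardize columns before testing (recommended; effect estimates
        downstream are then per standard deviation).
    knn_k, knn_permutations, random_state
        k-NN test parameters and the seed for its jitter/permutations.

    Attributes
    ----------
    graph_ : TimeSeriesGraph
    parents_ : ParentSets
    val_matrix_, p_matrix_, link_matrix_ : ndarray (N, N, tau_max + 1)
    n_ci_tests_ : dict with 'pc', 'mci', 'total' counters
    n_ci_tests_bound_ : int, the worst case for (N, tau_max)

    Examples
    --------
    >>> from lagcausal import PCMCI, simulate, make_var_model
    >>> model = make_var_model(2, [(0, 0, 1, 0.5), (1, 1, 1, 0.5), (0, 1, 2, 0.5)])
    >>> est = PCMCI(tau_max=5).fit(simulate(model, 1000, seed=3))
    >>> sorted((i, tau, j) for i, tau, j, _, _ in est.graph_.links())
    [(0, 1, 0), (0, 2, 1), (1, 1, 1)]
    """

    def __init__(
        self,
        tau_max: int = 15,
        alpha: float = 0.01,
        ci_test="parcorr",
        pc_alpha: float | None = None,
        max_conds: int | None = None,
        standardize: bool = True,
        knn_k: int = 10,
        knn_permutations: int = 200,
        random_state: int = 0,
        fdr: bool = False,
    ):
        self.tau_max = tau_max
        self.alpha = alpha
        self.ci_test = ci_test
        self.pc_alpha = pc_alpha
        self.max_conds = max_conds
        self.standardize = standardize
        self.knn_k = knn_k
        self.knn_permutations = knn_permutations
        self.random_state = random_state
        self.fdr = fdr

    def fit(self, X, y=None):
        series = X if isinstance(X, ROITimeSeries) else ROITimeSeries(
            np.asarray(X, dtype=float),
            [f"X{i + 1}" for i in range(np.asarray(X).shape[1])],
        )
        if self.standardize:
            series = preprocess(series, standardize=True)
        self.graph_ = run_pcmci(
            series,
            tau_max=self.tau_max,
            alpha=self.alpha,
            ci_test=self.ci_test,
            pc_alpha=self.pc_alpha,
            max_conds=self.max_conds,
            knn_k=self.knn_k,
            knn_permutations=self.knn_permutations,
            seed=self.random_state,
            fdr=self.fdr,
        )
        self.parents_ = self.graph_.parents
        self.val_matrix_ = self.graph_.val_matrix
        self.p_matrix_ = self.graph_.p_matrix
        self.link_matrix_ = self.graph_.link_matrix
        self.n_ci_tests_ = self.graph_.n_ci_tests
        self.n_ci_tests_bound_ = count_ci_tests(series.n_vars, self.tau_max)[2]
        self.labels_ = list(series.labels)
        return self
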