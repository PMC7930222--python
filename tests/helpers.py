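"""Independent oracles used across the test suite.

These deliberately avoid the package's own recursion/counting code paths:
causal effects are recomputed by explicit enumeration of directed paths,
and partial correlations by closed-form Gaussian algebra on a covariance
matrix.
"""

from __future__ import annotations

import numpy as np


def enumerate_paths_psi(phi: np.ndarray, tau_max: int) -> np.ndarray:
    """Accumulated causal effects by explicit directed-path enumeration.

    ``psi[j, i, tau]`` = sum over every directed path from i to j whose
    link lags sum to tau of the product of link coefficients.  Exponential;
    only for small sparse models.
    """
    n = phi.shape[0]
    psi = np.zeros((n, n, tau_max + 1))
    psi[:, :, 0] = np.eye(n)
    links = [
        (int(j), int(i), int(tau), float(phi[j, i, tau]))
        for j, i, tau in zip(*np.nonzero(phi))
    ]

    def dfs(node: int, lag_used: int, prod: float, src: int) -> None:
        for j, i, tau, c in links:
            if i == node and lag_used + tau <= tau_max:
                psi[j, src, lag_used + tau] += prod * c
                dfs(j, lag_used + tau, prod * c, src)

    for src in range(n):
        dfs(src, 0, 1.0, src)
    return psi


def gaussian_partial_correlation(cov: np.ndarray, i: int, j: int, conds) -> float:
    """Closed-form partial correlation of a Gaussian vector given ``conds``."""
    idx = [i, j] + list(conds)
    sub = cov[np.ix_(idx, idx)]
    prec = np.linalg.inv(sub)
    return float(-prec[0, 1] / np.sqrt(prec[0, 0] * prec[1, 1]))


def random_sparse_stable_model(rng: np.random.Generator, n_max=5, tau_max=5):
    """Draw a random sparse stable lagged linear model (for oracle checks)."""
    from lagcausal import make_var_model

    n = int(rng.integers(2, n_max + 1))
    L = int(rng.integers(1, tau_max + 1))
    links = {}
    for i in range(n):  # autolinks keep it realistically autocorrelated
        links[(i, i, 1)] = rng.uniform(0.2, 0.5)
    n_cross = int(rng.integers(1, 2 * n))
    for _ in range(n_cross):
        i, j = rng.integers(0, n, size=2)
        tau = int(rng.integers(1, L + 1))
        if i != j:
            links[(int(i), int(j), tau)] = rng.uniform(-0.4, 0.4)
    for attempt in range(20):
        try:
            scale = 0.9**attempt
            return make_var_model(
                n, [(i, j, t, c * scale) for (i, j, t), c in links.items()]
            )
        except ValueError:
            continue
    raise AssertionError("could not stabilize random model")
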