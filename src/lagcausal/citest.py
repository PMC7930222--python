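"""Conditional-independence tests.

Two tests of H0: X independent of Y given Z are provided:

* :class:`ParCorr` — linear partial correlation.  X and Y are residualized
  on Z by least squares; the residual correlation is referred to a Student
  t null with ``n - |Z| - 2`` degrees of freedom.  Fast, analytic, assumes
  linear-Gaussian dependence.
* :class:`CMIKnn` — conditional mutual information (nats) estimated with a
  Kraskov-type k-nearest-neighbor entropy estimator under the maximum
  norm, with a permutation null.  Model-free: sensitive to nonlinear
  dependence, at higher variance and cost.

The CMI estimate for sample points i uses the distance ``eps_i`` to the
k-th neighbor in the joint X (x) Y (x) Z space, counts ``k_xz, k_yz, k_z``
of points strictly closer than ``eps_i`` in the marginal-joint subspaces
(each count including the point itself), and combines them through the
digamma function psi:

    I_hat = psi(k) + mean_i[ psi(k_z_i) - psi(k_xz_i) - psi(k_yz_i) ].

With empty Z this degrades to the standard k-NN mutual-information form
``psi(k) + psi(n) - mean[psi(k_x) + psi(k_y)]``.  Estimates are not
clipped: small negative values are legitimate estimator noise, and the
permutation test uses the null distribution, not the sign.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from scipy.special import digamma
from scipy.stats import t as t_dist

__all__ = [
    "CITestResult",
    "ParCorr",
    "CMIKnn",
    "parcorr_test",
    "cmi_knn",
    "cmi_knn_test",
]


@dataclass
class CITestResult:
    """Outcome of one conditional-independence test.

    ``statistic`` is a partial correlation in [-1, 1] (ParCorr) or a CMI
    estimate in nats (CMIKnn); ``n_eff`` the number of samples actually
    used; ``cond_dim`` the dimension of the conditioning set.
    """

    statistic: float
    p_value: float
    n_eff: int
    cond_dim: int
    warning: str | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p_value {self.p_value} outside [0, 1]")


def _as_cond_matrix(z_set, n: int) -> np.ndarray:
    if z_set is None:
        return np.empty((n, 0))
    Z = np.asarray(z_set, dtype=float)
    if Z.ndim == 1:
        Z = Z[:, None]
    if Z.shape[0] != n:
        raise ValueError(f"conditioning set has {Z.shape[0]} rows, expected {n}")
    return Z


def _residualize(v: np.ndarray, Z: np.ndarray) -> np.ndarray:
    if Z.shape[1] == 0:
        return v - v.mean()
    A = np.column_stack([np.ones(len(v)), Z])
    coef, _, rank, _ = np.linalg.lstsq(A, v, rcond=None)
    if rank < A.shape[1]:
        raise ValueError(
            "singular regression design: conditioning variables are collinear"
        )
    return v - A @ coef


class ParCorr:
    """Partial-correlation CI test with an analytic Student-t null."""

    name = "parcorr"

    def run(self, x, y, z_set=None) -> CITestResult:
        x = np.asarray(x, dtype=float).ravel()
        y = np.asarray(y, dtype=float).ravel()
        n = len(x)
        if len(y) != n:
            raise ValueError("x and y must have equal length")
        Z = _as_cond_matrix(z_set, n)
        d = Z.shape[1]
        df = n - d - 2
        if df < 1:
            raise ValueError(
                f"sample too small: n={n} with {d} conditions leaves "
                f"{df} degrees of freedom (need n >= {d + 3})"
            )
        rx = _residualize(x, Z)
        ry = _residualize(y, Z)
        nx = np.linalg.norm(rx)
        ny = np.linalg.norm(ry)
        if nx == 0 or ny == 0:
            raise ValueError("zero residual variance; cannot form partial correlation")
        r = float(np.clip(rx @ ry / (nx * ny), -1.0, 1.0))
        if 1.0 - r * r < np.finfo(float).eps:
            p = 0.0
        else:
            tstat = r * np.sqrt(df / (1.0 - r * r))
            p = float(2.0 * t_dist.sf(abs(tstat), df))
        return CITestResult(statistic=r, p_value=p, n_eff=n, cond_dim=d)


def _strict_count(points: np.ndarray, eps: np.ndarray) -> np.ndarray:
    """Number of points (incl. self) at max-norm distance strictly < eps_i."""
    tree = cKDTree(points)
    # shrink the radius by one ulp so points exactly at eps_i are excluded
    return np.asarray(
        tree.query_ball_point(
            points, np.nextafter(eps, 0.0), p=np.inf, return_length=True
        )
    )


class CMIKnn:
    """k-NN conditional-mutual-information estimator with a permutation null.

    Parameters
    ----------
    k : int
        Number of neighbors in the joint space (bias/variance trade-off;
        small k = low bias, high variance).
    n_permutations : int
        Size B of the permutation null; the smallest attainable p-value is
        1/(B+1).
    seed : int
        Seeds both the deterministic tie-breaking jitter and the
        permutations, so identical calls give identical results.
    """

    name = "cmiknn"

    def __init__(self, k: int = 10, n_permutations: int = 200, seed: int = 0):
        if k < 1:
            raise ValueError("k must be >= 1")
        if n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        self.k = k
        self.n_permutations = n_permutations
        self.seed = seed

    # -- point estimate ---------------------------------------------------
    def estimate(self, x, y, z_set=None) -> float:
        x = np.asarray(x, dtype=float).ravel()
        y = np.asarray(y, dtype=float).ravel()
        n = len(x)
        if len(y) != n:
            raise ValueError("x and y must have equal length")
        Z = _as_cond_matrix(z_set, n)
        if self.k >= n - 1:
            raise ValueError(f"k={self.k} too large for n={n} samples")
        rng = np.random.default_rng(self.seed)
        data = np.column_stack([x, y, Z])
        scale = np.maximum(data.std(axis=0), 1.0)
        data = data + rng.normal(size=data.shape) * (1e-10 * scale)
        joint = cKDTree(data)
        eps = joint.query(data, k=[self.k + 1], p=np.inf)[0][:, 0]
        xz = data[:, [0] + list(range(2, data.shape[1]))]
        yz = data[:, 1:]
        k_xz = _strict_count(xz, eps)
        k_yz = _strict_count(yz, eps)
        if Z.shape[1] > 0:
            k_z = _strict_count(data[:, 2:], eps)
            est = digamma(self.k) + np.mean(
                digamma(k_z) - digamma(k_xz) - digamma(k_yz)
            )
        else:
            est = digamma(self.k) + digamma(n) - np.mean(
                digamma(k_xz) + digamma(k_yz)
            )
        return float(est)

    # -- permutation test -------------------------------------------------
    def run(self, x, y, z_set=None) -> CITestResult:
        x = np.asarray(x, dtype=float).ravel()
        y = np.asarray(y, dtype=float).ravel()
        Z = _as_cond_matrix(z_set, len(x))
        observed = self.estimate(x, y, Z)
        rng = np.random.default_rng(self.seed)
        exceed = 0
        for _ in range(self.n_permutations):
            xp = x[rng.permutation(len(x))]
            if self.estimate(xp, y, Z) >= observed:
                exceed += 1
        p = (1.0 + exceed) / (self.n_permutations + 1.0)
        warning = None
        if self.n_permutations < 19:
            warning = (
                f"only {self.n_permutations} permutations: smallest attainable "
                f"p-value is {1.0 / (self.n_permutations + 1):.3f}"
            )
        return CITestResult(
            statistic=observed,
            p_value=p,
            n_eff=len(x),
            cond_dim=Z.shape[1],
            warning=warning,
        )


# -- functional wrappers --------------------------------------------------

def parcorr_test(x, y, z_set=None) -> CITestResult:
    """Partial-correlation CI test (see :class:`ParCorr`)."""
    return ParCorr().run(x, y, z_set)


def cmi_knn(x, y, z_set=None, k: int = 10, seed: int = 0) -> float:
    """Point estimate of I(X; Y | Z) in nats (see :class:`CMIKnn`)."""
    return CMIKnn(k=k, seed=seed).estimate(x, y, z_set)


def cmi_knn_test(
    x, y, z_set=None, k: int = 10, n_permutations: int = 200, seed: int = 0
) -> CITestResult:
    """Permutation CI test on the k-NN CMI statistic (see :class:`CMIKnn`)."""
    return CMIKnn(k=k, n_permutations=n_permutations, seed=seed).run(x, y, z_set)


def make_ci_test(name_or_test, knn_k: int = 10, knn_permutations: int = 200, seed: int = 0):
    """Resolve a CI-test spec ('parcorr' | 'cmiknn' | instance) to a test object."""
    if hasattr(name_or_test, "run"):
        return name_or_test
    if name_or_test == "parcorr":
        return ParCorr()
    if name_or_test == "cmiknn":
        return CMIKnn(k=knn_k, n_permutations=knn_permutations, seed=seed)
    raise ValueError(f"unknown CI test {name_or_test!r}")
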