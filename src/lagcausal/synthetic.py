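"""Ground-truth lagged linear stochastic processes for validation.

Every downstream stage (discovery, effect estimation, mediation) is
validated against data whose causal structure is known exactly.  The
generator realizes a stationary vector-autoregressive process

    X_t = sum_{tau=1}^{L} Phi(tau) X_{t-tau} + eps_t,

with sparse, lag-specific links, i.i.d. Gaussian innovations, and no
contemporaneous (lag-0) links — mirroring the assumption that effects
faster than the sampling interval are not treated as causal.  An optional
smoothing-and-decimation stage emulates the sluggish hemodynamic response
and the 2.8 s sampling interval of BOLD recordings.

Models are validated for stability (companion-matrix spectral radius < 1)
before simulation, so every accepted model is stationary.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io import ROITimeSeries

__all__ = [
    "LinkSpec",
    "VARModel",
    "MOTOR_ROI_TABLE",
    "MOTOR_ROI_LABELS",
    "make_var_model",
    "companion_spectral_radius",
    "simulate",
    "simulate_impulse",
    "apply_hrf_downsample",
    "default_hrf_kernel",
    "write_fixture",
    "load_truth_links",
    "load_model",
    "motor_task_model",
]

#: The 14 regions of the motor-task connectivity model: (area name,
#: abbreviation, atlas).  Bilateral thalamus, premotor cortex (BA6),
#: anterior/posterior primary motor cortex (BA4), visual cortices V1
#: (BA17) and V2 (BA18), plus cerebellum and frontal lobe.
MOTOR_ROI_TABLE: list[tuple[str, str, str]] = [
    ("Left thalamus", "ThalL", "MNI structural"),
    ("Right thalamus", "ThalR", "MNI structural"),
    ("Left premotor cortex Brodmann area 6", "PcBA6L", "Juelich histological"),
    ("Right premotor cortex Brodmann area 6", "PcBA6R", "Juelich histological"),
    ("Left anterior primary motor cortex Brodmann area 4", "PmcBA4aL", "Juelich histological"),
    ("Right anterior primary motor cortex Brodmann area 4", "PmcBA4aR", "Juelich histological"),
    ("Left posterior primary motor cortex Brodmann area 4", "PmcBA4pL", "Juelich histological"),
    ("Right posterior primary motor cortex Brodmann area 4", "PmcBA4pR", "Juelich histological"),
    ("Left visual cortex V1 Brodmann area 17", "V1BA17L", "Juelich histological"),
    ("Right visual cortex V1 Brodmann area 17", "V1BA17R", "Juelich histological"),
    ("Left visual cortex V2 Brodmann area 18", "V1BA18L", "Juelich histological"),
    ("Right visual cortex V2 Brodmann area 18", "V1BA18R", "Juelich histological"),
    ("Cerebellum", "Cereb", "Harvard-Oxford cortical structural"),
    ("Frontal lobe", "FL", "Harvard-Oxford cortical structural"),
]

MOTOR_ROI_LABELS: list[str] = [row[1] for row in MOTOR_ROI_TABLE]


@dataclass(frozen=True)
class LinkSpec:
    """One lag-specific directed link X^source_{t-lag} -> X^target_t.

    Indices are 0-based.  ``lag`` must be >= 1: contemporaneous links are
    excluded by assumption.  ``coefficient`` is on the standardized scale
    (effect per standard deviation of the source).
    """

    source: int
    target: int
    lag: int
    coefficient: float

    def __post_init__(self) -> None:
        if self.lag < 1:
            raise ValueError(
                f"link lag must be >= 1 (no contemporaneous links); got {self.lag}"
            )
        if self.source < 0 or self.target < 0:
            raise ValueError("component indices must be non-negative")


@dataclass
class VARModel:
    """A validated sparse lagged linear model with Gaussian innovations."""

    n_vars: int
    max_lag: int
    links: tuple[LinkSpec, ...]
    noise_sd: np.ndarray  # per-component innovation SD
    labels: list[str]
    atlases: list[str] | None = None

    @property
    def phi(self) -> np.ndarray:
        """Coefficient array of shape (N, N, max_lag + 1), ``phi[target, source, lag]``."""
        out = np.zeros((self.n_vars, self.n_vars, self.max_lag + 1))
        for link in self.links:
            out[link.target, link.source, link.lag] = link.coefficient
        return out

    def spectral_radius(self) -> float:
        return companion_spectral_radius(self.phi)


def companion_spectral_radius(phi: np.ndarray) -> float:
    """Spectral radius of the companion form of coefficient array ``phi``.

    ``phi[j, i, tau]`` multiplies X^i_{t-tau} in the equation of X^j_t.
    The process is stable (hence stationary) iff the value is < 1.
    """
    n, _, lp1 = phi.shape
    max_lag = lp1 - 1
    if max_lag == 0:
        return 0.0
    comp = np.zeros((n * max_lag, n * max_lag))
    for tau in range(1, max_lag + 1):
        comp[:n, (tau - 1) * n : tau * n] = phi[:, :, tau]
    if max_lag > 1:
        comp[n:, : n * (max_lag - 1)] = np.eye(n * (max_lag - 1))
    return float(np.max(np.abs(np.linalg.eigvals(comp))))


def _unit_variance_noise(phi: np.ndarray) -> np.ndarray:
    """Innovation SDs giving every component unit stationary variance.

    The stationary covariance S of the companion form solves
    S = A S A^T + Q with Q carrying the per-component innovation
    variances; S is linear in Q, so the variances solve a small linear
    system targeting diag(S) = 1.
    """
    from scipy.linalg import solve_discrete_lyapunov

    n, _, lp1 = phi.shape
    max_lag = lp1 - 1
    comp = np.zeros((n * max_lag, n * max_lag))
    for tau in range(1, max_lag + 1):
        comp[:n, (tau - 1) * n : tau * n] = phi[:, :, tau]
    if max_lag > 1:
        comp[n:, : n * (max_lag - 1)] = np.eye(n * (max_lag - 1))
    M = np.zeros((n, n))
    for i in range(n):
        Q = np.zeros_like(comp)
        Q[i, i] = 1.0
        S = solve_discrete_lyapunov(comp, Q)
        M[:, i] = np.diag(S)[:n]
    var = np.linalg.solve(M, np.ones(n))
    if np.any(var <= 0):
        raise ValueError("cannot scale innovations to unit variance for this model")
    return np.sqrt(var)


def make_var_model(
    n_vars: int,
    links=(),
    noise_sd=1.0,
    labels: list[str] | None = None,
    atlases: list[str] | None = None,
    unit_variance: bool = False,
) -> VARModel:
    """Build and validate a :class:`VARModel`.

    ``links`` may contain :class:`LinkSpec` objects or ``(source, target,
    lag, coefficient)`` tuples (0-based indices).  Rejects out-of-range
    indices, duplicate ``(source, target, lag)`` triples, and unstable
    coefficient sets (companion spectral radius >= 1, reported in the
    error message).

    With ``unit_variance=True`` the innovation SDs are calibrated so every
    component has unit stationary variance: the data are then generated on
    the standardized scale and link coefficients read directly as effects
    per standard deviation (``noise_sd`` is ignored).
    """
    if n_vars < 1:
        raise ValueError("n_vars must be >= 1")
    specs = tuple(
        l if isinstance(l, LinkSpec) else LinkSpec(*l) for l in links
    )
    for l in specs:
        if l.source >= n_vars or l.target >= n_vars:
            raise ValueError(
                f"link {l} references component outside 0..{n_vars - 1}"
            )
    keys = [(l.source, l.target, l.lag) for l in specs]
    if len(set(keys)) != len(keys):
        dupes = sorted({k for k in keys if keys.count(k) > 1})
        raise ValueError(f"duplicate (source, target, lag) links: {dupes}")
    max_lag = max((l.lag for l in specs), default=1)
    noise = np.broadcast_to(np.asarray(noise_sd, dtype=float), (n_vars,)).copy()
    if np.any(noise <= 0):
        raise ValueError("noise_sd must be positive for every component")
    if labels is None:
        labels = [f"X{i + 1}" for i in range(n_vars)]
    if len(labels) != n_vars:
        raise ValueError(f"{len(labels)} labels for {n_vars} components")
    if len(set(labels)) != n_vars:
        raise ValueError("labels must be unique")
    model = VARModel(n_vars, max_lag, specs, noise, list(labels), atlases)
    rho = model.spectral_radius()
    if rho >= 1.0:
        raise ValueError(
            f"unstable model: companion spectral radius {rho:.4f} >= 1; "
            "reduce coefficient magnitudes"
        )
    if unit_variance:
        model.noise_sd = _unit_variance_noise(model.phi)
    return model


def simulate(
    model: VARModel,
    n_samples: int,
    burn_in: int | None = None,
    seed: int | None = 0,
    sampling_interval: float = 1.0,
) -> ROITimeSeries:
    """Draw one realization of the process; burn-in is discarded.

    ``burn_in`` defaults to 10 x max_lag so the retained stretch is close
    to the stationary distribution.  Identical ``(model, n_samples, seed)``
    give identical output.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if burn_in is None:
        burn_in = 10 * model.max_lag
    if burn_in < model.max_lag:
        raise ValueError(f"burn_in must be >= max_lag ({model.max_lag})")
    rng = np.random.default_rng(seed)
    L = model.max_lag
    phi = model.phi
    total = L + burn_in + n_samples
    X = np.zeros((total, model.n_vars))
    eps = rng.normal(size=(total, model.n_vars)) * model.noise_sd
    for t in range(L, total):
        acc = eps[t].copy()
        for tau in range(1, L + 1):
            acc += phi[:, :, tau] @ X[t - tau]
        X[t] = acc
    return ROITimeSeries(X[L + burn_in :], list(model.labels), sampling_interval)


def simulate_impulse(model: VARModel, source: int, horizon: int) -> np.ndarray:
    """Noiseless unit-impulse response of the model.

    Injects a unit perturbation into ``source`` at time 0 and propagates it
    through the deterministic part of the system.  Entry ``[tau, j]`` of the
    returned ``(horizon + 1, N)`` array is the response of component ``j``
    at lag ``tau`` — the accumulated (direct + indirect) linear causal
    effect of the impulse.
    """
    if not 0 <= source < model.n_vars:
        raise ValueError("source out of range")
    phi = model.phi
    X = np.zeros((horizon + 1, model.n_vars))
    X[0, source] = 1.0
    for t in range(1, horizon + 1):
        for tau in range(1, min(t, model.max_lag) + 1):
            X[t] += phi[:, :, tau] @ X[t - tau]
    return X


def default_hrf_kernel(n_taps: int = 7) -> np.ndarray:
    """A simple positive smoothing kernel (normalized gamma-shaped bump).

    A stand-in for hemodynamic smoothing: the BOLD response is a sluggish,
    positive, roughly gamma-shaped filter of neuronal activity.  No claim of
    physiological accuracy is made.
    """
    t = np.arange(n_taps, dtype=float)
    k = t**2 * np.exp(-t)
    k[0] = 0.05
    return k / k.sum()


def apply_hrf_downsample(
    series: ROITimeSeries,
    kernel: np.ndarray | None = None,
    out_interval: float | None = None,
) -> ROITimeSeries:
    """Convolve each column with a smoothing kernel, then decimate.

    ``out_interval`` (seconds) must be an integer multiple of the input
    sampling interval; it defaults to no decimation.  The causal
    convolution keeps the output aligned with the input grid.
    """
    if kernel is None:
        kernel = default_hrf_kernel()
    kernel = np.asarray(kernel, dtype=float)
    if kernel.ndim != 1 or kernel.size == 0:
        raise ValueError("kernel must be a non-empty 1-D sequence")
    if not np.all(np.isfinite(kernel)) or np.any(kernel < 0):
        raise ValueError("kernel must be finite and non-negative")
    if out_interval is None:
        out_interval = series.sampling_interval
    factor_f = out_interval / series.sampling_interval
    factor = int(round(factor_f))
    if factor < 1 or abs(factor_f - factor) > 1e-9:
        raise ValueError(
            f"out_interval ({out_interval}) must be an integer multiple of the "
            f"input sampling interval ({series.sampling_interval})"
        )
    T = series.n_samples
    smoothed = np.column_stack(
        [np.convolve(series.values[:, c], kernel)[:T] for c in range(series.n_vars)]
    )
    return ROITimeSeries(smoothed[::factor], list(series.labels), float(out_interval))


def write_fixture(series: ROITimeSeries, model: VARModel, directory) -> list[Path]:
    """Write a complete plain-text fixture: per-ROI series, labels, truth links.

    Layout: ``<abbrev>.txt`` (one float per line, fslmeants style),
    ``labels.tsv`` (index, abbreviation, atlas), ``truth_links.tsv``
    (source, target, lag, coefficient; labels used for components) and
    ``model.json`` (full model spec, round-trippable via
    :func:`load_model`).  Returns the written paths.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for c, label in enumerate(series.labels):
        p = directory / f"{label}.txt"
        np.savetxt(p, series.values[:, c], fmt="%.8f")
        written.append(p)
    atlases = model.atlases or ["-"] * model.n_vars
    p = directory / "labels.tsv"
    with open(p, "w") as fh:
        fh.write("index\tabbreviation\tatlas\n")
        for i, (label, atlas) in enumerate(zip(model.labels, atlases), start=1):
            fh.write(f"{i}\t{label}\t{atlas}\n")
    written.append(p)
    p = directory / "truth_links.tsv"
    with open(p, "w") as fh:
        fh.write("source\ttarget\tlag\tcoefficient\n")
        for l in sorted(model.links, key=lambda l: (l.source, l.target, l.lag)):
            fh.write(
                f"{model.labels[l.source]}\t{model.labels[l.target]}\t"
                f"{l.lag}\t{l.coefficient:.8f}\n"
            )
    written.append(p)
    p = directory / "model.json"
    with open(p, "w") as fh:
        json.dump(
            {
                "n_vars": model.n_vars,
                "max_lag": model.max_lag,
                "noise_sd": model.noise_sd.tolist(),
                "labels": model.labels,
                "atlases": model.atlases,
                "links": [
                    [l.source, l.target, l.lag, l.coefficient] for l in model.links
                ],
                "sampling_interval": series.sampling_interval,
            },
            fh,
            indent=1,
            sort_keys=True,
        )
    written.append(p)
    return written


def load_truth_links(directory) -> list[LinkSpec]:
    """Read ``truth_links.tsv`` back into :class:`LinkSpec` objects (0-based)."""
    directory = Path(directory)
    import pandas as pd

    labels = list(pd.read_csv(directory / "labels.tsv", sep="\t")["abbreviation"])
    df = pd.read_csv(directory / "truth_links.tsv", sep="\t")
    return [
        LinkSpec(labels.index(r.source), labels.index(r.target), int(r.lag), float(r.coefficient))
        for r in df.itertuples()
    ]


def load_model(path) -> VARModel:
    """Round-trip a model written by :func:`write_fixture` (``model.json``)."""
    with open(path) as fh:
        spec = json.load(fh)
    return make_var_model(
        spec["n_vars"],
        [LinkSpec(*l) for l in spec["links"]],
        noise_sd=np.asarray(spec["noise_sd"]),
        labels=spec["labels"],
        atlases=spec.get("atlases"),
    )


def motor_task_model(noise_sd: float = 1.0) -> VARModel:
    """The packaged 14-ROI example model emulating a visually cued motor task.

    Every region carries a moderate autolink (BOLD series are strongly
    autocorrelated).  Sparse cross-links at lags 1..5 trace a plausible cued
    pathway: right visual V2 drives V1 and contralateral visual cortex; V1
    drives primary motor cortex bilaterally; motor cortex engages premotor
    cortex, thalamus, cerebellum and the frontal lobe, with one negative
    (counteracting) thalamic link.  Coefficients are on the standardized
    scale and jointly stable.
    """
    labels = MOTOR_ROI_LABELS
    atlases = [row[2] for row in MOTOR_ROI_TABLE]
    idx = {l: i for i, l in enumerate(labels)}
    links: list[tuple[int, int, int, float]] = [
        (idx[a], idx[b], lag, c)
        for a, b, lag, c in [
            ("V1BA18R", "V1BA17R", 1, 0.40),
            ("V1BA18R", "V1BA18L", 1, 0.35),
            ("V1BA18L", "V1BA17L", 1, 0.30),
            ("V1BA17R", "PmcBA4aL", 2, 0.40),
            ("V1BA17R", "PmcBA4aR", 3, 0.30),
            ("PmcBA4aR", "PcBA6R", 1, 0.30),
            ("PmcBA4aL", "PmcBA4pL", 1, 0.30),
            ("PcBA6R", "ThalL", 2, 0.30),
            ("ThalL", "PmcBA4aL", 1, -0.25),
            ("FL", "PcBA6L", 3, 0.30),
            ("PcBA6L", "PmcBA4pL", 2, 0.25),
            ("Cereb", "PmcBA4pR", 2, 0.30),
            ("V1BA18R", "FL", 5, 0.25),
            ("ThalR", "Cereb", 1, 0.25),
        ]
    ]
    links += [(i, i, 1, 0.45 if i % 2 == 0 else 0.40) for i in range(len(labels))]
    return make_var_model(
        len(labels), links, noise_sd=noise_sd, labels=labels, atlases=atlases,
        unit_variance=True,
    )
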