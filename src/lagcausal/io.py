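"""Reading, validation and pre-conditioning of ROI time series.

ROI-averaged BOLD signals arrive either as one plain-text column per region
(the output style of FSL's ``fslmeants`` averaging tool) or as a single
delimited table with one column per region.  This module assembles them into
a validated :class:`ROITimeSeries`, optionally detrends/standardizes each
column, and estimates lagged *unconditional* dependencies, whose decay over
lag guides the choice of the maximum lag ``tau_max`` used downstream.

Missing values are rejected rather than imputed: lagged causal analysis is
sensitive to temporal noise, and silent imputation would distort time order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ROITimeSeries",
    "LaggedDependence",
    "read_roi_timeseries",
    "read_label_table",
    "preprocess",
    "lagged_dependence",
    "suggest_tau_max",
]


@dataclass
class ROITimeSeries:
    """A multivariate ROI time series: T time points by N labeled components.

    Parameters
    ----------
    values : ndarray of shape (T, N)
        The observed process, one column per component.  Must be finite.
    labels : list of str
        Unique component names (e.g. ROI abbreviations).
    sampling_interval : float, default 1.0
        Time between consecutive samples, in seconds (the fMRI repetition
        time when the data are BOLD series).
    """

    values: np.ndarray
    labels: list[str]
    sampling_interval: float = 1.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim == 1:
            self.values = self.values[:, None]
        if self.values.ndim != 2:
            raise ValueError(f"values must be 2-D (T, N); got shape {self.values.shape}")
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                f"non-finite value at time index {bad[0]}, component {bad[1]}; "
                "missing values are rejected, not imputed"
            )
        self.labels = [str(l) for l in self.labels]
        if len(self.labels) != self.values.shape[1]:
            raise ValueError(
                f"{len(self.labels)} labels for {self.values.shape[1]} columns"
            )
        if len(set(self.labels)) != len(self.labels):
            dupes = sorted({l for l in self.labels if self.labels.count(l) > 1})
            raise ValueError(f"duplicate component labels: {dupes}")
        if self.sampling_interval <= 0:
            raise ValueError("sampling_interval must be positive")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_vars(self) -> int:
        return self.values.shape[1]

    def index_of(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"unknown component label {label!r}") from None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.labels)


def _read_single_column(path: Path) -> np.ndarray:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            tokens = line.split()
            if not tokens:
                continue
            if len(tokens) != 1:
                raise ValueError(
                    f"{path}: expected one value per line, got {len(tokens)} "
                    f"tokens at line {lineno}"
                )
            try:
                out.append(float(tokens[0]))
            except ValueError:
                raise ValueError(
                    f"{path}: non-numeric token {tokens[0]!r} at line {lineno}"
                ) from None
    if not out:
        raise ValueError(f"{path}: file contains no data")
    return np.asarray(out)


def _sniff_delimiter(first_line: str) -> str | None:
    if "\t" in first_line:
        return "\t"
    if "," in first_line:
        return ","
    return None  # whitespace


def _read_table(path: Path, delimiter: str | None) -> tuple[np.ndarray, list[str] | None]:
    with open(path) as fh:
        first = fh.readline()
    if not first.strip():
        raise ValueError(f"{path}: file is empty")
    sep = delimiter if delimiter is not None else _sniff_delimiter(first)
    tokens = first.strip().split(sep)
    has_header = False
    for tok in tokens:
        try:
            float(tok)
        except ValueError:
            has_header = True
            break
    df = pd.read_csv(
        path,
        sep=sep if sep is not None else r"\s+",
        header=0 if has_header else None,
        engine="python",
    )
    try:
        values = df.to_numpy(dtype=float)
    except (ValueError, TypeError) as exc:
        raise ValueError(f"{path}: non-numeric entry in table: {exc}") from None
    labels = [str(c) for c in df.columns] if has_header else None
    return values, labels


def read_roi_timeseries(
    paths_or_table,
    labels: list[str] | None = None,
    sampling_interval: float = 1.0,
    delimiter: str | None = None,
) -> ROITimeSeries:
    """Assemble an :class:`ROITimeSeries` from text files.

    Parameters
    ----------
    paths_or_table : sequence of paths, or a single path
        Either a list of single-column text files, one per ROI (fslmeants
        style), read in the given order, or one delimited table (rows = time
        points, columns = ROIs).  Table delimiters are sniffed (tab, comma,
        whitespace) unless ``delimiter`` is given; a non-numeric first row is
        treated as a header of labels.
    labels : list of str, optional
        Component names.  Defaults to file stems (per-file input) or the
        table header; generic ``X1..XN`` names otherwise.
    sampling_interval : float
        Seconds between samples.

    Raises
    ------
    ValueError
        On length mismatch between files (files are named), non-numeric
        tokens (line number reported), or duplicate labels.
    """
    if isinstance(paths_or_table, (str, Path)):
        values, header = _read_table(Path(paths_or_table), delimiter)
        if labels is None:
            labels = header if header is not None else [
                f"X{i + 1}" for i in range(values.shape[1])
            ]
        return ROITimeSeries(values, labels, sampling_interval)

    paths = [Path(p) for p in paths_or_table]
    if not paths:
        raise ValueError("no input files given")
    columns = [_read_single_column(p) for p in paths]
    lengths = {len(c) for c in columns}
    if len(lengths) > 1:
        detail = ", ".join(f"{p.name}: {len(c)}" for p, c in zip(paths, columns))
        raise ValueError(f"time series lengths differ across files ({detail})")
    if labels is None:
        labels = [p.stem for p in paths]
    return ROITimeSeries(np.column_stack(columns), labels, sampling_interval)


def read_label_table(path) -> pd.DataFrame:
    """Read an ROI label table (index, abbreviation, atlas) as TSV/CSV.

    A headerless single-column file is treated as a bare list of
    abbreviations.  Returns a DataFrame with at least an ``abbreviation``
    column.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    sep = "\t" if "\t" in first else ("," if "," in first else r"\s+")
    head = first.strip().lower()
    has_header = "abbrev" in head or "label" in head or "area" in head
    df = pd.read_csv(path, sep=sep, header=0 if has_header else None, engine="python")
    if not has_header:
        if df.shape[1] == 1:
            df.columns = ["abbreviation"]
        else:
            df.columns = ["index", "abbreviation", "atlas"][: df.shape[1]]
    df.columns = [str(c).strip().lower() for c in df.columns]
    if "abbreviation" not in df.columns:
        raise ValueError(f"{path}: no abbreviation column found")
    return df


def preprocess(
    series: ROITimeSeries,
    standardize: bool = True,
    detrend: bool = False,
) -> ROITimeSeries:
    """Detrend and/or standardize each component.

    With ``detrend`` a least-squares line is removed from each column before
    standardization.  With ``standardize`` each column is centred and scaled
    to unit (population) variance; downstream path coefficients are then on
    the per-standard-deviation scale.

    Raises
    ------
    ValueError
        If a column has zero variance (the offending ROI is named).
    """
    X = series.values.copy()
    if detrend:
        t = np.arange(X.shape[0], dtype=float)
        t = t - t.mean()
        denom = float(t @ t)
        for col in range(X.shape[1]):
            slope = float(t @ (X[:, col] - X[:, col].mean())) / denom
            X[:, col] = X[:, col] - X[:, col].mean() - slope * t
    if standardize:
        sd = X.std(axis=0)
        zero = np.flatnonzero(sd == 0)
        if zero.size:
            names = [series.labels[i] for i in zero]
            raise ValueError(f"zero-variance component(s): {names}; cannot standardize")
        X = (X - X.mean(axis=0)) / sd
    return ROITimeSeries(X, list(series.labels), series.sampling_interval)


@dataclass
class LaggedDependence:
    """Absolute unconditional dependence between all ordered pairs per lag.

    ``dep[i, j, tau - 1]`` is the absolute dependence between component ``i``
    at time ``t - tau`` and component ``j`` at time ``t``, for lags
    ``1..tau_max``.
    """

    dep: np.ndarray  # (N, N, tau_max)
    measure: str
    labels: list[str] = field(default_factory=list)

    @property
    def tau_max(self) -> int:
        return self.dep.shape[2]

    def value(self, i: int, j: int, lag: int) -> float:
        if not 1 <= lag <= self.tau_max:
            raise ValueError(f"lag must be in 1..{self.tau_max}")
        return float(self.dep[i, j, lag - 1])

    def max_per_lag(self) -> np.ndarray:
        """Maximum dependence over all ordered pairs, per lag (1..tau_max)."""
        return self.dep.max(axis=(0, 1))

    def to_frame(self) -> pd.DataFrame:
        n = self.dep.shape[0]
        labels = self.labels or [f"X{i + 1}" for i in range(n)]
        rows = [
            (labels[i], labels[j], tau + 1, self.dep[i, j, tau])
            for i in range(n)
            for j in range(n)
            for tau in range(self.tau_max)
        ]
        return pd.DataFrame(rows, columns=["source", "target", "lag", "value"])


def lagged_dependence(
    series: ROITimeSeries,
    tau_max: int,
    measure: str = "correlation",
    knn_k: int = 5,
) -> LaggedDependence:
    """Estimate |dependence(X^i_{t-tau}, X^j_t)| for all pairs and lags.

    ``measure='correlation'`` uses absolute Pearson correlation (cheap, the
    default screening measure); ``measure='mutual_information'`` uses the
    k-NN mutual-information estimator (nats; slower, model-free).
    """
    if tau_max < 1:
        raise ValueError("tau_max must be >= 1")
    T, N = series.values.shape
    if T <= tau_max + 2:
        raise ValueError(f"need T > tau_max + 2 samples; got T={T}, tau_max={tau_max}")
    if measure not in ("correlation", "mutual_information"):
        raise ValueError(f"unknown measure {measure!r}")
    dep = np.zeros((N, N, tau_max))
    X = series.values
    if measure == "correlation":
        for tau in range(1, tau_max + 1):
            A = X[:-tau]  # source at t - tau
            B = X[tau:]  # target at t
            Az = (A - A.mean(axis=0)) / np.where(A.std(axis=0) == 0, 1.0, A.std(axis=0))
            Bz = (B - B.mean(axis=0)) / np.where(B.std(axis=0) == 0, 1.0, B.std(axis=0))
            dep[:, :, tau - 1] = np.abs(Az.T @ Bz) / A.shape[0]
    else:
        from .citest import cmi_knn

        for tau in range(1, tau_max + 1):
            for i in range(N):
                for j in range(N):
                    dep[i, j, tau - 1] = abs(
                        cmi_knn(X[:-tau, i], X[tau:, j], None, k=knn_k)
                    )
    return LaggedDependence(dep, measure, list(series.labels))


def suggest_tau_max(lagdep: LaggedDependence, threshold: float = 0.2) -> int:
    """Smallest lag beyond which every pairwise dependence stays below threshold.

    Returns the screening horizon itself (with a warning) when the
    dependencies never decay below ``threshold`` within it.  The result is at
    least 1: a maximum lag of zero would leave no lagged links to test.
    """
    m = lagdep.max_per_lag()
    above = np.flatnonzero(m >= threshold)
    if above.size == 0:
        return 1
    last = int(above[-1]) + 1  # lag value of the last exceedance
    if last == lagdep.tau_max:
        warnings.warn(
            f"lagged dependencies never decay below {threshold} within the "
            f"screening horizon {lagdep.tau_max}; returning the horizon",
            stacklevel=2,
        )
        return lagdep.tau_max
    return max(1, last + 1)
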