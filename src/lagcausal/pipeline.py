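"""End-to-end orchestration: config -> discovery -> effects -> exported report.

A single flat declarative config drives the whole analysis; all randomness
funnels through one seed, so a rerun with the same config, inputs and seed
regenerates every exported file bit-identically.  Defaults reproduce the
study settings for task-fMRI ROI series: ``tau_max = 15``, ``alpha = 0.01``,
partial-correlation test, 2.8 s sampling interval.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from ._version import __version__ as _pkg_version
from .effects import (
    CausalEffectAnalysis,
    decomposed_transfer_entropy,
    mediation_graph,
)
from .citest import CMIKnn
from .graph import TimeSeriesGraph
from .io import (
    ROITimeSeries,
    lagged_dependence,
    preprocess,
    read_label_table,
    read_roi_timeseries,
    suggest_tau_max,
)
from .pcmci import count_ci_tests, run_pcmci

__all__ = ["AnalysisConfig", "ResultsBundle", "PipelineError", "run_pipeline", "export_report"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class AnalysisConfig:
    """Flat declarative configuration of one analysis run.

    Input is either ``roi_files`` (one single-column text file per ROI) or
    ``table`` (one delimited matrix); ``labels_file`` optionally supplies
    the ROI label table.  Defaults mirror the study settings.
    """

    roi_files: list[str] | None = None
    table: str | None = None
    labels_file: str | None = None
    labels: list[str] | None = None
    sampling_interval: float = 2.8
    tau_max: int = 15
    alpha: float = 0.01
    pc_alpha: float | None = None
    ci_test: str = "parcorr"
    knn_k: int = 10
    knn_permutations: int = 200
    seed: int = 0
    max_conds: int | None = None
    standardize: bool = True
    detrend: bool = False
    fdr: bool = False
    output_dir: str = "results"
    report_ce_matrices: bool = True
    report_aggregates: bool = True
    report_lagged_dependence: bool = False
    screen_threshold: float = 0.2
    mediation_pairs: object = "argmax"  # "argmax" | [] | [[src, tgt], [src, tgt, lag], ...]
    dte_pairs: list = field(default_factory=list)
    tau_star: int | None = None

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def validate(self) -> None:
        if self.roi_files is None and self.table is None:
            raise ValueError("config must give either roi_files or table")
        if self.tau_max < 1:
            raise ValueError("tau_max must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.ci_test not in ("parcorr", "cmiknn"):
            raise ValueError(f"unknown ci_test {self.ci_test!r}")


@dataclass
class ResultsBundle:
    """Everything one analysis run produced, plus run metadata."""

    series: ROITimeSeries
    graph: TimeSeriesGraph
    effects: CausalEffectAnalysis
    mediations: list
    dte: list  # (source_label, target_label, dte, per-lag terms)
    lagdep: object | None
    metadata: dict


def _resolve_mediation_pairs(config: AnalysisConfig, effects: CausalEffectAnalysis):
    """Turn the config's mediation request into (i, j, tau) triples."""
    labels = effects.labels_
    psi = effects.psi_.psi
    ce_max = effects.ce_max_.copy()
    np.fill_diagonal(ce_max, 0.0)
    out = []
    spec = config.mediation_pairs
    if spec == "argmax":
        if ce_max.max() > 0:
            j, i = np.unravel_index(np.argmax(ce_max), ce_max.shape)
            tau = int(np.abs(psi[j, i, 1:]).argmax()) + 1
            out.append((int(i), int(j), tau))
        return out
    for entry in spec or []:
        src, tgt = entry[0], entry[1]
        i, j = labels.index(src), labels.index(tgt)
        if len(entry) > 2:
            tau = int(entry[2])
        else:
            tau = int(np.abs(psi[j, i, 1:]).argmax()) + 1
        out.append((i, j, tau))
    return out


def run_pipeline(config: AnalysisConfig) -> ResultsBundle:
    """Execute read -> preprocess -> (screen) -> discover -> effects -> mediation.

    Any stage error aborts with the stage name and cause.  The run metadata
    records the seed, parameters, effective sample size, per-stage timings
    and the CI-test counters together with their worst-case bound.
    """
    config.validate()
    timings: dict[str, float] = {}

    def stage(name):
        class _Timer:
            def __enter__(self):
                self.t0 = time.perf_counter()

            def __exit__(self, exc_type, exc, tb):
                timings[name] = round(time.perf_counter() - self.t0, 4)
                if exc is not None and not isinstance(exc, PipelineError):
                    raise PipelineError(name, exc) from exc

        return _Timer()

    with stage("read"):
        labels = config.labels
        if labels is None and config.labels_file:
            labels = list(read_label_table(config.labels_file)["abbreviation"])
        source = config.roi_files if config.roi_files is not None else config.table
        series = read_roi_timeseries(
            source, labels=labels, sampling_interval=config.sampling_interval
        )

    with stage("preprocess"):
        series = preprocess(
            series, standardize=config.standardize, detrend=config.detrend
        )

    lagdep = None
    if config.report_lagged_dependence:
        with stage("screen"):
            lagdep = lagged_dependence(series, config.tau_max)

    with stage("discover"):
        graph = run_pcmci(
            series,
            tau_max=config.tau_max,
            alpha=config.alpha,
            ci_test=config.ci_test,
            pc_alpha=config.pc_alpha,
            max_conds=config.max_conds,
            knn_k=config.knn_k,
            knn_permutations=config.knn_permutations,
            seed=config.seed,
            fdr=config.fdr,
        )

    with stage("effects"):
        effects = CausalEffectAnalysis(tau_max=config.tau_max).fit(series, graph)

    with stage("mediation"):
        mediations = [
            mediation_graph(graph, effects.phi_, i, j, tau, effects.mce_)
            for i, j, tau in _resolve_mediation_pairs(config, effects)
        ]

    dte = []
    if config.dte_pairs:
        with stage("dte"):
            knn = CMIKnn(k=config.knn_k, seed=config.seed)
            for src, tgt in config.dte_pairs:
                i, j = series.index_of(src), series.index_of(tgt)
                total, terms = decomposed_transfer_entropy(
                    series, graph, i, j,
                    tau_star=config.tau_star, knn=knn,
                    max_conds=config.max_conds,
                )
                dte.append((src, tgt, total, terms))

    bound = count_ci_tests(series.n_vars, config.tau_max)
    metadata = {
        "package": "lagcausal",
        "version": _pkg_version,
        "numpy_version": np.__version__,
        "seed": config.seed,
        "tau_max": config.tau_max,
        "alpha": config.alpha,
        "ci_test": config.ci_test,
        "n_vars": series.n_vars,
        "n_samples": series.n_samples,
        "sampling_interval": series.sampling_interval,
        "n_eff": graph.n_eff,
        "n_links": graph.n_links(),
        "ci_tests_run": graph.n_ci_tests,
        "ci_tests_worst_case": {"pc": bound[0], "mci": bound[1], "total": bound[2]},
        "timings_s": timings,
        "config": {
            k: v for k, v in asdict(config).items() if not isinstance(v, (list, type(None)))
        },
    }
    assert graph.n_ci_tests["total"] <= bound[2]
    return ResultsBundle(series, graph, effects, mediations, dte, lagdep, metadata)


def export_report(bundle: ResultsBundle, directory) -> list[Path]:
    """Write all requested artifacts; on failure, remove partial outputs.

    Files written (as requested in the config): the link edge list
    (``graph_edges.tsv``), summary graph (GraphML + DOT), the long CE table
    (``ce_matrices.tsv``; N*N*tau_max rows), per-node aggregates
    (``aggregates.tsv``), mediation graphs per requested pair (GraphML +
    DOT, time-resolved and summary), DTE terms, the lagged-dependence
    screen, and ``run_metadata.json``.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def out(name: str) -> Path:
        p = directory / name
        written.append(p)
        return p

    try:
        bundle.graph.write_edges_tsv(out("graph_edges.tsv"))
        bundle.graph.write_graphml(out("graph_summary.graphml"))
        bundle.graph.write_dot(out("graph_summary.dot"))
        meta = bundle.metadata
        cfg = meta.get("config", {})
        if cfg.get("report_ce_matrices", True):
            bundle.effects.psi_.to_frame().to_csv(
                out("ce_matrices.tsv"), sep="\t", index=False, float_format="%.10g"
            )
        if cfg.get("report_aggregates", True):
            bundle.effects.aggregates_.to_frame().to_csv(
                out("aggregates.tsv"), sep="\t", index=False, float_format="%.10g"
            )
        for med in bundle.mediations:
            stem = f"mediation_{med.source}_to_{med.target}_lag{med.lag}"
            med.write_graphml(out(f"{stem}.graphml"))
            med.write_dot(out(f"{stem}.dot"))
            med.write_dot(out(f"{stem}_summary.dot"), time_resolved=False)
        if bundle.dte:
            with open(out("dte.tsv"), "w") as fh:
                fh.write("source\ttarget\tlag\tterm_nats\n")
                for src, tgt, total, terms in bundle.dte:
                    for tau, term in enumerate(terms, start=1):
                        fh.write(f"{src}\t{tgt}\t{tau}\t{term:.10g}\n")
                    fh.write(f"{src}\t{tgt}\ttotal\t{total:.10g}\n")
        if bundle.lagdep is not None:
            bundle.lagdep.to_frame().to_csv(
                out("lagged_dependence.tsv"), sep="\t", index=False,
                float_format="%.10g",
            )
        with open(out("run_metadata.json"), "w") as fh:
            json.dump(bundle.metadata, fh, indent=1, sort_keys=True)
    except Exception as exc:
        for p in written:
            p.unlink(missing_ok=True)
        raise PipelineError("export", exc) from exc
    return written
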