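"""Repetition harness, naming grammar, frequency tables and summaries.

The evaluation protocol: establish a baseline by cross-validating the
linear discriminant on all features per task; then run each configured
selector R times with seeds base_seed + i, score the selected subset
with the same cross-validation, and report (a) the distribution of the R
balanced accuracies per selector x task and (b) how often each feature
was selected ("numerator/denominator" per catalog class), mirroring the
published reporting style for 100-repetition runs.

Run names follow the grammar
``<Phase1><q>[<Phase2><p>]_(HAFF|nohaff)_BACC``, e.g.
``SDA50GA10_HAFF_BACC`` or ``RND51_nohaff_BACC``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .catalog_io import (
    FeatureCatalogEntry,
    FeatureTable,
    LabelSet,
    feature_catalog,
)
from .classify import CVScheme, cv_bacc
from . import selectors as sel

__all__ = [
    "SelectorSpec",
    "BenchmarkConfig",
    "BenchmarkReport",
    "make_run_name",
    "run_benchmark",
    "selection_frequency_table",
    "summarize_distributions",
]

_PHASE_TOKENS = {"SDA", "RFE", "GA", "RND", "HCFR", "RFECV"}


def make_run_name(
    phase1: str,
    q: Optional[int],
    phase2: Optional[str],
    p: Optional[int],
    haff: bool,
    metric: str = "BACC",
) -> str:
    """Compose the canonical run name, e.g. ``SDA50GA10_HAFF_BACC``."""
    if phase1 not in _PHASE_TOKENS:
        raise ValueError(f"unknown phase token {phase1!r}")
    if phase2 is not None and phase2 not in _PHASE_TOKENS:
        raise ValueError(f"unknown phase token {phase2!r}")
    if metric != "BACC":
        raise ValueError(f"unknown metric {metric!r}")
    name = phase1 + ("" if q is None else str(q))
    if phase2 is not None:
        name += phase2 + ("" if p is None else str(p))
    name += "_HAFF_" if haff else "_nohaff_"
    return name + metric


@dataclass
class SelectorSpec:
    """One benchmark arm: selector family plus its targets and flags."""

    family: str  # rnd | hcfr | rfe | rfecv | sda | ga | sda-ga | rfe-ga
    p: Optional[int] = None
    q: Optional[int] = None
    haff: bool = False
    params: dict = field(default_factory=dict)

    def run_name(self) -> str:
        fam = self.family.lower()
        if fam in ("sda-ga", "rfe-ga"):
            return make_run_name(fam.split("-")[0].upper(), self.q, "GA",
                                 self.p, self.haff)
        token = {"rnd": "RND", "hcfr": "HCFR", "rfe": "RFE", "rfecv": "RFECV",
                 "sda": "SDA", "ga": "GA"}[fam]
        q = None if fam in ("hcfr", "rfecv") else self.p
        return make_run_name(token, q, None, None, self.haff)


@dataclass
class BenchmarkConfig:
    tasks: list[str]
    selector_specs: list[SelectorSpec]
    repetitions: int = 100
    cv: CVScheme = field(default_factory=CVScheme)
    base_seed: int = 0
    report_dir: Optional[str] = None

    def __post_init__(self) -> None:
        if self.repetitions < 1:
            raise ValueError("repetitions must be >= 1")


@dataclass
class BenchmarkReport:
    baseline_bacc: dict[str, float]
    #: (run_name, task) -> length-R array of final cross-validated BACCs
    distributions: dict[tuple[str, str], np.ndarray]
    #: (run_name, task) -> rows (feature_name, feature_class, numerator, denominator)
    frequency_tables: dict[tuple[str, str], list[tuple[str, str, int, int]]]
    repetitions: int
    #: (run_name, task) -> list of per-repetition records
    records: dict[tuple[str, str], list[dict]] = field(default_factory=dict)
    failures: dict[tuple[str, str], list[dict]] = field(default_factory=dict)

    def to_json(self) -> str:
        payload = {
            "repetitions": self.repetitions,
            "baseline_bacc": self.baseline_bacc,
            "runs": [
                {
                    "run_name": run,
                    "task": task,
                    "bacc": [float(v) for v in dist],
                    "frequency_table": [list(r) for r in
                                        self.frequency_tables[(run, task)]],
                    "records": self.records.get((run, task), []),
                    "failures": self.failures.get((run, task), []),
                }
                for (run, task), dist in self.distributions.items()
            ],
        }
        return json.dumps(payload, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "BenchmarkReport":
        payload = json.loads(text)
        dists, freqs, records, failures = {}, {}, {}, {}
        for run in payload["runs"]:
            key = (run["run_name"], run["task"])
            dists[key] = np.asarray(run["bacc"], dtype=float)
            freqs[key] = [tuple(r) for r in run["frequency_table"]]
            records[key] = run.get("records", [])
            failures[key] = run.get("failures", [])
        return cls(payload["baseline_bacc"], dists, freqs,
                   payload["repetitions"], records, failures)


def _dispatch(
    spec: SelectorSpec,
    table: FeatureTable,
    y: np.ndarray,
    cv: CVScheme,
    seed: int,
) -> sel.SelectionResult:
    fam = spec.family.lower()
    scheme = CVScheme(cv.k, cv.stratified, seed)
    if fam == "rnd":
        return sel.select_random(table, spec.p, seed)
    if fam == "hcfr":
        return sel.select_hcfr(
            table, sel.HCFRParams(spec.params.get("max_correlation", 0.95), seed)
        )
    if fam == "rfe":
        haff = sel.HAFFParams(**spec.params.get("haff", {})) if spec.haff else None
        return sel.select_rfe(table, y, sel.RFEParams(spec.p, haff=haff))
    if fam == "rfecv":
        return sel.select_rfe_cv_auto(
            table, y, scheme, spec.params.get("trade_off_sd", 1.0)
        )
    if fam == "sda":
        return sel.select_sda(
            table, y, sel.SDAParams(spec.p, gamma=spec.params.get("gamma", 0.1))
        )
    if fam == "ga":
        ga = sel.GAParams(target_p=spec.p, seed=seed,
                          **spec.params.get("ga", {}))
        return sel.select_ga(table, y, ga, scheme)
    if fam in ("sda-ga", "rfe-ga"):
        ga = sel.GAParams(target_p=spec.p, **spec.params.get("ga", {}))
        haff = sel.HAFFParams(**spec.params.get("haff", {})) if spec.haff else None
        return sel.dual_phase(
            table, y, fam.split("-")[0].upper(), spec.q, ga, scheme,
            haff=haff, seed=seed,
        )
    raise ValueError(f"unknown selector family {spec.family!r}")


def run_benchmark(
    table: FeatureTable,
    labels: LabelSet,
    config: BenchmarkConfig,
) -> BenchmarkReport:
    """Execute every selector_spec x task for R seeded repetitions.

    Repetition i uses seed base_seed + i for both the selector and the
    scoring CV split, so repetitions are independent but the whole report
    is a pure function of (data, config). Failed repetitions are
    recorded with their reason; a run aborts if more than 20% fail.
    """
    catalog = feature_catalog() if table.n_features == 120 else None
    baseline = {
        task: cv_bacc(table, labels.task(task),
                      CVScheme(config.cv.k, config.cv.stratified,
                               config.base_seed)).mean
        for task in config.tasks
    }
    R = config.repetitions
    distributions, freq_tables, records, failures = {}, {}, {}, {}
    for spec in config.selector_specs:
        run_name = spec.run_name()
        for task in config.tasks:
            y = labels.task(task)
            baccs, recs, fails = [], [], []
            counts: dict[str, int] = {}
            for i in range(R):
                seed = config.base_seed + i
                try:
                    result = _dispatch(spec, table, y, config.cv, seed)
                    scheme = CVScheme(config.cv.k, config.cv.stratified, seed)
                    score = cv_bacc(table.subset(result.selected), y, scheme)
                    baccs.append(score.mean)
                    for f in result.selected:
                        counts[f] = counts.get(f, 0) + 1
                    recs.append(
                        {"seed": seed, "n_selected": len(result.selected),
                         "bacc": score.mean, "bacc_sd": score.sd,
                         "selected": result.selected}
                    )
                except Exception as exc:  # noqa: BLE001 - recorded, not hidden
                    baccs.append(float("nan"))
                    fails.append({"seed": seed, "reason": repr(exc)})
            if len(fails) > 0.2 * R:
                raise RuntimeError(
                    f"run {run_name}/{task}: {len(fails)}/{R} repetitions "
                    f"failed; first: {fails[0]['reason']}"
                )
            key = (run_name, task)
            distributions[key] = np.asarray(baccs)
            records[key] = recs
            failures[key] = fails
            freq_tables[key] = _frequency_rows(counts, R, catalog)
    return BenchmarkReport(baseline, distributions, freq_tables, R,
                           records, failures)


def _frequency_rows(
    counts: dict[str, int],
    denominator: int,
    catalog: Optional[list[FeatureCatalogEntry]],
) -> list[tuple[str, str, int, int]]:
    classes = {e.name: e.feature_class.value for e in catalog} if catalog else {}
    rows = [
        (name, classes.get(name, "unknown"), num, denominator)
        for name, num in counts.items()
    ]
    rows.sort(key=lambda r: (r[1], -r[2], r[0]))
    return rows


def selection_frequency_table(
    results: list[sel.SelectionResult],
    catalog: Optional[list[FeatureCatalogEntry]] = None,
) -> list[tuple[str, str, int, int]]:
    """Per-feature selection counts over repeated runs of one selector.

    Rows are (feature_name, feature_class, numerator, denominator),
    sorted by class then descending count; render a row as
    ``f"{num}/{den}"`` for the published table style.
    """
    if not results:
        return []
    counts: dict[str, int] = {}
    for res in results:
        for f in res.selected:
            counts[f] = counts.get(f, 0) + 1
    return _frequency_rows(counts, len(results), catalog)


def summarize_distributions(report: BenchmarkReport) -> pd.DataFrame:
    """Five-number summary plus mean per (run_name, task), with baseline."""
    rows = []
    for (run, task), dist in report.distributions.items():
        d = dist[np.isfinite(dist)]
        q = np.percentile(d, [0, 25, 50, 75, 100]) if d.size else [np.nan] * 5
        rows.append(
            {
                "run_name": run,
                "task": task,
                "min": q[0], "q1": q[1], "median": q[2], "q3": q[3],
                "max": q[4],
                "mean": float(d.mean()) if d.size else np.nan,
                "baseline": report.baseline_bacc[task],
            }
        )
    return pd.DataFrame(rows)


def plot_distributions(report: BenchmarkReport, path: str | Path) -> None:
    """Boxplots of the per-run BACC distributions with baseline overlays."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    tasks = sorted({task for _, task in report.distributions})
    fig, axes = plt.subplots(
        len(tasks), 1, figsize=(8, 3 * len(tasks)), squeeze=False
    )
    for ax, task in zip(axes.ravel(), tasks):
        runs = [r for (r, t) in report.distributions if t == task]
        data = [
            report.distributions[(r, task)][
                np.isfinite(report.distributions[(r, task)])
            ]
            for r in runs
        ]
        ax.boxplot(data, tick_labels=runs)
        ax.axhline(report.baseline_bacc[task], color="green", ls="-.",
                   label="baseline (all features)")
        ax.set_ylabel("BACC")
        ax.set_title(task)
        ax.tick_params(axis="x", rotation=45)
        ax.legend(loc="lower left", fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def write_report(report: BenchmarkReport, report_dir: str | Path) -> None:
    """Persist report JSON, summary CSV and frequency CSVs."""
    out = Path(report_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "report.json").write_text(report.to_json())
    summarize_distributions(report).to_csv(out / "summary.csv", index=False)
    for (run, task), rows in report.frequency_tables.items():
        df = pd.DataFrame(
            rows,
            columns=["feature_name", "feature_class",
                     "frequency_numerator", "frequency_denominator"],
        )
        df.to_csv(out / f"frequencies_{run}_{task}.csv", index=False)
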