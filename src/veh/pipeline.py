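"""End-to-end orchestration of the three-stage selection workflow.

read -> impute -> normalize -> variance filter -> extra-trees gate ->
repeated independent HHO runs -> per-run classifier evaluation ->
selection of the reported subset.  Every run derives its own child
seed from the global seed, so a whole multi-run experiment is
reproducible from one integer.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .datatypes import ExpressionDataset, GeneSubset, VehError
from .evaluation import (
    ClassifierConfig,
    CVReport,
    repeated_cv_evaluate,
    select_optimal_subset,
)
from .expression_io import (
    LayoutConfig,
    impute_missing_mean,
    minmax_normalize,
    read_expression_table,
    write_gene_list,
    write_run_report,
)
from .hho import FitnessConfig, HHOConfig, HHOTrace, hho_select
from .prefilter import ERTConfig, FilterConfig, ert_filter, variance_filter

__all__ = ["RunConfig", "RunResult", "preprocess", "run_veh", "run_fixed_subset"]

logger = logging.getLogger("veh")


@dataclass
class RunConfig:
    """Everything needed for one full experiment on one dataset."""

    data_path: str | Path | None = None
    layout: LayoutConfig = field(default_factory=LayoutConfig)
    filter_cfg: FilterConfig = field(default_factory=FilterConfig)
    ert_cfg: ERTConfig = field(default_factory=ERTConfig)
    hho_cfg: HHOConfig = field(default_factory=HHOConfig)
    fitness_cfg: FitnessConfig = field(default_factory=FitnessConfig)
    classifiers: tuple[str, ...] = ("dt", "svm", "lr")
    repeats: int = 10
    cv_folds: int = 10
    n_independent_runs: int = 10
    seed: int = 0
    output_dir: str | Path | None = None
    leakage_safe_normalization: bool = False

    def __post_init__(self) -> None:
        if self.n_independent_runs < 1:
            raise VehError("n_independent_runs must be >= 1")
        for kind in self.classifiers:
            ClassifierConfig(kind=kind)  # validates


@dataclass
class RunResult:
    """Per-stage counts, per-run subsets/traces, reports, and the winner."""

    dataset_name: str
    stage_counts: dict[str, int]
    run_subsets: list[GeneSubset]
    run_traces: list[HHOTrace]
    run_reports: list[dict[str, CVReport]]
    selected: GeneSubset
    selected_reports: dict[str, CVReport]
    seed: int
    child_seeds: list[int]

    def summary(self) -> dict:
        return {
            "dataset": self.dataset_name,
            "stage_counts": self.stage_counts,
            "selected_size": len(self.selected),
            "selected_features": self.selected.feature_ids,
            "selected_fitness": self.selected.fitness,
            "metrics": {
                kind: dataclasses.asdict(rep)
                for kind, rep in self.selected_reports.items()
            },
            "seed": self.seed,
            "child_seeds": self.child_seeds,
        }


def preprocess(ds: ExpressionDataset) -> ExpressionDataset:
    """Mean-impute then min-max normalize (the fixed preprocessing order)."""
    return minmax_normalize(impute_missing_mean(ds))


def _child_seeds(seed: int, n: int) -> list[int]:
    # stable 32-bit child seeds derived from the global seed
    ss = np.random.SeedSequence(seed)
    return [int(s) for s in ss.generate_state(n) % (2**31)]


def run_veh(
    cfg: RunConfig, ds: ExpressionDataset | None = None
) -> RunResult:
    """Run the full three-stage pipeline with repeated optimizer runs.

    ``ds`` may be passed directly (e.g. a synthetic dataset); otherwise
    ``cfg.data_path`` is read.  Whole-dataset normalization before CV is
    the default for fidelity with the published protocol; set
    ``leakage_safe_normalization`` to refit scaling per training fold
    during evaluation instead.
    """
    if ds is None:
        if cfg.data_path is None:
            raise VehError("either a dataset or cfg.data_path is required")
        ds = read_expression_table(cfg.data_path, cfg.layout)
    raw_count = ds.n_genes
    imputed = impute_missing_mean(ds)
    normalized = minmax_normalize(imputed)

    # stage 1 scores raw (imputed) intensities unless configured otherwise;
    # downstream stages always see the normalized values
    stage1 = variance_filter(
        normalized if cfg.filter_cfg.on_normalized else imputed,
        cfg.filter_cfg,
    )
    stage1.dataset = normalized.subset_genes(stage1.kept_indices)
    ds = normalized
    logger.info(
        "variance filter: %d -> %d genes", raw_count, stage1.dataset.n_genes
    )
    ert_cfg = dataclasses.replace(cfg.ert_cfg, seed=cfg.seed)
    stage2 = ert_filter(stage1.dataset, ert_cfg)
    logger.info(
        "extra-trees gate: %d -> %d genes",
        stage1.dataset.n_genes,
        stage2.dataset.n_genes,
    )

    child_seeds = _child_seeds(cfg.seed, cfg.n_independent_runs)
    run_subsets: list[GeneSubset] = []
    run_traces: list[HHOTrace] = []
    run_reports: list[dict[str, CVReport]] = []
    for run_idx, child in enumerate(child_seeds):
        hcfg = dataclasses.replace(cfg.hho_cfg, seed=child)
        fcfg = dataclasses.replace(cfg.fitness_cfg, eval_seed=child)
        subset, trace = hho_select(stage2.dataset, hcfg, fcfg)
        subset.source_run = run_idx
        reports = {
            kind: repeated_cv_evaluate(
                ds,
                subset,
                ClassifierConfig(kind=kind),
                repeats=cfg.repeats,
                folds=cfg.cv_folds,
                seed=cfg.seed,
                fold_normalize=cfg.leakage_safe_normalization,
            )
            for kind in cfg.classifiers
        }
        # headline accuracy for subset selection: best classifier mean
        subset.accuracy = max(rep.acc for rep in reports.values())
        run_subsets.append(subset)
        run_traces.append(trace)
        run_reports.append(reports)
        logger.info(
            "run %d: %d genes, fitness %.5f, best acc %.2f",
            run_idx,
            len(subset),
            subset.fitness,
            subset.accuracy,
        )

    selected = select_optimal_subset(run_subsets)
    selected_reports = run_reports[selected.source_run]

    result = RunResult(
        dataset_name=ds.name,
        stage_counts={
            "raw": raw_count,
            "post_variance": stage1.dataset.n_genes,
            "post_ert": stage2.dataset.n_genes,
            "final": len(selected),
        },
        run_subsets=run_subsets,
        run_traces=run_traces,
        run_reports=run_reports,
        selected=selected,
        selected_reports=selected_reports,
        seed=cfg.seed,
        child_seeds=child_seeds,
    )
    if cfg.output_dir is not None:
        _write_outputs(result, Path(cfg.output_dir))
    return result


def run_fixed_subset(
    cfg: RunConfig,
    feature_ids: list[str],
    ds: ExpressionDataset | None = None,
) -> dict[str, CVReport]:
    """Evaluate a fixed (externally given) subset with every classifier.

    Preprocesses exactly as :func:`run_veh`, restricts to the named
    features, and runs the repeated-CV protocol; used to re-score a
    published gene list without re-running selection.
    """
    if ds is None:
        if cfg.data_path is None:
            raise VehError("either a dataset or cfg.data_path is required")
        ds = read_expression_table(cfg.data_path, cfg.layout)
    ds = preprocess(ds)
    subset = GeneSubset(feature_ids=list(feature_ids))
    return {
        kind: repeated_cv_evaluate(
            ds,
            subset,
            ClassifierConfig(kind=kind),
            repeats=cfg.repeats,
            folds=cfg.cv_folds,
            seed=cfg.seed,
            fold_normalize=cfg.leakage_safe_normalization,
        )
        for kind in cfg.classifiers
    }


def _write_outputs(result: RunResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    write_gene_list(result.selected, out_dir / "selected_genes.txt")
    write_run_report(result.summary(), out_dir / "report.json")
    # per-run convergence traces
    lines = ["run,iteration,best_fitness,subset_size"]
    for run_idx, trace in enumerate(result.run_traces):
        for it, (f, s) in enumerate(
            zip(trace.best_fitness_per_iter, trace.best_size_per_iter)
        ):
            lines.append(f"{run_idx},{it},{f:.10g},{s}")
    (out_dir / "trace.csv").write_text("\n".join(lines) + "\n")
    # metrics table, one row per classifier
    mlines = ["dataset,classifier,acc,sd,precision,recall,f1"]
    for kind, rep in result.selected_reports.items():
        mlines.append(
            f"{result.dataset_name},{kind},{rep.acc:.2f},{rep.sd:.2f},"
            f"{rep.precision:.2f},{rep.recall:.2f},{rep.f1:.2f}"
        )
    (out_dir / "metrics.csv").write_text("\n".join(mlines) + "\n")
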