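"""End-to-end orchestration: dataset -> features -> statistics -> redundancy
-> composite index -> evaluation, with deterministic seeding and a run log.

Artifacts written to the output directory:

* ``features.csv``       — id, label, 36 descriptors
* ``results.csv``        — full univariate report (one row per feature)
* ``results_table.csv``  — formatted report (median [Q1,Q3], HL [CI], ...)
* ``results.json``       — machine-readable univariate results
* ``rho.csv``            — Spearman matrix over the redundancy feature set
* ``clusters.json``      — redundancy clusters and retained representatives
* ``composite_model.json`` / ``metrics.csv`` — the index and its evaluation
* ``run_log.json``       — config, seed, library versions, table provenance
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import composite as composite_mod
from . import redundancy as redundancy_mod
from .features import FeatureMatrix, extract_features
from .residue_tables import ResiduePropertyTables, load_default_tables
from .sequence_io import LabeledDataset, write_feature_table
from .univariate import (
    StatsConfig,
    UnivariateResult,
    analyze_all,
    format_results_table,
    results_to_dataframe,
)


@dataclass
class PipelineConfig:
    fdr_alpha: float = 0.05
    bootstrap_B: int = 2000
    rho_threshold: float = 0.85
    delta_floor: float = 0.1
    representative_preference: tuple[str, ...] = ("length",)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.fdr_alpha < 1.0:
            raise ValueError("fdr_alpha must be in (0, 1)")
        if self.bootstrap_B != 0 and self.bootstrap_B < 100:
            raise ValueError("bootstrap_B must be 0 or >= 100")
        if not 0.0 < self.rho_threshold <= 1.01:
            raise ValueError("rho_threshold must be in (0, 1.01]")


@dataclass
class PipelineResult:
    matrix: FeatureMatrix
    results: list[UnivariateResult]
    redundancy: redundancy_mod.RedundancyReport | None
    model: composite_mod.CompositeModel | None
    metrics: composite_mod.ClassificationMetrics | None
    outdir: Path | None = None


def _select_redundancy_features(
    results: Sequence[UnivariateResult], alpha: float, delta_floor: float
) -> list[str]:
    """Significant features (q < alpha) with |delta| above the floor, ranked
    by |delta| descending (the set entering the redundancy stage)."""
    eligible = [r for r in results if r.q_value < alpha and abs(r.delta) >= delta_floor]
    eligible.sort(key=lambda r: (-abs(r.delta), r.feature_name))
    return [r.feature_name for r in eligible]


def run_all(
    dataset: LabeledDataset,
    config: PipelineConfig | None = None,
    outdir: str | Path | None = None,
    tables: ResiduePropertyTables | None = None,
) -> PipelineResult:
    """Run every stage on a labeled dataset; optionally write all artifacts."""
    config = config or PipelineConfig()
    tables = tables or load_default_tables()

    matrix = extract_features(dataset, tables)
    stats_cfg = StatsConfig(bootstrap_B=config.bootstrap_B, seed=config.seed)
    results = analyze_all(matrix, stats_cfg)
    delta_by_feature = {r.feature_name: r.delta for r in results}

    red_features = _select_redundancy_features(
        results, config.fdr_alpha, config.delta_floor
    )
    report = None
    retained = red_features
    if len(red_features) >= 2:
        report = redundancy_mod.build_report(
            matrix,
            red_features,
            delta_by_feature,
            threshold=config.rho_threshold,
            preference=config.representative_preference,
        )
        retained = report.retained

    model = None
    metrics = None
    if retained:
        model = composite_mod.fit_composite(matrix, results, retained)
        scores = composite_mod.composite_score(model, matrix)
        labels = (matrix.labels == "soluble").astype(int)
        metrics = composite_mod.evaluate(scores, labels, threshold=0.0)

    out = PipelineResult(
        matrix=matrix,
        results=results,
        redundancy=report,
        model=model,
        metrics=metrics,
    )
    if outdir is not None:
        out.outdir = _write_artifacts(out, dataset, config, tables, Path(outdir))
    return out


def _write_artifacts(
    result: PipelineResult,
    dataset: LabeledDataset,
    config: PipelineConfig,
    tables: ResiduePropertyTables,
    outdir: Path,
) -> Path:
    outdir.mkdir(parents=True, exist_ok=True)
    write_feature_table(result.matrix, outdir / "features.csv")
    results_to_dataframe(result.results).to_csv(outdir / "results.csv", index=False)
    format_results_table(result.results).to_csv(outdir / "results_table.csv", index=False)
    (outdir / "results.json").write_text(
        json.dumps([r.to_dict() for r in result.results], indent=2)
    )
    if result.redundancy is not None:
        result.redundancy.rho_dataframe().to_csv(outdir / "rho.csv")
        result.redundancy.to_json(outdir / "clusters.json")
    if result.model is not None:
        result.model.to_json(outdir / "composite_model.json")
    if result.metrics is not None:
        result.metrics.to_dataframe().to_csv(outdir / "metrics.csv", index=False)
    log = {
        "seed": config.seed,
        "config": {
            "fdr_alpha": config.fdr_alpha,
            "bootstrap_B": config.bootstrap_B,
            "rho_threshold": config.rho_threshold,
            "delta_floor": config.delta_floor,
            "representative_preference": list(config.representative_preference),
        },
        "dataset": {
            "n_records": len(dataset),
            "label_counts": dataset.label_counts(),
            "provenance": dataset.provenance,
        },
        "tables_provenance": dict(tables.provenance),
        "versions": _versions(),
    }
    (outdir / "run_log.json").write_text(json.dumps(log, indent=2, default=str))
    return outdir


def _versions() -> dict[str, str]:
    import Bio
    import scipy

    from . import __version__

    return {
        "soldissect": __version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "biopython": Bio.__version__,
    }
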