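"""End-to-end orchestration: simulate/read -> QC -> proportions -> stratify -> DPA.

Each enabled stage writes its tables into the output directory; a JSON run
manifest records inputs, seeds, package version, and the cell-count ledger
before/after every stage so removals can be audited. A stage failure writes a
failure marker next to any partial outputs and re-raises with a stage-tagged
message.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import pandas as pd

from . import __version__
from .composition import cluster_proportions, proportion_difference
from .composition import stratify as apply_stratification
from .dpa import dpa_test
from .io import (
    AnalysisConfig,
    read_cell_table,
    read_count_matrix,
    write_cell_table,
    write_count_matrix,
)
from .qc import compute_qc_metrics, filter_cells
from .synthetic import simulate_cell_table, simulate_clinical, simulate_count_matrix

logger = logging.getLogger("scdpa")

__all__ = ["run_pipeline", "dpa_result_table", "write_dpa_table"]


def dpa_result_table(result) -> pd.DataFrame:
    """DPA output in the canonical TSV column order."""
    cols = [
        "cluster", "n_ref", "n_test", "prop_ref", "prop_test",
        "statistic", "p_empirical", "p_bonferroni", "significant", "reliable",
    ]
    return result.table[cols]


def write_dpa_table(result, path) -> None:
    dpa_result_table(result).to_csv(path, sep="\t", index=False, float_format="%.10g")


def _stage(name):
    def wrap(fn):
        fn._stage_name = name
        return fn
    return wrap


def run_pipeline(config: AnalysisConfig, out_dir) -> Path:
    """Run the enabled stages in order; returns the artifact directory.

    Deterministic: equal master seeds give byte-identical outputs.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))

    manifest = {
        "version": __version__,
        "master_seed": config.seed,
        "inputs": {"cells_path": config.cells_path, "clinical_path": config.clinical_path},
        "stages": [],
        "cell_counts": {},
    }
    current_stage = "setup"
    try:
        # ---- cells ---------------------------------------------------------
        current_stage = "cells"
        if config.cells_path is not None:
            cells = read_cell_table(config.cells_path, config.columns, sep=config.sep)
            manifest["inputs"]["source"] = "file"
        else:
            if config.simulate is None:
                raise ValueError("config needs either cells_path or a simulate spec")
            spec = dataclasses.replace(config.simulate, seed=config.seed)
            cells = simulate_cell_table(spec)
            manifest["inputs"]["source"] = "simulated"
        manifest["cell_counts"]["input"] = len(cells)
        manifest["stages"].append("cells")
        write_cell_table(cells, out / "cells.tsv")
        logger.info("cells stage: %d cells", len(cells))

        # ---- counts + QC ---------------------------------------------------
        matrix = None
        if config.simulate_counts and config.cells_path is None:
            current_stage = "counts"
            matrix = simulate_count_matrix(cells, config.gene_model, seed=config.seed)
            write_count_matrix(matrix, out / "counts")
            manifest["stages"].append("counts")

        n_before_qc = len(cells)
        if config.qc_enabled and matrix is not None:
            current_stage = "qc"
            metrics = compute_qc_metrics(matrix)
            cells = cells.merge(metrics, on="cell_id", how="left")
            kept, report = filter_cells(cells, config.qc_thresholds)
            report.to_frame().to_csv(out / "qc_report.tsv", sep="\t", index=False)
            kept["cell_id"].to_csv(out / "barcodes_kept.tsv", sep="\t", index=False, header=False)
            logger.info(
                "qc stage: %d -> %d cells (low_features=%d, high_counts=%d, high_mito=%d)",
                report.n_input, report.n_kept, report.low_features,
                report.high_counts, report.high_mito,
            )
            cells = kept
            manifest["qc_removals"] = {
                "low_features": report.low_features,
                "high_counts": report.high_counts,
                "high_mito": report.high_mito,
            }
            manifest["stages"].append("qc")
        manifest["cell_counts"]["before_qc"] = n_before_qc
        manifest["cell_counts"]["after_qc"] = len(cells)
        write_cell_table(cells, out / "cells_filtered.tsv")

        # ---- clinical ------------------------------------------------------
        clinical = None
        current_stage = "clinical"
        if config.clinical_path is not None:
            clinical = pd.read_csv(config.clinical_path, sep=config.sep)
        elif config.cells_path is None and len(cells):
            sample_cond = cells.drop_duplicates("sample_id")[["sample_id", "condition"]]
            cmodel = dataclasses.replace(config.clinical_model, seed=config.seed)
            clinical = simulate_clinical(
                sample_cond["sample_id"].tolist(), sample_cond["condition"].tolist(), cmodel
            )
        if clinical is not None:
            clinical.to_csv(out / "clinical.tsv", sep="\t", index=False, float_format="%.10g")
            manifest["stages"].append("clinical")

        # ---- proportions ---------------------------------------------------
        current_stage = "proportions"
        pt = cluster_proportions(cells, "condition", "cluster", sample_col="sample_id")
        pt.proportions.to_csv(out / "proportions.tsv", sep="\t", float_format="%.10g")
        pt.counts.to_csv(out / "cluster_counts.tsv", sep="\t")
        manifest["stages"].append("proportions")

        # ---- stratify + DPA ------------------------------------------------
        comparisons = [("condition", "dpa_condition.tsv")]
        rules = config.resolved_rules()
        if rules and clinical is None:
            raise ValueError("stratification rules given but no clinical table available")
        current_stage = "stratify"
        for rule in rules:
            cells = apply_stratification(cells, clinical, rule)
            comparisons.append((rule.name, f"dpa_{rule.name}.tsv"))
        if rules:
            write_cell_table(cells, out / "cells_stratified.tsv")
            manifest["stages"].append("stratify")

        if config.dpa_enabled:
            current_stage = "dpa"
            cfg = dataclasses.replace(config.dpa, seed=config.seed)
            for group_col, fname in comparisons:
                n_groups = cells[group_col].nunique()
                if n_groups != 2:
                    logger.warning(
                        "skipping DPA on %r: %d group(s), need exactly 2", group_col, n_groups
                    )
                    continue
                result = dpa_test(cells, cfg, group_col=group_col, cluster_col="cluster")
                write_dpa_table(result, out / fname)
                logger.info(
                    "dpa stage (%s): %d/%d clusters significant at alpha=%g",
                    group_col, int(result.table["significant"].sum()),
                    result.n_clusters_tested, cfg.alpha,
                )
            manifest["stages"].append("dpa")
            manifest["dpa"] = {"w": cfg.w, "iterations": cfg.iterations,
                               "alpha": cfg.alpha, "seed": cfg.seed}
    except Exception as exc:
        (out / "FAILED").write_text(f"stage {current_stage}: {exc}\n", encoding="utf-8")
        raise RuntimeError(f"pipeline failed at stage {current_stage!r}: {exc}") from exc

    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return out
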