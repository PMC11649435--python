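"""Readers/writers for the pipeline's formats and the analysis configuration.

Canonical table dialect is tab-separated UTF-8 with a header row; comma-
separated files are accepted on read via ``sep=","``. Count matrices travel as
Matrix Market coordinate files with ``genes.tsv``/``barcodes.tsv`` sidecars.
Configurations round-trip losslessly through YAML. Column bindings let tables
from external atlases be analysed under their own header names.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
import yaml

from .composition import BUILTIN_RULES, StratificationRule
from .dpa import DPAConfig
from .qc import QCThresholds
from .synthetic import ClinicalModel, CompositionSpec, GeneMatrix, GeneModel

__all__ = [
    "ColumnBindings",
    "AnalysisConfig",
    "read_cell_table",
    "write_cell_table",
    "read_count_matrix",
    "write_count_matrix",
    "load_config",
    "save_config",
]


@dataclass(frozen=True)
class ColumnBindings:
    """Names of the required columns as they appear in the input files."""

    cell_id: str = "cell_id"
    sample_id: str = "sample_id"
    condition: str = "condition"
    cluster: str = "cluster"

    def __post_init__(self):
        names = [self.cell_id, self.sample_id, self.condition, self.cluster]
        if len(set(names)) != len(names):
            raise ValueError(f"bound column names must be distinct; got {names}")


def read_cell_table(
    path,
    bindings: ColumnBindings = ColumnBindings(),
    sep: str = "\t",
    require: tuple[str, ...] = ("cell_id", "sample_id", "condition", "cluster"),
) -> pd.DataFrame:
    """Read a delimited cell table, validating and renaming bound columns.

    Bound columns are renamed to their canonical names (cell_id, sample_id,
    condition, cluster); unknown columns are preserved as-is. Missing bound
    columns and duplicate cell ids are errors. An empty file yields an empty
    table with the canonical columns.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=sep, dtype={bindings.cell_id: str, bindings.sample_id: str})
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=list(require))
    rename = {}
    for canonical in require:
        bound = getattr(bindings, canonical)
        if bound not in df.columns:
            raise ValueError(f"{path}: missing bound column {bound!r} (for {canonical})")
        rename[bound] = canonical
    df = df.rename(columns=rename)
    if "cell_id" in df.columns and df["cell_id"].duplicated().any():
        dups = df["cell_id"][df["cell_id"].duplicated()].head(3).tolist()
        raise ValueError(f"{path}: duplicate cell ids, e.g. {dups}")
    return df


def write_cell_table(table: pd.DataFrame, path, sep: str = "\t") -> None:
    table.to_csv(path, sep=sep, index=False)


def read_count_matrix(mtx_path, genes_path, barcodes_path) -> GeneMatrix:
    """Read Matrix Market counts with gene/barcode sidecars (genes x cells)."""
    counts = sp.csr_matrix(scipy.io.mmread(str(mtx_path)))
    genes = pd.read_csv(genes_path, sep="\t", header=None)[0].to_numpy(dtype=object)
    barcodes = pd.read_csv(barcodes_path, sep="\t", header=None)[0].to_numpy(dtype=object)
    if counts.shape[0] != len(genes):
        raise ValueError(
            f"matrix has {counts.shape[0]} rows but {len(genes)} gene names"
        )
    if counts.shape[1] != len(barcodes):
        raise ValueError(
            f"matrix has {counts.shape[1]} columns but {len(barcodes)} barcodes"
        )
    return GeneMatrix(counts=counts, gene_names=genes, cell_ids=barcodes)


def write_count_matrix(matrix: GeneMatrix, out_dir) -> dict[str, Path]:
    """Write matrix.mtx + genes.tsv + barcodes.tsv into ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "mtx": out / "matrix.mtx",
        "genes": out / "genes.tsv",
        "barcodes": out / "barcodes.tsv",
    }
    scipy.io.mmwrite(str(paths["mtx"]), sp.coo_matrix(matrix.counts))
    pd.Series(matrix.gene_names).to_csv(paths["genes"], sep="\t", index=False, header=False)
    pd.Series(matrix.cell_ids).to_csv(paths["barcodes"], sep="\t", index=False, header=False)
    return paths


@dataclass
class AnalysisConfig:
    """End-to-end pipeline configuration.

    When ``cells_path`` is None the cohort is simulated from ``simulate``
    (and, when ``simulate_counts`` is on, UMI counts from ``gene_model``
    and per-sample clinical covariates from ``clinical_model``). Stage
    toggles: ``qc_enabled`` (needs counts), ``stratify_rules`` (names of
    built-in rules or inline rule definitions), ``dpa_enabled``. ``seed`` is
    the master seed recorded in the run manifest; every stage derives its
    stream from it.
    """

    seed: int = 0
    columns: ColumnBindings = field(default_factory=ColumnBindings)
    cells_path: str | None = None
    sep: str = "\t"
    simulate: CompositionSpec | None = None
    simulate_counts: bool = False
    gene_model: GeneModel = field(default_factory=GeneModel)
    clinical_model: ClinicalModel = field(default_factory=ClinicalModel)
    clinical_path: str | None = None
    qc_enabled: bool = True
    qc_thresholds: QCThresholds = field(default_factory=QCThresholds)
    stratify_rules: list = field(default_factory=list)
    dpa_enabled: bool = True
    dpa: DPAConfig = field(default_factory=DPAConfig)
    log_level: str = "INFO"

    def resolved_rules(self) -> list[StratificationRule]:
        rules = []
        for r in self.stratify_rules:
            if isinstance(r, StratificationRule):
                rules.append(r)
            elif isinstance(r, str):
                if r not in BUILTIN_RULES:
                    raise ValueError(f"unknown built-in rule {r!r}; known: {sorted(BUILTIN_RULES)}")
                rules.append(BUILTIN_RULES[r])
            elif isinstance(r, dict):
                rules.append(StratificationRule(**{
                    k: tuple(v) if isinstance(v, list) else v for k, v in r.items()
                }))
            else:
                raise TypeError(f"cannot interpret stratification rule {r!r}")
        return rules


def _spec_to_dict(spec: CompositionSpec) -> dict:
    return {
        "cluster_names": list(spec.cluster_names),
        "baseline_proportions": [float(x) for x in spec.baseline_proportions],
        "effect_multipliers": {c: [float(x) for x in m] for c, m in spec.effect_multipliers.items()},
        "n_samples_per_condition": {c: int(n) for c, n in spec.n_samples_per_condition.items()},
        "dirichlet_concentration": float(spec.dirichlet_concentration),
        "cells_per_sample": (
            list(spec.cells_per_sample)
            if isinstance(spec.cells_per_sample, (tuple, list))
            else int(spec.cells_per_sample)
        ),
        "seed": int(spec.seed),
    }


def _spec_from_dict(d: dict) -> CompositionSpec:
    d = dict(d)
    if isinstance(d.get("cells_per_sample"), list):
        d["cells_per_sample"] = tuple(d["cells_per_sample"])
    return CompositionSpec(**d)


def _clinical_to_dict(m: ClinicalModel) -> dict:
    return {
        "creatinine": {c: list(v) for c, v in m.creatinine.items()},
        "egfr": {c: list(v) for c, v in m.egfr.items()},
        "age_mean": m.age_mean,
        "age_sd": m.age_sd,
        "sex_probabilities": dict(m.sex_probabilities),
        "seed": m.seed,
    }


def _clinical_from_dict(d: dict) -> ClinicalModel:
    d = dict(d)
    for key in ("creatinine", "egfr"):
        if key in d:
            d[key] = {c: tuple(v) for c, v in d[key].items()}
    return ClinicalModel(**d)


def config_to_dict(config: AnalysisConfig) -> dict:
    """Plain-dict form of a config (YAML-safe, lossless round-trip)."""
    rules = []
    for r in config.stratify_rules:
        if isinstance(r, StratificationRule):
            rules.append({k: list(v) if isinstance(v, tuple) else v
                          for k, v in dataclasses.asdict(r).items()})
        else:
            rules.append(r)
    return {
        "seed": config.seed,
        "columns": dataclasses.asdict(config.columns),
        "cells_path": config.cells_path,
        "sep": config.sep,
        "simulate": _spec_to_dict(config.simulate) if config.simulate else None,
        "simulate_counts": config.simulate_counts,
        "gene_model": dataclasses.asdict(config.gene_model),
        "clinical_model": _clinical_to_dict(config.clinical_model),
        "clinical_path": config.clinical_path,
        "qc_enabled": config.qc_enabled,
        "qc_thresholds": dataclasses.asdict(config.qc_thresholds),
        "stratify_rules": rules,
        "dpa_enabled": config.dpa_enabled,
        "dpa": dataclasses.asdict(config.dpa),
        "log_level": config.log_level,
    }


def config_from_dict(d: dict) -> AnalysisConfig:
    d = dict(d)
    kwargs = {
        "seed": d.get("seed", 0),
        "columns": ColumnBindings(**d.get("columns", {})),
        "cells_path": d.get("cells_path"),
        "sep": d.get("sep", "\t"),
        "simulate": _spec_from_dict(d["simulate"]) if d.get("simulate") else None,
        "simulate_counts": d.get("simulate_counts", False),
        "gene_model": GeneModel(**d.get("gene_model", {})),
        "clinical_model": _clinical_from_dict(d.get("clinical_model", {})),
        "clinical_path": d.get("clinical_path"),
        "qc_enabled": d.get("qc_enabled", True),
        "qc_thresholds": QCThresholds(**d.get("qc_thresholds", {})),
        "stratify_rules": d.get("stratify_rules", []),
        "dpa_enabled": d.get("dpa_enabled", True),
        "dpa": DPAConfig(**d.get("dpa", {})),
        "log_level": d.get("log_level", "INFO"),
    }
    return AnalysisConfig(**kwargs)


def save_config(config: AnalysisConfig, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=False)


def load_config(path) -> AnalysisConfig:
    with open(path, encoding="utf-8") as fh:
        return config_from_dict(yaml.safe_load(fh))
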