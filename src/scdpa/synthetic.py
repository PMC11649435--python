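"""Synthetic cohorts with the statistical structure the analysis assumes.

Three generators, all reproducible from a single master seed:

* :func:`simulate_cell_table` draws per-sample cluster compositions from a
  Dirichlet centred on each condition's composition (Dirichlet-multinomial:
  between-sample overdispersion on top of multinomial counting noise) and
  assigns cluster labels per cell. Condition-level composition shifts are
  planted through per-cluster effect multipliers.
* :func:`simulate_count_matrix` draws sparse gene-by-cell UMI counts:
  negative-binomial totals per cell, multinomial allocation across genes with
  fixed lognormal gene weights, and the mitochondrial share binomially thinned
  toward a per-cell-class target. A designated low-quality cell class has
  totals low enough that its detected-gene count falls below the usual
  retention floor.
* :func:`simulate_clinical` draws per-sample clinical covariates (serum
  creatinine, eGFR, age, sex) whose distributions differ by condition so that
  clinical stratification correlates with the condition label.

Default cohort structure mirrors a two-condition kidney study: 42 normal and
23 chronic-kidney-disease samples (65 in total).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from ._rng import child_rng

__all__ = [
    "CompositionSpec",
    "GeneModel",
    "ClinicalModel",
    "GeneMatrix",
    "kidney_cohort_spec",
    "simulate_cell_table",
    "simulate_count_matrix",
    "simulate_clinical",
]

_SIMPLEX_TOL = 1e-12


@dataclass
class GeneMatrix:
    """Sparse gene-by-cell count matrix with name sidecars.

    ``counts`` is genes x cells; ``cell_classes`` (optional) records the
    generator's planted per-cell quality class for ground-truth tests.
    """

    counts: sp.spmatrix
    gene_names: np.ndarray
    cell_ids: np.ndarray
    cell_classes: np.ndarray | None = None

    def __post_init__(self):
        self.gene_names = np.asarray(self.gene_names, dtype=object)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        if self.counts.shape != (len(self.gene_names), len(self.cell_ids)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.gene_names)} genes x {len(self.cell_ids)} cells"
            )

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]


@dataclass
class CompositionSpec:
    """Generative model for per-sample cluster compositions.

    The condition named first in ``n_samples_per_condition`` is the reference;
    its effect multipliers are fixed to ones. A condition's composition is
    baseline_proportions * multipliers, renormalised. Per-sample compositions
    are Dirichlet(concentration * condition composition); a larger
    concentration means samples scatter less around their condition's
    composition (the infinite limit leaves pure multinomial noise).
    ``cells_per_sample`` is a fixed count or an inclusive (low, high) range
    sampled uniformly per sample.
    """

    cluster_names: Sequence[str]
    baseline_proportions: Sequence[float]
    effect_multipliers: Mapping[str, Sequence[float]]
    n_samples_per_condition: Mapping[str, int]
    dirichlet_concentration: float = 200.0
    cells_per_sample: int | tuple[int, int] = 1000
    seed: int = 0

    def __post_init__(self):
        self.baseline_proportions = np.asarray(self.baseline_proportions, dtype=float)
        k = len(self.cluster_names)
        if self.baseline_proportions.shape != (k,):
            raise ValueError("one baseline proportion per cluster required")
        if abs(self.baseline_proportions.sum() - 1.0) > _SIMPLEX_TOL:
            raise ValueError(
                f"baseline_proportions must sum to 1 within {_SIMPLEX_TOL}; "
                f"got {self.baseline_proportions.sum()!r}"
            )
        if (self.baseline_proportions < 0).any():
            raise ValueError("baseline_proportions must be non-negative")
        self.effect_multipliers = {
            c: np.asarray(m, dtype=float) for c, m in self.effect_multipliers.items()
        }
        for c, m in self.effect_multipliers.items():
            if m.shape != (k,):
                raise ValueError(f"condition {c!r}: one multiplier per cluster required")
            if (m < 0).any():
                raise ValueError(f"condition {c!r}: multipliers must be >= 0")
        if set(self.effect_multipliers) != set(self.n_samples_per_condition):
            raise ValueError("effect_multipliers and n_samples_per_condition must name the same conditions")
        for c, n in self.n_samples_per_condition.items():
            if n < 0:
                raise ValueError(f"condition {c!r}: sample count must be >= 0")
        if self.dirichlet_concentration <= 0:
            raise ValueError("dirichlet_concentration must be > 0")
        lo, hi = self._cells_range()
        if lo < 0 or hi < lo:
            raise ValueError(f"invalid cells_per_sample {self.cells_per_sample!r}")

    def _cells_range(self) -> tuple[int, int]:
        if isinstance(self.cells_per_sample, (tuple, list)):
            lo, hi = self.cells_per_sample
            return int(lo), int(hi)
        return int(self.cells_per_sample), int(self.cells_per_sample)

    @property
    def conditions(self) -> list[str]:
        return list(self.n_samples_per_condition)

    def condition_proportions(self, condition: str) -> np.ndarray:
        """Planted composition of one condition (baseline x multipliers, renormalised)."""
        p = self.baseline_proportions * self.effect_multipliers[condition]
        total = p.sum()
        if total <= 0:
            raise ValueError(f"condition {condition!r} has all-zero composition")
        return p / total


def kidney_cohort_spec(
    seed: int = 0,
    cells_per_sample: int | tuple[int, int] = 1000,
    dirichlet_concentration: float = 200.0,
) -> CompositionSpec:
    """Study-scale default cohort: 42 normal and 23 CKD samples.

    Eight lymphoid-like clusters; the disease condition contracts the
    CD16+ NK-like cluster and expands the CD4+ naive T-like cluster, the two
    headline shifts this kind of analysis is meant to detect. Effect sizes are
    test fixtures, not biological estimates.
    """
    clusters = [
        "CD16+_NK", "CD4+_naive_T", "CD4+_memory_T", "CD8+_T",
        "CD56bright_NK", "gdT", "Treg", "MAIT",
    ]
    baseline = np.array([0.20, 0.10, 0.20, 0.25, 0.08, 0.07, 0.06, 0.04])
    disease = np.array([0.06, 0.24, 0.20, 0.25, 0.08, 0.07, 0.06, 0.04])
    return CompositionSpec(
        cluster_names=clusters,
        baseline_proportions=baseline,
        effect_multipliers={"normal": np.ones(8), "ckd": disease / baseline},
        n_samples_per_condition={"normal": 42, "ckd": 23},
        dirichlet_concentration=dirichlet_concentration,
        cells_per_sample=cells_per_sample,
        seed=seed,
    )


def simulate_cell_table(spec: CompositionSpec) -> pd.DataFrame:
    """One row per cell: cell_id, sample_id, condition, cluster.

    Per sample, a composition is drawn from Dirichlet(concentration x the
    condition's planted composition) — clusters with planted proportion zero
    stay at exactly zero — and cluster labels are drawn multinomially from it.
    Byte-identical output for equal seeds.
    """
    rng = child_rng(spec.seed, "labels")
    k = len(spec.cluster_names)
    names = np.asarray(spec.cluster_names, dtype=object)
    lo, hi = spec._cells_range()

    rows = []
    for condition in spec.conditions:
        cond_p = spec.condition_proportions(condition)
        nz = cond_p > 0
        alpha = spec.dirichlet_concentration * cond_p[nz]
        for s in range(spec.n_samples_per_condition[condition]):
            sample_id = f"{condition}_s{s + 1:03d}"
            n_cells = int(rng.integers(lo, hi + 1)) if hi > lo else lo
            p = np.zeros(k)
            p[nz] = rng.dirichlet(alpha)
            cluster_counts = rng.multinomial(n_cells, p)
            labels = np.repeat(names, cluster_counts)
            rows.append(
                pd.DataFrame(
                    {
                        "cell_id": [f"{sample_id}_c{i + 1:05d}" for i in range(n_cells)],
                        "sample_id": sample_id,
                        "condition": condition,
                        "cluster": labels,
                    }
                )
            )
    if not rows:
        return pd.DataFrame(columns=["cell_id", "sample_id", "condition", "cluster"])
    return pd.concat(rows, ignore_index=True)


@dataclass
class GeneModel:
    """Generative model for sparse UMI counts.

    Totals per cell are negative binomial with the class's mean and a common
    ``dispersion`` (shape; variance = mu + mu^2/dispersion). Counts are split
    between the mitochondrial and nuclear gene pools by binomial thinning at
    the class's target mitochondrial fraction, then allocated multinomially
    within each pool using fixed lognormal gene weights. Gene names follow
    human nomenclature: "MT-" mitochondrial, "RPL"/"RPS" ribosomal.

    ``lowquality_cell_fraction`` of cells are drawn from the low-quality class
    (mean ``lowquality_mean_counts`` total counts, target mito fraction
    ``lowquality_mito_fraction``) — damaged cells with few detected genes and
    high mitochondrial share, the population QC filtering removes.
    """

    n_genes: int = 1000
    mito_gene_count: int = 13
    ribo_gene_count: int = 80
    mean_counts_per_cell: float = 2500.0
    dispersion: float = 2.0
    target_mito_fraction: float = 0.05
    lowquality_cell_fraction: float = 0.0
    lowquality_mean_counts: float = 60.0
    lowquality_mito_fraction: float = 0.5

    def __post_init__(self):
        if self.n_genes <= 0:
            raise ValueError("n_genes must be > 0")
        if self.mito_gene_count + self.ribo_gene_count > self.n_genes:
            raise ValueError("mito_gene_count + ribo_gene_count must not exceed n_genes")
        for name in ("target_mito_fraction", "lowquality_cell_fraction", "lowquality_mito_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.mean_counts_per_cell <= 0 or self.lowquality_mean_counts <= 0:
            raise ValueError("mean counts must be > 0")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")

    def gene_names(self) -> np.ndarray:
        names = [f"MT-G{i + 1}" for i in range(self.mito_gene_count)]
        half = self.ribo_gene_count // 2
        names += [f"RPL{i + 1}" for i in range(half)]
        names += [f"RPS{i + 1}" for i in range(self.ribo_gene_count - half)]
        names += [f"GENE{i + 1}" for i in range(self.n_genes - len(names))]
        return np.asarray(names, dtype=object)


def simulate_count_matrix(
    cells: pd.DataFrame, model: GeneModel, seed: int = 0
) -> GeneMatrix:
    """Sparse gene-by-cell counts for the cells of a cell table.

    The planted quality class of each cell ("good" or "lowquality") is
    recorded in the returned matrix's ``cell_classes``. Zero cells yield an
    empty matrix with the gene list intact.
    """
    rng = child_rng(seed, "counts")
    genes = model.gene_names()
    n_cells = len(cells)
    cell_ids = (
        cells["cell_id"].to_numpy(dtype=object)
        if "cell_id" in cells.columns
        else np.array([f"cell{i + 1}" for i in range(n_cells)], dtype=object)
    )
    if n_cells == 0:
        return GeneMatrix(
            counts=sp.csr_matrix((model.n_genes, 0), dtype=np.int64),
            gene_names=genes,
            cell_ids=cell_ids,
            cell_classes=np.array([], dtype=object),
        )

    mito_mask = np.zeros(model.n_genes, dtype=bool)
    mito_mask[: model.mito_gene_count] = True
    # fixed per-gene expression weights so every cell shares one profile
    weights = rng.lognormal(mean=0.0, sigma=1.0, size=model.n_genes)
    w_mito = weights[mito_mask]
    w_nuc = weights[~mito_mask]
    p_mito = w_mito / w_mito.sum() if mito_mask.any() else None
    p_nuc = w_nuc / w_nuc.sum()

    lowq = rng.random(n_cells) < model.lowquality_cell_fraction
    means = np.where(lowq, model.lowquality_mean_counts, model.mean_counts_per_cell)
    mito_target = np.where(lowq, model.lowquality_mito_fraction, model.target_mito_fraction)
    # NB(mean mu, shape r) as Gamma-Poisson mixture
    lam = rng.gamma(shape=model.dispersion, scale=means / model.dispersion, size=n_cells)
    totals = rng.poisson(lam)
    n_mito = rng.binomial(totals, mito_target) if mito_mask.any() else np.zeros(n_cells, dtype=np.int64)
    n_nuc = totals - n_mito

    # chunked multinomial allocation, assembled sparse
    blocks = []
    chunk = max(1, int(2_000_000 // max(model.n_genes, 1)))
    for start in range(0, n_cells, chunk):
        stop = min(start + chunk, n_cells)
        dense = np.zeros((stop - start, model.n_genes), dtype=np.int64)
        if mito_mask.any():
            dense[:, mito_mask] = rng.multinomial(n_mito[start:stop], p_mito)
        dense[:, ~mito_mask] = rng.multinomial(n_nuc[start:stop], p_nuc)
        blocks.append(sp.csr_matrix(dense))
    counts = sp.vstack(blocks).T.tocsr()  # genes x cells
    classes = np.where(lowq, "lowquality", "good").astype(object)
    return GeneMatrix(counts=counts, gene_names=genes, cell_ids=cell_ids, cell_classes=classes)


@dataclass
class ClinicalModel:
    """Per-condition distributions of the clinical covariates.

    ``creatinine`` and ``egfr`` map condition -> (family, location, scale):
    family "lognormal" parameterised by (median, sigma of log), family
    "normal" by (mean, sd) truncated at 0. Age is normal (mean, sd) clipped to
    [18, 95] regardless of condition; sex is drawn from ``sex_probabilities``.
    Defaults straddle the clinical thresholds (creatinine 140 uM, eGFR
    60 mL/min/1.73m^2): control creatinine lognormal(median 80, sigma 0.3) vs
    case lognormal(median 250, sigma 0.3); control eGFR normal(90, 15) vs case
    normal(35, 13). These are arbitrary test-fixture choices, not population
    estimates. Setting a scale to 0 gives every sample exactly the location
    value.
    """

    creatinine: Mapping[str, tuple[str, float, float]] = field(
        default_factory=lambda: {
            "normal": ("lognormal", 80.0, 0.3),
            "ckd": ("lognormal", 250.0, 0.3),
        }
    )
    egfr: Mapping[str, tuple[str, float, float]] = field(
        default_factory=lambda: {
            "normal": ("normal", 90.0, 15.0),
            "ckd": ("normal", 35.0, 13.0),
        }
    )
    age_mean: float = 55.0
    age_sd: float = 15.0
    sex_probabilities: Mapping[str, float] = field(
        default_factory=lambda: {"F": 0.5, "M": 0.5}
    )
    seed: int = 0

    def __post_init__(self):
        for spec in list(self.creatinine.values()) + list(self.egfr.values()):
            family, _, scale = spec
            if family not in ("lognormal", "normal"):
                raise ValueError(f"unknown distribution family {family!r}")
            if scale < 0:
                raise ValueError("distribution scales must be >= 0")
        if self.age_sd < 0:
            raise ValueError("age_sd must be >= 0")
        total = sum(self.sex_probabilities.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"sex probabilities must sum to 1; got {total}")


def _draw(rng, family: str, loc: float, scale: float, size: int) -> np.ndarray:
    if family == "lognormal":
        # loc is the median, scale the sigma of the log
        return np.exp(rng.normal(math.log(loc), scale, size=size))
    if family == "normal":
        return np.maximum(0.0, rng.normal(loc, scale, size=size))
    raise ValueError(f"unknown distribution family {family!r}")


def simulate_clinical(
    samples: Sequence[str],
    conditions: Sequence[str],
    model: ClinicalModel = ClinicalModel(),
) -> pd.DataFrame:
    """One row per sample: sample_id, condition, creatinine_uM, egfr, age, sex.

    Deterministic under a fixed model seed. Under the default model, case
    samples mostly exceed the 140 uM creatinine threshold and fall below the
    60 mL/min/1.73m^2 eGFR threshold, controls the reverse.
    """
    samples = list(samples)
    conditions = list(conditions)
    if len(samples) != len(conditions):
        raise ValueError("one condition per sample required")
    rng = child_rng(model.seed, "clinical")
    cond = np.asarray(conditions, dtype=object)
    n = len(samples)
    creat = np.empty(n)
    egfr = np.empty(n)
    for c in pd.unique(cond):
        if c not in model.creatinine or c not in model.egfr:
            raise ValueError(f"clinical model lacks distributions for condition {c!r}")
        mask = cond == c
        creat[mask] = _draw(rng, *model.creatinine[c], size=int(mask.sum()))
        egfr[mask] = _draw(rng, *model.egfr[c], size=int(mask.sum()))
    age = np.clip(rng.normal(model.age_mean, model.age_sd, size=n), 18.0, 95.0)
    sexes = list(model.sex_probabilities)
    probs = [model.sex_probabilities[s] for s in sexes]
    sex = rng.choice(np.asarray(sexes, dtype=object), size=n, p=probs)
    return pd.DataFrame(
        {
            "sample_id": samples,
            "condition": conditions,
            "creatinine_uM": creat,
            "egfr": egfr,
            "age": age,
            "sex": sex,
        }
    )
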