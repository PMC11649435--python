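"""Cluster proportions per group and clinical stratification.

The compositional summary of a clustered single-cell dataset is the vector of
cluster proportions within each condition (cells pooled across samples, which
is the primary statistic here) and, for diagnostics, within each sample.
Clinical stratification rules re-derive the two-level comparison label from a
per-sample covariate such as serum creatinine or eGFR.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ProportionTable",
    "StratificationRule",
    "cluster_proportions",
    "proportion_difference",
    "stratify",
    "CREATININE_RULE",
    "EGFR_RULE",
    "AGE_RULE",
    "SEX_RULE",
    "BUILTIN_RULES",
]


@dataclass
class ProportionTable:
    """Cluster-by-group cell counts and proportions.

    ``counts`` and ``proportions`` are cluster x group DataFrames; each
    proportion column sums to 1. ``per_sample`` (optional) holds cluster x
    sample proportions, each column summing to 1.
    """

    counts: pd.DataFrame
    proportions: pd.DataFrame
    per_sample: pd.DataFrame | None = None

    @property
    def clusters(self) -> list:
        return list(self.counts.index)

    @property
    def groups(self) -> list:
        return list(self.counts.columns)


def cluster_proportions(
    cells: pd.DataFrame,
    group_col: str = "condition",
    cluster_col: str = "cluster",
    sample_col: str | None = None,
) -> ProportionTable:
    """Pooled cluster proportions per group, optionally per sample.

    Every cell must carry a non-missing group and cluster label. Clusters
    absent from a group get proportion 0; clusters with zero cells overall are
    dropped with a warning. A declared (categorical) group with zero cells is
    an error, since a proportion over an empty group is undefined.
    """
    for col in (group_col, cluster_col):
        if col not in cells.columns:
            raise KeyError(f"cell table lacks required column {col!r}")
        if cells[col].isna().any():
            raise ValueError(f"column {col!r} contains missing labels")

    counts = pd.crosstab(cells[cluster_col], cells[group_col], dropna=False)
    empty_clusters = counts.index[counts.sum(axis=1) == 0]
    if len(empty_clusters):
        warnings.warn(
            f"dropping clusters with zero cells in every group: {list(empty_clusters)}",
            stacklevel=2,
        )
        counts = counts.drop(index=empty_clusters)
    col_totals = counts.sum(axis=0)
    empty_groups = col_totals.index[col_totals == 0]
    if len(empty_groups):
        raise ValueError(f"group(s) with zero cells: {list(empty_groups)}")
    proportions = counts / col_totals

    per_sample = None
    if sample_col is not None:
        if sample_col not in cells.columns:
            raise KeyError(f"cell table lacks sample column {sample_col!r}")
        sc = pd.crosstab(cells[cluster_col], cells[sample_col], dropna=False)
        sc = sc.reindex(index=counts.index, fill_value=0)
        per_sample = sc / sc.sum(axis=0)

    return ProportionTable(counts=counts, proportions=proportions, per_sample=per_sample)


def proportion_difference(
    pt: ProportionTable, reference_group, test_group
) -> pd.Series:
    """Per-cluster statistic T_c = p_c(test) - p_c(reference).

    Because both proportion columns sum to 1, the statistics sum to 0.
    """
    for g in (reference_group, test_group):
        if g not in pt.proportions.columns:
            raise KeyError(f"unknown group {g!r}; groups present: {pt.groups}")
    t = pt.proportions[test_group] - pt.proportions[reference_group]
    t.name = "statistic"
    return t


@dataclass(frozen=True)
class StratificationRule:
    """Map a per-sample covariate to a group label.

    kind "threshold": ``thresholds`` are strictly increasing cut points and
    ``labels`` has one more entry, ordered from the lowest stratum upward.
    ``boundary[i]`` says where a value exactly equal to ``thresholds[i]``
    goes: "upper" assigns it to the stratum above the cut, "lower" to the one
    below. kind "categorical": the covariate value itself is the group.
    """

    name: str
    covariate: str
    kind: str = "threshold"  # "threshold" | "categorical"
    thresholds: tuple[float, ...] = ()
    labels: tuple[str, ...] = ()
    boundary: tuple[str, ...] = ()

    def __post_init__(self):
        if self.kind not in ("threshold", "categorical"):
            raise ValueError(f"unknown rule kind {self.kind!r}")
        if self.kind == "threshold":
            if not self.thresholds:
                raise ValueError("threshold rule needs at least one threshold")
            if any(b - a <= 0 for a, b in zip(self.thresholds, self.thresholds[1:])):
                raise ValueError("thresholds must be strictly increasing")
            if len(self.labels) != len(self.thresholds) + 1:
                raise ValueError("need exactly one label per stratum")
            if len(self.boundary) != len(self.thresholds):
                raise ValueError("need one boundary convention per threshold")
            if any(b not in ("upper", "lower") for b in self.boundary):
                raise ValueError("boundary entries must be 'upper' or 'lower'")

    def assign(self, values: pd.Series) -> pd.Series:
        """Group label for each covariate value."""
        if self.kind == "categorical":
            return values.astype(str)
        x = values.to_numpy(dtype=float)
        if np.isnan(x).any():
            bad = list(values.index[np.isnan(x)])
            raise ValueError(f"missing covariate {self.covariate!r} for samples: {bad}")
        idx = np.zeros(len(x), dtype=int)
        for t, side in zip(self.thresholds, self.boundary):
            idx += (x >= t) if side == "upper" else (x > t)
        return pd.Series(np.asarray(self.labels, dtype=object)[idx], index=values.index)


# Built-in clinical rules. Equality conventions: creatinine exactly at
# 140 uM counts as impaired; eGFR exactly at 60 counts as normal; ages 30 and
# 60 both fall in the adult stratum.
CREATININE_RULE = StratificationRule(
    name="creatinine_group", covariate="creatinine_uM",
    thresholds=(140.0,), labels=("normal", "impaired"), boundary=("upper",),
)
EGFR_RULE = StratificationRule(
    name="egfr_group", covariate="egfr",
    thresholds=(60.0,), labels=("impaired", "normal"), boundary=("upper",),
)
AGE_RULE = StratificationRule(
    name="age_group", covariate="age",
    thresholds=(30.0, 60.0), labels=("young", "adult", "elderly"),
    boundary=("upper", "lower"),
)
SEX_RULE = StratificationRule(name="sex_group", covariate="sex", kind="categorical")

BUILTIN_RULES = {
    "creatinine": CREATININE_RULE,
    "egfr": EGFR_RULE,
    "age": AGE_RULE,
    "sex": SEX_RULE,
}


def stratify(
    cells: pd.DataFrame,
    clinical: pd.DataFrame,
    rule: StratificationRule,
    sample_col: str = "sample_id",
) -> pd.DataFrame:
    """Attach a derived group column; each cell inherits its sample's stratum.

    ``clinical`` has one row per sample (indexed by sample id or carrying a
    ``sample_id`` column) with the rule's covariate. Samples present in
    ``cells`` but missing from ``clinical`` are an error.
    """
    clin = clinical
    if sample_col in clin.columns:
        clin = clin.set_index(sample_col)
    if rule.covariate not in clin.columns:
        raise KeyError(f"clinical table lacks covariate {rule.covariate!r}")
    cell_samples = pd.Index(cells[sample_col].unique())
    missing = cell_samples.difference(clin.index)
    if len(missing):
        raise ValueError(
            f"covariate {rule.covariate!r} missing for samples: {sorted(missing)}"
        )
    strata = rule.assign(clin.loc[cell_samples, rule.covariate])
    out = cells.copy()
    out[rule.name] = out[sample_col].map(strata).to_numpy()
    return out
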