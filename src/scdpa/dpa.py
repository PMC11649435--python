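"""Permutation-based differential proportion analysis (DPA).

Given cells carrying a two-level group label G (e.g. normal vs disease) and a
cluster label L, the test statistic for cluster c is the difference in pooled
proportions T_c = p_c(test) - p_c(reference). The null distribution is built
by repeatedly permuting the cluster labels of a random fraction w of all cells
(default w = 0.1, 100,000 iterations): each iteration draws ceil(w*N) cells
uniformly without replacement from the pooled dataset and shuffles their
cluster labels among themselves, leaving group labels and all other cluster
labels fixed, so the global cluster-label multiset is preserved. Empirical
p-values use the add-one estimator p = (1 + exceedances) / (B + 1), which is
never zero at finite B, and a Bonferroni correction over the clusters tested
is applied.

An exact-enumeration oracle (:func:`exact_null_distribution`) computes the
same null distribution in closed form on instances small enough to enumerate,
for validating the Monte Carlo path.

Internally the statistic is compared on the integer grid
T_c * n_test * n_ref, so exceedance ties are counted exactly, with no
floating-point ambiguity.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import composition
from ._rng import child_rng

__all__ = [
    "DPAConfig",
    "DPAResult",
    "ExactNull",
    "permute_labels_once",
    "dpa_test",
    "exact_null_distribution",
    "bonferroni_adjust",
]


@dataclass(frozen=True)
class DPAConfig:
    """Parameters of the permutation test.

    w            fraction in (0, 1] of cells whose cluster labels are permuted
                 per iteration; the subset size is ceil(w * N).
    iterations   number of permutation iterations B.
    alpha        significance level applied to the Bonferroni-adjusted p.
    seed         master seed; the test's random stream is derived from it.
    sidedness    "two-sided" (default; contraction and expansion both count)
                 or "one-sided" (exceedance of the signed statistic).
    mode         "shuffle" (default): labels of the chosen subset are permuted
                 among themselves, preserving the global label multiset.
                 "resample": labels of the chosen subset are redrawn i.i.d.
                 from the global label frequencies.
    min_cluster_size  clusters with fewer total cells are still tested but
                 flagged unreliable in the output.
    """

    w: float = 0.1
    iterations: int = 100_000
    alpha: float = 0.05
    seed: int = 0
    sidedness: str = "two-sided"
    mode: str = "shuffle"
    min_cluster_size: int = 5

    def __post_init__(self):
        if not (0.0 < self.w <= 1.0):
            raise ValueError(f"w must lie in (0, 1]; got {self.w}")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0, 1)")
        if self.sidedness not in ("two-sided", "one-sided"):
            raise ValueError(f"unknown sidedness {self.sidedness!r}")
        if self.mode not in ("shuffle", "resample"):
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass
class DPAResult:
    """Per-cluster test outcomes plus run metadata.

    ``table`` columns: cluster, n_ref, n_test, prop_ref, prop_test, statistic,
    p_empirical, p_bonferroni, significant, reliable.
    """

    table: pd.DataFrame
    config: DPAConfig
    reference_group: object
    test_group: object
    n_clusters_tested: int

    def __eq__(self, other):
        if not isinstance(other, DPAResult):
            return NotImplemented
        return (
            self.table.equals(other.table)
            and self.config == other.config
            and self.reference_group == other.reference_group
            and self.test_group == other.test_group
        )


def _subset_size(w: float, n: int) -> int:
    # ceil(w*N) without float slop at exact multiples
    return min(n, int(math.ceil(w * n - 1e-12)))


def permute_labels_once(
    cluster_labels: np.ndarray,
    w: float,
    rng: np.random.Generator,
    mode: str = "shuffle",
) -> np.ndarray:
    """One null iteration: permute the cluster labels of a random w-fraction.

    ceil(w*N) cells are drawn uniformly without replacement from the pooled
    dataset; in "shuffle" mode their labels are shuffled uniformly among the
    chosen subset (the global label multiset is preserved), in "resample" mode
    they are redrawn i.i.d. from the global label frequencies. All other
    labels are untouched. Returns a new array.
    """
    if not (0.0 < w <= 1.0):
        raise ValueError(f"w must lie in (0, 1]; got {w}")
    labels = np.asarray(cluster_labels)
    n = labels.shape[0]
    if n < 2:
        raise ValueError("need at least 2 cells to permute")
    m = _subset_size(w, n)
    out = labels.copy()
    idx = rng.choice(n, size=m, replace=False)
    if mode == "shuffle":
        out[idx] = out[idx][rng.permutation(m)]
    elif mode == "resample":
        out[idx] = rng.choice(labels, size=m, replace=True)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return out


def _prepare(cells, group_col, cluster_col, reference_group, test_group):
    for col in (group_col, cluster_col):
        if col not in cells.columns:
            raise KeyError(f"cell table lacks required column {col!r}")
    groups = list(pd.unique(cells[group_col]))
    if len(groups) != 2:
        raise ValueError(f"DPA needs exactly two groups; found {len(groups)}: {groups}")
    if reference_group is None and test_group is None:
        reference_group, test_group = groups
    elif reference_group is None:
        reference_group = next(g for g in groups if g != test_group)
    elif test_group is None:
        test_group = next(g for g in groups if g != reference_group)
    for g in (reference_group, test_group):
        if g not in groups:
            raise ValueError(f"group {g!r} not present in column {group_col!r}")
    codes, clusters = pd.factorize(cells[cluster_col], sort=True)
    is_test = (cells[group_col] == test_group).to_numpy()
    n_test = int(is_test.sum())
    n_ref = int((~is_test).sum())
    if n_test == 0 or n_ref == 0:
        raise ValueError("each group must contain at least one cell")
    return codes.astype(np.int64), list(clusters), is_test, n_test, n_ref, reference_group, test_group


def dpa_test(
    cells: pd.DataFrame,
    config: DPAConfig = DPAConfig(),
    group_col: str = "condition",
    cluster_col: str = "cluster",
    reference_group=None,
    test_group=None,
) -> DPAResult:
    """Run the permutation test on a labelled cell table.

    If the reference/test groups are not named, the first two distinct values
    of ``group_col`` (in order of appearance) serve as reference and test.
    Fully reproducible from ``config.seed``.
    """
    codes, clusters, is_test, n_test, n_ref, ref_g, test_g = _prepare(
        cells, group_col, cluster_col, reference_group, test_group
    )
    k = len(clusters)
    n = codes.shape[0]
    rng = child_rng(config.seed, "dpa")

    totals = np.bincount(codes, minlength=k)
    cnt_test = np.bincount(codes[is_test], minlength=k)
    cnt_ref = totals - cnt_test
    # statistic on the integer grid: num = T * n_test * n_ref
    num_obs = cnt_test * n_ref - cnt_ref * n_test
    two_sided = config.sidedness == "two-sided"
    target = np.abs(num_obs) if two_sided else num_obs

    test_idx = np.flatnonzero(is_test)
    ref_idx = np.flatnonzero(~is_test)
    exceed = np.zeros(k, dtype=np.int64)
    for _ in range(config.iterations):
        perm = permute_labels_once(codes, config.w, rng, mode=config.mode)
        c_test = np.bincount(perm[test_idx], minlength=k)
        if config.mode == "shuffle":
            c_ref = totals - c_test
        else:
            c_ref = np.bincount(perm[ref_idx], minlength=k)
        num = c_test * n_ref - c_ref * n_test
        if two_sided:
            exceed += np.abs(num) >= target
        else:
            exceed += num >= target

    b = config.iterations
    p_emp = (1.0 + exceed) / (b + 1.0)
    p_bonf = np.minimum(1.0, k * p_emp)

    table = pd.DataFrame(
        {
            "cluster": clusters,
            "n_ref": cnt_ref,
            "n_test": cnt_test,
            "prop_ref": cnt_ref / n_ref,
            "prop_test": cnt_test / n_test,
            "statistic": num_obs / (n_test * n_ref),
            "p_empirical": p_emp,
            "p_bonferroni": p_bonf,
            "significant": p_bonf < config.alpha,
            "reliable": totals >= config.min_cluster_size,
        }
    )
    return DPAResult(
        table=table,
        config=config,
        reference_group=ref_g,
        test_group=test_g,
        n_clusters_tested=k,
    )


@dataclass
class ExactNull:
    """Exact null distribution of T_c under the partial-shuffle scheme.

    ``support[c]`` maps integer statistic numerators (T * n_test * n_ref) to
    their exact probabilities; ``observed_num`` holds the observed numerators.
    """

    clusters: list
    support: list[dict[int, float]]
    observed_num: np.ndarray
    n_test: int
    n_ref: int
    n_outcomes: int

    def pmf(self, cluster) -> tuple[np.ndarray, np.ndarray]:
        """(statistic values, probabilities) for one cluster."""
        i = self.clusters.index(cluster)
        nums = np.array(sorted(self.support[i]))
        probs = np.array([self.support[i][v] for v in nums])
        return nums / (self.n_test * self.n_ref), probs

    def exact_p(self, cluster, sidedness: str = "two-sided") -> float:
        """Null probability of a statistic at least as extreme as observed.

        This is the population quantity the Monte Carlo empirical p estimates
        (up to the add-one correction).
        """
        i = self.clusters.index(cluster)
        obs = self.observed_num[i]
        if sidedness == "two-sided":
            return float(sum(p for v, p in self.support[i].items() if abs(v) >= abs(obs)))
        return float(sum(p for v, p in self.support[i].items() if v >= obs))

    def exact_p_all(self, sidedness: str = "two-sided") -> np.ndarray:
        return np.array([self.exact_p(c, sidedness) for c in self.clusters])


def exact_null_distribution(
    cells: pd.DataFrame,
    w: float,
    group_col: str = "condition",
    cluster_col: str = "cluster",
    reference_group=None,
    test_group=None,
    max_outcomes: int = 10**6,
) -> ExactNull:
    """Enumerate the null distribution of T_c exactly.

    Averages over the uniform choice of the ceil(w*N)-cell subset and the
    uniform shuffle within it. The number of (subset, shuffle) outcomes
    C(N, m) * m! must not exceed ``max_outcomes``; larger instances are
    refused with the outcome count in the message.
    """
    if not (0.0 < w <= 1.0):
        raise ValueError(f"w must lie in (0, 1]; got {w}")
    codes, clusters, is_test, n_test, n_ref, _, _ = _prepare(
        cells, group_col, cluster_col, reference_group, test_group
    )
    k = len(clusters)
    n = codes.shape[0]
    m = _subset_size(w, n)
    n_outcomes = math.comb(n, m) * math.factorial(m)
    if n_outcomes > max_outcomes:
        raise ValueError(
            f"instance too large to enumerate: C({n},{m}) * {m}! = {n_outcomes} "
            f"outcomes exceeds the guard of {max_outcomes}"
        )

    totals = np.bincount(codes, minlength=k)
    cnt_test0 = np.bincount(codes[is_test], minlength=k)
    num_obs = cnt_test0 * n_ref - (totals - cnt_test0) * n_test

    # accumulate integer outcome counts; divide once so masses are exact
    outcome_counts: list[dict[int, int]] = [dict() for _ in range(k)]
    test_mask = is_test
    for subset in itertools.combinations(range(n), m):
        sub = np.fromiter(subset, dtype=np.int64, count=m)
        sub_labels = codes[sub]
        sub_in_test = test_mask[sub]
        # test-group counts outside the subset are fixed for this subset
        base = cnt_test0 - np.bincount(sub_labels[sub_in_test], minlength=k)
        for perm in itertools.permutations(sub_labels):
            pl = np.fromiter(perm, dtype=np.int64, count=m)
            c_test = base + np.bincount(pl[sub_in_test], minlength=k)
            num = c_test * n_ref - (totals - c_test) * n_test
            for i in range(k):
                key = int(num[i])
                outcome_counts[i][key] = outcome_counts[i].get(key, 0) + 1
    support = [
        {v: c / n_outcomes for v, c in counter.items()} for counter in outcome_counts
    ]

    return ExactNull(
        clusters=clusters,
        support=support,
        observed_num=num_obs,
        n_test=n_test,
        n_ref=n_ref,
        n_outcomes=n_outcomes,
    )


def bonferroni_adjust(p_values, k: int | None = None) -> np.ndarray:
    """Bonferroni correction: adjusted p = min(1, K * p).

    K defaults to the number of p-values and may exceed it (when the
    comparison at hand tested more clusters than are being adjusted here).
    """
    p = np.asarray(p_values, dtype=float)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    if k is None:
        k = p.size
    if k < p.size:
        raise ValueError(f"K ({k}) must be >= number of p-values ({p.size})")
    return np.minimum(1.0, k * p)
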