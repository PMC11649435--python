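# Methods

## The differential proportion test

The dataset is N cells pooled across samples, each carrying a two-level group
label G and a cluster label L over K clusters. The per-cluster statistic is
the pooled proportion difference T_c = p_c(test) − p_c(reference); because
both proportion vectors live on the simplex, Σ_c T_c = 0 identically.

The null distribution is built by *partial label shuffling*: each iteration
draws m = ⌈wN⌉ cells uniformly without replacement from the pooled dataset
(both groups together) and applies a uniform random permutation to the cluster
labels of that subset only. Group labels are never touched and the global
multiset of cluster labels is preserved by construction — an invariant the
test suite asserts on every iteration. Defaults are w = 0.1 and B = 100,000
iterations. Two-sided empirical p-values use the add-one estimator
p = (1 + #{|T*| ≥ |T|}) / (B + 1), with ties counted as exceedances, and a
Bonferroni correction min(1, K·p) over the K clusters tested in the comparison
at hand (not pooled across comparisons). Significance is called on the
adjusted p at α = 0.05.

Assumptions and caveats. With w = 1 this is the classical full label-shuffle
permutation test, valid under exchangeability of cluster labels across groups;
the suite verifies its rejection rate at raw p ≤ 0.05 stays in [0.035, 0.065]
under an independent null (slight conservatism is expected from the
discreteness of the permutation distribution and the add-one estimator). With
w < 1 the null is *not* a classical exchangeable null: only a fraction of
labels move per iteration, so null statistics stay correlated with the
observed configuration and the test is conservative in the usual direction —
shifts must be large relative to that narrowed null to register. We therefore
characterize the w = 0.1 operating point empirically (power study below)
rather than asserting nominal level for it. The pooled statistic also ignores
the sample hierarchy: cells from one donor are treated as independent, which
overstates the effective n when compositions vary strongly between donors.
Per-sample proportion tables are provided for diagnostics.

### Choices that were genuinely open

- **"Permuting labels for a fraction of cells"** can mean shuffling within a
  random subset or resampling that subset's labels from the global
  frequencies. The default is the within-subset shuffle: it preserves the
  label multiset exactly, which keeps the null enumerable in closed form and
  conservative about global composition. The resampling variant is available
  via `DPAConfig(mode="resample")`.
- **Sidedness**: two-sided by default, since both contractions and expansions
  are of interest; one-sided is a config switch.
- **Tie handling**: exceedances are counted with ≥ on an exact integer grid —
  internally T_c is compared as the integer T_c·n_test·n_ref — so tie
  decisions never depend on floating-point rounding.
- **Subset size rounding**: m = ⌈wN⌉ (with a 1e-12 guard so exact multiples
  are not bumped up by float error). A 1-cell subset makes the iteration the
  identity, so w small enough that ⌈wN⌉ = 1 yields a degenerate null.
- **Small clusters**: clusters with fewer than 5 cells in total are still
  tested but flagged `reliable = False` in the output.

### The exact oracle

`exact_null_distribution` enumerates every (subset, shuffle) outcome —
C(N, m)·m! of them, guarded at 10⁶ — accumulating integer outcome counts per
statistic value and dividing once, so the masses are exact. With w = 1 and one
cluster of interest the resulting law reduces to the multivariate
hypergeometric allocation of labels to groups, which the tests check against
`scipy.stats.hypergeom`. The Monte Carlo path is validated against the oracle
to within 3 binomial standard errors at B = 50,000.

## QC filtering

Per-cell metrics from the raw gene-by-cell count matrix: `n_counts` (total
UMIs), `n_features` (genes with non-zero count), `pct_mito` (percentage of
counts on genes with the case-insensitive `MT-` prefix; defined as 0 for
zero-count cells, which fail the feature floor anyway). Retention requires
`n_features > 200`, `n_counts < 12,000`, `pct_mito < 30`, all strict, so
boundary cells are removed. The filter is idempotent and its removal report
satisfies inclusion–exclusion against the input/output sizes.

Cytosolic ribosomal genes (case-insensitive `^RP[LS]`) are removed *after*
metric computation, so `n_counts`/`n_features` reflect the raw matrix; the
order is not dictated by the filtering rules themselves and is configurable by
calling `remove_ribosomal_genes` earlier. Mitochondrial-ribosomal `MRP*` genes
are kept — they do not match the cytosolic prefix and standard human
nomenclature separates the families. The expressed-gene background rule marks
a gene expressed within a cell group when it is non-zero in **at least** 10%
of the group's cells (inclusive threshold).

## Clinical stratification

Rules map a per-sample covariate to a stratum; every cell inherits its
sample's stratum. Built-ins: serum creatinine ≥ 140 μM → impaired; eGFR
< 60 mL/min/1.73 m² → impaired (exactly 60 is normal); age < 30 young,
30–60 adult (both endpoints adult), > 60 elderly; sex passed through. The
sources defining these cutoffs leave equality unassigned, so the boundary
conventions here are explicit package choices — equality goes to the impaired
side for creatinine and the normal side for eGFR — and every rule's boundary
handling is configurable per threshold (`boundary = "upper" | "lower"`).
Degenerate stratifications (a single stratum) are refused downstream by the
test, which requires exactly two groups.

## Synthetic data: what it emulates, what it does not

The generator exists so that every downstream stage has ground truth. It
emulates, per the default `kidney_cohort_spec`:

- **Cohort structure**: 65 samples, 42 normal and 23 disease, with a fixed
  per-sample cell count (default 1,000; a range is supported).
- **Composition**: 8 lymphoid-like clusters. Condition compositions are
  baseline × per-cluster effect multipliers, renormalized; the disease
  condition contracts the CD16+ NK-like cluster 0.20 → 0.06 and expands the
  CD4+ naive-T-like cluster 0.10 → 0.24. These effect sizes are test fixtures
  chosen to be detectable at study scale, not biological estimates. Per-sample
  compositions are Dirichlet(concentration × condition composition) with
  concentration 200 by default — moderate between-donor overdispersion on top
  of multinomial counting noise. The Dirichlet-multinomial variance
  p(1−p)/n · (n+α₀)/(1+α₀) is verified against simulation, including the
  α₀ → ∞ multinomial limit.
- **Counts**: per-cell totals are negative binomial (gamma–Poisson,
  dispersion 2), allocated multinomially across genes with fixed lognormal
  gene weights; the mitochondrial share is binomially thinned toward the
  cell class's target (5% for good cells). A planted low-quality class (mean
  60 total counts, 50% mitochondrial) produces cells that fail the feature
  floor ≥ 95% of the time, giving the QC filter a known answer.
- **Clinical covariates**: creatinine lognormal (control median 80 μM, case
  median 250 μM, σ = 0.3 on the log), eGFR normal truncated at 0 (control
  90 ± 15, case 35 ± 13), age normal 55 ± 15 clipped to [18, 95], sex 50/50.
  Chosen only to straddle the 140 μM and 60 mL/min/1.73 m² thresholds —
  documented as arbitrary.

It does **not** simulate batch effects, doublets' expression profiles,
embeddings, gene–gene correlation, cluster-specific expression programs, or
spatial structure. Passing tests therefore demonstrate the *statistical
machinery* — proportion bookkeeping, permutation validity, calibration, power
at planted effect sizes — not robustness to the technical artifacts real
atlases carry; those are handled upstream of this package.

Seed policy: one master seed; each stochastic stage (labels, counts, clinical,
permutation test) derives its generator from `SeedSequence(master,
spawn_key=(stage_offset,))` with fixed per-stage offsets, so runs are
byte-identical under equal seeds and stages do not perturb each other's
streams.

## Problem sizes in the test suite and acceptance script

The statistical checks run at sizes chosen to give tight Monte Carlo error on
one CPU in minutes: null calibration at 1,000 replicates × B = 1,000 (two
groups of 1,000 cells, 5 equal clusters); power at 100 replicates of a
0.10 → 0.02 contraction with 3,000 cells per group, w = 0.1, B = 2,000;
oracle agreement at B = 50,000 on an 8-cell enumerable instance; the
end-to-end cohort at 400–500 cells per sample with B = 10,000. The test's
per-iteration cost is O(N), so the paper-scale B = 100,000 at full atlas size
is a matter of wall-clock time, not of different code paths.

## Known limitations

- The partial-shuffle null (w < 1) has no closed-form level guarantee; it is
  characterized empirically and is conservative in our experiments.
- Bonferroni is the only multiplicity correction offered, matching the
  analysis this package supports; no FDR alternatives.
- Pooled proportions ignore donor identity; strongly unbalanced cohorts with
  donor-dominated clusters will overstate significance. Inspect the
  per-sample proportion table before trusting small effects.
- The CLI reads whole tables into memory; atlases beyond ~10⁷ cells should
  use the library API with their own chunking.
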