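"""Tests for the synthetic cohort, count-matrix, and clinical generators."""

import numpy as np
import pandas as pd
import pytest

from scdpa.qc import QCThresholds, compute_qc_metrics, filter_cells
from scdpa.synthetic import (
    ClinicalModel,
    CompositionSpec,
    GeneModel,
    kidney_cohort_spec,
    simulate_cell_table,
    simulate_clinical,
    simulate_count_matrix,
)
from tests.conftest import multinomial_spec


class TestCompositionSpec:
    def test_non_simplex_baseline_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            CompositionSpec(
                cluster_names=["a", "b"],
                baseline_proportions=[0.6, 0.5],
                effect_multipliers={"x": [1, 1], "y": [1, 1]},
                n_samples_per_condition={"x": 1, "y": 1},
            )

    def test_negative_multiplier_rejected(self):
        with pytest.raises(ValueError, match="multipliers"):
            CompositionSpec(
                cluster_names=["a", "b"],
                baseline_proportions=[0.5, 0.5],
                effect_multipliers={"x": [1, 1], "y": [-1, 1]},
                n_samples_per_condition={"x": 1, "y": 1},
            )

    def test_condition_proportions_renormalised(self):
        spec = CompositionSpec(
            cluster_names=["a", "b"],
            baseline_proportions=[0.5, 0.5],
            effect_multipliers={"x": [1, 1], "y": [3, 1]},
            n_samples_per_condition={"x": 1, "y": 1},
        )
        np.testing.assert_allclose(spec.condition_proportions("y"), [0.75, 0.25])
        assert spec.condition_proportions("y").sum() == pytest.approx(1.0, abs=1e-12)


class TestSimulateCellTable:
    def test_study_scale_cohort_structure(self):
        cells = simulate_cell_table(kidney_cohort_spec(seed=0, cells_per_sample=10))
        samples = cells.drop_duplicates("sample_id")
        assert len(samples) == 65
        split = samples["condition"].value_counts()
        assert split["normal"] == 42 and split["ckd"] == 23

    def test_per_sample_cell_counts(self):
        spec = kidney_cohort_spec(seed=1, cells_per_sample=37)
        cells = simulate_cell_table(spec)
        assert (cells.groupby("sample_id").size() == 37).all()

    def test_cells_per_sample_range(self):
        spec = kidney_cohort_spec(seed=1, cells_per_sample=(5, 15))
        sizes = simulate_cell_table(spec).groupby("sample_id").size()
        assert sizes.between(5, 15).all() and sizes.nunique() > 1

    def test_zero_effect_gives_balanced_composition(self):
        """With all multipliers = 1 the pooled per-cluster proportion
        difference stays within 3 binomial SE of zero (high concentration, so
        only multinomial noise remains)."""
        p = [0.2, 0.3, 0.1, 0.25, 0.15]
        n = 10_000
        spec = multinomial_spec(p, p, n_cells=n, seed=9)
        cells = simulate_cell_table(spec)
        prop = cells.pivot_table(index="cluster", columns="condition",
                                 values="cell_id", aggfunc="size").fillna(0) / n
        diff = prop["test"] - prop["ref"]
        se = np.sqrt(2 * np.array(p) * (1 - np.array(p)) / n)
        order = [f"c{i}" for i in range(5)]
        assert (np.abs(diff.reindex(order).to_numpy()) <= 3 * se).all()

    def test_zero_multiplier_bans_cluster(self):
        spec = CompositionSpec(
            cluster_names=["a", "b", "c"],
            baseline_proportions=[0.3, 0.3, 0.4],
            effect_multipliers={"ctrl": [1, 1, 1], "case": [0.0, 1, 1]},
            n_samples_per_condition={"ctrl": 3, "case": 3},
            cells_per_sample=500,
            seed=2,
        )
        cells = simulate_cell_table(spec)
        case = cells[cells["condition"] == "case"]
        assert not (case["cluster"] == "a").any()
        assert (cells[cells["condition"] == "ctrl"]["cluster"] == "a").any()

    def test_zero_cells_gives_empty_table(self):
        spec = kidney_cohort_spec(seed=0, cells_per_sample=0)
        cells = simulate_cell_table(spec)
        assert len(cells) == 0
        spec2 = CompositionSpec(
            cluster_names=["a"], baseline_proportions=[1.0],
            effect_multipliers={"x": [1.0], "y": [1.0]},
            n_samples_per_condition={"x": 0, "y": 0},
        )
        assert len(simulate_cell_table(spec2)) == 0

    def test_seed_reproducibility(self):
        spec = kidney_cohort_spec(seed=5, cells_per_sample=50)
        t1 = simulate_cell_table(spec)
        t2 = simulate_cell_table(kidney_cohort_spec(seed=5, cells_per_sample=50))
        t3 = simulate_cell_table(kidney_cohort_spec(seed=6, cells_per_sample=50))
        assert t1.to_csv() == t2.to_csv()
        assert t1.to_csv() != t3.to_csv()

    def test_dirichlet_concentration_limit(self):
        """Between-sample proportion variance approaches the closed-form
        Dirichlet-multinomial value Var = p(1-p)/n * (n + a0)/(1 + a0), which
        collapses to pure multinomial p(1-p)/n as a0 -> infinity."""
        p0, n, reps = 0.3, 100, 3000

        def sample_var(conc, seed):
            spec = CompositionSpec(
                cluster_names=["a", "b"],
                baseline_proportions=[p0, 1 - p0],
                effect_multipliers={"x": [1, 1], "y": [1, 1]},
                n_samples_per_condition={"x": reps, "y": 0},
                dirichlet_concentration=conc,
                cells_per_sample=n,
                seed=seed,
            )
            cells = simulate_cell_table(spec)
            props = cells.groupby("sample_id").apply(
                lambda s: (s["cluster"] == "a").mean(), include_groups=False
            )
            return props.var(ddof=1)

        for conc in (20.0, 1e9):
            expected = p0 * (1 - p0) / n * (n + conc) / (1 + conc)
            observed = sample_var(conc, seed=3)
            # var of a sample variance over 3000 draws: ~ +/- 2*sqrt(2/reps) relative
            assert observed == pytest.approx(expected, rel=0.15)


class TestSimulateCountMatrix:
    def test_mito_fraction_binomial_thinning(self):
        """Mean computed mito%% tracks the class target (binomial thinning has
        mean exactly the target fraction)."""
        cells = pd.DataFrame({"cell_id": [f"c{i}" for i in range(1000)]})
        model = GeneModel(n_genes=200, target_mito_fraction=0.5, mean_counts_per_cell=500)
        gm = simulate_count_matrix(cells, model, seed=4)
        m = compute_qc_metrics(gm)
        assert abs(m["pct_mito"].mean() - 50.0) < 2.0

    def test_lowquality_class_fails_feature_floor(self):
        """Cells of the planted low-quality class (expected ~50 detected genes)
        fail the nFeature > 200 rule at least 95%% of the time."""
        cells = pd.DataFrame({"cell_id": [f"c{i}" for i in range(1000)]})
        model = GeneModel(lowquality_cell_fraction=1.0, lowquality_mean_counts=60.0)
        gm = simulate_count_matrix(cells, model, seed=5)
        assert (gm.cell_classes == "lowquality").all()
        m = compute_qc_metrics(gm)
        _, report = filter_cells(m, QCThresholds())
        assert report.low_features >= 950

    def test_good_cells_mostly_pass(self):
        cells = pd.DataFrame({"cell_id": [f"c{i}" for i in range(500)]})
        gm = simulate_count_matrix(cells, GeneModel(), seed=6)
        kept, _ = filter_cells(compute_qc_metrics(gm))
        assert len(kept) >= 475

    def test_zero_cells_keeps_gene_list(self):
        gm = simulate_count_matrix(pd.DataFrame({"cell_id": []}), GeneModel(n_genes=50, ribo_gene_count=10), seed=0)
        assert gm.counts.shape == (50, 0)
        assert len(gm.gene_names) == 50

    def test_gene_name_conventions(self):
        model = GeneModel(n_genes=30, mito_gene_count=3, ribo_gene_count=6)
        names = model.gene_names()
        assert sum(n.startswith("MT-") for n in names) == 3
        assert sum(n.startswith(("RPL", "RPS")) for n in names) == 6

    def test_model_validation(self):
        with pytest.raises(ValueError, match="n_genes"):
            GeneModel(n_genes=0)
        with pytest.raises(ValueError, match="exceed"):
            GeneModel(n_genes=10, mito_gene_count=8, ribo_gene_count=5)
        with pytest.raises(ValueError, match="fraction"):
            GeneModel(target_mito_fraction=1.5)

    def test_seed_reproducibility(self):
        cells = pd.DataFrame({"cell_id": [f"c{i}" for i in range(50)]})
        g1 = simulate_count_matrix(cells, GeneModel(n_genes=100), seed=7)
        g2 = simulate_count_matrix(cells, GeneModel(n_genes=100), seed=7)
        assert (g1.counts != g2.counts).nnz == 0


class TestSimulateClinical:
    def test_default_case_samples_exceed_creatinine_threshold(self):
        """Monte Carlo of the default case lognormal (median 250 uM, sigma 0.3):
        the mass above 140 uM is Phi(log(250/140)/0.3) ~ 0.97, so well over 90%%
        of case samples are impaired."""
        clin = simulate_clinical(
            [f"s{i}" for i in range(1000)], ["ckd"] * 1000, ClinicalModel(seed=8)
        )
        assert (clin["creatinine_uM"] > 140).mean() >= 0.90
        assert (clin["egfr"] < 60).mean() >= 0.90

    def test_default_controls_on_the_normal_side(self):
        clin = simulate_clinical(
            [f"s{i}" for i in range(1000)], ["normal"] * 1000, ClinicalModel(seed=9)
        )
        assert (clin["creatinine_uM"] < 140).mean() >= 0.90
        assert (clin["egfr"] > 60).mean() >= 0.90

    def test_zero_variance_mode_hits_condition_means_exactly(self):
        model = ClinicalModel(
            creatinine={"normal": ("lognormal", 80.0, 0.0), "ckd": ("lognormal", 250.0, 0.0)},
            egfr={"normal": ("normal", 90.0, 0.0), "ckd": ("normal", 35.0, 0.0)},
            seed=0,
        )
        clin = simulate_clinical(["s1", "s2"], ["normal", "ckd"], model)
        assert clin["creatinine_uM"].tolist() == pytest.approx([80.0, 250.0])
        assert clin["egfr"].tolist() == pytest.approx([90.0, 35.0])

    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError, match="family"):
            ClinicalModel(creatinine={"x": ("gamma", 1.0, 1.0)})

    def test_one_row_per_sample_and_determinism(self):
        samples = [f"s{i}" for i in range(65)]
        conds = ["normal"] * 42 + ["ckd"] * 23
        c1 = simulate_clinical(samples, conds, ClinicalModel(seed=3))
        c2 = simulate_clinical(samples, conds, ClinicalModel(seed=3))
        assert len(c1) == 65
        pd.testing.assert_frame_equal(c1, c2)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="one condition per sample"):
            simulate_clinical(["s1"], ["a", "b"])
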