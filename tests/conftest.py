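import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from scdpa.synthetic import CompositionSpec, GeneMatrix


@pytest.fixture
def toy_matrix():
    """3 genes x 3 cells with hand-checkable QC metrics.

    cell1: 5 on MT-ND1, 5 on ACTB -> n_counts 10, n_features 2, pct_mito 50
    cell2: counts only on MT-ND1 -> pct_mito 100
    cell3: all-zero cell
    """
    genes = np.array(["MT-ND1", "ACTB", "RPL3"], dtype=object)
    dense = np.array(
        [
            [5, 7, 0],  # MT-ND1
            [5, 0, 0],  # ACTB
            [0, 0, 0],  # RPL3
        ]
    )
    return GeneMatrix(
        counts=sp.csr_matrix(dense),
        gene_names=genes,
        cell_ids=np.array(["cell1", "cell2", "cell3"], dtype=object),
    )


@pytest.fixture
def two_cluster_cells():
    """Group A: 30/70 split over clusters c1/c2; group B: 50/50."""
    rows = (
        [("A", "c1")] * 30 + [("A", "c2")] * 70 + [("B", "c1")] * 50 + [("B", "c2")] * 50
    )
    df = pd.DataFrame(rows, columns=["condition", "cluster"])
    df["cell_id"] = [f"cell{i}" for i in range(len(df))]
    df["sample_id"] = np.where(df["condition"] == "A", "sA", "sB")
    return df


def multinomial_spec(
    proportions_ref,
    proportions_test,
    n_cells: int,
    seed: int = 0,
    n_samples: tuple[int, int] = (1, 1),
):
    """Spec that draws labels (near-)multinomially from fixed group compositions.

    A very large Dirichlet concentration suppresses between-sample scatter so
    each group's labels are effectively multinomial at its planted composition.
    """
    p_ref = np.asarray(proportions_ref, dtype=float)
    p_test = np.asarray(proportions_test, dtype=float)
    k = len(p_ref)
    with np.errstate(divide="ignore", invalid="ignore"):
        mult = np.where(p_ref > 0, p_test / np.where(p_ref > 0, p_ref, 1.0), 0.0)
    return CompositionSpec(
        cluster_names=[f"c{i}" for i in range(k)],
        baseline_proportions=p_ref,
        effect_multipliers={"ref": np.ones(k), "test": mult},
        n_samples_per_condition={"ref": n_samples[0], "test": n_samples[1]},
        dirichlet_concentration=1e9,
        cells_per_sample=n_cells,
        seed=seed,
    )
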