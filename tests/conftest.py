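import numpy as np
import pandas as pd
import pytest

from uromet.preprocess import MetaboliteMatrix
from uromet.pipeline import COVARIATE_COLUMNS
from uromet.simulate import GeneSpec, SimulationConfig, simulate_cohort, simulate_covariates


@pytest.fixture(scope="session")
def small_cohort():
    """One causal gene (beta=0.7), n=1200, moderate MAFs so groups pass filters."""
    cfg = SimulationConfig(
        n_samples=1200,
        genes=[GeneSpec("G1", 6, 0.7)],
        maf_range=(2e-3, 8e-3),
        n_null_metabolites=6,
        n_reference_metabolites=4,
        seed=11,
    )
    covariates, genotypes, annotations, metabolites, truth = simulate_cohort(cfg)
    return {
        "config": cfg,
        "covariates": covariates,
        "genotypes": genotypes,
        "annotations": annotations,
        "metabolites": metabolites,
        "truth": truth,
    }


@pytest.fixture(scope="session")
def design_matrix():
    def make(covariates: pd.DataFrame) -> np.ndarray:
        return np.column_stack(
            [np.ones(len(covariates))]
            + [covariates[c].to_numpy(dtype=float) for c in COVARIATE_COLUMNS]
        )

    return make


@pytest.fixture()
def raw_matrix():
    """Tiny deterministic raw metabolite matrix with a missing cell."""
    rng = np.random.default_rng(5)
    values = pd.DataFrame(
        np.exp(rng.standard_normal((40, 4))),
        index=[f"S{i}" for i in range(40)],
        columns=["metA", "metB", "metC", "metD"],
    )
    values.iloc[0, 3] = np.nan
    pathways = {"metA": "amino acid", "metB": "amino acid",
                "metC": "lipid-fatty acid", "metD": "other"}
    return MetaboliteMatrix(values, pathways, "raw")
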