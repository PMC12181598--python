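import numpy as np
import pandas as pd
import pytest

from frailmark.simulate import PlantedMarker, SerumSpec, SimConfig, generate_cohort, generate_expression


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """Study-sized cohort with one planted marker per sex."""
    return SimConfig(
        n_old_female=24, n_old_male=28, n_young_female=13, n_young_male=13,
        n_genes=50,
        planted_markers=(
            PlantedMarker("MARK_F", "F", "gait4", 0.8),
            PlantedMarker("MARK_M", "M", "walk400", -0.8),
        ),
        serum_markers=(
            SerumSpec("S_F", sex_effect="F", standardized_shift_per_tertile=1.0),
            SerumSpec("S_NULL", sex_effect="none"),
        ),
        seed=11,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort(small_config)


@pytest.fixture(scope="session")
def small_expression(small_config, small_cohort):
    return generate_expression(small_cohort, small_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(202409)


def random_correlation_instance(rng, n_genes=None, n_samples=None):
    """A random expression matrix + phenotype for oracle comparisons."""
    n_genes = n_genes or int(rng.integers(2, 51))
    n_samples = n_samples or int(rng.integers(4, 31))
    genes = [f"g{i:03d}" for i in range(n_genes)]
    samples = [f"s{i:03d}" for i in range(n_samples)]
    expr = pd.DataFrame(
        rng.normal(size=(n_genes, n_samples)), index=pd.Index(genes, name="gene_id"),
        columns=samples,
    )
    cohort = pd.DataFrame(
        {
            "sex": "F", "age_group": "old", "age": 80.0, "bmi": 26.0, "fried_score": 1,
            "walk400": rng.normal(350, 50, n_samples),
            "gait4": rng.normal(4.2, 1.0, n_samples),
            "chair5": rng.normal(14, 4, n_samples),
        },
        index=pd.Index(samples, name="sample_id"),
    )
    return expr, cohort
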