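import numpy as np
import pytest

from regscreen.synthetic import (
    CohortConfig,
    SyntheticTruth,
    decoy_names,
    generate_annotation,
    generate_cohort,
)


def make_cohort(
    seed: int,
    alpha: float = 1.5,
    beta: float = 1.5,
    gamma: float = 1.5,
    noise: float = 0.5,
    n_samples: int = 41,
    n_decoy_tfs: int = 20,
    n_background_regions: int = 0,
    n_genes: int = 30,
    **cfg_kwargs,
):
    """Small, fast cohort used across the suite; ground truth is the oracle."""
    truth = SyntheticTruth(
        alpha=alpha, beta=beta, gamma=gamma,
        noise_sd_expr=noise, noise_sd_acc=noise, seed=seed,
    )
    config = CohortConfig(
        n_samples=n_samples,
        n_genes=n_genes,
        n_decoy_tfs=n_decoy_tfs,
        n_background_regions=n_background_regions,
        **cfg_kwargs,
    )
    named = [truth.regulator_gene, truth.target_gene, *decoy_names(config)]
    annotation = generate_annotation(config, seed=seed, named_genes=named)
    return generate_cohort(truth, config, annotation)


@pytest.fixture
def default_cohort():
    return make_cohort(seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
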