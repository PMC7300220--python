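import warnings

import numpy as np
import pytest

from siropk.evaluation import bootstrap, vpc
from siropk.model import FINAL_MODEL, CovariateSpec
from siropk.nlme import FitSettings, covariate_search, fit
from siropk.synthetic import CohortSpec, generate_cohort, simulate_observations

#: genotype counts of the six biallelic variants from the study cohort
#: (n = 15 children): variant -> (hom-ref, het, hom-alt)
STUDY_GENOTYPE_COUNTS = {
    "ABCB1_rs1045642": (1, 5, 9),
    "ABCC4_rs1751034": (1, 2, 12),
    "ABCC8_rs757110": (3, 8, 4),
    "ABCG2_rs2231142": (8, 6, 1),
    "UGT1A8_rs1042597": (3, 4, 8),
    "UGT2B15_rs1902023": (7, 6, 2),
}

#: fast settings for the many small fits in the suite
FAST_FIT = FitSettings(
    n_starts=1, compute_se=False, ftol=1e-8, maxiter=150, polish_maxfev=150
)


@pytest.fixture(scope="session")
def final_model():
    return FINAL_MODEL


@pytest.fixture(scope="session")
def small_dataset(final_model):
    """Two subjects, three trough observations each, final-model variability."""
    cohort = generate_cohort(CohortSpec(n=2, seed=3), final_model)
    return simulate_observations(cohort, final_model, 3)


@pytest.fixture(scope="session")
def tdm_dataset(final_model):
    """A 15-child TDM-like cohort: trough-only sparse sampling."""
    cohort = generate_cohort(CohortSpec(n=15, seed=42), final_model)
    return simulate_observations(cohort, final_model, 42)


@pytest.fixture(scope="session")
def recovery_fit(final_model):
    """Fit of the 100-subject rich-design recovery cohort (shared: expensive)."""
    cohort = generate_cohort(CohortSpec(n=100, seed=7, design="rich"), final_model)
    data = simulate_observations(cohort, final_model, 7)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return fit(data, final_model, FAST_FIT)


@pytest.fixture(scope="session")
def planted_covariate_search(final_model):
    """Stepwise search on data carrying a true genotype effect on CL/F."""
    gen = final_model.with_covariate(CovariateSpec("cl", "g", "genotype", theta=1.5))
    cohort = generate_cohort(
        CohortSpec(n=20, seed=77, design="rich", covariate_freqs={"g": 0.5}), gen
    )
    data = simulate_observations(cohort, gen, 77)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return covariate_search(
            data, final_model, [CovariateSpec("cl", "g", "genotype", theta=1.0)], FAST_FIT
        )


@pytest.fixture(scope="session")
def false_inclusion_count(final_model):
    """Inclusions of a null covariate over 20 replicate datasets (shared)."""
    candidate = [CovariateSpec("cl", "g", "genotype", theta=1.0)]
    inclusions = 0
    for rep in range(20):
        cohort = generate_cohort(
            CohortSpec(n=10, seed=500 + rep, design="rich", covariate_freqs={"g": 0.5}),
            final_model,
        )
        data = simulate_observations(cohort, final_model, 600 + rep)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            final, _ = covariate_search(data, final_model, candidate, FAST_FIT)
        if final.covariates:
            inclusions += 1
    return inclusions


@pytest.fixture(scope="session")
def boot_dataset(final_model):
    cohort = generate_cohort(CohortSpec(n=8, seed=13, design="rich"), final_model)
    return simulate_observations(cohort, final_model, 13)


@pytest.fixture(scope="session")
def bootstrap_pair(boot_dataset, final_model):
    """The same 10-replicate bootstrap run twice with one seed (shared)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        b1 = bootstrap(boot_dataset, final_model, n_reps=10, seed=99, settings=FAST_FIT)
        b2 = bootstrap(boot_dataset, final_model, n_reps=10, seed=99, settings=FAST_FIT)
    return b1, b2


@pytest.fixture(scope="session")
def vpc_dataset(final_model):
    cohort = generate_cohort(CohortSpec(n=40, seed=17, design="rich"), final_model)
    return simulate_observations(cohort, final_model, 17)


@pytest.fixture(scope="session")
def vpc_self_coverage(vpc_dataset, final_model):
    """Prediction-corrected VPC of data simulated from the model itself."""
    return vpc(vpc_dataset, final_model, n_sim=200, seed=5, bins=4)
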