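import numpy as np
import pytest

from oralfusion import (
    CohortSpec,
    CvConfig,
    EffectParams,
    feature_matrix_from_frame,
    generate_cohort,
    preprocess_cohort,
    quantify_cohort,
)

VEL_COLS = ["norm_intensity", "norm_heterogeneity"]


@pytest.fixture(scope="session")
def small_cohort():
    """4-patient default-effect cohort shared across tests."""
    return generate_cohort(CohortSpec(n_patients=4, replicates_per_sample=5, seed=7))


@pytest.fixture(scope="session")
def small_feature_matrices(small_cohort):
    """(raman, velscope) FeatureMatrix pair for the small cohort."""
    rfm = feature_matrix_from_frame(preprocess_cohort(small_cohort.spectra), modality="raman")
    vfm = feature_matrix_from_frame(
        quantify_cohort(small_cohort.images), VEL_COLS, modality="velscope"
    )
    return rfm, vfm


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def cohort_feature_matrices(spec: CohortSpec):
    """Generate a cohort and return its aligned per-modality feature matrices."""
    cohort = generate_cohort(spec)
    rfm = feature_matrix_from_frame(preprocess_cohort(cohort.spectra), modality="raman")
    vfm = feature_matrix_from_frame(quantify_cohort(cohort.images), VEL_COLS, modality="velscope")
    assert rfm.sample_ids == vfm.sample_ids
    return rfm, vfm
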