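import pytest

from tumorpkpd import TumorGrowthModel, default_parameters
from tumorpkpd.synthetic import NoiseModel, generate_cohort, generate_gcv_pk_samples


@pytest.fixture(scope="session")
def ref_params():
    return default_parameters()


@pytest.fixture(scope="session")
def zero_noise_cohort(ref_params):
    """All six arms, deterministic volumes (the calibration's exact forward model)."""
    return generate_cohort(ref_params, noise=NoiseModel(kind="none"))


@pytest.fixture(scope="session")
def zero_noise_pk(ref_params):
    return generate_gcv_pk_samples(
        ref_params.ka_gcv, ref_params.kex_gcv, 0.008, noise=NoiseModel(kind="none")
    )


@pytest.fixture(scope="session")
def zero_noise_fit(zero_noise_cohort, zero_noise_pk):
    """Full sequential calibration on the noise-free synthetic cohort."""
    model = TumorGrowthModel(zero_noise_cohort, gcv_pk=zero_noise_pk)
    return model.fit()
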