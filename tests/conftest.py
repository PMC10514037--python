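import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from bnctdose import BeamConfig, PhantomSpec, RunConfig, run_pipeline

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def _run(tmp_path_factory, name, **config_kwargs):
    outdir = tmp_path_factory.mktemp(name)
    return run_pipeline(RunConfig(seed=1, **config_kwargs), outdir)


@pytest.fixture(scope="session")
def sharp_gradient_spec():
    """Linear transverse TNR gradient sampled without blur or downsampling."""
    return PhantomSpec(tnr_field=("gradient", 1.5, 4.0), psf_fwhm_mm=0.0,
                       pet_downsample=(1, 1, 1))


@pytest.fixture(scope="session")
def sharp_gradient_result(tmp_path_factory, sharp_gradient_spec):
    return _run(tmp_path_factory, "sharp_grad", phantom=sharp_gradient_spec)


@pytest.fixture(scope="session")
def sharp_gradient_result_noshield(tmp_path_factory, sharp_gradient_spec):
    return _run(tmp_path_factory, "sharp_grad_ns", phantom=sharp_gradient_spec,
                beam=BeamConfig(self_shielding=False))


@pytest.fixture(scope="session")
def blurred_gradient_result(tmp_path_factory):
    return _run(tmp_path_factory, "blur_grad",
                phantom=PhantomSpec(tnr_field=("gradient", 1.5, 4.0)))


@pytest.fixture(scope="session")
def bimodal_result(tmp_path_factory):
    return _run(tmp_path_factory, "bimodal",
                phantom=PhantomSpec(tnr_field=("bimodal", 1.5, 3.5)))


def roi_mean_boron_dose(result, mode):
    mask = result.tnr.mask.mask
    return float(result.methods[mode].dose.d_phy_b10[mask].mean())
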