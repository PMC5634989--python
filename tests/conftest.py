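import numpy as np
import pytest

from vqfv import PhantomSpec, generate_phantom, segment_lungs


def small_spec(**kw) -> PhantomSpec:
    """Desk-scale 32^3 phantom spec for fast unit tests."""
    defaults = dict(shape=(32, 32, 32), spacing=(4.0, 4.0, 4.0), seed=0)
    defaults.update(kw)
    return PhantomSpec(**defaults)


@pytest.fixture(scope="session")
def noiseless_case():
    """Two-valued phantom: no defects, no gradient, no blur, no noise."""
    spec = small_spec(functional_fraction=1.0, ap_gradient=0.0,
                      psf_fwhm_mm=0.0, noise="none", defects=())
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def default_case():
    """One default-condition phantom (noise, blur, gradient, defects)."""
    spec = PhantomSpec(functional_fraction=0.7, seed=42)
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def default_wl(default_case):
    return segment_lungs(default_case.case.ct)
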