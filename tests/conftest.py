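import numpy as np
import pytest

from xlfdr.sn import SNParams


@pytest.fixture
def rng():
    return np.random.default_rng(20240613)


def random_sn(rng, mu_scale=3.0, sig_lo=0.5, sig_hi=3.0, lam_scale=2.0) -> SNParams:
    return SNParams(
        mu=float(rng.normal(0.0, mu_scale)),
        sigma=float(rng.uniform(sig_lo, sig_hi)),
        lam=float(rng.normal(0.0, lam_scale)),
    )
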