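import numpy as np
import pytest

from dielectrocell import DebyeModel, PermittivitySpectrum

GAMMA_PAIR = DebyeModel(terms=((60.0, 10e-12), (10.0, 50e-12)), eps_inf=3.5)


def loss_spectrum(model: DebyeModel, f_min=1e7, f_max=4.35e10, n=200,
                  noise_rel=0.0, seed=0, label="") -> PermittivitySpectrum:
    """Loss-only spectrum evaluated from a Debye model, optionally noisy."""
    f = np.geomspace(f_min, f_max, n)
    y = model.loss(f)
    if noise_rel > 0:
        rng = np.random.default_rng(seed)
        y = y * (1.0 + noise_rel * rng.standard_normal(y.shape))
    return PermittivitySpectrum(freq_hz=f, eps_real=np.real(model.eps_complex(f)),
                                eps_imag=np.clip(y, 0.0, None), label=label,
                                provenance="synthetic")


@pytest.fixture
def gamma_pair_model():
    """Two-term gamma decomposition: bulk-like (60, 10 ps) + hydration (10, 50 ps)."""
    return GAMMA_PAIR
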