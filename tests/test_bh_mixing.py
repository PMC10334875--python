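import numpy as np
import pytest
from hypothesis import assume, given, settings, strategies as st
from scipy.optimize import brentq

from dielectrocell import (DebyeModel, MixtureContext, PermittivitySpectrum,
                           extract_cell_spectrum, forward_bh, invert_bh)
from dielectrocell.bh_mixing import (BHSolverError, DegenerateInversionError,
                                     bh_residual, check_branch_continuity)
from dielectrocell.synthetic_data import SyntheticConfig, synthesize_experiment


def bisect_forward_real(eps_p: float, eps_m: float, phi: float) -> float:
    """Independent scalar oracle: bisection on the real-valued mixing relation."""

    def g(es):
        return (es - eps_p) / (eps_m - eps_p) * (eps_m / es) ** (1 / 3) - (1 - phi)

    lo, hi = sorted((eps_p, eps_m))
    return brentq(g, lo + 1e-12, hi - 1e-12, xtol=1e-13)


def test_homogeneous_mixture_returns_medium():
    eps = 78 - 10j
    assert invert_bh(eps, eps, 0.5) == pytest.approx(eps, rel=1e-12)


def test_pure_particle_limit():
    eps_sus, eps_med = 60 - 5j, 78 - 10j
    out = invert_bh(eps_sus, eps_med, 1 - 1e-9)
    assert abs(out - eps_sus) / abs(eps_sus) < 1e-6


def test_worked_point_against_bisection_oracle():
    es_oracle = bisect_forward_real(60.0, 78.0, 0.5)
    assert es_oracle == pytest.approx(68.63, abs=0.01)
    es = forward_bh(60 + 0j, 78 + 0j, 0.5)
    assert es.real == pytest.approx(es_oracle, abs=1e-8)
    assert abs(es.imag) < 1e-12
    back = invert_bh(es, 78 + 0j, 0.5)
    assert back.real == pytest.approx(60.0, abs=1e-6)


def test_forward_phi_limits_exact():
    ec, em = 60 - 8j, 78 - 12j
    assert forward_bh(ec, em, 0.0) == em
    assert forward_bh(ec, em, 1.0) == ec


def test_forward_monotone_in_phi():
    es = [forward_bh(60 + 0j, 78 + 0j, p).real for p in np.linspace(0.05, 0.95, 10)]
    assert np.all(np.diff(es) < 0)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    epr=st.floats(2.0, 100.0), epi=st.floats(0.0, 80.0),
    emr=st.floats(2.0, 100.0), emi=st.floats(0.0, 80.0),
    phi=st.floats(0.05, 0.95),
)
def test_roundtrip_property(epr, epi, emr, emi, phi):
    """invert(forward(e_p)) returns e_p to 1e-8 relative across the passive range."""
    ep = complex(epr, -epi)
    em = complex(emr, -emi)
    assume(abs(ep - em) > 1e-9)
    es = forward_bh(ep, em, phi)
    assert abs(bh_residual(es, em, ep, phi)) < 1e-10
    back = invert_bh(es, em, phi)
    assert abs(back - ep) / max(abs(ep), 1.0) < 1e-8


def test_residual_satisfied_on_vector_input():
    f = np.geomspace(1e8, 4e10, 50)
    cell = DebyeModel(terms=((55.0, 10e-12), (8.0, 50e-12)), eps_inf=3.5)
    med = DebyeModel(terms=((70.0, 9e-12),), eps_inf=3.5)
    es = forward_bh(cell.eps_complex(f), med.eps_complex(f), 0.54)
    res = np.abs(bh_residual(es, med.eps_complex(f), cell.eps_complex(f), 0.54))
    assert res.max() < 1e-10
    assert check_branch_continuity(es / med.eps_complex(f))


def test_degenerate_inversion_detected():
    # eps_sus/eps_med tuned so that B = (1-phi)(ratio)^(1/3) = 1 exactly
    phi = 0.5
    ratio = 1.0 / (1 - phi) ** 3
    with pytest.raises(DegenerateInversionError):
        invert_bh(78.0 * ratio + 0j, 78.0 + 0j, phi)


def test_extraction_recovers_cell_spectrum_noiseless():
    exp = synthesize_experiment(SyntheticConfig(
        c_suc=0.3, phi=0.54, noise_rel=0.0, n_points=200, f_min=1e7, seed=0))
    truth = exp.truth["cell_spectrum"]
    sus = exp.truth["suspension_relaxational"]
    med = exp.truth["medium_relaxational"]
    cell = extract_cell_spectrum(sus, med, MixtureContext(phi=0.54))
    band = cell.freq_hz >= 1e8
    rel_r = np.abs(cell.eps_real - truth.eps_real) / np.abs(truth.eps_real)
    rel_i = np.abs(cell.eps_imag[band] - truth.eps_imag[band]) / truth.eps_imag[band]
    assert rel_r.max() < 1e-6
    assert rel_i.max() < 1e-6
    assert cell.provenance == "bh_extracted"


def test_extraction_with_noise_stays_close_on_gamma_band():
    """1% multiplicative noise: median-seed gamma-band error stays below 5%."""
    base = synthesize_experiment(SyntheticConfig(
        c_suc=0.3, phi=0.54, noise_rel=0.0, n_points=120, f_min=1e8, seed=0))
    truth = base.truth["cell_spectrum"]
    sus, med = base.truth["suspension_relaxational"], base.truth["medium_relaxational"]
    band = sus.freq_hz >= 5e8
    errs = []
    for seed in range(100):
        rng = np.random.default_rng(seed)

        def jitter(s):
            return s.with_values(
                eps_real=s.eps_real * (1 + 0.01 * rng.standard_normal(len(s))),
                eps_imag=np.clip(s.eps_imag * (1 + 0.01 * rng.standard_normal(len(s))),
                                 0, None))

        cell = extract_cell_spectrum(jitter(sus), jitter(med),
                                     MixtureContext(phi=0.54))
        rel = np.abs(cell.eps_imag[band] - truth.eps_imag[band]) \
            / truth.eps_imag[band]
        errs.append(np.median(rel))   # typical-point error over the band
    assert np.median(errs) < 0.05


def test_non_overlapping_grids_rejected():
    a = PermittivitySpectrum(freq_hz=np.geomspace(1e7, 1e8, 10),
                             eps_real=np.full(10, 70.0), eps_imag=np.zeros(10))
    b = PermittivitySpectrum(freq_hz=np.geomspace(1e9, 1e10, 10),
                             eps_real=np.full(10, 70.0), eps_imag=np.zeros(10))
    with pytest.raises(ValueError):
        extract_cell_spectrum(a, b, MixtureContext(phi=0.5))


def test_mixture_context_validation():
    with pytest.raises(ValueError):
        MixtureContext(phi=1.2)
    with pytest.raises(ValueError):
        MixtureContext(phi=0.5, phi_sd=0.6)
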