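import json

import numpy as np
import pytest
from scipy.constants import epsilon_0

from dielectrocell import (KKOptions, MixtureContext, extract_cell_spectrum,
                           kk_loss_from_real, osmolarity_of_sucrose)
from dielectrocell.synthetic_data import (SyntheticConfig, make_cell_model,
                                          make_medium_model,
                                          synthesize_experiment,
                                          write_experiment)


class TestOsmolarity:
    @pytest.mark.parametrize("c,mosm", [(0.3, 308.0), (0.5, 518.0),
                                        (0.7, 732.0), (0.9, 949.0)])
    def test_table_exact(self, c, mosm):
        assert osmolarity_of_sucrose(c) == mosm

    def test_strictly_increasing(self):
        cs = np.linspace(0.0, 1.0, 21)
        vals = [osmolarity_of_sucrose(c) for c in cs]
        assert np.all(np.diff(vals) > 0)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            osmolarity_of_sucrose(-0.1)


class TestMediumModel:
    def test_pure_water_limit_single_term(self):
        model, _ = make_medium_model(0.0)
        assert model.n_terms == 1
        d, t = model.terms[0]
        assert 8e-12 <= t <= 10e-12
        assert d == pytest.approx(73.2, abs=1.0)

    def test_concentration_slows_and_strengthens_hydration(self):
        cs = np.linspace(0.05, 0.95, 10)
        tau1 = []
        d2 = []
        for c in cs:
            model, _ = make_medium_model(c)
            tau1.append(model.terms[0][1])
            d2.append(model.terms[1][0])
        assert np.all(np.diff(tau1) > 0)
        assert np.all(np.diff(d2) > 0)

    def test_peak_shift_with_concentration(self):
        lo, _ = make_medium_model(0.3)
        hi, _ = make_medium_model(0.9)
        assert hi.terms[0][1] > lo.terms[0][1]


class TestCellModel:
    def test_preset_slow_ratio_endpoints(self):
        for cond, expected in (("isotonic", 0.08), (0.3, 0.08),
                               ("hypertonic", 0.22), (0.9, 0.22)):
            model = make_cell_model(cond, include_beta=False)
            (d1, _), (d2, _) = model.terms
            assert d2 / (d1 + d2) == pytest.approx(expected, abs=1e-9)

    def test_retardation_fixed_at_five(self):
        for c in (0.3, 0.5, 0.7, 0.9):
            (_, t1), (_, t2) = make_cell_model(c, include_beta=False).terms
            assert t2 / t1 == pytest.approx(5.0, rel=1e-12)

    def test_beta_terms_above_gamma_window(self):
        model = make_cell_model(0.3)
        slow = [t for _, t in model.terms if t > 1e-9]
        assert len(slow) == 2
        assert min(slow) > 10e-9


class TestSynthesis:
    def test_determinism_and_seed_sensitivity(self):
        cfg = SyntheticConfig(n_points=64, seed=7)
        a = synthesize_experiment(cfg)
        b = synthesize_experiment(cfg)
        assert np.array_equal(a.medium.eps_real, b.medium.eps_real)
        assert np.array_equal(a.suspension.eps_imag, b.suspension.eps_imag)
        c = synthesize_experiment(SyntheticConfig(n_points=64, seed=8))
        assert not np.array_equal(a.medium.eps_real, c.medium.eps_real)

    def test_noiseless_closed_loop(self):
        """Without noise/EP/conductivity the chain inverts exactly."""
        from dielectrocell.preprocess import EPModel
        cfg = SyntheticConfig(c_suc=0.5, phi=0.5, noise_rel=0.0, sigma_dc=0.0,
                              ep=EPModel(0.0, 1.0), n_points=150, f_min=1e7,
                              seed=0)
        exp = synthesize_experiment(cfg)
        cell = extract_cell_spectrum(exp.suspension, exp.medium,
                                     MixtureContext(phi=0.5))
        truth = exp.truth["cell_spectrum"]
        band = cell.freq_hz >= 1e8
        rel = np.abs(cell.eps_imag[band] - truth.eps_imag[band]) \
            / truth.eps_imag[band]
        assert rel.max() < 1e-6

    def test_conductivity_inflates_measured_loss_not_kk(self):
        lo = synthesize_experiment(SyntheticConfig(noise_rel=0.0, sigma_dc=0.0,
                                                   n_points=128, seed=0))
        hi = synthesize_experiment(SyntheticConfig(noise_rel=0.0, sigma_dc=0.5,
                                                   n_points=128, seed=0))
        w0 = 2 * np.pi * lo.medium.freq_hz[0]
        # measured loss gains exactly sigma/(eps0 w) at low frequency
        gain = hi.medium.eps_imag[0] - lo.medium.eps_imag[0]
        assert gain == pytest.approx(0.5 / (epsilon_0 * w0), rel=1e-9)
        # KK-derived loss is invariant (real parts identical)
        kk_lo = kk_loss_from_real(lo.medium, KKOptions())
        kk_hi = kk_loss_from_real(hi.medium, KKOptions())
        assert np.array_equal(kk_lo.eps_imag, kk_hi.eps_imag)

    def test_suspension_loss_between_medium_and_cell(self):
        exp = synthesize_experiment(SyntheticConfig(noise_rel=0.0, n_points=128,
                                                    f_min=1e9, seed=0))
        f = exp.medium.freq_hz
        i = np.argmin(np.abs(f - 1.6e10))   # gamma peak region
        med = exp.truth["medium_relaxational"].eps_imag[i]
        sus = exp.truth["suspension_relaxational"].eps_imag[i]
        cell = exp.truth["cell_spectrum"].eps_imag[i]
        lo, hi = sorted((med, cell))
        assert lo < sus < hi

    def test_write_experiment_outputs(self, tmp_path):
        exp = synthesize_experiment(SyntheticConfig(n_points=32, seed=0))
        out = write_experiment(exp, tmp_path / "cond")
        truth = json.loads((out / "truth.json").read_text())
        assert (out / "medium.csv").exists()
        assert (out / "suspension.csv").exists()
        assert truth["osmolarity_mosm"] == 308.0
        assert truth["gamma"]["retardation"] == pytest.approx(5.0)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            SyntheticConfig(c_suc=-0.1)
        with pytest.raises(ValueError):
            SyntheticConfig(noise_rel=-1.0)
        with pytest.raises(ValueError):
            SyntheticConfig(beta_terms=((100.0, 1e-10),))
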