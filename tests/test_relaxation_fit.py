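import numpy as np
import pytest

from dielectrocell import (ColeColeModel, DebyeModel, eval_cole_cole,
                           eval_debye_loss, fit_cole_cole_gamma,
                           fit_multi_debye, gamma_metrics, select_n_bic)
from dielectrocell.relaxation_fit import (GammaMetricError,
                                          IdentifiabilityError, bic_from_rss)
from dielectrocell.synthetic_data import make_cell_model

from conftest import loss_spectrum


class TestEvaluation:
    def test_debye_loss_peak_value(self):
        model = DebyeModel(terms=((70.0, 10e-12),))
        f_peak = 1.0 / (2 * np.pi * 10e-12)
        assert eval_debye_loss(model, [f_peak])[0] == pytest.approx(35.0, rel=1e-12)

    def test_two_terms_sum(self):
        m12 = DebyeModel(terms=((60.0, 10e-12), (10.0, 50e-12)))
        m1 = DebyeModel(terms=((60.0, 10e-12),))
        m2 = DebyeModel(terms=((10.0, 50e-12),))
        f = np.array([1e9])
        assert eval_debye_loss(m12, f)[0] == pytest.approx(
            eval_debye_loss(m1, f)[0] + eval_debye_loss(m2, f)[0], rel=1e-14)

    def test_cole_cole_alpha_zero_equals_debye(self):
        cc = ColeColeModel(delta_eps=70.0, tau=10e-12, alpha=0.0, eps_inf=5.0)
        debye = DebyeModel(terms=((70.0, 10e-12),), eps_inf=5.0)
        f = np.geomspace(1e6, 1e12, 61)
        np.testing.assert_allclose(eval_cole_cole(cc, f), debye.eps_complex(f),
                                   rtol=1e-14)

    def test_cole_cole_limits(self):
        cc = ColeColeModel(delta_eps=70.0, tau=10e-12, alpha=0.2, eps_inf=5.0)
        assert eval_cole_cole(cc, [1e-2])[0].real == pytest.approx(75.0, rel=1e-4)
        assert eval_cole_cole(cc, [1e18])[0].real == pytest.approx(5.0, rel=1e-4)

    def test_model_validation(self):
        with pytest.raises(ValueError):
            DebyeModel(terms=((-1.0, 1e-11),))
        with pytest.raises(ValueError):
            DebyeModel(terms=((1.0, 1e-11), (2.0, 1e-11)))
        with pytest.raises(ValueError):
            ColeColeModel(delta_eps=1.0, tau=1e-11, alpha=1.0)

    def test_terms_canonicalized_ascending_tau(self):
        m = DebyeModel(terms=((10.0, 50e-12), (60.0, 10e-12)))
        assert m.terms[0][1] < m.terms[1][1]


class TestMultiDebyeFit:
    def test_single_term_exact_recovery(self):
        spec = loss_spectrum(DebyeModel(terms=((70.0, 10e-12),)))
        fr = fit_multi_debye(spec, 1, seed=0)
        (d, t), = fr.model.terms
        assert d == pytest.approx(70.0, rel=1e-6)
        assert t == pytest.approx(10e-12, rel=1e-6)

    def test_two_term_recovery(self, gamma_pair_model):
        spec = loss_spectrum(gamma_pair_model)
        fr = fit_multi_debye(spec, 2, seed=0)
        (d1, t1), (d2, t2) = fr.model.terms
        assert d1 == pytest.approx(60.0, rel=1e-3)
        assert t1 == pytest.approx(10e-12, rel=1e-3)
        assert d2 == pytest.approx(10.0, rel=1e-3)
        assert t2 == pytest.approx(50e-12, rel=1e-3)

    def test_start_permutation_invariance(self, gamma_pair_model):
        spec = loss_spectrum(gamma_pair_model)
        t1 = fit_multi_debye(spec, 2, seed=11).model.terms
        t2 = fit_multi_debye(spec, 2, seed=97).model.terms
        np.testing.assert_allclose(np.asarray(t1), np.asarray(t2), rtol=1e-5)

    def test_nested_fit_rss_never_increases(self, gamma_pair_model):
        spec = loss_spectrum(gamma_pair_model, noise_rel=0.01, seed=5)
        rss = [fit_multi_debye(spec, n, seed=0).rss for n in (1, 2, 3)]
        assert rss[1] <= rss[0]
        assert rss[2] <= rss[1] * (1 + 1e-9)

    def test_identifiability_guard(self, gamma_pair_model):
        spec = loss_spectrum(gamma_pair_model, n=10)
        with pytest.raises(IdentifiabilityError):
            fit_multi_debye(spec, 6, seed=0)


class TestBICSelection:
    def test_parsimony_on_exact_single_debye(self):
        spec = loss_spectrum(DebyeModel(terms=((70.0, 10e-12),)))
        best_n, fits = select_n_bic(spec, range(1, 5), seed=0)
        assert best_n == 1

    def test_two_gamma_terms_beat_one(self, gamma_pair_model):
        """A single Debye term cannot describe the two-component gamma process."""
        spec = loss_spectrum(gamma_pair_model, noise_rel=0.01, seed=2)
        _, fits = select_n_bic(spec, range(1, 3), seed=0)
        bic = {f.model.n_terms: f.bic for f in fits}
        assert bic[2] < bic[1]

    def test_bic_formula(self):
        # M ln(RSS/M) + k ln M for residuals above the floor
        assert bic_from_rss(2.0, 100, 4, y_scale=1.0) == pytest.approx(
            100 * np.log(0.02) + 4 * np.log(100))


class TestColeCole:
    def test_pure_debye_alpha_near_zero(self):
        spec = loss_spectrum(DebyeModel(terms=((70.0, 10e-12),)), f_min=5e8)
        fr = fit_cole_cole_gamma(spec, seed=0)
        assert fr.model.alpha < 0.01

    def test_two_debye_data_broadened(self, gamma_pair_model):
        spec = loss_spectrum(gamma_pair_model, f_min=5e8)
        fr = fit_cole_cole_gamma(spec, seed=0)
        assert fr.model.alpha > 0.02

    def test_dehydrated_broader_than_isotonic(self):
        iso = loss_spectrum(make_cell_model(0.3, include_beta=False), f_min=5e8)
        deh = loss_spectrum(make_cell_model(0.9, include_beta=False), f_min=5e8)
        a_iso = fit_cole_cole_gamma(iso, seed=0).model.alpha
        a_deh = fit_cole_cole_gamma(deh, seed=0).model.alpha
        assert a_deh > a_iso


class TestGammaMetrics:
    def test_arithmetic(self, gamma_pair_model):
        spec = loss_spectrum(gamma_pair_model)
        fr = fit_multi_debye(spec, 2, seed=0)
        g = gamma_metrics(fr)
        assert g.ratio_slow == pytest.approx(10.0 / 70.0, rel=1e-3)
        assert g.retardation == pytest.approx(5.0, rel=1e-3)

    def test_wrong_term_count_rejected(self):
        spec = loss_spectrum(DebyeModel(terms=((70.0, 10e-12),)))
        fr = fit_multi_debye(spec, 1, seed=0)
        with pytest.raises(GammaMetricError):
            gamma_metrics(fr)
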