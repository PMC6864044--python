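"""Least-squares spectral inversion: recovery, profiling, hyperparameters."""

import numpy as np
import pytest

from dslox.blood_optics import ForwardModelParams, forward_spectrum, load_blood_coefficients
from dslox.lsf import (
    LeastSquaresOximetry,
    LsfHyperparams,
    evaluate_mse,
    fit_sO2_lsf,
    optimize_lsf_hyperparams,
)
from dslox.preprocessing import WindowBank

LAM = WindowBank().centres_nm
COEFFS = load_blood_coefficients()


def _model_spectrum(so2, w=0.12, z=0.1, amplitude=1.3, alpha=0.8):
    p = ForwardModelParams(amplitude=amplitude, alpha=alpha, w=w, z=z)
    return forward_spectrum(p, so2, LAM, COEFFS)


class TestSingleFit:
    @pytest.mark.parametrize("so2", np.round(np.arange(0.0, 1.01, 0.1), 2))
    def test_exact_recovery_on_matched_noiseless_spectra(self, so2):
        spec = _model_spectrum(so2)
        res = fit_sO2_lsf(spec, LAM, hp=LsfHyperparams(w=0.12), coeffs=COEFFS, z=0.1)
        assert abs(res.so2 - so2) < 1e-3

    def test_exact_fit_at_zero_so2_has_zero_residual(self):
        spec = _model_spectrum(0.0)
        res = fit_sO2_lsf(spec, LAM, hp=LsfHyperparams(w=0.12), coeffs=COEFFS, z=0.1)
        assert res.so2 == pytest.approx(0.0, abs=1e-6)
        assert res.residual == pytest.approx(0.0, abs=1e-12)

    def test_nuisance_parameters_recovered(self):
        res = fit_sO2_lsf(_model_spectrum(0.7, amplitude=2.0, alpha=1.4), LAM,
                          hp=LsfHyperparams(w=0.12), coeffs=COEFFS, z=0.1)
        assert res.alpha == pytest.approx(1.4, abs=1e-6)
        assert res.amplitude == pytest.approx(2.0, rel=1e-5)

    def test_scattering_factor_mismatch_biases_recovery(self):
        # generated with W=0.2, fitted with W=0 -> systematic nonzero bias
        spec = _model_spectrum(0.8, w=0.2)
        res = fit_sO2_lsf(spec, LAM, hp=LsfHyperparams(w=0.0), coeffs=COEFFS, z=0.1)
        assert abs(res.so2 - 0.8) > 1e-4

    def test_nonpositive_intensity_in_range_rejected(self):
        spec = _model_spectrum(0.5)
        spec[7] = 0.0
        with pytest.raises(ValueError, match="non-positive"):
            fit_sO2_lsf(spec, LAM, coeffs=COEFFS)

    def test_profiled_nuisances_match_normal_equations_oracle(self):
        # at fixed sO2, the profiled (c0, alpha) must equal the direct
        # linear least-squares solution of log I = c0 - alpha*0.5*log(lam) - mu z
        so2, w, z = 0.35, 0.12, 0.1
        spec = _model_spectrum(so2, w=w, z=z)
        hp = LsfHyperparams(w=w)
        sel = hp.band_selector(LAM)
        lam = LAM[sel]
        from dslox.blood_optics import attenuation_coefficient

        mu = attenuation_coefficient(so2, lam, w, COEFFS)
        X = np.column_stack([np.ones(lam.size), -0.5 * np.log(lam)])
        target = np.log(spec[sel]) + mu * z
        beta_oracle, *_ = np.linalg.lstsq(X, target, rcond=None)
        res = fit_sO2_lsf(spec, LAM, hp=hp, coeffs=COEFFS, z=z)
        # fitted so2 equals the generating value, so profiled betas comparable
        assert res.alpha == pytest.approx(beta_oracle[1], abs=1e-6)
        assert np.log(res.amplitude) == pytest.approx(2 * beta_oracle[0], abs=1e-6)

    def test_refinement_never_worse_than_grid(self):
        rng = np.random.default_rng(5)
        spec = _model_spectrum(0.63) * np.exp(rng.normal(0, 0.02, LAM.size))
        model = LeastSquaresOximetry(spec, LAM, hyperparams=LsfHyperparams(w=0.12),
                                     coeffs=COEFFS, z=0.1)
        refined = model.fit(grid_points=21, refine=True)
        coarse = model.fit(grid_points=21, refine=False)
        assert refined.residual[0] <= coarse.residual[0] + 1e-15


class TestHyperparams:
    def test_defaults_carry_optimized_published_configuration(self):
        hp = LsfHyperparams()
        assert hp.w == 0.12
        assert (hp.lam_lo, hp.lam_hi) == (548.0, 586.0)

    def test_range_must_cover_contrast_region(self):
        with pytest.raises(ValueError, match="contrast"):
            LsfHyperparams(lam_lo=560.0, lam_hi=600.0)

    def test_too_few_bands_rejected(self):
        hp = LsfHyperparams(lam_lo=548.0, lam_hi=586.0)
        with pytest.raises(ValueError, match=">= 3"):
            hp.band_selector(np.array([560.0, 570.0]))

    def test_w_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            LsfHyperparams(w=1.2)

    def test_optimizer_recovers_generating_w_on_noiseless_data(self):
        so2s = np.linspace(0.55, 0.95, 25)
        spectra = np.stack([_model_spectrum(s, w=0.12) for s in so2s])
        hp, surface = optimize_lsf_hyperparams(
            spectra, LAM, so2s, w_grid=(0.0, 0.12, 0.3),
            range_grid=((548.0, 586.0),), z=0.1,
        )
        assert hp.w == 0.12
        assert surface.valid.all()

    def test_single_cell_grid_returned_with_its_mse(self):
        so2s = np.array([0.6, 0.8])
        spectra = np.stack([_model_spectrum(s) for s in so2s])
        hp, surface = optimize_lsf_hyperparams(
            spectra, LAM, so2s, w_grid=(0.12,), range_grid=((548.0, 586.0),), z=0.1,
        )
        assert len(surface) == 1
        assert hp == LsfHyperparams(w=0.12, lam_lo=548.0, lam_hi=586.0)
        assert surface.mse.iloc[0] == pytest.approx(0.0, abs=1e-12)


class TestEvaluateMse:
    def test_identity_gives_zero(self):
        x = np.linspace(0, 1, 7)
        assert evaluate_mse(x, x) == 0.0

    def test_constant_offset_squared(self):
        x = np.linspace(0, 0.9, 10)
        assert evaluate_mse(x + 0.1, x) == pytest.approx(0.01)

    def test_matches_brute_force_on_random_vectors(self):
        rng = np.random.default_rng(3)
        p, t = rng.random(50), rng.random(50)
        brute = sum((a - b) ** 2 for a, b in zip(p, t)) / 50
        assert evaluate_mse(p, t) == pytest.approx(brute, rel=1e-12)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            evaluate_mse(np.array([]), np.array([]))


class TestResultsObject:
    def test_summary_reports_mse_when_labels_given(self):
        so2s = np.array([0.6, 0.7, 0.8])
        spectra = np.stack([_model_spectrum(s) for s in so2s])
        res = LeastSquaresOximetry(spectra, LAM, labels=so2s,
                                   hyperparams=LsfHyperparams(w=0.12), z=0.1).fit()
        text = res.summary()
        assert "MSE" in text and "W (scattering)" in text
        assert res.params.shape == (3, 5)
        assert res.mse < 1e-10
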