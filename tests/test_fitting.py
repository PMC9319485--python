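"""Regressor training/prediction contracts, the NLLS oracle and the ADC map."""

import numpy as np
import pytest

import prostadiff as pf
from prostadiff.fitting import FitterConfig, nlls_fit, predict_parameters, train_fitter
from prostadiff.scheme import clinical_adc_scheme
from prostadiff.signals import batch_signals


class TestTrainFitter:
    def test_noise_free_single_parameter_regression_is_easy(self, scheme):
        """An ADC-like 1-parameter model trains to validation MSE < 1e-4 (scaled units)."""
        ds = pf.generate_training_set("ADC", scheme, n=4000, snr=None, seed=20)
        est = train_fitter(ds, FitterConfig(seed=21))
        assert est.validation_mse < 1e-4

    def test_determinism_same_seed_same_loss_curve(self, scheme):
        ds = pf.generate_training_set("DKI", scheme, n=1500, snr=35, seed=22)
        cfg = FitterConfig(seed=23, epochs=15, patience=15)
        a = train_fitter(ds, cfg)
        b = train_fitter(ds, cfg)
        np.testing.assert_array_equal(a.validation_loss_curve, b.validation_loss_curve)

    def test_single_epoch_degenerate_schedule(self, scheme):
        ds = pf.generate_training_set("DKI", scheme, n=500, snr=35, seed=24)
        est = train_fitter(ds, FitterConfig(seed=25, epochs=1))
        assert est.best_epoch == 1
        assert len(est.validation_loss_curve) == 1

    def test_training_requires_truth(self, scheme):
        ds = pf.generate_training_set("DKI", scheme, n=50, snr=35, seed=26)
        ds.truth = None
        with pytest.raises(ValueError, match="ground-truth"):
            train_fitter(ds, FitterConfig(seed=0, epochs=1))

    def test_validation_loss_improves(self, small_dki_estimator):
        curve = small_dki_estimator.validation_loss_curve
        assert curve[small_dki_estimator.best_epoch - 1] < curve[0]


class TestPredictParameters:
    def test_width_mismatch_rejected(self, small_dki_estimator):
        with pytest.raises(ValueError, match="width"):
            predict_parameters(small_dki_estimator, np.ones((3, 7)))

    def test_all_ones_prediction_stays_in_prior_box(self, small_dki_estimator):
        pred = predict_parameters(small_dki_estimator, np.ones((1, 10)))
        assert 0.5 <= pred["D_K"].iloc[0] <= 3.0
        assert 0.01 <= pred["K"].iloc[0] <= 2.99

    def test_verdict_residual_fraction_never_negative(self, scheme):
        ds = pf.generate_training_set("VERDICT", scheme, n=2000, snr=35, seed=27)
        est = train_fitter(ds, FitterConfig(seed=28, epochs=30, patience=30))
        extreme = batch_signals("VERDICT", scheme, [[0.99, 0.01, 8.0, 2.0]])
        pred = predict_parameters(est, extreme)
        assert pred["f_VASC"].iloc[0] >= 0.0
        assert pred["cellularity"].iloc[0] == pytest.approx(
            pred["f_IC"].iloc[0] / pred["R"].iloc[0] ** 3
        )

    def test_predicted_f_ic_monotone_in_true_f_ic(self, scheme):
        """Median predicted f_IC rises monotonically with true f_IC (others fixed)."""
        ds = pf.generate_training_set("VERDICT", scheme, n=6000, snr=35, seed=32)
        est = train_fitter(ds, FitterConfig(seed=33))
        medians = []
        for f_ic in np.linspace(0.1, 0.9, 5):
            truth = np.tile([f_ic, 0.05, 8.0, 2.0], (200, 1))
            sig = batch_signals("VERDICT", scheme, truth)
            medians.append(np.median(predict_parameters(est, sig)["f_IC"]))
        assert np.all(np.diff(medians) > 0), medians


class TestNLLSOracle:
    def test_noise_free_ivim_recovery(self, scheme):
        truth = np.array([[0.2, 1.0, 2.0]])
        sig = batch_signals("IVIM", scheme, truth)
        frame, resnorm, degenerate = nlls_fit("IVIM", scheme, sig)
        np.testing.assert_allclose(frame[["f", "D", "Dstar"]].to_numpy(), truth, rtol=1e-3)
        assert resnorm[0] < 1e-6
        assert not degenerate[0]

    def test_noise_free_dki_recovery(self, scheme):
        truth = np.array([[1.2, 0.8], [2.5, 1.9]])
        sig = batch_signals("DKI", scheme, truth)
        frame, _res, _deg = nlls_fit("DKI", scheme, sig)
        np.testing.assert_allclose(frame[["D_K", "K"]].to_numpy(), truth, rtol=1e-3)

    def test_constant_signal_flagged_degenerate(self, scheme):
        sig = np.ones((1, len(scheme)))
        frame, resnorm, degenerate = nlls_fit("ADC", scheme, sig)
        assert degenerate[0]
        # no decay: the diffusivity runs to its lower bound with ~zero residual slope
        assert frame["d"].iloc[0] == pytest.approx(0.1, abs=0.01)

    def test_verdict_sum_constraint_respected(self, scheme):
        truth = np.array([[0.55, 0.35, 8.0, 2.0]])
        sig = batch_signals("VERDICT", scheme, truth)
        frame, _res, _deg = nlls_fit("VERDICT", scheme, sig)
        assert frame["f_IC"].iloc[0] + frame["f_EES"].iloc[0] <= 1.0 + 1e-6


class TestADCMap:
    b_clin = [0.0, 150.0, 500.0, 1000.0]

    def _mono_exp_volume(self, d, shape=(3, 3, 2)):
        b = np.asarray(self.b_clin) * 1e-3
        return np.exp(-b * d) * np.ones(shape + (1,))

    def test_exact_recovery_on_mono_exponential(self):
        adc = pf.compute_adc_map(self._mono_exp_volume(1.0), self.b_clin)
        np.testing.assert_allclose(adc, 1.0, atol=1e-9)

    def test_plug_in_voxel(self):
        vol = np.exp(-np.array([0.15, 0.5, 1.0]))[None, None, None, :]
        adc = pf.compute_adc_map(vol, [150.0, 500.0, 1000.0])
        assert adc[0, 0, 0] == pytest.approx(1.0, abs=1e-9)

    def test_scale_invariance(self):
        rng = np.random.default_rng(29)
        vol = self._mono_exp_volume(1.3) * np.exp(rng.normal(0, 0.02, (3, 3, 2, 4)))
        a = pf.compute_adc_map(vol, self.b_clin)
        b = pf.compute_adc_map(1000.0 * vol, self.b_clin)
        np.testing.assert_allclose(a, b, rtol=1e-12)

    def test_excluding_b0_suppresses_perfusion_bias(self, ):
        """On IVIM-generated data the all-b fit overestimates D; dropping b=0 helps."""
        sch = clinical_adc_scheme()
        D = 1.0
        sig = batch_signals("IVIM", sch, [[0.2, D, 20.0]])  # fast pseudo-diffusion pool
        vol = sig.reshape(1, 1, 1, 4)
        without_b0 = pf.compute_adc_map(vol, sch.b * 1e3)[0, 0, 0]
        # same OLS including the b=0 row
        b = sch.b
        lnS = np.log(sig[0])
        bc = b - b.mean()
        with_b0 = -np.sum(bc * (lnS - lnS.mean())) / np.sum(bc**2)
        assert abs(without_b0 - D) < abs(with_b0 - D)

    def test_nonpositive_signals_excluded_per_voxel(self):
        vol = self._mono_exp_volume(1.0, shape=(1, 2, 1))
        vol[0, 0, 0, 2] = 0.0  # one corrupted measurement: fit on the rest
        adc = pf.compute_adc_map(vol, self.b_clin)
        assert adc[0, 0, 0] == pytest.approx(1.0, abs=1e-9)
        vol[0, 1, 0, 1:] = 0.0  # <2 usable points -> missing
        adc = pf.compute_adc_map(vol, self.b_clin)
        assert np.isnan(adc[0, 1, 0])

    def test_too_few_nonzero_b_values(self):
        with pytest.raises(ValueError, match="nonzero"):
            pf.compute_adc_map(np.ones((2, 2, 1, 2)), [0.0, 500.0])


class TestFitVolume:
    def test_unmasked_prediction_covers_grid_and_roi_medians(self, scheme, small_dki_estimator):
        rng = np.random.default_rng(30)
        truth = np.column_stack([rng.uniform(1.0, 2.0, 8), rng.uniform(0.5, 1.5, 8)])
        vol = batch_signals("DKI", scheme, truth).reshape(2, 2, 2, 10)
        roi = pf.ROITable([pf.ROIEntry("p1", "TP", [[0, 0, 0], [0, 0, 1]])], volume_shape=(2, 2, 2))
        maps, rows = pf.fit_volume(small_dki_estimator, vol, scheme, roi, patient_id="p1")
        assert maps["D_K"].shape == (2, 2, 2)  # whole unmasked grid
        assert set(rows["parameter"]) == {"D_K", "K"}
        assert set(rows.columns) == {"patient_id", "tissue_class", "parameter", "median", "iqr"}

    def test_empty_roi_gives_empty_table_with_warning(self, scheme, small_dki_estimator, caplog):
        import logging

        vol = np.ones((2, 2, 1, 10))
        roi = pf.ROITable([pf.ROIEntry("p1", "NT", np.empty((0, 3), dtype=int))])
        with caplog.at_level(logging.WARNING, logger="prostadiff"):
            _maps, rows = pf.fit_volume(small_dki_estimator, vol, scheme, roi)
        assert rows.empty
        assert "empty" in caplog.text.lower()

    def test_shape_mismatch_propagates(self, scheme, small_dki_estimator):
        with pytest.raises(ValueError):
            pf.fit_volume(small_dki_estimator, np.ones((2, 2, 1, 7)), scheme)


class TestEstimatorSerialization:
    def test_round_trip(self, tmp_path, small_dki_estimator, scheme):
        path = tmp_path / "est.pkl"
        pf.save_estimator(small_dki_estimator, path)
        back = pf.load_estimator(path)
        sig = pf.generate_training_set("DKI", scheme, n=20, snr=35, seed=31).signals
        np.testing.assert_array_equal(
            predict_parameters(back, sig).to_numpy(),
            predict_parameters(small_dki_estimator, sig).to_numpy(),
        )
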