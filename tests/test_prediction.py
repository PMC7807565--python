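"""Contours-only DVH prediction from the population model."""
from __future__ import annotations

import numpy as np
import pytest

from conftest import make_case, small_phantom_spec
from ovhqa.dose_distance import average_dose_distance_curve, dose_distance_points
from ovhqa.metrics import MetricSpec, achieved_dvh, evaluate_metric
from ovhqa.phantoms import generate_patient
from ovhqa.population import PopulationModel, save_model, load_model, train_population_model
from ovhqa.prediction import predict_dvh, predict_metrics


def flat_model(level=50.0, oar="oar", lo=-20.0, hi=80.0):
    grid = np.arange(lo, hi + 1, 2.5)
    c = np.full(grid.size, float(level))
    return PopulationModel(
        oar=oar, distance_grid=grid, p25=c, p50=c, p75=c, n_patients=3
    )


def sloped_model(oar="oar", lo=-20.0, hi=80.0, tau=30.0, spread=2.0):
    grid = np.arange(lo, hi + 1, 2.5)
    p50 = np.where(grid <= 0, 50.0, 50.0 * np.exp(-np.maximum(grid, 0) / tau))
    return PopulationModel(
        oar=oar,
        distance_grid=grid,
        p25=np.maximum(p50 - spread, 0),
        p50=p50,
        p75=p50 + spread,
        n_patients=5,
    )


class TestPredictDVH:
    def test_single_voxel_is_unit_step(self):
        case = make_case(dose=None, shape=(16, 10, 10), oar_voxels=[(12, 5, 5)])
        # voxel sits at +12 mm; build a model with p50(12) = 18 Gy
        grid = np.arange(-10.0, 40.0, 2.5)
        p50 = np.full(grid.size, 18.0)
        model = PopulationModel(
            oar="oar", distance_grid=grid, p25=p50 - 2, p50=p50, p75=p50 + 2, n_patients=2
        )
        pred = predict_dvh(case, model, "oar", dose_bin_gy=0.1)
        f = lambda x: float(np.interp(x, pred.dose_axis, pred.volume_fraction_p50))
        assert f(17.9) == 1.0
        assert f(18.0) == 1.0
        assert f(18.2) == 0.0

    def test_flat_model_step_at_50(self):
        case = make_case(dose=None)
        pred = predict_dvh(case, flat_model(), "oar", dose_bin_gy=0.1)
        axis = pred.dose_axis
        for vf in (pred.volume_fraction_p25, pred.volume_fraction_p50, pred.volume_fraction_p75):
            assert np.all(vf[axis <= 50.0] == 1.0)
            assert np.all(vf[axis > 50.0] == 0.0)
        pm = predict_metrics(pred, MetricSpec.dmean())
        for v in (pm.p25, pm.p50, pm.p75):
            assert v == pytest.approx(50.0, abs=0.05)

    def test_step_dvh_metrics(self):
        # DVH = 1 below 40 Gy, 0 above, on a 200 cm^3 OAR
        case = make_case(dose=None)
        pred = predict_dvh(case, flat_model(level=40.0), "oar", dose_bin_gy=0.1)
        pred.oar_volume_cm3 = 200.0
        assert evaluate_metric(pred.curve(50), MetricSpec.v_abs(45.0)) == 0.0
        assert evaluate_metric(pred.curve(50), MetricSpec.v_rel(35.0)) == pytest.approx(100.0)

    def test_prediction_ignores_dose_bit_exactly(self):
        case = make_case(dose=np.random.default_rng(0).uniform(0, 50, (10, 10, 10)))
        model = sloped_model()
        with_dose = predict_dvh(case, model, "oar")
        without = predict_dvh(case.without_dose(), model, "oar")
        np.testing.assert_array_equal(with_dose.dose_axis, without.dose_axis)
        for p in ("p25", "p50", "p75"):
            np.testing.assert_array_equal(
                getattr(with_dose, f"volume_fraction_{p}"),
                getattr(without, f"volume_fraction_{p}"),
            )

    def test_band_ordering_of_dmean(self):
        case = make_case(dose=None)
        pm = predict_metrics(
            predict_dvh(case, sloped_model(), "oar"), MetricSpec.dmean()
        )
        assert pm.p25 <= pm.p50 <= pm.p75

    def test_scaling_equivariance(self):
        case = make_case(dose=None)
        m = sloped_model()
        k = 1.7
        scaled = PopulationModel(
            oar="oar",
            distance_grid=m.distance_grid,
            p25=k * m.p25,
            p50=k * m.p50,
            p75=k * m.p75,
            n_patients=m.n_patients,
        )
        bin_gy = 0.1
        dm = predict_metrics(predict_dvh(case, m, "oar", bin_gy), MetricSpec.dmean())
        dm_k = predict_metrics(predict_dvh(case, scaled, "oar", bin_gy), MetricSpec.dmean())
        assert dm_k.p50 == pytest.approx(k * dm.p50, abs=2 * bin_gy)

    def test_out_of_range_distances_clamped_and_reported(self):
        case = make_case(dose=None, shape=(16, 10, 10), oar_voxels=[(12, 5, 5), (5, 5, 8)])
        model = sloped_model(lo=0.0, hi=5.0)  # much narrower than the anatomy
        pred = predict_dvh(case, model, "oar")
        assert pred.clamped_fraction > 0

    def test_wrong_model_oar_rejected(self):
        case = make_case(dose=None)
        with pytest.raises(ValueError, match="bladder"):
            predict_dvh(case, flat_model(oar="bladder"), "oar")

    def test_empty_oar_rejected(self):
        case = make_case(dose=None)
        case.oars["oar"].voxels[:] = False
        with pytest.raises(ValueError, match="empty"):
            predict_dvh(case, flat_model(), "oar")


class TestSelfConsistency:
    def test_identical_cohort_predicts_its_own_dvh(self):
        """Model trained on clones of one noiseless phantom reproduces the
        achieved mean dose up to binning discretization."""
        spec = small_phantom_spec(noise_sd_gy=0.0)
        case = generate_patient(spec, 0)
        curves = [
            average_dose_distance_curve(dose_distance_points(case, "bowel_bag"))
            for _ in range(3)
        ]
        model = train_population_model(curves, "bowel_bag")
        pred = predict_dvh(case.without_dose(), model, "bowel_bag")
        predicted = predict_metrics(pred, MetricSpec.dmean()).p50
        achieved = evaluate_metric(achieved_dvh(case, "bowel_bag"), MetricSpec.dmean())
        assert predicted == pytest.approx(achieved, abs=0.5)

    def test_saved_model_predicts_identically(self, tmp_path):
        spec = small_phantom_spec(noise_sd_gy=0.0)
        case = generate_patient(spec, 0)
        curves = [
            average_dose_distance_curve(dose_distance_points(case, "bladder"))
            for _ in range(2)
        ]
        model = train_population_model(curves, "bladder")
        save_model(model, tmp_path / "m.json")
        loaded = load_model(tmp_path / "m.json")
        a = predict_dvh(case.without_dose(), model, "bladder")
        b = predict_dvh(case.without_dose(), loaded, "bladder")
        np.testing.assert_array_equal(a.volume_fraction_p50, b.volume_fraction_p50)
        pa = predict_metrics(a, MetricSpec.dmean())
        pb = predict_metrics(b, MetricSpec.dmean())
        assert (pa.p25, pa.p50, pa.p75) == (pb.p25, pb.p50, pb.p75)
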