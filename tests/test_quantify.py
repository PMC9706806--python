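import numpy as np
import pytest

import etongue as et
from etongue.errors import ValidationError
from etongue.quantify import AffineScaler, shared_range_scaler


class TestScalers:
    def test_zero_margin_maps_extremes(self):
        x = np.array([[0.0, 5.0], [100.0, 15.0]])
        in_s, out_s = et.fit_scalers(x, x, margin=0.0)
        np.testing.assert_allclose(in_s.transform(x),
                                   [[-1.0, -1.0], [1.0, 1.0]])

    def test_round_trip_identity(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(-5, 50, size=(20, 4))
        in_s, _ = et.fit_scalers(x, x[:, :2], margin=0.1)
        np.testing.assert_allclose(in_s.inverse(in_s.transform(x)), x,
                                   atol=1e-12)

    def test_margin_keeps_data_strictly_inside(self):
        x = np.array([[0.0], [100.0]])
        in_s, _ = et.fit_scalers(x, x, margin=0.1)
        scaled = in_s.transform(x)
        # [−10, 110] → [−1, 1]: 0 maps to −10/12·... = −5/6
        np.testing.assert_allclose(scaled, [[-5.0 / 6.0], [5.0 / 6.0]])
        assert np.all(np.abs(scaled) < 1.0)

    def test_constant_dimension_named(self):
        x = np.column_stack([np.arange(5.0), np.full(5, 3.0)])
        with pytest.raises(ValidationError, match="1"):
            et.fit_scalers(x, x[:, :1], margin=0.1)

    def test_shared_range_scaler_uses_global_extremes(self):
        x = np.array([[0.0, 10.0], [2.0, 20.0]])
        s = shared_range_scaler(x, margin=0.0)
        np.testing.assert_allclose(s.transform(np.array([[0.0, 20.0]])),
                                   [[-1.0, 1.0]])


class TestTrainPredict:
    def test_paper_topology_and_determinism(self, study):
        model = et.train_ann(study["x_train"], study["y_train"], n_hidden=7,
                             config=et.TrainConfig(seed=1))
        assert model.layer_sizes == (48, 7, 3)
        again = et.train_ann(study["x_train"], study["y_train"], n_hidden=7,
                             config=et.TrainConfig(seed=1))
        np.testing.assert_allclose(et.predict(model, study["x_test"]),
                                   et.predict(again, study["x_test"]),
                                   atol=1e-9)

    def test_training_reduces_loss_and_fits(self, noiseless_study):
        model = et.train_ann(noiseless_study["x_train"],
                             noiseless_study["y_train"],
                             config=et.TrainConfig(seed=0))
        rep = et.evaluate(et.predict(model, noiseless_study["x_train"]),
                          noiseless_study["y_train"], subset="training")
        assert model.final_loss < 1e-4
        assert rep.min_r2 >= 0.999

    def test_prediction_shape_and_row_invariance(self, study):
        model = et.train_ann(study["x_train"], study["y_train"],
                             config=et.TrainConfig(seed=2))
        pred = et.predict(model, study["x_test"])
        assert pred.shape == (10, 3)
        perm = np.random.default_rng(0).permutation(10)
        np.testing.assert_allclose(et.predict(model, study["x_test"][perm]),
                                   pred[perm], atol=1e-12)

    def test_dimension_mismatch(self, study):
        model = et.train_ann(study["x_train"], study["y_train"],
                             config=et.TrainConfig(seed=3))
        with pytest.raises(ValidationError):
            et.predict(model, study["x_test"][:, :12])

    def test_nonfinite_inputs_rejected(self, study):
        x = study["x_train"].copy()
        x[0, 0] = np.nan
        with pytest.raises(ValidationError):
            et.train_ann(x, study["y_train"])


class TestEvaluate:
    def test_perfect_prediction(self):
        y = np.random.default_rng(1).uniform(2, 300, size=(10, 3))
        rep = et.evaluate(y, y)
        for a in rep.analytes:
            assert a.slope == pytest.approx(1.0)
            assert a.intercept == pytest.approx(0.0, abs=1e-9)
            assert a.r2 == pytest.approx(1.0)
        assert rep.total_nrmse == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_nrmse(self):
        expected = np.array([[100.0], [200.0], [150.0]])
        rep = et.evaluate(1.1 * expected, expected)
        assert rep.analytes[0].slope == pytest.approx(1.1)
        assert rep.analytes[0].intercept == pytest.approx(0.0, abs=1e-9)
        assert rep.analytes[0].r2 == pytest.approx(1.0)
        assert rep.total_nrmse == pytest.approx(0.1)

    def test_sample_order_invariance(self):
        rng = np.random.default_rng(2)
        e = rng.uniform(2, 300, size=(12, 3))
        p = e + rng.normal(size=(12, 3))
        rep1 = et.evaluate(p, e)
        perm = rng.permutation(12)
        rep2 = et.evaluate(p[perm], e[perm])
        assert rep1.total_nrmse == pytest.approx(rep2.total_nrmse)
        for a1, a2 in zip(rep1.analytes, rep2.analytes):
            assert a1.r2 == pytest.approx(a2.r2)

    def test_constant_expected_column_rejected(self):
        e = np.ones((5, 1))
        with pytest.raises(ValidationError):
            et.evaluate(e * 1.1, e)


class TestTopologySearch:
    def test_single_candidate_returned(self, study):
        best, scores = et.topology_search(study["x_train"], study["y_train"],
                                          [7], cv_folds=3, seed=0)
        assert best == 7 and set(scores) == {7}

    def test_winner_has_lowest_score(self, study):
        best, scores = et.topology_search(study["x_train"], study["y_train"],
                                          [2, 7], cv_folds=3, seed=0)
        assert scores[best] == min(scores.values())

    def test_tie_breaks_to_smaller(self, monkeypatch):
        import etongue.quantify as q
        x = np.random.default_rng(0).normal(size=(30, 4))
        y = x[:, :3] + 10.0

        calls = {}
        monkeypatch.setattr(q, "total_nrmse", lambda p, e: 0.5)
        best, scores = q.topology_search(x, y, [9, 5], cv_folds=2, seed=0)
        assert best == 5 and scores[5] == scores[9] == 0.5


def test_array_beats_single_nip_sensor(bank, study):
    """Cross-selective 4-sensor features quantify better than the single
    nonselective NIP sensor on identical samples and seeds."""
    cfg = study["config"]
    seeds = study["seeds"]
    nip = [s for s in bank if s.sensor_id == "NIP"]
    m_train = et.simulate_dataset(nip, study["train"],
                                  noise=cfg.noise(seeds["train_noise"]))
    m_test = et.simulate_dataset(nip, study["test"],
                                 noise=cfg.noise(seeds["test_noise"]))
    x_train, _ = et.feature_matrix(m_train)
    x_test, _ = et.feature_matrix(m_test)
    assert x_train.shape[1] == 12

    tc = et.TrainConfig(seed=seeds["ann_init"])
    nip_model = et.train_ann(x_train, study["y_train"], config=tc)
    nip_rep = et.evaluate(et.predict(nip_model, x_test), study["y_test"])
    array_model = et.train_ann(study["x_train"], study["y_train"], config=tc)
    array_rep = et.evaluate(et.predict(array_model, study["x_test"]),
                            study["y_test"])
    assert array_rep.total_nrmse < nip_rep.total_nrmse
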