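"""End-to-end model object: training contract, cold start, determinism."""

import numpy as np
import pytest

from vaxhes import (HesitancySTL, NodePanel, SpatialConfig,
                    TemporalConfig, TrainConfig, TrainSplit,
                    make_linear_panel, run_experiment)

from conftest import random_graph


def tiny_setup(rng, n=12, ts=6):
    panel = make_linear_panel(N=n, TS=ts, seed=1)
    from vaxhes import ZipGraph
    g = ZipGraph(list(panel.zips), random_graph(rng, n).W, normalized=True)
    split = TrainSplit.random(n, 0.7, 0)
    return panel, g, split


SMALL_SPATIAL = SpatialConfig(hidden=8, dropout_rate=0.0)
SMALL_TEMPORAL = TemporalConfig(hidden=4, dropout_rate=0.0)


class TestTrainingContract:
    def test_zero_lr_leaves_parameters_unchanged(self, rng):
        panel, g, split = tiny_setup(rng)
        tc = TrainConfig(epochs=3, lr=0.0, weight_decay=0.0, seed=0,
                         tail_average=0.0)
        model = HesitancySTL(panel, g, split, spatial=SMALL_SPATIAL,
                             temporal=SMALL_TEMPORAL, train=tc)
        res = model.fit()
        rng2 = np.random.default_rng(0)
        from vaxhes.spatial import SpatialModule
        from vaxhes.temporal import TemporalModule
        ms0 = SpatialModule(panel.n_features, SMALL_SPATIAL, rng2)
        mt0 = TemporalModule(SMALL_TEMPORAL, rng2)
        for p_new, p_init in zip(res.ms.state_dict(), ms0.state_dict()):
            np.testing.assert_array_equal(p_new, p_init)
        for p_new, p_init in zip(res.mt.state_dict(), mt0.state_dict()):
            np.testing.assert_array_equal(p_new, p_init)

    def test_fixed_seed_bitwise_identical_loss_traces(self, rng):
        panel, g, split = tiny_setup(rng)
        tc = TrainConfig(epochs=10, lr=1e-3, seed=5)
        kwargs = dict(spatial=SpatialConfig(hidden=8, dropout_rate=0.5),
                      temporal=SMALL_TEMPORAL, train=tc)
        r1 = HesitancySTL(panel, g, split, **kwargs).fit()
        r2 = HesitancySTL(panel, g, split, **kwargs).fit()
        np.testing.assert_array_equal(r1.loss1_trace, r2.loss1_trace)
        np.testing.assert_array_equal(r1.loss2_trace, r2.loss2_trace)

    def test_two_optimizer_isolation(self, rng):
        """A spatial update step never touches temporal parameters and
        vice versa (the modules are optimized separately)."""
        panel, g, split = tiny_setup(rng)
        tc = TrainConfig(epochs=1, lr=1e-2, seed=0, tail_average=0.0)
        res = HesitancySTL(panel, g, split, spatial=SMALL_SPATIAL,
                           temporal=SMALL_TEMPORAL, train=tc).fit()
        assert not (set(map(id, res.ms.parameters()))
                    & set(map(id, res.mt.parameters())))
        # gradient of loss1 does not reach Mt parameters
        from vaxhes.spatial import loss1
        out = res.ms(panel.nc[:, :, 0], g)
        l1 = loss1(panel.h[split.K, 0], out[np.asarray(split.K)], 0.0, res.ms)
        for p in res.mt.parameters():
            p.grad = None
        l1.backward()
        assert all(p.grad is None for p in res.mt.parameters())

    def test_identifiable_linear_recovery_quick(self):
        """Training error collapses on a noiseless linear panel (small n)."""
        panel = make_linear_panel(N=20, TS=6, seed=0)
        from vaxhes import ZipGraph
        g = ZipGraph(list(panel.zips),
                     random_graph(np.random.default_rng(2), 20).W,
                     normalized=True)
        split = TrainSplit(list(range(20)), [])
        tc = TrainConfig(epochs=800, lr=1e-2, seed=0, weight_decay=0.0)
        res = HesitancySTL(panel, g, split,
                           spatial=SpatialConfig(hidden=32, dropout_rate=0.0),
                           temporal=SMALL_TEMPORAL, train=tc).fit()
        assert res.loss1_trace[-1] < 0.1
        assert res.loss1_trace[-1] < res.loss1_trace[0] / 20

    def test_empty_labeled_set_rejected(self):
        with pytest.raises(ValueError):
            TrainSplit([], [1, 2])

    def test_overlapping_split_rejected(self):
        with pytest.raises(ValueError):
            TrainSplit([1, 2], [2, 3])


class TestColdStartPrediction:
    def test_eval_hesitancy_never_read(self, rng):
        """Altering h of eval nodes changes nothing (cold-start contract)."""
        panel, g, split = tiny_setup(rng)
        tc = TrainConfig(epochs=20, lr=1e-3, seed=0)
        res = HesitancySTL(panel, g, split, spatial=SMALL_SPATIAL,
                           temporal=SMALL_TEMPORAL, train=tc).fit()
        preds = res.predict()
        h2 = panel.h.copy()
        ev = np.asarray(split.eval_set)
        h2[ev] = 0.99
        panel2 = NodePanel(list(panel.zips), list(panel.timesteps),
                           panel.nc.copy(), h2, panel.p.copy(),
                           list(panel.feature_names), mask=panel.mask.copy(),
                           normalized=True)
        res2 = HesitancySTL(panel2, g, split, spatial=SMALL_SPATIAL,
                            temporal=SMALL_TEMPORAL, train=tc).fit()
        np.testing.assert_array_equal(preds, res2.predict())

    def test_in_sample_prediction_available(self, rng):
        panel, g, split = tiny_setup(rng)
        tc = TrainConfig(epochs=10, lr=1e-3, seed=0)
        res = HesitancySTL(panel, g, split, spatial=SMALL_SPATIAL,
                           temporal=SMALL_TEMPORAL, train=tc).fit()
        preds = res.predict(split.K)
        assert preds.shape == (len(split.K), 1)
        assert np.all(np.isfinite(preds))

    def test_multi_horizon_rollout_shape(self, rng):
        panel, g, split = tiny_setup(rng, ts=8)
        tc = TrainConfig(epochs=5, lr=1e-3, seed=0, horizon=4)
        res = HesitancySTL(panel, g, split, spatial=SMALL_SPATIAL,
                           temporal=SMALL_TEMPORAL, train=tc).fit()
        preds = res.predict(horizon=4)
        assert preds.shape == (len(split.eval_set), 4)

    def test_summary_contains_metrics(self, rng):
        panel, g, split = tiny_setup(rng)
        tc = TrainConfig(epochs=5, lr=1e-3, seed=0)
        res = HesitancySTL(panel, g, split, spatial=SMALL_SPATIAL,
                           temporal=SMALL_TEMPORAL, train=tc).fit()
        text = res.summary()
        for key in ("MAPE", "RMSE", "R2", "loss1", "loss2"):
            assert key in text


class TestRunExperiment:
    def test_report_keys_and_determinism(self, rng, tmp_path):
        panel, g, split = tiny_setup(rng)
        tc = TrainConfig(epochs=10, lr=1e-3, seed=3)
        rep1 = run_experiment(panel, g, split, tc, SMALL_SPATIAL,
                              SMALL_TEMPORAL, outdir=tmp_path / "a")
        rep2 = run_experiment(panel, g, split, tc, SMALL_SPATIAL,
                              SMALL_TEMPORAL)
        for key in ("mape", "mse", "rmse", "mae", "r2"):
            assert key in rep1["metrics"]
        assert rep1["metrics"] == rep2["metrics"]
        assert (tmp_path / "a" / "report.json").exists()
        assert (tmp_path / "a" / "predictions.csv").exists()


class TestPanelSerialization:
    def test_save_load_round_trip(self, small_study, tmp_path):
        panel = small_study["panel"]
        panel.save(tmp_path / "panel")
        loaded = NodePanel.load(tmp_path / "panel")
        assert loaded.zips == panel.zips
        assert loaded.timesteps == panel.timesteps
        np.testing.assert_allclose(loaded.nc, panel.nc, atol=1e-12)
        np.testing.assert_allclose(loaded.h, panel.h, atol=1e-12)
        np.testing.assert_array_equal(loaded.p, panel.p)
        np.testing.assert_array_equal(loaded.mask, panel.mask)
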