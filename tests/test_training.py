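"""Split arithmetic, oversampling, learning-rate schedule, and the train loop."""

import numpy as np
import pytest

from conftest import small_arch
from varcnn.classifier import ClassifierSpec
from varcnn.training import (FusionModel, TrainConfig, TrainingDivergedError,
                             cross_validate, learning_rate, oversample_weights,
                             split_cohort, train)
from varcnn.volume_io import SampleRecord, VolumePatch


def fake_records(n_ad, n_nc):
    patch = VolumePatch(np.zeros((2, 2, 2)))
    recs = [SampleRecord(patch, np.zeros(3), 1, f"ad{i}") for i in range(n_ad)]
    recs += [SampleRecord(patch, np.zeros(3), 0, f"nc{i}") for i in range(n_nc)]
    return recs


SMOKE = dict(lr_base=0.01, batch_size=8, epochs=5, alpha=1.0)


class TestSplit:
    def test_exact_division_10_samples(self):
        tr, va = split_cohort(fake_records(5, 5), 0.8, seed=0)
        assert len(tr) == 8 and len(va) == 2
        assert sum(s.label for s in tr) == 4 and sum(s.label for s in va) == 1

    def test_same_seed_reproduces_identical_index_sets(self):
        recs = fake_records(7, 9)
        a = split_cohort(recs, 0.8, seed=3)
        b = split_cohort(recs, 0.8, seed=3)
        assert [s.subject_id for s in a[0]] == [s.subject_id for s in b[0]]
        c = split_cohort(recs, 0.8, seed=4)
        assert [s.subject_id for s in a[0]] != [s.subject_id for s in c[0]]

    def test_cohort_of_351_ad_and_415_nc_splits_612_154(self):
        tr, va = split_cohort(fake_records(351, 415), 0.8, seed=1)
        assert len(tr) == 280 + 332 == 612
        assert len(va) == 154
        assert sum(s.label for s in tr) == 280

    def test_missing_class_raises(self):
        with pytest.raises(ValueError, match="class"):
            split_cohort(fake_records(4, 0), 0.8, seed=0)


class TestOversampling:
    def test_balanced_labels_uniform(self):
        w = oversample_weights([0, 1, 0, 1])
        np.testing.assert_allclose(w, 0.25)

    def test_inverse_frequency_ratio_for_351_415(self):
        labels = [1] * 351 + [0] * 415
        w = oversample_weights(labels)
        assert w[0] / w[-1] == pytest.approx(415 / 351)

    def test_weighted_draws_balance_a_1_to_3_cohort(self):
        labels = np.array([1] * 50 + [0] * 150)
        w = oversample_weights(labels)
        rng = np.random.default_rng(0)
        draws = rng.choice(len(labels), size=10 ** 5, p=w)
        frac_ad = labels[draws].mean()
        assert abs(frac_ad - 0.5) < 3 * np.sqrt(0.25 / 10 ** 5)

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            oversample_weights([1, 1, 1])


class TestLearningRate:
    CFG = TrainConfig()

    def test_warmup_starts_at_zero_and_ramps(self):
        assert learning_rate(0, 20, self.CFG) == 0.0
        ramp = [learning_rate(s, 20, self.CFG) for s in range(40)]
        assert all(b > a for a, b in zip(ramp, ramp[1:]))
        assert ramp[-1] < 0.0005

    def test_plateau_at_base_rate_through_epoch_39(self):
        for epoch in (2, 10, 39):
            assert learning_rate(epoch * 20, 20, self.CFG) == pytest.approx(0.0005)

    def test_decay_by_5_at_epochs_40_and_80(self):
        assert learning_rate(50 * 20, 20, self.CFG) == pytest.approx(0.0001)
        assert learning_rate(90 * 20, 20, self.CFG) == pytest.approx(0.00002)


class TestTrainLoop:
    def test_smoke_run_loss_finite_and_decreasing(self, tiny_cohort):
        _, cohort = tiny_cohort
        model, hist = train(cohort, small_arch((8, 12, 8)),
                            ClassifierSpec(latent_dim=4, morph_dim=3),
                            TrainConfig(seed=0, **SMOKE))
        df = hist.to_dataframe()
        assert len(df) == SMOKE["epochs"]
        assert np.isfinite(df["total"]).all()
        assert df["total"].iloc[-1] < df["total"].iloc[0]

    def test_identical_seed_gives_identical_history_and_weights(self, tiny_cohort):
        _, cohort = tiny_cohort
        arch = small_arch((8, 12, 8))
        spec = ClassifierSpec(latent_dim=4, morph_dim=3)
        cfg = TrainConfig(seed=5, lr_base=0.01, batch_size=8, epochs=3, alpha=1.0)
        m1, h1 = train(cohort, arch, spec, cfg)
        m2, h2 = train(cohort, arch, spec, cfg)
        assert h1.to_dataframe().equals(h2.to_dataframe())
        for p1, p2 in zip(m1.params(), m2.params()):
            np.testing.assert_array_equal(p1.value, p2.value)

    def test_alpha_zero_total_equals_cross_entropy(self, tiny_cohort):
        _, cohort = tiny_cohort
        _, hist = train(cohort, small_arch((8, 12, 8)),
                        ClassifierSpec(latent_dim=4, morph_dim=3),
                        TrainConfig(seed=0, lr_base=0.01, batch_size=8, epochs=2, alpha=0.0))
        df = hist.to_dataframe()
        np.testing.assert_allclose(df["total"], df["ce"], rtol=1e-12)

    def test_huge_alpha_keeps_latents_at_the_prior(self, tiny_cohort):
        _, cohort = tiny_cohort
        finals = {}
        for alpha in (0.0, 1000.0):
            _, hist = train(cohort, small_arch((8, 12, 8)),
                            ClassifierSpec(latent_dim=4, morph_dim=3),
                            TrainConfig(seed=0, lr_base=0.01, batch_size=8,
                                        epochs=6, alpha=alpha))
            finals[alpha] = hist.to_dataframe()["val_kl"].iloc[-1]
        assert finals[1000.0] < finals[0.0]

    def test_non_finite_loss_aborts_with_diagnostic(self, tiny_cohort):
        _, cohort = tiny_cohort
        with pytest.raises(TrainingDivergedError, match="non-finite"):
            train(cohort, small_arch((8, 12, 8)),
                  ClassifierSpec(latent_dim=4, morph_dim=3),
                  TrainConfig(seed=0, lr_base=0.01, batch_size=8, epochs=1,
                              alpha=float("inf")))

    def test_metrics_only_path_trains_without_backbone(self, tiny_cohort):
        _, cohort = tiny_cohort
        model, hist = train(cohort, None, ClassifierSpec(latent_dim=0, morph_dim=3),
                            TrainConfig(seed=0, **SMOKE))
        assert model.backbone is None
        df = hist.to_dataframe()
        assert (df["kl"] == 0).all()
        probs = model.predict_records(cohort[:4])
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, rtol=1e-5)

    def test_checkpoint_round_trip_preserves_predictions(self, tiny_cohort, tmp_path):
        _, cohort = tiny_cohort
        model, _ = train(cohort, small_arch((8, 12, 8)),
                         ClassifierSpec(latent_dim=4, morph_dim=3),
                         TrainConfig(seed=1, lr_base=0.01, batch_size=8, epochs=2, alpha=1.0))
        model.save(tmp_path / "ckpt.npz")
        back = FusionModel.load(tmp_path / "ckpt.npz")
        np.testing.assert_allclose(back.score_records(cohort[:6]),
                                   model.score_records(cohort[:6]), rtol=1e-6)


class TestCrossValidate:
    SPEC = ClassifierSpec(latent_dim=0, morph_dim=3)
    CFG = TrainConfig(lr_base=0.01, batch_size=8, epochs=2, alpha=1.0)

    def test_single_seed_reports_zero_sd(self, tiny_cohort):
        _, cohort = tiny_cohort
        reports, summary = cross_validate(cohort, None, self.SPEC, self.CFG, seeds=[0])
        assert len(reports) == 1
        assert summary["auc"][1] == 0.0

    def test_five_seeds_give_five_reports(self, tiny_cohort):
        _, cohort = tiny_cohort
        reports, summary = cross_validate(cohort, None, self.SPEC, self.CFG,
                                          seeds=[0, 1, 2, 3, 4])
        assert len(reports) == 5
        aucs = [r.auc for r in reports]
        assert summary["auc"] == (pytest.approx(np.mean(aucs)), pytest.approx(np.std(aucs)))

    def test_summary_invariant_to_seed_order(self, tiny_cohort):
        _, cohort = tiny_cohort
        _, fwd = cross_validate(cohort, None, self.SPEC, self.CFG, seeds=[0, 1])
        _, rev = cross_validate(cohort, None, self.SPEC, self.CFG, seeds=[1, 0])
        assert fwd == rev

    def test_empty_seed_list_raises(self, tiny_cohort):
        _, cohort = tiny_cohort
        with pytest.raises(ValueError):
            cross_validate(cohort, None, self.SPEC, self.CFG, seeds=[])
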