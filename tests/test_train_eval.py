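"""Training loop, learning-rate schedule, stitched inference, compositing
and gap-restricted metrics."""

import numpy as np
import pandas as pd
import pytest

from scattergap.augment import augment_dataset, crop_strips
from scattergap.models import (
    MSDNetConfig,
    PartialConvConfig,
    build_msdnet,
    build_partialconv_unet,
)
from scattergap.nn import Module, Tensor
from scattergap.synthetic import simulate_dataset
from scattergap.train import (
    BiharmonicMethod,
    TrainConfig,
    composite_non_gap,
    difference_map,
    evaluate,
    gap_metrics,
    infer_full_image,
    l1_loss,
    lr_at,
    train,
)


class IdentityModel(Module):
    """Pass-through stand-in network for plumbing tests."""

    def __call__(self, x: Tensor) -> Tensor:
        return x


class ConstantModel(Module):
    def __init__(self, value: float):
        self.value = value

    def __call__(self, x: Tensor) -> Tensor:
        return Tensor(np.full_like(x.data, self.value))


@pytest.fixture(scope="module")
def tiny_data(mask512):
    masked, truth = simulate_dataset(4, mask512, seed=5)
    pairs = list(zip(masked, truth))
    aug = augment_dataset(pairs, mask512, np.random.default_rng(6))
    return pairs, aug


class TestLossAndSchedule:
    def test_l1_basic_values(self):
        a = np.zeros((2, 3))
        assert l1_loss(a, a) == 0.0
        assert l1_loss(a + 0.5, a) == pytest.approx(0.5)
        assert l1_loss(np.array([0.0, 1.0]), np.array([1.0, 1.0])) == pytest.approx(0.5)

    def test_l1_shape_mismatch(self):
        with pytest.raises(ValueError):
            l1_loss(np.zeros(3), np.zeros(4))

    @pytest.mark.parametrize(
        "epoch,expected", [(0, 1e-3), (99, 1e-3), (100, 1e-4), (150, 1e-4), (250, 1e-5)]
    )
    def test_step_schedule_drops_twice(self, epoch, expected):
        cfg = TrainConfig()
        assert lr_at(epoch, cfg) == pytest.approx(expected)

    def test_msd200_variant_schedule(self):
        cfg = TrainConfig(lr_step=60, total_epochs=180)
        assert lr_at(59, cfg) == pytest.approx(1e-3)
        assert lr_at(60, cfg) == pytest.approx(1e-4)
        assert lr_at(179, cfg) == pytest.approx(1e-5)

    def test_epoch_out_of_range(self):
        with pytest.raises(ValueError):
            lr_at(300, TrainConfig())


class TestTrain:
    def test_zero_epochs_returns_model_unchanged(self, tiny_data):
        _, aug = tiny_data
        net = build_msdnet(MSDNetConfig(num_layers=2, max_dilation=2), seed=0)
        before = [p.data.copy() for p in net.parameters()]
        net, history = train(net, aug, TrainConfig(total_epochs=0))
        assert history.empty
        for p, b in zip(net.parameters(), before):
            assert np.array_equal(p.data, b)

    def test_training_is_deterministic_given_seed(self, tiny_data):
        _, aug = tiny_data
        cfg = TrainConfig(total_epochs=2, batch_size=4, seed=9, validation_fraction=0.25)
        losses = []
        for _ in range(2):
            net = build_msdnet(MSDNetConfig(num_layers=2, max_dilation=2), seed=1)
            _, history = train(net, aug, cfg)
            losses.append(history.train_loss.tolist())
        assert losses[0] == losses[1]

    def test_loss_decreases_on_small_msdnet(self, tiny_data):
        _, aug = tiny_data
        net = build_msdnet(MSDNetConfig(num_layers=4, max_dilation=3), seed=2)
        _, history = train(
            net, aug, TrainConfig(total_epochs=4, batch_size=4, seed=0, validation_fraction=0.25)
        )
        assert history.train_loss.iloc[-1] < history.train_loss.iloc[0]
        assert np.isfinite(history[["train_loss", "val_loss"]].to_numpy()).all()
        assert len(history) == 4

    def test_partialconv_model_receives_masks(self, tiny_data):
        _, aug = tiny_data
        net = build_partialconv_unet(PartialConvConfig(depth=2, base_channels=2), seed=0)
        _, history = train(
            net, aug, TrainConfig(total_epochs=1, batch_size=4, validation_fraction=0.0)
        )
        assert len(history) == 1 and np.isfinite(history.train_loss.iloc[0])

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError):
            train(IdentityModel(), [], TrainConfig(total_epochs=1))


class TestInference:
    def test_identity_model_roundtrips_through_stitching(self, mask512, rng):
        img = rng.random((512, 512))
        out = infer_full_image(IdentityModel(), img, mask512)
        np.testing.assert_array_equal(out, img)

    def test_constant_model_gives_constant_image(self, mask512, rng):
        out = infer_full_image(ConstantModel(0.3), rng.random((512, 512)), mask512)
        assert np.all(out == pytest.approx(0.3))
        assert out.shape == (512, 512)


class TestCompositing:
    def test_composite_replaces_only_gap_pixels(self, mask512, rng):
        pred = rng.random((512, 512))
        inp = rng.random((512, 512))
        out = composite_non_gap(pred, inp, mask512)
        assert np.array_equal(out[~mask512.raster], inp[~mask512.raster])
        assert np.array_equal(out[mask512.raster], pred[mask512.raster])

    def test_non_gap_agreement_fraction(self, mask512, rng):
        pred = rng.random((512, 512))
        inp = rng.random((512, 512))
        out = composite_non_gap(pred, inp, mask512)
        frac = (out == inp).mean()
        assert frac >= 1.0 - mask512.raster.mean()


class TestGapMetrics:
    def _mask(self):
        raster = np.zeros((2, 3), bool)
        raster[0] = True
        return raster

    def test_perfect_prediction(self, rng):
        t = [rng.random((2, 3))]
        l1, r = gap_metrics(t, t, self._mask())
        assert l1 == 0.0 and r == pytest.approx(1.0)

    def test_perfect_anticorrelation(self, rng):
        t = rng.random((2, 3))
        l1, r = gap_metrics([1 - t], [t], self._mask())
        assert r == pytest.approx(-1.0)

    def test_hand_computed_three_pixel_case(self):
        pred = np.array([[0.0, 0.5, 1.0], [0, 0, 0]])
        truth = np.array([[0.0, 1.0, 1.0], [0, 0, 0]])
        l1, r = gap_metrics([pred], [truth], self._mask())
        assert l1 == pytest.approx(1 / 6)
        assert r == pytest.approx(np.sqrt(3) / 2, abs=1e-9)

    def test_zero_variance_truth_gives_nan_pearson(self):
        pred = np.array([[0.1, 0.2, 0.3], [0, 0, 0]])
        truth = np.ones((2, 3))
        l1, r = gap_metrics([pred], [truth], self._mask())
        assert np.isnan(r) and l1 > 0

    def test_affine_invariance_of_pearson(self, rng):
        p = [rng.random((2, 3))]
        t = [rng.random((2, 3))]
        _, r1 = gap_metrics(p, t, self._mask())
        _, r2 = gap_metrics([3.0 * p[0] + 1.0], [0.5 * t[0] - 2.0], self._mask())
        assert r1 == pytest.approx(r2)


class TestEvaluate:
    def test_oracle_model_scores_perfectly_on_horizontal_gaps(self, mask512, tiny_data):
        pairs, aug = tiny_data

        class Oracle(Module):
            """Returns the ground-truth strip for each input strip."""

            def __init__(self):
                self.lookup = {}
                for masked, truth in pairs:
                    for s_in, s_t in zip(crop_strips(masked), crop_strips(truth)):
                        self.lookup[s_in.pixels.tobytes()] = s_t.pixels

            def __call__(self, x: Tensor) -> Tensor:
                out = np.stack(
                    [self.lookup.get(x.data[i, 0].tobytes(), x.data[i, 0])
                     for i in range(x.data.shape[0])]
                )[:, None]
                return Tensor(out.astype(x.data.dtype))

        # oracle on full frames: horizontal track must be exact
        report = evaluate(Oracle(), pairs, aug, mask512)
        assert report.horizontal_l1 == pytest.approx(0.0, abs=1e-7)
        assert report.horizontal_pearson == pytest.approx(1.0, abs=1e-6)

    def test_biharmonic_slot_runs_with_mask_always(self, mask512, tiny_data):
        pairs, aug = tiny_data
        report = evaluate(BiharmonicMethod(mask512), pairs, aug, mask512)
        assert report.method == "biharmonic"
        assert 0 <= report.horizontal_l1 < 1
        assert report.to_frame().shape == (2, 3)

    def test_empty_sets_rejected(self, mask512, tiny_data):
        pairs, aug = tiny_data
        with pytest.raises(ValueError):
            evaluate(IdentityModel(), [], aug, mask512)
        with pytest.raises(ValueError):
            evaluate(IdentityModel(), pairs, [], mask512)


class TestDifferenceMap:
    def test_zero_for_equal_frames(self, rng):
        x = rng.random((5, 5))
        assert np.all(difference_map(x, x) == 0)

    def test_clips_above_threshold(self):
        pred = np.array([[0.5]])
        truth = np.array([[0.2]])
        assert difference_map(pred, truth)[0, 0] == pytest.approx(0.15)
        assert difference_map(pred, truth, clip=np.inf)[0, 0] == pytest.approx(0.3)
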