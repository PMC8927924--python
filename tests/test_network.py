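import numpy as np
import pytest

from trabstiff.egi import SphericalMap, make_grid
from trabstiff.network import (
    ModelConfig,
    SampleRecord,
    SphCNN,
    TrainConfig,
    assign_folds,
    build_model,
    count_params,
    cross_validate,
    evaluate,
    frobenius_error,
    train,
)
from trabstiff.network import _loss_and_grad
from trabstiff.stiffness import StiffnessMatrix

TINY = ModelConfig(
    in_channels=1,
    conv_widths=(4, 8, 16),
    kernel_coeffs=(8, 4, 2),
    dense_widths=(16, 36),
    input_bandwidth=16,
)


def random_map(rng, b=16, channels=1):
    grid = make_grid(b)
    vals = np.abs(rng.standard_normal((channels, 2 * b, 2 * b)))
    return SphericalMap(grid=grid, channels=tuple(f"c{i}" for i in range(channels)), values=vals)


def random_dataset(rng, n, b=16, channels=1, sites=("synthetic",), target=None):
    ds = []
    for i in range(n):
        C = target or StiffnessMatrix(
            rng.standard_normal((6, 6)) * 100 + np.eye(6) * (500 + 200 * rng.random())
        )
        ds.append(
            SampleRecord(
                sample_id=f"s{i}",
                features=random_map(rng, b, channels),
                site=sites[i % len(sites)],
                observed=C,
                bvtv=float(rng.uniform(0.1, 0.4)),
            )
        )
    return ds


class TestParameterCount:
    def test_default_three_channel_count(self):
        assert count_params(build_model(ModelConfig(in_channels=3))) == 420_132

    def test_default_one_channel_count(self):
        assert count_params(build_model(ModelConfig(in_channels=1))) == 416_036

    @pytest.mark.parametrize("channels", [1, 3])
    def test_about_point4_million(self, channels):
        n = count_params(build_model(ModelConfig(in_channels=channels)))
        assert round(n / 1e6, 1) == 0.4

    def test_tiny_config_closed_form(self):
        cfg = ModelConfig(
            in_channels=1,
            conv_widths=(1, 1, 1),
            kernel_coeffs=(1, 1, 1),
            dense_widths=(1, 36),
            input_bandwidth=16,
        )
        model = build_model(cfg)
        # conv kernels 1*1*1 x3 + conv biases 3 + prelu 3+1 + bn 2*(1+1+1)+2
        # + dense 1*1+1 + 1*36+36
        expected = 3 + 3 + 4 + 8 + 2 + 72
        assert count_params(model) == expected
        # cross-check by enumerating parameter arrays
        assert expected == sum(a.size for _, _, _, a in model.parameters())

    def test_dropout_adds_no_parameters(self):
        with_do = build_model(ModelConfig(in_channels=3, use_dropout=True))
        without = build_model(ModelConfig(in_channels=3, use_dropout=False))
        assert count_params(with_do) == count_params(without)

    def test_kernel_coeffs_exceeding_bandwidth_rejected(self):
        with pytest.raises(ValueError, match="bandwidth"):
            ModelConfig(kernel_coeffs=(64, 16, 8))
        with pytest.raises(ValueError, match="bandwidth"):
            ModelConfig(kernel_coeffs=(32, 32, 32))  # 32 > 16 after one pooling


class TestForward:
    def test_output_is_6x6(self, rng):
        model = build_model(TINY, seed=0)
        out = model.forward(random_map(rng))
        assert out.entries.shape == (6, 6)

    def test_zero_input_zero_head_gives_zero_matrix(self):
        model = build_model(TINY, seed=0)
        grid = make_grid(16)
        zero = SphericalMap(grid=grid, channels=("c0",), values=np.zeros((1, 32, 32)))
        out = model.forward(zero)
        np.testing.assert_array_equal(out.entries, 0.0)

    def test_eval_mode_deterministic(self, rng):
        model = build_model(TINY, seed=0)
        smap = random_map(rng)
        a = model.forward(smap).entries
        b = model.forward(smap).entries
        np.testing.assert_array_equal(a, b)

    def test_shape_mismatch_rejected(self, rng):
        model = build_model(TINY, seed=0)
        with pytest.raises(ValueError, match="channels"):
            model.forward(random_map(rng, channels=3))


class TestGradients:
    def test_analytic_gradients_match_finite_differences(self, rng):
        cfg = ModelConfig(
            in_channels=2,
            conv_widths=(2, 2, 2),
            kernel_coeffs=(4, 2, 1),
            dense_widths=(3, 36),
            input_bandwidth=16,
        )
        model = build_model(cfg, seed=1)
        N = 3
        X = rng.standard_normal((N, 2, 32 * 32))
        Y = rng.standard_normal((N, 36)) * 5 + 20

        def loss():
            pred = model.forward_batch(X, training=True)
            return _loss_and_grad(pred, Y)

        _, grad = loss()
        model.backward_batch(grad)
        analytic = {k: layer.grads[name].copy() for k, layer, name, _ in model.parameters()}
        for key, layer, name, arr in model.parameters():
            flat = arr.ravel()
            for i in rng.choice(flat.size, size=min(4, flat.size), replace=False):
                h = 1e-6 * max(1.0, abs(flat[i]))
                orig = flat[i]
                flat[i] = orig + h
                lp, _ = loss()
                flat[i] = orig - h
                lm, _ = loss()
                flat[i] = orig
                fd = (lp - lm) / (2 * h)
                a = analytic[key].ravel()[i]
                assert abs(fd - a) <= 1e-4 * max(1e-6, abs(fd), abs(a)), (key, i)


class TestLoss:
    def test_error_of_self_is_zero(self, rng):
        C = StiffnessMatrix(rng.standard_normal((6, 6)))
        assert frobenius_error(C, C) == 0.0

    def test_error_against_zero_is_one(self, rng):
        C = StiffnessMatrix(rng.standard_normal((6, 6)))
        zero = StiffnessMatrix(np.zeros((6, 6)))
        assert frobenius_error(C, zero) == pytest.approx(1.0)

    def test_scaling_error(self, rng):
        C = StiffnessMatrix(rng.standard_normal((6, 6)))
        scaled = StiffnessMatrix(1.5 * C.entries)
        assert frobenius_error(C, scaled) == pytest.approx(0.5)

    def test_zero_observed_rejected(self):
        zero = StiffnessMatrix(np.zeros((6, 6)))
        with pytest.raises(ValueError):
            frobenius_error(zero, zero)

    def test_batch_loss_matches_mean_of_sample_errors(self, rng):
        pred = rng.standard_normal((4, 36))
        target = rng.standard_normal((4, 36)) + 3
        loss, _ = _loss_and_grad(pred, target)
        direct = np.mean(
            [
                frobenius_error(target[i].reshape(6, 6), pred[i].reshape(6, 6))
                for i in range(4)
            ]
        )
        assert loss == pytest.approx(direct)


class TestTraining:
    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            train(build_model(TINY), [], TrainConfig(epochs=1, lr_schedule=((0, 1, 0.01),)))

    def test_default_schedule_is_600_epochs(self):
        tc = TrainConfig()
        assert tc.epochs == 600
        assert tc.batch_size == 16
        assert tc.lr_at(0) == 0.01
        assert tc.lr_at(200) == 0.001
        assert tc.lr_at(599) == 0.001

    def test_schedule_must_cover_epochs(self):
        with pytest.raises(ValueError):
            TrainConfig(epochs=100, lr_schedule=((0, 50, 0.01),))

    def test_memorizes_identical_target(self, rng):
        target = StiffnessMatrix(rng.standard_normal((6, 6)) * 100 + np.eye(6) * 500)
        ds = random_dataset(rng, 10, target=target)
        cfg = TINY
        model = build_model(cfg, seed=0)
        tc = TrainConfig(
            epochs=50, lr_schedule=((0, 30, 0.01), (30, 50, 0.001)), seed=0, batch_size=10
        )
        train(model, ds, tc)
        assert evaluate(model, ds).mean() < 0.05

    def test_same_seed_identical_parameters(self, rng):
        ds = random_dataset(rng, 6)
        tc = TrainConfig(epochs=3, lr_schedule=((0, 3, 0.01),), seed=4, batch_size=4)
        m1 = train(build_model(TINY, seed=2), ds, tc)
        m2 = train(build_model(TINY, seed=2), ds, tc)
        for (_, _, _, a), (_, _, _, b) in zip(m1.parameters(), m2.parameters()):
            np.testing.assert_array_equal(a, b)

    def test_training_log_recorded(self, rng):
        ds = random_dataset(rng, 6)
        tc = TrainConfig(epochs=5, lr_schedule=((0, 5, 0.01),), seed=0)
        model = train(build_model(TINY, seed=0), ds, tc)
        assert len(model.training_log) == 5

    def test_azimuthal_augmentation_runs(self, rng):
        ds = random_dataset(rng, 6)
        tc = TrainConfig(
            epochs=2, lr_schedule=((0, 2, 0.01),), seed=0, augment_azimuthal=True
        )
        model = train(build_model(TINY, seed=0), ds, tc)
        assert len(model.training_log) == 2


class TestCheckpoint:
    def test_save_load_round_trip(self, rng, tmp_path):
        ds = random_dataset(rng, 4)
        tc = TrainConfig(epochs=2, lr_schedule=((0, 2, 0.01),), seed=0)
        model = train(build_model(TINY, seed=3), ds, tc)
        p = tmp_path / "model.h5"
        model.save(p)
        back = SphCNN.load(p)
        smap = random_map(rng)
        np.testing.assert_array_equal(
            model.forward(smap).entries, back.forward(smap).entries
        )


class TestCrossValidation:
    def test_fold_partition_properties(self, rng):
        ds = random_dataset(rng, 100, sites=("femur", "vertebra", "radius"))
        assign_folds(ds, 5, seed=0)
        folds = np.array([r.fold for r in ds])
        assert set(folds) == set(range(5))
        # every sample in exactly one fold; 100 samples -> folds of 20
        counts = np.bincount(folds)
        np.testing.assert_array_equal(counts, 20)
        # stratification: each fold contains every site
        for f in range(5):
            sites = {r.site for r in ds if r.fold == f}
            assert sites == {"femur", "vertebra", "radius"}

    def test_too_many_folds_rejected(self, rng):
        ds = random_dataset(rng, 3)
        with pytest.raises(ValueError):
            assign_folds(ds, 10, seed=0)
        with pytest.raises(ValueError):
            assign_folds(ds, 1, seed=0)

    def test_table_layout(self, rng):
        ds = random_dataset(rng, 12, sites=("rods", "plates"))
        tc = TrainConfig(epochs=2, lr_schedule=((0, 2, 0.01),), seed=0, folds=2, batch_size=8)
        table, per_sample = cross_validate(ds, tc, TINY, return_errors=True)
        assert list(table.index) == [0, 1, "mean"]
        assert set(table.columns) == {"all", "rods", "plates"}
        assert len(per_sample) == 12  # every sample validated exactly once
        assert np.isfinite(table.values).all()
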