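"""Training loop, estimator behaviour, and robustness tools."""

import numpy as np
import pytest

from snnloop import (
    AnalogSubstrate,
    InitSpec,
    NetworkWeights,
    SpikingNetClassifier,
    SyntheticTaskSpec,
    ablate_hidden,
    deploy_weights,
    dropout_mask,
    init_weights,
    itl_step,
    latency_encode,
    make_latency_images,
    shuffle_recurrent,
    train_software_only,
    weight_scale,
    weight_transfer,
)
from snnloop.encoders import LatencyCodeSpec
from snnloop.substrate import W_MAX


def _tiny_task(seed=0, n_classes=3, n_channels=36, samples=12):
    spec = SyntheticTaskSpec(
        task="latency_images", n_classes=n_classes, n_channels=n_channels,
        samples_per_class=samples, seed=seed,
    )
    images, y = make_latency_images(spec)
    x = latency_encode(
        images.reshape(len(y), -1), LatencyCodeSpec(), duration=60.0
    ).dense.astype(float)
    return x, y


# -- initialization ----------------------------------------------------------


def test_init_weights_statistics_and_determinism():
    spec = InitSpec(sigma_w=1.0, n_in=256, n_hidden=246, n_out=10, recurrent=True)
    w1 = init_weights(spec, seed=5)
    w2 = init_weights(spec, seed=5)
    w3 = init_weights(spec, seed=6)
    assert np.array_equal(w1.w_in, w2.w_in)
    assert not np.array_equal(w1.w_in, w3.w_in)
    assert abs(w1.w_in.std() - 1 / 16) < 0.003  # sigma_w / sqrt(256)
    assert abs(w1.w_rec.std() - 1 / np.sqrt(246)) < 0.003
    zero = init_weights(InitSpec(0.0, 10, 5, 2), seed=1)
    assert np.all(zero.w_in == 0) and np.all(zero.w_out == 0)


# -- weight scaling ----------------------------------------------------------


def test_output_layer_uses_dynamic_scale():
    w = NetworkWeights(np.zeros((4, 3)), np.array([[0.5, -0.25, 0.1, 0.0]]))
    q, scales = weight_scale(w)
    assert scales["w_out"] == pytest.approx(W_MAX / 0.5)
    assert np.abs(q["w_out"]).max() == W_MAX


def test_weight_scale_zero_output_fallback():
    w = NetworkWeights(np.ones((2, 2)), np.zeros((1, 2)))
    q, scales = weight_scale(w)
    assert scales["w_out"] == 1.0 and np.all(q["w_out"] == 0)


def test_dynamic_output_scaling_is_scale_covariant():
    rng = np.random.default_rng(0)
    w = NetworkWeights(rng.normal(0, 0.1, (4, 3)), rng.normal(0, 0.2, (2, 4)))
    doubled = NetworkWeights(w.w_in, 2.0 * w.w_out)
    assert np.array_equal(weight_scale(w)[0]["w_out"], weight_scale(doubled)[0]["w_out"])


def test_deployed_weights_lie_on_the_quantization_grid():
    rng = np.random.default_rng(1)
    w = NetworkWeights(rng.normal(0, 0.1, (6, 5)), rng.normal(0, 0.2, (2, 6)))
    dep = deploy_weights(w, scale_hidden=100.0)
    assert np.allclose(dep.w_in * 100.0, np.round(dep.w_in * 100.0))
    assert np.abs(dep.w_in * 100.0).max() <= W_MAX


# -- robustness tools --------------------------------------------------------


def test_ablate_hidden_counts_and_edge_cases():
    rng = np.random.default_rng(0)
    w = NetworkWeights(
        rng.normal(0, 1, (246, 20)), rng.normal(0, 1, (5, 246)),
        rng.normal(0, 1, (246, 246)),
    )
    same = ablate_hidden(w, 0.0, seed=1)
    assert np.array_equal(same.w_in, w.w_in)
    out = ablate_hidden(w, 0.15, seed=1)
    killed = np.nonzero(~out.w_in.any(axis=1))[0]
    assert killed.size == 36  # floor(0.15 * 246)
    assert not out.w_rec[killed].any() and not out.w_rec[:, killed].any()
    assert not out.w_out[:, killed].any()
    dead = ablate_hidden(w, 1.0, seed=1)
    assert not dead.w_in.any() and not dead.w_out.any()


def test_full_ablation_silences_the_readout():
    x, y = _tiny_task()
    clf = SpikingNetClassifier(n_hidden=8, n_epochs=1, random_state=0).fit(x, y)
    dead = ablate_hidden(clf.weights_, 1.0, seed=3)
    probe = SpikingNetClassifier(n_hidden=8, random_state=0).adopt(dead, clf.classes_)
    assert np.all(probe.output_traces(x[:4]) == 0.0)


def test_dropout_mask_rates():
    rng = np.random.default_rng(0)
    assert dropout_mask(10, 0.0, rng) is None
    assert np.all(dropout_mask(10, 1.0, rng) == 0)
    keeps = [dropout_mask(100, 0.4, rng).mean() for _ in range(200)]
    assert abs(np.mean(keeps) - 0.6) < 0.02


def test_shuffle_recurrent_preserves_the_weight_multiset():
    rng = np.random.default_rng(0)
    w = NetworkWeights(rng.normal(0, 1, (8, 4)), rng.normal(0, 1, (2, 8)),
                       rng.normal(0, 1, (8, 8)))
    out = shuffle_recurrent(w, seed=2)
    assert not np.array_equal(out.w_rec, w.w_rec)
    assert np.array_equal(np.sort(out.w_rec.ravel()), np.sort(w.w_rec.ravel()))
    again = shuffle_recurrent(w, seed=2)
    assert np.array_equal(out.w_rec, again.w_rec)
    with pytest.raises(ValueError):
        shuffle_recurrent(NetworkWeights(w.w_in, w.w_out), seed=1)


# -- the estimator -----------------------------------------------------------


def test_zero_learning_rate_leaves_weights_unchanged_but_logs_metrics():
    x, y = _tiny_task()
    clf = SpikingNetClassifier(n_hidden=8, n_epochs=2, lr=0.0, random_state=1)
    clf.initialize(x, y)
    before = clf.weights_.copy()
    clf.fit(x, y)
    assert np.array_equal(clf.weights_.w_in, before.w_in)
    assert np.array_equal(clf.weights_.w_out, before.w_out)
    assert len(clf.history_) == 2
    assert np.isfinite(clf.history_["total"]).all()


def test_frozen_recurrent_weights_receive_no_updates():
    x, y = _tiny_task()
    clf = SpikingNetClassifier(
        n_hidden=8, recurrent=True, train_recurrent=False, n_epochs=2,
        random_state=1,
    )
    clf.initialize(x, y)
    w_rec_before = clf.weights_.w_rec.copy()
    clf.fit(x, y)
    assert np.array_equal(clf.weights_.w_rec, w_rec_before)
    assert not np.array_equal(
        clf.weights_.w_in, init_weights(
            InitSpec(1.0, x.shape[2], 8, len(np.unique(y)), True), 1
        ).w_in
    )


def test_master_weights_stay_float_while_substrate_sees_quantized():
    x, y = _tiny_task()
    sub = AnalogSubstrate(x.shape[2], 8, 3, substeps=2)
    clf = SpikingNetClassifier(
        n_hidden=8, n_epochs=1, substrate=sub, quantize=True, random_state=0
    ).fit(x, y)
    dep = clf._deployed(clf.weights_)
    # deployed values sit on the integer grid, the master copy does not
    assert np.allclose(dep.w_in * clf.scale_hidden, np.round(dep.w_in * clf.scale_hidden))
    off_grid = clf.weights_.w_in * clf.scale_hidden
    assert not np.allclose(off_grid, np.round(off_grid))


def test_training_emerges_from_quiescent_hidden_layer():
    """With zero input weights the hidden layer is silent at first; the
    surrogate pathway still propagates task gradients, so spikes emerge and
    the task is learned."""
    x, y = _tiny_task(samples=20)
    n_out = len(np.unique(y))
    init = init_weights(InitSpec(1.0, x.shape[2], 16, n_out), seed=3)
    init.w_in[:] = 0.0
    # sum-over-time readout: the max-over-time subgradient of an all-zero
    # trace sits at t=0 where nothing upstream can receive it
    clf = SpikingNetClassifier(
        n_hidden=16, n_epochs=25, lr=4e-3, loss_mode="sum_over_time", random_state=3
    )
    clf.fit(x, y, initial_weights=init)
    assert clf.history_["hidden_spikes_per_sample"].iloc[0] == 0.0
    assert clf.history_["hidden_spikes_per_sample"].iloc[-1] > 0.0
    assert clf.score(x, y) > 0.5


def test_itl_step_updates_weights_and_reports_metrics():
    x, y = _tiny_task()
    sub = AnalogSubstrate(x.shape[2], 8, 3, substeps=2)
    clf = SpikingNetClassifier(n_hidden=8, substrate=sub, random_state=0)
    clf.initialize(x, y)
    before = clf.weights_.w_out.copy()
    metrics = itl_step(clf, x[:6], y[:6])
    assert {"total", "correct", "spikes"} <= metrics.keys()
    assert not np.array_equal(clf.weights_.w_out, before)


def test_ideal_substrate_itl_matches_software_trajectory():
    """On an ideal (grid-matched, noiseless, unquantized) substrate the ITL
    training trajectory coincides with pure software training."""
    x, y = _tiny_task()
    sub = AnalogSubstrate.ideal(x.shape[2], 8, 3)
    itl = SpikingNetClassifier(
        n_hidden=8, n_epochs=3, substrate=sub, quantize=False, random_state=5
    ).fit(x, y)
    sw = train_software_only(x, y, n_hidden=8, n_epochs=3, random_state=5)
    assert np.allclose(itl.weights_.w_in, sw.weights_.w_in, atol=1e-12)
    assert np.allclose(itl.weights_.w_out, sw.weights_.w_out, atol=1e-12)
    assert np.allclose(
        itl.history_["total"].to_numpy(), sw.history_["total"].to_numpy()
    )


def test_weight_transfer_is_side_effect_free_and_accurate_on_ideal_substrate():
    x, y = _tiny_task(samples=20)
    sw = train_software_only(x, y, n_hidden=16, n_epochs=20, lr=4e-3, random_state=2)
    w_before = sw.weights_.copy()
    sub = AnalogSubstrate.ideal(x.shape[2], 16, 3)
    res = weight_transfer(sw, sub, x, y)
    assert np.array_equal(sw.weights_.w_in, w_before.w_in)
    assert np.array_equal(sw.weights_.w_out, w_before.w_out)
    # quantization is the only difference on an ideal substrate
    assert abs(res["accuracy"] - sw.score(x, y)) <= 0.1


def test_estimator_respects_sklearn_param_interface():
    clf = SpikingNetClassifier(n_hidden=12, rho_b=0.5)
    params = clf.get_params()
    assert params["n_hidden"] == 12 and params["rho_b"] == 0.5
    clf.set_params(n_hidden=7)
    assert clf.n_hidden == 7


def test_checkpoint_roundtrip(tmp_path):
    from snnloop.training import load_checkpoint, save_checkpoint

    x, y = _tiny_task()
    clf = SpikingNetClassifier(n_hidden=8, n_epochs=2, random_state=4).fit(x, y)
    path = tmp_path / "ckpt.h5"
    save_checkpoint(clf, path, config_hash="abc123")
    fresh = SpikingNetClassifier(n_hidden=8, random_state=4)
    load_checkpoint(fresh, path)
    assert np.array_equal(fresh.weights_.w_in, clf.weights_.w_in)
    assert np.array_equal(fresh.classes_, clf.classes_)
    assert fresh._adam.t == clf._adam.t
    assert np.array_equal(fresh._adam.m["w_out"], clf._adam.m["w_out"])
    assert np.array_equal(fresh.predict(x[:5]), clf.predict(x[:5]))
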