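"""Substrate emulation: parameters, mismatch, quantization, dynamics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from snnloop import (
    AnalogSubstrate,
    MismatchSpec,
    NetworkWeights,
    NeuronParams,
    NoiseSpec,
    SubstrateRecording,
    decalibrate,
    quantize_weights,
)
from snnloop.substrate import W_MAX


# -- parameters and mismatch -------------------------------------------------


def test_neuron_params_reject_nonpositive_time_constants():
    with pytest.raises(ValueError):
        NeuronParams(np.array([1.0, -1.0]), np.ones(2), np.ones(2), np.zeros(2), np.zeros(2))


def test_leak_over_threshold_flags():
    p = NeuronParams(
        np.ones(3), np.ones(3), np.array([1.0, 0.0, -0.2]), np.zeros(3), np.zeros(3)
    )
    assert p.leak_over_threshold().tolist() == [False, True, True]


def test_decalibrate_zero_sigma_is_identity():
    p = NeuronParams.homogeneous(32)
    out = decalibrate(p, MismatchSpec(sigma_d=0.0, seed=3))
    assert np.array_equal(out.tau_mem, p.tau_mem)
    assert np.array_equal(out.threshold, p.threshold)


def test_decalibrate_sample_statistics_and_determinism():
    p = NeuronParams.homogeneous(256, tau_mem=20.0)
    spec = MismatchSpec(sigma_d=0.3, which=("tau_mem",), seed=7)
    a = decalibrate(p, spec)
    b = decalibrate(p, spec)
    assert np.array_equal(a.tau_mem, b.tau_mem)  # frozen given seed
    rel_sd = a.tau_mem.std() / a.tau_mem.mean()
    # rejection of negative draws biases the SD slightly; sampling error for
    # n=256 is ~5% of the SD itself
    assert abs(rel_sd - 0.3) < 0.05
    assert np.all(a.tau_mem > 0)
    c = decalibrate(p, MismatchSpec(sigma_d=0.3, which=("tau_mem",), seed=8))
    assert not np.array_equal(a.tau_mem, c.tau_mem)
    # untouched parameters stay at their targets
    assert np.array_equal(a.tau_syn, p.tau_syn)


def test_strong_threshold_decalibration_produces_flagged_neurons():
    """At sigma_d = 0.5 a few percent of thresholds fall below the leak;
    those neurons are flagged dysfunctional, not rejected."""
    p = NeuronParams.homogeneous(2000)
    out = decalibrate(p, MismatchSpec(sigma_d=0.5, which=("threshold",), seed=11))
    frac = out.leak_over_threshold().mean()
    # P(Normal(1, 0.5) <= 0) ~ 2.3%
    assert 0.005 < frac < 0.06


# -- quantization ------------------------------------------------------------


@pytest.mark.parametrize(
    "w, scale, expected",
    [(0.0, 63.0, 0), (1.0, 63.0, 63), (2.0, 63.0, 63), (-2.0, 63.0, -63), (0.5, 126.0, 63)],
)
def test_quantize_examples(w, scale, expected):
    assert quantize_weights(np.array([w]), scale)[0] == expected


def test_quantize_idempotent_on_integers():
    q = quantize_weights(np.array([-1.7, 0.2, 0.9]), 63.0)
    assert np.array_equal(quantize_weights(q, 1.0), q)


@settings(derandomize=True, max_examples=50)
@given(st.lists(st.floats(-1e6, 1e6), min_size=1, max_size=20), st.floats(0.01, 1e3))
def test_quantize_bounds(values, scale):
    q = quantize_weights(np.array(values), scale)
    assert q.min() >= -W_MAX and q.max() <= W_MAX
    assert np.issubdtype(q.dtype, np.integer)


# -- dynamics ----------------------------------------------------------------


def test_membrane_decay_is_exponential_per_neuron():
    """With the input current gone, V decays as exp(-k dt / tau_m) with each
    neuron's own time constant."""
    params = NeuronParams(
        tau_mem=np.array([10.0, 30.0]),
        tau_syn=np.array([0.4, 0.4]),  # current is gone within a few steps
        threshold=np.array([np.inf, np.inf]),
        v_leak=np.zeros(2),
        v_reset=np.zeros(2),
    )
    sub = AnalogSubstrate(1, 2, 1, substeps=10, hidden_params=params)
    T = 80
    x = np.zeros((1, T, 1))
    x[0, 0, 0] = 1.0
    w = NetworkWeights(np.array([[0.5], [0.5]]), np.zeros((1, 2)))
    rec_h, _ = sub.forward(x, w)
    v = rec_h.v_sampled[0]
    for j, tau in enumerate([10.0, 30.0]):
        ratio = v[40:70, j] / v[30:60, j]
        assert np.allclose(ratio, np.exp(-10.0 / tau), rtol=1e-6)


def test_reset_enables_identical_back_to_back_presentations(rng):
    C, H, O, T = 6, 5, 2, 30
    w = NetworkWeights(rng.normal(0, 0.4, (H, C)), rng.normal(0, 0.5, (O, H)))
    x = (rng.random((1, T, C)) < 0.15).astype(float)
    sub = AnalogSubstrate(C, H, O, substeps=10)
    rec1, out1 = sub.forward(x, w)
    sub.reset_state()
    rec2, out2 = sub.reset_state().forward(x, w)  # reset is idempotent
    assert np.array_equal(rec1.v_sampled, rec2.v_sampled)
    assert np.array_equal(rec1.spikes, rec2.spikes)
    assert np.array_equal(out1.v_sampled, out2.v_sampled)
    # after reset and with zero input the membranes sit at the leak
    zero = np.zeros_like(x)
    rec3, _ = sub.reset_state().forward(zero, w)
    assert np.all(rec3.v_sampled == 0.0)
    assert rec3.spikes.sum() == 0


def test_state_persists_without_reset(rng):
    C, H, O, T = 4, 3, 2, 20
    w = NetworkWeights(rng.normal(0, 0.4, (H, C)), rng.normal(0, 0.5, (O, H)))
    x = (rng.random((1, T, C)) < 0.2).astype(float)
    sub = AnalogSubstrate(C, H, O, substeps=5)
    sub.forward(x, w)
    cont, _ = sub.forward(np.zeros_like(x), w, reset=False)
    # the continuation starts from the decayed end state, not the leak
    assert np.abs(cont.v_sampled[0, 0]).max() > 0.0


def test_fixed_pattern_mismatch_frozen_while_trial_noise_varies(rng):
    C, H, O, T = 5, 8, 2, 20
    w = NetworkWeights(rng.normal(0, 0.3, (H, C)), rng.normal(0, 0.5, (O, H)))
    x = (rng.random((2, T, C)) < 0.1).astype(float)
    sub = AnalogSubstrate(
        C, H, O, substeps=5,
        mismatch=MismatchSpec(0.3, seed=1), noise=NoiseSpec(0.01, 0.01, seed=2),
    )
    params_before = sub.hidden_params.tau_mem.copy()
    r1, _ = sub.forward(x, w)
    r2, _ = sub.forward(x, w)  # same stimulus, new trial noise
    assert np.array_equal(sub.hidden_params.tau_mem, params_before)
    assert not np.array_equal(r1.v_sampled, r2.v_sampled)
    # reseeding the trial stream reproduces the first trial exactly
    sub.reseed_trials(sub.seed)
    r3, _ = sub.forward(x, w)
    sub.reseed_trials(sub.seed)
    r4, _ = sub.forward(x, w)
    assert np.array_equal(r3.v_sampled, r4.v_sampled)


def test_raw_spike_times_align_with_grid_bins(rng):
    C, H, O, T = 6, 5, 2, 25
    w = NetworkWeights(rng.normal(0, 0.6, (H, C)), rng.normal(0, 0.5, (O, H)))
    x = (rng.random((2, T, C)) < 0.25).astype(float)
    sub = AnalogSubstrate(C, H, O, substeps=10)
    rec, _ = sub.forward(x, w)
    assert rec.spikes.sum() > 0
    for b, (times, units) in enumerate(rec.spike_times):
        rebuilt = np.zeros((T, H), dtype=np.uint8)
        bins = (times / rec.grid_dt).astype(int)
        assert bins.min() >= 0 and bins.max() < T
        rebuilt[bins, units] = 1
        assert np.array_equal(rebuilt, rec.spikes[b])


def test_fan_in_limit_enforced():
    sub = AnalogSubstrate(10, 4, 2, fan_in_limit=8, substeps=1, integration="grid")
    w = NetworkWeights(np.ones((4, 10)), np.zeros((2, 4)))
    with pytest.raises(ValueError, match="fan-in"):
        sub.forward(np.zeros((1, 5, 10)), w)


def test_nonfinite_state_raises(rng):
    sub = AnalogSubstrate(2, 2, 1, substeps=5)
    w = NetworkWeights(np.full((2, 2), 1e308), np.full((1, 2), 1e308))
    x = np.ones((1, 40, 2))
    with pytest.raises(FloatingPointError):
        sub.forward(x, w)


def test_recording_hdf5_roundtrip(tmp_path, rng):
    C, H, O, T = 4, 3, 2, 15
    w = NetworkWeights(rng.normal(0, 0.5, (H, C)), rng.normal(0, 0.5, (O, H)))
    x = (rng.random((2, T, C)) < 0.2).astype(float)
    rec, _ = AnalogSubstrate(C, H, O, substeps=5).forward(x, w)
    path = tmp_path / "rec.h5"
    rec.to_hdf5(path)
    back = SubstrateRecording.from_hdf5(path)
    assert np.array_equal(back.v_sampled, rec.v_sampled)
    assert np.array_equal(back.spikes, rec.spikes)
    assert back.grid_dt == rec.grid_dt
    for (t1, u1), (t2, u2) in zip(back.spike_times, rec.spike_times):
        assert np.array_equal(t1, t2) and np.array_equal(u1, u2)
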