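"""Training graph: trace injection, surrogate derivative, BPTT."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from snnloop import (
    AnalogSubstrate,
    NetworkWeights,
    NeuronParams,
    SubstrateRecording,
    SurrogateSpec,
    UnrolledGraph,
    inject_value,
    interpolate_recording,
    surrogate_spike_derivative,
)


def _params(H, O):
    return (
        NeuronParams.homogeneous(H),
        NeuronParams.homogeneous(O, threshold=np.inf),
    )


# -- injection ---------------------------------------------------------------


def test_inject_value_forwards_the_measurement():
    assert inject_value(np.array([0.7]), np.array([0.4]))[0] == 0.7
    with pytest.raises(ValueError):
        inject_value(np.zeros(3), np.zeros(4))


def test_injected_forward_reproduces_measurements_not_the_model(rng):
    """Even a recording that disagrees with the model appears verbatim in the
    forward pass (the model estimate only carries gradients)."""
    C, H, O, T = 3, 2, 2, 10
    w = NetworkWeights(np.zeros((H, C)), np.ones((O, H)))
    hp, op = _params(H, O)
    v_h = rng.normal(0, 0.1, (1, T, H))
    v_o = rng.normal(0, 0.1, (1, T, O))
    empty = [(np.empty(0), np.empty(0, dtype=np.int64))]
    rec_h = SubstrateRecording(v_h, np.zeros((1, T, H), np.uint8), empty, 1.0)
    rec_o = SubstrateRecording(v_o, np.zeros((1, T, O), np.uint8), empty, 1.0)
    g = UnrolledGraph(w, hp, op)
    traces, spikes = g.forward(np.zeros((1, T, C)), (rec_h, rec_o))
    assert np.array_equal(traces, v_o)
    assert spikes.sum() == 0


# -- surrogate derivative ----------------------------------------------------


@pytest.mark.parametrize(
    "v, beta, form, expected",
    [
        (1.0, 5.0, "superspike", 1.0),  # at threshold
        (0.3, 0.0, "superspike", 1.0),  # beta = 0 flattens the derivative
        (2.0, 1.0, "superspike", 0.25),  # |v - theta| = 1 -> (1+1)^-2
        (2.0, 2.0, "literal", 0.25),  # (2*1)^-2
    ],
)
def test_surrogate_derivative_values(v, beta, form, expected):
    got = surrogate_spike_derivative(np.array([v]), 1.0, SurrogateSpec(beta, form))
    assert got[0] == pytest.approx(expected)


@settings(derandomize=True, max_examples=60)
@given(st.floats(-3, 3), st.floats(0, 50))
def test_surrogate_derivative_shape_properties(v, beta):
    spec = SurrogateSpec(beta)
    d = surrogate_spike_derivative(np.array([v, 2.0 - v]), 1.0, spec)
    assert 0 < d[0] <= 1.0
    assert d[0] == pytest.approx(d[1])  # symmetric about the threshold
    closer = surrogate_spike_derivative(np.array([1.0 + 0.5 * (v - 1.0)]), 1.0, spec)
    assert closer[0] >= d[0] - 1e-12  # monotone in |v - theta|


def test_forward_values_independent_of_beta(small_net):
    w, x, _ = small_net
    hp, op = _params(w.n_hidden, w.n_out)
    t1, s1 = UnrolledGraph(w, hp, op, surrogate=SurrogateSpec(1.0)).forward(x)
    t2, s2 = UnrolledGraph(w, hp, op, surrogate=SurrogateSpec(100.0)).forward(x)
    assert np.array_equal(t1, t2)
    assert np.array_equal(s1, s2)


# -- unrolling ---------------------------------------------------------------


def test_zero_inputs_give_zero_states_and_zero_gradients():
    C, H, O, T = 4, 3, 2, 12
    w = NetworkWeights(np.ones((H, C)) * 0.3, np.ones((O, H)) * 0.2)
    hp, op = _params(H, O)
    g = UnrolledGraph(w, hp, op)
    traces, spikes = g.forward(np.zeros((2, T, C)))
    assert np.all(traces == 0) and np.all(spikes == 0)
    grads = g.backward(np.ones((2, T, O)), np.ones((2, T, H)))
    assert np.all(grads["w_in"] == 0) and np.all(grads["w_out"] == 0)


def test_single_hidden_spike_drives_double_exponential_readout():
    """One injected hidden spike at bin t0: the output trace is the discrete
    double-exponential filter of that spike scaled by the readout weight, and
    d(sum of trace)/dw equals the filter sum (hand-unrolled oracle)."""
    H, O, T, t0, w_val = 1, 1, 30, 4, 0.37
    dt = 1.0
    lam_m, lam_s = np.exp(-dt / 20.0), np.exp(-dt / 10.0)
    # independent oracle: unroll the two-state recursion by hand
    i = v = 0.0
    filt = np.zeros(T)
    for t in range(T - 1):
        v = v * lam_m + i
        i = i * lam_s + (1.0 if t == t0 else 0.0)
        filt[t + 1] = v
    w = NetworkWeights(np.zeros((H, 1)), np.array([[w_val]]))
    hp, op = _params(H, O)
    spikes = np.zeros((1, T, H), np.uint8)
    spikes[0, t0, 0] = 1
    empty = [(np.empty(0), np.empty(0, dtype=np.int64))]
    rec_h = SubstrateRecording(np.zeros((1, T, H)), spikes, empty, dt)
    # output recording must match what the model would produce so that the
    # forward trace is consistent with the filter
    rec_o = SubstrateRecording((w_val * filt)[None, :, None], np.zeros((1, T, O), np.uint8), empty, dt)
    g = UnrolledGraph(w, hp, op)
    traces, _ = g.forward(np.zeros((1, T, 1)), (rec_h, rec_o))
    assert np.allclose(traces[0, :, 0], w_val * filt, atol=1e-12)
    grads = g.backward(np.ones((1, T, O)))
    assert grads["w_out"][0, 0] == pytest.approx(filt.sum(), rel=1e-12)


def test_grid_misalignment_rejected(small_net):
    w, x, _ = small_net
    hp, op = _params(w.n_hidden, w.n_out)
    sub = AnalogSubstrate.ideal(w.n_in, w.n_hidden, w.n_out)
    rec = sub.forward(x, w)
    g = UnrolledGraph(w, hp, op)
    with pytest.raises(ValueError, match="misaligned"):
        g.forward(x[:, :-5], rec)


def test_detach_reset_changes_only_the_backward_pass(recurrent_net):
    w, x = recurrent_net
    hp, op = _params(w.n_hidden, w.n_out)
    rng = np.random.default_rng(0)
    gv = rng.normal(0, 1, (x.shape[0], x.shape[1], w.n_out))
    g1 = UnrolledGraph(w, hp, op, detach_reset=True)
    g2 = UnrolledGraph(w, hp, op, detach_reset=False)
    t1, _ = g1.forward(x)
    t2, _ = g2.forward(x)
    assert np.array_equal(t1, t2)
    d1, d2 = g1.backward(gv), g2.backward(gv)
    assert not np.allclose(d1["w_in"], d2["w_in"])


# -- interpolation -----------------------------------------------------------


def test_interpolate_factor_one_is_identity(rng):
    v = rng.normal(0, 1, (1, 10, 2))
    rec = SubstrateRecording(v, np.zeros((1, 10, 2), np.uint8),
                             [(np.empty(0), np.empty(0, np.int64))], 1.0)
    assert interpolate_recording(rec, 1) is rec


def test_interpolate_linear_ramp_midpoints():
    v = np.arange(8, dtype=float)[None, :, None]
    rec = SubstrateRecording(v, np.zeros((1, 8, 1), np.uint8),
                             [(np.empty(0), np.empty(0, np.int64))], 1.0)
    fine = interpolate_recording(rec, 2)
    assert fine.grid_dt == 0.5
    assert np.allclose(fine.v_sampled[0, 1:14:2, 0], np.arange(7) + 0.5)


def test_interpolation_separates_events_within_one_coarse_bin():
    times = np.array([3.1, 3.6])
    units = np.array([0, 0])
    spikes = np.zeros((1, 8, 1), np.uint8)
    spikes[0, 3, 0] = 1  # both events share coarse bin 3
    rec = SubstrateRecording(np.zeros((1, 8, 1)), spikes, [(times, units)], 1.0)
    fine = interpolate_recording(rec, 2)
    assert fine.spikes.sum() == 2
    assert fine.spikes[0, 6, 0] == 1 and fine.spikes[0, 7, 0] == 1
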