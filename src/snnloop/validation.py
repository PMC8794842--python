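"""Self-contained validation routines for the core numerical claims.

These are the fast oracle checks behind the package's correctness story:

* in-the-loop gradients against pure software simulation on an ideal
  substrate (the equivalence that makes trace injection sound),
* backpropagation-through-time against central finite differences on the
  spike-free readout pathway,
* emulated dynamics against closed-form LIF solutions (postsynaptic
  potential peak, constant-drive inter-spike interval).

Each routine builds its own small problem from a seed and returns a dict of
measured discrepancies, so tests and reporting scripts share one
implementation.
"""

from __future__ import annotations

import numpy as np

from .graph import UnrolledGraph
from .objectives import sum_over_time_nll, total_loss, LossConfig
from .substrate import AnalogSubstrate, NetworkWeights, NeuronParams

__all__ = [
    "check_itl_matches_simulation",
    "check_bptt_against_finite_differences",
    "check_closed_form_dynamics",
]


def check_itl_matches_simulation(
    seed: int = 0, n_in: int = 10, n_hidden: int = 8, n_out: int = 3, T: int = 50
) -> dict:
    """Element-wise agreement of ITL and pure-simulation surrogate gradients.

    An ideal substrate (grid-matched integration, no mismatch, no noise,
    unquantized weights) is emulated, its recordings are injected into the
    graph, and the resulting BPTT gradients are compared with those of the
    graph simulating the same model itself.  Returns the maximum elementwise
    relative error over all weight gradients (relative to the largest
    gradient magnitude of each matrix) and the number of hidden spikes that
    the comparison exercised.
    """
    rng = np.random.default_rng(seed)
    w = NetworkWeights(
        rng.normal(0, 0.3, (n_hidden, n_in)),
        rng.normal(0, 0.5, (n_out, n_hidden)),
        rng.normal(0, 0.2, (n_hidden, n_hidden)),
    )
    x = (rng.random((4, T, n_in)) < 0.05).astype(float)
    y = rng.integers(0, n_out, 4)
    sub = AnalogSubstrate.ideal(n_in, n_hidden, n_out)
    rec = sub.forward(x, w)
    cfg = LossConfig("max_over_time", rho_b=0.1)

    def grads(recording):
        g = UnrolledGraph(w, sub.target_hidden, sub.target_output)
        traces, spikes = g.forward(x, recording)
        _, gv, gs = total_loss(traces, spikes, y, cfg)
        return g.backward(gv, gs), spikes.sum()

    g_itl, n_spikes = grads(rec)
    g_sim, _ = grads(None)
    rel = 0.0
    for k in ("w_in", "w_rec", "w_out"):
        scale = max(np.abs(g_sim[k]).max(), 1e-12)
        rel = max(rel, float(np.abs(g_itl[k] - g_sim[k]).max() / scale))
    return {"max_rel_err": rel, "n_hidden_spikes": int(n_spikes), "n_weights": int(
        w.w_in.size + w.w_rec.size + w.w_out.size
    )}


def check_bptt_against_finite_differences(seed: int = 1) -> dict:
    """Central-finite-difference check of BPTT on the readout pathway.

    The loss reaches the readout weights through non-spiking leaky
    integrators only, so the true gradient exists and finite differences are
    an independent oracle.  Returns the maximum relative error over the
    readout weight matrix.
    """
    rng = np.random.default_rng(seed)
    C, H, O, T, B = 6, 5, 3, 40, 3
    w = NetworkWeights(rng.normal(0, 0.25, (H, C)), rng.normal(0, 0.5, (O, H)))
    x = (rng.random((B, T, C)) < 0.08).astype(float)
    y = rng.integers(0, O, B)
    hp = NeuronParams.homogeneous(H)
    op = NeuronParams.homogeneous(O, threshold=np.inf)

    def loss_of(w_out):
        g = UnrolledGraph(NetworkWeights(w.w_in, w_out), hp, op)
        traces, _ = g.forward(x)
        return sum_over_time_nll(traces, y)[0]

    g = UnrolledGraph(w, hp, op)
    traces, _ = g.forward(x)
    _, gv = sum_over_time_nll(traces, y)
    analytic = g.backward(gv)["w_out"]
    fd = np.zeros_like(w.w_out)
    eps = 1e-6
    for i in range(O):
        for j in range(H):
            wp, wm = w.w_out.copy(), w.w_out.copy()
            wp[i, j] += eps
            wm[i, j] -= eps
            fd[i, j] = (loss_of(wp) - loss_of(wm)) / (2 * eps)
    rel = float(np.abs(analytic - fd).max() / np.abs(fd).max())
    return {"max_rel_err": rel, "n_weights": int(w.w_out.size)}


def check_closed_form_dynamics(substeps: int = 100) -> dict:
    """Emulated LIF dynamics against continuous closed-form solutions.

    (1) A single input spike through weight ``w`` produces the
    double-exponential postsynaptic potential; the fine-grid peak is compared
    with the analytic amplitude and timing.  (2) Under a constant
    suprathreshold current the steady-state inter-spike interval is compared
    with ``tau_m ln(J tau_m / (J tau_m - theta))``; the emulation's reset
    convention holds the membrane for one fine step after the crossing, which
    is subtracted before the comparison.  All errors are reported relative to
    the fine step ``delta``.
    """
    tau_m, tau_s, dt, w_val = 20.0, 10.0, 1.0, 0.1
    delta = dt / substeps
    sub = AnalogSubstrate(1, 1, 1, dt=dt, substeps=substeps)
    T = 200
    x = np.zeros((1, T, 1))
    t0 = 5
    x[0, t0, 0] = 1.0
    w = NetworkWeights(np.array([[w_val]]), np.array([[0.0]]))
    _, _, fine = sub.forward(x, w, record_fine=True)
    trace = fine[0, :, 0]
    peak = float(trace.max())
    t_peak = float(np.argmax(trace) * delta - (t0 + 1) * dt)  # onset at bin end
    r = tau_s / tau_m
    amp = (w_val / dt) * tau_m * tau_s / (tau_m - tau_s)
    peak_analytic = amp * (r ** (tau_s / (tau_m - tau_s)) - r ** (tau_m / (tau_m - tau_s)))
    t_peak_analytic = tau_m * tau_s / (tau_m - tau_s) * np.log(tau_m / tau_s)

    bias = 0.08  # model-unit current; continuous drive J = bias / dt
    J = bias / dt
    sub2 = AnalogSubstrate(1, 1, 1, dt=dt, substeps=substeps)
    x0 = np.zeros((1, 300, 1))
    rec, _ = sub2.forward(x0, NetworkWeights(np.zeros((1, 1)), np.zeros((1, 1))),
                          i_bias=np.array([bias]))
    times = rec.spike_times[0][0]
    isi = float(np.diff(times)[-1])
    isi_analytic = float(tau_m * np.log(J * tau_m / (J * tau_m - 1.0)))
    return {
        "delta": delta,
        "psp_peak": peak,
        "psp_peak_analytic": float(peak_analytic),
        "psp_peak_rel_err": abs(peak - peak_analytic) / peak_analytic,
        "psp_time_err_fine_steps": abs(t_peak - t_peak_analytic) / delta,
        "isi": isi,
        "isi_analytic": isi_analytic,
        "isi_err_fine_steps": abs(isi - delta - isi_analytic) / delta,
        "n_isi": int(len(times) - 1),
    }
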