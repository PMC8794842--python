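"""Differentiable computation graph for in-the-loop training.

The training graph mirrors the substrate's LIF dynamics as a discrete-time
recursion on the sampling grid (step ``dt``)::

    I[t+1] = I[t] * exp(-dt/tau_syn) + W_in x[t] + W_rec S[t]
    V[t+1] = (1 - S[t]) * (V[t] * exp(-dt/tau_mem) + I[t])
    S[t+1] = Theta(V[t+1] - threshold)

with the reset realised as a multiplicative gate on the previous step's spike
(detached from gradient flow by default).  The output layer follows the same
recursion without a spiking nonlinearity.

Two pieces make this graph trainable against an analog device:

* **Trace injection.**  Measured membrane samples and spikes replace the
  model estimates in the *forward* direction through an identity
  ``f(measured, modeled) = measured`` whose backward routes the full upstream
  gradient to the modeled argument (``d f/d measured = 0``,
  ``d f/d modeled = 1``).  The forward pass therefore reproduces what the
  substrate actually did, while BPTT differentiates the idealized model.
* **Surrogate spike derivative.**  The Heaviside spike nonlinearity is given
  the pseudo-derivative of :func:`surrogate_spike_derivative` in the backward
  pass, evaluated at the forward (i.e. measured, when injected) membrane
  values.

Because the graph is a fixed two-layer recurrent structure, reverse-mode
backpropagation through time is implemented directly as the adjoint
recursions of the forward equations rather than through a general autodiff
engine; :meth:`UnrolledGraph.backward` is the hand-derived transpose of
:meth:`UnrolledGraph.forward`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numba
import numpy as np

from .substrate import NetworkWeights, NeuronParams, SubstrateRecording

__all__ = [
    "SurrogateSpec",
    "surrogate_spike_derivative",
    "inject_value",
    "UnrolledGraph",
    "interpolate_recording",
]


@dataclass(frozen=True)
class SurrogateSpec:
    """Shape of the surrogate derivative used for the spike nonlinearity.

    ``form="superspike"`` (default): ``(1 + beta*|v - threshold|)**-2`` —
    bounded in (0, 1], maximal at threshold.  ``form="literal"``:
    ``(beta*|v - threshold|)**-2`` with an ``eps`` floor on the absolute
    deviation; unbounded near threshold, provided for completeness and meant
    to be combined with gradient clipping.
    """

    beta: float = 10.0
    form: str = "superspike"
    eps: float = 1e-6

    def __post_init__(self) -> None:
        if self.beta < 0:
            raise ValueError("beta must be >= 0")
        if self.form not in ("superspike", "literal"):
            raise ValueError("form must be 'superspike' or 'literal'")


def surrogate_spike_derivative(
    v_model: np.ndarray, threshold: np.ndarray, spec: SurrogateSpec
) -> np.ndarray:
    """Pseudo-derivative of the spike output with respect to the membrane."""
    dist = np.abs(np.asarray(v_model) - threshold)
    if spec.form == "superspike":
        return (1.0 + spec.beta * dist) ** -2
    return (np.maximum(spec.beta * dist, spec.eps)) ** -2


def inject_value(measured: np.ndarray, modeled: np.ndarray) -> np.ndarray:
    """Identity with rerouted gradient: forward value is ``measured``.

    The gradient convention (zero to the measured argument, one to the
    modeled argument) is realised structurally inside
    :meth:`UnrolledGraph.backward`; this function documents and applies the
    forward half and validates shapes.
    """
    measured = np.asarray(measured)
    modeled = np.asarray(modeled)
    if measured.shape != modeled.shape:
        raise ValueError(f"shape mismatch: {measured.shape} vs {modeled.shape}")
    return measured


@numba.njit(cache=False)
def _forward_kernel(
    x_in, w_rec, has_rec, w_out, lam_m_h, lam_s_h, lam_m_o, lam_s_o, thr,
    injected, rec_v_h, rec_s, rec_v_o, mask,
    vf_h, i_h, s, vf_o, i_o,
):  # pragma: no cover - exercised through UnrolledGraph.forward
    B, T, H = x_in.shape
    O = w_out.shape[0]
    for t in range(T - 1):
        for b in range(B):
            for h in range(H):
                v_est = (1.0 - s[b, t, h]) * (vf_h[b, t, h] * lam_m_h[h] + i_h[b, t, h])
                if injected:
                    vf = rec_v_h[b, t + 1, h]
                    s_raw = rec_s[b, t + 1, h]
                else:
                    vf = v_est
                    s_raw = 1.0 if v_est >= thr[h] else 0.0
                vf_h[b, t + 1, h] = vf
                s[b, t + 1, h] = s_raw * mask[h]
            for h in range(H):
                acc = x_in[b, t, h]
                if has_rec:
                    for g in range(H):
                        acc += w_rec[h, g] * s[b, t, g]
                i_h[b, t + 1, h] = i_h[b, t, h] * lam_s_h[h] + acc
            for o in range(O):
                vo_est = vf_o[b, t, o] * lam_m_o[o] + i_o[b, t, o]
                vf_o[b, t + 1, o] = rec_v_o[b, t + 1, o] if injected else vo_est
                acc = 0.0
                for h in range(H):
                    acc += w_out[o, h] * s[b, t, h]
                i_o[b, t + 1, o] = i_o[b, t, o] * lam_s_o[o] + acc


@numba.njit(cache=False)
def _backward_kernel(
    vf_h, i_h, s, sg, gv_dir, gs_dir, has_gs_dir,
    w_rec, has_rec, w_out, lam_m_h, lam_s_h, lam_m_o, lam_s_o,
    detach_reset, gi_h_all, gi_o_all,
):  # pragma: no cover - exercised through UnrolledGraph.backward
    B, T, H = vf_h.shape
    O = w_out.shape[0]
    gtv_o = np.empty((B, O))
    gtv_h = np.empty((B, H))
    gs_t = np.empty((B, H))
    for b in range(B):
        for o in range(O):
            gtv_o[b, o] = gv_dir[b, T - 1, o]
            gi_o_all[b, T - 1, o] = 0.0
        for h in range(H):
            g = gs_dir[b, T - 1, h] if has_gs_dir else 0.0
            gtv_h[b, h] = g * sg[b, T - 1, h]
            gi_h_all[b, T - 1, h] = 0.0
    for t in range(T - 2, -1, -1):
        for b in range(B):
            # spike node at t collects all downstream contributions
            for h in range(H):
                acc = 0.0
                for o in range(O):
                    acc += gi_o_all[b, t + 1, o] * w_out[o, h]
                if has_rec:
                    for g in range(H):
                        acc += gi_h_all[b, t + 1, g] * w_rec[g, h]
                if has_gs_dir:
                    acc += gs_dir[b, t, h]
                if not detach_reset:
                    acc -= (vf_h[b, t, h] * lam_m_h[h] + i_h[b, t, h]) * gtv_h[b, h]
                gs_t[b, h] = acc
            for h in range(H):
                gate = 1.0 - s[b, t, h]
                gi = gate * gtv_h[b, h] + lam_s_h[h] * gi_h_all[b, t + 1, h]
                gtv_h[b, h] = gs_t[b, h] * sg[b, t, h] + gate * lam_m_h[h] * gtv_h[b, h]
                gi_h_all[b, t, h] = gi
            for o in range(O):
                gi_o_all[b, t, o] = gtv_o[b, o] + lam_s_o[o] * gi_o_all[b, t + 1, o]
                gtv_o[b, o] = gv_dir[b, t, o] + lam_m_o[o] * gtv_o[b, o]


def _decays(params: NeuronParams, dt: float) -> Tuple[np.ndarray, np.ndarray]:
    lam_m = np.exp(-dt / params.tau_mem)
    lam_s = np.exp(-dt / params.tau_syn)
    if np.any(lam_m <= 0) or np.any(lam_m >= 1) or np.any(lam_s <= 0) or np.any(lam_s >= 1):
        raise ValueError("decay factors must lie strictly in (0, 1)")
    return lam_m, lam_s


class UnrolledGraph:
    """Unrolled BPTT graph for one batch.

    Parameters
    ----------
    weights:
        The weights the forward model assumes (for ITL these are the
        *deployed* values, i.e. the de-scaled quantized view).
    hidden_params, output_params:
        Idealized (calibration-target) parameters.  The graph always assumes
        ideal dynamics, even when the substrate is decalibrated — mismatch
        compensation comes from training against injected measurements, not
        from modelling the mismatch.
    surrogate:
        :class:`SurrogateSpec` controlling the backward pass only; forward
        values never depend on it.
    detach_reset:
        If True (default) the reset gate is treated as a constant in the
        backward pass; if False, the gate contributes
        ``-(V[t]*lam_m + I[t])`` to the spike gradient.
    dropout_mask:
        Optional ``[n_hidden]`` 0/1 mask multiplying hidden spikes wherever
        they are consumed (recurrent input, output drive, regularizers).
    """

    def __init__(
        self,
        weights: NetworkWeights,
        hidden_params: NeuronParams,
        output_params: NeuronParams,
        dt: float = 1.0,
        surrogate: SurrogateSpec = SurrogateSpec(),
        detach_reset: bool = True,
        dropout_mask: Optional[np.ndarray] = None,
    ) -> None:
        self.weights = weights
        self.hidden_params = hidden_params
        self.output_params = output_params
        self.dt = float(dt)
        self.surrogate = surrogate
        self.detach_reset = detach_reset
        self.dropout_mask = None if dropout_mask is None else np.asarray(dropout_mask, float)
        self.lam_m_h, self.lam_s_h = _decays(hidden_params, self.dt)
        self.lam_m_o, self.lam_s_o = _decays(output_params, self.dt)
        self._cache = None

    # -- forward ---------------------------------------------------------------

    def forward(
        self,
        x: np.ndarray,
        recording: Optional[Tuple[SubstrateRecording, SubstrateRecording]] = None,
    ) -> Tuple[np.ndarray, np.ndarray]:
        """Unroll the graph over a batch.

        With ``recording=None`` the graph simulates the idealized model
        itself (software mode).  With a ``(hidden, output)`` recording pair,
        measured membranes and spikes are injected: forward values are the
        measurements, model estimates only carry gradients.

        Returns ``(output_traces [B,T,n_out], hidden_spikes [B,T,n_hidden])``.
        """
        x = np.asarray(x, dtype=float)
        B, T, C = x.shape
        w = self.weights
        if C != w.n_in:
            raise ValueError(f"input has {C} channels, weights expect {w.n_in}")
        H, O = w.n_hidden, w.n_out
        injected = recording is not None
        if injected:
            rec_h, rec_o = recording
            if rec_h.n_steps != T or rec_o.n_steps != T:
                raise ValueError("recording grid misaligned with input bins")
            if abs(rec_h.grid_dt - self.dt) > 1e-12:
                raise ValueError("recording grid_dt differs from graph dt")
            if rec_h.n_units != H or rec_o.n_units != O:
                raise ValueError("recording is missing channels")

        thr = self.hidden_params.threshold
        mask = self.dropout_mask

        vf_h = np.zeros((B, T, H))  # forward membrane values (measured if injected)
        i_h = np.zeros((B, T, H))  # model synaptic currents (never measured)
        s = np.zeros((B, T, H))  # spikes as consumed downstream (masked)
        vf_o = np.zeros((B, T, O))
        i_o = np.zeros((B, T, O))

        v_init_h = np.tile(self.hidden_params.v_leak, (B, 1))
        v_init_o = np.tile(self.output_params.v_leak, (B, 1))
        if injected:
            vf_h[:, 0] = rec_h.v_sampled[:, 0]
            vf_o[:, 0] = rec_o.v_sampled[:, 0]
            s[:, 0] = rec_h.spikes[:, 0]
        else:
            vf_h[:, 0] = v_init_h
            vf_o[:, 0] = v_init_o
            s[:, 0] = (vf_h[:, 0] >= thr).astype(float)
        if mask is not None:
            s[:, 0] *= mask

        x_in = (x.reshape(-1, C) @ w.w_in.T).reshape(B, T, H)
        has_rec = w.w_rec is not None
        w_rec = w.w_rec if has_rec else np.zeros((0, 0))
        mask_vec = np.ones(H) if mask is None else mask
        if injected:
            rec_v_h = np.ascontiguousarray(rec_h.v_sampled, dtype=float)
            rec_s = np.ascontiguousarray(rec_h.spikes, dtype=float)
            rec_v_o = np.ascontiguousarray(rec_o.v_sampled, dtype=float)
        else:
            rec_v_h = rec_s = np.zeros((1, 1, 1))
            rec_v_o = np.zeros((1, 1, 1))
        _forward_kernel(
            x_in, w_rec, has_rec, w.w_out, self.lam_m_h, self.lam_s_h,
            self.lam_m_o, self.lam_s_o, thr, injected, rec_v_h, rec_s,
            rec_v_o, mask_vec, vf_h, i_h, s, vf_o, i_o,
        )

        self._cache = dict(x=x, vf_h=vf_h, i_h=i_h, s=s, vf_o=vf_o)
        return vf_o, s

    # -- backward --------------------------------------------------------------

    def backward(
        self, grad_v_out: np.ndarray, grad_s_hidden: Optional[np.ndarray] = None
    ) -> dict:
        """Backpropagate through the unrolled graph.

        ``grad_v_out``: gradient of the loss w.r.t. the output traces
        returned by :meth:`forward` (``[B,T,n_out]``).  ``grad_s_hidden``:
        optional gradient w.r.t. the hidden spike trains (regularizers).
        Returns ``{"w_in", "w_rec", "w_out"}`` summed over the batch
        (``w_rec`` is ``None`` for feed-forward graphs).
        """
        if self._cache is None:
            raise RuntimeError("backward called before forward")
        c = self._cache
        x, vf_h, i_h, s, _ = c["x"], c["vf_h"], c["i_h"], c["s"], c["vf_o"]
        B, T, H = vf_h.shape
        w = self.weights
        O = w.n_out
        thr = self.hidden_params.threshold
        mask = self.dropout_mask
        gv_dir = np.asarray(grad_v_out, dtype=float)
        gs_dir = None if grad_s_hidden is None else np.asarray(grad_s_hidden, dtype=float)

        # surrogate derivative of the spike w.r.t. the membrane node, taken at
        # the forward (sampled) values, times the dropout mask on the output
        sg = surrogate_spike_derivative(vf_h, thr, self.surrogate)
        if mask is not None:
            sg = sg * mask

        has_rec = w.w_rec is not None
        w_rec = w.w_rec if has_rec else np.zeros((0, 0))
        has_gs = gs_dir is not None
        gs_arr = gs_dir if has_gs else np.zeros((1, 1, 1))
        gi_h_all = np.empty((B, T, H))
        gi_o_all = np.empty((B, T, O))
        _backward_kernel(
            vf_h, i_h, s, sg, gv_dir, gs_arr, has_gs,
            w_rec, has_rec, w.w_out, self.lam_m_h, self.lam_s_h,
            self.lam_m_o, self.lam_s_o, self.detach_reset, gi_h_all, gi_o_all,
        )
        # weight gradients from the t -> t+1 current updates
        C = x.shape[2]
        s_flat = s[:, :-1].reshape(-1, H)
        dw_out = gi_o_all[:, 1:].reshape(-1, O).T @ s_flat
        dw_in = gi_h_all[:, 1:].reshape(-1, H).T @ x[:, :-1].reshape(-1, C)
        dw_rec = gi_h_all[:, 1:].reshape(-1, H).T @ s_flat if has_rec else None
        return {"w_in": dw_in, "w_rec": dw_rec, "w_out": dw_out}


# ---------------------------------------------------------------------------
# recording interpolation
# ---------------------------------------------------------------------------


def interpolate_recording(recording: SubstrateRecording, factor: int) -> SubstrateRecording:
    """Resample a recording onto a grid of step ``grid_dt / factor``.

    Membrane traces are linearly interpolated (held constant past the last
    sample); spikes are re-binned at the finer resolution from the raw event
    list, so events that shared a coarse bin but not a fine bin become
    separated.
    """
    factor = int(factor)
    if factor < 1:
        raise ValueError("factor must be >= 1")
    if factor == 1:
        return recording
    B, T, N = recording.v_sampled.shape
    dt_new = recording.grid_dt / factor
    T_new = T * factor
    pos = np.arange(T_new) / factor  # positions in units of the coarse grid
    i0 = np.minimum(pos.astype(int), T - 1)
    i1 = np.minimum(i0 + 1, T - 1)
    frac = (pos - i0)[None, :, None]
    v = recording.v_sampled
    v_new = v[:, i0] * (1 - frac) + v[:, i1] * frac

    spikes_new = np.zeros((B, T_new, N), dtype=np.uint8)
    for b, (times, units) in enumerate(recording.spike_times):
        if len(times) == 0:
            continue
        bins = np.minimum((np.asarray(times) / dt_new).astype(int), T_new - 1)
        spikes_new[b, bins, np.asarray(units, dtype=int)] = 1

    return SubstrateRecording(
        v_new, spikes_new, recording.spike_times, dt_new, recording.seed
    )
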