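"""Task losses and activity regularizers.

All functions operate on batched arrays — output membrane traces
``v_out [B, T, n_classes]`` and hidden spike trains ``s_hidden [B, T, n_hidden]``
— and return ``(value, gradient)`` pairs, where the value is averaged over the
batch and the gradient has the shape of the input.  The gradients are exact
(sub)gradients: the max-over-time readout routes its gradient to the argmax
time step only, with ties broken toward the earliest step.

Classification readouts take per-class scores from the non-spiking output
traces (maximum or sum over time), pass them through a softmax, and score the
negative log-likelihood of the true class.  The regularizers shape hidden
activity: a quadratic penalty on per-neuron spike counts drives the network
toward sparse firing and can only ever reduce activity, while the homeostatic
variant penalises only total activity above a threshold.  Gradients with
respect to spikes reach the weights exclusively through the surrogate
pathway of the training graph.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "LossConfig",
    "max_over_time_nll",
    "sum_over_time_nll",
    "amplitude_penalty",
    "sparsity_regularizer",
    "homeostatic_regularizer",
    "total_loss",
]


@dataclass(frozen=True)
class LossConfig:
    """Which readout loss to use and the regularizer strengths.

    ``rho_a``: amplitude penalty on squared per-unit trace maxima;
    ``rho_b``: sparsity penalty on squared per-neuron spike counts;
    ``rho_r``/``theta_r``: homeostatic penalty on total spikes above
    ``theta_r``.
    """

    mode: str = "max_over_time"
    rho_a: float = 0.0
    rho_b: float = 0.0
    rho_r: float = 0.0
    theta_r: float = 0.0

    def __post_init__(self) -> None:
        if self.mode not in ("max_over_time", "sum_over_time"):
            raise ValueError("mode must be 'max_over_time' or 'sum_over_time'")
        if min(self.rho_a, self.rho_b, self.rho_r) < 0:
            raise ValueError("regularizer strengths must be >= 0")


def _as_batch(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    if v.ndim == 2:
        v = v[None]
    if v.ndim != 3 or v.shape[1] == 0:
        raise ValueError("expected [batch, T, units] with T >= 1")
    return v


def _softmax_nll(scores: np.ndarray, labels: np.ndarray):
    """Batch-mean NLL of softmax scores plus d(loss)/d(scores).

    Computed as ``logsumexp(z) - z_label`` so the value and gradient stay
    exact and mutually consistent even for strongly saturated scores.
    """
    B = scores.shape[0]
    z = scores - scores.max(axis=1, keepdims=True)
    e = np.exp(z)
    denom = e.sum(axis=1, keepdims=True)
    p = e / denom
    idx = np.arange(B)
    loss = float(np.mean(np.log(denom[:, 0]) - z[idx, labels]))
    grad = p.copy()
    grad[idx, labels] -= 1.0
    return loss, grad / B, p


def max_over_time_nll(v_out: np.ndarray, labels) -> tuple:
    """NLL of softmax over per-class max-over-time scores.

    Returns ``(loss, grad)`` with ``grad`` the gradient w.r.t. ``v_out``,
    nonzero only at each class's (earliest) argmax time step.
    """
    v = _as_batch(v_out)
    labels = np.atleast_1d(np.asarray(labels, dtype=int))
    B, T, O = v.shape
    t_star = v.argmax(axis=1)  # [B, O]; np.argmax takes the earliest maximum
    scores = np.take_along_axis(v, t_star[:, None, :], axis=1)[:, 0, :]
    loss, gscore, _ = _softmax_nll(scores, labels)
    grad = np.zeros_like(v)
    b_idx = np.repeat(np.arange(B), O)
    o_idx = np.tile(np.arange(O), B)
    grad[b_idx, t_star.ravel(), o_idx] = gscore.ravel()
    return loss, grad


def sum_over_time_nll(v_out: np.ndarray, labels) -> tuple:
    """NLL of softmax over per-class sum-over-time scores."""
    v = _as_batch(v_out)
    labels = np.atleast_1d(np.asarray(labels, dtype=int))
    scores = v.sum(axis=1)
    loss, gscore, _ = _softmax_nll(scores, labels)
    grad = np.broadcast_to(gscore[:, None, :], v.shape).copy()
    return loss, grad


def readout_scores(v_out: np.ndarray, mode: str) -> np.ndarray:
    """Per-class decision scores used by the classifier (``[B, n_classes]``)."""
    v = _as_batch(v_out)
    return v.max(axis=1) if mode == "max_over_time" else v.sum(axis=1)


def amplitude_penalty(v_out: np.ndarray, rho_a: float) -> tuple:
    """``rho_a * mean_i (max_t V_i[t])**2`` — keeps output traces in the
    substrate's representable range.  Batch-averaged."""
    v = _as_batch(v_out)
    B, T, O = v.shape
    t_star = v.argmax(axis=1)
    z = np.take_along_axis(v, t_star[:, None, :], axis=1)[:, 0, :]
    value = rho_a * float(np.mean(z**2))
    grad = np.zeros_like(v)
    b_idx = np.repeat(np.arange(B), O)
    o_idx = np.tile(np.arange(O), B)
    grad[b_idx, t_star.ravel(), o_idx] = (2.0 * rho_a * z / (O * B)).ravel()
    return value, grad


def sparsity_regularizer(s_hidden: np.ndarray, rho_b: float) -> tuple:
    """Quadratic penalty on per-neuron spike counts,
    ``rho_b / N_H * sum_i (sum_t S_i[t])**2``, batch-averaged.

    Because it is monotone in every spike indicator, its gradient can only
    push activity down, never conjure spikes up.
    """
    s = _as_batch(s_hidden)
    B, T, H = s.shape
    counts = s.sum(axis=1)  # [B, H]
    value = rho_b / H * float(np.mean(np.sum(counts**2, axis=1)))
    grad = np.broadcast_to(
        (2.0 * rho_b / (H * B) * counts)[:, None, :], s.shape
    ).copy()
    return value, grad


def homeostatic_regularizer(s_hidden: np.ndarray, rho_r: float, theta_r: float) -> tuple:
    """``rho_r * max(0, sum_{i,t} S_i[t] - theta_r)**2`` per sample,
    batch-averaged: silent below the activity threshold, quadratic above."""
    s = _as_batch(s_hidden)
    B = s.shape[0]
    excess = np.maximum(0.0, s.sum(axis=(1, 2)) - theta_r)  # [B]
    value = rho_r * float(np.mean(excess**2))
    grad = np.broadcast_to(
        (2.0 * rho_r / B * excess)[:, None, None], s.shape
    ).copy()
    return value, grad


def total_loss(v_out: np.ndarray, s_hidden: np.ndarray, labels, config: LossConfig):
    """Weighted sum of the task loss and all active regularizers.

    Returns ``(terms, grad_v_out, grad_s_hidden)`` where ``terms`` maps
    ``{"nll", "amplitude", "sparsity", "homeostatic", "total"}`` to scalars.
    """
    nll_fn = max_over_time_nll if config.mode == "max_over_time" else sum_over_time_nll
    nll, grad_v = nll_fn(v_out, labels)
    terms = {"nll": nll, "amplitude": 0.0, "sparsity": 0.0, "homeostatic": 0.0}
    grad_s = np.zeros_like(_as_batch(s_hidden))
    if config.rho_a > 0:
        a, g = amplitude_penalty(v_out, config.rho_a)
        terms["amplitude"] = a
        grad_v = grad_v + g
    if config.rho_b > 0:
        b, g = sparsity_regularizer(s_hidden, config.rho_b)
        terms["sparsity"] = b
        grad_s = grad_s + g
    if config.rho_r > 0:
        r, g = homeostatic_regularizer(s_hidden, config.rho_r, config.theta_r)
        terms["homeostatic"] = r
        grad_s = grad_s + g
    terms["total"] = sum(terms.values())
    return terms, grad_v, grad_s
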