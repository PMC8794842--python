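"""Training: the in-the-loop (ITL) optimization loop and its baselines.

The central object is :class:`SpikingNetClassifier`, a scikit-learn style
estimator.  With ``substrate=None`` it trains a surrogate-gradient spiking
network purely in software (ignoring all hardware constraints, including
weight resolution).  With an :class:`~snnloop.substrate.AnalogSubstrate`
attached, every batch runs the ITL cycle:

1. quantize the float master weights with the weight-scaling rule and deploy
   the de-scaled integer view,
2. emulate the forward pass on the substrate, recording sampled membranes and
   binned spikes,
3. unroll the training graph with the *idealized* (calibration-target)
   parameters, injecting the recordings,
4. evaluate the loss and backpropagate through time,
5. update the float master copy with Adam.

Gradients therefore never touch the deployed integer weights directly
(master-copy discipline), and the graph never learns about the substrate's
mismatch — compensation emerges from training against measurements.

Robustness and control operations: spike-level dropout during training,
post-training ablation of hidden units, weight transfer of software-trained
networks onto a (possibly decalibrated) substrate, and the shuffled-frozen
recurrent control.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, clone

from .encoders import SpikeBatch
from .graph import SurrogateSpec, UnrolledGraph
from .objectives import LossConfig, readout_scores, total_loss
from .substrate import (
    W_MAX,
    AnalogSubstrate,
    NetworkWeights,
    NeuronParams,
    quantize_weights,
)

__all__ = [
    "InitSpec",
    "init_weights",
    "weight_scale",
    "deploy_weights",
    "ablate_hidden",
    "dropout_mask",
    "shuffle_recurrent",
    "SpikingNetClassifier",
    "train_software_only",
    "weight_transfer",
    "itl_step",
    "save_checkpoint",
    "load_checkpoint",
]


# ---------------------------------------------------------------------------
# initialization and weight deployment
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class InitSpec:
    """Kaiming-style initialization: each layer's entries are drawn from a
    zero-mean normal with SD ``sigma_w / sqrt(fan_in)``."""

    sigma_w: float
    n_in: int
    n_hidden: int
    n_out: int
    recurrent: bool = False

    def __post_init__(self) -> None:
        if self.sigma_w < 0:
            raise ValueError("sigma_w must be >= 0")


def init_weights(spec: InitSpec, seed: int) -> NetworkWeights:
    """Draw initial weights; deterministic given the seed."""
    rng = np.random.default_rng(seed)
    w_in = rng.normal(0.0, 1.0, (spec.n_hidden, spec.n_in)) * spec.sigma_w / np.sqrt(spec.n_in)
    w_rec = None
    if spec.recurrent:
        w_rec = (
            rng.normal(0.0, 1.0, (spec.n_hidden, spec.n_hidden))
            * spec.sigma_w
            / np.sqrt(spec.n_hidden)
        )
    w_out = (
        rng.normal(0.0, 1.0, (spec.n_out, spec.n_hidden)) * spec.sigma_w / np.sqrt(spec.n_hidden)
    )
    return NetworkWeights(w_in, w_out, w_rec)


def weight_scale(weights: NetworkWeights, scale_hidden: float = 100.0):
    """Quantize a float weight set for deployment.

    Hidden-side matrices (input and recurrent) use a fixed configurable
    scale.  The output layer — feeding non-spiking integrators whose traces
    may be scaled arbitrarily — uses the dynamic rule: the largest absolute
    software weight is aligned with the maximum representable integer, with a
    fallback scale of 1 for an all-zero matrix.

    Returns ``(quantized, scales)``: integer matrices and the per-layer
    scales needed to de-scale them consistently.
    """
    m = float(np.max(np.abs(weights.w_out))) if weights.w_out.size else 0.0
    scale_out = W_MAX / m if m > 0 else 1.0
    quantized = {
        "w_in": quantize_weights(weights.w_in, scale_hidden),
        "w_rec": None
        if weights.w_rec is None
        else quantize_weights(weights.w_rec, scale_hidden),
        "w_out": quantize_weights(weights.w_out, scale_out),
    }
    scales = {"w_in": scale_hidden, "w_rec": scale_hidden, "w_out": scale_out}
    return quantized, scales


def deploy_weights(weights: NetworkWeights, scale_hidden: float = 100.0) -> NetworkWeights:
    """Quantized-then-de-scaled view of the weights, i.e. the values the
    substrate actually realises."""
    q, s = weight_scale(weights, scale_hidden)
    return NetworkWeights(
        q["w_in"] / s["w_in"],
        q["w_out"] / s["w_out"],
        None if q["w_rec"] is None else q["w_rec"] / s["w_rec"],
    )


# ---------------------------------------------------------------------------
# robustness tools
# ---------------------------------------------------------------------------


def ablate_hidden(weights: NetworkWeights, fraction: float, seed: int) -> NetworkWeights:
    """Silence ``floor(fraction * n_hidden)`` randomly selected hidden units
    (drawn without replacement) by zeroing their input, recurrent and output
    connections.  Models post-deployment neuron failure."""
    if not 0 <= fraction <= 1:
        raise ValueError("fraction must lie in [0, 1]")
    out = weights.copy()
    n_kill = int(np.floor(fraction * weights.n_hidden))
    if n_kill == 0:
        return out
    killed = np.random.default_rng(seed).choice(weights.n_hidden, size=n_kill, replace=False)
    out.w_in[killed, :] = 0.0
    if out.w_rec is not None:
        out.w_rec[killed, :] = 0.0
        out.w_rec[:, killed] = 0.0
    out.w_out[:, killed] = 0.0
    return out


def dropout_mask(n_hidden: int, rate: float, rng: np.random.Generator) -> Optional[np.ndarray]:
    """Per-batch Bernoulli(1 - rate) keep mask on hidden units; ``None`` when
    dropout is off."""
    if not 0 <= rate <= 1:
        raise ValueError("rate must lie in [0, 1]")
    if rate == 0:
        return None
    return (rng.random(n_hidden) >= rate).astype(float)


def shuffle_recurrent(weights: NetworkWeights, seed: int) -> NetworkWeights:
    """Permute the entries of the recurrent matrix (multiset of weights is
    preserved).  Used as the initialization of the fixed-recurrent control."""
    if weights.w_rec is None:
        raise ValueError("network has no recurrent weights")
    out = weights.copy()
    flat = out.w_rec.ravel()
    perm = np.random.default_rng(seed).permutation(flat.size)
    out.w_rec = flat[perm].reshape(out.w_rec.shape)
    return out


# ---------------------------------------------------------------------------
# optimizer
# ---------------------------------------------------------------------------


class Adam:
    """Adam on a dict of arrays (keys with ``None`` values are skipped)."""

    def __init__(self, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = {}
        self.v = {}

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        for k, g in grads.items():
            if g is None or params.get(k) is None:
                continue
            if k not in self.m:
                self.m[k] = np.zeros_like(g)
                self.v[k] = np.zeros_like(g)
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g**2
            mhat = self.m[k] / (1 - self.beta1**self.t)
            vhat = self.v[k] / (1 - self.beta2**self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _clip_gradients(grads: dict, max_norm: float) -> dict:
    total = np.sqrt(sum(float(np.sum(g**2)) for g in grads.values() if g is not None))
    if total > max_norm > 0:
        factor = max_norm / total
        grads = {k: (None if g is None else g * factor) for k, g in grads.items()}
    return grads


# ---------------------------------------------------------------------------
# the estimator
# ---------------------------------------------------------------------------


class SpikingNetClassifier(BaseEstimator, ClassifierMixin):
    """Surrogate-gradient spiking-network classifier, optionally trained
    in-the-loop against an analog substrate emulation.

    Parameters
    ----------
    n_hidden : int
        Hidden-layer size (spiking LIF units).
    recurrent : bool
        Add trainable hidden-to-hidden connections (one-bin spike delay).
    tau_mem, tau_syn : float
        Idealized membrane/synaptic time constants of the training graph, in
        model time units.  The output layer uses the same constants without a
        threshold.
    dt : float
        Sampling-grid step; must match the input grid and any substrate.
    beta, surrogate_form :
        Surrogate-derivative steepness and shape (see
        :class:`~snnloop.graph.SurrogateSpec`).
    loss_mode, rho_a, rho_b, rho_r, theta_r :
        Readout loss and regularizer strengths (see
        :class:`~snnloop.objectives.LossConfig`).
    lr, lr_decay, n_epochs, batch_size, shuffle :
        Adam learning rate, per-epoch multiplicative decay, and batching.
    dropout_rate : float
        Spike-level dropout on hidden units during training (a per-batch
        Bernoulli keep mask; dropped units are silenced on the substrate
        deployment for that batch).  Disabled at evaluation.
    grad_clip : float or None
        Global-norm gradient clipping (recommended with the literal
        surrogate form).
    substrate : AnalogSubstrate or None
        ``None``: software-only training.  Otherwise forward passes are
        emulated on the given substrate and the graph sees only its
        recordings; layer sizes must match.
    quantize : bool
        Deploy quantized weights on the substrate (ignored in software mode).
    scale_hidden : float
        Fixed quantization scale of the hidden-side matrices.
    train_recurrent : bool
        If False, recurrent weights receive no updates (fixed-recurrent
        control).
    random_state : int
        Seed for initialization, shuffling, dropout and substrate trials.

    Attributes
    ----------
    classes_ : ndarray
        Class labels.
    weights_ : NetworkWeights
        Float master weights after training.
    history_ : pandas.DataFrame
        Per-epoch loss terms, training accuracy and hidden spike counts.
    """

    def __init__(
        self,
        n_hidden: int = 64,
        recurrent: bool = False,
        tau_mem: float = 20.0,
        tau_syn: float = 10.0,
        dt: float = 1.0,
        beta: float = 10.0,
        surrogate_form: str = "superspike",
        loss_mode: str = "max_over_time",
        rho_a: float = 0.0,
        rho_b: float = 0.0,
        rho_r: float = 0.0,
        theta_r: float = 0.0,
        lr: float = 1e-3,
        lr_decay: float = 1.0,
        n_epochs: int = 100,
        batch_size: int = 32,
        shuffle: bool = True,
        dropout_rate: float = 0.0,
        grad_clip: Optional[float] = None,
        sigma_w: float = 1.0,
        substrate: Optional[AnalogSubstrate] = None,
        quantize: bool = True,
        scale_hidden: float = 100.0,
        detach_reset: bool = True,
        train_recurrent: bool = True,
        random_state: int = 0,
    ) -> None:
        self.n_hidden = n_hidden
        self.recurrent = recurrent
        self.tau_mem = tau_mem
        self.tau_syn = tau_syn
        self.dt = dt
        self.beta = beta
        self.surrogate_form = surrogate_form
        self.loss_mode = loss_mode
        self.rho_a = rho_a
        self.rho_b = rho_b
        self.rho_r = rho_r
        self.theta_r = theta_r
        self.lr = lr
        self.lr_decay = lr_decay
        self.n_epochs = n_epochs
        self.batch_size = batch_size
        self.shuffle = shuffle
        self.dropout_rate = dropout_rate
        self.grad_clip = grad_clip
        self.sigma_w = sigma_w
        self.substrate = substrate
        self.quantize = quantize
        self.scale_hidden = scale_hidden
        self.detach_reset = detach_reset
        self.train_recurrent = train_recurrent
        self.random_state = random_state

    # -- plumbing --------------------------------------------------------------

    def _coerce_X(self, X) -> np.ndarray:
        if isinstance(X, SpikeBatch):
            if abs(X.dt - self.dt) > 1e-12:
                raise ValueError("SpikeBatch dt differs from estimator dt")
            return X.dense.astype(float)
        X = np.asarray(X, dtype=float)
        if X.ndim != 3:
            raise ValueError("X must be a SpikeBatch or a dense [batch, T, channels] array")
        return X

    def _ideal_params(self, n_out: int):
        if self.substrate is not None:
            return self.substrate.target_hidden, self.substrate.target_output
        hidden = NeuronParams.homogeneous(self.n_hidden, self.tau_mem, self.tau_syn)
        output = NeuronParams.homogeneous(n_out, self.tau_mem, self.tau_syn, threshold=np.inf)
        return hidden, output

    def _loss_config(self) -> LossConfig:
        return LossConfig(self.loss_mode, self.rho_a, self.rho_b, self.rho_r, self.theta_r)

    def _surrogate(self) -> SurrogateSpec:
        return SurrogateSpec(self.beta, self.surrogate_form)

    def _deployed(self, weights: NetworkWeights, mask=None) -> NetworkWeights:
        if self.substrate is not None and self.quantize:
            dep = deploy_weights(weights, self.scale_hidden)
        else:
            dep = weights.copy()
        if mask is not None:
            # silence dropped units and rescale the survivors' outgoing
            # weights by 1/keep (inverted dropout adapted to binary spikes)
            dropped = np.nonzero(mask == 0)[0]
            keep_p = max(1.0 - self.dropout_rate, 1e-9)
            dep.w_in[dropped, :] = 0.0
            if dep.w_rec is not None:
                dep.w_rec[dropped, :] = 0.0
                dep.w_rec /= keep_p
            dep.w_out /= keep_p
        return dep

    def _graph(self, deployed: NetworkWeights, n_out: int, mask=None) -> UnrolledGraph:
        hidden, output = self._ideal_params(n_out)
        return UnrolledGraph(
            deployed,
            hidden,
            output,
            dt=self.dt,
            surrogate=self._surrogate(),
            detach_reset=self.detach_reset,
            dropout_mask=mask,
        )

    def _forward(self, x: np.ndarray, deployed: NetworkWeights, n_out: int, mask=None):
        """One forward pass; returns (graph, output traces, hidden spikes)."""
        graph = self._graph(deployed, n_out, mask)
        if self.substrate is not None:
            recording = self.substrate.reset_state().forward(x, deployed)
            traces, spikes = graph.forward(x, recording)
        else:
            traces, spikes = graph.forward(x)
        return graph, traces, spikes

    # -- fitting ---------------------------------------------------------------

    def initialize(self, X, y, initial_weights: Optional[NetworkWeights] = None):
        """Set up classes, weights and optimizer without training (used by
        :func:`itl_step` and by :meth:`fit`)."""
        x = self._coerce_X(X)
        y = np.asarray(y)
        self.classes_, _ = np.unique(y, return_inverse=True)
        n_out = len(self.classes_)
        if self.substrate is not None:
            sub = self.substrate
            if (sub.n_inputs, sub.n_hidden, sub.n_outputs) != (x.shape[2], self.n_hidden, n_out):
                raise ValueError("substrate layer sizes do not match the task/estimator")
            if abs(sub.dt - self.dt) > 1e-12:
                raise ValueError("substrate dt differs from estimator dt")
            sub.reseed_trials(self.random_state + 7)
        if initial_weights is not None:
            self.weights_ = initial_weights.copy()
        else:
            spec = InitSpec(self.sigma_w, x.shape[2], self.n_hidden, n_out, self.recurrent)
            self.weights_ = init_weights(spec, self.random_state)
        self._rng = np.random.default_rng(self.random_state + 1)
        self._adam = Adam(self.lr)
        self._n_out = n_out
        self.history_ = []
        return self

    def _train_batch(self, xb: np.ndarray, yb: np.ndarray) -> dict:
        mask = dropout_mask(self.n_hidden, self.dropout_rate, self._rng)
        deployed = self._deployed(self.weights_, mask)
        graph, traces, spikes = self._forward(xb, deployed, self._n_out, mask)
        terms, grad_v, grad_s = total_loss(traces, spikes, yb, self._loss_config())
        if not np.isfinite(terms["total"]):
            raise FloatingPointError(
                f"non-finite loss {terms}; check surrogate form / learning rate"
            )
        grads = graph.backward(grad_v, grad_s)
        if not self.train_recurrent and grads["w_rec"] is not None:
            grads["w_rec"] = np.zeros_like(grads["w_rec"])
        if self.grad_clip is not None:
            grads = _clip_gradients(grads, self.grad_clip)
        params = {"w_in": self.weights_.w_in, "w_rec": self.weights_.w_rec,
                  "w_out": self.weights_.w_out}
        self._adam.step(params, grads)
        preds = readout_scores(traces, self.loss_mode).argmax(axis=1)
        return {
            **terms,
            "correct": int(np.sum(preds == yb)),
            "n": len(yb),
            "spikes": float(spikes.sum()),
        }

    def fit(self, X, y, initial_weights: Optional[NetworkWeights] = None):
        """Train for ``n_epochs`` full passes over ``(X, y)``."""
        self.initialize(X, y, initial_weights)
        x = self._coerce_X(X)
        y_idx = np.searchsorted(self.classes_, np.asarray(y))
        n = x.shape[0]
        for epoch in range(self.n_epochs):
            self._adam.lr = self.lr * self.lr_decay**epoch
            order = self._rng.permutation(n) if self.shuffle else np.arange(n)
            agg = {"nll": 0.0, "amplitude": 0.0, "sparsity": 0.0, "homeostatic": 0.0,
                   "total": 0.0, "correct": 0, "spikes": 0.0}
            for start in range(0, n, self.batch_size):
                sel = order[start : start + self.batch_size]
                m = self._train_batch(x[sel], y_idx[sel])
                w = m["n"] / n
                for k in ("nll", "amplitude", "sparsity", "homeostatic", "total"):
                    agg[k] += m[k] * w
                agg["correct"] += m["correct"]
                agg["spikes"] += m["spikes"]
            self.history_.append(
                {
                    "epoch": epoch,
                    **{k: agg[k] for k in ("nll", "amplitude", "sparsity", "homeostatic", "total")},
                    "train_accuracy": agg["correct"] / n,
                    "hidden_spikes_per_sample": agg["spikes"] / n,
                }
            )
        self.history_ = pd.DataFrame(self.history_)
        self.n_iter_ = self.n_epochs
        return self

    # -- inference -------------------------------------------------------------

    def output_traces(self, X) -> np.ndarray:
        """Output-layer membrane traces ``[batch, T, n_classes]`` (recorded
        from the substrate when one is attached, simulated otherwise)."""
        x = self._coerce_X(X)
        deployed = self._deployed(self.weights_)
        if self.substrate is not None:
            _, rec_o = self.substrate.reset_state().forward(x, deployed)
            return rec_o.v_sampled
        graph = self._graph(deployed, self._n_out)
        traces, _ = graph.forward(x)
        return traces

    def hidden_spike_counts(self, X) -> np.ndarray:
        """Hidden spikes per sample (summed over units and time)."""
        x = self._coerce_X(X)
        deployed = self._deployed(self.weights_)
        if self.substrate is not None:
            rec_h, _ = self.substrate.reset_state().forward(x, deployed)
            return rec_h.spikes.sum(axis=(1, 2)).astype(float)
        graph = self._graph(deployed, self._n_out)
        _, spikes = graph.forward(x)
        return spikes.sum(axis=(1, 2))

    def decision_function(self, X) -> np.ndarray:
        return readout_scores(self.output_traces(X), self.loss_mode)

    def predict_proba(self, X) -> np.ndarray:
        z = self.decision_function(X)
        z = z - z.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)

    def predict(self, X) -> np.ndarray:
        return self.classes_[self.decision_function(X).argmax(axis=1)]

    # -- fitted-state transplant (weight transfer, ablation studies) ----------

    def adopt(self, weights: NetworkWeights, classes: np.ndarray) -> "SpikingNetClassifier":
        """Mark the estimator as fitted with externally supplied weights."""
        self.weights_ = weights.copy()
        self.classes_ = np.asarray(classes)
        self._n_out = len(self.classes_)
        self.history_ = pd.DataFrame()
        return self


# ---------------------------------------------------------------------------
# module-level operations over the estimator
# ---------------------------------------------------------------------------


def save_checkpoint(clf: SpikingNetClassifier, path, config_hash: str = "") -> None:
    """Write weights, optimizer moments, classes, and a config hash to HDF5."""
    import h5py

    with h5py.File(path, "w") as f:
        f.attrs["config_hash"] = config_hash
        f.attrs["epoch"] = getattr(clf, "n_iter_", 0)
        g = f.create_group("weights")
        g.create_dataset("w_in", data=clf.weights_.w_in)
        g.create_dataset("w_out", data=clf.weights_.w_out)
        if clf.weights_.w_rec is not None:
            g.create_dataset("w_rec", data=clf.weights_.w_rec)
        f.create_dataset("classes", data=np.asarray(clf.classes_))
        if hasattr(clf, "_adam"):
            opt = f.create_group("optimizer")
            opt.attrs["t"] = clf._adam.t
            for k, arr in clf._adam.m.items():
                opt.create_dataset(f"m_{k}", data=arr)
            for k, arr in clf._adam.v.items():
                opt.create_dataset(f"v_{k}", data=arr)


def load_checkpoint(clf: SpikingNetClassifier, path) -> SpikingNetClassifier:
    """Restore a checkpoint into an estimator (weights, optimizer, classes)."""
    import h5py

    with h5py.File(path, "r") as f:
        g = f["weights"]
        weights = NetworkWeights(
            g["w_in"][()], g["w_out"][()],
            g["w_rec"][()] if "w_rec" in g else None,
        )
        clf.adopt(weights, f["classes"][()])
        clf.n_iter_ = int(f.attrs["epoch"])
        if "optimizer" in f:
            adam = Adam(clf.lr)
            adam.t = int(f["optimizer"].attrs["t"])
            for key in f["optimizer"]:
                kind, name = key.split("_", 1)
                target = adam.m if kind == "m" else adam.v
                target[name] = f["optimizer"][key][()]
            clf._adam = adam
    return clf


def itl_step(clf: SpikingNetClassifier, X_batch, y_batch) -> dict:
    """One ITL optimization step on an initialized estimator; returns the
    batch metrics (loss terms, correct count, hidden spike count)."""
    x = clf._coerce_X(X_batch)
    y_idx = np.searchsorted(clf.classes_, np.asarray(y_batch))
    return clf._train_batch(x, y_idx)


def train_software_only(X, y, **params) -> SpikingNetClassifier:
    """Train ignoring all hardware constraints (no substrate, float
    weights)."""
    params.pop("substrate", None)
    return SpikingNetClassifier(substrate=None, **params).fit(X, y)


def weight_transfer(
    trained: SpikingNetClassifier, substrate: AnalogSubstrate, X, y
) -> dict:
    """Deploy a software-trained network's weights onto a substrate (with
    quantization) and evaluate — no ITL fine-tuning.  Side-effect-free on the
    trained estimator."""
    clf = clone(trained)
    clf.set_params(substrate=substrate, quantize=True)
    clf.adopt(trained.weights_, trained.classes_)
    substrate.reseed_trials(clf.random_state + 7)
    acc = float(clf.score(X, y))
    return {"accuracy": acc, "error": 1.0 - acc}
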