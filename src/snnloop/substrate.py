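"""Simulated analog neuromorphic substrate.

This module emulates the physical device that the in-the-loop (ITL) training
scheme wraps around: a population of leaky integrate-and-fire (LIF) neuron
circuits with

* **fixed-pattern mismatch** — per-neuron parameters (time constants,
  thresholds) deviate statically from their calibration targets, frozen per
  substrate instance,
* **trial-to-trial noise** — additive membrane noise during integration and
  jitter on the sampled readout,
* **quantized synapses** — deployed weights are signed 7-bit integers in
  ``[-63, 63]``,
* **sampled observables** — membrane voltages are only available on a coarse
  sampling grid of step ``dt`` (the ADC abstraction), while spikes are
  time-stamped at the fine integration resolution and binned onto the grid.

All dynamics use the dimensionless LIF convention: leak potential 0, membrane
capacitance 1, firing threshold 1 unless overridden.

Two integration modes are provided.  ``"exact"`` (default) advances the
continuous LIF ODE with its exact exponential propagator at a fine step
``delta = dt / substeps``, so the emulation genuinely differs from the
discrete model the training graph assumes — like real hardware does.
``"grid"`` integrates the discrete model recursion itself at step ``dt``;
with mismatch and noise disabled it reproduces the training graph exactly,
which is the reference configuration for validating gradient injection.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import h5py
import numba
import numpy as np

__all__ = [
    "W_MAX",
    "NeuronParams",
    "MismatchSpec",
    "NoiseSpec",
    "NetworkWeights",
    "SubstrateRecording",
    "AnalogSubstrate",
    "decalibrate",
    "quantize_weights",
]

#: Weight resolution of the substrate: signed 7-bit (two merged 6-bit synapses).
W_MAX = 63


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------


@dataclass
class NeuronParams:
    """Per-neuron LIF parameters (model time units).

    ``tau_mem`` is the membrane time constant (capacitance over leak
    conductance), ``tau_syn`` the synaptic current time constant.  A neuron
    whose threshold does not exceed its leak potential is in a
    "leak-over-threshold" state: it fires without input.  Such neurons are
    permitted (they arise under strong decalibration) but flagged.
    """

    tau_mem: np.ndarray
    tau_syn: np.ndarray
    threshold: np.ndarray
    v_leak: np.ndarray
    v_reset: np.ndarray

    def __post_init__(self) -> None:
        n = None
        for name in ("tau_mem", "tau_syn", "threshold", "v_leak", "v_reset"):
            arr = np.atleast_1d(np.asarray(getattr(self, name), dtype=float))
            setattr(self, name, arr)
            if n is None:
                n = arr.shape[0]
            elif arr.shape[0] != n:
                raise ValueError(f"inconsistent length for {name!r}")
        if np.any(self.tau_mem <= 0) or np.any(self.tau_syn <= 0):
            raise ValueError("time constants must be positive")

    @classmethod
    def homogeneous(
        cls,
        n: int,
        tau_mem: float = 20.0,
        tau_syn: float = 10.0,
        threshold: float = 1.0,
        v_leak: float = 0.0,
        v_reset: float = 0.0,
    ) -> "NeuronParams":
        """Identical calibration targets for ``n`` neurons."""
        full = lambda v: np.full(n, float(v))
        return cls(full(tau_mem), full(tau_syn), full(threshold), full(v_leak), full(v_reset))

    @property
    def n(self) -> int:
        return self.tau_mem.shape[0]

    def leak_over_threshold(self) -> np.ndarray:
        """Boolean flags for neurons whose threshold is at or below the leak."""
        return self.threshold <= self.v_leak

    def copy(self) -> "NeuronParams":
        return NeuronParams(*(getattr(self, f).copy() for f in
                              ("tau_mem", "tau_syn", "threshold", "v_leak", "v_reset")))


@dataclass(frozen=True)
class MismatchSpec:
    """Fixed-pattern decalibration: per-neuron targets are redrawn from
    ``Normal(target, sigma_d * target)`` for each parameter in ``which``."""

    sigma_d: float = 0.0
    which: Sequence[str] = ("tau_mem", "tau_syn", "threshold")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_d < 0:
            raise ValueError("sigma_d must be >= 0")
        allowed = {"tau_mem", "tau_syn", "threshold"}
        if not set(self.which) <= allowed:
            raise ValueError(f"which must be a subset of {allowed}")
        if self.sigma_d > 0 and not self.which:
            raise ValueError("which must be non-empty when sigma_d > 0")


@dataclass(frozen=True)
class NoiseSpec:
    """Trial-varying noise: intrinsic membrane noise plus Gaussian jitter on
    the sampled readout.  ``membrane_noise_sd`` is the *stationary* SD of the
    noise component of the membrane (model units, i.e. fractions of the unit
    threshold); it is realised as per-sampling-bin Gaussian injections with
    variance ``sd**2 * (1 - exp(-2 dt / tau_mem))`` so the accumulated
    process has the stated SD regardless of the integration step.  All-zero
    standard deviations make the substrate deterministic."""

    membrane_noise_sd: float = 0.01
    sample_jitter_sd: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.membrane_noise_sd < 0 or self.sample_jitter_sd < 0:
            raise ValueError("noise SDs must be >= 0")

    @property
    def silent(self) -> bool:
        return self.membrane_noise_sd == 0 and self.sample_jitter_sd == 0


def decalibrate(params: NeuronParams, spec: MismatchSpec) -> NeuronParams:
    """Draw mismatched per-neuron parameters around their calibration targets.

    Each selected parameter of each neuron is redrawn from a normal
    distribution centred on its target with SD ``sigma_d`` times the target.
    Draws of time constants are rejected and redrawn until positive, so the
    result is always integrable; thresholds may legitimately fall below the
    leak potential (leak-over-threshold, see
    :meth:`NeuronParams.leak_over_threshold`).  Deterministic given
    ``spec.seed``.
    """
    out = params.copy()
    if spec.sigma_d == 0:
        return out
    rng = np.random.default_rng(spec.seed)
    for name in ("tau_mem", "tau_syn", "threshold"):
        if name not in spec.which:
            continue
        target = getattr(params, name)
        finite = np.isfinite(target)  # non-spiking units (threshold = inf) keep theirs
        drawn = rng.normal(target[finite], spec.sigma_d * np.abs(target[finite]))
        if name in ("tau_mem", "tau_syn"):
            bad = drawn <= 0
            attempts = 0
            while np.any(bad):
                attempts += 1
                if attempts > 1000:
                    raise RuntimeError(
                        "decalibrate: could not draw positive time constants "
                        f"for {name} after 1000 redraws (sigma_d={spec.sigma_d})"
                    )
                drawn[bad] = rng.normal(
                    target[finite][bad], spec.sigma_d * np.abs(target[finite][bad])
                )
                bad = drawn <= 0
        new = target.copy()
        new[finite] = drawn
        setattr(out, name, new)
    return out


# ---------------------------------------------------------------------------
# weights
# ---------------------------------------------------------------------------


def quantize_weights(w: np.ndarray, scale: float) -> np.ndarray:
    """Scale, round, and crop a weight matrix to the substrate's signed 7-bit
    resolution: ``clip(round(w * scale), -63, +63)``.  Saturation is the
    defined behaviour for out-of-range values."""
    if scale <= 0:
        raise ValueError("scale must be positive")
    return np.clip(np.rint(np.asarray(w, dtype=float) * scale), -W_MAX, W_MAX).astype(np.int32)


@dataclass
class NetworkWeights:
    """Signed input/recurrent/output weight matrices, oriented (post, pre).

    ``w_in``: (n_hidden, n_in); ``w_rec``: (n_hidden, n_hidden) or ``None``
    for feed-forward networks; ``w_out``: (n_out, n_hidden).  This is the
    float (trainable) view; the deployed integer view is produced by
    :func:`quantize_weights` / the training module's weight-scaling rule.
    """

    w_in: np.ndarray
    w_out: np.ndarray
    w_rec: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.w_in = np.asarray(self.w_in, dtype=float)
        self.w_out = np.asarray(self.w_out, dtype=float)
        if self.w_rec is not None:
            self.w_rec = np.asarray(self.w_rec, dtype=float)
            if self.w_rec.shape != (self.n_hidden, self.n_hidden):
                raise ValueError("w_rec must be square (n_hidden, n_hidden)")
        if self.w_out.shape[1] != self.n_hidden:
            raise ValueError("w_out second axis must match n_hidden")

    @property
    def n_in(self) -> int:
        return self.w_in.shape[1]

    @property
    def n_hidden(self) -> int:
        return self.w_in.shape[0]

    @property
    def n_out(self) -> int:
        return self.w_out.shape[0]

    def copy(self) -> "NetworkWeights":
        return NetworkWeights(
            self.w_in.copy(),
            self.w_out.copy(),
            None if self.w_rec is None else self.w_rec.copy(),
        )

    def check_fan_in(self, limit: int = 256) -> None:
        """Raise if any hidden neuron integrates more than ``limit`` synapses."""
        fan = np.count_nonzero(self.w_in, axis=1)
        if self.w_rec is not None:
            fan = fan + np.count_nonzero(self.w_rec, axis=1)
        if np.any(fan > limit):
            raise ValueError(f"hidden fan-in exceeds limit {limit} (max {fan.max()})")


# ---------------------------------------------------------------------------
# recordings
# ---------------------------------------------------------------------------


@dataclass
class SubstrateRecording:
    """Sampled observables from one forward pass over a batch.

    ``v_sampled``/``spikes`` live on the coarse grid ``t = 0..T-1`` with step
    ``grid_dt`` (shapes ``[batch, T, n]``); ``spike_times`` keeps the raw
    fine-resolution events per sample as ``(times, units)`` arrays.  Every raw
    spike time falls into exactly one grid bin.
    """

    v_sampled: np.ndarray
    spikes: np.ndarray
    spike_times: list
    grid_dt: float
    seed: int = 0

    @property
    def n_steps(self) -> int:
        return self.v_sampled.shape[1]

    @property
    def n_units(self) -> int:
        return self.v_sampled.shape[2]

    def to_hdf5(self, path, group: str = "recording") -> None:
        with h5py.File(path, "a") as f:
            if group in f:
                del f[group]
            g = f.create_group(group)
            g.create_dataset("v_sampled", data=self.v_sampled)
            g.create_dataset("spikes", data=self.spikes.astype(np.uint8))
            g.attrs["grid_dt"] = self.grid_dt
            g.attrs["seed"] = self.seed
            ev = g.create_group("spike_times")
            for b, (times, units) in enumerate(self.spike_times):
                gb = ev.create_group(str(b))
                gb.create_dataset("times", data=np.asarray(times, dtype=float))
                gb.create_dataset("units", data=np.asarray(units, dtype=np.int64))

    @classmethod
    def from_hdf5(cls, path, group: str = "recording") -> "SubstrateRecording":
        with h5py.File(path, "r") as f:
            g = f[group]
            ev = g["spike_times"]
            spike_times = [
                (ev[str(b)]["times"][()], ev[str(b)]["units"][()])
                for b in range(len(ev))
            ]
            return cls(
                v_sampled=g["v_sampled"][()],
                spikes=g["spikes"][()].astype(np.uint8),
                spike_times=spike_times,
                grid_dt=float(g.attrs["grid_dt"]),
                seed=int(g.attrs["seed"]),
            )


# ---------------------------------------------------------------------------
# the substrate
# ---------------------------------------------------------------------------


def _propagators(params: NeuronParams, delta: float, dt: float, mode: str):
    """Per-neuron decay factors and current-coupling coefficient for one fine
    step.

    In ``"exact"`` mode the coefficient is the exact ODE propagator entry for
    a current that decays with ``tau_syn`` within the step; current units are
    chosen such that a unit model current integrates one threshold unit per
    sampling interval on a non-leaky membrane (division by ``dt``).  In
    ``"grid"`` mode the model recursion is used literally: coupling 1 at step
    ``dt``.
    """
    lam_m = np.exp(-delta / params.tau_mem)
    lam_s = np.exp(-delta / params.tau_syn)
    if mode == "grid":
        b = np.ones_like(lam_m)
    else:
        inv_diff = 1.0 / params.tau_mem - 1.0 / params.tau_syn
        with np.errstate(divide="ignore", invalid="ignore"):
            b = (lam_s - lam_m) / (inv_diff * dt)
        degenerate = np.abs(inv_diff) < 1e-12
        if np.any(degenerate):
            b = np.where(degenerate, delta * lam_m / dt, b)
    return lam_m, lam_s, b


@numba.njit(cache=False)
def _forward_kernel(
    v, i, hold, lam_m, lam_s, bcoef, bias_drive, thr, v_reset, refr,
    x_in, R_T, noise_bin, use_noise, K, s_fine, v_samp, record_fine, fine,
):  # pragma: no cover - exercised through AnalogSubstrate.forward
    """Hot loop of the emulation over one homogeneously indexed population
    (hidden followed by output units; output thresholds are +inf)."""
    B, T, N = x_in.shape
    H = R_T.shape[0]
    s_bin = np.zeros((B, H))
    for n in range(T):
        for b in range(B):
            for m in range(N):
                v_samp[b, n, m] = v[b, m]
        if use_noise:
            for b in range(B):
                for m in range(N):
                    v[b, m] += noise_bin[b, n, m]
        for k in range(K):
            j = n * K + k + 1
            for b in range(B):
                for m in range(N):
                    vv = v[b, m] * lam_m[m] + bcoef[m] * i[b, m] + bias_drive[m]
                    if hold[b, m] > 0:
                        vv = v_reset[m]
                        hold[b, m] -= 1
                    if vv >= thr[m]:
                        s_fine[b, j, m] = 1
                        hold[b, m] = refr + 1
                    v[b, m] = vv
                    i[b, m] = i[b, m] * lam_s[m]
                    if record_fine:
                        fine[b, j, m] = vv
        # events of bin n are complete (fine indices n*K .. (n+1)*K - 1,
        # i.e. times within [n, n+1) * dt): route them and inject inputs
        for b in range(B):
            for h in range(H):
                sb = 0.0
                for k in range(K):
                    if s_fine[b, n * K + k, h] == 1:
                        sb = 1.0
                        break
                s_bin[b, h] = sb
        routed = np.dot(s_bin, R_T)
        for b in range(B):
            for m in range(N):
                i[b, m] += x_in[b, n, m] + routed[b, m]


class AnalogSubstrate:
    """Emulated analog LIF substrate with mismatch, noise and sampled readout.

    Parameters
    ----------
    n_inputs, n_hidden, n_outputs:
        Layer sizes.  Hidden neurons spike; the output layer is non-spiking
        (threshold at infinity) and read out as leaky integrator traces.
    dt:
        Sampling-grid step (model time units).  Observables are returned on
        this grid.
    substeps:
        Fine integration steps per sampling interval (``delta = dt/substeps``).
    integration:
        ``"exact"`` or ``"grid"`` (see module docstring).
    hidden_params, output_params:
        Calibration targets.  Defaults: ``tau_mem = 20 dt``, ``tau_syn =
        10 dt``, threshold 1 (hidden) / infinity (output), leak and reset 0.
    mismatch:
        Optional :class:`MismatchSpec`; applied once at construction, frozen
        for the lifetime of the instance (fixed-pattern deviations).
    noise:
        Optional :class:`NoiseSpec`; redrawn every trial.
    """

    def __init__(
        self,
        n_inputs: int,
        n_hidden: int,
        n_outputs: int,
        dt: float = 1.0,
        substeps: int = 10,
        integration: str = "exact",
        hidden_params: Optional[NeuronParams] = None,
        output_params: Optional[NeuronParams] = None,
        mismatch: Optional[MismatchSpec] = None,
        noise: Optional[NoiseSpec] = None,
        fan_in_limit: int = 256,
        refractory_substeps: int = 0,
        seed: int = 0,
    ) -> None:
        if integration not in ("exact", "grid"):
            raise ValueError("integration must be 'exact' or 'grid'")
        if integration == "grid" and substeps != 1:
            raise ValueError("grid integration requires substeps=1")
        self.n_inputs = n_inputs
        self.n_hidden = n_hidden
        self.n_outputs = n_outputs
        self.dt = float(dt)
        self.substeps = int(substeps)
        self.integration = integration
        self.fan_in_limit = fan_in_limit
        self.refractory_substeps = int(refractory_substeps)
        self.seed = seed

        self.target_hidden = hidden_params or NeuronParams.homogeneous(
            n_hidden, tau_mem=20 * dt, tau_syn=10 * dt
        )
        self.target_output = output_params or NeuronParams.homogeneous(
            n_outputs, tau_mem=20 * dt, tau_syn=10 * dt, threshold=np.inf
        )
        self.mismatch = mismatch
        if mismatch is not None and mismatch.sigma_d > 0:
            self.hidden_params = decalibrate(self.target_hidden, mismatch)
            self.output_params = decalibrate(
                self.target_output, replace(mismatch, seed=mismatch.seed + 1)
            )
        else:
            self.hidden_params = self.target_hidden.copy()
            self.output_params = self.target_output.copy()
        self.noise = noise
        self._trial_rng = np.random.default_rng(seed)
        self._state = None  # (v_h, i_h, v_o, i_o, hold_h) between calls

    # -- configuration helpers -------------------------------------------------

    @classmethod
    def ideal(
        cls, n_inputs: int, n_hidden: int, n_outputs: int, dt: float = 1.0, **kw
    ) -> "AnalogSubstrate":
        """Reference configuration: grid-matched integration, no mismatch, no
        noise.  In this configuration the emulation coincides exactly with the
        discrete model used by the training graph."""
        kw.setdefault("substeps", 1)
        kw.setdefault("integration", "grid")
        return cls(n_inputs, n_hidden, n_outputs, dt=dt, mismatch=None, noise=None, **kw)

    def reseed_trials(self, seed: int) -> None:
        """Reset the trial-noise stream (fixed-pattern mismatch is untouched)."""
        self._trial_rng = np.random.default_rng(seed)

    def leak_over_threshold(self) -> np.ndarray:
        """Flags for hidden neurons rendered dysfunctional by decalibration."""
        return self.hidden_params.leak_over_threshold()

    def reset_state(self) -> "AnalogSubstrate":
        """Reset membranes to the leak potential and clamp synaptic currents
        to baseline, enabling back-to-back sample presentation.  Idempotent."""
        self._state = None
        return self

    # -- forward emulation -----------------------------------------------------

    def forward(
        self,
        x: np.ndarray,
        weights: NetworkWeights,
        i_bias: Optional[np.ndarray] = None,
        reset: bool = True,
        record_fine: bool = False,
    ):
        """Emulate a batch of stimuli and return sampled recordings.

        Parameters
        ----------
        x:
            Dense input spikes, shape ``[batch, T, n_inputs]`` (binary).
        weights:
            Deployed weights in model units (already de-scaled from their
            integer representation by the caller).
        i_bias:
            Optional constant current drive per hidden neuron (model units);
            used for characterisation (f-I behaviour), not training.
        reset:
            Reset state before the batch (default).  With ``reset=False`` the
            dynamics continue from the previous call's final state.
        record_fine:
            Additionally return the fine-resolution hidden membrane trace
            (for characterisation tests).

        Returns
        -------
        (hidden, output) : tuple of :class:`SubstrateRecording`
            and, if ``record_fine``, a third array ``[batch, T*substeps+1,
            n_hidden]`` of fine membrane values.
        """
        x = np.asarray(x)
        if x.ndim != 3 or x.shape[2] != self.n_inputs:
            raise ValueError("x must have shape [batch, T, n_inputs]")
        weights.check_fan_in(self.fan_in_limit)
        B, T, _ = x.shape
        K = self.substeps
        delta = self.dt / K
        H, O = self.n_hidden, self.n_outputs
        N = H + O
        hp, op = self.hidden_params, self.output_params

        lam_m_h, lam_s_h, b_h = _propagators(hp, delta, self.dt, self.integration)
        lam_m_o, lam_s_o, b_o = _propagators(op, delta, self.dt, self.integration)
        lam_m = np.concatenate([lam_m_h, lam_m_o])
        lam_s = np.concatenate([lam_s_h, lam_s_o])
        bcoef = np.concatenate([b_h, b_o])
        thr = np.concatenate([hp.threshold, np.full(O, np.inf)])
        v_reset = np.concatenate([hp.v_reset, op.v_reset])

        if reset or self._state is None or self._state[0].shape[0] != B:
            v = np.concatenate([np.tile(hp.v_leak, (B, 1)), np.tile(op.v_leak, (B, 1))], axis=1)
            i = np.zeros((B, N))
            hold = np.zeros((B, N), dtype=np.int64)
        else:
            v, i, hold = (a.copy() for a in self._state)

        noise = self.noise
        noisy = noise is not None and noise.membrane_noise_sd > 0
        jitter = noise is not None and noise.sample_jitter_sd > 0
        rng = self._trial_rng

        # per-bin noise injection with the stationary-SD convention
        if noisy:
            tau_full = np.concatenate([hp.tau_mem, op.tau_mem])
            sd_bin = noise.membrane_noise_sd * np.sqrt(1.0 - np.exp(-2.0 * self.dt / tau_full))
            noise_bin = rng.normal(0.0, 1.0, size=(B, T, N)) * sd_bin
        else:
            noise_bin = np.zeros((1, 1, 1))

        bias_drive = np.zeros(N)
        if i_bias is not None:
            bias = np.broadcast_to(np.asarray(i_bias, dtype=float), (H,))
            if self.integration == "grid":
                bias_drive[:H] = bias
            else:
                # constant currents use the exact constant-input propagator
                bias_drive[:H] = bias * hp.tau_mem * (1.0 - lam_m_h) / self.dt

        # drive per coarse bin: external input onto hidden units, and the
        # routing matrix mapping binned hidden spikes to all units
        x_in = np.zeros((B, T, N))
        x_in[:, :, :H] = (
            x.reshape(-1, x.shape[2]).astype(float) @ weights.w_in.T
        ).reshape(B, T, H)
        R = np.zeros((N, H))
        if weights.w_rec is not None:
            R[:H] = weights.w_rec
        R[H:] = weights.w_out
        R_T = np.ascontiguousarray(R.T)

        # spikes per fine index (index j corresponds to time j * delta);
        # index 0 is the initial state and cannot spike
        s_fine = np.zeros((B, T * K + 1, N), dtype=np.uint8)
        v_samp = np.empty((B, T, N))
        fine = np.empty((B, T * K + 1, N)) if record_fine else np.empty((1, 1, 1))
        if record_fine:
            fine[:, 0] = v

        _forward_kernel(
            v, i, hold, lam_m, lam_s, bcoef, bias_drive, thr, v_reset,
            self.refractory_substeps, x_in, R_T,
            np.ascontiguousarray(noise_bin, dtype=float), noisy, K,
            s_fine, v_samp, record_fine, fine,
        )
        if not (np.all(np.isfinite(v)) and np.all(np.isfinite(i))):
            raise FloatingPointError(
                "non-finite substrate state; check weights/parameters for "
                "pathological configuration"
            )

        self._state = (v, i, hold)

        # coarse binning: fine index j -> grid bin floor(j / K); the final
        # fine index T*K falls outside the window and is dropped
        s_grid = s_fine[:, : T * K, :H].reshape(B, T, K, H).max(axis=2).astype(np.uint8)
        v_samp_h = v_samp[:, :, :H]
        v_samp_o = v_samp[:, :, H:]
        if jitter:
            v_samp_h = v_samp_h + rng.normal(0.0, noise.sample_jitter_sd, v_samp_h.shape)
            v_samp_o = v_samp_o + rng.normal(0.0, noise.sample_jitter_sd, v_samp_o.shape)

        spike_times = []
        for b in range(B):
            j_idx, units = np.nonzero(s_fine[b, : T * K, :H])
            spike_times.append((j_idx * delta, units.astype(np.int64)))

        hidden = SubstrateRecording(v_samp_h, s_grid, spike_times, self.dt, self.seed)
        empty = [(np.empty(0), np.empty(0, dtype=np.int64))] * B
        output = SubstrateRecording(
            v_samp_o, np.zeros((B, T, O), dtype=np.uint8), empty, self.dt, self.seed
        )
        if record_fine:
            return hidden, output, fine[:, :, :H]
        return hidden, output
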