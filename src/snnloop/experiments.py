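"""Reproducible experiment runners.

Each runner consumes an :class:`~snnloop.config.ExperimentConfig`, derives
all randomness from the config seed and deterministic per-cell hashes,
writes machine-readable CSV tables plus the resolved config to its output
directory, and returns the result table.  Sweeps are resumable: a cell whose
row already exists in the output table is skipped.

The four headline experiments:

* ``run_selfcal_sweep`` — ITL training versus software-trained weight
  transfer across decalibration levels (does learning self-calibrate?),
* ``run_sparsity_sweep`` — accuracy versus hidden spike count across the
  sparsity-regularizer strength,
* ``run_robustness`` — test-error inflation under post-training ablation of
  hidden units, with and without dropout during training,
* ``run_recurrence_control`` — trained recurrent network versus the
  shuffled-frozen-recurrent control on the order-sensitive temporal task,

plus ``run_train`` (single run) and ``run_latency_probe`` (accuracy of the
max-over-time decision when output traces are truncated to ``[0, T)``).
"""

from __future__ import annotations

import zlib
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .config import ExperimentConfig, archive_config
from .encoders import LatencyCodeSpec, SpikeBatch, latency_encode
from .substrate import AnalogSubstrate, MismatchSpec, NeuronParams, NoiseSpec
from .synthetic_data import SyntheticTaskSpec, make_latency_images, make_temporal_patterns, train_test_split
from .training import (
    SpikingNetClassifier,
    ablate_hidden,
    shuffle_recurrent,
    weight_transfer,
)

__all__ = [
    "build_dataset",
    "build_substrate",
    "build_classifier",
    "run_train",
    "run_selfcal_sweep",
    "run_sparsity_sweep",
    "run_robustness",
    "run_recurrence_control",
    "latency_probe",
    "run_latency_probe",
]

_CSV_FMT = "%.10g"


def cell_seed(base: int, *parts) -> int:
    """Deterministic, independent sub-seed for a sweep cell (< 2**31)."""
    tag = "|".join(str(p) for p in parts)
    return (int(base) ^ zlib.crc32(tag.encode())) & 0x7FFFFFFF


# ---------------------------------------------------------------------------
# builders
# ---------------------------------------------------------------------------


def build_dataset(cfg: ExperimentConfig, seed: int):
    """Generate (or load) the task data; returns dense spike tensors
    ``(x_train, x_test, y_train, y_test)`` on the config grid."""
    t = cfg.task
    if t.kind == "latency_images":
        spec = SyntheticTaskSpec(
            task="latency_images",
            n_classes=t.n_classes,
            n_channels=t.n_channels,
            samples_per_class=t.samples_per_class,
            pixel_noise_sd=t.pixel_noise_sd,
            rotation_max_deg=t.rotation_max_deg,
            duration=t.duration,
            dt=cfg.substrate.dt,
            seed=seed,
        )
        images, y = make_latency_images(spec)
        im_tr, im_te, y_tr, y_te = train_test_split(
            images, y, t.held_out_fraction, seed=seed + 1, disjoint_variant=t.disjoint_split
        )
        code = LatencyCodeSpec(t.tau_in, t.theta_in, t.t_max)
        enc = lambda im: latency_encode(
            im.reshape(im.shape[0], -1), code, dt=cfg.substrate.dt, duration=t.duration
        ).dense.astype(float)
        return enc(im_tr), enc(im_te), y_tr, y_te
    if t.dataset_path:
        if not Path(t.dataset_path).exists():
            raise FileNotFoundError(f"dataset file not found: {t.dataset_path}")
        batch, y = SpikeBatch.from_hdf5(t.dataset_path)
    else:
        spec = SyntheticTaskSpec(
            task="temporal_patterns",
            n_classes=t.n_classes,
            n_channels=t.n_channels,
            samples_per_class=t.samples_per_class,
            time_jitter_sd=t.time_jitter_sd,
            channel_jitter_sd=t.channel_jitter_sd,
            deletion_p=t.deletion_p,
            background_events=t.background_events,
            anchors_per_class=t.anchors_per_class,
            duration=t.duration,
            dt=cfg.substrate.dt,
            seed=seed,
        )
        batch, y = make_temporal_patterns(spec)
    b_tr, b_te, y_tr, y_te = train_test_split(
        batch, y, t.held_out_fraction, seed=seed + 1, disjoint_variant=t.disjoint_split
    )
    return b_tr.dense.astype(float), b_te.dense.astype(float), y_tr, y_te


def build_substrate(
    cfg: ExperimentConfig, n_in: int, n_out: int, seed: int, sigma_d: Optional[float] = None
) -> Optional[AnalogSubstrate]:
    """Instantiate the substrate described by the config (or ``None`` for
    software-only runs).  ``sigma_d`` overrides the config's decalibration."""
    s = cfg.substrate
    if not s.enabled:
        return None
    sigma = s.mismatch_sigma if sigma_d is None else sigma_d
    mismatch = (
        MismatchSpec(sigma, tuple(s.mismatch_which), seed=cell_seed(seed, "mismatch"))
        if sigma > 0
        else None
    )
    noise = (
        NoiseSpec(s.membrane_noise_sd, s.sample_jitter_sd, seed=seed)
        if (s.membrane_noise_sd > 0 or s.sample_jitter_sd > 0)
        else None
    )
    hidden = NeuronParams.homogeneous(cfg.network.n_hidden, s.tau_mem * s.dt, s.tau_syn * s.dt)
    output = NeuronParams.homogeneous(n_out, s.tau_mem * s.dt, s.tau_syn * s.dt, threshold=np.inf)
    return AnalogSubstrate(
        n_in,
        cfg.network.n_hidden,
        n_out,
        dt=s.dt,
        substeps=s.substeps,
        integration=s.integration,
        hidden_params=hidden,
        output_params=output,
        mismatch=mismatch,
        noise=noise,
        fan_in_limit=s.fan_in_limit,
        refractory_substeps=s.refractory_substeps,
        seed=seed,
    )


def build_classifier(
    cfg: ExperimentConfig, substrate: Optional[AnalogSubstrate], seed: int, **overrides
) -> SpikingNetClassifier:
    params = dict(
        n_hidden=cfg.network.n_hidden,
        recurrent=cfg.network.recurrent,
        tau_mem=cfg.substrate.tau_mem * cfg.substrate.dt,
        tau_syn=cfg.substrate.tau_syn * cfg.substrate.dt,
        dt=cfg.substrate.dt,
        beta=cfg.loss.beta,
        surrogate_form=cfg.loss.surrogate_form,
        loss_mode=cfg.loss.mode,
        rho_a=cfg.loss.rho_a,
        rho_b=cfg.loss.rho_b,
        rho_r=cfg.loss.rho_r,
        theta_r=cfg.loss.theta_r,
        lr=cfg.training.lr,
        lr_decay=cfg.training.lr_decay,
        n_epochs=cfg.training.n_epochs,
        batch_size=cfg.training.batch_size,
        shuffle=cfg.training.shuffle,
        dropout_rate=cfg.training.dropout_rate,
        grad_clip=cfg.training.grad_clip,
        sigma_w=cfg.network.sigma_w,
        substrate=substrate,
        quantize=cfg.network.quantize,
        scale_hidden=cfg.network.scale_hidden,
        random_state=seed,
    )
    params.update(overrides)
    return SpikingNetClassifier(**params)


# ---------------------------------------------------------------------------
# runners
# ---------------------------------------------------------------------------


def _write(df: pd.DataFrame, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format=_CSV_FMT)


def run_train(cfg: ExperimentConfig, out_dir, seed: Optional[int] = None) -> dict:
    """Single training run; writes per-epoch ``metrics.csv`` and a summary
    row, returns the summary."""
    out = Path(out_dir)
    seed = cfg.seed if seed is None else seed
    archive_config(cfg, out)
    x_tr, x_te, y_tr, y_te = build_dataset(cfg, cell_seed(seed, "data"))
    substrate = build_substrate(cfg, x_tr.shape[2], len(np.unique(y_tr)), seed)
    clf = build_classifier(cfg, substrate, seed)
    clf.fit(x_tr, y_tr)
    _write(clf.history_, out / "metrics.csv")
    summary = {
        "seed": seed,
        "train_accuracy": float(clf.score(x_tr, y_tr)),
        "test_accuracy": float(clf.score(x_te, y_te)),
        "hidden_spikes_per_sample": float(np.mean(clf.hidden_spike_counts(x_te))),
    }
    _write(pd.DataFrame([summary]), out / "summary.csv")
    return summary


def _resumable(path: Path, key_cols):
    if path.exists():
        done = pd.read_csv(path)
        keys = {tuple(r) for r in done[key_cols].itertuples(index=False)}
        return done, keys
    return None, set()


def run_selfcal_sweep(cfg: ExperimentConfig, out_dir) -> pd.DataFrame:
    """Grid over decalibration sigma_d x {itl, transfer} x seeds.

    For each replicate seed one network is trained in software; its weights
    are transferred (quantized, no fine-tuning) onto each decalibrated
    substrate.  Independently, ITL training is run on each substrate while
    the graph keeps assuming ideal dynamics.  Writes ``selfcal.csv`` and a
    median summary ``selfcal_summary.csv``."""
    out = Path(out_dir)
    archive_config(cfg, out)
    path = out / "selfcal.csv"
    done, keys = _resumable(path, ["sigma_d", "mode", "seed"])
    rows = [] if done is None else done.to_dict("records")
    for seed in cfg.experiment.seeds:
        data_seed = cell_seed(cfg.seed, "selfcal-data", seed)
        x_tr, x_te, y_tr, y_te = build_dataset(cfg, data_seed)
        n_in, n_out = x_tr.shape[2], len(np.unique(y_tr))
        software = None
        for sigma in cfg.experiment.sigma_grid:
            sub_seed = cell_seed(cfg.seed, "selfcal-sub", seed, sigma)
            if (sigma, "itl", seed) not in keys:
                sub = build_substrate(cfg, n_in, n_out, sub_seed, sigma_d=sigma)
                clf = build_classifier(cfg, sub, cell_seed(cfg.seed, "selfcal-itl", seed, sigma))
                clf.fit(x_tr, y_tr)
                rows.append(
                    dict(sigma_d=sigma, mode="itl", seed=seed,
                         train_accuracy=float(clf.score(x_tr, y_tr)),
                         test_accuracy=float(clf.score(x_te, y_te)))
                )
                _write(pd.DataFrame(rows), path)
            if (sigma, "transfer", seed) not in keys:
                if software is None:
                    software = build_classifier(
                        cfg, None, cell_seed(cfg.seed, "selfcal-sw", seed)
                    ).fit(x_tr, y_tr)
                sub = build_substrate(cfg, n_in, n_out, sub_seed, sigma_d=sigma)
                res = weight_transfer(software, sub, x_te, y_te)
                res_tr = weight_transfer(software, sub, x_tr, y_tr)
                rows.append(
                    dict(sigma_d=sigma, mode="transfer", seed=seed,
                         train_accuracy=res_tr["accuracy"],
                         test_accuracy=res["accuracy"])
                )
                _write(pd.DataFrame(rows), path)
    df = pd.DataFrame(rows)
    summary = (
        df.groupby(["sigma_d", "mode"])["test_accuracy"].median().reset_index()
    )
    _write(summary, out / "selfcal_summary.csv")
    return df


def run_sparsity_sweep(cfg: ExperimentConfig, out_dir) -> pd.DataFrame:
    """Grid over the sparsity-regularizer strength rho_b x seeds; records
    mean hidden spikes per test sample and test accuracy."""
    out = Path(out_dir)
    archive_config(cfg, out)
    path = out / "sparsity.csv"
    done, keys = _resumable(path, ["rho_b", "seed"])
    rows = [] if done is None else done.to_dict("records")
    for seed in cfg.experiment.seeds:
        x_tr, x_te, y_tr, y_te = build_dataset(cfg, cell_seed(cfg.seed, "sparsity-data", seed))
        n_in, n_out = x_tr.shape[2], len(np.unique(y_tr))
        for rho_b in cfg.experiment.rho_b_grid:
            if (rho_b, seed) in keys:
                continue
            sub = build_substrate(cfg, n_in, n_out, cell_seed(cfg.seed, "sp-sub", seed, rho_b))
            clf = build_classifier(
                cfg, sub, cell_seed(cfg.seed, "sp-clf", seed, rho_b), rho_b=rho_b
            )
            clf.fit(x_tr, y_tr)
            rows.append(
                dict(
                    rho_b=rho_b,
                    seed=seed,
                    test_accuracy=float(clf.score(x_te, y_te)),
                    hidden_spikes_per_sample=float(np.mean(clf.hidden_spike_counts(x_te))),
                )
            )
            _write(pd.DataFrame(rows), path)
    df = pd.DataFrame(rows)
    summary = (
        df.groupby("rho_b")[["hidden_spikes_per_sample", "test_accuracy"]]
        .median()
        .reset_index()
    )
    _write(summary, out / "sparsity_summary.csv")
    return df


def run_robustness(cfg: ExperimentConfig, out_dir) -> pd.DataFrame:
    """Train with each dropout rate, then ablate growing fractions of hidden
    units and record the test-error inflation relative to no ablation."""
    out = Path(out_dir)
    archive_config(cfg, out)
    path = out / "robustness.csv"
    done, keys = _resumable(path, ["dropout_rate", "ablation_fraction", "seed"])
    rows = [] if done is None else done.to_dict("records")
    for seed in cfg.experiment.seeds:
        x_tr, x_te, y_tr, y_te = build_dataset(cfg, cell_seed(cfg.seed, "rob-data", seed))
        n_in, n_out = x_tr.shape[2], len(np.unique(y_tr))
        for rate in cfg.experiment.dropout_rates:
            if all((rate, f, seed) in keys for f in cfg.experiment.ablation_fractions):
                continue
            sub = build_substrate(cfg, n_in, n_out, cell_seed(cfg.seed, "rob-sub", seed, rate))
            clf = build_classifier(
                cfg, sub, cell_seed(cfg.seed, "rob-clf", seed, rate), dropout_rate=rate
            )
            clf.fit(x_tr, y_tr)
            base_err = None
            for frac in cfg.experiment.ablation_fractions:
                # average over several ablation draws to reduce draw noise
                errs = []
                for rep in range(3 if frac > 0 else 1):
                    ablated = ablate_hidden(
                        clf.weights_,
                        frac,
                        cell_seed(cfg.seed, "rob-abl", seed, rate, frac, rep),
                    )
                    probe = build_classifier(
                        cfg, sub, cell_seed(cfg.seed, "rob-clf", seed, rate),
                        dropout_rate=0.0,
                    ).adopt(ablated, clf.classes_)
                    errs.append(1.0 - float(probe.score(x_te, y_te)))
                err = float(np.mean(errs))
                if frac == 0.0:
                    base_err = err
                rows.append(
                    dict(
                        dropout_rate=rate,
                        ablation_fraction=frac,
                        seed=seed,
                        test_error=err,
                        inflation=err - base_err,  # absolute error increase
                    )
                )
            _write(pd.DataFrame(rows), path)
    df = pd.DataFrame(rows)
    summary = (
        df.groupby(["dropout_rate", "ablation_fraction"])[["test_error", "inflation"]]
        .median()
        .reset_index()
    )
    _write(summary, out / "robustness_summary.csv")
    return df


def run_recurrence_control(cfg: ExperimentConfig, out_dir) -> pd.DataFrame:
    """Trained-recurrent network versus the shuffled-frozen-recurrent control
    on the temporal task: the control starts from the trained network's
    recurrent weights, permuted and frozen, and retrains only input and
    readout weights."""
    out = Path(out_dir)
    archive_config(cfg, out)
    path = out / "recurrence.csv"
    done, keys = _resumable(path, ["mode", "seed"])
    rows = [] if done is None else done.to_dict("records")
    for seed in cfg.experiment.seeds:
        x_tr, x_te, y_tr, y_te = build_dataset(cfg, cell_seed(cfg.seed, "rec-data", seed))
        n_in, n_out = x_tr.shape[2], len(np.unique(y_tr))
        if (("trained", seed) in keys) and (("frozen", seed) in keys):
            continue
        sub = build_substrate(cfg, n_in, n_out, cell_seed(cfg.seed, "rec-sub", seed))
        clf = build_classifier(cfg, sub, cell_seed(cfg.seed, "rec-clf", seed), recurrent=True)
        clf.fit(x_tr, y_tr)
        rows.append(dict(mode="trained", seed=seed,
                         test_error=1.0 - float(clf.score(x_te, y_te))))
        shuffled = shuffle_recurrent(clf.weights_, cell_seed(cfg.seed, "rec-shuf", seed))
        sub2 = build_substrate(cfg, n_in, n_out, cell_seed(cfg.seed, "rec-sub", seed))
        control = build_classifier(
            cfg, sub2, cell_seed(cfg.seed, "rec-ctl", seed),
            recurrent=True, train_recurrent=False,
        )
        control.fit(x_tr, y_tr, initial_weights=shuffled)
        rows.append(dict(mode="frozen", seed=seed,
                         test_error=1.0 - float(control.score(x_te, y_te))))
        _write(pd.DataFrame(rows), path)
    df = pd.DataFrame(rows)
    _write(df.groupby("mode")["test_error"].median().reset_index(), out / "recurrence_summary.csv")
    return df


# ---------------------------------------------------------------------------
# latency probe
# ---------------------------------------------------------------------------


def latency_probe(clf: SpikingNetClassifier, X, y) -> pd.DataFrame:
    """Accuracy of the max-over-time decision when the output traces are
    restricted to growing intervals ``[0, T)``.

    Returns a table with columns ``horizon`` (grid steps) and ``accuracy``;
    the curve reaches its full-trace value at the classification latency.
    """
    traces = clf.output_traces(X)
    y = np.asarray(y)
    T = traces.shape[1]
    rows = []
    for horizon in range(1, T + 1):
        scores = traces[:, :horizon, :].max(axis=1)
        preds = clf.classes_[scores.argmax(axis=1)]
        rows.append(dict(horizon=horizon, accuracy=float(np.mean(preds == y))))
    return pd.DataFrame(rows)


def run_latency_probe(cfg: ExperimentConfig, out_dir) -> pd.DataFrame:
    """Train one network per the config, then probe its decision latency on
    the test set; writes ``latency_probe.csv``."""
    out = Path(out_dir)
    archive_config(cfg, out)
    seed = cfg.seed
    x_tr, x_te, y_tr, y_te = build_dataset(cfg, cell_seed(seed, "data"))
    sub = build_substrate(cfg, x_tr.shape[2], len(np.unique(y_tr)), seed)
    clf = build_classifier(cfg, sub, seed)
    clf.fit(x_tr, y_tr)
    df = latency_probe(clf, x_te, y_te)
    final = df["accuracy"].iloc[-1]
    reached = df[df["accuracy"] >= final]["horizon"].iloc[0]
    df.attrs["earliest_peak_horizon"] = int(reached)
    _write(df, out / "latency_probe.csv")
    _write(
        pd.DataFrame([{"earliest_peak_horizon": reached, "final_accuracy": final}]),
        out / "latency_probe_summary.csv",
    )
    return df
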