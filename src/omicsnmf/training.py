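"""Adversarial training loop and missing-sample imputation.

One generator update is preceded by several critic updates (weight-clipped
Wasserstein critic).  The three generator terms play distinct roles:

* the adversarial term and the centroid-consistency term see every batch row,
  including samples whose target profile is missing — this is how unlabeled
  (target-less) samples contribute to training;
* the mean-squared-error term anchors reconstruction and is computed only on
  rows whose target profile is observed.

Ablation modes reproduce the baselines built from the same trainer:
``nmf_only`` drops the MSE anchor, ``mse_only`` drops both the critic and the
centroid loss and is then an ordinary feed-forward regression network.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd

from .io import OmicsMatrix, PairedOmicsDataset, SplitPlan
from .model import (
    MLP,
    CriticSpec,
    GeneratorSpec,
    RMSProp,
    _generator_loss_full,
    build_critic,
    build_generator,
    clip_weights,
    generate,
    load_checkpoint,
    save_checkpoint,
)
from .nmf import reference_centroids

__all__ = [
    "TrainingConfig",
    "TrainedImputer",
    "CompletedMatrix",
    "train",
    "impute",
    "grid_search",
]

MODES = ("full", "nmf_only", "mse_only")


@dataclass(frozen=True)
class TrainingConfig:
    """Hyperparameters of one training run.

    ``alpha`` weights the centroid-consistency term, ``beta`` the MSE term;
    ``c`` is the cluster count of the NMF decomposition (default 10).  The
    critic is updated ``critic_steps_per_gen_step`` times per generator
    update with weights clipped into ``[-clip_value, clip_value]``, and both
    networks use RMSprop at ``learning_rate``.
    """

    alpha: float = 1e-2
    beta: float = 1.0
    c: int = 10
    epochs: int = 50
    batch_size: int = 64
    critic_steps_per_gen_step: int = 5
    learning_rate: float = 5e-5
    clip_value: float = 0.01
    seed: int = 0
    mode: str = "full"
    generator_hidden: tuple[int, ...] = (512, 768)
    critic_hidden: tuple[int, ...] = (256, 128)
    nmf_batch_max_iter: int = 300

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        if self.alpha < 0 or self.beta < 0 or self.learning_rate <= 0:
            raise ValueError("weights must be >= 0 and learning_rate > 0")
        if self.epochs < 0 or self.batch_size < 1:
            raise ValueError("epochs >= 0 and batch_size >= 1 required")
        if self.effective_alpha > 0 and self.batch_size < self.c:
            raise ValueError(
                f"batch_size={self.batch_size} must be >= c={self.c} when the "
                "centroid loss is active"
            )

    @property
    def effective_alpha(self) -> float:
        return 0.0 if self.mode == "mse_only" else self.alpha

    @property
    def effective_beta(self) -> float:
        return 0.0 if self.mode == "nmf_only" else self.beta

    @property
    def adversarial(self) -> bool:
        return self.mode != "mse_only"


@dataclass
class TrainedImputer:
    """Trained generator/critic pair plus configuration and loss history."""

    generator: MLP
    critic: MLP
    config: TrainingConfig
    history: pd.DataFrame  # epoch, critic_loss, adv_term, nmf_term, mse_term, val_mse

    def save(self, path: str | Path) -> None:
        meta = {
            "config": {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in self.config.__dict__.items()
            },
            "history": self.history.to_dict(orient="list"),
        }
        save_checkpoint(path, self.generator, self.critic, meta)

    @classmethod
    def load(cls, path: str | Path) -> "TrainedImputer":
        G, C, meta = load_checkpoint(path)
        cfg_d = dict(meta["config"])
        for key in ("generator_hidden", "critic_hidden"):
            cfg_d[key] = tuple(cfg_d[key])
        return cls(G, C, TrainingConfig(**cfg_d), pd.DataFrame(meta["history"]))


@dataclass
class CompletedMatrix:
    """Target matrix completed over all n source samples.

    Observed rows are copied verbatim from the input target matrix; exactly
    the k missing rows are generator output.  ``provenance`` records which is
    which, per sample.
    """

    values: np.ndarray
    sample_ids: list[str]
    feature_ids: list[str]
    provenance: list[str]  # "observed" | "imputed"

    def __post_init__(self) -> None:
        assert self.values.shape == (len(self.sample_ids), len(self.feature_ids))
        assert all(p in ("observed", "imputed") for p in self.provenance)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.feature_ids)

    def rows(self, ids: list[str]) -> np.ndarray:
        index = {s: i for i, s in enumerate(self.sample_ids)}
        return self.values[[index[i] for i in ids]]

    @property
    def imputed_ids(self) -> list[str]:
        return [s for s, p in zip(self.sample_ids, self.provenance) if p == "imputed"]


def _derive_seeds(seed: int) -> dict[str, int]:
    """Named integer substreams derived from the single config seed."""
    ss = np.random.SeedSequence(seed)
    names = ["init_G", "init_C", "shuffle", "nmf_ref", "nmf_batch"]
    states = ss.generate_state(len(names))
    return {n: int(s % (2**31 - 1)) for n, s in zip(names, states)}


def train(
    ds: PairedOmicsDataset,
    plan: SplitPlan,
    cfg: TrainingConfig,
    step_callback: Callable[[str, MLP, MLP], None] | None = None,
) -> TrainedImputer:
    """Run the adversarial training loop.

    Mini-batches are drawn from a seeded shuffle of the training and missing
    samples.  Per batch: ``critic_steps_per_gen_step`` critic updates on
    (real = the batch's observed target rows, fake = generated rows for the
    same samples), each followed by weight clipping, then one generator
    update on the composite objective.  Reference centroids are computed once
    from the training-split target rows before the first epoch.  The model
    returned is the checkpoint with the best validation MSE.
    """
    seeds = _derive_seeds(cfg.seed)
    p = ds.source.n_features
    q = ds.target.n_features
    G = build_generator(
        GeneratorSpec(p, q, cfg.generator_hidden), seed=seeds["init_G"]
    )
    C = build_critic(
        CriticSpec(q, cfg.critic_hidden, cfg.clip_value), seed=seeds["init_C"]
    )
    opt_G = RMSProp(G.parameters(), lr=cfg.learning_rate)
    opt_C = RMSProp(C.parameters(), lr=cfg.learning_rate)

    train_ids = list(plan.train_ids)
    pool_ids = train_ids + list(plan.missing_ids)
    observed_set = set(ds.observed_ids)
    X_pool = ds.source_rows(pool_ids)
    # target rows only exist for observed pool members
    tgt_index = {s: i for i, s in enumerate(ds.target.sample_ids)}
    pool_obs_mask = np.array([s in observed_set for s in pool_ids])
    pool_tgt_row = np.array([tgt_index.get(s, -1) for s in pool_ids])

    X_val = ds.source_rows(plan.validation_ids)
    Y_val = ds.target_rows(plan.validation_ids)

    U_ref = None
    if cfg.effective_alpha > 0:
        Y_train = ds.target_rows(train_ids)
        U_ref = reference_centroids(
            Y_train, cfg.c, seed=seeds["nmf_ref"]
        ).U

    rng = np.random.default_rng(seeds["shuffle"])
    records: list[dict] = []
    best_val = np.inf
    best_params = _snapshot(G)

    if cfg.epochs == 0:
        history = _empty_history()
        return TrainedImputer(G, C, cfg, history)

    n_pool = len(pool_ids)
    for epoch in range(cfg.epochs):
        order = rng.permutation(n_pool)
        batches = _make_batches(order, cfg)
        critic_losses: list[float] = []
        terms = {"adversarial": [], "nmf": [], "mse": []}
        for batch_idx in batches:
            Xb = X_pool[batch_idx]
            obs_local = np.flatnonzero(pool_obs_mask[batch_idx])
            Yb_obs = ds.target.values[pool_tgt_row[batch_idx[obs_local]]]

            if cfg.mode == "mse_only" and obs_local.size == 0:
                warnings.warn(
                    "batch without observed targets skipped in mse_only mode",
                    RuntimeWarning,
                    stacklevel=2,
                )
                continue

            if cfg.adversarial and obs_local.size > 0:
                X_real_src = Xb[obs_local]
                for _ in range(cfg.critic_steps_per_gen_step):
                    Y_fake = generate(G, X_real_src)  # detached counterpart
                    c_val = _critic_step(C, opt_C, Yb_obs, Y_fake)
                    clip_weights(C)
                    critic_losses.append(c_val)
                    if step_callback is not None:
                        step_callback("critic", C, G)

            total, breakdown, grads, _ = _generator_loss_full(
                C,
                G,
                Xb,
                Yb_obs,
                obs_local,
                U_ref,
                cfg.effective_alpha,
                cfg.effective_beta,
                cfg.c,
                seed=seeds["nmf_batch"],
                adversarial=cfg.adversarial,
                nmf_max_iter=cfg.nmf_batch_max_iter,
            )
            flat = [g for pair in grads for g in pair]
            opt_G.step(flat)
            if step_callback is not None:
                step_callback("generator", C, G)
            for k in terms:
                terms[k].append(breakdown[k])

        val_mse = float(np.mean((generate(G, X_val) - Y_val) ** 2))
        records.append(
            {
                "epoch": epoch + 1,
                "critic_loss": float(np.mean(critic_losses)) if critic_losses else np.nan,
                "adv_term": float(np.mean(terms["adversarial"])) if terms["adversarial"] else np.nan,
                "nmf_term": float(np.mean(terms["nmf"])) if terms["nmf"] else np.nan,
                "mse_term": float(np.mean(terms["mse"])) if terms["mse"] else np.nan,
                "val_mse": val_mse,
            }
        )
        if val_mse < best_val:
            best_val = val_mse
            best_params = _snapshot(G)

    _restore(G, best_params)  # keep the best-validation checkpoint
    history = pd.DataFrame(records)
    return TrainedImputer(G, C, cfg, history)


def _make_batches(order: np.ndarray, cfg: TrainingConfig) -> list[np.ndarray]:
    batches = [
        order[i : i + cfg.batch_size] for i in range(0, len(order), cfg.batch_size)
    ]
    # a trailing batch too small for the centroid loss is merged backwards
    if cfg.effective_alpha > 0 and len(batches) > 1 and len(batches[-1]) < cfg.c:
        tail = batches.pop()
        batches[-1] = np.concatenate([batches[-1], tail])
    return batches


def _critic_step(C: MLP, opt: RMSProp, Y_real: np.ndarray, Y_fake: np.ndarray) -> float:
    b_r = Y_real.shape[0]
    b_f = Y_fake.shape[0]
    s_fake, cache_f = C.forward(Y_fake, want_cache=True)
    s_real, cache_r = C.forward(Y_real, want_cache=True)
    loss = float(s_fake.mean() - s_real.mean())
    g_f, _ = C.backward(cache_f, np.full_like(s_fake, 1.0 / b_f))
    g_r, _ = C.backward(cache_r, np.full_like(s_real, -1.0 / b_r))
    flat = [gf + gr for pf, pr in zip(g_f, g_r) for gf, gr in zip(pf, pr)]
    opt.step(flat)
    return loss


def _snapshot(net: MLP) -> list[np.ndarray]:
    return [p.copy() for p in net.parameters()]


def _restore(net: MLP, params: list[np.ndarray]) -> None:
    for p, saved in zip(net.parameters(), params):
        p[...] = saved


def _empty_history() -> pd.DataFrame:
    return pd.DataFrame(
        columns=["epoch", "critic_loss", "adv_term", "nmf_term", "mse_term", "val_mse"]
    )


def impute(imp: TrainedImputer, ds: PairedOmicsDataset) -> CompletedMatrix:
    """Complete the target matrix: copy observed rows, generate missing ones."""
    p_expected = imp.generator.dims[0]
    if ds.source.n_features != p_expected:
        raise ValueError(
            f"source has {ds.source.n_features} features, generator expects {p_expected}"
        )
    if ds.m == 0:
        raise ValueError(
            "dataset has no observed target samples; reference data required"
        )
    q = ds.target.n_features
    values = np.empty((ds.n, q))
    provenance: list[str] = []
    sample_ids = list(ds.source.sample_ids)
    tgt_index = {s: i for i, s in enumerate(ds.target.sample_ids)}
    missing_set = set(ds.missing_ids)
    if missing_set:
        X_missing = ds.source_rows(ds.missing_ids)
        Y_missing = generate(imp.generator, X_missing)
        miss_row = {s: i for i, s in enumerate(ds.missing_ids)}
    for i, s in enumerate(sample_ids):
        if s in missing_set:
            values[i] = Y_missing[miss_row[s]]
            provenance.append("imputed")
        else:
            values[i] = ds.target.values[tgt_index[s]]
            provenance.append("observed")
    return CompletedMatrix(values, sample_ids, list(ds.target.feature_ids), provenance)


def grid_search(
    ds: PairedOmicsDataset,
    plan: SplitPlan,
    base_cfg: TrainingConfig,
    alphas: tuple[float, ...] = (0.0, 1e-3, 1e-2, 1e-1),
    betas: tuple[float, ...] = (0.1, 1.0),
) -> tuple[TrainedImputer, pd.DataFrame]:
    """Small built-in grid over (alpha, beta), selected by validation MSE."""
    rows = []
    best: TrainedImputer | None = None
    best_val = np.inf
    for a in alphas:
        for b in betas:
            cfg = replace(base_cfg, alpha=a, beta=b)
            imp = train(ds, plan, cfg)
            val = float(imp.history["val_mse"].min()) if len(imp.history) else np.inf
            rows.append({"alpha": a, "beta": b, "best_val_mse": val})
            if val < best_val:
                best_val = val
                best = imp
    return best, pd.DataFrame(rows)
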