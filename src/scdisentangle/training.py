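"""Optimization loop, minibatching with condition-aware DSBN, and the
inference pass that produces the latent embeddings for a whole dataset.

Training runs a fixed number of Adam epochs (no early stopping, no schedule)
over shuffled minibatches drawn across all conditions jointly; the DSBN
branches normalize whichever condition subsets are present in each
minibatch. A single seed controls parameter initialization, shuffling and
reparameterization noise, so two single-threaded runs with the same seed are
bit-identical.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .datamodel import ExpressionDataset, OneHot, Stage
from .network import DisentangledVAE, LatentBundle, ModelConfig
from .objective import LossBreakdown

logger = logging.getLogger(__name__)

__all__ = ["TrainState", "Adam", "fit", "transform", "config_for", "save_checkpoint", "load_checkpoint"]


class Adam:
    """Adam optimizer over a list of (param, grad) array pairs."""

    def __init__(self, params, lr: float = 1e-4, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _ in params]
        self.v = [np.zeros_like(p) for p, _ in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        corr1 = 1 - b1 ** self.t
        corr2 = 1 - b2 ** self.t
        for (p, g), m, v in zip(self.params, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p -= self.lr * (m / corr1) / (np.sqrt(v / corr2) + self.eps)


@dataclass
class TrainState:
    """Fitted model plus everything needed to reproduce and apply it."""

    model: DisentangledVAE
    config: ModelConfig
    history: list[LossBreakdown]
    batch_levels: tuple[str, ...]
    condition_levels: tuple[str, ...]
    gene_ids: list[str] = field(default_factory=list)

    @property
    def epochs_completed(self) -> int:
        return len(self.history)

    def write_log(self, path: str | Path) -> None:
        """Per-epoch loss breakdown as CSV."""
        with open(path, "w", newline="") as f:
            w = csv.writer(f)
            w.writerow(["epoch", "recon", "kl", "cls", "total"])
            for i, h in enumerate(self.history, start=1):
                w.writerow([i, h.recon, h.kl, h.cls, h.total])


def config_for(ds: ExpressionDataset, **overrides) -> ModelConfig:
    """Build a ModelConfig with m, b, C inferred from the dataset."""
    return ModelConfig(
        m=ds.n_genes,
        b=ds.batch_onehot().n_levels,
        C=ds.condition_onehot().n_levels,
        **overrides,
    )


def fit(ds: ExpressionDataset, config: ModelConfig) -> TrainState:
    """Train the model on a z-scored dataset and return the final state."""
    if ds.stage != Stage.zscored:
        raise ValueError(f"fit expects stage=zscored, got {ds.stage.name}")
    if ds.n_genes != config.m:
        raise ValueError(f"config.m={config.m} does not match dataset gene count {ds.n_genes}")
    batch_oh = ds.batch_onehot()
    cond_oh = ds.condition_onehot()
    if batch_oh.n_levels != config.b or cond_oh.n_levels != config.C:
        raise ValueError("config b/C do not match the dataset's label levels")
    counts = np.bincount(cond_oh.codes, minlength=config.C)
    if np.any(counts == 0):
        raise ValueError("every condition level must have at least one cell")

    rng = np.random.default_rng(config.seed)
    model = DisentangledVAE(config, rng)
    opt_main = Adam(model.parameters("main"), lr=config.lr)
    opt_cls = Adam(model.parameters("cls"), lr=config.lr)

    X = ds.dense().astype(np.float64)
    B = batch_oh.matrix
    codes = cond_oh.codes
    n = ds.n_cells
    nb = min(config.minibatch, n)
    history: list[LossBreakdown] = []

    for epoch in range(config.epochs):
        order = rng.permutation(n)
        ep_recon = ep_kl = ep_cls = 0.0
        for start in range(0, n, nb):
            idx = order[start : start + nb]
            xb, bb, cb = X[idx], B[idx], codes[idx]
            k = len(idx)
            scale = n / k  # minibatch estimate of the full-data sums

            if config.alternating_cls:
                # classifier-only step: cross-entropy, gradients confined to Cls
                bundle = model.forward(xb, bb, cb, rng=rng, train=True)
                model.zero_grad()
                prob = np.exp(bundle.cls_logprob)
                d_logits = (prob - _onehot_rows(cb, config.C)) / k
                _cls_only_backward(model, d_logits)
                opt_cls.step()

            bundle = model.forward(xb, bb, cb, rng=rng, train=True)
            model.zero_grad()
            prob = np.exp(bundle.cls_logprob)
            one = _onehot_rows(cb, config.C)
            d_xt = 2.0 * (bundle.X_tilde - xb) * scale
            lam = config.lambda_kl * scale
            d_mu_bio = lam * bundle.mu_bio
            d_logvar_bio = lam * 0.5 * (bundle.var_bio - 1.0)
            d_mu_cond = lam * bundle.mu_cond
            d_logvar_cond = lam * 0.5 * (bundle.var_cond - 1.0)
            d_logits = config.mu_cls * (prob - one) / k
            model.backward(d_xt, d_logits, d_mu_bio, d_logvar_bio, d_mu_cond, d_logvar_cond)
            opt_main.step()
            if not config.alternating_cls:
                opt_cls.step()

            # epoch bookkeeping: each cell contributes once per epoch
            diff = bundle.X_tilde - xb
            ep_recon += float(np.sum(diff * diff))
            ep_kl += 0.5 * float(
                np.sum(bundle.mu_bio**2 + bundle.var_bio - 1 - np.log(bundle.var_bio))
                + np.sum(bundle.mu_cond**2 + bundle.var_cond - 1 - np.log(bundle.var_cond))
            )
            ep_cls += float(-bundle.cls_logprob[np.arange(k), cb].sum())
        history.append(LossBreakdown(recon=ep_recon, kl=ep_kl, cls=ep_cls / n,
                                     lambda_kl=config.lambda_kl, mu_cls=config.mu_cls))
        logger.debug("epoch %d/%d total=%.4g", epoch + 1, config.epochs, history[-1].total)

    return TrainState(model=model, config=config, history=history,
                      batch_levels=batch_oh.levels, condition_levels=cond_oh.levels,
                      gene_ids=list(ds.gene_ids))


def _onehot_rows(codes: np.ndarray, k: int) -> np.ndarray:
    out = np.zeros((len(codes), k))
    out[np.arange(len(codes)), codes] = 1.0
    return out


def _cls_only_backward(model: DisentangledVAE, d_logits: np.ndarray) -> None:
    g = model.cls[-1].backward(d_logits)
    for layer, act in zip(reversed(model.cls[:-1]), reversed(model.cls_act)):
        g = layer.backward(act.backward(g))


def transform(state: TrainState, ds: ExpressionDataset) -> LatentBundle:
    """Deterministic eval-mode pass: mean embeddings, running DSBN stats."""
    if ds.stage != Stage.zscored:
        raise ValueError(f"transform expects stage=zscored, got {ds.stage.name}")
    if list(ds.gene_ids) != list(state.gene_ids):
        raise ValueError("dataset gene set does not match the trained model")
    unseen_b = set(ds.batch) - set(state.batch_levels)
    unseen_c = set(ds.condition) - set(state.condition_levels)
    if unseen_b:
        raise ValueError(f"unseen batch levels: {sorted(unseen_b)}")
    if unseen_c:
        raise ValueError(f"unseen condition levels: {sorted(unseen_c)}")
    B = OneHot.from_labels(ds.batch, state.batch_levels).matrix
    codes = OneHot.from_labels(ds.condition, state.condition_levels).codes
    return state.model.forward(ds.dense().astype(np.float64), B, codes, train=False)


def save_checkpoint(state: TrainState, path: str | Path) -> None:
    state.model.save(path, extra={
        "batch_levels": list(state.batch_levels),
        "condition_levels": list(state.condition_levels),
        "gene_ids": list(state.gene_ids),
        "history": [[h.recon, h.kl, h.cls] for h in state.history],
    })


def load_checkpoint(path: str | Path) -> TrainState:
    model, extra = DisentangledVAE.load(path)
    cfg = model.config
    history = [LossBreakdown(recon=r, kl=k, cls=c, lambda_kl=cfg.lambda_kl, mu_cls=cfg.mu_cls)
               for r, k, c in extra.get("history", [])]
    return TrainState(model=model, config=cfg, history=history,
                      batch_levels=tuple(extra["batch_levels"]),
                      condition_levels=tuple(extra["condition_levels"]),
                      gene_ids=list(extra["gene_ids"]))
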