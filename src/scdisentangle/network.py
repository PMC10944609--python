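"""Disentangling VAE graph: shared encoder, bio/condition variational heads,
per-condition domain-specific batch normalization (DSBN), residual
condition-specific representation, condition classifier, and
batch-conditioned decoder.

All layers are plain numpy with explicit forward/backward passes. The
networks involved are small fully connected stacks, so hand-written
reverse-mode differentiation is both fast enough and fully checkable
against finite differences (the test suite does exactly that).

Shapes and roles
----------------
input  X (n, m) z-scored expression, B (n, b) one-hot batch
L      (n, d)   shared features, ReLU-positive
Z_bio  (n, d1)  shared biological embedding (variational)
Z_cond (n, d2)  condition-specific embedding (variational)
Z'     (n, d2)  condition-shared part: per-condition-domain normalized Z_cond
Z_sp   (n, d2)  condition-specific residual Z_cond - Z', fed to the classifier
X~     (n, m)   reconstruction from (Z_bio, Z_cond, B)
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Literal

import h5py
import numpy as np

__all__ = ["ModelConfig", "LatentBundle", "DsbnState", "DisentangledVAE", "reparameterize"]


@dataclass
class ModelConfig:
    """Architecture dimensions and training hyperparameters.

    Defaults follow the reference configuration: encoder/decoder hidden
    sizes 512-256-(bottleneck)-256-512, condition embedding dimension 8,
    classifier hidden stack 100x4, Adam lr 1e-4 for 50 epochs, loss weights
    lambda (KL) = mu (classifier) = 0.001.
    """

    m: int
    b: int
    C: int
    d: int = 256
    d1: int = 16
    d2: int = 8
    enc_hidden: tuple[int, ...] = (512,)
    dec_hidden: tuple[int, ...] = (256, 512)
    cls_hidden: tuple[int, ...] = (100, 100, 100, 100)
    eps_bn: float = 1e-5
    bn_momentum: float = 0.1
    lambda_kl: float = 0.001
    mu_cls: float = 0.001
    lr: float = 1e-4
    epochs: int = 50
    minibatch: int = 16
    seed: int = 0
    reparam_scale: Literal["variance", "stddev"] = "variance"
    dsbn_affine: bool = False
    alternating_cls: bool = False

    def __post_init__(self) -> None:
        if self.d1 < 1 or self.d2 < 1:
            raise ValueError("latent dimensions must be >= 1")
        if self.d1 + self.d2 >= self.m:
            raise ValueError("d1 + d2 must be smaller than the gene count")
        if self.eps_bn <= 0:
            raise ValueError("eps_bn must be positive")
        for sz in (*self.enc_hidden, self.d, *self.dec_hidden, *self.cls_hidden):
            if sz < 1:
                raise ValueError("all layer sizes must be positive")
        if self.reparam_scale not in ("variance", "stddev"):
            raise ValueError("reparam_scale must be 'variance' or 'stddev'")


@dataclass
class LatentBundle:
    """Per-cell outputs of one forward pass."""

    L: np.ndarray
    mu_bio: np.ndarray
    var_bio: np.ndarray
    Z_bio: np.ndarray
    mu_cond: np.ndarray
    var_cond: np.ndarray
    Z_cond: np.ndarray
    Z_cond_shared: np.ndarray
    Z_cond_sp: np.ndarray
    cls_logprob: np.ndarray
    X_tilde: np.ndarray


# ---------------------------------------------------------------------------
# primitive layers


class Dense:
    """Fully connected layer y = x W + b with cached input for backward."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, scale: str = "relu"):
        gain = np.sqrt(2.0 / n_in) if scale == "relu" else np.sqrt(1.0 / n_in)
        self.W = rng.normal(0.0, gain, size=(n_in, n_out))
        self.b = np.zeros(n_out)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.shape[1] != self.W.shape[0]:
            raise ValueError(f"expected input dim {self.W.shape[0]}, got {x.shape[1]}")
        self._x = x
        return x @ self.W + self.b

    def backward(self, g: np.ndarray) -> np.ndarray:
        self.gW += self._x.T @ g
        self.gb += g.sum(axis=0)
        return g @ self.W.T

    def params(self):
        return [(self.W, self.gW), (self.b, self.gb)]


class ReLU:
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, g: np.ndarray) -> np.ndarray:
        return np.where(self._mask, g, 0.0)


@dataclass
class DsbnState:
    """Running first/second moments for each condition domain's BN branch."""

    running_mean: np.ndarray  # (C, d2)
    running_var: np.ndarray  # (C, d2)
    momentum: float = 0.1

    @classmethod
    def init(cls, C: int, d2: int, momentum: float = 0.1) -> "DsbnState":
        return cls(np.zeros((C, d2)), np.ones((C, d2)), momentum)


def reparameterize(mu: np.ndarray, var: np.ndarray, noise: np.ndarray, scale: str = "variance") -> np.ndarray:
    """Latent draw as a deterministic function of (mu, var, noise).

    ``scale='variance'`` multiplies the noise by the variance itself;
    ``'stddev'`` uses the standard deviation. Either way noise=0 returns the
    mean exactly.
    """
    if np.any(var <= 0):
        raise ValueError("variance must be strictly positive")
    s = var if scale == "variance" else np.sqrt(var)
    return s * noise + mu


# ---------------------------------------------------------------------------
# the model graph


class DisentangledVAE:
    """The full model with explicit forward and backward passes.

    Parameter groups: ``main`` (shared encoder, variational heads, DSBN
    affine parameters when enabled, decoder) and ``cls`` (condition
    classifier), mirroring the two optimizer groups used in training.
    """

    def __init__(self, config: ModelConfig, rng: np.random.Generator | None = None):
        self.config = config
        rng = rng or np.random.default_rng(config.seed)
        c = config

        # shared encoder: (m+b) -> enc_hidden... -> d, ReLU everywhere incl. output
        dims = [c.m + c.b, *c.enc_hidden, c.d]
        self.enc = [Dense(dims[i], dims[i + 1], rng) for i in range(len(dims) - 1)]
        self.enc_act = [ReLU() for _ in self.enc]

        # variational heads: single linear layers (no activation)
        self.head_mu_bio = Dense(c.d, c.d1, rng, scale="linear")
        self.head_logvar_bio = Dense(c.d, c.d1, rng, scale="linear")
        self.head_mu_cond = Dense(c.d, c.d2, rng, scale="linear")
        self.head_logvar_cond = Dense(c.d, c.d2, rng, scale="linear")

        # condition classifier: d2 -> cls_hidden... -> C
        cdims = [c.d2, *c.cls_hidden, c.C]
        self.cls = [Dense(cdims[i], cdims[i + 1], rng, scale="relu" if i < len(cdims) - 2 else "linear")
                    for i in range(len(cdims) - 1)]
        self.cls_act = [ReLU() for _ in self.cls[:-1]]

        # decoder: (d1+d2+b) -> dec_hidden... -> m, linear output
        ddims = [c.d1 + c.d2 + c.b, *c.dec_hidden, c.m]
        self.dec = [Dense(ddims[i], ddims[i + 1], rng, scale="relu" if i < len(ddims) - 2 else "linear")
                    for i in range(len(ddims) - 1)]
        self.dec_act = [ReLU() for _ in self.dec[:-1]]

        self.dsbn = DsbnState.init(c.C, c.d2, c.bn_momentum)
        if c.dsbn_affine:
            self.dsbn_gamma = np.ones((c.C, c.d2))
            self.dsbn_beta = np.zeros((c.C, c.d2))
            self.g_dsbn_gamma = np.zeros_like(self.dsbn_gamma)
            self.g_dsbn_beta = np.zeros_like(self.dsbn_beta)

    # -- parameter access --------------------------------------------------
    def parameters(self, group: str = "all"):
        main = [p for layer in (*self.enc, self.head_mu_bio, self.head_logvar_bio,
                                self.head_mu_cond, self.head_logvar_cond, *self.dec)
                for p in layer.params()]
        if self.config.dsbn_affine:
            main += [(self.dsbn_gamma, self.g_dsbn_gamma), (self.dsbn_beta, self.g_dsbn_beta)]
        cls = [p for layer in self.cls for p in layer.params()]
        if group == "main":
            return main
        if group == "cls":
            return cls
        return main + cls

    def zero_grad(self) -> None:
        for _, g in self.parameters():
            g[...] = 0.0

    # -- forward -----------------------------------------------------------
    def encode_shared(self, X: np.ndarray, B: np.ndarray) -> np.ndarray:
        h = np.concatenate([X, B], axis=1)
        for layer, act in zip(self.enc, self.enc_act):
            h = act.forward(layer.forward(h))
        return h

    def dsbn_forward(self, Z_cond: np.ndarray, cond_codes: np.ndarray, train: bool) -> np.ndarray:
        """Normalize each condition domain's rows per feature.

        Train mode uses current-minibatch per-domain statistics (population
        variance) and updates the running moments by momentum; eval mode
        uses the running moments. Domains absent from a training minibatch
        are skipped.
        """
        c = self.config
        out = np.empty_like(Z_cond)
        self._bn_cache = []
        if train:
            for dom in range(c.C):
                idx = np.flatnonzero(cond_codes == dom)
                if idx.size == 0:
                    continue
                z = Z_cond[idx]
                mu = z.mean(axis=0)
                var = z.var(axis=0)
                s = np.sqrt(var + c.eps_bn)
                xhat = (z - mu) / s
                out[idx] = xhat
                mom = self.dsbn.momentum
                self.dsbn.running_mean[dom] = (1 - mom) * self.dsbn.running_mean[dom] + mom * mu
                self.dsbn.running_var[dom] = (1 - mom) * self.dsbn.running_var[dom] + mom * var
                self._bn_cache.append((dom, idx, xhat, s))
        else:
            for dom in range(c.C):
                idx = np.flatnonzero(cond_codes == dom)
                if idx.size == 0:
                    continue
                s = np.sqrt(self.dsbn.running_var[dom] + c.eps_bn)
                xhat = (Z_cond[idx] - self.dsbn.running_mean[dom]) / s
                out[idx] = xhat
                self._bn_cache.append((dom, idx, xhat, s))
        self._bn_train = train
        if c.dsbn_affine:
            self._bn_xhat = out.copy()
            for dom, idx, xhat, s in self._bn_cache:
                out[idx] = xhat * self.dsbn_gamma[dom] + self.dsbn_beta[dom]
        return out

    def classify(self, Z_sp: np.ndarray) -> np.ndarray:
        """Log-probabilities over condition classes (log-softmax output)."""
        h = Z_sp
        for layer, act in zip(self.cls[:-1], self.cls_act):
            h = act.forward(layer.forward(h))
        logits = self.cls[-1].forward(h)
        shifted = logits - logits.max(axis=1, keepdims=True)
        logz = np.log(np.exp(shifted).sum(axis=1, keepdims=True))
        self._cls_prob = np.exp(shifted - logz)
        return shifted - logz

    def decode(self, Z_bio: np.ndarray, Z_cond: np.ndarray, B: np.ndarray) -> np.ndarray:
        h = np.concatenate([Z_bio, Z_cond, B], axis=1)
        for layer, act in zip(self.dec[:-1], self.dec_act):
            h = act.forward(layer.forward(h))
        return self.dec[-1].forward(h)

    def decode_jvp(self, Z_bio: np.ndarray, Z_cond: np.ndarray, B: np.ndarray,
                   d_Z_cond: np.ndarray) -> np.ndarray:
        """Forward-mode directional derivative of the decoder: the exact
        first-order response of the reconstruction to moving the condition
        embedding along ``d_Z_cond``, row by row."""
        h = np.concatenate([Z_bio, Z_cond, B], axis=1)
        v = np.concatenate([np.zeros_like(Z_bio), d_Z_cond, np.zeros_like(B)], axis=1)
        for layer in self.dec[:-1]:
            pre = layer.forward(h)
            v = v @ layer.W
            mask = pre > 0
            h = np.where(mask, pre, 0.0)
            v = np.where(mask, v, 0.0)
        return v @ self.dec[-1].W

    def forward(
        self,
        X: np.ndarray,
        B: np.ndarray,
        cond_codes: np.ndarray,
        rng: np.random.Generator | None = None,
        train: bool = False,
    ) -> LatentBundle:
        """Full forward pass.

        In train mode latent draws use fresh reparameterization noise from
        ``rng``; in eval mode the mean heads are used (noise = 0) and DSBN
        reads its running statistics, so the pass is deterministic.
        """
        c = self.config
        L = self.encode_shared(X, B)
        mu_bio = self.head_mu_bio.forward(L)
        logvar_bio = self.head_logvar_bio.forward(L)
        var_bio = np.exp(logvar_bio)
        mu_cond = self.head_mu_cond.forward(L)
        logvar_cond = self.head_logvar_cond.forward(L)
        var_cond = np.exp(logvar_cond)
        if train:
            if rng is None:
                raise ValueError("train-mode forward requires an rng for reparameterization noise")
            noise_bio = rng.standard_normal(mu_bio.shape)
            noise_cond = rng.standard_normal(mu_cond.shape)
        else:
            noise_bio = np.zeros_like(mu_bio)
            noise_cond = np.zeros_like(mu_cond)
        Z_bio = reparameterize(mu_bio, var_bio, noise_bio, c.reparam_scale)
        Z_cond = reparameterize(mu_cond, var_cond, noise_cond, c.reparam_scale)
        Z_shared = self.dsbn_forward(Z_cond, cond_codes, train=train)
        Z_sp = Z_cond - Z_shared
        # recompose so Z_sp + Z_shared == Z_cond holds bit-exactly (floating
        # point does not guarantee (a-b)+b == a); downstream consumers all
        # see the recomposed array
        Z_cond = Z_sp + Z_shared
        cls_logprob = self.classify(Z_sp)
        X_tilde = self.decode(Z_bio, Z_cond, B)
        self._cache = dict(noise_bio=noise_bio, noise_cond=noise_cond,
                           var_bio=var_bio, var_cond=var_cond)
        return LatentBundle(L=L, mu_bio=mu_bio, var_bio=var_bio, Z_bio=Z_bio,
                            mu_cond=mu_cond, var_cond=var_cond, Z_cond=Z_cond,
                            Z_cond_shared=Z_shared, Z_cond_sp=Z_sp,
                            cls_logprob=cls_logprob, X_tilde=X_tilde)

    # -- backward ----------------------------------------------------------
    def _dsbn_backward(self, dZ_shared: np.ndarray) -> np.ndarray:
        """Backward through the DSBN branches (through minibatch statistics
        in train mode, constants in eval mode)."""
        c = self.config
        dZ = np.zeros_like(dZ_shared)
        for dom, idx, xhat, s in self._bn_cache:
            dy = dZ_shared[idx]
            if c.dsbn_affine:
                self.g_dsbn_gamma[dom] += (dy * xhat).sum(axis=0)
                self.g_dsbn_beta[dom] += dy.sum(axis=0)
                dy = dy * self.dsbn_gamma[dom]
            if self._bn_train:
                n = idx.size
                dZ[idx] = (dy - dy.mean(axis=0) - xhat * (dy * xhat).mean(axis=0)) / s
            else:
                dZ[idx] = dy / s
        return dZ

    def backward(
        self,
        d_X_tilde: np.ndarray,
        d_cls_logits: np.ndarray,
        d_mu_bio: np.ndarray,
        d_logvar_bio: np.ndarray,
        d_mu_cond: np.ndarray,
        d_logvar_cond: np.ndarray,
        d_Z_sp_extra: np.ndarray | None = None,
    ) -> np.ndarray:
        """Accumulate parameter gradients for the last forward pass.

        ``d_cls_logits`` is the gradient at the classifier's pre-softmax
        logits (for cross-entropy that is (p - onehot)/n). The KL gradients
        enter directly at the variational heads via ``d_mu_*`` and
        ``d_logvar_*``. Returns the gradient with respect to the
        concatenated (X, B) input block.
        """
        cache = self._cache

        # decoder
        h = self.dec[-1].backward(d_X_tilde)
        for layer, act in zip(reversed(self.dec[:-1]), reversed(self.dec_act)):
            h = layer.backward(act.backward(h))
        c = self.config
        dZ_bio = h[:, : c.d1]
        dZ_cond = h[:, c.d1 : c.d1 + c.d2].copy()

        # classifier -> Z_sp
        g = self.cls[-1].backward(d_cls_logits)
        for layer, act in zip(reversed(self.cls[:-1]), reversed(self.cls_act)):
            g = layer.backward(act.backward(g))
        dZ_sp = g
        if d_Z_sp_extra is not None:
            dZ_sp = dZ_sp + d_Z_sp_extra

        # Z_sp = Z_cond - Z_shared, Z_shared = BN(Z_cond)
        dZ_cond += dZ_sp - self._dsbn_backward(dZ_sp)

        # reparameterization
        dmu_bio = dZ_bio + d_mu_bio
        dmu_cond = dZ_cond + d_mu_cond
        if c.reparam_scale == "variance":
            dvar_bio = dZ_bio * cache["noise_bio"]
            dvar_cond = dZ_cond * cache["noise_cond"]
        else:
            dvar_bio = dZ_bio * cache["noise_bio"] * 0.5 / np.sqrt(cache["var_bio"])
            dvar_cond = dZ_cond * cache["noise_cond"] * 0.5 / np.sqrt(cache["var_cond"])
        # var = exp(logvar)
        dlogvar_bio = dvar_bio * cache["var_bio"] + d_logvar_bio
        dlogvar_cond = dvar_cond * cache["var_cond"] + d_logvar_cond

        dL = (self.head_mu_bio.backward(dmu_bio)
              + self.head_logvar_bio.backward(dlogvar_bio)
              + self.head_mu_cond.backward(dmu_cond)
              + self.head_logvar_cond.backward(dlogvar_cond))

        for layer, act in zip(reversed(self.enc), reversed(self.enc_act)):
            dL = layer.backward(act.backward(dL))
        return dL

    # -- checkpointing -----------------------------------------------------
    def _named_arrays(self):
        for i, layer in enumerate(self.enc):
            yield f"enc/{i}/W", layer
        for name, layer in [("head_mu_bio", self.head_mu_bio), ("head_logvar_bio", self.head_logvar_bio),
                            ("head_mu_cond", self.head_mu_cond), ("head_logvar_cond", self.head_logvar_cond)]:
            yield f"{name}/W", layer
        for i, layer in enumerate(self.cls):
            yield f"cls/{i}/W", layer
        for i, layer in enumerate(self.dec):
            yield f"dec/{i}/W", layer

    def save(self, path: str | Path, extra: dict | None = None) -> None:
        """Save parameters, DSBN running stats and config to HDF5."""
        with h5py.File(path, "w") as f:
            f.attrs["config"] = json.dumps(asdict(self.config))
            if extra:
                f.attrs["extra"] = json.dumps(extra)
            for key, layer in self._named_arrays():
                f[key] = layer.W
                f[key.rsplit("/", 1)[0] + "/b"] = layer.b
            f["dsbn/running_mean"] = self.dsbn.running_mean
            f["dsbn/running_var"] = self.dsbn.running_var
            if self.config.dsbn_affine:
                f["dsbn/gamma"] = self.dsbn_gamma
                f["dsbn/beta"] = self.dsbn_beta

    @classmethod
    def load(cls, path: str | Path) -> tuple["DisentangledVAE", dict]:
        with h5py.File(path, "r") as f:
            cfg = ModelConfig(**json.loads(f.attrs["config"]))
            extra = json.loads(f.attrs["extra"]) if "extra" in f.attrs else {}
            model = cls(cfg)
            for key, layer in model._named_arrays():
                layer.W[...] = f[key][...]
                layer.b[...] = f[key.rsplit("/", 1)[0] + "/b"][...]
            model.dsbn.running_mean[...] = f["dsbn/running_mean"][...]
            model.dsbn.running_var[...] = f["dsbn/running_var"][...]
            if cfg.dsbn_affine:
                model.dsbn_gamma[...] = f["dsbn/gamma"][...]
                model.dsbn_beta[...] = f["dsbn/beta"][...]
        return model, extra
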