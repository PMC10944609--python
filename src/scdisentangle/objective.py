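"""The three-term training objective: squared-error reconstruction, Gaussian
KL to the standard-normal prior over both latent blocks, and condition
cross-entropy, combined as recon + lambda * kl + mu * cls.

Reconstruction and KL are full-data sums; minibatch steps in the trainer
rescale them by n/batch so the expected full-data objective is optimized and
the printed lambda/mu keep their meaning across batch sizes. The
classification term is a per-cell mean (cross-entropy convention).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["LossBreakdown", "reconstruction_loss", "kl_loss", "classification_loss", "total_loss"]


@dataclass
class LossBreakdown:
    recon: float
    kl: float
    cls: float
    lambda_kl: float
    mu_cls: float

    @property
    def total(self) -> float:
        return self.recon + self.lambda_kl * self.kl + self.mu_cls * self.cls


def reconstruction_loss(X: np.ndarray, X_tilde: np.ndarray) -> float:
    """Sum of squared differences over all entries."""
    if X.shape != X_tilde.shape:
        raise ValueError(f"shape mismatch {X.shape} vs {X_tilde.shape}")
    diff = X - X_tilde
    return float(np.sum(diff * diff))


def kl_loss(mu_bio: np.ndarray, var_bio: np.ndarray, mu_cond: np.ndarray, var_cond: np.ndarray) -> float:
    """Closed-form KL of diagonal Gaussians to N(0, I), summed over both
    latent blocks: 1/2 * sum(mu^2 + sigma^2 - 1 - log sigma^2)."""
    total = 0.0
    for mu, var in ((mu_bio, var_bio), (mu_cond, var_cond)):
        if np.any(var <= 0):
            raise ValueError("variances must be strictly positive")
        total += 0.5 * float(np.sum(mu * mu + var - 1.0 - np.log(var)))
    return total


def classification_loss(cls_logprob: np.ndarray, cond_codes: np.ndarray) -> float:
    """Mean over cells of -log p(true condition)."""
    n = cls_logprob.shape[0]
    if np.any(cond_codes < 0) or np.any(cond_codes >= cls_logprob.shape[1]):
        raise ValueError("condition codes out of range")
    return float(-cls_logprob[np.arange(n), cond_codes].mean())


def total_loss(
    X: np.ndarray,
    X_tilde: np.ndarray,
    mu_bio: np.ndarray,
    var_bio: np.ndarray,
    mu_cond: np.ndarray,
    var_cond: np.ndarray,
    cls_logprob: np.ndarray,
    cond_codes: np.ndarray,
    lambda_kl: float = 0.001,
    mu_cls: float = 0.001,
) -> LossBreakdown:
    if lambda_kl < 0 or mu_cls < 0:
        raise ValueError("loss weights must be nonnegative")
    return LossBreakdown(
        recon=reconstruction_loss(X, X_tilde),
        kl=kl_loss(mu_bio, var_bio, mu_cond, var_cond),
        cls=classification_loss(cls_logprob, cond_codes),
        lambda_kl=lambda_kl,
        mu_cls=mu_cls,
    )
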