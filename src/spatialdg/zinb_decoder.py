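"""Zero-inflated negative binomial decoder and likelihood.

Three single-layer heads map the fused embedding to per-spot-per-gene ZINB
parameters: dropout probability pi (sigmoid), NB mean mu (exponential,
clamped to [1e-5, 1e6]) and NB dispersion theta (softplus, clamped to
[1e-4, 1e4]). The negative log-likelihood uses the mean-dispersion NB
parameterization

    NB(x; mu, theta) = Gamma(x+theta) / (Gamma(theta) x!)
                       * (theta/(theta+mu))^theta * (mu/(theta+mu))^x

with P_ZINB(x) = pi * 1[x=0] + (1-pi) * NB(x), evaluated in log space via
log-gamma, probabilities floored at 1e-12 inside the logarithms.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .autodiff import Tensor, glorot, zeros

MU_MIN, MU_MAX = 1e-5, 1e6
THETA_MIN, THETA_MAX = 1e-4, 1e4
P_FLOOR = 1e-12


@dataclass
class ZINBParams:
    """Per-spot-per-gene ZINB parameters (autodiff tensors)."""

    pi: Tensor
    mu: Tensor
    theta: Tensor


@dataclass
class ZINBHeads:
    """Three single-layer networks from the embedding to the parameters."""

    W_pi: Tensor
    b_pi: Tensor
    W_mu: Tensor
    b_mu: Tensor
    W_theta: Tensor
    b_theta: Tensor

    def parameters(self) -> list:
        return [self.W_pi, self.b_pi, self.W_mu, self.b_mu,
                self.W_theta, self.b_theta]

    @classmethod
    def init(cls, embed_dim: int, n_genes: int,
             rng: Optional[np.random.Generator] = None) -> "ZINBHeads":
        rng = rng or np.random.default_rng()
        return cls(
            W_pi=glorot(rng, embed_dim, n_genes), b_pi=zeros(n_genes),
            W_mu=glorot(rng, embed_dim, n_genes), b_mu=zeros(n_genes),
            W_theta=glorot(rng, embed_dim, n_genes), b_theta=zeros(n_genes),
        )


def zinb_heads(H: Tensor, heads: ZINBHeads) -> ZINBParams:
    """Decode embeddings to clamped ZINB parameters."""
    H = H if isinstance(H, Tensor) else Tensor(H)
    pi = (H @ heads.W_pi + heads.b_pi).sigmoid()
    mu = (H @ heads.W_mu + heads.b_mu).exp().clamp(MU_MIN, MU_MAX)
    theta = (H @ heads.W_theta + heads.b_theta).softplus().clamp(
        THETA_MIN, THETA_MAX)
    return ZINBParams(pi=pi, mu=mu, theta=theta)


def zinb_nll(x: np.ndarray, params: ZINBParams) -> Tensor:
    """Total ZINB negative log-likelihood of a count matrix.

    Returns the sum over all spots and genes of -log P_ZINB(x | pi, mu,
    theta). Raises on negative or non-integer counts.
    """
    x = np.asarray(x)
    if np.any(x < 0) or np.any(x != np.floor(x)):
        raise ValueError("counts must be non-negative integers")
    if x.shape != params.mu.shape:
        raise ValueError(f"shape mismatch: counts {x.shape} vs "
                         f"params {params.mu.shape}")
    xt = Tensor(np.asarray(x, dtype=np.float64))
    pi, mu, theta = params.pi, params.mu, params.theta

    log_theta_frac = (theta / (theta + mu)).clamp(lo=P_FLOOR).log()
    log_mu_frac = (mu / (theta + mu)).clamp(lo=P_FLOOR).log()
    log_nb = ((xt + theta).lgamma() - theta.lgamma() - (xt + 1.0).lgamma()
              + theta * log_theta_frac + xt * log_mu_frac)

    # x > 0: log(1-pi) + log NB(x); x = 0: log(pi + (1-pi) NB(0))
    ll_pos = (1.0 - pi).clamp(lo=P_FLOOR).log() + log_nb
    nb_zero = (theta * log_theta_frac).exp()  # NB(0) = (theta/(theta+mu))^theta
    ll_zero = (pi + (1.0 - pi) * nb_zero).clamp(lo=P_FLOOR).log()
    zero_mask = Tensor((x == 0).astype(np.float64))
    ll = zero_mask * ll_zero + (1.0 - zero_mask) * ll_pos
    return -ll.sum()


def impute_expression(params: ZINBParams, flag: str = "mean") -> np.ndarray:
    """Denoised expression from the fitted decoder.

    ``flag="mean"`` returns the NB mean mu; ``flag="expected"`` returns the
    zero-inflation-adjusted expectation (1 - pi) * mu.
    """
    if flag == "mean":
        return params.mu.data.copy()
    if flag == "expected":
        return (1.0 - params.pi.data) * params.mu.data
    raise ValueError("flag must be 'mean' or 'expected'")
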