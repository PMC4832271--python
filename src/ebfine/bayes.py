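"""Wakefield Bayes factors and the empirical-Bayes prior variance.

The Wakefield approximation assumes a Gaussian prior N(0, W) on the per-
allele log odds ratio and the asymptotic normality of its estimate,
beta_hat ~ N(beta, V), giving the closed-form Bayes factor

    WBF = sqrt(V / (V + W)) * exp(beta_hat^2 W / (2 V (V + W))),

oriented so that large values favour association (H1 over H0).

When no reliable prior information on effect sizes exists, W can be chosen
empirically: as a function of W the WBF is maximised at

    W_EB = max(beta_hat^2 - V, 0),

at which point the Bayes factor has the closed form (z^2 = beta_hat^2 / V)

    BF_EB = (1/z) exp((z^2 - 1)/2)   if z^2 >= 1, else exactly 1.

The causal SNP's (beta_hat, V) are unknown in practice, so this module also
provides the surrogate estimators: V is estimated by the median V over all
SNPs, and |beta_hat| by the median |beta_hat| of the top p% of SNPs ranked
by single-SNP model likelihood (default p = 30), or by the single top-
likelihood SNP.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "EffectSizePrior",
    "wakefield_bf",
    "log_wakefield_bf",
    "estimate_w_eb",
    "bf_eb",
    "surrogate_w_eb",
    "surrogate_w_max",
    "DEFAULT_TOP_PERCENT",
]

DEFAULT_TOP_PERCENT = 30.0


@dataclass(frozen=True)
class EffectSizePrior:
    """Gaussian prior variance W for the log odds ratio, with provenance.

    method is one of {"fixed", "oracle_causal", "surrogate_top_p",
    "surrogate_max"}.  For the surrogate methods the ingredients are kept:
    beta_p (median |beta_hat| of the top p% by likelihood), V_m (median V
    over all usable SNPs) and beta_max (beta_hat of the top-likelihood SNP).
    """

    W: float
    method: str = "fixed"
    p_percent: float | None = None
    beta_p: float | None = None
    V_m: float | None = None
    beta_max: float | None = None

    def __post_init__(self) -> None:
        if self.W < 0:
            raise ValueError("prior variance W must be non-negative")


def _check_v_w(V, W) -> tuple[np.ndarray, np.ndarray]:
    V = np.asarray(V, dtype=float)
    W = np.asarray(W, dtype=float)
    if np.any(V <= 0):
        raise ValueError("V must be positive")
    if np.any(W < 0):
        raise ValueError("W must be non-negative")
    return V, W


def log_wakefield_bf(beta_hat, V, W):
    """Natural log of :func:`wakefield_bf`; safe for extreme z."""
    V, W = _check_v_w(V, W)
    b = np.asarray(beta_hat, dtype=float)
    out = 0.5 * np.log(V / (V + W)) + b * b * W / (2.0 * V * (V + W))
    return out if out.ndim else float(out)


def wakefield_bf(beta_hat, V, W):
    """Wakefield approximate Bayes factor, H1:H0 orientation.

    Equals the ratio of Gaussian marginal likelihoods
    N(beta_hat; 0, V + W) / N(beta_hat; 0, V).  W = 0 (a point-mass prior at
    no effect) gives exactly 1.
    """
    out = np.exp(log_wakefield_bf(beta_hat, V, W))
    return out if isinstance(out, np.ndarray) else float(out)


def estimate_w_eb(beta_hat, V):
    """Empirical-Bayes prior variance: max(beta_hat^2 - V, 0).

    This is the W maximising the Wakefield Bayes factor for the given
    (beta_hat, V).
    """
    V = np.asarray(V, dtype=float)
    if np.any(V <= 0):
        raise ValueError("V must be positive")
    b = np.asarray(beta_hat, dtype=float)
    out = np.maximum(b * b - V, 0.0)
    return out if out.ndim else float(out)


def bf_eb(beta_hat, V):
    """Closed-form Bayes factor at W = W_EB.

    With z^2 = beta_hat^2 / V: (1/z) exp((z^2 - 1)/2) when z^2 >= 1, and
    exactly 1 otherwise (the prior collapses to a point mass at zero).
    Always >= 1.
    """
    V = np.asarray(V, dtype=float)
    if np.any(V <= 0):
        raise ValueError("V must be positive")
    b = np.asarray(beta_hat, dtype=float)
    z_sq = b * b / V
    z = np.sqrt(np.maximum(z_sq, 1.0))
    out = np.where(z_sq >= 1.0, np.exp((z_sq - 1.0) / 2.0) / z, 1.0)
    return out if out.ndim else float(out)


def _usable(summaries):
    usable = [s for s in summaries if s.usable]
    if not usable:
        raise ValueError("no usable SNP summaries")
    return usable


def _likelihood_order(usable):
    # descending log-likelihood; ties broken by smaller V, then snp_id
    return sorted(usable, key=lambda s: (-s.loglik, s.V, s.snp_id))


def surrogate_w_eb(summaries, p_percent: float = DEFAULT_TOP_PERCENT) -> EffectSizePrior:
    """Estimate W_EB from all SNPs' summaries via the top-p% surrogate.

    The top ceil(p% of M) SNPs ranked by single-SNP likelihood supply
    beta_p = median |beta_hat|; all usable SNPs supply V_m = median V; then
    W = max(beta_p^2 - V_m, 0).  SNPs flagged monomorphic or separated are
    excluded from both pools.
    """
    if not 0 < p_percent <= 100:
        raise ValueError("p_percent must be in (0, 100]")
    usable = _usable(summaries)
    V_m = float(np.median([s.V for s in usable]))
    k = math.ceil(p_percent / 100.0 * len(usable))
    top = _likelihood_order(usable)[:k]
    beta_p = float(np.median([abs(s.beta_hat) for s in top]))
    W = max(beta_p**2 - V_m, 0.0)
    return EffectSizePrior(W, "surrogate_top_p", p_percent=p_percent, beta_p=beta_p, V_m=V_m)


def surrogate_w_max(summaries) -> EffectSizePrior:
    """Estimate W_EB from the single top-likelihood SNP's beta_hat."""
    usable = _usable(summaries)
    V_m = float(np.median([s.V for s in usable]))
    beta_max = _likelihood_order(usable)[0].beta_hat
    W = max(beta_max**2 - V_m, 0.0)
    return EffectSizePrior(W, "surrogate_max", V_m=V_m, beta_max=beta_max)
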