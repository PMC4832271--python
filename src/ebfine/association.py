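"""Per-SNP univariate logistic regression summaries.

Every downstream quantity (Wakefield Bayes factors, the empirical-Bayes
prior variance, posterior probabilities) consumes only the per-SNP summary
(beta_hat, V): the maximum-likelihood estimate of the per-allele log odds
ratio and its sampling variance from the inverse observed information.

Fits use Newton-Raphson on data aggregated by dosage level, which is exact
for the logistic likelihood and fast enough to fit hundreds of SNPs in
hundreds of simulated replicates.  Fractional (imputed) dosages enter the
score equations directly as expected allele counts.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.special import expit
from scipy.stats import norm

logger = logging.getLogger(__name__)

__all__ = [
    "SnpAssocSummary",
    "fit_snp_logistic",
    "summarize_all",
    "or_ci_to_summary",
    "summaries_to_frame",
    "BETA_CAP",
]

# |beta_hat| cap applied under complete separation; keeps Bayes factors
# finite on degenerate inputs. Fits hitting the cap are flagged.
BETA_CAP = 10.0

FLAG_OK = "ok"
FLAG_MONOMORPHIC = "monomorphic"
FLAG_SEPARATED = "separated"


@dataclass(frozen=True)
class SnpAssocSummary:
    """Single-SNP logistic-regression summary statistics.

    beta_hat is the estimated log odds ratio, V its variance from the
    inverse observed information, loglik the maximized log-likelihood of the
    single-SNP model, maf the sample minor-allele frequency and flag one of
    {"ok", "monomorphic", "separated"}.  Only flag == "ok" summaries are
    usable for Bayes-factor work.
    """

    snp_id: str
    beta_hat: float
    V: float
    loglik: float
    maf: float
    n_used: int
    flag: str = FLAG_OK

    @property
    def z_sq(self) -> float:
        return self.beta_hat**2 / self.V

    @property
    def se(self) -> float:
        return math.sqrt(self.V)

    @property
    def usable(self) -> bool:
        return self.flag == FLAG_OK

    @property
    def p_value(self) -> float:
        """Two-sided Wald p-value."""
        return 2.0 * norm.sf(abs(self.beta_hat) / self.se)


def _softplus(eta: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, eta)


def _newton_counts(
    x: np.ndarray,
    n_case: np.ndarray,
    n_ctrl: np.ndarray,
    max_iter: int = 50,
    tol: float = 1e-8,
):
    """Vectorised two-parameter Newton fits on dosage-aggregated counts.

    ``x`` holds the dosage levels, shape (K, M) or (K, 1) broadcast against
    count matrices ``n_case``/``n_ctrl`` of shape (K, M) — one column per
    SNP.  Returns arrays (b0, b1, V, loglik, converged) of length M.
    Convergence is declared when the largest score component falls below
    ``tol``; updates are step-limited to keep separated fits from
    overflowing before they are flagged.
    """
    n_tot = n_case + n_ctrl
    M = n_tot.shape[1]
    total = n_tot.sum(axis=0)
    cases = n_case.sum(axis=0)
    with np.errstate(divide="ignore"):
        b0 = np.log(cases) - np.log(total - cases)
    b1 = np.zeros(M)
    converged = np.zeros(M, dtype=bool)
    for _ in range(max_iter):
        eta = b0 + b1 * x
        mu = expit(eta)
        resid = n_case - n_tot * mu
        s0 = resid.sum(axis=0)
        s1 = (x * resid).sum(axis=0)
        converged = np.maximum(np.abs(s0), np.abs(s1)) < tol
        if converged.all():
            break
        w = n_tot * mu * (1.0 - mu)
        i00 = w.sum(axis=0)
        i01 = (x * w).sum(axis=0)
        i11 = (x * x * w).sum(axis=0)
        det = i00 * i11 - i01 * i01
        safe = det > 1e-300
        d0 = np.where(safe, (i11 * s0 - i01 * s1) / np.where(safe, det, 1.0), 0.0)
        d1 = np.where(safe, (i00 * s1 - i01 * s0) / np.where(safe, det, 1.0), 0.0)
        np.clip(d0, -10.0, 10.0, out=d0)
        np.clip(d1, -10.0, 10.0, out=d1)
        b0 += np.where(converged, 0.0, d0)
        b1 += np.where(converged, 0.0, d1)

    # separated/diverged fits: clamp beta and refit the intercept alone
    bad = ~converged | (np.abs(b1) > BETA_CAP)
    if bad.any():
        b1 = np.where(bad, np.clip(b1, -BETA_CAP, BETA_CAP), b1)
        for _ in range(max_iter):
            eta = b0 + b1 * x
            mu = expit(eta)
            s0 = (n_case - n_tot * mu).sum(axis=0)
            if np.all(np.abs(np.where(bad, s0, 0.0)) < tol):
                break
            w = n_tot * mu * (1.0 - mu)
            b0 += np.where(bad, np.clip(s0 / np.maximum(w.sum(axis=0), 1e-300), -5, 5), 0.0)

    eta = b0 + b1 * x
    mu = expit(eta)
    w = n_tot * mu * (1.0 - mu)
    i00 = w.sum(axis=0)
    i01 = (x * w).sum(axis=0)
    i11 = (x * x * w).sum(axis=0)
    det = i00 * i11 - i01 * i01
    with np.errstate(divide="ignore", invalid="ignore"):
        V = np.where(det > 0, i00 / np.where(det > 0, det, 1.0), np.inf)
    loglik = (n_case * eta - n_tot * _softplus(eta)).sum(axis=0)
    return b0, b1, V, loglik, ~bad


def _maf_from_dosage(dosage: np.ndarray) -> float:
    af = float(np.mean(dosage)) / 2.0
    return min(af, 1.0 - af)


def fit_snp_logistic(
    dosages: np.ndarray,
    phenotype: np.ndarray,
    snp_id: str = "snp",
) -> SnpAssocSummary:
    """Fit the single-SNP logistic model P(case) = expit(b0 + b1 * dosage).

    Returns a summary flagged "monomorphic" when the SNP carries no
    variation (such summaries are excluded from ranking) and "separated"
    when the MLE diverges, in which case |beta_hat| is capped at
    ``BETA_CAP``.
    """
    dosage = np.asarray(dosages, dtype=float)
    y = np.asarray(phenotype)
    if dosage.ndim != 1 or dosage.shape != y.shape:
        raise ValueError("dosages and phenotype must be 1-D and equal length")
    if not ((y == 0).any() and (y == 1).any()):
        raise ValueError("both phenotype classes must be present")

    maf = _maf_from_dosage(dosage)
    n = dosage.size
    levels, inverse = np.unique(dosage, return_inverse=True)
    if levels.size < 2:
        return SnpAssocSummary(snp_id, 0.0, math.inf, math.nan, maf, n, FLAG_MONOMORPHIC)
    n_case = np.bincount(inverse, weights=(y == 1), minlength=levels.size)
    n_ctrl = np.bincount(inverse, weights=(y == 0), minlength=levels.size)
    x = levels[:, None]
    b0, b1, V, loglik, ok = _newton_counts(x, n_case[:, None], n_ctrl[:, None])
    flag = FLAG_OK if ok[0] else FLAG_SEPARATED
    return SnpAssocSummary(snp_id, float(b1[0]), float(V[0]), float(loglik[0]), maf, n, flag)


def summarize_all(dataset) -> list[SnpAssocSummary]:
    """Fit every SNP in a :class:`~ebfine.simulate.CaseControlDataset`.

    SNP order is preserved.  Hard-called (integer 0/1/2) dosage matrices use
    a single vectorised Newton pass across all SNPs; datasets containing
    fractional dosages fall back to per-SNP fits.  The count of excluded
    (monomorphic/separated) SNPs is logged.
    """
    D = np.asarray(dataset.dosages, dtype=float)
    y = np.asarray(dataset.phenotype)
    if D.size == 0:
        raise ValueError("empty dataset")
    if not ((y == 0).any() and (y == 1).any()):
        raise ValueError("both phenotype classes must be present")

    integer_coded = np.isin(D, (0.0, 1.0, 2.0)).all()
    summaries: list[SnpAssocSummary] = []
    if integer_coded:
        case_mask = (y == 1).astype(float)[:, None]
        ctrl_mask = 1.0 - case_mask
        n_case = np.stack([(D == g).astype(float).T @ case_mask[:, 0] for g in (0.0, 1.0, 2.0)])
        n_ctrl = np.stack([(D == g).astype(float).T @ ctrl_mask[:, 0] for g in (0.0, 1.0, 2.0)])
        x = np.array([[0.0], [1.0], [2.0]])
        b0, b1, V, loglik, ok = _newton_counts(x, n_case, n_ctrl)
        afs = D.mean(axis=0) / 2.0
        mafs = np.minimum(afs, 1.0 - afs)
        n_tot = n_case + n_ctrl
        poly = (n_tot > 0).sum(axis=0) > 1
        for m, snp_id in enumerate(dataset.snp_ids):
            if not poly[m]:
                summaries.append(
                    SnpAssocSummary(snp_id, 0.0, math.inf, math.nan, mafs[m], y.size, FLAG_MONOMORPHIC)
                )
            else:
                flag = FLAG_OK if ok[m] else FLAG_SEPARATED
                summaries.append(
                    SnpAssocSummary(snp_id, float(b1[m]), float(V[m]), float(loglik[m]), float(mafs[m]), y.size, flag)
                )
    else:
        for m, snp_id in enumerate(dataset.snp_ids):
            summaries.append(fit_snp_logistic(D[:, m], y, snp_id=snp_id))

    n_excluded = sum(not s.usable for s in summaries)
    if n_excluded:
        logger.info("summarize_all: excluded %d of %d SNPs", n_excluded, len(summaries))
    return summaries


def or_ci_to_summary(
    or_point: float,
    ci_low: float,
    ci_high: float,
    level: float = 0.95,
) -> tuple[float, float]:
    """Recover (beta_hat, V) from a printed odds ratio and confidence interval.

    beta_hat = ln(OR);  V = (ln(ci_high/ci_low) / (2 z))^2 with z the
    standard-normal quantile for the interval's confidence level.
    """
    if not 0 < ci_low <= or_point <= ci_high:
        raise ValueError("require 0 < ci_low <= or_point <= ci_high")
    if not 0 < level < 1:
        raise ValueError("confidence level must be in (0, 1)")
    z = norm.ppf(0.5 + level / 2.0)
    beta_hat = math.log(or_point)
    V = (math.log(ci_high / ci_low) / (2.0 * z)) ** 2
    return beta_hat, V


def summaries_to_frame(summaries, positions=None):
    """Tabulate summaries as a DataFrame (snp_id, maf, beta_hat, se, V, loglik, flag)."""
    import pandas as pd

    frame = pd.DataFrame(
        {
            "snp_id": [s.snp_id for s in summaries],
            "maf": [s.maf for s in summaries],
            "beta_hat": [s.beta_hat for s in summaries],
            "se": [s.se if np.isfinite(s.V) else np.nan for s in summaries],
            "V": [s.V for s in summaries],
            "loglik": [s.loglik for s in summaries],
            "flag": [s.flag for s in summaries],
        }
    )
    if positions is not None:
        frame.insert(1, "position", np.asarray(positions))
    return frame
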