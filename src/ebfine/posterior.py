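"""Posterior probabilities of causal association and SNP ranking.

The posterior odds of causal association for SNP i update the prior odds
through its Bayes factor:

    Delta_i / (1 - Delta_i) = delta_i / (1 - delta_i) * BF_i.

Ranking by Delta with all delta equal reproduces ranking by BF; group-
specific priors re-order SNPs by functional plausibility.  Computation is
done in log-odds space so Bayes factors up to ~1e300 remain exact.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

__all__ = ["SnpPosterior", "posterior_prob", "rank_scores", "rank_and_filter", "posterior_table"]


@dataclass(frozen=True)
class SnpPosterior:
    """Prior, Bayes factor and posterior probability for one SNP."""

    snp_id: str
    bf: float
    delta: float
    Delta: float
    group: int | None = None
    rank: int | None = None


def posterior_prob(delta, bf):
    """Posterior probability Delta from prior probability delta and BF.

    Vectorised; computed as expit(logit(delta) + log BF).  Boundary priors
    (0 or 1) are rejected — they cannot be updated by data.
    """
    d = np.asarray(delta, dtype=float)
    b = np.asarray(bf, dtype=float)
    if np.any((d <= 0) | (d >= 1)):
        raise ValueError("prior probabilities must lie strictly in (0, 1)")
    if np.any(b <= 0):
        raise ValueError("Bayes factors must be positive")
    out = expit(np.log(d) - np.log1p(-d) + np.log(b))
    return out if out.ndim else float(out)


def rank_scores(values, ascending: bool = False) -> np.ndarray:
    """Competition ("minimum") ranks: tied values share the smallest rank."""
    s = pd.Series(np.asarray(values, dtype=float))
    if not np.isfinite(s).all():
        raise ValueError("statistic values must be finite to rank")
    return s.rank(method="min", ascending=ascending).astype(int).to_numpy()


def display_rank(ranks: np.ndarray) -> list[str]:
    """Format competition ranks with an '=' prefix on ties (e.g. '=12')."""
    ranks = np.asarray(ranks)
    counts = pd.Series(ranks).value_counts()
    return [f"={r}" if counts[r] > 1 else str(r) for r in ranks]


def rank_and_filter(
    table: pd.DataFrame,
    statistic: str = "Delta",
    threshold: float | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Rank SNPs by a statistic and optionally retain those past a threshold.

    ``statistic`` is a column of ``table`` ("Delta", "bf", "p_value", ...);
    p-values rank ascending, everything else descending.  Returns the table
    sorted by rank with ``rank`` and ``rank_display`` columns, and the
    retained subset (scores at-or-above the threshold; at-or-below for
    p-values).  A threshold beyond every score yields an empty retained set,
    not an error.
    """
    if table.empty:
        raise ValueError("cannot rank an empty table")
    if statistic not in table.columns:
        raise KeyError(f"statistic column {statistic!r} not in table")
    ascending = statistic == "p_value"
    ranked = table.copy()
    ranked["rank"] = rank_scores(ranked[statistic].to_numpy(), ascending=ascending)
    ranked["rank_display"] = display_rank(ranked["rank"].to_numpy())
    ranked = ranked.sort_values(["rank", "snp_id"] if "snp_id" in ranked else "rank", kind="stable")
    if threshold is None:
        retained = ranked
    elif ascending:
        retained = ranked[ranked[statistic] <= threshold]
    else:
        retained = ranked[ranked[statistic] >= threshold]
    return ranked.reset_index(drop=True), retained.reset_index(drop=True)


def posterior_table(snp_ids, bf, delta, group=None) -> pd.DataFrame:
    """Build a per-SNP posterior table with competition ranks by Delta."""
    bf = np.asarray(bf, dtype=float)
    delta = np.asarray(delta, dtype=float)
    Delta = posterior_prob(delta, bf)
    table = pd.DataFrame({"snp_id": list(snp_ids), "bf": bf, "delta": delta, "Delta": Delta})
    if group is not None:
        table["group"] = np.asarray(group)
    table["rank"] = rank_scores(Delta)
    table["rank_display"] = display_rank(table["rank"].to_numpy())
    return table
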