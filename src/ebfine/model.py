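"""Model/Results front end for a fine-mapping analysis.

:class:`FineMappingModel` bundles a case-control dosage matrix, phenotype
and (optionally) per-SNP functional groups; :meth:`FineMappingModel.fit`
runs per-SNP logistic regressions, chooses the prior variance of the log
odds ratio (empirical-Bayes by default), computes Wakefield Bayes factors,
solves the elicited group priors and returns a
:class:`FineMappingResults` carrying the full per-SNP table with
posterior probabilities and competition ranks.

Example
-------
>>> panel = make_haplotype_panel(200, 60, ld_profile=0.8, seed=1)
>>> data = simulate_case_control(panel, 30, 1.3, 1500, 1500, seed=2)
>>> groups = annotate_snps(60, (0.6, 0.27, 0.12, 0.01), seed=3)
>>> spec = ElicitationSpec(n=tuple(groups.sizes(4)), p0=0.4, R=5)
>>> res = FineMappingModel.from_dataset(data, groups=groups).fit(elicitation=spec)
>>> print(res.summary())        # doctest: +SKIP
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .association import summaries_to_frame, summarize_all
from .bayes import (
    DEFAULT_TOP_PERCENT,
    EffectSizePrior,
    surrogate_w_eb,
    surrogate_w_max,
    wakefield_bf,
)
from .posterior import display_rank, posterior_prob, rank_scores
from .priors import (
    ElicitationSpec,
    GroupPriors,
    solve_delta_causal_count,
    solve_delta_exact,
    solve_delta_linear,
    solve_delta_quadratic,
)
from .simulate import CaseControlDataset, GroupAssignment

__all__ = ["FineMappingModel", "FineMappingResults"]

_SOLVERS = {
    "linear": solve_delta_linear,
    "quadratic": solve_delta_quadratic,
    "exact": solve_delta_exact,
    "causal_count": solve_delta_causal_count,
}


class FineMappingModel:
    """Single-region fine-mapping model over per-SNP logistic regressions.

    Parameters
    ----------
    dosages : (N, M) array
        Minor-allele dosages in [0, 2].
    phenotype : (N,) binary array
        1 = case, 0 = control.
    snp_ids, positions : optional per-SNP metadata.
    groups : optional :class:`GroupAssignment` or (M,) int array in 1..J
        Functional prior-probability groups; required to compute
        group-specific posteriors.
    """

    def __init__(self, dosages, phenotype, snp_ids=None, positions=None, groups=None):
        dosages = np.asarray(dosages, dtype=float)
        phenotype = np.asarray(phenotype)
        N, M = dosages.shape
        if snp_ids is None:
            snp_ids = [f"snp_{m + 1:04d}" for m in range(M)]
        if positions is None:
            positions = np.arange(1, M + 1, dtype=np.int64)
        if isinstance(groups, GroupAssignment):
            groups = groups.group
        self.dataset = CaseControlDataset(
            dosages=dosages,
            phenotype=phenotype.astype(np.int8),
            snp_ids=list(snp_ids),
            positions=np.asarray(positions, dtype=np.int64),
        )
        self.groups = None if groups is None else np.asarray(groups, dtype=int)
        if self.groups is not None and self.groups.shape != (M,):
            raise ValueError("groups must give one label per SNP")

    @classmethod
    def from_dataset(cls, dataset: CaseControlDataset, groups=None) -> "FineMappingModel":
        if isinstance(groups, GroupAssignment):
            groups = groups.group
        model = cls.__new__(cls)
        model.dataset = dataset
        model.groups = None if groups is None else np.asarray(groups, dtype=int)
        return model

    @classmethod
    def from_dataframe(
        cls,
        frame: pd.DataFrame,
        phenotype_col: str = "phenotype",
        group_row=None,
    ) -> "FineMappingModel":
        """Build from a subjects-by-SNPs DataFrame with a phenotype column."""
        frame = frame.copy()
        phenotype = frame.pop(phenotype_col).to_numpy()
        return cls(frame.to_numpy(dtype=float), phenotype, snp_ids=list(frame.columns), groups=group_row)

    def fit(
        self,
        w="eb",
        p_percent: float = DEFAULT_TOP_PERCENT,
        elicitation: ElicitationSpec | None = None,
        solver: str = "linear",
        delta=None,
    ) -> "FineMappingResults":
        """Fit per-SNP models and assemble Bayes factors and posteriors.

        Parameters
        ----------
        w : "eb", "max" or float
            Prior variance of the logOR: top-p% empirical-Bayes surrogate
            (default), top-likelihood-SNP surrogate, or a fixed value.
        elicitation : ElicitationSpec, optional
            Group sizes, p0 and R; solved with ``solver`` (one of "linear",
            "quadratic", "exact", "causal_count") to give per-group deltas.
            Requires the model to carry group labels.
        delta : float or (M,) array, optional
            Directly specified prior probabilities (overrides elicitation).
            With no delta and no elicitation all SNPs share delta = 0.5 so
            ranking by posterior reduces to ranking by Bayes factor.
        """
        summaries = summarize_all(self.dataset)
        if w == "eb":
            prior = surrogate_w_eb(summaries, p_percent)
        elif w == "max":
            prior = surrogate_w_max(summaries)
        else:
            prior = EffectSizePrior(float(w), "fixed")

        table = summaries_to_frame(summaries, positions=self.dataset.positions)
        usable = (table["flag"] == "ok").to_numpy()
        bf = np.full(len(table), np.nan)
        bf[usable] = wakefield_bf(
            table.loc[usable, "beta_hat"].to_numpy(),
            table.loc[usable, "V"].to_numpy(),
            prior.W,
        )
        table["bf"] = bf
        with np.errstate(invalid="ignore"):
            from scipy.stats import norm

            table["p_value"] = 2.0 * norm.sf(np.abs(table["beta_hat"]) / table["se"])

        group_priors: GroupPriors | None = None
        if delta is not None:
            table["delta"] = np.broadcast_to(np.asarray(delta, dtype=float), (len(table),)).copy()
        elif elicitation is not None:
            if self.groups is None:
                raise ValueError("elicitation requires per-SNP group labels")
            group_priors = _SOLVERS[solver](elicitation)
            table["delta"] = group_priors.per_snp(self.groups)
        else:
            table["delta"] = 0.5
        if self.groups is not None:
            table["group"] = self.groups

        Delta = np.full(len(table), np.nan)
        Delta[usable] = posterior_prob(table.loc[usable, "delta"].to_numpy(), bf[usable])
        table["Delta"] = Delta

        for stat, ascending in (("p_value", True), ("bf", False), ("Delta", False)):
            vals = table[stat].to_numpy(dtype=float)
            ranks = np.full(len(table), -1)
            if usable.any():
                ranks[usable] = rank_scores(vals[usable], ascending=ascending)
            table[f"rank_{stat}"] = ranks
        table["rank_display"] = [
            d if u else "-" for d, u in zip(display_rank(table["rank_Delta"].to_numpy()), usable)
        ]
        return FineMappingResults(self, summaries, prior, group_priors, table)


class FineMappingResults:
    """Results of a fine-mapping fit.

    Attributes
    ----------
    summaries : list of SnpAssocSummary
    prior : EffectSizePrior (the W actually used, with its ingredients)
    group_priors : GroupPriors or None
    table : per-SNP DataFrame with beta_hat, V, maf, p_value, bf, delta,
        Delta and competition ranks for each ranking statistic.
    """

    def __init__(self, model, summaries, prior, group_priors, table):
        self.model = model
        self.summaries = summaries
        self.prior = prior
        self.group_priors = group_priors
        self.table = table

    @property
    def W(self) -> float:
        return self.prior.W

    def top(self, n: int = 10) -> pd.DataFrame:
        return self.table.sort_values("rank_Delta").head(n)

    def summary(self, top: int = 10) -> str:
        """Human-readable fit summary with the top-ranked SNPs."""
        lines = [
            "Fine-mapping results",
            "====================",
            f"subjects: {len(self.model.dataset.phenotype)} "
            f"({self.model.dataset.n_cases} cases / {self.model.dataset.n_controls} controls); "
            f"SNPs: {self.model.dataset.n_snps}",
            f"prior variance W = {self.prior.W:.6g} ({self.prior.method}"
            + (f", p = {self.prior.p_percent:g}%" if self.prior.p_percent else "")
            + ")",
        ]
        if self.prior.beta_p is not None:
            lines.append(f"  beta_p = {self.prior.beta_p:.6g}, V_m = {self.prior.V_m:.6g}")
        if self.group_priors is not None:
            deltas = ", ".join(f"{d:.3g}" for d in self.group_priors.delta)
            lines.append(
                f"group priors ({self.group_priors.method}): delta = [{deltas}]; "
                f"achieved p0 = {self.group_priors.achieved_p0:.4g}"
            )
        cols = [
            c
            for c in ("snp_id", "maf", "beta_hat", "se", "p_value", "bf", "delta", "Delta", "group", "rank_display")
            if c in self.table.columns
        ]
        body = self.top(top)[cols].to_string(
            index=False, float_format=lambda v: f"{v:.4g}"
        )
        lines += ["", f"top {top} SNPs by posterior probability:", body]
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)
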