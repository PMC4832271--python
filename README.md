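# ebfine

Empirical-Bayes fine mapping of a disease-associated genomic region:
Wakefield approximate Bayes factors with a data-driven prior variance for
the effect size, expert-elicited functional-group prior probabilities of
causal association, and posterior-probability SNP ranking — together with a
case-control genotype simulator and threshold-averaged ROC evaluation for
method studies.

## The problem

After a fine-mapping association study, one wants to rank the SNPs of a
region by Δ_i, the posterior probability that SNP *i* is causally
associated with the disease. Bayes' theorem gives the posterior odds as

    Δ_i / (1 − Δ_i) = δ_i / (1 − δ_i) × BF_i,

where δ_i is the prior probability of causal association and BF_i the
Bayes factor from the genotype data. Two practical obstacles stand in the
way: the Bayes factor needs a prior variance *W* for the log odds ratio,
which is hard to specify for common-disease alleles; and the per-SNP priors
δ_i should reflect functional genomic knowledge, which is not naturally
numeric. `ebfine` addresses both.

**Effect-size prior.** With the single-SNP logistic estimate
β̂₁ ~ N(β₁, V) and prior β₁ ~ N(0, W), the Wakefield approximation gives

    WBF = sqrt(V / (V + W)) · exp(β̂₁² W / (2 V (V + W)))

(oriented so large values favour association). As a function of *W* this is
maximised at W_EB = max(β̂₁² − V, 0), yielding the closed-form empirical
Bayes factor BF_EB = (1/z)·exp((z² − 1)/2) for z² = β̂₁²/V ≥ 1 and 1
otherwise. Because the causal SNP's (β̂₁, V) are unknown, W_EB is estimated
by surrogates: the median V over all SNPs, and the median |β̂₁| of the top
p% of SNPs ranked by single-SNP likelihood (default p = 30).

**Functional priors.** SNPs are partitioned into J ordered groups ("very
unlikely" … "very likely" to be causal) by a decision tree over binary
functional summary variables (regional location, histone modification,
availability, conservation). An expert supplies p₀, the probability that no
SNP in the region is causal, and the ratio R = δ[j+1]/δ[j]; the solvers
recover δ[1] from p₀ = Π_j (1 − δ[j])^(n_j) at first order
(δ[1] = (1 − p₀) / Σ_j n_j R^(j−1)), second order, exactly by root finding,
or under a prior on the number (0–2) of causal SNPs.

## Worked example

```python
import numpy as np
import ebfine as eb

# 60-SNP region with block LD; causal SNP 30 (MAF 0.18, per-allele OR 1.3)
mafs = np.random.default_rng(1).uniform(0.05, 0.5, 60)
mafs[30] = 0.18
panel = eb.make_haplotype_panel(
    400, 60, maf_sampler=mafs, ld_profile=eb.block_ld_profile(60, 10, 0.9), seed=1
)
data = eb.simulate_case_control(panel, causal_index=30, or_per_allele=1.3,
                                n_cases=1500, n_controls=1500, seed=2)
groups = eb.annotate_snps(60, (0.55, 0.25, 0.15, 0.05), seed=3).with_snp_in_group(30, 4)
spec = eb.ElicitationSpec(n=tuple(int(v) for v in groups.sizes(4)), p0=0.4, R=5)
res = eb.FineMappingModel.from_dataset(data, groups=groups).fit(elicitation=spec, solver="exact")
print(res.summary(top=5))
```

prints

```
Fine-mapping results
====================
subjects: 3000 (1500 cases / 1500 controls); SNPs: 60
prior variance W = 0.00673548 (surrogate_top_p, p = 30%)
  beta_p = 0.0996428, V_m = 0.0031932
group priors (exact_root): delta = [0.00123, 0.00616, 0.0308, 0.154]; achieved p0 = 0.4

top 5 SNPs by posterior probability:
  snp_id    maf  beta_hat      se   p_value     bf   delta   Delta  group rank_display
snp_0031 0.2507    0.1971 0.05953 0.0009271  21.35  0.1539  0.7953      4            1
snp_0023  0.281  -0.09527 0.05837    0.1027  1.404  0.1539  0.2034      4            2
snp_0026 0.3747 -0.002783 0.05275    0.9579 0.5412  0.1539 0.08965      4            3
snp_0021 0.3507   -0.1204 0.05493   0.02838  2.923 0.03079 0.08496      3            4
snp_0058  0.387   0.09567 0.05388   0.07582  1.651 0.03079 0.04984      3            5
```

The prior variance W was estimated from the data (top-30% surrogate); the
true causal SNP (snp_0031, 1-based id for index 30) tops the posterior
ranking: its Bayes factor of 21 combines with the group-4 prior
δ = 0.154 to give Δ ≈ 0.80, while equally associated SNPs in lower groups
are shrunk towards their smaller priors. `achieved p0 = 0.4` confirms the
exact solver hit the elicited no-causal probability.

A command-line interface mirrors the library:

```sh
ebfine simulate --n-snps 60 --out-prefix toy         # GEN/SAMPLE output
ebfine assoc --gen toy.gen --sample toy.sample --out toy.summ
ebfine bf --summaries toy.summ --w auto --p 30 --out toy.bf
ebfine elicit --n 1698,780,362,31 --p0 0.4 --r 5 --method linear
ebfine rank --summaries toy.summ --groups toy.groups --out toy.rank
ebfine run-scenario --config scenario.yaml --out runs/
```

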