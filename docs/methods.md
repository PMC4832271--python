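# Methods

## Model and statistics

For each SNP *i* a univariate logistic regression of case status on
minor-allele dosage x ∈ [0, 2] gives the per-allele log odds ratio estimate
β̂₁ with variance V (inverse observed information) and the maximized
log-likelihood of the single-SNP model. Fits use Newton–Raphson on data
aggregated by dosage level, which is exact for the logistic likelihood;
convergence is declared when the largest score component is below 1e-8
(at most 50 iterations). Fractional (imputed) dosages enter the score
equations directly as expected allele counts. A multiplicative genetic
model is assumed throughout; covariates are out of scope.

The Wakefield approximation with prior β₁ ~ N(0, W) gives
WBF = sqrt(V/(V+W))·exp(β̂₁²W / (2V(V+W))), equal to the Gaussian
marginal-likelihood ratio N(β̂₁; 0, V+W)/N(β̂₁; 0, V) and oriented so large
values support association. As a function of W it is unimodal with maximum
at W_EB = max(β̂₁² − V, 0); at that maximum the Bayes factor is
BF_EB = (1/z)exp((z²−1)/2) for z² = β̂₁²/V ≥ 1 and exactly 1 otherwise (the
empirical prior collapses to a point mass, so the factor never falls below
1). Posterior probabilities follow from posterior odds = prior odds × BF,
computed in log-odds space so Bayes factors up to ~1e300 lose no precision.

## Surrogate estimators for W_EB

The causal SNP's (β̂₁, V) are unknown, so W_EB is built from surrogates:
V is replaced by the median V over all usable SNPs (V_m) and |β̂₁| by the
median |β̂₁| of the top p% of SNPs ranked by single-SNP likelihood (β̂_p),
with p = 30 by default; an alternative uses the single top-likelihood SNP
(β̂_max). Choices fixed here where the method description leaves room:

- "ranked by likelihood" means ranked by the maximized log-likelihood of
  the single-SNP model on complete data (all SNPs share the same subjects,
  so likelihoods are comparable; with per-SNP missingness a likelihood
  ratio against the SNP's own null fit would be the comparable quantity).
- The top set has ceil(p/100 · M) members; likelihood ties break by smaller
  V, then SNP id, so results are reproducible.
- Medians use the midpoint convention for even counts.
- SNPs flagged monomorphic or separated are excluded from both the top-p%
  pool and V_m: they carry no stable (β̂₁, V). Complete separation caps
  |β̂₁| at 10 (flagged), keeping Bayes factors finite on degenerate input.
- p is exposed as a parameter: 30 suits a region with LD structure like the
  one studied here, but no region-adaptive rule exists, so other regions
  may need a different value.

## Elicited functional-group priors

SNPs are partitioned into J ordered groups by an ordered decision-rule
config over four binary summary variables (regional location, histone
modification, availability, conservation). Missing annotation values are
zeroed before thresholding, on the assumption that they are missing because
the measurement did not exceed its reporting threshold. The exact expert
tree is study-specific, so the shipped default is a count-based tree
(0 positive variables → group 1, 1 → 2, 2 → 3, ≥3 → group 4); users supply
their own YAML rule list to encode a different expert tree. The synthetic
annotation generator produces tables whose default-tree partition has
prescribed group sizes (canonically 1698/780/362/31 over 2,871 SNPs).

Group priors solve p₀ = Π_j (1 − δ[j])^{n_j} with δ[j+1] = R_j·δ[j]:

- **linear** — δ[1] = (1 − p₀)/Σ_j n_j R^{j−1} (common R). Accurate only
  when every n_jδ[j] is small; its achieved p₀ is ≈ exp(−(1−p₀)), e.g.
  0.549 instead of an elicited 0.4 — a diagnostic the package recomputes
  and stores on every solution.
- **quadratic** — the second-order truncation a·δ² + b·δ + c = 0 with
  a = Σ n_j²R^{2j−2} + Σ_{j<j*} n_j n_{j*} R^{j+j*−2}, b = −Σ n_jR^{j−1},
  c = 1 − p₀, taking the smaller positive root (δ must be ≪ 1). The
  coefficient a uses n_j², not C(n_j, 2); the formula is implemented in
  that printed form deliberately, and the exact solver is the recommended
  path whenever precision matters. A negative discriminant raises a typed
  NoRealRootError directing callers to the exact solver — this genuinely
  happens for the canonical R = 5, p₀ = 0.4 sizes, where the truncation is
  poor.
- **exact** — bracketed Brent root finding on δ[1] (group-specific R_j
  allowed); achieved p₀ matches the elicited value to 1e-12.
- **causal-count** — the identity 1 = p₀ + p₁Σ n_jδ[j] + p₂[Σ n_j²δ[j]² +
  Σ_{j<k} n_j n_k δ_j δ_k] for a prior over 0/1/2 causal SNPs, solved as a
  quadratic in δ[1] with (p₀, p₁, p₂) taken as given weights in the printed
  identity (they are not renormalised; with weights (p₀, 1, 0) the solution
  reduces exactly to the linear solver's).

Diagnostics report achieved p₀, per-group mass n_jδ[j], the indicator
R^{j−1}/n_j for where expansion terms are needed, and the second-to-first
binomial term ratio δ[j](n_j−1)/2.

## Synthetic data generator

The simulator stands in for a coalescent/reference-panel pipeline at desk
scale. Haplotypes follow a first-order Markov chain across sites: site m+1
is Bernoulli with conditional mean matching a target adjacent-site
correlation, organised in blocks (within-block r, near-zero between
blocks). This gives direct control over adjacent r² at the cost of realism:
long-range LD decays geometrically rather than following a recombination
map, there is no mutation/gene-conversion fine structure, and allele
frequencies are drawn independently of LD. Consequences: simulation tests
demonstrate the method's behaviour under controllable LD, not performance
numbers transferable to a real region — published full-scale AUCs depend on
the real LD structure and are deliberately not targets. Monomorphic columns
arising by chance are repaired by flipping one haplotype so every site
stays polymorphic, and sites are recoded so allele 1 is the minor allele.

Case-control datasets are sampled retrospectively: individuals are formed
from two panel haplotypes drawn with replacement, disease status follows a
logistic model with per-allele log OR at the single causal site and an
intercept solved (Brent) to a population prevalence of 0.01 — the
prevalence is not part of the published design and only sets the rejection
rate, since β̂₁ and V drive every downstream statistic. Rejection sampling
fills the case and control quotas exactly and aborts after 10⁷ simulated
individuals. Positions are 1-based coordinates spread over a 1 Mb region
matching the studied locus. Everything is deterministic given the seed.

## Evaluation

Filtering performance over replicates uses threshold averaging: a common
descending threshold grid (512 pooled-score quantiles by default, plus ±inf
sentinels; the published analysis does not state its grid), per-replicate
TPR/FPR with "at-or-above" retention, averaged across replicates; AUC by
trapezoid. Uncertainty comes from a replicate-level bootstrap (1,000
resamples), which makes directional comparisons well defined.
`retained_at_tpr` picks the largest threshold whose mean TPR reaches the
target — the fewest-SNPs reading of "numbers retained at TPR 0.9"; the
smallest such threshold would trivially be the minimum score. The
train/test protocol estimates W_EB on one member of a dataset pair and
applies it to the other, so a same-data vs train-test curve gap measures
overfitting from using the data twice.

## Problem sizes used in the checks

The simulation-based checks run at sizes chosen once for a single CPU:
parameter recovery uses 500 replicates of 1,000+1,000 subjects on an
11-SNP panel (MAF 0.18, OR 1.10); the prior-ordering ROC check uses 300
SNPs (group sizes 177/82/38/3, the largest-remainder scaling of the
canonical proportions), 200 replicates per scenario, 2,500+2,500 subjects,
block LD (size 15, adjacent r 0.95), causal MAF 0.18, OR 1.1, R = 5 linear
priors. At these sizes the ordering AUC(Δ, causal in group 4) >
AUC(BF) > AUC(Δ, causal in group 1) is separated by many bootstrap
standard deviations; the absolute AUC values are panel-specific.

## Known limitations

- Single causal variant only; no credible sets, joint/multi-SNP Bayes
  factors, covariates, or X chromosome.
- The Bayes factor consistency check against published per-SNP values is
  limited by the precision of printed odds ratios and confidence limits:
  with V recovered from a 3-decimal CI, two of twenty published rows
  reconstruct more than 10% away from their printed Bayes factors while the
  rest agree well.
- The annotation pathway expects pre-summarized binary variables; raw
  ENCODE-style feature extraction and thresholds are the user's
  responsibility (rule configs are editable YAML).
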