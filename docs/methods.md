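# Methods

## Model and estimation

Droplet counts are modeled as a mixture of K+1 multinomials: one ambient
(debris) component and K cell types. For droplet i with counts **x**ᵢ and
total uᵢ,

    P(xᵢ) = Σₖ πₖ Mult(xᵢ | αₖ, uᵢ),   k = 0 … K,

with component 0 the debris pool. The multinomial coefficient depends only
on **x**ᵢ and cancels in every posterior, so component scores omit it;
reported log-likelihoods are therefore comparable only within a run (a
coefficient-including variant exists for absolute values). EM alternates:

- **E-step** (log space, max-subtraction): posterior
  p(zᵢ=k | xᵢ) ∝ πₖ exp(Σ_g x_g log α_kg). Droplets whose total count is
  below the fixed threshold T are overwritten with a one-hot posterior at
  the debris component. This E-step overwrite is mathematically equivalent
  to constraining the latent labels in the likelihood and is the entire
  semi-supervision mechanism.
- **M-step**: αₖ ∝ Σᵢ rᵢₖ xᵢ + 10⁻¹⁰ per gene (renormalized); πₖ = mean
  responsibility. The pseudocount keeps every probability strictly
  positive; a component that loses essentially all posterior mass
  (< 10⁻⁸·N) collapses to the uniform distribution rather than being
  pruned mid-run — pruning happens only at initialization.

Convergence: maximum absolute change over all α and π entries below
ε = 10⁻⁴ (infinity norm; the default cap is 1000 iterations). The trace
records the observed-data log-likelihood at each iteration's pre-update
parameters; for fixed droplets the debris-component joint term is used,
which is the quantity this EM provably ascends. Hard assignments take the
maximum posterior, ties to the lowest component index.

Because the pseudocount perturbs the exact M-step maximizer, monotonicity
holds up to a relative tolerance of 10⁻⁸ rather than exactly; in practice
the perturbation is many orders smaller.

## Initialization

Only expressed genes (nonzero total count) are used. Droplets with
< T = 100 counts form the fixed debris set; their pooled counts initialize
α₀. Test droplets with ≥ 200 genes detected form the cluster set. Cluster-
set counts are scaled per droplet to the median cluster-set depth and
log(1+·)-transformed (the median is taken over the cluster set, i.e. the
matrix actually being normalized). Variable genes: per-gene mean and
variance of the *raw* counts over the cluster set are log-transformed; a
lowess regression (span 0.3, no robustness iterations) of log variance on
log mean supplies the expected variance, and genes are ranked by the
residual (standardized variance), ties broken by gene id; the top
V = 2,000 are kept. The lowess smoother is locally linear; a locally
quadratic fit would differ slightly in curvature but only the *ranking* of
residuals enters downstream. Genes with zero mean or variance in the
cluster set are excluded from the fit (log of zero is undefined).

PCA (full SVD, genes centered but not scaled to unit variance) gives 30
components; k-means (k-means++ seeding, 10 restarts, seeded) labels the
cluster set with k clusters, k chosen by the user. A practical guideline:
overestimate the number of expected cell types, and add at least one extra
cluster when ambient droplets are expected to clear the cluster-set gene
cutoff, so the background can form its own cluster (the package's default
k = 20 is a generous overestimate in that spirit). Initial α and π pool
counts and frequencies over the labeled droplets; empty k-means clusters
are dropped with renumbering. Test droplets below the cluster-set cutoff
receive no initial label and simply enter the first E-step.

## Debris scoring

Debris clusters = the fixed component plus every cluster averaging fewer
than d = 200 detected genes. Expression is normalized per droplet to
proportions and log(1+·)-transformed (depth-invariant). Welch's t-test
between test-set droplets of the debris vs cell-type clusters, two-sided
p-values, Benjamini–Hochberg FDR; enriched = log fold change > 0 (difference
of group means on the normalized scale; only its sign matters) and
q < 0.05. Raw score = summed normalized expression over enriched genes,
computed for every droplet including fixed ones.

Normalization: with m_low the smallest per-cluster mean raw score and
m_deb the mean over droplets in debris clusters, normalized =
(raw − m_low) / (m_deb − m_low). Literal division by m_deb alone would pin
the debris average at 1 only if m_low were 0; the anchored form achieves
the intended effect for any m_low and is the default ("literal" is
available via `score_norm`). Cluster means are taken over *all* droplets
assigned to a cluster, fixed droplets included — the fixed debris cluster
may contain few or no test-set droplets, which would otherwise leave the
debris anchor undefined. Both anchors (cleanest cluster mean 0, debris
mean 1) then hold exactly by construction.

Filtering keeps test-set droplets with normalized score < t = 0.5 (score
mode) or outside the debris clusters (cluster mode, useful for single-cell
rather than single-nucleus data); fixed droplets are always removed. The
kept set is monotone in t. Scores are calibrated within one sample only
and are not comparable across independently processed samples.

## Quantile baseline

Totals are sorted in decreasing order; the threshold is the 0.99 quantile
(linear interpolation between order statistics — the convention is
configurable and mirrored by the test oracle) of the top C = 3,000 totals,
divided by 10; droplets with totals ≥ threshold are kept. The high
quantile protects the estimate from doublets at the top of the curve. With
fewer than C droplets, all are used, with a warning.

## Contamination metrics

Percent spliced = spliced / (spliced + unspliced) per droplet, ambiguous
molecules excluded from both numerator and denominator and mitochondrial
genes removed before aggregation (MT genes have no introns and would
inflate the spliced fraction). A zero denominator yields an undefined
(NaN) value, never a silent 0. MT% and MALAT1% are set-fraction metrics:
summed counts on the gene set over the droplet total.

The midpoint classifier fits a two-component Gaussian mixture to the
percent-spliced values (EM, means initialized at the 25th/75th percentiles
for determinism) and solves w₁φ₁(x) = w₂φ₂(x) — a quadratic in x, linear
when variances are equal. The root strictly between the means is the
midpoint; lacking one, the root nearest the means' midpoint is used with a
warning. A fit whose means are closer than twice the larger component
standard deviation is treated as single-mode (two equal-variance Gaussians
produce a bimodal density only beyond that separation) and the midpoint
falls back to the overall mean, with a warning. Droplets at or above the
midpoint are background (ties to background), below are nuclear, undefined
values unclassified. Clusters averaging ≥ 50% spliced are debris.

## Synthetic data

The generator draws one ambient and K cell-type gene-probability vectors
from a symmetric Dirichlet (concentration 1 by default — heavy-tailed
profiles with a realistic spread between types) and multiplies 50 marker
genes in the ambient profile by 5 before renormalizing, giving the
background pool an enriched signature analogous to the systematic
differences observed between background and nuclear RNA. Empty droplets
draw totals log-uniformly on [1, 300) and sample from the ambient profile
(ρ = 1). Nuclei draw totals log-uniformly on [200, 3000), a contamination
fraction ρ ~ Beta(1, 9) (mean 10%, long right tail — a minimal model of
the observed continuum of per-droplet contamination), an ambient molecule
count Binomial(u, ρ), and counts from the ambient/type multinomials, so
E[count_g] = u·((1−ρ)p_type,g + ρ·p_amb,g). The empty-droplet upper bound
of 300 deliberately overlaps the fixed threshold: about 80% of empties
fall into the fixed set, while the rest reproduce the defining failure
mode of hard-count filters — background droplets above any threshold. The
default scenario is 1,000 genes, 3 types × 300 nuclei, 5,000 empties; it
simulates and filters in a few seconds on one CPU.

The splice generator labels each molecule spliced via a Bernoulli with
probability 0.8 (ambient origin) or 0.25 (nuclear origin); ambiguous
counts are zero.

What the simulator does *not* emulate: gene-length and capture biases, UMI
collisions, doublets, batch effects, overdispersion beyond the mixed
multinomial, and realistic gene-count magnitudes. Passing tests therefore
demonstrate correctness of the estimation machinery and the internal
consistency of the scoring, not performance guarantees on real tissue.

## Evaluation conventions

- Component-recovery error is the total-variation distance between each
  fitted α and the *contamination-weighted* true component profile
  (Σᵢ uᵢ[(1−ρᵢ)p_type + ρᵢ p_amb] / Σᵢ uᵢ), i.e. the component's actual
  estimand; distance to the pure type profile would instead measure the
  contamination bias, ≈ E[ρ]·TV(type, ambient), which is a property of the
  data, not the estimator. A separate test confirms pure-profile recovery
  when ρ = 0.
- Midpoint-classifier agreement with true droplet origin is evaluated on
  droplets with ≥ 100 spliced+unspliced molecules; below that the percent
  spliced is dominated by binomial noise (a 3-molecule droplet cannot be
  classified), and downstream the classifier only ever sees test-set
  droplets (≥ 100 counts).
- Acceptance-style runs of the default scenario use k = 4 (three simulated
  types plus one ambient cluster), per the guideline above.

## Numerical notes and edge cases

- Zero-count droplets are retained at I/O time; they land in the fixed
  debris set (their E-step row is the prior, then overwritten one-hot).
- e_step raises if a droplet's likelihood is −∞ in every component;
  impossible once the pseudocount is applied.
- Exact posterior ties in assignment go to the lower component index.
- Welch's test on a gene with zero variance in both groups returns t = 0,
  p = 1 (never enriched).
- `normalize_scores` raises when the debris-cluster mean does not exceed
  the lowest cluster mean — the signal that differential expression found
  no real background signature upstream.
- All stochastic steps (simulation, k-means, mixture fits) consume an
  explicit integer seed; reruns are bit-identical.

## Known limitations

- K is user-specified; there is no model-selection rule over K.
- The multinomial ignores overdispersion; strongly heterogeneous ambient
  pools may need more than one debris cluster (the d-rule usually absorbs
  them).
- If the background differs little from the cell types, few or no
  debris-enriched genes exist and scoring degrades; the code raises rather
  than returning unreliable scores.
- Debris scores are not comparable across samples; filter each sample
  independently.
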