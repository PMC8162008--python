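# Methods

This note documents the models and procedures implemented in `expherit`,
the choices made where the design was genuinely open, and what the synthetic
data does and does not establish.

## Setting

The pipeline targets a recurring design in crop transcriptomics: a
genotyped, inbred diversity panel assayed by RNA-seq under a control and a
stress condition with a small number of biological replicates. The
scientific questions are (i) how heritable each gene's expression is under
each condition, (ii) which genes are heritable only under stress, and
(iii) whether such stress-specific heritability clusters in chromosomal
neighbourhoods and follows large-scale chromatin organisation.

## Expression representation and presence classes

Expression enters as gene-level TPM. A TPM of exactly zero is treated as a
missing observation, not as a small value: the matrix stores log2(TPM) with
an explicit boolean mask and no pseudocount. The per-gene, per-condition
missing rate (replicates pooled) defines three presence classes:
constitutive (< 5% missing), repressed (> 95% missing), mixed (otherwise).
Both inequalities are strict, so rates of exactly 0.05 or 0.95 classify as
mixed. A pooled-across-conditions rate is also exposed, since genome-wide
missingness summaries can be read either way. The 3×3 control × salt
contingency table carries margins and symmetric transition counts
(`transitions(a, b) = cell(a→b) + cell(b→a)`).

## Structure adjustment

Marker-derived population structure is removed from expression before any
heritability estimation. Genotype PCA uses the column-centered (not
variance-scaled) dosage matrix — the common convention for
population-structure PCs — with a deterministic sign rule (largest-magnitude
score positive). For each gene, expression is regressed by OLS on an
intercept plus the top k PCs (default k = 3) separately within each
condition × replicate stratum; residuals become the adjusted values. Masked
cells never enter the design; a gene-stratum with fewer than k + 2 unmasked
samples is marked missing rather than fitted. The adjustment is a
projection, hence idempotent, and residuals are orthogonal to the fitted
design within each stratum.

## Relationship matrix

Markers with minor-allele frequency below 5% (strict) are removed. The GRM
is VanRaden's first method with observed allele frequencies:
W = M − 2p, K = WW′ / (2 Σ p(1−p)). K is symmetrised and numerically
negative eigenvalues are clipped at zero (tolerance 1e−8), because the REML
solver requires K ⪰ 0. No shrinkage is applied.

## Heritability estimators

Three estimators per gene and condition:

* **Repeatability** — Pearson or Spearman correlation between the two
  replicate vectors across genotypes, an upper bound on h² for inbred
  lines. Pairs with a masked member are dropped; a zero-variance replicate
  vector yields a flagged undefined estimate.
* **Single-step GREML** — the mixed model y = 1μ + Zg + e with
  g ~ N(0, σg²K), e ~ N(0, σe²I) fitted on replicate-level observations.
* **Two-step GREML** — the same model on genotype means (Z = I). Averaging
  r replicates divides the error variance by r, so at generating
  (observation-scale) heritability h² the two-step estimand is
  r·h²/(1 + (r−1)h²); with r = 2 and h² = 0.5 this is 2/3, and the test
  suite checks recovery of that value.

h² is reported on the observation scale σg²/(σg²+σe²) for both GREML
variants; the mean-scale value is derivable from the stored components.

### REML solver

The solver follows the efficient mixed-model (EMMA-style) spectral
strategy. With S the intercept-projection, one eigendecomposition of
S(ZKZ′ + I)S reduces the restricted likelihood to a 1-D function of
λ = σg²/σe². The profile is evaluated on a 100-point log-spaced grid over
λ ∈ [e⁻¹⁰, e¹⁰] and the best bracket refined by bounded scalar minimisation
to |Δlog λ| < 1e−8. Boundary optima are legitimate: λ → 0 returns σg² = 0
and λ at the upper box edge returns h² ≈ 1, both with `converged = True`.
A response with no variance after projection raises a degenerate-gene
error. The workspace (eigendecomposition) depends only on K and the
observation→genotype layout, so it is computed once and reused across
genes and permutations sharing a missingness pattern — this is what makes
the permutation null affordable (~1 ms per fit at n = 168).

The solver is verified against two independent oracles: a dense
matrix-inversion restricted likelihood (agreement to 1e−6 on random small
instances; in practice ~1e−11) and, for K = I with balanced replicates,
the closed-form one-way ANOVA estimators σ̂g² = (MSB − MSW)/2, σ̂e² = MSW.

### Confidence intervals

95% intervals invert the profile restricted likelihood at the χ²(1) 0.95
quantile, on the λ scale and mapped to h². Estimates frequently sit on the
[0, 1] boundary at n = 84, where curvature-based (Wald) intervals are
invalid; profile intervals remain defined and simply truncate at 0 or 1.

## Permutation significance

The null h² distribution is built by repeatedly (default 40,000 iterations;
the iteration budget is a parameter) drawing one gene uniformly at random,
shuffling its expression, and re-fitting single-step GREML. One pooled null
and one threshold — the empirical (1−α) quantile, linear (type-7)
interpolation, α = 0.01 — apply to all genes. The default shuffle permutes
genotype blocks with replicate pairs kept intact, which nulls exactly the
genotype–kinship association the GREML tests while preserving the replicate
error structure; shuffling all samples independently (a stricter null that
also destroys within-genotype correlation) is available as
`permute_mode="samples"`. Note the pair-preserving null is conservative
when heritable genes are included in the shuffled pool, because permuted
heritable genes retain within-pair covariance that REML attributes to σg²;
the calibration guarantee (empirical type-I error = α within Monte-Carlo
error) is stated for a null transcriptome. Genes are then classified
general / control-specific / salt-specific / not heritable by strict
threshold exceedance per condition.

## Spatial enrichment

Sliding windows (1.5 Mb every 100 kb for enrichment; 3 Mb is the density
default) start at position 1; a chromosome shorter than one window yields a
single covering window. Genes are assigned to windows by midpoint,
floor((start+end)/2) — the one rule that makes a non-overlapping tiling
conserve the gene count exactly. Each window's one-tailed Fisher exact p
is the upper hypergeometric tail of [in-window vs out] × [salt-specific vs
other-heritable]. Windows with no heritable genes get p = 1 and a flag.

Adjusted p-values come from a resampled null: each iteration draws a
random subset of the heritable genes of the same size as the salt-specific
set and recomputes every window's Fisher p; adjusted_p =
(1 + #{null p ≤ observed p}) / (1 + B). The +1 correction keeps adjusted_p
positive and gives the escalation rule a concrete trigger: windows with
zero exceedances after the base B = 4000 iterations escalate in batches to
B_max = 50,000. Significance is strict (adjusted p < 0.001). Significant
windows on a chromosome merge into regions when overlapping or abutting
within one step. Because the null subset is an exchangeable draw, each
window's adjusted p converges to an exact hypergeometric tail probability;
the tests exploit this as an analytic calibration oracle.

## Compartment correlation

Gene-class density is counted by midpoint in fixed non-overlapping bins
(default 500 kb) and correlated per chromosome (Spearman by default) with
an A/B compartment eigenvector track re-binned by length-weighted
averaging onto the same grid. Chromosomes with fewer than 5 usable bins
are flagged unreliable. Positive eigenvector = A compartment.

## Synthetic data

The generator's defaults are the study conditions: 84 genotypes in 5
subpopulations, 2 conditions × 2 replicates, 2000 markers and 3000 genes on
4 chromosomes of 30 Mb, subpopulation divergence F = 0.2, class fractions
0.30/0.47/0.23 (the observed genome-wide mix), per-gene h² drawn from
{0, 0.2, 0.5, 0.8} for constitutive genes, replicate σe = 1, one planted
hotspot of 17 salt-specific genes (h² 0/0.6 control/salt) in a 1.5 Mb
interval of Chr1 — the magnitude of the reported enrichment windows — and
an eigenvector noise SD of 0.5, which puts the constitutive-density
correlation near 0.85–0.9, the strength regime reported for real data.

Genotypes follow the Balding–Nichols model (ancestral p ~ U(0.1, 0.9),
subpopulation frequencies Beta-drifted with parameter F, inbred dosages
Binomial(2, p)). Genetic values are drawn directly as u ~ N(0, σg²K) rather
than through explicit marker effects — the analysis consumes only K-level
signal. Zero-inflation overwrites latent values (zero probabilities 0.003 /
U(0.15, 0.85) / 0.995 by class, chosen so realized missingness stays inside
each class's defining band even with only a few dozen samples per
condition). Repressed genes concentrate 80% in a central pericentromeric
interval (30% of the chromosome) and constitutive genes avoid it (20%
acceptance inside), which makes repressed density anticorrelate with the
eigenvector by construction. Determinism: one integer seed, with
independent substreams per component, reproduces every artifact exactly.

Passing tests on this generator demonstrate that the estimators, nulls and
scans behave correctly when their modelling assumptions hold. They do not
establish robustness to features of real RNA-seq the generator omits:
count-level noise and library-size effects, LD beyond subpopulation drift,
cis/trans eQTL architecture, condition-dependent class switching, or
non-Gaussian expression tails.

## Problem sizes used in the shipped checks

The automated checks run at the study's design scale where the property
concerns the estimators (84 genotypes × 2 × 2; 50 genes per h² level; 2000
null genes with a 5000-iteration permutation null) and at reduced scale for
pure-arithmetic or oracle checks (REML instances of n ≤ 10; Fisher margins
≤ 30 enumerated exhaustively; 10 seeds for hotspot recovery with B = 4000
resampling iterations escalating to 50,000). These sizes are the package's
own verification choices; every threshold (±0.10 recovery, type-I error
within 1.96·√(α(1−α)(1/5000 + 1/2000)), ≥ 9/10 hotspot recovery) was fixed
from the design before measurement.

## Known limitations

* The GREML model is intercept-only; no fixed covariates beyond the PC
  pre-adjustment are supported inside the REML fit.
* The two-step/single-step CIs assume the χ²(1) profile calibration, which
  is approximate at n = 84 and near boundaries.
* Window chromosome lengths default to the maximum annotated gene end when
  no length table is supplied, which shortens terminal windows on sparsely
  annotated chromosome ends.
* Multi-allelic VCF sites are collapsed to any-alternate dosage.
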