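# Methods

## Estimation model

All information quantities are Gaussian-copula estimates in bits.  A
node vector of n observations is mapped to normal scores
Φ⁻¹(r/(n+1)) from its ranks (average rank on ties), and entropies of
1-, 2- and 3-dimensional score blocks use the closed Gaussian form
½·log₂((2πe)^d det Σ̂) with the sample covariance (ddof = 1) of the
demeaned scores.  By construction every MI is invariant under strictly
monotone transforms of any margin, so standardization or other monotone
preprocessing of expression values is irrelevant to the result.  The
price of the copula model is that only monotone-dependence structure is
seen: purely non-monotone interactions (an XOR-style relation between
sources and target) are invisible to it.  This is a known property of
the estimator, not of PID itself, and is the reason the synthetic
generators below are built from Gaussian factor models where the
estimator's target quantities have exact closed forms.

A digamma-based correction for the expected log-determinant of a Wishart
sample covariance is subtracted from each estimated entropy
(`bias_correct=True`, the default for estimates).  The analytic oracle
`mi_gaussian_analytic` never applies it.  The correction removes
essentially all bias at the sample sizes used here (seed-averaged error
≤ 0.01 bits at n = 1000); single-draw scatter is governed by sampling
variance, roughly (1−ρ²)-scaled and irreducible for any
correlation-plug-in estimator.

Degenerate inputs: constant node vectors are rejected at load time.
Two variables with *identical ranks* (one a monotone copy of the other)
have unbounded copula MI; `gcmi` raises a named error rather than
jittering, because any deterministic perturbation would merely fabricate
an arbitrary large value for a quantity that is genuinely undefined.
Heavily tied but non-identical variables need no special handling.

## PID and the synergy tensor

The minimum-MI completion defines redundancy as min(I(X₁;Y), I(X₂;Y));
unique and synergistic atoms follow by the lattice equations, so the
closure identity I(X₁,X₂;Y) = Red + Unq₁ + Unq₂ + Syn holds *exactly by
construction* for estimated atoms, and all atoms are non-negative for
exact Gaussian inputs.  Estimated synergy may be slightly negative
through estimation noise; it is retained in the tensor (useful as a
diagnostic) and clipped only when a matrix is converted to a
dissimilarity.

The all-triplet sweep is evaluated from a single (n_nodes × n_nodes)
score covariance: 1-/2-/3-dimensional entropies are closed-form
determinant expressions, broadcast over source pairs and chunked over
the target index, so memory stays at O(n²) per chunk and the full
140-node tensor (1.3 M triplets) takes seconds.  The broadcast applies
exactly the same elementwise expressions as a per-triplet loop over the
same covariance, and a test asserts bit-identity between the two routes;
agreement with fully independent `pid_triplet` calls (which re-rank from
raw data) is asserted at 1e-9 bits.  A node never serves as both source
and target in one triplet; the tensor is symmetric in its sources and
its (i<j, k) entry count is C(n,2)·(n−2).

"Averaging over targets" is the arithmetic mean of syn(i,j;k) over the
n−2 admissible targets k, giving a symmetric pairwise matrix with a zero
diagonal.

## Synergy as similarity, not distance

A substantive design finding: in jointly Gaussian systems with shared
latent factors, *redundant* (same-group) source pairs carry **higher**
target-averaged synergy than unrelated pairs.  Two noisy copies of the
same factor jointly denoise it, and that joint gain is exactly what the
synergy atom measures.  The analytic factor-model computation shows this
uniformly across noise levels and angle separations for two-group
systems.  Consequently the averaged synergy matrix behaves as a
similarity, and the default conversion inverts it
(`max_minus`: d = max(M) − M off-diagonal), the same convention used for
the pairwise-MI baseline.  The non-inverted `direct` mode (clip
negatives, zero the diagonal) remains available as a flag; for
three-group systems with near-orthogonal loadings (0°/45°/90°) it is
the convention under which the planted partition is recoverable, because
middle-angle nodes act as high-synergy targets for outer source pairs
and break the simple block ordering.  Both conventions can be run and
compared from the CLI.

## Clustering and model selection

PAM is the classical BUILD + SWAP algorithm on a precomputed
dissimilarity: greedy seeding that minimizes total cost, then repeated
application of the single (medoid, non-medoid) exchange with the largest
cost decrease until no exchange improves, with all ties broken by lowest
node index so results are deterministic.  `max_swaps` defaults to 10·n
purely as a termination guard.  The number of clusters is chosen by the
mean silhouette width over k = 2..min(10, n−1), ties to the smaller k;
members of singleton clusters get silhouette 0 (the usual convention).

Classical PAM has genuine swap-local optima on unstructured random
dissimilarities: on uniform-random symmetric 8-node matrices it returns
the exhaustive-search optimum on roughly 85–95% of instances, and the
reference R implementation (`cluster::pam`) returns the same suboptimal
medoid sets on the same instances.  On clustered (blob-like) instances
agreement with exhaustive search is essentially complete when k matches
the structure.  The acceptance script reports both fractions; the suite
additionally verifies local optimality (no single improving exchange
exists from any returned medoid set) and that SWAP never worsens the
BUILD cost.

## Synthetic data

`generate_clustered_community` draws node i of group g as
cos(θ_g)·F₁ + sin(θ_g)·F₂ + ε, with iid standard-normal factors and
N(0, noise_sd²) noise, giving the exact covariance
cov[i,j] = cos(θᵢ−θⱼ) + noise_sd²·δᵢⱼ.  Defaults emulate the target
study conditions at module scale: 2 groups × 8 nodes, angles 15°/75°,
noise_sd 0.3, n_obs 500.  The generator self-validates against its own
analytic oracle: PAM with silhouette selection on the *analytic*
target-averaged synergy dissimilarity must reproduce the planted
partition exactly, else the parameter set is rejected with the analytic
silhouette as a diagnostic.  Because the analytic two-group
dissimilarity has only two distinct off-diagonal values, this check is
scale-free — it rejects bad geometry (e.g. three evenly spaced angle
groups), not weak signal; recoverability under estimation noise is
established separately by the recovery tests at n_obs = 500.

`generate_expression_study` reuses the factor structure across genes
(50 genes × 140 samples by default, mirroring a community of ~50 genes
and ~140 subjects), then adds an `effect_size` (default 2.0 log2 units)
mean shift to `n_de` randomly chosen genes in cases only.  A
`gene_structure="independent"` variant draws iid genes and is used for
calibration studies, where cross-gene independence is what makes a
Kolmogorov–Smirnov uniformity check on per-gene p-values valid.  What
the generators deliberately do not emulate: probe-level noise,
batch/array effects, heavy-tailed intensity distributions, and
non-monotone gene–gene interactions — so passing tests demonstrate
correctness of the estimators and pipeline mechanics under the stated
dependence model, not robustness to microarray artifacts.

## Downstream statistics

The differential-expression screen is a per-gene Welch two-sample t on
log2 values with Benjamini–Hochberg adjustment; a gene is called at
|log2 FC| > 1.5 AND adjusted p < 0.01.  This deliberately replaces a
moderated-variance linear-model screen: with ≥ 50 samples per class the
empirical-Bayes shrinkage of gene variances changes little, and the
screen is an evaluation device here, not the contribution.  The
fold change is the difference of class means (data are already log2).
A tie-corrected Kruskal–Wallis test with a χ² upper tail serves as the
distribution-free fallback, returning (H=0, p=1) on all-identical
input.  Within-cluster contrasts are case-vs-control *inside* the
cluster's subjects.

Empirical p-values compare the observed within-cluster |t| per gene
against B (default 1000) random subject subsets matched on both subset
size and class composition, with the add-one convention
p = (#{null ≥ obs} + 1)/(B + 1), so p ∈ (0, 1] and a cluster equal to
the whole community is rejected as a degenerate null.  Over-
representation uses the upper-tail hypergeometric p (equivalently a
one-sided Fisher exact test) of the overlap between a gene cluster and
each GMT set intersected with the community universe, corrected by BH
(default) or Bonferroni, both at α = 0.05.  Gene-community bootstraps
draw with replacement at original cardinality and deduplicate each draw
before enrichment.

## Determinism and problem sizes

Every random stage derives its generator from a single top-level seed
via named substreams, and a rerun with identical inputs and config
writes byte-identical artifacts (asserted in the suite at the full
50 × 140 community scale, both orientations).  Test and acceptance
problem sizes are chosen so exactness checks run on thousands of random
covariances, estimator checks on 50–100 seeds at n_obs 500–2000, and
recovery checks on 50–100 generator seeds at module scale — large
enough for the stated tolerances, small enough that the whole suite
runs in a couple of minutes on one CPU.  The O(n³) triplet sweep is the
only stage that grows quickly; the CLI logs node and triplet counts and
warns above 300 nodes.

## Known limitations

- Monotone-dependence-only vision (copula model), as discussed above.
- MMI redundancy depends only on the two marginal MIs, so one unique
  term is always exactly zero; other PID completions (Williams–Beer,
  BROJA) are out of scope.
- Triplets only; higher orders (quadruplets and beyond) multiply the
  combinatorial cost and are not implemented.
- PAM is a greedy local search; see the optimality discussion above.
- The synergy-as-similarity inversion is the right default for
  factor-structured data but is a convention, not a theorem; for data
  suspected to contain genuinely complementary node groups the `direct`
  mode should be run alongside (one flag) and the two partitions
  compared.
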