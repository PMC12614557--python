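# synpid

Higher-order interaction analysis of gene-expression communities:
Gaussian-copula mutual information, minimum-MI partial information
decomposition (PID) over all node triplets, and k-medoid clustering of
the resulting synergy structure, with the differential-expression,
resampling and enrichment statistics needed to evaluate the clusters.

## Who this is for

Transcriptomics groups that have already identified a gene module (a
"community" of ~40–60 genes measured on ~100–160 class-labelled
samples, log2 scale) and want to ask whether it hides sub-structure that
pairwise co-expression measures cannot see.  Pairwise MI or correlation
treats every gene pair in isolation; PID asks, for every triplet, how
much information two *sources* jointly carry about a *target* beyond
what either carries alone.  Clustering nodes (samples or genes) by their
synergy profiles can split a community into subgroups with distinct
differential-expression and enrichment signals.

## The method

For two sources X₁, X₂ and a target Y, the joint mutual information
splits into four non-negative atoms

```
I(X₁,X₂;Y) = Red + Unq(X₁) + Unq(X₂) + Syn
I(Xᵢ;Y)    = Red + Unq(Xᵢ)
```

and the minimum-MI (MMI) completion fixes the decomposition with

```
Red(X₁,X₂;Y) = min( I(X₁;Y), I(X₂;Y) )
Syn(X₁,X₂;Y) = I(X₁,X₂;Y) − I(X₁;Y) − I(X₂;Y) + Red
```

For jointly Gaussian variables every proposed PID reduces to MMI, which
pairs it naturally with the Gaussian-copula MI estimator (GCMI): each
margin is rank-transformed through the standard-normal quantile
function, and MI is read off the closed-form Gaussian entropies of the
scores (in bits, with a digamma small-sample bias correction).  GCMI is
exactly invariant under monotone marginal transforms.

The pipeline evaluates Syn for every (source pair, target) triplet of a
node system — samples as nodes or genes as nodes — averages the tensor
over targets to a pairwise matrix, converts it to a dissimilarity, and
clusters with classical PAM (BUILD + SWAP), choosing k ∈ [2, 10] by the
mean silhouette width.  The same machinery runs with pairwise MI as the
baseline metric.  Downstream, sample clusters are scored with a Welch-t
/ Benjamini–Hochberg differential-expression screen (|log2 FC| > 1.5 at
1% adjusted significance), a Kruskal–Wallis fallback, and empirical
p-values against 1,000 random subject subsets matched on size and class
composition; gene clusters are scored with hypergeometric
over-representation against GMT gene sets and gene-bootstrap robustness
resampling.

Everything composes as scikit-learn estimators:

```python
from sklearn.pipeline import Pipeline
from synpid import InformationDissimilarity, PAMedoids

pipe = Pipeline([("diss", InformationDissimilarity(metric="synergy")),
                 ("pam", PAMedoids())])          # auto-k by silhouette
labels = pipe.fit_predict(node_matrix)           # (n_nodes, n_obs)
```

## Worked example

The triplet X₁, X₂ ~ iid N(0,1), Y = X₁ + X₂ + N(0,1) has closed-form
atoms: each source alone carries I(Xᵢ;Y) = ½·log₂(3/2) ≈ 0.2925 bits,
nothing is unique, and half a bit is purely synergistic:

```python
import numpy as np, synpid as sp

cov = np.array([[1.0, 0.0, 1.0],
                [0.0, 1.0, 1.0],
                [1.0, 1.0, 3.0]])
sp.analytic_pid_from_cov(cov, [0], [1], [2])
# PIDAtoms(joint_mi=0.792481..., mi_1=0.292481..., mi_2=0.292481...,
#          red=0.292481..., unq_1=0.0, unq_2=0.0, syn=0.500000...)

nodes, _ = sp.generate_gaussian_nodes(cov, 2000, seed=0)
sp.pid_triplet(*nodes.data)
# mi_1=0.3185 mi_2=0.2564 joint=0.7883 red=0.2564 syn=0.4698
```

The estimated synergy (0.4698 bits at n = 2000 for this seed) fluctuates
around the exact 0.5; averaged over seeds it is within 0.03 bits.

A full run on a synthetic community with two planted gene groups:

```python
expr, truth = sp.generate_expression_study(n_genes=16, n_case=250,
                                           n_control=250, n_de=0, seed=3)
report = sp.run_pipeline(expr, sp.RunConfig(orientation="genes",
                                            metric="synergy", seed=3))
report.k, report.silhouette      # (2, 0.7607)
report.cluster_members()         # two clusters of 8 genes = the planted groups
```

The same is available from a shell:

```
synpid simulate --n-genes 50 --n-case 70 --n-control 70 --seed 1 --out sim/
synpid run --expression sim/expression.tsv --labels sim/labels.tsv \
           --orientation samples --metric both --seed 1 --out run/
```

which writes the synergy tensor, dissimilarity matrices, cluster
assignments, the silhouette-vs-k selection trace, the class × cluster
contingency table, DGE / empirical-p / ORA tables and a JSON report.

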