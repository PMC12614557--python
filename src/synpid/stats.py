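"""Cluster-evaluation statistics: differential expression, resampling nulls,
and over-representation analysis.

The screening contrast is a per-gene Welch two-sample t statistic on
log2 expression with Benjamini–Hochberg adjustment; a gene is called
differential when |log2 fold change| exceeds a threshold (default 1.5)
AND the adjusted p-value is below alpha (default 1%).  A Kruskal–Wallis
rank test is available as the distribution-free fallback.  Cluster-level
findings are stress-tested with empirical p-values against nulls built
from random subject subsets matched on size and class composition, and
gene clusters are scored for gene-set enrichment with a hypergeometric
(one-sided Fisher) over-representation test.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "dge_test",
    "kruskal_wallis",
    "bh_adjust",
    "empirical_pvalues",
    "bootstrap_communities",
    "ora_hypergeometric",
    "read_gmt",
]


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (capped at 1)."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return pvals.copy()
    if np.any((pvals < 0) | (pvals > 1) | ~np.isfinite(pvals)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(pvals, method="fdr_bh")[1]


def _welch_t(case: np.ndarray, ctrl: np.ndarray):
    """Row-wise Welch t statistic and two-sided p for (genes x samples) blocks."""
    res = scipy.stats.ttest_ind(case, ctrl, axis=1, equal_var=False)
    return np.asarray(res.statistic, dtype=float), np.asarray(res.pvalue, dtype=float)


def _split_classes(expr, subjects=None):
    matrix = expr.matrix
    labels = expr.class_labels
    if subjects is not None:
        subjects = list(subjects)
        matrix = matrix[subjects]
        labels = labels.loc[subjects]
    case_ids = labels.index[labels == expr.case_label]
    ctrl_ids = labels.index[labels != expr.case_label]
    return matrix[case_ids], matrix[ctrl_ids]


def dge_test(expr, subjects=None, lfc_threshold: float = 1.5,
             alpha: float = 0.01) -> pd.DataFrame:
    """Per-gene differential-expression screen on a (sub)set of subjects.

    log_fold_change is the difference of class means on the log2 scale;
    raw p from a Welch t test, adjusted by Benjamini–Hochberg; a gene is
    flagged when |lfc| > lfc_threshold and adjusted_p < alpha.
    """
    case, ctrl = _split_classes(expr, subjects)
    if case.shape[1] < 2 or ctrl.shape[1] < 2:
        raise ValueError("contrast undefined: need >= 2 samples per class")
    lfc = case.mean(axis=1) - ctrl.mean(axis=1)
    t, p = _welch_t(case.to_numpy(), ctrl.to_numpy())
    adj = bh_adjust(p)
    out = pd.DataFrame(
        {
            "log_fold_change": lfc,
            "t_stat": t,
            "raw_p": p,
            "adjusted_p": adj,
        },
        index=case.index,
    )
    out["is_differential"] = (out.log_fold_change.abs() > lfc_threshold) & (out.adjusted_p < alpha)
    return out


def kruskal_wallis(groups):
    """Kruskal–Wallis H (tie-corrected) and its chi-square upper-tail p.

    The degenerate all-identical case returns (H=0, p=1) rather than an
    error, so it can run as a screening fallback over arbitrary genes.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(g.size == 0 for g in groups):
        raise ValueError("need >= 2 nonempty groups")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = scipy.stats.kruskal(*groups)
    return float(h), float(p)


def empirical_pvalues(expr, cluster_subjects, B: int = 1000, seed: int = 0,
                      rng=None) -> pd.DataFrame:
    """Empirical per-gene p-values against matched random subject subsets.

    The observed statistic is |t| of the within-cluster case/control
    contrast; each of the B null draws uses a random subject subset with
    identical size and identical class composition.  p uses the add-one
    convention (#{null >= observed} + 1) / (B + 1), so it is never 0.
    """
    cluster_subjects = list(cluster_subjects)
    all_ids = list(expr.matrix.columns)
    if set(cluster_subjects) == set(all_ids):
        raise ValueError("null degenerate: cluster equals the whole community")
    labels = expr.class_labels
    case_all = [s for s in all_ids if labels[s] == expr.case_label]
    ctrl_all = [s for s in all_ids if labels[s] != expr.case_label]
    n_case = sum(1 for s in cluster_subjects if labels[s] == expr.case_label)
    n_ctrl = len(cluster_subjects) - n_case
    if n_case < 2 or n_ctrl < 2:
        raise ValueError("contrast undefined: need >= 2 samples per class in cluster")

    obs_tab = dge_test(expr, cluster_subjects)
    observed = obs_tab.t_stat.abs().to_numpy()

    if rng is None:
        rng = np.random.default_rng(seed)
    exceed = np.zeros(observed.size, dtype=int)
    case_arr = np.array(case_all)
    ctrl_arr = np.array(ctrl_all)
    for _ in range(B):
        draw = np.concatenate([
            rng.choice(case_arr, size=n_case, replace=False),
            rng.choice(ctrl_arr, size=n_ctrl, replace=False),
        ])
        case, ctrl = _split_classes(expr, list(draw))
        t, _ = _welch_t(case.to_numpy(), ctrl.to_numpy())
        exceed += (np.abs(t) >= observed)

    return pd.DataFrame(
        {
            "observed_abs_t": observed,
            "null_count": B,
            "exceed_count": exceed,
            "empirical_p": (exceed + 1) / (B + 1),
        },
        index=obs_tab.index,
    )


def bootstrap_communities(gene_ids, n_boot: int = 10, seed: int = 0, rng=None):
    """Bootstrap gene subsets: draw with replacement at the original
    cardinality, then deduplicate each draw (for downstream enrichment)."""
    gene_ids = list(gene_ids)
    if len(gene_ids) < 2:
        raise ValueError("need >= 2 genes to bootstrap")
    if rng is None:
        rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_boot):
        draw = rng.choice(np.array(gene_ids, dtype=object), size=len(gene_ids), replace=True)
        out.append(sorted(set(draw.tolist())))
    return out


def ora_hypergeometric(cluster_genes, gene_sets: dict, universe,
                       correction: str = "fdr", alpha: float = 0.05) -> pd.DataFrame:
    """Hypergeometric over-representation of gene sets in a gene cluster.

    raw_p = P(X >= overlap) drawing |cluster| genes from |universe| with
    |set ∩ universe| successes — identical to a one-sided Fisher exact
    test.  Correction is 'fdr' (Benjamini–Hochberg) or 'bonferroni'.
    """
    cluster = set(cluster_genes)
    universe = set(universe)
    if not universe or not cluster:
        raise ValueError("empty universe or cluster")
    if not cluster <= universe:
        raise ValueError("cluster genes must be a subset of the universe")
    if correction not in {"fdr", "bonferroni"}:
        raise ValueError("correction must be 'fdr' or 'bonferroni'")
    rows = []
    for name, genes in gene_sets.items():
        inset = set(genes) & universe
        overlap = len(cluster & inset)
        raw_p = float(scipy.stats.hypergeom.sf(overlap - 1, len(universe),
                                               len(inset), len(cluster)))
        rows.append((name, overlap, len(inset), len(universe), len(cluster), raw_p))
    tab = pd.DataFrame(rows, columns=["gene_set", "overlap", "set_size",
                                      "universe_size", "cluster_size", "raw_p"])
    tab = tab.set_index("gene_set")
    if correction == "fdr":
        tab["corrected_p"] = bh_adjust(tab.raw_p.to_numpy())
    else:
        tab["corrected_p"] = np.minimum(tab.raw_p.to_numpy() * len(tab), 1.0)
    tab["method"] = correction
    tab["significant"] = tab.corrected_p < alpha
    return tab


def read_gmt(path) -> dict:
    """Read a GMT gene-set file: name <tab> description <tab> gene ids..."""
    sets = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed GMT line: {line[:60]!r}")
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets
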