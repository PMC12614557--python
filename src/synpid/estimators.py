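"""Scikit-learn transformer mapping a node system to an information
dissimilarity, so the whole pipeline composes as

    Pipeline([("diss", InformationDissimilarity(metric="synergy")),
              ("pam", PAMedoids())])
"""

from __future__ import annotations

from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array

from .cluster import to_dissimilarity
from .pid import average_over_targets, pairwise_mi_matrix, synergy_tensor

__all__ = ["InformationDissimilarity"]


class InformationDissimilarity(TransformerMixin, BaseEstimator):
    """Pairwise dissimilarity between nodes from higher-order or pairwise MI.

    Rows of ``X`` are the nodes to be clustered (shape n_nodes x n_obs).

    Parameters
    ----------
    metric : {"synergy", "mi"}
        "synergy": target-averaged triplet synergy.  "mi": bivariate
        Gaussian-copula MI.
    mode : {"direct", "max_minus"} or None
        Dissimilarity conversion; None (default) inverts both metrics
        (``max_minus``).  For jointly Gaussian node systems redundant,
        same-group sources carry *higher* averaged synergy than
        cross-group pairs — using two noisy copies of a factor jointly
        denoises it, and that gain is synergy — so synergy, like MI,
        acts as a similarity and is inverted; ``direct`` treats the
        (negative-clipped) matrix as a dissimilarity as-is.
    bias_correct : bool
        Small-sample bias correction of the copula entropies.
    """

    def __init__(self, metric: str = "synergy", mode=None, bias_correct: bool = True):
        self.metric = metric
        self.mode = mode
        self.bias_correct = bias_correct

    def _resolved_mode(self) -> str:
        return self.mode if self.mode is not None else "max_minus"

    def fit(self, X, y=None):
        X = check_array(X)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        X = check_array(X)
        if self.metric == "synergy":
            m = average_over_targets(synergy_tensor(X, bias_correct=self.bias_correct))
        elif self.metric == "mi":
            m = pairwise_mi_matrix(X, bias_correct=self.bias_correct)
        else:
            raise ValueError("metric must be 'synergy' or 'mi'")
        return to_dissimilarity(m, mode=self._resolved_mode())
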