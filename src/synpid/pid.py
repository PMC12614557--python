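"""Minimum-MI partial information decomposition over node triplets.

For two sources X1, X2 and a target Y the joint mutual information
I(X1,X2;Y) is split into four non-negative atoms

    I(X1,X2;Y) = Red + Unq(X1) + Unq(X2) + Syn

where, under the minimum-MI (MMI) completion,

    Red = min(I(X1;Y), I(X2;Y))
    Unq(Xi) = I(Xi;Y) - Red
    Syn = I(X1,X2;Y) - I(X1;Y) - I(X2;Y) + Red.

For jointly Gaussian variables every proposed PID completion reduces to
MMI, which is why it is the natural companion of the Gaussian-copula MI
estimator.  Evaluating the synergy atom for every ordered target and
unordered source pair of a node system yields a three-way synergy
tensor; averaging over targets reduces it to a pairwise matrix that is
used directly as a clustering dissimilarity (redundant, same-group
sources have low synergy; complementary sources have high synergy).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import psi

from .copula import _LN2, _LN_2PI, _bias_term_nats, copula_normalize, gcmi

__all__ = [
    "PIDAtoms",
    "NodeMatrix",
    "SynergyTensor",
    "pid_atoms_from_mi",
    "pid_triplet",
    "synergy_tensor",
    "average_over_targets",
    "pairwise_mi_matrix",
]


@dataclass(frozen=True)
class PIDAtoms:
    """PID atoms (bits) for one (source pair, target) triplet."""

    joint_mi: float
    mi_1: float
    mi_2: float
    red: float
    unq_1: float
    unq_2: float
    syn: float

    def closure_error(self) -> float:
        """|I(X1,X2;Y) - (Red + Unq1 + Unq2 + Syn)| — zero by construction."""
        return abs(self.joint_mi - (self.red + self.unq_1 + self.unq_2 + self.syn))


@dataclass
class NodeMatrix:
    """Orientation-resolved node system: n_nodes vectors of n_obs observations.

    ``orientation`` records whether nodes are samples (subjects) or genes;
    it is bookkeeping only — all information-theoretic operations treat
    rows as nodes regardless.
    """

    data: np.ndarray
    orientation: str = "genes"
    node_ids: list = field(default_factory=list)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("node matrix must be 2-D (n_nodes x n_obs)")
        if not self.node_ids:
            self.node_ids = [f"node{i}" for i in range(self.data.shape[0])]
        if len(self.node_ids) != self.data.shape[0]:
            raise ValueError("node_ids length must match n_nodes")
        if np.any(np.ptp(self.data, axis=1) == 0):
            bad = [self.node_ids[i] for i in np.flatnonzero(np.ptp(self.data, axis=1) == 0)]
            raise ValueError(f"constant node vectors not allowed: {bad}")

    @property
    def n_nodes(self) -> int:
        return self.data.shape[0]

    @property
    def n_obs(self) -> int:
        return self.data.shape[1]


@dataclass
class SynergyTensor:
    """All-triplet synergy values syn(i,j;k) in bits.

    Stored as a dense (n, n, n) array indexed [i, j, k] with sources
    (i, j) and target k; entries with repeated indices are NaN.  The
    tensor is symmetric in its source indices.
    """

    values: np.ndarray
    node_ids: list

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]

    def entry(self, i: int, j: int, k: int) -> float:
        return float(self.values[i, j, k])

    def n_entries(self) -> int:
        """Number of distinct (i<j, k) triplets: C(n,2)*(n-2)."""
        n = self.n_nodes
        return (n * (n - 1) // 2) * (n - 2)

    def to_frame(self):
        """Long-format (i, j, k, syn_bits) table over distinct triplets."""
        import pandas as pd

        n = self.n_nodes
        iu, ju = np.triu_indices(n, k=1)
        i = np.repeat(iu, n)
        j = np.repeat(ju, n)
        k = np.tile(np.arange(n), iu.size)
        keep = (k != i) & (k != j)
        i, j, k = i[keep], j[keep], k[keep]
        ids = np.asarray(self.node_ids, dtype=object)
        return pd.DataFrame({"source_i": ids[i], "source_j": ids[j],
                             "target": ids[k], "syn_bits": self.values[i, j, k]})


def pid_atoms_from_mi(mi_1: float, mi_2: float, joint_mi: float) -> PIDAtoms:
    """MMI atoms forced by the three mutual informations."""
    red = min(mi_1, mi_2)
    unq_1 = mi_1 - red
    unq_2 = mi_2 - red
    syn = joint_mi - mi_1 - mi_2 + red
    return PIDAtoms(joint_mi, mi_1, mi_2, red, unq_1, unq_2, syn)


def pid_triplet(x1, x2, y, bias_correct: bool = True) -> PIDAtoms:
    """Estimate MMI PID atoms for sources ``x1``, ``x2`` and target ``y``.

    All three marginal/joint MIs come from the Gaussian-copula estimator,
    so the atoms inherit its invariance under monotone marginal
    transforms.  The closure identity holds exactly by construction.
    """
    x1 = np.asarray(x1, dtype=float).ravel()
    x2 = np.asarray(x2, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if not (x1.size == x2.size == y.size):
        raise ValueError("x1, x2, y must have equal length")
    mi_1 = gcmi(x1, y, bias_correct=bias_correct)
    mi_2 = gcmi(x2, y, bias_correct=bias_correct)
    joint = gcmi(np.column_stack([x1, x2]), y, bias_correct=bias_correct)
    return pid_atoms_from_mi(mi_1, mi_2, joint)


# ---------------------------------------------------------------------------
# Vectorized all-triplet evaluation.
#
# All triplet quantities are functions of the (n_nodes x n_nodes) sample
# covariance C of the demeaned copula scores.  Entropies of 1-, 2- and
# 3-dimensional sub-blocks use closed-form determinants; the broadcast
# evaluation below applies exactly the same elementwise expressions as a
# per-triplet loop over C, so the two are bit-identical (tested).
# ---------------------------------------------------------------------------


def _score_covariance(nodes: np.ndarray) -> tuple[np.ndarray, int]:
    z = np.vstack([copula_normalize(row) for row in nodes])
    z -= z.mean(axis=1, keepdims=True)
    n_obs = z.shape[1]
    return z @ z.T / (n_obs - 1.0), n_obs


def _entropy_bits_from_det(det, d: int, n_obs: int, bias_correct: bool):
    h = 0.5 * np.log(det) + 0.5 * d * (_LN_2PI + 1.0)
    if bias_correct:
        h = h - _bias_term_nats(d, n_obs)
    return h / _LN2


def _pairwise_mi_from_cov(cov: np.ndarray, n_obs: int, bias_correct: bool) -> np.ndarray:
    v = np.diagonal(cov)
    h1 = _entropy_bits_from_det(v, 1, n_obs, bias_correct)
    det2 = v[:, None] * v[None, :] - cov**2
    with np.errstate(invalid="ignore", divide="ignore"):
        h2 = _entropy_bits_from_det(det2, 2, n_obs, bias_correct)
    mi = h1[:, None] + h1[None, :] - h2
    np.fill_diagonal(mi, 0.0)
    return mi


def _as_node_array(nodes) -> tuple[np.ndarray, list]:
    if isinstance(nodes, NodeMatrix):
        return nodes.data, list(nodes.node_ids)
    arr = np.asarray(nodes, dtype=float)
    return arr, [f"node{i}" for i in range(arr.shape[0])]


def synergy_tensor(nodes, bias_correct: bool = True) -> SynergyTensor:
    """Synergy atom for every (source pair, target) triplet of a node system.

    Negative estimated synergies (estimation noise) are retained; they are
    clipped only when the averaged matrix is converted to a dissimilarity.
    """
    data, node_ids = _as_node_array(nodes)
    n = data.shape[0]
    if n < 3:
        raise ValueError("need at least 3 nodes for triplets")
    cov, n_obs = _score_covariance(data)
    v = np.diagonal(cov)
    h1 = _entropy_bits_from_det(v, 1, n_obs, bias_correct)
    det2 = v[:, None] * v[None, :] - cov**2
    with np.errstate(invalid="ignore", divide="ignore"):
        h2 = _entropy_bits_from_det(det2, 2, n_obs, bias_correct)
    mi2 = h1[:, None] + h1[None, :] - h2

    values = np.full((n, n, n), np.nan)
    # chunk over the target index: each slice is an (n, n) broadcast;
    # entries with repeated indices produce NaN (det <= 0) and are masked
    with np.errstate(invalid="ignore", divide="ignore"):
        for k in range(n):
            c_ik = cov[:, k][:, None]
            c_jk = cov[k, :][None, :]
            det3 = (v[:, None] * (v[None, :] * v[k] - c_jk**2)
                    - cov * (cov * v[k] - c_jk * c_ik)
                    + c_ik * (cov * c_jk - v[None, :] * c_ik))
            h3 = _entropy_bits_from_det(det3, 3, n_obs, bias_correct)
            joint = h2 + h1[k] - h3
            mik_col = mi2[:, k][:, None]
            mik_row = mi2[:, k][None, :]
            syn = joint - mik_col - mik_row + np.minimum(mik_col, mik_row)
            values[:, :, k] = syn
    # invalidate repeated indices
    idx = np.arange(n)
    values[idx, idx, :] = np.nan
    values[idx, :, idx] = np.nan
    values[:, idx, idx] = np.nan
    return SynergyTensor(values=values, node_ids=node_ids)


def average_over_targets(tensor: SynergyTensor) -> np.ndarray:
    """Mean synergy over admissible targets: M[i,j] = mean_k syn(i,j;k).

    Symmetric with a zero diagonal by convention; each off-diagonal entry
    averages the n_nodes - 2 targets k not in {i, j}.
    """
    valid = ~np.isnan(tensor.values)
    counts = valid.sum(axis=2)
    m = np.where(valid, tensor.values, 0.0).sum(axis=2) / np.maximum(counts, 1)
    np.fill_diagonal(m, 0.0)
    return m


def pairwise_mi_matrix(nodes, bias_correct: bool = True) -> np.ndarray:
    """Bivariate GCMI between every node pair; zero diagonal by convention."""
    data, _ = _as_node_array(nodes)
    if data.shape[0] < 2:
        raise ValueError("need at least 2 nodes")
    cov, n_obs = _score_covariance(data)
    return _pairwise_mi_from_cov(cov, n_obs, bias_correct)
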