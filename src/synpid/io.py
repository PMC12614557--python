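"""Reading, writing and validating the pipeline's tabular formats.

Files follow microarray convention: genes are rows, samples are columns
(TSV/CSV with gene ids in the first column and sample ids in the
header); class labels live in a separate two-column TSV.  Orientation
(samples-as-nodes vs genes-as-nodes) is a view taken in memory, never a
file transform.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pid import NodeMatrix, SynergyTensor

__all__ = [
    "ExpressionCommunity",
    "read_expression",
    "write_expression",
    "read_matrix",
    "write_matrix",
    "write_tensor",
    "contingency",
]

_CONTROL_ALIASES = {"control", "ctrl", "controls", "healthy"}


def _infer_case_label(classes) -> str:
    named_ctrl = [c for c in classes if str(c).lower() in _CONTROL_ALIASES]
    if len(named_ctrl) == 1:
        return next(c for c in classes if c not in named_ctrl)
    return sorted(classes)[0]


@dataclass
class ExpressionCommunity:
    """A gene community: genes x samples log2 expression plus class labels."""

    matrix: pd.DataFrame
    class_labels: pd.Series
    case_label: str | None = None

    def __post_init__(self):
        m = self.matrix
        if m.isna().any().any():
            raise ValueError("expression matrix contains missing values")
        if m.index.duplicated().any():
            dup = m.index[m.index.duplicated()].tolist()
            raise ValueError(f"duplicate gene ids: {dup}")
        if m.columns.duplicated().any():
            raise ValueError("duplicate sample ids")
        constant = m.index[(m.max(axis=1) - m.min(axis=1)) == 0].tolist()
        if constant:
            raise ValueError(f"constant gene rows rejected: {constant}")
        missing = [s for s in m.columns if s not in self.class_labels.index]
        if missing:
            raise ValueError(f"samples without class label: {missing}")
        self.class_labels = self.class_labels.loc[m.columns]
        classes = sorted(set(self.class_labels))
        if len(classes) != 2:
            raise ValueError(f"expected exactly 2 classes, got {classes}")
        if self.case_label is None:
            self.case_label = _infer_case_label(classes)
        elif self.case_label not in classes:
            raise ValueError(f"case_label {self.case_label!r} not among {classes}")

    @property
    def gene_ids(self):
        return list(self.matrix.index)

    @property
    def sample_ids(self):
        return list(self.matrix.columns)

    def to_node_matrix(self, orientation: str) -> NodeMatrix:
        """Resolve the node view: rows become nodes, the other axis observations."""
        if orientation == "genes":
            return NodeMatrix(self.matrix.to_numpy(), orientation="genes",
                              node_ids=self.gene_ids)
        if orientation == "samples":
            return NodeMatrix(self.matrix.to_numpy().T, orientation="samples",
                              node_ids=self.sample_ids)
        raise ValueError("orientation must be 'genes' or 'samples'")


def _sep_for(path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def read_expression(path, labels_path, case_label=None) -> ExpressionCommunity:
    """Load an expression TSV/CSV plus a (sample_id, class) labels TSV."""
    matrix = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    labels = pd.read_csv(labels_path, sep=_sep_for(labels_path), index_col=0).iloc[:, 0]
    return ExpressionCommunity(matrix=matrix, class_labels=labels, case_label=case_label)


def write_expression(expr: ExpressionCommunity, path, labels_path):
    expr.matrix.to_csv(path, sep=_sep_for(path))
    expr.class_labels.rename("class").to_csv(labels_path, sep=_sep_for(labels_path),
                                             index_label="sample_id")


def read_matrix(path) -> pd.DataFrame:
    m = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    m.columns = m.columns.astype(str)
    m.index = m.index.astype(str)
    return m


def write_matrix(matrix, node_ids, path):
    pd.DataFrame(np.asarray(matrix), index=node_ids, columns=node_ids).to_csv(
        path, sep=_sep_for(path))


def write_tensor(tensor: SynergyTensor, path):
    """Long-format (source_i, source_j, target, syn_bits) TSV."""
    tensor.to_frame().to_csv(path, sep="\t", index=False)


def contingency(class_labels, cluster_labels) -> pd.DataFrame:
    """Class x cluster count table over a shared sample universe."""
    class_labels = pd.Series(class_labels)
    cluster_labels = pd.Series(cluster_labels)
    if len(class_labels) != len(cluster_labels):
        raise ValueError("label vectors must cover the same sample universe")
    if not class_labels.index.equals(cluster_labels.index):
        cluster_labels.index = class_labels.index
    return pd.crosstab(class_labels, cluster_labels,
                       rownames=["class"], colnames=["cluster"])
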