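"""Normalization and QC of expression and methylation matrices.

Expression arrays are quantile normalized and probe rows collapsed to gene
rows; sequencing counts are log2(count+1) regularized after removing genes
with all-zero counts or no variation.  A singular-value-decomposition QC
step checks that the top component of variation tracks the phenotype of
interest rather than an unknown confounder.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats import rank_sum_test

__all__ = [
    "Phenotype",
    "QCReport",
    "quantile_normalize",
    "collapse_probes_to_genes",
    "log2_regularize",
    "svd_qc",
]

#: recognised per-sample phenotype labels
Phenotype = ("hESC", "NormalFetal", "NormalAdult", "NormalAdjacent", "Tumour")


@dataclass(frozen=True)
class QCComponent:
    component_index: int  # 1-based
    assoc_stat: float  # rank-sum p for association with phenotype


@dataclass(frozen=True)
class QCReport:
    components: tuple[QCComponent, ...]
    flagged: bool  # True iff the top component fails the association rule

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            [(c.component_index, c.assoc_stat) for c in self.components],
            columns=["component_index", "assoc_p"],
        )
        df["flagged"] = [self.flagged if c.component_index == 1 else False
                         for c in self.components]
        return df


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Force every column onto the common distribution of row-wise means.

    Each column's sorted values are replaced by the mean of the
    column-sorted input (the reference distribution); tied entries receive
    the mean of the reference values their positions span.  Idempotent.
    """
    if matrix.isna().any().any():
        raise ValueError("quantile_normalize: remove or filter missing values "
                         "before normalization")
    if matrix.shape[1] < 2:
        raise ValueError("quantile_normalize needs >=2 samples")
    values = matrix.to_numpy(dtype=float)
    reference = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    for j in range(values.shape[1]):
        col = values[:, j]
        order = np.argsort(col, kind="mergesort")
        mapped = np.empty_like(col)
        mapped[order] = reference
        # ties: average the reference quantiles the tied group occupies
        sorted_col = col[order]
        i = 0
        while i < sorted_col.size:
            k = i
            while k + 1 < sorted_col.size and sorted_col[k + 1] == sorted_col[i]:
                k += 1
            if k > i:
                mapped[order[i:k + 1]] = reference[i:k + 1].mean()
            i = k + 1
        out[:, j] = mapped
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def collapse_probes_to_genes(probe_matrix: pd.DataFrame,
                             probe_to_gene: dict[str, str]) -> pd.DataFrame:
    """Average probe rows mapping to the same gene; drop unmapped probes."""
    if not probe_to_gene:
        raise ValueError("probe-to-gene map is empty")
    genes = probe_matrix.index.map(probe_to_gene.get)
    keep = genes.notna()
    collapsed = probe_matrix.loc[keep].groupby(genes[keep]).mean()
    collapsed.index.name = probe_matrix.index.name
    return collapsed


def log2_regularize(count_matrix: pd.DataFrame) -> pd.DataFrame:
    """log2(count + 1) after removing all-zero and zero-variance genes.

    The +1 offset keeps zero counts at zero.  Variance is assessed on the
    raw count scale; a gene row removed by either filter never reaches the
    transform.
    """
    values = count_matrix.to_numpy(dtype=float)
    if np.any(values < 0):
        raise ValueError("counts must be non-negative")
    all_zero = np.all(values == 0, axis=1)
    no_var = np.var(values, axis=1) == 0
    keep = ~(all_zero | no_var)
    return pd.DataFrame(np.log2(values[keep] + 1.0),
                        index=count_matrix.index[keep],
                        columns=count_matrix.columns)


def svd_qc(matrix: pd.DataFrame, phenotype: pd.Series,
           n_components: int = 5, alpha: float = 0.05) -> QCReport:
    """Check that the top component of variation tracks phenotype.

    Computes right singular vectors of the row-centred matrix and, for two
    phenotype classes, the rank-sum association p of each of the top
    ``n_components`` components with the class labels.  The report is
    flagged when component 1's association p exceeds ``alpha`` — the
    signature of a dataset dominated by confounding variation.
    """
    pheno = phenotype.loc[matrix.columns]
    classes = pd.unique(pheno)
    if len(classes) < 2:
        raise ValueError("svd_qc needs >=2 phenotype classes")
    if matrix.shape[1] < 3:
        raise ValueError("svd_qc needs >=3 samples")
    values = matrix.to_numpy(dtype=float)
    centred = values - values.mean(axis=1, keepdims=True)
    _, _, vt = np.linalg.svd(centred, full_matrices=False)
    k = min(n_components, vt.shape[0])
    comps = []
    for i in range(k):
        loadings = vt[i]
        groups = [loadings[(pheno == c).to_numpy()] for c in classes[:2]]
        p = rank_sum_test(groups[0], groups[1], alternative="two_sided")
        comps.append(QCComponent(component_index=i + 1, assoc_stat=p))
    flagged = comps[0].assoc_stat > alpha
    return QCReport(components=tuple(comps), flagged=flagged)
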