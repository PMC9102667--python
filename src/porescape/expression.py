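"""Relative qPCR expression and correlation-based hierarchical clustering.

Expression is quantified by the ΔΔCt convention: each gene's Ct is first
normalized against a reference gene measured in the same sample
(ΔCt = Ct_gene − Ct_ref), then against a calibrator condition, and
reported as fold change 2^(−ΔΔCt).  Samples are compared by unrestricted
(all genes) agglomerative clustering under the Pearson correlation
distance d = 1 − r, which is invariant to per-sample affine transforms of
the clustered values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage
from scipy.spatial.distance import squareform

from .errors import InvalidInputError

__all__ = [
    "ExpressionMatrix",
    "HClustResult",
    "relative_expression",
    "pearson_hcluster",
]

REQUIRED_CT_COLUMNS = ("sample_id", "condition", "gene", "ct")


@dataclass(frozen=True)
class ExpressionMatrix:
    """Genes × samples fold-change table with condition annotations."""

    fold: pd.DataFrame  # index = genes, columns = sample_ids
    sample_conditions: pd.Series  # sample_id -> condition
    reference_gene: str
    calibrator_condition: str

    @property
    def log2(self) -> pd.DataFrame:
        return np.log2(self.fold)


@dataclass(frozen=True)
class HClustResult:
    """Sample dendrogram: scipy linkage matrix plus derived views."""

    linkage_matrix: np.ndarray
    sample_ids: tuple[str, ...]
    method: str

    @property
    def leaf_order(self) -> tuple[str, ...]:
        return tuple(self.sample_ids[i] for i in leaves_list(self.linkage_matrix))

    def cut(self, k: int) -> pd.Series:
        """Flat cluster labels for the top k-group partition."""
        labels = fcluster(self.linkage_matrix, t=k, criterion="maxclust")
        return pd.Series(labels, index=list(self.sample_ids), name="cluster")

    def newick(self) -> str:
        """Dendrogram as a Newick string with height-difference branch lengths."""
        Z = self.linkage_matrix
        n = len(self.sample_ids)

        def height(node: int) -> float:
            return 0.0 if node < n else float(Z[node - n, 2])

        def build(node: int) -> str:
            if node < n:
                return str(self.sample_ids[node])
            a, b = int(Z[node - n, 0]), int(Z[node - n, 1])
            h = height(node)
            return (
                f"({build(a)}:{h - height(a):.6g},{build(b)}:{h - height(b):.6g})"
            )

        return build(2 * n - 2) + ";"


def relative_expression(
    ct_table: pd.DataFrame,
    calibrator_condition: str,
    reference_gene: str = "GAPDH",
) -> ExpressionMatrix:
    """ΔΔCt fold changes relative to a reference gene and calibrator condition.

    ``ct_table`` is long-format with columns (sample_id, condition, gene,
    ct).  For each sample, ΔCt = Ct_gene − Ct_reference; the calibrator
    ΔCt per gene is the mean over calibrator-condition samples, and
    fold = 2^(−(ΔCt_sample − ΔCt_calibrator)).  With a single calibrator
    sample its folds are exactly 1 for every gene.
    """
    missing_cols = set(REQUIRED_CT_COLUMNS) - set(ct_table.columns)
    if missing_cols:
        raise InvalidInputError(f"ct table missing columns {sorted(missing_cols)}")
    ct = ct_table.copy()
    if not np.isfinite(ct["ct"]).all() or (ct["ct"] <= 0).any():
        raise InvalidInputError("Ct values must be finite and positive")
    conditions = ct.drop_duplicates("sample_id").set_index("sample_id")["condition"]
    if calibrator_condition not in set(conditions):
        raise InvalidInputError(f"calibrator condition {calibrator_condition!r} not present")

    wide = ct.pivot_table(index="gene", columns="sample_id", values="ct")
    if reference_gene not in wide.index:
        raise InvalidInputError(f"reference gene {reference_gene!r} not measured")
    ref = wide.loc[reference_gene]
    for sample in wide.columns:
        if not np.isfinite(ref[sample]):
            raise InvalidInputError(
                f"reference gene {reference_gene!r} missing for sample {sample!r}"
            )
    delta = wide.drop(index=reference_gene).subtract(ref, axis=1)
    calib_samples = conditions.index[conditions == calibrator_condition]
    calib_delta = delta[calib_samples].mean(axis=1)
    fold = np.power(2.0, -(delta.subtract(calib_delta, axis=0)))
    return ExpressionMatrix(fold, conditions[fold.columns], reference_gene, calibrator_condition)


def pearson_hcluster(
    matrix: ExpressionMatrix | pd.DataFrame,
    method: Literal["average", "complete", "single"] = "average",
    values: Literal["log2_fold", "fold"] = "log2_fold",
) -> HClustResult:
    """Agglomerative clustering of samples under d = 1 − Pearson r.

    Accepts an :class:`ExpressionMatrix` (clustered on log2 fold by
    default, or raw fold) or any genes × samples DataFrame.  Samples with
    zero variance across genes have an undefined correlation and raise an
    error naming them.
    """
    if isinstance(matrix, ExpressionMatrix):
        data = matrix.log2 if values == "log2_fold" else matrix.fold
    else:
        data = matrix
    if data.shape[1] < 2 or data.shape[0] < 2:
        raise InvalidInputError("need at least 2 samples and 2 genes")
    X = data.to_numpy(dtype=float)
    sds = X.std(axis=0)
    flat = [data.columns[i] for i in np.nonzero(sds == 0)[0]]
    if flat:
        raise InvalidInputError(f"zero-variance sample(s): {flat}")
    dist = 1.0 - np.corrcoef(X.T)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, 2.0)
    np.fill_diagonal(dist, 0.0)
    Z = linkage(squareform(dist, checks=False), method=method)
    return HClustResult(Z, tuple(str(c) for c in data.columns), method)
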