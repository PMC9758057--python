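"""Trajectory clustering and dTE-gene enrichment.

Genes are described by their log2 fold changes relative to the first
stage in RNA and protein (2 x (T-1) columns; 8 for a five-stage course).
After a full-rank PCA rotation (distance-preserving, retained to mirror
the stated procedure) the genes are hierarchically clustered with the
Ward variance criterion (Ward.D2) on Euclidean distances and the tree is
cut at k clusters. Each cluster is summarized by the median and quartile
meta-trajectories and tested for enrichment of
translation-efficiency-changing genes by Fisher's exact test.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests

from .io import GeneMatrix, PipelineError


def build_trajectory_matrix(rna: GeneMatrix, ms: GeneMatrix,
                            pseudocount: float = 0.5) -> pd.DataFrame:
    """Genes x 2(T-1) matrix of vs-first-stage log2 fold changes (RNA
    block then MS block), complete cases only."""
    blocks = []
    for m, name in ((rna, "RNA"), (ms, "MS")):
        means = np.log2(m.stage_means() + pseudocount)
        fc = means.sub(means.iloc[:, 0], axis=0).iloc[:, 1:]
        fc.columns = [f"{name}_{c}" for c in fc.columns]
        blocks.append(fc)
    mat = blocks[0].join(blocks[1], how="inner")
    n_before = len(mat)
    mat = mat.dropna()
    if n_before > len(mat):
        import logging
        logging.getLogger("ribodyn").info(
            "trajectory matrix: %d genes dropped as incomplete",
            n_before - len(mat))
    return mat


def ward_clusters(matrix: pd.DataFrame, k: int = 13) -> pd.Series:
    """Cut a Ward.D2 tree at k clusters; deterministic; labels 1..k."""
    if k > len(matrix):
        raise PipelineError(f"k={k} exceeds {len(matrix)} genes")
    if k > len(matrix.drop_duplicates()):
        raise PipelineError("k exceeds the number of distinct rows")
    X = matrix.to_numpy(dtype=float)
    # full-rank PCA rotation: preserves Euclidean distances exactly
    Xc = X - X.mean(axis=0)
    _, _, vt = np.linalg.svd(Xc, full_matrices=False)
    scores = Xc @ vt.T
    Z = hierarchy.linkage(scores, method="ward")
    labels = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    return pd.Series(labels, index=matrix.index, name="cluster")


def meta_trajectories(matrix: pd.DataFrame, labels: pd.Series
                      ) -> pd.DataFrame:
    """Median and quartile trajectory per cluster (tidy: cluster,
    column, median, q25, q75)."""
    rows = []
    for cl, idx in labels.groupby(labels).groups.items():
        block = matrix.loc[idx]
        for col in matrix.columns:
            rows.append({
                "cluster": cl, "column": col,
                "median": float(block[col].median()),
                "q25": float(block[col].quantile(0.25)),
                "q75": float(block[col].quantile(0.75)),
                "n_genes": len(block),
            })
    return pd.DataFrame(rows)


def dte_enrichment(labels: pd.Series, dte_calls: pd.Series,
                   direction: str = "up") -> pd.DataFrame:
    """Per-cluster Fisher's exact test of dTE enrichment.

    For each cluster the 2x2 table crosses cluster membership with dTE
    status in the given direction; two-sided p-values are BH-adjusted
    across clusters. Empty clusters are skipped with a note.
    """
    common = labels.index.intersection(dte_calls.index)
    labels = labels.loc[common]
    is_dte = (dte_calls.loc[common] == direction)
    rows = []
    for cl in sorted(labels.unique()):
        in_cl = labels == cl
        if in_cl.sum() == 0:
            continue
        a = int((in_cl & is_dte).sum())
        b = int((in_cl & ~is_dte).sum())
        c = int((~in_cl & is_dte).sum())
        d = int((~in_cl & ~is_dte).sum())
        odds, p = fisher_exact([[a, b], [c, d]], alternative="two-sided")
        rows.append({"cluster": cl, "n_in": a + b, "dte_in": a,
                     "dte_out": c, "odds_ratio": odds, "p": p})
    out = pd.DataFrame(rows)
    if not out.empty:
        out["padj"] = multipletests(out["p"], method="fdr_bh")[1]
    return out
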