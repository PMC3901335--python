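"""Cross-assembly statistics: Spearman correlations, hierarchical
clustering of the correlation structure, and correlation-based PCA.

These summarize how the assembly statistics co-vary across a panel of
assemblies — e.g. which measurable quantities (N50, reads assembled)
track the quantities one actually cares about (chimera rate, reads on
original genome)."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster import hierarchy


def _check_matrix(m: pd.DataFrame) -> None:
    if len(m) < 3:
        raise ValueError("at least 3 assemblies (rows) are required")


def spearman_matrix(m: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Spearman rho over columns with two-sided p-values
    (t-approximation).  Constant columns yield NaN markers."""
    _check_matrix(m)
    cols = list(m.columns)
    k = len(cols)
    rho = np.full((k, k), np.nan)
    pval = np.full((k, k), np.nan)
    constant = {c for c in cols if m[c].nunique() <= 1}
    if constant:
        warnings.warn(f"constant columns flagged: {sorted(constant)}", stacklevel=2)
    for i, a in enumerate(cols):
        for j, b in enumerate(cols):
            if a in constant or b in constant:
                continue
            if i == j:
                rho[i, j], pval[i, j] = 1.0, 0.0
                continue
            r = sps.spearmanr(m[a], m[b])
            rho[i, j], pval[i, j] = r.statistic, r.pvalue
    return (
        pd.DataFrame(rho, index=cols, columns=cols),
        pd.DataFrame(pval, index=cols, columns=cols),
    )


def cluster_statistics(rho: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Complete-linkage agglomerative clustering on Euclidean distances
    between the correlation matrix rows.  Returns the SciPy linkage matrix
    and the (label-sorted, hence deterministic) leaf labels."""
    if rho.shape[0] != rho.shape[1]:
        raise ValueError("correlation matrix must be square")
    keep = [c for c in rho.columns if not rho[c].isna().all()]
    ordered = sorted(keep)
    x = rho.loc[ordered, ordered].to_numpy()
    z = hierarchy.linkage(x, method="complete", metric="euclidean")
    return z, ordered


@dataclass
class PcaResult:
    scores: pd.DataFrame  # assemblies x components
    loadings: pd.DataFrame  # variables x components
    explained_variance: np.ndarray  # eigenvalues, sum = number of variables


def pca_assemblies(m: pd.DataFrame) -> PcaResult:
    """Correlation-based PCA of the assembly statistics matrix.

    Columns are standardized, the column correlation matrix is
    eigendecomposed, and components are ordered by decreasing eigenvalue.
    Constant columns are removed with a warning.  Each loading vector's
    largest-magnitude entry is made positive for a reproducible sign."""
    _check_matrix(m)
    keep = [c for c in m.columns if m[c].nunique() > 1]
    dropped = [c for c in m.columns if c not in keep]
    if dropped:
        warnings.warn(f"constant columns removed: {dropped}", stacklevel=2)
    x = m[keep].to_numpy(dtype=float)
    z = (x - x.mean(axis=0)) / x.std(axis=0, ddof=1)
    corr = np.corrcoef(z, rowvar=False)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    for j in range(eigvec.shape[1]):
        top = np.argmax(np.abs(eigvec[:, j]))
        if eigvec[top, j] < 0:
            eigvec[:, j] = -eigvec[:, j]
    comps = [f"PC{j + 1}" for j in range(len(eigval))]
    return PcaResult(
        scores=pd.DataFrame(z @ eigvec, index=m.index, columns=comps),
        loadings=pd.DataFrame(eigvec, index=keep, columns=comps),
        explained_variance=eigval,
    )
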