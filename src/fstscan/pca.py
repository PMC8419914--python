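"""Genotype PCA for population-structure inspection.

Uses the allele-frequency (Patterson) scaling: missing dosages are imputed
with the SNP mean, each SNP column is centered and divided by
sqrt(2 p_hat (1 - p_hat)) with p_hat = column mean / 2, zero-variance
columns dropped, then the sample covariance is decomposed exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import MISSING, VariantTable


@dataclass
class PcaResult:
    """Scores (samples x k), explained-variance fractions, loadings.

    Score columns are scaled so the variance of PC k equals its eigenvalue;
    sign is fixed so the largest-magnitude score in each component is
    positive.  ``scaling`` records the imputation/scaling policy.
    """

    samples: list[str]
    scores: np.ndarray
    explained_variance_fraction: np.ndarray
    eigenvalues: np.ndarray
    loadings: np.ndarray | None
    scaling: str = "mean-impute, Patterson sqrt(2p(1-p))"

    def scores_frame(self) -> pd.DataFrame:
        cols = [f"PC{i + 1}" for i in range(self.scores.shape[1])]
        return pd.DataFrame(self.scores, index=self.samples, columns=cols)


def _scaled_dosage_matrix(table: VariantTable) -> np.ndarray:
    """Samples x SNPs matrix, imputed, centered, frequency-scaled;
    zero-variance SNP columns dropped."""
    X = table.genotypes.T.astype(float)  # samples x snps
    miss = X == MISSING
    X[miss] = np.nan
    col_mean = np.nanmean(X, axis=0)
    inds = np.where(np.isnan(X))
    X[inds] = col_mean[inds[1]]
    p_hat = col_mean / 2.0
    scale = np.sqrt(2.0 * p_hat * (1.0 - p_hat))
    polymorphic = (scale > 0) & (np.nanstd(X, axis=0) > 0)
    X = (X[:, polymorphic] - col_mean[polymorphic]) / scale[polymorphic]
    return X


def genotype_pca(
    table: VariantTable, k: int = 20, return_loadings: bool = False
) -> PcaResult:
    """Exact PCA of the scaled genotype matrix; top-k scores and variance
    fractions.  k is truncated with a warning if it exceeds the rank bound."""
    if table.n_samples < 2:
        raise ValueError("PCA needs at least two samples")
    X = _scaled_dosage_matrix(table)
    n, m = X.shape
    if m == 0:
        raise ValueError("no polymorphic SNPs; PCA undefined")
    k_max = min(n, m)
    if k > k_max:
        warnings.warn(f"k={k} exceeds min(n_samples, n_snps)={k_max}; truncated")
        k = k_max

    # SVD of the scaled matrix; eigenvalues of cov C = X X^T / m are s^2 / m
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    eigvals = s**2 / m
    total = eigvals.sum()
    if total <= 0:
        raise ValueError("zero total variance; all samples identical")
    scores = U[:, :k] * np.sqrt(eigvals[:k])[None, :]
    # fix signs: largest-|score| entry positive per component
    for j in range(k):
        i = np.argmax(np.abs(scores[:, j]))
        if scores[i, j] < 0:
            scores[:, j] = -scores[:, j]
            Vt[j] = -Vt[j]
    return PcaResult(
        samples=list(table.samples),
        scores=scores,
        explained_variance_fraction=eigvals[:k] / total,
        eigenvalues=eigvals[:k],
        loadings=Vt[:k].T if return_loadings else None,
    )


def write_pca(result: PcaResult, prefix: str) -> None:
    result.scores_frame().rename_axis("sample").to_csv(
        f"{prefix}.scores.tsv", sep="\t"
    )
    pd.DataFrame(
        {
            "component": [f"PC{i + 1}" for i in range(len(result.eigenvalues))],
            "eigenvalue": result.eigenvalues,
            "explained_variance_fraction": result.explained_variance_fraction,
        }
    ).to_csv(f"{prefix}.variance.tsv", sep="\t", index=False)
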