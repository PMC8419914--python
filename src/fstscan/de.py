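"""FPKM standardization and a two-group negative-binomial Wald test.

The test is a transparent NB Wald test, not a DESeq2 re-implementation:
counts are normalized by median-of-ratios size factors, the per-gene
dispersion alpha (Var = mu + alpha mu^2) is estimated by pooled method of
moments across the two conditions with a floor, and the Wald statistic on
the log2 fold change uses the delta-method NB variance with a Student-t
reference on n1 + n2 - 2 degrees of freedom (the small-sample correction
for the estimated dispersion; a normal reference is anticonservative at
n = 7 per group).  Genes pass the DEG rule when |fold change| > 1.5 and
the BH-adjusted p is < 0.05 (both strict).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import CountMatrix

logger = logging.getLogger("fstscan")


@dataclass(frozen=True)
class DeParams:
    fc_threshold: float = 1.5
    alpha: float = 0.05
    dispersion_floor: float = 1e-8
    size_factor_method: str = "median-of-ratios"

    def __post_init__(self) -> None:
        if self.fc_threshold <= 1:
            raise ValueError("fc_threshold must exceed 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")


def fpkm(counts: CountMatrix) -> pd.DataFrame:
    """Fragments per kilobase per million: count * 1e9 / (length * library)."""
    totals = counts.counts.sum(axis=0)
    zero = totals[totals == 0]
    if not zero.empty:
        raise ValueError(f"zero library size for sample(s) {list(zero.index)}")
    mat = counts.counts.to_numpy(dtype=float)
    out = mat * 1e9 / (
        counts.gene_length.to_numpy(dtype=float)[:, None]
        * totals.to_numpy(dtype=float)[None, :]
    )
    return pd.DataFrame(out, index=counts.counts.index, columns=counts.counts.columns)


def size_factors(counts: CountMatrix) -> pd.Series:
    """Median-of-ratios normalization factors, geometric mean 1.

    Falls back to library-size ratios (logged) when no gene is nonzero in
    every sample.
    """
    mat = counts.counts.to_numpy(dtype=float)
    all_nonzero = (mat > 0).all(axis=1)
    if all_nonzero.any():
        logref = np.log(mat[all_nonzero]).mean(axis=1)
        ratios = np.log(mat[all_nonzero]) - logref[:, None]
        factors = np.exp(np.median(ratios, axis=0))
    else:
        logger.warning("no gene nonzero in all samples; using library-size factors")
        totals = mat.sum(axis=0)
        factors = totals / np.exp(np.mean(np.log(totals)))
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.counts.columns, name="size_factor")


def nb_test(counts: CountMatrix, params: DeParams = DeParams()) -> pd.DataFrame:
    """Per-gene NB Wald test of condition 2 vs condition 1.

    Returns a DataFrame indexed by gene_id with baseMean, fpkm means per
    condition, log2fc, pvalue, padj and deg flag.  All-zero genes are
    excluded from testing and from the BH denominator (padj NaN).
    """
    conditions = counts.conditions
    labels = list(dict.fromkeys(conditions[s] for s in counts.samples))
    if len(labels) != 2:
        raise ValueError(f"exactly two conditions required, got {labels}")
    idx1 = [s for s in counts.samples if conditions[s] == labels[0]]
    idx2 = [s for s in counts.samples if conditions[s] == labels[1]]
    n1, n2 = len(idx1), len(idx2)
    if n1 < 2 or n2 < 2:
        raise ValueError("each condition needs >= 2 samples")

    sf = size_factors(counts)
    norm = counts.counts.to_numpy(dtype=float) / sf.to_numpy()[None, :]
    c1 = norm[:, [counts.samples.index(s) for s in idx1]]
    c2 = norm[:, [counts.samples.index(s) for s in idx2]]

    m1, m2 = c1.mean(axis=1), c2.mean(axis=1)
    v1, v2 = c1.var(axis=1, ddof=1), c2.var(axis=1, ddof=1)
    tested = (m1 + m2) > 0

    # pooled method-of-moments dispersion: Var = mu + alpha mu^2 per condition
    with np.errstate(invalid="ignore", divide="ignore"):
        num = (n1 - 1) * (v1 - m1) + (n2 - 1) * (v2 - m2)
        den = (n1 - 1) * m1**2 + (n2 - 1) * m2**2
        alpha_g = np.where(den > 0, num / np.where(den == 0, 1, den), 0.0)
    alpha_g = np.maximum(alpha_g, params.dispersion_floor)

    # moderated means keep the log fold change finite for one-sided zeros
    eps = 0.5
    mm1, mm2 = m1 + eps, m2 + eps
    log2fc = np.log2(mm2 / mm1)
    var_log2 = (
        (mm1 + alpha_g * mm1**2) / (n1 * mm1**2)
        + (mm2 + alpha_g * mm2**2) / (n2 * mm2**2)
    ) / np.log(2.0) ** 2
    with np.errstate(invalid="ignore", divide="ignore"):
        z = log2fc / np.sqrt(var_log2)
    df = n1 + n2 - 2
    pvalue = np.where(tested, 2.0 * stats.t.sf(np.abs(z), df=df), np.nan)

    padj = np.full(len(pvalue), np.nan)
    if tested.any():
        padj[tested] = multipletests(pvalue[tested], method="fdr_bh")[1]

    fpkm_mat = fpkm(counts)
    res = pd.DataFrame(
        {
            "baseMean": norm.mean(axis=1),
            f"fpkm_mean_{labels[0]}": fpkm_mat[idx1].mean(axis=1).to_numpy(),
            f"fpkm_mean_{labels[1]}": fpkm_mat[idx2].mean(axis=1).to_numpy(),
            "log2fc": np.where(tested, log2fc, np.nan),
            "pvalue": pvalue,
            "padj": padj,
        },
        index=counts.counts.index,
    )
    res.index.name = "gene_id"
    res["deg"] = call_deg_flags(res, params)
    res.attrs["conditions"] = labels
    return res


def call_deg_flags(results: pd.DataFrame, params: DeParams = DeParams()) -> np.ndarray:
    """DEG rule: |log2FC| > log2(fc_threshold) AND padj < alpha, both strict."""
    lfc_cut = np.log2(params.fc_threshold)
    with np.errstate(invalid="ignore"):
        flag = (
            (np.abs(results["log2fc"].to_numpy()) > lfc_cut)
            & (results["padj"].to_numpy() < params.alpha)
        )
    return np.asarray(flag, dtype=bool) & results["padj"].notna().to_numpy()


def call_degs(results: pd.DataFrame, params: DeParams = DeParams()) -> pd.DataFrame:
    """Filter to DEGs; keeps both directions with sign and logs a summary."""
    flag = call_deg_flags(results, params)
    out = results[flag].copy()
    n_up = int((out["log2fc"] > 0).sum())
    n_down = int((out["log2fc"] < 0).sum())
    logger.info("call_degs: %d DEGs (%d up, %d down)", len(out), n_up, n_down)
    out.attrs["n_up"] = n_up
    out.attrs["n_down"] = n_down
    return out
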