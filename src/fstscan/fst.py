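"""Two-population Weir-Cockerham Fst, windowed scan, candidate regions.

Per SNP the Weir & Cockerham (1984) variance components are computed for
r = 2 populations from non-missing diploid genotypes:

    n_bar = (n1 + n2)/2                     mean sample size
    n_c   = (r n_bar - sum n_i^2/(r n_bar))/(r - 1)
    p_bar = weighted mean alt frequency
    s^2   = sum n_i (p_i - p_bar)^2 / ((r-1) n_bar)
    h_bar = weighted mean observed heterozygosity

    a = (n_bar/n_c) [s^2 - (p_bar q_bar - s^2 (r-1)/r - h_bar/4)/(n_bar-1)]
    b = (n_bar/(n_bar-1)) [p_bar q_bar - s^2 (r-1)/r - h_bar (2 n_bar-1)/(4 n_bar)]
    c = h_bar/2

with theta = a/(a+b+c), undefined when a+b+c = 0 (monomorphic sites) or a
group has no calls.  Windows aggregate as the ratio of sums
sum(a)/sum(a+b+c), the standard weighted windowed estimator; the per-window
mean of per-SNP theta is kept as a diagnostic.  Hudson's estimator is
available as a cross-check.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import MISSING, GeneModel, GroupAssignment, VariantTable


@dataclass
class SnpFstComponents:
    """Per-SNP variance components as parallel arrays.

    ``defined`` marks SNPs where theta exists (both groups called and
    a+b+c > 0); ``theta`` is NaN where undefined and must be consumed
    through the mask, never blindly averaged.
    """

    chrom: np.ndarray
    pos: np.ndarray
    a: np.ndarray
    b: np.ndarray
    c: np.ndarray
    theta: np.ndarray
    defined: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": self.chrom,
                "pos": self.pos,
                "a": self.a,
                "b": self.b,
                "c": self.c,
                "theta": self.theta,
                "defined": self.defined,
            }
        )


def _group_stats(geno: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-SNP (n called, alt frequency, het proportion) for one group."""
    called = geno != MISSING
    n = called.sum(axis=1).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(called, geno, 0).sum(axis=1) / (2 * n)
        h = (geno == 1).sum(axis=1) / n
    return n, p, h


def snp_fst(table: VariantTable, groups: GroupAssignment) -> SnpFstComponents:
    """Weir-Cockerham (1984) variance components per SNP, two populations."""
    labels = groups.groups
    if len(labels) != 2:
        raise ValueError(f"exactly two groups required, got {labels}")
    groups.validate_for(table.samples)
    col = {s: j for j, s in enumerate(table.samples)}
    idx1 = [col[s] for s in groups.members(labels[0])]
    idx2 = [col[s] for s in groups.members(labels[1])]

    n1, p1, h1 = _group_stats(table.genotypes[:, idx1])
    n2, p2, h2 = _group_stats(table.genotypes[:, idx2])

    r = 2.0
    defined = (n1 > 0) & (n2 > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        n_bar = (n1 + n2) / r
        n_c = (r * n_bar - (n1**2 + n2**2) / (r * n_bar)) / (r - 1)
        p_bar = (n1 * p1 + n2 * p2) / (r * n_bar)
        s2 = (n1 * (p1 - p_bar) ** 2 + n2 * (p2 - p_bar) ** 2) / ((r - 1) * n_bar)
        h_bar = (n1 * h1 + n2 * h2) / (r * n_bar)
        inner = p_bar * (1 - p_bar) - ((r - 1) / r) * s2 - h_bar / 4
        a = (n_bar / n_c) * (s2 - inner / (n_bar - 1))
        b = (n_bar / (n_bar - 1)) * (
            p_bar * (1 - p_bar)
            - ((r - 1) / r) * s2
            - ((2 * n_bar - 1) / (4 * n_bar)) * h_bar
        )
        c = h_bar / 2
    a = np.where(defined, a, 0.0)
    b = np.where(defined, b, 0.0)
    c = np.where(defined, c, 0.0)
    denom = a + b + c
    defined &= denom != 0
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = np.where(defined, a / np.where(denom == 0, 1.0, denom), np.nan)
    return SnpFstComponents(
        chrom=np.asarray(table.chrom),
        pos=np.asarray(table.pos),
        a=a,
        b=b,
        c=c,
        theta=theta,
        defined=defined,
    )


def hudson_fst(table: VariantTable, groups: GroupAssignment) -> np.ndarray:
    """Hudson's per-SNP estimator, 1 - Hw/Hb, as an independent cross-check.

    Numerator/denominator per SNP: N = (p1-p2)^2 - p1 q1/(2n1-1) - p2 q2/(2n2-1),
    D = p1 q2 + p2 q1; NaN where undefined.
    """
    labels = groups.groups
    col = {s: j for j, s in enumerate(table.samples)}
    idx1 = [col[s] for s in groups.members(labels[0])]
    idx2 = [col[s] for s in groups.members(labels[1])]
    n1, p1, _ = _group_stats(table.genotypes[:, idx1])
    n2, p2, _ = _group_stats(table.genotypes[:, idx2])
    with np.errstate(invalid="ignore", divide="ignore"):
        num = (
            (p1 - p2) ** 2
            - p1 * (1 - p1) / (2 * n1 - 1)
            - p2 * (1 - p2) / (2 * n2 - 1)
        )
        den = p1 * (1 - p2) + p2 * (1 - p1)
        out = num / den
    out[(n1 == 0) | (n2 == 0) | (den == 0)] = np.nan
    return out


# ---------------------------------------------------------------------------
# Windows
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScanParams:
    window_bp: int = 50_000
    step_bp: int = 25_000
    top_fraction: float = 0.01
    flank_bp: int = 50_000
    min_snps_per_window: int = 1

    def __post_init__(self) -> None:
        if self.step_bp > self.window_bp:
            raise ValueError("step_bp must be <= window_bp")
        if not 0 < self.top_fraction <= 1:
            raise ValueError("top_fraction must lie in (0, 1]")
        if self.flank_bp < 0 or self.min_snps_per_window < 0:
            raise ValueError("flank_bp and min_snps_per_window must be >= 0")


def make_windows(
    chrom_lengths: dict[str, int], params: ScanParams = ScanParams()
) -> pd.DataFrame:
    """Sliding-window grid: starts 1 + k*step while start <= chrom length.

    Trailing windows keep their nominal [start, start + window - 1] bounds
    (no truncation; no SNPs exist past the chromosome end anyway).
    """
    rows = []
    for chrom, length in chrom_lengths.items():
        if length < 1:
            raise ValueError(f"chromosome {chrom} length < 1")
        n_win = 1 + (length - 1) // params.step_bp
        starts = 1 + params.step_bp * np.arange(n_win, dtype=np.int64)
        rows.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": starts,
                    "end": starts + params.window_bp - 1,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def window_fst(
    components: SnpFstComponents,
    windows: pd.DataFrame,
    params: ScanParams = ScanParams(),
) -> pd.DataFrame:
    """Aggregate per-SNP components into every window containing them.

    Overlapping windows double-count SNPs by design.  Adds n_snps,
    fst_weighted (sum a / sum(a+b+c)), fst_mean (mean per-SNP theta) and an
    ``eligible`` flag (n_snps >= min_snps_per_window and defined ratio).
    """
    win = windows.copy().reset_index(drop=True)
    n_win = len(win)
    n_snps = np.zeros(n_win, dtype=np.int64)
    sum_a = np.zeros(n_win)
    sum_abc = np.zeros(n_win)
    sum_theta = np.zeros(n_win)

    win_groups = {c: g for c, g in win.groupby("chrom", sort=False).groups.items()}
    step = params.step_bp
    span = params.window_bp
    mask = components.defined
    chrom_arr = np.asarray(components.chrom)
    for c, widx in win_groups.items():
        widx = np.asarray(widx)
        starts = win.loc[widx, "start"].to_numpy()
        smask = mask & (chrom_arr == c)
        pos = components.pos[smask]
        if len(pos) == 0:
            continue
        a = components.a[smask]
        abc = a + components.b[smask] + components.c[smask]
        theta = components.theta[smask]
        # window k (0-based, start 1 + k*step) contains pos iff
        # start <= pos <= start + span - 1
        k_hi = (pos - 1) // step  # last window starting at or before pos
        k_lo = np.maximum(0, np.ceil((pos - span) / step).astype(np.int64))
        k_hi = np.minimum(k_hi, len(widx) - 1)
        for k_off in range(int((span + step - 1) // step)):
            k = k_lo + k_off
            ok = k <= k_hi
            tgt = widx[k[ok]]
            np.add.at(n_snps, tgt, 1)
            np.add.at(sum_a, tgt, a[ok])
            np.add.at(sum_abc, tgt, abc[ok])
            np.add.at(sum_theta, tgt, theta[ok])

    with np.errstate(invalid="ignore", divide="ignore"):
        fst_weighted = np.where(sum_abc != 0, sum_a / np.where(sum_abc == 0, 1, sum_abc), np.nan)
        fst_mean = np.where(n_snps > 0, sum_theta / np.maximum(n_snps, 1), np.nan)
    win["n_snps"] = n_snps
    win["fst_weighted"] = fst_weighted
    win["fst_mean"] = fst_mean
    win["eligible"] = (n_snps >= max(params.min_snps_per_window, 1)) & (sum_abc != 0)
    return win


def top_windows(stats: pd.DataFrame, params: ScanParams = ScanParams()) -> pd.DataFrame:
    """Top-fraction windows by weighted Fst: ceil(f * n) plus cutoff ties."""
    elig = stats[stats["eligible"]].copy()
    if elig.empty:
        raise ValueError("no eligible windows to rank")
    k = math.ceil(params.top_fraction * len(elig))
    elig = elig.sort_values(
        ["fst_weighted", "chrom", "start"], ascending=[False, True, True]
    )
    cutoff = elig["fst_weighted"].iloc[k - 1]
    return elig[elig["fst_weighted"] >= cutoff].reset_index(drop=True)


# ---------------------------------------------------------------------------
# Candidate regions and genes
# ---------------------------------------------------------------------------

@dataclass
class CandidateRegionSet:
    """Merged flank-extended top windows plus the genes overlapping them.

    ``regions``: chrom, start, end, n_windows, max_window_fst.
    ``candidate_genes``: gene_id, chrom, start, end, best_window_fst
    (populated by :func:`annotate_candidates`).
    """

    regions: pd.DataFrame
    candidate_genes: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["gene_id", "chrom", "start", "end", "best_window_fst"]
        )
    )


def candidate_regions(
    top: pd.DataFrame,
    params: ScanParams = ScanParams(),
    chrom_lengths: dict[str, int] | None = None,
) -> CandidateRegionSet:
    """Extend each top window by the flank, clip to the chromosome, merge
    overlapping or book-ended intervals."""
    if top.empty:
        raise ValueError("top window set is empty")
    ext = top.copy()
    ext["rstart"] = np.maximum(1, ext["start"] - params.flank_bp)
    ext["rend"] = ext["end"] + params.flank_bp
    if chrom_lengths:
        lens = ext["chrom"].map(chrom_lengths)
        ext["rend"] = np.minimum(ext["rend"], lens)
        ext["rstart"] = np.minimum(ext["rstart"], lens)
    rows = []
    for chrom, grp in ext.groupby("chrom", sort=True):
        grp = grp.sort_values("rstart")
        cur_s = cur_e = None
        cur_fst: float = -np.inf
        cur_n = 0
        for s, e, f in zip(grp["rstart"], grp["rend"], grp["fst_weighted"]):
            if cur_s is None or s > cur_e + 1:
                if cur_s is not None:
                    rows.append((chrom, cur_s, cur_e, cur_n, cur_fst))
                cur_s, cur_e, cur_fst, cur_n = s, e, f, 1
            else:
                cur_e = max(cur_e, e)
                cur_fst = max(cur_fst, f)
                cur_n += 1
        if cur_s is not None:
            rows.append((chrom, cur_s, cur_e, cur_n, cur_fst))
    regions = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "n_windows", "max_window_fst"]
    )
    return CandidateRegionSet(regions=regions)


def annotate_candidates(
    region_set: CandidateRegionSet, genes: list[GeneModel]
) -> CandidateRegionSet:
    """A gene is a candidate iff its body overlaps any region by >= 1 bp;
    records the best overlapping-region window Fst, sorted descending."""
    regions = region_set.regions
    rows = []
    for g in genes:
        sub = regions[regions["chrom"] == g.chrom]
        hit = sub[(sub["start"] <= g.end) & (sub["end"] >= g.start)]
        if not hit.empty:
            rows.append(
                (g.gene_id, g.chrom, g.start, g.end, hit["max_window_fst"].max())
            )
    genes_df = pd.DataFrame(
        rows, columns=["gene_id", "chrom", "start", "end", "best_window_fst"]
    ).sort_values("best_window_fst", ascending=False, kind="mergesort").reset_index(drop=True)
    return CandidateRegionSet(regions=regions.copy(), candidate_genes=genes_df)


# ---------------------------------------------------------------------------
# End-to-end scan
# ---------------------------------------------------------------------------

@dataclass
class ScanResult:
    windows: pd.DataFrame
    top: pd.DataFrame
    candidates: CandidateRegionSet
    summary: dict


def scan(
    table: VariantTable,
    groups: GroupAssignment,
    genes: list[GeneModel],
    chrom_lengths: dict[str, int],
    params: ScanParams = ScanParams(),
) -> ScanResult:
    """Full scan: per-SNP components -> windows -> top 1% -> regions -> genes."""
    comp = snp_fst(table, groups)
    win = window_fst(comp, make_windows(chrom_lengths, params), params)
    top = top_windows(win, params)
    cands = annotate_candidates(
        candidate_regions(top, params, chrom_lengths), genes
    )
    elig = win[win["eligible"]]
    denom = comp.a[comp.defined] + comp.b[comp.defined] + comp.c[comp.defined]
    genomewide = float(comp.a[comp.defined].sum() / denom.sum()) if denom.sum() else float("nan")
    best = elig.loc[elig["fst_weighted"].idxmax()]
    summary = {
        "n_snps": int(table.n_records),
        "n_snps_defined": int(comp.defined.sum()),
        "n_windows": int(len(win)),
        "n_windows_eligible": int(len(elig)),
        "mean_window_fst_weighted": float(elig["fst_weighted"].mean()),
        "mean_window_fst_mean": float(elig["fst_mean"].mean()),
        "genomewide_fst_weighted": genomewide,
        "max_window_fst": float(best["fst_weighted"]),
        "max_window": f"{best['chrom']}:{int(best['start'])}-{int(best['end'])}",
        "n_top_windows": int(len(top)),
        "n_candidate_regions": int(len(cands.regions)),
        "n_candidate_genes": int(len(cands.candidate_genes)),
    }
    return ScanResult(windows=win, top=top, candidates=cands, summary=summary)


def write_scan(result: ScanResult, prefix: str) -> None:
    """Write windows TSV, regions BED (0-based half-open), candidate-gene
    TSV and a JSON summary under the given path prefix."""
    result.windows.to_csv(f"{prefix}.windows.tsv", sep="\t", index=False)
    bed = result.candidates.regions.copy()
    bed["start"] = bed["start"] - 1  # BED is 0-based half-open
    bed.to_csv(f"{prefix}.regions.bed", sep="\t", index=False, header=False)
    result.candidates.candidate_genes.to_csv(
        f"{prefix}.candidate_genes.tsv", sep="\t", index=False
    )
    with open(f"{prefix}.summary.json", "wt") as fh:
        json.dump(result.summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
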