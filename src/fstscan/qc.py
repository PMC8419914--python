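"""SNP retention rules: hard filters, the 10-bp cluster rule, missing rate.

Hard-filter inequalities are strict (QUAL > 30.0 keeps 30.01 and drops
30.0 exactly).  A record that lacks an INFO annotation passes that single
test by default, following the GATK convention for rank-sum annotations,
which are undefined at sites without heterozygotes; ``missing_info="fail"``
flips that policy.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .io import VariantTable


@dataclass(frozen=True)
class HardFilterThresholds:
    qual_min: float = 30.0
    qd_min: float = 5.0
    fs_max: float = 60.0
    mq_min: float = 40.0
    mqranksum_min: float = -12.5
    readposranksum_min: float = -8.0

    def __post_init__(self) -> None:
        for name, v in asdict(self).items():
            if not np.isfinite(v):
                raise ValueError(f"threshold {name} must be finite")


@dataclass(frozen=True)
class ClusterFilterParams:
    window_bp: int = 10
    max_snps: int = 3

    def __post_init__(self) -> None:
        if self.window_bp < 1 or self.max_snps < 1:
            raise ValueError("window_bp and max_snps must be >= 1")


@dataclass
class QcReport:
    """Per-rule removal counts; removals are attributed to the first rule
    (in the listed order) that fails the record."""

    stage: str
    n_input: int
    n_output: int
    removed: dict[str, int]

    def __post_init__(self) -> None:
        if self.n_output != self.n_input - sum(self.removed.values()):
            raise ValueError("QcReport counts do not reconcile")

    def to_frame(self) -> pd.DataFrame:
        rows = [{"stage": self.stage, "rule": r, "removed": c}
                for r, c in self.removed.items()]
        rows.append({"stage": self.stage, "rule": "input", "removed": self.n_input})
        rows.append({"stage": self.stage, "rule": "output", "removed": self.n_output})
        return pd.DataFrame(rows)


#: (rule name, value accessor, comparison) in attribution order.
_HARD_RULES = (
    ("QUAL", lambda t: t.qual, "gt", "qual_min"),
    ("QD", lambda t: t.info["QD"], "gt", "qd_min"),
    ("FS", lambda t: t.info["FS"], "lt", "fs_max"),
    ("MQ", lambda t: t.info["MQ"], "gt", "mq_min"),
    ("MQRankSum", lambda t: t.info["MQRankSum"], "gt", "mqranksum_min"),
    ("ReadPosRankSum", lambda t: t.info["ReadPosRankSum"], "gt", "readposranksum_min"),
)


def hard_filter(
    table: VariantTable,
    thresholds: HardFilterThresholds = HardFilterThresholds(),
    missing_info: str = "pass",
) -> tuple[VariantTable, QcReport]:
    """Keep records satisfying all six strict threshold tests.

    NaN annotation values (absent INFO keys) pass their test under the
    default policy and fail it under ``missing_info="fail"``.
    """
    if missing_info not in ("pass", "fail"):
        raise ValueError("missing_info must be 'pass' or 'fail'")
    n = table.n_records
    keep = np.ones(n, dtype=bool)
    removed: dict[str, int] = {}
    for rule, accessor, op, attr in _HARD_RULES:
        values = np.asarray(accessor(table), dtype=float)
        thr = getattr(thresholds, attr)
        with np.errstate(invalid="ignore"):
            ok = values > thr if op == "gt" else values < thr
        absent = np.isnan(values)
        ok[absent] = missing_info == "pass"
        removed[rule] = int(np.count_nonzero(keep & ~ok))
        keep &= ok
    out = table.subset(keep)
    return out, QcReport("hard_filter", n, out.n_records, removed)


def _cluster_mask(pos: np.ndarray, window_bp: int, max_snps: int) -> np.ndarray:
    """True where a sorted position belongs to some window_bp-base span
    holding more than max_snps SNPs (any placement of the span)."""
    n = len(pos)
    bad = np.zeros(n, dtype=bool)
    # j = first index with pos[j] > pos[i] + window_bp - 1; the run i..j-1
    # fits one span placement
    ends = np.searchsorted(pos, pos + window_bp - 1, side="right")
    viol = ends - np.arange(n) > max_snps
    for i in np.flatnonzero(viol):
        bad[i : ends[i]] = True
    return bad


def cluster_filter(
    table: VariantTable,
    params: ClusterFilterParams = ClusterFilterParams(),
) -> tuple[VariantTable, QcReport]:
    """Remove every SNP lying in any 10-bp span with more than three SNPs."""
    n = table.n_records
    bad = np.zeros(n, dtype=bool)
    chrom = np.asarray(table.chrom)
    # table invariant guarantees (chrom, pos) sorted
    for c in pd.unique(chrom):
        idx = np.flatnonzero(chrom == c)
        bad[idx] = _cluster_mask(table.pos[idx], params.window_bp, params.max_snps)
    out = table.subset(~bad)
    return out, QcReport(
        "cluster_filter", n, out.n_records, {"snp_cluster": int(bad.sum())}
    )


def missing_rate_filter(
    table: VariantTable, max_missing: float = 0.1
) -> tuple[VariantTable, QcReport]:
    """Remove records whose missing-genotype fraction exceeds max_missing
    (strictly; a rate of exactly max_missing is retained)."""
    n = table.n_records
    keep = table.missing_rate() <= max_missing
    out = table.subset(keep)
    return out, QcReport(
        "missing_rate_filter", n, out.n_records,
        {"missing_rate": int(n - out.n_records)},
    )


def autosome_filter(
    table: VariantTable, excluded_chroms: list[str] = ()
) -> VariantTable:
    """Drop records on the listed (sex) chromosomes; empty list is identity."""
    excluded = set(excluded_chroms)
    keep = np.array([c not in excluded for c in table.chrom], dtype=bool)
    return table.subset(keep)


def apply_qc(
    table: VariantTable,
    thresholds: HardFilterThresholds = HardFilterThresholds(),
    cluster_params: ClusterFilterParams = ClusterFilterParams(),
    max_missing: float = 0.1,
    excluded_chroms: list[str] = (),
    missing_info: str = "pass",
) -> tuple[VariantTable, list[QcReport]]:
    """Full QC pipeline in fixed order: hard -> cluster -> missing-rate
    (-> chromosome exclusion), with reconciling reports."""
    t1, r1 = hard_filter(table, thresholds, missing_info)
    t2, r2 = cluster_filter(t1, cluster_params)
    t3, r3 = missing_rate_filter(t2, max_missing)
    t4 = autosome_filter(t3, excluded_chroms)
    r4 = QcReport(
        "autosome_filter", t3.n_records, t4.n_records,
        {"excluded_chrom": t3.n_records - t4.n_records},
    )
    return t4, [r1, r2, r3, r4]
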