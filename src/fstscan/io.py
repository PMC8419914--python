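"""Readers and writers for the file formats the pipeline consumes.

All genomic coordinates are 1-based inclusive internally.  BED input
(0-based half-open) is converted at the boundary, once.  Variant records are
restricted to biallelic SNPs; multiallelic and indel records are counted and
skipped on input.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("fstscan")

#: INFO annotations carried through filtering, in canonical order.
INFO_KEYS = ("QD", "FS", "MQ", "MQRankSum", "ReadPosRankSum")

_NUCLEOTIDES = frozenset("ACGT")

MISSING = -1  # genotype dosage sentinel


class FormatError(ValueError):
    """A file violates the format contract (bad header, bad record)."""


@dataclass
class VariantTable:
    """Biallelic-SNP records with per-sample alternate-allele dosages.

    ``genotypes`` is an ``(n_records, n_samples)`` int8 array of dosages in
    {0, 1, 2} with ``-1`` marking a missing call.  ``info`` maps annotation
    name to a float array (NaN where the record lacks the key).
    """

    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    qual: np.ndarray
    info: dict[str, np.ndarray]
    genotypes: np.ndarray
    samples: list[str]

    def __post_init__(self) -> None:
        n = len(self.pos)
        for name in ("chrom", "ref", "alt", "qual"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length != record count")
        if self.genotypes.shape != (n, len(self.samples)):
            raise ValueError("genotype matrix shape mismatch")
        if n and np.any(self.pos < 1):
            raise ValueError("positions must be >= 1")
        # sorted by (chrom, pos), unique per (chrom, pos)
        order_key = pd.MultiIndex.from_arrays([self.chrom, self.pos])
        if n and not order_key.is_monotonic_increasing:
            raise ValueError("records must be sorted by (chrom, pos)")
        if n and order_key.duplicated().any():
            raise ValueError("duplicate (chrom, pos) record")

    @property
    def n_records(self) -> int:
        return len(self.pos)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def subset(self, mask: np.ndarray) -> "VariantTable":
        """Row-subset by boolean mask or index array, preserving order."""
        return VariantTable(
            chrom=self.chrom[mask],
            pos=self.pos[mask],
            ref=self.ref[mask],
            alt=self.alt[mask],
            qual=self.qual[mask],
            info={k: v[mask] for k, v in self.info.items()},
            genotypes=self.genotypes[mask],
            samples=list(self.samples),
        )

    def missing_rate(self) -> np.ndarray:
        """Per-record fraction of missing genotype calls."""
        if self.n_samples == 0:
            return np.zeros(self.n_records)
        return (self.genotypes == MISSING).mean(axis=1)


@dataclass(frozen=True)
class GeneModel:
    """A gene body with 1-based inclusive coordinates."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise FormatError(
                f"gene {self.gene_id}: start {self.start} > end {self.end}"
            )
        if self.strand not in ("+", "-", "."):
            raise FormatError(f"gene {self.gene_id}: bad strand {self.strand!r}")


@dataclass
class GroupAssignment:
    """Sample -> population label; exactly two labels for an Fst contrast."""

    assignment: dict[str, str]

    @property
    def groups(self) -> list[str]:
        seen: dict[str, None] = {}
        for g in self.assignment.values():
            seen.setdefault(g, None)
        return list(seen)

    def members(self, group: str) -> list[str]:
        return [s for s, g in self.assignment.items() if g == group]

    def validate_for(self, samples: list[str]) -> None:
        missing = [s for s in samples if s not in self.assignment]
        if missing:
            raise ValueError(f"samples without group assignment: {missing[:5]}")
        for g in self.groups:
            if not self.members(g):
                raise ValueError(f"group {g!r} is empty")


@dataclass
class CountMatrix:
    """Gene x sample integer read counts with gene lengths and conditions."""

    counts: pd.DataFrame  # genes x samples, integer
    gene_length: pd.Series  # bp, indexed by gene_id
    conditions: dict[str, str]  # sample -> condition label

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise FormatError("negative count")
        if (self.gene_length < 1).any():
            raise FormatError("gene length < 1")
        for s in self.counts.columns:
            if s not in self.conditions:
                raise FormatError(f"sample {s!r} has no condition label")

    @property
    def genes(self) -> list[str]:
        return list(self.counts.index)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path) -> VariantTable:
    """Parse a VCF into a :class:`VariantTable`, keeping biallelic SNPs only.

    Multiallelic and non-SNP records are skipped with a logged tally.
    Diploid GT values parsed with ``/`` or ``|``; ``./.`` or ``.`` is missing.
    """
    from cyvcf2 import VCF

    path = str(path)
    try:
        vcf = VCF(path, gts012=True)
    except Exception as exc:  # htslib raises on malformed headers
        raise FormatError(f"cannot parse VCF {path}: {exc}") from exc
    samples = list(vcf.samples)

    chroms, poss, refs, alts, quals = [], [], [], [], []
    info_cols: dict[str, list[float]] = {k: [] for k in INFO_KEYS}
    gts = []
    skipped = 0
    for v in vcf:
        if len(v.ALT) != 1 or v.REF not in _NUCLEOTIDES or v.ALT[0] not in _NUCLEOTIDES:
            skipped += 1
            continue
        if samples and "GT" not in (v.FORMAT or []):
            raise FormatError(
                f"record {v.CHROM}:{v.POS} lacks GT in FORMAT"
            )
        chroms.append(v.CHROM)
        poss.append(v.POS)
        refs.append(v.REF)
        alts.append(v.ALT[0])
        quals.append(np.nan if v.QUAL is None else float(v.QUAL))
        for k in INFO_KEYS:
            val = v.INFO.get(k)
            info_cols[k].append(np.nan if val is None else float(val))
        if samples:
            # gts012: 0/1/2 dosage, 3 = missing
            g = np.asarray(v.gt_types, dtype=np.int8)
            g[g == 3] = MISSING
            gts.append(g)
    vcf.close()
    if skipped:
        logger.info("read_vcf: skipped %d non-biallelic-SNP records", skipped)

    n = len(poss)
    genotypes = (
        np.vstack(gts) if gts else np.empty((n, len(samples)), dtype=np.int8)
    )
    table = VariantTable(
        chrom=np.asarray(chroms, dtype=object),
        pos=np.asarray(poss, dtype=np.int64),
        ref=np.asarray(refs, dtype=object),
        alt=np.asarray(alts, dtype=object),
        qual=np.asarray(quals, dtype=float),
        info={k: np.asarray(v, dtype=float) for k, v in info_cols.items()},
        genotypes=genotypes,
        samples=samples,
    )
    table.skipped_records = skipped  # type: ignore[attr-defined]
    return table


_VCF_HEADER = """##fileformat=VCFv4.2
##INFO=<ID=QD,Number=1,Type=Float,Description="Variant quality by depth">
##INFO=<ID=FS,Number=1,Type=Float,Description="Fisher strand bias (phred)">
##INFO=<ID=MQ,Number=1,Type=Float,Description="RMS mapping quality">
##INFO=<ID=MQRankSum,Number=1,Type=Float,Description="Mapping quality rank-sum Z">
##INFO=<ID=ReadPosRankSum,Number=1,Type=Float,Description="Read position rank-sum Z">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
"""

_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(table: VariantTable, path) -> None:
    """Write a minimal VCF v4.2 (GT-only FORMAT, no contig lines)."""
    path = str(path)
    opener = gzip.open if path.endswith(".gz") else open
    with opener(path, "wt") as fh:
        fh.write(_VCF_HEADER)
        cols = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO"]
        if table.samples:
            cols += ["FORMAT"] + table.samples
        fh.write("\t".join(cols) + "\n")
        for i in range(table.n_records):
            qual = table.qual[i]
            qual_s = "." if np.isnan(qual) else f"{qual:g}"
            info_parts = []
            for k in INFO_KEYS:
                v = table.info.get(k)
                if v is not None and not np.isnan(v[i]):
                    info_parts.append(f"{k}={v[i]:g}")
            info_s = ";".join(info_parts) or "."
            fields = [
                str(table.chrom[i]),
                str(table.pos[i]),
                ".",
                str(table.ref[i]),
                str(table.alt[i]),
                qual_s,
                ".",
                info_s,
            ]
            if table.samples:
                fields.append("GT")
                fields.extend(_GT_STRINGS[int(g)] for g in table.genotypes[i])
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# Gene annotation
# ---------------------------------------------------------------------------

def read_genes(path) -> list[GeneModel]:
    """Read gene bodies from BED6 or GFF3, autodetected by extension.

    BED (0-based half-open) is normalized to 1-based inclusive; GFF3 is
    already 1-based inclusive.  Gene ids must be unique.
    """
    path = str(path)
    if path.endswith((".gff", ".gff3", ".gff.gz", ".gff3.gz")):
        genes = _read_gff3(path)
    else:
        genes = _read_bed6(path)
    seen: set[str] = set()
    for g in genes:
        if g.gene_id in seen:
            raise FormatError(f"duplicate gene_id {g.gene_id!r}")
        seen.add(g.gene_id)
    return genes


def _read_bed6(path: str) -> list[GeneModel]:
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "name", "score", "strand"],
        dtype={"chrom": str, "name": str, "strand": str},
    )
    genes = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        start = int(row.start) + 1  # BED 0-based half-open -> 1-based inclusive
        end = int(row.end)
        if start > end:
            raise FormatError(f"{path} line {i}: start > end after normalization")
        strand = row.strand if isinstance(row.strand, str) else "."
        genes.append(GeneModel(str(row.name), str(row.chrom), start, end, strand))
    return genes


def _read_gff3(path: str) -> list[GeneModel]:
    import gffutils

    db = gffutils.create_db(
        path, dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="error",
    )
    genes = []
    for feat in db.features_of_type("gene", order_by=("seqid", "start")):
        gid = feat.attributes.get("ID", [feat.id])[0]
        genes.append(
            GeneModel(gid, feat.seqid, feat.start, feat.end, feat.strand or ".")
        )
    return genes


def write_genes_bed(genes: list[GeneModel], path) -> None:
    """Write gene models as BED6 (converting back to 0-based half-open)."""
    with open(path, "wt") as fh:
        for g in genes:
            fh.write(
                f"{g.chrom}\t{g.start - 1}\t{g.end}\t{g.gene_id}\t.\t{g.strand}\n"
            )


# ---------------------------------------------------------------------------
# Tabular inputs
# ---------------------------------------------------------------------------

def read_groups(path) -> GroupAssignment:
    """Two-column TSV (sample, group), no header required."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if df.shape[1] < 2:
        raise FormatError("group file needs two tab-separated columns")
    if df[0].duplicated().any():
        dup = df[0][df[0].duplicated()].iloc[0]
        raise FormatError(f"sample {dup!r} assigned more than once")
    return GroupAssignment(dict(zip(df[0], df[1])))


def write_groups(groups: GroupAssignment, path) -> None:
    with open(path, "wt") as fh:
        for s, g in groups.assignment.items():
            fh.write(f"{s}\t{g}\n")


def read_counts(path, conditions_path=None,
                conditions: dict[str, str] | None = None) -> CountMatrix:
    """Read a gene-level count TSV: gene_id, length, then sample columns.

    Conditions come from a two-column TSV (``conditions_path``) or a dict.
    """
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 3:
        raise FormatError("count matrix needs gene_id, length and sample columns")
    gene_col, length_col = df.columns[0], df.columns[1]
    df = df.set_index(gene_col)
    lengths = df[length_col]
    counts = df.drop(columns=[length_col])
    arr = counts.to_numpy()
    if not np.allclose(arr, np.round(arr)) or (arr < 0).any():
        raise FormatError("counts must be non-negative integers")
    counts = counts.astype(np.int64)
    if conditions is None:
        if conditions_path is None:
            raise ValueError("conditions required (path or dict)")
        conditions = read_groups(conditions_path).assignment
    missing = [s for s in counts.columns if s not in conditions]
    if missing:
        raise FormatError(f"samples absent from condition map: {missing}")
    return CountMatrix(counts, lengths.astype(np.int64), dict(conditions))


def write_counts(cm: CountMatrix, path) -> None:
    out = cm.counts.copy()
    out.insert(0, "length", cm.gene_length)
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")


def read_gmt(path) -> dict[str, set[str]]:
    """Standard GMT: set name, description, then member genes, tab-separated."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            name, members = parts[0], {m for m in parts[2:] if m}
            if name in sets:
                raise FormatError(f"duplicate gene set {name!r}")
            sets[name] = members
    return sets
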