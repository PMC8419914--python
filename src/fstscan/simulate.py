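"""Synthetic genotype, annotation and expression data with known truth.

Genotypes follow the Balding-Nichols model: daughter-population allele
frequencies are Beta-distributed around an ancestral frequency p with
divergence parameter F,

    p_k ~ Beta(p (1-F)/F, (1-p)(1-F)/F),   k = 1, 2,

so that E(Fst) ~= F.  Sweep regions are planted by raising F locally.
Expression counts are negative-binomial with per-sample size factors and
planted log2 fold changes, mirroring a two-group (7 vs 7) RNA-seq design.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import (
    INFO_KEYS,
    MISSING,
    CountMatrix,
    GeneModel,
    GroupAssignment,
    VariantTable,
)


class ConfigError(ValueError):
    """A simulation configuration violates its invariants."""


@dataclass
class SweepSimConfig:
    """Two-population diploid genotype simulation with planted sweeps.

    Defaults describe the study conditions this package models: background
    divergence near the genome-wide wild-vs-domestic level (F ~ 0.06),
    20 diploids per group, and a SNP every ~500 bp.
    """

    n_wild: int = 20
    n_dom: int = 20
    n_chrom: int = 1
    chrom_length: int = 5_000_000
    snp_density: float = 1 / 500
    F_background: float = 0.06
    sweep_regions: list[tuple] = field(default_factory=list)
    # each: (chrom_name, start, end, F_sweep), 1-based inclusive
    maf_min: float = 0.05
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.F_background < 1:
            raise ConfigError("F_background must lie in (0, 1)")
        if self.snp_density <= 0:
            raise ConfigError("snp_density must be positive")
        if not 0 <= self.missing_rate < 1:
            raise ConfigError("missing_rate must lie in [0, 1)")
        if not 0 < self.maf_min < 0.5:
            raise ConfigError("maf_min must lie in (0, 0.5)")
        chrom_names = {self.chrom_name(i) for i in range(self.n_chrom)}
        for chrom, start, end, f_sweep in self.sweep_regions:
            if chrom not in chrom_names:
                raise ConfigError(f"sweep region on unknown chromosome {chrom!r}")
            if not (1 <= start <= end <= self.chrom_length):
                raise ConfigError(
                    f"sweep region {chrom}:{start}-{end} outside chromosome"
                )
            if not self.F_background < f_sweep < 1:
                raise ConfigError("F_sweep must satisfy F_background < F_sweep < 1")

    def chrom_name(self, i: int) -> str:
        return f"chr{i + 1}"

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {self.chrom_name(i): self.chrom_length for i in range(self.n_chrom)}


def simulate_genotypes(
    config: SweepSimConfig,
) -> tuple[VariantTable, GroupAssignment, pd.DataFrame]:
    """Draw a :class:`VariantTable` under the Balding-Nichols model.

    Returns the table, the wild/domestic group assignment, and a truth
    DataFrame with one row per SNP (chrom, pos, F used, ancestral p, and the
    two population frequencies actually drawn).
    """
    rng = np.random.default_rng(config.seed)
    n1, n2 = config.n_wild, config.n_dom
    samples = [f"wild_{i + 1}" for i in range(n1)] + [
        f"dom_{i + 1}" for i in range(n2)
    ]
    groups = GroupAssignment(
        {s: ("wild" if i < n1 else "domestic") for i, s in enumerate(samples)}
    )

    chroms_all, pos_all, f_all = [], [], []
    for ci in range(config.n_chrom):
        name = config.chrom_name(ci)
        n_snps = rng.poisson(config.snp_density * config.chrom_length)
        n_snps = min(n_snps, config.chrom_length)
        pos = np.sort(
            rng.choice(config.chrom_length, size=n_snps, replace=False) + 1
        )
        f_snp = np.full(n_snps, config.F_background)
        for chrom, start, end, f_sweep in config.sweep_regions:
            if chrom == name:
                inside = (pos >= start) & (pos <= end)
                f_snp[inside] = f_sweep
        chroms_all.append(np.full(n_snps, name, dtype=object))
        pos_all.append(pos.astype(np.int64))
        f_all.append(f_snp)

    chrom = np.concatenate(chroms_all) if chroms_all else np.empty(0, object)
    pos = np.concatenate(pos_all) if pos_all else np.empty(0, np.int64)
    f_snp = np.concatenate(f_all) if f_all else np.empty(0)
    m = len(pos)

    p_anc = rng.uniform(config.maf_min, 1 - config.maf_min, size=m)
    lam = (1 - f_snp) / f_snp
    p1 = rng.beta(p_anc * lam, (1 - p_anc) * lam)
    p2 = rng.beta(p_anc * lam, (1 - p_anc) * lam)
    geno = np.empty((m, n1 + n2), dtype=np.int8)
    geno[:, :n1] = rng.binomial(2, p1[:, None], size=(m, n1))
    geno[:, n1:] = rng.binomial(2, p2[:, None], size=(m, n2))
    if config.missing_rate > 0:
        mask = rng.random(geno.shape) < config.missing_rate
        geno[mask] = MISSING

    # ref/alt letters carry no signal; assign deterministically
    ref = np.full(m, "A", dtype=object)
    alt = np.full(m, "G", dtype=object)
    info = {k: np.full(m, np.nan) for k in INFO_KEYS}
    table = VariantTable(
        chrom=chrom,
        pos=pos,
        ref=ref,
        alt=alt,
        qual=np.full(m, 100.0),
        info=info,
        genotypes=geno,
        samples=samples,
    )
    truth = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": pos,
            "F": f_snp,
            "p_ancestral": p_anc,
            "p_wild": p1,
            "p_dom": p2,
        }
    )
    return table, groups, truth


# ---------------------------------------------------------------------------
# INFO annotations for filter testing
# ---------------------------------------------------------------------------

#: For each hard-filter criterion: (strictly-passing range, strictly-failing
#: range).  Thresholds sit between the two ranges, so no boundary values are
#: ever emitted.
_ANNOTATION_RANGES = {
    "QUAL": ((40.0, 200.0), (1.0, 25.0)),
    "QD": ((6.0, 40.0), (0.1, 4.5)),
    "FS": ((0.0, 50.0), (70.0, 200.0)),
    "MQ": ((45.0, 60.0), (10.0, 35.0)),
    "MQRankSum": ((-10.0, 10.0), (-30.0, -14.0)),
    "ReadPosRankSum": ((-6.0, 6.0), (-20.0, -9.0)),
}

ANNOTATION_CRITERIA = tuple(_ANNOTATION_RANGES)


def simulate_info_annotations(
    table: VariantTable,
    fail_spec: dict[str, float],
    seed: int = 0,
) -> tuple[VariantTable, pd.DataFrame]:
    """Assign QUAL/INFO values so known record subsets fail known criteria.

    ``fail_spec`` maps criterion name (QUAL, QD, FS, MQ, MQRankSum,
    ReadPosRankSum) to the fraction of records that must fail it.  Failure
    sets are disjoint across criteria, so fractions must sum to <= 1.
    Returns the annotated table and a truth DataFrame with one boolean
    ``fail_<criterion>`` column per criterion plus a ``pass`` column.
    """
    unknown = set(fail_spec) - set(ANNOTATION_CRITERIA)
    if unknown:
        raise ConfigError(f"unknown criteria in fail_spec: {sorted(unknown)}")
    for name, frac in fail_spec.items():
        if not 0 <= frac <= 1:
            raise ConfigError(f"fail fraction for {name} outside [0, 1]")
    if sum(fail_spec.values()) > 1 + 1e-12:
        raise ConfigError("fail fractions must sum to <= 1 (disjoint sets)")

    rng = np.random.default_rng(seed)
    n = table.n_records
    pool = rng.permutation(n)
    cursor = 0
    fail_idx: dict[str, np.ndarray] = {}
    for name in ANNOTATION_CRITERIA:
        k = int(round(fail_spec.get(name, 0.0) * n))
        fail_idx[name] = pool[cursor : cursor + k]
        cursor += k

    out = table.subset(np.arange(n))
    truth = pd.DataFrame({"chrom": out.chrom, "pos": out.pos})
    for name in ANNOTATION_CRITERIA:
        (plo, phi), (flo, fhi) = _ANNOTATION_RANGES[name]
        values = rng.uniform(plo, phi, size=n)
        idx = fail_idx[name]
        values[idx] = rng.uniform(flo, fhi, size=len(idx))
        if name == "QUAL":
            out.qual = values
        else:
            out.info[name] = values
        flag = np.zeros(n, dtype=bool)
        flag[idx] = True
        truth[f"fail_{name}"] = flag
    truth["pass"] = ~truth[[f"fail_{c}" for c in ANNOTATION_CRITERIA]].any(axis=1)
    return out, truth


def simulate_gene_annotation(
    n_genes: int,
    chrom_lengths: dict[str, int],
    gene_length_range: tuple[int, int] = (2_000, 20_000),
    seed: int = 0,
) -> list[GeneModel]:
    """Place non-overlapping gene bodies uniformly across chromosomes."""
    lo, hi = gene_length_range
    if lo < 1 or hi < lo:
        raise ConfigError("bad gene_length_range")
    rng = np.random.default_rng(seed)
    chrom_names = list(chrom_lengths)
    per_chrom = np.bincount(
        rng.integers(0, len(chrom_names), size=n_genes), minlength=len(chrom_names)
    )
    genes: list[GeneModel] = []
    gi = 0
    for name, k in zip(chrom_names, per_chrom):
        length = chrom_lengths[name]
        lens = rng.integers(lo, hi + 1, size=k)
        slack = length - int(lens.sum())
        if slack < 0:
            raise ConfigError(f"cannot pack {k} genes into {name} without overlap")
        # distribute the slack as random inter-gene gaps
        cuts = np.sort(rng.integers(0, slack + 1, size=k))
        start = 1
        prev_cut = 0
        for gene_len, cut in zip(lens, cuts):
            start = start + (cut - prev_cut)
            prev_cut = cut
            gi += 1
            genes.append(
                GeneModel(f"gene_{gi}", name, int(start), int(start + gene_len - 1))
            )
            start += gene_len
    return genes


# ---------------------------------------------------------------------------
# Expression counts
# ---------------------------------------------------------------------------

@dataclass
class CountSimConfig:
    """Two-group NB count simulation with planted fold changes.

    The default design is 7 vs 7 samples, matching the wild-vs-domestic
    RNA-seq contrast the pipeline models; dispersion follows the
    Var = mu + alpha mu^2 parameterization.
    """

    n_genes: int = 5_000
    n_per_group: int = 7
    frac_de: float = 0.1
    lfc: float = 2.0
    mean_log_mu: float = float(np.log(200.0))
    sd_log_mu: float = 1.5
    dispersion: float = 0.05
    gene_length_range: tuple[int, int] = (500, 5_000)
    seed: int = 0
    #: explicit 0-based indices of DE genes; overrides the frac_de draw
    de_gene_indices: list[int] | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.frac_de <= 1:
            raise ConfigError("frac_de must lie in [0, 1]")
        if self.dispersion < 0:
            raise ConfigError("dispersion must be >= 0")
        if self.n_per_group < 2:
            raise ConfigError("need >= 2 samples per group")


def simulate_counts(config: CountSimConfig) -> tuple[CountMatrix, pd.DataFrame]:
    """Draw an NB count matrix; returns it with signed-lfc truth labels."""
    rng = np.random.default_rng(config.seed)
    g, n = config.n_genes, config.n_per_group
    genes = [f"gene_{i + 1}" for i in range(g)]
    samples = [f"A_{i + 1}" for i in range(n)] + [f"B_{i + 1}" for i in range(n)]
    conditions = {s: ("A" if i < n else "B") for i, s in enumerate(samples)}

    mu = np.exp(rng.normal(config.mean_log_mu, config.sd_log_mu, size=g))
    if config.de_gene_indices is not None:
        de_idx = np.asarray(config.de_gene_indices, dtype=int)
        n_de = len(de_idx)
    else:
        n_de = int(round(config.frac_de * g))
        de_idx = rng.choice(g, size=n_de, replace=False)
    sign = rng.choice([-1.0, 1.0], size=n_de)
    true_lfc = np.zeros(g)
    true_lfc[de_idx] = sign * config.lfc

    size_factors = rng.uniform(0.7, 1.3, size=2 * n)
    mean_mat = mu[:, None] * size_factors[None, :]
    mean_mat[:, n:] *= 2.0 ** true_lfc[:, None]

    if config.dispersion == 0:
        counts = rng.poisson(mean_mat)
    else:
        shape = 1.0 / config.dispersion
        p = shape / (shape + mean_mat)
        counts = rng.negative_binomial(shape, p)

    lengths = pd.Series(
        rng.integers(*config.gene_length_range, size=g), index=genes, name="length"
    )
    cm = CountMatrix(
        counts=pd.DataFrame(counts, index=genes, columns=samples),
        gene_length=lengths,
        conditions=conditions,
    )
    truth = pd.DataFrame(
        {"gene_id": genes, "is_de": true_lfc != 0, "true_lfc": true_lfc}
    ).set_index("gene_id")
    return cm, truth
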