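"""End-to-end composition: filter -> scan -> PCA -> DE -> integration.

``run_pipeline`` executes every stage in order, writes every intermediate
under an output prefix, and emits a JSON run manifest with the resolved
configuration and per-stage record counts.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .de import DeParams, nb_test
from .fst import ScanParams, scan, write_scan
from .integrate import intersect_candidates
from .io import read_counts, read_genes, read_groups, read_vcf, write_vcf
from .pca import genotype_pca, write_pca
from .qc import ClusterFilterParams, HardFilterThresholds, apply_qc

logger = logging.getLogger("fstscan")


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Input paths and stage parameters for a full run.

    ``counts`` maps tissue name to a (counts_tsv, conditions_tsv) pair;
    ``chrom_lengths`` maps chromosome name to bp.
    """

    vcf: str
    groups: str
    genes: str
    chrom_lengths: dict[str, int]
    counts: dict[str, tuple[str, str]] = field(default_factory=dict)
    out_prefix: str = "fstscan"
    thresholds: HardFilterThresholds = field(default_factory=HardFilterThresholds)
    cluster: ClusterFilterParams = field(default_factory=ClusterFilterParams)
    max_missing: float = 0.1
    excluded_chroms: list[str] = field(default_factory=list)
    scan_params: ScanParams = field(default_factory=ScanParams)
    de_params: DeParams = field(default_factory=DeParams)
    pca_k: int = 20

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        kwargs = dict(raw)
        if "thresholds" in kwargs:
            kwargs["thresholds"] = HardFilterThresholds(**kwargs["thresholds"])
        if "cluster" in kwargs:
            kwargs["cluster"] = ClusterFilterParams(**kwargs["cluster"])
        if "scan_params" in kwargs:
            kwargs["scan_params"] = ScanParams(**kwargs["scan_params"])
        if "de_params" in kwargs:
            kwargs["de_params"] = DeParams(**kwargs["de_params"])
        if "counts" in kwargs:
            kwargs["counts"] = {
                t: tuple(v) for t, v in kwargs["counts"].items()
            }
        return cls(**kwargs)


def _config_hash(config: PipelineConfig) -> str:
    # hash the scientific configuration only, not the output location
    fields = {k: v for k, v in vars(config).items() if k != "out_prefix"}
    blob = repr(sorted(fields.items(), key=lambda kv: kv[0])).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages; returns the manifest dict (also written to disk).

    Any stage error aborts with :class:`PipelineError` naming the stage;
    outputs written before the failure are left in place.
    """
    prefix = config.out_prefix
    Path(prefix).parent.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config_hash": _config_hash(config),
        "stages": {},
    }

    def _stage(name, fn):
        try:
            return fn()
        except PipelineError:
            raise
        except Exception as exc:
            _write_manifest(manifest, prefix)
            raise PipelineError(name, exc) from exc

    def _load():
        for key in ("vcf", "groups", "genes"):
            p = getattr(config, key)
            if not Path(p).exists():
                raise FileNotFoundError(f"missing input {key}: {p}")
        return read_vcf(config.vcf), read_groups(config.groups), read_genes(config.genes)

    table, groups, genes = _stage("load", _load)
    manifest["stages"]["load"] = {
        "n_snps": table.n_records,
        "n_samples": table.n_samples,
        "n_genes": len(genes),
    }

    def _qc():
        filtered, reports = apply_qc(
            table,
            thresholds=config.thresholds,
            cluster_params=config.cluster,
            max_missing=config.max_missing,
            excluded_chroms=config.excluded_chroms,
        )
        pd.concat([r.to_frame() for r in reports]).to_csv(
            f"{prefix}.qc.tsv", sep="\t", index=False
        )
        write_vcf(filtered, f"{prefix}.filtered.vcf")
        return filtered, reports

    filtered, reports = _stage("variant_qc", _qc)
    manifest["stages"]["variant_qc"] = {
        "n_input": table.n_records,
        "n_output": filtered.n_records,
        "removed": {r.stage: sum(r.removed.values()) for r in reports},
    }

    def _scan():
        result = scan(filtered, groups, genes, config.chrom_lengths, config.scan_params)
        write_scan(result, prefix)
        return result

    scan_result = _stage("sweep_scan", _scan)
    manifest["stages"]["sweep_scan"] = scan_result.summary

    def _pca():
        res = genotype_pca(filtered, k=config.pca_k)
        write_pca(res, prefix)
        return res

    pca_result = _stage("popstruct", _pca)
    manifest["stages"]["popstruct"] = {
        "k": int(pca_result.scores.shape[1]),
        "top3_variance_fraction": float(
            pca_result.explained_variance_fraction[:3].sum()
        ),
    }

    deg_tables: dict[str, pd.DataFrame] = {}

    def _de():
        for tissue, (counts_path, cond_path) in config.counts.items():
            cm = read_counts(counts_path, conditions_path=cond_path)
            res = nb_test(cm, config.de_params)
            res.to_csv(f"{prefix}.de.{tissue}.tsv", sep="\t")
            deg_tables[tissue] = res
        return deg_tables

    _stage("diffexpr", _de)
    manifest["stages"]["diffexpr"] = {
        t: {"n_genes": len(tab), "n_degs": int(tab["deg"].sum())}
        for t, tab in deg_tables.items()
    }

    def _integrate():
        tbl = intersect_candidates(
            scan_result.candidates, deg_tables, config.de_params
        )
        tbl.to_csv(f"{prefix}.integration.tsv", sep="\t", index=False)
        return tbl

    integration = _stage("integrate", _integrate)
    manifest["stages"]["integrate"] = {
        "n_rows": len(integration),
        "per_tissue": {
            t: int((integration["tissue"] == t).sum()) for t in deg_tables
        },
    }

    _write_manifest(manifest, prefix)
    return manifest


def _write_manifest(manifest: dict, prefix: str) -> None:
    with open(f"{prefix}.manifest.json", "wt") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
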