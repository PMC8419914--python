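"""Intersection of Fst candidate genes with per-tissue DEG lists, and a
database-free hypergeometric over-representation test on user gene sets."""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .de import DeParams, call_deg_flags
from .fst import CandidateRegionSet

logger = logging.getLogger("fstscan")


def intersect_candidates(
    candidates: CandidateRegionSet,
    deg_tables: dict[str, pd.DataFrame],
    params: DeParams = DeParams(),
) -> pd.DataFrame:
    """Rows for every (gene, tissue) that is both an Fst candidate and a DEG.

    ``deg_tables`` maps tissue name to an :func:`fstscan.de.nb_test` result
    (full table; the DEG rule is applied here).  Output is sorted by tissue
    then best window Fst descending.
    """
    cand = candidates.candidate_genes
    cand_ids = set(cand["gene_id"])
    rows = []
    for tissue, table in deg_tables.items():
        deg = table[call_deg_flags(table, params)]
        shared = cand_ids & set(table.index)
        if not shared and cand_ids and len(table):
            logger.warning(
                "intersect_candidates: no shared gene ids for tissue %s "
                "(candidates look like %s, DE table like %s)",
                tissue, sorted(cand_ids)[:3], list(table.index[:3]),
            )
        for gid in cand_ids & set(deg.index):
            crow = cand[cand["gene_id"] == gid].iloc[0]
            rows.append(
                {
                    "gene_id": gid,
                    "tissue": tissue,
                    "log2fc": float(deg.loc[gid, "log2fc"]),
                    "direction": "up" if deg.loc[gid, "log2fc"] > 0 else "down",
                    "padj": float(deg.loc[gid, "padj"]),
                    "best_window_fst": float(crow["best_window_fst"]),
                    "chrom": crow["chrom"],
                    "gene_start": int(crow["start"]),
                    "gene_end": int(crow["end"]),
                }
            )
    out = pd.DataFrame(
        rows,
        columns=[
            "gene_id", "tissue", "log2fc", "direction", "padj",
            "best_window_fst", "chrom", "gene_start", "gene_end",
        ],
    )
    return out.sort_values(
        ["tissue", "best_window_fst"], ascending=[True, False], kind="mergesort"
    ).reset_index(drop=True)


def hypergeom_enrich(
    query: set[str],
    gene_sets: dict[str, set[str]],
    universe: set[str],
) -> pd.DataFrame:
    """One-sided over-representation: p = P(X >= k), X ~ Hypergeom(N, K, n).

    Each set is intersected with the universe first; sets empty within the
    universe are skipped.  BH correction across the tested sets.
    """
    outside = query - universe
    if outside:
        raise ValueError(f"query genes outside universe: {sorted(outside)[:5]}")
    N, n = len(universe), len(query)
    rows = []
    for name, members in gene_sets.items():
        members_u = members & universe
        K = len(members_u)
        if K == 0:
            continue
        k = len(query & members_u)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append(
            {
                "set_name": name,
                "k_overlap": k,
                "set_size": K,
                "query_size": n,
                "universe_size": N,
                "pvalue": min(p, 1.0),
                "overlap_genes": ",".join(sorted(query & members_u)),
            }
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "set_name", "k_overlap", "set_size", "query_size",
            "universe_size", "pvalue", "overlap_genes",
        ],
    )
    if len(out):
        out["padj"] = multipletests(out["pvalue"].to_numpy(), method="fdr_bh")[1]
        out = out.sort_values("pvalue", kind="mergesort").reset_index(drop=True)
    else:
        out["padj"] = np.empty(0)
    return out
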