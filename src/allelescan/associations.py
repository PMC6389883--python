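"""Linking AS-SNPs to GWAS traits and eQTL genes, directly or via LD.

Linkage disequilibrium is computed from phased haplotypes directly:
r^2 = D^2 / (p_A p_a p_B p_b) with D = f(AB) - p_A p_B over all 2N
haplotype columns of the panel.  Index SNPs from the catalogs are expanded
to proxies above an r^2 threshold (default 0.8, strict inequality as in
"r^2 > 0.8") within a bounded genomic window, and AS-SNPs matching an
index directly or any proxy inherit the trait / target-gene annotation.
Rare AS-SNPs sharing a regulatory neighbourhood (+/-300 bp, inclusive)
with trait- or eQTL-linked common AS-SNPs are reported separately: they
are candidates to contribute hidden heterogeneity to the association.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .genomes import Panel

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# r^2 from phased haplotypes
# ---------------------------------------------------------------------------

def haplotype_matrix(panel: Panel) -> np.ndarray:
    """(n_sites, 2N) matrix of 0/1 alternative-allele indicators."""
    return panel.haplotypes.reshape(panel.n_sites, -1)


def compute_r2(hap_a: np.ndarray, hap_b: np.ndarray) -> float:
    """Squared haplotype correlation of two biallelic sites.

    Returns NaN if either site is monomorphic in the panel (r^2 undefined).
    """
    a = np.asarray(hap_a, dtype=float)
    b = np.asarray(hap_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("haplotype vectors differ in length")
    p_a = a.mean()
    p_b = b.mean()
    if p_a in (0.0, 1.0) or p_b in (0.0, 1.0):
        return float("nan")
    d = (a * b).mean() - p_a * p_b
    return float(d * d / (p_a * (1 - p_a) * p_b * (1 - p_b)))


def expand_proxies(
    panel: Panel,
    index_snps: list[str],
    r2_threshold: float = 0.8,
    window: int = 1_000_000,
) -> pd.DataFrame:
    """All panel SNPs in high LD (r^2 > threshold) with any index SNP.

    Returns one row per (index, proxy) link with columns ``index_snp``,
    ``proxy_snp``, ``r2`` and ``is_best`` (True on the strongest index for
    each proxy; ties broken by genomic proximity then id order).  Index
    SNPs absent from the panel are logged and skipped.
    """
    hm = haplotype_matrix(panel)
    sites = panel.sites
    id_to_idx = {sid: i for i, sid in enumerate(sites["id"])}
    pos = sites["pos"].to_numpy()
    chrom = sites["chrom"].to_numpy()
    rows = []
    for idx_id in index_snps:
        i = id_to_idx.get(idx_id)
        if i is None:
            logger.warning("index SNP %s absent from panel; skipped", idx_id)
            continue
        near = np.flatnonzero(
            (chrom == chrom[i]) & (np.abs(pos - pos[i]) <= window)
        )
        for j in near:
            if j == i:
                continue
            r2 = compute_r2(hm[i], hm[j])
            if not np.isnan(r2) and r2 > r2_threshold:
                rows.append(
                    (idx_id, sites["id"].iloc[j], r2, abs(int(pos[j]) - int(pos[i])))
                )
    pairs = pd.DataFrame(rows, columns=["index_snp", "proxy_snp", "r2", "dist"])
    if pairs.empty:
        pairs["is_best"] = pd.Series(dtype=bool)
        return pairs.drop(columns=["dist"])
    best = (
        pairs.sort_values(["proxy_snp", "r2", "dist", "index_snp"],
                          ascending=[True, False, True, True])
        .groupby("proxy_snp")
        .head(1)
        .index
    )
    pairs["is_best"] = pairs.index.isin(best)
    return pairs.drop(columns=["dist"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# Catalog annotation
# ---------------------------------------------------------------------------

def annotate_associations(
    as_snps: pd.DataFrame,
    gwas_table: pd.DataFrame,
    eqtl_table: pd.DataFrame,
    ld_pairs: pd.DataFrame,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Attach GWAS/eQTL association records to AS-SNPs.

    ``as_snps`` needs ``site_id``; catalogs need ``snp_id`` plus ``trait``
    (GWAS) or ``gene`` (eQTL).  ``ld_pairs`` is the proxy expansion over
    the union of both catalogs' index SNPs.  Returns the association
    records (one row per AS-SNP x catalog entry link) and the summary
    ``{"gwas": ..., "eqtl": ..., "both": ...}`` of unique AS-SNP counts.
    """
    proxy_to_index: dict[str, list[str]] = {}
    for row in ld_pairs.itertuples(index=False):
        proxy_to_index.setdefault(row.proxy_snp, []).append(row.index_snp)
    r2_of = {
        (row.index_snp, row.proxy_snp): row.r2
        for row in ld_pairs.itertuples(index=False)
    }

    records = []
    for source, catalog, label_col in (
        ("gwas", gwas_table, "trait"),
        ("eqtl", eqtl_table, "gene"),
    ):
        by_index: dict[str, list[str]] = {}
        for row in catalog.itertuples(index=False):
            by_index.setdefault(row.snp_id, []).append(getattr(row, label_col))
        for sid in as_snps["site_id"].unique():
            # direct hit: the AS-SNP is itself a catalog index SNP
            for label in by_index.get(sid, []):
                records.append((sid, source, sid, "direct", 1.0, label))
            # proxy hit: the AS-SNP is in high LD with an index SNP
            for idx in proxy_to_index.get(sid, []):
                for label in by_index.get(idx, []):
                    records.append(
                        (sid, source, idx, "proxy", r2_of[(idx, sid)], label)
                    )
    rec = pd.DataFrame(
        records,
        columns=["site_id", "source", "index_snp", "link", "r2", "annotation"],
    )
    gwas_set = set(rec.loc[rec["source"] == "gwas", "site_id"])
    eqtl_set = set(rec.loc[rec["source"] == "eqtl", "site_id"])
    summary = {
        "gwas": len(gwas_set),
        "eqtl": len(eqtl_set),
        "both": len(gwas_set & eqtl_set),
    }
    return rec, summary


# ---------------------------------------------------------------------------
# Rare-variant window scan
# ---------------------------------------------------------------------------

def rare_window_scan(
    rare_as_snps: pd.DataFrame,
    associated_common_as_snps: pd.DataFrame,
    flank: int = 300,
) -> pd.DataFrame:
    """Rare AS-SNPs within +/-flank bp (inclusive) of associated commons.

    ``associated_common_as_snps`` needs ``site_id``, ``chrom``, ``pos`` and
    ``source`` (gwas/eqtl); one output row per (rare, common) pair with the
    distance and the common SNP's association source.
    """
    rows = []
    for common in associated_common_as_snps.itertuples(index=False):
        near = rare_as_snps.loc[
            (rare_as_snps["chrom"] == common.chrom)
            & ((rare_as_snps["pos"] - common.pos).abs() <= flank)
        ]
        for rare in near.itertuples(index=False):
            if rare.site_id == common.site_id:
                continue
            rows.append(
                (
                    rare.site_id,
                    common.site_id,
                    common.source,
                    int(rare.pos - common.pos),
                )
            )
    return pd.DataFrame(
        rows, columns=["rare_snp", "common_snp", "source", "offset"]
    ).drop_duplicates().reset_index(drop=True)
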