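"""Allele-specific signal detection at heterozygous sites.

The core statistic: at a heterozygous SNV covered by ChIP-seq reads, one
allele acts as the internal control for the other.  Read support for the
two haplotype alleles is counted per assay, a two-sided exact binomial test
against a null ratio (default 0.5) flags imbalanced sites, and
Benjamini-Hochberg correction over all tested site x assay pairs of a
sample controls the genome-wide false discovery rate.  Candidates are then
pruned against artifact regions (blacklist, CNVs, repeats), restricted to
active regulatory elements, attributed to the defining assay(s), and
aggregated across the cohort so that weak but consistent signals surface
at the population level.
"""
from __future__ import annotations

import logging
from functools import lru_cache

import numpy as np
import pandas as pd
import pysam
from intervaltree import IntervalTree
from scipy.stats import binomtest
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

#: Assays used in the study design: three histone marks and two
#: architectural proteins.
ASSAYS = ("H3K27ac", "H3K4me1", "H3K4me3", "CTCF", "SA1")
HISTONE_MARKS = frozenset({"H3K27ac", "H3K4me1", "H3K4me3"})
ARCHITECTURAL = frozenset({"CTCF", "SA1"})

#: The seven condensed chromatin-state categories; AS-SNPs are retained
#: only inside the first four.
CATEGORIES_7 = (
    "enhancer",
    "promoter",
    "mixed",
    "insulator",
    "heterochromatin",
    "repressed",
    "transcribed",
)
RETAINED_CATEGORIES = frozenset({"enhancer", "promoter", "mixed", "insulator"})

AGGREGATE_LABEL = "7LCLs"


# ---------------------------------------------------------------------------
# Allele counting
# ---------------------------------------------------------------------------

def count_alleles(
    alignment_path: str,
    het: pd.DataFrame,
    min_base_q: int = 20,
) -> pd.DataFrame:
    """Count per-allele read support at heterozygous sites.

    Streams the alignment once (SAM or BAM, sorted or not; no index
    required).  Each read contributes at most one base per overlapped site.
    Duplicate-flagged, secondary, supplementary and unmapped reads are
    skipped.  A base below ``min_base_q`` is tallied in ``n_lowq`` only;
    otherwise it increments ``n_g1``, ``n_g2`` or ``n_other`` according to
    whether it matches the haplotype-1 allele, the haplotype-2 allele, or
    neither.

    Parameters
    ----------
    het : DataFrame
        Output of :func:`allelescan.genomes.het_sites`.
    """
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, grp in het.groupby("chrom", sort=False):
        pos0 = grp["pos"].to_numpy() - 1
        order = np.argsort(pos0)
        by_chrom[chrom] = (pos0[order], grp.index.to_numpy()[order])

    n = len(het)
    n_g1 = np.zeros(n, dtype=np.int64)
    n_g2 = np.zeros(n, dtype=np.int64)
    n_other = np.zeros(n, dtype=np.int64)
    n_lowq = np.zeros(n, dtype=np.int64)
    g1 = het["g1"].to_numpy()
    g2 = het["g2"].to_numpy()

    with pysam.AlignmentFile(str(alignment_path), check_sq=False) as af:
        sq_names = set(af.references or [])
        missing = set(by_chrom) - sq_names
        if sq_names and missing:
            raise ValueError(
                "chromosome names absent from alignment header: "
                + ", ".join(sorted(missing))
            )
        for read in af:
            if (
                read.is_unmapped
                or read.is_duplicate
                or read.is_secondary
                or read.is_supplementary
            ):
                continue
            chrom = read.reference_name
            if chrom not in by_chrom:
                continue
            pos_sorted, idx_sorted = by_chrom[chrom]
            start, end = read.reference_start, read.reference_end
            lo = np.searchsorted(pos_sorted, start, side="left")
            hi = np.searchsorted(pos_sorted, end, side="left")
            if lo == hi:
                continue
            seq = read.query_sequence
            quals = read.query_qualities
            # map reference position -> query offset (SNV reads are gapless,
            # but go through aligned pairs so indel-containing reads stay
            # correct)
            ref2query = None
            if read.cigartuples and len(read.cigartuples) == 1 and read.cigartuples[0][0] == 0:
                pass  # simple M-only read: offset arithmetic below
            else:
                ref2query = {
                    rp: qp
                    for qp, rp in read.get_aligned_pairs(matches_only=True)
                }
            for k in range(lo, hi):
                rp = int(pos_sorted[k])
                if ref2query is None:
                    qp = rp - start
                else:
                    qp = ref2query.get(rp)
                    if qp is None:
                        continue
                i = int(idx_sorted[k])
                base = seq[qp]
                q = quals[qp] if quals is not None else 0
                if q < min_base_q:
                    n_lowq[i] += 1
                elif base == g1[i]:
                    n_g1[i] += 1
                elif base == g2[i]:
                    n_g2[i] += 1
                else:
                    n_other[i] += 1

    out = het[["chrom", "pos", "site_id", "ref", "alt", "g1", "g2", "af", "maf"]].copy()
    out["n_g1"] = n_g1
    out["n_g2"] = n_g2
    out["n_other"] = n_other
    out["n_lowq"] = n_lowq
    return out


def orient_counts(counts: pd.DataFrame) -> pd.DataFrame:
    """Add ref/alt-oriented counts (``n_ref``, ``n_alt``) to a counts table.

    Aggregation across samples must sum allele counts in a fixed ref/alt
    orientation, not by haplotype index, because phase is arbitrary.
    """
    out = counts.copy()
    g1_is_ref = out["g1"].to_numpy() == out["ref"].to_numpy()
    n_g1 = out["n_g1"].to_numpy()
    n_g2 = out["n_g2"].to_numpy()
    out["n_ref"] = np.where(g1_is_ref, n_g1, n_g2)
    out["n_alt"] = np.where(g1_is_ref, n_g2, n_g1)
    return out


# ---------------------------------------------------------------------------
# Testing and genome-wide correction
# ---------------------------------------------------------------------------

@lru_cache(maxsize=200_000)
def _binom_p(k: int, n: int, ratio: float) -> float:
    return binomtest(k, n, ratio, alternative="two-sided").pvalue


def test_imbalance(n_g1: int, n_g2: int, null_ratio: float = 0.5) -> float:
    """Two-sided exact binomial p-value for an allelic split."""
    n = int(n_g1) + int(n_g2)
    if n == 0:
        raise ValueError("cannot test a site with zero informative reads")
    return _binom_p(int(n_g1), n, null_ratio)


def add_imbalance_tests(
    counts: pd.DataFrame,
    min_depth: int = 10,
    null_ratio: float = 0.5,
    a_col: str = "n_g1",
    b_col: str = "n_g2",
) -> pd.DataFrame:
    """Attach ``depth``, ``testable`` and ``p_value`` columns.

    Sites below ``min_depth`` informative reads are marked untestable
    (``p_value`` NaN) rather than erroring.
    """
    out = counts.copy()
    depth = out[a_col].to_numpy() + out[b_col].to_numpy()
    out["depth"] = depth
    out["testable"] = depth >= min_depth
    pvals = np.full(len(out), np.nan)
    ka = out[a_col].to_numpy()
    for i in np.flatnonzero(out["testable"].to_numpy()):
        pvals[i] = _binom_p(int(ka[i]), int(depth[i]), null_ratio)
    out["p_value"] = pvals
    return out


def correct_genome_wide(
    p_values: np.ndarray | pd.Series, method: str = "fdr_bh"
) -> np.ndarray:
    """Genome-wide multiple-testing correction (BH by default).

    ``method`` is any ``statsmodels.stats.multitest`` method name;
    ``"bonferroni"`` is the supported alternative.  Empty input yields an
    empty array.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([])
    return multipletests(p, method=method)[1]


def add_q_values(tested: pd.DataFrame, method: str = "fdr_bh") -> pd.DataFrame:
    """q-values over the testable rows of one sample's full collection."""
    out = tested.copy()
    q = np.full(len(out), np.nan)
    mask = out["testable"].to_numpy() & ~np.isnan(out["p_value"].to_numpy())
    q[mask] = correct_genome_wide(out.loc[mask, "p_value"], method=method)
    out["q_value"] = q
    return out


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------

def _tree_from_bed(bed: pd.DataFrame) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for row in bed.itertuples(index=False):
        if row.end <= row.start:
            continue
        trees.setdefault(row.chrom, IntervalTree()).addi(row.start, row.end, row)
    return trees


def prune_artifacts(
    candidates: pd.DataFrame,
    blacklist: pd.DataFrame,
    cnv: pd.DataFrame,
    repeats: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove candidates inside exclusion regions (half-open BED intervals).

    Returns the surviving candidates and a removal log with one row per
    removed candidate and the reason (first matching exclusion class in the
    order blacklist, cnv, repeat).
    """
    exclusions = [
        ("blacklist", _tree_from_bed(blacklist)),
        ("cnv", _tree_from_bed(cnv)),
        ("repeat", _tree_from_bed(repeats)),
    ]
    reasons = []
    keep = np.ones(len(candidates), dtype=bool)
    chroms = candidates["chrom"].to_numpy()
    pos0 = candidates["pos"].to_numpy() - 1
    ids = candidates["site_id"].to_numpy()
    for i in range(len(candidates)):
        for reason, trees in exclusions:
            tree = trees.get(chroms[i])
            if tree is not None and tree.overlaps_point(int(pos0[i])):
                keep[i] = False
                reasons.append((ids[i], chroms[i], int(pos0[i]) + 1, reason))
                logger.debug("pruned %s (%s)", ids[i], reason)
                break
    log = pd.DataFrame(reasons, columns=["site_id", "chrom", "pos", "reason"])
    return candidates.loc[keep].reset_index(drop=True), log


def restrict_to_elements(
    candidates: pd.DataFrame,
    annotation: pd.DataFrame,
    retained: frozenset[str] = RETAINED_CATEGORIES,
) -> pd.DataFrame:
    """Keep candidates inside retained-category regulatory elements.

    ``annotation`` needs columns ``chrom``, ``start``, ``end`` (half-open),
    ``element_id``, ``category``.  Unknown category labels raise.
    """
    bad = set(annotation["category"]) - set(CATEGORIES_7)
    if bad:
        raise ValueError(f"unknown element categories: {sorted(bad)}")
    trees = _tree_from_bed(annotation)
    elem_id = []
    elem_cat = []
    keep = np.zeros(len(candidates), dtype=bool)
    chroms = candidates["chrom"].to_numpy()
    pos0 = candidates["pos"].to_numpy() - 1
    for i in range(len(candidates)):
        tree = trees.get(chroms[i])
        hits = sorted(tree[int(pos0[i])], key=lambda iv: iv.begin) if tree else []
        hit = next((h for h in hits if h.data.category in retained), None)
        if hit is not None:
            keep[i] = True
            elem_id.append(hit.data.element_id)
            elem_cat.append(hit.data.category)
    out = candidates.loc[keep].reset_index(drop=True)
    out["element_id"] = elem_id
    out["element_category"] = elem_cat
    return out


# ---------------------------------------------------------------------------
# Mark attribution / frequency class
# ---------------------------------------------------------------------------

def attribute_marks(significant_assays: list[str] | set[str]) -> str:
    """Defining-assay label from the set of significant assays at a site.

    Two or more significant histone marks yield ``"mixed"``; otherwise the
    single histone mark or architectural protein names itself.  When one
    histone mark and one architectural protein are both significant the
    histone mark wins (architectural proteins keep their own label only
    when they are the sole signal); a histone+architectural pair is not a
    "mixed chromatin signal".
    """
    sig = set(significant_assays)
    if not sig:
        raise ValueError("at least one significant assay required")
    hist = sig & HISTONE_MARKS
    if len(hist) >= 2:
        return "mixed"
    if len(hist) == 1:
        return next(iter(hist))
    arch = sorted(sig & ARCHITECTURAL)
    if len(arch) == 1:
        return arch[0]
    # both architectural proteins, no histone signal: "mixed" is reserved
    # for chromatin (histone) combinations
    return "+".join(arch)


def classify_frequency(maf: float, threshold: float = 0.01) -> str:
    """``rare`` iff MAF < threshold; exactly at threshold counts as common."""
    if maf is None or (isinstance(maf, float) and np.isnan(maf)):
        return "unknown"
    return "rare" if maf < threshold else "common"


# ---------------------------------------------------------------------------
# Per-sample calling and population aggregation
# ---------------------------------------------------------------------------

def call_sample(
    counts_by_assay: dict[str, pd.DataFrame],
    sample: str,
    min_depth: int = 10,
    null_ratio: float = 0.5,
    alpha: float = 0.05,
    method: str = "fdr_bh",
) -> pd.DataFrame:
    """Test and correct one sample's full site x assay collection.

    All tested pairs of the sample enter a single correction; a site is a
    candidate AS-SNP if any assay reaches ``q <= alpha``.  Returns a
    site-level table with the minimum q, the per-assay significance set and
    the defining-assay label.
    """
    frames = []
    for assay, counts in counts_by_assay.items():
        t = add_imbalance_tests(counts, min_depth=min_depth, null_ratio=null_ratio)
        t["assay"] = assay
        frames.append(t)
    allt = pd.concat(frames, ignore_index=True)
    allt = allt.loc[allt["testable"]].reset_index(drop=True)
    if allt.empty:
        return pd.DataFrame(
            columns=[
                "chrom", "pos", "site_id", "ref", "alt", "af", "maf",
                "sample", "p_value", "q_value", "defining_assay", "sig_assays",
            ]
        )
    allt = add_q_values(allt, method=method)
    allt["significant"] = allt["q_value"] <= alpha
    sig = allt.loc[allt["significant"]]
    rows = []
    for (chrom, pos), grp in sig.groupby(["chrom", "pos"], sort=True):
        assays = sorted(grp["assay"])
        best = grp.loc[grp["q_value"].idxmin()]
        rows.append(
            {
                "chrom": chrom,
                "pos": pos,
                "site_id": best["site_id"],
                "ref": best["ref"],
                "alt": best["alt"],
                "af": best["af"],
                "maf": best["maf"],
                "sample": sample,
                "p_value": best["p_value"],
                "q_value": best["q_value"],
                "defining_assay": attribute_marks(assays),
                "sig_assays": ",".join(assays),
            }
        )
    return pd.DataFrame(rows)


def aggregate_population(
    counts_by_sample: dict[str, pd.DataFrame],
) -> pd.DataFrame:
    """Sum ref/alt-oriented allele counts across heterozygous samples.

    Only samples heterozygous at a site contribute (each per-sample table
    already contains only that sample's het sites).  Counts are oriented to
    the fixed ref/alt frame before summation; an orientation conflict
    (same site id with differing ref/alt) raises.
    """
    frames = []
    for sample, counts in counts_by_sample.items():
        oc = orient_counts(counts)
        oc["n_het_samples"] = 1
        frames.append(
            oc[
                ["chrom", "pos", "site_id", "ref", "alt", "af", "maf",
                 "n_ref", "n_alt", "n_other", "n_lowq", "n_het_samples"]
            ]
        )
    allc = pd.concat(frames, ignore_index=True)
    alleles = allc.groupby("site_id")[["ref", "alt"]].nunique()
    conflicts = alleles[(alleles["ref"] > 1) | (alleles["alt"] > 1)]
    if len(conflicts):
        raise ValueError(
            "allele-orientation conflict at sites: "
            + ", ".join(conflicts.index[:5])
        )
    agg = (
        allc.groupby(["chrom", "pos", "site_id", "ref", "alt"], as_index=False)
        .agg(
            af=("af", "first"),
            maf=("maf", "first"),
            n_ref=("n_ref", "sum"),
            n_alt=("n_alt", "sum"),
            n_other=("n_other", "sum"),
            n_lowq=("n_lowq", "sum"),
            n_het_samples=("n_het_samples", "sum"),
        )
        .sort_values(["chrom", "pos"])
        .reset_index(drop=True)
    )
    return agg


def call_aggregate(
    counts_by_sample_assay: dict[str, dict[str, pd.DataFrame]],
    single_sample_calls: pd.DataFrame,
    min_depth: int = 10,
    null_ratio: float = 0.5,
    alpha: float = 0.05,
    method: str = "fdr_bh",
) -> pd.DataFrame:
    """Population-level (7LCLs-style) calling with case labels.

    Per assay, allele counts are summed across heterozygous samples in the
    ref/alt frame; the aggregate site x assay collection is re-tested and
    re-corrected as one set.  ``case1`` marks aggregate AS-SNPs already
    significant in at least one single sample, ``case2`` those that surface
    only in the aggregate.
    """
    assays = sorted({a for d in counts_by_sample_assay.values() for a in d})
    per_assay: dict[str, pd.DataFrame] = {}
    for assay in assays:
        per_sample = {
            s: d[assay] for s, d in counts_by_sample_assay.items() if assay in d
        }
        agg = aggregate_population(per_sample)
        agg = agg.rename(columns={"n_ref": "n_g1", "n_alt": "n_g2"})
        agg["g1"] = agg["ref"]
        agg["g2"] = agg["alt"]
        per_assay[assay] = agg
    calls = call_sample(
        per_assay,
        sample=AGGREGATE_LABEL,
        min_depth=min_depth,
        null_ratio=null_ratio,
        alpha=alpha,
        method=method,
    )
    single_keys = set(
        zip(single_sample_calls["chrom"], single_sample_calls["pos"])
    )
    calls["population_case"] = [
        "case1" if (c, p) in single_keys else "case2"
        for c, p in zip(calls["chrom"], calls["pos"])
    ]
    return calls
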