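"""Synthetic cohort generator with planted ground truth.

Emulates the study design at desk scale: a small phased SNV panel over a
cohort of lymphoblastoid-like samples with a mixed common/rare allele
frequency spectrum, ChIP-seq-like 101 bp reads carrying planted allelic
ratios at heterozygous sites, a condensed 7-category regulatory-element
landscape with exclusion regions, GWAS/eQTL catalogs whose index SNPs have
engineered LD proxies, nested contact/loop domains with genes and
replicated capture read-pair tables with planted true interactions, and
motif training sets sampled from models with planted intra-motif
dependencies.  Every planted feature is recorded in a JSON manifest; one
seed determines all outputs byte-for-byte.

The generated reads are the ground truth for allele counts: a read
targeted at one heterozygous site carries its haplotype's alleles at every
heterozygous site it spans, and the generator tallies the resulting
per-site counts itself (recorded in the manifest), so downstream counting
can be reconciled exactly.
"""
from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.integrate import quad

from .genomes import (
    Panel,
    het_sites,
    personal_genomes_for_sample,
    write_panel_vcf,
    write_reference,
)
from .imbalance import ASSAYS, CATEGORIES_7, RETAINED_CATEGORIES
from .associations import compute_r2, haplotype_matrix

logger = logging.getLogger(__name__)

BASES = "ACGT"

DEFAULT_TRAITS = (
    "inflammatory bowel disease",
    "multiple sclerosis",
    "systemic lupus erythematosus",
    "rheumatoid arthritis",
    "type 1 diabetes",
)


def stage_seed(seed: int, stage: str) -> np.random.SeedSequence:
    """Deterministic per-stage seed derivation from the run seed."""
    return np.random.SeedSequence([int(seed), zlib.crc32(stage.encode()) & 0xFFFF])


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng(stage_seed(seed, stage))


# ---------------------------------------------------------------------------
# Closed-form design quantities
# ---------------------------------------------------------------------------

def prob_het_any(af: float, n_samples: int) -> float:
    """P(a SNP with allele frequency ``af`` is het in >=1 of n individuals).

    Under Hardy-Weinberg, per-individual het probability is 2p(1-p).
    """
    return 1.0 - (1.0 - 2.0 * af * (1.0 - af)) ** n_samples


def het_coverage_min(af_lo: float, af_hi: float, n_samples: int) -> float:
    """Minimum of :func:`prob_het_any` over an AF interval.

    2p(1-p) is concave with its minimum at the interval endpoints, so the
    minimum coverage is attained at the endpoint farther from 0.5.
    """
    return min(prob_het_any(af_lo, n_samples), prob_het_any(af_hi, n_samples))


def expected_het_uniform_af() -> float:
    """E[2p(1-p)] for p ~ Uniform(0,1): the single-individual het limit."""
    return quad(lambda p: 2 * p * (1 - p), 0.0, 1.0)[0]


# ---------------------------------------------------------------------------
# AF spectra
# ---------------------------------------------------------------------------

def draw_afs(spec, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw allele frequencies from a spectrum specification.

    ``("uniform", lo, hi)``; ``("point", p)``; ``("mixture", rare_frac)``
    which mixes common Uniform(0.05, 0.95) with rare Uniform(0.001, 0.01)
    mass ``rare_frac``.
    """
    kind = spec[0]
    if kind == "uniform":
        return rng.uniform(spec[1], spec[2], size=n)
    if kind == "point":
        return np.full(n, float(spec[1]))
    if kind == "mixture":
        rare = rng.random(n) < spec[1]
        af = rng.uniform(0.05, 0.95, size=n)
        af[rare] = rng.uniform(0.001, 0.01, size=rare.sum())
        return af
    raise ValueError(f"unknown AF spectrum {spec!r}")


# ---------------------------------------------------------------------------
# Panel
# ---------------------------------------------------------------------------

@dataclass
class GeneratedPanel:
    panel: Panel
    #: (common_site_id, rare_site_id) pairs planted within short range of
    #: each other to exercise the rare-variant window scan
    twin_pairs: list[tuple[str, str]]


def generate_panel(
    n_samples: int = 7,
    n_sites: int = 600,
    af_spectrum=("mixture", 0.15),
    chrom_length: int = 400_000,
    seed=0,
    chrom: str = "chr1",
    margin: int = 400,
    n_rare_twins: int = 0,
    sample_prefix: str = "LCL",
) -> GeneratedPanel:
    """Reference sequence plus phased multi-sample SNV panel.

    Genotypes are drawn per sample under Hardy-Weinberg at each site's
    drawn AF; haplotype phase is the draw itself.  ``n_rare_twins`` extra
    rare sites are planted 80-250 bp from randomly chosen common sites,
    each conditioned to be heterozygous in exactly one sample (a rare
    variant observed in the cohort).
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if n_samples < 1:
        raise ValueError("need at least one sample")
    usable = chrom_length - 2 * margin
    if usable < 10 * (n_sites + n_rare_twins):
        raise ValueError(
            f"chromosome length {chrom_length} too small for {n_sites} sites"
        )

    ref_codes = rng.integers(0, 4, size=chrom_length)
    positions = np.sort(
        rng.choice(np.arange(margin, chrom_length - margin), size=n_sites, replace=False)
    )
    afs = draw_afs(af_spectrum, n_sites, rng)
    haps = (rng.random((n_sites, n_samples, 2)) < afs[:, None, None]).astype(np.int8)

    # twins: a rare site planted near a common site, het in exactly 1 sample
    twin_pairs_pos: list[tuple[int, int]] = []
    if n_rare_twins:
        common_idx = np.flatnonzero((afs > 0.2) & (afs < 0.8))
        chosen = rng.choice(common_idx, size=n_rare_twins, replace=False)
        taken = set(positions.tolist())
        extra_pos, extra_hap, extra_af = [], [], []
        for ci in chosen:
            for _ in range(100):
                off = int(rng.integers(80, 251)) * (1 if rng.random() < 0.5 else -1)
                p = int(positions[ci]) + off
                if margin <= p < chrom_length - margin and p not in taken:
                    break
            taken.add(p)
            h = np.zeros((n_samples, 2), dtype=np.int8)
            h[rng.integers(n_samples), rng.integers(2)] = 1
            extra_pos.append(p)
            extra_hap.append(h)
            extra_af.append(rng.uniform(0.001, 0.01))
            twin_pairs_pos.append((int(positions[ci]), p))
        positions = np.concatenate([positions, np.array(extra_pos, dtype=positions.dtype)])
        haps = np.concatenate([haps, np.array(extra_hap)], axis=0)
        afs = np.concatenate([afs, np.array(extra_af)])
        order = np.argsort(positions)
        positions, haps, afs = positions[order], haps[order], afs[order]

    n_total = len(positions)
    ref_bases = ref_codes[positions]
    alt_bases = (ref_bases + rng.integers(1, 4, size=n_total)) % 4
    sites = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": positions + 1,
            "id": [f"snp{i:05d}" for i in range(n_total)],
            "ref": [BASES[b] for b in ref_bases],
            "alt": [BASES[b] for b in alt_bases],
            "af": afs,
        }
    )
    reference = {chrom: "".join(BASES[c] for c in ref_codes)}
    panel = Panel(
        samples=[f"{sample_prefix}{i+1:02d}" for i in range(n_samples)],
        reference=reference,
        sites=sites,
        haplotypes=haps,
    )
    pos_to_id = dict(zip(positions, sites["id"]))
    twin_pairs = [(pos_to_id[c], pos_to_id[r]) for c, r in twin_pairs_pos]
    return GeneratedPanel(panel=panel, twin_pairs=twin_pairs)


# ---------------------------------------------------------------------------
# Regulatory landscape and exclusions
# ---------------------------------------------------------------------------

@dataclass
class Landscape:
    elements: pd.DataFrame
    blacklist: pd.DataFrame
    cnv: pd.DataFrame
    repeats: pd.DataFrame
    #: het sites deliberately covered by blacklist intervals
    blacklist_site_ids: list[str]


#: category sampling weights (retained categories get most of the mass)
_CATEGORY_W = (0.25, 0.15, 0.10, 0.10, 0.15, 0.15, 0.10)


def generate_landscape(
    panel: Panel,
    n_elements: int = 60,
    categories=CATEGORIES_7,
    seed=0,
    cover_sites: list[str] | None = None,
    n_blacklist_planted: int = 3,
    element_size=(200, 800),
) -> Landscape:
    """Non-overlapping categorized elements plus exclusion regions.

    ``cover_sites`` are guaranteed to fall inside retained-category
    elements.  ``n_blacklist_planted`` het-in-cohort sites inside retained
    elements are selected and covered by blacklist intervals, to exercise
    artifact pruning downstream.
    """
    bad = set(categories) - set(CATEGORIES_7)
    if bad:
        raise ValueError(f"unknown categories {sorted(bad)}")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    chrom = panel.sites["chrom"].iloc[0]
    L = len(panel.reference[chrom])
    cover_sites = list(cover_sites or [])

    retained = [c for c in categories if c in RETAINED_CATEGORIES]
    weights = np.array([_CATEGORY_W[CATEGORIES_7.index(c)] for c in categories])
    weights = weights / weights.sum()

    slot_w = L // n_elements
    site_pos = dict(zip(panel.sites["id"], panel.sites["pos"] - 1))
    # forced elements first: cover requested sites, grouping nearby ones
    # (e.g. a rare variant near a common one) into a single element
    forced = []
    cover_pos = sorted(site_pos[sid] for sid in cover_sites)
    k = 0
    while k < len(cover_pos):
        grp = [cover_pos[k]]
        while k + 1 < len(cover_pos) and cover_pos[k + 1] - grp[0] <= 350:
            k += 1
            grp.append(cover_pos[k])
        k += 1
        start = max(0, grp[0] - int(rng.integers(60, 140)))
        end = min(L, grp[-1] + int(rng.integers(80, 160)))
        if end - start < element_size[0]:
            end = min(L, start + element_size[0])
        forced.append((chrom, start, end, retained[len(forced) % len(retained)]))
    forced.sort(key=lambda r: r[1])

    def overlaps_forced(s, e):
        return any(fs < e and s < fe for _, fs, fe, _ in forced)

    rows = list(forced)
    covered_slots = {p // slot_w for p in cover_pos}
    for _ in range(n_elements - len(rows)):
        for _ in range(50):
            slot = int(rng.integers(n_elements))
            if slot not in covered_slots:
                break
        covered_slots.add(slot)
        size = int(rng.integers(*element_size))
        lo = slot * slot_w
        start = int(rng.integers(lo, max(lo + 1, lo + slot_w - size)))
        if overlaps_forced(start, start + size):
            continue
        cat = categories[int(rng.choice(len(categories), p=weights))]
        rows.append((chrom, start, min(L, start + size), cat))
    rows.sort(key=lambda r: r[1])
    forced_set = set(forced)
    # drop any accidental overlaps, never dropping a forced element
    pruned = []
    last_end = -1
    for r in rows:
        if r[1] >= last_end:
            pruned.append(r)
            last_end = r[2]
        elif r in forced_set and pruned and pruned[-1] not in forced_set:
            pruned[-1] = r
            last_end = r[2]
    elements = pd.DataFrame(pruned, columns=["chrom", "start", "end", "category"])
    elements["element_id"] = [f"el{i:04d}" for i in range(len(elements))]
    elements = elements[["chrom", "start", "end", "element_id", "category"]]

    # blacklist planted over het sites inside retained elements
    het_any = (panel.haplotypes[:, :, 0] != panel.haplotypes[:, :, 1]).any(axis=1)
    tab = panel.site_table()
    in_retained = []
    ret_el = elements.loc[elements["category"].isin(RETAINED_CATEGORIES)]
    starts = ret_el["start"].to_numpy()
    ends = ret_el["end"].to_numpy()
    for i, p in enumerate(tab["pos"].to_numpy() - 1):
        inside = ((starts <= p) & (p < ends)).any()
        in_retained.append(inside)
    cover_pos0 = np.array(sorted(site_pos[sid] for sid in cover_sites), dtype=int)

    def _near_cover(pos0: int) -> bool:
        return bool(len(cover_pos0)) and np.abs(cover_pos0 - pos0).min() <= 100

    candidates = tab.loc[
        het_any
        & np.array(in_retained)
        & ~tab["id"].isin(cover_sites)
        & ~np.array([_near_cover(p - 1) for p in tab["pos"]])
    ]
    k = min(n_blacklist_planted, len(candidates))
    if k < n_blacklist_planted:
        logger.warning("only %d blacklist-planted candidates available", k)
    picked = candidates.sample(n=k, random_state=int(rng.integers(2**31)))
    bl_rows = [
        (chrom, int(p) - 1 - 50, int(p) - 1 + 50) for p in picked["pos"]
    ]
    # random exclusion intervals avoid deliberately covered sites, so the
    # only planted AS sites lost to pruning are the blacklist-planted ones
    protected = sorted(site_pos[sid] for sid in cover_sites) + [
        int(p) - 1 for p in picked["pos"]
    ]

    def _rand_interval(size):
        for _ in range(200):
            s = int(rng.integers(0, L - size))
            if not any(s - 5 <= p < s + size + 5 for p in protected):
                return (chrom, s, s + size)
        return (chrom, 0, 0)

    bl_rows.append(_rand_interval(2000))
    blacklist = pd.DataFrame(bl_rows, columns=["chrom", "start", "end"])

    def _rand_intervals(n, size):
        return pd.DataFrame(
            [_rand_interval(size) for _ in range(n)],
            columns=["chrom", "start", "end"],
        )

    cnv = _rand_intervals(2, 3000)
    repeats = _rand_intervals(3, 1000)
    return Landscape(
        elements=elements,
        blacklist=blacklist,
        cnv=cnv,
        repeats=repeats,
        blacklist_site_ids=list(picked["id"]),
    )


# ---------------------------------------------------------------------------
# Reads
# ---------------------------------------------------------------------------

@dataclass
class ReadsResult:
    sample: str
    assay: str
    path: str | None
    n_reads: int
    #: generator-side tally of informative (non-duplicate, high-quality)
    #: allele counts per het site, in the fixed ref/alt orientation
    true_counts: pd.DataFrame


def generate_reads(
    panel: Panel,
    sample: str,
    assay: str,
    depth: int = 40,
    planted_ratios: dict[str, float] | None = None,
    read_len: int = 101,
    seed=0,
    out_sam: str | None = None,
    lowq_frac: float = 0.05,
    dup_frac: float = 0.02,
    base_qual: int = 35,
    lowq_qual: int = 15,
    genomes=None,
) -> ReadsResult:
    """Emit pre-aligned SAM reads over a sample's heterozygous sites.

    Each het site receives exactly ``depth`` targeted reads whose start is
    uniform among placements overlapping the site; a read carries the G1
    haplotype with probability equal to the site's planted ratio (default
    0.5).  The read sequence is copied from the chosen personal haplotype
    genome, so a read spanning several het sites is allele-consistent.  A
    ``lowq_frac`` fraction of reads get base qualities below the Phred-20
    cutoff and a ``dup_frac`` fraction are duplicate-flagged; neither
    contributes to the recorded true counts.
    """
    if depth < 0:
        raise ValueError("depth must be >= 0")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    planted_ratios = dict(planted_ratios or {})
    het = het_sites(panel, sample)
    unknown = set(planted_ratios) - set(het["site_id"])
    for sid in sorted(unknown):
        logger.warning(
            "planted site %s is not heterozygous in %s; skipped", sid, sample
        )
        planted_ratios.pop(sid)
    for ratio in planted_ratios.values():
        if not 0.0 <= ratio <= 1.0:
            raise ValueError("planted ratio must be in [0, 1]")
    if genomes is None:
        genomes = personal_genomes_for_sample(panel, sample)

    reads = []  # (chrom, start0, use_g1, lowq, dup)
    for row in het.itertuples(index=False):
        ratio = planted_ratios.get(row.site_id, 0.5)
        pos0 = row.pos - 1
        L = len(panel.reference[row.chrom])
        lo = max(0, pos0 - read_len + 1)
        hi = min(pos0, L - read_len)
        if hi < lo or depth == 0:
            continue
        starts = rng.integers(lo, hi + 1, size=depth)
        g1 = rng.random(depth) < ratio
        lowq = rng.random(depth) < lowq_frac
        dup = rng.random(depth) < dup_frac
        for k in range(depth):
            reads.append((row.chrom, int(starts[k]), bool(g1[k]), bool(lowq[k]), bool(dup[k])))

    # generator-side tally in ref/alt orientation
    n = len(het)
    n_ref = np.zeros(n, dtype=np.int64)
    n_alt = np.zeros(n, dtype=np.int64)
    n_lowq = np.zeros(n, dtype=np.int64)
    by_chrom = {}
    for chrom, grp in het.groupby("chrom", sort=False):
        pos0 = grp["pos"].to_numpy() - 1
        order = np.argsort(pos0)
        by_chrom[chrom] = (pos0[order], grp.index.to_numpy()[order])
    g1_is_ref = (het["g1"] == het["ref"]).to_numpy()
    for chrom, start, use_g1, lowq, dup in reads:
        if dup:
            continue
        pos_sorted, idx_sorted = by_chrom[chrom]
        lo_i = np.searchsorted(pos_sorted, start)
        hi_i = np.searchsorted(pos_sorted, start + read_len)
        for k in range(lo_i, hi_i):
            i = int(idx_sorted[k])
            if lowq:
                n_lowq[i] += 1
            elif use_g1 == g1_is_ref[i]:
                n_ref[i] += 1
            else:
                n_alt[i] += 1

    true_counts = het[["chrom", "pos", "site_id", "ref", "alt"]].copy()
    true_counts["n_ref"] = n_ref
    true_counts["n_alt"] = n_alt
    true_counts["n_lowq"] = n_lowq
    true_counts["sample"] = sample
    true_counts["assay"] = assay

    if out_sam is not None:
        with open(out_sam, "w") as fh:
            fh.write("@HD\tVN:1.6\tSO:unsorted\n")
            for chrom, seq in panel.reference.items():
                fh.write(f"@SQ\tSN:{chrom}\tLN:{len(seq)}\n")
            for i, (chrom, start, use_g1, lowq, dup) in enumerate(reads):
                src = genomes.g1_sequences if use_g1 else genomes.g2_sequences
                seq = src[chrom][start : start + read_len]
                flag = 1024 if dup else 0
                q = lowq_qual if lowq else base_qual
                fh.write(
                    f"r{i:07d}\t{flag}\t{chrom}\t{start + 1}\t60\t"
                    f"{len(seq)}M\t*\t0\t0\t{seq}\t{chr(33 + q) * len(seq)}\n"
                )
    return ReadsResult(
        sample=sample,
        assay=assay,
        path=out_sam,
        n_reads=len(reads),
        true_counts=true_counts,
    )


# ---------------------------------------------------------------------------
# GWAS / eQTL catalogs with engineered LD
# ---------------------------------------------------------------------------

@dataclass
class Catalogs:
    gwas: pd.DataFrame
    eqtl: pd.DataFrame
    #: list of dicts: index, proxies, negatives, target_r2
    ld_groups: list[dict]
    index_gwas: list[str]
    index_eqtl: list[str]


def generate_catalogs(
    panel: Panel,
    gene_ids: list[str],
    n_index_gwas: int = 5,
    n_index_eqtl: int = 5,
    proxies_per_index: int = 3,
    negatives_per_index: int = 1,
    seed=0,
    shared_index: bool = True,
    preferred_eqtl_index: list[str] | None = None,
    traits=DEFAULT_TRAITS,
) -> Catalogs:
    """GWAS/eQTL index SNP tables with planted LD structure in the panel.

    Proxies are planted by copying the index site's haplotype column
    (r^2 = 1); negatives are redrawn independently until r^2 < 0.5 (an
    impossible draw is simply redrawn, logged at debug level).  With
    ``shared_index`` the last GWAS index SNP also appears in the eQTL
    table, so its proxies link to both catalogs.  Mutates the panel's
    haplotypes in place.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    tab = panel.site_table()
    het_counts = (panel.haplotypes[:, :, 0] != panel.haplotypes[:, :, 1]).sum(axis=1)
    pool = tab.loc[
        (tab["af"] > 0.15) & (tab["af"] < 0.85) & (het_counts >= 2), "id"
    ].tolist()
    rng.shuffle(pool)
    preferred = [s for s in (preferred_eqtl_index or []) if s in set(tab["id"])]
    pool = [s for s in pool if s not in set(preferred)]

    needed = (
        n_index_gwas
        + max(0, n_index_eqtl - len(preferred))
        + (n_index_gwas + n_index_eqtl) * (proxies_per_index + negatives_per_index)
    )
    if len(pool) < needed:
        raise ValueError(
            f"panel too small for the requested catalog structure "
            f"({len(pool)} eligible sites, {needed} needed)"
        )
    index_gwas = [pool.pop() for _ in range(n_index_gwas)]
    index_eqtl = list(preferred)
    while len(index_eqtl) < n_index_eqtl:
        index_eqtl.append(pool.pop())
    if shared_index:
        index_eqtl[-1] = index_gwas[-1]

    id_to_idx = {sid: i for i, sid in enumerate(panel.sites["id"])}
    hm = haplotype_matrix(panel)
    ld_groups = []
    used = set(index_gwas) | set(index_eqtl)
    for idx_id in dict.fromkeys(index_gwas + index_eqtl):  # unique, ordered
        i = id_to_idx[idx_id]
        proxies, negatives = [], []
        for _ in range(proxies_per_index):
            pid = pool.pop()
            used.add(pid)
            panel.haplotypes[id_to_idx[pid]] = panel.haplotypes[i]
            proxies.append(pid)
        for _ in range(negatives_per_index):
            nid = pool.pop()
            used.add(nid)
            j = id_to_idx[nid]
            af = float(tab.loc[tab["id"] == nid, "af"].iloc[0])
            for _ in range(200):
                draw = (rng.random(panel.haplotypes.shape[1:]) < af).astype(np.int8)
                panel.haplotypes[j] = draw
                r2 = compute_r2(hm[i], haplotype_matrix(panel)[j])
                if not np.isnan(r2) and r2 < 0.5:
                    break
                logger.debug("redrawing negative %s (r2=%s)", nid, r2)
            negatives.append(nid)
        ld_groups.append(
            {
                "index": idx_id,
                "proxies": proxies,
                "negatives": negatives,
                "target_r2": 1.0,
            }
        )

    pos_of = dict(zip(tab["id"], tab["pos"]))
    chrom_of = dict(zip(tab["id"], tab["chrom"]))
    gwas = pd.DataFrame(
        {
            "snp_id": index_gwas,
            "chrom": [chrom_of[s] for s in index_gwas],
            "pos": [pos_of[s] for s in index_gwas],
            "trait": [traits[i % len(traits)] for i in range(len(index_gwas))],
        }
    )
    eqtl = pd.DataFrame(
        {
            "snp_id": index_eqtl,
            "chrom": [chrom_of[s] for s in index_eqtl],
            "pos": [pos_of[s] for s in index_eqtl],
            "gene": [gene_ids[i % len(gene_ids)] for i in range(len(index_eqtl))],
        }
    )
    return Catalogs(
        gwas=gwas,
        eqtl=eqtl,
        ld_groups=ld_groups,
        index_gwas=index_gwas,
        index_eqtl=index_eqtl,
    )


# ---------------------------------------------------------------------------
# 3D structure: TADs, genes, capture probes and read pairs
# ---------------------------------------------------------------------------

@dataclass
class ThreeD:
    contacts: pd.DataFrame
    genes: pd.DataFrame
    probes: pd.DataFrame | None = None
    read_pairs: pd.DataFrame | None = None
    planted_interactions: list[dict] = field(default_factory=list)


def generate_tads_genes(
    panel: Panel, n_tads: int = 4, genes_per_loop: int = 2, seed=0
) -> ThreeD:
    """Ordered, non-crossing contact-domain pairs with loop/anchor genes."""
    chrom = panel.sites["chrom"].iloc[0]
    L = len(panel.reference[chrom])
    seg = L // n_tads
    m = max(seg // 20, 20)  # contact-domain margin/width unit
    gw = max(100, min(2000, seg // 12))  # gene width
    contacts, genes = [], []
    gi = 0
    for t in range(n_tads):
        s = t * seg
        a = (s + m, s + 5 * m)
        b = (s + seg - 5 * m, s + seg - m)
        contacts.append((chrom, a[0], a[1], b[0], b[1]))
        loop = (a[1], b[0])
        span = loop[1] - loop[0]
        for k in range(genes_per_loop):
            gs = loop[0] + (k + 1) * span // (genes_per_loop + 1)
            genes.append((chrom, gs, gs + gw, f"gene{gi:03d}"))
            gi += 1
    # one anchor gene straddling the first TAD's second contact domain
    b0 = contacts[0][3]
    genes.append((chrom, b0 - gw // 4, b0 + gw * 3 // 4, f"gene{gi:03d}"))
    return ThreeD(
        contacts=pd.DataFrame(
            contacts, columns=["chrom", "a_start", "a_end", "b_start", "b_end"]
        ),
        genes=pd.DataFrame(genes, columns=["chrom", "start", "end", "gene_id"]),
    )


def generate_capture(
    panel: Panel,
    threed: ThreeD,
    planted: list[dict],
    snp_probe_sites: list[str] | None = None,
    n_control_probes: int = 30,
    replicates: int = 3,
    frag_size: int = 4000,
    max_dist: int = 60_000,
    seed=0,
    background_rate: float = 4.0,
    background_scale: float = 20_000.0,
    signal_rate: float = 20.0,
) -> ThreeD:
    """Replicated capture read-pair tables with planted true interactions.

    ``planted`` entries are dicts with ``probe_id`` and ``frag_start``
    (fragment-aligned); their read support is redrawn until at least two
    replicates carry >= 12 read pairs, guaranteeing they clear both the
    read-support and the empirical-p components of the replicate filter.
    Background counts decay exponentially with probe-fragment distance;
    control probes in unannotated regions provide the null.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    chrom = panel.sites["chrom"].iloc[0]
    L = len(panel.reference[chrom])
    pos_of = dict(zip(panel.sites["id"], panel.sites["pos"]))

    probes = []
    for g in threed.genes.itertuples(index=False):
        probes.append((f"pr_{g.gene_id}", chrom, g.start + 100, "promoter", g.gene_id))
    for sid in snp_probe_sites or []:
        probes.append((f"ps_{sid}", chrom, int(pos_of[sid]) - 1, "snp", ""))
    for c in range(n_control_probes):
        probes.append(
            (f"pc{c:03d}", chrom, int(rng.integers(2000, L - 2000)), "control", "")
        )
    probes_df = pd.DataFrame(
        probes, columns=["probe_id", "chrom", "pos", "kind", "gene"]
    )

    n_frags = L // frag_size
    rows = []
    for p in probes_df.itertuples(index=False):
        own = p.pos // frag_size
        lo = max(0, (p.pos - max_dist) // frag_size)
        hi = min(n_frags - 1, (p.pos + max_dist) // frag_size)
        for f in range(lo, hi + 1):
            if f == own:
                continue
            fs, fe = f * frag_size, (f + 1) * frag_size
            d = abs((fs + fe) // 2 - p.pos)
            lam = background_rate * np.exp(-d / background_scale)
            for rep in range(1, replicates + 1):
                rows.append(
                    (p.probe_id, chrom, fs, fe, int(rng.poisson(lam)), rep)
                )
    rp = pd.DataFrame(
        rows,
        columns=["probe_id", "distal_chrom", "distal_start", "distal_end",
                 "read_pairs", "replicate"],
    )

    planted_out = []
    for spec in planted:
        fs = int(spec["frag_start"]) // frag_size * frag_size
        fe = fs + frag_size
        while True:
            counts = rng.poisson(signal_rate, size=replicates)
            if (counts >= 12).sum() >= 2:
                break
        mask = (
            (rp["probe_id"] == spec["probe_id"])
            & (rp["distal_start"] == fs)
        )
        rp = rp.loc[~mask]
        extra = pd.DataFrame(
            {
                "probe_id": spec["probe_id"],
                "distal_chrom": chrom,
                "distal_start": fs,
                "distal_end": fe,
                "read_pairs": counts,
                "replicate": np.arange(1, replicates + 1),
            }
        )
        rp = pd.concat([rp, extra], ignore_index=True)
        planted_out.append(
            {**spec, "frag_start": fs, "frag_end": fe, "counts": counts.tolist()}
        )
    rp = rp.sort_values(
        ["probe_id", "distal_start", "replicate"], kind="mergesort"
    ).reset_index(drop=True)
    return ThreeD(
        contacts=threed.contacts,
        genes=threed.genes,
        probes=probes_df,
        read_pairs=rp,
        planted_interactions=planted_out,
    )


def generate_3d(
    panel: Panel,
    n_tads: int = 4,
    n_probes: int = 30,
    replicates: int = 3,
    seed=0,
    genes_per_loop: int = 2,
    planted: list[dict] | None = None,
    **kwargs,
) -> ThreeD:
    """Convenience wrapper: TAD/gene structure plus capture tables."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    struct = generate_tads_genes(panel, n_tads=n_tads, genes_per_loop=genes_per_loop, seed=rng)
    return generate_capture(
        panel,
        struct,
        planted or [],
        n_control_probes=n_probes,
        replicates=replicates,
        seed=rng,
        **kwargs,
    )


# ---------------------------------------------------------------------------
# Motif specs, sampling, implanting
# ---------------------------------------------------------------------------

def pwm_motif_spec(length: int, seed=0, sharpness: float = 0.85) -> list[dict]:
    """Independence (PWM-like) spec: one favored base per position."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    spec = []
    for _ in range(length):
        fav = int(rng.integers(4))
        probs = np.full(4, (1 - sharpness) / 3)
        probs[fav] = sharpness
        spec.append({"probs": probs.tolist()})
    return spec


def add_first_order_dependency(spec: list[dict], pos: int, strength: float = 0.9) -> list[dict]:
    """Make position ``pos`` strongly depend on the previous base.

    The favored base at ``pos`` becomes a fixed permutation of the
    previous base (A->C, C->G, G->T, T->A), so the marginal at ``pos`` is
    near-uniform while the conditional entropy is low.
    """
    if pos < 1:
        raise ValueError("dependency needs a preceding position")
    out = [dict(p) for p in spec]
    mapping = {0: 1, 1: 2, 2: 3, 3: 0}
    cond = {}
    for prev in range(4):
        probs = np.full(4, (1 - strength) / 3)
        probs[mapping[prev]] = strength
        cond[BASES[prev]] = probs.tolist()
    out[pos] = {"cond": cond}
    return out


def sample_motif_sites(spec: list[dict], n_sites: int, seed=0) -> list[str]:
    """Sample i.i.d. sites from a motif spec."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    sites = []
    for _ in range(n_sites):
        chars = []
        for p in spec:
            if "probs" in p:
                probs = np.asarray(p["probs"])
            else:
                probs = np.asarray(p["cond"][chars[-1]])
            chars.append(BASES[rng.choice(4, p=probs / probs.sum())])
        sites.append("".join(chars))
    return sites


def consensus_site(spec: list[dict]) -> str:
    chars = []
    for p in spec:
        if "probs" in p:
            probs = np.asarray(p["probs"])
        else:
            probs = np.asarray(p["cond"][chars[-1]])
        chars.append(BASES[int(np.argmax(probs))])
    return "".join(chars)


def implant_motif(
    panel: Panel, site_id: str, spec: list[dict], effect: str, rng
) -> dict:
    """Write a motif instance into the reference around a het site.

    The motif consensus is implanted so the variant position falls inside
    the motif; for ``effect="gain"`` the site's reference allele becomes a
    weak base and the alternative allele the consensus base (the motif is
    intact only on the alternative-allele window), and vice versa for
    ``"loss"``.  Updates the panel's reference sequence and the site's
    ref/alt alleles in place.
    """
    i = panel.sites.index[panel.sites["id"] == site_id][0]
    chrom = panel.sites.at[i, "chrom"]
    pos0 = int(panel.sites.at[i, "pos"]) - 1
    Lm = len(spec)
    j = int(rng.integers(1, Lm - 1))
    start = pos0 - j
    cons = consensus_site(spec)
    p = spec[j]
    probs = np.asarray(p["probs"] if "probs" in p else p["cond"][cons[j - 1]])
    weak = BASES[int(np.argmin(probs))]
    strong = cons[j]
    if weak == strong:  # degenerate flat position
        weak = BASES[(BASES.index(strong) + 1) % 4]
    ref_allele, alt_allele = (weak, strong) if effect == "gain" else (strong, weak)
    seq = panel.reference[chrom]
    new_region = cons[:j] + ref_allele + cons[j + 1 :]
    panel.reference[chrom] = seq[:start] + new_region + seq[start + Lm :]
    panel.sites.at[i, "ref"] = ref_allele
    panel.sites.at[i, "alt"] = alt_allele
    return {
        "site_id": site_id,
        "effect": effect,
        "motif_start": start,
        "snp_motif_offset": j,
        "ref": ref_allele,
        "alt": alt_allele,
    }


def generate_motif_sites(motif_spec: list[dict], n_sites: int, seed=0,
                         out_fasta: str | None = None) -> list[str]:
    """Training-site FASTA sampled from a motif spec (may be empty)."""
    sites = sample_motif_sites(motif_spec, n_sites, seed)
    if out_fasta is not None:
        from .motifs import write_sites_fasta

        write_sites_fasta(sites, out_fasta)
    return sites


# ---------------------------------------------------------------------------
# Whole-study simulation
# ---------------------------------------------------------------------------

@dataclass
class SimParams:
    """Study conditions of the synthetic cohort (defaults = main design)."""

    n_samples: int = 7
    n_sites: int = 600
    chrom: str = "chr1"
    chrom_length: int = 400_000
    rare_fraction: float = 0.15
    margin: int = 400
    n_rare_twins: int = 3
    assays: tuple = ASSAYS
    depth: int = 40
    read_len: int = 101
    lowq_frac: float = 0.05
    dup_frac: float = 0.02
    planted_ratio: float = 0.9
    n_planted_as: int = 20
    n_weak_planted: int = 2
    weak_ratio: float = 0.7
    n_blacklist_planted: int = 3
    n_elements: int = 60
    n_index_gwas: int = 5
    n_index_eqtl: int = 5
    proxies_per_index: int = 3
    negatives_per_index: int = 1
    n_tads: int = 4
    genes_per_loop: int = 2
    replicates: int = 3
    n_control_probes: int = 30
    frag_size: int = 4000
    capture_max_dist: int = 60_000
    motif_length: int = 10
    motif_training_sites: int = 500
    n_motif_gain: int = 3
    n_motif_loss: int = 3


@dataclass
class SyntheticDataset:
    """All generated inputs plus planted truth, in memory and on disk."""

    params: SimParams
    seed: int
    panel: Panel
    twin_pairs: list[tuple[str, str]]
    landscape: Landscape
    catalogs: Catalogs
    threed: ThreeD
    motif_specs: dict[str, list[dict]]
    motif_training: dict[str, list[str]]
    planted_as: pd.DataFrame
    planted_motifs: list[dict]
    true_counts: pd.DataFrame
    manifest: dict
    outdir: str | None = None
    paths: dict = field(default_factory=dict)


def _retained_element_lookup(landscape: Landscape):
    ret = landscape.elements.loc[
        landscape.elements["category"].isin(RETAINED_CATEGORIES)
    ]
    starts = ret["start"].to_numpy()
    ends = ret["end"].to_numpy()
    ids = ret["element_id"].to_numpy()

    def lookup(pos0: int):
        hit = (starts <= pos0) & (pos0 < ends)
        return ids[hit][0] if hit.any() else None

    return lookup


def _excluded_lookup(landscape: Landscape):
    frames = [landscape.blacklist, landscape.cnv, landscape.repeats]
    starts = np.concatenate([f["start"].to_numpy() for f in frames])
    ends = np.concatenate([f["end"].to_numpy() for f in frames])

    def lookup(pos0: int) -> bool:
        return bool(((starts <= pos0) & (pos0 < ends)).any())

    return lookup


def simulate_all(seed: int, params: SimParams | None = None,
                 outdir: str | None = None) -> SyntheticDataset:
    """Generate the full synthetic study with planted ground truth.

    One seed determines every output; files are written under ``outdir``
    when given (reference FASTA, phased VCF, element and exclusion BEDs,
    catalog/contact/probe/read-pair TSVs, training FASTAs, per
    sample-and-assay SAMs, the true-count table and the JSON manifest).
    """
    p = params or SimParams()
    gp = generate_panel(
        n_samples=p.n_samples,
        n_sites=p.n_sites,
        af_spectrum=("mixture", p.rare_fraction),
        chrom_length=p.chrom_length,
        seed=stage_rng(seed, "panel"),
        chrom=p.chrom,
        margin=p.margin,
        n_rare_twins=p.n_rare_twins,
    )
    panel = gp.panel
    twin_commons = [c for c, _ in gp.twin_pairs]
    twin_rares = [r for _, r in gp.twin_pairs]

    struct = generate_tads_genes(
        panel, n_tads=p.n_tads, genes_per_loop=p.genes_per_loop
    )
    gene_ids = list(struct.genes["gene_id"])

    catalogs = generate_catalogs(
        panel,
        gene_ids=gene_ids,
        n_index_gwas=p.n_index_gwas,
        n_index_eqtl=p.n_index_eqtl,
        proxies_per_index=p.proxies_per_index,
        negatives_per_index=p.negatives_per_index,
        seed=stage_rng(seed, "catalogs"),
        preferred_eqtl_index=twin_commons,
    )

    # --- association-linked AS-SNP picks ---------------------------------
    rng_pick = stage_rng(seed, "picks")
    het_any = (panel.haplotypes[:, :, 0] != panel.haplotypes[:, :, 1]).any(axis=1)
    het_ids = set(panel.sites.loc[het_any, "id"])
    prox_of = {g["index"]: [x for x in g["proxies"] if x in het_ids]
               for g in catalogs.ld_groups}
    shared = catalogs.index_gwas[-1]  # also an eQTL index
    gwas_direct = [s for s in catalogs.index_gwas[:-1] if s in het_ids][:2]
    gwas_proxy = [prox_of[i][0] for i in catalogs.index_gwas[:2] if prox_of.get(i)][:2]
    both_pick = prox_of.get(shared, [])[:1]
    eqtl_only = [s for s in catalogs.index_eqtl
                 if s not in set(twin_commons) and s != shared and s in het_ids]
    eqtl_direct = eqtl_only[:1]
    eqtl_proxy = [prox_of[i][0] for i in eqtl_only[:1] if prox_of.get(i)][:1]
    assoc_picks = list(dict.fromkeys(
        gwas_direct + gwas_proxy + both_pick
        + [t for t in twin_commons if t in het_ids] + eqtl_direct + eqtl_proxy
    ))

    landscape = generate_landscape(
        panel,
        n_elements=p.n_elements,
        seed=stage_rng(seed, "landscape"),
        cover_sites=assoc_picks + [t for t in twin_rares if t in het_ids],
        n_blacklist_planted=p.n_blacklist_planted,
    )

    # --- fill with random in-element het sites ---------------------------
    elem_of = _retained_element_lookup(landscape)
    excluded = _excluded_lookup(landscape)
    tab = panel.site_table()
    picked = set(assoc_picks) | set(twin_rares) | set(landscape.blacklist_site_ids)
    fill_candidates = [
        row.id
        for row in tab.itertuples(index=False)
        if row.id in het_ids
        and row.id not in picked
        and elem_of(row.pos - 1) is not None
        and not excluded(row.pos - 1)
    ]
    n_fill = max(0, p.n_planted_as - len(assoc_picks) - len(twin_rares))
    fill = [str(s) for s in rng_pick.choice(
        fill_candidates, size=min(n_fill, len(fill_candidates)), replace=False
    )]
    # weak sites need several het samples so the aggregate has power the
    # single samples lack (the case2 mechanism)
    het_n = dict(zip(
        panel.sites["id"],
        (panel.haplotypes[:, :, 0] != panel.haplotypes[:, :, 1]).sum(axis=1),
    ))
    weak_pool = [s for s in fill_candidates if s not in set(fill) and het_n[s] >= 4]
    weak = [str(s) for s in rng_pick.choice(
        weak_pool, size=min(p.n_weak_planted, len(weak_pool)), replace=False
    )]

    # --- assay assignment -------------------------------------------------
    planted_rows = []
    ordered = (
        [(s, "assoc") for s in assoc_picks]
        + [(s, "rare_twin") for s in twin_rares if s in het_ids]
        + [(s, "fill") for s in fill]
        + [(s, "weak") for s in weak]
        + [(s, "blacklist") for s in landscape.blacklist_site_ids]
    )
    for k, (sid, kind) in enumerate(ordered):
        assays = [p.assays[k % len(p.assays)]]
        ratio = p.weak_ratio if kind == "weak" else p.planted_ratio
        planted_rows.append({"site_id": sid, "kind": kind, "assays": assays,
                             "ratio_alt": ratio})
    # two mixed-signal sites: add a second histone mark
    histones = [a for a in p.assays if a in {"H3K27ac", "H3K4me1", "H3K4me3"}]
    n_mixed = 0
    for row in planted_rows:
        if row["kind"] == "fill" and n_mixed < 2:
            first = row["assays"][0]
            second = next((h for h in histones if h != first), None)
            if second:
                if first not in histones:
                    row["assays"] = [histones[0], histones[1]]
                else:
                    row["assays"].append(second)
                n_mixed += 1

    # --- motif implanting (before personal genomes / reads) --------------
    rng_motif = stage_rng(seed, "motif")
    spec_dep = add_first_order_dependency(
        pwm_motif_spec(p.motif_length, seed=rng_motif), pos=p.motif_length // 2
    )
    spec_ind = pwm_motif_spec(p.motif_length, seed=rng_motif)
    motif_specs = {"TFA": spec_dep, "TFB": spec_ind}
    all_pos = np.sort(panel.sites["pos"].to_numpy())

    def isolated(sid: str) -> bool:
        pos = int(tab.loc[tab["id"] == sid, "pos"].iloc[0])
        d = np.abs(all_pos - pos)
        return (d[d > 0].min() if (d > 0).any() else 10**9) > p.motif_length + 4

    implant_pool = [r["site_id"] for r in planted_rows
                    if r["kind"] in ("assoc", "fill") and isolated(r["site_id"])]
    planted_motifs = []
    want = [("TFA", "gain")] * p.n_motif_gain + [("TFB", "loss")] * p.n_motif_loss
    for (tf, effect), sid in zip(want, implant_pool):
        rec = implant_motif(panel, sid, motif_specs[tf], effect, rng_motif)
        rec["tf"] = tf
        planted_motifs.append(rec)

    motif_training = {
        tf: sample_motif_sites(spec, p.motif_training_sites,
                               seed=stage_rng(seed, f"train:{tf}"))
        for tf, spec in motif_specs.items()
    }

    # --- reads ------------------------------------------------------------
    paths: dict[str, str] = {}
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        (out / "reads").mkdir(parents=True, exist_ok=True)
        (out / "motifs").mkdir(exist_ok=True)

    assay_sites = {a: {} for a in p.assays}  # assay -> {site_id: ratio_alt}
    for row in planted_rows:
        for a in row["assays"]:
            assay_sites[a][row["site_id"]] = row["ratio_alt"]

    tc_frames = []
    for sample in panel.samples:
        genomes = personal_genomes_for_sample(panel, sample)
        het = het_sites(panel, sample)
        g1_is_alt = dict(zip(het["site_id"], het["g1"] == het["alt"]))
        for assay in p.assays:
            ratios = {
                sid: (r if g1_is_alt[sid] else 1.0 - r)
                for sid, r in assay_sites[assay].items()
                if sid in g1_is_alt
            }
            sam_path = str(out / "reads" / f"{sample}.{assay}.sam") if out else None
            rr = generate_reads(
                panel,
                sample,
                assay,
                depth=p.depth,
                planted_ratios=ratios,
                read_len=p.read_len,
                seed=stage_rng(seed, f"reads:{sample}:{assay}"),
                out_sam=sam_path,
                lowq_frac=p.lowq_frac,
                dup_frac=p.dup_frac,
                genomes=genomes,
            )
            if sam_path:
                paths[f"reads:{sample}:{assay}"] = sam_path
            tc_frames.append(rr.true_counts)
    true_counts = pd.concat(tc_frames, ignore_index=True)

    # --- capture interactions --------------------------------------------
    pos_of = dict(zip(panel.sites["id"], panel.sites["pos"]))
    eqtl_gene = dict(zip(catalogs.eqtl["snp_id"], catalogs.eqtl["gene"]))
    index_of_proxy = {}
    for g in catalogs.ld_groups:
        for x in g["proxies"]:
            index_of_proxy[x] = g["index"]
    planted_int = []

    def frag_start(sid):
        return (int(pos_of[sid]) - 1) // p.frag_size * p.frag_size

    confirmed_sites, different_sites, indirect_site = [], [], None
    if twin_commons and twin_commons[0] in het_ids:
        sid = twin_commons[0]
        planted_int.append({"probe_id": f"pr_{eqtl_gene[sid]}",
                            "frag_start": frag_start(sid), "as_snp": sid,
                            "label": "confirmed"})
        confirmed_sites.append(sid)
    if eqtl_proxy:
        sid = eqtl_proxy[0]
        g = eqtl_gene[index_of_proxy[sid]]
        planted_int.append({"probe_id": f"pr_{g}", "frag_start": frag_start(sid),
                            "as_snp": sid, "label": "confirmed"})
        confirmed_sites.append(sid)
    if len(twin_commons) > 1 and twin_commons[1] in het_ids:
        sid = twin_commons[1]
        other = next(g for g in gene_ids if g != eqtl_gene[sid])
        planted_int.append({"probe_id": f"pr_{other}", "frag_start": frag_start(sid),
                            "as_snp": sid, "label": "different"})
        different_sites.append(sid)
    snp_probe_sites = gwas_proxy[:1]
    if snp_probe_sites:
        sid = snp_probe_sites[0]
        indirect_site = sid
        target_gene = gene_ids[0]
        g_pos = int(struct.genes.loc[struct.genes["gene_id"] == target_gene,
                                     "start"].iloc[0]) + 100
        fa = frag_start(sid) // p.frag_size
        fb = g_pos // p.frag_size
        fx = (fa + fb) // 2
        if fx in (fa, fb):
            fx = max(fa, fb) + 2
        planted_int.append({"probe_id": f"ps_{sid}", "frag_start": fx * p.frag_size,
                            "as_snp": sid, "label": "indirect_hop"})
        planted_int.append({"probe_id": f"pr_{target_gene}",
                            "frag_start": fx * p.frag_size,
                            "as_snp": sid, "label": "indirect_hop"})

    threed = generate_capture(
        panel,
        struct,
        planted_int,
        snp_probe_sites=snp_probe_sites,
        n_control_probes=p.n_control_probes,
        replicates=p.replicates,
        frag_size=p.frag_size,
        max_dist=p.capture_max_dist,
        seed=stage_rng(seed, "capture"),
    )

    # --- assemble planted-AS table and manifest ---------------------------
    elem_of = _retained_element_lookup(landscape)
    for row in planted_rows:
        pos = int(tab.loc[tab["id"] == row["site_id"], "pos"].iloc[0])
        row["element_id"] = elem_of(pos - 1)
        row["assays"] = list(row["assays"])
    planted_as = pd.DataFrame(planted_rows)

    manifest = {
        "seed": int(seed),
        "samples": list(panel.samples),
        "chrom": p.chrom,
        "chrom_length": int(p.chrom_length),
        "planted_as_sites": [
            {"site_id": r["site_id"], "true_ratio": float(r["ratio_alt"]),
             "element_id": r["element_id"], "assays": r["assays"],
             "kind": r["kind"]}
            for r in planted_rows
        ],
        "blacklist_planted": list(landscape.blacklist_site_ids),
        "twin_pairs": [list(t) for t in gp.twin_pairs],
        "planted_ld_groups": catalogs.ld_groups,
        "planted_interactions": [
            {k: (int(v) if isinstance(v, (int, np.integer)) else v)
             for k, v in d.items()}
            for d in threed.planted_interactions
        ],
        "planted_motifs": planted_motifs,
        "capture_truth": {
            "confirmed": confirmed_sites,
            "different": different_sites,
            "indirect": indirect_site,
        },
        "true_counts_file": "true_counts.tsv",
    }

    ds = SyntheticDataset(
        params=p,
        seed=int(seed),
        panel=panel,
        twin_pairs=gp.twin_pairs,
        landscape=landscape,
        catalogs=catalogs,
        threed=threed,
        motif_specs=motif_specs,
        motif_training=motif_training,
        planted_as=planted_as,
        planted_motifs=planted_motifs,
        true_counts=true_counts,
        manifest=manifest,
        outdir=str(out) if out else None,
        paths=paths,
    )
    if out is not None:
        _write_dataset_files(ds, out)
    return ds


def _write_dataset_files(ds: SyntheticDataset, out: Path) -> None:
    from .motifs import write_sites_fasta

    out.mkdir(parents=True, exist_ok=True)
    write_reference(ds.panel.reference, out / "reference.fa")
    write_panel_vcf(ds.panel, out / "panel.vcf")
    ds.landscape.elements.to_csv(
        out / "elements.bed", sep="\t", header=False, index=False
    )
    for name in ("blacklist", "cnv", "repeats"):
        getattr(ds.landscape, name).to_csv(
            out / f"{name}.bed", sep="\t", header=False, index=False
        )
    ds.catalogs.gwas.to_csv(out / "gwas.tsv", sep="\t", index=False)
    ds.catalogs.eqtl.to_csv(out / "eqtl.tsv", sep="\t", index=False)
    ds.threed.contacts.to_csv(out / "contacts.tsv", sep="\t", index=False)
    ds.threed.genes.to_csv(out / "genes.bed", sep="\t", header=False, index=False)
    ds.threed.probes.to_csv(out / "probes.tsv", sep="\t", index=False)
    ds.threed.read_pairs.to_csv(out / "read_pairs.tsv", sep="\t", index=False)
    for tf, sites in ds.motif_training.items():
        write_sites_fasta(sites, out / "motifs" / f"{tf}.fa")
    ds.true_counts.to_csv(out / "true_counts.tsv", sep="\t", index=False)
    with open(out / "manifest.json", "w") as fh:
        json.dump(ds.manifest, fh, indent=2, default=_jsonable)
    ds.paths.update(
        {
            "reference": str(out / "reference.fa"),
            "vcf": str(out / "panel.vcf"),
            "elements": str(out / "elements.bed"),
            "blacklist": str(out / "blacklist.bed"),
            "cnv": str(out / "cnv.bed"),
            "repeats": str(out / "repeats.bed"),
            "gwas": str(out / "gwas.tsv"),
            "eqtl": str(out / "eqtl.tsv"),
            "contacts": str(out / "contacts.tsv"),
            "genes": str(out / "genes.bed"),
            "probes": str(out / "probes.tsv"),
            "read_pairs": str(out / "read_pairs.tsv"),
            "manifest": str(out / "manifest.json"),
            "true_counts": str(out / "true_counts.tsv"),
            "motifs_dir": str(out / "motifs"),
        }
    )


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON serializable: {type(x)}")


# ---------------------------------------------------------------------------
# Planted-signal recovery experiment
# ---------------------------------------------------------------------------

def planted_recovery_experiment(
    seed: int,
    n_null: int = 500,
    n_planted: int = 20,
    ratio: float = 0.9,
    depth: int = 100,
    alpha: float = 0.05,
    min_depth: int = 10,
    workdir: str | None = None,
) -> dict:
    """Power/FDR of the full counting+testing path on planted imbalance.

    Generates a single-sample study whose het sites are all null (ratio
    0.5) except ``n_planted`` sites at the planted ratio, emits reads to a
    SAM file, counts alleles back from the alignment, tests and corrects
    genome-wide, and measures empirical power over planted sites and the
    empirical false discovery rate among called sites.
    """
    import tempfile

    from .imbalance import add_imbalance_tests, add_q_values, count_alleles

    rng = stage_rng(seed, "recovery")
    n_sites = int((n_null + n_planted) * 2.4)
    gp = generate_panel(
        n_samples=1,
        n_sites=n_sites,
        af_spectrum=("point", 0.5),
        chrom_length=max(3_000_000, 25 * n_sites),
        seed=rng,
        margin=400,
    )
    panel = gp.panel
    sample = panel.samples[0]
    het = het_sites(panel, sample)
    if len(het) < n_null + n_planted:
        raise ValueError("not enough heterozygous sites; increase n_sites")
    # plant only at isolated sites: a het neighbour within a read length
    # would receive haplotype-correlated reads and cease to be null
    read_len = 101
    pos = het["pos"].to_numpy()
    gaps_ok = np.ones(len(het), dtype=bool)
    gaps_ok[1:] &= np.diff(pos) >= read_len
    gaps_ok[:-1] &= np.diff(pos) >= read_len
    isolated = het.loc[gaps_ok, "site_id"].to_numpy()
    planted = set(rng.choice(isolated, size=n_planted, replace=False))
    with tempfile.TemporaryDirectory(dir=workdir) as tmp:
        sam = str(Path(tmp) / "reads.sam")
        generate_reads(
            panel, sample, "CTCF",
            depth=depth,
            planted_ratios={s: ratio for s in planted},
            seed=rng,
            out_sam=sam,
            lowq_frac=0.0,
            dup_frac=0.0,
        )
        counts = count_alleles(sam, het, min_base_q=20)
    tested = add_imbalance_tests(counts, min_depth=min_depth)
    tested = add_q_values(tested.loc[tested["testable"]].reset_index(drop=True))
    called = set(tested.loc[tested["q_value"] <= alpha, "site_id"])
    tp = len(called & planted)
    fp = len(called - planted)
    return {
        "n_tested": int(len(tested)),
        "n_null": int(len(tested) - n_planted),
        "n_called": len(called),
        "true_positives": tp,
        "false_positives": fp,
        "power": tp / n_planted,
        "fdr": fp / len(called) if called else 0.0,
        "alpha": alpha,
    }
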