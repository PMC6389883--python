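"""TAD loop derivation, capture-interaction calling and target assignment.

A contact-domain pair (the two anchor intervals of a TAD) defines a loop
domain spanning from the end of the first contact domain to the start of
the second.  Genes inside the loop are the loop genes; genes overlapping
an anchor are that anchor's genes; loops with identical gene sets are
unified.  Probe-anchored capture interactions are called against an
empirical, distance-binned background built from control probes placed in
regions without annotation or regulatory potential: a pair is significant
when it has at least ``min_reads`` read pairs and an empirical p-value
below ``alpha`` jointly in at least ``min_reps`` replicates.  Significant
interactions then resolve AS-SNPs to candidate target genes, directly
(SNP fragment touching a promoter probe's interaction) or indirectly via
distal-distal "hops", and target calls are labelled by their concordance
with eQTL-derived genes.
"""
from __future__ import annotations

import logging
from collections import deque

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Loop domains
# ---------------------------------------------------------------------------

def derive_loops(contact_pairs: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Loop intervals from ordered contact-domain pairs.

    ``contact_pairs`` columns: ``chrom``, ``a_start``, ``a_end``,
    ``b_start``, ``b_end`` (half-open).  The loop of an accepted pair is
    exactly ``[a_end, b_start)``.  Degenerate (zero/negative loop) or
    crossing pairs are rejected and logged.
    """
    kept, rejected = [], []
    for i, row in enumerate(contact_pairs.itertuples(index=False)):
        if not (row.a_start < row.a_end and row.b_start < row.b_end):
            rejected.append((i, "empty contact domain"))
            continue
        if row.a_end > row.b_start:
            rejected.append((i, "crossing domains"))
            continue
        if row.a_end == row.b_start:
            rejected.append((i, "zero-length loop"))
            continue
        kept.append(
            (
                row.chrom, row.a_start, row.a_end, row.b_start, row.b_end,
                row.a_end, row.b_start,
            )
        )
    tads = pd.DataFrame(
        kept,
        columns=["chrom", "a_start", "a_end", "b_start", "b_end",
                 "loop_start", "loop_end"],
    )
    tads["tad_id"] = [f"tad{i:04d}" for i in range(len(tads))]
    rej = pd.DataFrame(rejected, columns=["row", "reason"])
    for row in rej.itertuples(index=False):
        logger.info("rejected contact pair %d: %s", row.row, row.reason)
    return tads, rej


def assign_genes(tads: pd.DataFrame, genes: pd.DataFrame) -> pd.DataFrame:
    """Attach loop and anchor genes; unify loops with identical gene sets.

    ``genes`` columns: ``chrom``, ``start``, ``end`` (half-open),
    ``gene_id``.  A gene wholly or partly inside the loop interval is a
    loop gene; a gene overlapping a contact domain is an anchor gene of
    that domain.  Loops sharing an identical loop-gene set collapse to one
    representative, the widest span.  Idempotent.
    """
    gene_tree: dict[str, IntervalTree] = {}
    for g in genes.itertuples(index=False):
        gene_tree.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end, g.gene_id)

    def overlapping(chrom: str, start: int, end: int) -> frozenset[str]:
        tree = gene_tree.get(chrom)
        if tree is None or end <= start:
            return frozenset()
        return frozenset(iv.data for iv in tree.overlap(start, end))

    out = tads.copy()
    out["loop_genes"] = [
        overlapping(r.chrom, r.loop_start, r.loop_end)
        for r in out.itertuples(index=False)
    ]
    out["anchor_genes_a"] = [
        overlapping(r.chrom, r.a_start, r.a_end) for r in out.itertuples(index=False)
    ]
    out["anchor_genes_b"] = [
        overlapping(r.chrom, r.b_start, r.b_end) for r in out.itertuples(index=False)
    ]
    out["span"] = out["b_end"] - out["a_start"]
    unified = (
        out.sort_values(["span"], ascending=False, kind="mergesort")
        .groupby(out["loop_genes"].map(lambda s: (len(s), tuple(sorted(s)))))
        .head(1)
    )
    unified = unified.sort_values(["chrom", "a_start"]).reset_index(drop=True)
    return unified.drop(columns=["span"])


def place_as_snps(as_snps: pd.DataFrame, tads: pd.DataFrame) -> pd.Series:
    """Label each AS-SNP as interaction_domain, loop or outside.

    A position inside a contact domain takes the ``interaction_domain``
    label even if it also falls inside another TAD's loop: the two classes
    are reported disjointly.
    """
    anchor_tree: dict[str, IntervalTree] = {}
    loop_tree: dict[str, IntervalTree] = {}
    for t in tads.itertuples(index=False):
        at = anchor_tree.setdefault(t.chrom, IntervalTree())
        at.addi(t.a_start, t.a_end)
        at.addi(t.b_start, t.b_end)
        loop_tree.setdefault(t.chrom, IntervalTree()).addi(t.loop_start, t.loop_end)
    labels = []
    for r in as_snps.itertuples(index=False):
        p0 = r.pos - 1
        at = anchor_tree.get(r.chrom)
        lt = loop_tree.get(r.chrom)
        if at is not None and at.overlaps_point(p0):
            labels.append("interaction_domain")
        elif lt is not None and lt.overlaps_point(p0):
            labels.append("loop")
        else:
            labels.append("outside")
    return pd.Series(labels, index=as_snps.index, name="tad_placement")


# ---------------------------------------------------------------------------
# Capture-interaction calling
# ---------------------------------------------------------------------------

def _distance_bin(dist: np.ndarray, bins_per_decade: int) -> np.ndarray:
    d = np.maximum(np.asarray(dist, dtype=float), 1.0)
    return np.floor(np.log10(d) * bins_per_decade).astype(int)


def call_interactions(
    read_pairs: pd.DataFrame,
    probes: pd.DataFrame,
    min_reads: int = 3,
    alpha: float = 0.05,
    min_reps: int = 2,
    bins_per_decade: int = 10,
    min_null: int = 50,
) -> pd.DataFrame:
    """Call significant probe-distal interactions with the replicate rule.

    ``read_pairs`` columns: ``probe_id``, ``distal_chrom``,
    ``distal_start``, ``distal_end``, ``read_pairs``, ``replicate``.
    ``probes`` columns: ``probe_id``, ``chrom``, ``pos``, ``kind``
    (promoter/snp/control), ``gene`` (promoter probes).

    Per replicate, a pair's p-value is the empirical upper-tail
    probability of its read-pair count within the control-probe contact
    counts of the matching log-spaced distance bin (add-one estimator).
    Sparse bins are widened: nearest bins are pooled until the null holds
    at least ``min_null`` observations, since an empirical p below alpha
    is unattainable from a handful of controls.  A pair is significant
    when read_pairs >= ``min_reads`` and p < ``alpha`` jointly in at
    least ``min_reps`` replicates.  An empty control set is an error: the
    null is undefined.
    """
    probe_info = probes.set_index("probe_id")
    control_ids = set(probes.loc[probes["kind"] == "control", "probe_id"])
    if not control_ids:
        raise ValueError("no control probes: background null undefined")

    rp = read_pairs.copy()
    rp["probe_pos"] = probe_info.loc[rp["probe_id"], "pos"].to_numpy()
    mid = (rp["distal_start"].to_numpy() + rp["distal_end"].to_numpy()) // 2
    rp["dist"] = np.abs(mid - rp["probe_pos"].to_numpy())
    rp["bin"] = _distance_bin(rp["dist"].to_numpy(), bins_per_decade)
    rp["is_control"] = rp["probe_id"].isin(control_ids)

    replicates = sorted(rp["replicate"].unique())
    # background per (replicate, bin): sorted control counts
    background: dict[tuple[int, int], np.ndarray] = {}
    for (rep, b), grp in rp.loc[rp["is_control"]].groupby(["replicate", "bin"]):
        background[(rep, b)] = np.sort(grp["read_pairs"].to_numpy())
    if not background:
        raise ValueError("control probes have no contacts: null undefined")
    bins_by_rep = {
        rep: sorted(b for (r, b) in background if r == rep) for rep in replicates
    }

    def empirical_p(rep: int, b: int, x: float) -> float:
        bins = bins_by_rep.get(rep, [])
        if not bins:  # replicate without controls: pool everything
            null = np.sort(np.concatenate(list(background.values())))
        else:
            # widen over nearest bins until the null is large enough
            parts = []
            total = 0
            for bb in sorted(bins, key=lambda bb: (abs(bb - b), bb)):
                parts.append(background[(rep, bb)])
                total += len(parts[-1])
                if total >= min_null:
                    break
            null = np.sort(np.concatenate(parts))
        n_ge = len(null) - np.searchsorted(null, x, side="left")
        return float((1 + n_ge) / (1 + len(null)))

    tested = rp.loc[~rp["is_control"]].copy()
    tested["p_value"] = [
        empirical_p(r.replicate, r.bin, r.read_pairs)
        for r in tested.itertuples(index=False)
    ]
    tested["qualifies"] = (tested["read_pairs"] >= min_reads) & (
        tested["p_value"] < alpha
    )

    rows = []
    keys = ["probe_id", "distal_chrom", "distal_start", "distal_end"]
    for key, grp in tested.groupby(keys):
        n_qual = int(grp["qualifies"].sum())
        support = {
            int(r.replicate): (int(r.read_pairs), float(r.p_value))
            for r in grp.itertuples(index=False)
        }
        rows.append(
            dict(
                zip(keys, key),
                n_qualifying=n_qual,
                status="significant" if n_qual >= min_reps else "filtered",
                support=support,
            )
        )
    out = pd.DataFrame(rows)
    if not out.empty:
        out["probe_kind"] = probe_info.loc[out["probe_id"], "kind"].to_numpy()
        out["probe_gene"] = probe_info.loc[out["probe_id"], "gene"].to_numpy()
    return out


# ---------------------------------------------------------------------------
# Target resolution and eQTL concordance
# ---------------------------------------------------------------------------

def resolve_targets(
    as_snps: pd.DataFrame,
    interactions: pd.DataFrame,
    probes: pd.DataFrame,
    frag_size: int = 4000,
    max_hops: int = 2,
) -> pd.DataFrame:
    """Assign candidate target genes to AS-SNPs through the contact graph.

    Fragments are fixed-size genomic windows (``frag_size``).  Significant
    interactions are edges between a probe's fragment and its distal
    fragment; promoter-probe fragments carry the gene label.  An AS-SNP in
    a fragment adjacent to a promoter fragment is a direct target call
    (hops=0); paths through intermediate distal fragments give indirect
    calls with the number of intermediate fragments as the hop count.
    SNP-probe anchored interactions contribute edges symmetrically.
    """

    def frag(chrom: str, pos0: int) -> tuple[str, int]:
        return (chrom, pos0 // frag_size)

    sig = interactions.loc[interactions["status"] == "significant"]
    probe_info = probes.set_index("probe_id")
    edges: dict[tuple[str, int], set[tuple[str, int]]] = {}
    promoter_frags: dict[tuple[str, int], set[str]] = {}
    for p in probes.itertuples(index=False):
        if p.kind == "promoter":
            promoter_frags.setdefault(frag(p.chrom, int(p.pos)), set()).add(p.gene)
    for r in sig.itertuples(index=False):
        pinfo = probe_info.loc[r.probe_id]
        a = frag(pinfo["chrom"], int(pinfo["pos"]))
        mid = (int(r.distal_start) + int(r.distal_end)) // 2
        b = frag(r.distal_chrom, mid)
        edges.setdefault(a, set()).add(b)
        edges.setdefault(b, set()).add(a)

    rows = []
    for snp in as_snps.itertuples(index=False):
        start = frag(snp.chrom, snp.pos - 1)
        # BFS over fragment graph
        seen = {start: 0}
        queue = deque([start])
        while queue:
            node = queue.popleft()
            depth = seen[node]
            if depth >= max_hops + 1:
                continue
            for nxt in edges.get(node, ()):
                if nxt not in seen:
                    seen[nxt] = depth + 1
                    queue.append(nxt)
        for node, depth in seen.items():
            if depth == 0 or node not in promoter_frags:
                continue
            for gene in sorted(promoter_frags[node]):
                rows.append(
                    (
                        snp.site_id,
                        gene,
                        "direct" if depth == 1 else "indirect",
                        depth - 1,
                    )
                )
    out = pd.DataFrame(rows, columns=["site_id", "target_gene", "kind", "hops"])
    if out.empty:
        return out
    # keep the closest (fewest hops) call per (snp, gene)
    out = (
        out.sort_values(["site_id", "target_gene", "hops"])
        .groupby(["site_id", "target_gene"], as_index=False)
        .head(1)
        .reset_index(drop=True)
    )
    return out


def eqtl_concordance(
    targets: pd.DataFrame, associations: pd.DataFrame
) -> pd.DataFrame:
    """Label each AS-SNP with capture targets by eQTL concordance.

    ``confirmed``: some capture target gene equals an eQTL gene of the
    SNP; ``different``: the SNP has eQTL gene(s) but no capture target
    matches; ``no_eqtl``: the SNP has capture targets but no eQTL link.
    """
    eqtl_genes = (
        associations.loc[associations["source"] == "eqtl"]
        .groupby("site_id")["annotation"]
        .agg(set)
        .to_dict()
    )
    rows = []
    for sid, grp in targets.groupby("site_id"):
        tg = set(grp["target_gene"])
        eg = eqtl_genes.get(sid, set())
        if not eg:
            label = "no_eqtl"
        elif tg & eg:
            label = "confirmed"
        else:
            label = "different"
        rows.append((sid, label))
    return pd.DataFrame(rows, columns=["site_id", "concordance"])
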