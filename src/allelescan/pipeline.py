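"""End-to-end orchestration: from raw inputs to the AS-SNP funnel report.

Stages run in dependency order: allele counting at heterozygous sites per
sample and assay, imbalance testing with genome-wide FDR, artifact
pruning, restriction to regulatory elements, population aggregation,
GWAS/eQTL association through LD proxies, rare-variant window scanning,
TAD-loop placement, capture-interaction target assignment with eQTL
concordance, and dependency-aware motif scanning of the two allele
windows.  The funnel report counts survivors at every stage and is
byte-deterministic given the seed.

``funnel_from_manifest`` recomputes the expected funnel directly from a
synthetic dataset's in-memory truth objects and the generator's recorded
read tallies, bypassing all file I/O and alignment parsing; agreement
with the pipeline's funnel verifies the full plumbing (FASTA/VCF/SAM/TSV
round-trips, read counting, allele orientation) end to end.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import associations as assoc
from . import chromatin3d as c3d
from . import imbalance as imb
from . import motifs as mot
from .genomes import Panel, het_sites, load_panel, personal_genomes_for_sample
from .synthetic import SimParams, SyntheticDataset, simulate_all, stage_seed

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """All pipeline thresholds, in documented units.

    Defaults follow the study design: Phred-20 base quality, minimum
    informative depth 10, BH FDR at 0.05, MAF < 0.01 for rare, r^2 > 0.8
    LD proxies within 1 Mb, +/-300 bp windows, >= 3 read pairs with
    p < 0.05 in >= 2 replicates for capture interactions, and motif
    predictions at p <= 1e-3 from k_max = 2 models.
    """

    seed: int = 1
    min_base_q: int = 20
    min_depth: int = 10
    null_ratio: float = 0.5
    alpha: float = 0.05
    correction: str = "fdr_bh"
    maf_rare: float = 0.01
    r2_threshold: float = 0.8
    ld_window: int = 1_000_000
    flank: int = 300
    min_reads: int = 3
    capture_alpha: float = 0.05
    min_reps: int = 2
    bins_per_decade: int = 10
    frag_size: int = 4000
    max_hops: int = 2
    p_motif: float = 1e-3
    k_max: int = 2
    pseudocount: float = 0.5
    n_shuffles_per_window: int = 25
    max_calib_windows: int = 12
    run_associate: bool = True
    run_threed: bool = True
    run_motif: bool = True

    def validate(self) -> None:
        if not (0 < self.alpha < 1 and 0 < self.p_motif < 1):
            raise ValueError("alpha and p_motif must be in (0,1)")
        if not (0 <= self.r2_threshold <= 1):
            raise ValueError("r2_threshold must be in [0,1]")
        if self.min_depth < 1 or self.min_reads < 1 or self.min_reps < 1:
            raise ValueError("depth/read/replicate minima must be >= 1")
        if not (0 < self.null_ratio < 1):
            raise ValueError("null_ratio must be in (0,1)")

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))


# ---------------------------------------------------------------------------
# Inputs
# ---------------------------------------------------------------------------

@dataclass
class PipelineInputs:
    """Everything the funnel computation consumes, already in memory."""

    panel: Panel
    #: sample -> assay -> allele-count table (count_alleles schema)
    counts: dict[str, dict[str, pd.DataFrame]]
    elements: pd.DataFrame
    blacklist: pd.DataFrame
    cnv: pd.DataFrame
    repeats: pd.DataFrame
    gwas: pd.DataFrame
    eqtl: pd.DataFrame
    contacts: pd.DataFrame
    genes: pd.DataFrame
    probes: pd.DataFrame
    read_pairs: pd.DataFrame
    motif_training: dict[str, list[str]]


def load_inputs(data_dir: str, cfg: RunConfig) -> PipelineInputs:
    """Load a run directory produced by the generator (or equivalents)."""
    d = Path(data_dir)
    panel = load_panel(d / "reference.fa", d / "panel.vcf")
    counts: dict[str, dict[str, pd.DataFrame]] = {}
    for sam in sorted((d / "reads").glob("*.sam")):
        sample, assay = sam.stem.split(".", 1)
        het = het_sites(panel, sample)
        counts.setdefault(sample, {})[assay] = imb.count_alleles(
            str(sam), het, min_base_q=cfg.min_base_q
        )
    bed3 = ["chrom", "start", "end"]
    return PipelineInputs(
        panel=panel,
        counts=counts,
        elements=pd.read_csv(
            d / "elements.bed", sep="\t",
            names=["chrom", "start", "end", "element_id", "category"],
        ),
        blacklist=pd.read_csv(d / "blacklist.bed", sep="\t", names=bed3),
        cnv=pd.read_csv(d / "cnv.bed", sep="\t", names=bed3),
        repeats=pd.read_csv(d / "repeats.bed", sep="\t", names=bed3),
        gwas=pd.read_csv(d / "gwas.tsv", sep="\t"),
        eqtl=pd.read_csv(d / "eqtl.tsv", sep="\t"),
        contacts=pd.read_csv(d / "contacts.tsv", sep="\t"),
        genes=pd.read_csv(
            d / "genes.bed", sep="\t", names=["chrom", "start", "end", "gene_id"]
        ),
        probes=pd.read_csv(d / "probes.tsv", sep="\t", keep_default_na=False),
        read_pairs=pd.read_csv(d / "read_pairs.tsv", sep="\t"),
        motif_training={
            fa.stem: mot.read_sites_fasta(str(fa))
            for fa in sorted((d / "motifs").glob("*.fa"))
        },
    )


def inputs_from_dataset(ds: SyntheticDataset) -> PipelineInputs:
    """Truth-side inputs: generator objects + recorded read tallies."""
    site_tab = ds.panel.site_table().rename(columns={"id": "site_id"})
    af_of = site_tab.set_index("site_id")[["af", "maf"]]
    counts: dict[str, dict[str, pd.DataFrame]] = {}
    for (sample, assay), grp in ds.true_counts.groupby(["sample", "assay"]):
        t = grp.copy().reset_index(drop=True)
        t["g1"] = t["ref"]
        t["g2"] = t["alt"]
        t = t.rename(columns={"n_ref": "n_g1", "n_alt": "n_g2"})
        t["n_other"] = 0
        t = t.join(af_of, on="site_id")
        counts.setdefault(sample, {})[assay] = t[
            ["chrom", "pos", "site_id", "ref", "alt", "g1", "g2", "af", "maf",
             "n_g1", "n_g2", "n_other", "n_lowq"]
        ]
    return PipelineInputs(
        panel=ds.panel,
        counts=counts,
        elements=ds.landscape.elements,
        blacklist=ds.landscape.blacklist,
        cnv=ds.landscape.cnv,
        repeats=ds.landscape.repeats,
        gwas=ds.catalogs.gwas,
        eqtl=ds.catalogs.eqtl,
        contacts=ds.threed.contacts,
        genes=ds.threed.genes,
        probes=ds.threed.probes,
        read_pairs=ds.threed.read_pairs,
        motif_training=ds.motif_training,
    )


# ---------------------------------------------------------------------------
# Core funnel computation (shared by pipeline and manifest predictor)
# ---------------------------------------------------------------------------

def compute_funnel(
    inputs: PipelineInputs, cfg: RunConfig
) -> tuple[dict, dict[str, pd.DataFrame]]:
    """Run every stage on in-memory inputs; return (funnel, tables)."""
    cfg.validate()
    tables: dict[str, pd.DataFrame] = {}

    # --- per-sample and aggregate AS calling ------------------------------
    single_frames = []
    for sample, by_assay in inputs.counts.items():
        calls = imb.call_sample(
            by_assay, sample,
            min_depth=cfg.min_depth, null_ratio=cfg.null_ratio,
            alpha=cfg.alpha, method=cfg.correction,
        )
        single_frames.append(calls)
    single = (
        pd.concat(single_frames, ignore_index=True)
        if single_frames else pd.DataFrame()
    )
    agg = imb.call_aggregate(
        inputs.counts, single,
        min_depth=cfg.min_depth, null_ratio=cfg.null_ratio,
        alpha=cfg.alpha, method=cfg.correction,
    )
    tables["single_sample_calls"] = single
    tables["aggregate_calls"] = agg

    # --- unique candidate set --------------------------------------------
    allcalls = pd.concat([single, agg], ignore_index=True)
    cand_rows = []
    if not allcalls.empty:
        for key, grp in allcalls.groupby(["chrom", "pos", "ref", "alt"], sort=True):
            sig_assays = sorted(
                {a for s in grp["sig_assays"] for a in s.split(",") if a}
            )
            in_agg = grp["sample"].eq(imb.AGGREGATE_LABEL)
            samples = sorted(grp.loc[~in_agg, "sample"])
            case = (
                grp.loc[in_agg, "population_case"].iloc[0] if in_agg.any() else "n/a"
            )
            first = grp.iloc[0]
            cand_rows.append(
                {
                    "chrom": key[0], "pos": key[1], "ref": key[2], "alt": key[3],
                    "site_id": first["site_id"],
                    "af": first["af"], "maf": first["maf"],
                    "p_value": grp["p_value"].min(),
                    "q_value": grp["q_value"].min(),
                    "samples": ",".join(samples),
                    "n_samples_sig": len(samples),
                    "in_aggregate": bool(in_agg.any()),
                    "population_case": case,
                    "sig_assays": ",".join(sig_assays),
                    "defining_assay": imb.attribute_marks(sig_assays),
                }
            )
    candidates = pd.DataFrame(cand_rows)

    # --- funnel head counts ----------------------------------------------
    all_counts = pd.concat(
        [t for d in inputs.counts.values() for t in d.values()], ignore_index=True
    )
    n_het_union = all_counts["site_id"].nunique()
    depth = all_counts["n_g1"] + all_counts["n_g2"]
    n_testable = all_counts.loc[depth >= cfg.min_depth, "site_id"].nunique()

    # --- prune and restrict ----------------------------------------------
    if candidates.empty:
        pruned = candidates
        prune_log = pd.DataFrame(columns=["site_id", "chrom", "pos", "reason"])
        as_snps = candidates
    else:
        pruned, prune_log = imb.prune_artifacts(
            candidates, inputs.blacklist, inputs.cnv, inputs.repeats
        )
        as_snps = imb.restrict_to_elements(pruned, inputs.elements)
        as_snps["freq_class"] = [
            imb.classify_frequency(m, cfg.maf_rare) for m in as_snps["maf"]
        ]
    tables["prune_log"] = prune_log
    tables["as_snps"] = as_snps

    funnel = {
        "n_samples": len(inputs.counts),
        "n_assays": len({a for d in inputs.counts.values() for a in d}),
        "n_het_union": int(n_het_union),
        "n_testable": int(n_testable),
        "n_significant_unique": int(len(candidates)),
        "n_post_prune": int(len(pruned)),
        "n_as_snps": int(len(as_snps)),
        "n_common": int((as_snps["freq_class"] == "common").sum()) if len(as_snps) else 0,
        "n_rare": int((as_snps["freq_class"] == "rare").sum()) if len(as_snps) else 0,
        "n_aggregate": int(len(agg)),
        "n_case1": int((agg["population_case"] == "case1").sum()) if len(agg) else 0,
        "n_case2": int((agg["population_case"] == "case2").sum()) if len(agg) else 0,
    }

    # --- associations -----------------------------------------------------
    records = pd.DataFrame(
        columns=["site_id", "source", "index_snp", "link", "r2", "annotation"]
    )
    if cfg.run_associate and len(as_snps):
        index_union = list(
            dict.fromkeys(list(inputs.gwas["snp_id"]) + list(inputs.eqtl["snp_id"]))
        )
        ld_pairs = assoc.expand_proxies(
            inputs.panel, index_union,
            r2_threshold=cfg.r2_threshold, window=cfg.ld_window,
        )
        records, summary = assoc.annotate_associations(
            as_snps, inputs.gwas, inputs.eqtl, ld_pairs
        )
        tables["ld_pairs"] = ld_pairs
        tables["associations"] = records
        funnel["n_gwas_linked"] = summary["gwas"]
        funnel["n_eqtl_linked"] = summary["eqtl"]
        funnel["n_both"] = summary["both"]

        assoc_sources = records.groupby("site_id")["source"].agg(set).to_dict()
        common = as_snps.loc[as_snps["freq_class"] == "common"]
        assoc_common = []
        for row in common.itertuples(index=False):
            for src in sorted(assoc_sources.get(row.site_id, ())):
                assoc_common.append(
                    {"site_id": row.site_id, "chrom": row.chrom,
                     "pos": row.pos, "source": src}
                )
        assoc_common = pd.DataFrame(
            assoc_common, columns=["site_id", "chrom", "pos", "source"]
        )
        rare = as_snps.loc[as_snps["freq_class"] == "rare"]
        near = assoc.rare_window_scan(rare, assoc_common, flank=cfg.flank)
        tables["rare_near_associated"] = near
        funnel["n_rare_near_gwas"] = int(
            near.loc[near["source"] == "gwas", "rare_snp"].nunique()
        ) if len(near) else 0
        funnel["n_rare_near_eqtl"] = int(
            near.loc[near["source"] == "eqtl", "rare_snp"].nunique()
        ) if len(near) else 0

    # --- 3D ---------------------------------------------------------------
    if cfg.run_threed and len(as_snps):
        tads, _rej = c3d.derive_loops(inputs.contacts)
        tads = c3d.assign_genes(tads, inputs.genes)
        placement = c3d.place_as_snps(as_snps, tads)
        tables["tads"] = tads
        as_snps = as_snps.assign(tad_placement=placement)
        tables["as_snps"] = as_snps
        funnel["n_loop"] = int((placement == "loop").sum())
        funnel["n_interaction_domain"] = int(
            (placement == "interaction_domain").sum()
        )
        funnel["n_outside"] = int((placement == "outside").sum())

        interactions = c3d.call_interactions(
            inputs.read_pairs, inputs.probes,
            min_reads=cfg.min_reads, alpha=cfg.capture_alpha,
            min_reps=cfg.min_reps, bins_per_decade=cfg.bins_per_decade,
        )
        targets = c3d.resolve_targets(
            as_snps, interactions, inputs.probes,
            frag_size=cfg.frag_size, max_hops=cfg.max_hops,
        )
        conc = c3d.eqtl_concordance(targets, records)
        tables["interactions"] = interactions
        tables["targets"] = targets
        tables["concordance"] = conc
        funnel["n_capture_targeted"] = int(targets["site_id"].nunique()) if len(targets) else 0
        for label in ("confirmed", "different", "no_eqtl"):
            funnel[f"n_{label}"] = int(
                (conc["concordance"] == label).sum()
            ) if len(conc) else 0

    # --- motifs -----------------------------------------------------------
    if cfg.run_motif and len(as_snps) and inputs.motif_training:
        ordered = as_snps.sort_values(["chrom", "pos"]).reset_index(drop=True)
        windows = {}
        for row in ordered.itertuples(index=False):
            windows[row.site_id] = mot.extract_allele_windows(
                row, inputs.panel.reference, flank=cfg.flank
            )
        # order-1 background from the scanned window set, not the motif
        # training sites (those would absorb the motif composition)
        background = mot.BackgroundModel.train(
            [w[0] for w in windows.values()]
        )
        models = {}
        for tf, sites in sorted(inputs.motif_training.items()):
            models[tf] = mot.MotifModel.train(
                sites, tf=tf, k_max=cfg.k_max, pseudocount=cfg.pseudocount,
                background=background,
            )
        calib_windows = [
            windows[sid][0]
            for sid in ordered["site_id"][: cfg.max_calib_windows]
        ]
        pred_rows = []
        for tf, m in models.items():
            m.calibrate(
                calib_windows,
                n_shuffles_per_window=cfg.n_shuffles_per_window,
                seed=np.random.default_rng(stage_seed(cfg.seed, f"calib:{tf}")),
            )
            for row in ordered.itertuples(index=False):
                ref_w, alt_w, center, _trunc = windows[row.site_id]
                for hit in mot.scan_windows(
                    m, ref_w, alt_w, center, p_threshold=cfg.p_motif
                ):
                    start0 = (row.pos - 1) - center + hit["offset"]
                    effect = (
                        mot.classify_effect(hit["score_ref"], hit["score_alt"])
                        if hit["overlaps_snp"] else None
                    )
                    pred_rows.append(
                        {
                            "site_id": row.site_id, "chrom": row.chrom,
                            "start": start0, "end": start0 + m.length,
                            **hit, "effect": effect,
                        }
                    )
        predictions = pd.DataFrame(pred_rows)
        tables["motif_predictions"] = predictions
        if len(predictions):
            altered = predictions.loc[predictions["overlaps_snp"]]
            funnel["n_motif_altered"] = int(altered["site_id"].nunique())
            funnel["n_pred_gain"] = int((altered["effect"] == "gain").sum())
            funnel["n_pred_loss"] = int((altered["effect"] == "loss").sum())
            snp_pos = {
                c: (g["pos"] - 1).tolist()
                for c, g in as_snps.groupby("chrom")
            }
            tables["tf_summaries"] = mot.tf_summaries(predictions, snp_pos)
        else:
            funnel["n_motif_altered"] = 0
            funnel["n_pred_gain"] = 0
            funnel["n_pred_loss"] = 0
            tables["tf_summaries"] = pd.DataFrame()

    return funnel, tables


def funnel_from_manifest(ds: SyntheticDataset, cfg: RunConfig) -> dict:
    """Expected funnel computed from the generator's recorded ground truth."""
    funnel, _tables = compute_funnel(inputs_from_dataset(ds), cfg)
    return funnel


# ---------------------------------------------------------------------------
# Run directory orchestration
# ---------------------------------------------------------------------------

def run_pipeline(
    cfg: RunConfig,
    outdir: str,
    data_dir: str | None = None,
    sim_params: SimParams | None = None,
) -> tuple[dict, dict[str, pd.DataFrame]]:
    """Execute the full pipeline into ``outdir``.

    Without ``data_dir`` a synthetic dataset is generated first (under
    ``outdir/data``) and then re-read from disk, so the run exercises the
    same file formats a real study would provide.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    cfg.validate()
    cfg.to_yaml(out / "config.yaml")
    if data_dir is None:
        data_dir = out / "data"
        simulate_all(cfg.seed, sim_params, str(data_dir))
    inputs = load_inputs(str(data_dir), cfg)
    funnel, tables = compute_funnel(inputs, cfg)
    write_report(funnel, out / "funnel.json")
    for name, df in tables.items():
        if isinstance(df, pd.DataFrame):
            df.to_csv(out / f"{name}.tsv", sep="\t", index=False)
    if len(tables.get("as_snps", ())):
        export(tables["as_snps"], out, formats=("vcf", "bed"))
    return funnel, tables


def write_report(funnel: dict, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(funnel, fh, indent=2)
        fh.write("\n")


def export(as_snps: pd.DataFrame, outdir: str, formats=("vcf", "bed", "tsv")) -> dict:
    """Export the AS-SNP catalog as annotated VCF / BED / TSV."""
    out = Path(outdir)
    paths = {}
    ordered = as_snps.sort_values(["chrom", "pos"])
    for fmt in formats:
        if fmt == "vcf":
            p = out / "as_snps.vcf"
            with open(p, "w") as fh:
                fh.write("##fileformat=VCFv4.2\n")
                fh.write(
                    '##INFO=<ID=DA,Number=1,Type=String,'
                    'Description="Defining assay">\n'
                )
                fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
                for r in ordered.itertuples(index=False):
                    fh.write(
                        f"{r.chrom}\t{r.pos}\t{r.site_id}\t{r.ref}\t{r.alt}"
                        f"\t.\tPASS\tDA={r.defining_assay}\n"
                    )
        elif fmt == "bed":
            p = out / "as_snps_export.bed"
            with open(p, "w") as fh:
                for r in ordered.itertuples(index=False):
                    fh.write(
                        f"{r.chrom}\t{r.pos - 1}\t{r.pos}\t{r.site_id}\t0\t.\n"
                    )
        elif fmt == "tsv":
            p = out / "as_snps_export.tsv"
            ordered.to_csv(p, sep="\t", index=False)
        else:
            raise ValueError(f"unknown export format {fmt!r}")
        paths[fmt] = str(p)
    return paths


def import_export_bed(path: str) -> pd.DataFrame:
    """Round-trip loader for the BED export (1 bp half-open intervals)."""
    df = pd.read_csv(
        path, sep="\t",
        names=["chrom", "start", "end", "site_id", "score", "strand"],
    )
    df["pos"] = df["start"] + 1
    return df[["chrom", "pos", "site_id"]]


def personalize(data_dir: str, outdir: str, samples: list[str] | None = None) -> list[str]:
    """Write per-sample G1/G2 genome FASTAs plus substitution tables."""
    d = Path(data_dir)
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    panel = load_panel(d / "reference.fa", d / "panel.vcf")
    written = []
    for sample in samples or panel.samples:
        pair = personal_genomes_for_sample(panel, sample)
        g1 = out / f"{sample}.g1.fa"
        g2 = out / f"{sample}.g2.fa"
        pair.write_fastas(str(g1), str(g2))
        pair.substitution_table.to_csv(
            out / f"{sample}.substitutions.tsv", sep="\t", index=False
        )
        written += [str(g1), str(g2)]
    return written
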