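"""Synthetic-data generator: planted truth, determinism, design math."""
import math

import numpy as np
import pandas as pd
import pytest

from allelescan.genomes import het_sites
from allelescan.imbalance import count_alleles, orient_counts
from allelescan.synthetic import (
    SimParams,
    add_first_order_dependency,
    draw_afs,
    generate_landscape,
    generate_motif_sites,
    generate_panel,
    generate_reads,
    generate_tads_genes,
    prob_het_any,
    pwm_motif_spec,
    sample_motif_sites,
    simulate_all,
)


def test_panel_counts_and_vcf_records(tmp_path):
    from allelescan.genomes import write_panel_vcf

    gp = generate_panel(n_samples=7, n_sites=500, af_spectrum=("uniform", 0.05, 0.95),
                        chrom_length=100_000, seed=1, margin=200)
    assert gp.panel.n_sites == 500 and gp.panel.n_samples == 7
    write_panel_vcf(gp.panel, tmp_path / "p.vcf")
    records = [l for l in (tmp_path / "p.vcf").read_text().splitlines()
               if l and not l.startswith("#")]
    assert len(records) == 500
    # biallelic SNVs, alt differs from ref
    assert all(r.split("\t")[3] != r.split("\t")[4] for r in records)


def test_point_mass_half_gives_half_het():
    gp = generate_panel(n_samples=7, n_sites=1000, af_spectrum=("point", 0.5),
                        chrom_length=200_000, seed=2, margin=200)
    h = gp.panel.haplotypes
    frac = (h[:, :, 0] != h[:, :, 1]).mean()
    # binomial CI on 7000 draws at p=0.5
    assert abs(frac - 0.5) < 3 * math.sqrt(0.25 / 7000)


def test_het_in_any_of_seven_closed_form():
    # 1 - (1 - 2*0.35*0.65)^7
    expected = 1 - (1 - 2 * 0.35 * 0.65) ** 7
    assert prob_het_any(0.35, 7) == pytest.approx(expected, abs=1e-12)
    assert expected == pytest.approx(0.986, abs=5e-4)
    gp = generate_panel(n_samples=7, n_sites=2000, af_spectrum=("point", 0.35),
                        chrom_length=200_000, seed=3, margin=200)
    h = gp.panel.haplotypes
    frac = (h[:, :, 0] != h[:, :, 1]).any(axis=1).mean()
    assert abs(frac - expected) < 3 * math.sqrt(expected * (1 - expected) / 2000)


def test_sizing_error():
    with pytest.raises(ValueError, match="too small"):
        generate_panel(n_sites=500, chrom_length=3_000, margin=200, seed=0)


def test_rare_twins_have_rare_population_af_and_single_het_carrier():
    gp = generate_panel(n_samples=7, n_sites=400, chrom_length=300_000,
                        seed=4, n_rare_twins=3)
    tab = gp.panel.site_table().set_index("id")
    for common, rare in gp.twin_pairs:
        assert tab.loc[rare, "maf"] < 0.01
        i = gp.panel.sites.index[gp.panel.sites["id"] == rare][0]
        h = gp.panel.haplotypes[i]
        assert (h[:, 0] != h[:, 1]).sum() == 1
        assert abs(tab.loc[rare, "pos"] - tab.loc[common, "pos"]) <= 250


def test_landscape_elements_nonoverlapping_and_categorized():
    gp = generate_panel(n_samples=4, n_sites=200,
                        af_spectrum=("uniform", 0.2, 0.8),
                        chrom_length=100_000, seed=7, margin=200)
    panel = gp.panel
    land = generate_landscape(panel, n_elements=50, seed=0,
                              n_blacklist_planted=2)
    el = land.elements.sort_values("start")
    assert len(el) == 50
    starts = el["start"].to_numpy()
    ends = el["end"].to_numpy()
    assert (ends > starts).all()
    assert (starts[1:] >= ends[:-1]).all()  # zero overlapping pairs
    # blacklist-planted sites are het and covered by blacklist intervals
    tab = panel.site_table().set_index("id")
    for sid in land.blacklist_site_ids:
        p = tab.loc[sid, "pos"] - 1
        assert ((land.blacklist["start"] <= p) & (p < land.blacklist["end"])).any()


def test_unknown_category_rejected(small_panel):
    with pytest.raises(ValueError):
        generate_landscape(small_panel, categories=("enhancer", "exon"), seed=0)


def test_reads_depth_zero_and_planted_ratio(small_panel, tmp_path):
    rr = generate_reads(small_panel, small_panel.samples[0], "CTCF", depth=0, seed=0)
    assert rr.n_reads == 0 and (rr.true_counts[["n_ref", "n_alt"]].sum().sum() == 0)

    # binomial draw at ratio 0.5 / depth 40 on an isolated site
    sample = small_panel.samples[0]
    het = het_sites(small_panel, sample)
    rr = generate_reads(small_panel, sample, "CTCF", depth=40, seed=1,
                        lowq_frac=0.0, dup_frac=0.0, read_len=31)
    tc = rr.true_counts
    # sites with no neighbour within a read length get exactly depth reads
    pos = np.sort(small_panel.sites["pos"].to_numpy())
    for row in tc.itertuples(index=False):
        d = np.abs(pos - row.pos)
        if (d[d > 0] >= 31).all():
            assert row.n_ref + row.n_alt == 40


def test_reads_warn_on_non_het_planted_site(small_panel, caplog):
    sample = small_panel.samples[0]
    het_ids = set(het_sites(small_panel, sample)["site_id"])
    non_het = next(s for s in small_panel.sites["id"] if s not in het_ids)
    with caplog.at_level("WARNING"):
        generate_reads(small_panel, sample, "CTCF", depth=5,
                       planted_ratios={non_het: 0.9}, seed=0)
    assert any(non_het in r.message for r in caplog.records)


def test_counts_from_sam_match_generator_tally(small_panel, tmp_path):
    """Pileup counting of the emitted SAM reconciles exactly with the
    generator's own tally -- reads are the ground truth."""
    sample = small_panel.samples[1]
    het = het_sites(small_panel, sample)
    sam = tmp_path / "r.sam"
    rr = generate_reads(small_panel, sample, "H3K27ac", depth=30,
                        planted_ratios={het["site_id"].iloc[0]: 0.9},
                        seed=5, out_sam=str(sam))
    counted = orient_counts(count_alleles(str(sam), het, min_base_q=20))
    merged = counted.merge(rr.true_counts, on="site_id", suffixes=("_c", "_t"))
    assert (merged["n_ref_c"] == merged["n_ref_t"]).all()
    assert (merged["n_alt_c"] == merged["n_alt_t"]).all()
    assert (merged["n_lowq_c"] == merged["n_lowq_t"]).all()
    assert (counted["n_other"] == 0).all()


def test_same_seed_byte_identical_outputs(tmp_path):
    params = SimParams(n_samples=3, n_sites=200, chrom_length=150_000,
                       depth=12, n_planted_as=6, n_weak_planted=0,
                       n_rare_twins=1, n_elements=25, n_index_gwas=2,
                       n_index_eqtl=2, proxies_per_index=1, n_tads=2,
                       n_control_probes=10, motif_training_sites=50)
    a, b = tmp_path / "a", tmp_path / "b"
    simulate_all(seed=42, params=params, outdir=str(a))
    simulate_all(seed=42, params=params, outdir=str(b))
    files_a = sorted(p.relative_to(a) for p in a.rglob("*") if p.is_file())
    files_b = sorted(p.relative_to(b) for p in b.rglob("*") if p.is_file())
    assert files_a == files_b
    for rel in files_a:
        assert (a / rel).read_bytes() == (b / rel).read_bytes(), rel


def test_manifest_ids_resolve(dataset):
    ids = set(dataset.panel.sites["id"])
    m = dataset.manifest
    for rec in m["planted_as_sites"]:
        assert rec["site_id"] in ids
    for grp in m["planted_ld_groups"]:
        assert grp["index"] in ids
        assert set(grp["proxies"]) <= ids
    probe_ids = set(dataset.threed.probes["probe_id"])
    for rec in m["planted_interactions"]:
        assert rec["probe_id"] in probe_ids
    for rec in m["planted_motifs"]:
        assert rec["site_id"] in ids


def test_tads_structure(small_panel):
    td = generate_tads_genes(small_panel, n_tads=4, genes_per_loop=2)
    assert len(td.contacts) == 4
    # 2 genes per loop -> 8 loop genes (+1 anchor gene)
    assert len(td.genes) == 9
    c = td.contacts
    assert (c["a_end"] <= c["b_start"]).all()


def test_planted_interaction_support_rule(dataset):
    """Planted pairs carry >=3 read pairs in >=2 replicates; a (2,2,2)
    support profile fails the rule in every replicate."""
    rp = dataset.threed.read_pairs
    for rec in dataset.manifest["planted_interactions"]:
        sub = rp[(rp["probe_id"] == rec["probe_id"])
                 & (rp["distal_start"] == rec["frag_start"])]
        assert (sub["read_pairs"] >= 3).sum() >= 2
    assert sum(c >= 3 for c in (2, 2, 2)) < 2


def test_motif_spec_sampling():
    # deterministic spec: all mass on one base per position
    spec = [{"probs": [1.0, 0.0, 0.0, 0.0]}, {"probs": [0.0, 0.0, 1.0, 0.0]}]
    sites = sample_motif_sites(spec, 20, seed=0)
    assert set(sites) == {"AG"}
    assert generate_motif_sites(spec, 0, seed=0) == []


def test_planted_dependency_lowers_conditional_entropy():
    spec = add_first_order_dependency(pwm_motif_spec(8, seed=1), pos=4)
    sites = sample_motif_sites(spec, 1500, seed=2)
    col = np.array([["ACGT".index(s[4]) for s in sites]])
    prev = np.array([["ACGT".index(s[3]) for s in sites]])

    def entropy(counts):
        p = counts / counts.sum()
        p = p[p > 0]
        return -(p * np.log2(p)).sum()

    marg = np.bincount(col.ravel(), minlength=4)
    h_marginal = entropy(marg)
    h_cond = 0.0
    for b in range(4):
        sel = col.ravel()[prev.ravel() == b]
        if len(sel):
            h_cond += len(sel) / col.size * entropy(np.bincount(sel, minlength=4))
    assert h_cond < h_marginal - 0.2


def test_af_spectrum_shapes():
    rng = np.random.default_rng(0)
    u = draw_afs(("uniform", 0.2, 0.4), 1000, rng)
    assert u.min() >= 0.2 and u.max() <= 0.4
    m = draw_afs(("mixture", 0.3), 5000, rng)
    assert 0.2 < (m < 0.01).mean() < 0.4
    with pytest.raises(ValueError):
        draw_afs(("beta", 1), 10, rng)
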