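"""Allelic-imbalance testing, correction, filtering and aggregation."""
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from allelescan.imbalance import (
    add_imbalance_tests,
    aggregate_population,
    attribute_marks,
    call_aggregate,
    call_sample,
    classify_frequency,
    correct_genome_wide,
    count_alleles,
    prune_artifacts,
    restrict_to_elements,
    test_imbalance as exact_binom_p,
)


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def binom_two_sided_oracle(k: int, n: int) -> float:
    """Exact two-sided binomial p at ratio 0.5 by integer tail enumeration.

    Sums P(j) over all j whose probability does not exceed P(k); with a
    fair-coin null every P(j) is C(n,j)/2^n, so the comparison is exact
    integer arithmetic.
    """
    ck = math.comb(n, k)
    total = sum(math.comb(n, j) for j in range(n + 1) if math.comb(n, j) <= ck)
    return total / 2**n


def bh_oracle(p: np.ndarray) -> np.ndarray:
    """Textbook step-up BH adjusted p-values."""
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


# ---------------------------------------------------------------------------
# exact binomial test
# ---------------------------------------------------------------------------

def test_binomial_matches_oracle_exhaustively():
    for n in range(1, 26):
        for k in range(n + 1):
            assert exact_binom_p(k, n - k) == pytest.approx(
                binom_two_sided_oracle(k, n), abs=1e-12
            )


def test_binomial_examples():
    assert exact_binom_p(10, 10) == pytest.approx(1.0)
    assert exact_binom_p(20, 0) == pytest.approx(2 * 0.5**20, rel=1e-9)
    # exact tail sum 2 * sum_{k=15..20} C(20,k) / 2^20
    expected = 2 * sum(math.comb(20, k) for k in range(15, 21)) / 2**20
    assert exact_binom_p(15, 5) == pytest.approx(expected, abs=1e-12)
    assert expected == pytest.approx(0.0414, abs=5e-5)


def test_zero_depth_raises_but_min_depth_marks_untestable():
    with pytest.raises(ValueError):
        exact_binom_p(0, 0)
    counts = pd.DataFrame({"n_g1": [3, 30], "n_g2": [2, 10]})
    t = add_imbalance_tests(counts, min_depth=10)
    assert not t["testable"].iloc[0] and np.isnan(t["p_value"].iloc[0])
    assert t["testable"].iloc[1] and t["p_value"].iloc[1] > 0


@given(st.integers(0, 60), st.integers(0, 60), st.floats(0.1, 0.9))
@settings(max_examples=200, deadline=None, derandomize=True)
def test_two_sided_symmetry_under_allele_swap(a, b, r):
    if a + b == 0:
        return
    # swapping alleles mirrors the null ratio
    assert exact_binom_p(a, b, r) == pytest.approx(
        exact_binom_p(b, a, 1 - r), rel=1e-9
    )


# ---------------------------------------------------------------------------
# genome-wide correction
# ---------------------------------------------------------------------------

def test_bh_examples():
    assert correct_genome_wide([0.01]) == pytest.approx([0.01])
    np.testing.assert_allclose(
        correct_genome_wide([0.01, 0.02, 0.03, 0.04]), [0.04] * 4
    )
    np.testing.assert_allclose(correct_genome_wide([1.0, 1.0, 1.0]), 1.0)
    assert correct_genome_wide([]).size == 0


def test_bh_matches_textbook_step_up_on_random_vectors():
    rng = np.random.default_rng(12)
    for _ in range(1000):
        p = rng.random(rng.integers(1, 40))
        np.testing.assert_allclose(
            correct_genome_wide(p), bh_oracle(p), atol=1e-12
        )


def test_bh_significant_set_matches_step_up_rule():
    rng = np.random.default_rng(5)
    for _ in range(50):
        p = rng.random(60) ** 3
        q = correct_genome_wide(p)
        alpha = 0.05
        # direct step-up: largest k with p_(k) <= k/m * alpha
        order = np.sort(p)
        ks = np.nonzero(order <= (np.arange(1, 61) / 60) * alpha)[0]
        cutoff = order[ks.max()] if len(ks) else -1.0
        np.testing.assert_array_equal(q <= alpha, p <= cutoff)


def test_bonferroni_option():
    np.testing.assert_allclose(
        correct_genome_wide([0.01, 0.3], method="bonferroni"), [0.02, 0.6]
    )


# ---------------------------------------------------------------------------
# counting from alignments
# ---------------------------------------------------------------------------

def _write_sam(path, reads, chrom="chr1", ln=1000):
    lines = ["@HD\tVN:1.6\tSO:unsorted", f"@SQ\tSN:{chrom}\tLN:{ln}"]
    for i, (pos1, seq, qual, flag) in enumerate(reads):
        lines.append(
            f"r{i}\t{flag}\t{chrom}\t{pos1}\t60\t{len(seq)}M\t*\t0\t0\t{seq}\t{qual}"
        )
    path.write_text("\n".join(lines) + "\n")


def _het_row(pos1, ref="A", alt="G"):
    return pd.DataFrame(
        [{"chrom": "chr1", "pos": pos1, "site_id": "s0", "ref": ref,
          "alt": alt, "g1": ref, "g2": alt, "af": 0.5, "maf": 0.5}]
    )


def test_count_alleles_quality_threshold_and_duplicates(tmp_path):
    het = _het_row(11)
    q20 = chr(33 + 20)
    q19 = chr(33 + 19)
    reads = [
        (9, "AAA", q20 * 3, 0),     # covers pos0 10 with base A (g1), q20
        (10, "GGG", q20 * 3, 0),    # base G (g2)
        (11, "AAA", q19 * 3, 0),    # quality 19 at the site -> lowq
        (9, "CCC", q20 * 3, 0),     # base C -> other
        (10, "GGG", q20 * 3, 1024), # duplicate -> skipped entirely
    ]
    sam = tmp_path / "t.sam"
    _write_sam(sam, reads)
    c = count_alleles(str(sam), het, min_base_q=20).iloc[0]
    assert (c["n_g1"], c["n_g2"], c["n_other"], c["n_lowq"]) == (1, 1, 1, 1)


def test_count_alleles_chrom_mismatch(tmp_path):
    sam = tmp_path / "t.sam"
    _write_sam(sam, [(1, "AAA", "III", 0)], chrom="chrX")
    with pytest.raises(ValueError, match="chr1"):
        count_alleles(str(sam), _het_row(11))


def test_planted_ratio_recovered_within_3se(small_panel, tmp_path):
    from allelescan.genomes import het_sites
    from allelescan.synthetic import generate_reads

    sample = small_panel.samples[0]
    het = het_sites(small_panel, sample)
    target = het["site_id"].iloc[2]
    sam = tmp_path / "r.sam"
    generate_reads(small_panel, sample, "CTCF", depth=200,
                   planted_ratios={target: 0.9}, seed=3, out_sam=str(sam),
                   lowq_frac=0.0, dup_frac=0.0)
    c = count_alleles(str(sam), het)
    row = c.loc[c["site_id"] == target].iloc[0]
    frac = row["n_g1"] / (row["n_g1"] + row["n_g2"])
    assert abs(frac - 0.9) <= 3 * math.sqrt(0.9 * 0.1 / 200) + 0.02


# ---------------------------------------------------------------------------
# pruning / element restriction
# ---------------------------------------------------------------------------

def _cand(pos_list):
    return pd.DataFrame(
        {"chrom": "chr1", "pos": pos_list,
         "site_id": [f"s{p}" for p in pos_list]}
    )


def test_prune_half_open_boundaries():
    bl = pd.DataFrame([{"chrom": "chr1", "start": 100, "end": 200}])
    empty = bl.iloc[:0]
    # 1-based pos 151 = 0-based 150 inside; pos 201 = 0-based 200 excluded
    kept, log = prune_artifacts(_cand([151, 201, 101]), bl, empty, empty)
    assert list(kept["pos"]) == [201]
    assert set(log["reason"]) == {"blacklist"}
    assert len(log) == 2


def test_prune_reason_precedence():
    bl = pd.DataFrame([{"chrom": "chr1", "start": 0, "end": 300}])
    cnv = pd.DataFrame([{"chrom": "chr1", "start": 0, "end": 300}])
    kept, log = prune_artifacts(_cand([10]), bl, cnv, bl.iloc[:0])
    assert log["reason"].iloc[0] == "blacklist"


def test_restrict_to_retained_categories():
    ann = pd.DataFrame(
        [
            {"chrom": "chr1", "start": 100, "end": 200, "element_id": "e1",
             "category": "enhancer"},
            {"chrom": "chr1", "start": 300, "end": 400, "element_id": "e2",
             "category": "heterochromatin"},
        ]
    )
    out = restrict_to_elements(_cand([151, 351, 901]), ann)
    assert list(out["site_id"]) == ["s151"]
    assert out["element_id"].iloc[0] == "e1"
    with pytest.raises(ValueError, match="unknown"):
        restrict_to_elements(_cand([151]), ann.assign(category=["exonic", "x"]))


# ---------------------------------------------------------------------------
# mark attribution / frequency
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "assays,label",
    [
        (["H3K27ac"], "H3K27ac"),
        (["H3K27ac", "H3K4me1"], "mixed"),
        (["H3K27ac", "H3K4me3", "CTCF"], "mixed"),
        (["CTCF"], "CTCF"),
        (["SA1"], "SA1"),
        (["H3K4me3", "SA1"], "H3K4me3"),
        (["CTCF", "SA1"], "CTCF+SA1"),
    ],
)
def test_attribute_marks(assays, label):
    assert attribute_marks(assays) == label


def test_attribute_marks_requires_signal():
    with pytest.raises(ValueError):
        attribute_marks([])


@pytest.mark.parametrize(
    "maf,cls", [(0.005, "rare"), (0.30, "common"), (0.01, "common"),
                (float("nan"), "unknown")]
)
def test_classify_frequency(maf, cls):
    assert classify_frequency(maf, threshold=0.01) == cls


# ---------------------------------------------------------------------------
# aggregation across samples
# ---------------------------------------------------------------------------

def _counts(sample, site, ref, alt, g1, g2, n_g1, n_g2):
    return pd.DataFrame(
        [{"chrom": "chr1", "pos": 100, "site_id": site, "ref": ref, "alt": alt,
          "g1": g1, "g2": g2, "af": 0.4, "maf": 0.4,
          "n_g1": n_g1, "n_g2": n_g2, "n_other": 0, "n_lowq": 0}]
    )


def test_aggregate_orients_by_ref_alt_not_haplotype():
    # sample A: alt on haplotype 2; sample B: alt on haplotype 1
    a = _counts("A", "s0", "A", "G", "A", "G", 14, 6)   # ref=14, alt=6
    b = _counts("B", "s0", "A", "G", "G", "A", 5, 15)   # alt=5, ref=15
    agg = aggregate_population({"A": a, "B": b})
    row = agg.iloc[0]
    assert (row["n_ref"], row["n_alt"]) == (29, 11)
    assert row["n_het_samples"] == 2


def test_aggregate_single_het_sample_passthrough():
    a = _counts("A", "s0", "A", "G", "A", "G", 12, 8)
    agg = aggregate_population({"A": a})
    assert (agg.iloc[0]["n_ref"], agg.iloc[0]["n_alt"]) == (12, 8)


def test_aggregate_orientation_conflict_raises():
    a = _counts("A", "s0", "A", "G", "A", "G", 1, 1)
    b = _counts("B", "s0", "A", "C", "A", "C", 1, 1)
    with pytest.raises(ValueError, match="orientation"):
        aggregate_population({"A": a, "B": b})


def test_weak_signal_surfaces_only_in_aggregate():
    """Three samples at (14,6) each: individually unremarkable inside a
    large test collection, but the summed (42,18) is strong."""
    p_single = exact_binom_p(14, 6)
    p_agg = exact_binom_p(42, 18)
    oracle = binom_two_sided_oracle(42, 60)
    assert p_agg == pytest.approx(oracle, abs=1e-12)
    assert p_agg == pytest.approx(0.0025, abs=2e-4)
    assert p_single > 0.05 > p_agg


def test_call_sample_and_case_labels():
    rng = np.random.default_rng(0)
    # one strong site among many nulls, per sample
    def mk(sample, strong_k):
        rows = []
        for i in range(80):
            n = 30
            k = strong_k if i == 0 else int(rng.binomial(n, 0.5))
            rows.append({"chrom": "chr1", "pos": 1000 + i * 10,
                         "site_id": f"s{i}", "ref": "A", "alt": "G",
                         "g1": "A", "g2": "G", "af": 0.4, "maf": 0.4,
                         "n_g1": k, "n_g2": n - k, "n_other": 0, "n_lowq": 0})
        return {"CTCF": pd.DataFrame(rows)}

    counts = {"X": mk("X", 29), "Y": mk("Y", 28)}
    single = pd.concat(
        [call_sample(counts[s], s) for s in counts], ignore_index=True
    )
    assert "s0" in set(single["site_id"])
    agg = call_aggregate(counts, single)
    assert set(agg["population_case"]) <= {"case1", "case2"}
    s0 = agg.loc[agg["site_id"] == "s0"]
    assert len(s0) and s0["population_case"].iloc[0] == "case1"


def test_orientation_invariance_haplotype_swap():
    """Swapping G1/G2 labels leaves the two-sided p and, after ref/alt
    orientation, the aggregate counts unchanged."""
    a = _counts("A", "s0", "A", "G", "A", "G", 14, 6)
    swapped = a.copy()
    swapped[["g1", "g2"]] = swapped[["g2", "g1"]].to_numpy()
    swapped[["n_g1", "n_g2"]] = swapped[["n_g2", "n_g1"]].to_numpy()
    assert exact_binom_p(14, 6) == pytest.approx(exact_binom_p(6, 14))
    agg_a = aggregate_population({"A": a})
    agg_s = aggregate_population({"A": swapped})
    pd.testing.assert_frame_equal(agg_a, agg_s)
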