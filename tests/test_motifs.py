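"""Motif models, dinucleotide shuffling, calibration, allele scanning."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from allelescan.motifs import (
    BackgroundModel,
    MotifModel,
    classify_effect,
    dinucleotide_counts,
    dinucleotide_shuffle,
    encode,
    extract_allele_windows,
    interval_jaccard,
    revcomp,
    scan_windows,
    tf_summaries,
    write_sites_fasta,
    read_sites_fasta,
)
from allelescan.synthetic import (
    add_first_order_dependency,
    pwm_motif_spec,
    sample_motif_sites,
)

DNA = st.text(alphabet="ACGT", min_size=2, max_size=60)


# ---------------------------------------------------------------------------
# dinucleotide shuffle
# ---------------------------------------------------------------------------

def test_shuffle_degenerate_sequences():
    assert dinucleotide_shuffle("AAAA", seed=0) == "AAAA"
    assert dinucleotide_shuffle("AC", seed=0) == "AC"
    assert dinucleotide_shuffle("A", seed=0) == "A"


@given(DNA)
@settings(max_examples=300, deadline=None, derandomize=True)
def test_shuffle_preserves_dinucleotide_counts_and_ends(s):
    out = dinucleotide_shuffle(s, seed=11)
    assert len(out) == len(s)
    assert out[0] == s[0] and out[-1] == s[-1]
    assert dinucleotide_counts(out) == dinucleotide_counts(s)


def test_shuffle_diversity_on_601bp_window():
    rng = np.random.default_rng(3)
    seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 601))
    outs = {dinucleotide_shuffle(seq, rng) for _ in range(1000)}
    assert len(outs) >= 100


def test_shuffle_uniformity_small_case():
    """All valid shuffles of a short sequence appear with similar frequency."""
    rng = np.random.default_rng(0)
    from collections import Counter

    counts = Counter(dinucleotide_shuffle("ACACGT", rng) for _ in range(4000))
    for s in counts:
        assert dinucleotide_counts(s) == dinucleotide_counts("ACACGT")
    freqs = np.array(list(counts.values())) / 4000
    assert freqs.max() / freqs.min() < 1.5


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def test_training_requires_clean_uniform_sites():
    with pytest.raises(ValueError, match=">= 10"):
        MotifModel.train(["ACGT"] * 5)
    with pytest.raises(ValueError, match="uniform length"):
        MotifModel.train(["ACGT"] * 10 + ["ACGTA"] * 5)
    # non-ACGT sites are skipped, remaining must still be >= 10
    m = MotifModel.train(["ACGT"] * 12 + ["ACNT"] * 3)
    assert m.n_training_sites == 12


def test_independence_model_selects_depth_zero():
    sites = sample_motif_sites(pwm_motif_spec(8, seed=5), 400, seed=6)
    m = MotifModel.train(sites, k_max=2)
    assert all(p.depth == 0 for p in m.positions)


def test_planted_dependency_selects_positive_depth():
    spec = add_first_order_dependency(pwm_motif_spec(8, seed=1), pos=4)
    hits = 0
    for run in range(20):
        sites = sample_motif_sites(spec, 400, seed=100 + run)
        m = MotifModel.train(sites, k_max=2)
        hits += m.positions[4].depth >= 1
    assert hits >= 18


def test_deterministic_sites_concentrate_mass():
    m = MotifModel.train(["ACG"] * 50, k_max=0, pseudocount=0.5)
    # (50 + 0.5) / (50 + 2) mass on the observed base
    p0 = np.exp(m.positions[0].log_probs[0, 0])
    assert p0 == pytest.approx(50.5 / 52, abs=1e-12)


def test_marginal_recovery_within_tv_005():
    spec = pwm_motif_spec(10, seed=9, sharpness=0.8)
    sites = sample_motif_sites(spec, 500, seed=10)
    m = MotifModel.train(sites, k_max=2)
    for i, pos_spec in enumerate(spec):
        truth = np.asarray(pos_spec["probs"])
        if m.positions[i].depth == 0:
            est = np.exp(m.positions[i].log_probs[0])
        else:
            # marginalize the conditional over observed contexts
            est = np.exp(m.positions[i].log_probs).mean(axis=0)
        assert 0.5 * np.abs(est - truth).sum() <= 0.05


# ---------------------------------------------------------------------------
# scanning and PWM reduction
# ---------------------------------------------------------------------------

def pwm_oracle_scores(sites, seq, background, pseudocount=0.5):
    """Independent PWM log-odds scan (forward strand)."""
    X = np.array([[ "ACGT".index(c) for c in s] for s in sites])
    L = X.shape[1]
    logp = []
    for i in range(L):
        counts = np.bincount(X[:, i], minlength=4).astype(float)
        counts += pseudocount
        probs = counts / counts.sum()
        logp.append(np.log(probs))
    codes = encode(seq)
    out = []
    for off in range(len(codes) - L + 1):
        w = codes[off : off + L]
        s = 0.0
        for i in range(L):
            s += logp[i][w[i]]
        s -= background.log_marginal[w[0]]
        for i in range(1, L):
            s -= background.log_transition[w[i - 1], w[i]]
        out.append(s)
    return np.array(out)


def test_kmax0_scan_reduces_to_pwm_bit_exactly():
    rng = np.random.default_rng(4)
    sites = sample_motif_sites(pwm_motif_spec(9, seed=2), 150, seed=3)
    seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 400))
    bg = BackgroundModel.train([seq])
    m = MotifModel.train(sites, k_max=0, background=bg)
    got = m.scan_sequence(seq)[:, 0]
    exp = pwm_oracle_scores(sites, seq, bg)
    np.testing.assert_array_equal(got, exp)


def test_strand_consistency():
    sites = sample_motif_sites(pwm_motif_spec(7, seed=8), 100, seed=9)
    rng = np.random.default_rng(5)
    seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 200))
    m = MotifModel.train(sites, k_max=1)
    fwd = m.scan_sequence(seq)
    rev = m.scan_sequence(revcomp(seq))
    # scanning the reverse complement swaps strands and reverses offsets
    np.testing.assert_allclose(fwd[:, 0], rev[::-1, 1], atol=1e-12)
    np.testing.assert_allclose(fwd[:, 1], rev[::-1, 0], atol=1e-12)


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def calibrated_model():
    sites = sample_motif_sites(pwm_motif_spec(8, seed=20), 300, seed=21)
    rng = np.random.default_rng(22)
    windows = ["".join("ACGT"[i] for i in rng.integers(0, 4, 301))
               for _ in range(6)]
    bg = BackgroundModel.train(windows)
    m = MotifModel.train(sites, k_max=1, background=bg)
    m.calibrate(windows, n_shuffles_per_window=10, seed=23)
    return m, windows


def test_gaussian_calibration_tail(calibrated_model):
    m, _ = calibrated_model
    mean, sd = m.calibration
    assert sd > 0
    assert m.p_value(mean) == pytest.approx(0.5, abs=1e-12)
    p = m.p_value(mean + 3.09 * sd)
    assert p == pytest.approx(1e-3, rel=0.05)


def test_calibrated_null_p_values_roughly_uniform_tail(calibrated_model):
    m, windows = calibrated_model
    rng = np.random.default_rng(7)
    scores = []
    for w in windows:
        for _ in range(10):
            sc = m.scan_sequence(dinucleotide_shuffle(w, rng)).ravel()
            scores.append(sc[np.isfinite(sc)])
    p = m.p_value(np.concatenate(scores))
    assert len(p) >= 10_000
    assert abs((p <= 0.05).mean() - 0.05) <= 0.02


def test_calibration_guards():
    sites = sample_motif_sites(pwm_motif_spec(6, seed=1), 50, seed=2)
    m = MotifModel.train(sites, k_max=0)
    with pytest.raises(ValueError, match="not calibrated"):
        m.p_value(0.0)
    with pytest.raises(ValueError, match=">= 1000"):
        m.calibrate(["ACGTACGTAC"], n_shuffles_per_window=2)


# ---------------------------------------------------------------------------
# allele windows and effect calls
# ---------------------------------------------------------------------------

def test_extract_allele_windows_geometry():
    rng = np.random.default_rng(1)
    seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 2000))
    ref = {"chr1": seq}
    pos = 1000
    snp = {"chrom": "chr1", "pos": pos, "ref": seq[pos - 1],
           "alt": "ACGT"[("ACGT".index(seq[pos - 1]) + 1) % 4]}
    rw, aw, center, trunc = extract_allele_windows(snp, ref, flank=300)
    assert len(rw) == len(aw) == 601 and center == 300 and not trunc
    diffs = [i for i in range(601) if rw[i] != aw[i]]
    assert diffs == [300]
    # near the chromosome start the window truncates and is flagged
    snp_edge = {"chrom": "chr1", "pos": 100, "ref": seq[99],
                "alt": "ACGT"[("ACGT".index(seq[99]) + 1) % 4]}
    rw, aw, center, trunc = extract_allele_windows(snp_edge, ref, flank=300)
    assert trunc and center == 99 and len(rw) == 400


def test_scan_windows_monotone_in_threshold(calibrated_model):
    m, windows = calibrated_model
    w = windows[0]
    alt = w[:150] + ("A" if w[150] != "A" else "C") + w[151:]
    loose = scan_windows(m, w, alt, 150, p_threshold=1e-2)
    tight = scan_windows(m, w, alt, 150, p_threshold=1e-4)
    keys = lambda hits: {(h["offset"], h["strand"]) for h in hits}
    assert keys(tight) <= keys(loose)


def test_implanted_motif_found_center_only(calibrated_model):
    m, windows = calibrated_model
    cons = "".join(
        "ACGT"[int(np.argmax(np.exp(p.log_probs[0])))] for p in m.positions
    )
    w = windows[1]
    center = 150
    # implant on the "alt" window only, centered on the variant
    alt = w[: center - 3] + cons + w[center - 3 + len(cons):]
    hits = scan_windows(m, w, alt, center, p_threshold=1e-3)
    overl = [h for h in hits if h["overlaps_snp"]]
    assert any(h["offset"] == center - 3 for h in overl)
    # same motif far from the variant: reported but not SNP-overlapping
    off_w = w[:50] + cons + w[50 + len(cons):]
    hits = scan_windows(m, off_w, off_w, center, p_threshold=1e-3)
    far = [h for h in hits if h["offset"] == 50]
    assert far and not far[0]["overlaps_snp"]


def test_classify_effect():
    assert classify_effect(8.3, 12.1) == "gain"
    assert classify_effect(12.1, 8.3) == "loss"
    assert classify_effect(5.0, 5.0) is None


# ---------------------------------------------------------------------------
# summaries and FASTA round trip
# ---------------------------------------------------------------------------

def test_interval_jaccard_identities():
    a = [(0, 10), (20, 30)]
    assert interval_jaccard(a, a) == 1.0
    assert interval_jaccard(a, [(50, 60)]) == 0.0
    assert interval_jaccard([(0, 10)], [(5, 15)]) == pytest.approx(5 / 15)


def test_tf_summaries_fraction_altered():
    pred = pd.DataFrame(
        [{"tf": "T", "chrom": "chr1", "start": i * 100, "end": i * 100 + 10,
          "overlaps_snp": i < 2, "effect": "loss" if i == 0 else
          ("gain" if i == 1 else None)}
         for i in range(10)]
    )
    out = tf_summaries(pred, {"chr1": [5, 105]})
    row = out.iloc[0]
    assert row["n_sites"] == 10 and row["fraction_altered"] == 0.2
    assert row["fraction_gain"] == 0.5 and row["fraction_loss"] == 0.5
    assert 0 < row["jaccard"] < 1


def test_sites_fasta_round_trip(tmp_path):
    sites = ["ACGTACGT", "TTGGCCAA"]
    write_sites_fasta(sites, tmp_path / "s.fa")
    assert read_sites_fasta(tmp_path / "s.fa") == sites
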