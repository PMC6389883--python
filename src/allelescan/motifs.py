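"""Dependency-aware motif models and allele-differential binding prediction.

Motif models here are inhomogeneous variable-order Markov models: the
nucleotide distribution at each motif position may condition on up to
``k_max`` preceding positions, with the context depth selected per
position by BIC.  With ``k_max=0`` the model reduces exactly to a PWM.
Scores are log-likelihood ratios against an order-1 background.  Score
p-values come from a Gaussian fitted to the score distribution obtained
by dinucleotide-shuffling the input windows (exact Altschul-Erickson
shuffles preserving all 16 adjacent-pair counts), and predictions are
kept at p <= 1e-3.  For each heterozygous site two 601 bp windows are
scanned, one per allele, and predictions overlapping the variant itself
are classified as allelic gain (alternative allele scores higher) or
loss.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

logger = logging.getLogger(__name__)

BASES = "ACGT"
_CODE = {b: i for i, b in enumerate(BASES)}
#: Default prediction threshold on the calibrated Gaussian p-value.
P_THRESHOLD = 1e-3


def encode(seq: str) -> np.ndarray:
    """ACGT -> 0..3; any other character -> -1."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    out = np.full(len(arr), -1, dtype=np.int64)
    for b, i in _CODE.items():
        out[arr == ord(b)] = i
    return out


def revcomp(seq: str) -> str:
    return seq.upper().translate(str.maketrans("ACGT", "TGCA"))[::-1]


# ---------------------------------------------------------------------------
# Dinucleotide shuffle (Altschul-Erickson, Eulerian path)
# ---------------------------------------------------------------------------

def dinucleotide_shuffle(sequence: str, seed=None) -> str:
    """Uniform random shuffle preserving all adjacent-pair counts.

    The sequence is viewed as an Eulerian path in the multigraph whose
    edges are its dinucleotides.  A uniformly random arborescence toward
    the final character fixes each vertex's last outgoing edge (sampled by
    rejection), the remaining edges are permuted, and walking the path
    yields a shuffle with exactly the original dinucleotide counts and the
    original first and last characters.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    s = sequence
    if len(s) < 3 or len(set(s)) == 1:
        return s

    succ: dict[str, list[str]] = {}
    for a, b in zip(s, s[1:]):
        succ.setdefault(a, []).append(b)
    last = s[-1]
    vertices = [v for v in succ if v != last]

    # sample the last-edge function; accept only arborescences toward `last`
    for _ in range(100_000):
        t = {v: succ[v][rng.integers(len(succ[v]))] for v in vertices}
        ok = True
        for v in vertices:
            seen = {v}
            cur = v
            while cur != last:
                cur = t.get(cur)
                if cur is None or cur in seen:
                    ok = False
                    break
                seen.add(cur)
            if not ok:
                break
        if ok:
            break
    else:  # pragma: no cover - astronomically unlikely for DNA alphabets
        raise RuntimeError("failed to sample an arborescence")

    ordered: dict[str, list[str]] = {}
    for v, edges in succ.items():
        edges = list(edges)
        if v != last:
            edges.remove(t[v])
        perm = rng.permutation(len(edges))
        shuffled = [edges[i] for i in perm]
        if v != last:
            shuffled.append(t[v])
        ordered[v] = shuffled

    out = [s[0]]
    counters = {v: 0 for v in ordered}
    cur = s[0]
    for _ in range(len(s) - 1):
        nxt = ordered[cur][counters[cur]]
        counters[cur] += 1
        out.append(nxt)
        cur = nxt
    return "".join(out)


def dinucleotide_counts(seq: str) -> dict[str, int]:
    counts: dict[str, int] = {}
    for a, b in zip(seq, seq[1:]):
        counts[a + b] = counts.get(a + b, 0) + 1
    return counts


# ---------------------------------------------------------------------------
# Background model (order 1)
# ---------------------------------------------------------------------------

@dataclass
class BackgroundModel:
    """Order-1 nucleotide model: marginal start + transition probabilities."""

    log_marginal: np.ndarray  # (4,)
    log_transition: np.ndarray  # (4, 4), row = previous base

    @classmethod
    def train(cls, sequences: list[str], pseudocount: float = 0.5) -> "BackgroundModel":
        marg = np.full(4, pseudocount)
        trans = np.full((4, 4), pseudocount)
        for seq in sequences:
            c = encode(seq)
            c = c[c >= 0]
            for v in c:
                marg[v] += 1
            np.add.at(trans, (c[:-1], c[1:]), 1)
        return cls(
            log_marginal=np.log(marg / marg.sum()),
            log_transition=np.log(trans / trans.sum(axis=1, keepdims=True)),
        )


# ---------------------------------------------------------------------------
# Motif model
# ---------------------------------------------------------------------------

@dataclass
class PositionModel:
    depth: int
    log_probs: np.ndarray  # (4**depth, 4)


@dataclass
class MotifModel:
    """Inhomogeneous variable-order Markov motif model."""

    tf: str
    length: int
    k_max: int
    pseudocount: float
    positions: list[PositionModel]
    background: BackgroundModel
    calibration: tuple[float, float] | None = None  # (mean, sd)
    n_training_sites: int = 0

    # -- training ----------------------------------------------------------

    @classmethod
    def train(
        cls,
        sites: list[str],
        tf: str = "TF",
        k_max: int = 2,
        pseudocount: float = 0.5,
        background: BackgroundModel | None = None,
    ) -> "MotifModel":
        """Fit per-position conditional distributions with BIC depth choice.

        Sites must be aligned and equal-length; sites containing non-ACGT
        characters are skipped with a log message; fewer than 10 usable
        sites is an error.
        """
        clean = []
        for s in sites:
            c = encode(s)
            if (c < 0).any():
                logger.warning("skipping training site with non-ACGT base: %s", s)
                continue
            clean.append(c)
        if len(clean) < 10:
            raise ValueError(f"need >= 10 clean training sites, got {len(clean)}")
        lengths = {len(c) for c in clean}
        if len(lengths) != 1:
            raise ValueError("training sites must have uniform length")
        X = np.array(clean)
        n, L = X.shape

        positions = []
        for i in range(L):
            best = None
            for d in range(0, min(i, k_max) + 1):
                ctx = np.zeros(n, dtype=np.int64)
                for j in range(d):
                    ctx = ctx * 4 + X[:, i - d + j]
                counts = np.full((4**d, 4), pseudocount)
                np.add.at(counts, (ctx, X[:, i]), 1)
                probs = counts / counts.sum(axis=1, keepdims=True)
                ll = float(np.log(probs[ctx, X[:, i]]).sum())
                bic = -2.0 * ll + 3 * (4**d) * np.log(n)
                if best is None or bic < best[0] - 1e-12:
                    best = (bic, d, np.log(probs))
            positions.append(PositionModel(depth=best[1], log_probs=best[2]))

        bg = background or BackgroundModel.train(["".join(BASES[c] for c in row) for row in X])
        return cls(
            tf=tf,
            length=L,
            k_max=k_max,
            pseudocount=pseudocount,
            positions=positions,
            background=bg,
            n_training_sites=n,
        )

    # -- scoring -----------------------------------------------------------

    def _score_codes(self, codes: np.ndarray) -> np.ndarray:
        """Scores for every offset of an encoded sequence (one strand)."""
        L = self.length
        M = len(codes)
        if M < L:
            return np.empty(0)
        n_off = M - L + 1
        idx = np.arange(n_off)[:, None] + np.arange(L)[None, :]
        W = codes[idx]
        valid = (W >= 0).all(axis=1)
        Wv = np.where(W >= 0, W, 0)
        score = np.zeros(n_off)
        for i, pm in enumerate(self.positions):
            ctx = np.zeros(n_off, dtype=np.int64)
            for j in range(pm.depth):
                ctx = ctx * 4 + Wv[:, i - pm.depth + j]
            score += pm.log_probs[ctx, Wv[:, i]]
        bg = self.background
        score -= bg.log_marginal[Wv[:, 0]]
        for i in range(1, L):
            score -= bg.log_transition[Wv[:, i - 1], Wv[:, i]]
        score[~valid] = -np.inf
        return score

    def scan_sequence(self, seq: str) -> np.ndarray:
        """(n_offsets, 2) score array: column 0 = '+' strand, 1 = '-'.

        The minus-strand score at offset o is the model score of the
        reverse complement of ``seq[o:o+L]``.
        """
        fwd = self._score_codes(encode(seq))
        rc = self._score_codes(encode(revcomp(seq)))[::-1]
        return np.stack([fwd, rc], axis=1)

    # -- calibration -------------------------------------------------------

    def calibrate(
        self,
        input_windows: list[str],
        n_shuffles_per_window: int = 25,
        seed=None,
        min_scores: int = 1000,
    ) -> tuple[float, float]:
        """Fit the null-score Gaussian from dinucleotide-shuffled windows.

        All sliding-window scores on both strands of every shuffled
        sequence are pooled; the Gaussian is the pooled sample mean and
        standard deviation, and ``p(score)`` is its upper tail.
        """
        rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
        scores = []
        for w in input_windows:
            for _ in range(n_shuffles_per_window):
                sh = dinucleotide_shuffle(w, rng)
                sc = self.scan_sequence(sh).ravel()
                scores.append(sc[np.isfinite(sc)])
        pooled = np.concatenate(scores) if scores else np.empty(0)
        if pooled.size < min_scores:
            raise ValueError(
                f"calibration needs >= {min_scores} shuffled scores, got {pooled.size}"
            )
        mean = float(pooled.mean())
        sd = float(pooled.std(ddof=1))
        if sd <= 0:
            raise ValueError("zero variance in shuffled scores; cannot calibrate")
        self.calibration = (mean, sd)
        return self.calibration

    def p_value(self, score) -> np.ndarray:
        """Upper-tail Gaussian p-value of a motif score."""
        if self.calibration is None:
            raise ValueError("model is not calibrated")
        mean, sd = self.calibration
        return norm.sf((np.asarray(score, dtype=float) - mean) / sd)

    # -- (de)serialization --------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "tf": self.tf,
            "length": self.length,
            "k_max": self.k_max,
            "pseudocount": self.pseudocount,
            "n_training_sites": self.n_training_sites,
            "positions": [
                {"depth": p.depth, "log_probs": p.log_probs.tolist()}
                for p in self.positions
            ],
            "background": {
                "log_marginal": self.background.log_marginal.tolist(),
                "log_transition": self.background.log_transition.tolist(),
            },
            "calibration": list(self.calibration) if self.calibration else None,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MotifModel":
        return cls(
            tf=d["tf"],
            length=d["length"],
            k_max=d["k_max"],
            pseudocount=d["pseudocount"],
            n_training_sites=d.get("n_training_sites", 0),
            positions=[
                PositionModel(depth=p["depth"], log_probs=np.array(p["log_probs"]))
                for p in d["positions"]
            ],
            background=BackgroundModel(
                log_marginal=np.array(d["background"]["log_marginal"]),
                log_transition=np.array(d["background"]["log_transition"]),
            ),
            calibration=tuple(d["calibration"]) if d["calibration"] else None,
        )

    def save(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def load(cls, path: str) -> "MotifModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# Allele windows
# ---------------------------------------------------------------------------

def extract_allele_windows(
    as_snp, reference: dict[str, str], flank: int = 300
) -> tuple[str, str, int, bool]:
    """Two (2*flank+1) bp windows centered on the two alleles of a SNV.

    ``as_snp`` needs attributes/keys ``chrom``, ``pos`` (1-based), ``ref``,
    ``alt``.  Returns (ref_window, alt_window, center_index, truncated);
    windows at chromosome edges are truncated and flagged.  The two
    windows differ at exactly the center position.
    """
    get = as_snp.get if hasattr(as_snp, "get") else lambda k: getattr(as_snp, k)
    chrom, pos, ref, alt = get("chrom"), int(get("pos")), get("ref"), get("alt")
    if len(ref) != 1 or len(alt) != 1 or ref == alt:
        raise ValueError(f"site {chrom}:{pos} is not a biallelic SNV")
    seq = reference[chrom]
    if seq[pos - 1] != ref:
        raise ValueError(f"reference base at {chrom}:{pos} is not {ref}")
    lo = max(0, pos - 1 - flank)
    hi = min(len(seq), pos + flank)
    center = pos - 1 - lo
    truncated = (hi - lo) != 2 * flank + 1
    left, right = seq[lo : pos - 1], seq[pos:hi]
    return left + ref + right, left + alt + right, center, truncated


# ---------------------------------------------------------------------------
# Window scanning and allelic-effect calls
# ---------------------------------------------------------------------------

def scan_windows(
    model: MotifModel,
    ref_window: str,
    alt_window: str,
    center: int,
    p_threshold: float = P_THRESHOLD,
) -> list[dict]:
    """Predicted binding-site loci over a pair of allele windows.

    Both strands of both windows are scanned; a (offset, strand) locus is
    emitted when either allele reaches ``p <= p_threshold``, carrying both
    alleles' scores and p-values.  ``overlaps_snp`` flags loci whose site
    interval covers the window center; only those enter allelic-effect
    analysis.
    """
    s_ref = model.scan_sequence(ref_window)
    s_alt = model.scan_sequence(alt_window)
    p_ref = model.p_value(s_ref)
    p_alt = model.p_value(s_alt)
    L = model.length
    out = []
    hit = (p_ref <= p_threshold) | (p_alt <= p_threshold)
    for off, strand_i in zip(*np.nonzero(hit)):
        off = int(off)
        out.append(
            {
                "tf": model.tf,
                "offset": off,
                "strand": "+" if strand_i == 0 else "-",
                "score_ref": float(s_ref[off, strand_i]),
                "score_alt": float(s_alt[off, strand_i]),
                "p_ref": float(p_ref[off, strand_i]),
                "p_alt": float(p_alt[off, strand_i]),
                "overlaps_snp": off <= center <= off + L - 1,
            }
        )
    return out


def classify_effect(score_ref: float, score_alt: float) -> str | None:
    """``gain`` iff the alternative allele scores higher, else ``loss``.

    Exact ties are excluded (returns None): a site truly overlapping the
    variant can only tie if the model is insensitive to that position.
    """
    if score_alt > score_ref:
        return "gain"
    if score_alt < score_ref:
        return "loss"
    logger.info("tied allele scores; prediction excluded from effect analysis")
    return None


# ---------------------------------------------------------------------------
# Per-TF summaries
# ---------------------------------------------------------------------------

def _merge_intervals(iv: list[tuple[int, int]]) -> list[tuple[int, int]]:
    if not iv:
        return []
    iv = sorted(iv)
    merged = [list(iv[0])]
    for s, e in iv[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [tuple(x) for x in merged]


def _intersection_bp(a: list[tuple[int, int]], b: list[tuple[int, int]]) -> int:
    inter = 0
    i = j = 0
    while i < len(a) and j < len(b):
        s = max(a[i][0], b[j][0])
        e = min(a[i][1], b[j][1])
        if s < e:
            inter += e - s
        if a[i][1] <= b[j][1]:
            i += 1
        else:
            j += 1
    return inter


def interval_jaccard(
    a: list[tuple[int, int]], b: list[tuple[int, int]]
) -> float:
    """bp-level Jaccard (overlap / union) of two interval sets."""
    a, b = _merge_intervals(a), _merge_intervals(b)
    total_a = sum(e - s for s, e in a)
    total_b = sum(e - s for s, e in b)
    inter = _intersection_bp(a, b)
    union = total_a + total_b - inter
    return inter / union if union else 0.0


def tf_summaries(predictions, as_snp_positions: dict[str, list[int]]) -> "pd.DataFrame":
    """Per-TF statistics over a genome-anchored prediction table.

    ``predictions`` is a DataFrame with columns ``tf``, ``chrom``,
    ``start``, ``end`` (half-open genomic site interval), ``overlaps_snp``
    and ``effect`` (gain/loss/None).  ``as_snp_positions`` maps chrom ->
    0-based AS-SNP positions.  Jaccard is bp-based between the 1 bp
    AS-SNP intervals and the TF's predicted-site intervals.
    """
    import pandas as pd  # local import keeps numpy-only callers light

    snp_iv = [
        (chrom, p, p + 1) for chrom, ps in as_snp_positions.items() for p in ps
    ]
    rows = []
    for tf, grp in predictions.groupby("tf"):
        site_iv = list(zip(grp["chrom"], grp["start"], grp["end"]))
        # bp intersection/union pooled over chromosomes
        chroms = {c for c, *_ in site_iv} | {c for c, *_ in snp_iv}
        inter = union = 0
        for c in chroms:
            a = _merge_intervals([(s, e) for cc, s, e in site_iv if cc == c])
            b = _merge_intervals([(s, e) for cc, s, e in snp_iv if cc == c])
            ta = sum(e - s for s, e in a)
            tb = sum(e - s for s, e in b)
            ii = _intersection_bp(a, b)
            inter += ii
            union += ta + tb - ii
        jaccard = inter / union if union else 0.0
        n_sites = len(grp)
        altered = grp.loc[grp["overlaps_snp"]]
        n_alt = len(altered)
        n_gain = int((altered["effect"] == "gain").sum())
        n_loss = int((altered["effect"] == "loss").sum())
        rows.append(
            {
                "tf": tf,
                "n_sites": n_sites,
                "n_altered": n_alt,
                "fraction_altered": n_alt / n_sites if n_sites else 0.0,
                "fraction_gain": n_gain / n_alt if n_alt else 0.0,
                "fraction_loss": n_loss / n_alt if n_alt else 0.0,
                "jaccard": jaccard,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# FASTA helpers for training sites
# ---------------------------------------------------------------------------

def read_sites_fasta(path: str) -> list[str]:
    sites = []
    cur: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                if cur:
                    sites.append("".join(cur))
                cur = []
            elif line:
                cur.append(line)
    if cur:
        sites.append("".join(cur))
    return sites


def write_sites_fasta(sites: list[str], path: str, prefix: str = "site") -> None:
    with open(path, "w") as fh:
        for i, s in enumerate(sites):
            fh.write(f">{prefix}{i:05d}\n{s}\n")
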