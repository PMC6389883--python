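"""Personal diploid genome construction from phased SNVs.

A phased panel assigns every sample two haplotypes per biallelic SNV.  The
two haploid personal genome sequences are named G1 (the allele left of the
phase bar) and G2 (right of the phase bar).  Note that G1 is *not* "the
reference haplotype": either haplotype can mix reference and alternative
alleles along a chromosome; the substitution table preserves the mapping
back to reference/alternative.

Coordinates follow the standard dialects: VCF positions are 1-based,
all internal interval arithmetic is 0-based half-open, and conversion
happens only at I/O boundaries.  Variation is SNV-only, so reference, G1
and G2 share a single coordinate frame.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pysam
from pyfaidx import Fasta

logger = logging.getLogger(__name__)

BASES = "ACGT"


class RefMismatchError(ValueError):
    """A variant's REF allele does not match the reference base."""


class UnphasedGenotypeError(ValueError):
    """A genotype required to be phased is not."""


# ---------------------------------------------------------------------------
# Panel container
# ---------------------------------------------------------------------------

@dataclass
class Panel:
    """A phased, biallelic SNV panel for a sample cohort.

    Attributes
    ----------
    samples : list of str
        Sample identifiers, column order of ``haplotypes``.
    reference : dict
        Chromosome name -> sequence string (upper-case).
    sites : pandas.DataFrame
        One row per SNV with columns ``chrom``, ``pos`` (1-based), ``id``,
        ``ref``, ``alt``; sorted by (chrom, pos).
    haplotypes : numpy.ndarray, shape (n_sites, n_samples, 2), int8
        0 = reference allele, 1 = alternative allele.  Index 0 of the last
        axis is the left (G1) haplotype.
    """

    samples: list[str]
    reference: dict[str, str]
    sites: pd.DataFrame
    haplotypes: np.ndarray

    def __post_init__(self) -> None:
        if self.haplotypes.shape != (len(self.sites), len(self.samples), 2):
            raise ValueError(
                f"haplotype array shape {self.haplotypes.shape} does not match "
                f"{len(self.sites)} sites x {len(self.samples)} samples x 2"
            )

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def allele_freq(self) -> np.ndarray:
        """Cohort alternative-allele frequency per site (2N haplotypes)."""
        return self.haplotypes.reshape(self.n_sites, -1).mean(axis=1)

    def site_table(self) -> pd.DataFrame:
        """Sites with ``af`` (population alt AF) and ``maf`` columns.

        The population AF is the panel's annotated frequency (``af``
        column of ``sites``, e.g. VCF INFO/AF) when available; the cohort
        haplotype frequency is only a fallback.  Rare/common calls must
        not depend on the cohort's handful of haplotypes.
        """
        out = self.sites.copy()
        if "af" not in out.columns:
            out["af"] = self.allele_freq()
        out["maf"] = np.minimum(out["af"], 1.0 - out["af"])
        return out


# ---------------------------------------------------------------------------
# FASTA / VCF I/O
# ---------------------------------------------------------------------------

def load_reference(path: str) -> dict[str, str]:
    with Fasta(str(path), as_raw=True, sequence_always_upper=True) as fa:
        return {name: str(fa[name][:]) for name in fa.keys()}


def write_reference(reference: dict[str, str], path: str, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in reference.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_panel_vcf(panel: Panel, path: str) -> None:
    """Write the panel as a minimal phased VCF 4.2 (pipe-separated GT)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom, seq in panel.reference.items():
            fh.write(f"##contig=<ID={chrom},length={len(seq)}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            '##INFO=<ID=AF,Number=A,Type=Float,'
            'Description="Population allele frequency">\n'
        )
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(panel.samples)
            + "\n"
        )
        has_af = "af" in panel.sites.columns
        for i, row in enumerate(panel.sites.itertuples(index=False)):
            gts = "\t".join(
                f"{panel.haplotypes[i, s, 0]}|{panel.haplotypes[i, s, 1]}"
                for s in range(panel.n_samples)
            )
            info = f"AF={row.af:.10g}" if has_af else "."
            fh.write(
                f"{row.chrom}\t{row.pos}\t{row.id}\t{row.ref}\t{row.alt}"
                f"\t.\tPASS\t{info}\tGT\t{gts}\n"
            )


def load_panel(fasta_path: str, vcf_path: str, permissive: bool = False) -> Panel:
    """Load a phased panel from FASTA + VCF.

    Multi-allelic records and non-SNVs raise ``ValueError``; unphased
    genotypes raise ``UnphasedGenotypeError`` unless ``permissive`` is set,
    in which case the record is skipped with a log message.
    """
    reference = load_reference(fasta_path)
    rows: list[tuple] = []
    haps: list[list[tuple[int, int]]] = []
    afs: list[float] = []
    with pysam.VariantFile(str(vcf_path)) as vf:
        samples = list(vf.header.samples)
        for rec in vf:
            if rec.alts is None or len(rec.alts) != 1:
                raise ValueError(
                    f"multi-allelic or ALT-less record at {rec.chrom}:{rec.pos}; "
                    "only biallelic SNVs are supported"
                )
            ref, alt = rec.ref, rec.alts[0]
            if len(ref) != 1 or len(alt) != 1:
                raise ValueError(f"non-SNV record at {rec.chrom}:{rec.pos}")
            gt_row = []
            ok = True
            for s in samples:
                call = rec.samples[s]
                alleles = call["GT"]
                if None in alleles:
                    raise ValueError(f"missing genotype at {rec.chrom}:{rec.pos}")
                if not call.phased and alleles[0] != alleles[1]:
                    if permissive:
                        logger.warning(
                            "skipping unphased het %s:%d (%s)", rec.chrom, rec.pos, s
                        )
                        ok = False
                        break
                    raise UnphasedGenotypeError(
                        f"unphased heterozygous genotype at {rec.chrom}:{rec.pos} "
                        f"for sample {s}"
                    )
                gt_row.append((alleles[0], alleles[1]))
            if ok:
                rows.append((rec.chrom, rec.pos, rec.id or ".", ref, alt))
                haps.append(gt_row)
                af = rec.info.get("AF")
                afs.append(float(af[0]) if af is not None else np.nan)
    sites = pd.DataFrame(rows, columns=["chrom", "pos", "id", "ref", "alt"])
    if not np.isnan(afs).all():
        sites["af"] = afs
    hap_arr = np.array(haps, dtype=np.int8).reshape(len(sites), len(samples), 2)
    return Panel(samples=samples, reference=reference, sites=sites, haplotypes=hap_arr)


# ---------------------------------------------------------------------------
# Heterozygous sites
# ---------------------------------------------------------------------------

def het_sites(panel: Panel, sample: str) -> pd.DataFrame:
    """Biallelic sites heterozygous in ``sample``.

    Returns a DataFrame with one row per het site: ``chrom``, ``pos``
    (1-based), ``site_id``, ``ref``, ``alt``, ``g1`` / ``g2`` (allele
    bases carried by the left / right haplotype), ``af`` and ``maf``.
    """
    s = panel.samples.index(sample)
    h = panel.haplotypes[:, s, :]
    mask = h[:, 0] != h[:, 1]
    tab = panel.site_table().loc[mask].reset_index(drop=True)
    hm = h[mask]
    refs = tab["ref"].to_numpy()
    alts = tab["alt"].to_numpy()
    tab["g1"] = np.where(hm[:, 0] == 0, refs, alts)
    tab["g2"] = np.where(hm[:, 1] == 0, refs, alts)
    tab = tab.rename(columns={"id": "site_id"})
    return tab[["chrom", "pos", "site_id", "ref", "alt", "g1", "g2", "af", "maf"]]


# ---------------------------------------------------------------------------
# Personal genome pair
# ---------------------------------------------------------------------------

@dataclass
class PersonalGenomePair:
    """The two haploid personal genomes of one sample.

    ``substitution_table`` lists every position where at least one haplotype
    deviates from the reference, with columns ``chrom``, ``pos`` (1-based),
    ``ref_base``, ``g1_base``, ``g2_base``.
    """

    sample: str
    g1_sequences: dict[str, str]
    g2_sequences: dict[str, str]
    substitution_table: pd.DataFrame = field(repr=False)

    def write_fastas(self, g1_path: str, g2_path: str) -> None:
        write_reference(self.g1_sequences, g1_path)
        write_reference(self.g2_sequences, g2_path)


def build_personal_genomes(
    reference: dict[str, str], variants: pd.DataFrame, sample: str = "sample"
) -> PersonalGenomePair:
    """Apply phased SNVs to a reference, yielding the G1/G2 sequence pair.

    ``variants`` needs columns ``chrom``, ``pos`` (1-based), ``ref``,
    ``alt``, ``hap1``, ``hap2`` (0 = ref allele, 1 = alt allele).  Only
    genotypes carrying at least one alternative allele enter the
    substitution table; homozygous-reference rows leave both genomes
    untouched.
    """
    g1 = {c: bytearray(s, "ascii") for c, s in reference.items()}
    g2 = {c: bytearray(s, "ascii") for c, s in reference.items()}
    subs = []
    for row in variants.itertuples(index=False):
        chrom, pos = row.chrom, int(row.pos)
        if chrom not in reference:
            raise ValueError(f"unknown chromosome {chrom!r}")
        if not (1 <= pos <= len(reference[chrom])):
            raise ValueError(f"position {chrom}:{pos} outside chromosome bounds")
        if len(row.ref) != 1 or len(row.alt) != 1 or row.ref == row.alt:
            raise ValueError(f"non-biallelic-SNV variant at {chrom}:{pos}")
        ref_base = reference[chrom][pos - 1]
        if ref_base != row.ref:
            raise RefMismatchError(
                f"REF mismatch at {chrom}:{pos}: VCF says {row.ref}, "
                f"reference has {ref_base}"
            )
        if row.hap1 == 0 and row.hap2 == 0:
            continue
        b1 = row.ref if row.hap1 == 0 else row.alt
        b2 = row.ref if row.hap2 == 0 else row.alt
        g1[chrom][pos - 1] = ord(b1)
        g2[chrom][pos - 1] = ord(b2)
        subs.append((chrom, pos, ref_base, b1, b2))
    table = pd.DataFrame(
        subs, columns=["chrom", "pos", "ref_base", "g1_base", "g2_base"]
    )
    return PersonalGenomePair(
        sample=sample,
        g1_sequences={c: s.decode("ascii") for c, s in g1.items()},
        g2_sequences={c: s.decode("ascii") for c, s in g2.items()},
        substitution_table=table,
    )


def personal_genomes_for_sample(panel: Panel, sample: str) -> PersonalGenomePair:
    """Build the G1/G2 pair for one panel sample."""
    s = panel.samples.index(sample)
    var = panel.sites.copy()
    var["hap1"] = panel.haplotypes[:, s, 0]
    var["hap2"] = panel.haplotypes[:, s, 1]
    return build_personal_genomes(panel.reference, var, sample=sample)


def apply_substitution_table(
    reference: dict[str, str], table: pd.DataFrame
) -> tuple[dict[str, str], dict[str, str]]:
    """Re-apply a substitution table to the reference (round-trip check)."""
    g1 = {c: bytearray(s, "ascii") for c, s in reference.items()}
    g2 = {c: bytearray(s, "ascii") for c, s in reference.items()}
    for row in table.itertuples(index=False):
        g1[row.chrom][row.pos - 1] = ord(row.g1_base)
        g2[row.chrom][row.pos - 1] = ord(row.g2_base)
    return (
        {c: s.decode("ascii") for c, s in g1.items()},
        {c: s.decode("ascii") for c, s in g2.items()},
    )
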