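"""Seed-complementarity target matching and variant-driven target diffs.

A site on a 3'UTR (read 5'->3') matches a miRNA when the six UTR bases are
the reverse complement of the miRNA seed (transcript nucleotides 2-7).
Canonical site classes follow the usual hierarchy: a 6mer is upgraded to
7mer-m8 when the base 5' of the site also pairs miRNA nucleotide 8, to
7mer-A1 when an adenosine faces miRNA nucleotide 1 (the base 3' of the
site), and to 8mer when both hold. G:U wobble pairs never count as
matches. No context scoring, conservation weighting or accessibility model
is applied: the prediction is pure seed complementarity.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Mapping

from .mirna_geometry import MirnaGene
from .variant_model import SNP, Variant

_RNA_COMPLEMENT = str.maketrans("ACGU", "UGCA")
_DNA_COMPLEMENT = str.maketrans("ACGT", "TGCA")

SITE_CLASSES = ("6mer", "7mer-A1", "7mer-m8", "8mer")


def to_rna(seq: str) -> str:
    """Upper-case and transliterate T->U so DNA and RNA input are equivalent."""
    return seq.upper().replace("T", "U")


def rna_revcomp(seq: str) -> str:
    return seq.translate(_RNA_COMPLEMENT)[::-1]


@dataclasses.dataclass(frozen=True)
class MatureSequence:
    """A mature miRNA transcript, 5'->3', with its derived seed (nt 2-7)."""

    name: str
    sequence: str

    def __post_init__(self):
        seq = to_rna(self.sequence)
        object.__setattr__(self, "sequence", seq)
        if len(seq) < 8:
            raise ValueError(f"mature sequence of {self.name} shorter than 8 nt")
        if set(seq) - set("ACGU"):
            raise ValueError(f"non-RNA characters in mature sequence of {self.name}")

    @property
    def seed(self) -> str:
        return self.sequence[1:7]


@dataclasses.dataclass(frozen=True)
class SeedSite:
    """One seed-match site on a transcript.

    ``position`` is the 1-based start of the 6-nt seed match in the UTR.
    """

    transcript: str
    position: int
    match_class: str


def seed_match(mature: MatureSequence, utr: str, transcript: str = "") -> list[SeedSite]:
    """All seed-complementary sites of ``mature`` on one UTR sequence."""
    utr = to_rna(utr)
    core = rna_revcomp(mature.seed)  # pairs miRNA nt 7..2, read 5'->3' on the UTR
    m8 = mature.sequence[7].translate(_RNA_COMPLEMENT)  # UTR base pairing nt 8
    sites = []
    n = len(utr)
    pos = utr.find(core)
    while pos != -1:
        has_m8 = pos >= 1 and utr[pos - 1] == m8
        has_a1 = pos + 6 < n and utr[pos + 6] == "A"
        if has_m8 and has_a1:
            cls = "8mer"
        elif has_m8:
            cls = "7mer-m8"
        elif has_a1:
            cls = "7mer-A1"
        else:
            cls = "6mer"
        sites.append(SeedSite(transcript=transcript, position=pos + 1, match_class=cls))
        pos = utr.find(core, pos + 1)
    return sites


def apply_variant_to_mature(
    gene: MirnaGene, arm_name: str, variant: Variant, genome
) -> MatureSequence:
    """Mature transcript sequence with a SNP's alternative base substituted.

    The genomic alt base is placed at the strand-correct transcript offset;
    on the - strand the substituted transcript base is the complement of
    the alt allele. Indels in arms are not supported and raise.
    """
    arms = dict(gene.mature_arms)
    if arm_name not in arms:
        raise ValueError(f"gene {gene.name} has no arm {arm_name!r}")
    arm = arms[arm_name]
    if variant.change != SNP:
        raise ValueError(
            f"only SNPs are supported in mature arms; got {variant.change} at "
            f"{variant.interval.chrom}:{variant.interval.start}"
        )
    pos = variant.interval.start
    if not (arm.start <= pos <= arm.end):
        raise ValueError(f"variant position {pos} outside arm {arm_name}")
    strand = gene.precursor.strand
    dna = genome.fetch(arm.chrom, arm.start, arm.end).upper()
    if strand == "+":
        offset = pos - arm.start
        base = variant.alt
        transcript_dna = dna
    else:
        offset = arm.end - pos
        base = variant.alt.translate(_DNA_COMPLEMENT)
        transcript_dna = dna.translate(_DNA_COMPLEMENT)[::-1]
    expected_ref = variant.ref if strand == "+" else variant.ref.translate(_DNA_COMPLEMENT)
    if transcript_dna[offset] != expected_ref:
        raise ValueError(
            f"reference allele mismatch at {arm.chrom}:{pos}: genome has "
            f"{transcript_dna[offset]} on the transcript strand, variant says "
            f"{expected_ref}"
        )
    seq = transcript_dna[:offset] + base + transcript_dna[offset + 1 :]
    return MatureSequence(name=f"{arm_name}|{variant.alt}", sequence=to_rna(seq))


def mature_from_genome(gene: MirnaGene, arm_name: str, genome) -> MatureSequence:
    """Reference mature transcript sequence of one arm, read off the genome."""
    arms = dict(gene.mature_arms)
    arm = arms[arm_name]
    dna = genome.fetch(arm.chrom, arm.start, arm.end).upper()
    if gene.precursor.strand == "-":
        dna = dna.translate(_DNA_COMPLEMENT)[::-1]
    return MatureSequence(name=arm_name, sequence=to_rna(dna))


@dataclasses.dataclass(frozen=True)
class TargetDiff:
    """Transcript-level consequence of swapping one mature allele for another."""

    gained: frozenset[str]
    lost: frozenset[str]
    retained: frozenset[str]


def diff_targets(
    ref: MatureSequence, alt: MatureSequence, utrs: Mapping[str, str]
) -> TargetDiff:
    """Targets gained, lost and retained when ``ref`` is replaced by ``alt``.

    A transcript is a target of a mature sequence when it carries at least
    one seed-match site. ``utrs`` maps transcript id to UTR sequence.
    """
    if len(ref.sequence) != len(alt.sequence):
        raise ValueError("ref and alt mature sequences must have equal length")
    ref_t = {t for t, u in utrs.items() if seed_match(ref, u, t)}
    alt_t = {t for t, u in utrs.items() if seed_match(alt, u, t)}
    return TargetDiff(
        gained=frozenset(alt_t - ref_t),
        lost=frozenset(ref_t - alt_t),
        retained=frozenset(ref_t & alt_t),
    )


def read_fasta_dict(path: str) -> dict[str, str]:
    """Load a FASTA file as an id -> sequence dict (Biopython parser)."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(path, "fasta")}
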