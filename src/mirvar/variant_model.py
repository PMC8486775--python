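"""Biallelic variant normalisation, allele-change classes and allele frequencies.

Only biallelic records enter the cascade; insertions or deletions of 60 bp
or more are structural variants and are excluded. Frequencies are computed
from called diploid genotypes, pooled over the panel and per breed.
"""

from __future__ import annotations

import dataclasses
import re
from typing import Mapping

from .intervals import GenomicInterval
from .io_formats import RawVcfRecord

SNP = "SNP"
INSERTION = "insertion"
DELETION = "deletion"
COMPLEX = "complex"

#: indel length at and above which an event counts as structural, not small
SV_LENGTH = 60

_NUC = re.compile(r"^[ACGTN]+$")


@dataclasses.dataclass
class Variant:
    """One biallelic allele record with genotype-derived frequencies.

    The interval spans the reference allele: ``[pos, pos + len(ref) - 1]``,
    so an insertion occupies only its single anchor base.
    """

    interval: GenomicInterval
    ref: str
    alt: str
    change: str
    indel_length: int
    af_overall: float
    af_by_breed: dict[str, float]
    n_called: int

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.interval.chrom_key, self.interval.start, self.ref, self.alt)


def classify_allele_change(ref: str, alt: str) -> tuple[str, int, bool]:
    """Classify a ref/alt pair as SNP, insertion, deletion or complex.

    Returns ``(change, indel_length, keep)`` where ``keep`` is False for
    indels of ``SV_LENGTH`` (60 bp) or more, which are structural variants
    outside the scope of the small-variant cascade.
    """
    if not _NUC.match(ref) or not _NUC.match(alt):
        raise ValueError(f"non-nucleotide allele: ref={ref!r} alt={alt!r}")
    indel_length = abs(len(ref) - len(alt))
    if len(ref) == len(alt):
        change = SNP if len(ref) == 1 else COMPLEX
    elif len(alt) > len(ref):
        change = INSERTION if alt.startswith(ref) or alt.endswith(ref) else COMPLEX
    else:
        change = DELETION if ref.startswith(alt) or ref.endswith(alt) else COMPLEX
    keep = indel_length < SV_LENGTH
    return change, indel_length, keep


class UndefinedFrequencyError(ValueError):
    """No called genotypes: the allele frequency is undefined."""


def allele_frequency(
    genotypes: Mapping[str, tuple[int | None, int | None]],
    breeds: Mapping[str, str],
) -> tuple[float, dict[str, float], int]:
    """Pooled and per-breed alternative-allele frequencies from genotypes.

    A sample contributes only when both alleles are called; missing
    genotypes are excluded from numerator and denominator alike. Breeds
    with no called samples are absent from the per-breed map.
    """
    alt_total = 0
    called_total = 0
    breed_alt: dict[str, int] = {}
    breed_called: dict[str, int] = {}
    for sample, gt in genotypes.items():
        if gt is None or any(a is None for a in gt):
            continue
        breed = breeds.get(sample, "unknown")
        alt = sum(1 for a in gt if a != 0)
        alt_total += alt
        called_total += 1
        breed_alt[breed] = breed_alt.get(breed, 0) + alt
        breed_called[breed] = breed_called.get(breed, 0) + 1
    if called_total == 0:
        raise UndefinedFrequencyError("no called genotypes")
    af_overall = alt_total / (2 * called_total)
    af_by_breed = {b: breed_alt[b] / (2 * breed_called[b]) for b in breed_called}
    return af_overall, af_by_breed, called_total


_SYMBOLIC = re.compile(r"[<>\[\]*.]")

#: drop reasons reported by :func:`normalise_record`
MULTI_ALLELIC = "multi_allelic"
SYMBOLIC_ALT = "symbolic_alt"
SV_INDEL = "sv_indel"
NO_CALLED_GENOTYPES = "no_called_genotypes"


def normalise_record(record: RawVcfRecord) -> tuple[Variant | None, str | None]:
    """Normalise a raw record to a biallelic :class:`Variant`, or say why not.

    Multi-allelic records are dropped whole (not decomposed), as are
    records whose single alt is symbolic (``<DEL>``, breakends), indels at
    or above the structural threshold, and records with no called
    genotypes (frequency undefined). Returns ``(variant, None)`` on
    success, ``(None, reason)`` otherwise.
    """
    if len(record.alts) != 1:
        return None, MULTI_ALLELIC
    alt = record.alts[0]
    if _SYMBOLIC.search(alt):
        return None, SYMBOLIC_ALT
    change, indel_length, keep = classify_allele_change(record.ref, alt)
    if not keep:
        return None, SV_INDEL
    try:
        af_overall, af_by_breed, n_called = allele_frequency(
            record.genotypes, record.sample_breeds
        )
    except UndefinedFrequencyError:
        return None, NO_CALLED_GENOTYPES
    iv = record.interval
    span = GenomicInterval(iv.chrom, iv.start, iv.start + len(record.ref) - 1, ".")
    variant = Variant(
        interval=span,
        ref=record.ref,
        alt=alt,
        change=change,
        indel_length=indel_length,
        af_overall=af_overall,
        af_by_breed=af_by_breed,
        n_called=n_called,
    )
    return variant, None


def split_biallelic(record: RawVcfRecord) -> list[Variant]:
    """List form of :func:`normalise_record`: one Variant, or empty when dropped."""
    variant, _ = normalise_record(record)
    return [variant] if variant is not None else []
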