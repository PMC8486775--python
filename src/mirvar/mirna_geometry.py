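"""Seed-interval derivation and variant localisation relative to miRNA genes.

The seed of a mature miRNA is nucleotides 2-7 counted from the 5' end of
the transcript, so on the genome it sits just inside the 5' edge of the
mature arm: positions ``[start+1, start+6]`` on the + strand and
``[end-6, end-1]`` on the - strand.

A variant's localisation is the most specific of
``seed < mature < precursor < flank50 < flank100 < flank500 < flank1000``,
using any-overlap semantics for multi-base spans: a deletion touching a
region counts as inside it. Insertions occupy only their single reference
anchor base.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

from intervaltree import IntervalTree

from .intervals import GenomicInterval
from .variant_model import Variant

SEED_LABELS = ("seed", "mature", "precursor")
DEFAULT_WINDOWS = (50, 100, 500, 1000)

#: total specificity order of localisation labels (most specific first)
LABEL_ORDER = (
    "seed",
    "mature",
    "precursor",
    "flank50",
    "flank100",
    "flank500",
    "flank1000",
    "none",
)


def seed_interval(mature: GenomicInterval, strand: str | None = None) -> GenomicInterval:
    """Genomic interval of the seed (transcript nucleotides 2-7) of a mature arm."""
    strand = strand or mature.strand
    if strand not in ("+", "-"):
        raise ValueError(f"seed derivation needs a strand, got {strand!r}")
    if len(mature) < 8:
        raise ValueError(
            f"mature arm of length {len(mature)} is too short to carry a seed"
        )
    if strand == "+":
        return GenomicInterval(mature.chrom, mature.start + 1, mature.start + 6, strand)
    return GenomicInterval(mature.chrom, mature.end - 6, mature.end - 1, strand)


@dataclasses.dataclass(frozen=True)
class MirnaGene:
    """A miRNA precursor with its 0-2 mature arms and derived seed intervals."""

    name: str
    precursor: GenomicInterval
    mature_arms: tuple[tuple[str, GenomicInterval], ...] = ()

    def __post_init__(self):
        for arm_name, arm in self.mature_arms:
            if not self.precursor.contains(arm):
                raise ValueError(
                    f"mature arm {arm_name} lies outside precursor {self.name}"
                )

    @property
    def seed_intervals(self) -> tuple[GenomicInterval, ...]:
        return tuple(
            seed_interval(arm, self.precursor.strand) for _, arm in self.mature_arms
        )


@dataclasses.dataclass(frozen=True)
class Localisation:
    """Where a variant falls relative to one miRNA gene."""

    label: str
    mirna: str
    distance_to_precursor: int

    def __post_init__(self):
        if self.label not in LABEL_ORDER:
            raise ValueError(f"unknown localisation label {self.label!r}")

    @property
    def rank(self) -> int:
        return LABEL_ORDER.index(self.label)


def variant_span(variant: Variant) -> GenomicInterval:
    """Reference-allele footprint of a variant (insertions: the anchor base)."""
    return variant.interval


def localise(
    variant: Variant,
    gene: MirnaGene,
    windows: Sequence[int] = DEFAULT_WINDOWS,
) -> Localisation:
    """Most specific localisation of ``variant`` relative to ``gene``.

    ``windows`` must be sorted ascending; a variant at gap distance d from
    the precursor (adjacent base = 1) gets the smallest window label with
    ``d <= w``, and ``none`` beyond the largest window.
    """
    span = variant_span(variant)
    if list(windows) != sorted(windows):
        raise ValueError("flank windows must be sorted ascending")
    d = span.gap_to(gene.precursor)
    if d is None:
        return Localisation("none", gene.name, 0)
    if d == 0:
        for seed in gene.seed_intervals:
            if span.overlaps(seed):
                return Localisation("seed", gene.name, 0)
        for _, arm in gene.mature_arms:
            if span.overlaps(arm):
                return Localisation("mature", gene.name, 0)
        if span.overlaps(gene.precursor):
            return Localisation("precursor", gene.name, 0)
        # gap 0 without overlap cannot happen for closed intervals
        raise AssertionError("zero gap without overlap")
    for w in windows:
        if d <= w:
            return Localisation(f"flank{w}", gene.name, d)
    return Localisation("none", gene.name, d)


class TrackIndex:
    """Interval-tree index over an unstranded track (CpG islands, TFBS, QTLs)."""

    def __init__(self, intervals: Iterable[GenomicInterval]):
        self._trees: dict[str, IntervalTree] = {}
        self._items: list[GenomicInterval] = []
        for iv in intervals:
            # closed [start, end] -> half-open [start, end+1)
            self._trees.setdefault(iv.chrom_key, IntervalTree()).addi(
                iv.start, iv.end + 1, len(self._items)
            )
            self._items.append(iv)

    def overlapping(self, span: GenomicInterval) -> list[int]:
        """Indices of track intervals sharing >= 1 base with ``span``, in input order."""
        tree = self._trees.get(span.chrom_key)
        if tree is None:
            return []
        return sorted(hit.data for hit in tree.overlap(span.start, span.end + 1))

    def hits(self, span: GenomicInterval) -> bool:
        return bool(self.overlapping(span))


def overlay_tracks(
    variant: Variant, cpg: TrackIndex | None, tfbs: TrackIndex | None
) -> tuple[bool, bool]:
    """Flags for strict overlap of the variant span with CpG and TFBS tracks."""
    span = variant_span(variant)
    in_cpg = cpg.hits(span) if cpg is not None else False
    in_tfbs = tfbs.hits(span) if tfbs is not None else False
    return in_cpg, in_tfbs


class GeneIndex:
    """Interval-tree index over precursors padded by the largest flank window."""

    def __init__(self, genes: Sequence[MirnaGene], max_window: int):
        self.genes = list(genes)
        self._trees: dict[str, IntervalTree] = {}
        for i, g in enumerate(self.genes):
            p = g.precursor
            lo = max(1, p.start - max_window)
            self._trees.setdefault(p.chrom_key, IntervalTree()).addi(
                lo, p.end + max_window + 1, i
            )

    def candidates(self, span: GenomicInterval) -> list[MirnaGene]:
        tree = self._trees.get(span.chrom_key)
        if tree is None:
            return []
        return [self.genes[h.data] for h in sorted(tree.overlap(span.start, span.end + 1))]


def localise_all(
    variant: Variant,
    index: GeneIndex,
    windows: Sequence[int] = DEFAULT_WINDOWS,
) -> list[Localisation]:
    """One localisation per miRNA gene within reach, most specific first.

    A variant overlapping two genes yields one entry per gene; entries with
    label ``none`` are omitted.
    """
    out = [
        loc
        for g in index.candidates(variant_span(variant))
        if (loc := localise(variant, g, windows)).label != "none"
    ]
    out.sort(key=lambda loc: (loc.rank, loc.mirna))
    return out
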