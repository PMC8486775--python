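"""The filtering cascade: from raw VCF records to annotated miRNA variants.

Stage order (the QTL stage is optional):

1. biallelic normalisation (multi-allelic, symbolic and structural-length
   records dropped; allele change classified);
2. miRNA localisation — keep variants whose span lies in a precursor,
   mature arm, seed, or within a flanking window of a precursor;
3. dairy/mastitis QTL intersection (when QTL regions are supplied);
4. miRNome membership of the localised miRNA name;
5. allele-frequency threshold (pooled by default, >= 0.01).

Also provides the Table-style nested summaries (seed <= mature <= precursor;
flank windows cumulative) and per-megabase density arithmetic.
"""

from __future__ import annotations

import dataclasses
import logging
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Mapping, Sequence

from .intervals import GenomicInterval
from .io_formats import RawVcfRecord
from .mirna_geometry import (
    DEFAULT_WINDOWS,
    GeneIndex,
    Localisation,
    MirnaGene,
    TrackIndex,
    localise_all,
    overlay_tracks,
    variant_span,
)
from .variant_model import Variant, normalise_record

logger = logging.getLogger(__name__)

#: trait synonym map, normalising prose labels to the controlled vocabulary
TRAIT_SYNONYMS = {
    "milk yield": "MILK",
    "fat yield": "FAT",
    "protein yield": "PROT",
    "quantity of proteins": "PROT",
    "fat content": "FC",
    "protein content": "PC",
    "somatic cell score": "SCS",
    "somatic cell count": "SCS",
    "clinical mastitis": "CM",
}

KNOWN_TRAITS = frozenset(
    {"MILK", "FAT", "PROT", "FC", "PC", "SCS", "CM"} | set(TRAIT_SYNONYMS.values())
)


def normalise_trait(trait: str) -> str:
    t = trait.strip()
    mapped = TRAIT_SYNONYMS.get(t.lower(), t)
    if mapped not in KNOWN_TRAITS:
        logger.warning("unknown QTL trait %r passed through verbatim", trait)
    return mapped


@dataclasses.dataclass(frozen=True)
class QtlRegion:
    """A dairy/mastitis QTL confidence interval with trait and breed labels."""

    interval: GenomicInterval
    trait: str
    breeds: frozenset[str] = frozenset()

    def __post_init__(self):
        if not self.trait:
            raise ValueError("QTL trait must be non-empty")


def qtl_regions_from_bed(
    regions: Iterable[tuple[GenomicInterval, Mapping[str, str]]]
) -> list[QtlRegion]:
    """Build QtlRegions from ``read_regions`` output (name=trait, extra1=breeds)."""
    out = []
    for iv, meta in regions:
        trait = normalise_trait(meta.get("name", ""))
        breeds = frozenset(
            b.strip() for b in meta.get("extra1", "").split(",") if b.strip()
        )
        out.append(QtlRegion(interval=iv, trait=trait, breeds=breeds))
    return out


def in_qtl(variant: Variant, qtls: Sequence[QtlRegion]) -> list[QtlRegion]:
    """All QTL regions whose interval shares at least one base with the variant."""
    span = variant_span(variant)
    return [q for q in qtls if q.interval.overlaps(span)]


class QtlIndex:
    """Interval-tree accelerated form of :func:`in_qtl` for the cascade."""

    def __init__(self, qtls: Sequence[QtlRegion]):
        self.qtls = list(qtls)
        self._index = TrackIndex(q.interval for q in self.qtls)

    def hits(self, span: GenomicInterval) -> list[QtlRegion]:
        return [self.qtls[i] for i in self._index.overlapping(span)]


@dataclasses.dataclass
class AnnotatedVariant:
    """A variant that survived the cascade, joined to one miRNA gene."""

    variant: Variant
    localisation: Localisation
    qtl_hits: list[QtlRegion]
    in_cpg: bool
    in_tfbs: bool
    breeds_polymorphic: frozenset[str]


@dataclasses.dataclass
class CascadeConfig:
    """Tunable knobs of the filtering cascade.

    min_af:
        pooled (or per-breed, see ``freq_mode``) alternative-allele
        frequency threshold, inclusive; default 0.01.
    freq_mode:
        ``"pooled"`` applies the threshold to the panel-wide frequency;
        ``"max-breed"`` passes a variant when any single breed reaches it.
    windows:
        flanking window sizes in bp, ascending.
    qtl_breed_match:
        when True, a variant is kept only if it is polymorphic in at least
        one breed listed on an overlapping QTL; off by default.
    flanks_include_gene:
        when True (default) the cumulative flank summaries count
        within-precursor variants as distance <= w.
    """

    min_af: float = 0.01
    freq_mode: str = "pooled"
    windows: tuple[int, ...] = DEFAULT_WINDOWS
    qtl_breed_match: bool = False
    flanks_include_gene: bool = True

    def __post_init__(self):
        if self.freq_mode not in ("pooled", "max-breed"):
            raise ValueError(f"unknown freq_mode {self.freq_mode!r}")
        if tuple(self.windows) != tuple(sorted(self.windows)):
            raise ValueError("windows must be ascending")


@dataclasses.dataclass
class FilterLog:
    """Input and surviving record counts at every cascade stage."""

    n_input: int = 0
    n_multi_allelic: int = 0
    n_symbolic: int = 0
    n_sv_indel: int = 0
    n_no_genotypes: int = 0
    n_biallelic: int = 0
    n_localised: int = 0
    n_in_qtl: int = 0
    n_in_mirnome: int = 0
    n_pass_frequency: int = 0

    def stage_counts(self, qtl_mode: bool) -> list[tuple[str, int]]:
        stages = [("input", self.n_input), ("biallelic", self.n_biallelic),
                  ("localised", self.n_localised)]
        if qtl_mode:
            stages.append(("in_qtl", self.n_in_qtl))
        stages += [("in_mirnome", self.n_in_mirnome),
                   ("pass_frequency", self.n_pass_frequency)]
        return stages


def _passes_frequency(variant: Variant, config: CascadeConfig) -> bool:
    if config.freq_mode == "pooled":
        return variant.af_overall >= config.min_af
    return any(f >= config.min_af for f in variant.af_by_breed.values())


def polymorphic_breeds(variant: Variant, min_af: float) -> frozenset[str]:
    """Breeds in which the alternative allele reaches the frequency threshold."""
    return frozenset(b for b, f in variant.af_by_breed.items() if f >= min_af)


def run_cascade(
    records: Iterable[RawVcfRecord],
    mirnas: Sequence[MirnaGene],
    mirnome: set[str],
    qtls: Sequence[QtlRegion] | None = None,
    cpg: TrackIndex | None = None,
    tfbs: TrackIndex | None = None,
    config: CascadeConfig | None = None,
) -> tuple[list[AnnotatedVariant], FilterLog]:
    """Run the full cascade over a stream of raw VCF records.

    Returns one :class:`AnnotatedVariant` per surviving (variant, miRNA)
    pair and the per-stage :class:`FilterLog`. With ``qtls=None`` the QTL
    stage is skipped entirely (the no-QTL mode of the pipeline).
    """
    config = config or CascadeConfig()
    if not mirnas:
        raise ValueError("empty miRNA annotation: nothing to localise against")
    if not mirnome:
        logger.warning("empty miRNome with non-empty annotation: result will be empty")
    qtl_mode = qtls is not None
    qtl_index = QtlIndex(qtls) if qtl_mode else None
    gene_index = GeneIndex(mirnas, max(config.windows))
    log = FilterLog()
    out: list[AnnotatedVariant] = []
    for record in records:
        log.n_input += 1
        variant, reason = normalise_record(record)
        if variant is None:
            if reason == "multi_allelic":
                log.n_multi_allelic += 1
            elif reason == "symbolic_alt":
                log.n_symbolic += 1
            elif reason == "sv_indel":
                log.n_sv_indel += 1
            else:
                log.n_no_genotypes += 1
            continue
        log.n_biallelic += 1

        locs = localise_all(variant, gene_index, config.windows)
        if not locs:
            continue
        log.n_localised += 1

        qtl_hits: list[QtlRegion] = []
        if qtl_mode:
            qtl_hits = qtl_index.hits(variant_span(variant))
            if config.qtl_breed_match and qtl_hits:
                poly = polymorphic_breeds(variant, config.min_af)
                qtl_hits = [q for q in qtl_hits if not q.breeds or (q.breeds & poly)]
            if not qtl_hits:
                continue
            log.n_in_qtl += 1

        locs = [loc for loc in locs if loc.mirna in mirnome]
        if not locs:
            continue
        log.n_in_mirnome += 1

        if not _passes_frequency(variant, config):
            continue
        log.n_pass_frequency += 1

        in_cpg, in_tfbs = overlay_tracks(variant, cpg, tfbs)
        breeds = polymorphic_breeds(variant, config.min_af)
        for loc in locs:
            out.append(
                AnnotatedVariant(
                    variant=variant,
                    localisation=loc,
                    qtl_hits=qtl_hits,
                    in_cpg=in_cpg,
                    in_tfbs=in_tfbs,
                    breeds_polymorphic=breeds,
                )
            )
    out.sort(
        key=lambda av: (
            av.variant.interval.chrom_key,
            av.variant.interval.start,
            av.variant.ref,
            av.variant.alt,
            av.localisation.mirna,
        )
    )
    for name, count in log.stage_counts(qtl_mode):
        logger.info("cascade stage %-14s %d", name, count)
    return out, log


@dataclasses.dataclass
class SummaryTables:
    """Nested cumulative counts in the style of the per-location tables.

    ``nested_counts[label] = (n_variants, n_distinct_mirnas)`` where the
    gene-internal chain is cumulative (mature includes seed, precursor
    includes mature) and each flank row includes all smaller windows plus,
    by default, the within-precursor variants.
    """

    nested_counts: dict[str, tuple[int, int]]
    cpg_counts: dict[str, tuple[int, int]]
    per_mb: float
    per_kb: float


def _nested_tally(
    annotated: Sequence[AnnotatedVariant],
    windows: Sequence[int],
    flanks_include_gene: bool,
    predicate=lambda av: True,
) -> dict[str, tuple[int, int]]:
    inside = {"seed": {"seed"}, "mature": {"seed", "mature"},
              "precursor": {"seed", "mature", "precursor"}}
    counts: dict[str, tuple[int, int]] = {}
    for label, members in inside.items():
        sel = [av for av in annotated
               if av.localisation.label in members and predicate(av)]
        counts[label] = (
            len({(av.variant.key, av.localisation.mirna) for av in sel}),
            len({av.localisation.mirna for av in sel}),
        )
    for w in windows:
        allowed = set(inside["precursor"]) if flanks_include_gene else set()
        allowed |= {f"flank{v}" for v in windows if v <= w}
        sel = [av for av in annotated
               if av.localisation.label in allowed and predicate(av)]
        counts[f"flank{w}"] = (
            len({(av.variant.key, av.localisation.mirna) for av in sel}),
            len({av.localisation.mirna for av in sel}),
        )
    return counts


def summarize(
    annotated: Sequence[AnnotatedVariant],
    span_bp: int | float | None = None,
    config: CascadeConfig | None = None,
) -> SummaryTables:
    """Nested location counts, CpG-restricted counts, and variant density.

    ``span_bp`` is the genomic span the variants were searched in (total
    QTL length in QTL mode); densities are 0 when it is not given.
    """
    config = config or CascadeConfig()
    nested = _nested_tally(annotated, config.windows, config.flanks_include_gene)
    cpg = _nested_tally(
        annotated, config.windows, config.flanks_include_gene, lambda av: av.in_cpg
    )
    n = len({(av.variant.key, av.localisation.mirna) for av in annotated})
    if span_bp:
        per_mb, per_kb = density(n, span_bp)
    else:
        per_mb = per_kb = 0.0
    return SummaryTables(nested_counts=nested, cpg_counts=cpg, per_mb=per_mb, per_kb=per_kb)


def _round2(x: float) -> float:
    return float(Decimal(repr(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def density(n_variants: int, span_bp: int | float) -> tuple[float, float]:
    """Variants per megabase and per kilobase, rounded half-up to 2 decimals."""
    if span_bp <= 0:
        raise ValueError("span must be positive")
    per_mb = _round2(n_variants / (span_bp / 1e6))
    per_kb = _round2(n_variants / (span_bp / 1e3))
    return per_mb, per_kb
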