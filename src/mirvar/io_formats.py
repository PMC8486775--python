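"""Readers and writers for the external formats the pipeline touches.

VCF 4.x (plain or bgzipped) is read through :mod:`pysam`; miRBase-dialect
GFF3 through :mod:`gffutils`; BED and TSV region files through plain column
parsing. All coordinates are normalised to the internal 1-based closed
convention of :class:`mirvar.intervals.GenomicInterval` at this boundary.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import gffutils
import pysam

from .intervals import GenomicInterval


class VcfParseError(ValueError):
    """Malformed VCF content; carries the 1-based line number when known."""


@dataclasses.dataclass
class RawVcfRecord:
    """One VCF body line, prior to biallelic splitting.

    ``genotypes`` maps sample name to a pair of allele indices (``None`` for
    a missing allele); ``sample_breeds`` maps sample name to breed label,
    with ``"unknown"`` for samples absent from the sidecar map.
    """

    interval: GenomicInterval
    ref: str
    alts: tuple[str, ...]
    genotypes: dict[str, tuple[int | None, int | None]]
    sample_breeds: dict[str, str]

    @property
    def pos(self) -> int:
        return self.interval.start


def _locate_bad_line(path: str | Path) -> int | None:
    """Best-effort scan for the first structurally invalid VCF body line."""
    opener = pysam.BGZFile if str(path).endswith((".gz", ".bgz")) else open
    try:
        with opener(str(path), "rb") as fh:
            for lineno, raw in enumerate(fh, start=1):
                line = raw.decode() if isinstance(raw, bytes) else raw
                if line.startswith("#") or not line.strip():
                    continue
                fields = line.rstrip("\n").split("\t")
                if len(fields) < 8:
                    return lineno
                try:
                    int(fields[1])
                except ValueError:
                    return lineno
    except OSError:
        return None
    return None


def read_vcf(
    path: str | Path, breed_map: Mapping[str, str] | None = None
) -> Iterator[RawVcfRecord]:
    """Stream records from a VCF file in file order.

    Positions are kept 1-based as in the file; multi-allelic records are
    yielded intact and split downstream. Samples absent from ``breed_map``
    are assigned breed ``"unknown"``.

    Raises
    ------
    VcfParseError
        On a malformed header or record (with the line number when it can
        be located), or when the file carries no GT format field, in which
        case allele frequencies cannot be computed.
    """
    breed_map = dict(breed_map or {})
    try:
        vf = pysam.VariantFile(str(path))
    except (ValueError, OSError) as exc:
        raise VcfParseError(f"cannot parse VCF header of {path}: {exc}") from exc
    if "GT" not in vf.header.formats:
        raise VcfParseError(
            f"{path} has no GT FORMAT field: allele frequencies cannot be computed"
        )
    samples = list(vf.header.samples)
    sample_breeds = {s: breed_map.get(s, "unknown") for s in samples}
    try:
        for rec in vf:
            if rec.alts is None or len(rec.alts) == 0:
                continue
            genotypes = {}
            for s in samples:
                gt = rec.samples[s].get("GT", (None, None))
                if gt is None:
                    gt = (None, None)
                genotypes[s] = tuple(gt)
            n_alleles = 1 + len(rec.alts)
            for s, gt in genotypes.items():
                for a in gt:
                    if a is not None and a >= n_alleles:
                        raise VcfParseError(
                            f"{path}: genotype index {a} out of range at "
                            f"{rec.chrom}:{rec.pos}"
                        )
            yield RawVcfRecord(
                interval=GenomicInterval(rec.chrom, rec.pos, rec.pos, "."),
                ref=rec.ref.upper(),
                alts=tuple(a.upper() for a in rec.alts),
                genotypes=genotypes,
                sample_breeds=sample_breeds,
            )
    except VcfParseError:
        raise
    except (ValueError, OSError) as exc:
        lineno = _locate_bad_line(path)
        where = f" at line {lineno}" if lineno is not None else ""
        raise VcfParseError(f"malformed VCF record in {path}{where}: {exc}") from exc


def read_breed_map(path: str | Path) -> dict[str, str]:
    """Read a two-column ``sample<TAB>breed`` sidecar file."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"breed map line needs 2 columns: {line!r}")
            out[fields[0]] = fields[1]
    return out


def read_regions(
    path: str | Path, dialect: str = "bed"
) -> list[tuple[GenomicInterval, dict[str, str]]]:
    """Read genomic regions from BED (0-based half-open) or 1-based TSV.

    BED ``[s, e)`` becomes internal ``[s+1, e]``. Columns beyond the third
    become metadata under keys ``name``, ``extra1``, ``extra2`` ... — QTL
    files use ``name`` for the trait and ``extra1`` for the breed list.
    """
    if dialect not in ("bed", "tsv_1based"):
        raise ValueError(f"unknown region dialect {dialect!r}")
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 columns")
            chrom = fields[0]
            try:
                a, b = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if dialect == "bed":
                start, end = a + 1, b
            else:
                start, end = a, b
            if end < start:
                raise ValueError(
                    f"{path}:{lineno}: empty or inverted interval [{a}, {b}]"
                )
            meta: dict[str, str] = {}
            for i, extra in enumerate(fields[3:]):
                meta["name" if i == 0 else f"extra{i}"] = extra
            out.append((GenomicInterval(chrom, start, end, "."), meta))
    return out


def write_regions_bed(
    regions: Sequence[tuple[GenomicInterval, Mapping[str, str]]], path: str | Path
) -> None:
    """Write internal intervals back to BED (inverse of ``read_regions``)."""
    with open(path, "w") as fh:
        for iv, meta in regions:
            extras = [meta[k] for k in sorted(meta, key=_meta_order)]
            fields = [iv.chrom, str(iv.start - 1), str(iv.end), *extras]
            fh.write("\t".join(fields) + "\n")


def _meta_order(key: str) -> int:
    return 0 if key == "name" else int(key.removeprefix("extra")) + 1


def read_mirna_annotation(path: str | Path):
    """Parse a miRBase-dialect GFF3 into :class:`~mirvar.mirna_geometry.MirnaGene`.

    Precursors are ``miRNA_primary_transcript`` features; mature arms are
    ``miRNA`` features linked to their precursor by ``Derives_from``. Each
    arm must lie inside its precursor and both must carry a strand.
    """
    from .mirna_geometry import MirnaGene  # deferred to avoid an import cycle

    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True, merge_strategy="error"
    )
    precursors: dict[str, gffutils.Feature] = {}
    for feat in db.features_of_type("miRNA_primary_transcript"):
        if feat.strand not in ("+", "-"):
            raise ValueError(f"precursor {feat.id} has no strand")
        precursors[feat.id] = feat
    arms: dict[str, list] = {pid: [] for pid in precursors}
    for feat in db.features_of_type("miRNA"):
        parents = feat.attributes.get("Derives_from", [])
        if not parents:
            raise ValueError(f"mature miRNA {feat.id} has no Derives_from parent")
        pid = parents[0]
        if pid not in precursors:
            raise ValueError(f"mature miRNA {feat.id} derives from unknown {pid}")
        parent = precursors[pid]
        if feat.start < parent.start or feat.end > parent.end:
            raise ValueError(
                f"mature miRNA {feat.id} [{feat.start},{feat.end}] lies outside "
                f"its precursor {pid} [{parent.start},{parent.end}]"
            )
        if feat.strand != parent.strand:
            raise ValueError(f"mature miRNA {feat.id} strand differs from {pid}")
        name = feat.attributes.get("Name", [feat.id])[0]
        arms[pid].append(
            (name, GenomicInterval(feat.seqid, feat.start, feat.end, feat.strand))
        )
    genes = []
    for pid, feat in precursors.items():
        name = feat.attributes.get("Name", [pid])[0]
        genes.append(
            MirnaGene(
                name=name,
                precursor=GenomicInterval(feat.seqid, feat.start, feat.end, feat.strand),
                mature_arms=tuple(arms[pid]),
            )
        )
    return genes


def read_mirnome(path: str | Path) -> set[str]:
    """Read a plain-text miRNome list, one miRNA name per line, ``#`` comments."""
    names = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                names.add(line)
    return names


REPORT_COLUMNS = [
    "chrom",
    "pos",
    "ref",
    "alt",
    "change",
    "breeds",
    "breed_frequencies",
    "af_overall",
    "mirna",
    "localisation",
    "qtl_traits",
    "in_cpg",
    "in_tfbs",
]


def write_report(rows, path: str | Path) -> None:
    """Write annotated variants as a TSV report.

    One row per (variant, miRNA) pair; breeds passing the frequency
    threshold and QTL traits are semicolon-joined within the row. Rows are
    sorted by (chrom, pos, miRNA name) so identical inputs always produce
    byte-identical reports.
    """
    import pandas as pd

    records = []
    for av in rows:
        v = av.variant
        records.append(
            {
                "chrom": v.interval.chrom,
                "pos": v.interval.start,
                "ref": v.ref,
                "alt": v.alt,
                "change": v.change,
                "breeds": ";".join(sorted(av.breeds_polymorphic)),
                "breed_frequencies": ";".join(
                    f"{b}={v.af_by_breed[b]:.4g}" for b in sorted(av.breeds_polymorphic)
                ),
                "af_overall": f"{v.af_overall:.4g}",
                "mirna": av.localisation.mirna,
                "localisation": av.localisation.label,
                "qtl_traits": ";".join(
                    sorted({q.trait for q in av.qtl_hits})
                ),
                "in_cpg": int(av.in_cpg),
                "in_tfbs": int(av.in_tfbs),
            }
        )
    df = pd.DataFrame.from_records(records, columns=REPORT_COLUMNS)
    if len(df):
        df = df.sort_values(["chrom", "pos", "mirna"], kind="mergesort")
    df.to_csv(path, sep="\t", index=False)
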