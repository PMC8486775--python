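"""Synthetic input bundles with planted, recomputed ground truth.

The generator emulates the shape of the real inputs — a multi-breed
whole-genome call set (biallelic and multi-allelic records, SNPs and
InDels including structural-length decoys), a miRBase-style annotation, a
mammary miRNome list, dairy QTL intervals with trait and breed labels and
CpG/TFBS tracks — at desk scale, so every stage of the cascade can be
verified end to end without any download.

Truth is defined by recomputation on the emitted records, not by intent:
after placing each variant the generator re-derives its localisation, QTL
overlap and realised allele frequency with the same geometry the pipeline
uses, and stores those. A placement that drifts from the intended class
(e.g. a deletion crossing a seed boundary) is therefore recorded under its
actual class, never as an approximation.

It does not emulate linkage disequilibrium, mutation-rate heterogeneity or
a realistic site-frequency spectrum.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

from .intervals import GenomicInterval
from .mirna_geometry import (
    DEFAULT_WINDOWS,
    GeneIndex,
    MirnaGene,
    TrackIndex,
    localise_all,
    seed_interval,
)
from .qtl_cascade import QtlIndex, QtlRegion
from .variant_model import Variant

_BASES = np.array(list("ACGT"))

TRAITS = ("MILK", "FAT", "PROT", "FC", "PC", "SCS", "CM")


@dataclasses.dataclass
class SynthConfig:
    """Knobs of the synthetic-bundle generator (all counts are intents).

    The planted per-class counts are chosen so a default bundle carries
    roughly 500 variant records, split across every localisation class the
    cascade distinguishes, with decoys for each drop reason.
    """

    seed: int = 0
    n_chroms: int = 2
    chrom_length: int = 40_000
    n_mirnas: int = 24
    precursor_length: tuple[int, int] = (70, 90)
    arms_per_precursor: tuple[int, int] = (1, 2)
    # planted variant counts per localisation class
    n_seed: int = 40
    n_mature: int = 60
    n_precursor: int = 80
    n_flank: dict[int, int] = dataclasses.field(
        default_factory=lambda: {50: 60, 100: 60, 500: 60, 1000: 60}
    )
    n_outside: int = 80
    windows: tuple[int, ...] = DEFAULT_WINDOWS
    # decoy and stratification fractions
    multi_allelic_fraction: float = 0.10
    indel_fraction: float = 0.15
    sv_indel_fraction: float = 0.03
    indel_lengths: tuple[int, ...] = (1, 2, 3)
    sv_indel_lengths: tuple[int, ...] = (60, 65, 75)
    fraction_below_af: float = 0.20
    fraction_gene_in_qtl: float = 0.5
    mirnome_fraction: float = 0.8
    min_af: float = 0.01
    breeds: dict[str, int] = dataclasses.field(
        default_factory=lambda: {"Holstein": 50, "Normande": 50, "Montbeliarde": 50}
    )
    n_cpg: int = 20
    n_tfbs: int = 20
    track_length: tuple[int, int] = (100, 400)

    @property
    def total_planted(self) -> int:
        return (
            self.n_seed
            + self.n_mature
            + self.n_precursor
            + sum(self.n_flank.values())
            + self.n_outside
        )


@dataclasses.dataclass
class Bundle:
    """Paths of one emitted input bundle."""

    root: Path
    genome: Path
    mirna_gff: Path
    mirnome: Path
    vcf: Path
    qtl_bed: Path
    cpg_bed: Path
    tfbs_bed: Path
    breeds_tsv: Path
    truth_tsv: Path


TRUTH_COLUMNS = [
    "chrom",
    "pos",
    "ref",
    "alt",
    "record_kind",  # biallelic | multi_allelic | sv_indel
    "change",
    "label",
    "mirna",
    "in_mirnome",
    "in_qtl",
    "af_realised",
    "af_stratum",  # above | below
    "expected_in_output",
]


def _rand_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=n)])


def _feasibility_check(cfg: SynthConfig, genes: list[MirnaGene]) -> None:
    seed_bases = sum(6 * len(g.mature_arms) for g in genes)
    mature_bases = sum(len(arm) for g in genes for _, arm in g.mature_arms)
    prec_bases = sum(len(g.precursor) for g in genes)
    if cfg.n_seed > seed_bases:
        raise ValueError(
            f"cannot plant {cfg.n_seed} seed variants in {seed_bases} seed bases"
        )
    if cfg.n_seed + cfg.n_mature > mature_bases:
        raise ValueError("more mature-class variants requested than mature bases")
    if cfg.total_planted - cfg.n_outside > prec_bases + 2 * sum(cfg.n_flank.values()):
        pass  # flank space is ample by construction; precursor space checked below
    if cfg.n_precursor + cfg.n_mature + cfg.n_seed > prec_bases:
        raise ValueError("more gene-internal variants requested than precursor bases")


def _place_genes(cfg: SynthConfig, rng: np.random.Generator) -> list[MirnaGene]:
    """Place precursors so no two genes' largest flank windows can touch."""
    max_w = max(cfg.windows)
    spacing = 2 * max_w + 200
    per_chrom = -(-cfg.n_mirnas // cfg.n_chroms)
    genes: list[MirnaGene] = []
    idx = 0
    for c in range(cfg.n_chroms):
        chrom = f"chr{c + 1}"
        cursor = max_w + 100
        for _ in range(per_chrom):
            if idx >= cfg.n_mirnas:
                break
            plen = int(rng.integers(cfg.precursor_length[0], cfg.precursor_length[1] + 1))
            start = cursor + int(rng.integers(0, 50))
            end = start + plen - 1
            if end + max_w + 100 > cfg.chrom_length:
                raise ValueError(
                    "chromosome too short for the requested gene count and spacing"
                )
            strand = "+" if rng.random() < 0.5 else "-"
            n_arms = int(
                rng.integers(cfg.arms_per_precursor[0], cfg.arms_per_precursor[1] + 1)
            )
            arms = []
            name = f"syn-miR-{idx + 1}"
            if n_arms == 1:
                arm_len = int(rng.integers(20, 25))
                a_start = start + int(rng.integers(2, plen - arm_len - 1))
                arms.append(
                    (f"{name}-5p",
                     GenomicInterval(chrom, a_start, a_start + arm_len - 1, strand))
                )
            else:
                # 5p arm near one end, 3p arm near the other, never touching
                arm_len = 22
                a1 = start + 2
                a2 = end - 2 - (arm_len - 1)
                if a2 <= a1 + arm_len:
                    a2 = a1 + arm_len + 1  # degenerate only for tiny precursors
                arms.append(
                    (f"{name}-5p", GenomicInterval(chrom, a1, a1 + arm_len - 1, strand))
                )
                arms.append(
                    (f"{name}-3p", GenomicInterval(chrom, a2, a2 + arm_len - 1, strand))
                )
            genes.append(
                MirnaGene(
                    name=name,
                    precursor=GenomicInterval(chrom, start, end, strand),
                    mature_arms=tuple(arms),
                )
            )
            cursor = end + spacing
            idx += 1
    return genes


def _planned_positions(
    cfg: SynthConfig, rng: np.random.Generator, genes: list[MirnaGene]
) -> list[tuple[str, int, str, str]]:
    """(chrom, pos, intended class, gene name) for every planted variant."""
    plans: list[tuple[str, int, str, str]] = []
    used: set[tuple[str, int]] = set()

    def take(chrom: str, lo: int, hi: int, n: int, label: str, gene: str):
        pool = np.array(
            [p for p in range(lo, hi + 1) if (chrom, p) not in used], dtype=int
        )
        rng.shuffle(pool)
        for p in (int(x) for x in pool[:n]):
            used.add((chrom, p))
            plans.append((chrom, p, label, gene))
        return min(n, len(pool))

    # gene-internal classes, spread round-robin over genes
    def spread(total: int, label: str, regions):
        remaining = total
        order = [int(x) for x in rng.permutation(len(regions))]
        i = 0
        while remaining > 0 and order:
            gi = order[i % len(order)]
            gene, lo, hi, chrom = regions[gi]
            got = take(chrom, lo, hi, 1, label, gene)
            if got == 0:
                order.remove(gi)
                continue
            remaining -= got
            i += 1
        if remaining > 0:
            raise ValueError(f"could not place all {label} variants")

    seeds = []
    matures = []
    precs = []
    for g in genes:
        chrom = g.precursor.chrom
        seed_pos = set()
        for arm_iv in g.seed_intervals:
            seeds.append((g.name, arm_iv.start, arm_iv.end, chrom))
            seed_pos.update(range(arm_iv.start, arm_iv.end + 1))
        arm_pos = set()
        for _, arm in g.mature_arms:
            arm_pos.update(range(arm.start, arm.end + 1))
        mature_only = sorted(arm_pos - seed_pos)
        for lo, hi in _runs(mature_only):
            matures.append((g.name, lo, hi, chrom))
        prec_only = sorted(
            set(range(g.precursor.start, g.precursor.end + 1)) - arm_pos
        )
        for lo, hi in _runs(prec_only):
            precs.append((g.name, lo, hi, chrom))

    spread(cfg.n_seed, "seed", seeds)
    spread(cfg.n_mature, "mature", matures)
    spread(cfg.n_precursor, "precursor", precs)

    # flank classes: distance drawn within (w_prev, w] on a random side
    for w, count in cfg.n_flank.items():
        wi = cfg.windows.index(w)
        lo_d = 1 if wi == 0 else cfg.windows[wi - 1] + 1
        placed = 0
        attempts = 0
        while placed < count:
            attempts += 1
            if attempts > 100 * count:
                raise ValueError(f"could not place all flank{w} variants")
            g = genes[int(rng.integers(0, len(genes)))]
            d = int(rng.integers(lo_d, w + 1))
            side = -1 if rng.random() < 0.5 else 1
            pos = g.precursor.start - d if side < 0 else g.precursor.end + d
            chrom = g.precursor.chrom
            if pos < 1 or pos > cfg.chrom_length or (chrom, pos) in used:
                continue
            used.add((chrom, pos))
            plans.append((chrom, pos, f"flank{w}", g.name))
            placed += 1

    # outside: beyond the largest window from every precursor
    max_w = max(cfg.windows)
    placed = 0
    attempts = 0
    while placed < cfg.n_outside:
        attempts += 1
        if attempts > 100 * cfg.n_outside:
            raise ValueError("could not place all outside variants")
        chrom = f"chr{int(rng.integers(0, cfg.n_chroms)) + 1}"
        pos = int(rng.integers(1, cfg.chrom_length + 1))
        if (chrom, pos) in used:
            continue
        span = GenomicInterval(chrom, pos, pos)
        gaps = (span.gap_to(g.precursor) for g in genes)
        if any(d is not None and d <= max_w for d in gaps):
            continue
        used.add((chrom, pos))
        plans.append((chrom, pos, "outside", ""))
        placed += 1
    return plans


def _runs(sorted_positions):
    """Maximal consecutive runs [(lo, hi), ...] of a sorted position list."""
    runs = []
    for p in sorted_positions:
        if runs and p == runs[-1][1] + 1:
            runs[-1][1] = p
        else:
            runs.append([p, p])
    return [tuple(r) for r in runs]


def _draw_genotype_columns(
    rng: np.random.Generator, cfg: SynthConfig, planned_af: float
) -> tuple[dict[str, list[int]], float, dict[str, float]]:
    """Binomial genotypes per breed around ``planned_af``; realised af returned."""
    counts: dict[str, list[int]] = {}
    total_alt = 0
    total_alleles = 0
    by_breed: dict[str, float] = {}
    for breed, n in cfg.breeds.items():
        p = min(1.0, max(0.0, planned_af * float(rng.uniform(0.5, 1.5))))
        alts = rng.binomial(2, p, size=n)
        counts[breed] = [int(a) for a in alts]
        total_alt += int(alts.sum())
        total_alleles += 2 * n
        by_breed[breed] = float(alts.sum()) / (2 * n)
    return counts, total_alt / total_alleles, by_breed


def _gt_string(n_alt: int, alt_index: int = 1) -> str:
    if n_alt == 0:
        return "0/0"
    if n_alt == 1:
        return f"0/{alt_index}"
    return f"{alt_index}/{alt_index}"


def generate_dataset(config: SynthConfig, out_dir: str | Path) -> tuple[Bundle, pd.DataFrame]:
    """Emit a complete input bundle under ``out_dir`` and return its truth table.

    Deterministic for a given ``config.seed``. The truth table records, per
    emitted variant record, the recomputed localisation label and gene, the
    miRNome and QTL flags, the realised pooled allele frequency and its
    stratum, and whether the QTL-mode cascade is expected to keep it.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)

    genes = _place_genes(config, rng)
    _feasibility_check(config, genes)

    # genome, with gene placements independent of sequence content
    genome = {f"chr{c + 1}": _rand_seq(rng, config.chrom_length)
              for c in range(config.n_chroms)}

    # miRNome membership: a deterministic subset of gene names
    names = [g.name for g in genes]
    n_in = max(1, int(round(config.mirnome_fraction * len(names))))
    member_idx = rng.choice(len(names), size=n_in, replace=False)
    mirnome = {names[i] for i in member_idx}

    # QTLs cover the full flank neighbourhood of a subset of genes
    max_w = max(config.windows)
    qtls: list[QtlRegion] = []
    for g in genes:
        if rng.random() < config.fraction_gene_in_qtl:
            trait = TRAITS[int(rng.integers(0, len(TRAITS)))]
            breeds = frozenset(
                b for b in config.breeds if rng.random() < 0.7
            ) or frozenset(list(config.breeds)[:1])
            lo = max(1, g.precursor.start - max_w - 20)
            hi = min(config.chrom_length, g.precursor.end + max_w + 20)
            qtls.append(
                QtlRegion(GenomicInterval(g.precursor.chrom, lo, hi), trait, breeds)
            )
    qtl_index = QtlIndex(qtls)

    # CpG / TFBS tracks at random positions
    def _random_track(n: int) -> list[GenomicInterval]:
        out = []
        for _ in range(n):
            chrom = f"chr{int(rng.integers(0, config.n_chroms)) + 1}"
            length = int(rng.integers(config.track_length[0], config.track_length[1] + 1))
            start = int(rng.integers(1, config.chrom_length - length))
            out.append(GenomicInterval(chrom, start, start + length - 1))
        return out

    cpg = _random_track(config.n_cpg)
    tfbs = _random_track(config.n_tfbs)

    plans = _planned_positions(config, rng, genes)
    gene_index = GeneIndex(genes, max_w)

    rows = []
    vcf_rows = []
    sample_names = [
        f"{breed[:3].upper()}{i + 1:03d}"
        for breed, n in config.breeds.items()
        for i in range(n)
    ]
    breed_of = {
        f"{breed[:3].upper()}{i + 1:03d}": breed
        for breed, n in config.breeds.items()
        for i in range(n)
    }

    for chrom, pos, intended, gene_name in plans:
        seq = genome[chrom]
        ref_base = seq[pos - 1]
        u = rng.random()
        kind = "biallelic"
        if u < config.multi_allelic_fraction:
            kind = "multi_allelic"
        elif u < config.multi_allelic_fraction + config.sv_indel_fraction:
            kind = "sv_indel"

        if kind == "sv_indel":
            length = int(
                config.sv_indel_lengths[rng.integers(0, len(config.sv_indel_lengths))]
            )
            if rng.random() < 0.5 and pos + length <= len(seq):
                ref, alt = seq[pos - 1 : pos - 1 + length + 1], ref_base
            else:
                ref, alt = ref_base, ref_base + _rand_seq(rng, length)
            alts = [alt]
            change = "sv_indel"
        elif rng.random() < config.indel_fraction:
            length = int(config.indel_lengths[rng.integers(0, len(config.indel_lengths))])
            if rng.random() < 0.5 and pos + length <= len(seq):
                ref, alt = seq[pos - 1 : pos - 1 + length + 1], ref_base
                change = "deletion"
            else:
                ref, alt = ref_base, ref_base + _rand_seq(rng, length)
                change = "insertion"
            alts = [alt]
        else:
            choices = [b for b in "ACGT" if b != ref_base]
            ref = ref_base
            alt = choices[int(rng.integers(0, 3))]
            alts = [alt]
            change = "SNP"
        if kind == "multi_allelic":
            extra = [b for b in "ACGT" if b not in (ref[0], alts[0][0])][0]
            alts = [alts[0], extra]

        below = rng.random() < config.fraction_below_af
        planned = float(rng.uniform(0.001, 0.008)) if below else float(rng.uniform(0.05, 0.9))
        counts, af_realised, _ = _draw_genotype_columns(rng, config, planned)
        stratum = "above" if af_realised >= config.min_af else "below"

        # recomputed truth: geometry and QTL overlap on the emitted record
        span = GenomicInterval(chrom, pos, pos + len(ref) - 1)
        probe = Variant(span, ref, alts[0], "SNP", 0, af_realised, {}, 0)
        locs = localise_all(probe, gene_index, config.windows)
        label = locs[0].label if locs else "none"
        mirna = locs[0].mirna if locs else ""
        in_qtl_flag = bool(qtl_index.hits(span))
        in_mirnome = mirna in mirnome if mirna else False
        expected = (
            kind == "biallelic"
            and change != "sv_indel"
            and label != "none"
            and in_qtl_flag
            and in_mirnome
            and stratum == "above"
        )
        rows.append(
            dict(
                chrom=chrom,
                pos=pos,
                ref=ref,
                alt=",".join(alts),
                record_kind=kind,
                change=change,
                label=label,
                mirna=mirna,
                in_mirnome=in_mirnome,
                in_qtl=in_qtl_flag,
                af_realised=af_realised,
                af_stratum=stratum,
                expected_in_output=expected,
            )
        )
        gts = []
        for breed, n in config.breeds.items():
            alt_idx = 1 if kind == "biallelic" else int(rng.integers(1, len(alts) + 1))
            gts.extend(_gt_string(a, alt_idx) for a in counts[breed])
        vcf_rows.append((chrom, pos, ref, ",".join(alts), gts))

    truth = pd.DataFrame(rows, columns=TRUTH_COLUMNS)

    bundle = _write_bundle(
        out_dir, genome, genes, mirnome, vcf_rows, qtls, cpg, tfbs,
        sample_names, breed_of, truth,
    )
    return bundle, truth


def _write_bundle(
    out_dir: Path, genome, genes, mirnome, vcf_rows, qtls, cpg, tfbs,
    sample_names, breed_of, truth,
) -> Bundle:
    genome_p = out_dir / "genome.fa"
    with open(genome_p, "w") as fh:
        for chrom in sorted(genome):
            fh.write(f">{chrom}\n")
            seq = genome[chrom]
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")

    gff_p = out_dir / "mirna.gff3"
    with open(gff_p, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, g in enumerate(genes):
            p = g.precursor
            pid = f"MI{i + 1:05d}"
            fh.write(
                f"{p.chrom}\t.\tmiRNA_primary_transcript\t{p.start}\t{p.end}\t.\t"
                f"{p.strand}\t.\tID={pid};Name={g.name}\n"
            )
            for j, (arm_name, arm) in enumerate(g.mature_arms):
                fh.write(
                    f"{arm.chrom}\t.\tmiRNA\t{arm.start}\t{arm.end}\t.\t{p.strand}\t.\t"
                    f"ID=MIMAT{i + 1:05d}{j};Name={arm_name};Derives_from={pid}\n"
                )

    mirnome_p = out_dir / "mirnome.txt"
    with open(mirnome_p, "w") as fh:
        fh.write("# miRNAs expressed in the mammary gland or present in milk\n")
        for name in sorted(mirnome):
            fh.write(name + "\n")

    vcf_p = out_dir / "variants.vcf"
    with open(vcf_p, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in sorted(genome):
            fh.write(f"##contig=<ID={chrom},length={len(genome[chrom])}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(sample_names) + "\n")
        for chrom, pos, ref, alts, gts in sorted(vcf_rows, key=lambda r: (r[0], r[1])):
            fh.write(
                f"{chrom}\t{pos}\t.\t{ref}\t{alts}\t.\tPASS\t.\tGT\t" + "\t".join(gts) + "\n"
            )

    qtl_p = out_dir / "qtl.bed"
    with open(qtl_p, "w") as fh:
        for q in qtls:
            iv = q.interval
            fh.write(
                f"{iv.chrom}\t{iv.start - 1}\t{iv.end}\t{q.trait}\t"
                f"{','.join(sorted(q.breeds))}\n"
            )

    def _write_track(path: Path, track):
        with open(path, "w") as fh:
            for iv in sorted(track, key=lambda t: (t.chrom, t.start)):
                fh.write(f"{iv.chrom}\t{iv.start - 1}\t{iv.end}\n")

    cpg_p = out_dir / "cpg.bed"
    tfbs_p = out_dir / "tfbs.bed"
    _write_track(cpg_p, cpg)
    _write_track(tfbs_p, tfbs)

    breeds_p = out_dir / "breeds.tsv"
    with open(breeds_p, "w") as fh:
        for s in sample_names:
            fh.write(f"{s}\t{breed_of[s]}\n")

    truth_p = out_dir / "truth.tsv"
    truth.to_csv(truth_p, sep="\t", index=False)

    return Bundle(
        root=out_dir, genome=genome_p, mirna_gff=gff_p, mirnome=mirnome_p,
        vcf=vcf_p, qtl_bed=qtl_p, cpg_bed=cpg_p, tfbs_bed=tfbs_p,
        breeds_tsv=breeds_p, truth_tsv=truth_p,
    )


# --------------------------------------------------------------------------
# Printed-table fixture: the 26 bovine precursor variants in dairy QTLs
# --------------------------------------------------------------------------

# (chrom, pos, ref, alt, [(breed, af), ...], miRNA, [traits], localisation)
# The two rows with ambiguous multi-nucleotide allele columns are encoded as
# one single-nucleotide insertion (chr5:118,347,364) and one
# single-nucleotide deletion (chr19:38,542,897), consistent with the
# class totals (22 SNPs, insertions of one and two nucleotides, two
# single-nucleotide deletions); the SNP tally is invariant to either reading.
BOVINE_QTL_VARIANT_ROWS = [
    ("3", 102923794, "G", "A", [("Holstein", 0.136)], "bta-miR-2415", ["MILK", "PROT"], "precursor"),
    ("4", 114614954, "T", "G", [("Holstein", 0.047)], "bta-miR-671", ["MILK", "FC"], "precursor"),
    ("5", 30251690, "G", "C", [("Holstein", 0.673)], "bta-miR-2425", ["PROT"], "precursor"),
    ("5", 30952192, "T", "G", [("Holstein", 0.038)], "bta-miR-2426", ["PROT"], "precursor"),
    ("5", 62117780, "G", "A", [("Holstein", 0.019)], "bta-miR-135a-2", ["FC"], "precursor"),
    ("5", 84244517, "G", "A", [("Holstein", 0.071), ("Montbeliarde", 0.017)], "bta-miR-2436", ["FC", "FAT"], "precursor"),
    ("5", 101542291, "C", "T", [("Holstein", 0.019)], "bta-miR-2284r", ["FAT"], "precursor"),
    ("5", 118347364, "C", "CT", [("Holstein", 0.012)], "bta-miR-2284h", ["PROT"], "precursor"),
    ("6", 99976608, "T", "C", [("Normande", 0.048)], "bta-miR-2446", ["PROT"], "mature"),
    ("6", 99976613, "G", "A", [("Holstein", 0.013)], "bta-miR-2446", ["PROT"], "precursor"),
    ("7", 50687460, "T", "C", [("Holstein", 0.210)], "bta-miR-874", ["FC"], "precursor"),
    ("7", 63886927, "C", "CCA", [("Holstein", 0.026)], "bta-miR-2461", ["PROT", "FC"], "mature"),
    ("15", 34628957, "C", "T", [("Holstein", 0.296)], "bta-miR-2313", ["FC"], "precursor"),
    ("18", 56407853, "TC", "T", [("Holstein", 0.056)], "bta-miR-150", ["PROT"], "precursor"),
    ("18", 56407916, "T", "G", [("Holstein", 0.013)], "bta-miR-150", ["PROT"], "mature"),
    ("18", 58015050, "G", "A", [("Holstein", 0.051)], "bta-let-7e", ["PROT"], "seed"),
    ("18", 61145895, "G", "T", [("Normande", 0.012)], "bta-miR-371", ["PROT"], "precursor"),
    ("19", 38542897, "CG", "C", [("Holstein", 0.304)], "bta-miR-2886", ["PROT", "SCS"], "mature"),
    ("19", 39081170, "T", "C", [("Holstein", 0.903)], "bta-miR-152", ["SCS"], "precursor"),
    ("20", 23967291, "G", "T", [("Normande", 0.083)], "bta-miR-449b", ["FAT"], "seed"),
    ("20", 23967292, "T", "A", [("Normande", 0.083)], "bta-miR-449b", ["FAT"], "mature"),
    ("21", 36134549, "C", "T", [("Montbeliarde", 0.121)], "bta-miR-2888-1", ["PROT"], "precursor"),
    ("21", 36134560, "T", "G", [("Montbeliarde", 0.044)], "bta-miR-2888-1", ["PROT"], "mature"),
    ("25", 35300154, "G", "C", [("Holstein", 0.051)], "bta-miR-2388", ["PROT"], "precursor"),
    ("25", 35300168, "G", "A", [("Holstein", 0.756)], "bta-miR-2388", ["PROT"], "precursor"),
    ("29", 45520815, "C", "T", [("Holstein", 0.294)], "bta-miR-2408", ["PROT"], "precursor"),
]

FIXTURE_BREEDS = ("Holstein", "Normande", "Montbeliarde")
FIXTURE_PANEL_SIZE = 50  # samples per breed: 3-decimal frequencies within 1/(2n)


def _fit_gene_geometry(name: str, rows) -> MirnaGene:
    """Construct a precursor + single arm consistent with each row's printed label.

    The arm start is found by scanning all placements of a 22-nt arm inside
    the precursor until every seed row falls in transcript nucleotides 2-7,
    every mature row in the arm but outside the seed, and every precursor
    row outside the arm (any-overlap semantics, + strand).
    """
    chrom = rows[0][0]
    spans = [(pos, pos + len(ref) - 1, label) for _, pos, ref, label in
             ((r[0], r[1], r[2], r[7]) for r in rows)]
    lo = min(s for s, _, _ in spans) - 30
    hi = max(e for _, e, _ in spans) + 30
    precursor = GenomicInterval(chrom, lo, hi, "+")
    arm_len = 22
    for m_s in range(lo + 1, hi - arm_len + 1):
        arm = GenomicInterval(chrom, m_s, m_s + arm_len - 1, "+")
        seed = seed_interval(arm, "+")
        ok = True
        for s, e, label in spans:
            in_seed = s <= seed.end and seed.start <= e
            in_arm = s <= arm.end and arm.start <= e
            if label == "seed" and not in_seed:
                ok = False
            elif label == "mature" and (in_seed or not in_arm):
                ok = False
            elif label == "precursor" and in_arm:
                ok = False
            if not ok:
                break
        if ok:
            return MirnaGene(
                name=name, precursor=precursor,
                mature_arms=((f"{name}-arm", arm),),
            )
    raise AssertionError(f"no arm placement satisfies the printed labels of {name}")


def bovine_qtl_fixture(out_dir: str | Path) -> Bundle:
    """Emit the 26-variant bovine fixture bundle under ``out_dir``.

    VCF positions, alleles and per-breed frequencies follow the printed
    rows (genotypes are synthesised so each frequency is reproduced to the
    nearest allele count in a 50-samples-per-breed panel); the annotation
    is synthetic geometry placing every variant in its printed
    localisation; the QTL file carries the printed traits; the miRNome
    lists all 21 names. The fixture's genome sequence is synthetic.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    by_gene: dict[str, list] = {}
    for row in BOVINE_QTL_VARIANT_ROWS:
        by_gene.setdefault(row[5], []).append(row)
    genes = [_fit_gene_geometry(name, rows) for name, rows in by_gene.items()]

    # verify the constructed geometry reproduces every printed localisation
    gene_index = GeneIndex(genes, max(DEFAULT_WINDOWS))
    for chrom, pos, ref, alt, _, mirna, _, label in BOVINE_QTL_VARIANT_ROWS:
        probe = Variant(
            GenomicInterval(chrom, pos, pos + len(ref) - 1), ref, alt, "SNP", 0, 1.0, {}, 0
        )
        locs = [l for l in localise_all(probe, gene_index) if l.mirna == mirna]
        assert locs and locs[0].label == label, (mirna, pos, label, locs)

    sample_names = [
        f"{b[:3].upper()}{i + 1:03d}" for b in FIXTURE_BREEDS
        for i in range(FIXTURE_PANEL_SIZE)
    ]
    breed_of = {s: b for b in FIXTURE_BREEDS for s in sample_names if s.startswith(b[:3].upper())}

    vcf_p = out_dir / "variants.vcf"
    chrom_order = {c: i for i, c in enumerate(
        sorted({r[0] for r in BOVINE_QTL_VARIANT_ROWS}, key=int))}
    with open(vcf_p, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in sorted(chrom_order, key=chrom_order.get):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(sample_names) + "\n")
        for chrom, pos, ref, alt, freqs, *_ in sorted(
            BOVINE_QTL_VARIANT_ROWS, key=lambda r: (chrom_order[r[0]], r[1])
        ):
            af = dict(freqs)
            gts = []
            for breed in FIXTURE_BREEDS:
                n_alt = int(round(af.get(breed, 0.0) * 2 * FIXTURE_PANEL_SIZE))
                homs, het = divmod(n_alt, 2)
                col = ["1/1"] * homs + ["0/1"] * het
                col += ["0/0"] * (FIXTURE_PANEL_SIZE - len(col))
                gts.extend(col)
            fh.write(
                f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT\t" + "\t".join(gts) + "\n"
            )

    gff_p = out_dir / "mirna.gff3"
    with open(gff_p, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, g in enumerate(genes):
            p = g.precursor
            pid = f"MI9{i + 1:04d}"
            fh.write(
                f"{p.chrom}\t.\tmiRNA_primary_transcript\t{p.start}\t{p.end}\t.\t+"
                f"\t.\tID={pid};Name={g.name}\n"
            )
            for j, (arm_name, arm) in enumerate(g.mature_arms):
                fh.write(
                    f"{arm.chrom}\t.\tmiRNA\t{arm.start}\t{arm.end}\t.\t+\t.\t"
                    f"ID=MIMAT9{i + 1:04d}{j};Name={arm_name};Derives_from={pid}\n"
                )

    mirnome_p = out_dir / "mirnome.txt"
    with open(mirnome_p, "w") as fh:
        for name in sorted(by_gene):
            fh.write(name + "\n")

    qtl_p = out_dir / "qtl.bed"
    with open(qtl_p, "w") as fh:
        for chrom, pos, ref, _, freqs, _, traits, _ in BOVINE_QTL_VARIANT_ROWS:
            for trait in traits:
                fh.write(
                    f"{chrom}\t{pos - 1001}\t{pos + 1000}\t{trait}\t"
                    f"{','.join(b for b, _ in freqs)}\n"
                )

    cpg_p = out_dir / "cpg.bed"
    tfbs_p = out_dir / "tfbs.bed"
    cpg_p.write_text("")
    tfbs_p.write_text("")

    breeds_p = out_dir / "breeds.tsv"
    with open(breeds_p, "w") as fh:
        for s in sample_names:
            fh.write(f"{s}\t{breed_of[s]}\n")

    return Bundle(
        root=out_dir, genome=out_dir / "genome.fa", mirna_gff=gff_p,
        mirnome=mirnome_p, vcf=vcf_p, qtl_bed=qtl_p, cpg_bed=cpg_p,
        tfbs_bed=tfbs_p, breeds_tsv=breeds_p, truth_tsv=out_dir / "truth.tsv",
    )
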