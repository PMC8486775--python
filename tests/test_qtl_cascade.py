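import random

import pytest

from mirvar import io_formats, qtl_cascade
from mirvar.intervals import GenomicInterval
from mirvar.mirna_geometry import MirnaGene
from mirvar.qtl_cascade import CascadeConfig, QtlRegion, density, in_qtl, run_cascade, summarize

from conftest import snp, write_vcf


def qtl(chrom, start, end, trait="PROT", breeds=()):
    return QtlRegion(GenomicInterval(chrom, start, end), trait, frozenset(breeds))


class TestInQtl:
    def test_inside_one(self):
        q = qtl("chr1", 100, 200)
        assert in_qtl(snp("chr1", 150), [q]) == [q]

    def test_overlap_of_two_reports_both(self):
        q1, q2 = qtl("chr1", 100, 200, "PROT"), qtl("chr1", 150, 300, "FC")
        assert in_qtl(snp("chr1", 180), [q1, q2]) == [q1, q2]

    def test_one_bp_outside_is_empty(self):
        assert in_qtl(snp("chr1", 201), [qtl("chr1", 100, 200)]) == []

    def test_index_agrees_with_linear_scan(self):
        rng = random.Random(5)
        qtls = []
        for _ in range(30):
            s = rng.randint(1, 8000)
            qtls.append(qtl(f"chr{rng.randint(1, 2)}", s, s + rng.randint(10, 800)))
        index = qtl_cascade.QtlIndex(qtls)
        for _ in range(1000):
            v = snp(f"chr{rng.randint(1, 2)}", rng.randint(1, 9000))
            assert index.hits(v.interval) == in_qtl(v, qtls)


class TestDensity:
    @pytest.mark.parametrize(
        "n,span_bp,per_mb",
        [
            (4679, 401.5e6, 11.65),
            (127, 18.0e6, 7.06),
            (0, 1e6, 0.0),
        ],
    )
    def test_per_megabase(self, n, span_bp, per_mb):
        assert density(n, span_bp)[0] == pytest.approx(per_mb)

    def test_per_kb(self):
        assert density(2180, 100e3)[1] == pytest.approx(21.8)

    def test_zero_span_is_an_error(self):
        with pytest.raises(ValueError):
            density(10, 0)

    def test_rounding_is_half_up(self):
        assert density(125, 1e7)[0] == 12.5
        assert density(1, 8e6)[0] == 0.13  # 0.125 rounds up, not to even


GFF = (
    "##gff-version 3\n"
    "chr1\t.\tmiRNA_primary_transcript\t1000\t1080\t.\t+\t.\tID=MI1;Name=mir-A\n"
    "chr1\t.\tmiRNA\t1010\t1031\t.\t+\t.\tID=MA1;Name=mir-A-5p;Derives_from=MI1\n"
    "chr2\t.\tmiRNA_primary_transcript\t5000\t5080\t.\t-\t.\tID=MI2;Name=mir-B\n"
    "chr2\t.\tmiRNA\t5040\t5061\t.\t-\t.\tID=MA2;Name=mir-B-3p;Derives_from=MI2\n"
)


@pytest.fixture
def mini_inputs(tmp_path):
    gff = tmp_path / "m.gff3"
    gff.write_text(GFF)
    mirnas = io_formats.read_mirna_annotation(gff)
    vcf = write_vcf(
        tmp_path / "v.vcf",
        [
            # seed of mir-A (1011-1016)
            "chr1\t1012\t.\tG\tA\t.\t.\t.\tGT\t0/1\t0/1\t0/0",
            # precursor of mir-A, multi-allelic: dropped at stage 1
            "chr1\t1050\t.\tG\tA,T\t.\t.\t.\tGT\t0/1\t0/2\t0/0",
            # flank100 of mir-A (60 bp upstream)
            "chr1\t940\t.\tC\tT\t.\t.\t.\tGT\t0/1\t0/0\t0/0",
            # far from any gene
            "chr1\t20000\t.\tC\tT\t.\t.\t.\tGT\t0/1\t0/1\t1/1",
            # mature (non-seed) of mir-B; seed is 5055-5060, arm 5040-5061
            "chr2\t5045\t.\tA\tG\t.\t.\t.\tGT\t1/1\t0/1\t0/0",
            # below frequency threshold in the precursor of mir-B
            "chr2\t5002\t.\tT\tC\t.\t.\t.\tGT\t0/0\t0/0\t0/0",
        ],
    )
    breeds = {"S1": "Holstein", "S2": "Holstein", "S3": "Normande"}
    qtls = [qtl("chr1", 1, 2000), qtl("chr2", 4000, 6000, "FC")]
    return vcf, breeds, mirnas, qtls


class TestRunCascade:
    def test_stage_filters_and_labels(self, mini_inputs):
        vcf, breeds, mirnas, qtls = mini_inputs
        ann, log = run_cascade(
            io_formats.read_vcf(vcf, breeds), mirnas, {"mir-A", "mir-B"}, qtls
        )
        labels = {(a.variant.interval.chrom, a.variant.interval.start): a.localisation.label
                  for a in ann}
        assert labels == {
            ("chr1", 1012): "seed",
            ("chr1", 940): "flank100",
            ("chr2", 5045): "mature",
        }
        assert (log.n_input, log.n_multi_allelic, log.n_biallelic) == (6, 1, 5)
        assert (log.n_localised, log.n_in_qtl, log.n_in_mirnome, log.n_pass_frequency) == (
            4, 4, 4, 3,
        )

    def test_mirnome_filter_drops_unlisted_gene(self, mini_inputs):
        vcf, breeds, mirnas, qtls = mini_inputs
        ann, _ = run_cascade(io_formats.read_vcf(vcf, breeds), mirnas, {"mir-A"}, qtls)
        assert {a.localisation.mirna for a in ann} == {"mir-A"}

    def test_qtl_mode_output_subset_of_no_qtl(self, mini_inputs):
        vcf, breeds, mirnas, _ = mini_inputs
        narrow = [qtl("chr1", 1, 2000)]  # chr2 gene not covered
        with_qtl, _ = run_cascade(io_formats.read_vcf(vcf, breeds), mirnas,
                                  {"mir-A", "mir-B"}, narrow)
        without, _ = run_cascade(io_formats.read_vcf(vcf, breeds), mirnas,
                                 {"mir-A", "mir-B"}, None)
        keys = lambda anns: {a.variant.key for a in anns}
        assert keys(with_qtl) < keys(without)

    def test_empty_vcf_gives_empty_output(self, tmp_path, mini_inputs):
        _, breeds, mirnas, qtls = mini_inputs
        vcf = write_vcf(tmp_path / "e.vcf", [])
        ann, log = run_cascade(io_formats.read_vcf(vcf, breeds), mirnas, {"mir-A"}, qtls)
        assert ann == [] and log.n_input == 0 and log.n_pass_frequency == 0

    def test_empty_annotation_is_an_error(self, mini_inputs):
        vcf, breeds, _, _ = mini_inputs
        with pytest.raises(ValueError, match="empty miRNA annotation"):
            run_cascade(io_formats.read_vcf(vcf, breeds), [], {"mir-A"})

    def test_record_order_does_not_change_report(self, tmp_path, mini_inputs):
        vcf, breeds, mirnas, qtls = mini_inputs
        lines = vcf.read_text().splitlines()
        header = [l for l in lines if l.startswith("#")]
        body = [l for l in lines if not l.startswith("#")]
        shuffled = tmp_path / "shuf.vcf"
        shuffled.write_text("\n".join(header + body[::-1]) + "\n")
        a1, _ = run_cascade(io_formats.read_vcf(vcf, breeds), mirnas, {"mir-A", "mir-B"}, qtls)
        a2, _ = run_cascade(io_formats.read_vcf(shuffled, breeds), mirnas, {"mir-A", "mir-B"}, qtls)
        p1, p2 = tmp_path / "r1.tsv", tmp_path / "r2.tsv"
        io_formats.write_report(a1, p1)
        io_formats.write_report(a2, p2)
        assert p1.read_text() == p2.read_text()

    def test_filterlog_counts_non_increasing(self, mini_inputs):
        vcf, breeds, mirnas, qtls = mini_inputs
        _, log = run_cascade(io_formats.read_vcf(vcf, breeds), mirnas, {"mir-A", "mir-B"}, qtls)
        counts = [c for _, c in log.stage_counts(qtl_mode=True)]
        assert counts == sorted(counts, reverse=True)


class TestSummarize:
    def test_single_seed_variant_counts_up_the_nesting(self, plus_gene):
        from mirvar.mirna_geometry import Localisation
        from mirvar.qtl_cascade import AnnotatedVariant

        av = AnnotatedVariant(
            variant=snp("chr1", 1012),
            localisation=Localisation("seed", "syn-miR-plus", 0),
            qtl_hits=[],
            in_cpg=True,
            in_tfbs=False,
            breeds_polymorphic=frozenset({"Holstein"}),
        )
        tables = summarize([av])
        for label in ("seed", "mature", "precursor", "flank50", "flank1000"):
            assert tables.nested_counts[label] == (1, 1)
            assert tables.cpg_counts[label] == (1, 1)

    def test_nested_counts_weakly_increase(self, mini_inputs):
        vcf, breeds, mirnas, qtls = mini_inputs
        ann, _ = run_cascade(io_formats.read_vcf(vcf, breeds), mirnas, {"mir-A", "mir-B"}, qtls)
        tables = summarize(ann)
        chain = ["seed", "mature", "precursor", "flank50", "flank100", "flank500", "flank1000"]
        ns = [tables.nested_counts[l][0] for l in chain]
        assert ns == sorted(ns)

    def test_flank_rows_without_gene_internal_mode(self, mini_inputs):
        vcf, breeds, mirnas, qtls = mini_inputs
        ann, _ = run_cascade(io_formats.read_vcf(vcf, breeds), mirnas, {"mir-A", "mir-B"}, qtls)
        cfg = CascadeConfig(flanks_include_gene=False)
        tables = summarize(ann, config=cfg)
        # only the flank100 variant remains in the flank chain
        assert tables.nested_counts["flank50"][0] == 0
        assert tables.nested_counts["flank100"][0] == 1


class TestTraitNormalisation:
    @pytest.mark.parametrize(
        "raw,expected",
        [
            ("Quantity of proteins", "PROT"),
            ("protein yield", "PROT"),
            ("Somatic cell count", "SCS"),
            ("FC", "FC"),
        ],
    )
    def test_synonyms(self, raw, expected):
        assert qtl_cascade.normalise_trait(raw) == expected

    def test_unknown_trait_passes_through(self):
        assert qtl_cascade.normalise_trait("wool yield") == "wool yield"
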