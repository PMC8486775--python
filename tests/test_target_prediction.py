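import random

import pytest

from mirvar import target_prediction as tp
from mirvar.intervals import GenomicInterval
from mirvar.liftover import SequenceStore
from mirvar.mirna_geometry import MirnaGene

from conftest import snp
from oracles import oracle_seed_sites

LET7 = "UGAGGUAGUAGGUUGUAUAGUU"  # seed nt 2-7 = GAGGUA, complement site = UACCUC


class TestSeedMatch:
    def test_canonical_6mer(self):
        mature = tp.MatureSequence("let-7", LET7)
        sites = tp.seed_match(mature, "GGGUACCUCGGG", "t1")
        assert [(s.position, s.match_class) for s in sites] == [(4, "6mer")]

    def test_7mer_a1_when_adenosine_faces_position_1(self):
        mature = tp.MatureSequence("let-7", LET7)
        (site,) = tp.seed_match(mature, "UACCUCA", "t1")
        assert site.match_class == "7mer-A1"

    def test_7mer_m8_and_8mer(self):
        mature = tp.MatureSequence("let-7", LET7)
        # position 8 of let-7 is G; its complement C sits 5' of the core site
        (site,) = tp.seed_match(mature, "GCUACCUCG", "t1")
        assert site.match_class == "7mer-m8"
        (site,) = tp.seed_match(mature, "GCUACCUCA", "t1")
        assert site.match_class == "8mer"

    def test_utr_shorter_than_site_is_empty(self):
        mature = tp.MatureSequence("let-7", LET7)
        assert tp.seed_match(mature, "UACCU", "t1") == []

    def test_u_t_transliteration_invariance(self):
        mature_t = tp.MatureSequence("let-7", LET7.replace("U", "T"))
        mature_u = tp.MatureSequence("let-7", LET7)
        utr_t, utr_u = "GGTACCTCAGG", "GGUACCUCAGG"
        s1 = tp.seed_match(mature_t, utr_t, "t")
        s2 = tp.seed_match(mature_u, utr_u, "t")
        assert s1 == s2 and s1

    def test_gu_wobble_does_not_match(self):
        # replacing the site's C (pairing seed G) with U would need a G:U pair
        mature = tp.MatureSequence("let-7", LET7)
        assert tp.seed_match(mature, "GGGUACCUUGGG", "t1") == []

    def test_matches_exhaustive_window_oracle_on_random_utrs(self):
        rng = random.Random(21)
        for _ in range(60):
            mature = tp.MatureSequence(
                "m", "".join(rng.choice("ACGU") for _ in range(22))
            )
            utr = "".join(rng.choice("ACGU") for _ in range(500))
            got = [s.position for s in tp.seed_match(mature, utr, "t")]
            assert got == oracle_seed_sites(mature.sequence, utr)

    def test_8mer_position_set_nested_in_both_7mers(self):
        rng = random.Random(22)
        m8_pos, a1_pos, mer8_pos = set(), set(), set()
        for _ in range(300):
            mature = tp.MatureSequence("m", "".join(rng.choice("ACGU") for _ in range(22)))
            utr = "".join(rng.choice("ACGU") for _ in range(300))
            for s in tp.seed_match(mature, utr, "t"):
                key = (mature.sequence, s.position)
                if s.match_class in ("7mer-m8", "8mer"):
                    m8_pos.add(key)
                if s.match_class in ("7mer-A1", "8mer"):
                    a1_pos.add(key)
                if s.match_class == "8mer":
                    mer8_pos.add(key)
        assert mer8_pos <= m8_pos and mer8_pos <= a1_pos
        assert mer8_pos  # the draw is large enough to exercise the class


def _gene_with_genome(strand, rng_seed=3):
    """A 80-bp precursor with one 22-nt arm and a synthetic genome around it."""
    rng = random.Random(rng_seed)
    genome_seq = "".join(rng.choice("ACGT") for _ in range(400))
    gene = MirnaGene(
        name="g",
        precursor=GenomicInterval("c", 101, 180, strand),
        mature_arms=(("g-arm", GenomicInterval("c", 111, 132, strand)),),
    )
    return gene, SequenceStore({"c": genome_seq})


class TestApplyVariantToMature:
    def test_plus_strand_offset(self):
        gene, genome = _gene_with_genome("+")
        ref_base = genome.fetch("c", 113, 113)
        alt_base = {"A": "G", "G": "A", "C": "T", "T": "C"}[ref_base]
        v = snp("c", 113, ref=ref_base, alt=alt_base)
        out = tp.apply_variant_to_mature(gene, "g-arm", v, genome)
        ref_seq = tp.mature_from_genome(gene, "g-arm", genome).sequence
        assert out.sequence[2] == tp.to_rna(alt_base)  # arm start +2 -> transcript nt 3
        assert out.sequence[:2] == ref_seq[:2] and out.sequence[3:] == ref_seq[3:]

    def test_minus_strand_substitutes_complement(self):
        gene, genome = _gene_with_genome("-")
        pos = 128  # transcript offset = end - pos = 132 - 128 = 4 -> nt 5
        ref_base = genome.fetch("c", pos, pos)
        alt_base = {"A": "G", "G": "A", "C": "T", "T": "C"}[ref_base]
        v = snp("c", pos, ref=ref_base, alt=alt_base)
        out = tp.apply_variant_to_mature(gene, "g-arm", v, genome)
        comp = {"A": "U", "T": "A", "G": "C", "C": "G"}
        assert out.sequence[4] == comp[alt_base]

    def test_reference_allele_is_identity(self):
        gene, genome = _gene_with_genome("+")
        ref_base = genome.fetch("c", 113, 113)
        v = snp("c", 113, ref=ref_base, alt=ref_base)
        out = tp.apply_variant_to_mature(gene, "g-arm", v, genome)
        assert out.sequence == tp.mature_from_genome(gene, "g-arm", genome).sequence

    def test_indel_in_arm_is_unsupported(self):
        gene, genome = _gene_with_genome("+")
        v = snp("c", 113, ref="GA", alt="G")
        with pytest.raises(ValueError, match="SNP"):
            tp.apply_variant_to_mature(gene, "g-arm", v, genome)

    def test_variant_outside_arm_is_an_error(self):
        gene, genome = _gene_with_genome("+")
        ref_base = genome.fetch("c", 150, 150)
        v = snp("c", 150, ref=ref_base, alt="A" if ref_base != "A" else "C")
        with pytest.raises(ValueError, match="outside arm"):
            tp.apply_variant_to_mature(gene, "g-arm", v, genome)


def _plant(seq_rng, seed_rna, other_seed):
    """A 60-nt UTR with exactly one complement of `seed_rna` and none of the other."""
    site = tp.rna_revcomp(seed_rna)
    while True:
        utr = "".join(seq_rng.choice("ACGU") for _ in range(60))
        planted = utr[:30] + site + utr[30:]
        if (
            len(oracle_seed_sites("N" + seed_rna + "N" * 15, planted)) == 1
            and not oracle_seed_sites("N" + other_seed + "N" * 15, planted)
        ):
            return planted


class TestDiffTargets:
    def test_identical_sequences_change_nothing(self):
        m = tp.MatureSequence("m", LET7)
        diff = tp.diff_targets(m, m, {"t1": "GGUACCUCGG", "t2": "AAAA"})
        assert diff.gained == diff.lost == frozenset()
        assert diff.retained == {"t1"}

    def test_non_seed_variant_keeps_6mer_sites(self):
        ref = tp.MatureSequence("m", LET7)
        alt = tp.MatureSequence("m*", LET7[:-1] + "A")  # change outside nt 2-7
        utrs = {"t1": "GGUACCUCGG", "t2": "CCCCCCCCCC"}
        diff = tp.diff_targets(ref, alt, utrs)
        assert diff.gained == diff.lost == frozenset()

    def test_planted_panel_counts(self):
        """A seed SNP on a panel with 3 ref-only and 2 alt-only complements."""
        rng = random.Random(33)
        ref = tp.MatureSequence("m", "AGAGGUAGUAGGUUGUAUAGUU")
        alt = tp.MatureSequence("m*", "AGAGCUAGUAGGUUGUAUAGUU")  # seed G->C at nt 5
        utrs = {}
        for i in range(3):
            utrs[f"ref{i}"] = _plant(rng, ref.seed, alt.seed)
        for i in range(2):
            utrs[f"alt{i}"] = _plant(rng, alt.seed, ref.seed)
        # guard: planted panels are exclusive
        for name, utr in utrs.items():
            has_ref = bool(tp.seed_match(ref, utr, name))
            has_alt = bool(tp.seed_match(alt, utr, name))
            assert has_ref != has_alt
        diff = tp.diff_targets(ref, alt, utrs)
        assert len(diff.lost) == 3 and len(diff.gained) == 2
        assert diff.retained == frozenset()

    def test_length_mismatch_is_an_error(self):
        with pytest.raises(ValueError, match="equal length"):
            tp.diff_targets(
                tp.MatureSequence("a", LET7),
                tp.MatureSequence("b", LET7 + "A"),
                {},
            )
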