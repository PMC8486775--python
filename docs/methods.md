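# Methods

## Coordinate model

All coordinates inside the package are 1-based and closed on both ends;
conversion happens only at I/O boundaries (BED `[s, e)` becomes
`[s+1, e]`). Chromosome names are compared after stripping an optional
`chr` prefix, because annotation sources mix the two spellings; the
original spelling is preserved on output. Intervals overlap when they
share at least one base; the distance between two disjoint intervals is
the gap in bases, so adjacent intervals are 1 apart and a variant exactly
50 bases from a precursor lands at the edge of the 50 bp flanking window.

## Variant normalisation and frequencies

Only biallelic records enter the cascade; multi-allelic records are
dropped whole rather than decomposed, since downstream accounting is
defined over single ref/alt pairs. Symbolic alts (`<DEL>`, breakends) are
excluded as structural. Allele changes are classified by length and
anchor sharing: equal single-base lengths are SNPs, a longer alt sharing
its anchor with the ref is an insertion, the converse a deletion, and
everything else is kept as "complex" so unusual records never vanish
silently. Insertions or deletions of 60 bp or more are treated as
structural variants and excluded; the boundary is inclusive (an exact
60 bp deletion is dropped).

Allele frequency is the count of alternative alleles over twice the number
of fully called diploid samples; half-called and missing genotypes are
excluded from numerator and denominator alike. Frequencies are computed
pooled over the panel and per breed (from a sample→breed sidecar file; the
panel composition is metadata, not VCF content). The frequency filter is
inclusive (`af ≥ 0.01`) and defaults to the pooled value; `max-breed` mode
passes a variant when any single breed reaches the threshold. The
per-breed mode exists because reported variant tables in this field are
breed-stratified: a variant at 1.2 % in one breed of a three-breed panel
is real and reportable even though its pooled frequency (0.4 %) is not.

A record with no called genotypes has no defined frequency; it is dropped
with its own filter-log reason rather than being given a pseudo-value.

## Localisation geometry

The seed interval of a mature arm is derived from transcript nucleotides
2–7: `[start+1, start+6]` on the + strand, `[end−6, end−1]` on the −
strand. Arms shorter than 8 nt are rejected. Localisation is the most
specific label whose region the variant's reference-allele span
intersects (any-overlap semantics: a deletion touching a seed is a seed
variant — the inclusion-maximising convention, preferable for a screening
tool where a miss is costlier than a false lead). Insertions occupy only
their single reference anchor base, matching how VCF anchors them. When a
precursor has two arms, the most specific label across arms wins; a
variant within reach of two genes yields one localisation per gene, since
per-gene accounting is what the distinct-miRNA tallies require.

Flank labels use the smallest window `w` with `0 < distance ≤ w`; windows
default to 50/100/500/1000 bp. Summary tables count the gene-internal
chain cumulatively (mature includes seed, precursor includes mature) and
flank rows cumulatively over windows including the gene-internal variants
(`distance ≤ w` with distance 0 allowed); a `flanks_include_gene=False`
switch restricts flank rows to true flanking variants, because published
location tables are ambiguous on this point.

Interval queries (gene candidates, QTL hits, CpG/TFBS overlays) run on
interval trees; every one of these paths is tested against naive per-base
or pairwise scans on randomised instances.

## Cascade order and report shape

With QTL regions supplied, the stage order is: biallelic → localisation →
QTL intersection → miRNome membership → frequency. Omitting the QTL file
yields the unconditioned variant panel; the QTL-mode output is provably a
subset of it on the same inputs. QTL breed labels are carried into the
report but not used as a filter by default (variants are reported per
polymorphic breed, which need not equal the QTL's mapping breed); a strict
breed-match mode exists.

The report has one row per (variant, miRNA) pair, with polymorphic breeds,
per-breed frequencies and QTL traits joined within the row. One row per
pair — rather than per breed or per QTL hit — keeps the row count equal to
the number of prioritised (variant, gene) events, which is the quantity
the summary tables count; the per-breed and per-trait detail is preserved
in dedicated columns. Rows are sorted by (chrom, pos, miRNA), making the
report byte-identical under input reordering.

QTL trait names are normalised through a synonym map to a controlled
vocabulary (MILK, FAT, PROT, FC, PC, SCS, CM, …); unknown traits pass
through verbatim with a warning rather than failing, since trait panels
differ between species.

Densities (variants per Mb / per kb) are rounded half-up to two decimals
for reporting.

## Liftover

Assembly transposition anchors an interval by its first and last
k (= 100) nucleotides, truncated symmetrically (never overlapping) for
intervals shorter than 2k. Each anchor is searched in the target on both
strands: exact string search as a fast path, then a vectorised
sliding-window Hamming scan with `max_mismatch` (default 2). The matcher
is deliberately gapless: on highly similar assemblies a gapped anchor
indicates local rearrangement, and failing as `not_found` is safer than a
mislift. A lift is `unique` only when both anchors have exactly one best
placement, on one strand, in consistent order; equal-mismatch ties are
`ambiguous`, never resolved arbitrarily. Identity and mirror (reverse
complement) lifts are property-tested.

## Target prediction

Seed matching is pure complementarity: a 6-nt UTR window equal to the
reverse complement of miRNA nucleotides 2–7 is a site; the class is
upgraded to 7mer-m8 (UTR base 5′ of the window pairs nucleotide 8),
7mer-A1 (adenosine faces nucleotide 1) or 8mer (both). G:U wobble does not
count, and no context scoring, conservation weighting or accessibility
model is applied — the module answers the qualitative question of which
targets a seed variant gains and loses, not a quantitative repression
score. U/T transliteration on input makes DNA and RNA sequences
equivalent. Target diffs compare the transcript sets with ≥ 1 site under
the reference and alternative mature sequences; only SNPs are supported in
arms (an indel shifts the whole transcript register and is reported as
unsupported rather than guessed at).

## Synthetic data

The generator emulates the *shape* of a multi-breed whole-genome call
set — biallelic and multi-allelic records, SNPs and 1–3 bp InDels,
structural-length (≥ 60 bp) decoys, three breed panels of 50 samples with
binomially drawn genotypes, below-threshold frequency strata, genes
in and out of the miRNome, QTL coverage of about half the genes — at desk
scale: by default 24 genes on 2 × 40 kb chromosomes and 500 variant
records split across every localisation class (40 seed, 60 mature, 80
precursor, 60 per flank window, 80 outside). Genes are spaced by more
than twice the largest flank window so every variant resolves to at most
one gene. It does not emulate linkage disequilibrium, mutation-rate
heterogeneity or a realistic site-frequency spectrum, so passing tests
demonstrate the correctness of the filtering logic, not calibration
against population-genetic structure.

Truth is defined by recomputation, not intent: after placement, each
record's localisation, QTL overlap and realised allele frequency are
re-derived from the emitted files with the same geometry the pipeline
uses, and the truth table stores those values. A deletion drawn at a
class boundary is therefore recorded under its actual label, and a
planned-rare variant that realises above threshold is recorded as above —
the truth table is exact by construction, and planted-truth recovery
tests compare cascade output to it with zero tolerance.

The packaged 26-variant bovine fixture encodes a published table of
precursor variants in dairy QTL regions: printed positions, alleles,
per-breed frequencies (reproduced to the nearest allele count in a
50-samples-per-breed panel, i.e. within 1/(2·50)), traits and
localisation labels. The gene geometry around those positions is
synthetic: for each miRNA a + strand precursor and a 22-nt arm are
searched so that every variant reproduces its printed label under the
package's own localisation rules, and the builder asserts this before
emitting. Two rows whose multi-nucleotide allele columns are
typographically ambiguous in the source are encoded as a 1-nt insertion
(chr5:118,347,364 C→CT) and a 1-nt deletion (chr19:38,542,897 CG→C),
consistent with the table's class totals (22 SNPs, insertions of 1 and
2 nt, two 1-nt deletions), which are invariant to either reading. The
fixture's acceptance run uses `max-breed` frequency mode, since the
printed frequencies are per breed (see above). CpG/TFBS tracks are empty
in the fixture because the source table does not identify which rows
carry those flags.

## Error handling and degenerate inputs

Malformed VCF records raise a parse error carrying the first structurally
invalid line number (located by a rescan, since the underlying htslib
parser does not expose line numbers); a VCF without GT fields fails early
with the reason that frequencies cannot be computed. Empty BED intervals,
mature arms outside their precursor, orphan arms and missing strands are
hard errors at read time. An empty miRNA annotation is an error; an empty
miRNome with a non-empty annotation yields a warning and an empty result.
Infeasible generator configurations (more planted seed variants than seed
bases) fail before any file is written.

## Known limitations

- Multi-allelic records are dropped, not decomposed; sites where a second
  allele masks an interesting first allele are invisible.
- The liftover is gapless by design and will report `not_found` for
  anchors spanning indel-containing regions that a gapped aligner would
  place.
- Seed-match prediction ignores site context, conservation and
  thermodynamics; gained/lost target sets are candidate lists, not
  effect-size predictions.
- The frequency model treats genotypes as exact; genotype likelihoods and
  imputation uncertainty are out of scope.
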