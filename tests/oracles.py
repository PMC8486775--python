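"""Independent brute-force oracles used to check the fast implementations.

Everything here is deliberately naive — per-base membership scans and
per-window Hamming comparisons — and shares no code with the interval-tree
or vectorised paths it verifies.
"""

from __future__ import annotations

from mirvar.intervals import GenomicInterval
from mirvar.mirna_geometry import MirnaGene


def oracle_localise(
    span: GenomicInterval, gene: MirnaGene, windows=(50, 100, 500, 1000)
) -> str:
    """Per-base membership scan for the most specific localisation label."""
    if span.chrom_key != gene.precursor.chrom_key:
        return "none"
    bases = range(span.start, span.end + 1)
    seed_bases = set()
    for iv in gene.seed_intervals:
        seed_bases.update(range(iv.start, iv.end + 1))
    arm_bases = set()
    for _, arm in gene.mature_arms:
        arm_bases.update(range(arm.start, arm.end + 1))
    prec_bases = set(range(gene.precursor.start, gene.precursor.end + 1))
    if any(b in seed_bases for b in bases):
        return "seed"
    if any(b in arm_bases for b in bases):
        return "mature"
    if any(b in prec_bases for b in bases):
        return "precursor"
    d = min(min(abs(b - p) for p in (gene.precursor.start, gene.precursor.end))
            for b in bases)
    for w in windows:
        if d <= w:
            return f"flank{w}"
    return "none"


def oracle_overlap(span: GenomicInterval, track: list[GenomicInterval]) -> bool:
    """O(n*m) pairwise scan: does any track interval share a base with span?"""
    for iv in track:
        if iv.chrom_key != span.chrom_key:
            continue
        for b in range(span.start, span.end + 1):
            if iv.start <= b <= iv.end:
                return True
    return False


def oracle_locate(anchor_seq: str, target: dict[str, str], max_mismatch: int):
    """Per-window Hamming scan over both strands of every target sequence."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    rc = "".join(comp[b] for b in reversed(anchor_seq))
    k = len(anchor_seq)
    hits = []
    for chrom, seq in target.items():
        for strand, query in (("+", anchor_seq), ("-", rc)):
            for i in range(len(seq) - k + 1):
                mm = sum(1 for a, b in zip(seq[i : i + k], query) if a != b)
                if mm <= max_mismatch:
                    hits.append((chrom, i + 1, strand, mm))
    hits.sort(key=lambda h: (h[3], h[0], h[1], h[2]))
    return hits


def oracle_seed_sites(mature_seq: str, utr: str) -> list[int]:
    """Exhaustive window check for 6mer seed complementarity (1-based starts)."""
    pairs = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
    m = mature_seq.upper().replace("T", "U")
    u = utr.upper().replace("T", "U")
    seed = m[1:7]
    out = []
    for i in range(len(u) - 5):
        window = u[i : i + 6]
        # antiparallel pairing: window base j pairs seed base 5-j
        if all((window[j], seed[5 - j]) in pairs for j in range(6)):
            out.append(i + 1)
    return out
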