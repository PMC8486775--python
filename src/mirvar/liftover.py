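"""Flank-anchored coordinate transposition between genome assemblies.

An interval is anchored by its first and last 100 nucleotides. Each anchor
is searched in the target assembly on both strands, exact matches first,
then with a small Hamming-distance tolerance (gapless by design: an anchor
that only aligns with gaps fails as ``not_found`` rather than mislifting).
The lifted interval spans from the first anchor's start to the last
anchor's end, strand-adjusted; anything other than a single consistent
placement per anchor is reported as ``ambiguous``, ``not_found`` or
``inconsistent`` instead of a guess.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping

import numpy as np

from .intervals import GenomicInterval

DEFAULT_FLANK = 100
DEFAULT_MAX_MISMATCH = 2

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class SequenceStore:
    """Minimal genome accessor over a name -> sequence mapping.

    Accepts a plain dict or a :class:`pyfaidx.Fasta`; sequences are
    upper-cased on access. Coordinates are 1-based closed.
    """

    def __init__(self, seqs: Mapping[str, str]):
        self._seqs = {name: str(seqs[name]).upper() for name in seqs.keys()}

    @classmethod
    def from_fasta(cls, path: str) -> "SequenceStore":
        import pyfaidx

        fa = pyfaidx.Fasta(path, as_raw=True, rebuild=False)
        return cls({name: str(fa[name][:]) for name in fa.keys()})

    def names(self):
        return self._seqs.keys()

    def __getitem__(self, name: str) -> str:
        return self._seqs[name]

    def fetch(self, chrom: str, start: int, end: int) -> str:
        seq = self._seqs[chrom]
        if start < 1 or end > len(seq):
            raise ValueError(
                f"{chrom}:[{start},{end}] outside sequence of length {len(seq)}"
            )
        return seq[start - 1 : end]


@dataclasses.dataclass(frozen=True)
class FlankAnchor:
    """Terminal flank of a source interval used as a liftover anchor."""

    side: str  # "first" | "last"
    sequence: str
    source_interval: GenomicInterval


@dataclasses.dataclass(frozen=True)
class LiftResult:
    status: str  # unique | ambiguous | not_found | inconsistent
    target_interval: GenomicInterval | None = None
    mismatches: tuple[int, int] | None = None


def extract_flanks(
    interval: GenomicInterval, genome: SequenceStore, k: int = DEFAULT_FLANK
) -> tuple[FlankAnchor, FlankAnchor]:
    """First and last ``k`` nucleotides of an interval as anchors.

    For intervals shorter than ``2k`` both anchors are truncated
    symmetrically to ``len // 2`` so they never overlap.
    """
    if len(interval) < 2:
        raise ValueError("interval too short to anchor (length < 2)")
    eff_k = min(k, len(interval) // 2)
    first = genome.fetch(interval.chrom, interval.start, interval.start + eff_k - 1)
    last = genome.fetch(interval.chrom, interval.end - eff_k + 1, interval.end)
    return (
        FlankAnchor("first", first, interval),
        FlankAnchor("last", last, interval),
    )


def _hamming_scan(target: str, query: str, max_mismatch: int) -> list[tuple[int, int]]:
    """All windows of ``target`` within ``max_mismatch`` substitutions of ``query``.

    Returns (0-based position, mismatches) pairs. Vectorised over window
    positions: one pass per query base.
    """
    n, k = len(target), len(query)
    if k == 0 or k > n:
        return []
    t = np.frombuffer(target.encode(), dtype=np.uint8)
    q = np.frombuffer(query.encode(), dtype=np.uint8)
    n_win = n - k + 1
    mism = np.zeros(n_win, dtype=np.int32)
    for j in range(k):
        mism += t[j : j + n_win] != q[j]
    idx = np.nonzero(mism <= max_mismatch)[0]
    return [(int(i), int(mism[i])) for i in idx]


def locate_flank(
    anchor: FlankAnchor, target: SequenceStore, max_mismatch: int = DEFAULT_MAX_MISMATCH
) -> list[tuple[GenomicInterval, int]]:
    """All gapless placements of an anchor in the target, both strands.

    Returns ``(placement interval, mismatches)`` sorted by mismatches, then
    chromosome, position and strand. Exact hits are found by plain string
    search as a fast path; the mismatch-tolerant scan runs only when
    ``max_mismatch > 0``.
    """
    k = len(anchor.sequence)
    hits: list[tuple[GenomicInterval, int]] = []
    for chrom in target.names():
        seq = target[chrom]
        for strand, query in (("+", anchor.sequence), ("-", revcomp(anchor.sequence))):
            if max_mismatch == 0:
                pos = seq.find(query)
                while pos != -1:
                    hits.append(
                        (GenomicInterval(chrom, pos + 1, pos + k, strand), 0)
                    )
                    pos = seq.find(query, pos + 1)
            else:
                for pos, mm in _hamming_scan(seq, query, max_mismatch):
                    hits.append(
                        (GenomicInterval(chrom, pos + 1, pos + k, strand), mm)
                    )
    hits.sort(key=lambda h: (h[1], h[0].chrom, h[0].start, h[0].strand))
    return hits


def _best_hits(hits: list[tuple[GenomicInterval, int]]):
    if not hits:
        return []
    best = hits[0][1]
    return [h for h in hits if h[1] == best]


def transpose_interval(
    interval: GenomicInterval,
    source: SequenceStore,
    target: SequenceStore,
    k: int = DEFAULT_FLANK,
    max_mismatch: int = DEFAULT_MAX_MISMATCH,
) -> LiftResult:
    """Lift an interval from ``source`` to ``target`` via its terminal flanks.

    unique: each flank has exactly one best placement, both on the same
    strand and in the right order; the lifted interval runs from the first
    anchor's start to the last anchor's end (mirrored on the - strand).
    """
    try:
        first, last = extract_flanks(interval, source, k)
    except ValueError:
        return LiftResult(status="not_found")
    hits_first = _best_hits(locate_flank(first, target, max_mismatch))
    hits_last = _best_hits(locate_flank(last, target, max_mismatch))
    if not hits_first or not hits_last:
        return LiftResult(status="not_found")
    if len(hits_first) > 1 or len(hits_last) > 1:
        return LiftResult(status="ambiguous")
    (iv_f, mm_f), (iv_l, mm_l) = hits_first[0], hits_last[0]
    if iv_f.chrom != iv_l.chrom or iv_f.strand != iv_l.strand:
        return LiftResult(status="inconsistent")
    if iv_f.strand == "+":
        start, end = iv_f.start, iv_l.end
    else:
        # on the reverse strand the first (source-5') anchor lies downstream
        start, end = iv_l.start, iv_f.end
    if end < start:
        return LiftResult(status="inconsistent")
    return LiftResult(
        status="unique",
        target_interval=GenomicInterval(iv_f.chrom, start, end, iv_f.strand),
        mismatches=(mm_f, mm_l),
    )
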