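"""Metagenomic fragment recruitment and the RPKG abundance statistic.

Reads are aligned against a reference genome, hits are passed through the
recruitment filters (minimum alignment length 50 bp, identity >= 95%,
e-value <= 1e-5, one best hit per read), and abundance is expressed as RPKG:
reads recruited per kilobase of genome per gigabase of metagenome,

    RPKG = reads_recruited / (genome_kb * metagenome_gb),

where the metagenome size counts *all* bases sequenced, recruited or not —
that is what makes the number comparable across datasets of different depth.

A desk-scale gapless aligner (`mini_align`) substitutes for an external
BLASTN run: exact k-mer seeding on both strands followed by ungapped
extension over the full read.  Hits may also be supplied as a precomputed
BLAST tabular file through :mod:`maglake.io_formats`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .io_formats import SeqRecord, TabularHit

_ENC = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENC[_b] = _i

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _encode(seq: str) -> np.ndarray:
    return _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


class GenomeIndex:
    """Exact k-mer position index over one reference sequence."""

    def __init__(self, genome: SeqRecord, k: int = 21):
        self.genome = genome
        self.k = k
        self.arr = _encode(genome.sequence)
        self.index: dict[str, list[int]] = {}
        s = genome.sequence
        for i in range(len(s) - k + 1):
            self.index.setdefault(s[i : i + k], []).append(i)

    def candidate_offsets(self, read: str, step: int | None = None) -> set[int]:
        """0-based genome offsets suggested by shared exact k-mers."""
        k = self.k
        if step is None:
            step = 1
        positions = list(range(0, len(read) - k + 1, step))
        last = len(read) - k
        if last >= 0 and positions and positions[-1] != last:
            positions.append(last)
        offsets: set[int] = set()
        for i in positions:
            for g in self.index.get(read[i : i + k], ()):
                offsets.add(g - i)
        return offsets


@dataclass
class RecruitmentResult:
    genome_id: str
    genome_kb: float
    metagenome_gb: float
    reads_recruited: int
    rpkg: float
    profile: list[tuple[float, float]]


def filter_hits(
    hits: Sequence[TabularHit],
    min_len: int = 50,
    min_identity: float = 95.0,
    max_evalue: float = 1e-5,
    inclusive_identity: bool = True,
) -> list[TabularHit]:
    """Apply the recruitment filters, then keep one best hit per query.

    A hit survives if its alignment length is >= ``min_len``, its identity
    passes ``min_identity`` (inclusive by default; exclusive selectable) and
    its e-value is <= ``max_evalue``.  Among surviving hits of one query, the
    highest bit score wins; ties go to the earlier hit in input order, so the
    operation is deterministic and idempotent.
    """
    best: dict[str, TabularHit] = {}
    order: list[str] = []
    for h in hits:
        if h.alignment_length < min_len or h.evalue > max_evalue:
            continue
        if inclusive_identity:
            if h.percent_identity < min_identity:
                continue
        elif h.percent_identity <= min_identity:
            continue
        prev = best.get(h.query_id)
        if prev is None:
            best[h.query_id] = h
            order.append(h.query_id)
        elif h.bit_score > prev.bit_score:
            best[h.query_id] = h
    return [best[q] for q in order]


def rpkg(reads_recruited: int, genome_kb: float, metagenome_gb: float) -> float:
    """Reads recruited per kb of genome per Gb of metagenome."""
    if genome_kb <= 0:
        raise ValueError("genome size must be positive")
    if metagenome_gb <= 0:
        raise ValueError("metagenome size must be positive")
    return reads_recruited / (genome_kb * metagenome_gb)


def gapless_best_hit(
    query: str,
    index: GenomeIndex,
    allow_overhang: bool = False,
) -> tuple[int, int, int, int] | None:
    """Best ungapped placement of ``query`` on the indexed genome.

    Returns ``(offset, matches, aln_start, aln_len)`` with ``offset`` the
    0-based genome position of the query's first base (possibly negative with
    overhang), ``aln_start`` the 0-based query position where the compared
    region starts, and ``aln_len`` its length.  ``None`` when no shared
    k-mer seeds the placement.
    """
    L = len(query)
    G = index.arr.size
    offsets = index.candidate_offsets(query)
    if not offsets:
        return None
    q = _encode(query)
    best = None
    for off in sorted(offsets):
        if allow_overhang:
            a_start = max(0, -off)
            a_end = min(L, G - off)
            if a_end - a_start < index.k:
                continue
        else:
            if off < 0 or off + L > G:
                continue
            a_start, a_end = 0, L
        seg_q = q[a_start:a_end]
        seg_g = index.arr[off + a_start : off + a_end]
        matches = int(np.count_nonzero(seg_q == seg_g))
        cand = (matches, -abs(off), off, a_start, a_end - a_start)
        if best is None or cand[:2] > best[:2]:
            best = cand
    if best is None:
        return None
    matches, _, off, a_start, a_len = best
    return off, matches, a_start, a_len


def mini_align(
    reads: Iterable[SeqRecord],
    genome: SeqRecord,
    k: int = 21,
    index: GenomeIndex | None = None,
) -> list[TabularHit]:
    """Seed-and-extend gapless alignment of reads against one genome.

    Both strands are tried; the best placement (most matching bases) is
    reported as a single hit per read with identity = matches / read length.
    The e-value is reported as 0 because every exact-seeded gapless hit at
    these read lengths is far beyond any practical significance cutoff;
    e-value filtering applies to externally computed hit tables instead.
    Reads that share no exact k-mer with the genome yield no hit.
    """
    if index is None:
        index = GenomeIndex(genome, k=k)
    hits: list[TabularHit] = []
    for read in reads:
        L = len(read.sequence)
        if L < index.k:
            continue
        best = None  # (matches, strand_rank, offset, strand)
        for strand, seq in (("+", read.sequence), ("-", reverse_complement(read.sequence))):
            res = gapless_best_hit(seq, index, allow_overhang=False)
            if res is None:
                continue
            off, matches, _, _ = res
            cand = (matches, 0 if strand == "+" else 1, off, strand)
            if best is None or (cand[0], -cand[1], -cand[2]) > (best[0], -best[1], -best[2]):
                best = cand
        if best is None:
            continue
        matches, _, off, strand = best
        if strand == "+":
            s_start, s_end = off + 1, off + L
        else:
            s_start, s_end = off + L, off + 1
        hits.append(
            TabularHit(
                query_id=read.id,
                subject_id=genome.id,
                percent_identity=100.0 * matches / L,
                alignment_length=L,
                mismatches=L - matches,
                gap_opens=0,
                q_start=1,
                q_end=L,
                s_start=s_start,
                s_end=s_end,
                evalue=0.0,
                bit_score=2.0 * matches,
            )
        )
    return hits


def recruitment_profile(
    filtered_hits: Sequence[TabularHit], genome_length: int
) -> list[tuple[float, float]]:
    """(subject midpoint, percent identity) points, sorted by position."""
    profile = []
    for h in filtered_hits:
        lo, hi = min(h.s_start, h.s_end), max(h.s_start, h.s_end)
        if lo < 1 or hi > genome_length:
            raise ValueError(
                f"hit {h.query_id!r} subject interval [{lo}, {hi}] outside "
                f"genome of length {genome_length}"
            )
        profile.append(((lo + hi) / 2.0, h.percent_identity))
    profile.sort(key=lambda p: (p[0], p[1]))
    return profile


def recruit(
    reads: Sequence[SeqRecord],
    genome: SeqRecord,
    min_len: int = 50,
    min_identity: float = 95.0,
    max_evalue: float = 1e-5,
    k: int = 21,
    hits: Sequence[TabularHit] | None = None,
) -> RecruitmentResult:
    """Full recruitment of a read set against one genome.

    ``hits`` may carry precomputed alignments (e.g. parsed BLAST tabular);
    otherwise `mini_align` is used.  The metagenome size is the total base
    count of *all* reads.
    """
    if hits is None:
        hits = mini_align(reads, genome, k=k)
    kept = filter_hits(
        hits, min_len=min_len, min_identity=min_identity, max_evalue=max_evalue
    )
    genome_kb = len(genome.sequence) / 1e3
    metagenome_gb = sum(len(r.sequence) for r in reads) / 1e9
    return RecruitmentResult(
        genome_id=genome.id,
        genome_kb=genome_kb,
        metagenome_gb=metagenome_gb,
        reads_recruited=len(kept),
        rpkg=rpkg(len(kept), genome_kb, metagenome_gb),
        profile=recruitment_profile(kept, len(genome.sequence)),
    )
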