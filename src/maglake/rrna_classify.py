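"""16S rRNA read classification against a redundancy-reduced reference.

The classification logic mirrors a standard raw-read community profiling
scheme: (1) the reference collection is reduced by greedy identity
clustering at 90%, longest sequence first; (2) reads hitting the clustered
reference at e-value < 1e-5 become rRNA candidates; (3) each candidate is
assigned the taxon of its best reference hit when identity >= 80% and
alignment length >= 90 bp, and discarded otherwise.  An external keep-list
hook lets a full pipeline splice in an HMM-based rRNA validation stage
between steps 2 and 3.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import edlib

from .io_formats import SeqRecord, TabularHit
from .recruitment import GenomeIndex, gapless_best_hit, mini_align, reverse_complement

DISCARDED = "DISCARDED"


@dataclass(frozen=True)
class TaxonomyRecord:
    ref_id: str
    taxon: str


@dataclass
class ClassifiedRead:
    read_id: str
    taxon: str
    best_identity: float
    best_aln_len: int


def _kmer_set(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def pairwise_identity(
    a: str, b: str, method: str = "offset", prefilter_k: int = 8
) -> float:
    """Global identity between two sequences, as a fraction.

    ``offset`` (default): gapless best-offset alignment — candidate offsets
    come from shared k-mers and identity is matches over the overlap length
    at the best offset.  ``dp``: full dynamic-programming edit distance
    (edlib, Needleman-Wunsch mode) with identity = 1 - dist / max(len); the
    exact oracle route.
    """
    if method == "dp":
        res = edlib.align(a, b, mode="NW", task="distance")
        return 1.0 - res["editDistance"] / max(len(a), len(b))
    if method != "offset":
        raise ValueError(f"unknown identity method {method!r}")
    if not _kmer_set(a, prefilter_k) & _kmer_set(b, prefilter_k):
        return 0.0
    rec = SeqRecord(id="_b", description="", sequence=b)
    idx = GenomeIndex(rec, k=prefilter_k)
    res = gapless_best_hit(a, idx, allow_overhang=True)
    if res is None:
        return 0.0
    _, matches, _, aln_len = res
    return matches / aln_len if aln_len else 0.0


def greedy_cluster(
    references: Sequence[SeqRecord],
    identity: float = 0.90,
    method: str = "offset",
) -> list[SeqRecord]:
    """Greedy centroid clustering; returns the centroid sequences.

    Sequences are processed longest first (ties keep input order); each
    joins the first existing centroid it matches at >= the identity
    threshold, otherwise it founds a new centroid.  Deterministic, and
    invariant to duplicated inputs.
    """
    if not references:
        raise ValueError("need at least one reference sequence")
    ordered = sorted(
        enumerate(references), key=lambda t: (-len(t[1].sequence), t[0])
    )
    centroids: list[SeqRecord] = []
    for _, rec in ordered:
        joined = False
        for cen in centroids:
            if pairwise_identity(rec.sequence, cen.sequence, method=method) >= identity:
                joined = True
                break
        if not joined:
            centroids.append(rec)
    return centroids


def screen_candidates(
    read_hits: Sequence[TabularHit], max_evalue: float = 1e-5
) -> set[str]:
    """Read ids with any hit at e-value strictly below the cutoff."""
    return {h.query_id for h in read_hits if h.evalue < max_evalue}


def classify_reads(
    candidate_hits: Sequence[TabularHit],
    taxonomy: Sequence[TaxonomyRecord],
    min_identity: float = 80.0,
    min_len: int = 90,
    keep_list: set[str] | None = None,
) -> tuple[list[ClassifiedRead], dict[str, float]]:
    """Assign each read the taxon of its best reference hit.

    The best hit is the highest bit score (ties resolved by input order);
    the read is assigned its taxon when identity >= ``min_identity`` and
    alignment length >= ``min_len``, else marked DISCARDED.  ``keep_list``
    (e.g. from an external HMM validation) restricts which reads are
    classified at all.  The composition table gives percentages over
    assigned reads.
    """
    taxon_of = {t.ref_id: t.taxon for t in taxonomy}
    best: dict[str, TabularHit] = {}
    order: list[str] = []
    for h in candidate_hits:
        if h.subject_id not in taxon_of:
            raise KeyError(
                f"subject id {h.subject_id!r} not present in the taxonomy table"
            )
        if keep_list is not None and h.query_id not in keep_list:
            continue
        prev = best.get(h.query_id)
        if prev is None:
            best[h.query_id] = h
            order.append(h.query_id)
        elif h.bit_score > prev.bit_score:
            best[h.query_id] = h
    classified: list[ClassifiedRead] = []
    for read_id in order:
        h = best[read_id]
        ok = h.percent_identity >= min_identity and h.alignment_length >= min_len
        classified.append(
            ClassifiedRead(
                read_id=read_id,
                taxon=taxon_of[h.subject_id] if ok else DISCARDED,
                best_identity=h.percent_identity,
                best_aln_len=h.alignment_length,
            )
        )
    assigned = [c for c in classified if c.taxon != DISCARDED]
    composition: dict[str, float] = {}
    if assigned:
        for c in assigned:
            composition[c.taxon] = composition.get(c.taxon, 0.0) + 1.0
        for taxon in composition:
            composition[taxon] = 100.0 * composition[taxon] / len(assigned)
    return classified, composition


def align_reads_to_references(
    reads: Iterable[SeqRecord],
    references: Sequence[SeqRecord],
    k: int = 15,
) -> list[TabularHit]:
    """Desk-scale stand-in for a BLASTN search of reads vs. a 16S reference.

    Each read is gaplessly aligned against every reference (both strands);
    the best placement per (read, reference) pair is emitted, so downstream
    best-hit selection sees the full competition across references.
    """
    hits: list[TabularHit] = []
    indexes = [GenomeIndex(ref, k=k) for ref in references]
    for read in reads:
        for ref, idx in zip(references, indexes):
            per_ref = mini_align([read], ref, k=k, index=idx)
            hits.extend(per_ref)
    return hits
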