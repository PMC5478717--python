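"""Fully labeled synthetic metagenomic community generator.

Everything downstream of assembly is testable without external data by
generating a community whose truth is known: genomes with controlled GC and
implanted single-copy markers, contigs with recorded provenance, reads with
known source position and error count, 16S-like reference families at
controlled divergence, gene annotations with a controlled spacer scale, and
proteomes with a controlled acidic/basic residue bias.

Genomes are i.i.d. base draws at a target GC — compositional separation
between community members is then carried by GC, which is exactly the axis
composition binning exploits; an optional order-2 Markov mode produces
genomes with correlated 4-mer structure for harder binning problems.  Reads
carry substitution errors only: the recruitment filters under test act on
identity and length, so indels would add bookkeeping without coverage.
All generators are bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .composition_binning import ContigRecord
from .io_formats import GeneFeature, SeqRecord
from .marker_completeness import MarkerSet
from .proteome_pi import ProteinRecord
from .rrna_classify import TaxonomyRecord

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

# residue pools for the proteome generator: a neutral background plus both
# charged blocks, tilted per class.  An 18% total charged-residue budget
# split 14/4 puts the acidic class's pI peak near 4.5 and the basic class's
# near 11 — the bimodal shape whole-proteome pI profiles actually show.
_AA_BACKGROUND = "ALGVSTIPFNQYWMH"
_CHARGED_MAJOR = 0.14  # share of the class's favored pair (D/E or K/R)
_CHARGED_MINOR = 0.04  # share of the opposing pair


@dataclass
class SyntheticGenome:
    id: str
    sequence: str
    target_gc: float
    markers_present: tuple[str, ...] = ()
    marker_positions: dict[str, int] = field(default_factory=dict)  # 1-based
    truth_label: str = ""

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class LabeledRead:
    id: str
    sequence: str
    source_genome: str
    source_pos: int  # 1-based start on the + strand of the source
    strand: str
    n_errors: int

    def as_seqrecord(self) -> SeqRecord:
        return SeqRecord(id=self.id, description="", sequence=self.sequence)


def _random_sequence(length: int, gc: float, rng: np.random.Generator) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    idx = rng.choice(4, size=length, p=p)
    return _BASES[idx].tobytes().decode("ascii")


def _markov2_sequence(length: int, gc: float, rng: np.random.Generator) -> str:
    """Order-2 Markov chain whose stationary composition still targets gc."""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    # perturb conditional rows deterministically from the generator so the
    # 4-mer structure is genome-specific yet the GC target is preserved
    trans = np.tile(p, (16, 1))
    trans += rng.uniform(-0.08, 0.08, size=trans.shape)
    trans = np.clip(trans, 0.01, None)
    trans /= trans.sum(axis=1, keepdims=True)
    seq = list(rng.choice(4, size=2, p=p))
    for _ in range(length - 2):
        ctx = seq[-2] * 4 + seq[-1]
        seq.append(rng.choice(4, p=trans[ctx]))
    return _BASES[np.array(seq)].tobytes().decode("ascii")


def generate_genome(
    length: int,
    gc: float,
    seed: int,
    genome_id: str = "genome",
    truth_label: str = "",
    markers: Sequence[str] = (),
    mode: str = "iid",
) -> SyntheticGenome:
    """Generate a random genome with target GC and implanted marker anchors.

    Each listed marker id is assigned a distinct anchor position on the
    genome; a contig recovered from a region containing the anchor is
    considered to carry the marker (see :func:`markers_in_contigs`).
    """
    if length < 1000:
        raise ValueError("genome length must be >= 1000")
    if not 0.0 <= gc <= 1.0:
        raise ValueError(f"gc must lie in [0, 1], got {gc}")
    rng = np.random.default_rng(seed)
    if mode == "iid":
        sequence = _random_sequence(length, gc, rng)
    elif mode == "markov2":
        sequence = _markov2_sequence(length, gc, rng)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    markers = tuple(markers)
    positions = {}
    if markers:
        anchors = rng.choice(length, size=len(markers), replace=False)
        positions = {m: int(a) + 1 for m, a in zip(markers, sorted(anchors))}
    return SyntheticGenome(
        id=genome_id,
        sequence=sequence,
        target_gc=gc,
        markers_present=markers,
        marker_positions=positions,
        truth_label=truth_label or genome_id,
    )


def fragment_genome(
    genome: SyntheticGenome,
    n_contigs: int,
    min_len: int,
    seed: int,
    coverage: dict[str, float] | None = None,
) -> list[ContigRecord]:
    """Cut a genome into consecutive non-overlapping contigs, each >= min_len.

    The contigs tile the genome in order (total length = genome length) and
    record their source genome and 1-based start, so every downstream result
    can be scored against truth.
    """
    L = len(genome.sequence)
    if n_contigs < 1 or n_contigs * min_len > L:
        raise ValueError(
            f"cannot cut {L} bp into {n_contigs} contigs of >= {min_len} bp"
        )
    rng = np.random.default_rng(seed)
    slack = L - n_contigs * min_len
    extra = rng.multinomial(slack, np.full(n_contigs, 1.0 / n_contigs))
    lengths = (min_len + extra).tolist()
    contigs: list[ContigRecord] = []
    pos = 0
    for i, ln in enumerate(lengths):
        contigs.append(
            ContigRecord(
                id=f"{genome.id}_c{i:03d}",
                sequence=genome.sequence[pos : pos + ln],
                coverage=dict(coverage or {}),
                source_genome=genome.id,
                source_start=pos + 1,
            )
        )
        pos += ln
    return contigs


def markers_in_contigs(
    genome: SyntheticGenome, contigs: Iterable[ContigRecord]
) -> list[tuple[str, str]]:
    """Marker hit table for the genome's markers recovered in the contigs.

    A marker is recovered when its anchor position falls inside a contig
    that originates from the genome.  Returns (protein_id, marker_id) pairs
    in the shape `call_marker_presence` consumes.
    """
    hits: list[tuple[str, str]] = []
    for c in contigs:
        if c.source_genome != genome.id or c.source_start is None:
            continue
        lo = c.source_start
        hi = c.source_start + c.length - 1
        for marker, pos in genome.marker_positions.items():
            if lo <= pos <= hi:
                hits.append((f"{c.id}_p{pos}", marker))
    return hits


def mutate_sequence(sequence: str, divergence: float, seed: int) -> str:
    """Substitute an exact ``divergence`` fraction of sites to another base."""
    if not 0.0 <= divergence < 1.0:
        raise ValueError("divergence must lie in [0, 1)")
    n_sub = round(divergence * len(sequence))
    if n_sub == 0:
        return sequence
    rng = np.random.default_rng(seed)
    sites = rng.choice(len(sequence), size=n_sub, replace=False)
    seq = np.frombuffer(sequence.encode("ascii"), dtype="S1").copy()
    base_order = {b: i for i, b in enumerate(_BASES)}
    shifts = rng.integers(1, 4, size=n_sub)
    for site, shift in zip(sites, shifts):
        cur = base_order[seq[site]]
        seq[site] = _BASES[(cur + shift) % 4]
    return seq.tobytes().decode("ascii")


def simulate_reads(
    genomes: Sequence,
    coverages: dict[str, float],
    read_len: int = 100,
    error_rate: float = 0.02,
    seed: int = 0,
) -> list[LabeledRead]:
    """Uniform shotgun reads with i.i.d. substitution errors and truth labels.

    Per genome, the read count is round(coverage * genome_length / read_len);
    start positions and strands are uniform; each base flips to a different
    base independently with probability ``error_rate``.  ``genomes`` may be
    any objects exposing ``.id`` and ``.sequence``.
    """
    if not genomes:
        raise ValueError("need at least one source genome")
    if not 0.0 <= error_rate < 0.25:
        raise ValueError("error_rate must lie in [0, 0.25)")
    for g in genomes:
        if read_len > len(g.sequence):
            raise ValueError(f"read_len exceeds genome {g.id!r} length")
    rng = np.random.default_rng(seed)
    reads: list[LabeledRead] = []
    counter = 0
    for g in genomes:
        cov = coverages.get(g.id, 0.0)
        n_reads = round(cov * len(g.sequence) / read_len)
        if n_reads == 0:
            continue
        starts = rng.integers(0, len(g.sequence) - read_len + 1, size=n_reads)
        strands = rng.integers(0, 2, size=n_reads)
        for s0, fwd in zip(starts, strands):
            raw = g.sequence[s0 : s0 + read_len]
            strand = "+" if fwd == 0 else "-"
            if strand == "-":
                raw = raw.translate(_COMPLEMENT)[::-1]
            err_mask = rng.random(read_len) < error_rate
            n_err = int(err_mask.sum())
            if n_err:
                arr = np.frombuffer(raw.encode("ascii"), dtype="S1").copy()
                base_order = {b: i for i, b in enumerate(_BASES)}
                shifts = rng.integers(1, 4, size=n_err)
                for site, shift in zip(np.flatnonzero(err_mask), shifts):
                    cur = base_order[arr[site]]
                    arr[site] = _BASES[(cur + shift) % 4]
                raw = arr.tobytes().decode("ascii")
            reads.append(
                LabeledRead(
                    id=f"read{counter:07d}",
                    sequence=raw,
                    source_genome=g.id,
                    source_pos=int(s0) + 1,
                    strand=strand,
                    n_errors=n_err,
                )
            )
            counter += 1
    return reads


def make_taxonomy_reference(
    n_taxa: int,
    divergence: float,
    ref_len: int = 1200,
    seed: int = 0,
    gc: float = 0.5,
) -> tuple[list[SeqRecord], list[TaxonomyRecord]]:
    """Labeled 16S-like reference family derived from a common root.

    Each taxon substitutes an exact ``divergence`` fraction of root sites
    (independent site sets, each to one of the 3 other bases), so two taxa
    at divergence d mismatch at a site with probability
    2d(1 - d) + (2/3)d^2, i.e. expected identity 1 - 2d(1 - 2d/3).
    """
    if n_taxa < 2:
        raise ValueError("need at least 2 taxa")
    if not 0.0 < divergence < 0.5:
        raise ValueError("divergence must lie in (0, 0.5); 0 collapses taxa")
    rng = np.random.default_rng(seed)
    root = _random_sequence(ref_len, gc, rng)
    records: list[SeqRecord] = []
    taxonomy: list[TaxonomyRecord] = []
    for i in range(n_taxa):
        sub_seed = int(rng.integers(0, 2**31 - 1))
        seq = mutate_sequence(root, divergence, sub_seed)
        ref_id = f"ref_{i:02d}"
        records.append(SeqRecord(id=ref_id, description=f"taxon Taxon_{i:02d}", sequence=seq))
        taxonomy.append(TaxonomyRecord(ref_id=ref_id, taxon=f"Taxon_{i:02d}"))
    return records, taxonomy


def annotate_genes(
    genome: SyntheticGenome,
    mean_gene_len: int = 900,
    mean_spacer: float = 20.0,
    seed: int = 0,
) -> list[GeneFeature]:
    """Tile a genome with genes separated by geometric spacers.

    The spacer scale (default mean 20 bp) emulates a streamlined genome in
    which coding regions are packed tightly; gene lengths are normal around
    ``mean_gene_len`` and strands alternate pseudo-randomly.
    """
    rng = np.random.default_rng(seed)
    genes: list[GeneFeature] = []
    pos = 1
    i = 0
    L = len(genome.sequence)
    while True:
        gene_len = max(90, int(rng.normal(mean_gene_len, mean_gene_len / 6)))
        if pos + gene_len - 1 > L:
            break
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(
            GeneFeature(
                contig_id=genome.id,
                start=pos,
                end=pos + gene_len - 1,
                strand=strand,
                gene_id=f"{genome.id}_g{i:04d}",
            )
        )
        spacer = int(rng.geometric(1.0 / (mean_spacer + 1.0))) - 1
        pos += gene_len + spacer + 1
        i += 1
    return genes


def generate_proteome(
    n_proteins: int,
    basic_fraction: float,
    mean_len: int = 250,
    seed: int = 0,
) -> list[ProteinRecord]:
    """Proteins with a controlled acidic/basic residue bias.

    Exactly round(basic_fraction * n) proteins (not a binomial draw) are
    built with a K/R-tilted composition; the rest are D/E-tilted.  The
    truth class is recorded on each record, and annotations mark a share of
    each class as transporter/membrane proteins so keyword subsetting has
    labeled input.
    """
    if not 0.0 <= basic_fraction <= 1.0:
        raise ValueError("basic_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n_basic = round(basic_fraction * n_proteins)
    pool = np.array(list(_AA_BACKGROUND + "DE" + "KR"))
    bg_share = 1.0 - _CHARGED_MAJOR - _CHARGED_MINOR
    proteins: list[ProteinRecord] = []
    for i in range(n_proteins):
        is_basic = i < n_basic
        de = _CHARGED_MINOR if is_basic else _CHARGED_MAJOR
        kr = _CHARGED_MAJOR if is_basic else _CHARGED_MINOR
        probs = np.concatenate(
            [
                np.full(len(_AA_BACKGROUND), bg_share / len(_AA_BACKGROUND)),
                np.full(2, de / 2),
                np.full(2, kr / 2),
            ]
        )
        length = max(30, int(rng.poisson(mean_len)))
        seq = "".join(rng.choice(pool, size=length, p=probs))
        cls = "basic" if is_basic else "acidic"
        if rng.random() < 0.3:
            kind = rng.choice(
                ["ABC-type transporter", "permease", "efflux pump", "membrane protein"]
            )
            annotation = f"synthetic {cls}-class {kind}"
        else:
            annotation = f"synthetic {cls}-class cytosolic protein"
        proteins.append(
            ProteinRecord(
                id=f"prot{i:05d}",
                sequence=seq,
                annotation=annotation,
                truth_class=cls,
            )
        )
    return proteins
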