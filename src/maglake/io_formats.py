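"""Readers and writers for the flat-file formats the pipeline touches.

Sequence data move as FASTA/FASTQ, local-alignment hits as 12-column BLAST
tabular (outfmt 6), and gene coordinates as GFF3.  Parsing is strict: records
are validated on read (unique ids, legal alphabet, sane coordinates) and
malformed input is rejected with the offending line number, because silently
tolerated junk in a metagenomic pipeline surfaces much later as an
unexplainable bin.  All coordinates are 1-based inclusive, the GFF/BLAST
convention; any half-open arithmetic stays internal and is never serialized.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

NT_ALPHABET = frozenset("ACGTN")
AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")
_ALPHABETS = {"nt": NT_ALPHABET, "aa": AA_ALPHABET}


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass
class SeqRecord:
    """A validated sequence record (nucleotide or protein)."""

    id: str
    description: str
    sequence: str

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class TabularHit:
    """One local-alignment hit in the 12-column BLAST tabular dialect."""

    query_id: str
    subject_id: str
    percent_identity: float
    alignment_length: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    evalue: float
    bit_score: float

    def __post_init__(self) -> None:
        if self.alignment_length < 1:
            raise FormatError(
                f"alignment_length must be >= 1, got {self.alignment_length}"
            )
        if not 0.0 <= self.percent_identity <= 100.0:
            raise FormatError(
                f"percent_identity out of [0, 100]: {self.percent_identity}"
            )
        if self.evalue < 0:
            raise FormatError(f"negative e-value: {self.evalue}")


@dataclass(frozen=True)
class GeneFeature:
    """A gene (CDS) interval on a contig, 1-based inclusive."""

    contig_id: str
    start: int
    end: int
    strand: str
    gene_id: str

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise FormatError(
                f"bad coordinates for {self.gene_id!r}: "
                f"start={self.start} end={self.end}"
            )
        if self.strand not in {"+", "-"}:
            raise FormatError(
                f"unknown strand {self.strand!r} for {self.gene_id!r}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def _validate_records(
    records: list[SeqRecord], molecule: str, path: Path
) -> list[SeqRecord]:
    alphabet = _ALPHABETS[molecule]
    seen: set[str] = set()
    for rec in records:
        if not rec.id:
            raise FormatError(f"{path}: record with empty id")
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        if not rec.sequence:
            raise FormatError(f"{path}: empty sequence for {rec.id!r}")
        bad = set(rec.sequence) - alphabet
        if bad:
            line = _find_offending_line(path, bad)
            raise FormatError(
                f"{path}: illegal {molecule} character(s) "
                f"{sorted(bad)} in record {rec.id!r} (line {line})"
            )
    return records


def _find_offending_line(path: Path, bad_chars: set[str]) -> int:
    """Locate the first sequence line containing a rejected character."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith((">", "@", "+")):
                continue
            if bad_chars & set(line.strip().upper()):
                return lineno
    return -1


def read_fasta(path: str | Path, molecule: str = "nt") -> list[SeqRecord]:
    """Read a FASTA file into validated records, in file order.

    Lowercase bases are normalized to uppercase.  Duplicate ids and
    characters outside the declared alphabet are errors.
    """
    path = Path(path)
    if molecule not in _ALPHABETS:
        raise ValueError(f"molecule must be 'nt' or 'aa', got {molecule!r}")
    records = [
        SeqRecord(id=r.id, description=r.description, sequence=str(r.seq).upper())
        for r in SeqIO.parse(str(path), "fasta")
    ]
    return _validate_records(records, molecule, path)


def read_fastq(path: str | Path, molecule: str = "nt") -> list[SeqRecord]:
    """Read FASTQ reads; qualities are checked for length, then dropped."""
    path = Path(path)
    records = [
        SeqRecord(id=r.id, description=r.description, sequence=str(r.seq).upper())
        for r in SeqIO.parse(str(path), "fastq")
    ]
    return _validate_records(records, molecule, path)


def write_fasta(records: Iterable[SeqRecord], path: str | Path, width: int = 70) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id
            if rec.description and rec.description != rec.id:
                desc = rec.description
                if desc.startswith(rec.id + " "):
                    desc = desc[len(rec.id) + 1 :]
                header = f"{rec.id} {desc}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def read_tabular_hits(path: str | Path) -> list[TabularHit]:
    """Parse BLAST tabular (outfmt 6) hits.

    Comment lines (``#``) and blank lines are skipped; any other line must
    have exactly 12 tab-separated columns with numeric fields that parse.
    """
    path = Path(path)
    hits: list[TabularHit] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 12:
                raise FormatError(
                    f"{path}:{lineno}: expected 12 tab-separated columns, "
                    f"got {len(cols)}"
                )
            try:
                hit = TabularHit(
                    query_id=cols[0],
                    subject_id=cols[1],
                    percent_identity=float(cols[2]),
                    alignment_length=int(cols[3]),
                    mismatches=int(cols[4]),
                    gap_opens=int(cols[5]),
                    q_start=int(cols[6]),
                    q_end=int(cols[7]),
                    s_start=int(cols[8]),
                    s_end=int(cols[9]),
                    evalue=float(cols[10]),
                    bit_score=float(cols[11]),
                )
            except (ValueError, FormatError) as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            if math.isnan(hit.evalue) or math.isnan(hit.bit_score):
                raise FormatError(f"{path}:{lineno}: NaN numeric field")
            hits.append(hit)
    return hits


def write_tabular_hits(hits: Iterable[TabularHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                "\t".join(
                    [
                        h.query_id,
                        h.subject_id,
                        f"{h.percent_identity:.2f}",
                        str(h.alignment_length),
                        str(h.mismatches),
                        str(h.gap_opens),
                        str(h.q_start),
                        str(h.q_end),
                        str(h.s_start),
                        str(h.s_end),
                        f"{h.evalue:.2g}",
                        f"{h.bit_score:.1f}",
                    ]
                )
                + "\n"
            )


def read_gff_genes(
    path: str | Path, feature_type: str = "CDS"
) -> list[GeneFeature]:
    """Read gene features of one type from GFF3, sorted by (contig, start).

    The gene id is taken from the ``ID=`` attribute when present, else a
    positional id is synthesized.
    """
    path = Path(path)
    feats: list[GeneFeature] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise FormatError(
                    f"{path}:{lineno}: expected 9 GFF3 columns, got {len(cols)}"
                )
            if cols[2] != feature_type:
                continue
            try:
                start, end = int(cols[3]), int(cols[4])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            gene_id = f"{cols[0]}:{start}-{end}"
            for attr in cols[8].split(";"):
                if attr.startswith("ID="):
                    gene_id = attr[3:]
                    break
            try:
                feats.append(
                    GeneFeature(
                        contig_id=cols[0],
                        start=start,
                        end=end,
                        strand=cols[6],
                        gene_id=gene_id,
                    )
                )
            except FormatError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    feats.sort(key=lambda f: (f.contig_id, f.start, f.end))
    return feats


def write_gff_genes(
    features: Sequence[GeneFeature], path: str | Path, feature_type: str = "CDS"
) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            fh.write(
                "\t".join(
                    [
                        f.contig_id,
                        "maglake",
                        feature_type,
                        str(f.start),
                        str(f.end),
                        ".",
                        f.strand,
                        "0",
                        f"ID={f.gene_id}",
                    ]
                )
                + "\n"
            )
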