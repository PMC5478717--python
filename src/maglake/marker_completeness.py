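"""Marker-based genome completeness and total-size extrapolation.

The fraction of a universal single-copy gene set detected in an assembly
estimates its completeness, and dividing the assembled length by that
fraction extrapolates the total genome size:

    completeness = 100 * markers_found / markers_total        [percent]
    estimated_size = assembled_bp / (completeness / 100)      [bases]

Marker detection itself (HMM or BLAST screening) is delegated to upstream
tools; this module consumes a hit table of (protein_id, marker_id) pairs.
Copy number is ignored — completeness counts distinct markers present.  Two
universal set sizes are bundled (35 and 111 genes) with user-replaceable
content; completeness is reported to 2 decimals and extrapolated sizes to
2 decimals in Mb.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence


@dataclass(frozen=True)
class MarkerSet:
    """A named universal single-copy gene list."""

    name: str
    markers: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.markers)) != len(self.markers):
            raise ValueError(f"duplicate marker ids in set {self.name!r}")

    @property
    def size(self) -> int:
        return len(self.markers)

    @classmethod
    def from_tsv(cls, path: str | Path, name: str | None = None) -> "MarkerSet":
        path = Path(path)
        markers = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if line and not line.startswith("#"):
                    markers.append(line.split("\t")[0])
        return cls(name=name or path.stem, markers=tuple(markers))

    @classmethod
    def bundled(cls, which: str) -> "MarkerSet":
        """Load a bundled set: ``"set35"`` or ``"set111"``."""
        fname = {"set35": "markers_set35.tsv", "set111": "markers_set111.tsv"}[which]
        text = resources.files("maglake.data").joinpath(fname).read_text()
        markers = tuple(
            line.split("\t")[0]
            for line in text.splitlines()
            if line.strip() and not line.startswith("#")
        )
        return cls(name=which, markers=markers)


@dataclass
class CompletenessReport:
    markers_found: int
    markers_total: int
    completeness_pct: float
    assembled_bp: int
    estimated_bp: float

    @property
    def estimated_mb(self) -> float:
        return round(self.estimated_bp / 1e6, 2)


def completeness(found: int, total: int) -> float:
    """Percent of the marker set present, to 2 decimals."""
    if total < 1:
        raise ValueError("marker set must contain at least one marker")
    if not 0 <= found <= total:
        raise ValueError(f"found={found} outside [0, {total}]")
    return round(100.0 * found / total, 2)


def estimated_genome_size(assembled_bp: float, completeness_pct: float) -> float:
    """Extrapolated total genome size in bases."""
    if completeness_pct <= 0:
        raise ValueError("completeness must be positive to extrapolate size")
    return assembled_bp / (completeness_pct / 100.0)


def estimated_genome_size_mb(assembled_bp: float, completeness_pct: float) -> float:
    """Extrapolated genome size in Mb, to 2 decimals (reporting scale)."""
    return round(estimated_genome_size(assembled_bp, completeness_pct) / 1e6, 2)


def call_marker_presence(
    hits: Iterable[tuple[str, str]] | str | Path,
    marker_set: MarkerSet,
) -> dict[str, bool]:
    """Boolean presence per marker from a (protein_id, marker_id) hit table.

    ``hits`` may be an iterable of pairs or a path to a 2-column TSV.
    Duplicate hits to one marker count once; hits naming a marker outside the
    set raise a warning and are ignored.
    """
    if isinstance(hits, (str, Path)):
        pairs = []
        with open(hits) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line.strip() or line.startswith("#"):
                    continue
                cols = line.split("\t")
                if len(cols) < 2:
                    raise ValueError(f"marker hit line needs 2 columns: {line!r}")
                pairs.append((cols[0], cols[1]))
    else:
        pairs = list(hits)
    known = set(marker_set.markers)
    present: set[str] = set()
    for _protein, marker in pairs:
        if marker not in known:
            warnings.warn(
                f"hit to marker {marker!r} not in set {marker_set.name!r}; ignored",
                stacklevel=2,
            )
            continue
        present.add(marker)
    return {m: (m in present) for m in marker_set.markers}


def completeness_report(
    hits: Iterable[tuple[str, str]] | str | Path,
    marker_set: MarkerSet,
    assembled_bp: int,
) -> CompletenessReport:
    """Full report: presence calls -> completeness -> extrapolated size."""
    presence = call_marker_presence(hits, marker_set)
    found = sum(presence.values())
    pct = completeness(found, marker_set.size)
    est = estimated_genome_size(assembled_bp, pct) if pct > 0 else float("inf")
    return CompletenessReport(
        markers_found=found,
        markers_total=marker_set.size,
        completeness_pct=pct,
        assembled_bp=assembled_bp,
        estimated_bp=est,
    )
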