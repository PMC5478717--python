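"""Composition- and taxonomy-based contig binning.

Contigs assembled from a metagenome are assigned to draft genomes by combining
four signals: a per-contig taxonomy vote over gene-level top hits, the first
principal components of tetranucleotide word frequencies, GC content, and
per-sample read coverage.  Clustering on these standardized axes recovers the
population structure because co-occurring clones of one species share
composition (GC, 4-mer usage) and abundance, while different species differ on
at least one axis.

Tetranucleotide counts are pooled over each contig and its reverse complement
so the signature is strand-invariant; windows containing non-ACGT characters
are skipped.  All 256 raw words are kept (no canonical collapsing).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .genome_stats import gc_content

_LUT = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _LUT[_b] = _i

# index of the reverse complement of each 4-mer word
_RC_PERM = np.empty(256, dtype=np.intp)
for _w in range(256):
    _d = [(_w >> s) & 3 for s in (6, 4, 2, 0)]
    _RC_PERM[_w] = sum((3 - d) << s for d, s in zip(reversed(_d), (6, 4, 2, 0)))


@dataclass
class ContigRecord:
    """An assembled contig with composition and coverage metadata."""

    id: str
    sequence: str
    coverage: dict[str, float] = field(default_factory=dict)
    gene_tophits: list[tuple[str, str]] = field(default_factory=list)
    source_genome: str | None = None  # truth label, synthetic data only
    source_start: int | None = None  # 1-based position in source genome

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"empty contig {self.id!r}")
        if any(c < 0 for c in self.coverage.values()):
            raise ValueError(f"negative coverage on contig {self.id!r}")

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def gc(self) -> float:
        return gc_content(self.sequence)


@dataclass
class CompositionFeatures:
    """Per-contig feature bundle used for clustering."""

    contig_id: str
    tetra: np.ndarray
    pc_scores: np.ndarray
    gc: float
    log_coverage: dict[str, float]


@dataclass
class Bin:
    """A group of contigs putatively from one genome."""

    bin_id: str
    contig_ids: list[str]
    total_bp: int
    mean_gc: float
    mean_coverage: float


@dataclass
class PCAResult:
    scores: np.ndarray
    components: np.ndarray
    explained_variance: np.ndarray
    mean: np.ndarray


def tetra_freqs(sequence: str) -> np.ndarray:
    """Strand-pooled tetranucleotide frequency vector (length 256, sums to 1).

    Counts every 4-bp window of the sequence and of its reverse complement;
    windows containing a non-ACGT character are skipped on both strands.
    """
    arr = np.frombuffer(sequence.upper().encode("ascii"), dtype=np.uint8)
    if arr.size < 4:
        raise ValueError("sequence shorter than one 4-mer window")
    vals = _LUT[arr].astype(np.int64)
    ok = vals >= 0
    valid = ok[:-3] & ok[1:-2] & ok[2:-1] & ok[3:]
    if not valid.any():
        raise ValueError("no valid ACGT 4-mer window in sequence")
    v = np.where(ok, vals, 0)
    idx = (v[:-3] << 6) | (v[1:-2] << 4) | (v[2:-1] << 2) | v[3:]
    counts = np.bincount(idx[valid], minlength=256).astype(np.float64)
    pooled = counts + counts[_RC_PERM]
    return pooled / pooled.sum()


def taxonomy_vote(
    gene_tophits: Sequence[tuple[str, str]],
    target_taxon: str,
    threshold: float = 0.6,
) -> str:
    """Classify a contig by its genes' top-hit taxa.

    Returns ``"accept"`` when the share of genes hitting the target taxon is
    strictly greater than the threshold, ``"unassigned"`` when the contig has
    no genes, else ``"reject"``.  Adding a target hit can never flip an
    accept to a reject.
    """
    if not gene_tophits:
        return "unassigned"
    n_target = sum(1 for _, taxon in gene_tophits if taxon == target_taxon)
    return "accept" if n_target / len(gene_tophits) > threshold else "reject"


def project_pca(feature_matrix: np.ndarray, n_components: int) -> PCAResult:
    """Column-centered, unscaled PCA with a deterministic sign convention.

    Components are ordered by decreasing explained variance and each is
    flipped, if needed, so its largest-magnitude loading is positive.
    """
    X = np.asarray(feature_matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 rows")
    if n_components > min(X.shape):
        raise ValueError("n_components exceeds matrix rank bound")
    if np.allclose(X.var(axis=0), 0.0):
        raise ValueError("constant feature matrix has no principal axes")
    model = PCA(n_components=n_components, svd_solver="full")
    scores = model.fit_transform(X)
    components = model.components_.copy()
    for j in range(components.shape[0]):
        lead = np.argmax(np.abs(components[j]))
        if components[j, lead] < 0:
            components[j] *= -1.0
            scores[:, j] *= -1.0
    return PCAResult(
        scores=scores,
        components=components,
        explained_variance=model.explained_variance_.copy(),
        mean=model.mean_.copy(),
    )


def compute_features(
    contigs: Sequence[ContigRecord],
    n_components: int = 2,
    min_len: int = 5000,
) -> list[CompositionFeatures]:
    """Tetranucleotide PCA scores + GC + log-coverage for contigs >= min_len.

    Coverage enters as log10(coverage + 0.1): fold-coverage is multiplicative
    and the offset keeps zero-coverage contigs finite.
    """
    kept = [c for c in contigs if c.length >= min_len]
    if len(kept) < 2:
        raise ValueError("need at least 2 contigs above the length cutoff")
    tetra = np.vstack([tetra_freqs(c.sequence) for c in kept])
    pca = project_pca(tetra, n_components=n_components)
    feats = []
    for i, c in enumerate(kept):
        feats.append(
            CompositionFeatures(
                contig_id=c.id,
                tetra=tetra[i],
                pc_scores=pca.scores[i],
                gc=c.gc,
                log_coverage={
                    s: float(np.log10(v + 0.1)) for s, v in c.coverage.items()
                },
            )
        )
    return feats


def _feature_matrix(features: Sequence[CompositionFeatures]) -> np.ndarray:
    """Standardized clustering matrix [PC axes, GC, per-sample log-coverage].

    GC and log-coverage are z-scored so units do not matter.  The tetra PC
    axes are z-scored and then weighted by their share of the variance the
    kept components explain: when the community has real compositional
    structure PC1 keeps nearly full weight, and when composition is
    uninformative (identical-GC genomes) the PC axes shrink instead of
    flooding the distance metric with unit-variance noise, which would
    otherwise swamp a genuine coverage separation.
    """
    samples = sorted({s for f in features for s in f.log_coverage})
    rows = []
    for f in features:
        pcs = list(f.pc_scores[:2])
        while len(pcs) < 2:
            pcs.append(0.0)
        row = [*pcs, f.gc]
        row.extend(f.log_coverage.get(s, np.log10(0.1)) for s in samples)
        rows.append(row)
    X = np.asarray(rows, dtype=float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd
    pc_var = X[:, :2].var(axis=0)
    total = pc_var.sum()
    if total > 0:
        Z[:, :2] *= pc_var / total
    return Z


def bin_contigs(
    features: Sequence[CompositionFeatures],
    contigs: Sequence[ContigRecord],
    k: int,
    seed: int = 0,
    gates: Mapping[str, Mapping[str, tuple[float, float]]] | None = None,
) -> list[Bin]:
    """Partition contigs into ``k`` bins on [PC1, PC2, GC, log-coverage].

    Uses k-means (within-cluster variance minimization) on the standardized
    axes — tetra PC scores weighted by explained-variance share, z-scored GC
    and log-coverage — deterministic for a fixed seed.  If manual ``gates`` are supplied
    (bin id -> axis -> (lo, hi) rectangles over the axes ``pc1``, ``pc2``,
    ``gc``, ``log_coverage``), gating overrides clustering and ungated
    contigs are dropped.
    """
    if k > len(features):
        raise ValueError(f"k={k} exceeds number of contigs ({len(features)})")
    by_id = {c.id: c for c in contigs}
    if gates is not None:
        assignment: dict[str, str] = {}
        for f in features:
            axes = {
                "pc1": float(f.pc_scores[0]),
                "pc2": float(f.pc_scores[1]) if len(f.pc_scores) > 1 else 0.0,
                "gc": f.gc,
                "log_coverage": float(np.mean(list(f.log_coverage.values()))),
            }
            for bin_id, rect in gates.items():
                if all(lo <= axes[a] <= hi for a, (lo, hi) in rect.items()):
                    assignment[f.contig_id] = bin_id
                    break
        labels = [assignment.get(f.contig_id) for f in features]
        bin_ids = sorted(gates)
    else:
        X = _feature_matrix(features)
        km = KMeans(n_clusters=k, n_init=10, random_state=seed)
        raw = km.fit_predict(X)
        labels = [f"bin{lbl}" for lbl in raw]
        bin_ids = sorted(set(labels))

    bins: list[Bin] = []
    for bin_id in bin_ids:
        members = [
            by_id[f.contig_id]
            for f, lbl in zip(features, labels)
            if lbl == bin_id and f.contig_id in by_id
        ]
        if not members:
            continue
        total = sum(m.length for m in members)
        mean_gc = sum(m.gc * m.length for m in members) / total
        covs = [np.mean(list(m.coverage.values())) for m in members if m.coverage]
        bins.append(
            Bin(
                bin_id=bin_id,
                contig_ids=[m.id for m in members],
                total_bp=total,
                mean_gc=float(mean_gc),
                mean_coverage=float(np.mean(covs)) if covs else 0.0,
            )
        )
    return bins


def elbow_inertia(
    features: Sequence[CompositionFeatures], k_max: int = 8, seed: int = 0
) -> list[float]:
    """k-means inertia for k = 1..k_max — an elbow diagnostic, never acted on."""
    X = _feature_matrix(features)
    out = []
    for k in range(1, min(k_max, len(features)) + 1):
        km = KMeans(n_clusters=k, n_init=10, random_state=seed)
        km.fit(X)
        out.append(float(km.inertia_))
    return out


def binning_accuracy(
    bins: Sequence[Bin], contigs: Sequence[ContigRecord], weight_by_length: bool = False
) -> float:
    """Fraction of truth-labeled contigs placed in the best-matching bin.

    Bins are matched to source genomes by maximum-weight assignment so the
    score does not depend on arbitrary bin numbering.
    """
    labeled = {c.id: c for c in contigs if c.source_genome is not None}
    if not labeled:
        raise ValueError("no truth-labeled contigs")
    genomes = sorted({c.source_genome for c in labeled.values()})
    g_idx = {g: i for i, g in enumerate(genomes)}
    M = np.zeros((len(bins), len(genomes)))
    for bi, b in enumerate(bins):
        for cid in b.contig_ids:
            if cid in labeled:
                w = labeled[cid].length if weight_by_length else 1
                M[bi, g_idx[labeled[cid].source_genome]] += w
    rows, cols = linear_sum_assignment(-M)
    correct = M[rows, cols].sum()
    total = sum(
        (labeled[cid].length if weight_by_length else 1)
        for b in bins
        for cid in b.contig_ids
        if cid in labeled
    )
    return float(correct / total) if total else 0.0
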