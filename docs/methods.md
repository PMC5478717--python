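# Methods

This note documents the models and procedures `maglake` implements, the
parameters that matter, what the synthetic community does and does not
emulate, and the numerical choices made where the design was genuinely open.

## Scope and data model

The package reconstructs and characterizes picocyanobacterial
metagenome-assembled genomes (MAGs) from the post-assembly stage onward.
Assembly, read mapping and gene prediction are upstream concerns: inputs are
contigs and reads (FASTA/FASTQ), local-alignment hits (BLAST tabular,
outfmt 6), gene coordinates (GFF3) and marker/taxonomy tables (TSV).  All
coordinates are 1-based inclusive throughout; any half-open arithmetic is
internal and never serialized.

## Composition binning

Contigs ≥ 5 kb are described by four signals:

- **Tetranucleotide frequencies.** All 256 raw 4-mer words, counted over the
  contig *and its reverse complement* so the signature is strand-invariant,
  with windows containing non-ACGT characters skipped, normalized to sum 1.
  Raw words with strand pooling are used rather than collapsing to the 136
  canonical words; pooling already guarantees the invariance canonicalization
  would buy, and keeps the vector directly comparable to plain word counts.
- **PCA of the tetra matrix.** Column-centered, unscaled; components ordered
  by explained variance with the sign fixed so each component's
  largest-magnitude loading is positive (removes the eigenvector sign
  ambiguity, making scores reproducible).
- **GC content** (N excluded from numerator and denominator).
- **Per-sample fold-coverage**, entering as log10(coverage + 0.1): coverage
  is multiplicative across abundance regimes and the offset keeps
  zero-coverage contigs finite.

A per-contig **taxonomy vote** screens candidate contigs before binning:
accept when strictly more than 60% of a contig's genes give their top hit to
the target taxon, unassigned when the contig has no genes.  The threshold is
strict (0.60 itself rejects), and the vote is monotone — adding a
target-taxon hit can never turn an accept into a reject.

**Clustering.** k-means (within-cluster variance minimization, fixed seed,
10 restarts) on the axes [PC1, PC2, GC, log-coverage per sample].  GC and
log-coverage are z-scored.  The PC axes are z-scored and then *weighted by
their share of explained variance among the kept components*.  The weighting
matters: when community members share GC, the tetra PCs carry no signal, and
leaving them at unit variance lets k-means find a spurious noise split with
strictly lower inertia than the true coverage split (we measured 80.9 vs
83.0 on a two-genome, 10× coverage-ratio community — the truth is not the
optimum on equally scaled axes, so no variance-minimizing method could
recover it).  With variance-share weighting the informative configuration
wins in both regimes: GC-separated communities (PC1 keeps ≈ full weight) and
coverage-only-separated communities (both PCs shrink toward zero).

The number of bins k is user-supplied; no automatic model selection is
invented (an inertia-vs-k elbow diagnostic is emitted but never acted on).
Manual axis-rectangle gating is available as an override, since hand
curation in PCA/GC/coverage space is how such bins are drawn in practice.
An under-clustering diagnostic flags any bin whose within-bin GC standard
deviation exceeds 0.02 — several genomes merged into one bin spread far
beyond the ~0.002 sampling scatter of 5 kb contigs from one genome.

## Marker completeness and genome size

Completeness is presence/absence over a universal single-copy gene set:
`100 × found / total`, reported to 2 decimals; copy number is ignored.
Total genome size is extrapolated as `assembled_bp / (completeness/100)`,
reported in Mb to 2 decimals.  Two set sizes are bundled (35 and 111 genes)
with user-replaceable content; marker *detection* (HMM/BLAST search) is
delegated — the module consumes (protein_id, marker_id) hit tables.

## Fragment recruitment and RPKG

Recruitment filters: alignment length ≥ 50 bp, identity ≥ 95% (inclusive;
an exclusive variant is selectable), e-value ≤ 1e-5, then one best hit per
read (highest bit score, ties to input order — deterministic and
idempotent, and a read can never be counted twice against repeated
regions).  Abundance is RPKG = reads recruited / (genome kb × metagenome
Gb), where the metagenome size counts **all** read bases, recruited or not;
that denominator is what makes the statistic comparable across datasets.

The built-in aligner (`mini_align`) is a desk-scale gapless seed-and-extend:
exact 21-mer seeding at every read position on both strands, ungapped
extension over the full read, identity = matches/read length.  It reports
e-value 0 — an exact-seeded gapless hit at these read lengths is beyond any
practical significance cutoff — so the e-value filter effectively applies to
externally computed hit tables.  Seeding at every position (not a sparser
stride) makes the aligner exactly equivalent to a full Hamming scan for any
read retaining one intact seed k-mer, which is how it is tested.

## ANI

Fragment-based two-way average nucleotide identity: the query genome is cut
into consecutive 1020 bp fragments; each fragment's best gapless placement
on the subject (either strand, clipped at contig ends) is kept when identity
≥ 70% and fragment coverage ≥ 70%; the one-way ANI is the mean identity of
retained fragments and the reported ANI is the mean of both directions
(symmetric by construction).  All three constants are configurable; the
1020/70/70 convention is the standard fragment-ANI recipe.  When nothing
passes the floors the ANI is undefined (NaN) with aligned fraction 0 — the
non-species signal.  ANI is computed over aligned fragments only, with the
aligned fraction reported alongside rather than folded into the mean.

## Intergenic spacers

Per contig, genes sorted by start; spacer = next.start − prev.end − 1,
clamped at 0 for overlapping genes (the statistics then summarize true
gaps); strand ignored; contigs linear; gaps pooled across contigs; median
and mean reported.  Order of gene input is irrelevant.

## Proteome isoelectric points

Net charge at a given pH is the Henderson–Hasselbalch sum over ionizable
groups (side chains C, D, E, H, K, R, Y and both termini); the pI is its
unique root, found by bisection on [0, 14].  The bisection converges the
*pH interval* (width < 1e-8) rather than stopping at a small |Q|: for
weakly ionizable sequences the charge curve is shallow and an |Q|-only stop
can sit > 0.05 pH units from the root.  The |Q| < 1e-4 condition holds at
the converged root.  A brute-force 1e-4-step grid search over the same
charge function serves as the independent oracle in tests.

pKa scale (bundled as a swappable JSON config): C 8.5, D 3.9, E 4.1, H 6.5,
K 10.8, R 12.5, Y 10.1, N-terminus 8.6, C-terminus 3.6 — a widely used
sequence-analysis convention.  Proteome profiles report a 0.5-unit histogram
over [0, 14] plus the acidic [3.5, 6.5] and basic [8.5, 12.5] window shares
(closed intervals on both ends; a pI of exactly 6.5 counts acidic).
Keyword subsetting (default: transporter, permease, efflux, ABC, channel,
membrane) selects the membrane-associated fraction where salinity adaptation
shows most strongly: saline-adapted proteomes shift acidic, freshwater ones
basic.

## 16S read classification

1. **Reference reduction**: greedy centroid clustering at 90% identity,
   longest sequence first, each sequence joining the first centroid it
   matches at or above threshold.  Identity is matches over overlap length
   at the best gapless offset (candidate offsets from shared 8-mers); an
   exact dynamic-programming identity (edlib) is available behind a flag as
   the oracle route.
2. **Candidate screening**: any hit at e-value strictly below 1e-5.
3. **Assignment**: best hit per read (bit score, ties to input order);
   assign its taxon when identity ≥ 80% and alignment length ≥ 90 bp, else
   discard.  Equally scoring hits with conflicting taxa resolve
   first-by-order.  An external keep-list hook lets a full pipeline splice
   an HMM-based rRNA validation stage between screening and assignment.

## Cell abundance

Flow cytometry: N = n × 1000 / (q × t) cells/mL for n events at flow rate q
(µL/min) over t minutes — the only operator grouping of the conventional
inline formula with units of cells per volume.  FISH: absolute density =
hybridized fraction of DAPI-stained objects × DAPI direct count, with a
warning (not an error) below 500 measured cells.  Cell dimensions use the
sample (n−1) standard deviation.

## The synthetic community

Generators emit full truth labels (source genome, position, strand, error
count, marker anchors, taxon, protein class) so every downstream stage is
scored against known ground truth without any downloads.

- **Genomes** are i.i.d. base draws at a target GC.  Compositional
  separation between members is then carried by GC — exactly the axis the
  binning exploits — while 4-mer structure beyond GC is noise.  An optional
  order-2 Markov mode generates genome-specific correlated 4-mer structure
  for harder binning problems.
- **Standard community**: three 100 kb genomes at GC 0.35/0.50/0.65 and
  coverage 5×/20×/80×, 15 contigs each of ≥ 5 kb, implanted with 34/35/30
  of the 35 universal markers.  Marker implantation is positional: each
  marker gets an anchor coordinate, and a marker counts as recovered when a
  contig covering its anchor lands in the evaluated bin — so completeness
  recovery is exact arithmetic, not detection noise.
- **Reads**: uniform positions and strands, count = round(coverage ×
  length / read length), i.i.d. substitution errors (default 2%, read
  length 100).  Substitutions only — the recruitment filters under test act
  on identity and length, and indels would add bookkeeping without
  exercising anything new.
- **16S references**: taxa derived from a common root by substituting an
  exact divergence fraction of sites; two taxa at divergence d then share
  expected identity 1 − 2d(1 − 2d/3).
- **Gene annotations**: genes of ~900 bp separated by geometric spacers
  with mean 20 bp, the streamlined-genome scale.
- **Proteomes**: an exact (not sampled) class split; 18% charged-residue
  budget tilted 14%/4% between D/E and K/R per class, which places the
  acidic-class pI peak near 4.5 and the basic-class peak near 11 — inside
  the standard acidic/basic windows, mirroring the bimodal profile of real
  proteomes.

What the community does **not** emulate: assembly artifacts and chimeras,
strain microheterogeneity within a species, indels and quality-score error
profiles, horizontally transferred composition outliers, rRNA secondary
structure, and real marker-gene detection noise.  Passing tests therefore
demonstrate that the statistics and decision rules are implemented correctly
and recover planted truth under controlled conditions — not that binning or
classification accuracy would reach the same numbers on real metagenomes.

## Problem sizes and determinism

The standard community (3 × 100 kb, 105k reads) keeps every stage within
seconds to tens of seconds on one CPU; ANI uses 100 kb genomes (~98
fragments per direction) and the spacer statistic uses a 500 kb annotation
(~550 gaps) for a stable mean.  All randomness flows from one top-level seed
through per-stage derived seeds (seed + stage index), so stages re-run in
isolation reproduce exactly and the end-to-end report is byte-identical for
a fixed seed.

## Known limitations

- The gapless aligner cannot model indel divergence; identities it reports
  are Hamming-based.  For externally aligned (gapped) hits, supply BLAST
  tabular files instead.
- Greedy centroid clustering is order-dependent by design (longest first);
  it reproduces the threshold semantics of standard tools, not any
  particular tool's centroid set.
- The pI model ignores structure-dependent pKa shifts and charge
  interactions; different pKa scales shift absolute pI values, which is why
  the scale is a config file and histogram comparisons should use one scale
  throughout.
- k-means with k supplied by the user will split or merge populations if k
  is wrong; the GC-spread flag catches merges, but k selection remains the
  analyst's call, as it is in practice.
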