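# maglake

Recovery and characterization of freshwater picocyanobacterial genomes from
metagenomes, as a tested, reusable pipeline.  Freshwater *Synechococcus*
are badly undersampled at the genome level compared to their marine
relatives; the way new ones get characterized is not isolation but
metagenome-assembled genome (MAG) recovery: bin assembled contigs into a
composite genome, estimate how complete it is, measure its abundance across
water bodies, place it against known genomes, and read its ecology off
genome-level statistics.  `maglake` implements that computational chain for
anyone doing MAG work on aquatic communities, exercised end-to-end on a
fully labeled synthetic community so every stage is scored against ground
truth.

## What it computes

- **Composition binning** — contigs ≥ 5 kb grouped by a taxonomy vote
  (> 60% of genes hitting the target taxon), PCA of strand-pooled
  tetranucleotide frequencies, GC, and per-sample log-coverage, clustered
  by k-means on standardized axes (`composition_binning`).
- **Marker completeness and genome size** — for a universal single-copy
  gene set of size *T* with *F* members detected:
  completeness = 100·F/T and estimated size = assembled_bp/(F/T).
  Bundled 35- and 111-gene set configs (`marker_completeness`).
- **Fragment recruitment / RPKG** — reads aligned to a genome, filtered at
  ≥ 50 bp, ≥ 95% identity, e ≤ 1e-5, one best hit per read;
  RPKG = reads/(genome kb × metagenome Gb), the
  dataset-size-normalized abundance statistic (`recruitment`).
- **ANI** — two-way fragment-based average nucleotide identity (1020 bp
  fragments, 70%/70% retention floors); ~95–96% is the conventional
  same-species boundary (`genome_stats`).
- **Genome streamlining** — pooled intergenic spacer statistics
  (next.start − prev.end − 1, clamped at 0) (`genome_stats`).
- **Proteome pI profiling** — per-protein isoelectric point by bisection of
  the Henderson–Hasselbalch net-charge function; acidic [3.5, 6.5] and
  basic [8.5, 12.5] window fractions; keyword subsets for transporters and
  membrane proteins (`proteome_pi`).
- **16S read classification** — greedy 90%-identity reference reduction,
  e < 1e-5 candidate screen, taxon assignment at ≥ 80% identity over
  ≥ 90 bp (`rrna_classify`).
- **Cell abundance** — flow-cytometric density N = n·1000/(q·t) and FISH
  density = hybridized fraction × DAPI count (`cell_abundance`).
- **Synthetic community** — genomes, contigs, reads, marker implants, 16S
  reference families and biased proteomes with full truth labels
  (`synthetic_community`).

See `docs/methods.md` for the models, parameter defaults and numerical
choices.

## Worked example

Run the whole chain on the default synthetic community (three 100 kb
genomes at GC 0.35/0.50/0.65 and coverage 5×/20×/80×):

```bash
maglake run-all --seed 1 --out report.json
# binning accuracy 100.0% — full report in report.json
```

The report contains, among other things:

```json
"binning_accuracy_pct": 100.0,
"bins": {
  "bin2": {"matched_genome": "gA", "markers_found": 34, "markers_total": 35,
           "completeness_pct": 97.14, "assembled_bp": 100000,
           "estimated_mb": 0.1, "true_genome_mb": 0.1}
},
"rpkg": {"gA": {"reads_recruited": 4914, "rpkg": 4680.0},
         "gB": {"reads_recruited": 19692, "rpkg": 18754.29},
         "gC": {"reads_recruited": 78646, "rpkg": 74900.95}},
"spacers": {"median_bp": 17.0, "mean_bp": 21.83, "n_pairs": 109}
```

Reading it: all 45 contigs land in the bin of their source genome; the bin
matched to genome gA recovers 34 of its 35 implanted markers, i.e. 97.14%
completeness, and extrapolating the binned 0.1 Mb by that completeness
brackets the true 0.1 Mb genome; RPKG rises with simulated coverage
(4 680 ≈ 5× coverage expressed per kb of genome per Gb of the 10.5 Mb read
set, and 16× more coverage gives 16× the RPKG); the intergenic gaps average
~20 bp, the streamlined-genome scale.

Individual stages are available as library calls and as subcommands:

```bash
maglake completeness --found 34 --marker-set set35 --assembled-bp 1798000
# {"markers_found": 34, "markers_total": 35,
#  "completeness_pct": 97.14, "estimated_mb": 1.85}
maglake ani tous.fna lanier.fna
maglake recruit reads.fastq genome.fna --min-id 95 --min-len 50
maglake abundance flow --n 1536 --q 128 --t 2    # 6000 cells/mL
```

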