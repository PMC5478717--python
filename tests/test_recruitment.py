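"""Recruitment filters, the RPKG statistic and the desk-scale aligner."""

import numpy as np
import pytest

from maglake import recruitment as rec
from maglake import synthetic_community as sc
from maglake.io_formats import SeqRecord, TabularHit


def make_hit(query="r1", identity=96.0, length=60, evalue=1e-10, bit=110.0,
             s_start=100, s_end=159):
    return TabularHit(
        query_id=query, subject_id="g1", percent_identity=identity,
        alignment_length=length, mismatches=2, gap_opens=0,
        q_start=1, q_end=length, s_start=s_start, s_end=s_end,
        evalue=evalue, bit_score=bit,
    )


class TestFilterHits:
    def test_passing_hit_kept(self):
        assert rec.filter_hits([make_hit()]) == [make_hit()]

    def test_identity_below_threshold_removed(self):
        assert rec.filter_hits([make_hit(identity=94.9)]) == []

    def test_identity_exactly_95_kept_inclusive(self):
        assert len(rec.filter_hits([make_hit(identity=95.0)])) == 1

    def test_identity_exactly_95_removed_exclusive(self):
        hits = [make_hit(identity=95.0)]
        assert rec.filter_hits(hits, inclusive_identity=False) == []

    def test_short_alignment_removed(self):
        assert rec.filter_hits([make_hit(identity=99.0, length=49)]) == []

    def test_evalue_above_cutoff_removed(self):
        assert rec.filter_hits([make_hit(evalue=1e-4)]) == []

    def test_one_best_hit_per_query_by_bit_score(self):
        low = make_hit(bit=100.0, s_start=1, s_end=60)
        high = make_hit(bit=120.0, s_start=500, s_end=559)
        assert rec.filter_hits([low, high]) == [high]

    def test_tie_keeps_first_in_input_order(self):
        first = make_hit(bit=100.0, s_start=1, s_end=60)
        second = make_hit(bit=100.0, s_start=500, s_end=559)
        assert rec.filter_hits([first, second]) == [first]

    def test_idempotent(self):
        hits = [make_hit(), make_hit(query="r2", identity=99.0),
                make_hit(query="r2", identity=98.0, bit=90.0)]
        once = rec.filter_hits(hits)
        assert rec.filter_hits(once) == once


class TestRpkg:
    def test_zero_recruitment(self):
        assert rec.rpkg(0, 2000, 5) == 0.0

    def test_definition_arithmetic(self):
        assert rec.rpkg(1000, 2000, 5) == pytest.approx(0.1)

    def test_zero_sizes_rejected(self):
        with pytest.raises(ValueError):
            rec.rpkg(10, 0, 5)
        with pytest.raises(ValueError):
            rec.rpkg(10, 2000, 0)

    def test_scale_invariance_under_dataset_duplication(self):
        g = sc.generate_genome(20_000, 0.5, seed=0, genome_id="g")
        reads = [r.as_seqrecord() for r in sc.simulate_reads(
            [g], {"g": 2.0}, read_len=100, error_rate=0.01, seed=1)]
        genome = SeqRecord("g", "", g.sequence)
        single = rec.recruit(reads, genome)
        doubled_reads = reads + [
            SeqRecord(r.id + "_dup", "", r.sequence) for r in reads
        ]
        doubled = rec.recruit(doubled_reads, genome)
        assert doubled.reads_recruited == 2 * single.reads_recruited
        assert doubled.metagenome_gb == 2 * single.metagenome_gb
        assert doubled.rpkg == single.rpkg


class TestMiniAlign:
    def test_exact_substring_perfect_hit(self):
        g = sc.generate_genome(5000, 0.5, seed=0, genome_id="g")
        genome = SeqRecord("g", "", g.sequence)
        read = SeqRecord("r", "", g.sequence[1000:1100])
        (hit,) = rec.mini_align([read], genome)
        assert hit.percent_identity == 100.0
        assert (hit.s_start, hit.s_end) == (1001, 1100)

    def test_reverse_strand_hit_has_swapped_coordinates(self):
        g = sc.generate_genome(5000, 0.5, seed=0, genome_id="g")
        genome = SeqRecord("g", "", g.sequence)
        read = SeqRecord("r", "", rec.reverse_complement(g.sequence[1000:1100]))
        (hit,) = rec.mini_align([read], genome)
        assert hit.percent_identity == 100.0
        assert (hit.s_start, hit.s_end) == (1100, 1001)

    def test_unrelated_read_yields_no_hit(self):
        g = sc.generate_genome(5000, 0.30, seed=0, genome_id="g")
        other = sc.generate_genome(5000, 0.70, seed=99, genome_id="o")
        genome = SeqRecord("g", "", g.sequence)
        read = SeqRecord("r", "", other.sequence[:100])
        assert rec.mini_align([read], genome) == []

    def test_matches_brute_force_hamming_scan(self):
        """Seeded hits equal a full Hamming scan for reads whose true
        placement retains at least one exact 21-mer."""
        g = sc.generate_genome(3000, 0.5, seed=5, genome_id="g")
        genome = SeqRecord("g", "", g.sequence)
        sim = sc.simulate_reads([g], {"g": 4.0}, read_len=100,
                                error_rate=0.02, seed=6)
        garr = np.frombuffer(g.sequence.encode(), dtype=np.uint8)

        def brute_best(read_seq: str) -> tuple[int, str, int]:
            best = (-1, "+", 0)
            for strand in ("+", "-"):
                s = read_seq if strand == "+" else rec.reverse_complement(read_seq)
                rarr = np.frombuffer(s.encode(), dtype=np.uint8)
                for off in range(len(garr) - 100 + 1):
                    m = int(np.count_nonzero(rarr == garr[off:off + 100]))
                    if m > best[0]:
                        best = (m, strand, off)
            return best

        def has_intact_seed(read) -> bool:
            src = g.sequence[read.source_pos - 1 : read.source_pos - 1 + 100]
            s = (read.sequence if read.strand == "+"
                 else rec.reverse_complement(read.sequence))
            return any(s[i:i + 21] == src[i:i + 21] for i in range(80))

        eligible = [r for r in sim if has_intact_seed(r)][:60]
        hits = {h.query_id: h for h in rec.mini_align(
            [r.as_seqrecord() for r in eligible], genome)}
        for r in eligible:
            m, _, _ = brute_best(r.sequence)
            assert r.id in hits
            assert hits[r.id].percent_identity == pytest.approx(m)


class TestRecruitmentProfile:
    def test_midpoint_of_subject_interval(self):
        profile = rec.recruitment_profile([make_hit()], genome_length=5000)
        assert profile == [(129.5, 96.0)]

    def test_empty_hits_empty_profile(self):
        assert rec.recruitment_profile([], genome_length=5000) == []

    def test_out_of_bounds_coordinates_rejected(self):
        with pytest.raises(ValueError):
            rec.recruitment_profile([make_hit(s_end=6000)], genome_length=5000)

    def test_simulated_profile_identities_above_threshold(self, community_genomes,
                                                          community_reads):
        g = community_genomes[0]
        genome = SeqRecord(g.id, "", g.sequence)
        own = [r.as_seqrecord() for r in community_reads
               if r.source_genome == g.id][:2000]
        hits = rec.mini_align(own, genome)
        profile = rec.recruitment_profile(hits, len(g.sequence))
        frac = np.mean([identity >= 95.0 for _, identity in profile])
        assert frac >= 0.95


class TestRecruitTruth:
    def test_rpkg_matches_simulated_coverage(self, community_genomes,
                                             community_reads):
        """RPKG of a genome present at coverage c with read length L is
        (c / L per kb) / metagenome_gb, up to the identity-filter loss."""
        g = community_genomes[0]  # 5x coverage, 100 kb
        genome = SeqRecord(g.id, "", g.sequence)
        reads = [r.as_seqrecord() for r in community_reads]
        res = rec.recruit(reads, genome)
        expected = (5.0 / 100) * 1000 / res.metagenome_gb
        assert res.rpkg == pytest.approx(expected, rel=0.05)

    def test_absent_genome_recruits_nothing(self, community_reads):
        absent = sc.generate_genome(50_000, 0.50, seed=12345,
                                    genome_id="absent")
        genome = SeqRecord("absent", "", absent.sequence)
        reads = [r.as_seqrecord() for r in community_reads[:20_000]]
        res = rec.recruit(reads, genome)
        assert res.reads_recruited == 0
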