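"""Tetranucleotide signatures, taxonomy votes, PCA and contig clustering."""

from itertools import product

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from maglake import composition_binning as cb
from maglake import synthetic_community as sc
from maglake.recruitment import reverse_complement


def brute_force_tetra(sequence: str) -> np.ndarray:
    """Sliding-window dictionary count over sequence + reverse complement."""
    counts: dict[str, int] = {}
    for seq in (sequence, reverse_complement(sequence)):
        for i in range(len(seq) - 3):
            w = seq[i : i + 4]
            if set(w) <= set("ACGT"):
                counts[w] = counts.get(w, 0) + 1
    total = sum(counts.values())
    words = ["".join(p) for p in product("ACGT", repeat=4)]
    return np.array([counts.get(w, 0) / total for w in words])


class TestTetraFreqs:
    def test_single_window_and_its_complement(self):
        v = cb.tetra_freqs("AAAA")
        words = ["".join(p) for p in product("ACGT", repeat=4)]
        assert v[words.index("AAAA")] == 0.5
        assert v[words.index("TTTT")] == 0.5
        assert v.sum() == pytest.approx(1.0)

    def test_strand_invariance(self):
        g = sc.generate_genome(3000, 0.45, seed=1)
        np.testing.assert_allclose(
            cb.tetra_freqs(g.sequence),
            cb.tetra_freqs(reverse_complement(g.sequence)),
        )

    def test_matches_brute_force_oracle(self):
        g = sc.generate_genome(10_000, 0.55, seed=2)
        np.testing.assert_allclose(
            cb.tetra_freqs(g.sequence), brute_force_tetra(g.sequence), atol=1e-12
        )

    def test_n_windows_skipped(self):
        # windows containing N are dropped on both strands
        np.testing.assert_allclose(
            cb.tetra_freqs("ACGTNACGT"), cb.tetra_freqs("ACGT")
        )

    def test_no_valid_window_rejected(self):
        with pytest.raises(ValueError):
            cb.tetra_freqs("ACNGT")  # every 4-window contains the N


class TestTaxonomyVote:
    def test_seven_of_ten_accepts(self):
        hits = [(f"g{i}", "Cyanobacteria") for i in range(7)]
        hits += [(f"g{i}", "Other") for i in range(7, 10)]
        assert cb.taxonomy_vote(hits, "Cyanobacteria") == "accept"

    def test_exactly_sixty_percent_rejects(self):
        hits = [(f"g{i}", "Cyanobacteria") for i in range(6)]
        hits += [(f"g{i}", "Other") for i in range(6, 10)]
        assert cb.taxonomy_vote(hits, "Cyanobacteria") == "reject"

    def test_no_genes_unassigned(self):
        assert cb.taxonomy_vote([], "Cyanobacteria") == "unassigned"

    @settings(max_examples=50, derandomize=True)
    @given(
        n_target=st.integers(min_value=0, max_value=20),
        n_other=st.integers(min_value=0, max_value=20),
    )
    def test_adding_target_hit_is_monotone(self, n_target, n_other):
        hits = [("g", "T")] * n_target + [("g", "O")] * n_other
        before = cb.taxonomy_vote(hits, "T")
        after = cb.taxonomy_vote(hits + [("g", "T")], "T")
        if before == "accept":
            assert after == "accept"


class TestProjectPca:
    def test_gc_groups_separate_on_pc1(self):
        lo = [sc.generate_genome(8000, 0.35, seed=i, genome_id=f"lo{i}")
              for i in range(8)]
        hi = [sc.generate_genome(8000, 0.65, seed=50 + i, genome_id=f"hi{i}")
              for i in range(8)]
        X = np.vstack([cb.tetra_freqs(g.sequence) for g in lo + hi])
        res = cb.project_pca(X, n_components=2)
        a, b = res.scores[:8, 0], res.scores[8:, 0]
        pooled_sd = np.sqrt((a.std(ddof=1) ** 2 + b.std(ddof=1) ** 2) / 2)
        assert abs(a.mean() - b.mean()) > 5 * pooled_sd

    def test_duplicated_rows_get_identical_scores(self):
        rng = np.random.default_rng(0)
        X = rng.random((6, 10))
        X[3] = X[0]
        res = cb.project_pca(X, n_components=3)
        np.testing.assert_allclose(res.scores[0], res.scores[3], atol=1e-12)

    def test_full_rank_reconstruction(self):
        rng = np.random.default_rng(1)
        X = rng.random((10, 6))
        res = cb.project_pca(X, n_components=6)
        back = res.scores @ res.components + res.mean
        assert np.max(np.abs(back - X)) < 1e-8

    def test_constant_matrix_rejected(self):
        with pytest.raises(ValueError):
            cb.project_pca(np.ones((5, 4)), n_components=2)

    def test_sign_convention_positive_lead_loading(self):
        rng = np.random.default_rng(2)
        X = rng.random((12, 8))
        res = cb.project_pca(X, n_components=4)
        for comp in res.components:
            assert comp[np.argmax(np.abs(comp))] > 0


class TestBinContigs:
    def test_single_genome_one_bin(self):
        g = sc.generate_genome(40_000, 0.5, seed=0, genome_id="g")
        contigs = sc.fragment_genome(g, 8, 5000, seed=1, coverage={"s": 10.0})
        feats = cb.compute_features(contigs)
        bins = cb.bin_contigs(feats, contigs, k=1, seed=0)
        assert len(bins) == 1
        assert sorted(bins[0].contig_ids) == sorted(c.id for c in contigs)

    @pytest.mark.parametrize("seed", range(5))
    def test_three_genome_community_recovery(self, seed):
        specs = [("gA", 0.35, 5.0), ("gB", 0.50, 20.0), ("gC", 0.65, 80.0)]
        contigs = []
        for i, (gid, gc, cov) in enumerate(specs):
            g = sc.generate_genome(100_000, gc, seed=10 * seed + i, genome_id=gid)
            contigs += sc.fragment_genome(g, 15, 5000, seed=77 + i,
                                          coverage={"s1": cov})
        feats = cb.compute_features(contigs)
        bins = cb.bin_contigs(feats, contigs, k=3, seed=seed)
        assert cb.binning_accuracy(bins, contigs) >= 0.95

    def test_identical_gc_separated_by_coverage(self):
        contigs = []
        for i, (gid, cov) in enumerate([("gX", 4.0), ("gY", 40.0)]):
            g = sc.generate_genome(100_000, 0.50, seed=200 + i, genome_id=gid)
            contigs += sc.fragment_genome(g, 15, 5000, seed=300 + i,
                                          coverage={"s1": cov})
        feats = cb.compute_features(contigs)
        bins = cb.bin_contigs(feats, contigs, k=2, seed=0)
        assert cb.binning_accuracy(bins, contigs) >= 0.95

    def test_k_exceeding_contigs_rejected(self):
        g = sc.generate_genome(20_000, 0.5, seed=0, genome_id="g")
        contigs = sc.fragment_genome(g, 3, 5000, seed=1, coverage={"s": 1.0})
        feats = cb.compute_features(contigs)
        with pytest.raises(ValueError):
            cb.bin_contigs(feats, contigs, k=10, seed=0)

    def test_manual_gates_override_clustering(self):
        specs = [("gA", 0.35, 5.0), ("gC", 0.65, 80.0)]
        contigs = []
        for i, (gid, gc, cov) in enumerate(specs):
            g = sc.generate_genome(60_000, gc, seed=400 + i, genome_id=gid)
            contigs += sc.fragment_genome(g, 10, 5000, seed=500 + i,
                                          coverage={"s1": cov})
        feats = cb.compute_features(contigs)
        gates = {
            "low_gc": {"gc": (0.0, 0.5)},
            "high_gc": {"gc": (0.5, 1.0)},
        }
        bins = cb.bin_contigs(feats, contigs, k=2, seed=0, gates=gates)
        by_id = {b.bin_id: b for b in bins}
        assert all(cid.startswith("gA") for cid in by_id["low_gc"].contig_ids)
        assert all(cid.startswith("gC") for cid in by_id["high_gc"].contig_ids)

    def test_elbow_inertia_is_nonincreasing(self):
        g = sc.generate_genome(40_000, 0.5, seed=0, genome_id="g")
        contigs = sc.fragment_genome(g, 8, 5000, seed=1, coverage={"s": 10.0})
        feats = cb.compute_features(contigs)
        inertia = cb.elbow_inertia(feats, k_max=4)
        assert all(a >= b - 1e-9 for a, b in zip(inertia, inertia[1:]))
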