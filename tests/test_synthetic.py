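"""Generator contracts: composition control, conservation, determinism."""

import numpy as np
import pytest

from magsom import synthetic as syn
from magsom import tnf
from magsom.utils import gc_fraction, reverse_complement, substream


class TestGenerateGenome:
    def test_length_and_gc_control(self):
        spec = syn.GenomeSpec("g", 100_000, 0.5, seed=1)
        g = syn.generate_genome(spec)
        assert len(g) == 100_000
        assert 0.48 <= gc_fraction(g) <= 0.52

    @pytest.mark.parametrize("gc", [0.99, 0.15, 1.2, -0.1])
    def test_gc_outside_band_rejected(self, gc):
        with pytest.raises(ValueError, match="gc_target"):
            syn.generate_genome(syn.GenomeSpec("g", 10_000, gc, seed=0))

    def test_bad_length_rejected(self):
        with pytest.raises(ValueError, match="length"):
            syn.generate_genome(syn.GenomeSpec("g", 2, 0.5, seed=0))

    def test_deterministic(self):
        spec = syn.GenomeSpec("g", 50_000, 0.45, seed=9)
        assert syn.generate_genome(spec) == syn.generate_genome(spec)

    def test_distinct_seeds_distinct_composition(self):
        a = syn.generate_genome(syn.GenomeSpec("g", 200_000, 0.5, seed=1))
        b = syn.generate_genome(syn.GenomeSpec("g", 200_000, 0.5, seed=2))
        da = tnf.tetranucleotide_frequencies(a)
        db = tnf.tetranucleotide_frequencies(b)
        assert np.linalg.norm(da - db) > 0.02


class TestFragmentGenome:
    def test_fixed_cut_points(self):
        g = syn.generate_genome(syn.GenomeSpec("g", 50_000, 0.5, seed=3))
        scaffolds = syn.fragment_genome(g, lengths=[10_000] * 5, genome_id="g")
        assert len(scaffolds) == 5
        assert "".join(s.sequence for s in scaffolds) == g
        assert [(s.start, s.end) for s in scaffolds] == [
            (i * 10_000, (i + 1) * 10_000) for i in range(5)
        ]

    def test_length_conservation_random_draws(self):
        g = syn.generate_genome(syn.GenomeSpec("g", 300_000, 0.5, seed=4))
        for seed in range(5):
            scaffolds = syn.fragment_genome(g, seed=seed, genome_id="g")
            assert sum(len(s) for s in scaffolds) == len(g)
            assert all(len(s) >= 200 for s in scaffolds)

    def test_sub5kb_tail_present(self):
        lens = syn.draw_scaffold_lengths(50, 20, np.random.default_rng(0))
        assert (lens < 5000).sum() == 20
        assert (lens >= 5000).sum() == 50
        assert lens.min() >= 200 and lens.max() <= 177_401

    def test_min_above_max_rejected(self):
        with pytest.raises(ValueError, match="min_len"):
            syn.fragment_genome("A" * 1000, min_len=5000, max_len=300)


class TestInjectContaminants:
    def _toy_truth(self, n_per=100):
        rng = np.random.default_rng(5)
        truth = syn.TruthTable()
        seqs = {}
        for gid, gc in (("lo", 0.30), ("hi", 0.70)):
            genome = syn.generate_genome(
                syn.GenomeSpec(gid, n_per * 6000, gc, seed=int(rng.integers(2**31)))
            )
            for sc in syn.fragment_genome(genome, genome_id=gid, lengths=[6000] * n_per):
                seqs[sc.scaffold_id] = sc.sequence
                truth.scaffolds[sc.scaffold_id] = syn.ScaffoldTruth(gid, sc.start, sc.end)
                truth.bin_of[sc.scaffold_id] = gid
        return truth, seqs

    def test_rate_zero_noop(self):
        truth, seqs = self._toy_truth(10)
        before = dict(truth.bin_of)
        assert syn.inject_contaminants(truth, seqs, 0.0) == []
        assert truth.bin_of == before

    def test_rate_counts(self):
        truth, seqs = self._toy_truth(100)
        injected = syn.inject_contaminants(truth, seqs, 0.1, seed=1)
        # both 100-scaffold bins receive round(0.1 * 100) = 10 contaminants
        assert len(injected) == 20
        per_bin = {}
        for sid in injected:
            per_bin.setdefault(truth.scaffolds[sid].contaminant_in, []).append(sid)
        assert {len(v) for v in per_bin.values()} == {10}

    def test_gc_extreme_offset(self):
        truth, seqs = self._toy_truth(100)
        injected = syn.inject_contaminants(truth, seqs, 0.1, "gc_extreme", seed=2)
        for sid in injected:
            recipient = truth.scaffolds[sid].contaminant_in
            natives = [
                s
                for s, t in truth.scaffolds.items()
                if t.genome_id == recipient and t.contaminant_in is None
            ]
            mean_gc = np.mean([gc_fraction(seqs[s]) for s in natives])
            assert abs(gc_fraction(seqs[sid]) - mean_gc) >= 0.25

    def test_invalid_rate_rejected(self):
        truth, seqs = self._toy_truth(5)
        for rate in (-0.1, 0.5, 0.9):
            with pytest.raises(ValueError, match="rate"):
                syn.inject_contaminants(truth, seqs, rate)


class TestSimulateReads:
    def _two_genomes(self):
        scaffolds, genome_of = {}, {}
        for gid, seed in (("x", 1), ("y", 2)):
            g = syn.generate_genome(syn.GenomeSpec(gid, 100_000, 0.5, seed=seed))
            for sc in syn.fragment_genome(g, genome_id=gid, lengths=[10_000] * 10):
                scaffolds[sc.scaffold_id] = sc.sequence
                genome_of[sc.scaffold_id] = gid
        return scaffolds, genome_of

    def test_error_free_reads_are_substrings(self):
        scaffolds, genome_of = self._two_genomes()
        reads, truth = syn.simulate_reads(
            scaffolds, genome_of, {"x": 1.0, "y": 1.0}, n_pairs=200, error_rate=0.0, seed=3
        )
        joined = {gid: "|".join(s for s, g in genome_of.items()) for gid in ("x", "y")}
        per_genome = {
            gid: [seq for s, seq in scaffolds.items() if genome_of[s] == gid]
            for gid in ("x", "y")
        }
        for rid, seq in reads:
            gid = truth[rid]
            hit = any(
                seq in ref or reverse_complement(seq) in ref for ref in per_genome[gid]
            )
            assert hit, f"read {rid} not an exact substring of genome {gid}"

    def test_equal_depth_split_within_binomial_bound(self):
        scaffolds, genome_of = self._two_genomes()
        reads, truth = syn.simulate_reads(
            scaffolds, genome_of, {"x": 1.0, "y": 1.0}, n_pairs=10_000, seed=4
        )
        # mates share a pair's genome, so count pairs, not reads
        pairs_x = sum(1 for rid, g in truth.items() if g == "x" and rid.endswith("/1"))
        n_pairs = len(truth) // 2
        # 99% binomial interval around n_pairs/2
        half_width = 2.576 * np.sqrt(n_pairs * 0.25)
        assert abs(pairs_x - n_pairs / 2) < half_width

    def test_deterministic_fastq_bytes(self, tmp_path):
        from magsom.io import write_fastq

        scaffolds, genome_of = self._two_genomes()
        paths = []
        for i in (1, 2):
            reads, _ = syn.simulate_reads(
                scaffolds, genome_of, {"x": 1.0, "y": 2.0}, n_pairs=100,
                error_rate=0.01, seed=9
            )
            p = tmp_path / f"r{i}.fastq"
            write_fastq(reads, p)
            paths.append(p.read_bytes())
        assert paths[0] == paths[1]

    def test_invalid_n_pairs(self):
        scaffolds, genome_of = self._two_genomes()
        with pytest.raises(ValueError, match="n_pairs"):
            syn.simulate_reads(scaffolds, genome_of, {"x": 1, "y": 1}, n_pairs=0)


class TestPlaceMarkers:
    MARKERS = [f"m{i:02d}" for i in range(40)]

    def test_complete_single_copy(self):
        t = syn.place_markers("g", ["s1", "s2"], self.MARKERS, 1.0, 0.0, seed=1)
        assert len(t) == 40
        assert t.marker.value_counts().max() == 1

    def test_half_complete(self):
        t = syn.place_markers("g", ["s1"], self.MARKERS, 0.5, 0.0, seed=2)
        assert t.marker.nunique() == 20

    def test_duplication_counts(self):
        t = syn.place_markers("g", ["s1"], self.MARKERS, 0.7, 0.1, seed=3)
        counts = t.marker.value_counts()
        assert len(counts) == 28
        assert (counts == 2).sum() == 4
        assert len(t) == 28 + 4

    def test_duplication_above_completeness_rejected(self):
        with pytest.raises(ValueError, match="duplication"):
            syn.place_markers("g", ["s1"], self.MARKERS, 0.3, 0.5)


class TestSimulateAnnotations:
    TRUTH = {"g1": {"e1", "e2"}, "g2": {"e3"}}

    def test_perfect_detection(self):
        t = syn.simulate_annotations(self.TRUTH, ["A", "B"], 1.0, 0.0, subthreshold_rate=0.0)
        assert len(t) == (2 + 1) * 2
        assert set(t.database) == {"A", "B"}

    def test_zero_detection(self):
        t = syn.simulate_annotations(self.TRUTH, ["A", "B"], 0.0, 0.0, subthreshold_rate=0.0)
        assert len(t) == 0

    def test_two_database_consensus_fraction(self):
        truth = {"g": {f"e{i}" for i in range(100)}}
        t = syn.simulate_annotations(truth, ["A", "B"], 0.9, 0.0, seed=5, subthreshold_rate=0.0)
        ndb = t.groupby("enzyme_id").database.nunique()
        seen_in_both = int((ndb == 2).sum())
        # E = 100 * 0.81, 99% binomial bound
        assert abs(seen_in_both - 81) < 2.576 * np.sqrt(100 * 0.81 * 0.19) + 1

    def test_single_database_rejected(self):
        with pytest.raises(ValueError, match="databases"):
            syn.simulate_annotations(self.TRUTH, ["A"], 1.0, 0.0)


class TestCommunity:
    def test_truth_covers_every_record(self, community):
        assert set(community.truth.scaffolds) == set(community.scaffolds)
        assert set(community.truth.bin_of) == set(community.scaffolds)
        assert {r[0] for r in community.reads} == set(community.truth.reads)

    def test_enforced_tnf_separation(self, community):
        from scipy.spatial.distance import pdist

        profs = np.vstack(
            [tnf.tetranucleotide_frequencies(g) for g in community.genomes.values()]
        )
        assert pdist(profs).min() >= community.config.min_tnf_separation

    def test_substreams_are_independent_and_stable(self):
        a1 = substream(7, "genome").integers(2**31, size=3)
        a2 = substream(7, "genome").integers(2**31, size=3)
        b = substream(7, "read").integers(2**31, size=3)
        assert (a1 == a2).all()
        assert not (a1 == b).all()
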