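"""Exact-match read scanning, filtering rules, and the density matrix."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from neomerkit import (
    NeomerQuery,
    SampleScan,
    SimulationConfig,
    Variant,
    build_ndm,
    build_presence_set,
    downsample_scan,
    enumerate_nullomers,
    estimate_coverage,
    genome_anchor_filter,
    pair_consistency_filter,
    resurfaced_nullomers,
    reverse_complement,
    scan_read_pair,
    scan_sample,
    simulate_cfdna_reads,
    simulate_genome,
    support_filter,
)
from neomerkit.scanner import NeomerQuery as NQ
from neomerkit.scanner import scan_read

from conftest import random_dna


@pytest.fixture(scope="module")
def query():
    return NeomerQuery(["ACGTTACAGGTT", "TTGACCAGATCC", "AAAACCCCGGGG"])


class TestScanRead:
    def test_verbatim_hit(self, query):
        read = "GGG" + "ACGTTACAGGTT" + "CCC"
        hits = scan_read(read, query)
        assert len(hits) == 1

    def test_reverse_complement_hit_same_unit(self, query):
        fwd = "GG" + "ACGTTACAGGTT" + "CC"
        rc = "GG" + reverse_complement("ACGTTACAGGTT") + "CC"
        assert scan_read(fwd, query) == scan_read(rc, query)
        assert scan_read(rc, query)

    def test_single_mismatch_misses(self, query):
        read = "GGG" + "ACGTTACAGGTA" + "CCC"  # last base wrong
        assert scan_read(read, query) == set()

    def test_n_in_window_never_matches(self, query):
        read = "GGG" + "ACGTTANAGGTT" + "CCC"
        assert scan_read(read, query) == set()

    def test_short_read_no_matches(self, query):
        assert scan_read("ACGT", query) == set()

    def test_mixed_length_query_rejected(self):
        with pytest.raises(ValueError, match="mixed"):
            NQ(["ACGT", "ACGTA"])

    def test_exactness_against_bruteforce_substring_search(self):
        rng = np.random.default_rng(0)
        genome = simulate_genome(4000, seed=1)
        pset = build_presence_set(genome, 8)
        neomers = [k for k, _ in zip(enumerate_nullomers(pset), range(100))]
        q = NeomerQuery(neomers)
        reads = []
        for i in range(100):
            r = random_dna(rng, 60)
            if i % 3 == 0:  # embed a neomer in a third of the reads
                n = neomers[int(rng.integers(len(neomers)))]
                pos = int(rng.integers(0, len(r) - len(n)))
                r = r[:pos] + n + r[pos + len(n):]
            reads.append(r)
        for r in reads:
            # brute force: which query neomers occur on either strand
            brute = set()
            for n in neomers:
                if n in r or reverse_complement(n) in r:
                    cn = min(n, reverse_complement(n))
                    brute.add(cn)
            mine = {q.decode(c) for c in scan_read(r, q)}
            mine = {min(m, reverse_complement(m)) for m in mine}
            assert mine == brute


class TestPairRules:
    def test_neomer_in_one_mate_only_dropped(self, query):
        r1 = "GG" + "ACGTTACAGGTT" + "CC"
        r2 = "GGTTTTTTTTTTTTCC"
        h1, h2 = scan_read_pair(r1, r2, query)
        assert h1 and not h2
        assert pair_consistency_filter(h1, h2) == set()

    def test_rc_in_other_mate_kept(self, query):
        r1 = "GG" + "ACGTTACAGGTT" + "CC"
        r2 = "AA" + reverse_complement("ACGTTACAGGTT") + "TT"
        h1, h2 = scan_read_pair(r1, r2, query)
        assert pair_consistency_filter(h1, h2) == h1

    def test_empty_hits(self):
        assert pair_consistency_filter(set(), {1}) == set()

    def test_support_filter_default_two_pairs(self):
        counts = {1: 1, 2: 2, 3: 7}
        assert support_filter(counts) == {2: 2, 3: 7}
        assert support_filter(counts, min_pairs=1) == counts

    def test_support_filter_rejects_zero(self):
        with pytest.raises(ValueError):
            support_filter({}, min_pairs=0)


class TestGenomeAnchor:
    def test_genomic_read_with_neomer_retained(self):
        genome = simulate_genome(20_000, seed=2)
        pset = build_presence_set(genome, 8)
        seq = genome.contigs["chr1"]
        rng = np.random.default_rng(3)
        # engineer a substitution creating a nullomer, then read around it
        while True:
            pos0 = int(rng.integers(100, len(seq) - 100))
            ref = seq[pos0]
            alt = "ACGT"[("ACGT".index(ref) + 1) % 4]
            recs = resurfaced_nullomers(Variant("chr1", pos0 + 1, ref, alt), genome, pset)
            if recs:
                break
        read = seq[pos0 - 40:pos0] + alt + seq[pos0 + 1:pos0 + 41]
        q = NeomerQuery([r.kmer for r in recs])
        hits = scan_read(read, q)
        assert hits
        assert genome_anchor_filter(read, read, hits, q, pset) == hits

    def test_random_reads_mostly_dropped(self):
        # small genome, k=12: random flanking windows are almost never
        # genuine genome k-mers, so non-genomic reads fail to anchor
        genome = simulate_genome(10_000, seed=4)
        pset = build_presence_set(genome, 12)
        neomer = next(iter(enumerate_nullomers(pset)))
        q = NeomerQuery([neomer])
        rng = np.random.default_rng(5)
        dropped = 0
        n_reads = 300
        for _ in range(n_reads):
            read = random_dna(rng, 14) + neomer + random_dna(rng, 14)
            hits = scan_read(read, q)
            assert hits
            if not genome_anchor_filter(read, read, hits, q, pset):
                dropped += 1
        assert dropped / n_reads > 0.8

    def test_read_equal_to_neomer_retained_with_warning(self):
        genome = simulate_genome(5_000, seed=6)
        pset = build_presence_set(genome, 10)
        neomer = next(iter(enumerate_nullomers(pset)))
        q = NeomerQuery([neomer])
        hits = scan_read(neomer, q)
        with pytest.warns(UserWarning, match="too short to anchor"):
            kept = genome_anchor_filter(neomer, neomer, hits, q, pset)
        assert kept == hits


class TestCoverageAndNdm:
    def test_coverage_arithmetic(self):
        assert estimate_coverage(1000 * 100, 10_000) == 10.0
        assert estimate_coverage(2000 * 100, 10_000) == 20.0

    def test_coverage_errors(self):
        with pytest.raises(ValueError):
            estimate_coverage(0, 100)
        with pytest.raises(ValueError):
            estimate_coverage(100, 0)

    @staticmethod
    def _scan(sample_id, coverage, counts, k=12):
        return SampleScan(
            sample_id=sample_id, coverage=coverage, counts=counts,
            pairs_scanned=100, pairs_with_hits=len(counts), query_k=k,
        )

    def test_density_is_count_over_coverage(self):
        ndm = build_ndm([self._scan("s1", 8.0, {4: 4})])
        assert ndm.densities.iloc[0, 0] == pytest.approx(0.5)

    def test_disjoint_samples_block_structure(self):
        ndm = build_ndm(
            [self._scan("s1", 2.0, {1: 2}), self._scan("s2", 2.0, {2: 4})]
        )
        dense = ndm.densities
        assert (dense > 0).sum().sum() == 2
        assert dense.loc["s1"].sum() == pytest.approx(1.0)
        assert dense.loc["s2"].sum() == pytest.approx(2.0)

    def test_zero_coverage_sample_rejected(self):
        with pytest.raises(ValueError, match="coverage"):
            build_ndm([self._scan("bad", 0.0, {1: 2})])

    def test_duplicating_pairs_leaves_density_fixed(self):
        scan1 = self._scan("s", 5.0, {1: 2, 2: 3})
        scan2 = self._scan("s", 10.0, {1: 4, 2: 6})
        d1 = build_ndm([scan1]).densities
        d2 = build_ndm([scan2]).densities
        pd.testing.assert_frame_equal(d1, d2)

    def test_triplet_export(self):
        ndm = build_ndm(
            [self._scan("s1", 2.0, {1: 2}), self._scan("s2", 2.0, {})]
        )
        trip = ndm.to_triplets()
        assert list(trip.columns) == ["sample", "neomer", "density"]
        assert len(trip) == 1


class TestDownsampling:
    @staticmethod
    def _scan_with_hits(n_pairs):
        # each hit pair supports a distinct neomer
        return SampleScan(
            sample_id="s", coverage=10.0,
            counts={i: 1 for i in range(n_pairs)},
            pairs_scanned=n_pairs, pairs_with_hits=n_pairs,
            pair_hit_sets=[frozenset({i}) for i in range(n_pairs)],
            query_k=12,
        )

    def test_full_coverage_keeps_everything(self):
        scan = self._scan_with_hits(50)
        reps = downsample_scan(scan, c=10.0, reps=5, seed=0, min_pairs=1)
        assert all(len(r) == 50 for r in reps)

    def test_half_coverage_keeps_half_on_average(self):
        scan = self._scan_with_hits(200)
        reps = downsample_scan(scan, c=5.0, reps=100, seed=1, min_pairs=1)
        fractions = np.array([len(r) / 200 for r in reps])
        se = np.sqrt(0.25 / 200 / len(reps))
        assert abs(fractions.mean() - 0.5) < 3 * se

    def test_target_above_full_rejected(self):
        with pytest.raises(ValueError):
            downsample_scan(self._scan_with_hits(10), c=11.0)

    def test_default_replicates_is_100(self):
        import inspect

        assert inspect.signature(downsample_scan).parameters["reps"].default == 100


class TestScanSample:
    @pytest.fixture(scope="class")
    @staticmethod
    def engineered():
        genome = simulate_genome(30_000, seed=7)
        pset = build_presence_set(genome, 10)
        seq = genome.contigs["chr1"]
        rng = np.random.default_rng(8)
        while True:
            pos0 = int(rng.integers(500, len(seq) - 500))
            ref = seq[pos0]
            alt = "ACGT"[("ACGT".index(ref) + 1) % 4]
            v = Variant("chr1", pos0 + 1, ref, alt, "p", "t")
            recs = resurfaced_nullomers(v, genome, pset)
            if recs:
                return genome, pset, v, NeomerQuery([r.kmer for r in recs])

    def _config(self, tumor_fraction, coverage=20.0, error_rate=0.0):
        return SimulationConfig(
            genome_length=30_000, k=10, tumor_fraction=tumor_fraction,
            coverage=coverage, error_rate=error_rate, seed=0,
        )

    def test_zero_tumor_fraction_zero_error_yields_nothing(self, engineered):
        genome, pset, v, q = engineered
        cfg = self._config(0.0)
        reads = simulate_cfdna_reads(genome, [v], cfg, seed=9)
        scan = scan_sample(reads.pairs, q, "s", len(genome), pset=pset)
        assert scan.counts == {}
        assert scan.pairs_with_hits == 0

    def test_support_counts_increase_with_tumor_fraction(self, engineered):
        genome, pset, v, q = engineered
        totals = []
        for tf in (0.0, 0.1, 0.4, 1.0):
            cfg = self._config(tf, coverage=30.0)
            reads = simulate_cfdna_reads(genome, [v], cfg, seed=10)
            scan = scan_sample(
                reads.pairs, q, "s", len(genome), pset=pset, min_pairs=1
            )
            totals.append(sum(scan.counts.values()))
        rho, _ = spearmanr([0.0, 0.1, 0.4, 1.0], totals)
        assert rho > 0.9

    def test_pair_overlap_geometry_retains_center_neomer(self, engineered):
        # 167 bp fragments with 150 bp mates overlap by ~133 bp, so a
        # tumor k-mer regularly appears in both mates
        genome, pset, v, q = engineered
        cfg = self._config(1.0, coverage=30.0)
        reads = simulate_cfdna_reads(genome, [v], cfg, seed=11)
        scan = scan_sample(reads.pairs, q, "s", len(genome), pset=pset, min_pairs=1)
        assert scan.pairs_with_hits > 0

    def test_deduplication_flag(self, engineered):
        genome, pset, v, q = engineered
        cfg = self._config(1.0)
        reads = simulate_cfdna_reads(genome, [v], cfg, seed=12)
        doubled = reads.pairs + reads.pairs
        s1 = scan_sample(doubled, q, "s", len(genome), pset=pset, min_pairs=1,
                         dedup_identical_pairs=True)
        s2 = scan_sample(reads.pairs, q, "s", len(genome), pset=pset, min_pairs=1)
        assert s1.counts == s2.counts
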