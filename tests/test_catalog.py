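"""Recurrence catalogs, supervised selection, and enrichment statistics."""

import numpy as np
import pytest
from scipy.stats import hypergeom

from neomerkit import (
    NeomerCatalog,
    Variant,
    build_presence_set,
    choose_threshold,
    classify_by_threshold,
    driver_enrichment,
    germline_creatable_filter,
    harmonic_threshold,
    hypergeom_enrichment,
    jaccard_matrix,
    msi_motif_count,
    patient_profile,
    pole_context_filter,
    recurrence_filter,
    resurfaced_nullomers,
    reverse_complement,
    simulate_genome,
)

from conftest import random_dna

A, B, C, W = "AACC", "AAGG", "ACAC", "AGAG"


class TestRecurrenceFilter:
    def test_patient_counting(self):
        sets = {"p1": {A, B}, "p2": {B, C}, "p3": {B}}
        assert set(recurrence_filter(sets, 2)) == {B}
        assert set(recurrence_filter(sets, 3)) == {B}
        assert recurrence_filter(sets, 3)[B] == 3

    def test_r_below_two_rejected(self):
        with pytest.raises(ValueError):
            recurrence_filter({"p": {A}}, 1)

    def test_disjoint_sets_give_empty_catalog(self):
        assert recurrence_filter({"p1": {A}, "p2": {B}}, 2) == {}

    def test_duplicated_patient_ids_would_inflate(self):
        # identical donors under two ids reach r=2: ids must be distinct people
        assert set(recurrence_filter({"d1": {A}, "d2": {A}}, 2)) == {A}

    def test_rc_counted_as_one_unit(self):
        fwd = {"p1": {"AACG"}, "p2": {"AACG"}}
        mixed = {"p1": {"AACG"}, "p2": {reverse_complement("AACG")}}
        assert recurrence_filter(fwd, 2) == recurrence_filter(mixed, 2)

    def test_strand_separate_accounting_flag(self):
        mixed = {"p1": {"AACG"}, "p2": {reverse_complement("AACG")}}
        assert recurrence_filter(mixed, 2, rc_as_one_unit=False) == {}


class TestChooseThreshold:
    def test_closest_to_target_wins(self):
        rng = np.random.default_rng(1)
        # 60 distinct kmers seen by exactly 2 patients, 5 by 3 patients
        sets = {f"p{j}": set() for j in range(8)}
        kmers = set()
        while len(kmers) < 65:
            kmers.add(random_dna(rng, 12))
        kmers = sorted(kmers)
        for i, kmer in enumerate(kmers):
            depth = 2 if i < 60 else 3
            for j in rng.choice(8, size=depth, replace=False):
                sets[f"p{j}"].add(kmer)
        # sizes: r=2 -> 65, r=3 -> 5; target 10 -> r=3 is closer
        assert choose_threshold(sets, target=10) == 3

    def test_fallback_to_two_when_under_target(self):
        sets = {"p1": {A, B}, "p2": {B}, "p3": {B, C}}
        assert choose_threshold(sets, target=10000) == 2

    def test_size_monotone_in_r(self):
        rng = np.random.default_rng(2)
        sets = {
            f"p{j}": {random_dna(rng, 8) for _ in range(30)} for j in range(6)
        }
        sizes = []
        for r in range(2, 7):
            sizes.append(len(recurrence_filter(sets, r)))
        assert sizes == sorted(sizes, reverse=True)

    def test_needs_two_patients(self):
        with pytest.raises(ValueError):
            choose_threshold({"p1": {A}})


def canonical(kmer):
    rc = reverse_complement(kmer)
    return kmer if kmer <= rc else rc


class TestJaccardAndProfiles:
    def _catalog(self, sets_by_type):
        return NeomerCatalog(
            sets={t: {k: 2 for k in s} for t, s in sets_by_type.items()},
            thresholds={t: 2 for t in sets_by_type},
        )

    def test_identical_disjoint_and_half(self):
        x, y, z, w = map(canonical, ("AAAC", "AAAG", "AAAT", "AACA"))
        cat = self._catalog({"t1": {x, y, z}, "t2": {y, z, w}, "t3": {w}})
        J = jaccard_matrix(cat)
        assert J.loc["t1", "t1"] == 1.0
        assert J.loc["t1", "t2"] == pytest.approx(0.5)
        assert J.loc["t1", "t3"] == 0.0
        assert np.allclose(J.values, J.values.T)

    def test_profile_counts(self):
        x, y, z = map(canonical, ("AAAC", "AAAG", "AAAT"))
        cat = self._catalog({"t1": {x, y}, "t2": {z}})
        assert patient_profile(set(), cat).tolist() == [0, 0]
        assert patient_profile({x, y}, cat).tolist() == [2, 0]
        # RC-aware intersection
        assert patient_profile({reverse_complement(x)}, cat).tolist() == [1, 0]


class TestSupervisedSelection:
    def test_msi_motif_counting(self):
        assert msi_motif_count({"AAAAAAAAGCGTACGT"}) == 1
        assert msi_motif_count({"ACGTACGTACGTACGT"}) == 0
        pair = {"TTTTTTTTGCATGCAT", reverse_complement("TTTTTTTTGCATGCAT")}
        assert msi_motif_count(pair) == 2

    def test_pole_context_filter(self, small_genome, small_pset):
        seq = small_genome.contigs["chr1"]
        # find a TCT context and mutate its center C
        pos0 = seq.find("TCT") + 1
        kept_v = Variant("chr1", pos0 + 1, "C", "A", "p", "t")   # TCT>TAT
        dropped_v = Variant("chr1", pos0 + 1, "C", "G", "p", "t")
        recs = resurfaced_nullomers(kept_v, small_genome, small_pset)
        recs_dropped = resurfaced_nullomers(dropped_v, small_genome, small_pset)
        kept = pole_context_filter(recs | recs_dropped, small_genome)
        assert {r.kmer for r in recs} <= kept | set()
        assert not ({r.kmer for r in recs_dropped} & kept)

    def test_pole_reverse_strand_context_flag(self, small_genome, small_pset):
        seq = small_genome.contigs["chr1"]
        pos0 = seq.find("AGA") + 1  # G>T here is TCT>TAT on the other strand
        v = Variant("chr1", pos0 + 1, "G", "T", "p", "t")
        recs = resurfaced_nullomers(v, small_genome, small_pset)
        if recs:  # the variant may create no nullomer on this genome
            assert pole_context_filter(recs, small_genome, both_strands=True)
            assert not pole_context_filter(recs, small_genome, both_strands=False)

    def test_indel_records_dropped(self, small_genome, small_pset):
        seq = small_genome.contigs["chr1"]
        v = Variant("chr1", 101, seq[100:102], seq[100], "p", "t")
        recs = resurfaced_nullomers(v, small_genome, small_pset)
        assert pole_context_filter(recs, small_genome) == set()

    def test_harmonic_threshold_closed_form(self):
        t = harmonic_threshold([1, 4], [9, 12])
        assert t == pytest.approx(72 / 13)
        assert classify_by_threshold(6, t)
        assert not classify_by_threshold(5, t)

    def test_harmonic_equal_classes_boundary_positive(self):
        t = harmonic_threshold([5], [5])
        assert t == 5
        assert classify_by_threshold(5, t)

    def test_harmonic_undefined_when_all_zero(self):
        with pytest.raises(ValueError):
            harmonic_threshold([0, 0], [0])

    def test_harmonic_separates_disjoint_supports(self):
        rng = np.random.default_rng(3)
        neg = rng.integers(0, 10, 30)
        pos = rng.integers(12, 30, 30)
        t = harmonic_threshold(neg, pos)
        assert all(not classify_by_threshold(c, t) for c in neg)
        assert all(classify_by_threshold(c, t) for c in pos)


class TestGermlineFilter:
    def _creatable_neomer(self, genome, pset, rng):
        seq = genome.contigs["chr1"]
        while True:
            pos0 = int(rng.integers(10, len(seq) - 10))
            ref = seq[pos0]
            alt = "ACGT"[("ACGT".index(ref) + 1) % 4]
            v = Variant("chr1", pos0 + 1, ref, alt)
            recs = resurfaced_nullomers(v, genome, pset)
            if recs:
                return v, next(iter(recs)).kmer

    def test_common_snp_creatable_neomer_removed(self, small_genome, small_pset):
        rng = np.random.default_rng(4)
        v, kmer = self._creatable_neomer(small_genome, small_pset, rng)
        kept = germline_creatable_filter(
            {kmer, "A" * 8}, [(v, 0.05)], small_genome, small_pset
        )
        assert kmer not in kept and "A" * 8 in kept

    def test_af_min_one_is_identity(self, small_genome, small_pset):
        rng = np.random.default_rng(5)
        v, kmer = self._creatable_neomer(small_genome, small_pset, rng)
        kept = germline_creatable_filter(
            {kmer}, [(v, 0.5)], small_genome, small_pset, af_min=1.0
        )
        assert kept == {kmer}

    def test_empty_panel_is_identity(self, small_genome, small_pset):
        assert germline_creatable_filter(
            {"ACGTACGT"}, [], small_genome, small_pset
        ) == {"ACGTACGT"}


class TestDriverEnrichment:
    def test_null_drivers_give_fold_near_one(self):
        genome = simulate_genome(3000, seed=6)
        pset = build_presence_set(genome, 6)
        rng = np.random.default_rng(7)
        seq = genome.contigs["chr1"]
        drivers = []
        for _ in range(40):
            pos0 = int(rng.integers(len(seq)))
            ref = seq[pos0]
            alt = "ACGT"[("ACGT".index(ref) + int(rng.integers(1, 4))) % 4]
            drivers.append(Variant("chr1", pos0 + 1, ref, alt))
        res = driver_enrichment(drivers, genome, pset, n_perm=200, seed=8)
        assert 0.5 < res["fold"] < 2.0
        assert res["p_value"] > 0.01

    def test_engineered_drivers_enriched(self):
        genome = simulate_genome(2000, seed=9)
        # k=5 on 2 kb: most 5-mers present, so background rarely creates
        pset = build_presence_set(genome, 5)
        rng = np.random.default_rng(10)
        seq = genome.contigs["chr1"]
        drivers = []
        while len(drivers) < 15:
            pos0 = int(rng.integers(10, len(seq) - 10))
            ref = seq[pos0]
            alt = "ACGT"[("ACGT".index(ref) + int(rng.integers(1, 4))) % 4]
            v = Variant("chr1", pos0 + 1, ref, alt)
            if resurfaced_nullomers(v, genome, pset):
                drivers.append(v)
        res = driver_enrichment(drivers, genome, pset, n_perm=100, seed=11)
        assert res["fold"] > 1.0
        assert res["p_value"] == pytest.approx(1 / 101)

    def test_small_n_perm_rejected(self):
        genome = simulate_genome(500, seed=0)
        pset = build_presence_set(genome, 5)
        with pytest.raises(ValueError):
            driver_enrichment(
                [Variant("chr1", 10, genome.contigs["chr1"][9], "A"
                         if genome.contigs["chr1"][9] != "A" else "C")],
                genome, pset, n_perm=10,
            )


class TestHypergeomEnrichment:
    def test_neoantigen_urn_expectation(self):
        res = hypergeom_enrichment(1700, 188_659, 186_067_892, 13)
        assert res.expectation == pytest.approx(1.72, abs=0.005)
        assert res.fold == pytest.approx(13 / res.expectation)
        assert res.p_value < 1e-6

    def test_zero_observed(self):
        res = hypergeom_enrichment(10, 5, 5, 0)
        assert res.p_value == 1.0
        assert res.fold == 0.0

    def test_impossible_observation(self):
        res = hypergeom_enrichment(10, 5, 5, 10)
        assert res.p_value == 0.0

    def test_expectation_matches_monte_carlo(self):
        n, white, black = 10, 5, 15
        rng = np.random.default_rng(12)
        urn = np.array([1] * white + [0] * black)
        draws = np.array(
            [rng.choice(urn, size=n, replace=False).sum() for _ in range(10_000)]
        )
        exp = hypergeom_enrichment(n, white, black, 3).expectation
        se = draws.std() / np.sqrt(len(draws))
        assert abs(draws.mean() - exp) < 3 * se

    def test_empty_urn_rejected(self):
        with pytest.raises(ValueError):
            hypergeom_enrichment(0, 0, 0, 0)

    def test_tail_matches_scipy_direct(self):
        res = hypergeom_enrichment(20, 30, 70, 9)
        assert res.p_value == pytest.approx(hypergeom.sf(8, 100, 30, 20))
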