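"""End-to-end benchmark pipelines on synthetic cohorts.

These functions wire the full chain — simulate genome and cohort,
annotate resurfacing nullomers, build the recurrence catalog, filter
against a germline panel, scan simulated cfDNA read pairs, and run the
classifiers — at desk-scale problem sizes.  They are the workloads the
test suite and the reproduction script both execute.

Problem sizes are chosen from the coverage geometry so that the planted
signal is detectable under the filtering rules.  With fragment length
~167 bp and 150 bp mates, a k-mer is seen by both mates only inside the
~133 bp mate-overlap region, so a mutation site is covered by a
both-mate pair at rate

    lambda = n_tumor_pairs * (overlap - k + 1) / genome_length.

A neomer passes the >= 2-supporting-pairs rule with probability
P(Pois(lambda) >= 2), and the per-patient site count is set so the
expected number of surviving sites is well above zero for cases.  The
per-patient mutation burden (2,000 substitutions on 1 Mb for the cfDNA
cohort) mirrors the ~10^4 resurfacing-nullomer sites per patient seen in
real whole-genome cohorts, scaled to the synthetic genome.
"""

from __future__ import annotations

from typing import Dict, List, Sequence, Tuple

import numpy as np

from .catalog import germline_creatable_filter, recurrence_filter
from .detect import (
    hash_features,
    nested_cv_detect,
    repeated_threshold_f1,
)
from .genome import GenomeSequence
from .kmer import KmerPresenceSet, build_presence_set
from .scanner import NeomerQuery, SampleScan, build_ndm, downsample_scan, scan_sample
from .simulate import (
    SimulationConfig,
    germline_panel_variants,
    simulate_cfdna_reads,
    simulate_cohort,
    simulate_genome,
    simulate_germline_panel,
    simulate_individual_germline,
)
from .tissue import cross_validate_tissue
from .variants import annotate_cohort


def tissue_benchmark(seed: int = 0, folds: int = 10) -> dict:
    """Tissue-of-origin recovery on a 5-type, 20-patients-per-type cohort
    with disjoint planted signatures (300 kb genome, k=10)."""
    cfg = SimulationConfig(
        genome_length=300_000,
        k=10,
        n_cancer_types=5,
        patients_per_type=20,
        substitutions_per_patient=50,
        indels_per_patient=5,
        recurrent_fraction=0.3,
        recurrence_depth=3,
        seed=seed,
    )
    genome = simulate_genome(cfg.genome_length, seed=seed)
    pset = build_presence_set(genome, cfg.k)
    cohort = simulate_cohort(genome, cfg, pset=pset, disjoint_signatures=True,
                             seed=seed + 1)
    ann = annotate_cohort(cohort.variants, genome, pset)
    report = cross_validate_tissue(
        ann.patient_sets, ann.patient_cancer_type, folds=folds, seed=seed
    )
    return {
        "accuracy": report.accuracy,
        "per_class_accuracy": report.per_class_accuracy,
        "macro_f1": report.macro_f1,
        "n_patients": len(ann.patient_sets),
        "n_types": cfg.n_cancer_types,
    }


def _cfdna_config(
    seed: int,
    genome_length: int,
    k: int,
    n_patients: int,
    tumor_fraction: float,
    coverage: float,
    substitutions_per_patient: int,
) -> SimulationConfig:
    return SimulationConfig(
        genome_length=genome_length,
        k=k,
        n_cancer_types=1,
        patients_per_type=n_patients,
        substitutions_per_patient=substitutions_per_patient,
        indels_per_patient=5,
        recurrent_fraction=0.5,
        recurrence_depth=3,
        tumor_fraction=tumor_fraction,
        coverage=coverage,
        seed=seed,
    )


def simulate_cfdna_cohort(
    seed: int = 0,
    genome_length: int = 1_000_000,
    k: int = 12,
    n_cases: int = 50,
    n_controls: int = 50,
    tumor_fraction: float = 0.05,
    coverage: float = 5.0,
    substitutions_per_patient: int = 10_000,
    germline_snps: int = 100,
    rare_germline_per_sample: int = 30,
) -> Tuple[List[SampleScan], np.ndarray, NeomerQuery, GenomeSequence, KmerPresenceSet]:
    """Simulate and scan a case/control cfDNA cohort.

    Cases carry a shared recurrent mutation signature (depth 3, r=2
    catalog as used for cfDNA detection) at the study's absolute
    per-patient site count (~10^4 resurfacing sites); every individual,
    case or control, additionally carries a personal germline genotype
    (common panel SNPs by allele frequency plus ~30 private rare het
    SNPs), which gives controls the realistic nonzero neomer noise floor
    that rare variants below the common-AF filter produce.  The neomer
    query list is the germline-filtered recurrence catalog.  Returns the
    per-sample scans, the 0/1 labels, the query, and the reference
    objects.
    """
    cfg = _cfdna_config(
        seed, genome_length, k, n_cases, tumor_fraction, coverage,
        substitutions_per_patient,
    )
    genome = simulate_genome(cfg.genome_length, seed=seed)
    pset = build_presence_set(genome, cfg.k)
    cohort = simulate_cohort(genome, cfg, pset=pset, seed=seed + 1)
    ann = annotate_cohort(cohort.variants, genome, pset, keep_records=False)

    # cfDNA rule: neomers recurrent in >= 2 patients of the type
    catalog_counts = recurrence_filter(ann.patient_sets, r=2)
    neomers = set(catalog_counts)
    panel = simulate_germline_panel(genome, germline_snps, seed=seed + 2)
    if germline_snps:
        neomers = germline_creatable_filter(
            neomers, germline_panel_variants(panel), genome, pset
        )
    query = NeomerQuery(neomers)

    patients = sorted(ann.patient_sets)[:n_cases]
    by_patient: Dict[str, list] = {p: [] for p in patients}
    for v in cohort.variants:
        if v.patient_id in by_patient:
            by_patient[v.patient_id].append(v)

    scans: List[SampleScan] = []
    labels: List[int] = []
    for i, p in enumerate(patients):
        germ = simulate_individual_germline(
            genome, panel, n_private=rare_germline_per_sample, seed=seed + 5000 + i,
        )
        reads = simulate_cfdna_reads(
            genome, by_patient[p], cfg, seed=seed + 100 + i,
            germline_variants=germ,
        )
        scans.append(
            scan_sample(reads.pairs, query, f"case_{i}", len(genome), pset=pset)
        )
        labels.append(1)
    for i in range(n_controls):
        germ = simulate_individual_germline(
            genome, panel, n_private=rare_germline_per_sample, seed=seed + 7000 + i,
        )
        reads = simulate_cfdna_reads(
            genome, [], cfg, seed=seed + 1000 + i, germline_variants=germ
        )
        scans.append(
            scan_sample(reads.pairs, query, f"control_{i}", len(genome), pset=pset)
        )
        labels.append(0)
    return scans, np.array(labels), query, genome, pset


def cfdna_benchmark(
    seed: int = 0,
    n_permutations: int = 3,
    hash_dim: int = 8192,
    **cohort_kwargs,
) -> dict:
    """Nested-CV detection AUC on the synthetic cfDNA cohort, plus the
    label-permutation chance level and the threshold-detector F1."""
    scans, labels, query, genome, pset = simulate_cfdna_cohort(
        seed=seed, **cohort_kwargs
    )
    ndm = build_ndm(scans)
    hashed = hash_features(ndm, m=hash_dim, seed=seed)
    report = nested_cv_detect(hashed, labels, model="lr_l2", seed=seed)

    rng = np.random.default_rng(seed)
    perm_aucs = []
    for _ in range(n_permutations):
        perm = rng.permutation(labels)
        perm_aucs.append(
            nested_cv_detect(hashed, perm, model="lr_l2", seed=seed).auc
        )

    counts = np.array([s.total_neomers() for s in scans], dtype=float)
    thr = repeated_threshold_f1(
        counts[labels == 0], counts[labels == 1], n_splits=100, seed=seed
    )
    return {
        "auc": report.auc,
        "balanced_accuracy": report.balanced_accuracy,
        "sensitivity": report.sensitivity,
        "specificity": report.specificity,
        "permuted_auc_mean": float(np.mean(perm_aucs)),
        "permuted_aucs": perm_aucs,
        "threshold_f1_mean": thr["f1_mean"],
        "threshold_f1_sd": thr["f1_sd"],
        "n_samples": len(labels),
        "n_query_neomers": len(query),
    }


def downsampling_benchmark(
    seed: int = 0,
    genome_length: int = 300_000,
    k: int = 12,
    n_cases: int = 30,
    n_controls: int = 30,
    tumor_fraction: float = 0.2,
    full_coverage: float = 10.0,
    target_coverage: float = 3.0,
    substitutions_per_patient: int = 2000,
) -> dict:
    """Detection AUC at full vs downsampled coverage.

    The cohort is simulated once at ``full_coverage``; the 3x condition
    keeps each read pair with probability c/C_i (one replicate per
    sample) before re-applying the support filter, mirroring the
    without-replacement downsampling design.
    """
    scans, labels, query, genome, pset = simulate_cfdna_cohort(
        seed=seed,
        genome_length=genome_length,
        k=k,
        n_cases=n_cases,
        n_controls=n_controls,
        tumor_fraction=tumor_fraction,
        coverage=full_coverage,
        substitutions_per_patient=substitutions_per_patient,
    )

    def auc_of(scan_list: Sequence[SampleScan]) -> float:
        ndm = build_ndm(scan_list)
        hashed = hash_features(ndm, m=8192, seed=seed)
        return nested_cv_detect(hashed, labels, model="lr_l2", seed=seed).auc

    auc_full = auc_of(scans)
    down: List[SampleScan] = []
    for s in scans:
        counts = downsample_scan(s, c=target_coverage, reps=1, seed=seed)[0]
        down.append(
            SampleScan(
                sample_id=s.sample_id,
                coverage=s.coverage * target_coverage / full_coverage,
                counts=counts,
                pairs_scanned=s.pairs_scanned,
                pairs_with_hits=s.pairs_with_hits,
                query_k=s.query_k,
            )
        )
    auc_down = auc_of(down)
    return {
        "auc_full": auc_full,
        "auc_downsampled": auc_down,
        "full_coverage": full_coverage,
        "target_coverage": target_coverage,
        "abs_difference": abs(auc_full - auc_down),
    }
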