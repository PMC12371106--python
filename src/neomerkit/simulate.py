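"""Synthetic genomes, somatic cohorts, germline panels, and cfDNA reads.

The generator emulates the data the pipeline consumes in production —
a reference genome, per-cancer-type somatic mutation cohorts with
controllable recurrence, a common-variant panel with allele frequencies,
and paired-end cfDNA reads at a configurable tumor fraction — at sizes
where every stage runs on a desk.  Engineered ("planted") neomers are
recorded in a truth table so recovery can be asserted end to end.

Fragment lengths follow a truncated Normal(167, 10) on [120, 220],
mirroring the cfDNA fragment-size distribution centered at 167 bp;
mates are 150 bp, so a typical pair overlaps by ~133 bp and a neomer
near the fragment center is seen by both mates.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .genome import GenomeSequence
from .kmer import KmerPresenceSet, build_presence_set
from .scanner import NeomerQuery, _batch_hits
from .variants import Variant, canonical_kmer, resurfaced_nullomers

_LETTERS = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    Defaults describe a desk-scale analog of the real study: a 1 Mb
    genome with k=12 (so nullomers are abundant), 5 cancer types of 20
    patients, ~30% of each patient's substitutions drawn from a shared
    recurrent signature planted at depth 3, cfDNA at 5x coverage with a
    5% tumor fraction, PE150 reads from ~167 bp fragments, and a 0.1%
    uniform base-error rate.
    """

    genome_length: int = 1_000_000
    k: int = 12
    n_cancer_types: int = 5
    patients_per_type: int = 20
    substitutions_per_patient: int = 50
    indels_per_patient: int = 5
    indel_size_max: int = 10
    recurrent_fraction: float = 0.3
    recurrence_depth: int = 3
    n_germline_snps: int = 100
    germline_common_fraction: float = 0.2
    rare_germline_per_sample: int = 30
    tumor_fraction: float = 0.05
    coverage: float = 5.0
    fragment_mean: float = 167.0
    fragment_sd: float = 10.0
    fragment_min: int = 120
    fragment_max: int = 220
    read_length: int = 150
    error_rate: float = 0.001
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.tumor_fraction <= 1:
            raise ValueError("tumor_fraction must be in [0, 1]")
        if self.genome_length < 10 * self.k:
            raise ValueError("genome_length must be at least 10*k")
        if not 1 <= self.indel_size_max <= 100:
            raise ValueError("indel sizes are limited to 1-100 bp")


def simulate_genome(
    length: int, gc: float = 0.41, seed: int = 0, contig: str = "chr1"
) -> GenomeSequence:
    """I.i.d. random genome at the given GC content (default 0.41)."""
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    codes = rng.choice(4, size=length, p=p)
    seq = _LETTERS[codes].tobytes().decode("ascii")
    return GenomeSequence({contig: seq}, genome_id=f"sim(len={length},gc={gc},seed={seed})")


@dataclass
class CohortTruth:
    """Planted signal bookkeeping for a simulated cohort."""

    variants: List[Variant]
    truth_table: pd.DataFrame  # neomer, cancer_type, chrom, pos, ref, alt
    signature_neomers: Dict[str, Set[str]] = field(default_factory=dict)


def _free_position(
    rng: np.random.Generator, L: int, occupied: Set[int], span: int = 1,
    margin: int = 20,
) -> Optional[int]:
    for _ in range(200):
        pos0 = int(rng.integers(margin, L - margin - span))
        if all(p not in occupied for p in range(pos0 - 1, pos0 + span + 1)):
            return pos0
    return None


def simulate_cohort(
    genome: GenomeSequence,
    config: SimulationConfig,
    pset: Optional[KmerPresenceSet] = None,
    disjoint_signatures: bool = True,
    seed: Optional[int] = None,
) -> CohortTruth:
    """Plant recurrent nullomer-creating substitutions per cancer type.

    Each cancer type receives a pool of signature substitutions, chosen
    by rejection sampling so that each one resurrects at least one
    nullomer; every signature variant is shared by ``recurrence_depth``
    distinct patients of its type.  Private background substitutions and
    indels (no resurfacing requirement) are added per patient.  With
    ``disjoint_signatures`` the planted neomer sets of different types
    share no canonical k-mer.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    if pset is None:
        pset = build_presence_set(genome, cfg.k)
    contig = next(iter(genome.contigs))
    seq = genome.contigs[contig]
    L = len(seq)

    n_slots = max(1, round(cfg.recurrent_fraction * cfg.substitutions_per_patient))
    n_sig = max(1, cfg.patients_per_type * n_slots // cfg.recurrence_depth)

    variants: List[Variant] = []
    truth_rows: List[dict] = []
    signature_neomers: Dict[str, Set[str]] = {}
    used_neomers: Set[str] = set()
    # positions already edited, per patient, so one haplotype can apply
    # all of a patient's variants without overlap
    occupied_by_patient: Dict[str, Set[int]] = {}

    for t in range(cfg.n_cancer_types):
        ctype = f"type{t}"
        patients = [f"{ctype}_p{i}" for i in range(cfg.patients_per_type)]
        for p in patients:
            occupied_by_patient.setdefault(p, set())
        sig_variants: List[Tuple[int, str, str, Set[str]]] = []
        type_neomers: Set[str] = set()
        attempts = 0
        while len(sig_variants) < n_sig:
            attempts += 1
            if attempts > 200 * n_sig:
                raise RuntimeError(
                    f"could not plant {n_sig} nullomer-creating substitutions "
                    f"for {ctype} after {attempts} attempts; the genome may be "
                    f"too small or k too short for abundant nullomers"
                )
            pos0 = int(rng.integers(cfg.k, L - cfg.k))
            ref = seq[pos0]
            alt = "ACGT"[int(rng.integers(4))]
            if alt == ref or ref not in "ACGT":
                continue
            v = Variant(contig, pos0 + 1, ref, alt)
            recs = resurfaced_nullomers(v, genome, pset)
            if not recs:
                continue
            created = {canonical_kmer(r.kmer) for r in recs}
            if disjoint_signatures and created & used_neomers:
                continue
            used_neomers |= created
            type_neomers |= created
            sig_variants.append((pos0, ref, alt, created))
        signature_neomers[ctype] = type_neomers

        for pos0, ref, alt, created in sig_variants:
            carriers = rng.choice(
                cfg.patients_per_type,
                size=min(cfg.recurrence_depth, cfg.patients_per_type),
                replace=False,
            )
            for ci in carriers:
                p = patients[int(ci)]
                if pos0 in occupied_by_patient[p]:
                    continue
                occupied_by_patient[p].update(range(pos0 - 1, pos0 + 2))
                variants.append(Variant(contig, pos0 + 1, ref, alt, p, ctype))
            for kmer in created:
                truth_rows.append(
                    {
                        "neomer": kmer,
                        "cancer_type": ctype,
                        "chrom": contig,
                        "pos": pos0 + 1,
                        "ref": ref,
                        "alt": alt,
                    }
                )

        # private background mutations, no resurfacing requirement
        n_private = cfg.substitutions_per_patient - n_slots
        for p in patients:
            for _ in range(max(0, n_private)):
                pos0 = _free_position(rng, L, occupied_by_patient[p])
                if pos0 is None:
                    continue
                ref = seq[pos0]
                alt = "ACGT"[("ACGT".index(ref) + int(rng.integers(1, 4))) % 4]
                occupied_by_patient[p].update(range(pos0 - 1, pos0 + 2))
                variants.append(Variant(contig, pos0 + 1, ref, alt, p, ctype))
            for _ in range(cfg.indels_per_patient):
                size = int(rng.integers(1, cfg.indel_size_max + 1))
                if rng.random() < 0.5:  # deletion
                    pos0 = _free_position(rng, L, occupied_by_patient[p], span=size + 1)
                    if pos0 is None:
                        continue
                    ref = seq[pos0:pos0 + size + 1]
                    alt = ref[0]
                else:  # insertion after an anchor base
                    pos0 = _free_position(rng, L, occupied_by_patient[p])
                    if pos0 is None:
                        continue
                    ref = seq[pos0]
                    ins = _LETTERS[rng.integers(0, 4, size)].tobytes().decode()
                    alt = ref + ins
                occupied_by_patient[p].update(range(pos0 - 1, pos0 + len(ref) + 1))
                variants.append(Variant(contig, pos0 + 1, ref, alt, p, ctype))

    truth = pd.DataFrame(
        truth_rows, columns=["neomer", "cancer_type", "chrom", "pos", "ref", "alt"]
    )
    return CohortTruth(
        variants=variants, truth_table=truth, signature_neomers=signature_neomers
    )


def simulate_germline_panel(
    genome: GenomeSequence,
    n_snps: int,
    seed: int = 0,
    common_fraction: float = 0.2,
) -> pd.DataFrame:
    """Random SNP panel with allele frequencies.

    A ``common_fraction`` of SNPs draw AF uniformly from (0.01, 0.5]
    (the "common" stratum the germline filter removes); the rest are
    rare, log-uniform on [1e-4, 0.01].
    """
    rng = np.random.default_rng(seed)
    contig = next(iter(genome.contigs))
    seq = genome.contigs[contig]
    rows = []
    while len(rows) < n_snps:
        pos0 = int(rng.integers(len(seq)))
        ref = seq[pos0]
        if ref not in "ACGT":
            continue
        alt = "ACGT"[int(rng.integers(4))]
        if alt == ref:
            continue
        if rng.random() < common_fraction:
            af = float(rng.uniform(0.01, 0.5))
        else:
            af = float(10 ** rng.uniform(-4, -2))
        rows.append({"chrom": contig, "pos": pos0 + 1, "ref": ref, "alt": alt, "af": af})
    return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "af"])


def germline_panel_variants(panel: pd.DataFrame):
    """Adapt a panel DataFrame to (Variant, af) pairs for the filter."""
    for row in panel.itertuples(index=False):
        yield Variant(row.chrom, int(row.pos), row.ref, row.alt), float(row.af)


def simulate_individual_germline(
    genome: GenomeSequence,
    panel: pd.DataFrame,
    n_private: int = 30,
    seed: int = 0,
    avoid_positions: Optional[Set[int]] = None,
) -> List[Variant]:
    """One individual's heterozygous germline genotype.

    Panel SNPs are carried with probability ~2*AF (Hardy-Weinberg
    heterozygote rate for small AF); ``n_private`` additional private
    rare SNPs are drawn at random positions, emulating the rare-variant
    load (below the common-AF filter) every real genome carries.
    Positions in ``avoid_positions`` (e.g. the individual's somatic
    sites) are skipped so haplotypes stay consistent.
    """
    rng = np.random.default_rng(seed)
    contig = next(iter(genome.contigs))
    seq = genome.contigs[contig]
    avoid = set(avoid_positions or ())
    out: List[Variant] = []
    taken: Set[int] = set()
    for row in panel.itertuples(index=False):
        pos0 = int(row.pos) - 1
        if rng.random() < min(1.0, 2 * float(row.af)):
            if pos0 in avoid or pos0 in taken:
                continue
            out.append(Variant(row.chrom, int(row.pos), row.ref, row.alt))
            taken.add(pos0)
    made = 0
    while made < n_private:
        pos0 = int(rng.integers(len(seq)))
        if pos0 in avoid or pos0 in taken:
            continue
        ref = seq[pos0]
        if ref not in "ACGT":
            continue
        alt = "ACGT"[("ACGT".index(ref) + int(rng.integers(1, 4))) % 4]
        out.append(Variant(contig, pos0 + 1, ref, alt))
        taken.add(pos0)
        made += 1
    return out


def apply_variants(seq: str, variants: Sequence[Variant]) -> str:
    """Apply non-overlapping variants to one contig (a haplotype)."""
    parts: List[str] = []
    cursor = 0
    for v in sorted(variants, key=lambda v: v.pos):
        pos0 = v.pos - 1
        if pos0 < cursor:
            raise ValueError(f"overlapping variants at {v.chrom}:{v.pos}")
        if seq[pos0:pos0 + len(v.ref)] != v.ref:
            raise ValueError(f"reference mismatch applying {v.chrom}:{v.pos}")
        parts.append(seq[cursor:pos0])
        parts.append(v.alt)
        cursor = pos0 + len(v.ref)
    parts.append(seq[cursor:])
    return "".join(parts)


@dataclass
class SimulatedReads:
    """Paired reads plus per-pair provenance and planted-neomer truth."""

    pairs: List[Tuple[str, str]]
    is_tumor: np.ndarray
    frag_start: np.ndarray
    frag_len: np.ndarray
    truth_pair_hits: Dict[int, FrozenSet[int]] = field(default_factory=dict)


def _draw_reads(
    hap: np.ndarray,
    starts: np.ndarray,
    frag_lens: np.ndarray,
    read_length: int,
    error_rate: float,
    rng: np.random.Generator,
) -> Tuple[List[str], List[str], List[str], List[str]]:
    """Extract mate code windows and return (r1, r2, clean_r1, clean_r2)."""
    n = len(starts)
    L = len(hap)
    read_lens = np.minimum(frag_lens, read_length)
    offs = np.arange(read_length)
    idx1 = np.minimum(starts[:, None] + offs[None, :], L - 1)
    r1 = hap[idx1]
    ends = starts + frag_lens
    idx2 = np.clip(ends[:, None] - 1 - offs[None, :], 0, L - 1)
    r2 = (3 - hap[idx2]).astype(np.uint8)

    def finish(codes: np.ndarray, with_errors: bool) -> List[str]:
        c = codes
        if with_errors and error_rate > 0:
            err = rng.random(c.shape) < error_rate
            shift = rng.integers(1, 4, size=c.shape, dtype=np.uint8)
            c = np.where(err, (c + shift) % 4, c).astype(np.uint8)
        letters = _LETTERS[c]
        return [
            letters[i, : read_lens[i]].tobytes().decode("ascii") for i in range(n)
        ]

    return finish(r1, True), finish(r2, True), finish(r1, False), finish(r2, False)


def simulate_cfdna_reads(
    genome: GenomeSequence,
    patient_variants: Sequence[Variant],
    config: SimulationConfig,
    seed: int = 0,
    n_pairs: Optional[int] = None,
    truth_neomers: Optional[Sequence[str]] = None,
    germline_variants: Optional[Sequence[Variant]] = None,
) -> SimulatedReads:
    """Paired-end cfDNA reads from a haplotype mixture.

    Each pair derives from the tumor haplotype (the patient's somatic
    variants plus any germline variants) with probability
    ``tumor_fraction``; otherwise from one of the two parental
    haplotypes — germline variants are modeled heterozygous on one of
    them, so their effective allele fraction is ~0.5.  Fragments start
    uniformly with truncated-Normal lengths; mates are the first and the
    reverse-complemented last ``read_length`` bases of the fragment,
    with i.i.d. substitution errors.  When ``truth_neomers`` is given,
    the pairs whose error-free mates BOTH contain a planted neomer are
    logged as truth hits.
    """
    cfg = config
    rng = np.random.default_rng(seed)
    contig = next(iter(genome.contigs))
    ref_seq = genome.contigs[contig]

    germ = list(germline_variants or ())
    if germ and patient_variants:
        blocked = set()
        for v in patient_variants:
            blocked.update(range(v.pos - 2, v.pos + len(v.ref) + 1))
        germ = [g for g in germ if g.pos - 1 not in blocked]
    germ_seq = apply_variants(ref_seq, germ) if germ else ref_seq
    tumor_seq = (
        apply_variants(ref_seq, list(patient_variants) + germ)
        if patient_variants
        else germ_seq
    )

    if n_pairs is None:
        n_pairs = int(round(cfg.coverage * len(ref_seq) / (2 * cfg.read_length)))
    u = rng.random(n_pairs)
    is_tumor = u < cfg.tumor_fraction
    # non-tumor pairs split evenly between the two parental haplotypes
    is_germ_hap = ~is_tumor & (u >= (1 + cfg.tumor_fraction) / 2)

    frag_lens = np.clip(
        np.round(rng.normal(cfg.fragment_mean, cfg.fragment_sd, n_pairs)),
        max(cfg.fragment_min, cfg.k),
        cfg.fragment_max,
    ).astype(np.int64)

    code_of = np.zeros(256, dtype=np.uint8)
    for i, b in enumerate("ACGT"):
        code_of[ord(b)] = i
    hap_ref = code_of[np.frombuffer(ref_seq.encode("ascii"), dtype=np.uint8)]
    hap_germ = code_of[np.frombuffer(germ_seq.encode("ascii"), dtype=np.uint8)]
    hap_tum = code_of[np.frombuffer(tumor_seq.encode("ascii"), dtype=np.uint8)]
    sources = (
        (~is_tumor & ~is_germ_hap, hap_ref),
        (is_germ_hap, hap_germ),
        (is_tumor, hap_tum),
    )

    starts = np.empty(n_pairs, dtype=np.int64)
    for mask, hap in sources:
        hi = np.maximum(len(hap) - frag_lens[mask], 1)
        starts[mask] = (rng.random(mask.sum()) * hi).astype(np.int64)

    pairs: List[Tuple[str, str]] = [("", "")] * n_pairs
    clean: List[Tuple[str, str]] = [("", "")] * n_pairs
    for mask, hap in sources:
        sel = np.flatnonzero(mask)
        if not len(sel):
            continue
        r1, r2, c1, c2 = _draw_reads(
            hap, starts[sel], frag_lens[sel], cfg.read_length, cfg.error_rate, rng
        )
        for j, i in enumerate(sel):
            pairs[i] = (r1[j], r2[j])
            clean[i] = (c1[j], c2[j])

    truth_hits: Dict[int, FrozenSet[int]] = {}
    if truth_neomers:
        query = NeomerQuery(truth_neomers)
        tumor_idx = np.flatnonzero(is_tumor)
        if len(tumor_idx):
            h1 = _batch_hits([clean[i][0] for i in tumor_idx], query)
            h2 = _batch_hits([clean[i][1] for i in tumor_idx], query)
            for i, a, b in zip(tumor_idx, h1, h2):
                both = a & b
                if both:
                    truth_hits[int(i)] = frozenset(both)
    return SimulatedReads(
        pairs=pairs,
        is_tumor=is_tumor,
        frag_start=starts,
        frag_len=frag_lens,
        truth_pair_hits=truth_hits,
    )


def write_fastq_pairs(
    pairs: Sequence[Tuple[str, str]], r1_path: str, r2_path: str, sample: str = "sim"
) -> None:
    """Write mates to (gzipped if *.gz) FASTQ files with uniform quality."""
    def _write(path: str, mate: int) -> None:
        opener = gzip.open if str(path).endswith(".gz") else open
        with opener(path, "wt") as fh:
            for i, pair in enumerate(pairs):
                seq = pair[mate]
                fh.write(f"@{sample}:{i}/{mate + 1}\n{seq}\n+\n{'I' * len(seq)}\n")

    _write(r1_path, 0)
    _write(r2_path, 1)
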