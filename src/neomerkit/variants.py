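"""Somatic variants and the nullomers they resurrect.

Applying a substitution or short indel to the reference can create k-mers
that were previously absent from the genome ("resurfacing" nullomers).
Every k-mer overlapping the edit in the mutated sequence lies inside a
window of (k-1) reference bases on each side of the replaced region, so
only that window is examined.  Variants are applied independently against
the unmutated reference — nearby variants in one patient are never phased
together.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Set, Tuple

import numpy as np
import pandas as pd

from .genome import GenomeSequence, reverse_complement
from .kmer import _CODE_OF_BASE, _POWERS, KmerPresenceSet

logger = logging.getLogger(__name__)

MAX_INDEL = 100


_RC = str.maketrans("ACGTN", "TGCAN")


def canonical_kmer(kmer: str) -> str:
    """The lexicographically smaller of a k-mer and its reverse complement.

    Used as the recurrence / counting unit: a k-mer and its RC are the
    same biological event; downstream tallies re-expand to RC pairs.
    """
    rc = kmer.translate(_RC)[::-1]
    return kmer if kmer <= rc else rc


@dataclass(frozen=True)
class Variant:
    """A somatic substitution or short indel (<= 100 bp length change).

    ``pos`` is the 1-based position of the first reference base.
    Pure insertions use an empty ``ref`` at the insertion point
    (or a shared anchor base, VCF-style; both are accepted).
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    patient_id: str = ""
    cancer_type: str = ""

    def __post_init__(self) -> None:
        ref, alt = self.ref.upper(), self.alt.upper()
        object.__setattr__(self, "ref", ref)
        object.__setattr__(self, "alt", alt)
        if ref == alt:
            raise ValueError(f"{self.chrom}:{self.pos} ref equals alt ({ref!r})")
        if abs(len(ref) - len(alt)) > MAX_INDEL:
            raise ValueError(
                f"{self.chrom}:{self.pos} indel length change exceeds {MAX_INDEL} bp"
            )
        if self.pos < 1:
            raise ValueError("pos is 1-based and must be >= 1")

    @property
    def is_substitution(self) -> bool:
        return len(self.ref) == len(self.alt)


@dataclass(frozen=True)
class ResurfacingRecord:
    """A nullomer created by applying one variant to the reference."""

    kmer: str
    variant: Variant
    window_offset: int

    @property
    def is_palindrome(self) -> bool:
        return self.kmer == reverse_complement(self.kmer)


def mutated_window(
    genome: GenomeSequence, v: Variant, k: int
) -> Tuple[str, Tuple[int, int]]:
    """Build the local mutated sequence around a variant.

    Returns ``(window, (alt_start, alt_end))`` where the window is
    (k-1) reference bases left of the edit, the alt allele, then (k-1)
    reference bases right of it (flanks clipped at contig boundaries), and
    the half-open span locates the alt allele within the window.
    """
    if v.chrom not in genome.contigs:
        raise KeyError(f"unknown contig {v.chrom!r}")
    seq = genome.contigs[v.chrom]
    pos0 = v.pos - 1
    observed = seq[pos0:pos0 + len(v.ref)]
    if observed != v.ref:
        raise ValueError(
            f"reference mismatch at {v.chrom}:{v.pos}: expected {v.ref!r}, "
            f"genome has {observed!r}"
        )
    left = seq[max(0, pos0 - (k - 1)):pos0]
    right = seq[pos0 + len(v.ref):pos0 + len(v.ref) + (k - 1)]
    window = left + v.alt + right
    return window, (len(left), len(left) + len(v.alt))


def resurfaced_nullomers(
    v: Variant, genome: GenomeSequence, pset: KmerPresenceSet
) -> Set[ResurfacingRecord]:
    """Every k-mer of the mutated window that overlaps the edit and is
    absent from the reference presence set.

    Records store the forward (window-strand) k-mer once per
    (variant, k-mer); reverse complements are re-expanded by downstream
    counting, with palindromes flagged.  Windows containing N are skipped.
    """
    k = pset.k
    window, (s, e) = mutated_window(genome, v, k)
    if len(window) < k:
        return set()
    # offsets of windows overlapping the edit (for a pure deletion, those
    # spanning the junction between the flanks)
    if v.alt:
        lo, hi = max(0, s - k + 1), min(len(window) - k, e - 1)
    else:
        lo, hi = max(0, s - k + 1), min(len(window) - k, s - 1)
    if hi < lo:
        return set()
    raw = np.frombuffer(window.encode("ascii"), dtype=np.uint8)
    base_codes = _CODE_OF_BASE[raw].astype(np.int64)
    win = np.lib.stride_tricks.sliding_window_view(base_codes, k)[lo:hi + 1]
    valid = (win < 4).all(axis=1)
    codes = win @ _POWERS[k]
    absent = valid & ~pset.contains_codes(np.where(valid, codes, 0))
    found: Dict[str, ResurfacingRecord] = {}
    for off in np.flatnonzero(absent):
        i = int(off) + lo
        kmer = window[i:i + k]
        if kmer not in found:
            found[kmer] = ResurfacingRecord(kmer=kmer, variant=v, window_offset=i)
    return set(found.values())


def rc_expanded_count(records: Iterable[ResurfacingRecord]) -> int:
    """Number of nullomer entries with the RC of each non-palindromic
    k-mer counted separately."""
    return sum(1 if r.is_palindrome else 2 for r in records)


@dataclass
class CohortAnnotation:
    """Per-patient resurfaced nullomer sets plus cohort summary statistics.

    ``patient_sets`` hold canonical k-mers (RC pairs collapsed to one
    unit); ``records`` keeps the full per-variant evidence.
    """

    patient_sets: Dict[str, Set[str]] = field(default_factory=dict)
    patient_cancer_type: Dict[str, str] = field(default_factory=dict)
    records: List[ResurfacingRecord] = field(default_factory=list)
    # (patient_id, is_substitution, RC-expanded nullomer count) per variant
    per_variant_counts: List[Tuple[str, bool, int]] = field(default_factory=list)
    per_patient_rc_expanded: Dict[str, int] = field(default_factory=dict)
    n_variants: int = 0
    n_skipped: int = 0

    def summary(self) -> dict:
        df = pd.DataFrame(
            self.per_variant_counts,
            columns=["patient_id", "is_substitution", "n_nullomers"],
        )
        out = {
            "n_variants": self.n_variants,
            "n_skipped": self.n_skipped,
            "n_patients": len(self.patient_sets),
        }
        if len(df):
            subs = df[df.is_substitution]
            indels = df[~df.is_substitution]
            out["fraction_substitutions_with_nullomer"] = (
                float((subs.n_nullomers > 0).mean()) if len(subs) else float("nan")
            )
            out["median_nullomers_per_substitution"] = (
                float(subs.n_nullomers.median()) if len(subs) else float("nan")
            )
            out["median_nullomers_per_indel"] = (
                float(indels.n_nullomers.median()) if len(indels) else float("nan")
            )
        totals = {p: len(s) for p, s in self.patient_sets.items()}
        out["per_patient_distinct_units"] = totals
        out["per_patient_rc_expanded"] = dict(self.per_patient_rc_expanded)
        if totals:
            out["median_nullomers_per_patient"] = float(
                np.median(list(totals.values()))
            )
        return out


def annotate_cohort(
    variants: Iterable[Variant],
    genome: GenomeSequence,
    pset: KmerPresenceSet,
    keep_records: bool = True,
) -> CohortAnnotation:
    """Annotate a stream of somatic variants for resurfacing nullomers.

    Each variant is processed independently; malformed or
    reference-mismatching variants are logged and skipped with a count.
    Per-variant nullomer counts use the separate-RC accounting (a
    non-palindromic k-mer and its RC count as two).  For very large
    cohorts ``keep_records=False`` drops the per-record evidence and
    retains only the per-patient sets and summary tallies.
    """
    ann = CohortAnnotation()
    for v in variants:
        ann.n_variants += 1
        pid = v.patient_id
        ann.patient_sets.setdefault(pid, set())
        ann.per_patient_rc_expanded.setdefault(pid, 0)
        if v.cancer_type:
            ann.patient_cancer_type[pid] = v.cancer_type
        try:
            recs = resurfaced_nullomers(v, genome, pset)
        except (ValueError, KeyError) as exc:
            logger.warning("skipping variant %s:%s: %s", v.chrom, v.pos, exc)
            ann.n_skipped += 1
            continue
        if keep_records:
            ann.records.extend(recs)
        ann.patient_sets[pid].update(canonical_kmer(r.kmer) for r in recs)
        n_expanded = rc_expanded_count(recs)
        ann.per_patient_rc_expanded[pid] += n_expanded
        ann.per_variant_counts.append((pid, v.is_substitution, n_expanded))
    return ann


# ---------------------------------------------------------------------------
# readers

TSV_COLUMNS = ["chrom", "pos", "ref", "alt", "patient_id", "cancer_type"]


def read_variant_tsv(path: str) -> List[Variant]:
    """Read the minimal 6-column dialect: chrom, 1-based pos, ref, alt,
    patient, cancer type.  A header line is detected and allowed."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if df.iloc[0, 0] in ("chrom", "CHROM", "#chrom"):
        df = df.iloc[1:]
    df.columns = TSV_COLUMNS[: df.shape[1]]
    variants = []
    n_bad = 0
    for row in df.itertuples(index=False):
        try:
            variants.append(
                Variant(
                    chrom=row.chrom,
                    pos=int(row.pos),
                    ref="" if row.ref in ("-", ".") else row.ref,
                    alt="" if row.alt in ("-", ".") else row.alt,
                    patient_id=getattr(row, "patient_id", "") or "",
                    cancer_type=getattr(row, "cancer_type", "") or "",
                )
            )
        except (ValueError, TypeError) as exc:
            n_bad += 1
            logger.warning("skipping malformed row %s: %s", tuple(row), exc)
    if n_bad:
        logger.warning("skipped %d malformed variant rows", n_bad)
    return variants


def read_variant_vcf(
    path: str,
    patient_id: str = "",
    cancer_type: str = "",
    sample_map: Optional[Mapping[str, Tuple[str, str]]] = None,
) -> List[Variant]:
    """Read CHROM/POS/REF/ALT records from a VCF.

    Multi-allelic sites are decomposed into one record per alternate
    allele.  Patient and cancer-type labels come either from the
    per-file arguments or from ``sample_map`` (file sample name ->
    (patient, cancer_type)).
    """
    from pysam import VariantFile

    variants = []
    with VariantFile(path) as vcf:
        for rec in vcf:
            for alt in rec.alts or ():
                if any(c not in "ACGTN" for c in alt.upper()):
                    continue  # symbolic / breakend alleles
                pid, ctype = patient_id, cancer_type
                if sample_map and rec.samples:
                    name = next(iter(rec.samples))
                    if name in sample_map:
                        pid, ctype = sample_map[name]
                try:
                    variants.append(
                        Variant(rec.chrom, rec.pos, rec.ref, alt, pid, ctype)
                    )
                except ValueError as exc:
                    logger.warning("skipping %s:%s: %s", rec.chrom, rec.pos, exc)
    return variants


def write_records_tsv(records: Iterable[ResurfacingRecord], path: str) -> None:
    rows = [
        {
            "kmer": r.kmer,
            "chrom": r.variant.chrom,
            "pos": r.variant.pos,
            "ref": r.variant.ref,
            "alt": r.variant.alt,
            "patient_id": r.variant.patient_id,
            "cancer_type": r.variant.cancer_type,
            "window_offset": r.window_offset,
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
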