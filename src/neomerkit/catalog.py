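"""Cancer-type neomer catalogs, supervised selection, and enrichment stats.

A *neomer* is a recurrent resurfacing nullomer: one created by somatic
mutations in at least r_i distinct patients of a single cancer type.  The
recurrence threshold r_i is chosen per type to bring the catalog close to
a target size (~10,000 by default) and falls back to the minimum of 2.

A k-mer and its reverse complement are one recurrence unit here; all sets
store canonical k-mers (lexicographic min of the pair).  A flag on
:func:`recurrence_filter` restores the strand-separate accounting.
"""

from __future__ import annotations

import json
import logging
import warnings
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .genome import GenomeSequence
from .kmer import KmerPresenceSet
from .variants import (
    ResurfacingRecord,
    Variant,
    canonical_kmer,
    resurfaced_nullomers,
)

logger = logging.getLogger(__name__)

DEFAULT_TARGET = 10_000
MIN_RECURRENCE = 2


def recurrence_filter(
    patient_sets: Mapping[str, Iterable[str]],
    r: int,
    rc_as_one_unit: bool = True,
) -> Dict[str, int]:
    """Keep k-mers found in >= r distinct patients of one cancer type.

    Returns {canonical k-mer: number of supporting patients}.  With
    ``rc_as_one_unit`` (default) a k-mer and its RC count toward the same
    patients; disabling it tallies each strand separately.
    """
    if r < MIN_RECURRENCE:
        raise ValueError(f"recurrence threshold must be >= {MIN_RECURRENCE}")
    counts: Counter = Counter()
    for patient, kmers in patient_sets.items():
        if rc_as_one_unit:
            # deduplicate within the patient after canonicalization, so a
            # k-mer and its RC in one patient's set count that patient once
            counts.update({canonical_kmer(k) for k in kmers})
        else:
            counts.update(set(kmers))
    return {k: n for k, n in counts.items() if n >= r}


def choose_threshold(
    patient_sets: Mapping[str, Iterable[str]],
    target: int = DEFAULT_TARGET,
) -> int:
    """Pick the recurrence threshold r_i for one cancer type.

    Scans r = 2, 3, ... and returns the r whose filtered catalog size is
    closest to ``target`` (ties to the smaller r).  If even r=2 yields a
    catalog at or under the target, r=2 is returned directly.
    """
    if len(patient_sets) < 2:
        raise ValueError("need at least 2 patients to choose a threshold")
    counts = Counter()
    for patient, kmers in patient_sets.items():
        for kmer in set(canonical_kmer(k) for k in kmers):
            counts[kmer] += 1
    if not counts:
        return MIN_RECURRENCE
    recurrences = np.array(sorted(counts.values()))
    max_r = int(recurrences[-1])
    best_r, best_gap = MIN_RECURRENCE, None
    for r in range(MIN_RECURRENCE, max_r + 1):
        size = int((recurrences >= r).sum())
        if size == 0:
            break
        if r == MIN_RECURRENCE and size <= target:
            return MIN_RECURRENCE
        gap = abs(size - target)
        if best_gap is None or gap < best_gap:
            best_r, best_gap = r, gap
    return best_r


@dataclass
class NeomerCatalog:
    """Per-cancer-type recurrence-filtered neomer sets.

    ``sets[t]`` maps canonical neomer -> patient recurrence count;
    ``thresholds[t]`` is the r_i used for type t.
    """

    sets: Dict[str, Dict[str, int]] = field(default_factory=dict)
    thresholds: Dict[str, int] = field(default_factory=dict)
    k: int = 0
    cohort_id: str = ""

    @property
    def cancer_types(self) -> List[str]:
        return sorted(self.sets)

    def save(self, tsv_path: str, json_path: Optional[str] = None) -> None:
        rows = [
            {"cancer_type": t, "neomer": k, "recurrence": c}
            for t in self.cancer_types
            for k, c in sorted(self.sets[t].items())
        ]
        pd.DataFrame(rows).to_csv(tsv_path, sep="\t", index=False)
        if json_path:
            with open(json_path, "w") as fh:
                json.dump(
                    {
                        "thresholds": self.thresholds,
                        "k": self.k,
                        "cohort_id": self.cohort_id,
                    },
                    fh,
                    indent=2,
                )

    @classmethod
    def load(cls, tsv_path: str, json_path: Optional[str] = None) -> "NeomerCatalog":
        df = pd.read_csv(tsv_path, sep="\t", dtype={"neomer": str})
        sets: Dict[str, Dict[str, int]] = defaultdict(dict)
        for row in df.itertuples(index=False):
            sets[row.cancer_type][row.neomer] = int(row.recurrence)
        meta = {}
        if json_path:
            with open(json_path) as fh:
                meta = json.load(fh)
        return cls(
            sets=dict(sets),
            thresholds=meta.get("thresholds", {}),
            k=meta.get("k", len(df.neomer.iloc[0]) if len(df) else 0),
            cohort_id=meta.get("cohort_id", ""),
        )


def build_catalog(
    patient_sets_by_type: Mapping[str, Mapping[str, Iterable[str]]],
    target: int = DEFAULT_TARGET,
    fixed_r: Optional[int] = None,
    k: int = 0,
    cohort_id: str = "",
) -> NeomerCatalog:
    """Recurrence-filter each cancer type's patient sets into a catalog."""
    catalog = NeomerCatalog(k=k, cohort_id=cohort_id)
    for ctype, psets in patient_sets_by_type.items():
        if fixed_r is not None:
            r = fixed_r
        elif len(psets) < 2:
            logger.warning(
                "cancer type %s has < 2 patients; using r=%d", ctype, MIN_RECURRENCE
            )
            r = MIN_RECURRENCE
        else:
            r = choose_threshold(psets, target)
        catalog.thresholds[ctype] = r
        catalog.sets[ctype] = recurrence_filter(psets, r)
    return catalog


def jaccard_matrix(catalog: NeomerCatalog) -> pd.DataFrame:
    """Pairwise Jaccard index |A∩B|/|A∪B| between per-type neomer sets."""
    types = catalog.cancer_types
    if len(types) < 2:
        raise ValueError("need at least 2 cancer types")
    mat = np.eye(len(types))
    for i, a in enumerate(types):
        for j in range(i + 1, len(types)):
            sa, sb = set(catalog.sets[a]), set(catalog.sets[types[j]])
            union = len(sa | sb)
            if union == 0:
                warnings.warn(f"empty union for {a}/{types[j]}; Jaccard set to 0")
                val = 0.0
            else:
                val = len(sa & sb) / union
            mat[i, j] = mat[j, i] = val
    return pd.DataFrame(mat, index=types, columns=types)


def patient_profile(
    patient_nullomers: Iterable[str], catalog: NeomerCatalog
) -> np.ndarray:
    """Per-cancer-type neomer intersection counts for one patient.

    Component t is |patient set ∩ catalog[t]| on canonical units; the
    vector length equals the number of cancer types in the catalog.
    """
    if not catalog.sets:
        raise ValueError("catalog is empty")
    canon = {canonical_kmer(k) for k in patient_nullomers}
    return np.array(
        [len(canon & set(catalog.sets[t])) for t in catalog.cancer_types]
    )


# ---------------------------------------------------------------------------
# supervised selection

MSI_MOTIFS = ("AAAAAAAA", "TTTTTTTT")


def msi_motif_count(sample_neomers: Iterable[str]) -> int:
    """Count neomers containing a polyA/polyT run of length 8.

    Microsatellite-instable tumors preferentially mutate mononucleotide
    repeat tracts, so their neomers are enriched for A8/T8 substrings.
    Counting is per entry as given (RC pairs kept separate contribute 2).
    """
    return sum(
        1 for k in sample_neomers if MSI_MOTIFS[0] in k or MSI_MOTIFS[1] in k
    )


def pole_context_filter(
    records: Iterable[ResurfacingRecord],
    genome: GenomeSequence,
    both_strands: bool = True,
) -> Set[str]:
    """Neomers created by TCT>TAT or TCG>TTG substitutions.

    These trinucleotide contexts are the signature of polymerase-epsilon
    proofreading deficiency.  The context is the reference base and its
    two reference neighbors; with ``both_strands`` (default) the
    reverse-complement presentation of each context also qualifies.
    Indel records and records whose context cannot be fetched are skipped.
    """
    wanted = {("TCT", "A"), ("TCG", "T")}
    if both_strands:
        # TCT>TAT read on the other strand is AGA>ATA; TCG>TTG is CGA>CAA
        wanted |= {("AGA", "T"), ("CGA", "A")}
    kept: Set[str] = set()
    n_skipped = 0
    for rec in records:
        v = rec.variant
        if not (v.is_substitution and len(v.ref) == 1):
            continue
        pos0 = v.pos - 1
        context = genome.fetch(v.chrom, pos0 - 1, pos0 + 2)
        if len(context) != 3:
            n_skipped += 1
            continue
        if (context, v.alt) in wanted:
            kept.add(rec.kmer)
    if n_skipped:
        logger.warning("%d records lacked a full trinucleotide context", n_skipped)
    return kept


def harmonic_threshold(
    neg_counts: Sequence[float], pos_counts: Sequence[float]
) -> float:
    """Decision cut between two count distributions.

    t = 2ab/(a+b) with a the maximum of the negative class and b the
    minimum of the positive class; a sample classifies positive when its
    count is >= t.
    """
    if not len(neg_counts) or not len(pos_counts):
        raise ValueError("both count lists must be nonempty")
    a, b = max(neg_counts), min(pos_counts)
    if a == 0 and b == 0:
        raise ValueError("harmonic mean undefined: both classes are all-zero")
    return 2.0 * a * b / (a + b)


def classify_by_threshold(count: float, t: float) -> bool:
    """Positive iff count >= t (the boundary sample is called positive)."""
    return count >= t


def germline_creatable_filter(
    neomers: Iterable[str],
    germline_variants: Iterable[Tuple[Variant, Optional[float]]],
    genome: GenomeSequence,
    pset: KmerPresenceSet,
    af_min: float = 0.01,
) -> Set[str]:
    """Drop neomers creatable by a common germline variant (AF > af_min).

    ``germline_variants`` yields (variant, allele frequency) pairs;
    missing frequencies are treated as rare (kept) and logged.  Matching
    is RC-aware: a neomer is removed if it or its RC can resurface from
    any qualifying variant.
    """
    kept = {canonical_kmer(k): k for k in neomers}
    n_no_af = 0
    for v, af in germline_variants:
        if af is None:
            n_no_af += 1
            continue
        if af <= af_min:
            continue
        try:
            recs = resurfaced_nullomers(v, genome, pset)
        except (ValueError, KeyError) as exc:
            logger.warning("skipping germline variant %s:%s: %s", v.chrom, v.pos, exc)
            continue
        for rec in recs:
            kept.pop(canonical_kmer(rec.kmer), None)
    if n_no_af:
        logger.warning("%d germline variants without AF treated as rare", n_no_af)
    return set(kept.values())


# ---------------------------------------------------------------------------
# enrichment statistics


def _random_substitutions(
    genome: GenomeSequence, n: int, rng: np.random.Generator
) -> List[Variant]:
    """Uniform random substitutions at uniform random N-free positions."""
    names = list(genome.contigs)
    lengths = np.array([len(genome.contigs[c]) for c in names], dtype=float)
    out: List[Variant] = []
    while len(out) < n:
        ci = rng.choice(len(names), p=lengths / lengths.sum())
        seq = genome.contigs[names[ci]]
        pos0 = int(rng.integers(len(seq)))
        ref = seq[pos0]
        if ref not in "ACGT":
            continue
        alt = "ACGT"[int(rng.integers(4))]
        if alt == ref:
            continue
        out.append(Variant(names[ci], pos0 + 1, ref, alt))
    return out


def driver_enrichment(
    driver_variants: Sequence[Variant],
    genome: GenomeSequence,
    pset: KmerPresenceSet,
    n_perm: int = 1000,
    seed: int = 0,
) -> dict:
    """Permutation test: are driver mutations likelier to resurrect
    nullomers than random substitutions?

    fold = (fraction of drivers creating >= 1 nullomer) / (mean fraction
    over n_perm random variant sets of equal size); the p-value uses the
    add-one permutation estimator.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    if not driver_variants:
        raise ValueError("empty driver list")
    rng = np.random.default_rng(seed)

    def creating_fraction(vs: Sequence[Variant]) -> float:
        hits = 0
        for v in vs:
            try:
                if resurfaced_nullomers(v, genome, pset):
                    hits += 1
            except (ValueError, KeyError):
                continue
        return hits / len(vs)

    observed = creating_fraction(driver_variants)
    perm_fracs = np.array(
        [
            creating_fraction(_random_substitutions(genome, len(driver_variants), rng))
            for _ in range(n_perm)
        ]
    )
    mean_perm = float(perm_fracs.mean())
    if mean_perm == 0:
        raise ValueError("no permuted variant created a nullomer; fold undefined")
    return {
        "observed_fraction": observed,
        "permuted_mean_fraction": mean_perm,
        "fold": observed / mean_perm,
        "p_value": float((1 + (perm_fracs >= observed).sum()) / (n_perm + 1)),
        "n_perm": n_perm,
    }


@dataclass
class EnrichmentResult:
    expectation: float
    observed: int
    fold: float
    p_value: float


def hypergeom_enrichment(
    n_draws: int, white: int, black: int, observed: int
) -> EnrichmentResult:
    """Urn-model enrichment of an observed overlap count.

    Drawing ``n_draws`` balls without replacement from an urn of ``white``
    successes and ``black`` failures: expectation = n_draws * white /
    (white + black), fold = observed / expectation, p = P(X >= observed)
    under the hypergeometric law.
    """
    if min(n_draws, white, black, observed) < 0:
        raise ValueError("all arguments must be >= 0")
    if observed > n_draws:
        raise ValueError("observed cannot exceed the number of draws")
    total = white + black
    if total == 0:
        raise ValueError("urn is empty")
    expectation = n_draws * white / total
    p_value = float(hypergeom.sf(observed - 1, total, white, n_draws))
    return EnrichmentResult(
        expectation=expectation,
        observed=observed,
        fold=observed / expectation if expectation > 0 else float("nan"),
        p_value=p_value,
    )
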