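"""Exact-match neomer scanning of paired cfDNA reads.

Reads are scanned for exact occurrences of query neomers (or their
reverse complements — sequencing strand is arbitrary, so an RC pair is a
single detection unit).  The engine computes 2-bit rolling k-mer codes
over each read and tests canonical codes against a sorted query-code
array, so cost is O(read length) per read regardless of query-set size.

Filtering rules applied per sample:
  * both-mates rule: a neomer counts for a read pair only if found in
    both mates;
  * support rule: neomers backed by fewer than ``min_pairs`` (default 2)
    read pairs are dropped;
  * genome-anchor rule: a hit pair is kept only if a mate shows evidence
    of genomic origin — at least one N-free k-mer outside the neomer
    match is present in the reference presence set (a desk-scale stand-in
    for requiring the read to align to the genome; a full aligner can be
    substituted).

Per-sample results become a neomer density matrix d_ij = n_ij / C_j
(supporting-pair count over mean coverage).
"""

from __future__ import annotations

import gzip
import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .kmer import (
    KmerPresenceSet,
    _CODE_OF_BASE,
    decode_kmer,
    revcomp_codes,
)

logger = logging.getLogger(__name__)

DEFAULT_MIN_PAIRS = 2


class NeomerQuery:
    """A fixed-k neomer list prepared for O(1) membership tests.

    Stores sorted canonical codes (min of code and RC code); lookup by
    either strand maps to the same unit.
    """

    def __init__(self, kmers: Iterable[str]):
        kmers = list(kmers)
        if not kmers:
            raise ValueError("empty neomer query list")
        lengths = {len(s) for s in kmers}
        if len(lengths) != 1:
            raise ValueError(f"mixed k-mer lengths in query: {sorted(lengths)}")
        self.k = lengths.pop()
        raw = np.frombuffer("".join(kmers).upper().encode("ascii"), dtype=np.uint8)
        base = _CODE_OF_BASE[raw]
        if (base > 3).any():
            bad = int(np.flatnonzero(base > 3)[0])
            raise ValueError(
                f"invalid base {kmers[bad // self.k][bad % self.k]!r} "
                f"in query k-mer {bad // self.k}"
            )
        mat = base.reshape(len(kmers), self.k).astype(np.int64)
        powers = (4 ** np.arange(self.k - 1, -1, -1)).astype(np.int64)
        codes = mat @ powers
        canon = np.minimum(codes, revcomp_codes(codes, self.k))
        self.codes = np.unique(canon)

    def __len__(self) -> int:
        return len(self.codes)

    def decode(self, code: int) -> str:
        return decode_kmer(code, self.k)

    @classmethod
    def from_file(cls, path: str) -> "NeomerQuery":
        opener = gzip.open if str(path).endswith(".gz") else open
        with opener(path, "rt") as fh:
            return cls(line.strip() for line in fh if line.strip())


def _window_code_array(base_codes: np.ndarray, k: int) -> Tuple[np.ndarray, np.ndarray]:
    """(window codes, validity) over a 1-D base-code array (255 = non-ACGT).

    Codes are built by k shifted adds on contiguous slices (no strided
    copy); validity uses a cumulative count of bad bases per window.
    """
    n = len(base_codes)
    if n < k:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    m = n - k + 1
    wcodes = np.zeros(m, dtype=np.int64)
    for j in range(k):
        wcodes += base_codes[j:j + m].astype(np.int64) << (2 * (k - 1 - j))
    bad = np.concatenate(([0], np.cumsum(base_codes > 3, dtype=np.int64)))
    valid = (bad[k:] - bad[:-k]) == 0
    return wcodes, valid


def _read_window_codes(seq: str, k: int) -> Tuple[np.ndarray, np.ndarray]:
    """(codes, valid) for every length-k window of one read."""
    raw = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    return _window_code_array(_CODE_OF_BASE[raw], k)


def scan_read(seq: str, query: NeomerQuery) -> Set[int]:
    """Canonical query codes occurring exactly in one read (either strand)."""
    codes, valid = _read_window_codes(seq, query.k)
    if not len(codes):
        return set()
    canon = np.minimum(codes, revcomp_codes(codes, query.k))
    idx = np.searchsorted(query.codes, canon)
    idx[idx == len(query.codes)] = 0
    hits = valid & (query.codes[idx] == canon)
    return set(int(c) for c in np.unique(canon[hits]))


def scan_read_pair(
    r1: str, r2: str, query: NeomerQuery
) -> Tuple[Set[int], Set[int]]:
    """Hit sets (canonical codes) for each mate of a read pair."""
    return scan_read(r1, query), scan_read(r2, query)


def pair_consistency_filter(hits_r1: Set[int], hits_r2: Set[int]) -> Set[int]:
    """Keep only neomers detected in BOTH mates (RC-equated units)."""
    return hits_r1 & hits_r2


def _anchored(
    seq: str, neomer_codes: Set[int], query_k: int, pset: KmerPresenceSet
) -> Optional[bool]:
    """Does a read carry reference k-mers outside its neomer windows?

    Returns None when the read is too short to hold any window outside
    the neomer match (cannot be anchored either way).
    """
    k = pset.k
    codes, valid = _read_window_codes(seq, k)
    if not len(codes):
        return None
    if query_k == k:
        qcodes, qvalid = codes, valid
    else:
        qcodes, qvalid = _read_window_codes(seq, query_k)
    canon = np.minimum(qcodes, revcomp_codes(qcodes, query_k))
    inside = np.zeros(len(codes), dtype=bool)
    for j in np.flatnonzero(qvalid):
        if int(canon[j]) in neomer_codes:
            lo = max(0, j - k + 1)
            inside[lo:min(len(inside), j + query_k)] = True
    outside = np.flatnonzero(valid & ~inside)
    if not len(outside):
        return None
    return bool(pset.contains_codes(codes[outside]).any())


def genome_anchor_filter(
    r1: str,
    r2: str,
    pair_hits: Set[int],
    query: NeomerQuery,
    pset: KmerPresenceSet,
) -> Set[int]:
    """Keep a pair's hits only with evidence of genomic origin.

    At least one mate must contain an N-free reference k-mer outside the
    neomer match window.  Reads too short to anchor are retained with a
    warning, since the test cannot be applied.
    """
    if not pair_hits:
        return pair_hits
    verdicts = [_anchored(r, pair_hits, query.k, pset) for r in (r1, r2)]
    if all(v is None for v in verdicts):
        warnings.warn("read pair too short to anchor; retained unverified")
        return pair_hits
    return pair_hits if any(v for v in verdicts if v is not None) else set()


def estimate_coverage(total_bases_scanned: int, genome_length: int) -> float:
    """Mean coverage C_j = scanned bases / genome length."""
    if genome_length <= 0:
        raise ValueError("genome_length must be positive")
    if total_bases_scanned <= 0:
        raise ValueError("no scanned bases; coverage undefined")
    return total_bases_scanned / genome_length


@dataclass
class SampleScan:
    """Per-sample scan result: supporting-pair counts per neomer."""

    sample_id: str
    coverage: float
    counts: Dict[int, int] = field(default_factory=dict)
    pairs_scanned: int = 0
    pairs_with_hits: int = 0
    # hit evidence retained for downsampling: one frozenset of canonical
    # codes per (post-anchor, pair-consistent) hit pair
    pair_hit_sets: List[FrozenSet[int]] = field(default_factory=list)
    query_k: int = 0

    def total_neomers(self) -> int:
        return len(self.counts)


def support_filter(
    counts: Dict[int, int], min_pairs: int = DEFAULT_MIN_PAIRS
) -> Dict[int, int]:
    """Drop neomers supported by fewer than ``min_pairs`` read pairs."""
    if min_pairs < 1:
        raise ValueError("min_pairs must be >= 1")
    return {c: n for c, n in counts.items() if n >= min_pairs}


def _batch_hits(
    reads: Sequence[str],
    query: NeomerQuery,
    batch: int = 20_000,
    absent_prefilter: Optional[KmerPresenceSet] = None,
) -> List[Set[int]]:
    """Per-read canonical hit sets, computed in concatenated batches.

    ``absent_prefilter`` (the reference presence set the query's
    nullomers are absent from) restricts the candidate windows to those
    absent from the reference before the query lookup — sound because a
    window matching a neomer can never be present in the reference.
    """
    k = query.k
    out: List[Set[int]] = []
    for start in range(0, len(reads), batch):
        chunk = reads[start:start + batch]
        joined = "\x00".join(chunk)
        raw = np.frombuffer(joined.upper().encode("latin-1"), dtype=np.uint8)
        wcodes, valid = _window_code_array(_CODE_OF_BASE[raw], k)
        if not len(wcodes):
            out.extend(set() for _ in chunk)
            continue
        if absent_prefilter is not None and absent_prefilter.k == k:
            probe = np.where(valid, wcodes, 0)
            valid = valid & ~absent_prefilter.contains_codes(probe)
        cand = np.flatnonzero(valid)
        sets: List[Set[int]] = [set() for _ in chunk]
        if len(cand):
            canon = np.minimum(wcodes[cand], revcomp_codes(wcodes[cand], k))
            idx = np.searchsorted(query.codes, canon)
            idx[idx == len(query.codes)] = 0
            is_hit = query.codes[idx] == canon
            hit_pos = cand[is_hit]
            # map window start positions back to read indices
            bounds = np.cumsum([len(r) + 1 for r in chunk])
            read_of = np.searchsorted(bounds, hit_pos, side="right")
            for code, ri in zip(canon[is_hit], read_of):
                sets[ri].add(int(code))
        out.extend(sets)
    return out


def scan_sample(
    pairs: Sequence[Tuple[str, str]],
    query: NeomerQuery,
    sample_id: str,
    genome_length: int,
    pset: Optional[KmerPresenceSet] = None,
    min_pairs: int = DEFAULT_MIN_PAIRS,
    anchor: bool = True,
    dedup_identical_pairs: bool = False,
) -> SampleScan:
    """Scan a sample's read pairs and apply all filtering rules.

    ``pset`` (the reference presence set) is required when ``anchor`` is
    enabled.  ``dedup_identical_pairs`` collapses byte-identical pairs
    (simple PCR-duplicate guard; UMI-based dedup is assumed upstream).
    """
    if anchor and pset is None:
        raise ValueError("genome anchoring requires the reference presence set")
    if dedup_identical_pairs:
        pairs = list(dict.fromkeys(pairs))
    total_bases = sum(len(a) + len(b) for a, b in pairs)
    coverage = estimate_coverage(total_bases, genome_length) if pairs else 0.0

    # scan all first mates; second mates only for pairs whose first mate
    # hit (the both-mates rule makes other pairs irrelevant)
    r1_hits = _batch_hits([p[0] for p in pairs], query, absent_prefilter=pset)
    candidates = [i for i, h in enumerate(r1_hits) if h]
    r2_hits = _batch_hits(
        [pairs[i][1] for i in candidates], query, absent_prefilter=pset
    )

    counts: Dict[int, int] = {}
    hit_sets: List[FrozenSet[int]] = []
    pairs_with_hits = 0
    for i, h2 in zip(candidates, r2_hits):
        r1, r2 = pairs[i]
        kept = pair_consistency_filter(r1_hits[i], h2)
        if kept and anchor:
            kept = genome_anchor_filter(r1, r2, kept, query, pset)  # type: ignore[arg-type]
        if not kept:
            continue
        pairs_with_hits += 1
        hit_sets.append(frozenset(kept))
        for code in kept:
            counts[code] = counts.get(code, 0) + 1
    return SampleScan(
        sample_id=sample_id,
        coverage=coverage,
        counts=support_filter(counts, min_pairs),
        pairs_scanned=len(pairs),
        pairs_with_hits=pairs_with_hits,
        pair_hit_sets=hit_sets,
        query_k=query.k,
    )


def read_fastq_pairs(r1_path: str, r2_path: str) -> List[Tuple[str, str]]:
    """Load mate sequences from paired (possibly gzipped) FASTQ files."""
    from Bio import SeqIO

    def _read(path: str) -> List[str]:
        opener = gzip.open if str(path).endswith(".gz") else open
        with opener(path, "rt") as fh:
            return [str(rec.seq) for rec in SeqIO.parse(fh, "fastq")]

    r1, r2 = _read(r1_path), _read(r2_path)
    if len(r1) != len(r2):
        raise ValueError(
            f"mate files differ in read count: {len(r1)} vs {len(r2)}"
        )
    return list(zip(r1, r2))


@dataclass
class NeomerDensityMatrix:
    """Samples x neomers matrix of coverage-normalized counts."""

    densities: pd.DataFrame  # index: sample_id, columns: neomer sequence
    metadata: pd.DataFrame  # index: sample_id; label / stage / coverage

    def to_triplets(self) -> pd.DataFrame:
        stacked = self.densities.stack()
        stacked = stacked[stacked > 0]
        out = stacked.rename("density").reset_index()
        out.columns = ["sample", "neomer", "density"]
        return out


def build_ndm(
    scans: Sequence[SampleScan],
    metadata: Optional[pd.DataFrame] = None,
    neomer_universe: Optional[Sequence[int]] = None,
) -> NeomerDensityMatrix:
    """Combine per-sample scans into the density matrix d_ij = n_ij / C_j."""
    ks = {s.query_k for s in scans}
    if len(ks) != 1:
        raise ValueError("scans use different neomer universes (mixed k)")
    k = ks.pop()
    for s in scans:
        if s.coverage <= 0:
            raise ValueError(f"sample {s.sample_id} has non-positive coverage")
    if neomer_universe is None:
        universe = sorted({c for s in scans for c in s.counts})
    else:
        universe = sorted(neomer_universe)
    cols = [decode_kmer(c, k) for c in universe]
    data = np.zeros((len(scans), len(universe)))
    col_of = {c: j for j, c in enumerate(universe)}
    for i, s in enumerate(scans):
        for code, n in s.counts.items():
            if code in col_of:
                data[i, col_of[code]] = n / s.coverage
    dens = pd.DataFrame(data, index=[s.sample_id for s in scans], columns=cols)
    if metadata is None:
        metadata = pd.DataFrame(index=dens.index)
    metadata = metadata.reindex(dens.index)
    metadata["coverage"] = [s.coverage for s in scans]
    return NeomerDensityMatrix(densities=dens, metadata=metadata)


def downsample_scan(
    scan: SampleScan,
    c: float,
    reps: int = 100,
    seed: int = 0,
    min_pairs: int = DEFAULT_MIN_PAIRS,
) -> List[Dict[int, int]]:
    """Simulate scanning at a lower target coverage c.

    Each hit read pair is retained independently with probability
    c / C_i (sampling without replacement from the original pairs); the
    support filter is re-applied per replicate.  Returns one
    {neomer code: supporting pairs} dict per replicate.
    """
    C_i = scan.coverage
    if not 0 < c <= C_i:
        raise ValueError(f"target coverage must be in (0, {C_i}], got {c}")
    p_keep = c / C_i
    root = np.random.default_rng(seed)
    out: List[Dict[int, int]] = []
    for rep in range(reps):
        rng = np.random.default_rng(root.integers(2 ** 31))
        keep = rng.random(len(scan.pair_hit_sets)) < p_keep
        counts: Dict[int, int] = {}
        for flag, hits in zip(keep, scan.pair_hit_sets):
            if not flag:
                continue
            for code in hits:
                counts[code] = counts.get(code, 0) + 1
        out.append(support_filter(counts, min_pairs))
    return out
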