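"""K-mer presence sets and nullomer enumeration.

A k-mer (k <= 17) is encoded in 2 bits per base, big-endian, with
A=0, C=1, G=2, T=3, so the all-A k-mer has code 0 and the all-T k-mer has
code 4**k - 1.  A :class:`KmerPresenceSet` is a dense bitmap over all 4**k
codes recording which k-mers occur in a genome on either strand; it is
closed under reverse complement by construction, so its complement — the
nullomers — is reverse-complement closed too.  Genome windows containing
any non-ACGT symbol are skipped silently.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

from .genome import GenomeSequence

MAX_K = 17

_BASES = "ACGT"
_CODE_OF_BASE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(_BASES):
    _CODE_OF_BASE[ord(_b)] = _i
    _CODE_OF_BASE[ord(_b.lower())] = _i

# popcount of each byte, for present/nullomer tallies
_POPCOUNT8 = np.array([bin(i).count("1") for i in range(256)], dtype=np.uint32)

# big-endian 2-bit place values, per k
_POWERS = {
    k: (4 ** np.arange(k - 1, -1, -1)).astype(np.int64) for k in range(1, MAX_K + 1)
}

_INDEX_MAGIC = b"NMKIDX1\x00"


def _check_k(k: int) -> None:
    if not 1 <= k <= MAX_K:
        raise ValueError(f"k must be in 1..{MAX_K}, got {k}")


def encode_kmer(seq: str) -> int:
    """Encode an ACGT string as its 2-bit big-endian integer code."""
    _check_k(len(seq))
    code = 0
    for i, base in enumerate(seq.upper()):
        v = _CODE_OF_BASE[ord(base)]
        if v > 3:
            raise ValueError(f"invalid base {seq[i]!r} at position {i}")
        code = (code << 2) | int(v)
    return code


def decode_kmer(code: int, k: int) -> str:
    """Inverse of :func:`encode_kmer`."""
    _check_k(k)
    out = []
    for shift in range(2 * (k - 1), -1, -2):
        out.append(_BASES[(code >> shift) & 3])
    return "".join(out)


def revcomp_codes(codes: np.ndarray | int, k: int) -> np.ndarray | int:
    """Vectorized reverse-complement on integer k-mer codes."""
    scalar = np.isscalar(codes)
    c = np.atleast_1d(np.asarray(codes, dtype=np.int64)).copy()
    rc = np.zeros_like(c)
    for _ in range(k):
        rc = (rc << 2) | (3 - (c & 3))
        c >>= 2
    return int(rc[0]) if scalar else rc


def _window_codes(seq: str, k: int, chunk: int = 1 << 20) -> Iterator[np.ndarray]:
    """Yield the codes of every N-free length-k window of ``seq``."""
    raw = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    codes = _CODE_OF_BASE[raw]
    powers = (4 ** np.arange(k - 1, -1, -1)).astype(np.int64)
    n = len(codes)
    for start in range(0, max(n - k + 1, 0), chunk):
        stop = min(start + chunk + k - 1, n)
        block = codes[start:stop].astype(np.int64)
        if len(block) < k:
            break
        win = np.lib.stride_tricks.sliding_window_view(block, k)
        valid = (win < 4).all(axis=1)
        if valid.any():
            yield (win[valid] @ powers)


@dataclass
class KmerPresenceSet:
    """Dense bitmap membership structure over all 4**k k-mers.

    Invariant: present(x) iff present(revcomp(x)).
    """

    k: int
    genome_id: str = ""
    bits: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        _check_k(self.k)
        nbytes = (4 ** self.k + 7) // 8
        if self.bits is None:
            self.bits = np.zeros(nbytes, dtype=np.uint8)
        elif len(self.bits) != nbytes:
            raise ValueError("bitmap length does not match k")

    # -- mutation ---------------------------------------------------------
    def add_codes(self, codes: np.ndarray) -> None:
        """Mark codes and their reverse complements as present."""
        codes = np.asarray(codes, dtype=np.int64)
        if codes.size == 0:
            return
        both = np.concatenate([codes, revcomp_codes(codes, self.k)])
        both = np.unique(both)
        np.bitwise_or.at(
            self.bits, both >> 3, (1 << (both & 7)).astype(np.uint8)
        )

    # -- queries ----------------------------------------------------------
    def contains_codes(self, codes: np.ndarray | int):
        """Bit test; vectorized over an array of codes."""
        scalar = np.isscalar(codes)
        c = np.atleast_1d(np.asarray(codes, dtype=np.int64))
        hit = (self.bits[c >> 3] >> (c & 7).astype(np.uint8)) & 1
        out = hit.astype(bool)
        return bool(out[0]) if scalar else out

    def __contains__(self, kmer: str) -> bool:
        if len(kmer) != self.k:
            raise ValueError(f"expected a {self.k}-mer, got {len(kmer)} bases")
        return self.contains_codes(encode_kmer(kmer))

    @property
    def n_present(self) -> int:
        total = int(_POPCOUNT8[self.bits].sum())
        # mask possible padding bits in the final byte (only when 4^k < 8)
        return min(total, 4 ** self.k)

    @property
    def n_nullomers(self) -> int:
        return 4 ** self.k - self.n_present

    # -- serialization ----------------------------------------------------
    def save(self, path: str) -> None:
        gid = self.genome_id.encode("utf-8")
        with open(path, "wb") as fh:
            fh.write(_INDEX_MAGIC)
            fh.write(struct.pack("<BH", self.k, len(gid)))
            fh.write(gid)
            self.bits.tofile(fh)

    @classmethod
    def load(cls, path: str) -> "KmerPresenceSet":
        with open(path, "rb") as fh:
            magic = fh.read(8)
            if magic != _INDEX_MAGIC:
                raise ValueError(f"{path} is not a neomerkit index")
            k, gid_len = struct.unpack("<BH", fh.read(3))
            genome_id = fh.read(gid_len).decode("utf-8")
            bits = np.fromfile(fh, dtype=np.uint8)
        return cls(k=k, genome_id=genome_id, bits=bits)


def build_presence_set(genome: GenomeSequence, k: int) -> KmerPresenceSet:
    """Collect every N-free k-mer window of the genome, both strands."""
    _check_k(k)
    pset = KmerPresenceSet(k=k, genome_id=genome.genome_id)
    for _name, seq in genome:
        for codes in _window_codes(seq, k):
            pset.add_codes(codes)
    return pset


def enumerate_nullomers(
    pset: KmerPresenceSet, chunk: int = 1 << 20
) -> Iterator[str]:
    """Yield every absent k-mer once, in code order.

    A nullomer and its reverse complement are yielded as distinct entries
    (unless palindromic), matching the separate-RC accounting used for all
    downstream counts.
    """
    total = 4 ** pset.k
    chunk = max(8, chunk - chunk % 8)  # keep chunk boundaries byte-aligned
    for start in range(0, total, chunk):
        stop = min(start + chunk, total)
        flags = np.unpackbits(
            pset.bits[start >> 3:(stop + 7) >> 3], bitorder="little"
        )[: stop - start]
        for code in np.flatnonzero(flags == 0) + start:
            yield decode_kmer(int(code), pset.k)


def _edit_neighbors(seq: str) -> set[str]:
    """All strings at edit distance exactly 1 (sub/ins/del) from ``seq``."""
    out: set[str] = set()
    for i in range(len(seq)):
        for b in _BASES:
            if b != seq[i]:
                out.add(seq[:i] + b + seq[i + 1:])      # substitution
        out.add(seq[:i] + seq[i + 1:])                   # deletion
    for i in range(len(seq) + 1):
        for b in _BASES:
            out.add(seq[:i] + b + seq[i:])               # insertion
    out.discard(seq)
    return out


def nullomer_order_at_least(
    kmer: str,
    pset: KmerPresenceSet,
    genome: GenomeSequence,
    d: int = 1,
) -> bool:
    """True iff no sequence of <= d single-base edits to the genome can
    create an occurrence of ``kmer``.

    Creatability by one genome edit is tested through the equivalent
    neighbor formulation: the k-mer is creatable by one substitution iff a
    Hamming-1 neighbor occurs in the genome; by one genome insertion iff a
    single-base deletion of the k-mer occurs; by one genome deletion iff a
    single-base insertion into the k-mer occurs.  Depths beyond 1 iterate
    the neighborhood.
    """
    if d not in (1, 2):
        raise ValueError("order depth d must be 1 or 2")
    if kmer in pset:
        raise ValueError(f"{kmer} is present in the reference, not a nullomer")
    frontier = {kmer}
    seen = {kmer}
    for _depth in range(d):
        nxt: set[str] = set()
        for s in frontier:
            for nb in _edit_neighbors(s):
                if nb in seen or not nb:
                    continue
                seen.add(nb)
                if genome.contains_substring(nb):
                    return False
                nxt.add(nb)
        frontier = nxt
    return True
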