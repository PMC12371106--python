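"""Genome sequence container and FASTA I/O.

Coordinates are 1-based inclusive in all files and CLI output and 0-based
half-open internally.  Contigs are stored uppercased; soft-masked
(lowercase) bases are treated as ordinary bases, since masking reflects
repeat annotation, not absence.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from typing import Dict, Iterator, Tuple

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

VALID_BASES = frozenset("ACGTN")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string over {A,C,G,T,N} (case kept).

    Raises ``ValueError`` on any other character, reporting its position.
    """
    bad = set(seq.upper()) - VALID_BASES
    if bad:
        pos = next(i for i, c in enumerate(seq.upper()) if c in bad)
        raise ValueError(
            f"invalid base {seq[pos]!r} at position {pos} (expected A/C/G/T/N)"
        )
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class GenomeSequence:
    """A named collection of DNA contigs over {A,C,G,T,N}."""

    contigs: Dict[str, str] = field(default_factory=dict)
    genome_id: str = ""

    def __post_init__(self) -> None:
        cleaned = {}
        for name, seq in self.contigs.items():
            if len(seq) < 1:
                raise ValueError(f"contig {name!r} is empty")
            cleaned[name] = seq.upper()
        self.contigs = cleaned

    def __len__(self) -> int:
        return sum(len(s) for s in self.contigs.values())

    def __iter__(self) -> Iterator[Tuple[str, str]]:
        return iter(self.contigs.items())

    def fetch(self, chrom: str, start0: int, end0: int) -> str:
        """Fetch [start0, end0) from a contig, clipped at the boundaries."""
        seq = self.contigs[chrom]
        return seq[max(0, start0):max(0, end0)]

    def contains_substring(self, pattern: str) -> bool:
        """True if ``pattern`` occurs in any contig on either strand."""
        rc = reverse_complement(pattern)
        return any(pattern in seq or rc in seq for seq in self.contigs.values())


def read_fasta(path: str, genome_id: str | None = None) -> GenomeSequence:
    """Read a (possibly gzipped) multi-contig FASTA into memory."""
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as handle:
        contigs = {rec.id: str(rec.seq) for rec in SeqIO.parse(handle, "fasta")}
    if not contigs:
        raise ValueError(f"no sequences found in {path}")
    return GenomeSequence(contigs, genome_id=genome_id or str(path))


def write_fasta(genome: GenomeSequence, path: str, width: int = 70) -> None:
    opener = gzip.open if str(path).endswith(".gz") else open
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in genome
    ]
    with opener(path, "wt") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=width)
        writer.write_file(records)
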