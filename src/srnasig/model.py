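"""Core data model: aligned small-RNA reads, genomes, and libraries.

Coordinates are 0-based half-open throughout the package; SAM input is
converted on load. Nucleotides at read 5' ends are reported in RNA space
(U, not T), as is conventional in the small-RNA literature.
"""
from __future__ import annotations

from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field

from .errors import DataError

_DNA_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return seq.translate(_DNA_COMPLEMENT)[::-1]


def to_rna(base: str) -> str:
    """Map a DNA base to RNA space (T -> U); unknown characters become N."""
    base = base.upper()
    if base == "T":
        return "U"
    return base if base in "ACGU" else "N"


@dataclass(frozen=True, order=True)
class AlignedRead:
    """One mapped small-RNA alignment.

    ``first_nt`` is the nucleotide at the read's 5' end in read orientation:
    the genome base at ``start`` for + reads, the complement of the genome
    base at ``end - 1`` for - reads, expressed in RNA space.
    """

    chrom: str
    start: int
    end: int
    strand: str
    first_nt: str = "N"
    copy: int = 1

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise DataError(
                f"invalid interval [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in ("+", "-"):
            raise DataError(f"invalid strand {self.strand!r}")
        if self.copy < 1:
            raise DataError(f"copy number must be >= 1, got {self.copy}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def five_prime(self) -> int:
        """Genomic coordinate of the 5'-most base (strand-aware)."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def three_prime(self) -> int:
        """Genomic coordinate of the 3'-most base (strand-aware)."""
        return self.end - 1 if self.strand == "+" else self.start


class Genome(Mapping):
    """Named chromosome sequences with length and 5'-base lookup."""

    def __init__(self, sequences: Mapping[str, str]):
        self._seqs = {name: str(seq).upper() for name, seq in sequences.items()}
        if not self._seqs:
            raise DataError("genome contains no sequences")

    def __getitem__(self, name: str) -> str:
        return self._seqs[name]

    def __iter__(self):
        return iter(self._seqs)

    def __len__(self) -> int:
        return len(self._seqs)

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self._seqs.items()}

    @property
    def total_length(self) -> int:
        return sum(len(seq) for seq in self._seqs.values())

    def first_nt(self, chrom: str, start: int, end: int, strand: str) -> str:
        """5'-end nucleotide (RNA space) of a read at the given interval."""
        seq = self._seqs[chrom]
        if strand == "+":
            base = seq[start]
        else:
            base = seq[end - 1].translate(_DNA_COMPLEMENT)
        return to_rna(base)

    def fetch(self, chrom: str, start: int, end: int, strand: str = "+") -> str:
        """Read-orientation sequence of an interval (DNA space)."""
        seq = self._seqs[chrom][start:end]
        return seq if strand == "+" else revcomp(seq)


@dataclass
class Library:
    """A sample's read collection with the totals needed for RPM scaling.

    ``total_mapped`` counts all retained alignments (sum of copy numbers
    within the length window applied on load); the pre-filter alignment
    count is kept in ``metadata['prefilter_total']`` when known.
    """

    sample_id: str
    reads: list[AlignedRead]
    chrom_lengths: dict[str, int]
    metadata: dict = field(default_factory=dict)

    @property
    def total_mapped(self) -> int:
        return sum(r.copy for r in self.reads)

    def __len__(self) -> int:
        return len(self.reads)

    def validate(self) -> None:
        """Check every read against chromosome bounds."""
        for r in self.reads:
            limit = self.chrom_lengths.get(r.chrom)
            if limit is None:
                raise DataError(f"read on unknown chromosome {r.chrom}")
            if r.end > limit:
                raise DataError(
                    f"read [{r.start},{r.end}) exceeds {r.chrom} length {limit}"
                )

    def reads_by_chrom(self) -> dict[str, list[AlignedRead]]:
        out: dict[str, list[AlignedRead]] = {}
        for r in self.reads:
            out.setdefault(r.chrom, []).append(r)
        return out


def dedupe_reads(reads: Iterable[AlignedRead]) -> list[AlignedRead]:
    """Collapse identical alignments summing copies. The 5' nucleotide is
    part of the identity so that 1U filters survive collapsing (genuine
    duplicate alignments always share it)."""
    acc: dict[tuple, list] = {}
    for r in reads:
        key = (r.chrom, r.start, r.end, r.strand, r.first_nt)
        if key in acc:
            acc[key][1] += r.copy
        else:
            acc[key] = [r, r.copy]
    out = []
    for (chrom, start, end, strand, first_nt), (r, copies) in acc.items():
        if copies == r.copy:
            out.append(r)
        else:
            out.append(
                AlignedRead(chrom, start, end, strand, first_nt=first_nt, copy=copies)
            )
    return sorted(out)
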