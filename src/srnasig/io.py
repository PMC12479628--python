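"""Reading and writing genomes, alignments, loci and tables.

SAM/BAM input goes through pysam; FASTA through Biopython. Internal
coordinates are 0-based half-open; SAM's 1-based coordinates are converted
on load, BED passes through. Small-RNA alignments are expected to be
ungapped (bowtie-style); records whose CIGAR contains indels or splices are
skipped with a logged warning.
"""
from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO

from .errors import ConfigurationError, DataError
from .model import AlignedRead, Genome, Library, revcomp

logger = logging.getLogger(__name__)

# CIGAR ops consuming the reference without gaps: M, =, X
_UNGAPPED_OPS = {0, 7, 8}


def load_genome(path: str | Path) -> Genome:
    """Load a FASTA file into a Genome (sequences uppercased)."""
    path = Path(path)
    try:
        records = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
    except (ValueError, FileNotFoundError) as exc:  # malformed record
        raise DataError(f"cannot parse FASTA {path}: {exc}") from exc
    if not records:
        raise DataError(f"no FASTA records found in {path}")
    return Genome(records)


def _read_from_sam(rec: pysam.AlignedSegment, genome: Genome) -> AlignedRead:
    chrom = rec.reference_name
    start, end = rec.reference_start, rec.reference_end
    strand = "-" if rec.is_reverse else "+"
    return AlignedRead(
        chrom, start, end, strand, first_nt=genome.first_nt(chrom, start, end, strand)
    )


def load_alignments(
    path: str | Path,
    genome: Genome,
    min_len: int = 15,
    max_len: int = 35,
    sample_id: str | None = None,
    primary_only: bool = False,
) -> Library:
    """Load SAM/BAM or BED6 alignments, keeping reads with length in
    [min_len, max_len].

    ``total_mapped`` of the returned library counts retained alignments;
    the pre-filter mapped count is kept as ``metadata['prefilter_total']``
    and the number of length-filtered / skipped records as metadata too.
    """
    if min_len > max_len:
        raise ConfigurationError(f"min_len {min_len} > max_len {max_len}")
    path = Path(path)
    sample_id = sample_id or path.stem
    if path.suffix.lower() == ".bed":
        return _load_bed(path, genome, min_len, max_len, sample_id)

    reads: list[AlignedRead] = []
    n_input = n_filtered = n_skipped = 0
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped:
                continue
            if primary_only and (rec.is_secondary or rec.is_supplementary):
                continue
            n_input += 1
            if rec.reference_name not in genome:
                raise DataError(
                    f"record {rec.query_name} maps to unknown chromosome "
                    f"{rec.reference_name}"
                )
            if any(op not in _UNGAPPED_OPS for op, _ in (rec.cigartuples or [])):
                n_skipped += 1
                logger.warning(
                    "skipping gapped alignment %s (%s)", rec.query_name, rec.cigarstring
                )
                continue
            read = _read_from_sam(rec, genome)
            if min_len <= read.length <= max_len:
                reads.append(read)
            else:
                n_filtered += 1
    lib = Library(
        sample_id=sample_id,
        reads=sorted(reads),
        chrom_lengths=genome.lengths,
        metadata={
            "prefilter_total": n_input,
            "length_filtered": n_filtered,
            "skipped_gapped": n_skipped,
            "min_len": min_len,
            "max_len": max_len,
        },
    )
    lib.validate()
    return lib


def _load_bed(
    path: Path, genome: Genome, min_len: int, max_len: int, sample_id: str
) -> Library:
    cols = ["chrom", "start", "end", "name", "score", "strand"]
    df = pd.read_csv(path, sep="\t", header=None, names=cols, comment="#")
    reads: list[AlignedRead] = []
    n_input = len(df)
    n_filtered = 0
    for row in df.itertuples(index=False):
        if row.chrom not in genome:
            raise DataError(f"BED record {row.name} on unknown chromosome {row.chrom}")
        length = row.end - row.start
        if not (min_len <= length <= max_len):
            n_filtered += 1
            continue
        copy = int(row.score) if int(row.score) >= 1 else 1
        reads.append(
            AlignedRead(
                row.chrom,
                int(row.start),
                int(row.end),
                row.strand,
                first_nt=genome.first_nt(row.chrom, int(row.start), int(row.end), row.strand),
                copy=copy,
            )
        )
    lib = Library(
        sample_id=sample_id,
        reads=sorted(reads),
        chrom_lengths=genome.lengths,
        metadata={
            "prefilter_total": n_input,
            "length_filtered": n_filtered,
            "skipped_gapped": 0,
            "min_len": min_len,
            "max_len": max_len,
        },
    )
    lib.validate()
    return lib


def size_distribution(
    library: Library, min_len: int = 15, max_len: int = 35
) -> pd.Series:
    """Copy-weighted read counts per length over [min_len, max_len]."""
    if min_len > max_len:
        raise ConfigurationError("empty length window")
    counts = pd.Series(
        0, index=pd.RangeIndex(min_len, max_len + 1, name="length"), dtype=int
    )
    for r in library.reads:
        if min_len <= r.length <= max_len:
            counts[r.length] += r.copy
    return counts


def rpm(count: float, total_mapped: int) -> float:
    """Reads-per-million-mapped normalization of a raw count."""
    if total_mapped <= 0:
        raise DataError("total_mapped must be positive for RPM scaling")
    return count * 1_000_000 / total_mapped


# ---------------------------------------------------------------- writers


def write_fasta(genome: Genome, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in genome:
            fh.write(f">{name}\n")
            seq = genome[name]
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def sam_header(chrom_lengths: dict[str, int]) -> pysam.AlignmentHeader:
    return pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": name, "LN": length} for name, length in chrom_lengths.items()],
        }
    )


def write_sam(library: Library, genome: Genome, path: str | Path) -> None:
    """Write a library as coordinate-sorted SAM; one record per alignment copy
    group, copy number in the XC tag. Sequences are taken from the genome."""
    header = sam_header(library.chrom_lengths)
    order = {name: i for i, name in enumerate(library.chrom_lengths)}
    reads = sorted(
        library.reads, key=lambda r: (order[r.chrom], r.start, r.end, r.strand)
    )
    with pysam.AlignmentFile(str(path), "wh", header=header, add_sam_header=True) as fh:
        for i, r in enumerate(reads):
            seg = pysam.AlignedSegment(header)
            seg.query_name = f"r{i:07d}"
            seg.reference_name = r.chrom
            seg.reference_start = r.start
            seg.flag = 16 if r.strand == "-" else 0
            seg.mapping_quality = 255
            seg.cigarstring = f"{r.length}M"
            seg.query_sequence = genome.fetch(r.chrom, r.start, r.end, r.strand)
            seg.set_tag("XC", r.copy)
            fh.write(seg)


def write_bed(
    intervals: Iterable[tuple], path: str | Path, names: Sequence[str] | None = None
) -> None:
    """Write (chrom, start, end[, name, score, strand]) tuples as BED6."""
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            chrom, start, end = iv[0], iv[1], iv[2]
            name = iv[3] if len(iv) > 3 else (names[i] if names else f"feature_{i}")
            score = iv[4] if len(iv) > 4 else 0
            strand = iv[5] if len(iv) > 5 else "."
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\t{score}\t{strand}\n")


def write_table(df: pd.DataFrame, path: str | Path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.6g")
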