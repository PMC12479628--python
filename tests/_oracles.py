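"""Independent brute-force reference implementations used as test oracles.

These are deliberately naive O(n^2) / per-base algorithms, kept free of any
code shared with the package's optimized implementations.
"""
from __future__ import annotations

import numpy as np

from srnasig.model import AlignedRead


def brute_overlap_hist(reads, k_max: int) -> np.ndarray:
    hist = np.zeros(k_max + 1, dtype=float)
    for p in reads:
        if p.strand != "+":
            continue
        for m in reads:
            if m.strand != "-" or m.chrom != p.chrom:
                continue
            k = m.end - p.start
            if 1 <= k <= k_max and m.start < p.end:
                hist[k] += p.copy * m.copy
    return hist


def brute_dicer_pair_count(reads, size_range=(20, 24), overhang=2) -> int:
    lo, hi = size_range
    seen = set()
    for p in reads:
        if p.strand != "+" or not (lo <= p.length <= hi):
            continue
        for m in reads:
            if m.strand != "-" or m.chrom != p.chrom:
                continue
            if not (lo <= m.length <= hi):
                continue
            if p.end - m.end == overhang and p.start - m.start == overhang:
                seen.add((p.chrom, p.start, p.end, m.start, m.end))
    return len(seen)


def brute_phasing_hist(reads, d_max: int, require_1u: bool = True) -> np.ndarray:
    hist = np.zeros(d_max + 1, dtype=float)
    for u in reads:
        for d_read in reads:
            if d_read is u or d_read.chrom != u.chrom or d_read.strand != u.strand:
                continue
            if u.strand == "+":
                d = d_read.start - (u.end - 1)
            else:
                d = u.start - (d_read.end - 1)
            if 1 <= d <= d_max:
                if require_1u and d_read.first_nt != "U":
                    continue
                hist[d] += u.copy * d_read.copy
    return hist


def brute_islands(reads, chrom_lengths, min_depth=1):
    out = []
    for chrom in sorted(chrom_lengths):
        cov = np.zeros(chrom_lengths[chrom], dtype=int)
        for r in reads:
            if r.chrom == chrom:
                cov[r.start : r.end] += r.copy
        above = cov >= min_depth
        start = None
        for i, flag in enumerate(above):
            if flag and start is None:
                start = i
            elif not flag and start is not None:
                out.append((chrom, start, i))
                start = None
        if start is not None:
            out.append((chrom, start, len(cov)))
    return out


def brute_size_factors(values) -> np.ndarray:
    """Median-of-ratios size factors recomputed cell by cell."""
    arr = np.asarray(values, dtype=float)
    factors = []
    for j in range(arr.shape[1]):
        ratios = []
        for i in range(arr.shape[0]):
            row = arr[i]
            if (row > 0).all():
                gm = float(np.prod(row)) ** (1.0 / len(row))
                ratios.append(arr[i, j] / gm)
        factors.append(float(np.median(ratios)))
    return np.array(factors)


def random_reads(
    rng: np.random.Generator,
    n: int,
    chroms=("chrA", "chrB"),
    span: int = 2000,
    len_range=(15, 32),
    with_copies: bool = False,
) -> list[AlignedRead]:
    """Random read sets dense enough to populate many histogram bins."""
    reads = []
    for _ in range(n):
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        length = int(rng.integers(len_range[0], len_range[1] + 1))
        start = int(rng.integers(0, span - length))
        strand = "+" if rng.random() < 0.5 else "-"
        first = "ACGU"[int(rng.integers(0, 4))]
        copy = int(rng.integers(1, 4)) if with_copies else 1
        reads.append(AlignedRead(chrom, start, start + length, strand, first, copy))
    return reads
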