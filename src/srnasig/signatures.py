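"""Small-RNA biogenesis signature statistics.

Three screens are implemented, all on 0-based half-open alignments:

* **Ping Pong**: the histogram of 5'-5' overlap distances k between
  opposite-strand read pairs, and the z-score of the k = 10 bin against all
  other bins — the piRNA amplification-loop signature.
* **Dicer pairs**: opposite-strand pairs of ~20–24 nt reads forming a
  duplex with 2-nt 3' overhangs on *both* ends, the geometry of an RNase
  III product; summarized as the percentage of Dicer pairs per library.
* **Phasing**: the histogram of head-to-tail distances d between
  same-strand reads (d = downstream 5' minus upstream 3'; d = 1 means
  immediately adjacent), restricted by default to 1U downstream reads, and
  the z-score of the d = 1 bin — the Zucchini processing signature.

Histogram bins accumulate copy(a) x copy(b) products, which reduces to pair
counts for copy = 1 alignments. z-scores use the sample standard deviation
(n - 1) of the background bins and are NaN (flagged undefined) when that
standard deviation is zero.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .errors import ConfigurationError, DataError
from .model import AlignedRead, Library, dedupe_reads

DEFAULT_K_MAX = 25
DEFAULT_D_MAX = 9


@dataclass
class SignatureProfile:
    """Overlap/phasing histograms and z-scores for one read set.

    Histogram arrays are indexed by distance: position k holds bin k
    (position 0 is unused and always zero). z-scores are NaN when the
    background bins have zero variance.
    """

    overlap_hist: np.ndarray
    pingpong_z: float
    phasing_hist: np.ndarray
    phasing_z: float
    n_pairs_considered: int

    @property
    def pingpong_defined(self) -> bool:
        return not math.isnan(self.pingpong_z)

    @property
    def phasing_defined(self) -> bool:
        return not math.isnan(self.phasing_z)


def _as_reads(obj) -> list[AlignedRead]:
    return list(obj.reads) if isinstance(obj, Library) else list(obj)


def overlap_histogram(reads: Iterable[AlignedRead], k_max: int = DEFAULT_K_MAX) -> np.ndarray:
    """5'-5' overlap histogram between opposite-strand reads.

    For a plus read P = [pS, pE) and minus read M = [mS, mE) on the same
    chromosome, the overlap is k = mE - pS (the minus 5' end sits at
    mE - 1); bin k accumulates copy(P) x copy(M) for 1 <= k <= k_max,
    provided the reads physically overlap (mS < pE).
    """
    if k_max < 1:
        raise ConfigurationError(f"k_max must be >= 1, got {k_max}")
    hist = np.zeros(k_max + 1, dtype=float)
    reads = dedupe_reads(_as_reads(reads))
    minus_by_end: dict[tuple[str, int], list[tuple[int, int]]] = {}
    for r in reads:
        if r.strand == "-":
            minus_by_end.setdefault((r.chrom, r.end), []).append((r.start, r.copy))
    for r in reads:
        if r.strand != "+":
            continue
        for k in range(1, k_max + 1):
            for m_start, m_copy in minus_by_end.get((r.chrom, r.start + k), ()):
                if m_start < r.end:
                    hist[k] += r.copy * m_copy
    return hist


def _background_zscore(hist: Sequence[float], focal: int) -> float:
    bins = np.asarray(hist, dtype=float)[1:]
    if len(bins) < 2 or not (1 <= focal <= len(bins)):
        raise ConfigurationError("histogram too short for the focal bin")
    background = np.delete(bins, focal - 1)
    sd = float(np.std(background, ddof=1))
    if sd == 0.0:
        return float("nan")
    return (float(bins[focal - 1]) - float(np.mean(background))) / sd


def pingpong_zscore(overlap_hist: Sequence[float], focal: int = 10) -> float:
    """z of the 10-nt overlap bin against all other bins (sample sd);
    NaN when the background has zero variance."""
    return _background_zscore(overlap_hist, focal)


def phasing_zscore(phasing_hist: Sequence[float], focal: int = 1) -> float:
    """z of the distance-1 bin against bins 2..d_max; same contract as
    :func:`pingpong_zscore`."""
    return _background_zscore(phasing_hist, focal)


def find_dicer_pairs(
    reads,
    size_range: tuple[int, int] = (20, 24),
    overhang: int = 2,
    both_ends: bool = True,
) -> list[tuple[AlignedRead, AlignedRead]]:
    """All opposite-strand pairs forming a Dicer duplex.

    Both reads must have lengths within ``size_range`` and the duplex 2-nt
    3' overhangs: pE - mE == overhang and pS - mS == overhang (both ends by
    default; ``both_ends=False`` accepts either end). Reads are first
    collapsed to distinct alignment coordinates, so each unordered
    coordinate pair is reported exactly once.
    """
    if size_range[0] > size_range[1]:
        raise ConfigurationError(f"inverted size_range {size_range}")
    if overhang < 0:
        raise ConfigurationError("overhang must be >= 0")
    lo, hi = size_range
    reads = dedupe_reads(_as_reads(reads))
    minus_index: dict[tuple[str, int, int], AlignedRead] = {}
    minus_by_start: dict[tuple[str, int], list[AlignedRead]] = {}
    minus_by_end: dict[tuple[str, int], list[AlignedRead]] = {}
    for r in reads:
        if r.strand == "-" and lo <= r.length <= hi:
            minus_index[(r.chrom, r.start, r.end)] = r
            minus_by_start.setdefault((r.chrom, r.start), []).append(r)
            minus_by_end.setdefault((r.chrom, r.end), []).append(r)
    pairs: list[tuple[AlignedRead, AlignedRead]] = []
    seen: set[tuple] = set()
    for p in reads:
        if p.strand != "+" or not (lo <= p.length <= hi):
            continue
        if both_ends:
            m = minus_index.get((p.chrom, p.start - overhang, p.end - overhang))
            candidates = [m] if m is not None else []
        else:
            candidates = [
                m
                for m in (
                    minus_by_start.get((p.chrom, p.start - overhang), [])
                    + minus_by_end.get((p.chrom, p.end - overhang), [])
                )
            ]
        for m in candidates:
            key = (p.chrom, p.start, p.end, m.start, m.end)
            if key not in seen:
                seen.add(key)
                pairs.append((p, m))
    return pairs


def percent_dicer_pairs(
    library: Library,
    size_range: tuple[int, int] = (20, 24),
    overhang: int = 2,
) -> dict[str, float]:
    """Percent of Dicer pairs: 100 x n_pairs / total retained alignments.

    Returns the percentage plus the underlying numerator choices: the
    distinct-coordinate pair count (default numerator) and the
    copy-weighted count of reads participating in at least one pair.
    """
    total = library.total_mapped
    if total <= 0:
        raise DataError("empty library: percent of Dicer pairs undefined")
    pairs = find_dicer_pairs(library, size_range, overhang)
    participants = {}
    for p, m in pairs:
        participants[(p.chrom, p.start, p.end, p.strand)] = p.copy
        participants[(m.chrom, m.start, m.end, m.strand)] = m.copy
    n_pairs = len(pairs)
    return {
        "percent_dicer_pairs": 100.0 * n_pairs / total,
        "n_pairs": float(n_pairs),
        "n_pair_reads": float(sum(participants.values())),
        "total_alignments": float(total),
        "prefilter_total": float(
            library.metadata.get("prefilter_total", total)
        ),
    }


def phasing_histogram(
    reads,
    d_max: int = DEFAULT_D_MAX,
    require_1u: bool = True,
) -> np.ndarray:
    """Head-to-tail distance histogram between same-strand reads.

    For an upstream read U and downstream read D in the 5'->3' orientation
    of their shared strand, d = (D's 5' coordinate) - (U's 3' coordinate);
    d = 1 means immediately adjacent. Bins 1..d_max accumulate
    copy(U) x copy(D); when ``require_1u`` only downstream reads whose first
    nucleotide is U contribute.
    """
    if d_max < 1:
        raise ConfigurationError(f"d_max must be >= 1, got {d_max}")
    hist = np.zeros(d_max + 1, dtype=float)
    reads = dedupe_reads(_as_reads(reads))
    plus_by_start: dict[tuple[str, int], list[AlignedRead]] = {}
    minus_by_end: dict[tuple[str, int], list[AlignedRead]] = {}
    for r in reads:
        if r.strand == "+":
            plus_by_start.setdefault((r.chrom, r.start), []).append(r)
        else:
            minus_by_end.setdefault((r.chrom, r.end), []).append(r)
    for r in reads:
        if r.strand == "+":
            # downstream 5' = upstream 3' + d  =>  start = (end - 1) + d
            for d in range(1, d_max + 1):
                for ds in plus_by_start.get((r.chrom, r.end - 1 + d), ()):
                    if require_1u and ds.first_nt != "U":
                        continue
                    hist[d] += r.copy * ds.copy
        else:
            # minus orientation runs right-to-left: upstream 3' is at start,
            # downstream 5' at its end - 1; d = U.start - (D.end - 1)
            for d in range(1, d_max + 1):
                for ds in minus_by_end.get((r.chrom, r.start + 1 - d), ()):
                    if require_1u and ds.first_nt != "U":
                        continue
                    hist[d] += r.copy * ds.copy
    return hist


def first_nt_fraction(reads, nucleotide: str = "U") -> float:
    """Copy-weighted fraction of reads whose 5' nucleotide equals
    ``nucleotide`` (RNA space)."""
    reads = _as_reads(reads)
    total = sum(r.copy for r in reads)
    if total == 0:
        raise DataError("empty read set: first-nucleotide fraction undefined")
    hit = sum(r.copy for r in reads if r.first_nt == nucleotide)
    return hit / total


def signature_profile(
    reads,
    k_max: int = DEFAULT_K_MAX,
    d_max: int = DEFAULT_D_MAX,
    require_1u: bool = True,
) -> SignatureProfile:
    """Compute the full signature profile of a read set."""
    ohist = overlap_histogram(reads, k_max)
    phist = phasing_histogram(reads, d_max, require_1u)
    return SignatureProfile(
        overlap_hist=ohist,
        pingpong_z=pingpong_zscore(ohist),
        phasing_hist=phist,
        phasing_z=phasing_zscore(phist),
        n_pairs_considered=int(ohist.sum() + phist.sum()),
    )
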