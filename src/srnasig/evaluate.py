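"""Ground-truth evaluation of the pipeline on simulated libraries.

Couples the synthetic generator's truth tables to the analysis stages:
per-truth-locus signature recovery, shuffled-position nulls, locus
annotation recovery at reciprocal overlap, and truth-label classification
agreement. Used by benchmark scripts and the acceptance checks.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from . import loci as loci_mod
from . import profiles, signatures, simulate
from .loci import Locus, assign_reads
from .model import AlignedRead, Library

#: truth class -> expected size-profile label
EXPECTED_LABEL = {
    "mirna": "dicer_sized",
    "sirna": "dicer_sized",
    "pingpong": "pirna_like",
    "phased": "pirna_like",
    "degradation": "degradation_like",
}


def truth_locus_reads(
    library: Library, truth: pd.DataFrame
) -> dict[str, list[AlignedRead]]:
    """Reads falling inside each truth locus interval (5'-end containment)."""
    rows = list(truth.itertuples())
    regions = [(r.chrom, r.start, r.end) for r in rows]
    assigned = assign_reads(library.reads, regions)
    return {rows[i].locus_id: assigned.get(i, []) for i in range(len(rows))}


def shuffle_positions(
    reads: list[AlignedRead], start: int, end: int, rng: np.random.Generator
) -> list[AlignedRead]:
    """Positional null: re-draw each read's start uniformly within
    [start, end), preserving length, strand and 5' nucleotide."""
    out = []
    for r in reads:
        s = int(rng.integers(start, max(start + 1, end - r.length)))
        out.append(AlignedRead(r.chrom, s, s + r.length, r.strand, r.first_nt, r.copy))
    return out


def pingpong_locus_zscores(
    library: Library, truth: pd.DataFrame, shuffled: bool = False, seed: int = 0
) -> list[float]:
    """Ping Pong z per simulated pingpong locus (optionally on the
    position-shuffled null of the same reads)."""
    rng = np.random.default_rng(seed)
    by_locus = truth_locus_reads(library, truth)
    zs = []
    for row in truth[truth.class_label == "pingpong"].itertuples():
        reads = by_locus[row.locus_id]
        if shuffled:
            reads = shuffle_positions(reads, row.start, row.end, rng)
        zs.append(signatures.pingpong_zscore(signatures.overlap_histogram(reads)))
    return zs


def phased_locus_stats(
    library: Library, truth: pd.DataFrame
) -> tuple[list[bool], list[float]]:
    """(bin-1 modal flags, phasing z) per simulated phased locus."""
    by_locus = truth_locus_reads(library, truth)
    modal, zs = [], []
    for row in truth[truth.class_label == "phased"].itertuples():
        hist = signatures.phasing_histogram(by_locus[row.locus_id])
        modal.append(bool(hist.argmax() == 1) and hist.sum() > 0)
        zs.append(signatures.phasing_zscore(hist))
    return modal, zs


def locus_recovery(
    called: list[Locus], truth: pd.DataFrame, min_reciprocal: float = 0.5
) -> float:
    """Fraction of truth loci matched by a called locus with reciprocal
    overlap >= ``min_reciprocal`` on both intervals."""
    if truth.empty:
        return float("nan")
    recovered = 0
    for row in truth.itertuples():
        width_t = row.end - row.start
        for l in called:
            if l.chrom != row.chrom:
                continue
            inter = min(l.end, row.end) - max(l.start, row.start)
            if (
                inter > 0
                and inter >= min_reciprocal * width_t
                and inter >= min_reciprocal * l.width
            ):
                recovered += 1
                break
    return recovered / len(truth)


def classification_accuracy(
    library: Library, truth: pd.DataFrame
) -> tuple[float, pd.DataFrame]:
    """Agreement between size-profile class calls on truth intervals and the
    labels expected for each simulated class."""
    loci = [
        Locus(r.locus_id, r.chrom, r.start, r.end, r.n_reads, 0.0)
        for r in truth.itertuples()
    ]
    table = profiles.classify_loci(loci, library)
    expected = truth.set_index("locus_id")["class_label"].map(EXPECTED_LABEL)
    table = table.assign(expected=expected, truth_class=truth.set_index("locus_id")["class_label"])
    return float((table["label"] == table["expected"]).mean()), table


def dicer_discrimination(seed: int, reads_per_locus: int = 60) -> dict[str, float]:
    """Percent Dicer pairs of an siRNA-rich library (~30% duplex reads)
    versus a piRNA-only library built under the same conditions."""
    rich_cfg = simulate.SimulationConfig(
        seed=seed,
        n_loci_per_class={"sirna": 3, "pingpong": 7},
        reads_per_locus=reads_per_locus,
        noise_reads=0,
    )
    pirna_cfg = simulate.SimulationConfig(
        seed=seed + 1000,
        n_loci_per_class={"pingpong": 7, "phased": 3},
        reads_per_locus=reads_per_locus,
        noise_reads=0,
    )
    rich_lib, _, _ = simulate.simulate_library(rich_cfg)
    pirna_lib, _, _ = simulate.simulate_library(pirna_cfg)
    rich = signatures.percent_dicer_pairs(rich_lib)["percent_dicer_pairs"]
    pirna = signatures.percent_dicer_pairs(pirna_lib)["percent_dicer_pairs"]
    ratio = float("inf") if pirna == 0 else rich / pirna
    return {"sirna_rich": rich, "pirna_only": pirna, "ratio": ratio}


def annotation_report(
    library: Library, truth: pd.DataFrame, merge_gap: int = 500, min_rpm: float = 1000.0
) -> dict[str, float]:
    called = loci_mod.annotate_loci(library, merge_gap=merge_gap, min_rpm=min_rpm)
    genome_bp = sum(library.chrom_lengths.values())
    return {
        "n_loci": float(len(called)),
        "recovery": locus_recovery(called, truth),
        "genome_coverage": sum(l.width for l in called) / genome_bp,
    }
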