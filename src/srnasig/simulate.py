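"""Synthetic small-RNA alignment libraries with known biogenesis signatures.

The generator writes the same artifacts a sequencing experiment would leave
behind — a genome FASTA, a coordinate-sorted SAM of 15–35 nt alignments,
and a per-locus truth table — but with every locus built to carry one of
the canonical small-RNA biogenesis signatures:

* ``mirna``       one dominant ~22 nt duplex (mature + low-abundance star)
                  with 2-nt 3' overhangs;
* ``sirna``       head-to-tail tiled Dicer duplexes, every duplex with 2-nt
                  3' overhangs on both ends;
* ``pingpong``    opposite-strand piRNA pairs whose 5' ends overlap by
                  exactly 10 nt, initiators 1U-biased;
* ``phased``      same-strand head-to-tail piRNA trains (inter-read
                  distance mostly 1), 1U-biased;
* ``degradation`` short (<18 nt) fragments of random strand.

Genome bases under biased read 5' positions are overwritten so that the 1U
bias is recoverable from the genome exactly as for real alignments. Reads
are emitted as distinct alignments (copy = 1); collapsing identical
alignments is an io-layer concern. A single seeded numpy Generator is
threaded through every operation, so identical (config, seed) yields
byte-identical output files.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as srio
from .errors import ConfigurationError, SimulationError
from .model import AlignedRead, Genome, Library

CLASSES = ("mirna", "sirna", "pingpong", "phased", "degradation")

_BASES = np.frombuffer(b"ACGT", dtype="S1")

# Spacing kept between placed loci so that gap-merge sweeps behave predictably.
LOCUS_SPACING = 2000


@dataclass
class SimulationConfig:
    """Parameters of one simulated library.

    ``reads_per_locus`` counts biogenesis events per locus: duplexes for
    mirna/sirna, pairs (or unpaired reads) for pingpong, reads for
    phased/degradation; duplex classes therefore emit about twice that many
    alignments.
    """

    seed: int = 0
    n_chromosomes: int = 4
    chrom_length: int = 300_000
    n_loci_per_class: dict = field(
        default_factory=lambda: {c: 10 for c in CLASSES}
    )
    reads_per_locus: int = 60
    pirna_len_range: tuple[int, int] = (26, 30)
    dicer_len_range: tuple[int, int] = (20, 24)
    deg_len_range: tuple[int, int] = (12, 17)
    noise_len_range: tuple[int, int] = (15, 35)
    u1_bias: float = 0.9
    pingpong_fraction: float = 0.9
    noise_reads: int = 300
    sample_id: str = "sim"

    def validate(self) -> None:
        if self.n_chromosomes < 1 or self.chrom_length < 10_000:
            raise ConfigurationError(
                "need >= 1 chromosome of >= 10 kb "
                f"(got {self.n_chromosomes} x {self.chrom_length})"
            )
        for name, rng_ in (
            ("pirna_len_range", self.pirna_len_range),
            ("dicer_len_range", self.dicer_len_range),
            ("deg_len_range", self.deg_len_range),
            ("noise_len_range", self.noise_len_range),
        ):
            lo, hi = rng_
            if not (10 <= lo <= hi <= 40):
                raise ConfigurationError(f"{name}={rng_} outside [10, 40]")
        for name, frac in (
            ("u1_bias", self.u1_bias),
            ("pingpong_fraction", self.pingpong_fraction),
        ):
            if not 0.0 <= frac <= 1.0:
                raise ConfigurationError(f"{name}={frac} outside [0, 1]")
        if self.reads_per_locus < 0 or self.noise_reads < 0:
            raise ConfigurationError("counts must be non-negative")
        unknown = set(self.n_loci_per_class) - set(CLASSES)
        if unknown:
            raise ConfigurationError(f"unknown locus classes: {sorted(unknown)}")
        if any(v < 0 for v in self.n_loci_per_class.values()):
            raise ConfigurationError("locus counts must be non-negative")


# ------------------------------------------------------------------ genome


def simulate_genome(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> dict[str, bytearray]:
    """Uniformly random A/C/G/T chromosomes, as mutable bytearrays so locus
    generators can plant 5'-bias bases before the FASTA is finalized."""
    config.validate()
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    out = {}
    for i in range(config.n_chromosomes):
        idx = rng.integers(0, 4, size=config.chrom_length)
        out[f"chr{i + 1}"] = bytearray(_BASES[idx].tobytes())
    return out


def _draw_len(rng: np.random.Generator, len_range: tuple[int, int]) -> int:
    return int(rng.integers(len_range[0], len_range[1] + 1))


def _plant_first_nt(
    chrom_seq: bytearray, read: tuple[int, int, str], is_u: bool, rng: np.random.Generator
) -> None:
    """Overwrite the genome base under a read's 5' end: T (so the read starts
    with U) when ``is_u``, otherwise a random non-T base."""
    start, end, strand = read
    base = b"T" if is_u else bytes(_BASES[rng.integers(0, 3)])  # A/C/G
    if strand == "+":
        chrom_seq[start : start + 1] = base
    else:
        # read 5' base U corresponds to genome A at end-1 (complement)
        comp = {b"T": b"A", b"A": b"T", b"C": b"G", b"G": b"C"}[base]
        chrom_seq[end - 1 : end] = comp


# ------------------------------------------------------------ locus models


def _check_fits(chrom_seq, lo: int, hi: int) -> None:
    if lo < 0 or hi > len(chrom_seq):
        raise SimulationError(
            f"locus [{lo}, {hi}) outside chromosome of length {len(chrom_seq)}"
        )


def simulate_sirna_locus(
    chrom_seq: bytearray,
    position: int,
    n_duplexes: int,
    dicer_len_range: tuple[int, int] = (20, 24),
    rng: np.random.Generator | None = None,
) -> list[tuple[int, int, str]]:
    """Head-to-tail tiled Dicer duplexes starting at ``position``.

    Each duplex is a (+, -) read pair of equal length L with 2-nt 3'
    overhangs on both ends: plus [s, s+L), minus [s-2, s-2+L).
    Returns (start, end, strand) tuples.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    reads: list[tuple[int, int, str]] = []
    pos = position
    for _ in range(n_duplexes):
        L = _draw_len(rng, dicer_len_range)
        _check_fits(chrom_seq, pos - 2, pos + L)
        reads.append((pos, pos + L, "+"))
        reads.append((pos - 2, pos - 2 + L, "-"))
        pos += L
    return reads


def simulate_pingpong_locus(
    chrom_seq: bytearray,
    position: int,
    n_pairs: int,
    pirna_len_range: tuple[int, int] = (26, 30),
    u1_bias: float = 0.9,
    rng: np.random.Generator | None = None,
    n_singles: int = 0,
    density: int = 40,
) -> list[tuple[int, int, str]]:
    """Ping Pong piRNA pairs: for each pair the plus-strand initiator 5' end
    at p and the minus-strand responder 5' end at p+9, so the 5'-5' overlap
    is exactly 10 nt. Initiator 5' positions are distinct uniform draws over
    a span of ``density`` bp per pair (incidental overlaps at other
    distances form the histogram background, as in real loci). Initiators
    and unpaired singles start with U at probability ``u1_bias``.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    span = max((n_pairs + n_singles) * density, 100)
    lo, hi = position + 30, position + 30 + span
    _check_fits(chrom_seq, position, hi + 30)
    n_sites = n_pairs + n_singles
    starts: set[int] = set()
    while len(starts) < n_sites:
        starts.update(
            int(s) for s in rng.integers(lo, hi, size=n_sites - len(starts))
        )
    site_list = sorted(starts)
    order = rng.permutation(n_sites)
    reads: list[tuple[int, int, str]] = []
    for i, site_idx in enumerate(order):
        p = site_list[site_idx]
        lp = _draw_len(rng, pirna_len_range)
        initiator = (p, p + lp, "+")
        reads.append(initiator)
        _plant_first_nt(chrom_seq, initiator, rng.random() < u1_bias, rng)
        if i < n_pairs:
            lm = _draw_len(rng, pirna_len_range)
            # minus responder 5' end at p+9  =>  interval end = p+10
            reads.append((p + 10 - lm, p + 10, "-"))
    return reads


def simulate_phased_locus(
    chrom_seq: bytearray,
    position: int,
    n_reads: int,
    pirna_len_range: tuple[int, int] = (26, 30),
    u1_bias: float = 0.9,
    rng: np.random.Generator | None = None,
    strand: str = "+",
    p_gap1: float = 0.85,
) -> list[tuple[int, int, str]]:
    """Head-to-tail phased piRNA train on one strand.

    Successive reads are immediately adjacent (5'-to-3' distance d = 1) with
    probability ``p_gap1``, otherwise d is uniform in 2..9. Every read's
    first nucleotide is U with probability ``u1_bias``. On the minus strand
    the same genomic tiling is used; read order simply runs right-to-left.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    reads: list[tuple[int, int, str]] = []
    pos = position
    for _ in range(n_reads):
        L = _draw_len(rng, pirna_len_range)
        _check_fits(chrom_seq, pos, pos + L)
        read = (pos, pos + L, strand)
        reads.append(read)
        _plant_first_nt(chrom_seq, read, rng.random() < u1_bias, rng)
        gap = 1 if rng.random() < p_gap1 else int(rng.integers(2, 10))
        # distance d = next 5' - this 3', so next start = end - 1 + d
        pos = pos + L - 1 + gap
    return reads


def simulate_mirna_locus(
    chrom_seq: bytearray,
    position: int,
    n_reads: int,
    rng: np.random.Generator | None = None,
    mature_fraction: float = 0.9,
) -> list[tuple[int, int, str]]:
    """One dominant 22-nt duplex: identical mature reads (+) plus a minority
    of star reads (-), the two forming a 2-nt 3'-overhang Dicer duplex."""
    rng = rng if rng is not None else np.random.default_rng(0)
    L = 22
    _check_fits(chrom_seq, position - 2, position + L)
    n_mature = max(1, int(round(mature_fraction * n_reads)))
    n_star = max(0, n_reads - n_mature)
    reads = [(position, position + L, "+")] * n_mature
    reads += [(position - 2, position - 2 + L, "-")] * n_star
    return reads


def simulate_degradation_locus(
    chrom_seq: bytearray,
    position: int,
    n_reads: int,
    deg_len_range: tuple[int, int] = (12, 17),
    rng: np.random.Generator | None = None,
    span: int = 300,
) -> list[tuple[int, int, str]]:
    """Short fragments of random strand scattered over a small region."""
    rng = rng if rng is not None else np.random.default_rng(0)
    _check_fits(chrom_seq, position, position + span)
    reads = []
    for _ in range(n_reads):
        L = _draw_len(rng, deg_len_range)
        s = position + int(rng.integers(0, span - L))
        strand = "+" if rng.random() < 0.5 else "-"
        reads.append((s, s + L, strand))
    return reads


# ----------------------------------------------------------- full library


def _locus_width(cls: str, config: SimulationConfig) -> int:
    n = config.reads_per_locus
    if cls == "sirna":
        return n * config.dicer_len_range[1] + 10
    if cls == "pingpong":
        return n * 40 + 120
    if cls == "phased":
        return n * (config.pirna_len_range[1] + 9) + 10
    if cls == "mirna":
        return 40
    return 320  # degradation


def _place_loci(
    config: SimulationConfig, rng: np.random.Generator
) -> list[tuple[str, str, int, int]]:
    """Non-overlapping locus placement with LOCUS_SPACING bp between loci.
    Returns (class, chrom, start, width); raises SimulationError when the
    genome cannot host the requested loci."""
    chroms = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    placed: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    out = []
    jobs = [
        (cls, i)
        for cls in CLASSES
        for i in range(config.n_loci_per_class.get(cls, 0))
    ]
    for cls, _ in jobs:
        width = _locus_width(cls, config)
        for _attempt in range(2000):
            chrom = chroms[int(rng.integers(0, len(chroms)))]
            limit = config.chrom_length - width - 100
            if limit <= 100:
                raise SimulationError(
                    f"chromosome too short for a {cls} locus of width {width}"
                )
            start = int(rng.integers(100, limit))
            lo, hi = start - LOCUS_SPACING, start + width + LOCUS_SPACING
            if all(e <= lo or s >= hi for s, e in placed[chrom]):
                placed[chrom].append((start, start + width))
                out.append((cls, chrom, start, width))
                break
        else:
            raise SimulationError(
                "could not place all loci without overlap; enlarge the genome"
            )
    return out


def _emit_locus(
    cls: str,
    chrom_seq: bytearray,
    start: int,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> list[tuple[int, int, str]]:
    n = config.reads_per_locus
    if cls == "mirna":
        return simulate_mirna_locus(chrom_seq, start + 2, n, rng)
    if cls == "sirna":
        return simulate_sirna_locus(
            chrom_seq, start + 2, n, config.dicer_len_range, rng
        )
    if cls == "pingpong":
        n_pairs = int(round(n * config.pingpong_fraction))
        return simulate_pingpong_locus(
            chrom_seq,
            start,
            n_pairs,
            config.pirna_len_range,
            config.u1_bias,
            rng,
            n_singles=n - n_pairs,
        )
    if cls == "phased":
        strand = "+" if rng.random() < 0.5 else "-"
        return simulate_phased_locus(
            chrom_seq, start, n, config.pirna_len_range, config.u1_bias, rng,
            strand=strand,
        )
    return simulate_degradation_locus(chrom_seq, start, n, config.deg_len_range, rng)


def simulate_library(config: SimulationConfig) -> tuple[Library, pd.DataFrame, Genome]:
    """Compose a full library: loci of every configured class plus uniform
    noise reads. Returns (library, truth_table, genome); the truth table has
    one row per simulated locus with its class label and read-bounding
    interval."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    chrom_seqs = simulate_genome(config, rng)
    placements = _place_loci(config, rng)

    truth_rows = []
    all_reads: list[tuple[str, int, int, str]] = []
    class_counters: dict[str, int] = {}
    for cls, chrom, start, _width in placements:
        idx = class_counters.get(cls, 0)
        class_counters[cls] = idx + 1
        reads = _emit_locus(cls, chrom_seqs[chrom], start, config, rng)
        if not reads:
            continue
        lo = min(r[0] for r in reads)
        hi = max(r[1] for r in reads)
        truth_rows.append(
            {
                "locus_id": f"{cls}_{idx:03d}",
                "chrom": chrom,
                "start": lo,
                "end": hi,
                "class_label": cls,
                "n_reads": len(reads),
                "params": f"reads_per_locus={config.reads_per_locus};u1_bias={config.u1_bias}",
            }
        )
        all_reads.extend((chrom, s, e, st) for s, e, st in reads)

    # uniform noise reads anywhere in the genome, random strand and length
    chroms = list(chrom_seqs)
    for _ in range(config.noise_reads):
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        L = _draw_len(rng, config.noise_len_range)
        s = int(rng.integers(0, len(chrom_seqs[chrom]) - L))
        strand = "+" if rng.random() < 0.5 else "-"
        all_reads.append((chrom, s, s + L, strand))

    genome = Genome({name: bytes(seq).decode() for name, seq in chrom_seqs.items()})
    reads = sorted(
        AlignedRead(c, s, e, st, first_nt=genome.first_nt(c, s, e, st))
        for c, s, e, st in all_reads
    )
    library = Library(
        sample_id=config.sample_id,
        reads=reads,
        chrom_lengths=genome.lengths,
        metadata={"prefilter_total": len(reads), "simulated": True},
    )
    truth = pd.DataFrame(
        truth_rows,
        columns=["locus_id", "chrom", "start", "end", "class_label", "n_reads", "params"],
    )
    return library, truth, genome


def write_bundle(
    library: Library, truth: pd.DataFrame, genome: Genome,
    config: SimulationConfig, outdir: str | Path,
) -> dict[str, Path]:
    """Write genome FASTA, SAM alignments, truth TSV and config YAML."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome": outdir / "genome.fa",
        "alignments": outdir / "reads.sam",
        "truth": outdir / "truth.tsv",
        "config": outdir / "config.yaml",
    }
    srio.write_fasta(genome, paths["genome"])
    srio.write_sam(library, genome, paths["alignments"])
    truth.to_csv(paths["truth"], sep="\t", index=False)
    plain = {
        k: list(v) if isinstance(v, tuple) else v for k, v in asdict(config).items()
    }
    with open(paths["config"], "w") as fh:
        yaml.safe_dump(plain, fh, sort_keys=True)
    return paths


# ------------------------------------------------- expression-level draws


def simulate_expression_matrix(
    n_loci: int,
    group_profiles: list[np.ndarray] | None = None,
    n_per_group: int = 4,
    depth: float = 200.0,
    rng: np.random.Generator | None = None,
    dispersion: float = 0.15,
) -> tuple[pd.DataFrame, list[str]]:
    """Locus x sample count matrix drawn around per-group expression profiles.

    Each group has a mean RPM-scale profile over loci; per-sample counts are
    gamma-Poisson (negative binomial) draws around profile * depth. Returns
    the count DataFrame and the per-sample group labels.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    if group_profiles is None:
        base = rng.lognormal(mean=0.0, sigma=1.0, size=n_loci)
        shift = rng.lognormal(mean=0.0, sigma=1.0, size=n_loci)
        group_profiles = [base, base * shift]
    cols = {}
    labels = []
    for g, profile in enumerate(group_profiles):
        if len(profile) != n_loci:
            raise ConfigurationError("profile length must equal n_loci")
        for j in range(n_per_group):
            mean = np.asarray(profile, dtype=float) * depth
            lam = rng.gamma(1.0 / dispersion, mean * dispersion)
            cols[f"g{g}_s{j}"] = rng.poisson(lam)
            labels.append(f"group{g}")
    df = pd.DataFrame(
        cols, index=pd.Index([f"L{i:04d}" for i in range(n_loci)], name="locus_id")
    )
    return df, labels
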