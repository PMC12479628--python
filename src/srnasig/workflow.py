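"""End-to-end survey workflow: load -> signatures -> loci -> classify -> counts.

Every run writes a machine-readable ``summary.json`` plus TSV/BED artifacts
and an echo of the resolved configuration, so results are reproducible from
the output directory alone. All randomness is seeded; two runs with the
same inputs and seed produce byte-identical summaries.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import expression, io as srio, loci as loci_mod, profiles, signatures
from .errors import ConfigurationError
from .model import Library

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Resolved parameters of one survey run; defaults follow the survey's
    standard thresholds (15–35 nt window, 20–24 nt Dicer reads with 2-nt
    overhangs, Ping Pong focal overlap 10, phasing distances 1–9, 500 bp
    merge gap, >= 1000 RPM loci)."""

    genome: str = ""
    alignments: list[str] = field(default_factory=list)
    outdir: str = "survey_out"
    min_len: int = 15
    max_len: int = 35
    dicer_size_range: tuple[int, int] = (20, 24)
    pirna_size_range: tuple[int, int] = (26, 30)
    overhang: int = 2
    k_max: int = 25
    d_max: int = 9
    merge_gap: int = 500
    min_rpm: float = 1000.0
    z_min: float = 1.96
    sweep: bool = False
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        cfg.dicer_size_range = tuple(cfg.dicer_size_range)
        cfg.pirna_size_range = tuple(cfg.pirna_size_range)
        return cfg


def _plain_config(config: "RunConfig") -> dict:
    out = asdict(config)
    for key, val in out.items():
        if isinstance(val, tuple):
            out[key] = list(val)
    return out


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def run_survey(config: RunConfig) -> dict:
    """Execute the full survey and write the report bundle.

    Stages: load genome and alignments; library-wide signature statistics
    (percent Dicer pairs, Ping Pong and phasing z, 1U fraction, size
    distribution); locus annotation with optional threshold sweep; per-locus
    classification; count matrix (and per-sample summaries) when several
    libraries are given.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if not config.genome or not config.alignments:
        raise ConfigurationError("survey needs a genome and >= 1 alignment file")

    def stage(name):
        logger.info("survey stage: %s", name)

    stage("load")
    genome = srio.load_genome(config.genome)
    libraries: list[Library] = [
        srio.load_alignments(p, genome, config.min_len, config.max_len)
        for p in config.alignments
    ]
    primary = libraries[0]

    stage("signatures")
    per_sample = {}
    for lib in libraries:
        prof = signatures.signature_profile(lib, config.k_max, config.d_max)
        dicer = signatures.percent_dicer_pairs(
            lib, config.dicer_size_range, config.overhang
        )
        per_sample[lib.sample_id] = {
            "n_alignments": lib.total_mapped,
            "prefilter_total": lib.metadata.get("prefilter_total"),
            "percent_dicer_pairs": dicer["percent_dicer_pairs"],
            "n_dicer_pairs": dicer["n_pairs"],
            "pingpong_z": prof.pingpong_z,
            "phasing_z": prof.phasing_z,
            "u1_fraction": signatures.first_nt_fraction(lib),
        }
        srio.write_table(
            srio.size_distribution(lib, config.min_len, config.max_len).to_frame("count"),
            outdir / f"size_distribution.{lib.sample_id}.tsv",
        )

    stage("loci")
    called = loci_mod.annotate_loci(
        primary, merge_gap=config.merge_gap, min_rpm=config.min_rpm
    )
    srio.write_bed(
        [(l.chrom, l.start, l.end, l.locus_id, l.read_count, ".") for l in called],
        outdir / "loci.bed",
    )
    if config.sweep:
        sweep = loci_mod.threshold_sweep(primary)
        srio.write_table(sweep, outdir / "threshold_sweep.tsv", index=False)

    stage("classify")
    class_counts: dict[str, int] = {}
    if called:
        table = profiles.classify_loci(
            called,
            primary,
            len_range=(config.min_len, config.max_len),
            thresholds=profiles.ClassThresholds(
                pirna_size_range=config.pirna_size_range, z_min=config.z_min
            ),
        )
        srio.write_table(table, outdir / "locus_classes.tsv")
        class_counts = {
            str(k): int(v) for k, v in sorted(table["label"].value_counts().items())
        }
        matrix = profiles.locus_size_matrix(
            called, primary, (config.min_len, config.max_len)
        )
        zmat, _ = profiles.row_zscore(matrix)
        order = profiles.cluster_rows(zmat)
        srio.write_table(zmat.iloc[order], outdir / "size_matrix_z.tsv")

    stage("counts")
    if called and len(libraries) > 1:
        cm = expression.count_matrix(called, libraries)
        srio.write_table(cm.values, outdir / "counts.tsv")

    genome_bp = sum(genome.lengths.values())
    summary = {
        "config": _plain_config(config),
        "samples": per_sample,
        "n_loci": len(called),
        "genome_coverage": sum(l.width for l in called) / genome_bp,
        "class_counts": class_counts,
    }
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")
    with open(outdir / "resolved_config.yaml", "w") as fh:
        yaml.safe_dump(_plain_config(config), fh, sort_keys=True)
    return summary
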