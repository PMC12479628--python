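"""Per-locus size profiles, row normalization, clustering order and class calls.

A locus's read-length histogram is its fingerprint: Dicer products (miRNA,
endo-siRNA) concentrate at 18–24 nt, piRNAs at 26–30 nt, degradation
fragments below 18 nt. Rows are z-normalized for heatmap display and
hierarchically clustered; classes are assigned by majority size mass, with
an optional strict piRNA mode that additionally requires a high Ping Pong
z-score.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage

from .errors import ConfigurationError, DataError
from .loci import Locus, assign_reads
from .model import Library
from .signatures import SignatureProfile, signature_profile


def locus_size_matrix(
    loci: list[Locus], library: Library, len_range: tuple[int, int] = (15, 35)
) -> pd.DataFrame:
    """Locus x read-length count matrix (5'-end read assignment)."""
    lo, hi = len_range
    if lo > hi:
        raise ConfigurationError(f"inverted length range {len_range}")
    regions = [(l.chrom, l.start, l.end) for l in loci]
    assigned = assign_reads(library.reads, regions)
    mat = np.zeros((len(loci), hi - lo + 1), dtype=int)
    for i in range(len(loci)):
        for r in assigned.get(i, []):
            if lo <= r.length <= hi:
                mat[i, r.length - lo] += r.copy
    return pd.DataFrame(
        mat,
        index=pd.Index([l.locus_id for l in loci], name="locus_id"),
        columns=pd.RangeIndex(lo, hi + 1, name="length"),
    )


def row_zscore(matrix: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Per-row standardization to mean 0, sample sd 1.

    Constant rows (zero sd) become all-zero and are flagged degenerate in
    the returned boolean Series.
    """
    values = matrix.to_numpy(dtype=float)
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=1, keepdims=True)
    degenerate = (sd[:, 0] == 0.0) | ~np.isfinite(sd[:, 0])
    sd_safe = np.where(sd == 0.0, 1.0, sd)
    z = (values - mean) / sd_safe
    z[degenerate, :] = 0.0
    return (
        pd.DataFrame(z, index=matrix.index, columns=matrix.columns),
        pd.Series(degenerate, index=matrix.index, name="degenerate"),
    )


def cluster_rows(matrix: pd.DataFrame, method: str = "average") -> list[int]:
    """Leaf order from hierarchical clustering of rows (Euclidean distance,
    average linkage by default). Fewer than two rows: identity order."""
    if len(matrix) < 2:
        return list(range(len(matrix)))
    link = linkage(matrix.to_numpy(dtype=float), method=method, metric="euclidean")
    return [int(i) for i in leaves_list(link)]


@dataclass
class ClassThresholds:
    """Tunable classification rule: majority-mass cutoffs per size class and
    the Ping Pong z floor used by the strict piRNA mode."""

    majority: float = 0.5
    pirna_size_range: tuple[int, int] = (26, 30)
    dicer_size_range: tuple[int, int] = (18, 24)
    degradation_below: int = 18
    z_min: float = 1.96


@dataclass
class LocusClass:
    label: str
    evidence: dict = field(default_factory=dict)


def _mass_fraction(row: pd.Series, lo: int, hi: int) -> float:
    total = float(row.sum())
    mask = (row.index >= lo) & (row.index <= hi)
    return float(row[mask].sum()) / total


def classify_locus(
    size_row: pd.Series,
    signature: SignatureProfile | None = None,
    thresholds: ClassThresholds | None = None,
    strict_pirna: bool = False,
) -> LocusClass:
    """Assign a locus class from its size profile (and signature in strict
    mode): pirna_like if the 26–30 nt fraction holds the majority, else
    dicer_sized (18–24 nt), else degradation_like (<18 nt), else ambiguous.
    """
    t = thresholds or ClassThresholds()
    if float(size_row.sum()) <= 0:
        raise DataError("empty locus: no reads in the size window")
    frac_pi = _mass_fraction(size_row, *t.pirna_size_range)
    frac_dicer = _mass_fraction(size_row, *t.dicer_size_range)
    frac_deg = _mass_fraction(size_row, int(size_row.index.min()), t.degradation_below - 1)
    pingpong_z = signature.pingpong_z if signature is not None else float("nan")
    phasing_z = signature.phasing_z if signature is not None else float("nan")
    evidence = {
        "frac_pirna_size": frac_pi,
        "frac_dicer_size": frac_dicer,
        "frac_degradation_size": frac_deg,
        "pingpong_z": pingpong_z,
        "phasing_z": phasing_z,
    }
    label = "ambiguous"
    if frac_pi >= t.majority and (
        not strict_pirna or (not np.isnan(pingpong_z) and pingpong_z >= t.z_min)
    ):
        label = "pirna_like"
    elif frac_dicer >= t.majority:
        label = "dicer_sized"
    elif frac_deg >= t.majority:
        label = "degradation_like"
    return LocusClass(label, evidence)


def classify_loci(
    loci: list[Locus],
    library: Library,
    len_range: tuple[int, int] = (15, 35),
    thresholds: ClassThresholds | None = None,
    strict_pirna: bool = False,
    with_signatures: bool = True,
) -> pd.DataFrame:
    """Classify every locus; returns a table of labels and evidence.

    Per-locus signature profiles (Ping Pong and phasing z) are computed from
    the reads assigned to each locus when ``with_signatures`` is on.
    """
    matrix = locus_size_matrix(loci, library, len_range)
    regions = [(l.chrom, l.start, l.end) for l in loci]
    assigned = assign_reads(library.reads, regions)
    rows = []
    for i, locus in enumerate(loci):
        sig = None
        if with_signatures:
            sig = signature_profile(assigned.get(i, []))
        row = matrix.iloc[i]
        cls = classify_locus(row, sig, thresholds, strict_pirna)
        rows.append(
            {"locus_id": locus.locus_id, "label": cls.label, **cls.evidence}
        )
    return pd.DataFrame(rows).set_index("locus_id")
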