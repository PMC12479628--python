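"""Locus x sample count matrices, normalization, fold changes and PCA.

Counts come from the same 5'-end read-to-locus assignment used by locus
annotation. Two normalizations are offered: reads-per-million and DESeq-style
median-of-ratios size factors (per-sample median of count / row geometric
mean over loci with no zero counts). Differential testing itself is left to
dedicated tools; this module computes the point log2 fold changes and the
PCA coordinates that such analyses visualize.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .errors import ConfigurationError, DataError
from .loci import Locus, assign_reads
from .model import Library

logger = logging.getLogger(__name__)


@dataclass
class CountMatrix:
    """Integer counts (loci x samples) plus per-sample mapped totals."""

    values: pd.DataFrame
    total_mapped: pd.Series


@dataclass
class PCAResult:
    coordinates: pd.DataFrame  # samples x components
    explained_variance_ratio: np.ndarray
    degenerate: bool = False


def count_matrix(loci: list[Locus], libraries: list[Library]) -> CountMatrix:
    """Count reads per locus per sample (5'-end containment assignment).

    All libraries must be aligned against the same genome.
    """
    if not libraries:
        raise ConfigurationError("no libraries given")
    lengths = libraries[0].chrom_lengths
    for lib in libraries[1:]:
        if lib.chrom_lengths != lengths:
            raise DataError(
                f"library {lib.sample_id} aligned to a different genome"
            )
    regions = [(l.chrom, l.start, l.end) for l in loci]
    data = {}
    totals = {}
    for lib in libraries:
        assigned = assign_reads(lib.reads, regions)
        data[lib.sample_id] = [
            sum(r.copy for r in assigned.get(i, [])) for i in range(len(loci))
        ]
        totals[lib.sample_id] = lib.total_mapped
    values = pd.DataFrame(
        data, index=pd.Index([l.locus_id for l in loci], name="locus_id")
    )
    return CountMatrix(values, pd.Series(totals, name="total_mapped"))


def median_of_ratios_size_factors(values: pd.DataFrame) -> pd.Series:
    """DESeq-style size factors: per sample, the median over loci of
    count / geometric-mean(row), using only rows without zeros.

    Raises DataError when no row is zero-free.
    """
    mat = values.to_numpy(dtype=float)
    usable = (mat > 0).all(axis=1)
    if not usable.any():
        raise DataError("every locus has a zero count; size factors undefined")
    sub = mat[usable]
    log_gm = np.log(sub).mean(axis=1, keepdims=True)
    ratios = sub / np.exp(log_gm)
    return pd.Series(np.median(ratios, axis=0), index=values.columns, name="size_factor")


def normalize(
    matrix: CountMatrix, method: str = "median_of_ratios"
) -> tuple[pd.DataFrame, pd.Series]:
    """Normalize counts; returns (normalized values, size factors).

    ``rpm`` scales each sample by total_mapped / 1e6; ``median_of_ratios``
    uses DESeq-style size factors, falling back to rpm (with a warning) when
    every locus contains a zero.
    """
    if method not in ("rpm", "median_of_ratios"):
        raise ConfigurationError(f"unknown normalization method {method!r}")
    nonzero = matrix.values.loc[(matrix.values != 0).any(axis=1)]
    if method == "median_of_ratios":
        try:
            sf = median_of_ratios_size_factors(nonzero)
            return nonzero / sf, sf
        except DataError:
            logger.warning(
                "median-of-ratios undefined (zeros in every locus); "
                "falling back to RPM"
            )
    sf = matrix.total_mapped.astype(float) / 1e6
    if (sf <= 0).any():
        raise DataError("non-positive library total; cannot RPM-normalize")
    return nonzero / sf, sf.rename("size_factor")


def log2fc(
    normalized: pd.DataFrame,
    group_a: list[str],
    group_b: list[str],
    pseudocount: float = 1.0,
) -> pd.Series:
    """Per-locus log2((mean_b + pseudocount) / (mean_a + pseudocount))."""
    if not group_a or not group_b:
        raise ConfigurationError("both groups must be non-empty")
    if set(group_a) & set(group_b):
        raise ConfigurationError("groups must be disjoint")
    mean_a = normalized[group_a].mean(axis=1)
    mean_b = normalized[group_b].mean(axis=1)
    return np.log2((mean_b + pseudocount) / (mean_a + pseudocount)).rename("log2fc")


def pca(normalized: pd.DataFrame, n_components: int | None = None) -> PCAResult:
    """PCA of samples on log2(normalized + 1) locus features.

    Features are centered per locus; components are ordered by decreasing
    explained variance. With (near-)identical samples the variance is ~0 and
    the result is flagged degenerate, with all coordinates at the origin.
    """
    n_samples = normalized.shape[1]
    if n_samples < 2:
        raise ConfigurationError("PCA needs at least 2 samples")
    X = np.log2(normalized.to_numpy(dtype=float).T + 1.0)
    total_var = float(X.var(axis=0, ddof=1).sum())
    k = n_components or min(n_samples, normalized.shape[0], 10)
    k = min(k, n_samples, normalized.shape[0])
    if total_var < 1e-12:
        coords = pd.DataFrame(
            np.zeros((n_samples, k)),
            index=normalized.columns,
            columns=[f"PC{i + 1}" for i in range(k)],
        )
        return PCAResult(coords, np.zeros(k), degenerate=True)
    model = PCA(n_components=k, svd_solver="full")
    coords = model.fit_transform(X)
    return PCAResult(
        pd.DataFrame(
            coords,
            index=normalized.columns,
            columns=[f"PC{i + 1}" for i in range(coords.shape[1])],
        ),
        model.explained_variance_ratio_,
        degenerate=False,
    )
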