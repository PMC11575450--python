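"""Count-matrix QC filters and log-CPM normalization.

Two filters mirror standard bulk RNA-seq practice on this kind of cohort:
genes detected (count > 0) in fewer than 15 samples are discarded, and
libraries with fewer than 500,000 total reads or fewer than 10,000 detected
genes are excluded. Both thresholds are strict "less than" exclusions: a
sample with exactly 500,000 reads is retained.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ConfigError, EmptyResultError
from .io import CountMatrix, ExpressionMatrix

logger = logging.getLogger(__name__)


@dataclass
class QCReport:
    genes_before: int
    genes_after: int
    samples_before: int
    samples_after: int
    exclusions: dict[str, list[str]] = field(default_factory=dict)
    """sample_id -> list of reasons ("min_reads", "min_detected")."""

    def to_frame(self) -> pd.DataFrame:
        rows = [{"sample_id": s, "reasons": ";".join(r)}
                for s, r in self.exclusions.items()]
        return pd.DataFrame(rows, columns=["sample_id", "reasons"])


def filter_genes(counts: CountMatrix, min_nonzero: int = 15
                 ) -> tuple[CountMatrix, QCReport]:
    """Retain genes with count > 0 in at least ``min_nonzero`` samples."""
    n_samples = len(counts.samples)
    if min_nonzero > n_samples:
        raise ConfigError(
            f"min_nonzero ({min_nonzero}) exceeds sample count ({n_samples}); "
            "no gene could pass"
        )
    nonzero = (counts.counts > 0).sum(axis=1)
    keep = nonzero >= min_nonzero
    kept_genes = [g for g, k in zip(counts.genes, keep) if k]
    out = CountMatrix(kept_genes, list(counts.samples), counts.counts[keep, :])
    report = QCReport(
        genes_before=len(counts.genes), genes_after=len(kept_genes),
        samples_before=n_samples, samples_after=n_samples,
    )
    logger.info("filter_genes: %d -> %d genes (min_nonzero=%d)",
                report.genes_before, report.genes_after, min_nonzero)
    return out, report


def filter_libraries(
    counts: CountMatrix,
    metadata: pd.DataFrame | None = None,
    min_reads: int = 500_000,
    min_detected: int = 10_000,
) -> tuple[CountMatrix, QCReport]:
    """Exclude samples with < ``min_reads`` reads or < ``min_detected`` genes.

    Total reads are taken from a ``total_reads`` metadata column when present
    (sequencing depth precedes quantification); otherwise column sums are used.
    Detected genes are always counted from the matrix.
    """
    col_sums = counts.counts.sum(axis=0)
    totals = col_sums.astype(float)
    if metadata is not None and "total_reads" in metadata.columns:
        meta = metadata.set_index("sample_id")
        for j, s in enumerate(counts.samples):
            if s in meta.index and pd.notna(meta.loc[s, "total_reads"]):
                totals[j] = float(meta.loc[s, "total_reads"])
    detected = (counts.counts > 0).sum(axis=0)
    exclusions: dict[str, list[str]] = {}
    keep = []
    for j, s in enumerate(counts.samples):
        reasons = []
        if totals[j] < min_reads:
            reasons.append("min_reads")
        if detected[j] < min_detected:
            reasons.append("min_detected")
        if reasons:
            exclusions[s] = reasons
        else:
            keep.append(s)
    if not keep:
        raise EmptyResultError(
            "library QC removed every sample; review min_reads/min_detected"
        )
    out = counts.subset_samples(keep)
    report = QCReport(
        genes_before=len(counts.genes), genes_after=len(counts.genes),
        samples_before=len(counts.samples), samples_after=len(keep),
        exclusions=exclusions,
    )
    logger.info("filter_libraries: %d -> %d samples", report.samples_before,
                report.samples_after)
    return out, report


def normalize_log_cpm(counts: CountMatrix, pseudocount: float = 1.0
                      ) -> ExpressionMatrix:
    """log2(CPM + pseudocount) per gene and sample.

    The pseudocount is added on the CPM scale, so a zero count maps to
    log2(pseudocount) regardless of library size, and doubling every count in
    a sample leaves the column unchanged.
    """
    if pseudocount <= 0:
        raise ConfigError("pseudocount must be positive")
    libsize = counts.counts.sum(axis=0).astype(float)
    zero = np.flatnonzero(libsize == 0)
    if zero.size:
        raise EmptyResultError(
            f"sample {counts.samples[zero[0]]!r} has zero library size"
        )
    cpm = counts.counts * (1e6 / libsize)
    values = np.log2(cpm + pseudocount)
    return ExpressionMatrix(
        list(counts.genes), list(counts.samples), values,
        normalization={"method": "log2_cpm", "pseudocount": pseudocount},
    )
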