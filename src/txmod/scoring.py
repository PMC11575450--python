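"""Per-sample transcriptional-module scores: geometric mean of constituent genes.

A module score summarizes the expression of a gene set in one number per
sample, the geometric mean of the constituent genes' linear expression. On
log2 expression this is the arithmetic mean of logs, which is how scores are
computed and (by default) reported: ``score(s) = mean_g log2-expression(g, s)``.
A ``linear`` flag antilogs back to the geometric mean in linear units.

Genes in a module but absent from the matrix are dropped and reported via a
coverage fraction; modules below the minimum coverage are flagged but still
computed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import EmptyResultError, ValidationError
from .io import ExpressionMatrix, GeneModule

logger = logging.getLogger(__name__)

DEFAULT_MIN_COVERAGE = 0.5


@dataclass
class ModuleScoreMatrix:
    """Module x sample score matrix plus per-module gene coverage."""

    scores: pd.DataFrame  # modules x samples
    coverage: pd.Series  # module -> fraction of constituent genes found
    units: str = "log2"
    low_coverage: list[str] = field(default_factory=list)

    @property
    def modules(self) -> list[str]:
        return list(self.scores.index)

    @property
    def samples(self) -> list[str]:
        return list(self.scores.columns)


def score_module(
    expr: ExpressionMatrix,
    module: GeneModule,
    linear: bool = False,
) -> tuple[pd.Series, float]:
    """Score one module on every sample; returns (scores, coverage).

    ``expr`` holds log2-scale values; the score is the arithmetic mean of the
    log2 values of the module genes present in the matrix (equivalently the
    log2 geometric mean of the linear values), antilogged when ``linear``.
    """
    present = [g for g in module.genes if g in set(expr.genes)]
    if not present:
        raise EmptyResultError(
            f"module {module.name!r}: no constituent gene present in matrix"
        )
    pos = {g: i for i, g in enumerate(expr.genes)}
    rows = expr.values[[pos[g] for g in present], :]
    score = rows.mean(axis=0)
    if linear:
        score = np.exp2(score)
    coverage = len(present) / len(module.genes)
    return pd.Series(score, index=expr.samples, name=module.name), coverage


def score_all_modules(
    expr: ExpressionMatrix,
    modules: Sequence[GeneModule],
    linear: bool = False,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
) -> ModuleScoreMatrix:
    """Score a module collection; skips (with a warning) unscoreable modules."""
    names = [m.name for m in modules]
    if len(set(names)) != len(names):
        raise ValidationError("duplicate module names in collection")
    rows, covs, low = [], {}, []
    for module in modules:
        try:
            score, coverage = score_module(expr, module, linear=linear)
        except EmptyResultError:
            warnings.warn(f"module {module.name!r} has no genes in the matrix; "
                          "skipped")
            continue
        if coverage < min_coverage:
            low.append(module.name)
            logger.warning("module %r coverage %.2f below %.2f; score kept but "
                           "flagged unreliable", module.name, coverage, min_coverage)
        rows.append(score)
        covs[module.name] = coverage
    if not rows:
        raise EmptyResultError("every module was skipped (no genes in matrix)")
    scores = pd.DataFrame(rows)
    scores.columns = expr.samples
    return ModuleScoreMatrix(
        scores=scores,
        coverage=pd.Series(covs, name="coverage"),
        units="linear" if linear else "log2",
        low_coverage=low,
    )


def write_scores(scores: ModuleScoreMatrix, path, coverage_path=None) -> None:
    scores.scores.to_csv(path, sep="\t", index_label="module")
    if coverage_path is not None:
        scores.coverage.to_csv(coverage_path, sep="\t", index_label="module",
                               header=["coverage"])
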