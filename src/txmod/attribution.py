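"""Regression residualization: attributing condition effects to cell types.

To ask whether a gene's condition-associated differential expression merely
reflects a change in the abundance of one immune cell type, each gene's log2
expression is regressed (ordinary least squares, one covariate plus intercept)
on that cell type's module score across samples. The residual matrix keeps
whatever variation the module cannot explain; re-testing the group difference
on residuals then shows whether significance survives. Abrogation of
significance after regressing on a module attributes the original signal to
that module's cell type; persistence after regressing on unrelated modules
shows the attribution is specific.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .de import mann_whitney_u, _welch_t_rows
from .exceptions import EmptyResultError, ValidationError
from .io import ExpressionMatrix, GeneModule
from .scoring import ModuleScoreMatrix, score_module

STAR_THRESHOLDS = ((0.0001, "***"), (0.005, "**"), (0.05, "*"))


def star_code(p: float) -> str:
    """Significance stars: *** p<0.0001, ** p<0.005, * p<0.05."""
    for threshold, stars in STAR_THRESHOLDS:
        if p < threshold:
            return stars
    return ""


@dataclass
class ResidualMatrix:
    """Per-gene OLS residuals of expression on one module score."""

    genes: list[str]
    samples: list[str]
    values: np.ndarray
    slopes: np.ndarray
    intercepts: np.ndarray
    module: str = ""
    provenance: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genes, columns=self.samples)


def regress_out_module(
    expr: ExpressionMatrix, module_score: pd.Series, module_name: str = ""
) -> ResidualMatrix:
    """OLS of each gene's expression on the module score; residuals kept.

    For gene g: expression(g, .) = a_g + b_g * score + e; the returned values
    are the residuals e, orthogonal to the (centered) score by construction.
    """
    score = pd.Series(module_score)
    missing = [s for s in expr.samples if s not in score.index]
    if missing:
        raise ValidationError(f"score missing samples: {missing!r}")
    x = score.reindex(expr.samples).to_numpy(dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValidationError("module score must be finite")
    xc = x - x.mean()
    denom = float(xc @ xc)
    if denom == 0:
        raise ValidationError("constant module score: regression undefined")
    y = expr.values
    ybar = y.mean(axis=1)
    slopes = (y - ybar[:, None]) @ xc / denom
    intercepts = ybar - slopes * x.mean()
    residuals = y - (intercepts[:, None] + np.outer(slopes, x))
    return ResidualMatrix(
        genes=list(expr.genes), samples=list(expr.samples), values=residuals,
        slopes=slopes, intercepts=intercepts, module=module_name,
        provenance={"module": module_name, "n_samples": len(expr.samples)},
    )


def _group_pvalues(values: np.ndarray, idx_a: list[int], idx_b: list[int],
                   test: str) -> np.ndarray:
    a, b = values[:, idx_a], values[:, idx_b]
    if test == "welch":
        return _welch_t_rows(a, b)
    return np.array([mann_whitney_u(a[i], b[i]) for i in range(values.shape[0])])


def attribution_grid(
    expr: ExpressionMatrix,
    focal_genes: list[str],
    modules: list[GeneModule],
    metadata: pd.DataFrame,
    stratum: str | None = None,
    group_col: str = "condition",
    test: str = "mann_whitney",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Gene x module grid of group-difference p-values on residual matrices.

    The first column ("unadjusted") tests each focal gene's expression between
    the two groups directly; each subsequent column repeats the test on the
    residuals after regressing every gene on that module's score. Returns
    (p-value grid, star-coded grid). Unscoreable modules are omitted with a
    warning.
    """
    meta = metadata.set_index("sample_id")
    samples = list(expr.samples)
    if stratum is not None:
        samples = [s for s in samples if meta.loc[s, "compartment"] == stratum]
        expr = expr.subset_samples(samples)
    groups = sorted(meta.loc[samples, group_col].unique())
    if len(groups) != 2:
        raise ValidationError(f"need exactly 2 groups in {group_col!r}, "
                              f"got {groups!r}")
    idx_a = [j for j, s in enumerate(samples) if meta.loc[s, group_col] == groups[1]]
    idx_b = [j for j, s in enumerate(samples) if meta.loc[s, group_col] == groups[0]]
    gene_pos = {g: i for i, g in enumerate(expr.genes)}
    missing = [g for g in focal_genes if g not in gene_pos]
    if missing:
        raise ValidationError(f"focal genes absent from matrix: {missing!r}")
    focal_idx = [gene_pos[g] for g in focal_genes]

    grid = {}
    grid["unadjusted"] = _group_pvalues(
        expr.values[focal_idx], idx_a, idx_b, test
    )
    for module in modules:
        try:
            score, _ = score_module(expr, module)
        except EmptyResultError:
            warnings.warn(f"module {module.name!r} unscoreable; column omitted")
            continue
        residuals = regress_out_module(expr, score, module_name=module.name)
        grid[module.name] = _group_pvalues(
            residuals.values[focal_idx], idx_a, idx_b, test
        )
    pgrid = pd.DataFrame(grid, index=pd.Index(focal_genes, name="gene"))
    stars = pgrid.map(star_code)
    return pgrid, stars


def residual_module_quantification(
    residuals: ResidualMatrix, modules: list[GeneModule]
) -> ModuleScoreMatrix:
    """Module quantification on a residual matrix.

    Residuals can be negative, so the linear-scale geometric mean is undefined;
    scores are the arithmetic mean of the (log-domain) residuals of the module
    genes, with the deviation recorded in the score units.
    """
    rows, covs = [], {}
    pos = {g: i for i, g in enumerate(residuals.genes)}
    for module in modules:
        present = [g for g in module.genes if g in pos]
        if not present:
            warnings.warn(f"module {module.name!r} has no genes in residual "
                          "matrix; skipped")
            continue
        vals = residuals.values[[pos[g] for g in present], :].mean(axis=0)
        rows.append(pd.Series(vals, index=residuals.samples, name=module.name))
        covs[module.name] = len(present) / len(module.genes)
    if not rows:
        raise EmptyResultError("every module was skipped")
    return ModuleScoreMatrix(
        scores=pd.DataFrame(rows),
        coverage=pd.Series(covs, name="coverage"),
        units="mean_residual_log2",
    )
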