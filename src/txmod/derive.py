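"""Derivation of cell-type transcriptional modules from sorted-cell data.

A cell-type module is the set of genes significantly elevated (BH q < 0.05,
direction up) in the cognate sorted population relative to comparator
populations. A derivation plan lists one or more comparator sets; under the
default intersection rule a gene must be elevated versus *every* comparator
set (the stricter reading, maximizing specificity), under the union rule
versus any one.

Central-memory / effector-memory (CM/EM) CD8 modules use a different rule:
two-sided t-test p < 0.01 (uncorrected) on log2 expression AND a strict
>10-fold difference of linear-scale means, computed symmetrically for the two
subsets. Specificity of any module collection can be validated on labeled
expression via per-module cognate-vs-rest AUROC.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .de import _welch_t_rows, differential_expression
from .exceptions import ConfigError, EmptyResultError, ValidationError
from .io import CountMatrix, ExpressionMatrix, GeneModule
from .qc import normalize_log_cpm
from .scoring import score_all_modules

MIN_MODULE_SIZE = 3


@dataclass
class DerivationPlan:
    """How to derive one cell type's module.

    ``comparator_sets`` is a list of cell-type-name lists; each inner list is
    pooled into one comparison group. E.g. the CD4 plan compares CD4 to CD8 and
    to MAIT separately (two singleton sets), while a "versus all others" plan
    uses a single pooled set.
    """

    cognate_cell: str
    comparator_sets: list[list[str]]
    fdr_threshold: float = 0.05
    combination_rule: str = "intersection"

    def __post_init__(self) -> None:
        if not (0 < self.fdr_threshold < 1):
            raise ConfigError("fdr_threshold must be in (0, 1)")
        if self.combination_rule not in ("intersection", "union"):
            raise ConfigError(f"unknown combination rule {self.combination_rule!r}")
        if not self.comparator_sets:
            raise ConfigError("need at least one comparator set")
        for comp in self.comparator_sets:
            if self.cognate_cell in comp:
                raise ConfigError("cognate cell cannot appear in a comparator set")


@dataclass
class ValidationReport:
    mean_scores: pd.DataFrame  # modules x cell types, mean module score
    auroc: pd.Series  # module -> cognate-vs-rest AUROC
    cognate_rank: pd.Series  # module -> rank of cognate mean score (1 = top)

    @property
    def all_cognate_top(self) -> bool:
        return bool((self.cognate_rank == 1).all())


def _dataset_hash(counts: CountMatrix) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(counts.counts).tobytes())
    h.update("\t".join(counts.genes).encode())
    h.update("\t".join(counts.samples).encode())
    return h.hexdigest()[:16]


def derive_cell_module(
    sorted_counts: CountMatrix,
    sorted_meta: pd.DataFrame,
    plan: DerivationPlan,
    de_method: str = "moderated_t",
    min_module_size: int = MIN_MODULE_SIZE,
) -> GeneModule:
    """Derive one cell-type module from sorted-cell counts.

    Runs the DE engine cognate-vs-comparator for each comparator set and keeps
    genes with q < fdr_threshold and direction up in every (intersection) or
    any (union) comparison. Raises with per-comparison diagnostics when no
    gene passes.
    """
    meta = sorted_meta.set_index("sample_id")
    cognate_samples = [s for s in sorted_counts.samples
                       if meta.loc[s, "cell_type"] == plan.cognate_cell]
    if len(cognate_samples) < 2:
        raise ValidationError(
            f"need >= 2 replicates of cognate type {plan.cognate_cell!r}"
        )
    per_comparison: list[set[str]] = []
    diagnostics = []
    for comp in plan.comparator_sets:
        comp_samples = [s for s in sorted_counts.samples
                        if meta.loc[s, "cell_type"] in set(comp)]
        if len(comp_samples) < 2:
            raise ValidationError(f"need >= 2 replicates in comparator set {comp!r}")
        res = differential_expression(
            sorted_counts, cognate_samples, comp_samples,
            method=de_method, fdr=plan.fdr_threshold,
        )
        passed = set(res.index[(res["qvalue"] < plan.fdr_threshold)
                               & (res["log2fc"] > 0)])
        per_comparison.append(passed)
        diagnostics.append(f"vs {'+'.join(comp)}: {len(passed)} genes pass")
    if plan.combination_rule == "intersection":
        selected = set.intersection(*per_comparison)
    else:
        selected = set.union(*per_comparison)
    if not selected:
        raise EmptyResultError(
            f"no gene passes for {plan.cognate_cell!r} "
            f"({'; '.join(diagnostics)})"
        )
    genes = [g for g in sorted_counts.genes if g in selected]  # stable gene order
    if len(genes) < min_module_size:
        warnings.warn(f"module {plan.cognate_cell!r} has only {len(genes)} "
                      f"gene(s) (< {min_module_size}); geometric mean may be fragile")
    return GeneModule(
        name=plan.cognate_cell,
        genes=genes,
        provenance={
            "cognate_cell": plan.cognate_cell,
            "comparator_sets": [list(c) for c in plan.comparator_sets],
            "fdr_threshold": plan.fdr_threshold,
            "combination_rule": plan.combination_rule,
            "de_method": de_method,
            "dataset_hash": _dataset_hash(sorted_counts),
            "description": f"derived {plan.cognate_cell} module "
                           f"({plan.combination_rule}, q<{plan.fdr_threshold})",
        },
    )


def default_plans(cell_types: list[str]) -> list[DerivationPlan]:
    """One "cognate versus all others" plan per cell type."""
    return [
        DerivationPlan(ct, [[o for o in cell_types if o != ct]])
        for ct in cell_types
    ]


def _linear_cpm_means(data: CountMatrix | ExpressionMatrix,
                      pseudocount: float = 1.0
                      ) -> tuple[list[str], np.ndarray, np.ndarray]:
    """(genes, log2 values, linear values) for the memory-module rule.

    From counts: CPM with pseudocount. From a log2 matrix: linear values are
    the antilog (already pseudocount-protected by the normalization).
    """
    if isinstance(data, CountMatrix):
        expr = normalize_log_cpm(data, pseudocount=pseudocount)
    else:
        expr = data
    return expr.genes, expr.values, np.exp2(expr.values)


def derive_memory_modules(
    cm_profiles: CountMatrix | ExpressionMatrix,
    em_profiles: CountMatrix | ExpressionMatrix,
    p_threshold: float = 0.01,
    fold_threshold: float = 10.0,
    min_module_size: int = MIN_MODULE_SIZE,
) -> tuple[GeneModule | None, GeneModule | None]:
    """CM and EM CD8 modules by the t-test + fold rule.

    A gene joins the EM module when the two-sided t-test on log2 expression has
    p < ``p_threshold`` (no multiplicity correction) and the linear-scale mean
    ratio EM/CM is strictly greater than ``fold_threshold``; the CM module is
    symmetric. The two modules are disjoint by construction (a >10-fold ratio
    one way excludes the other). Returns None for an empty module.
    """
    genes_cm, log_cm, lin_cm = _linear_cpm_means(cm_profiles)
    genes_em, log_em, lin_em = _linear_cpm_means(em_profiles)
    if genes_cm != genes_em:
        raise ValidationError("CM and EM profiles must share the same gene list")
    if log_cm.shape[1] < 2 or log_em.shape[1] < 2:
        raise ConfigError("need >= 2 replicates per memory subset")
    p = _welch_t_rows(log_em, log_cm)
    mean_cm = lin_cm.mean(axis=1)
    mean_em = lin_em.mean(axis=1)
    fold_em = mean_em / mean_cm  # linear-scale ratio, pseudocount-protected
    em_mask = (p < p_threshold) & (fold_em > fold_threshold)
    cm_mask = (p < p_threshold) & ((1.0 / fold_em) > fold_threshold)
    if (em_mask & cm_mask).any():  # impossible for fold_threshold >= 1
        raise ValidationError("a gene qualified for both CM and EM modules")
    provenance = {
        "p_threshold": p_threshold,
        "fold_threshold": fold_threshold,
        "rule": "two-sided t on log2, uncorrected; strict linear fold",
    }

    def _build(name: str, mask: np.ndarray) -> GeneModule | None:
        selected = [g for g, m in zip(genes_cm, mask) if m]
        if not selected:
            return None
        if len(selected) < min_module_size:
            warnings.warn(f"{name} module has only {len(selected)} gene(s)")
        prov = dict(provenance)
        prov["cognate_cell"] = name
        prov["description"] = f"{name} memory module (p<{p_threshold}, " \
                              f">{fold_threshold}-fold)"
        return GeneModule(name, selected, prov)

    return _build("CD8_CM", cm_mask), _build("CD8_EM", em_mask)


def validate_module_specificity(
    modules: list[GeneModule],
    labeled_expr: ExpressionMatrix,
    labels: pd.Series | dict,
) -> ValidationReport:
    """Score labeled samples with each module; AUROC of cognate vs rest.

    ``labels`` maps sample id to cell-type label. A module passes when its
    cognate type has the top mean score (rank 1) and AUROC near 1.
    """
    labels = pd.Series(labels)
    labels = labels.reindex(labeled_expr.samples)
    if labels.isna().any():
        raise ValidationError("every sample needs a cell-type label")
    scoreable = []
    for m in modules:
        cognate = m.provenance.get("cognate_cell", m.name)
        if cognate not in set(labels):
            raise ValidationError(
                f"cognate type {cognate!r} of module {m.name!r} absent from labels"
            )
        if not set(m.genes) & set(labeled_expr.genes):
            warnings.warn(f"module {m.name!r} has no genes in the matrix; skipped")
            continue
        scoreable.append(m)
    if not scoreable:
        raise EmptyResultError("no module could be scored on the labeled data")
    scored = score_all_modules(labeled_expr, scoreable)
    mean_rows, aurocs, ranks = {}, {}, {}
    for m in scoreable:
        cognate = m.provenance.get("cognate_cell", m.name)
        row = scored.scores.loc[m.name]
        means = row.groupby(labels).mean()
        mean_rows[m.name] = means
        is_cognate = (labels == cognate).to_numpy().astype(int)
        aurocs[m.name] = float(roc_auc_score(is_cognate, row.to_numpy()))
        order = means.rank(ascending=False, method="min")
        ranks[m.name] = int(order[cognate])
    return ValidationReport(
        mean_scores=pd.DataFrame(mean_rows).T,
        auroc=pd.Series(aurocs, name="auroc"),
        cognate_rank=pd.Series(ranks, name="cognate_rank"),
    )
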