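"""Differential expression, multiple-testing correction and group statistics.

The DE engine is intentionally lightweight and self-contained: a two-group
contrast per gene (Welch t on log2(CPM+1) by default, Mann-Whitney optional)
with Benjamini-Hochberg control at FDR 0.05. It is pluggable by the ``method``
argument so an external negative-binomial engine can be substituted; the
decision rule (q < fdr) is unchanged either way.
"""

from __future__ import annotations

import logging
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

from .exceptions import ConfigError, EmptyResultError, ValidationError
from .io import CountMatrix, ExpressionMatrix, GeneModule
from .qc import normalize_log_cpm

logger = logging.getLogger(__name__)

DE_METHODS = ("welch_t_logcpm", "moderated_t", "mann_whitney")


def _squeeze_variances(s2: np.ndarray, df: float) -> tuple[np.ndarray, float]:
    """Empirical-Bayes shrinkage of per-gene variances (limma-style).

    Models s2 ~ s0^2 * F(df, d0) and estimates the prior (s0^2, d0) by
    Smyth's method of moments on log variances, then returns the posterior
    variances (d0*s0^2 + df*s2) / (d0 + df) and the prior df d0. With few
    replicates this repairs the heavy tail of t statistics driven by
    chance-small variance estimates.
    """
    from scipy.special import digamma, polygamma

    s2 = np.maximum(np.asarray(s2, dtype=float), 1e-12)
    z = np.log(s2)
    e = z - digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = e.mean()
    e_var = max(z.var(ddof=1) - float(polygamma(1, df / 2.0)), 0.0)
    if e_var <= 1e-12:
        return np.full_like(s2, np.exp(e_mean)), np.inf
    # invert trigamma(d0/2) = e_var by Newton iteration
    x = 0.5 + 1.0 / e_var
    for _ in range(50):
        tri = float(polygamma(1, x))
        delta = tri * (1.0 - tri / e_var) / float(polygamma(2, x))
        x += delta
        if abs(delta) < 1e-8 * x:
            break
    d0 = 2.0 * x
    s0_sq = np.exp(e_mean + digamma(x) - np.log(x))
    post = (d0 * s0_sq + df * s2) / (d0 + df)
    return post, d0


def _moderated_t_rows(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-wise two-sample t with empirical-Bayes moderated pooled variance."""
    n1, n2 = a.shape[1], b.shape[1]
    df = n1 + n2 - 2
    ss = a.var(axis=1, ddof=1) * (n1 - 1) + b.var(axis=1, ddof=1) * (n2 - 1)
    s2 = ss / df
    s2_post, d0 = _squeeze_variances(s2, df)
    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    diff = a.mean(axis=1) - b.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / se
    df_total = df + d0 if np.isfinite(d0) else df * 1e6
    p = 2.0 * stats.t.sf(np.abs(t), df_total)
    zero = se == 0
    if zero.any():
        p = np.where(zero, np.where(np.isclose(diff, 0.0), 1.0, 0.0), p)
    return np.nan_to_num(p, nan=1.0)


def benjamini_hochberg(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in input order, clipped to [0, 1]."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if not np.all(np.isfinite(p)) or np.any((p < 0) | (p > 1)):
        raise ValidationError("p-values must be finite and in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def mann_whitney_u(a: np.ndarray, b: np.ndarray,
                   exact_max_n: int = 8) -> float:
    """Two-sided Mann-Whitney p-value.

    Exact tail enumeration when both groups have <= ``exact_max_n``
    observations and no ties span the groups; tie-corrected normal
    approximation otherwise. Degenerate data (zero range overall) gives p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        return 1.0
    use_exact = (a.size <= exact_max_n and b.size <= exact_max_n
                 and np.unique(pooled).size == pooled.size)
    method = "exact" if use_exact else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    p = float(res.pvalue)
    return 1.0 if np.isnan(p) else min(p, 1.0)


def _welch_t_rows(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-wise Welch t p-values with the zero-variance convention.

    Genes with zero variance in both groups get p = 1 when the group means are
    equal and p = 0 when they differ (perfect, noise-free separation).
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        p = stats.ttest_ind(a, b, axis=1, equal_var=False).pvalue
    var0 = (a.var(axis=1) == 0) & (b.var(axis=1) == 0)
    if var0.any():
        logger.info("%d gene(s) with zero variance in both groups", var0.sum())
        equal = np.isclose(a.mean(axis=1), b.mean(axis=1))
        p = np.where(var0, np.where(equal, 1.0, 0.0), p)
    return np.nan_to_num(p, nan=1.0)


def differential_expression(
    data: CountMatrix | ExpressionMatrix,
    group_a: Sequence[str],
    group_b: Sequence[str],
    method: str = "welch_t_logcpm",
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Per-gene two-group contrast (A vs B) with BH-adjusted q-values.

    Returns a DataFrame indexed by gene with columns log2fc (mean A - mean B on
    the log2 scale), pvalue, qvalue, direction ('up' means higher in A) and
    significant (q < ``fdr``).
    """
    if method not in DE_METHODS:
        raise ConfigError(f"unknown DE method {method!r}")
    group_a, group_b = list(group_a), list(group_b)
    if set(group_a) & set(group_b):
        raise ValidationError("groups overlap")
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValidationError("each group needs >= 2 samples")
    expr = normalize_log_cpm(data) if isinstance(data, CountMatrix) else data
    pos = {s: j for j, s in enumerate(expr.samples)}
    missing = [s for s in group_a + group_b if s not in pos]
    if missing:
        raise ValidationError(f"samples not in matrix: {missing!r}")
    a = expr.values[:, [pos[s] for s in group_a]]
    b = expr.values[:, [pos[s] for s in group_b]]
    log2fc = a.mean(axis=1) - b.mean(axis=1)
    if method == "welch_t_logcpm":
        p = _welch_t_rows(a, b)
    elif method == "moderated_t":
        p = _moderated_t_rows(a, b)
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p = stats.mannwhitneyu(
                a, b, axis=1, alternative="two-sided", method="asymptotic"
            ).pvalue
        p = np.nan_to_num(np.asarray(p, dtype=float), nan=1.0)
        ptp = np.ptp(np.concatenate([a, b], axis=1), axis=1)
        p = np.where(ptp == 0, 1.0, p)
    q = benjamini_hochberg(p)
    return pd.DataFrame(
        {
            "log2fc": log2fc,
            "pvalue": p,
            "qvalue": q,
            "direction": np.where(log2fc >= 0, "up", "down"),
            "significant": q < fdr,
        },
        index=pd.Index(expr.genes, name="gene"),
    )


def mann_whitney_module_test(
    scores: "pd.DataFrame | object",
    metadata: pd.DataFrame,
    stratify_by: str = "compartment",
    group_col: str = "condition",
) -> pd.DataFrame:
    """Per-module, per-stratum two-sided Mann-Whitney p (condition contrast).

    ``scores`` is a modules x samples DataFrame (or a ModuleScoreMatrix).
    Strata with an empty group get a missing p with a warning.
    """
    frame = scores.scores if hasattr(scores, "scores") else scores
    meta = metadata.set_index("sample_id")
    rows = []
    for stratum in sorted(meta[stratify_by].unique()):
        in_stratum = meta.index[meta[stratify_by] == stratum]
        in_stratum = [s for s in frame.columns if s in set(in_stratum)]
        groups = sorted(meta.loc[in_stratum, group_col].unique())
        split = {g: [s for s in in_stratum if meta.loc[s, group_col] == g]
                 for g in groups}
        if len(groups) != 2 or any(len(v) < 2 for v in split.values()):
            warnings.warn(f"stratum {stratum!r}: need two groups with >= 2 "
                          "samples; p reported as missing")
            for module in frame.index:
                rows.append({"module": module, "stratum": stratum, "pvalue": np.nan})
            continue
        ga, gb = groups
        for module in frame.index:
            p = mann_whitney_u(frame.loc[module, split[ga]].to_numpy(),
                               frame.loc[module, split[gb]].to_numpy())
            rows.append({"module": module, "stratum": stratum, "pvalue": p})
    return pd.DataFrame(rows)


def overlap_summary(list_a: Sequence[str], list_b: Sequence[str]) -> dict:
    """Overlap of two deduplicated gene lists, pooled-with-multiplicity style.

    The denominator is nA + nB (a gene shared by both lists is pooled twice),
    and percent_shared is 100 * n_shared / (nA + nB) rounded half-up for
    display.
    """
    set_a, set_b = set(list_a), set(list_b)
    n_a, n_b = len(set_a), len(set_b)
    shared = len(set_a & set_b)
    pooled = n_a + n_b
    percent = int(np.floor(100.0 * shared / pooled + 0.5)) if pooled else 0
    return {
        "nA": n_a,
        "nB": n_b,
        "n_shared": shared,
        "pooled_total": pooled,
        "percent_shared": percent,
    }


def ora_enrichment(
    hit_genes: Sequence[str],
    universe_genes: Sequence[str],
    gene_sets: Sequence[GeneModule],
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation with BH across tested sets."""
    universe = set(universe_genes)
    if not universe:
        raise EmptyResultError("empty gene universe")
    hits = set(hit_genes)
    if not hits <= universe:
        raise ValidationError("hit genes must be a subset of the universe")
    rows = []
    for module in gene_sets:
        in_universe = [g for g in module.genes if g in universe]
        if not in_universe:
            warnings.warn(f"gene set {module.name!r} disjoint from universe; skipped")
            continue
        big_k = len(in_universe)
        k = len(set(in_universe) & hits)
        p = float(stats.hypergeom.sf(k - 1, len(universe), big_k, len(hits)))
        rows.append({"set": module.name, "overlap": k, "set_size": big_k,
                     "pvalue": p})
    result = pd.DataFrame(rows, columns=["set", "overlap", "set_size", "pvalue"])
    if len(result):
        result["qvalue"] = benjamini_hochberg(result["pvalue"].to_numpy())
    else:
        result["qvalue"] = pd.Series(dtype=float)
    return result


def pca_embedding(expr: ExpressionMatrix, n_components: int = 2
                  ) -> tuple[pd.DataFrame, np.ndarray]:
    """Gene-centered PCA of the samples with a deterministic sign convention.

    Returns (samples x components coordinates, percent variance explained).
    Each component is flipped so its largest-magnitude gene loading is
    positive; a constant matrix gives all-zero coordinates.
    """
    if len(expr.samples) < 2:
        raise ValidationError("PCA needs >= 2 samples")
    n_components = min(n_components, len(expr.samples), len(expr.genes))
    x = expr.values.T - expr.values.mean(axis=1)  # samples x genes, per-gene centered
    if np.allclose(x, 0):
        coords = np.zeros((len(expr.samples), n_components))
        var = np.zeros(n_components)
    else:
        pca = PCA(n_components=n_components, svd_solver="full")
        coords = pca.fit_transform(x)
        for i in range(n_components):
            j = np.argmax(np.abs(pca.components_[i]))
            if pca.components_[i, j] < 0:
                coords[:, i] *= -1
        var = pca.explained_variance_ratio_ * 100.0
    frame = pd.DataFrame(coords, index=expr.samples,
                         columns=[f"PC{i + 1}" for i in range(n_components)])
    return frame, var
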