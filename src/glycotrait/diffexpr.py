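"""Glyco-gene differential-expression screen.

An RMA-flavoured preprocessing chain (background floor, quantile
normalisation, log2, Tukey median-polish probe-set summarisation) followed
by a moderated two-group comparison per gene: the pooled residual variance
s^2 with d = n1 + n2 - 2 degrees of freedom is shrunk toward a prior
(d0, s0^2) estimated from the spread of log s^2 across genes (an
empirical-Bayes method-of-moments fit), giving

    s_tilde^2 = (d0 * s0^2 + d * s^2) / (d0 + d)
    t = log2FC / (s_tilde * sqrt(1/n1 + 1/n2)),   df = d0 + d

P-values are Benjamini-Hochberg adjusted; genes pass with
|fold change| >= 1.5 and adjusted p < 0.1 by default, and passing genes are
rolled up into functional categories (glycosyltransferase subgroups, GAG,
etc., with a miscellaneous catch-all).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from scipy import special, stats
from scipy.cluster.hierarchy import leaves_list, linkage
from statsmodels.stats.multitest import multipletests

__all__ = [
    "background_floor",
    "quantile_normalize",
    "medianpolish_summarize",
    "fit_two_group",
    "bh_adjust",
    "select_differential",
    "summarize_categories",
    "export_heatmap_table",
    "run_de_screen",
]


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def background_floor(
    matrix: pd.DataFrame, q: float = 0.02, floor: float = 1.0
) -> pd.DataFrame:
    """Per array (column), subtract the q-quantile and clip at a small
    positive floor; monotone within each array, a simplified stand-in for
    convolution-model background correction."""
    if not 0 <= q < 0.5:
        raise ValueError("background quantile must be in [0, 0.5)")
    if q == 0:
        return matrix.copy()
    shifted = matrix - matrix.quantile(q, axis=0)
    return shifted.clip(lower=floor)


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Replace each entry by the across-array mean of the values at its
    within-array rank; ties receive the mean of their rank-values.
    Afterwards every column has identical sorted values."""
    if matrix.empty:
        raise ValueError("empty matrix")
    values = matrix.to_numpy(dtype=float)
    mean_sorted = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    for j in range(values.shape[1]):
        ranks = stats.rankdata(values[:, j], method="average")  # 1-based
        lo = np.floor(ranks).astype(int) - 1
        hi = np.ceil(ranks).astype(int) - 1
        out[:, j] = 0.5 * (mean_sorted[lo] + mean_sorted[hi])
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def _median_polish(block: np.ndarray, tol: float = 1e-6, max_iter: int = 50):
    """Tukey median polish; returns (overall, row_effects, col_effects,
    residuals)."""
    residuals = block.astype(float).copy()
    overall = 0.0
    row_eff = np.zeros(block.shape[0])
    col_eff = np.zeros(block.shape[1])
    for _ in range(max_iter):
        row_med = np.median(residuals, axis=1)
        residuals -= row_med[:, None]
        row_eff += row_med
        col_med_of_row = np.median(row_eff)
        row_eff -= col_med_of_row
        overall += col_med_of_row

        col_med = np.median(residuals, axis=0)
        residuals -= col_med[None, :]
        col_eff += col_med
        row_med_of_col = np.median(col_eff)
        col_eff -= row_med_of_col
        overall += row_med_of_col

        change = max(np.abs(row_med).max(initial=0.0), np.abs(col_med).max(initial=0.0))
        if change < tol:
            break
    return overall, row_eff, col_eff, residuals


def medianpolish_summarize(
    matrix: pd.DataFrame, probe_gene: Mapping[str, str]
) -> pd.DataFrame:
    """Summarise log2 probe intensities into one expression value per gene
    and array: per probe-set median polish, expression = overall effect +
    array (column) effect."""
    log2 = np.log2(matrix)
    genes = pd.Series({p: probe_gene[p] for p in matrix.index}, name="gene")
    rows = {}
    for gene, probes in genes.groupby(genes).groups.items():
        block = log2.loc[list(probes)].to_numpy(dtype=float)
        overall, _row_eff, col_eff, _res = _median_polish(block)
        rows[gene] = overall + col_eff
    expr = pd.DataFrame.from_dict(rows, orient="index", columns=matrix.columns)
    return expr.sort_index()


# ---------------------------------------------------------------------------
# moderated two-group fit
# ---------------------------------------------------------------------------

def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 (Newton on 1/trigamma, which is
    nearly linear)."""
    if x <= 0:
        return np.inf
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < 1e-8 * y:
            break
    return float(y)


def _fit_log_variance_prior(s2: np.ndarray, d: int) -> tuple[float, float]:
    """Method-of-moments fit of the inverse-chi-square prior (d0, s0^2)
    from the spread of log sample variances across genes."""
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if ok.sum() < 2:
        return np.inf, float(np.mean(s2[ok])) if ok.any() else 1.0
    z = np.log(s2[ok])
    e_z = z.mean()
    var_z = z.var(ddof=1)
    resid_var = var_z - special.polygamma(1, d / 2.0)
    if resid_var <= 0:
        # no excess spread beyond chi-square sampling noise: variances are
        # exchangeable, the prior mean is just the average sample variance
        return np.inf, float(np.mean(s2[ok]))
    d0 = 2.0 * _trigamma_inverse(resid_var)
    log_s0 = (
        e_z
        - special.digamma(d / 2.0)
        + np.log(d / 2.0)
        + special.digamma(d0 / 2.0)
        - np.log(d0 / 2.0)
    )
    return float(d0), float(np.exp(log_s0))


@dataclass
class TwoGroupFit:
    genes: list
    log2_fc: np.ndarray
    moderated_t: np.ndarray
    p: np.ndarray
    d0: float
    s0_squared: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene": self.genes,
                "log2_fc": self.log2_fc,
                "moderated_t": self.moderated_t,
                "p": self.p,
            }
        )


def fit_two_group(
    expr: pd.DataFrame, design: Mapping[str, str], prior: str = "moments"
) -> TwoGroupFit:
    """Per-gene two-group comparison on a gene x array log2 table.

    ``design`` maps array name -> group label (exactly two groups).
    log2_fc = mean(group2) - mean(group1) with groups in sorted label
    order.  ``prior="moments"`` moderates the variance with the empirical
    prior; ``prior="none"`` is the ordinary pooled-variance t-test.
    """
    if prior not in ("none", "moments"):
        raise ValueError(f"unknown prior {prior!r}")
    groups = sorted(set(design[a] for a in expr.columns))
    if len(groups) != 2:
        raise ValueError(f"need exactly two groups, got {groups}")
    cols1 = [a for a in expr.columns if design[a] == groups[0]]
    cols2 = [a for a in expr.columns if design[a] == groups[1]]
    n1, n2 = len(cols1), len(cols2)
    if min(n1, n2) < 1 or (min(n1, n2) < 2 and prior == "none"):
        raise ValueError("each group needs n >= 2 (n = 1 only with prior='moments')")
    if n1 + n2 < 3:
        raise ValueError("need at least one residual degree of freedom")
    x1 = expr[cols1].to_numpy(dtype=float)
    x2 = expr[cols2].to_numpy(dtype=float)
    fc = x2.mean(axis=1) - x1.mean(axis=1)
    ss = ((x1 - x1.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    ss += ((x2 - x2.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    d = n1 + n2 - 2
    s2 = ss / d
    if prior == "none":
        if (s2 <= 0).any():
            raise ValueError("all-constant gene with prior='none'")
        d0, s0 = 0.0, 0.0
        s2_mod = s2
        df = float(d)
    else:
        d0, s0 = _fit_log_variance_prior(s2, d)
        if np.isinf(d0):
            s2_mod = np.full_like(s2, s0)
        else:
            s2_mod = (d0 * s0 + d * s2) / (d0 + d)
        # information cannot exceed the pooled residual df over all genes
        df = min(d0 + d, float(len(s2) * d))
    se = np.sqrt(s2_mod * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, fc / se, 0.0)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return TwoGroupFit(list(expr.index), fc, t, p, d0, s0)


# ---------------------------------------------------------------------------
# selection and reporting
# ---------------------------------------------------------------------------

def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def select_differential(
    fit: TwoGroupFit | pd.DataFrame,
    fc_threshold: float = 1.5,
    alpha: float = 0.1,
    category_map: Optional[Mapping[str, str]] = None,
) -> pd.DataFrame:
    """DEResult table: gene, log2_fc, moderated_t, p, adjusted_p, passes,
    category.  A gene passes with |FC| >= fc_threshold (linear scale) and
    adjusted p < alpha."""
    if fc_threshold < 1:
        raise ValueError("fc_threshold must be >= 1")
    frame = fit.to_frame() if isinstance(fit, TwoGroupFit) else fit.copy()
    frame["adjusted_p"] = bh_adjust(frame["p"].to_numpy())
    frame["passes"] = (np.abs(frame["log2_fc"]) >= np.log2(fc_threshold)) & (
        frame["adjusted_p"] < alpha
    )
    category_map = category_map or {}
    frame["category"] = [
        category_map.get(g, "miscellaneous") for g in frame["gene"]
    ]
    return frame


def summarize_categories(de_results: pd.DataFrame) -> pd.DataFrame:
    """Counts and rounded percentages of passing genes per functional
    category (unmapped genes fall into 'miscellaneous')."""
    passing = de_results[de_results["passes"]]
    total = len(passing)
    counts = passing.groupby("category").size().sort_values(ascending=False)
    out = counts.rename("count").reset_index()
    out["percent"] = (
        (100.0 * out["count"] / total).round().astype(int) if total else 0
    )
    return out


def export_heatmap_table(
    expr: pd.DataFrame, passing_genes, path=None
) -> pd.DataFrame:
    """Passing-gene expression matrix ordered by average-linkage
    hierarchical clustering on 1 - Pearson correlation (deterministic:
    rows pre-sorted by gene name before linkage)."""
    genes = sorted(set(passing_genes) & set(expr.index))
    if len(genes) < 2:
        raise ValueError("need at least two passing genes to cluster")
    sub = expr.loc[genes]
    values = sub.to_numpy(dtype=float)
    corr = np.corrcoef(values)
    corr = np.nan_to_num(corr, nan=0.0)
    dist = 1.0 - corr
    iu = np.triu_indices(len(genes), k=1)
    order = leaves_list(linkage(np.clip(dist[iu], 0, None), method="average"))
    ordered = sub.iloc[order]
    if path is not None:
        ordered.to_csv(path, sep="\t", index_label="gene")
    return ordered


def run_de_screen(
    matrix: pd.DataFrame,
    probe_gene: Mapping[str, str],
    design: Mapping[str, str],
    category_map: Optional[Mapping[str, str]] = None,
    fc_threshold: float = 1.5,
    alpha: float = 0.1,
    background_quantile: float = 0.02,
    prior: str = "moments",
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Full screen: background floor -> quantile normalisation ->
    median-polish summarisation -> moderated fit -> BH -> selection.
    Returns (de_results, category_summary, gene expression table)."""
    adjusted = background_floor(matrix, q=background_quantile)
    normalized = quantile_normalize(adjusted)
    expr = medianpolish_summarize(normalized, probe_gene)
    fit = fit_two_group(expr, design, prior=prior)
    results = select_differential(
        fit, fc_threshold=fc_threshold, alpha=alpha, category_map=category_map
    )
    summary = summarize_categories(results)
    return results, summary, expr
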