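"""Scoring of gene pairs for "AND" and "AND-NOT" logic-gated CAR designs.

An ideal "AND" pair is co-expressed by tumor cells but mutually exclusive
across normal tissues; an ideal "AND-NOT" pair combines a tumor-expressed
activator with an inhibitor that is silent in tumor but covers the
activator everywhere in normal tissue. Tumor co-expression (rho_Tumor)
comes from a pluggable single-cell estimator; normal co-expression is
summarized across six reference panels — signed Pearson correlation for
the two bulk RNA panels, the normal single-cell panel and the proteomics
panel with tissue-level samples, and a modified odds ratio for the two
panels with few columns — into the raw scores N (AND) and TS_'AND-NOT',
which are min-max normalized over the analyzed pair pool.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import Callable, Iterable

import numpy as np
import pandas as pd
from scipy.stats import pearsonr, spearmanr
from statsmodels.stats.multitest import multipletests

from .core_io import CellTable, ExpressionPanel, quantile

#: Dataset tags -> (scoring kind, weight) for normal co-expression.
NORMAL_DATASETS = {
    "hpa_rna": ("corr", 1.0),
    "gtex_rna": ("corr", 1.0),
    "hpa_ihc": ("or", 2.0),
    "hpm": ("or", 2.0),
    "sc": ("corr", 1.5),
    "gtex_prot": ("corr", 2.0),
}

INF = float("inf")


@dataclass
class PairScore:
    """One gene pair with its tumor and normal co-expression evidence."""

    gene_a: str
    gene_b: str
    rho_tumor: float
    raw: float
    norm: float
    score: float
    selected: bool


# ---------------------------------------------------------------------------
# Tumor co-expression
# ---------------------------------------------------------------------------


def spearman_estimator(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Default pluggable estimator: Spearman on log2(CPM+1) cell profiles.

    Returns (rho, p). Stands in for dedicated sparse-count co-expression
    estimators, whose output tables can be ingested instead.
    """
    res = spearmanr(x, y)
    rho = 0.0 if math.isnan(res.statistic) else float(res.statistic)
    p = 1.0 if math.isnan(res.pvalue) else float(res.pvalue)
    return rho, p


def tumor_coexpression(
    cells: CellTable,
    genes: list[str],
    tumor_mask: np.ndarray | None = None,
    estimator: Callable[[np.ndarray, np.ndarray], tuple[float, float]] | None = None,
    alpha: float = 0.05,
    pairs: Iterable[tuple[str, str]] | None = None,
) -> pd.Series:
    """rho_Tumor for every requested gene pair, zeroed where not significant.

    p-values are Benjamini-Hochberg corrected across all tested pairs;
    pairs with adjusted p >= ``alpha`` get rho = 0.
    """
    mask = np.ones(len(cells.cells), bool) if tumor_mask is None else tumor_mask
    if int(mask.sum()) < 20:
        raise ValueError("need at least 20 tumor cells for co-expression")
    est = estimator or spearman_estimator
    log_cpm = cells.log2_cpm()[:, mask]
    gi = {g: cells.genes.index(g) for g in genes}
    expr = {g: log_cpm[gi[g]] for g in genes}
    pair_list = list(pairs) if pairs is not None else list(
        itertools.combinations(genes, 2)
    )
    rhos, pvals = [], []
    for a, b in pair_list:
        if a == b:
            rhos.append(1.0)
            pvals.append(0.0)
            continue
        rho, p = est(expr[a], expr[b])
        rhos.append(rho)
        pvals.append(p)
    padj = multipletests(pvals, method="fdr_bh")[1]
    out = pd.Series(
        [r if q < alpha else 0.0 for r, q in zip(rhos, padj)],
        index=pd.MultiIndex.from_tuples(pair_list, names=["gene_a", "gene_b"]),
    )
    return out


# ---------------------------------------------------------------------------
# Modified odds ratios
# ---------------------------------------------------------------------------


def or_mod_and(
    zpanel: ExpressionPanel, gene_i: str, gene_j: str, zcut: float = 1.0
) -> float:
    """Modified odds ratio d / (b * c) for an "AND" pair.

    d counts columns where both genes have z > zcut; b and c count the
    single-gene columns. Returns 0 when both d and b*c are 0; +inf when
    only the denominator is 0 (treated as co-expressed downstream).
    """
    zi = zpanel.values.loc[gene_i] > zcut
    zj = zpanel.values.loc[gene_j] > zcut
    d = int((zi & zj).sum())
    b = int((zi & ~zj).sum())
    c = int((zj & ~zi).sum())
    if d == 0 and b * c == 0:
        return 0.0
    if b * c == 0:
        return INF
    return d / (b * c)


def or_mod_andnot(
    zpanel: ExpressionPanel, activator: str, inhibitor: str, zcut: float = 1.0
) -> float:
    """Modified odds ratio d / b for an "AND-NOT" pair.

    d counts columns where both activator and inhibitor have z > zcut; b
    counts activator-only columns. +inf (the favorable outcome: the
    inhibitor covers the activator everywhere) whenever b = 0, including
    the d = 0, b = 0 case.
    """
    za = zpanel.values.loc[activator] > zcut
    zi = zpanel.values.loc[inhibitor] > zcut
    d = int((za & zi).sum())
    b = int((za & ~zi).sum())
    if b == 0:
        return INF
    return d / b


# ---------------------------------------------------------------------------
# Normal co-expression scores
# ---------------------------------------------------------------------------


def _prepare_panel(tag: str, panel: ExpressionPanel, max_missing: float) -> pd.DataFrame:
    z = panel.values
    if tag == "gtex_prot":
        frac_na = z.isna().mean(axis=1)
        z = z.loc[frac_na <= max_missing]
    return z


def _pair_correlations(
    z: pd.DataFrame,
    pairs: list[tuple[str, str]],
    zero_sd: frozenset[str],
) -> tuple[list[float | None], list[float]]:
    """Pearson rho and p per pair; None marks pairs scored 0 (absent gene
    or zero-SD gene). p-values for scored pairs only."""
    rhos: list[float | None] = []
    pvals: list[float] = []
    for a, b in pairs:
        if a not in z.index or b not in z.index or a in zero_sd or b in zero_sd:
            rhos.append(None)
            continue
        xa, xb = z.loc[a], z.loc[b]
        ok = xa.notna() & xb.notna()
        if ok.sum() < 3 or xa[ok].std() == 0 or xb[ok].std() == 0:
            rhos.append(None)
            continue
        res = pearsonr(xa[ok], xb[ok])
        rhos.append(float(res.statistic))
        pvals.append(float(res.pvalue))
    return rhos, pvals


def _zfrac(z: pd.DataFrame, a: str, b: str) -> tuple[float, float]:
    """(I, A): fraction of columns with z_b >= z_a, and with z_a > z_b."""
    xa, xb = z.loc[a], z.loc[b]
    ok = xa.notna() & xb.notna()
    n = int(ok.sum())
    if n == 0:
        return 0.0, 0.0
    i_frac = float((xb[ok] >= xa[ok]).sum() / n)
    return i_frac, 1.0 - i_frac


def normal_coexpression_N(
    pairs: list[tuple[str, str]],
    panels: dict[str, ExpressionPanel],
    alpha: float = 0.05,
    max_missing: float = 0.25,
    zcut: float = 1.0,
) -> pd.Series:
    """Raw N score per "AND" pair across the normal reference panels.

    Correlation datasets contribute +w for significant negative (mutually
    exclusive) correlation and -w for significant positive correlation;
    odds-ratio datasets contribute +w when OR_mod = 0 and -w otherwise;
    absent genes contribute 0. Weights: bulk 1, odds-ratio panels 2,
    single-cell 1.5, tissue-proteomics 2.
    """
    raw = pd.Series(0.0, index=pd.MultiIndex.from_tuples(pairs))
    for tag, panel in panels.items():
        kind, w = NORMAL_DATASETS[tag]
        z = _prepare_panel(tag, panel, max_missing)
        if kind == "corr":
            rhos, pvals = _pair_correlations(z, pairs, panel.zero_sd_genes)
            padj = iter(multipletests(pvals, method="fdr_bh")[1] if pvals else [])
            for (a, b), rho in zip(pairs, rhos):
                if rho is None:
                    continue
                q = next(padj)
                if q >= alpha or rho == 0:
                    continue
                raw[(a, b)] += w if rho < 0 else -w
        else:
            for a, b in pairs:
                if a not in z.index or b not in z.index:
                    continue
                om = or_mod_and(ExpressionPanel(z, "zscore"), a, b, zcut=zcut)
                raw[(a, b)] += w if om == 0 else -w
    return raw


def n_norm(raw: pd.Series) -> pd.Series:
    """Min-max normalize raw N over the pool and flip the sign so that
    -1 marks the most mutually exclusive pair and +1 the most co-expressed."""
    lo, hi = raw.min(), raw.max()
    if hi == lo:
        warnings.warn("degenerate pair pool: all raw N equal; N_norm set to 0")
        return raw * 0.0
    return -(((raw - lo) / (hi - lo)) * 2.0 - 1.0)


def ts_and(
    rho_tumor: pd.Series, n_normalized: pd.Series, cutoff: float = 1.0
) -> pd.DataFrame:
    """TS_'AND' = rho_Tumor - N_norm, selected at score >= cutoff."""
    score = rho_tumor - n_normalized
    return pd.DataFrame(
        {
            "rho_tumor": rho_tumor,
            "n_norm": n_normalized,
            "ts": score,
            "selected": score >= cutoff,
        }
    )


def inhibitor_pool(
    down_genes: list[str],
    surfaceome: set[str],
    sc_expr: pd.Series,
    pct: float = 50.0,
) -> list[str]:
    """Candidate inhibitors: downregulated surfaceome genes with mean tumor
    log2(CPM+1) strictly below the pool's 50th percentile."""
    pool = [g for g in down_genes if g in surfaceome and g in sc_expr.index]
    if not pool:
        raise ValueError("no downregulated surfaceome genes to draw inhibitors from")
    cut = quantile(sc_expr.reindex(pool), pct)
    return [g for g in pool if sc_expr[g] < cut]


def ts_and_not_raw(
    pairs: list[tuple[str, str]],
    panels: dict[str, ExpressionPanel],
    alpha: float = 0.05,
    max_missing: float = 0.25,
    zcut: float = 1.0,
) -> pd.Series:
    """Raw TS_'AND-NOT' per (activator, inhibitor) pair.

    Correlation datasets reward significant positive correlation (the
    inhibitor shadows the activator in normal tissue) with +w*(1+I) and
    penalize significant negative correlation with -w*(1+A); odds-ratio
    datasets reward OR_mod = inf with +w*(1+I) and penalize otherwise with
    -w*(1+A). I is the fraction of a dataset's comparisons where the
    inhibitor's z-score is at or above the activator's; A is its
    complement. Absent genes contribute 0.
    """
    raw = pd.Series(0.0, index=pd.MultiIndex.from_tuples(pairs))
    for tag, panel in panels.items():
        kind, w = NORMAL_DATASETS[tag]
        z = _prepare_panel(tag, panel, max_missing)
        if kind == "corr":
            rhos, pvals = _pair_correlations(z, pairs, panel.zero_sd_genes)
            padj = iter(multipletests(pvals, method="fdr_bh")[1] if pvals else [])
            for (a, i), rho in zip(pairs, rhos):
                if rho is None:
                    continue
                q = next(padj)
                if q >= alpha or rho == 0:
                    continue
                I, A = _zfrac(z, a, i)
                raw[(a, i)] += w * (1 + I) if rho > 0 else -w * (1 + A)
        else:
            for a, i in pairs:
                if a not in z.index or i not in z.index:
                    continue
                om = or_mod_andnot(ExpressionPanel(z, "zscore"), a, i, zcut=zcut)
                I, A = _zfrac(z, a, i)
                raw[(a, i)] += w * (1 + I) if om == INF else -w * (1 + A)
    return raw


def andnot_norm(raw: pd.Series) -> pd.Series:
    """Min-max normalize raw TS_'AND-NOT' to [-1, 1] (no sign flip)."""
    lo, hi = raw.min(), raw.max()
    if hi == lo:
        warnings.warn("degenerate pair pool: all raw scores equal; set to 0")
        return raw * 0.0
    return ((raw - lo) / (hi - lo)) * 2.0 - 1.0


def ts_and_not(
    pairs: list[tuple[str, str]],
    panels: dict[str, ExpressionPanel],
    alpha: float = 0.05,
    select_percentile: float = 99.0,
    zcut: float = 1.0,
) -> pd.DataFrame:
    """Raw + normalized TS_'AND-NOT' with selection above the pool's 99th
    percentile of the normalized score (strict >)."""
    raw = ts_and_not_raw(pairs, panels, alpha=alpha, zcut=zcut)
    norm = andnot_norm(raw)
    cut = quantile(norm, select_percentile)
    return pd.DataFrame(
        {"raw": raw, "norm": norm, "selected": norm > cut}
    )
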