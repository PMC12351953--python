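"""Monospecific CAR-T target nomination.

Candidates (tumor-upregulated surfaceome genes) pass through a
high-expression filter, then a permissive and a stringent on-target
off-tumor toxicity screen benchmarked against clinically tested CAR-T
targets, and are finally ranked by a weighted targetability score::

    TS_CAR(g) = sum(m_bulk) + sum(m_protein) + m_sc

with per-dataset contributions of +/-1 for the two categorized bulk
RNA panels, +/-2 for the four protein panels, +/-1.5 for the normal
single-cell RNA panel, and 0 where the gene is absent from a dataset.
Genes with TS_CAR at or above the 25th percentile of the reference
targets' scores (5 with the published references) are nominated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import ExpressionPanel, ReferenceTargetSet, quantile

#: Dataset tags and their TS_CAR weights.
DATASET_WEIGHTS = {
    "hpa_rna": 1.0,
    "gtex_rna": 1.0,
    "hpa_ihc": 2.0,
    "gtex_prot": 2.0,
    "hpm": 2.0,
    "hpa_num": 2.0,
    "sc": 1.5,
}

PERMISSIVE_DATASETS = ("hpa_rna", "gtex_rna", "hpa_ihc")
STRINGENT_PROTEIN_DATASETS = ("gtex_prot", "hpm", "hpa_num")

TS_CAR_MAX = sum(DATASET_WEIGHTS.values())  # 11.5


@dataclass
class ToxicityFilterResult:
    """Per-gene verdicts (pass/fail/absent per dataset) and TS_CAR."""

    gene: str
    verdicts: dict[str, str]
    ts_car: float
    selected: bool = False


def high_expression_filter(
    up_genes: list[str],
    sc_expr: pd.Series,
    bulk_expr: pd.Series,
    cellline_expr: pd.Series,
    pct: float = 50.0,
) -> list[str]:
    """Retain genes with high tumor expression.

    Keep a gene when its single-cell mean is at or above the pool
    percentile AND (the bulk cohort value is also at/above its pool
    percentile, OR the cell-line value is, OR both external values are
    missing). Percentiles are computed within the candidate pool.
    """
    if not up_genes:
        raise ValueError("empty candidate pool")
    sc = sc_expr.reindex(up_genes)
    bulk = bulk_expr.reindex(up_genes)
    line = cellline_expr.reindex(up_genes)
    q_sc = quantile(sc.dropna(), pct)
    q_bulk = quantile(bulk.dropna(), pct) if bulk.notna().any() else np.nan
    q_line = quantile(line.dropna(), pct) if line.notna().any() else np.nan
    keep = []
    for g in up_genes:
        if pd.isna(sc[g]) or sc[g] < q_sc:
            continue
        bulk_hi = pd.notna(bulk[g]) and bulk[g] >= q_bulk
        line_hi = pd.notna(line[g]) and line[g] >= q_line
        if bulk_hi or line_hi or (pd.isna(bulk[g]) and pd.isna(line[g])):
            keep.append(g)
    return keep


def _mh_counts(categorized: pd.DataFrame, genes: list[str]) -> pd.Series:
    """Number of tissue groups with M-H category per gene (present only)."""
    present = [g for g in genes if g in categorized.index]
    return (categorized.loc[present] == "M-H").sum(axis=1)


def permissive_filter(
    candidates: list[str],
    categorized_panels: dict[str, pd.DataFrame],
    references: ReferenceTargetSet,
    ref_percentile: float = 90.0,
) -> dict[str, dict[str, str]]:
    """Permissive on-target off-tumor filter on categorized panels.

    Per dataset, the cutoff is the 90th percentile of the number of M-H
    tissue groups among the reference targets; a candidate passes when its
    own M-H count is strictly below the cutoff, and is 'absent' when the
    gene is missing from the dataset.
    """
    verdicts: dict[str, dict[str, str]] = {g: {} for g in candidates}
    for tag, cat in categorized_panels.items():
        ref_counts = _mh_counts(cat, references.genes)
        if ref_counts.empty:
            raise ValueError(f"no reference targets present in dataset {tag!r}")
        cutoff = quantile(ref_counts, ref_percentile)
        for g in candidates:
            if g not in cat.index:
                verdicts[g][tag] = "absent"
            else:
                count = int((cat.loc[g] == "M-H").sum())
                verdicts[g][tag] = "pass" if count < cutoff else "fail"
    return verdicts


def stringent_sc_filter(
    candidates: list[str],
    sc_panel: ExpressionPanel,
    references: ReferenceTargetSet,
    excluded_celltypes: tuple[str, ...] = (),
    z_high: float = 1.0,
    ref_percentile: float = 75.0,
) -> dict[str, str]:
    """Stringent single-cell filter on the z-scored cell-type panel.

    A candidate passes when (a) its number of cell types with z > 1 is at
    or below the 75th percentile of the reference targets' counts, and (b)
    its expression stays strictly below the per-cell-type maximum over the
    references in every non-excluded cell type.
    """
    z = sc_panel.values
    refs = [g for g in references.genes if g in z.index]
    if not refs:
        raise ValueError("no reference targets present in single-cell panel")
    ref_counts = (z.loc[refs] > z_high).sum(axis=1)
    count_cut = quantile(ref_counts, ref_percentile)
    retained_cols = [c for c in z.columns if c not in set(excluded_celltypes)]
    ref_max = z.loc[refs, retained_cols].max(axis=0)
    out: dict[str, str] = {}
    for g in candidates:
        if g not in z.index:
            out[g] = "absent"
            continue
        n_high = int((z.loc[g] > z_high).sum())
        below_max = bool((z.loc[g, retained_cols] < ref_max).all())
        out[g] = "pass" if (n_high <= count_cut and below_max) else "fail"
    return out


def stringent_protein_filter(
    candidates: list[str],
    protein_panels: dict[str, ExpressionPanel],
    references: ReferenceTargetSet,
    excluded_tissues: tuple[str, ...] = (),
) -> dict[str, dict[str, str]]:
    """Stringent protein filter: per dataset, a candidate passes when it is
    strictly below the reference maximum in every retained tissue (or
    tissue group); NA tissues are ignored, absent genes score 'absent'."""
    verdicts: dict[str, dict[str, str]] = {g: {} for g in candidates}
    for tag, panel in protein_panels.items():
        z = panel.values
        refs = [g for g in references.genes if g in z.index]
        if not refs:
            raise ValueError(f"no reference targets present in dataset {tag!r}")
        cols = [c for c in z.columns if c not in set(excluded_tissues)]
        ref_max = z.loc[refs, cols].max(axis=0)
        for g in candidates:
            if g not in z.index:
                verdicts[g][tag] = "absent"
                continue
            vals = z.loc[g, cols]
            ok = bool(((vals < ref_max) | vals.isna()).all())
            verdicts[g][tag] = "pass" if ok else "fail"
    return verdicts


def ts_car(verdicts: dict[str, str]) -> float:
    """Weighted sum of per-dataset verdicts (pass +w, fail -w, absent 0)."""
    score = 0.0
    for tag, verdict in verdicts.items():
        if tag not in DATASET_WEIGHTS:
            raise ValueError(f"unknown dataset tag {tag!r}")
        w = DATASET_WEIGHTS[tag]
        if verdict == "pass":
            score += w
        elif verdict == "fail":
            score -= w
        elif verdict != "absent":
            raise ValueError(f"unknown verdict {verdict!r}")
    return score


def select_mono_targets(
    scored: dict[str, float],
    reference_scores: list[float] | None,
    ref_percentile: float = 25.0,
    fallback_cutoff: float = 5.0,
    min_references: int = 4,
) -> tuple[list[str], float]:
    """Nominate genes whose TS_CAR meets the reference-derived cutoff.

    The cutoff is the 25th percentile of the reference targets' TS_CAR
    scores (inclusive >=); with fewer than ``min_references`` references
    the explicit numeric cutoff from the configuration is used instead.
    """
    if reference_scores and len(reference_scores) >= min_references:
        cutoff = quantile(reference_scores, ref_percentile)
    else:
        if reference_scores:
            warnings.warn(
                "fewer than %d reference scores; using explicit cutoff"
                % min_references
            )
        cutoff = fallback_cutoff
    selected = [g for g, s in scored.items() if s >= cutoff]
    return selected, cutoff


def score_candidates(
    candidates: list[str],
    categorized_panels: dict[str, pd.DataFrame],
    sc_panel: ExpressionPanel,
    protein_panels: dict[str, ExpressionPanel],
    references: ReferenceTargetSet,
    excluded_celltypes: tuple[str, ...] = (),
    excluded_tissues: tuple[str, ...] = (),
) -> dict[str, ToxicityFilterResult]:
    """Run both filters and combine verdicts into TS_CAR per candidate."""
    perm = permissive_filter(candidates, categorized_panels, references)
    sc = stringent_sc_filter(
        candidates, sc_panel, references, excluded_celltypes=excluded_celltypes
    )
    prot = stringent_protein_filter(
        candidates, protein_panels, references, excluded_tissues=excluded_tissues
    )
    out = {}
    for g in candidates:
        verdicts = {**perm[g], **prot[g], "sc": sc[g]}
        out[g] = ToxicityFilterResult(gene=g, verdicts=verdicts, ts_car=ts_car(verdicts))
    return out


def results_frame(results: dict[str, ToxicityFilterResult]) -> pd.DataFrame:
    rows = []
    for g, r in results.items():
        row = {"gene": g}
        row.update({f"verdict_{k}": v for k, v in sorted(r.verdicts.items())})
        row["ts_car"] = r.ts_car
        row["selected"] = r.selected
        rows.append(row)
    return pd.DataFrame(rows)
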