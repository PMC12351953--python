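"""Malignant-cell classification from CNA states and bulk similarity.

A cell is called malignant when it is CD45-negative (raw PTPRC count of 0)
and shows either a detected copy-number abnormality — its per-gene CNA
profile correlates with the tumor consensus profile above the 25th
percentile of all cells in the sample — or a positive similarity score,
defined as Spearman rho against the mean bulk tumor profile minus Spearman
rho against the mean normal-cell profile.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata, spearmanr

from .core_io import CellTable, CNAStateMatrix, ExpressionPanel, quantile


@dataclass
class MalignancyCall:
    """Per-cell classification with the intermediate evidence retained."""

    cells: list[str]
    cd45_negative: np.ndarray
    cna_burden: np.ndarray
    rho_to_tumor_profile: np.ndarray  # NaN where undefined
    cna_detected: np.ndarray
    similarity_score: np.ndarray
    malignant: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cell": self.cells,
                "cd45_negative": self.cd45_negative,
                "cna_burden": self.cna_burden,
                "rho_to_tumor_profile": self.rho_to_tumor_profile,
                "cna_detected": self.cna_detected,
                "similarity_score": self.similarity_score,
                "malignant": self.malignant,
            }
        )


def normalize_cna_matrix(states: CNAStateMatrix) -> pd.DataFrame:
    """Map HMM states 1..6 to squared deviations from the neutral state.

    States of 6 (gain of more than two alleles) are first capped at 5, then
    each state s becomes ((s - 3) / 2) ** 2 so that complete loss (1) and
    two-allele gain (5) both weigh 1 and the neutral state weighs 0.
    """
    capped = states.states.clip(upper=5)
    return ((capped - 3) / 2.0) ** 2


def tumor_cna_profile(
    norm: pd.DataFrame, cells: CellTable, top_frac: float = 0.10
) -> tuple[pd.Series, pd.Series]:
    """Consensus per-gene CNA profile from the highest-burden CD45- cells.

    Burden is the per-cell mean of the normalized matrix over all genes;
    the profile averages the top ``top_frac`` (ceil) CD45- cells by burden,
    ties broken by cell order.
    """
    burden = norm.mean(axis=0)
    cd45neg = pd.Series(cells.cd45_negative(), index=cells.cells)
    neg_ids = [c for c in norm.columns if cd45neg.get(c, False)]
    if not neg_ids:
        raise ValueError("no CD45- cells in sample")
    k = int(np.ceil(top_frac * len(neg_ids)))
    # stable sort: ties broken by cell order
    top = sorted(neg_ids, key=lambda c: -burden[c])[:k]
    profile = norm[top].mean(axis=1)
    return profile, burden


def call_cna_detected(
    norm: pd.DataFrame, profile: pd.Series, pct: float = 25.0
) -> tuple[np.ndarray, np.ndarray]:
    """Flag cells whose Spearman rho to the tumor profile is above the
    ``pct`` percentile of all defined rho values in the sample (strict >).

    Returns (flags, rho); cells with a constant CNA vector have undefined
    rho (NaN) and are never flagged.
    """
    prof = profile.reindex(norm.index).to_numpy()
    mat = norm.to_numpy()
    rho = np.full(mat.shape[1], np.nan)
    if np.ptp(prof) == 0:
        warnings.warn("tumor profile is constant; no CNA can be detected")
        return np.zeros(mat.shape[1], bool), rho
    prank = rankdata(prof)
    prank = (prank - prank.mean()) / prank.std()
    for j in range(mat.shape[1]):
        col = mat[:, j]
        if np.ptp(col) == 0:
            continue
        crank = rankdata(col)
        crank = (crank - crank.mean()) / crank.std()
        rho[j] = float(np.mean(prank * crank))
    defined = ~np.isnan(rho)
    if not defined.any():
        warnings.warn("all cells have constant CNA vectors; nothing flagged")
        return np.zeros(mat.shape[1], bool), rho
    cut = quantile(rho[defined], pct)
    flags = np.where(defined, rho > cut, False)
    return flags, rho


def similarity_score(
    cells: CellTable,
    bulk_reference: ExpressionPanel,
    normal_reference: ExpressionPanel,
    min_genes: int = 50,
) -> np.ndarray:
    """Per-cell similarity score: rho(cell, mean bulk tumor) - rho(cell,
    mean normal reference), Spearman, over the common gene set."""
    common = [
        g
        for g in cells.genes
        if g in bulk_reference.values.index and g in normal_reference.values.index
    ]
    if len(common) < min_genes:
        raise ValueError(
            f"only {len(common)} genes shared between cells and references"
        )
    idx = [cells.genes.index(g) for g in common]
    expr = np.asarray(cells.counts[idx, :].todense())
    tumor_mean = bulk_reference.values.loc[common].mean(axis=1).to_numpy()
    normal_mean = normal_reference.values.loc[common].mean(axis=1).to_numpy()
    scores = np.empty(expr.shape[1])
    for j in range(expr.shape[1]):
        rt = spearmanr(expr[:, j], tumor_mean).statistic
        rn = spearmanr(expr[:, j], normal_mean).statistic
        scores[j] = (0.0 if np.isnan(rt) else rt) - (0.0 if np.isnan(rn) else rn)
    return scores


def classify_malignant(
    cells: CellTable,
    cd45_negative: np.ndarray,
    cna_detected: np.ndarray,
    similarity: np.ndarray,
    cna_burden: np.ndarray | None = None,
    rho: np.ndarray | None = None,
) -> MalignancyCall:
    """Combine the two routes: malignant iff CD45- and (detected CNA or
    similarity score strictly > 0)."""
    malignant = cd45_negative & (cna_detected | (similarity > 0))
    n = len(cells.cells)
    return MalignancyCall(
        cells=list(cells.cells),
        cd45_negative=np.asarray(cd45_negative, bool),
        cna_burden=np.full(n, np.nan) if cna_burden is None else np.asarray(cna_burden),
        rho_to_tumor_profile=np.full(n, np.nan) if rho is None else np.asarray(rho),
        cna_detected=np.asarray(cna_detected, bool),
        similarity_score=np.asarray(similarity, float),
        malignant=malignant,
    )


def call_sample(
    cells: CellTable,
    states: CNAStateMatrix,
    bulk_reference: ExpressionPanel,
    normal_reference: ExpressionPanel,
    top_frac: float = 0.10,
    pct: float = 25.0,
) -> MalignancyCall:
    """Run the full malignancy classification for one sample."""
    norm = normalize_cna_matrix(states)
    profile, burden = tumor_cna_profile(norm, cells, top_frac=top_frac)
    flags, rho = call_cna_detected(norm, profile, pct=pct)
    sim = similarity_score(cells, bulk_reference, normal_reference)
    return classify_malignant(
        cells,
        cells.cd45_negative(),
        flags,
        sim,
        cna_burden=burden.reindex(cells.cells).to_numpy(),
        rho=rho,
    )
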