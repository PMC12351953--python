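"""Shared domain types, readers/writers, and normalization primitives.

Expression data moves through the pipeline as :class:`ExpressionPanel`
objects — a gene-by-column numeric matrix whose columns may be tissues,
tissue groups, cell types, or samples — together with an explicit unit tag
so that unit-sensitive operations (log transforms, z-scoring,
categorization) can refuse inputs on the wrong scale. Per-cell count data
for one tumor sample lives in :class:`CellTable`, and inferCNV-style
copy-number state calls in :class:`CNAStateMatrix`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

UNITS = {
    "raw-count",
    "CPM",
    "TPM",
    "nTPM",
    "log2p1",
    "zscore",
    "categorical-ordinal",
}

#: Closed vocabulary for per-cell labels.
CELL_LABELS = {"tumor", "endothelial", "myeloid", "lymphoid", "CAF", "unknown"}

#: Numeric recoding of immunohistochemistry categories.
IHC_NUMERIC = {"Not Detected": 1, "Low": 2, "Medium": 3, "High": 4}

#: Hierarchy used when collapsing tissue categories to a tissue group.
IHC_HIERARCHY = ["M-H", "Variable", "Medium", "ND-L"]


class PanelUnitError(ValueError):
    """Raised when an operation receives a panel on the wrong scale."""


@dataclass
class ExpressionPanel:
    """Gene x column numeric matrix with a declared unit.

    Parameters
    ----------
    values
        DataFrame indexed by gene symbol with one column per tissue,
        tissue group, cell type, or sample.
    unit
        One of :data:`UNITS`.
    grouping
        Optional mapping from column label to tissue-group label.
    zero_sd_genes
        Genes flagged as constant during z-scoring; excluded from
        correlation-based operations downstream.
    """

    values: pd.DataFrame
    unit: str
    grouping: Mapping[str, str] | None = None
    zero_sd_genes: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.unit not in UNITS:
            raise ValueError(f"unknown unit {self.unit!r}")
        if self.values.shape[0] == 0 or self.values.shape[1] == 0:
            raise ValueError("empty expression matrix")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def columns(self) -> list[str]:
        return list(self.values.columns)

    def group_means(self) -> pd.DataFrame:
        """Average columns within each tissue group (requires grouping)."""
        if self.grouping is None:
            raise ValueError("panel has no grouping")
        groups = pd.Series({c: self.grouping[c] for c in self.values.columns})
        return self.values.T.groupby(groups).mean().T

    def write(self, path: str | Path) -> None:
        out = self.values.copy()
        out.insert(0, "gene", out.index)
        out.to_csv(path, sep="\t", index=False)


@dataclass
class CellTable:
    """Per-cell counts and metadata for one tumor sample.

    counts is stored sparse, genes x cells, in the same gene order as
    ``genes``.
    """

    sample_id: str
    genes: list[str]
    cells: list[str]
    counts: scipy.sparse.csr_matrix
    labels: pd.Series  # cell id -> label from CELL_LABELS

    def __post_init__(self) -> None:
        bad = set(self.labels.unique()) - CELL_LABELS
        if bad:
            raise ValueError(f"labels outside closed vocabulary: {sorted(bad)}")
        if self.counts.shape != (len(self.genes), len(self.cells)):
            raise ValueError("count matrix shape does not match label lists")

    def gene_counts(self, gene: str) -> np.ndarray:
        i = self.genes.index(gene)
        return np.asarray(self.counts[i, :].todense()).ravel()

    def ptprc_counts(self) -> np.ndarray:
        """Raw PTPRC counts per cell; CD45- cells have count 0."""
        return self.gene_counts("PTPRC")

    def cd45_negative(self) -> np.ndarray:
        return self.ptprc_counts() == 0

    def cpm(self) -> scipy.sparse.csr_matrix:
        """Counts-per-million per cell (column-wise scaling)."""
        totals = np.asarray(self.counts.sum(axis=0)).ravel()
        totals[totals == 0] = 1.0
        scale = scipy.sparse.diags(1e6 / totals)
        return (self.counts @ scale).tocsr()

    def log2_cpm(self) -> np.ndarray:
        """Dense log2(CPM + 1) matrix, genes x cells."""
        return np.log2(np.asarray(self.cpm().todense()) + 1.0)


@dataclass
class CNAStateMatrix:
    """Genes x cells integer matrix of inferCNV HMM states in 1..6."""

    states: pd.DataFrame

    def __post_init__(self) -> None:
        vals = self.states.to_numpy()
        if not np.isin(vals, [1, 2, 3, 4, 5, 6]).all():
            raise ValueError("CNA states must be integers in 1..6")


@dataclass
class ReferenceTargetSet:
    """Reference target genes (tested CAR-T targets or CGA TCR-T targets)."""

    genes: list[str]
    role: str  # "tested-CAR-T" | "CGA-TCR-T"

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError("reference target set must be non-empty")
        if self.role not in {"tested-CAR-T", "CGA-TCR-T"}:
            raise ValueError(f"unknown role {self.role!r}")


@dataclass
class Config:
    """All numeric constants of the scoring framework, overridable.

    Defaults reproduce the published thresholds.
    """

    mh_log2_tpm_cutoff: float = 4.0
    deg_fdr: float = 0.25
    coexpr_alpha: float = 0.05
    high_expr_percentile: float = 50.0
    tcr_high_expr_percentile: float = 25.0
    permissive_ref_percentile: float = 90.0
    stringent_sc_ref_percentile: float = 75.0
    stringent_sc_zscore_high: float = 1.0
    ts_car_cutoff: float = 5.0
    ts_car_ref_percentile: float = 25.0
    ts_and_cutoff: float = 1.0
    ts_andnot_percentile: float = 99.0
    n_score_cutoff: float = 3.5
    ts_tcr_percentile: float = 99.0
    hlathena_min: float = 0.85
    s_sim_cutoff: float = 1.15
    s_cr_observed_boost: float = 1.25
    s_cr_presentation_offset: float = 0.5
    s_cr_diff_alpha: float = 2.0
    presentation_floor: float = 0.5
    affinity_percentile_max: float = 2.0
    gtex_prot_max_missing: float = 0.25
    cna_top_frac: float = 0.10
    cna_detect_percentile: float = 25.0
    excluded_cell_types: tuple[str, ...] = ()
    excluded_tissues: tuple[str, ...] = ()
    hla_exclusion: tuple[str, ...] = ()
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "Config":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("excluded_cell_types", "excluded_tissues", "hla_exclusion"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def _detect_sep(path: Path) -> str:
    head = path.open().readline()
    return "," if ("," in head and "\t" not in head) else "\t"


def read_expression_panel(
    path: str | Path,
    unit: str,
    grouping: Mapping[str, str] | None = None,
    gene_column: str = "gene",
) -> ExpressionPanel:
    """Read a TSV/CSV gene x column matrix into an :class:`ExpressionPanel`.

    Duplicate gene symbols (alternative transcripts) are kept distinct by
    suffixing ``.1``, ``.2``, ... and a warning is emitted.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_detect_sep(path))
    if gene_column not in df.columns:
        raise ValueError(f"no {gene_column!r} column in {path}")
    genes = df[gene_column].astype(str)
    mat = df.drop(columns=[gene_column])
    bad = mat.columns[~mat.apply(lambda c: pd.api.types.is_numeric_dtype(c))]
    if len(bad):
        # pinpoint the first offending cell for the error message
        col = bad[0]
        row = mat[col][pd.to_numeric(mat[col], errors="coerce").isna()].index[0]
        raise ValueError(
            f"non-numeric value in column {col!r}, row {genes.iloc[row]!r} of {path}"
        )
    if mat.shape[1] == 0 or mat.shape[0] == 0:
        raise ValueError(f"empty matrix in {path}")
    if genes.duplicated().any():
        dups = sorted(genes[genes.duplicated()].unique())
        warnings.warn(f"duplicated gene symbols kept as suffixed rows: {dups}")
        counts: dict[str, int] = {}
        out = []
        for g in genes:
            if g in counts:
                counts[g] += 1
                out.append(f"{g}.{counts[g]}")
            else:
                counts[g] = 0
                out.append(g)
        genes = pd.Series(out)
    mat.index = pd.Index(genes, name="gene")
    return ExpressionPanel(values=mat.astype(float), unit=unit, grouping=grouping)


def read_cell_table(
    mtx_path: str | Path,
    genes_path: str | Path,
    barcodes_path: str | Path,
    labels_path: str | Path,
    sample_id: str = "sample",
) -> CellTable:
    """Read an MTX triplet (matrix + features + barcodes) and a label TSV."""
    counts = scipy.sparse.csr_matrix(scipy.io.mmread(str(mtx_path)))
    genes = [line.strip().split("\t")[0] for line in open(genes_path)]
    cells = [line.strip() for line in open(barcodes_path)]
    lab = pd.read_csv(labels_path, sep="\t", index_col=0)["label"]
    lab = lab.reindex(cells).fillna("unknown")
    return CellTable(
        sample_id=sample_id, genes=genes, cells=cells, counts=counts, labels=lab
    )


def resolve_aliases(genes: Sequence[str], alias_table: Mapping[str, str]) -> list[str]:
    """Map gene aliases to standard symbols via a user-supplied table.

    Unresolved symbols pass through unchanged with a warning.
    """
    out, missing = [], []
    for g in genes:
        if g in alias_table:
            out.append(alias_table[g])
        else:
            out.append(g)
            missing.append(g)
    if missing:
        warnings.warn(f"{len(missing)} gene symbols not in alias table; kept as-is")
    return out


# ---------------------------------------------------------------------------
# Normalization primitives
# ---------------------------------------------------------------------------


def median_center_zscore(panel: ExpressionPanel) -> ExpressionPanel:
    """Median-center each column, then z-score each gene row.

    The z-score uses the sample standard deviation (n-1 denominator).
    Constant rows are set to all-zero and flagged in ``zero_sd_genes`` so
    that downstream correlation-based scores can skip them instead of
    propagating NaN.
    """
    if panel.unit == "categorical-ordinal":
        raise PanelUnitError("cannot z-score a categorical panel")
    if panel.values.shape[1] < 2:
        raise ValueError("z-score undefined for a single-column panel")
    centered = panel.values - panel.values.median(axis=0)
    sd = centered.std(axis=1, ddof=1)
    flagged = frozenset(sd.index[(sd == 0) | sd.isna()])
    z = centered.sub(centered.mean(axis=1), axis=0).div(sd.replace(0, np.nan), axis=0)
    z.loc[list(flagged)] = 0.0
    return ExpressionPanel(
        values=z, unit="zscore", grouping=panel.grouping, zero_sd_genes=flagged
    )


def categorize_bulk_expression(
    panel: ExpressionPanel, threshold: float = 4.0
) -> pd.DataFrame:
    """Categorize tissue-group mean expression as M-H / ND-L.

    Expression is first averaged within tissue groups; a group is
    "Medium-High" when its mean log2(TPM+1) is >= ``threshold`` (boundary
    inclusive), else "Not Detected-Low".
    """
    if panel.unit != "log2p1":
        raise PanelUnitError("categorization requires log2(TPM+1) values")
    means = panel.group_means() if panel.grouping is not None else panel.values
    cats = np.where(means.to_numpy() >= threshold, "M-H", "ND-L")
    return pd.DataFrame(cats, index=means.index, columns=means.columns)


def classify_ihc_tissue(cell_categories: Sequence[str]) -> str:
    """Collapse per-cell-type IHC categories within one tissue.

    Rules: "ND-L" if every cell type is Not Detected or Low; "M-H" if every
    cell type is Medium or High (including only-High); "Medium" if every
    cell type is exactly Medium; "Variable" for any other mixture.
    """
    cats = set(cell_categories)
    unknown = cats - set(IHC_NUMERIC)
    if unknown:
        raise ValueError(f"unknown IHC category token(s): {sorted(unknown)}")
    if cats <= {"Not Detected", "Low"}:
        return "ND-L"
    if cats == {"Medium"}:
        return "Medium"
    if cats <= {"Medium", "High"}:
        return "M-H"
    return "Variable"


def aggregate_ihc_tissue_group(
    tissue_categories: Mapping[str, Sequence[str]],
    grouping: Mapping[str, str],
) -> dict[str, str]:
    """Tissue-group IHC category as the hierarchy-max over member tissues.

    ``tissue_categories`` maps tissue -> per-cell-type categories; the
    hierarchy is M-H > Variable > Medium > ND-L.
    """
    per_tissue = {t: classify_ihc_tissue(c) for t, c in tissue_categories.items()}
    rank = {cat: i for i, cat in enumerate(IHC_HIERARCHY)}
    out: dict[str, str] = {}
    for tissue, cat in per_tissue.items():
        grp = grouping[tissue]
        if grp not in out or rank[cat] < rank[out[grp]]:
            out[grp] = cat
    return out


def quantile(values: Sequence[float], pct: float) -> float:
    """Linear-interpolation (Hyndman-Fan type 7) percentile, 0-100 scale."""
    arr = np.asarray(values, dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size == 0:
        raise ValueError("quantile of empty sequence")
    return float(np.percentile(arr, pct))
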