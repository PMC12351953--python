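"""Aggregation of differential-expression tables into up/down gene calls.

The pipeline never re-runs the pseudobulk or distribution tests; their
result tables (gene, log2FC, adjusted p, comparison id, reference class)
are the input contract. A gene is called up-regulated in a histotype when
it is significantly up (log2FC > 0, FDR < 0.25) in at least one
comparison; down-regulated when significantly down in at least one
comparison and never significantly up, with the "never up" rule evaluated
separately within each reference class (tumor-microenvironment versus
normal-tissue panels) before the per-class down lists are unioned.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

REF_CLASSES = {"TME", "normal-panel"}

COMPARISON_COLUMNS = ["gene", "log2fc", "padj", "comparison", "ref_class"]


@dataclass
class DEGComparison:
    """One differential-expression contrast."""

    comparison_id: str
    ref_class: str
    table: pd.DataFrame  # columns: gene, log2fc, padj
    method: str = "limma-voom"

    def __post_init__(self) -> None:
        if self.ref_class not in REF_CLASSES:
            raise ValueError(f"unknown reference class {self.ref_class!r}")
        p = self.table["padj"]
        if ((p < 0) | (p > 1)).any():
            raise ValueError("adjusted p-values outside [0, 1]")


@dataclass
class DEGCallSet:
    """Per-histotype up/down calls with their supporting comparisons."""

    histotype: str
    up: dict[str, list[str]] = field(default_factory=dict)
    down: dict[str, list[str]] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"gene": g, "direction": d, "comparisons": ";".join(ids)}
            for d, calls in (("up", self.up), ("down", self.down))
            for g, ids in sorted(calls.items())
        ]
        return pd.DataFrame(rows, columns=["gene", "direction", "comparisons"])


def log2fc_cpm(mean_tumor_cpm: float, mean_normal_cpm: float) -> float:
    """log2 fold change on CPM means with a 0.01 pseudocount."""
    if mean_tumor_cpm < 0 or mean_normal_cpm < 0:
        raise ValueError("CPM means must be non-negative")
    return float(np.log2((mean_tumor_cpm + 0.01) / (mean_normal_cpm + 0.01)))


def _significant(table: pd.DataFrame, fdr: float) -> pd.DataFrame:
    return table[(table["padj"] < fdr) & (table["log2fc"] != 0)]


def aggregate_deg_calls(
    comparisons: list[DEGComparison],
    histotype: str = "",
    fdr: float = 0.25,
    joint_never_up: bool = False,
) -> DEGCallSet:
    """Collapse comparisons into one up/down call set.

    With ``joint_never_up`` the "never upregulated" exclusion spans both
    reference classes instead of being applied per class.
    """
    if not comparisons:
        raise ValueError("no comparisons supplied")
    up_support: dict[str, list[str]] = {}
    down_by_class: dict[str, dict[str, list[str]]] = {c: {} for c in REF_CLASSES}
    up_by_class: dict[str, set[str]] = {c: set() for c in REF_CLASSES}
    for comp in comparisons:
        sig = _significant(comp.table, fdr)
        for gene in sig.loc[sig["log2fc"] > 0, "gene"]:
            up_support.setdefault(gene, []).append(comp.comparison_id)
            up_by_class[comp.ref_class].add(gene)
        for gene in sig.loc[sig["log2fc"] < 0, "gene"]:
            down_by_class[comp.ref_class].setdefault(gene, []).append(
                comp.comparison_id
            )
    all_up = set(up_support)
    down: dict[str, list[str]] = {}
    for cls, calls in down_by_class.items():
        blocked = all_up if joint_never_up else up_by_class[cls]
        for gene, ids in calls.items():
            if gene in blocked:
                continue
            down.setdefault(gene, []).extend(ids)
    return DEGCallSet(histotype=histotype, up=up_support, down=down)


def normal_bias_filter(gene: str, comparisons: list[DEGComparison], fdr: float = 0.25) -> bool:
    """Keep a gene unless it is significantly up in normal cells more often
    than in tumor cells across all comparisons in which it appears.

    A significant comparison with log2FC > 0 favors tumor; log2FC < 0
    favors normal (tumor-vs-normal orientation). Ties keep the gene.
    """
    tumor = normal = 0
    for comp in comparisons:
        sig = _significant(comp.table, fdr)
        rows = sig[sig["gene"] == gene]
        tumor += int((rows["log2fc"] > 0).sum())
        normal += int((rows["log2fc"] < 0).sum())
    return not normal > tumor


def read_comparisons(path) -> list[DEGComparison]:
    """Read a combined comparison TSV (gene, log2fc, padj, comparison,
    ref_class) into per-comparison objects."""
    df = pd.read_csv(path, sep="\t")
    missing = set(COMPARISON_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"comparison table missing columns: {sorted(missing)}")
    out = []
    for (cid, cls), grp in df.groupby(["comparison", "ref_class"], sort=True):
        out.append(
            DEGComparison(
                comparison_id=str(cid),
                ref_class=str(cls),
                table=grp[["gene", "log2fc", "padj"]].reset_index(drop=True),
            )
        )
    return out


def collapse_transcripts(calls: DEGCallSet) -> DEGCallSet:
    """Collapse suffixed alternative-transcript rows (GENE.1, GENE.2, ...)
    onto the parent symbol, keeping the union of supporting comparisons
    (max-evidence reporting rule)."""

    def collapse(d: dict[str, list[str]]) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for g, ids in d.items():
            parent = g.rsplit(".", 1)[0] if "." in g and g.rsplit(".", 1)[1].isdigit() else g
            out.setdefault(parent, [])
            out[parent] = sorted(set(out[parent]) | set(ids))
        return out

    return DEGCallSet(histotype=calls.histotype, up=collapse(calls.up), down=collapse(calls.down))
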