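"""Target Priority Indices: H_RNA, validation scores, and TPI ranking.

Every TPI is a sum of min-max-normalized components over the pool of
nominated targets in one histotype:

    TPI_CAR      = TS_CAR(norm)    + V_CAR(norm)            in [0, 2]
    TPI_gate     = mean-TS(norm)   + V_CAR(norm)            in [0, 2]
    TPI_TCR/PC   = N(g)(norm) + V_TCR/PC(norm) + HLA_TOT(norm)
                   + pMHC_TOT(norm) + pMHC_SCR(norm)        in [0, 5]

The validation scores V_CAR (eight evidence items, max 10) and V_TCR/PC
(six items, max 7) combine expression homogeneity, proteomics support,
prior therapeutic development, cell-line essentiality, and recurrent
genomic lesions, each drawn from closed class vocabularies in the
evidence table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

THREE_LEVEL = {"histotype": 1.0, "any": 0.5, "none": 0.0}
DEV_LEVEL = {"clinical": 1.0, "preclinical": 0.5, "none": 0.0}
#: CNA classes: correlated = in-histotype CNA with positive CNA-RNA correlation.
CNA_LEVEL = {"correlated": 1.0, "histotype": 0.5, "none": 0.0}

V_CAR_MAX = 10.0
V_TCR_PC_MAX = 7.0


@dataclass
class EvidenceTable:
    """Per-gene validation evidence with closed class vocabularies."""

    table: pd.DataFrame

    FIELDS = {
        "essentiality": THREE_LEVEL,
        "fusion": THREE_LEVEL,
        "snv": THREE_LEVEL,
        "cna": CNA_LEVEL,
        "antibody": DEV_LEVEL,
        "car": DEV_LEVEL,
    }

    def __post_init__(self) -> None:
        for col, vocab in self.FIELDS.items():
            if col in self.table.columns:
                bad = set(self.table[col].dropna()) - set(vocab)
                if bad:
                    raise ValueError(f"unknown {col} class(es): {sorted(bad)}")

    def level(self, gene: str, col: str) -> float:
        vocab = self.FIELDS[col]
        if gene not in self.table.index or col not in self.table.columns:
            warnings.warn(f"missing evidence {col!r} for {gene}; scored as none")
            return 0.0
        val = self.table.loc[gene, col]
        if pd.isna(val):
            warnings.warn(f"missing evidence {col!r} for {gene}; scored as none")
            return 0.0
        return vocab[val]

    def numeric(self, gene: str, col: str) -> float:
        if gene not in self.table.index or col not in self.table.columns:
            return np.nan
        return float(self.table.loc[gene, col])


def h_rna(cell_expr: np.ndarray) -> float:
    """Expression homogeneity: mean log2(CPM+1) times percent positive cells."""
    arr = np.asarray(cell_expr, dtype=float)
    if arr.size == 0:
        raise ValueError("no tumor cells")
    return float(arr.mean() * (arr > 0).mean() * 100.0)


def v_car(
    gene: str,
    evidence: EvidenceTable,
    h_rna_value: float,
    h_rna_reference: float,
    proteomics_mh_pct: float,
    proteomics_mh_reference: float,
) -> float:
    """Eight-item validation score for CAR-T targets, range [0, 10].

    2 points each for expression homogeneity and clinical-proteomics
    support at or above the reference target's values; 1 / 0.5 / 0 for
    each of antibody development, CAR development, essentiality, fusions,
    SNVs/indels, and CNAs.
    """
    score = 0.0
    score += 2.0 if h_rna_value >= h_rna_reference else 0.0
    score += 2.0 if proteomics_mh_pct >= proteomics_mh_reference else 0.0
    for col in ("antibody", "car", "essentiality", "fusion", "snv", "cna"):
        score += evidence.level(gene, col)
    return score


def v_tcr_pc(
    gene: str,
    evidence: EvidenceTable,
    h_rna_value: float,
    h_rna_reference: float,
    cellline_protein_support: bool,
) -> float:
    """Six-item validation score for TCR-T / PC-CAR-T antigens, range [0, 7].

    2 for homogeneity at/above the reference antigen, 1 for protein
    detection (z >= 0) in at least two tumor cell lines, plus the four
    genomic evidence items.
    """
    score = 2.0 if h_rna_value >= h_rna_reference else 0.0
    score += 1.0 if cellline_protein_support else 0.0
    for col in ("essentiality", "fusion", "snv", "cna"):
        score += evidence.level(gene, col)
    return score


def minmax(values: pd.Series) -> pd.Series:
    """(x - min) / (max - min); degenerate pools map to 0 with a warning."""
    lo, hi = values.min(), values.max()
    if len(values) < 2 or hi == lo:
        warnings.warn("degenerate normalization pool; normalized values set to 0")
        return values * 0.0
    return (values - lo) / (hi - lo)


def tpi_car(ts_values: pd.Series, v_values: pd.Series) -> pd.DataFrame:
    """TPI for monospecific CAR-T targets, stable-ranked descending."""
    ts_n = minmax(ts_values)
    v_n = minmax(v_values.reindex(ts_values.index))
    tpi = ts_n + v_n
    out = pd.DataFrame(
        {"ts_norm": ts_n, "v_norm": v_n, "tpi": tpi}
    ).sort_values("tpi", ascending=False, kind="stable")
    return out


def mean_ts_per_gene(pair_scores: pd.DataFrame, mode: str) -> pd.Series:
    """Average TS over all selected pairs in which a gene appears.

    For "AND" pairs both members count; for "AND-NOT" only the activator
    (first member).
    """
    sel = pair_scores[pair_scores["selected"]]
    if sel.empty:
        raise ValueError("no selected pairs")
    col = "ts" if "ts" in sel.columns else "norm"
    sums: dict[str, list[float]] = {}
    for (a, b), row in sel.iterrows():
        genes = (a, b) if mode == "and" else (a,)
        for g in genes:
            sums.setdefault(g, []).append(row[col])
    return pd.Series({g: float(np.mean(v)) for g, v in sums.items()})


def tpi_gate(pair_scores: pd.DataFrame, v_values: pd.Series, mode: str) -> pd.DataFrame:
    """TPI for logic-gated targets from their per-gene mean TS."""
    return tpi_car(mean_ts_per_gene(pair_scores, mode), v_values)


def hla_tot(records: pd.DataFrame) -> float:
    """Sum over loci of the mean allele frequency of an antigen's pMHCs.

    ``records`` needs columns allele and f_allele; the locus is the
    letter before the '*'. Loci with no pMHC contribute 0.
    """
    total = 0.0
    for locus in ("A", "B", "C"):
        at = records[records["allele"].str.startswith(locus)]
        if len(at):
            total += float(at["f_allele"].mean())
    return total


def tpi_tcr_pc(
    n_scores: pd.Series,
    v_values: pd.Series,
    candidate_pmhcs: pd.DataFrame,
    acceptable_pmhcs: set[str],
    protein_lengths: pd.Series,
) -> pd.DataFrame:
    """Five-component TPI for TCR-T / PC-CAR-T antigens.

    candidate_pmhcs: one row per retained pMHC with columns antigen,
    peptide, allele, f_allele; acceptable_pmhcs: ids "peptide|allele" with
    S_CR Diff <= 0; protein_lengths: amino acids per antigen.
    """
    antigens = n_scores.index
    hla, n_tot, n_scr = {}, {}, {}
    for g in antigens:
        recs = candidate_pmhcs[candidate_pmhcs["antigen"] == g]
        L = float(protein_lengths.get(g, np.nan))
        if not L > 0:
            raise ValueError(f"missing protein length for {g}")
        hla[g] = hla_tot(recs)
        n_tot[g] = len(recs) / L
        ids = recs["peptide"] + "|" + recs["allele"]
        n_scr[g] = int(ids.isin(acceptable_pmhcs).sum()) / L
    comp = pd.DataFrame(
        {
            "n_norm": minmax(n_scores),
            "v_norm": minmax(v_values.reindex(antigens)),
            "hla_tot_norm": minmax(pd.Series(hla)),
            "pmhc_tot_norm": minmax(pd.Series(n_tot)),
            "pmhc_scr_norm": minmax(pd.Series(n_scr)),
        }
    )
    comp["hla_tot"] = pd.Series(hla)
    comp["pmhc_tot"] = pd.Series(n_tot)
    comp["pmhc_scr"] = pd.Series(n_scr)
    comp["tpi"] = comp[
        ["n_norm", "v_norm", "hla_tot_norm", "pmhc_tot_norm", "pmhc_scr_norm"]
    ].sum(axis=1)
    return comp.sort_values("tpi", ascending=False, kind="stable")
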