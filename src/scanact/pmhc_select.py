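"""TCR-T / peptide-centric CAR-T antigen and pMHC candidate nomination.

Intracellular (and surface) tumor-upregulated genes are benchmarked
against cancer germline antigens already in clinical TCR-T development:
the summative score N(g) awards +1 per bulk RNA panel, +2 per protein
panel, and +1.5 for the normal single-cell panel whenever the candidate
stays below the reference maximum everywhere in that panel (no penalty
branch; absent genes score 0; maximum 9.5). Peptides of length 9 and 10
are enumerated from each retained antigen, and each peptide-allele pair is
scored as

    TS_TCR/PC = (S_presentation + S_immunogenicity) * (1 + F_allele)

with predictor scores consumed from tables and F_allele the
population-size-weighted world allele frequency.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import SeqIO

from .core_io import ExpressionPanel, ReferenceTargetSet, quantile

STANDARD_RESIDUES = set("ACDEFGHIKLMNPQRSTVWY")

#: Dataset tags -> N(g) weights (bulk RNA 1, protein 2, single-cell 1.5).
N_SCORE_WEIGHTS = {
    "hpa_rna": 1.0,
    "gtex_rna": 1.0,
    "hpa_ihc": 2.0,
    "gtex_prot": 2.0,
    "hpm": 2.0,
    "sc": 1.5,
}

N_SCORE_MAX = sum(N_SCORE_WEIGHTS.values())  # 9.5


@dataclass
class AntigenScore:
    gene: str
    t_scores: dict[str, float]
    n_score: float
    high_expression: bool = False
    relaxed: bool = False


@dataclass
class PMHCRecord:
    """One peptide-allele pair with predictor scores and targetability."""

    antigen: str
    peptide: str
    allele: str
    s_hlathena: float
    s_deepimmuno: float
    f_allele: float
    ts: float
    cumfreq_rank: int = 0
    selected: bool = False

    def __post_init__(self) -> None:
        if len(self.peptide) not in (9, 10):
            raise ValueError("peptides must be 9 or 10 residues")
        if set(self.peptide) - STANDARD_RESIDUES:
            raise ValueError(f"nonstandard residues in {self.peptide!r}")


def n_score(
    gene: str,
    panels: dict[str, ExpressionPanel],
    references: ReferenceTargetSet,
) -> AntigenScore:
    """N(g): per-dataset comparison of the candidate to the reference
    cancer germline antigens' per-column maxima.

    +weight when the candidate is below the reference maximum in every
    column of the dataset; 0 when it exceeds it anywhere, or is absent.
    """
    t_scores: dict[str, float] = {}
    for tag, panel in panels.items():
        w = N_SCORE_WEIGHTS[tag]
        z = panel.values
        refs = [g for g in references.genes if g in z.index]
        if not refs:
            warnings.warn(f"no reference antigens in dataset {tag!r}; scores 0")
            t_scores[tag] = 0.0
            continue
        if gene not in z.index:
            t_scores[tag] = 0.0
            continue
        ref_max = z.loc[refs].max(axis=0)
        vals = z.loc[gene]
        ok = ((vals < ref_max) | vals.isna()).all()
        t_scores[tag] = w if bool(ok) else 0.0
    return AntigenScore(gene=gene, t_scores=t_scores, n_score=sum(t_scores.values()))


def tcr_high_expression_filter(
    genes: list[str],
    sc_expr: pd.Series,
    bulk_expr: pd.Series,
    cellline_expr: pd.Series,
    n_scores: dict[str, float],
    pct: float = 25.0,
    n_cutoff: float = 3.5,
) -> pd.DataFrame:
    """Primary and relaxed high-expression flags for antigen candidates.

    Primary: single-cell expression at/above the pool's 25th percentile
    together with either the bulk cohort or the cell-line panel also
    at/above theirs (or both externals missing). Relaxed: N(g) >= 3.5 and
    the single-cell criterion alone.
    """
    sc = sc_expr.reindex(genes)
    bulk = bulk_expr.reindex(genes)
    line = cellline_expr.reindex(genes)
    q_sc = quantile(sc.dropna(), pct)
    q_bulk = quantile(bulk.dropna(), pct) if bulk.notna().any() else np.nan
    q_line = quantile(line.dropna(), pct) if line.notna().any() else np.nan
    rows = []
    for g in genes:
        sc_hi = pd.notna(sc[g]) and sc[g] >= q_sc
        bulk_hi = pd.notna(bulk[g]) and bulk[g] >= q_bulk
        line_hi = pd.notna(line[g]) and line[g] >= q_line
        primary = sc_hi and (
            bulk_hi or line_hi or (pd.isna(bulk[g]) and pd.isna(line[g]))
        )
        relaxed = sc_hi and n_scores.get(g, 0.0) >= n_cutoff
        rows.append({"gene": g, "primary": primary, "relaxed": relaxed})
    return pd.DataFrame(rows).set_index("gene")


def enumerate_peptides_from_sequence(
    seq: str, lengths: tuple[int, ...] = (9, 10)
) -> dict[str, list[int]]:
    """Sliding 9/10-mer windows of one sequence, deduplicated with their
    0-based start positions; windows with nonstandard residues skipped."""
    seq = seq.upper()
    peptides: dict[str, list[int]] = {}
    for L in lengths:
        for start in range(max(len(seq) - L + 1, 0)):
            window = seq[start : start + L]
            if set(window) - STANDARD_RESIDUES:
                continue
            peptides.setdefault(window, []).append(start)
    return peptides


def enumerate_peptides(
    fasta_path, lengths: tuple[int, ...] = (9, 10)
) -> dict[str, dict[str, list[int]]]:
    """All 9-mer and 10-mer windows per antigen, deduplicated with their
    start positions (0-based). Windows containing nonstandard residues are
    skipped with a warning; sequences shorter than the window yield none.
    """
    out: dict[str, dict[str, list[int]]] = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        seq = str(rec.seq).upper()
        if len(seq) < min(lengths):
            warnings.warn(f"{rec.id}: sequence shorter than {min(lengths)}")
        n_windows = sum(max(len(seq) - L + 1, 0) for L in lengths)
        peptides = enumerate_peptides_from_sequence(seq, lengths)
        n_kept = sum(len(v) for v in peptides.values())
        if n_kept < n_windows:
            warnings.warn(
                f"{rec.id}: skipped {n_windows - n_kept} windows with nonstandard residues"
            )
        out[rec.id] = peptides
    return out


def world_allele_frequency(table: pd.DataFrame) -> pd.Series:
    """Combine population allele frequencies into a world frequency.

    Within each country, population frequencies are averaged unweighted;
    across countries, the mean is weighted by country population size.
    Countries missing a population size are dropped with a warning.
    Expects columns: allele, population, frequency, country, population_size.
    """
    req = {"allele", "frequency", "country", "population_size"}
    missing = req - set(table.columns)
    if missing:
        raise ValueError(f"allele frequency table missing columns {sorted(missing)}")
    bad = ((table["frequency"] < 0) | (table["frequency"] > 1)).any()
    if bad:
        raise ValueError("allele frequencies outside [0, 1]")
    out = {}
    for allele, grp in table.groupby("allele"):
        per_country = grp.groupby("country").agg(
            f=("frequency", "mean"), size=("population_size", "first")
        )
        usable = per_country[per_country["size"].notna() & (per_country["size"] > 0)]
        if len(usable) < len(per_country):
            warnings.warn(f"{allele}: countries without population size dropped")
        if usable.empty:
            continue
        out[allele] = float(
            np.average(usable["f"], weights=usable["size"])
        )
    return pd.Series(out, name="f_allele")


def ts_tcr_pc(s_hlathena: float, s_deepimmuno: float, f_allele: float) -> float:
    """(S_presentation + S_immunogenicity) * (1 + F_allele)."""
    return (s_hlathena + s_deepimmuno) * (1.0 + f_allele)


def build_pmhc_records(
    antigen: str,
    peptides: list[str],
    predictor_scores: pd.DataFrame,
    allele_freqs: pd.Series,
) -> list[PMHCRecord]:
    """Join peptides with predictor score tables keyed by (peptide, allele).

    Records missing either predictor score are excluded with a warning.
    Expects columns: peptide, allele, s_hlathena, s_deepimmuno.
    """
    scores = predictor_scores.set_index(["peptide", "allele"])
    records = []
    dropped = 0
    for pep in peptides:
        if pep not in scores.index.get_level_values(0):
            continue
        for allele, row in scores.loc[pep].iterrows():
            if pd.isna(row["s_hlathena"]) or pd.isna(row["s_deepimmuno"]):
                dropped += 1
                continue
            f = float(allele_freqs.get(allele, np.nan))
            if np.isnan(f):
                dropped += 1
                continue
            records.append(
                PMHCRecord(
                    antigen=antigen,
                    peptide=pep,
                    allele=allele,
                    s_hlathena=float(row["s_hlathena"]),
                    s_deepimmuno=float(row["s_deepimmuno"]),
                    f_allele=f,
                    ts=ts_tcr_pc(row["s_hlathena"], row["s_deepimmuno"], f),
                )
            )
    if dropped:
        warnings.warn(f"{antigen}: {dropped} pMHC records dropped (missing scores)")
    return records


def select_candidate_pmhcs(
    records: list[PMHCRecord],
    k_peptides: int = 5,
    ts_pct: float = 99.0,
    hlathena_min: float = 0.85,
    global_ts_pool: list[float] | None = None,
) -> list[PMHCRecord]:
    """Retain pMHCs for cross-reactivity assessment.

    Three intersected criteria: the parent peptide ranks in the top
    ``k_peptides`` by cumulative allele frequency (ties at the boundary all
    kept); TS_TCR/PC at or above the pool's 99th percentile (per antigen by
    default, or against ``global_ts_pool``); presentation score at or
    above ``hlathena_min``.
    """
    if not records:
        return []
    cumfreq: dict[str, float] = {}
    for r in records:
        cumfreq[r.peptide] = cumfreq.get(r.peptide, 0.0) + r.f_allele
    ordered = sorted(set(cumfreq.values()), reverse=True)
    boundary = ordered[min(k_peptides, len(ordered)) - 1]
    top_peptides = {p for p, f in cumfreq.items() if f >= boundary}
    ranks = {
        p: i + 1
        for i, (p, _) in enumerate(
            sorted(cumfreq.items(), key=lambda kv: -kv[1])
        )
    }
    pool = global_ts_pool if global_ts_pool is not None else [r.ts for r in records]
    ts_cut = quantile(pool, ts_pct)
    out = []
    for r in records:
        r.cumfreq_rank = ranks[r.peptide]
        r.selected = (
            r.peptide in top_peptides
            and r.ts >= ts_cut
            and r.s_hlathena >= hlathena_min
        )
        if r.selected:
            out.append(r)
    return out


def records_frame(records: list[PMHCRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "antigen": r.antigen,
                "peptide": r.peptide,
                "allele": r.allele,
                "s_hlathena": r.s_hlathena,
                "s_deepimmuno": r.s_deepimmuno,
                "f_allele": r.f_allele,
                "ts": r.ts,
                "cumfreq_rank": r.cumfreq_rank,
                "selected": r.selected,
            }
            for r in records
        ]
    )
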