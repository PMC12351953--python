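"""PS-TRACT: peptide-MHC cross-reactivity assessment.

Given a tumoral peptide-MHC pair, the module scores its similarity to
every normal peptide presented on the same allele (entropy-weighted
substitution similarity S_sim, combining a binding-energy-covariance
matrix and a physicochemical residue embedding), flags normal peptides
with S_sim > 1.15 as potentially cross-reactive, scores each of those per
normal tissue

    S_CR = (presentation + 0.5) * E_tissue * (1.25 if observed else 1)

where E is the median-centered z-scored consensus expression of the
peptide's parent antigen, takes the per-tissue maximum as the tumoral
pMHC's cross-reactivity profile, and benchmarks that profile against a
clinically tolerated reference pMHC with a penalized mean difference
(excursions above the reference weigh alpha = 2 times excursions below).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import ExpressionPanel

RESIDUES = list("ACDEFGHIKLMNPQRSTVWY")

ALLELE_RE = re.compile(r"^(?:HLA-)?([ABC])\*\d{2}:\d{2}$")

LIGANDOME_COLUMNS = [
    "peptide",
    "allele",
    "parent",
    "length",
    "source",
    "presentation_score",
    "affinity_percentile",
]


@dataclass
class ResidueSubstitutionModel:
    """Residue substitution similarity (20x20) and 9-D embedding (20x9).

    ``pmbec`` holds a symmetric similarity matrix; distances are derived
    as max(matrix) - matrix. ``embedding`` holds one row per residue; the
    embedding distance is Euclidean.
    """

    pmbec: pd.DataFrame
    embedding: pd.DataFrame

    def __post_init__(self) -> None:
        m = self.pmbec
        if not np.allclose(m.to_numpy(), m.to_numpy().T):
            raise ValueError("substitution matrix must be symmetric")
        self._max = float(m.to_numpy().max())

    def dist_pmbec(self, a: str, b: str) -> float:
        return self._max - float(self.pmbec.loc[a, b])

    def dist_embedding(self, a: str, b: str) -> float:
        d = self.embedding.loc[a].to_numpy() - self.embedding.loc[b].to_numpy()
        return float(np.sqrt((d * d).sum()))

    @classmethod
    def from_tsv(cls, pmbec_path, embedding_path) -> "ResidueSubstitutionModel":
        pm = pd.read_csv(pmbec_path, sep="\t", index_col=0)
        em = pd.read_csv(embedding_path, sep="\t", index_col=0)
        return cls(pmbec=pm, embedding=em)


@dataclass
class LigandomeIndex:
    """Unified normal ligandome with per-(allele, length) entropy vectors."""

    records: pd.DataFrame  # LIGANDOME_COLUMNS
    entropies: dict[tuple[str, int], np.ndarray] = field(default_factory=dict)

    def peptides(self, allele: str, length: int) -> pd.DataFrame:
        r = self.records
        return r[(r["allele"] == allele) & (r["length"] == length)]

    def entropy(self, allele: str, length: int) -> np.ndarray:
        key = (allele, length)
        if key not in self.entropies:
            peps = self.peptides(allele, length)["peptide"].tolist()
            self.entropies[key] = residue_entropy(peps, length)
        return self.entropies[key]


def normalize_allele(allele: str) -> str | None:
    """Accept only four-digit class I allele names; canonical short form."""
    m = ALLELE_RE.match(allele.strip())
    if not m:
        return None
    return allele.strip().removeprefix("HLA-")


def build_ligandome_index(
    observed: pd.DataFrame,
    predicted: pd.DataFrame,
    presentation_floor: float = 0.5,
    affinity_percentile_max: float = 2.0,
) -> LigandomeIndex:
    """Merge observed and predicted normal ligandomes.

    Predictions are filtered to affinity percentile < 2.0; records with
    presentation score <= 0.5 are removed unless the (peptide, allele)
    appears in the observed ligandome. Records are deduplicated on
    (peptide, allele, parent); only 9/10-mers with valid four-digit
    alleles are kept.
    """

    def clean(df: pd.DataFrame, source: str) -> pd.DataFrame:
        df = df.copy()
        df["source"] = source
        df["allele"] = df["allele"].map(lambda a: normalize_allele(str(a)))
        dropped = df["allele"].isna().sum()
        if dropped:
            warnings.warn(f"{source}: {dropped} records with non-4-digit alleles dropped")
        df = df[df["allele"].notna()]
        df["length"] = df["peptide"].str.len()
        return df[df["length"].isin([9, 10])]

    obs = clean(observed, "observed")
    pred = clean(predicted, "predicted")
    if "affinity_percentile" in pred.columns:
        pred = pred[pred["affinity_percentile"] < affinity_percentile_max]
    observed_keys = set(zip(obs["peptide"], obs["allele"]))
    keep = pred.apply(
        lambda r: r["presentation_score"] > presentation_floor
        or (r["peptide"], r["allele"]) in observed_keys,
        axis=1,
    )
    pred = pred[keep] if len(pred) else pred
    parts = [df for df in (obs, pred) if len(df)]
    if not parts:
        empty = pd.DataFrame(columns=LIGANDOME_COLUMNS)
        return LigandomeIndex(records=empty)
    unified = pd.concat(parts, ignore_index=True)
    for col in ("presentation_score", "affinity_percentile"):
        if col not in unified.columns:
            unified[col] = np.nan
    # observed records take precedence in deduplication
    unified["_order"] = (unified["source"] != "observed").astype(int)
    unified = (
        unified.sort_values("_order")
        .drop_duplicates(subset=["peptide", "allele", "parent"], keep="first")
        .drop(columns="_order")
        .reset_index(drop=True)
    )
    return LigandomeIndex(records=unified[LIGANDOME_COLUMNS])


def residue_entropy(peptides: list[str], length: int) -> np.ndarray:
    """Normalized Shannon entropy per peptide position, in [0, 1].

    Natural-log entropy of the residue distribution divided by log(20);
    the base cancels under normalization. Fewer than two peptides give an
    all-zero vector with a warning.
    """
    peps = [p for p in peptides if len(p) == length]
    if len(peps) < 2:
        warnings.warn("fewer than 2 peptides; entropy vector set to 0")
        return np.zeros(length)
    out = np.zeros(length)
    for i in range(length):
        counts = pd.Series([p[i] for p in peps]).value_counts().to_numpy()
        freqs = counts / counts.sum()
        out[i] = -(freqs * np.log(freqs)).sum() / np.log(20.0)
    return out


def _sim_component(
    pt: str, pn: str, entropy: np.ndarray, dist
) -> float:
    """Mean over positions of (1 / (1 + dist)) * (1 + H_i)."""
    L = len(pt)
    total = 0.0
    for i in range(L):
        total += (1.0 / (1.0 + dist(pt[i], pn[i]))) * (1.0 + entropy[i])
    return total / L


def s_sim(
    tumoral: str,
    normals: list[str],
    model: ResidueSubstitutionModel,
    entropy: np.ndarray,
) -> pd.Series:
    """S_sim of a tumoral peptide against a pool of normal peptides.

    Both similarity components (substitution-matrix based and
    embedding based) are min-max scaled within the comparison pool and
    summed, giving values in [0, 2] with 2 for the pool's most similar
    peptide on both components.
    """
    if not normals:
        raise ValueError("empty comparison pool")
    same_len = sorted({p for p in normals if len(p) == len(tumoral)})
    if not same_len:
        raise ValueError("no normal peptides of matching length in pool")
    comp1 = np.array(
        [_sim_component(tumoral, pn, entropy, model.dist_pmbec) for pn in same_len]
    )
    comp2 = np.array(
        [_sim_component(tumoral, pn, entropy, model.dist_embedding) for pn in same_len]
    )

    def scale(x: np.ndarray) -> np.ndarray:
        lo, hi = x.min(), x.max()
        if hi == lo:
            return np.zeros_like(x)
        return (x - lo) / (hi - lo)

    return pd.Series(scale(comp1) + scale(comp2), index=same_len)


def s_cr(
    normal_record: pd.Series,
    expression_panel: ExpressionPanel,
    observed_boost: float = 1.25,
    presentation_offset: float = 0.5,
) -> pd.Series | None:
    """Per-tissue cross-reactivity score of one normal pMHC record.

    (presentation + 0.5) * E_tissue * (1.25 if observed else 1), where E
    is the consensus z-scored expression of the record's parent antigen.
    Records whose parent is absent from the panel are skipped.
    """
    parent = normal_record["parent"]
    if parent not in expression_panel.values.index:
        warnings.warn(f"parent antigen {parent!r} absent from consensus panel")
        return None
    e = expression_panel.values.loc[parent]
    p = normal_record["presentation_score"]
    p = 0.0 if pd.isna(p) else float(p)
    boost = observed_boost if normal_record["source"] == "observed" else 1.0
    return (p + presentation_offset) * e * boost


@dataclass
class CrossReactivityProfile:
    pmhc_id: str
    scores: pd.Series  # per tissue
    no_crossreactive: bool = False
    s_cr_diff: float | None = None
    acceptable: bool | None = None


def cr_profile(
    pmhc_id: str,
    crossreactive_records: pd.DataFrame,
    expression_panel: ExpressionPanel,
    floor: float = 0.0,
) -> CrossReactivityProfile:
    """Per-tissue maximum S_CR over the filtered cross-reactive pMHCs.

    With no cross-reactive peptide the profile is the configured floor in
    every tissue and is flagged (no detected risk, not evidence of
    absence).
    """
    tissues = expression_panel.values.columns
    vectors = []
    for _, rec in crossreactive_records.iterrows():
        v = s_cr(rec, expression_panel)
        if v is not None:
            vectors.append(v)
    if not vectors:
        return CrossReactivityProfile(
            pmhc_id, pd.Series(floor, index=tissues), no_crossreactive=True
        )
    return CrossReactivityProfile(pmhc_id, pd.concat(vectors, axis=1).max(axis=1))


def s_cr_diff(
    profile: pd.Series,
    reference_profile: pd.Series,
    all_profiles: list[pd.Series],
    alpha: float = 2.0,
) -> tuple[float, bool]:
    """Penalized mean difference of a profile against the reference.

    Per tissue j, (delta / sigma_j) * alpha when the candidate exceeds the
    reference, delta / sigma_j otherwise, averaged over tissues; sigma_j
    is the standard deviation of all profiles (candidates + reference) in
    tissue j, and zero-sigma tissues are excluded from the mean with a
    warning. Acceptable risk at S_CR Diff <= 0.
    """
    if reference_profile.reindex(profile.index).isna().any():
        raise ValueError("reference profile missing tissues")
    mat = pd.concat(all_profiles, axis=1)
    sigma = mat.std(axis=1, ddof=1)
    terms = []
    excluded = 0
    for j in profile.index:
        if sigma[j] == 0 or np.isnan(sigma[j]):
            excluded += 1
            continue
        delta = (profile[j] - reference_profile[j]) / sigma[j]
        terms.append(delta * alpha if delta > 0 else delta)
    if excluded:
        warnings.warn(f"{excluded} tissues with zero score variance excluded")
    if not terms:
        raise ValueError("no tissues with nonzero score variance")
    value = float(np.mean(terms))
    return value, value <= 0


def assess_pmhc(
    pmhc_id: str,
    tumoral_peptide: str,
    allele: str,
    index: LigandomeIndex,
    model: ResidueSubstitutionModel,
    expression_panel: ExpressionPanel,
    s_sim_cutoff: float = 1.15,
) -> tuple[CrossReactivityProfile, pd.Series]:
    """Similarity screen + cross-reactivity profile for one tumoral pMHC."""
    length = len(tumoral_peptide)
    pool = index.peptides(allele, length)
    if pool.empty:
        raise ValueError(f"no normal ligandome for {allele} {length}-mers")
    entropy = index.entropy(allele, length)
    sims = s_sim(tumoral_peptide, pool["peptide"].tolist(), model, entropy)
    crossreactive = pool[pool["peptide"].map(sims) > s_sim_cutoff]
    profile = cr_profile(pmhc_id, crossreactive, expression_panel)
    return profile, sims
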