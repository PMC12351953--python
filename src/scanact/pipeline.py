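"""End-to-end orchestration of the target-discovery stages.

Stage order: simulate (or ingest) inputs -> malignant-cell classification
-> differential-expression aggregation -> monospecific CAR scoring ->
logic-gated pair scoring -> pMHC nomination -> cross-reactivity -> target
priority indices. Every stage writes TSV outputs into the run directory
and the run ends with a content-addressed JSON manifest (seed,
configuration, and sha256 of every output), so deterministic reruns
produce bit-identical manifests.
"""

from __future__ import annotations

import hashlib
import itertools
import json
import warnings
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import deg_calls, gate_pairs, malignancy, mono_car, pmhc_select, prioritize, pstract
from .core_io import ExpressionPanel
from .synthfix import (
    SimSpec,
    gen_cohort,
    gen_deg_tables,
    gen_evidence_table,
    gen_ligandome,
    gen_normal_panels,
    gene_layout,
)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(spec: SimSpec, out_dir: str | Path) -> dict:
    """Run every stage on a synthetic study and write outputs + manifest.

    Returns a dict of in-memory stage results (useful for tests and for
    the acceptance script).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {"spec": spec}

    layout = gene_layout(spec)
    cohort = gen_cohort(spec, layout)
    panels = gen_normal_panels(spec, layout)
    deg_table = gen_deg_tables(spec, layout)
    lig = gen_ligandome(spec, layout)
    evidence_df = gen_evidence_table(spec, layout.genes)
    results.update(layout=layout, cohort=cohort, panels=panels, ligandome=lig)

    # ---- malignancy ------------------------------------------------------
    call = malignancy.call_sample(
        cohort.cells, cohort.states, cohort.bulk_reference, cohort.normal_reference
    )
    call_df = call.to_frame()
    call_df.to_csv(out / "malignancy_calls.tsv", sep="\t", index=False)
    truth = cohort.truth
    tumor_mask_truth = (truth == "tumor").to_numpy()
    recall = float(call.malignant[tumor_mask_truth].mean())
    fpr = float(call.malignant[~tumor_mask_truth].mean())
    results["malignancy"] = {"call": call, "recall": recall, "fpr": fpr}

    # ---- differential expression -----------------------------------------
    tmp = out / "deg_comparisons.tsv"
    deg_table.to_csv(tmp, sep="\t", index=False)
    comparisons = deg_calls.read_comparisons(tmp)
    calls = deg_calls.aggregate_deg_calls(comparisons, histotype="synthetic")
    up = [g for g in calls.up if deg_calls.normal_bias_filter(g, comparisons)]
    down = list(calls.down)
    calls.to_frame().to_csv(out / "deg_calls.tsv", sep="\t", index=False)
    results["deg"] = {"calls": calls, "up": up, "down": down}

    # ---- expression summaries used by several stages ---------------------
    malignant_mask = call.malignant
    log_cpm = cohort.cells.log2_cpm()
    tumor_cells_expr = log_cpm[:, malignant_mask]
    sc_mean = pd.Series(tumor_cells_expr.mean(axis=1), index=cohort.cells.genes)
    bulk_log = np.log2(cohort.bulk_reference.values + 1.0)
    bulk_mean = bulk_log.mean(axis=1)
    cellline_mean = bulk_mean  # single synthetic cohort stands in for lines
    surfaceome = set(
        layout.signature + layout.and_pool + layout.activators + layout.inhibitors
    )

    # ---- monospecific CAR ------------------------------------------------
    candidates = [g for g in up if g in surfaceome]
    high = mono_car.high_expression_filter(candidates, sc_mean, bulk_mean, cellline_mean)
    protein_panels = {
        "gtex_prot": panels.z_panels["gtex_prot"],
        "hpm": panels.z_panels["hpm"],
        "hpa_num": panels.z_panels["hpa_ihc"],
    }
    scored = mono_car.score_candidates(
        high,
        panels.categorized,
        panels.z_panels["sc"],
        protein_panels,
        panels.references,
    )
    ref_scored = mono_car.score_candidates(
        layout.references,
        panels.categorized,
        panels.z_panels["sc"],
        protein_panels,
        panels.references,
    )
    ref_scores = [r.ts_car for r in ref_scored.values()]
    selected, cutoff = mono_car.select_mono_targets(
        {g: r.ts_car for g, r in scored.items()}, ref_scores
    )
    for g in selected:
        scored[g].selected = True
    mono_car.results_frame(scored).to_csv(out / "mono_targets.tsv", sep="\t", index=False)
    results["mono"] = {
        "scored": scored,
        "selected": selected,
        "cutoff": cutoff,
        "high": high,
    }

    # ---- logic-gated pairs -----------------------------------------------
    and_pool = [g for g in high if g in set(layout.and_pool)]
    and_pairs = [
        (a, b) for a, b in itertools.combinations(sorted(and_pool), 2)
    ]
    gates_out = {}
    if len(and_pairs) >= 2:
        rho = gate_pairs.tumor_coexpression(
            cohort.cells, and_pool, tumor_mask=malignant_mask, pairs=and_pairs
        )
        raw_n = gate_pairs.normal_coexpression_N(and_pairs, panels.z_panels)
        and_scores = gate_pairs.ts_and(rho, gate_pairs.n_norm(raw_n))
        and_scores.to_csv(out / "and_pairs.tsv", sep="\t")
        gates_out["and"] = and_scores
    inhibitors = gate_pairs.inhibitor_pool(down, surfaceome, sc_mean)
    activators = [g for g in high if g in set(layout.activators)]
    andnot_pairs = [(a, i) for a in activators for i in inhibitors]
    if len(andnot_pairs) >= 2:
        andnot_scores = gate_pairs.ts_and_not(andnot_pairs, panels.z_panels)
        andnot_scores.to_csv(out / "andnot_pairs.tsv", sep="\t")
        gates_out["andnot"] = andnot_scores
    results["gates"] = gates_out

    # ---- pMHC nomination --------------------------------------------------
    antigens = list(lig.antigens)
    n_scores = {
        g: pmhc_select.n_score(g, panels.z_panels, panels.cga_references)
        for g in antigens
    }
    freqs = pmhc_select.world_allele_frequency(lig.allele_frequencies)
    all_records: dict[str, list[pmhc_select.PMHCRecord]] = {}
    candidates_per_antigen: dict[str, list[pmhc_select.PMHCRecord]] = {}
    for g, seq in lig.antigens.items():
        peps = list(
            pmhc_select.enumerate_peptides_from_sequence(seq)
        )
        recs = pmhc_select.build_pmhc_records(g, peps, lig.predictor_scores, freqs)
        all_records[g] = recs
        candidates_per_antigen[g] = pmhc_select.select_candidate_pmhcs(recs)
    flat = [r for recs in all_records.values() for r in recs]
    pmhc_select.records_frame(flat).to_csv(out / "pmhc_records.tsv", sep="\t", index=False)
    results["pmhc"] = {
        "n_scores": n_scores,
        "freqs": freqs,
        "records": all_records,
        "candidates": candidates_per_antigen,
    }

    # ---- cross-reactivity -------------------------------------------------
    index = pstract.build_ligandome_index(lig.observed, lig.predicted)
    ref_pep, ref_allele = lig.reference_pmhc
    ref_profile, _ = pstract.assess_pmhc(
        f"{ref_pep}|{ref_allele}", ref_pep, ref_allele, index, lig.model,
        lig.consensus_panel,
    )
    profiles: dict[str, pstract.CrossReactivityProfile] = {}
    for g, recs in candidates_per_antigen.items():
        for r in recs:
            pid = f"{r.peptide}|{r.allele}"
            if pid in profiles:
                continue
            try:
                prof, _ = pstract.assess_pmhc(
                    pid, r.peptide, r.allele, index, lig.model, lig.consensus_panel
                )
            except ValueError:
                continue
            profiles[pid] = prof
    all_prof = [p.scores for p in profiles.values()] + [ref_profile.scores]
    acceptable: set[str] = set()
    for pid, prof in profiles.items():
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            diff, ok = pstract.s_cr_diff(prof.scores, ref_profile.scores, all_prof)
        prof.s_cr_diff, prof.acceptable = diff, ok
        if ok:
            acceptable.add(pid)
    prof_rows = [
        {
            "pmhc": pid,
            "s_cr_diff": p.s_cr_diff,
            "acceptable": p.acceptable,
            "no_crossreactive": p.no_crossreactive,
        }
        for pid, p in profiles.items()
    ]
    pd.DataFrame(prof_rows).to_csv(out / "crossreactivity.tsv", sep="\t", index=False)
    results["pstract"] = {
        "profiles": profiles,
        "reference": ref_profile,
        "acceptable": acceptable,
    }

    # ---- priority indices -------------------------------------------------
    evidence = prioritize.EvidenceTable(evidence_df)
    gene_idx = {g: i for i, g in enumerate(cohort.cells.genes)}
    tumor_expr = log_cpm[:, tumor_mask_truth]

    def h_of(g: str) -> float:
        return prioritize.h_rna(tumor_expr[gene_idx[g]])

    h_ref = h_of(layout.references[0])
    prot_ref = float(evidence_df.loc[layout.references[0], "proteomics_mh_pct"])
    tpi_out = {}
    if selected:
        v_vals = pd.Series(
            {
                g: prioritize.v_car(
                    g, evidence, h_of(g), h_ref,
                    float(evidence_df.loc[g, "proteomics_mh_pct"]), prot_ref,
                )
                for g in selected
            }
        )
        ts_vals = pd.Series({g: scored[g].ts_car for g in selected})
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            tpi_out["mono"] = prioritize.tpi_car(ts_vals, v_vals)
        tpi_out["mono"].to_csv(out / "tpi_mono.tsv", sep="\t")
    for mode in ("and", "andnot"):
        frame = gates_out.get(mode)
        if frame is None or not frame["selected"].any():
            continue
        gate_genes = sorted(
            {g for pair in frame[frame["selected"]].index for g in (
                pair if mode == "and" else pair[:1]
            )}
        )
        v_vals = pd.Series(
            {
                g: prioritize.v_car(
                    g, evidence, h_of(g), h_ref,
                    float(evidence_df.loc[g, "proteomics_mh_pct"]), prot_ref,
                )
                for g in gate_genes
            }
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            tpi_out[mode] = prioritize.tpi_gate(frame, v_vals, mode)
        tpi_out[mode].to_csv(out / f"tpi_{mode}.tsv", sep="\t")
    # TCR/PC antigens
    h_ref_tcr = h_of(antigens[0])
    n_series = pd.Series({g: s.n_score for g, s in n_scores.items()})
    v_tcr = pd.Series(
        {
            g: prioritize.v_tcr_pc(
                g, evidence, h_of(g), h_ref_tcr,
                bool(evidence_df.loc[g, "cellline_protein_support"]),
            )
            for g in antigens
        }
    )
    cand_frame = pmhc_select.records_frame(
        [r for recs in candidates_per_antigen.values() for r in recs]
    )
    lengths = pd.Series({g: len(seq) for g, seq in lig.antigens.items()})
    if len(cand_frame):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            tpi_out["tcr"] = prioritize.tpi_tcr_pc(
                n_series, v_tcr, cand_frame, acceptable, lengths
            )
        tpi_out["tcr"].to_csv(out / "tpi_tcr.tsv", sep="\t")
    results["tpi"] = tpi_out

    # ---- manifest ---------------------------------------------------------
    outputs = sorted(p for p in out.iterdir() if p.suffix == ".tsv")
    manifest = {
        "command": "run",
        "version": __version__,
        "seed": spec.seed,
        "config": asdict(spec),
        "outputs": {p.name: _sha256(p) for p in outputs},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    results["manifest"] = manifest
    return results
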