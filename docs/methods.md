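# Methods

This note documents the models and procedures implemented in `scanact`,
the conventions fixed where the design was genuinely open, what the
synthetic-study generator does and does not emulate, and known
limitations.

## Malignant-cell classification

Copy-number states come from an external HMM-based caller as a gene ×
cell integer matrix with states 1 (complete allele loss) to 6 (gain of
more than two alleles). State 6 is capped at 5, states are mapped to
((s − 3)/2)² so gains and losses weigh equally and the neutral state
contributes nothing. Per-cell burden is the mean of this matrix over all
genes (genes with neutral state included — the alternative, averaging
only non-neutral genes, changes the ranking little because neutral
entries are zeros). The tumor consensus profile averages the top 10%
(ceil, ties broken by cell order) of CD45⁻ cells by burden; a cell "has
detected CNA" when its Spearman ρ against the profile is strictly above
the 25th percentile (type-7) of all defined ρ in the sample. Cells whose
normalized CNA vector is constant have undefined ρ and are never flagged
— this matters in practice, because reference (non-tumor) cells emerge
from the caller with clean neutral states.

The similarity score is Spearman ρ of the cell's raw counts against the
mean bulk tumor profile minus ρ against the mean normal-cell profile,
over the intersected gene set (≥ 50 genes enforced). Rank-based
correlation makes the score insensitive to the units of either
reference. A cell is malignant iff CD45⁻ (raw *PTPRC* count = 0, no
imputation) and (CNA detected or similarity strictly > 0).

## Differential-expression aggregation

Upstream tests (pseudobulk linear models, distribution tests) are input
tables of (gene, log2FC, adjusted p, comparison id, reference class).
A gene is up if significantly up (log2FC > 0, FDR < 0.25) in ≥ 1
comparison; down if significantly down in ≥ 1 comparison and never
significantly up, the "never up" rule evaluated within each reference
class (tumor-microenvironment vs normal-panel) and the per-class down
lists unioned. A strict-joint option spans both classes. The
normal-bias filter drops a gene when significant comparisons favoring
normal outnumber those favoring tumor (ties keep). The pseudocount
log-fold-change helper uses log2((t + 0.01)/(n + 0.01)). Alternative
transcripts ride along as suffixed rows (`GENE.1`) and are collapsed to
the parent symbol only at reporting, keeping the union of evidence.

## Normalization conventions

- Quantiles: linear interpolation (Hyndman–Fan type 7, numpy default)
  everywhere a percentile is named.
- z-scores: sample SD (n − 1). Panels are median-centered by column
  (the median across genes per tissue/sample) and then z-scored within
  gene rows. Rows constant after centering are zeroed and flagged;
  flagged genes score 0 in correlation-based operations instead of
  propagating NaN.
- Bulk categorization: tissue-group mean log2(TPM+1) ≥ 4 → "M-H",
  boundary inclusive.
- IHC: per-tissue collapse of cell-type categories (ND-L if all
  Not Detected/Low; M-H if all Medium/High; Medium if all Medium;
  Variable otherwise), then tissue-group max by the hierarchy
  M-H > Variable > Medium > ND-L. Numeric recoding Not Detected=1,
  Low=2, Medium=3, High=4.
- "Below" cutoffs are strict (<); "at or above" selections are
  inclusive (≥), matching the wording of each rule.

## Monospecific CAR scoring

The permissive filter counts tissue groups with M-H expression per
categorized panel and passes a candidate when its count is strictly
below the 90th percentile of the reference (clinically tested) targets'
counts. The stringent filters require the candidate to sit strictly
below the per-column reference maximum in every retained column; the
single-cell variant additionally caps the number of cell types with
z > 1 at the references' 75th percentile. Lymphoid, stromal, gonadal and
placental cell types (and reproductive/immune tissues for the protein
panels) are excluded via configurable lists. Verdicts are weighted
±1 (two bulk RNA panels), ±2 (four protein panels), ±1.5 (normal
single-cell panel), absent = 0, giving TS_CAR ∈ [−11.5, 11.5]; the
nomination cutoff is the 25th percentile of the references' own scores
(inclusive ≥), falling back to an explicit configured value when fewer
than four references are available. One immunohistochemistry source
backs two of the four protein datasets (categorical for the permissive
filter, numeric z-scores for the stringent one); the double use is
deliberate and mirrors the weighting scheme.

## Logic-gated pair scoring

Tumor co-expression is a pluggable estimator over the pool of candidate
pairs; the default is Spearman correlation of log2(CPM+1) cell profiles
with the analytic t-approximation p-value (hundreds of cells make this
indistinguishable from resampling at a fraction of the cost), and
dedicated sparse-count co-expression estimates can be ingested from
tables instead. p-values are BH-corrected across all pairs in the run
and non-significant correlations zeroed at α = 0.05.

Normal co-expression: per panel, signed Pearson (negative correlation —
mutual exclusivity — earns +w, positive earns −w) for the two bulk
panels, the single-cell panel and tissue-level proteomics (genes with
> 25% missing values dropped first, pairwise-complete correlation); a
modified odds ratio for the two low-column-count panels, OR = d/(b·c)
over z > 1 columns with OR = 0 earning +2 (0/0 counts as 0; a positive
d over a zero denominator counts as co-expressed). N_norm min-max
scales N over all computed pairs of the run (not only pairs with
nonzero tumor ρ) and flips the sign so −1 marks the most mutually
exclusive pair. TS_'AND' = ρ_Tumor − N_norm, selected at ≥ 1.

For "AND-NOT", the odds ratio is d/b (activator-only columns), with
OR = ∞ — the inhibitor covers the activator everywhere — the favorable
outcome (0/0 counts as ∞). Rewards are magnified by (1 + I) and
penalties by (1 + A), with I the fraction of a panel's columns where the
inhibitor's z-score is at or above the activator's and A its complement
(reading the activator-side condition as z_a > z_i). Normalization is
min-max to [−1, 1] without a sign flip; selection takes pairs strictly
above the 99th percentile. Infinities never reach serialized output
(token "Inf"). Candidate inhibitors are downregulated surfaceome genes
with mean tumor log2(CPM+1) strictly below that pool's median.

## pMHC nomination and cross-reactivity

N(g) compares a candidate antigen to reference cancer germline antigens
already in clinical development: +1 per bulk RNA panel, +2 per protein
panel, +1.5 for the single-cell panel when the candidate stays below the
reference maximum in every column; no penalty branch, absent = 0, max
9.5. Candidates also need high tumor expression (25th-percentile rule,
with a relaxed single-cell-only path for genes with N(g) ≥ 3.5).

World allele frequencies combine population records as an unweighted
mean within each country and a population-size-weighted mean across
countries. TS_TCR/PC = (S_presentation + S_immunogenicity)(1 +
F_allele); per antigen, retained pMHCs must come from one of the top
five peptides by cumulative allele frequency (ties at the boundary all
kept), reach the 99th percentile of TS (computed per antigen — the
natural reading of a per-antigen ranking; a global-scope option exists),
and have presentation score ≥ 0.85.

PS-TRACT builds a unified normal ligandome from observed
(mass-spectrometry) and predicted records: predictions filtered to
affinity percentile < 2, records with presentation score ≤ 0.5 dropped
unless observed, four-digit alleles only, deduplicated on (peptide,
allele, parent). Positional entropy per (allele, length) is Shannon
entropy normalized by log 20 (the base cancels). S_sim sums two
components — a substitution-matrix similarity and a physicochemical
embedding similarity, each the positional mean of (1/(1 + dist)) ×
(1 + H_i) min-max scaled within the comparison pool of same-length
peptides on that allele — so S_sim ∈ [0, 2] and the threshold 1.15
flags cross-reactive peptides. The matrix and embedding load from TSV;
the package also ships a deterministic synthetic substitution model
(labelled synthetic) with the structural properties of published ones
(symmetry, self-distance zero, embedding-consistent similarities) for
testing and simulation.

S_CR = (presentation + 0.5) × E_tissue × 1.25^[observed], with E the
consensus z-scored expression of the cross-reactive peptide's parent.
Negative E (below-median tissues) yields negative S_CR and is kept:
it means low risk. The cross-reactivity profile takes the per-tissue
maximum over flagged peptides; an empty flagged set produces a floor
profile of 0 with an explicit "no detected risk" flag. S_CR Diff
averages (Δ/σ_j)·α for tissues where the candidate exceeds the
reference (α = 2) and Δ/σ_j elsewhere; σ_j is the sample SD over the
candidate profiles plus the reference, and zero-variance tissues are
excluded from the mean (reducing n). Acceptable risk at ≤ 0.

## Priority indices

H_RNA is mean log2(CPM+1) over tumor cells times the percentage of
positive cells. V_CAR sums eight items (homogeneity and clinical-
proteomics support vs a reference target's values, 2 each; antibody and
CAR development, essentiality, fusions, SNVs/indels, CNAs at 1/0.5/0),
range [0, 10]; V_TCR/PC sums six (max 7). Reference constants (the
comparator target's H_RNA and proteomics support) are required inputs —
no silent defaults. Each TPI is a sum of min-max-normalized components
over the nominated pool of one histotype; degenerate pools (one member,
or max = min) normalize to 0 with a warning so the index stays defined.
Gate TPIs average TS over all selected pairs containing the gene (both
members for "AND", activators only for "AND-NOT"). The TCR/PC index
adds per-locus mean allele frequencies (loci with no pMHC contribute 0)
and pMHC counts divided by protein length.

## Synthetic study generator

The generator emulates the statistical structure each stage assumes, so
the pipeline runs end-to-end with no downloads. Defaults (the study
conditions used by the tests and the acceptance script): 1000 cells
(600 tumor, 150 fibroblast-like, 100 endothelial-like, 150 immune), 300
genes, negative-binomial counts (dispersion 0.5, ~2000 counts per
cell), a 30-gene tumor signature at 4× effect, two 60-gene CNA blocks
(one loss, one gain) in 90% of tumor cells with clean neutral states in
the non-tumor classes, *PTPRC* restricted to immune cells. Normal
panels share a per-gene tissue program: 10 planted mutually-exclusive
"AND" pairs (anti-correlated patterns at strength 3) among 190 decoy
pairs from 20 independent genes, 2 planted activator-shadowing
"AND-NOT" pairs in a 200-pair pool, tissue-restricted reference targets
whose spikes cover every column (what makes below-the-reference-maximum
filters informative), and immune-privileged-restricted reference
antigens. The ligandome draws peptides from position-specific residue
distributions (anchors at positions 2 and last concentrated at 0.9,
others near-uniform) and plants single-substitution neighbors of chosen
tumoral peptides at a central high-entropy position, using the
embedding-nearest residue. The cohort's single bulk reference also
stands in for the cell-line expression series in the end-to-end run.

What it does not emulate: ambient RNA, doublets, batch effects, realistic
gene-length or GC structure, linkage between panels beyond the planted
patterns, or predictor-score biases of real presentation models. Tests
passing on these fixtures show the scoring machinery is implemented as
specified and recovers planted structure at realistic effect sizes; they
do not certify performance on real cohorts, where effect sizes,
reference-target behavior and ligandome composition differ.

## Reproducibility

All randomness flows from a single integer seed. `scanact run` writes a
JSON manifest containing the command, seed, full configuration, package
version, and sha256 of every stage output; deterministic reruns yield
bit-identical manifests (the manifest deliberately carries no wall-clock
timestamp — timing goes to the console). Problem sizes in the test
suite and acceptance script are the generator defaults above, chosen so
planted effects are comfortably detectable by rank-based statistics at
n in the hundreds.

## Known limitations

- The default tumor co-expression estimator is a rank correlation on
  normalized counts, not a sparse-count measurement-error model; for
  real data, ingest a dedicated estimator's output table.
- The permissive/stringent filters inherit the units and composition of
  the supplied panels; mixing incompatible normalizations across panels
  is not detected beyond the declared unit tags.
- S_sim min-max scaling is pool-relative: scores are comparable within
  one (tumoral peptide, allele, length) screen, not across screens.
  A global-scaling option exists for cross-screen comparisons.
- The worked-example validation of S_sim against a published
  cross-reactive peptide pair requires the published substitution
  matrix, embedding, and an assembled real ligandome, none of which
  ship with the package; the synthetic substitution model is clearly
  labelled and is not a reconstruction of the published matrix.
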