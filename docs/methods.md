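# Methods

`synergyscan` implements the computational analysis of signal integration
between interferon-γ (IFNγ) and the TLR4 agonist LPS in vascular cells:
how two stimuli acting through the JAK/STAT1 and NFκB/IRF pathways combine
at the level of gene expression, which genes respond *more* than the two
stimuli would predict separately, and what the promoters of those genes look
like. This note describes the models, the defaults and why they were chosen,
what the synthetic-data generator does and does not emulate, and the known
limitations.

## The signal-integration statistic

For a gene with linear fold changes `f_I` (IFNγ alone), `f_L` (LPS alone) and
`f_IL` (IFNγ followed by LPS), each relative to untreated control:

    si = f_IL / (f_I + f_L)

`si ≈ 1` means the combined response equals the sum of the single-agent
responses; `si ≥ 2` defines a *synergistically amplified* gene. The ratio is
scale-invariant (multiplying all folds by a constant cancels) and is always
computed on unrounded folds; the threshold is inclusive.

A gene is *called* amplified only when it is also significantly up-regulated
by the combined treatment: fold ≥ 2 (inclusive) with p < 0.05 from a
two-sided Welch test on log2 intensities. Fold changes themselves are ratios
of linear-scale replicate means (the convention of averaging fluorescence
signals before ratioing); the location test runs on the log2 scale where
array noise is approximately additive. When no p-value is available (e.g.
fold-only published tables), the caller either treats the gene as not
significant (default, with a warning) or falls back to the fold criterion
alone (`missing_p="significant"`), which is how the packaged published table
is recomputed.

Note the additive null is additive in *linear fold* space, while the
simulator's generative model is linear in log2 space; a gene with no
interaction term (γ = 0) therefore has `si = 2^(β_I+β_L)/(2^β_I+2^β_L)`,
which approaches 2 as both main effects grow. This is intentional — it is
the published statistic — but it means "no statistical interaction" and
"si < 2" are not the same claim for strongly double-responsive genes.

## STAT1 dependence

A response is STAT1-dependent when the STAT1-null fold drops to ≤ 50% of the
wild-type fold (inclusive) **or** falls below 2-fold induction. Dependence is
only assessable for genes regulated in wild type; others are reported as
`not_assessable`. The rule is applied per condition (IFNγ, LPS, combined) and
all three verdicts are reported.

## A–E response clusters

The five qualitative clusters group amplified genes by single-agent response
pattern: A (high IFNγ, high LPS), B (high IFNγ, mild LPS), C (mild/no IFNγ,
high LPS), D (mild both), E (minor/no single-agent response, amplified only
in combination). The published description is qualitative, so the decision
tree's numeric cut-offs are this package's own calibration:

1. LPS fold < 2 → **E** (checked first: a gene with no real LPS response
   belongs to the minor-response class even when its IFNγ response is
   appreciable);
2. IFNγ ≥ 20 and LPS ≥ 15 → **A**;
3. IFNγ ≥ 20 → **B**;
4. LPS ≥ 15 → **C**;
5. otherwise → **D**.

With these defaults the tree reproduces all 30 printed cluster labels of the
packaged table. All three cut-offs are ordinary `SynergyThresholds` fields
and are echoed into every report.

## Preprocessing

- **Detection filter**: keep genes with detection p < 0.05 in at least one
  treated sample (`any_treated`, configurable to `all_treated`). Filtering
  happens before replicate averaging; a flag order-swaps it.
- **Background subtraction**: default `min_shift` shifts each sample so its
  minimum intensity equals the floor (default 1.0), guaranteeing strictly
  positive values for ratioing without requiring tagged control probes; a
  `negative_controls` method subtracts the mean of tagged control rows and
  clips at the floor. A zero floor is rejected because it breaks folds.
- **Quantile normalization**: each sample's values are replaced by the
  rank-indexed mean of sorted columns; a run of tied values receives the mean
  of the reference values its positions span. With that tie convention the
  operation is exactly idempotent and distribution-identical on tie-free
  columns; columns with differing tie patterns retain small deviations by
  construction. *Limitation*: like any rank normalization, it assumes most
  genes do not change. When a large fraction of genes is strongly induced in
  one condition (as in the synthetic screens, where 10% of genes carry
  designed synergy), forcing identical distributions compresses genuine fold
  changes — the simulated-data examples therefore skip this step, and it
  should be used on real arrays where between-sample intensity differences
  are technical.
- **qPCR**: relative expression by 2^−ΔΔCt (ΔCt = target − reference per
  sample; ΔΔCt = mean ΔCt difference, treated − control). ChIP enrichment as
  fraction of input: the input Ct is first advanced by log2(1/fraction)
  cycles to account for the chromatin fraction it represents, then
  `2^(adjusted input − IP)`. No amplification-efficiency correction is
  modelled.

## Promoter scanning

Matrix similarity of a window against an L-position frequency matrix is the
conservation-weighted sum `Σ ci(i)·f_i(base_i)` normalized between the
lowest and highest attainable sums, so the consensus scores exactly 1 and
the anti-consensus 0. The per-column conservation weight is
`ci = Σ_b f_b·ln(4 f_b) / ln 4` (0 for a uniform column, 1 for an invariant
one); the published tooling's exact weighting constant is not public, so
this fixed monotone form was chosen once for reproducibility. Core
similarity is the same score restricted to the contiguous `k = 4` positions
with maximal total weight (leftmost on ties). A zero-information matrix
scores 1 for every window by convention; an `N` base contributes the
column's mean score and flags the hit. Both strands are scanned and hits are
reported on plus-strand, TSS-relative, half-open coordinates (TSS = 0,
upstream negative). Default emission thresholds: core similarity ≥ 0.85,
matrix similarity ≥ 0.80. Frequencies carry a pseudocount of 0.01 per base.

**Matrix building** from unaligned site occurrences is anchored-tuple
alignment: find the exact 8-mer present (on either strand) in ≥ 60% of
sites, align the containing sites on it, build a pseudocounted frequency
matrix over the commonly covered positions, trim flanking columns with
`ci < 0.30` so the matrix spans only the conserved region, then iterate:
rescore every site (best window, both strands), keep those reaching matrix
similarity ≥ 0.90, rebuild from the kept windows, until the kept set is
stable or 10 iterations. If no 8-mer reaches the 60% quorum the build fails
with a suggestion to lower the tuple size.

**Generic class matrices.** Proprietary matrix libraries are not shipped;
instead three generic classes are built from field-standard consensus
strings — STAT/GAS `TTCCCGGAA` (the palindromic IFNγ-activated sequence
bound by STAT1 homodimers), ISRE `GGAAAGTGAAAC` (the direct-repeat
interferon-stimulated response element bound by IRF-family factors), and
NFκB `GGGACTTTCC` (the canonical decameric κB site) — with 85% consensus
concentration per position by default. Users can supply their own matrices
in the JASPAR-style text format.

**Composite modules.** A STAT–NFκB (or IRF–NFκB) module is called when a
STAT-class (ISRE-class) hit and an NFκB-class hit co-occur on one promoter
with an inner-edge gap ≤ 100 bp, order- and strand-agnostic; overlapping
hits count as gap 0. The spacing bound is a package default (the source
analysis states none) and is logged in every report. The per-gene presence
table mirrors an either/or presentation: a singleton class column is marked
only when the class has a hit not already consumed by a reported module; the
full hit list is always emitted alongside.

## Cross-cohort integration

Probes are collapsed to genes by the arithmetic mean on the normalized
linear scale; ambiguous multi-symbol probes are rejected and unmapped probes
dropped with a count. Batch structure between combined cohorts is removed by
a per-gene location–scale adjustment on log2 values (each batch standardized
to the pooled gene mean and pooled SD; location-only for zero-variance
genes). This is a deliberate simplification of empirical-Bayes batch
correction — no shrinkage across genes — sufficient to remove planted
additive offsets exactly while preserving within-batch rank order.
Signatures are selected at fold ≥ 1.5 (inclusive), mouse symbols mapped to
human by case-folding plus a packaged legacy-alias list (MCP-2 → CCL8,
MCP-5 → CCL12, …; a proper ortholog table is a pluggable input), and
2–3-way Venn regions computed with exact member lists. Overlap enrichment is
the exact one-tailed upper hypergeometric tail with optional
Benjamini–Hochberg correction across categories — a plain substitute for
rank-based GO tooling, flagged as such in reports.

## The synthetic-data generator

Expression: `log2 x = μ + β_I·I + β_L·L + γ·I·L + ε`, `ε ~ N(0, σ²)`, over
WT/STAT1-null × {control, IFNγ, LPS, combined} × replicates. Defaults mirror
the study conditions: 3 replicates, σ = 0.25 log2 units, 2,000 genes, 10%
amplified. Amplified genes draw main effects from U(0.5, 4) log2 and receive
`γ = γ_min + U(1, 2)` where `γ_min` is the smallest interaction meeting the
synergy rule with equality, so every designed-amplified gene passes
`2^(β_I+β_L+γ) ≥ 2(2^β_I + 2^β_L)` with at least a twofold margin.
Non-amplified genes combine multiplicatively (γ = 0) with main effects
capped at U(0, 1.5) so their designed `si` stays below ~1.41 — separating
the classes by design, which is what the recall/FPR acceptance properties
measure. In the knockout, STAT1-dependent genes (default fraction 0.5) lose
β_I and γ entirely and keep `ρ·β_L` with ρ = 0.5 — chosen to exercise both
branches of the dependence rule. A 5% "undetected" fraction sits near
background with uniform detection p-values; detected genes get detection
p ~ U(0, 0.01) directly rather than via a background model, the simplest
structure satisfying the filter's contract.

Promoters: i.i.d. background bases (default uniform), consensus sites
planted at recorded TSS-relative positions and strands. `mutation_rate` is
the per-site probability that a planted occurrence carries one random point
substitution — modelling occasional site divergence while leaving most
occurrences exact, the regime the anchored-tuple builder is designed for. At
10% mutation a single substitution in a 12-position matrix still scores
≈ 11/12 ≈ 0.92, so mutated occurrences remain above the 0.90 inclusion and
0.80 scan thresholds.

**What the generator does not emulate**: probe-level bead structure,
correlated noise between genes, realistic promoter base composition or
dinucleotide structure, multi-copy or heterogeneous binding sites, and any
biological network coupling between the expression and promoter layers.
Passing the recovery tests therefore shows the pipeline is correct under its
own model assumptions, not that it would achieve the same operating
characteristics on real arrays or real genomic sequence.

## Numerical conventions

All thresholds are inclusive where "at least" is meant. Sorting of the
synergy table is cluster A→E, then combined fold descending, then gene id.
Down-regulation is a fold < 1, never sign-flipped. Coordinates are 0-based
half-open, TSS at 0. Equality comparisons against printed 2-decimal values
use round-half-even on the unrounded ratio. The packaged published table is
checksummed on load. Single-replicate groups yield folds without p-values;
single-sample matrices skip quantile normalization with a warning; empty
control groups, non-positive denominators, and zero floors are hard errors.

## Known limitations

- The published table's own `si` column was evidently computed from
  unrounded upstream intensities: four of 30 printed values differ from the
  ratio of the printed folds by 0.01 (Ubd, MCP-5, Oasl1, Itpk1), and one
  gene (Egr2, si 1.98) sits below the stated ≥ 2 criterion while appearing
  in the table. The package reports these as computed and does not force
  agreement.
- Genome-wide and cohort-level counts depend on the original array
  annotation and proprietary matrix libraries and are not reproduced here.
- The hypergeometric enrichment is not a replacement for rank-based GO
  analysis; the location–scale batch step is not empirical-Bayes batch
  correction; both are labelled in their reports.
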