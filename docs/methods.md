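# Methods

This note documents the statistical models, defaults, and design choices
behind `sceqtlmr`, and what the synthetic-data generator does and does not
emulate.

## Two-sample MR model

The exposure is the expression of gene *g* in cell type *c* (SD units);
outcomes are obesity (log-odds), BMI and body-fat percentage (SD units).
Instruments are cis-eQTL SNPs assumed to satisfy the usual IV conditions
(relevance, independence, exclusion restriction). Estimators:

* **Wald ratio** (one instrument): β̂ = β_out/β_exp, se = se_out/|β_exp|
  (first-order delta method). The first-order se ignores exposure-side
  error; it is accurate when the instrument's exposure z-statistic is large
  relative to its outcome z-statistic (the relative variance omitted is
  z²_out/z²_exp). A second-order variant is not provided because the
  pipeline's instrument-strength filters (F > 10, and typically F ≫ 10 in
  cis-eQTL data) put it in the regime where the first-order term dominates.
* **IVW** (two or more instruments): inverse-variance weighting of per-SNP
  ratios with weights wᵢ = (β_exp,ᵢ/se_out,ᵢ)², algebraically the
  weighted-least-squares slope through the origin of β_out on β_exp with
  weights 1/se²_out (verified against statsmodels in the tests). The
  default mode is multiplicative random effects — fixed-effect se scaled by
  max(1, √(Q/df)) — matching the behavior of the common two-sample MR
  toolchain; a fixed-effect flag exists. Cochran's Q uses the same weights.

P-values are BH-adjusted within each (cell type, trait) stratum; strata
never share a pool. "Q value < 0.05" is read as the Cochran's Q p-value,
unadjusted — the most direct reading of the published gate.

### Harmonization

Outcome records are aligned to the exposure effect allele: matching alleles
copy through, swapped coding negates β_out and flips EAF. Palindromic SNPs
(A/T, C/G) with EAF in (0.42, 0.58) on either side are strand-ambiguous and
dropped; the window is configurable. Any other allele mismatch drops the
SNP with a reason code. These rules are this package's choice — sources
rarely state theirs — and are deliberately conservative.

## Instrument selection

Filters run in the order: p < 0.005 (strict inequality), greedy LD clumping
at r² < 0.01 (most significant SNP retained first; ties broken by genomic
position then SNP id, which makes the greedy deterministic and
order-invariant), F = (β/se)² > 10 per SNP, then Steiger directionality.
Steiger variance explained is computed from the z-statistic,
r² = z²/(z² + n − 2), which is robust to unit differences between binary
and quantitative outcomes; the SNP is kept iff r²_exposure > r²_outcome
(strict). A Fisher-transform z-test p-value is reported but not
thresholded, since the published procedure filters on direction only.
The strict sensitivity rerun repeats everything at p < 5 × 10⁻⁶.

## Colocalization

Per-SNP evidence is the Wakefield approximate Bayes factor; with z = β/se,
V = se², W the prior effect variance:

    log ABF = ½ log(V/(V+W)) + (z²/2) · W/(V+W)

Prior effect sd: 0.15 for quantitative traits, 0.2 for the binary outcome
on the log-odds scale (the standard defaults of the method; configurable).
One causal variant per trait per locus is assumed. Hypothesis masses use
per-SNP priors p₁ = p₂ = 10⁻⁴, p₁₂ = 10⁻⁵ and are accumulated entirely in
log space; the H3 cross term Σ_{i≠j} BF1ᵢ·BF2ⱼ is computed as a masked
pairwise logsumexp, which is exact and cannot suffer the catastrophic
cancellation of the "product minus diagonal" form. On loci of ≤ 6 SNPs the
posteriors match exhaustive configuration enumeration to 1e-9 (tested).

Windows are ±100 kb (closed) around each instrument SNP. For
multi-instrument genes, windows are per-instrument and locus evidence is
the OR over instruments; the reported posterior vector comes from the most
significant instrument's window. The LD-check fallback declares approximate
colocalization when the instrument has r² ≥ 0.7 with any outcome SNP at
p < 5 × 10⁻⁸ in the window (the "signal" definition is configurable; the
source procedure does not define it).

## Aggregation

A (gene, cell type, trait) signal is a candidate iff stratified FDR < 0.05,
not excluded by the Q gate, and coloc evidence holds. Replicable genes have
evidence for all three traits; by default the cell type may differ between
traits (multi-cell-type replicable genes do occur in real data), and a
strict same-cell-type mode is available by flag.

## Enrichment

Over-representation is the hypergeometric upper tail P[X ≥ k] for k
candidate genes in a K-gene term from an N-gene universe. The universe
defaults to the union of term genes; pipeline runs pass the MR-tested gene
background explicitly. Raw p < 0.05 defines "significant" for the Tier
pathway counts — faithful to the published cutoff — while BH-adjusted
values are always reported alongside. No curated GO/KEGG content is
bundled; any GMT file works.

## Single-cell DEG

Cells pass QC with detected genes in [200, 8000] (closed) and
mitochondrial fraction ≤ 0.25 ("exceeding" is strict). Normalization is
library-size scaling to 10⁴ followed by log1p — the de-facto standard of
the single-cell toolchain. Genes detected in ≥ 10% of cells in at least one
group are tested per cell type with a two-sided Wilcoxon rank-sum: the
exact null distribution when both groups have ≤ 25 cells, otherwise the
normal approximation with tie and continuity correction. Bonferroni uses
the number of genes actually tested within the cell type. The log fold
change is log(mean(expm1(x))+1) obese minus lean. No fold-change pre-filter
is applied (the published criterion is adjusted p only); min-pct and the
Bonferroni denominator are configurable. Direction consistency with MR
compares the obese-minus-lean sign to the MR beta sign and requires
significance; mapping blood cell types to other tissues' labels is always
an explicit user-supplied map.

## Tier scoring

All component scores are multiples of 0.1, so totals are accumulated in
integer tenths: boundary totals of exactly 1.0 and 0.5 land in Tiers 1 and
2 with no floating-point ambiguity. An enrichment count of 0 scores 0
(the worked rows print 0 even though the scale's lowest band starts at
"X < 5"; the rows override the header's implicit lower bound). The
ranking-stability analysis reweights component scores before summation:
the equal-weight scheme rescales every evidence domain to a common maximum
contribution of 1 (the original scales give druggability max 1.0, MR/coloc/
enrichment max 0.5, DEG max 0.3), and the down-weight scheme halves the
annotation-dependent domains (enrichment, DEG, druggability). Spearman ρ is
tie-corrected on average ranks; top-k persistence is the retained fraction
of the original top k.

## Synthetic-data generator

The generator works at the marginal-summary-statistic level — no
individual-level genotypes. For a locus with AR(1) LD matrix R (parameter
ld_rho, default 0.9) and causal SNP c with joint effect γ, marginal
z-scores are N(μ, R) with μⱼ = (γ/se_c)·R[j,c] and
seⱼ = 1/√(2·mafⱼ(1−mafⱼ)·n). Scenarios mirror the coloc hypotheses; H4
outcome effects are θ·γ at the shared SNP (plus optional per-SNP direct
pleiotropy, default 0 so the exclusion restriction holds at baseline), and
H3 anchors the outcome at a SNP with r² < 0.05 to the exposure SNP. Each
gene owns two independent LD blocks (block-diagonal gene LD), so clumping
yields multi-instrument genes and IVW is actually exercised. Binary-trait
standard errors use the case/control effective sample size
4/(1/cases + 1/controls).

Default conditions are the study's: n_eqtl = 982; outcomes at the published
sample sizes (obesity 31,499/468,693; BMI 484,680; %BF 432,262); 14 cell
type labels. The eQTL effect (0.7 SD, causal z ≈ 15) reflects strong
cis-eQTLs; per-trait causal effects (obesity 0.04 log-odds, BMI/%BF
0.02 SD per SD expression) are sized so the shared variant reaches
genome-wide significance (z ≈ 7) in each outcome at its sample size —
i.e. loci of the kind the published analysis takes forward. One master
seed drives everything; per-gene streams come from counter-based
seed-sequence spawning, so outputs are byte-identical under a fixed seed
and independent of iteration order.

Single-cell counts are negative binomial (default mean 1.5, dispersion 2,
400 non-mito genes + 10 MT- genes) over 10 donors per group × 200 cells,
with designated genes shifted by a natural-log fold change (default 1.0)
in a designated cell type of the obese group, and a small fraction of
planted QC violations (low-depth and mito-dominated cells).

What the generator does **not** emulate: realistic population-genetic LD
(no coalescent, no allele-frequency/LD coupling), sample overlap between
exposure and outcome cohorts, polygenic background outside the simulated
loci, cell-type proportion shifts, donor-level pseudo-replication in the
DEG test (cells are treated as exchangeable within group, as the published
per-cell Wilcoxon does), or the eQTL discovery model behind any real
sc-eQTL resource. Passing recovery tests therefore demonstrates
correctness of the inference machinery under the stated generative model,
not robustness to these real-data complications.

## Problem sizes used in tests and the acceptance script

MR bias/coverage uses 200 all-H4 genes (600 gene-trait estimates);
coloc gate rates use 200 loci per scenario at a strong causal effect
(θ = 0.3, the regime where shared-variant recovery is expected); the
global-null pipeline uses 200 H0/H1 genes; DEG power and null calibration
use 50 seeds of ~400 (power) or ~200 (null) cells per group over 100
genes. These sizes give Monte-Carlo error comfortably below the margins of
the properties being checked while keeping a full run in minutes on one
CPU.

## Known limitations

* Single-causal-variant colocalization: multi-signal loci can yield biased
  posteriors (conditional/fine-mapping colocalization is out of scope).
* First-order Wald/IVW standard errors under-cover when the outcome signal
  is stronger than the instrument's exposure signal; the pipeline's
  instrument-strength filters make this rare but cannot exclude it.
* The Q-heterogeneity gate excludes a few percent of genuinely homogeneous
  multi-instrument signals by construction (alpha = 0.05), which compounds
  across three traits in the replicable set — visible as < 100% recall in
  the end-to-end recovery metrics.
* The DEG stage tests cells, not donors; with few donors per group,
  donor-level variance can inflate significance on real data.
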