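# Methods

`tosca` re-implements, as a tested library, a computational pipeline for
extracting somatic genetic risk information from whole-exome variant calls in
benign (pre-malignant) tissue when matched normal DNA is unavailable for most
samples. This note records the models, the tunable parameters and their
defaults, what the synthetic cohorts do and do not emulate, and the numerical
choices made where the design was genuinely open.

## Problem setting

Benign-tissue biopsies sequenced without matched normals yield variant calls
that mix true somatic mutations with germline polymorphisms. The pipeline
(1) separates the two classes with a supervised model trained on the subset
of samples that *do* have matched normals, (2) validates calls against
orthogonal genotyping-array data, (3) summarizes somatic SNVs as 96-channel
trinucleotide catalogs and extracts mutational signatures by NMF,
(4) tests signature exposures and gene/hotspot mutation status for
case-control and histology-subgroup associations, (5) relates gene-level
copy-number deletions to signature exposures, and (6) estimates cancer-risk
discrimination from protein-domain mutation burdens.

## Somatic/germline classification

Training labels come from samples with matched normals: a tumor-only call
that overlaps the sample's germline call set is labeled germline, one that
overlaps the tumor-normal paired somatic set is labeled somatic, and calls
claimed by neither or both truth sources are excluded (counts reported).
Before classification two hard filters apply: a panel of normals containing
every site observed in at least 2 normal samples (exact match on chromosome,
position, ref, alt), and removal of calls with total depth below 20 reads
(depth 20 itself is retained). The two filters commute.

The feature matrix has 31 named columns: VAF, alt/ref/total depth, cohort
recurrence (number of cohort samples carrying the identical variant),
population allele frequency, dbSNP-common flag, somatic-catalog presence and
count, six pathogenicity/conservation scores (SIFT, PolyPhen, CADD, phyloP,
GERP, REVEL), an 8-level variant-class one-hot, a 6-level pyrimidine-folded
base-change one-hot, a context-GC flag and a homopolymer-context flag.
Missing numeric annotations are imputed with the column median (all-missing
columns fall back to 0), so assembly is total and deterministic. The schema
is declared as a named tuple of columns so real annotation sources can be
mapped onto it.

Seven model families (L2 logistic regression, linear SVM, random forest,
gradient-boosted trees, k-NN, RBF SVM, one-hidden-layer MLP) are tuned by
grid search with stratified 5-fold cross-validation on a stratified
training split and compared by F1 on the held-out split, somatic positive.
Grids are deliberately small (≤ 3–6 points per family) to keep desk-scale
runtime; the MLP hidden width is tuned over {32, 64, 128} with early
stopping (the architecture was an open choice). The default held-out
fraction is 0.2 for model selection (0.3 in the end-to-end evaluation
scenario); neither fraction is fixed by the source protocol, so both are
arguments. Scores returned by `classify` are class-1 probabilities where
the estimator provides them, otherwise a logistic transform of the decision
function — monotone in the decision function either way.

## Array concordance

For sites present on both platforms the overlap rate at discrepancy
allowance *a* is the fraction with |VAF_WES − AF_array| ≤ *a*; the array AF
takes values {0, 0.5, 1}. The boundary is inclusive, so an allowance of
0.25 admits a discrepancy of exactly 0.25 (inclusivity was unspecified; the
inclusive convention makes the rate right-continuous in the allowance).
Sites are pooled across samples by default, with a per-sample breakdown
reported alongside, because the validation compares mutations common to the
platforms rather than per-sample averages.

## Mutational signatures

SNVs are folded to the pyrimidine strand and binned into the 96 COSMIC-order
channels (6 substitution types × 16 flanking contexts); records whose
context middle base contradicts the reference allele are skipped and
counted. Row sums equal each sample's valid-context SNV count exactly.

NMF uses multiplicative updates under Frobenius loss with seeded random
restarts, keeping the best restart. Defaults: 10 restarts, 1000 max
iterations, tolerance 1e-5 (all arguments); planted-signature recovery is
already at ceiling under these settings, and tighter settings are available
where exact noise-free recovery is wanted. H rows are normalized to sum 1
and W rescaled compensatingly, so W holds attributed mutation counts.

The signature count is chosen from the residual-sum-of-squares curve over
candidate ranks. "The first inflection" is operationalized as the interior
candidate k maximizing the discrete second difference
RSS(k−1) − 2·RSS(k) + RSS(k+1), ties to the smallest k; a flat curve
(spread below 1e-9 of the catalog's total sum of squares) degenerates to
the smallest candidate with a warning. No closed-form rule was given for
the inflection, so the second difference — the discrete analogue of
maximum convexity — is this package's choice.

Extracted signatures are assigned to a reference catalog one-to-one by
optimal bipartite matching on cosine similarity; assignments below a
threshold (default 0.8) are flagged uncatalogued. The bundled reference is
a synthetic stand-in (aging-like, MMR-like, UV-like, APOBEC-like profiles),
not a COSMIC reproduction; COSMIC-style 96-row TSVs can be read in its
place. A caveat inherent to NMF: exact factor recovery is only identifiable
when signatures do not share background mass and some samples are
near-pure; the recovery tests use that construction, while the study-scale
tests assert cosine/correlation thresholds instead of exact equality.

Exposure-phenotype association is a logistic regression of the binary
outcome on the (by default standardized) attributed-count exposure plus
covariates — age, menopausal status, histology class — with Wald effect,
95% CI and two-sided p. Perfect separation falls back to an L2-penalized
fit flagged as such, with no p-value. Whether exposures should enter as
proportions instead of counts was open; counts standardized is the default
and proportions are a transform away. Group comparisons of exposures
(e.g. deletion carriers vs non-carriers) use Welch's two-sample t test
with per-group means and 95% t intervals.

## Enrichment

Per-gene case-control enrichment fits a logistic regression of group on the
mutation indicator and reports the Wald p; on zero cells, separation or
non-convergence the two-sided Fisher exact test replaces it (degenerate-case
handling was unspecified; the fallback keeps every gene testable). Hotspot
level groups variants by (gene, protein change). Non-silent means missense,
nonsense, frameshift, stop-gain or splice. Length-adjusted rates are
mutations per sample per coding kb, so doubling a gene's length halves its
rate exactly. Ser/Thr accounting parses p.RefPosAlt changes; p.S100T counts
as both loss-of-serine and gain-of-threonine. BH step-up q-values preserve
input order.

## CNV deletions

A gene is deleted in a sample when ≥ 50% of its interval is covered by
segments with log2 ratio ≤ −0.3 (union of segments, 1-based inclusive
SEG convention). Neither threshold was stated in the source protocol; both
are arguments, and calls are invariant to segment ordering and to splitting
a segment into contiguous equal-ratio pieces.

## Domain-burden risk model

Somatic mutations are aggregated per sample into counts over a 1966-domain
vocabulary (gene or cytoband units work through the same interface).
Discrimination is estimated by repeated stratified 7:3 splits (10 runs by
default): per run an L1-penalized logistic model is fit on the training
70% with the penalty chosen by internal 5-fold CV over a fixed log-spaced
grid (penalty selection was unspecified), columns standardized (also an
open choice; raw mode is a flag), and AUC measured on the held-out 30%.
The report carries per-run AUCs, their mean, and a percentile 95% interval
over runs (the source CI construction over 10 runs was unstated).
Degenerate single-class test splits are redrawn and counted.

## Synthetic cohorts

The generator reproduces the statistical structure the pipeline is designed
for, with ground truth retained:

- **Cohort**: 135 cases / 69 controls; histology planted at exactly
  round(76/195 · n) proliferative-without-atypia (PDWA) samples (the
  analysis subgroup sizes are 76 vs 119; a printed summary table gives
  75/115 — the analysis numbers are used).
- **VAF/depth**: somatic VAF ~ Beta with mean 0.232 (shape 2.3, ~95% of
  mass below 0.5); germline VAF a het/hom mixture of Betas with modes 0.5
  (concentration 120) and 0.97 (concentration 70); depth ~ negative
  binomial with mean 99 and size 20. Only means/modes were reported;
  shapes and dispersion are this package's choices. Read counts are then
  binomially resampled at the drawn VAF.
- **Mutation catalogs**: ~180 somatic SNVs per sample (Poisson), channels
  multinomial in w·H0 where w ~ Dirichlet(4, 2.5, 1.5) and H0 holds three
  planted signatures: aging-like (CpG C>T), MMR-like (non-CpG C>T plus a
  minor C>A component) and an oxidation-like O/TN signature with 60% of
  mass on T>G and T[T>G]C the largest channel (the pyrimidine-strand
  representation of the 5′GAA3′>5′GCA3′ motif). The concentration was
  chosen so per-sample exposures are dispersed enough to be identifiable
  (truth correlation ≥ 0.9 at study scale); profiles are stand-ins, not
  COSMIC rows.
- **Class-dependent features**: germline variants are drawn from a shared
  site pool (popularity ~ Beta(0.25, 1)), giving cohort recurrence and
  high population AF; somatic sites are mostly private with population AF
  near 0 and class-shifted pathogenicity scores.
- **Planted effects are exact-count plantings**: a planted rate r among n
  eligible samples selects exactly round(r·n) carriers at random. This
  makes "25% vs 5%" mean what it says in every replicate; under per-sample
  Bernoulli sampling the realized contrast varies enough that the stated
  detection rates (e.g. hotspot p < 0.001 in ≥ 90% of seeds) are not
  achievable at these sample sizes, so exact planting is the generator's
  defined semantics. The TNBC flag is the exception: it is generated from
  a logistic model (intercept at a 15% rate among cases, slope 1.0 per SD
  of O/TN exposure), because the association analysis estimates exactly
  that model and calibration under the null is required.
- **CNV subset**: 26 samples; MLH3 deletions planted in round(0.3·26) = 8
  samples (observed deletion frequencies in the motivating data range from
  6/26 to 10/20 per gene); deleted samples' MMR exposure is shifted by
  2 SD. PMS2 deletions are planted independently without an exposure link.
- **Array calls**: nearest of {0, 0.5, 1} to the VAF, flipped to a random
  wrong state with probability 0.15, which reproduces the ~85% concordance
  scale at allowance 0.25.
- **Domain burdens**: 1966 domains, Poisson burdens with lognormal
  per-domain rates; each informative domain (default: five, log-odds 1.0,
  baseline rate 0.3) has its case rate multiplied by e^β, which makes the
  Bayes log-odds of case status linear in the burden with slope β.

What the generator does **not** emulate: alignment and sequencing artifacts,
FFPE deamination damage, linkage between sites, realistic gene coordinates
(the intervals are invented), caller-specific error modes, or overlap
between the mutation-catalog channels and the germline site pool's base
composition. Passing tests therefore demonstrate that the pipeline recovers
planted structure under its own generative assumptions — classifier F1 near
1.0 on synthetic cohorts, in particular, reflects the cleanly separated
feature distributions and should not be read as field performance.

## Problem sizes and determinism

All stochastic stages are pure functions of a seed; every study-scale check
fixes its seeds. Default sizes used by the tests and the acceptance script:
signature recovery over 20 catalog seeds (204 × 96, ~180 SNVs/sample);
association power over 100 cohorts and type-I error over 300–500 null
cohorts at n = 204; classifier selection on a ~6,300-variant labeled
cohort; burden model over 20 cohort seeds at 204 × 1966 with 10 splits
each; CNV association over 100 subsets of 26. These sizes mirror the
motivating study's scale while keeping a full run on one CPU in minutes.

## Known limitations

- Exact NMF non-identifiability under shared background mass (above).
- Wald-based logistic p-values are mildly anti-conservative at small event
  counts; measured type-I error at n = 204 is within 0.03–0.07 at α = 0.05.
- The Fisher fallback makes gene-level p-values discrete and conservative
  for rarely mutated genes; FDR control inherits that conservatism.
- Deletion calling assumes segment coordinates and gene intervals share an
  assembly; only chromosome-name mismatches are detected automatically.
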