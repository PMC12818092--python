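# Methods

This note documents the models and procedures the package implements, the
parameters that matter, the numerical choices behind them, and what the
synthetic-data generator does and does not emulate.

## Microsatellite distances and clone detection

Alleles are fragment sizes in base pairs; dividing by the locus motif length
converts them to (possibly fractional) repeat counts, the natural unit of
the stepwise mutation model.

**Stepwise distance.** Per shared locus, the minimal total |Δ repeats| over
one-to-one allele matchings; with unequal allele counts every unmatched
allele of the larger multiset pays its distance to the nearest allele of the
smaller one, and the matching is optimized jointly with those residual costs
(a linear assignment on reduced costs `|a_i − b_j| − c_j` plus the constant
`Σ c_j`). Locus contributions are **summed**, so the genotype distance is
the smallest number of single-repeat mutations separating two genotypes.
Tests verify the assignment against exhaustive enumeration for up to four
alleles per locus.

**Bruvo distance.** Per allele pair `1 − 2^(−|Δ repeats|)`, per locus the
minimal mean over matchings, per genotype the mean over shared loci, hence
bounded in [0, 1]. Unequal allele counts (mixed ploidy, unrestored dosage)
use the combined convention: the genome-addition model (the smaller
genotype filled with copies of its own alleles) and the genome-loss model
(filled with alleles of the larger genotype) are each averaged over every
possible fill, then the two model values are averaged. Fill enumeration is
exact for ploidy ≤ 4; the inner matching uses the Hungarian algorithm.

**Missing loci** are skipped pairwise. Pairs sharing fewer than
`min_shared_loci` (default 10) loci are computed but flagged rather than
silently trusted.

**Clone detection.** Ramets are grouped into genets by single linkage:
connected components of the graph whose edges are pairwise distances at or
below the threshold. The default threshold of 22 mutation steps is the
study convention; `suggest_clone_threshold` recovers a data-driven value as
the first interior minimum of a Silverman-bandwidth kernel density of the
pairwise distances, returning none (with a warning) when the distribution
is unimodal. Clonality per group is reported as
`100 × (ramets in multi-member genets) / ramets`, rounded half-up to one
decimal, matching how such tables are conventionally printed.

**Dosage restoration.** Polyploid genotypes scored with each distinct
allele recorded once are completed to full ploidy by choosing, per
under-filled locus, the extra copies that maximize the multinomial
probability of the genotype under population allele frequencies; the
frequencies are re-estimated from the current assignment and the procedure
iterates to a fixed point (at most 50 sweeps, deterministic lexicographic
tie-break). This is a maximum-likelihood stand-in for proprietary
implementations whose exact algorithm is undocumented.

**PCoA.** Gower double-centering of `−½ d²` followed by an
eigen-decomposition. Negative eigenvalues (non-Euclidean distances) are
reported unmodified; percentage variance uses positive eigenvalues only. An
independent library implementation serves as a test oracle on Euclidean
inputs.

## Admixture taxon calls

Thresholds are applied at the species level first, then the subgroup level:
an individual is *pure* when one species holds ≥ 0.85 of its ancestry and
one subgroup of that species does too; *intra-species admixed* when the
species is fixed but no subgroup dominates; an *interspecific hybrid* when
exactly two species each hold 0.15–0.85 and jointly ≥ 0.85 (named MED, MAC
or SUB from the parent pair); and *unresolved* otherwise (three-way
admixture has no conventional name and is reported separately). Boundary
values are inclusive: exactly 0.85 counts as pure, since "at most 15 %
foreign admixture" defines purity. Raising the upper threshold can only
shrink the pure class, so hybrid calls never flip to pure — a property the
tests assert. Evanno's ΔK is the absolute second difference of the mean
log-likelihood over replicate runs divided by their standard deviation;
zero standard deviation is rejected as degenerate input rather than
silently yielding infinities.

## Flow cytometry and the seed screen

**Ploidy binning.** A 1-D Gaussian mixture is fitted by EM per (tissue,
standard) context; the component count is chosen by BIC over 1..6 with ties
broken toward fewer components (the printed fluorescence histograms justify
nothing more elaborate). Bins span mean ± 2 sd; the lowest component is
assigned the base ploidy (diploid for leaves and embryos; endosperm
contexts may override, since the lowest endosperm peak of a sexual diploid
is triploid). Other components are labelled
`round(base × mean_i / mean_lowest)`; a label collision means the peaks are
not resolvable and the fit is rejected outright rather than reported with
duplicate bins. Strict assignment returns the unique containing range,
"intermediate" between ranges, or "out-of-range"; nearest-mode assignment
falls back to a half-integer label when the best integer bin lies more than
2 sd away, which is how intermediate endosperm values (imbalanced gametes,
polyspermy) are represented downstream.

**Pathway inference.** Endosperm arises from the central cell (two polar
nuclei, ⚇ = 2♀) plus sperm; the embryo from the egg plus at most one
sperm. Four rules are checked in order, mutually exclusive for integer
inputs at tolerance < 0.5 (the tests prove this by exhaustion over all
maternal/embryo/endosperm combinations):

1. **sexual** — solving e = ♀ + ♂ and n = 2♀ + ♂ gives ♀ = n − e and
   ♂ = 2e − n; accepted when ♀ is a half-integer in [0.5, m] and ♂ an
   integer in {1, 2, 3}, each within `tol` (default 0.25×). The same sperm
   ploidy fertilizes egg and central cell; allowing them to differ would
   misclassify autonomous seeds, so polyspermy is confined to the apomictic
   endosperm.
2. **autonomous apomixis** — e = m and n = 2m: no paternal contribution at
   all.
3. **pseudogamous apomixis** — e = m and 2m + 1 ≤ n ≤ 2m + `smax`
   (default 4): maternal embryo, endosperm fertilized by up to `smax` sperm
   equivalents.
4. **extended apomixis** — polyploid mothers (m ≥ 3) with maternal embryo
   and endosperm beyond 2m + `smax`: reported as pseudogamous with the
   sperm contribution recorded as "> smax" and flagged, since
   endoreduplication and polyspermy cannot be separated at that point.

Anything else is ambiguous, notated `e+(n)`. Open endosperm readings
(">10", "≥8") are evaluated at their bound (">" adds one) and flagged.
Half-integer eggs from triploids (♀ ≈ 1.5) are accepted and notated with a
tilde (♀∼1.5). An optional `unbalanced_egg_max_sperm` cap declares sexual
solutions with an egg that is neither reduced (m/2) nor unreduced (m) and a
high sperm ploidy ambiguous instead; the default leaves it off.

Per-taxon summaries count seeds per (maternal ploidy, pathway notation)
with percentages over the taxon's classified seeds, plus aggregate
sexual/apomictic/ambiguous shares, rounded half-up to one decimal.

**Reporting choice.** Integer ploidy-frequency percentages use
largest-remainder rounding so the column sums to exactly 100 (plain
rounding of 158/124/24 out of 306 yields 52+41+8 = 101; the
largest-remainder triple is 52/40/8).

## Morphometrics

**GPA.** Configurations are centered, scaled to unit centroid size and
iteratively rotated to the running mean (SVD rotation, reflection forbidden
by default because leaves have fixed left/right landmark chirality); the
mean is renormalized each pass and iteration stops when it moves < 1e−8
(at most 100 iterations). Outliers are removed per individual at the
robust threshold median + 2 × MAD on Procrustes distances to the
individual mean; at least one leaf always survives. Retained leaves are
averaged per individual and shoot type and concatenated into a 26-landmark
composite; a missing shoot-type block (13 landmarks) is imputed by a
thin-plate spline fitted from the reference mean's observed landmarks to
the specimen's (exact for specimens that are affine images of the
reference — a property the tests exploit); specimens with fewer than three
observed landmarks are excluded.

**Relative warps.** With `alpha = 0` (the default) this is a plain PCA of
the aligned coordinates. Nonzero `alpha` weights the non-affine shape
subspace by bending-energy eigenvalues to the power `−alpha/2`, leaving the
affine component unweighted; scores are then computed in that metric.

**Trait handling.** Procrustes x/y coordinates are treated as individual
traits alongside the seven fruit characters. Spearman-correlated pairs with
|r| strictly above 0.9 are pruned (lower-variance member dropped, pairs
processed in decreasing |r|, correlations re-evaluated after each removal);
constant traits are dropped up front. Missing trait cells are completed by
a deterministic chained-equations scheme (rows over 50 % missing dropped,
column-mean initialization, ten sweeps of per-column least-squares
regressions); determinism was chosen over stochastic multiple imputation
because a single completed dataset feeds the discriminant analyses and
reproducibility aids testing.

**CDA and LOO-LDA.** Canonical axes solve the generalized eigenproblem of
between-group versus pooled within-group covariance, scaled to unit pooled
within-group variance with a deterministic sign convention. Hybrids are
centered with the active grand mean and projected with the same
coefficients, so they never influence the axes — the tests assert the
coefficients are bit-identical with and without passive samples. Because
52 Procrustes coordinates carry exact linear constraints (centering,
scaling, rotation alignment), the pooled within-group covariance of the
full trait set is singular; the pipeline adds a logged ridge of 1e−8.
Validation is leave-one-out LDA (pooled covariance, priors proportional to
training group size, uniform optional). Note that leave-one-out is
pessimistically biased at chance level — on two identical distributions the
measured accuracy sits near or below 50 %, because removing a sample shifts
its own class mean away from it.

## Synthetic data

The generator is a structural replica of the emulated study design: 22
microsatellite loci (motifs of 2–4 bp, alleles within 100–500 bp); taxa L,
M, R, MED, MAC, SUB at sample sizes 111/32/71/17/57/18; L, M and MED
essentially diploid, R and MAC tri-/tetraploid, SUB mixed; diploid leaf
index 0.19 against the *Pisum* standard with sd 0.008 (component
separation far above 6 sd, as in the printed ranges); clone structure
concentrated in R (11 clonal genets) and its hybrids; reproduction mixtures
of 10 % sexual / 88 % pseudogamous for R, ~96 % sexual for the diploids,
intermediate for MAC and SUB.

Species allele frequencies are Dirichlet draws over per-species allele
ladders offset by a divergence parameter (12 repeat units by default),
which makes between-species and between-genet distances (≥ 60 steps) vastly
exceed within-clone mutation distances (≤ 5 planted steps), so the 22-step
threshold separates them with margin — the condition under which exact
clone recovery is asserted. Hybrids combine gametes of both parents, the
polyploid parent contributing the unreduced share of odd-ploid hybrids.
Q-matrix rows are Dirichlet draws concentrated (α ≈ 200) on the true
ancestry vector. Seeds follow the forward pathway rules exactly and are
converted to fluorescence indices with 1.5 % multiplicative noise. Leaf
shapes are hand-built lobed templates (shallow-lobed, deep-lobed,
intermediate-serrate — illustrative, not digitized from specimens) plus
individual and leaf-level Gaussian landmark noise in a random digitization
frame; hybrids sit at the midpoint of their parent templates with three
times the parental between-individual variance, emulating the broad
morphological overlap reported for hybrid classes (without it the planted
hybrid clusters are linearly separable and the documented hybrid-inclusive
accuracy drop does not emerge). Fruit vectors are Gaussian around
per-taxon means with categorical pyrene counts (one-pyrene M/R versus
two-to-three-pyrene L).

What the generator does **not** emulate: linkage and coalescent structure,
mutation-model realism beyond single-repeat steps, genotyping error and
allelic dropout, FCM debris or cell-cycle artefacts, digitization error
structure in landmarks, and environmental trait covariance. Passing the
recovery suites therefore demonstrates that the pipeline's inference is
correct under its own model assumptions — not that those assumptions hold
for any particular field dataset.

## Problem sizes and determinism

The default synthetic study (306 individuals, ~1 500 seeds, ~1 200 leaves)
runs end to end in well under a minute; the test suite uses a scaled-down
configuration (~67 individuals) with the same structure for the exhaustive
property checks. All stages are deterministic given the configuration
seed: identical inputs produce byte-identical report tables, which the
pipeline tests verify, and every report directory carries a SHA-256
manifest.

Pathway-share recovery is judged against the realized (ground-truth)
pathway draw of the generated seed set rather than the nominal mixture,
since at 500 seeds the binomial fluctuation of the draw itself is of the
same order as the ±4-point tolerance; the realized draw is separately
checked to lie within 3σ of nominal.
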