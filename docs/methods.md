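# Methods

This note documents the models behind each stage, the parameters that matter,
what the synthetic-data generator does and does not emulate, and the numerical
and design choices made where the design was genuinely open.

## Modification calling

The caller assumes per-molecule IPD ratios at a position-strand are
exchangeable draws from a two-component mixture: unmodified molecules around
the control mean μ₀ = 1 and modified molecules around μ_m > μ₀. The test is a
one-sample, upper-tailed t test of the sample mean against μ₀ — a Welch
two-sample mode is a natural extension when measured control observations are
available, but the default compares against the in-silico control expectation.
QV = −10·log₁₀(p), capped at 1000 so p-underflow never produces infinities.

Degenerate zero-variance samples cannot be t-tested: the policy is p = 1
(no call) unless the mean exceeds μ₀ with n ≥ 10, where the evidence is
overwhelming and p is treated as underflowed (QV at cap). This is documented,
deterministic behaviour, exercised in tests.

Site status is deliberately three-valued. A position with < 10 molecules on a
strand is *unevaluable*, never "unmethylated": conflating the two would let
coverage gaps masquerade as epigenetic signal, which matters everywhere
ratios, profiles, and SNMV matrices are built.

The methylation fraction is estimated by the method of moments,
f = clip((x̄−μ₀)/(μ_m−μ₀), 0, 1), rather than by mixture EM: at the per-site
coverages this pipeline targets (~100×) EM adds variance and convergence
failure modes without improving the point estimate, and the moment estimator
is provably unbiased before clipping. Measured on the generator's own study
conditions (depth 100, f ∈ {0.1…0.9}), the mean absolute error is ≈ 0.04.

## Motif scanning and methylome profiles

Scanning compiles an IUPAC pattern to a regular expression with a lookahead so
overlapping occurrences are all reported; the minus strand is scanned by
matching the reverse-complement pattern in plus-strand coordinates, and every
site records the plus-strand coordinate of its methylated base. Sequence N
never matches any motif symbol — conservative, avoiding phantom sites in
ambiguous assembly regions. A self-complementary motif (GANTC, GATC, TTAA…)
yields one site per strand per locus; "both strands" counts therefore double
the locus count, and full- vs hemimethylation is decided by pairing the two
strand-sites of a locus.

A motif's methylation ratio divides methylated by evaluable sites; a
genome–sample pair whose ratio falls below 0.20 is noise, not a candidate
motif (boundary inclusive: 0.20 is a candidate). The breadth gates (10×
breadth ≥ 0.20 prokaryote/giant virus, 0.10 eukaryote, 0.60 virus) drop pairs
strictly below threshold. Two methylation thresholds deliberately coexist:
"methylated" for ratio purposes means passing the QV/coverage filters, while
the SNMV binary view uses frac > 0.5 — they answer different questions
(detection vs. majority-of-cells state).

5-mer profiles pool both strands: an occurrence of 5-mer w is the plus-strand
window around a plus-strand center and the reverse-complemented window around
a minus-strand center. Whether strand-pooled or strand-separate counting is
the better convention is genuinely open; pooling is implemented and flagged
here. 5-mers with no evaluable occurrence are *missing*, never zero, and
missingness propagates into dissimilarities via pairwise-complete handling.

Context-motif discovery is intentionally simple (a full branch-and-bound
discoverer is out of scope): windows of size k ∈ {5…8} centred on methylated
bases are stacked; positions whose base composition departs from the genome
background (chi-square, Bonferroni at α = 0.001 across window positions)
become constrained IUPAC symbols (smallest base set holding ≥ 90% of observed
mass), others collapse to N; the trimmed consensus is reported with a
Bonferroni-corrected binomial p. The per-position gate keeps the false
positive rate on random calls well under 5% (measured 0/100 seeds), at the
cost of missing weakly constrained motifs — an acceptable trade for a
screening tool.

## Dissimilarities, ordination, SNMV

Kulczynski (the default for 5-mer methylome profiles) and Bray–Curtis (the
default for SNMV/SNV vectors) are implemented directly from their formulas
with pairwise-complete missing handling. Kulczynski is undefined when either
vector sums to zero; Bray–Curtis only when both do. PCoA is classical scaling:
double-center −D²/2, eigendecompose, coordinates from positive eigenvalues
scaled by √λ. Negative eigenvalues (non-Euclidean input) are retained in the
report, uncorrected — Cailliez/Lingoes corrections are out of scope and would
obscure how non-Euclidean an input is. Axis signs are fixed by forcing the
largest-magnitude loading of each axis positive, so ordinations are
reproducible run to run.

SNMV matrices keep only positions covered at ≥ 20× per strand *in every
sample* (complete rows), so between-sample comparisons are never driven by
which samples happened to cover a site. The binary view (frac > 0.5, strict)
feeds UpSet-style exclusive intersection counts.

## Population genetics

The SNP rule (> 1% frequency and ≥ 4 supporting reads, union over samples) is
applied exactly at its boundaries: 4 reads of 100 qualifies, 3 does not, and
4 of 400 (exactly 1%) does not. π uses the (n/(n−1)) small-sample correction;
between-sample diversity uses none, because cross-sample read draws are
independent. The F_ST estimator is Hudson-style ratio-of-averages — stable
when most sites carry little diversity, and verified against the algebraic
evaluation of the same estimator on true frequencies (the generator records
that truth). Shannon diversity uses the natural log. The methylome–F_ST
correlation reports the parametric Pearson p alongside an optional Mantel
permutation p, because sample pairs share samples and are not independent.

## Replication structure

GC skew uses 1 kb windows with 100 bp steps by default (the scale at which
bacterial replichore structure is visible; both configurable). *ori* is the
cumulative-skew global minimum and *ter* the global maximum under the
leading-strand G-excess convention; ties break to the lowest coordinate, and a
flat cumulative skew returns nothing rather than a fabricated origin.
Multi-contig genomes are analyzed in their given contig order — concatenation
order is an explicit input, never guessed, since contig reordering against a
reference is out of scope.

The gradient model is linear: hemimethylated cell fraction h(d) = h₀(1−d)
with d the relative replichore position, giving pooled per-strand fraction
m(d) = 1 − h₀(1−d)/2. Linearity is the simplest monotone model consistent
with a replication fork advancing at roughly constant speed in an
exponentially growing population; richer exponential-age models are an
extension point. The fit is closed-form least squares, h₀ clipped to [0,1],
and is applied to sites methylated in the sample (frac > 0.5): unmethylated
loci reflect target-site competition, not cell-cycle state, and would bias h₀
upward. Region comparisons use *ori* = d ≤ 0.1, *ter* = d ≥ 0.9 (10% of each
replichore — the region widths are this package's declared defaults) with
two-sided rank-sum tests.

## Motif enrichment

The regulatory region is defined as 100 bp upstream of each gene start,
strand-aware, truncated at contig edges and at neighboring gene bodies —
the definition is this package's own (typical bacterial promoter spacing),
configurable and reported in output. Precedence is genic > regulatory >
intergenic; overlapping genes resolve to genic.

The null shuffles gene placement, not motif sites: each replicate places the
observed number of genes per strand at the observed mean length (the fixed
mean, read literally; resampling empirical lengths is exposed by flag),
uniformly without overlap within a strand, genes on opposite strands free to
overlap. 500 replicates by default. Tests are two-sided (both enrichment and
depletion are of interest). When the null's Shapiro–Wilk p > 0.05 the
observed density becomes z = (obs−mean)/sd with a normal p; otherwise the
two-sided empirical p (1 + #{|null−mean| ≥ |obs−mean|})/(n+1) is used.
Calibration was verified by simulation at the null's own generating process:
type-I error 5.1% at α = 0.05 over 1000 genomes at 200 replicates each.

## Viral clustering

The Dice distance is computed as D = 1 − 2·AB/(AA+BB), clamped to [0,1].
Because translated alignment is not symmetric, AB and BA hit sums are averaged
when both directions are present; whether upstream tools deduplicate
reciprocal hits varies, and averaging restores metric symmetry regardless.
Neighbor joining is the standard Saitou–Nei agglomeration with deterministic
tie-breaking (lowest label-index pair) and negative branch lengths clamped to
zero with the deficit reported; it recovers every additive matrix exactly
(property-tested to n = 12 against a path-length oracle and cross-checked
against an independent implementation). The depletion score divides observed
motif counts by the expectation under an order-1 Markov model fitted to the
genome itself, correcting for mono- and dinucleotide composition.

## The synthetic-data generator

The generator's defaults are the emulated study conditions: 10 samples
("stations"), ~100× per-strand depth (the study genome averaged ≈ 113×),
GANTC planted at 1 locus/kb (≈ 2 strand-sites/kb, matching the observed
~2,500 strand-sites on a ~1.3 Mb genome), per-locus methylation probability
0.85 (observed per-sample rates spanned ~71–95%), and 2.4% of loci
permanently unmethylated in all samples. The genome is 100 kb — an order of
magnitude below a real Pelagibacter genome, chosen so full corpora regenerate
in seconds; every estimator tested is scale-free in genome length.

IPD ratios are lognormal (positive support, heavier right tail, mimicking
kinetic noise): control mean 1.0 with sd 0.35, modified mean 4.0 (m6A) or 2.0
(m4C) with a matching coefficient of variation. These magnitudes are plausible
stand-ins, not measured values, and are configurable. Strain mixtures place
two sample groups at ±divergence/2 around a common baseline frequency; read
counts are binomial at Poisson depth, and the analytic F_ST of the true group
frequencies is recorded as ground truth. Phage sets plant the motif at a
normal and a depleted rate (factor 0.2 by default) after scrubbing background
occurrences, with a bit-score table whose within-clade similarity exceeds
between-clade by construction.

A single integer seed fans out to per-component substreams via spawn keys, so
the corpus is byte-identical across runs and adding a new component never
perturbs existing draws.

**What the generator does not emulate** — and hence what passing tests do not
show about real data: read-level sequence errors and mapping artifacts,
context-dependent kinetic variation (real IPD signal depends on surrounding
bases), linkage between SNV loci, partial motif-site occupancy dynamics over
time, horizontal transfer, and real phage–host alignment structure (bit-score
sums are constructed, not derived from alignments). Parameter-recovery results
demonstrate estimator correctness under the stated model, not robustness to
these real-world violations.

## Problem sizes used in routine runs

The test suite and the acceptance script run scaled-down corpora chosen as
the package's own defaults for quick verification: genomes of 4–100 kb,
1000 population loci at depth 100, enrichment calibration over 1000 null
genomes × 200 shuffle replicates, discovery false positives over 100 seeds,
and phage sets of 8 + 8 genomes of 10 kb. All sizes are configurable upward.

## Known limitations

- De novo motif discovery handles contiguous motifs only; bipartite motifs
  (e.g. CGANNNNNNAATC) are scanned and profiled but not discovered.
- The moment fraction estimator assumes the configured μ_m; a mis-specified
  modified-site mean biases fractions multiplicatively.
- GC-skew localization needs a coherent replichore structure; heavily
  rearranged or misordered multi-contig MAGs yield unstable extrema (the
  flat-skew warning path).
- F_ST from pooled reads ignores within-sample linkage; it matches the
  analytic truth under independent sampling, which real reads violate when
  strains are few and coverage deep.
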