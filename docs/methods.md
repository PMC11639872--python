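# Methods

`coralstress` implements a comparative thermal-stress transcriptome analysis
for coral holobionts: separating host and symbiont transcripts, cataloguing
stress-response genes (SRGs), testing differential expression between
time-matched control and heated libraries, quantifying transcriptome-wide
plasticity, and classifying SRGs as *frontloaded* (constitutively high,
stress-stable) versus *low-basal responsive* (inducible).  This note records
the models, the defaults and their rationale, what the synthetic generator
does and does not emulate, and the numerical choices made where the design
was genuinely open.

## Study design assumed

Per species: 3 colonies x 2 treatments (control 28 °C, heated 32 °C) x
2 sampling times (4 h, 24 h) = 12 libraries, with colony as the biological
replicate.  Counts are RSEM-style expected counts per gene per library;
non-integer values are rounded half-to-even on ingest (the NB exact test
requires integers) with a logged warning.

## Transcript filtering and binning

Isoform retention follows three rules applied in order: (1) isoforms with
zero combined IsoPct (summed across libraries — the aggregation is an
explicit choice, since per-library percentages must be pooled somehow before
comparison) are dropped; (2) one representative isoform per transcript is
kept, keyed by highest combined IsoPct, then longest length, then
lexicographic isoform id (a deterministic order is required; IsoPct is the
primary key because it reflects expression support); (3) only
protein-coding isoforms survive (the coding flag is an input — ORF
prediction is upstream).

Binning uses the taxonomy of the best protein hit with e-value <= 1e-5:
Cnidaria -> host, Dinophyceae -> symbiont, anything else or no hit ->
dropped.  Hit ranking is e-value ascending, then percent identity
descending, then bitscore, then subject id: e-value is the standard primary
criterion, identity resolves exact ties (common when e-values underflow).
Lineage resolution to Cnidaria/Dinophyceae must happen before ingestion;
taxon matching is by exact label.  Symbiont affiliation takes, per
symbiont-bin transcript, the best hit against Symbiodiniaceae reference
genomes (Smic/Bmin/Cgor/Dtre/Fkaw labels) and reports count fractions.
Per-bin GC content is (G+C)/(A+C+G+T) pooled over the bin, ambiguous bases
excluded — a coarse composition check: host assemblies sit near 42% GC,
symbiont assemblies near 55%.

## SRG catalogue

A gene joins an SRG family when it carries >= 1 of the family's defining
Pfam accessions at domain e-value <= 1e-5.  A gene maps to at most one
family; ties go to the first family in definition-file order (logged), which
makes the catalogue a deterministic function of its inputs.  The shipped
`srg_families.tsv` is a small example spanning the chemical / pathogen /
wounding categories with real Pfam accessions; it is a labelled synthetic
stand-in, and real analyses should supply a curated table.  Family
abundances are reported relative to the species' total predicted peptides.
Group screens (e.g. Robusta vs Complexa) use OLS on
log(relative abundance + half-minimum-positive pseudocount) against a
two-level group indicator with Benjamini–Hochberg correction and the
conventional q < 0.25 screen — a transparent re-expression of the
linear-model-on-transformed-abundance approach used by microbiome
association frameworks, without importing one.  Orthogroup gene-count
profiles are compared by Pearson correlation; zero-variance vectors yield
missing entries rather than arbitrary values.

## Normalization and transforms

* CPM = count / library size x 1e6; TPM divides by gene length first and
  renormalizes.  Both column-sum identities hold to machine precision.
* Expression filter: keep genes with CPM strictly > 2 in >= 2 libraries
  (strict inequality deliberately — the boundary value 2.0 fails).
* TMM factors: M-values against a reference sample (75th-percentile rule),
  doubly trimmed (30% per M tail, 5% per A tail), averaged with
  inverse-asymptotic-variance weights, rescaled to geometric mean 1.
* Median-of-ratios size factors use only genes positive in every sample.
* The ordination/plasticity transform is `log2(count / size_factor + 1)` on
  median-of-ratios factors: a depth-corrected, variance-stabilized log scale.
  It deliberately replaces shrinkage-based regularized-log transforms —
  empirical-Bayes shrinkage is an implementation detail of another
  framework, while the role the transform plays here (comparable log-scale
  profiles for PCA, PERMANOVA, and distances) is preserved and the
  transform is exactly reproducible.
* Fold changes use a symmetric prior count of 0.5 on group-mean expression:
  log2((m_heated + 0.5) / (m_control + 0.5)).  The prior keeps zero means
  finite and makes the statistic antisymmetric under group exchange.

## Differential expression

Counts for the two groups are first rescaled to a common effective depth
(geometric mean of TMM-effective library sizes) and rounded — a pragmatic
stand-in for quantile-to-quantile NB pseudo-count adjustment whose behaviour
is pinned by enumeration tests where it matters (small counts).  With
NB(μ, φ) counts (variance μ + φμ²) and n_g replicates, the group sum is NB
with size n_g/φ, so conditional on a gene's total t the group-A sum follows
a ratio-of-NB-pmfs distribution free of μ; at φ = 0 it reduces to a
binomial split.  Two-sided p-values double the smaller tail (observed point
included in both tails), capped at 1 — deterministic and conservative for
skewed conditionals.  The common dispersion maximizes the conditional
log-likelihood given per-group totals (the conditional likelihood is free of
the gene means), via bounded search on log φ, floored at 0.

Calls use |log2FC| >= 4 with BH FDR < 0.05.  Note the interplay of
estimation noise with the call threshold: when the *true* effect sits
exactly at the threshold, the estimated log2FC exceeds it only about half
the time even though the test is essentially always significant — so
"fraction of planted threshold-sized effects called" measures estimator
noise around the threshold, not test power.  Power proper (FDR < 0.05 with
correct sign) is ~1.0 at |log2FC| = 4, baseline CPM > 50, n = 3+3, φ = 0.1.

## Multivariate statistics

PCA runs on the 500 highest-variance genes of the transformed matrix
(gene-centered, full SVD).  PERMANOVA is one-way on Euclidean distances of
the transformed profiles: pseudo-F from total and within-group sums of
squared distances, free permutation of labels (no strata — no blocking
structure is modelled), p = (1 + #{F_perm >= F_obs}) / (n_perm + 1) so p is
never 0; an exhaustive mode enumerates all distinct labelings for small n.
The pipeline runs it per species and origin bin on (a) treatment and (b) the
four treatment x timepoint cells — two one-way analyses rather than a
multi-factor decomposition, which is out of scope.

Plasticity is the Euclidean distance of each sample's transformed profile
from the centroid of the 4 h control group, computed in the full gene space
by default ("transcriptome profile" names no projection); a first-two-PCs
variant is available as a flag.  Differences across the four treatment x
timepoint cells are tested by one-way ANOVA with Tukey HSD post-hoc
contrasts (studentized-range family-wise control at α = 0.05).

## Frontloading

Basal expression is the mean CPM over all control libraries (both
timepoints; CPM is the normalized gene-level unit the methods work in, and
the unit is switchable cpm|tpm|vst).  A gene is frontloaded iff basal >
transcriptome median (strict) and |log2FC| < 2 (strict) at *both*
timepoints — a gene frontloaded overall should be stable throughout the
exposure; an either-timepoint variant is a flag.  Low-basal responsive
genes have basal <= median and an "up" DE call; the two flags are mutually
exclusive by construction.  Per-family enrichment of frontloaded genes is a
one-sided hypergeometric test (frontloaded-in-family against the overall
frontloaded fraction given family size), BH-adjusted — the test is a
design choice, as no specific test is canonical for this contrast.

## Synthetic data generator

The generator plants exactly the structure the analysis assumes, per
species: baseline log2 mean expression ~ Normal(5, 2) (a realistic
right-skewed expression distribution with a meaningful median); NB counts
with common φ = 0.1 (variance μ + φμ²); library sizes log-normal around
1e6 (σ = 0.3) with expected library totals matching the drawn size, so CPM
differs from raw counts and normalization is exercised; planted DE in 5% of
host genes at |log2FC| = 4 (half up, half down) in heated libraries at both
timepoints; 10% of host genes are SRGs, split 50% frontloaded (basal drawn
1.5–4 log2 units above the baseline median, |planted log2FC| < 0.5), 30%
responsive (basal 1–3 log2 units below the median, planted log2FC = 4
under heat), and the remainder low-basal and stable — mirroring the
observation that inducible species hold their SRGs below the transcriptome
median until stressed.  Hit tables give each gene 1–3 hits whose best entry
carries the true lineage with probability 0.98 (default); symbiont genes
draw a reference-genome affiliation from a configurable mixture (default
dominated by Cladocopium goreaui with a Durusdinium trenchii minority, the
generalist pattern; a Dtre-dominated mixture emulates the
thermally-sensitive-host pattern).  Sequences are i.i.d. nucleotides at
origin-specific GC (host 0.42, symbiont 0.55).

What the generator does **not** emulate: per-gene dispersion heterogeneity
(a single common φ by default), gene–gene correlation, colony (repeated
measures) structure, isoform-level redundancy, length biases in counting,
and real domain architectures.  Passing recovery tests therefore
demonstrates the machinery is correct under its stated assumptions — not
that real coral data satisfy those assumptions.

## Problem sizes used in tests and the acceptance script

Chosen as comfortable desk-scale defaults: exact-test oracle checks on ~300
small instances; type-I error on 20 simulated null datasets of 2000 genes
(n = 3+3, φ = 0.1); power on 1000 planted genes across 5 datasets;
PERMANOVA null calibration on 200 runs of 999 permutations (n = 8);
plasticity scenarios on 50 seeds of a 400-gene species; frontloading
recovery on the default 2000+1000-gene species; the end-to-end run on the
default 4-species bundle (3000 genes x 12 libraries each).

## Known limitations

* The exact test's depth equalization (rescale + round) is an approximation;
  its error is negligible for near-equal libraries and pinned by tests at
  small counts, but extreme depth imbalance will distort small-sample tails.
* The common-dispersion model underfits data with strong per-gene dispersion
  trends; a per-gene φ hook exists in the generator but not the estimator.
* PERMANOVA and the plasticity ANOVA ignore colony as a blocking factor.
* The group-association screen assumes two groups and >= 2 species per
  group; with 2 species per group it has minimal power and flags this.
* GC summaries pool bases across a bin; they are not per-transcript
  distributions.
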