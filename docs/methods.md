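# Methods

This note documents the models, conventions and design choices behind
trio-mirnet: what each stage assumes, which parameters matter, what the
synthetic generator does and does not emulate, and the limitations a user
should keep in mind.

## Study design and data model

The design is factorial: genotype ∈ {TG (stress-tolerant), SG
(stress-sensitive)} × treatment ∈ {CG (control), WS (pre-anthesis water
deficit), HS (post-anthesis heat), WH (combined)} × time-point ∈
{5, 15, 25, 35, 45} days post anthesis (DPA), with replicate libraries per
cell. Abundance matrices are features × libraries with a declared unit
(raw counts, RPM, or FPKM; FPKM requires feature lengths). Degradome
libraries are sampled at one time-point (default 5 DPA, where transcriptome
and degradome sequencing are performed), over genotype × treatment ×
replicate.

## Normalization

- RPM: `x / library_total × 10⁶`; column sums are exactly 10⁶. Used for
  sRNA counts and for degradome site tags (over the library's *total* tag
  count, not just the tags at candidate sites).
- FPKM: `x × 10⁹ / (length_nt × library_total)`. Used for mRNA counts.
- Zero-total libraries are an error naming the library; per-library
  five-number summaries (min, quartiles, median, max) are provided for
  abundance-distribution reporting.

Per-million scaling is not compositionally robust: a few extreme features
can shift every other feature's normalized value. The synthetic defaults
keep catalogues large enough (hundreds of features) that this effect is
negligible; on real data with dominant features a robust scale factor
(TMM/median-of-ratios) would be a sensible pre-step, which this package
does not implement.

## Differential expression

Tests run per feature on log₂(x + pc) transformed normalized abundances
(pc = 1.0 by default); the log transform stabilizes the strong
mean–variance relationship of sequencing counts before a location test.
Methods:

- `moderated_t` (default, two groups): pooled-variance t-statistic whose
  per-feature variance is shrunk toward a prior shared across features.
  The prior (d₀, s₀²) is a scaled inverse chi-square fitted by moments on
  the log sample variances (digamma/trigamma equations; d₀ = ∞ when the
  spread of log variances is within chi-square sampling noise, in which
  case all features share s₀²). Posterior variance
  (d₀s₀² + d·s²)/(d₀ + d) with d₀ + d degrees of freedom. At 3 replicates
  per group a plain t-test has 2–4 residual df, which makes it both
  conservative (measured type-I error ≈ 0.034 at α = 0.05 for Welch) and
  weak (per-side power ≈ 0.90 at a 4-fold effect, dispersion 0.1); the
  moderated test restores both (measured type-I error ≈ 0.046–0.051,
  per-side power ≈ 1.0 under the same conditions). This is why it is the
  default rather than the plain Welch test.
- `welch_t`, `student_t`: the plain unequal-variance and pooled t-tests,
  for transparency and for contracts that specify them.
- `anova`: one-way ANOVA for >2 groups (e.g. four-treatment DEM calls at
  one time-point). An omnibus test carries no direction, so log₂FC is
  reported as 0.0 and such results are excluded from the antagonism step.

Effect size is always `log2((mean₁ + pc)/(mean₂ + pc))` on the
untransformed group means. All-zero features get p = 1 and log₂FC = 0.
Benjamini–Hochberg q-values are computed over the tested features and
reported alongside raw p; the pipeline's significance filter is raw
p < 0.05 (configurable), matching the analysis convention this pipeline
reproduces, with q available for stricter filtering.

## Temporal classification and presence

Five-point developmental profiles (mean abundance at 5/15/25/35/45 DPA)
fall into six classes: descending (non-increasing with a ≥ 2-fold
end-to-end drop), ascending (mirror), peak_15/25/35 (unique maximum at an
interior time-point), else other. The 2-fold trend requirement is
configurable; the rule is scale-invariant. Presence/Venn membership calls a
feature "expressed" in a group when its maximum normalized abundance there
exceeds a threshold (default 0, i.e. any signal), supporting per-time-point
treatment Venn counts and exclusive/common set reporting.

## Target prediction

Allen-type plant scoring on gapless duplexes: per miRNA position, match 0,
G:U wobble 0.5, mismatch 1.0, penalties doubled across positions 2–13; a
window passes at score ≤ 4.5 (configurable). Coordinates are 1-based on the
transcript sense strand; the miRNA binds antiparallel, so position 1 pairs
the site's 3′-most base, and the recorded cleavage position is the
transcript nucleotide opposite miRNA position 10 (the 10–11 duplex centre).
Gapless-only scanning keeps exhaustive window scoring exact and matches the
dominant plant cleavage-site geometry; bulged sites and translational
repression are out of scope. Note one asymmetry: the positional doubling is
indexed on the miRNA strand, so duplex scores are strand-exchange symmetric
only with uniform weights, and G:U wobbles are not invariant under
complementing both strands (G:U ↦ C:A); the tests pin both properties where
they do hold.

## Degradome categories

A candidate site's category depends on its tag count c within its
transcript's t-plot: none (c = 0, fails validation), 4 (c = 1), and for
c > 1: 0 if c is the profile's unique maximum, 1 if a tied maximum, 2 if
below the maximum but above the median, 3 otherwise. Maximum and median are
computed over tag-bearing positions only — including the structural zeros
of a long transcript would make category 2 nearly unattainable. Categories
are called per library on raw integer tags; a site is validated when its
category is ≤ `max_category` (default 4, i.e. any tag evidence) in at least
one library, recording the best category and library. Differential
degradation across conditions uses the site-level tag-RPM matrix under the
same testing contract as expression.

## Enrichment

Upper-tail hypergeometric test (one-sided Fisher): p = P(X ≥ k) for k study
hits in a term of n_term genes, study size n_study, universe N. The
universe defaults to all annotated genes and can be set to a measured-gene
universe explicitly — the choice changes p-values and is deliberately
explicit. Rich factor = k / n_term. Terms below 3 members are skipped;
BH q over tested terms. No GO-DAG propagation or term redundancy pruning.

## Three-step integration

1. **Pair universe**: one (miRNA, gene) pair per degradome-validated site
   set, keeping the best category; both members must pass the presence
   rule. Transcript→gene collapsing is an explicit map when supplied.
2. **Joint significance**: both members at raw p < α (default 0.05) in the
   same contrast.
3. **Antagonism**: strictly opposite log₂FC signs; direction annotated as
   mirna_up_mrna_down or mirna_down_mrna_up. Zero log₂FC (possible under
   ANOVA) is excluded as directionless.

Contrasts are evaluated independently (a pair may appear under several),
and come as stress-response (treatment vs CG within genotype) or genotype
(TG vs SG within treatment, "up" = higher in the tolerant genotype).
Differential degradation is available as an optional fourth predicate but
is off by default. Soundness is auditable: an independent predicate pass
(`is_antagonistic_module`) re-checks every exported module. Under a global
null the expected module yield per pair-contrast is ≈ α²/2 (both sides
significant × opposite signs), which the calibration checks measure
empirically rather than assume.

## Synthetic data generator

The generator is first-class, tested code; its defaults are the reference
study conditions used throughout the tests:

| parameter | default | meaning |
|---|---|---|
| n_mirna, n_transcript | 400, 400 | catalogue sizes |
| mirna_length_range | 21–24 nt | mature miRNA lengths |
| transcript_length | 600 nt | host transcript length |
| n_planted_pairs | 500 | embedded target sites (≥30 nt apart) |
| n_antagonistic | 50 | pairs with coupled differential effects |
| effect_log2fc | 2.0 | planted effect (miRNA +, mRNA −, or mirrored) |
| dispersion | 0.1 | NB overdispersion, Var = μ + 0.1μ² |
| n_replicates | 3 | libraries per design cell |
| base mean | log-normal, median 100 | per-feature baseline count |
| degradome_peak_fraction / scale | 0.5 / 10 | peak mean = 0.5 × cell miRNA mean / 10 |
| background_tag_rate | 0.05 | Poisson tags per position |

Sites are exact reverse complements of their miRNA unless weakened by a
per-site edit plan (mismatch or G:U at a chosen miRNA position); the truth
table records site coordinates, cleavage positions, the antagonistic
contrast of each coupled pair and its direction, and the null features.
Antagonistic pairs use disjoint miRNAs and transcripts — two pairs sharing
a transcript in one contrast would cancel each other's planted mRNA effect
and make the truth unrecoverable in principle. Each generation stage draws
from its own stream spawned from the seed, so outputs are byte-identical
under a fixed seed regardless of which stages run. Catalogue sizes default
to 400×400 so that per-million totals are insensitive to the ~8 planted
effects per design cell, as they are in real libraries with hundreds to
thousands of features.

What the generator does **not** emulate: sequencing-read level noise and
adapter/size-selection artifacts; mapping ambiguity in a polyploid genome;
correlated biological replicates; isoform structure (one transcript per
gene); miRNA biogenesis (no hairpins); degradome tags from general decay
pathways that concentrate at non-cleavage hotspots; library-composition
skew. Passing the recovery tests therefore demonstrates the statistical
machinery is correct under its stated model, not that a real study of this
design would reach the same recall.

## Numerical and edge-case conventions

- RPM column sums equal 10⁶ to float precision; tests assert closed forms.
- Degenerate variance (identical groups) yields p = 1 rather than NaN.
- Temporal monotonicity uses a 10⁻⁹ relative tolerance for ties.
- Category calls ignore zero-count positions entirely, so profiles may be
  stored sparse or dense interchangeably.
- Candidate sites on transcripts without degradome profiles are dropped
  with a warning, not an error.
- The trigamma inversion in the variance-prior fit uses Newton iteration
  from the 1/x asymptote; d₀ = ∞ (common variance) is handled explicitly.

## Problem sizes

The reference scenario (400×400 catalogue, 120 expression libraries, 24
degradome libraries) runs the full pipeline in ~20 s on one core; the null
calibration uses 2000 features per assay; oracle checks use 1000 random
instances each. These sizes were chosen so the complete validation suite
runs comfortably on a laptop while keeping binomial error bars on the
calibration estimates small.

## Known limitations

- Raw-p filtering at 0.05 is the reproduced convention, not a
  recommendation; q-based filtering is available and generally preferable.
- Per-million normalization and the independence assumption between pair
  members under the null are approximations; both are measured, not
  assumed, by the calibration checks.
- The degradome coupling (peak mean linear in miRNA abundance) is the
  simplest model that produces category-0 signatures at expressed sites;
  real cleavage efficiency varies with site accessibility and pairing
  details that are not modelled.
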