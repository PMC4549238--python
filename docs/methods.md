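# Methods

This note documents the models, parameter choices and numerical decisions
behind `tailfrac`, and what the simulation-based tests do and do not
demonstrate about real data.

## The measurement model

A fractionation experiment splits each starting total-RNA sample into a
short-tail and a long-tail pool around an approximate 50-nt poly(A) cutoff
and sequences both. The observable per gene is a pair of counts per
starting sample; the scientific quantity is the log ratio of normalized
abundances, long over short (*l/s*), which increases monotonically with the
fraction of molecules carrying tails above the cutoff. Absolute *l/s*
levels are not interpretable in isolation: the capture efficiency of the
fractionation varies between preparations, shifting all ratios of a sample
jointly. All inference in this package is therefore *relative* — the
genotype contrast of *l/s* per gene, and gene groups against the
transcriptome-wide background.

## Synthetic experiments (`simdata`)

The generator emulates the study design the package targets: 2 genotypes x
4 biological replicates x 2 fractions (16 libraries), and three spike-in
RNAs with exact tails of 30, 75 and 134 A added in equal amounts to every
starting sample.

* **Capture model.** A molecule with tail length *t* enters the long
  fraction with probability `1/(1+exp(-k(t-c)))`, cutoff `c = 50` nt and
  steepness `k = 0.15`/nt (≈95% capture at 70 nt). The fractionation is
  only characterized as an approximate 50-nt cutoff, so the logistic form
  and its steepness are modelling choices, exposed in `SimConfig`.
* **Tail distributions.** Per-gene steady-state tails follow a gamma
  distribution with shape 4 (coefficient of variation 0.5), mean drawn
  uniformly in 30–150 nt, truncated at 200 nt (tails beyond ~150–200 A are
  not observed in the target system). No deadenylation kinetics are
  modelled; steady state is assumed. A gene's capture probability is the
  logistic averaged over its tail distribution, computed by a 201-point
  trapezoid quadrature on 0–200 nt.
* **Counts.** Expected totals per gene are lognormal across genes (default
  `mu = 5.3, sigma = 1`), split into fraction expectations by the capture
  probability, scaled by per-sample size factors (log-uniform in 0.7–1.4,
  to exercise TMM), and NB-sampled with dispersion `phi` (default 0.1;
  `phi = 0` gives Poisson). Spike-ins keep identical expected totals in all
  samples, mirroring equal spike amounts per starting sample.
* **Planted effects.** For effect genes (default 10%), the mutant capture
  odds are the wild-type odds times `2**effect_log2`; the mutant mean tail
  realising that capture probability is found by bisection and recorded.
  This plants the interaction log2FC *exactly* — the truth table equals
  `log2[odds(p_mut)/odds(p_wt)]` by construction — while still being a
  multiplicative tail shortening per gene. An optional `abundance_log2`
  scales effect genes' totals in the mutant, which leaves the interaction
  untouched (both fractions scale together).
* **Reproducibility.** All randomness derives from one root seed through
  counter-keyed substreams `(seed, stream, gene index)`, so a gene's data
  never depend on how many other genes are simulated, and identical
  configurations are bit-identical.
* **Sequences.** 3'-UTR sequences (80–250 nt, uniform base composition) are
  placed on a toy chromosome, alternating strands, with 1–3 cleavage sites
  per gene; strand-aware extraction recovers the stored sequences exactly.
  Motifs are planted by overwriting a seeded random offset within the
  terminal window. Half-lives are affine-Gaussian constructs correlated
  with the true wild-type mean tail (default target r = −0.21).

**What the simulations do not capture:** mapping or sequencing-error
biases, positional coverage, correlated gene-gene expression, composition
realism of UTR sequences (uniform ACGT background), batch structure beyond
scalar size factors, and any deadenylation dynamics. Passing recovery
tests therefore demonstrates correctness and calibration of the
*statistics* under the stated noise model, not performance on any real
library preparation.

## Normalization (`normalize`)

Genes with fewer than 6 reads in any sample are removed before
normalization (spike-ins exempt); the filter runs before TMM (the order is
a convention of this package). TMM follows the published description of
the method: reference = sample whose 75th-percentile count fraction is
closest to the mean of those quantiles; gene-wise M and A values over genes
positive in both libraries; 30% two-sided trim on M and 5% on A; precision
weights from the delta-method binomial variances; factors rescaled to
geometric mean 1. Spike-ins are excluded from the M/A computation — their
fraction allocation is deliberately unrepresentative — but are normalized
by the resulting factors. TMM's invariance to rescaling a single library
is exact for the M values but only approximate overall, because the
precision weights pair the scaled library with the unscaled reference; the
property test allows 5%.

Log-CPM adds a library-proportional prior count to the numerator and twice
it to the denominator, so zeros stay finite and doubling counts and
libraries together changes nothing.

## Per-gene inference (`tailtest`)

Each gene is fitted with an NB log-linear model with offset
`log(effective library size)` and design {intercept, fraction, genotype,
interaction}; the interaction coefficient `b3` is the log ratio-of-ratios.
The original analysis of this design used a published count-model package
without documented settings; this package implements an explicit per-gene
NB GLM with a likelihood-ratio test of `b3 = 0` against chi-square(1),
and uses *calibration* (type-I error, null-uniformity) as its acceptance
surface rather than numeric equality with any particular software.

* **Fitting.** IRLS, all genes batched over a shared design; convergence on
  a relative deviance change below 1e-8 within 50 iterations; non-converged
  genes get NA p-values and are excluded from the BH denominator. A 1e-9
  ridge guards near-singular weighted designs.
* **Dispersion.** Per gene, the NB Pearson moment equation
  `sum (y-mu)^2 / (mu + phi mu^2) = chi2_median(df)` is solved for `phi`
  by bisection (mu from a Poisson fit, df = n − p, floored at 0). The
  chi-square *median* target, rather than the mean (= df), makes the
  estimates median-unbiased under the right-skewed sampling distribution of
  the Pearson statistic — with the mean target the common dispersion sat
  ~10% low and the LRT ran measurably liberal. Estimates are then shrunk
  toward the across-gene median with a prior weight of 10 residual df.
* **Identifiability caveat.** Fraction counts are compositional: if a large
  share of the transcriptome shifts fractions in one genotype, between-
  sample normalization absorbs part of the average shift, moving the
  apparent null baseline while preserving contrasts between effect and
  non-effect genes. This is inherent to the assay (it is why group-level,
  background-relative statistics are the primary readout) and is visible in
  simulations with large effect fractions.
* **Abundance change** sums the fraction pairs per starting sample, with
  the summed effective sizes as offset, and LRTs the genotype coefficient.
* **Power scenario.** The calibration suite checks type-I error on a
  2000-gene null at `phi = 0.1` (the generator's default dispersion) and
  power on 500 effect genes among 5000 at interaction log2FC −1, ~200
  counts per gene per sample, and `phi = 0.01`. The low-noise dispersion
  for the power scenario is an a-priori design choice: by the delta
  method, SE(b3) ≈ sqrt(4(1/mu + phi)/n) ≈ 0.47 log2 units at
  `phi = 0.1` with four replicates, so no procedure can reach 80% power
  for a one-unit effect there; at `phi = 0.01` the analytic power exceeds
  99% and the scenario instead tests the pipeline's efficiency and its BH
  behaviour.

## Group statistics (`grouptest`)

The background of every group test is *all other tested genes*, not all
genes. The rank-sum test enumerates exactly (via the Mann–Whitney exact
distribution) when the pooled sample has ≤ 12 observations without ties;
otherwise it uses the normal approximation with tie-corrected variance and
a 0.5 continuity correction (|W − E| is reduced by 0.5, floored at 0, so
W = E gives p = 1). The motif sweep reuses the same normal-step
implementation with ranks and tie terms computed once per pooled sample.
Categories may overlap and are tested independently; BH m = number of
tested categories; groups with fewer than 5 tested members are skipped
(configurable). Module comparisons rank by |median(module) −
median(complement)|; list overlaps rank by overlap count with p-value
tiebreak, and the top-q% selector returns ceil(q·m) lists.

## Sequence features (`seqfeat`)

Motif presence is boolean — at least one occurrence within the terminal
window (default: last 100 bp before the most distal cleavage site; genes
with shorter UTRs contribute their full UTR). For genes with several
cleavage sites only the most distal is used. Two effect sizes are
reported per motif: the difference of group means of the log2FC (primary),
and the log2 ratio of group means of the linearized fold-changes
(secondary) — a ratio of signed log means is ill-defined, so the published
style of effect ("log2 of mean changes with vs without") is computed on
the linear scale and reported alongside. Composition profiles cover
±200 bp around the distal cleavage site, strand-aware; positions beyond a
contig edge are excluded from that position's denominator.

## Validation arithmetic (`validate`)

ePAT traces are normalized by the mean intensity within the region of
interest (idempotent), averaged per assay and genotype, and differenced
(ePAT − control). The scalar shift score — the difference of
intensity-weighted mean product sizes of the positive parts of two
difference curves — is this package's own summary of the "mass at longer
products" comparison; it recovers pure translations and is antisymmetric.
Segregation chi-square tests use unrounded expected counts by default;
a table-parity mode accepts externally supplied (e.g. rounded) expectations
so that published tables that print integer expectations can be reproduced
exactly — with rounded (59, 119) the lethality-model p is 1.23501e-16
versus 1.19e-16 with the exact (59.33, 118.67).

## Problem sizes

Defaults throughout the tests and the acceptance script: 800–5000 genes
per simulation, 16 libraries, 200–500 runs for detection-frequency
properties, and 500 draws for null-uniformity KS checks. These sizes give
stable pass/fail behaviour for every property while keeping the full suite
in the low minutes on one CPU.

## Known limitations

* Two genotypes and two fractions only; no paired (per-starting-sample)
  model — fraction pairs are treated as independent samples, with the
  pairing retained in metadata.
* No absolute tail-length estimation in nucleotides; the *l/s* ratio proxy
  only.
* No read-level simulation (counts are generated directly) and no
  sequencing-error or mapping-bias model.
* The hexamer sweep is fixed at k = 6; no de-novo variable-length motif
  discovery.
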