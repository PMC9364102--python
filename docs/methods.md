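# Methods

`snpruns` implements a population-genomic analysis chain for livestock SNP
panels: detection of runs of heterozygosity (ROHet) and homozygosity (ROH)
per individual, population-level island calling, genomic inbreeding,
region-presence association with litter traits, and selection scans on
population pairs. This note records the models, the numerical choices, and
what the synthetic data generator does and does not emulate.

## Coordinate and genotype conventions

All coordinates are 1-based inclusive (PLINK MAP convention); a run from
`start_bp` to `end_bp` has length `end_bp - start_bp + 1`. Genotypes are
coded 0 (homozygous major/REF), 1 (heterozygous), 2 (homozygous
minor/ALT), -1 (missing). Only autosomes are analysed; non-autosomal map
entries are dropped with a warning because every genome-wide summary
(including the autosomal length `L_AUTO` in F_ROH) is defined over
autosomes. MAF is computed over non-missing calls only.

## Run detection

**ROHet (consecutive strategy).** Per individual and chromosome, maximal
stretches of heterozygous calls containing no homozygous and no missing
genotype, with inter-SNP gaps of at most `max_gap_bp` (default 500 kb), are
reported when they span at least `min_length_bp` (default 1 Mb) and contain
at least `min_snps` SNPs (default 16, i.e. "more than 15" read strictly;
the threshold is a parameter). Run boundaries are the first and last SNP
positions of the stretch — SNP positions, not midpoints, the simplest
defensible convention.

**ROH (sliding-window strategy).** A window of `window_snps` (default 50)
consecutive SNPs slides along each chromosome; a window is compatible when
it contains at most `max_opposite_calls` heterozygotes and
`max_missing_calls` missing calls (both default 0). Each SNP's hit
fraction is the share of covering windows that are compatible; a SNP is
eligible when the fraction reaches `window_hit_threshold` (default 0.05,
the convention of the PLINK-style method; the source method description
does not state it). Maximal stretches of consecutive eligible SNPs with
bounded gaps become candidate runs, retained when they meet the length,
SNP-count and SNP-density (default 2 SNPs/Mb) thresholds. Chromosomes
with fewer SNPs than the window are evaluated with a single truncated
window rather than rejected, so edge SNPs stay detectable.

A consequence of the window vote worth knowing: the outermost ~2 SNPs of a
genuinely homozygous stretch are never eligible at the default threshold
(they are covered almost entirely by windows that reach outside the
stretch), so detected ROH are systematically about two SNPs short at each
boundary. Recovery checks therefore score a planted segment as found when
a run covers at least 90% of it, rather than demanding exact boundaries.

**Minimum SNP count.** The ROH SNP threshold comes from the
false-positive bound

    l = ln( alpha / (n_s * n_i) ) / ln(1 - het_bar)

with `alpha` the tolerated genome-wide false-positive rate (0.05), `n_s`
SNPs per individual, `n_i` individuals and `het_bar` the mean
heterozygosity across SNPs. The value is floored (rounding is a
parameter; only resulting integers are ever published, so the convention
cannot be pinned down from outside). `l` is non-increasing in `het_bar`
and non-decreasing in `n_s * n_i`.

**Post-filters.** Runs with fewer than 5 SNPs, and runs whose merged
population region is carried by fewer than 5% of individuals, are dropped.

## Length classes and F_ROH

Runs fall into five classes: (1-2], (2-4], (4-8], (8-16] and >16 Mb,
upper-inclusive so a run of exactly 2.0 Mb is "1-2 Mb". Percentages are
reported to two decimals. Genomic inbreeding is
`F_ROH = sum(L_ROH) / L_AUTO` per individual, with `L_AUTO` defaulting to
2.452 Gb (the autosomal span covered by a porcine 50K panel).

## Islands

Each SNP's occurrence is the fraction of individuals whose runs cover its
position. The empirical p-value is the classical one-sided construction
`(number of SNPs with strictly higher occurrence + 1) / n` — equivalently
rank/n with minimum rank for ties — adjusted by Benjamini-Hochberg over
all SNPs. Island SNPs are those with adjusted p below 0.01 that are
covered by at least one run; consecutive island SNPs (gap <= 500 kb) merge
into island intervals.

The tie rule matters. Rank/n p-values are exactly the uniform order
statistics, so with average-rank ties BH returns values near 1 (never
below 0.5, even for a fully tied top group) and a 0.01 cut-off can never
fire. With minimum-rank ties a plateau of k top-tied SNPs adjusts to 1/k:
extended regions of elevated occurrence — which is what an island is —
clear the cut-off when they hold more than ~100 SNPs, while isolated
high-occurrence SNPs cannot. The degenerate corner case (every SNP tied
at one positive occurrence) would mark the whole genome significant;
real occurrence profiles are never flat, and the coverage requirement
already removes the all-zero case.

Consensus regions merge overlapping runs across individuals and breeds by
single linkage (any bp overlap by default; a minimum reciprocal-overlap
fraction is exposed). A region is *shared* when carried in two or more
breeds, else unique to its breed. Output order is (chromosome, start) and
invariant to input order.

## Litter variability traits (LnVar)

Per-record residuals come from the repeatability model

    y = W a + Z b + U pe + e

with fixed effects `a` (farm-year-season, parity), additive sow effects
`b ~ N(0, G sigma2_b)` under a VanRaden method-1 genomic relationship
matrix `G` (centered dosage cross-product over `2 sum p(1-p)`, missing
calls mean-imputed, small diagonal stabiliser), permanent-environment
effects `pe ~ N(0, I sigma2_pe)` and residuals `e ~ N(0, I sigma2_e)`.
Records with zero total born and sows with a single record are removed
before fitting.

Variance components are estimated by EM-REML on Henderson's mixed-model
equations (convergence when successive component changes fall below 1e-6,
cap 500 iterations), with Aitken extrapolation applied every few
iterations to accelerate the geometric EM tail; non-convergence returns
the last iterate with a flag. Components may instead be supplied and held
fixed — with both sow components at zero the model collapses exactly to
fixed-effects least squares, which is also the sensible route when a
component is known to be zero, since REML estimates at a boundary approach
zero only asymptotically under EM. LnVar is the natural log (not log10)
of the per-sow sample variance (n-1 denominator) of the residuals; sows
with zero residual variance get NA with a warning. Adding a constant to
all records of a fixed-effect level changes no LnVar (the level absorbs
it).

Identifiability note: `sigma2_b` and `sigma2_pe` are separated only by the
off-diagonal structure of `G`. In a panmictic sample of unrelated
individuals the two are confounded (a flat likelihood ridge); recovery
experiments therefore simulate full-sib families (`family_size` in the
generator) so the GRM carries within-family relatedness of ~0.5.

## Region association

Each consensus region present in more than 1% of phenotyped individuals
becomes a two-level fixed effect in

    y = breed + farm_year_season + region + e

fitted by OLS one region at a time, on per-parity records, pooled records,
or per-sow LnVar values. The model deliberately has no sow effect
(mirroring the published model); repeated records per sow therefore enter
as independent rows and record-level p-values are anti-conservative when
sow-level variance exists. This inflation is documented, not corrected.
Significance uses Bonferroni over the N regions tested per run kind:
significant when p <= 0.05/N (boundary inclusive), suggestive when
0.05/N < p <= 1/N (upper boundary kept suggestive; the verbal definition
is contradictory at exactly 1/N and the inclusive reading is flagged).
Regions without presence/absence contrast, or confounded with a
fixed-effect level, return NA with a reason. The association degree of a
region is its count of significant-or-suggestive results across traits and
parity groups, ties broken by smallest p.

## Selection scan

Per-site diversity is the unbiased heterozygosity `n/(n-1) * 2p(1-p)` over
`n` non-missing alleles; window theta-pi divides the sum of site values by
the window span in bp (50 kb windows, 10 kb step by default — the
denominator is the span, not the variant count, matching the windowed-pi
convention of the standard tools). F_ST uses the Weir & Cockerham (1984)
two-population variance components a, b, c, combined per window as
`sum(a) / sum(a+b+c)` (the weighted, ratio-of-sums estimate; per-site
averaging was rejected as it is not what the cited tooling reports).
Windows where both populations are monomorphic, or without usable sites,
carry NA. `ln(pi_1/pi_2)` is antisymmetric under population swap by
construction.

Region summaries take the median log ratio over all windows with any bp
overlap. Across breed pairs the median ratio is correlated (Pearson, with
the two-sided t-test p-value) against the difference in breed mean trait
value; because pairs share breeds they are not independent, so the output
flags this and a permutation p-value is available alongside.

## Synthetic data

The generator emulates the statistical structure the analysis assumes, not
a full population history:

- Background genotypes are independent Hardy-Weinberg draws per SNP, with
  allele frequencies from a symmetric Beta whose expectation matches the
  target mean heterozygosity (default 0.20). There is **no linkage
  disequilibrium**: run structure comes only from planted segments, which
  keeps the truth set unambiguous but means chance run-like stretches are
  rarer than in real data.
- Planted segments overwrite calls (homozygous or heterozygous) for chosen
  individuals at known coordinates; missingness (default 1%, uniform) is
  injected outside planted segments only.
- Optional full-sib family structure draws children Mendelian-style from
  two Hardy-Weinberg parents.
- Litter records follow the repeatability model above with breed,
  farm-year-season (64 levels, matching the published design), parity
  (1-8) and optional region effects; per-sow residual SDs can be set to
  plant log-variance signals. TNB is the rounded, floor-1 latent value,
  TND binomial given TNB, NBA the difference; the continuous latent value
  is kept for calibration work where rounding noise (variance ~1/12)
  would bias component recovery.
- Divergent pairs draw per-SNP population frequencies from the
  Balding-Nichols Beta around a shared ancestral frequency (uniform on
  0.05-0.95) at a target fixation index; an optional window rescales
  population-2 heterozygosity by a factor to plant a diversity-ratio
  signal.

Passing tests on these data show the detection, ranking, model-fitting and
estimation machinery is correct under the assumed structure; they do not
certify behaviour under LD, genotyping-error clustering, or non-Gaussian
litter-trait distributions.

## Problem sizes used in the checks

The test and acceptance experiments run at desk scale, chosen to keep the
full suite in the minutes range while leaving Monte-Carlo error well below
the asserted tolerances: detector-vs-enumeration agreement on 500 random
instances of up to 60 SNPs x 5 individuals; planted-recovery panels of
10,000 SNPs x 100 individuals; null association calibration with 2,000
region tests on 120 sows x 8 parities; variance-component recovery
averaged over 20 seeds of 400 sows x 4 parities with 3,000 SNPs;
F_ST recovery with 5,000 SNPs and 50 diploids per population.

## Known limitations

- No LD in the generator, hence no test of run detection against LD-driven
  false homozygous stretches.
- The association stage inherits the published model's lack of a sow
  effect; its p-values on repeated records are calibrated only under the
  fixed-effects-only generating model.
- EM-REML (even accelerated) is slow near variance boundaries; supply
  fixed components when a term is known absent.
- Breed-pair correlations treat pairs as exchangeable points; the t-test
  p-value ignores the dependence between pairs sharing a breed.
- The X chromosome is excluded everywhere.
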