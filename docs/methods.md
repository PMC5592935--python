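# Methods

This note documents the models, numerical choices and limitations of
`gpascent` in enough detail to reproduce or audit any result it computes.

## Doubled-haploid genome simulation

Each line carries one fully homozygous genome over `n_chromosomes` linkage
groups (default 10) of equal genetic length (default 1 Morgan), with the
total marker count split evenly over chromosomes and markers equally
spaced within each.  When the marker count is not divisible by the
chromosome count, the default is to reject the configuration
(`remainder_policy="strict"`); the `"spread"` policy, used automatically
when evaluating steepest-ascent coordinates such as m = 34, gives the
leading `m mod n_chromosomes` chromosomes one extra marker.  Genotype
codes are −1/+1 (Cockerham scaling for a diallelic homozygous population),
which makes every additive code and every additive×additive product a
unit-variance ±1 variable.

Genotypes are drawn directly as one recombinant gamete per line (doubling
is deterministic, so this is distributionally identical to simulating F1
meiosis and doubling): the first marker of each chromosome is ±1 with
probability ½, and each subsequent marker flips with probability
`r(d) = (1 − e^(−2d))/2` — the Haldane map function at the inter-marker
distance `d`.  The map function and chromosome length are modelling
choices; Haldane was chosen because it has a closed form that doubles as
an independent test oracle (adjacent-marker discordance, LD decay
`corr = (1 − 2r)^k`).  There are no missing genotypes, no mutation, no
selection and no pedigree structure.

QTL are restricted to marker loci.  Default placement is deterministic and
evenly spaced (indices `floor(i·m/q)`), for reproducibility; uniform
random placement without replacement is available.  The constraint
`q ≤ m` is enforced everywhere.

## Trait architecture

The phenotype model is `Pheno = mu + Xa·a + Xe·epi + eps` with scalar
effects shared across loci (`a = a·1`, `epi = epi·1`).  Epistatic columns
are products of **disjoint** consecutive QTL pairs in genome order —
(1,2), (3,4), … — giving ⌊q/2⌋ columns; an odd trailing QTL stays purely
additive.  A sliding-chain pairing ((1,2), (2,3), …, q−1 columns) is
available behind the `pairing="chain"` flag.  Disjoint pairing is the
default because it keeps the additive/epistatic covariance small and the
variance-share bookkeeping clean; with a DH population only
additive×additive terms exist, so an epistatic design wider than this
(e.g. one with 2q columns) has no natural construction from pairwise
interactions of q loci.

Effect scalars are solved from the empirical variances of the row sums of
`Xa` and `Xe`: `a = sqrt((1−t)/Va)`, `epi = sqrt(t/Vepi)` for a target
epistatic proportion `t`, so that `a²Va + epi²Vepi = 1` with the epistatic
share exactly `t`.  The share deliberately excludes the `2·a·epi·Cov`
cross-term, whose sign is data-dependent and which would make "proportion"
ill-defined; the cross-term **is** included in `VG` when calibrating the
error variance `Ve = VG(1−h)/h`.  Errors are i.i.d. Normal — the
conventional reading of a mean-zero error term — and `h = 1` produces
exactly noiseless phenotypes.  `mu` defaults to 0 (accuracy is
translation-invariant).  Because `Va`, `Vepi`, `Cov` are estimated per
simulated data set, the realized heritability matches the target up to
sampling error (within ±0.05 at n = 2000 in the test suite).

## Predictors

**RRBLUP.**  `y = 1μ + Zu + e` with `u ~ N(0, σu²I)`.  The shrinkage
`λ = σe²/σu²` is estimated by REML: after projecting out the intercept,
the restricted likelihood reduces to a one-dimensional profile in `log λ`
over the spectrum of the marker cross-product (`Zc'Zc` when m ≤ n,
`ZcZc'` otherwise), minimized by bounded scalar search on
`log λ ∈ [−12, 12]` with a floor of 1e−8 for the noiseless-degenerate
case.  Given `λ`, `(μ, u)` solve the ridge normal equations with an
unpenalized intercept, and test predictions are `μ + Z_test·u`.  A
fixed-`λ` mode exists and is checked against a brute-force matrix-inverse
ridge solution in the tests; the spectral profile likelihood is checked
against a dense matrix-inversion REML criterion (agreement to an additive
constant, < 1e−8 spread).  Constant training phenotypes fall back to mean
prediction with a warning.

**SVR.**  ε-insensitive support-vector regression with an RBF kernel and
the standard libsvm defaults: cost 1, γ = 1/m, ε = 0.1, all configurable.
These defaults reproduce the R `e1071::svm` behaviour on identical data to
seven decimals (±1 genotype codes are already near zero-mean/unit-variance,
so input scaling is immaterial).  A linear kernel is available through the
same configuration record.

**Accuracy.**  `r(ph, p̂h)` is the Pearson correlation between held-out
*phenotypes* (not genetic values) and predictions.  Replication follows
the study protocol: `n_datasets` independently simulated
genotype/phenotype data sets × `n_splits` independent random 80/20
train/test partitions (defaults 20 × 25 = 500; these are *independent*
splits, not rotation folds, with |test| = round(0.2·n)).  BLUP and SVR
consume identical data sets and splits, so the SVM−BLUP difference is
computed replicate-wise.  A replicate with zero-variance predictions or
responses is recorded as r = 0 and flagged, keeping the averaging total.

## Design of experiments

Factors code linearly (low → −1, high → +1; values outside the region map
linearly beyond ±1).  Full factorials enumerate all 2^p sign vectors in
lexicographic order; a regular half fraction keeps the runs whose product
over the defining word's letters equals the word's sign.  The package's
default 5-factor fraction is `I = −ABCDE`: the 16 evaluated treatment
combinations of the reference half fraction all satisfy
ABCDE-product = −1 (verified in the acceptance tests), so the negative
fraction is the one the study actually ran.  Aliases follow from word
multiplication modulo squared letters.  First-order fits are OLS on
intercept + coded main effects; on orthogonal ±1 designs each slope equals
half the high-minus-low contrast of response means, which the tests verify
to 1e−12 as an independent computation.  Singular designs raise an error
naming the collinear column pairs.  The Box–Cox transform
`w = (y^λ − 1)/λ` (log at λ = 0) with a profile-likelihood grid MLE is
provided for response-metric exploration; it is rank-preserving for any λ.

Second-order models, central-composite designs and ridge analysis are out
of scope.

## Steepest ascent

The basis is the factor with the largest |slope| (overridable).  Its coded
step is `|basis_step_natural| / half_range`, carrying the sign of the
basis coefficient (reversed for descent); other factors follow by
coefficient ratios.  Natural increments are `Δᵢ = half_rangeᵢ × stepᵢ`;
coordinates are `base + kΔ` (never cumulatively rounded), with counts
rounded to integers, proportions to two decimals, and everything clamped
to the operability regions (proportions to [0, 1]).  The default basis
step for proportion-type factors is 0.25 natural units; the step size is a
researcher choice that trades path resolution against the number of
evaluations.

Two rounding conventions exist.  The **default** keeps full precision in
every intermediate.  The **compatibility** mode reproduces hand-computed
tables: coded steps are rounded to a caller-chosen number of decimals
(the two reference paths use 2 and 3 decimals respectively), and each
increment that is not integer-valued is rounded to two significant
figures before accumulation, integers being kept exact.  This is the
unique simple rule we found that reproduces every printed increment of
both reference paths (91.2 → 91, −4.35 → −4.4, 6.57 → 6.6, 0.117 → 0.12,
0.1263 → 0.13, with 296, −24, −5.4 and ±0.25 untouched); the reference
tables themselves are not mutually consistent about decimal places, so
the convention is exposed as an explicit option rather than hard-wired.

The iterated procedure (`run_ascent`) repeats: evaluate a half fraction of
the current two-level region (full factorial when fewer than three factors
remain active, since a smaller fraction cannot support a first-order
fit) → fit → path → recenter the region on the best path point.  It stops
when the best path response fails to beat the previous round's best by a
configurable margin (default 0), when all slopes vanish, or when every
factor's region has collapsed against its operability boundary; the
stopping rule is a design choice, as the source procedure is narrative on
this point.  An audit trail records every design, fit and path.

## Surface exploration and the yield demo

`enumerate_grid` builds the 405-point study grid (levels: n ∈ {200, 1000,
2000}, m ∈ {100, 400, 1000}, q ∈ {10, 50, 100}, epi ∈ {0, 0.2, 0.5, 0.8,
1}, h ∈ {0.2, 0.5, 0.8}); the reference text is inconsistent about whether
the top heritability level was 0.8 or 1.0, so custom level lists
(including an h = 1 grid) are accepted and the summary simply reports what
was computed.  `summarize_surface` reports the maximum, argmax,
user-chosen threshold-exceedance fractions and a histogram (default bin
width 0.05).  The yield demo surface
`110 + cos²(0.25·d) + sin²(0.15·T) + 0.0024375·d·T` is evaluated with
radian arguments — the only reading under which its maximum falls at
73–74 °F (sin(0.15·T) peaks near T = 73.3) — and its 0.01-resolution grid
argmax agrees with gradient-based optimization to two decimals in the
tests.

## Seeds and determinism

Every random stream derives from `(master seed, purpose label, index)`
through `numpy` `SeedSequence` spawn keys, so identical configurations and
seeds give bit-identical genotype matrices, splits and outputs, and
changing one component's settings does not perturb another's streams.

## Problem sizes used in the shipped checks

The acceptance script and the replicated-accuracy tests use 100 replicates
per design point (10 data sets × 10 splits) rather than the full 500; at
100 replicates the Monte-Carlo standard error of a mean accuracy is well
under 0.02, comfortably inside the ±0.07 comparison tolerance, and the
full-replication protocol remains the library default.

## What the simulator does and does not capture

The generator reproduces the study's idealized conditions: equal-length
chromosomes, equally spaced markers, QTL at marker loci, no missing data,
a single biallelic cross with allele frequency ½, and i.i.d. Gaussian
noise.  Real breeding data differ in every one of these respects —
population structure, uneven maps, allele-frequency spectra,
genotype×environment interaction (deliberately excluded here), dominance
and higher-order epistasis (absent in DH material or excluded by design).
Passing tests therefore validate the machinery and the simulated response
surfaces, not claims about any particular crop data set.

## Known limitations and open observations

- Two printed surface-extreme values could not be reconciled with the
  stated simulation conditions: under full pairwise epistasis at n = 2000,
  m = 100 the measured SVM−BLUP advantage substantially exceeds the quoted
  surface maximum of 0.3 (the reference's own path table already lists
  differences up to 0.98 under comparable conditions), and the measured
  peak BLUP accuracy (≈0.88) sits above the quoted maximum of 0.80 while
  agreeing with the companion statement that 6% of grid cells exceed 0.80.
  The corresponding checks assert the printed values and are expected to
  fail; they are kept red rather than loosened.
- The printed first-order coefficients for the two responses are not
  recoverable by OLS from the printed (rounded) 16-run mean responses;
  they are treated as stored inputs to the ascent stage, never as fit
  targets.
- REML shrinkage is weakly identified when m ≫ n and heritability is
  high (the profile likelihood is nearly flat below the smallest
  eigenvalue); predictions are insensitive to λ in exactly that regime,
  so this does not affect accuracy estimates.
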