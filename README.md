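# gpascent

**Response-surface exploration of genomic-prediction accuracy in simulated
doubled-haploid populations.**

Genomic prediction (GP) trains a statistical model on genotyped and
phenotyped individuals and predicts the phenotypes of individuals with
genotypes only.  How well a method performs depends on the training
population: its size *n*, the number of markers *m*, the number of QTL *q*,
the proportion of genetic variance due to epistasis (*epi*), and the
broad-sense heritability *h*.  Comparing a linear mixed-model predictor
(ridge-regression BLUP) with a kernel machine (support-vector regression)
across these factors is interesting in its own right — a large SVM−BLUP gap
is a diagnostic for epistatic genetic architecture — but the full factor
grid (3·3·3·5·3 = 405 combinations, each needing hundreds of replicated
simulations) is expensive.  `gpascent` instead applies **response-surface
methodology (RSM)**: evaluate a two-level half-fraction of the factor
space, fit a first-order model on coded variables, and follow the **path of
steepest ascent** to the optimum in a few dozen evaluations.

The package is aimed at quantitative geneticists and simulation
methodologists who want to (a) simulate DH populations with controllable
additive/epistatic architecture, (b) estimate cross-validated GP
accuracies, and (c) drive those simulations with factorial designs and
steepest-ascent searches instead of brute-force grids.

## The model

Phenotypes of *n* DH lines are simulated as

```
Pheno = mu + Xa·a + Xe·epi + eps,        eps ~ N(0, Ve)
```

where `Xa` (n×q) holds the −1/+1 Cockerham codes at the QTL, `Xe` holds
element-wise products of the codes of disjoint pairs of neighboring QTL
(additive×additive epistasis; DH lines have no heterozygotes), and `a`,
`epi` are scalar effects shared by all loci.  The genetic variance is

```
VG = a²·Va + epi²·Vepi + 2·a·epi·Cov,
```

with `Va`, `Vepi`, `Cov` the empirical (co)variances of the additive and
epistatic row sums.  Effects are solved so the epistatic share of
`a²Va + epi²Vepi` equals the requested proportion, and `Ve = VG(1−h)/h`
fixes the heritability.  Genotypes follow a per-chromosome Markov chain
with Haldane recombination at equal marker spacing.

Prediction accuracy at a design point is `r(ph, p̂h)`: the Pearson
correlation between held-out phenotypes and their predictions, averaged
over independently simulated data sets × independent random 80/20
train/test splits (20 × 25 = 500 replicates by default).  RRBLUP estimates
its shrinkage `λ = σe²/σu²` by REML through the spectrum of the marker
cross-product; SVR uses an RBF kernel with cost 1, γ = 1/m, ε = 0.1.

For the ascent, factors are coded so low = −1 and high = +1; a first-order
OLS fit `ŷ = b0 + Σ bᵢxᵢ` on a half fraction (defining relation
`I = −ABCDE`) yields coded steps `stepᵢ = (bᵢ/b_basis)·step_basis` anchored
at the basis factor (largest |bᵢ|), natural increments
`Δᵢ = half_rangeᵢ·stepᵢ`, and path coordinates `base + kΔ`, rounded and
clamped to each factor's operability region.

## Worked example

Score RRBLUP and SVR at one design point (1000 lines, 400 markers, 100
QTL, 20% epistatic variance, h = 0.5) at reduced replication:

```bash
gpascent evaluate --ind 1000 --markers 400 --qtl 100 --epi 0.2 --h 0.5 \
    --datasets 5 --splits 5 --seed 1
```

prints (accuracies are means over the 25 replicates):

```
ind: 1000
m: 400
qtl: 100
epi: 0.2
h: 0.5
seed: 1
mean_r_blup: 0.6054321962918325
sd_r_blup: 0.04236208784070773
n_replicates_blup: 25
n_degenerate_blup: 0
mean_r_svm: 0.5992291008596229
sd_r_svm: 0.043442997859024404
n_replicates_svm: 25
n_degenerate_svm: 0
mean_diff: -0.006203095432209582
```

BLUP edges out SVR here (mostly additive variance), consistent with the
reference half-fraction table for this point (0.59 / 0.58 at full
replication).  The same computation from Python:

```python
from gpascent import DesignPoint, estimate_accuracy

cmp_ = estimate_accuracy(DesignPoint(1000, 400, 100, 0.2, 0.5),
                         method="both", n_datasets=5, n_splits=5, seed=1)
print(cmp_.blup.mean_r, cmp_.svm.mean_r, cmp_.mean_diff)
```

Follow a steepest-ascent path of the SVM−BLUP difference, or reproduce the
hand-computed path tables exactly:

```python
from gpascent import FirstOrderFit, build_path
from gpascent.config import default_factors

fit = FirstOrderFit(-0.130, {"ind": 0.019, "m": -0.004, "qtl": -0.003,
                             "epi": 0.043, "h": 0.020}, 0.0)
factors = {f.name: f.to_factor() for f in default_factors()}
path = build_path(fit, factors, basis_step_natural=0.25, k_max=9,
                  compat=True, coded_step_decimals=2)
print(path.path_table())
```

which ends at the coordinate `(3264 ind, 34 m, 6 qtl, epi 1, h 1)` with
epistasis and heritability clamped at their operability ceilings.  Other
commands: `gpascent surface` (full 405-point grid), `gpascent design`
(factorial/fraction tables with alias structure), `gpascent ascend`
(iterated ascent on simulated responses), `gpascent demo-yield`
(deterministic toy surface).

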