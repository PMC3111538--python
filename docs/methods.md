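# Methods

## Model family

All regressions in this package are generalized least squares on a response
vector `y` (n species) and a design matrix `X` (intercept first) with
residual covariance `σ²V`:

```
β̂        = (X'V⁻¹X)⁻¹ X'V⁻¹y
σ̂²_ML    = e'V⁻¹e / n,   e = y − Xβ̂
lnL_ML   = −(n/2)[ln 2π + ln σ̂²_ML + 1] − ½ ln|V|
```

The three model families differ only in `V`:

- **OLS**: `V = I`. This is not "phylogeny-free" — it is the covariance a
  star phylogeny implies under Brownian-motion residual evolution.
- **PGLS**: `V` is the Brownian-motion (BM) tree covariance, `V_ij` = length
  of the root-to-MRCA path shared by tips i and j. The PGLS slope is
  numerically identical to the through-origin regression slope of
  phylogenetically independent contrasts (verified against a Felsenstein
  pruning oracle to 1e−8 on random trees).
- **RegOU**: `V = V(d)`, the one-parameter Ornstein–Uhlenbeck family below.

Because all three share one likelihood-constant convention and `ln|I| = 0`,
their `lnL_ML` values are directly comparable on a common species set; this
is what makes a cross-model likelihood column meaningful.

## The OU covariance family

With tip depths `t_i` and shared depths `s_ij` (the BM matrix entries), and
the dimensionless parameter `d = e^{−2α}` of an OU process with restraining
force α around a fixed root state:

```
V_ij(d) = d^{(t_i + t_j)/2 − s_ij} · (1 − d^{s_ij}) / (1 − d)
```

with analytic limits `V(1) = BM` and `V(0) = I`. `d > 1` (admissible here,
bounds default [0, 5]) makes relatives *more* similar than BM predicts. The
implementation evaluates `(1 − d^s)/(1 − d)` via `expm1`/`log` so the family
is numerically continuous through d = 1. For non-ultrametric trees the
generalized exponent `(t_i + t_j)/2 − s_ij` is used and a warning is logged,
because the d → 0 limit is then identity-structured only up to diagonal
scale. Several OU parameterizations circulate in the comparative-methods
literature (they differ in root treatment and matrix normalization); interior
d estimates are comparable across implementations only up to that choice.

## Estimation of d (RegOU)

`d` is estimated by restricted maximum likelihood,

```
lnL_R(d) = −½[(n−p) ln σ̂²_R(d) + ln|V(d)| + ln|X'V(d)⁻¹X| + (n−p)(1 + ln 2π)]
σ̂²_R(d) = e'V(d)⁻¹e / (n−p)
```

profiled over d by a 41-point grid on the bounds plus bounded scalar
refinement (tolerance 1e−6) around the grid maximum and fixed restarts at
{0.01, 1, 3}; exact ties resolve toward smaller d (parsimony toward OLS), and
boundary solutions are flagged. The *reported* likelihood of a RegOU fit is
the ML value evaluated at d̂ (the REML/ML hybrid keeps d free of fixed-effect
bias while preserving cross-model likelihood comparability). One consequence,
deliberate: the ML likelihood at the REML d̂ can sit marginally below the
PGLS value even though the OU family nests PGLS at d = 1 — the nesting
inequality is guaranteed only on the scale being profiled, and the
likelihood-ratio machinery guards for it.

RegOU vs OLS uses a χ²₁ likelihood-ratio test (they nest at d = 0). Because
d = 0 lies on the parameter boundary, the plain χ²₁ reference is
conservative; it is retained as the field-standard convention. PGLS vs OLS
are non-nested (two different *fixed* covariances) and are compared by raw
lnL only, with no p-value attached.

## Phylogenetic signal

Blomberg's K compares observed to BM-expected similarity of relatives:

```
â   = (1'V⁻¹1)⁻¹ 1'V⁻¹y                    (phylogenetic mean)
MSE₀ = (y−â)'(y−â)/(n−1)                    (ordinary metric)
MSE  = (y−â)'V⁻¹(y−â)/(n−1)                 (GLS metric)
K    = (MSE₀/MSE) / [(tr V − n/(1'V⁻¹1))/(n−1)]
```

On a star tree the two metrics coincide and K ≡ 1 exactly for any
non-constant trait. Significance uses a one-sided randomization test: tip
values are permuted across tips (raw values, not standardized), smaller
GLS-metric MSE meaning stronger signal, with the add-one convention
`P = (1 + #{MSE_perm ≤ MSE_obs})/(n_perm + 1)` (default n_perm = 999, so the
smallest attainable P is 0.001 and P is never zero).

Residual signal — the model-choice criterion for phylogenetic vs ordinary
regression — applies the same test to **response-scale** residuals
`y − Xβ̂`. Whitened (GLS-rotated) residuals are never used for this purpose:
the rotation destroys the very signal being tested.

## Synthetic data: what it emulates, what it does not

The generator emulates the structure of cross-species genome-architecture
datasets: a few dozen taxa (default 29), log₁₀-scale traits, a linear
relationship `y = a + bx + ε` with steep negative slope (default b = −1.17,
a = 0.5), and residuals `ε ~ MVN(0, σ²V(d))` with strong phylogenetic
structure (defaults σ = 0.6, d = 1). The predictor is itself BM-distributed
by default, which matters: type-I error inflation of OLS requires signal in
both x and the residuals. Trees are Yule (pure-birth, own sampler with a
trailing exponential waiting time so every terminal branch is positive) or
fully balanced; Yule trees are rescaled to unit depth so d means the same
thing across replicates. Every stochastic step derives its seed
deterministically from the run seed plus an operation tag; the root state is
fixed at 0 (location is absorbed by the intercept).

What passing tests on these data do **not** show: robustness to measurement
error in x (not modeled — it would need quantified sampling error),
to tree misspecification beyond the alternatives explicitly put in a grid,
to non-Gaussian residuals, or to the biological realism of any particular
trait. The generator makes the *statistical* machinery falsifiable, not the
biology.

## Problem sizes and numerical choices

- Calibration and recovery checks run at the scale that makes their
  expectations sharp: 1000 replicates for K calibration and type-I error
  (binomial SE ≈ 0.7% at the 5% level), 500 for slope bias, 200 per value
  for d recovery. d-recovery uses the balanced 64-tip tree with unit branch
  lengths (depth 6): deeper ultrametric trees carry far more information
  about d than unit-depth trees, where the REML profile is flat and medians
  drift.
- All production solves go through Cholesky factorizations; explicit
  inverses appear only in test oracles.
- Covariance matrices are symmetrized at 1e−10 tolerance; a PSD repair may
  add diagonal jitter up to 1e−10 × mean(diag), logged, never silently more.
- Slope inference uses t with n − p degrees of freedom (small-n practice),
  conditioning on d̂ for RegOU (the uncertainty of d̂ is not propagated into
  the slope test; this is documented behaviour, not an oversight).
- r² is the GLS-metric proportion of variance about the phylogenetic mean;
  reports carry a footnote that it is not comparable across phylogenetic and
  nonphylogenetic models.
- Degenerate inputs fail loudly: constant traits, groups with < 2 members,
  < 3 complete cases, singular designs, non-positive branch lengths.

## Known limitations

- The OU family assumes a fixed root and the parameterization above;
  numerical d̂ values from other programs agree only up to their own
  parameterization and normalization choices.
- The ANCOVA supports exactly two groups; highly unbalanced designs are
  flagged (min group < 5) rather than "corrected" — no reweighting scheme
  rescues a 13-vs-2 split.
- Complete-case analysis throughout; no imputation. Per-trait sample sizes
  therefore differ and are always reported.
- The boundary-at-zero conservatism of the RegOU LR test is documented, not
  adjusted (no 50:50 mixture reference).
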