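# Methods

This note describes, in the package's own terms, every statistical and
numerical method it implements, the conventions chosen where the literature
admits variants, and the known limitations.

## 1. Synthetic study generator

**Design.** A study is 8 exposure concentrations (0.00, 0.16, 0.42, 1.09,
2.84, 7.40, 19.23, 50.0 µg/L) × 3 replicate fish, each contributing one
video trajectory and one biomarker replicate (paired one-to-one within
condition).

**Dose-response curves.** Every generated endpoint follows

```
value(d) = baseline · (1 + emax · d^h / (ed50^h + d^h)
                         + a_horm · (d/s_horm) · exp(1 − d/s_horm))
```

a saturating Hill term plus an optional single-peak hormetic bump that
vanishes at zero and at high dose. `value(0) == baseline` exactly.

**Trajectories.** A correlated random walk at 25 fps inside a circular
arena of radius 52 mm: per-frame speed is a stationary log-normal AR(1)
process (parameters solved so the stationary mean equals the dose-dependent
target speed and the coefficient of variation equals `speed_cv`), heading
evolves by wrapped Gaussian increments whose standard deviation is itself
dose-dependent, and wall contacts are resolved by exact segment–circle
intersection with specular reflection. Default generator conditions: target
speed baseline 12 mm/s with stimulant emax 0.8 (ed50 2.0 µg/L, Hill 1.2)
and a low-dose hormetic bump; turning s.d. baseline 4°/frame rising with
dose; speed CV 0.35, AR(1) coefficient 0.6; 41 s per fish (≈1025 frames).

**Biomarkers.** Twelve endpoints (SOD, CAT, GPx, GRed, GSH, GSTs, TBARS,
GLY, LIP, PROT, LDH, AChE) with multiplicative Gaussian noise
(`value · (1+ε)`, default CV 5%). Antioxidant enzymes rise with dose (SOD,
CAT and GSTs with small hormetic bumps), TBARS rises (lipid peroxidation),
energy reserves and AChE fall.

**Seeding.** One master seed drives everything through
`numpy.random.SeedSequence` spawn keys, so each fish and the biomarker table
get independent, reproducible substreams, and any substream is < 2³¹.

## 2. Movement descriptors

Six per-frame descriptors in fixed order: mean meander (deg/mm), mean
velocity, instantaneous velocity, distance to the arena centre, mean angular
velocity (deg/s), instantaneous (signed, tangential) acceleration.
Conventions:

- Instantaneous velocity `v_i = |Δp_i|/Δt_i`; acceleration is the signed
  forward difference of speed.
- Headings are only updated on steps longer than a 0.1 mm motion threshold
  (tracking jitter would otherwise produce unbounded angular noise); turn
  angles are wrapped to (−180°, 180°].
- Meander is absolute turn per step path length; angular velocity is
  absolute turn per time. For uniform circular motion of radius r the
  meander is exactly `(180/π)/r`, which the tests verify.
- "Mean" descriptors are centred moving averages over a 1 s window
  (NaN-ignoring, exact cumulative-sum implementation); frames whose window
  is truncated at either end are flagged invalid and excluded downstream.

All descriptors are invariant under rigid motions of the coordinate system,
and scale covariantly under unit changes (velocity ∝ s, meander ∝ 1/s).

## 3. SOM ethogram

A 3×3 Kohonen self-organizing map trained online on pooled standardized
frames (population-s.d. z-scores). Per step: best-matching unit by minimal
squared Euclidean distance (lowest index on ties), Gaussian neighbourhood on
the grid, learning rate 0.5 → 0.01 and radius 1.5 → 0.1, both decaying
linearly over 50 epochs with per-epoch reshuffling; quantization error is
recorded per epoch. The nine nodes are the behavioural classes N1–N9
(row-major grid order, or most-frequent-first relabelling).

Classes are characterized by per-descriptor one-way ANOVA across classes
(frame-level, numerator d.f. = 8 for nine classes) and all pairwise
Tukey–Kramer comparisons — studentized-range reference with unequal-n
standard errors `√(MSW/2·(1/nᵢ+1/nⱼ))` — summarised as a compact letter
display (insert–absorb algorithm; classes sharing a letter do not differ at
α = 0.05).

## 4. Contingency profile and correspondence analysis

Frame labels pooled per condition give an 8×9 contingency table
(d.f. = 56). Independence is tested by the uncorrected chi-square statistic;
cell-wise association by partial chi-square `(O−E)²/E` screened against a
Bonferroni-corrected χ²₁ critical value at `1 − α/(R·C)` — the screen is by
construction never more liberal than the unadjusted cell test.

Correspondence analysis decomposes the standardized residual matrix
`D_r^{-1/2}(P − r cᵀ)D_c^{-1/2}` by SVD; squared singular values are the
principal inertias and their sum equals χ²/n exactly (verified as a
property-based test).

## 5. Discriminant analysis and best-subset search

Equal-priors LDA: group means plus pooled within-group covariance
`S = W/(N−G)`; observations are assigned to the group of minimal squared
Mahalanobis distance. Subsets larger than the rank bound `N−G` (= 16 for 24
fish in 8 groups) are refused; numerically singular pooled covariances
(condition estimate > 1e10) are skipped and reported as such.

Leave-one-out CV removes each observation by an exact rank-one downdate of
W and the group mean (`S' = W'/(N−1−G)`), classifies the held-out point, and
reports the misclassified fraction. The downdate path is tested fold-by-fold
against a naive refit oracle.

Searches: exhaustive over all non-empty subsets (pools ≤ 20 regressors;
12-biomarker and 9-behaviour pools), and fixed-size over the 21-regressor
combined pool for k in a configurable range (default 1–5; any range up to
the rank bound is supported but combinatorially heavy). Ranking is (LOOCV error, subset size, lexicographic); zero-error
models are collected across pools, de-duplicated by regressor set.

## 6. Integrative index and model selection

For each candidate model, every replicate is scored by its squared
Mahalanobis distance to the **control-group centroid** under the model's
pooled covariance. The index is tested by one-way ANOVA
(d.f. = (7, 16) at reference scale) and by two-sided Dunnett many-to-one
comparisons.

Dunnett inference is implemented from first principles: the familywise
adjusted p-value of each contrast is `P(max_j |T_j| ≥ |t_i|)` under the
joint null, estimated by seeded Monte-Carlo over the exact generating
representation (correlated normal contrasts over a shared χ scale; default
200 000 draws), floored at the unadjusted t p-value. The tests validate the
implied critical value against an independent 2-D quadrature oracle
(Gauss–Hermite × Gauss–Legendre over the χ density): for 8 groups of 3,
d.f. 16, α = 0.05 both routes give 2.9238, and `scipy.stats.dunnett` agrees.

The dose-response verdict takes the peak condition (maximal mean index);
the pattern is *non-monotone* if a condition above the peak concentration is
significantly below it (Dunnett against the peak), else *plateau* if the top
concentration lies non-significantly below the peak, else *monotone*; the
monotonicity score is the Kendall rank correlation between concentration
order and group means. Final-model selection keeps ANOVA-significant
candidates, drops non-monotone ones, and ranks by (monotonicity score desc,
ANOVA F desc, fewer effects); the outcome is invariant to candidate input
order.

## 7. Reference-scale behaviour and limitations

- At reference conditions (master seed 1) the analysis reaches 95.8% LOOCV
  accuracy on biomarkers and the combined pool (k ≤ 5) and 66.7% on
  behaviour frequencies; no zero-error model arises at that noise level, and
  the pipeline then falls back to the best available model, which is
  ANOVA-significant (F[7,16] = 237) and perfectly monotone (Kendall 1.0).
  Zero-error models do appear under lower measurement noise (the acceptance
  suite plants CV = 1% effects and recovers thousands of them), or with
  larger combined subset sizes.
- Frame-level ANOVA treats frames as independent, ignoring within-fish
  autocorrelation — deliberate, as the standard practice this pipeline
  mirrors; its p-values are therefore anti-conservative and should be read
  as descriptive screening.
- The Dunnett Monte-Carlo p-values carry sampling noise of order
  `1/√draws`; the seed is fixed and recorded so decisions are reproducible.
- The SOM is an online (stochastic) algorithm; different seeds give
  different but similarly adequate maps. All reported runs fix the seed.
- Best-subset LOOCV selection is an optimistic model-selection procedure
  (selection and evaluation share the same 24 observations), mirroring the
  field-standard workflow it reproduces; the index-stage ANOVA/Dunnett
  inference on the chosen model inherits that optimism.
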