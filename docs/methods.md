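# Methods

This note records the statistical models implemented in `hdeeg`, the
conventions and numerical choices behind them, what the synthetic designs
emulate, and the limitations we know about.  Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Mean-vector testing (ridge-regularized Hotelling T²)

**Model.** G independent groups of p-variate observations
`x_j^{(g)} = T_g ξ_j + μ_g`, with `Σ = T_g T_g'` common to all groups and
ξ having i.i.d. standardized components whose first four moments match the
Gaussian ones (mean 0, variance 1, skewness 0, kurtosis 3).  Gaussianity
itself is not required.  Equal covariance across groups is assumed and
*documented, not enforced*: a diagnostic warning is logged when group-wise
covariance traces differ by more than a factor of 4.

**Statistic.** With pooled covariance
`S_n = (1/e1) Σ_g Σ_j (x − x̄_g)(x − x̄_g)'`, `e1 = n − G`, `e2 = G − 1`:

```
RIHT      = Σ_g n_g (x̄_g − μ̂)' (S_n + λI)⁻¹ (x̄_g − μ̂)
T         = (RIHT − e2·tr1) / sqrt(2·e2·tr2)
tr1       = tr((S_n+λI)⁻¹ Σ)        tr2 = tr(((S_n+λI)⁻¹ Σ)²)
```

When Σ is unknown, tr1 and tr2 are replaced by `p·Θ⁽¹⁾` and `p·Θ⁽²⁾`
computed from the Stieltjes transform of the S_n spectrum:

```
m  = (1/p) tr((S_n+λI)⁻¹)       m' = (1/p) tr((S_n+λI)⁻²)
D  = 1 − γ(1 − λm)
Θ⁽¹⁾ = (1 − λm)/D               Θ⁽²⁾ = (1 − λm)/D³ − λ(m − λm')/D⁴
```

All spectral quantities come from one symmetric eigendecomposition of S_n,
reused for m, m′ and the quadratic forms.

**Aspect ratio γ.** The theory's limit condition is γ = lim p/n.  We
evaluate the plug-ins at γ = p/e1 rather than p/n: S_n is a covariance
estimate with e1 = n − G degrees of freedom, so its eigenvalue law follows
the p/e1 ratio.  The two coincide asymptotically; in small samples
(total n = 40, p = 63) the e1 form is consistently better calibrated —
across all eight null designs at 3000 replicates the worst empirical size
improves from 0.065 to 0.053 (the suite recomputes this).

**Ridge parameter λ.** Validity holds for any fixed λ > 0; only power
depends on it.  Default λ = 1.0, exposed everywhere.  D ≤ 0 (λ too small
for the aspect ratio) raises a clear error.

**Change validation.** For epoched recordings the procedure is two-stage:
test all G epochs jointly; only if |T| exceeds the critical value (default
1.96) are adjacent epoch pairs tested individually, and each rejecting
boundary is reported as a change point.  No multiple-testing correction is
applied across the pairwise tests by default (an optional
Benjamini–Hochberg flag exists), matching the procedure's original form.

## Joint precision estimation (fused graphical lasso)

**Objective.** Over symmetric positive definite Θ_1…Θ_G:

```
Σ_g [tr(S_g Θ_g) − log det Θ_g]
  + λ1 Σ_g ||offdiag(Θ_g)||₁
  + λ2 Σ_{g<g'} ||offdiag(Θ_g − Θ_g')||₁
```

S_g is the group-mean-centered second-moment matrix (1/n_g scaling).
Centering matters for real recordings whose channels have nonzero means;
the simulated designs are mean-zero, so results there are unaffected.

**ADMM.** Slack variables Z_g (sparsity) and Δ_g (adjacent-pair fusion)
with scaled duals V_g, U_g.  The Θ_g subproblem has the spectral closed
form `eigenvalue d → (−d + sqrt(d² + 4ρ))/(2ρ)`, which is strictly
positive, so every iterate is positive definite by construction.
Conventions that required care:

- *Diagonals.* The ℓ1 penalties act on off-diagonals only, so the
  soft-threshold steps shrink off-diagonal entries and pass diagonals
  through unchanged, while the consensus constraints bind entrywise.
  Zeroing the slack/dual diagonals instead leaves a fixed point with a
  biased diagonal ((Θ⁻¹)_ii = S_ii + ρΘ_ii); the implemented convention
  is verified against an independent proximal-gradient solver to 1e-10
  on small instances.
- *Sweep order.* Θ updates are Gauss–Seidel over groups (each update sees
  the freshest neighbor).  A parallel (Jacobi) sweep couples the two
  groups symmetrically through the fusion terms and can lock into a
  period-two oscillation on realistic inputs; Gauss–Seidel converges on
  every design we generate.
- *Fusion pairs.* The objective fuses all G(G−1)/2 pairs; the ADMM chains
  only the G−1 adjacent pairs.  For G = 2 — every intended use — the two
  are identical.  For G ≥ 3 the solver follows the adjacent chain and this
  discrepancy is deliberate and documented rather than silently resolved.
- *Initialization.* Θ⁽⁰⁾ = (S_g + 0.1I)⁻¹, Z⁽⁰⁾ = Θ⁽⁰⁾,
  Δ⁽⁰⁾ = Θ⁽⁰⁾_g − Θ⁽⁰⁾_{g+1}, duals all-ones (a `zeros` option exists and
  reaches the same solution).  Stopping: relative ℓ1 change of the Θ block
  ≤ ε (default 1e-9), max 500 sweeps; non-convergence sets a flag and
  warns instead of raising so simulation harnesses never abort.
- *Penalty weights.* ρ1 = ρ2 = 1 by default.  ρ trades conditioning for
  speed only (the fixed point is ρ-free); very small λ with ill-scaled S
  benefits from smaller ρ (the normality study below uses 0.05).

## De-biased entrywise inference (MPDe)

`Θ̃_g = 2Θ̂_g − Θ̂_g S_g Θ̂_g` removes the first-order penalization bias;
`Θ̂ = S⁻¹` is an exact fixed point.  For coefficients a₁…a_G the entry
statistic is

```
T_ij   = Σ_g a_g Θ̃_g;ij
σ̂²_ij = Σ_g a_g² (Θ̃_g;ii Θ̃_g;jj + Θ̃²_g;ij)
Z_ij   = sqrt(n_eff) (T_ij − Θ⁰_ij) / σ̂_ij   ~  N(0,1) under H0
```

Conventions: Θ⁰ defaults to zero; n_eff = min_g n_g with a logged warning
when group sizes differ (every intended design uses equal sizes); no
finite-sample n vs n−1 correction; entries with σ̂ = 0 give NaN statistics
(skipped deterministically downstream) rather than ±∞.  Edges are retained
at p < 0.01 two-sided by default, uncorrected (a BH flag exists).

**Calibration regime (important limitation).** The de-bias correction is
first-order.  When the true precision matrix is genuinely sparse and the
penalty sits at the recovery scale λ ≍ sqrt(log p / n), the statistic is
approximately standard normal.  On *dense* truths (the s = 0.5 designs)
recovery-scale penalties leave residual shrinkage that the single
correction does not remove, and the null statistic is visibly
under-dispersed (per-location sd ≈ 0.5–0.9 in our measurements).  With
weak penalization λ = 0.2/n — negligible estimation bias, appropriate
since p < n in these designs — the statistic is calibrated (means within
±0.08, sd 1.02–1.09, KS p > 0.18 at 400 null replicates; the suite
recomputes this).  `null_distribution_study` therefore defaults to the
weak-penalization protocol (`tune="weak"`, ρ = 0.05 for conditioning) and
also exposes the AIC/DD tuners for comparison.  Practical guidance: use
recovery-scale penalties for *support estimation*, weak penalties for
*entrywise testing* when n comfortably exceeds p.

## Hyperparameter selection

**AIC grid.** λ1, λ2 range over 0.05–0.3, 30 points per axis (step
0.0034); a 10×10 coarsening is used where runtime matters.  The score is

```
AIC = Σ_g { [tr(S_g Θ̂_g) − log det Θ̂_g] + 2 k_g }
```

with k_g = p + #{nonzero upper-triangle off-diagonals of Θ̂_g at
|entry| > 1e-6}.  The deviance is scored on the per-observation scale of
the fitted objective.  This scaling is the decision that makes the
criterion meaningful here: with the n_g-weighted deviance the 2k term is
negligible (n·Δdeviance ≫ 2Δk on every design we generate) and the
densest grid point always wins; on the per-observation scale the
criterion selects genuinely sparse fits.  Ties break toward larger
(λ1, λ2), i.e. the sparser model.  Grid cells are warm-started from the
previous cell (selection only; the winning pair is refit from the
standard initialization so the result does not depend on sweep order).
ρ1, ρ2 are not searched (fixed at 1).

**Data-driven (DD) tuning — experimental.** Inside the ADMM loop, four
single-layer networks update the hyperparameters each sweep from residual
summaries of the current iterate: λ1 from Σ‖Z−Θ‖²_F, λ2 from
Σ‖Δ−(Θ_g−Θ_{g+1})‖²_F, ρ1 from (Σ‖SΘ−I‖²_F, Σ‖Θ−Z‖²_F), ρ2 from
Σ‖Θ_g−Θ_{g+1}−Δ‖²_F (features log-compressed).  Each network multiplies
the current value by `exp(w·features + b)`, clipped to [1e-4, 1e3], so
outputs are strictly positive and the zero-weight initialization is the
identity: untrained networks exactly reproduce a plain FGL fit at the
initial hyperparameters (asserted in the suite).  Initial values:
λ1 = λ2 = sqrt(log p / n) (the standard graphical-lasso rate), ρ = 1.
Training searches the ~13 network weights with a derivative-free Powell
loop minimizing support-recovery error on synthetic problems with known
truth, holding out alternate problems; the candidate is kept only if the
held-out loss does not increase, so training can never make the networks
worse than the identity.  The full training protocol for such learned
tuners is not settled methodology; this module is deliberately
conservative about it.  One DD run costs a single ADMM solve versus 900
for the full grid.

## Channel analyses

Channel selection regresses the pre/post indicator (0 before the stimulus
row, 1 after) on the standardized channel matrix with an ℓ1 penalty on
the (1/n)‖Y − Xβ‖² + λ‖β‖₁ scale (the printed squared-error form; an ℓ1
logistic variant is available behind a flag).  The solver is
coordinate descent (scikit-learn; its alpha equals λ/2 on this scale).
λ = 0 falls back to least squares; λ = "cv" (default) uses seeded 10-fold
cross-validation with the minimum-error rule.  Selected = exactly nonzero
coefficients (coordinate descent produces exact zeros).  Selections are
aggregated into per-channel frequencies across individual fits; grouping
across experiments is left to the caller.  Dominant channels of the
significant-change network are ranked by degree (incident-edge count),
top-5 by default, ties broken by label order for deterministic reports.

## Synthetic designs

- **Mean-test designs:** two groups from the independent component model
  with identity ("independent") or `0.3I + 0.7·11'` ("spike") covariance,
  via the symmetric square root (any T with TT' = Σ is valid; the
  symmetric choice is deterministic).  Component models: standard normal
  ("Model I"), or the mixture `0.7827·z1 + 0.6224·z2` with z1 uniform on
  (−√3, √3) and z2 Laplace(1/√2) ("Model II") — variance 1.0000 and
  fourth moment 2.9998 analytically, i.e. heavy-tailed but
  Gaussian-moment-matched.  (A uniform on (−3, 3) would give variance 3
  and violate the moment conditions; the √3 interval is forced by the
  printed mixing constants.)  Alternative means:
  `μ2j = (−1)^j κ s* ν_j`, ν_j ~ N(0,1) drawn fresh each replicate;
  κ = 0 is the null; s* = 3e-3 for (n1,n2) = (100,20) and 3e-2 for
  (20,20).
- **Precision designs:** Θ0 = ((Ds ∘ U) + (Ds ∘ U)')/2 + εI with Ds a
  symmetric 0/1 adjacency holding an *exact* count round(s·p(p−1)/2) of
  upper-triangle edges (realized sparsity is deterministic), U uniform on
  (0.5, 1), and ε = max(0, −λ_min) + 0.1 so the minimum eigenvalue is at
  least 0.1.  Scenario designs I–VI: p = 50 with (s, n) = (0.1, 200),
  (0.1, 500), (0.3, 200), (0.3, 500), (0.5, 200), (0.5, 500), data
  multivariate normal with covariance Θ0⁻¹, both groups sharing Θ0 (the
  null).  Support metrics R1 (recall of true edges), R0 (recall of true
  non-edges) and off-diagonal accuracy are computed from the penalized
  Θ̂ at |entry| > 1e-6 — the de-biased Θ̃ is generically dense, so
  reading support off it would make R0 trivially 0; this thresholded-Θ̂
  reading is an interpretation, noted here rather than asserted as the
  only one.

What these designs do *not* emulate about real recordings: temporal
autocorrelation within an epoch (observations are i.i.d. rows),
nonstationarity within epochs, volume conduction, artifacts, or
between-subject heterogeneity.  Passing the synthetic suite shows the
estimators and their calibration behave as the theory predicts under the
stated models; it does not certify behavior under violations of
within-epoch independence.

## Problem sizes used in the checks

The suite and the acceptance script run at the study's native sizes where
cheap (null size at p = 63 with 2000–5000 replicates; normality at
p = 50, n = 200 with 400 replicates) and at documented reductions where
a full sweep would be wasteful: the support-recovery experiment uses 50
replicates with a 10×10 grid coarsening (the full 30×30 grid is
available), and grid cells run at a loosened tolerance (ε = 1e-6, 60
sweeps) for selection, with the selected pair refit at the strict
tolerance.  These sizes are the package's own defaults for a desk-scale
reproduction; all are parameters, not constants.

## Known limitations

- The fused penalty couples the group estimates; entrywise difference
  tests on strongly fused fits are conservative/under-dispersed (see the
  calibration note above).
- The adjacent-chain fusion differs from the all-pairs objective for
  G ≥ 3.
- Model II's heavy tails inflate the mean test's size slightly at very
  small samples (empirical size ≈ 0.053–0.055 at total n = 40 against
  nominal 0.05 with the e1 aspect ratio).
- DD tuning is a reconstruction of an under-specified procedure; treat it
  as a research feature.  Its guarantee is graceful degradation to plain
  FGL, not optimality.
- The AIC's published companion values for the sparse design are mutually
  inconsistent with their own definitions (the printed accuracy is below
  the minimum implied by the printed R0 at s = 0.1), so support-recovery
  comparisons against them carry an irreducible discrepancy in R1.
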