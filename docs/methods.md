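# Methods

## Model

`netmoments` analyses contrast-based network meta-analysis data. Treatments
are labelled by case-sensitive strings and ordered lexicographically (byte
order); the first label overall is the reference A, and within each design
the lexicographically first member is the baseline. A design is identified
with its unordered treatment set; studies with equal treatment sets share a
design. Study *i* of design *d* contributes

    Y_di = δ_d + B_di + Ω_d + ε_di,

with B_di ~ N(0, τβ² P_cd), Ω_d ~ N(0, τω² P_cd), ε_di ~ N(0, S_di), all
independent, and P_c = I + J/2. The within-study covariance matrices S_di
are required inputs and are treated as fixed and known — the standard
meta-analytic convention, adequate when the individual trials are not very
small. The single matrix P_c for both random-effect levels expresses a
common heterogeneity (and inconsistency) variance for every pairwise
comparison; this is restrictive but keeps the model identifiable in the
small networks typical of practice. δ_d is the consistency-implied linear
combination of the c basic parameters, so consistency is assumed for the
*average* effects while design-level departures are absorbed by Ω_d.
Marginally, Y ~ N(Xδ, S + τβ²P₁ + τω²P₂), where P₁ is block-diagonal by
study (blocks P_cd) and P₂ block-diagonal by design (blocks J_{n_d} ⊗ P_cd).

Multi-arm studies with a repeated treatment category are rejected: the
design abstraction has no representation for two arms of the same label, and
any ad hoc workaround (e.g. picking one contrast at random) belongs in the
user's data preparation, not the model.

## Estimation

Two moment equations are solved, in this order and without iteration:

1. τ̂β² = (Σ_d Q_het,d − Σ_d (n_d−1)c_d) / Σ_d K_d, where Q_het,d is the
   weighted (W_d = S_d⁻¹) residual sum of squares about the design-specific
   GLS mean and K_d = tr(B_d (I ⊗ P_cd)) with B_d the usual GLS residual
   operator. Requires replication within at least one design (Σ K_d > 0);
   otherwise an identifiability error is raised.
2. τ̂ω² = (Q_net − (Σ n_d c_d − c) − τ̂β² tr(BP₁)) / tr(BP₂), substituting
   the *untruncated* τ̂β², including when it is negative. For a
   single-design network tr(BP₂) = 0 — no between-design information exists
   — and the fit degrades to the classical DerSimonian–Laird analysis with
   τ̂ω² = 0, a warning, and an `omega_inestimable` flag (a warning rather
   than an error, so pairwise meta-analyses work unchanged).

Both untruncated estimators are exactly unbiased under the model. For
inference each is truncated at zero (even when only one is negative), and
V = S + τ̂β²P₁ + τ̂ω²P₂ is treated as known: δ̂ = (XᵀV⁻¹X)⁻¹XᵀV⁻¹Y,
Var(δ̂) = (XᵀV⁻¹X)⁻¹. Confidence intervals use standard normal quantiles
rather than t quantiles: the simulation evidence shows the excess kurtosis
of the estimates is sometimes positive and sometimes negative, so a t
correction would not be a consistent improvement. Truncation makes small
networks conservative when consistency actually holds, and ignoring
variance-component uncertainty makes intervals anti-conservative when
inconsistency is substantial; both behaviours are quantified by the
simulation engine and its tests.

The consistency (RC) model re-estimates τ̂β² = (Q_net − df_net)/tr(BP₁)
with τ̂ω² ≡ 0, attributing the inconsistency sum of squares to
heterogeneity — more precise when consistency holds, at the cost that a
fitted RI model with τ̂ω² = 0 does not collapse exactly to it. Users who
prefer the collapse property can pass `method="het"` to keep the
within-design estimator. The common-effect (CC) model sets V = S. The RI
and CC fits share one code path, so when both truncated variances are zero
the RI output is bit-for-bit the CC output. Loop-inconsistency models are
fitted by zeroing entries of P₂ (validated to stay symmetric, {0, ½, 1},
and zero across designs) and rerunning the identical pipeline; the ratio
τ̂ω²/τ̂β² of the point estimates is exposed for comparing magnitudes.

### Numerical choices

Within-study covariance blocks are factorized by Cholesky so indefinite
input fails loudly naming the study; global solves go through factorizations
rather than explicit inverses, except the final c×c information matrix which
is inverted (c is small) and symmetrized. Matrices are dense throughout:
realistic networks have at most a few hundred contrast rows, and clarity
wins over sparsity. Q_inc is computed by subtraction and clipped at zero
only against round-off (an error is raised if it is more negative than
1e−8, since the fits are nested and genuine negativity indicates a bug).
Connectivity is checked with union–find on the design hypergraph; a
disconnected network is a hard error naming the stranded treatments, and a
rank-deficient design matrix is likewise an error rather than a pseudo-
inverse fallback.

## Further inference

* **Contrasts.** Any linear combination Lδ̂ with covariance L Var(δ̂) Lᵀ;
  `GLSResult.relative_to` re-expresses all effects against another
  reference treatment.
* **Ranking.** Effect vectors are drawn from N(δ̂, Var(δ̂)) with the
  reference fixed at exactly 0, and the full treatment-by-rank probability
  matrix is tallied (P(best) alone is a misleading summary in sparse
  networks). The benefit direction has no default — sign conventions differ
  by outcome, and a silent default could invert the ranking.
* **R / I².** R = |C_num C_den⁻¹|^{1/(2c)} compares confidence-region
  volumes of two nested fits (the confidence level cancels), and
  I² = (R² − 1)/R² × 100%, reported to 0 decimals. Sub-network versions use
  submatrices with the reduced dimension. The familiar (Q − df)/Q form of
  I² is deliberately not provided: its estimand under this Q decomposition
  is unclear.
* **Uncertainty in τ̂β², τ̂ω².** Not provided, matching the scope of the
  moment method; bootstrap or likelihood-based intervals are future work.

## Synthetic-data generator

The generator emulates networks of 2- and 3-arm trials over four treatments
A–D. Per study a single within-study variance σ² is drawn as 0.25·χ²₁
rejection-sampled into [0.009, 0.6] (bounds inclusive; the distinction has
measure zero) — a standard generator for log-odds-ratio variances — and
S_di = σ²P_cd, i.e. equal variances with correlation ½, reflecting equal
allocation to arms. Responses are drawn from the stacked marginal model with
the chosen (τβ², τω²) and δ = 0 by default; variance estimation is
location-invariant and point estimates merely translate under δ ≠ 0. Three
stock layouts are provided: run1 (2 studies of each of ABC, ABD, AB, AC,
AD), run2 (10 of each of the same five designs) and run3 (5 studies of each
of all ten 2-/3-arm designs), chosen to separate the effects of within-design
replication (τβ²) and design replication (τω²) on accuracy. The grid values
{0, 0.024, 0.168} for both variances correspond to I² of 0%, 30% and 75%
against the generator's typical within-study variance — the harmonic-type
value 1/E[1/σ²] ≈ 0.056 (the realized I² on a network with heterogeneous
drawn variances is larger, by Jensen's inequality, and the test suite checks
both facts separately).

What the generator does *not* emulate: non-normal within-study likelihoods
(real log odds ratios from small trials are skewed and their variances are
estimated, not known), unequal arm allocation, comparison-specific
heterogeneity, missing-at-random design choice, or networks larger than four
treatments. Passing simulation tests therefore demonstrates the estimator's
repeated-sampling behaviour under its own assumptions, not robustness to
their failure.

The engine runs each grid cell on an independent child stream spawned from
the master seed, so any cell is reproducible in isolation; replicates with
inestimable components are counted and reported, never silently dropped.
Default replication is 3000 datasets per cell, which makes estimated
coverage probabilities accurate to about ±0.01; the bundled acceptance
script uses that replication and completes all six reported quantities in
under a minute on one CPU. Monte-Carlo tests in the suite use 3 (or for a
few generator checks 4–5) standard errors as their tolerance.

## Known limitations

* Normal approximations throughout; no arm-level (binomial-likelihood)
  analysis. The binary-arm helper applies a 0.5 continuity correction to
  every cell of a study containing a zero cell.
* Two variance parameters only; comparison- or design-specific
  heterogeneity structures are out of scope.
* No DIC/AIC-type model selection and no inconsistency *location* tools
  (node splitting, fixed-effect inconsistency terms); the I² comparisons
  quantify overall impact only.
* Standard errors understate uncertainty in small, highly inconsistent
  networks because estimated variance components are treated as known.
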